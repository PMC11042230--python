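"""Binary genotype container with sparse difflist and dense 2-bit encodings.

A cohort of diploid biallelic genotypes is stored one variant at a time in
the ``.sgen`` container. Rare variants are stored as *difflists*: an ordered
list of (sample index, genotype value) pairs covering only the samples that
deviate from the all-reference default ("all genotype values are 0 except
sample x, which has genotype value y"). A difflist entry costs 5 bytes
(4-byte little-endian sample index + 1-byte genotype code) and every variant
contributes 4 bytes to the record directory (1 record-type byte + 3-byte
little-endian record length), so a singleton among 400,000 samples costs
5 + 4 bytes against the 100,000-byte dense 2-bit record a PLINK-1 BED file
would use. Downstream regression code consumes difflists directly, without
densification (see :mod:`sparsegwas.glm_core`).

Genotype codes are additive alternate-allele counts 0/1/2, with 3 as the
MISSING sentinel in both encodings. Variant and sample metadata live in
sidecar text files (``.svar``/``.ssam``, BIM/FAM dialects).

File layout of ``PREFIX.sgen``::

    magic "SG" | n_variants u64le | n_samples u64le
    directory: per variant, 1 type byte (0=DENSE, 1=SPARSE) + u24le length
    bodies:    concatenated records in directory order
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterator, Union

import numpy as np
import pandas as pd

# Genotype codes (additive alt-allele counts); MISSING is never conflated with 0.
MISSING = 3

# Record types. Codes 2+ are reserved (LD-compressed / dosage records are not
# implemented in this dialect).
DENSE = 0
SPARSE = 1

MAGIC = b"SG"
GLOBAL_HEADER_BYTES = 2 + 8 + 8
DIRECTORY_BYTES_PER_VARIANT = 4  # 1 record-type byte + 3-byte LE record length
_MAX_RECORD_LEN = (1 << 24) - 1
_MAX_SPARSE_INDEX = (1 << 32) - 1

_VARIANT_COLS = ["chrom", "id", "cm", "pos", "a1", "a2"]
_SAMPLE_COLS = ["fid", "iid", "pat", "mat", "sex", "pheno"]

# PLINK-1 BED 2-bit code -> internal additive code. BED (SNP-major):
# 00 hom A1 (2 copies of allele 1), 01 missing, 10 het, 11 hom A2.
_BED_TO_CODE = np.array([2, 3, 1, 0], dtype=np.uint8)
_CODE_TO_BED = np.array([3, 2, 0, 1], dtype=np.uint8)


class SgenError(Exception):
    """Base class for genotype-container errors."""


class FormatError(SgenError):
    """Input is not in the expected file format (bad magic, bad layout)."""


class CorruptRecordError(SgenError):
    """A variant record body violates its encoding invariants."""


class CorruptFileError(SgenError):
    """Directory and body region of a fileset disagree."""


class ConsistencyError(SgenError):
    """Cross-file metadata (FAM vs BED vs BIM) does not line up."""


class UnrepresentableIndexError(SgenError):
    """Sample index does not fit in the 4-byte difflist index field."""


@dataclass
class SparseVariantRecord:
    """A rare variant as an ordered difflist of nonzero (index, value) pairs.

    ``values`` holds additive codes in {1, 2} or the MISSING sentinel 3;
    samples absent from the list are homozygous reference (0). ``indices``
    must be strictly increasing (canonical order).
    """

    n_samples: int
    indices: np.ndarray
    values: np.ndarray

    # Instrumentation: class-level tally of genotype-entry touches, used to
    # verify the O(k) work-avoidance contract of the sparse regression paths.
    touch_count: int = 0

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.uint8)
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if self.indices.shape != self.values.shape or self.indices.ndim != 1:
            raise ValueError("indices and values must be equal-length 1-D arrays")
        if self.indices.size:
            if self.indices[0] < 0 or self.indices[-1] >= self.n_samples:
                raise ValueError("sample index out of range")
            if np.any(np.diff(self.indices) <= 0):
                raise ValueError("sample indices must be strictly increasing")
        if np.any(self.values == 0) or np.any(self.values > 3):
            raise ValueError("sparse entry values must be in {1, 2, 3}")

    @property
    def k(self) -> int:
        return int(self.indices.size)

    def entry_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Hand out the difflist arrays, tallying k entry touches."""
        SparseVariantRecord.touch_count += self.k
        return self.indices, self.values

    def to_dense(self) -> np.ndarray:
        """Densify to an n_samples code array, tallying n touches."""
        SparseVariantRecord.touch_count += self.n_samples
        codes = np.zeros(self.n_samples, dtype=np.uint8)
        codes[self.indices] = self.values
        return codes

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SparseVariantRecord):
            return NotImplemented
        return (
            self.n_samples == other.n_samples
            and np.array_equal(self.indices, other.indices)
            and np.array_equal(self.values, other.values)
        )


@dataclass
class DenseVariantRecord:
    """A variant as a full array of per-sample genotype codes (2-bit packed on disk)."""

    n_samples: int
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.uint8)
        if self.codes.shape != (self.n_samples,):
            raise ValueError("codes must have length n_samples")
        if np.any(self.codes > 3):
            raise ValueError("genotype codes must be in {0, 1, 2, 3}")

    def to_dense(self) -> np.ndarray:
        return self.codes

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DenseVariantRecord):
            return NotImplemented
        return self.n_samples == other.n_samples and np.array_equal(
            self.codes, other.codes
        )


VariantRecord = Union[SparseVariantRecord, DenseVariantRecord]


# ---------------------------------------------------------------------------
# Record codecs
# ---------------------------------------------------------------------------

def encode_sparse(record: SparseVariantRecord) -> bytes:
    """Encode a difflist record: 5 bytes per entry (u32le index + u8 code)."""
    k = record.k
    if k == 0:
        return b""
    if int(record.indices[-1]) > _MAX_SPARSE_INDEX:
        raise UnrepresentableIndexError(
            f"sample index {int(record.indices[-1])} exceeds 4-byte range"
        )
    buf = np.empty((k, 5), dtype=np.uint8)
    buf[:, :4] = record.indices.astype("<u4").view(np.uint8).reshape(k, 4)
    buf[:, 4] = record.values
    return buf.tobytes()


def decode_sparse(data: bytes, n_samples: int) -> SparseVariantRecord:
    """Inverse of :func:`encode_sparse`; validates all difflist invariants."""
    if len(data) % 5 != 0:
        raise CorruptRecordError(
            f"sparse record length {len(data)} is not a multiple of 5"
        )
    arr = np.frombuffer(data, dtype=np.uint8).reshape(-1, 5)
    indices = arr[:, :4].copy().view("<u4").ravel().astype(np.int64)
    values = arr[:, 4].copy()
    try:
        return SparseVariantRecord(n_samples, indices, values)
    except ValueError as exc:
        raise CorruptRecordError(str(exc)) from exc


def encode_dense(record: DenseVariantRecord) -> bytes:
    """Pack genotype codes 2 bits per sample, sample 0 in the low bit pair."""
    codes = record.codes
    pad = (-codes.size) % 4
    if pad:
        codes = np.concatenate([codes, np.zeros(pad, dtype=np.uint8)])
    quads = codes.reshape(-1, 4)
    packed = quads[:, 0] | (quads[:, 1] << 2) | (quads[:, 2] << 4) | (quads[:, 3] << 6)
    return packed.astype(np.uint8).tobytes()


def decode_dense(data: bytes, n_samples: int) -> DenseVariantRecord:
    if len(data) != (n_samples + 3) // 4:
        raise CorruptRecordError(
            f"dense record length {len(data)} != ceil({n_samples}/4)"
        )
    packed = np.frombuffer(data, dtype=np.uint8)
    codes = np.empty(packed.size * 4, dtype=np.uint8)
    codes[0::4] = packed & 3
    codes[1::4] = (packed >> 2) & 3
    codes[2::4] = (packed >> 4) & 3
    codes[3::4] = (packed >> 6) & 3
    return DenseVariantRecord(n_samples, codes[:n_samples])


def choose_encoding(n_samples: int, k: int) -> int:
    """SPARSE iff the 5k-byte difflist body is strictly smaller than dense."""
    return SPARSE if 5 * k < (n_samples + 3) // 4 else DENSE


# ---------------------------------------------------------------------------
# Fileset container
# ---------------------------------------------------------------------------

def _default_variant_table(m: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": ["1"] * m,
            "id": [f"V{i + 1}" for i in range(m)],
            "cm": [0.0] * m,
            "pos": np.arange(1, m + 1, dtype=np.int64),
            "a1": ["A"] * m,
            "a2": ["C"] * m,
        }
    )


def _default_sample_table(n: int) -> pd.DataFrame:
    ids = [f"S{i + 1}" for i in range(n)]
    return pd.DataFrame(
        {
            "fid": ids,
            "iid": ids,
            "pat": ["0"] * n,
            "mat": ["0"] * n,
            "sex": [0] * n,
            "pheno": [-9] * n,
        }
    )


@dataclass
class GenoFileset:
    """An ``.sgen`` fileset: record directory + bodies + sidecar metadata.

    Construct with :meth:`from_matrix` or :meth:`read`; persist with
    :meth:`write`. Iteration decodes records lazily, one variant at a time.
    """

    n_samples: int
    record_types: np.ndarray
    record_bodies: list
    variants: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.record_types = np.asarray(self.record_types, dtype=np.uint8)
        if len(self.record_bodies) != self.record_types.size:
            raise ConsistencyError("directory entry count != number of record bodies")
        if len(self.variants) != self.record_types.size:
            raise ConsistencyError("variant table length != number of records")
        if len(self.samples) != self.n_samples:
            raise ConsistencyError("sample table length != n_samples")

    @property
    def n_variants(self) -> int:
        return int(self.record_types.size)

    @property
    def body_size(self) -> int:
        return sum(len(b) for b in self.record_bodies)

    # -- construction -------------------------------------------------------

    @classmethod
    def from_matrix(
        cls,
        codes: np.ndarray,
        variants: pd.DataFrame | None = None,
        samples: pd.DataFrame | None = None,
        force_dense: bool = False,
    ) -> "GenoFileset":
        """Encode an m × n genotype-code matrix, choosing per-variant encoding."""
        codes = np.asarray(codes, dtype=np.uint8)
        if codes.ndim != 2:
            raise ValueError("codes must be an (n_variants, n_samples) matrix")
        if np.any(codes > 3):
            raise ValueError("genotype codes must be in {0, 1, 2, 3}")
        m, n = codes.shape
        types = np.empty(m, dtype=np.uint8)
        bodies: list[bytes] = []
        for i in range(m):
            row = codes[i]
            nz = np.flatnonzero(row)
            if not force_dense and choose_encoding(n, nz.size) == SPARSE:
                types[i] = SPARSE
                bodies.append(
                    encode_sparse(SparseVariantRecord(n, nz, row[nz]))
                )
            else:
                types[i] = DENSE
                bodies.append(encode_dense(DenseVariantRecord(n, row)))
        return cls(
            n_samples=n,
            record_types=types,
            record_bodies=bodies,
            variants=variants.reset_index(drop=True) if variants is not None else _default_variant_table(m),
            samples=samples.reset_index(drop=True) if samples is not None else _default_sample_table(n),
        )

    # -- access --------------------------------------------------------------

    def record(self, i: int, force_dense: bool = False) -> VariantRecord:
        rtype = int(self.record_types[i])
        body = self.record_bodies[i]
        if rtype == SPARSE:
            rec = decode_sparse(body, self.n_samples)
            if force_dense:
                return DenseVariantRecord(self.n_samples, rec.to_dense())
            return rec
        if rtype == DENSE:
            return decode_dense(body, self.n_samples)
        raise CorruptFileError(f"unknown record type {rtype} for variant {i}")

    def iter_variants(
        self, mode: str = "AS_STORED"
    ) -> Iterator[tuple[int, VariantRecord]]:
        """Stream (index, record) pairs in directory order.

        ``AS_STORED`` yields :class:`SparseVariantRecord` for sparse-stored
        variants without densification; ``FORCE_DENSE`` always densifies.
        """
        if mode not in ("AS_STORED", "FORCE_DENSE"):
            raise ValueError(f"unknown iteration mode {mode!r}")
        for i in range(self.n_variants):
            yield i, self.record(i, force_dense=(mode == "FORCE_DENSE"))

    def to_matrix(self) -> np.ndarray:
        out = np.empty((self.n_variants, self.n_samples), dtype=np.uint8)
        for i, rec in self.iter_variants(mode="FORCE_DENSE"):
            out[i] = rec.codes
        return out

    # -- persistence ---------------------------------------------------------

    def write(self, prefix: str) -> None:
        m = self.n_variants
        lengths = np.array([len(b) for b in self.record_bodies], dtype=np.int64)
        if m and lengths.max(initial=0) > _MAX_RECORD_LEN:
            raise FormatError("record exceeds 3-byte length field (16 MiB)")
        directory = np.zeros((m, 4), dtype=np.uint8)
        directory[:, 0] = self.record_types
        if m:
            directory[:, 1:4] = (
                lengths.astype("<u4").view(np.uint8).reshape(m, 4)[:, :3]
            )
        tmp = prefix + ".sgen.tmp"
        with open(tmp, "wb") as fh:
            fh.write(MAGIC)
            fh.write(int(m).to_bytes(8, "little"))
            fh.write(int(self.n_samples).to_bytes(8, "little"))
            fh.write(directory.tobytes())
            for body in self.record_bodies:
                fh.write(body)
        os.replace(tmp, prefix + ".sgen")
        self.variants[_VARIANT_COLS].to_csv(
            prefix + ".svar", sep="\t", header=False, index=False
        )
        self.samples[_SAMPLE_COLS].to_csv(
            prefix + ".ssam", sep="\t", header=False, index=False
        )

    @classmethod
    def read(cls, prefix: str) -> "GenoFileset":
        with open(prefix + ".sgen", "rb") as fh:
            raw = fh.read()
        if raw[:2] != MAGIC:
            raise FormatError("bad .sgen magic bytes")
        if len(raw) < GLOBAL_HEADER_BYTES:
            raise CorruptFileError("truncated .sgen header")
        m = int.from_bytes(raw[2:10], "little")
        n = int.from_bytes(raw[10:18], "little")
        dir_end = GLOBAL_HEADER_BYTES + 4 * m
        if len(raw) < dir_end:
            raise CorruptFileError("truncated .sgen directory")
        directory = np.frombuffer(
            raw[GLOBAL_HEADER_BYTES:dir_end], dtype=np.uint8
        ).reshape(m, 4)
        types = directory[:, 0].copy()
        lengths = np.zeros(m, dtype=np.int64)
        for shift, col in enumerate(range(1, 4)):
            lengths |= directory[:, col].astype(np.int64) << (8 * shift)
        if dir_end + int(lengths.sum()) != len(raw):
            raise CorruptFileError(
                "sum of directory record lengths != body-region length"
            )
        bodies = []
        offset = dir_end
        for length in lengths:
            bodies.append(raw[offset : offset + int(length)])
            offset += int(length)
        variants = pd.read_csv(
            prefix + ".svar", sep="\t", header=None, names=_VARIANT_COLS,
            dtype={"chrom": str, "id": str, "a1": str, "a2": str},
        )
        samples = pd.read_csv(
            prefix + ".ssam", sep="\t", header=None, names=_SAMPLE_COLS,
            dtype={"fid": str, "iid": str, "pat": str, "mat": str},
        )
        if len(samples) != n:
            raise ConsistencyError(".ssam row count != header n_samples")
        if len(variants) != m:
            raise ConsistencyError(".svar row count != header n_variants")
        return cls(
            n_samples=n,
            record_types=types,
            record_bodies=bodies,
            variants=variants,
            samples=samples,
        )


def subset_record(rec: VariantRecord, keep: np.ndarray) -> VariantRecord:
    """Restrict a record to the samples flagged in boolean mask ``keep``.

    Difflists are subset in O(k): entries for dropped samples are removed and
    surviving indices are remapped to the compacted sample order.
    """
    keep = np.asarray(keep, dtype=bool)
    if keep.size != rec.n_samples:
        raise ConsistencyError("keep mask length != n_samples")
    n_new = int(keep.sum())
    if isinstance(rec, SparseVariantRecord):
        new_index_of = np.cumsum(keep) - 1
        m = keep[rec.indices]
        return SparseVariantRecord(
            n_new, new_index_of[rec.indices[m]], rec.values[m]
        )
    return DenseVariantRecord(n_new, rec.codes[keep])


# ---------------------------------------------------------------------------
# PLINK-1 BED import / export
# ---------------------------------------------------------------------------

BED_MAGIC = b"\x6c\x1b\x01"  # SNP-major


def import_bed(
    bed_path: str, bim_path: str, fam_path: str, force_dense: bool = False
) -> GenoFileset:
    """Re-encode a PLINK-1 BED/BIM/FAM fileset into a GenoFileset.

    Genotype values (including MISSING) are preserved exactly; each variant
    is stored sparse or dense per :func:`choose_encoding`. Allele-1 copies
    are counted, matching PLINK's additive coding of the A1 allele.
    """
    fam = pd.read_csv(
        fam_path, sep=r"\s+", header=None, names=_SAMPLE_COLS,
        dtype={"fid": str, "iid": str, "pat": str, "mat": str},
    )
    bim = pd.read_csv(
        bim_path, sep=r"\s+", header=None, names=_VARIANT_COLS,
        dtype={"chrom": str, "id": str, "a1": str, "a2": str},
    )
    with open(bed_path, "rb") as fh:
        raw = fh.read()
    if raw[:3] != BED_MAGIC:
        raise FormatError("bad BED magic bytes (want SNP-major PLINK 1)")
    n, m = len(fam), len(bim)
    row_bytes = (n + 3) // 4
    if len(raw) != 3 + row_bytes * m:
        raise (
            ConsistencyError if len(raw) > 3 + row_bytes * m else CorruptFileError
        )(
            f"BED body is {len(raw) - 3} bytes; expected {row_bytes} x {m} "
            f"for {n} FAM samples"
        )
    packed = np.frombuffer(raw[3:], dtype=np.uint8).reshape(m, row_bytes)
    bed_codes = np.empty((m, row_bytes * 4), dtype=np.uint8)
    bed_codes[:, 0::4] = packed & 3
    bed_codes[:, 1::4] = (packed >> 2) & 3
    bed_codes[:, 2::4] = (packed >> 4) & 3
    bed_codes[:, 3::4] = (packed >> 6) & 3
    codes = _BED_TO_CODE[bed_codes[:, :n]]
    return GenoFileset.from_matrix(
        codes, variants=bim, samples=fam, force_dense=force_dense
    )


def write_bed(prefix: str, fileset: GenoFileset) -> None:
    """Export a GenoFileset as a PLINK-1 BED/BIM/FAM fileset."""
    codes = fileset.to_matrix()
    bed_codes = _CODE_TO_BED[codes]
    m, n = bed_codes.shape
    pad = (-n) % 4
    if pad:
        bed_codes = np.concatenate(
            [bed_codes, np.zeros((m, pad), dtype=np.uint8)], axis=1
        )
    quads = bed_codes.reshape(m, -1, 4)
    packed = (
        quads[:, :, 0]
        | (quads[:, :, 1] << 2)
        | (quads[:, :, 2] << 4)
        | (quads[:, :, 3] << 6)
    ).astype(np.uint8)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(BED_MAGIC)
        fh.write(packed.tobytes())
    fileset.variants[_VARIANT_COLS].to_csv(
        prefix + ".bim", sep="\t", header=False, index=False
    )
    fileset.samples[_SAMPLE_COLS].to_csv(
        prefix + ".fam", sep="\t", header=False, index=False
    )
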