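"""Simultaneous multi-phenotype scans and SVD phenotype reduction.

When several phenotypes share the exact same analysis samples, the
variant-dependent half of the block-inverse fast path (B = Xc'xg, D, F) is
computed once per variant and reused across every phenotype column, so a
k-phenotype scan costs far less than k independent scans while producing
identical results.

``pheno_svd`` implements rank reduction for large correlated phenotype
panels: complete rows of the n x k phenotype matrix Y are standardized
(centered, unit variance) and decomposed with a thin SVD; the smallest
number of components d whose cumulative squared singular values reach the
requested variance-explained fraction is retained, and association scans
run on the d component-score columns instead of the k raw phenotypes.
Because p-values of a per-variant linear fit are invariant under affine
transforms of the phenotype, a rank-1 panel (e.g. one phenotype duplicated
50 times) reduces to d = 1 with component p-values equal to the underlying
single-phenotype scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genostore import ConsistencyError, GenoFileset
from .glm_core import DesignContext, RegressionResult, build_cache, scan_multi


class DegeneratePhenotypeError(Exception):
    """A phenotype column has zero variance over the complete rows."""


@dataclass
class PhenotypeMatrix:
    """n x k matrix of aligned phenotypes; NaN marks a missing value."""

    values: np.ndarray
    names: list

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if len(self.names) != self.values.shape[1]:
            raise ValueError("names length != number of phenotype columns")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclass
class ReducedPhenotypes:
    """Output of :func:`pheno_svd`: component scores plus back-projection data."""

    scores: np.ndarray  # (n_complete, d)
    loadings: np.ndarray  # (k, d)
    singular_values: np.ndarray  # all k singular values
    variance_explained_cum: np.ndarray  # (d,)
    center: np.ndarray
    scale: np.ndarray
    complete_rows: np.ndarray  # boolean mask into the original n rows
    names: list = field(default_factory=list)

    @property
    def d(self) -> int:
        return self.scores.shape[1]


def multi_scan(
    ctx_full: DesignContext,
    pm: PhenotypeMatrix,
    fileset: GenoFileset,
) -> dict:
    """Scan every phenotype column; results match independent single scans.

    Phenotypes are grouped by their missingness mask; each group shares one
    covariate cache (and one pass over the variants). Groups with missing
    rows use a row-subset design and O(k)-subset difflists.
    """
    if pm.n != fileset.n_samples or ctx_full.n != fileset.n_samples:
        raise ConsistencyError("phenotype/design rows != fileset sample count")
    masks = ~np.isnan(pm.values)
    if not masks.any():
        raise ConsistencyError("no overlap between phenotype and genotype samples")
    groups: dict[bytes, list[int]] = {}
    for j in range(pm.k):
        groups.setdefault(masks[:, j].tobytes(), []).append(j)
    out: dict[str, list[tuple[int, RegressionResult]]] = {}
    for cols in groups.values():
        mask = masks[:, cols[0]]
        complete = bool(mask.all())
        ctx = ctx_full if complete else DesignContext(ctx_full.Xc[mask])
        cache = build_cache(
            ctx,
            pm.values[mask][:, cols],
            names=[pm.names[j] for j in cols],
        )
        streams: dict[int, list] = {j: [] for j in cols}
        for i, results in scan_multi(
            ctx, cache, fileset, keep=None if complete else mask
        ):
            for pos, j in enumerate(cols):
                streams[j].append((i, results[pos]))
        for j in cols:
            out[pm.names[j]] = streams[j]
    return out


def pheno_svd(
    pm: PhenotypeMatrix | np.ndarray,
    variance_explained: float,
    names=None,
) -> ReducedPhenotypes:
    """Standardize complete rows of Y and keep the leading SVD components.

    d is the smallest integer with (sum_{i<=d} s_i^2) / (sum_i s_i^2) >=
    ``variance_explained``. Component signs follow the convention that each
    component's largest-magnitude loading is positive, making output
    deterministic across runs and LAPACK drivers.
    """
    if isinstance(pm, PhenotypeMatrix):
        Y, names = pm.values, pm.names
    else:
        Y = np.asarray(pm, dtype=float)
        names = list(names) if names is not None else [
            f"P{j + 1}" for j in range(Y.shape[1])
        ]
    if not 0.0 < variance_explained <= 1.0:
        raise ValueError("variance_explained must be in (0, 1]")
    if Y.ndim != 2 or Y.shape[1] < 2:
        raise ValueError("pheno_svd needs at least 2 phenotype columns")
    complete = ~np.isnan(Y).any(axis=1)
    Yc = Y[complete]
    if Yc.shape[0] < 3:
        raise ValueError("fewer than 3 complete phenotype rows")
    center = Yc.mean(axis=0)
    scale = Yc.std(axis=0, ddof=1)
    dead = np.flatnonzero(scale == 0)
    if dead.size:
        raise DegeneratePhenotypeError(
            f"zero-variance phenotype column(s): {[names[j] for j in dead]}"
        )
    Z = (Yc - center) / scale
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    ve = s**2 / np.sum(s**2)
    cum = np.cumsum(ve)
    d = int(np.searchsorted(cum, variance_explained - 1e-12) + 1)
    d = min(d, s.size)
    # Deterministic sign: largest-|loading| entry of each component positive.
    for j in range(d):
        i_max = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i_max] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    return ReducedPhenotypes(
        scores=U[:, :d] * s[:d],
        loadings=Vt[:d].T.copy(),
        singular_values=s,
        variance_explained_cum=cum[:d],
        center=center,
        scale=scale,
        complete_rows=complete,
        names=[f"C{j + 1}" for j in range(d)],
    )


def scan_reduced(
    ctx_full: DesignContext,
    rp: ReducedPhenotypes,
    fileset: GenoFileset,
) -> dict:
    """Run the standard multi-phenotype scan on the d component-score columns."""
    mask = rp.complete_rows
    pm = PhenotypeMatrix(
        values=_embed(rp.scores, mask), names=list(rp.names)
    )
    return multi_scan(ctx_full, pm, fileset)


def _embed(scores: np.ndarray, mask: np.ndarray) -> np.ndarray:
    out = np.full((mask.size, scores.shape[1]), np.nan)
    out[mask] = scores
    return out
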