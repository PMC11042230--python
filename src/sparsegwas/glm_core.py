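"""Per-variant least-squares association engine.

For each variant the model is y = X beta + e with X = [Xc xg]: Xc holds the
intercept and covariates (shared across all variants), xg is the genotype
column. The dense path solves the normal equations per variant and serves as
the oracle. The fast path exploits the block structure of

    X'X = [[Xc'Xc, Xc'xg], [xg'Xc, xg'xg]] = [[A, B], [C, D]]

whose inverse, when A and the Schur complement F := D - C A^-1 B are
invertible, is

    [[A^-1 + A^-1 B F^-1 C A^-1, -A^-1 B F^-1],
     [-F^-1 C A^-1,              F^-1        ]].

A, A^-1, Xc'y and y'y are computed once before any variant is processed; a
sparse variant with k nonzero genotype entries then costs O(p(k+p))
arithmetic: B = Xc'xg and xg'y touch only the k listed entries, D = xg'xg
costs O(k), and the remaining block algebra is O(p^2). RSS = y'y - y'X beta,
and the genotype standard error, t statistic and p-value are simple
functions of beta and RSS. The sparse path never materializes a dense
genotype column.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

from .genostore import (
    MISSING,
    ConsistencyError,
    DenseVariantRecord,
    GenoFileset,
    SparseVariantRecord,
)

# Result status codes.
OK = "OK"
SINGULAR = "SINGULAR"
SKIPPED_MISSING = "SKIPPED_MISSING"
NONCONVERGED = "NONCONVERGED"

# Schur-complement singularity tolerance: F <= F_TOL * max(D, 1) -> SINGULAR.
F_TOL = 1e-12


class DesignSingularError(Exception):
    """The covariate design matrix is rank deficient."""


class SingularBlockError(Exception):
    """Schur complement F below tolerance in the block inverse."""


class MissingGenotypePrecondition(Exception):
    """A sparse record with MISSING entries reached the no-missing fast path."""


@dataclass
class RegressionResult:
    """Genotype-term estimate for one variant (one phenotype)."""

    beta_g: float
    se_g: float
    t_stat: float
    p_value: float
    rss: float
    n_used: int
    status: str = OK
    engine: str | None = None

    @classmethod
    def singular(cls, n_used: int, engine: str | None = None) -> "RegressionResult":
        nan = float("nan")
        return cls(nan, nan, nan, nan, nan, n_used, status=SINGULAR, engine=engine)


@dataclass
class DesignContext:
    """Non-genotype design matrix Xc (intercept first), validated at build."""

    Xc: np.ndarray

    def __post_init__(self) -> None:
        self.Xc = np.ascontiguousarray(np.asarray(self.Xc, dtype=float))
        if self.Xc.ndim != 2 or self.Xc.shape[0] <= self.Xc.shape[1]:
            raise DesignSingularError(
                "Xc must be n x (p-1) with more rows than columns"
            )
        if not np.all(self.Xc[:, 0] == 1.0):
            raise DesignSingularError("first column of Xc must be the intercept")
        if not np.all(np.isfinite(self.Xc)):
            raise DesignSingularError("Xc contains non-finite values")
        # Pivoted QR exposes (near-)dependent columns by name.
        _, r, piv = linalg.qr(self.Xc, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(self.Xc.shape) * np.finfo(float).eps
        rank = int(np.sum(diag > tol))
        if rank < self.Xc.shape[1]:
            bad = sorted(int(j) for j in piv[rank:])
            raise DesignSingularError(
                f"covariate design is rank deficient; offending columns {bad}"
            )

    @property
    def n(self) -> int:
        return self.Xc.shape[0]

    @property
    def p(self) -> int:
        """Total predictor count including the genotype column."""
        return self.Xc.shape[1] + 1


@dataclass
class CovariateCache:
    """Precomputed A = Xc'Xc, A^-1, Xc'Y and per-phenotype y'y.

    Holds the variant-independent half of the block inverse; must be rebuilt
    whenever Xc or the sample set changes.
    """

    A: np.ndarray
    A_inv: np.ndarray
    Xc_t_Y: np.ndarray  # (p-1, n_pheno)
    y_t_y: np.ndarray  # (n_pheno,)
    Y: np.ndarray  # (n, n_pheno)
    names: list = field(default_factory=list)

    @property
    def n_pheno(self) -> int:
        return self.Y.shape[1]


def build_cache(ctx: DesignContext, Y: np.ndarray, names=None) -> CovariateCache:
    """Compute the reusable covariate products once, before any variant."""
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.shape[0] != ctx.n:
        raise ConsistencyError("phenotype rows not aligned to design rows")
    if not np.all(np.isfinite(Y)):
        raise ValueError("phenotypes must be complete (caller filters missing rows)")
    A = ctx.Xc.T @ ctx.Xc
    A_inv = linalg.inv(A)
    if not np.allclose(A @ A_inv, np.eye(A.shape[0]), atol=1e-6):
        raise DesignSingularError("A * A_inv deviates from identity")
    return CovariateCache(
        A=A,
        A_inv=A_inv,
        Xc_t_Y=ctx.Xc.T @ Y,
        y_t_y=np.einsum("ij,ij->j", Y, Y),
        Y=Y,
        names=list(names) if names is not None else [f"P{j + 1}" for j in range(Y.shape[1])],
    )


def block_inverse(A_inv: np.ndarray, B: np.ndarray, D: float):
    """Four blocks of (X'X)^-1 from A^-1 and the border B, D (scalar).

    Returns ``(top_left, top_right, bottom_left, bottom_right, F)``; raises
    :class:`SingularBlockError` when the Schur complement F is below
    tolerance (collinear or monomorphic genotype).
    """
    B = np.asarray(B, dtype=float).ravel()
    u = A_inv @ B
    F = float(D - B @ u)
    if F <= F_TOL * max(float(D), 1.0):
        raise SingularBlockError(f"Schur complement F={F:.3e} below tolerance")
    top_left = A_inv + np.outer(u, u) / F
    top_right = -u / F
    return top_left, top_right, top_right.copy(), 1.0 / F, F


def _t_result(beta_g, se2, rss, df, n_used) -> RegressionResult:
    if se2 < 0 or not np.isfinite(se2):
        return RegressionResult.singular(n_used)
    if se2 == 0.0:
        # Exact fit (rss == 0): the estimate is reported with a degenerate test.
        t = math.inf if beta_g > 0 else (-math.inf if beta_g < 0 else 0.0)
        return RegressionResult(
            float(beta_g), 0.0, t, 0.0 if beta_g != 0 else 1.0,
            float(rss), int(n_used),
        )
    se = float(np.sqrt(se2))
    t = float(beta_g) / se
    p = float(2.0 * stats.t.sf(abs(t), df))
    return RegressionResult(float(beta_g), se, t, p, float(rss), int(n_used))


def _sparse_fit_multi(
    ctx: DesignContext, cache: CovariateCache, sv: SparseVariantRecord
) -> list[RegressionResult]:
    """Block-inverse fast path over every cached phenotype; O(p(k+p)) each."""
    idx, vals = sv.entry_arrays()
    if np.any(vals == MISSING):
        raise MissingGenotypePrecondition(
            "sparse fast path requires a record without MISSING entries"
        )
    n, p = ctx.n, ctx.p
    df = n - p
    if df <= 0:
        return [RegressionResult.singular(n) for _ in range(cache.n_pheno)]
    g = vals.astype(float)
    B = ctx.Xc[idx].T @ g  # O(kp)
    D = float(g @ g)  # O(k)
    u = cache.A_inv @ B
    F = float(D - B @ u)
    if F <= F_TOL * max(D, 1.0):
        return [RegressionResult.singular(n) for _ in range(cache.n_pheno)]
    # Xg'y over the k entries only; covariate products come from the cache.
    xg_t_Y = g @ cache.Y[idx]  # (n_pheno,)
    beta_g = (xg_t_Y - u @ cache.Xc_t_Y) / F
    beta_c = cache.A_inv @ cache.Xc_t_Y - np.outer(u, beta_g)
    rss = cache.y_t_y - np.einsum("ij,ij->j", cache.Xc_t_Y, beta_c) - xg_t_Y * beta_g
    rss = np.maximum(rss, 0.0)
    sigma2 = rss / df
    return [
        _t_result(beta_g[j], sigma2[j] / F, rss[j], df, n)
        for j in range(cache.n_pheno)
    ]


def _dense_fit_multi(
    ctx: DesignContext, cache: CovariateCache, g: np.ndarray
) -> list[RegressionResult]:
    """Oracle path: per-variant normal equations on rows with observed genotype."""
    g = np.asarray(g)
    if np.issubdtype(g.dtype, np.floating):
        keep = np.isfinite(g)
        gf = g
    else:
        keep = g != MISSING
        gf = g.astype(float)
    n_used = int(keep.sum())
    p = ctx.p
    if n_used <= p:
        return [RegressionResult.singular(n_used) for _ in range(cache.n_pheno)]
    gk = gf[keep]
    if np.ptp(gk) == 0:
        return [RegressionResult.singular(n_used) for _ in range(cache.n_pheno)]
    X = np.column_stack([ctx.Xc[keep], gk])
    Yk = cache.Y[keep]
    XtX = X.T @ X
    XtY = X.T @ Yk
    try:
        c, low = linalg.cho_factor(XtX)
        beta = linalg.cho_solve((c, low), XtY)
        XtX_inv_gg = float(linalg.cho_solve((c, low), np.eye(p)[:, -1])[-1])
    except linalg.LinAlgError:
        return [RegressionResult.singular(n_used) for _ in range(cache.n_pheno)]
    rss = np.maximum(
        np.einsum("ij,ij->j", Yk, Yk) - np.einsum("ij,ij->j", XtY, beta), 0.0
    )
    df = n_used - p
    sigma2 = rss / df
    return [
        _t_result(beta[-1, j], sigma2[j] * XtX_inv_gg, rss[j], df, n_used)
        for j in range(cache.n_pheno)
    ]


def sparse_linreg(
    ctx: DesignContext, cache: CovariateCache, sv: SparseVariantRecord, pheno: int = 0
) -> RegressionResult:
    """Fast-path fit of one sparse variant (no MISSING entries allowed)."""
    return _sparse_fit_multi(ctx, cache, sv)[pheno]


def dense_linreg(
    ctx: DesignContext, cache: CovariateCache, g: np.ndarray, pheno: int = 0
) -> RegressionResult:
    """Oracle dense fit; rows with missing genotype dropped for this variant only."""
    return _dense_fit_multi(ctx, cache, g)[pheno]


def scan(
    ctx: DesignContext,
    cache: CovariateCache,
    fileset: GenoFileset,
    force_dense: bool = False,
    keep: np.ndarray | None = None,
    tally: dict | None = None,
):
    """Stream (variant index, RegressionResult) for phenotype 0 of the cache.

    Routing: sparse-stored record with no MISSING entries -> block-inverse
    fast path; anything else -> dense oracle path. ``keep`` optionally
    restricts the fileset's samples to the (pre-aligned) analysis rows.
    Output order is variant-directory order and is deterministic.
    """
    for i, res_list in scan_multi(
        ctx, cache, fileset, force_dense=force_dense, keep=keep, tally=tally
    ):
        yield i, res_list[0]


def scan_multi(
    ctx: DesignContext,
    cache: CovariateCache,
    fileset: GenoFileset,
    force_dense: bool = False,
    keep: np.ndarray | None = None,
    tally: dict | None = None,
):
    from .genostore import subset_record

    if keep is not None:
        keep = np.asarray(keep, dtype=bool)
        if keep.size != fileset.n_samples:
            raise ConsistencyError("keep mask length != fileset sample count")
        if int(keep.sum()) != ctx.n:
            raise ConsistencyError("design rows != analysis sample count")
    elif fileset.n_samples != ctx.n:
        raise ConsistencyError("fileset sample count != design rows")
    mode = "FORCE_DENSE" if force_dense else "AS_STORED"
    for i, rec in fileset.iter_variants(mode=mode):
        if keep is not None:
            rec = subset_record(rec, keep)
        if isinstance(rec, SparseVariantRecord) and not np.any(rec.values == MISSING):
            if tally is not None:
                tally["sparse"] = tally.get("sparse", 0) + 1
            yield i, _sparse_fit_multi(ctx, cache, rec)
        else:
            if tally is not None:
                tally["dense"] = tally.get("dense", 0) + 1
            codes = rec.to_dense() if isinstance(rec, SparseVariantRecord) else rec.codes
            yield i, _dense_fit_multi(ctx, cache, codes)
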