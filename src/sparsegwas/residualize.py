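"""Residualized fast association modes for quantitative and binary traits.

qt-residualize: the covariate model is fitted once, the phenotype is replaced
by its residuals r = y - Xc (Xc'Xc)^-1 Xc' y, and every per-variant fit then
has only p = 2 predictors (intercept + genotype). Because p = 2, missing
genotypes become cheap to handle: the sufficient statistics n, sum(r) and
sum(r^2) are precomputed over all samples and the per-variant pass simply
*subtracts* the contribution of each sample whose genotype is missing, then
accumulates the genotype sums over the listed nonzero entries. The whole
per-variant cost is O(k) for a difflist with k entries — the record is
processed directly, never expanded to an n-length array.

cc-residualize: the binary-trait analogue. The covariate-only logistic (or
Firth) model is fitted once and frozen as a per-sample offset eta; each
variant then gets a 2-parameter logistic fit logit(mu) = eta + b0 + bg * g.
firth-fallback is the slow baseline it is compared against: a full-covariate
per-variant logistic fit that refits with the Firth penalty
l*(b) = l(b) + 1/2 log|I(b)| whenever the plain fit fails to converge,
an estimate diverges, or fitted probabilities pin to 0/1 — the penalty
guarantees finite estimates under separation.

Wald tests are used throughout for binary traits.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats
from scipy.special import expit

from .genostore import (
    MISSING,
    DenseVariantRecord,
    GenoFileset,
    SparseVariantRecord,
)
from .glm_core import (
    NONCONVERGED,
    OK,
    SINGULAR,
    DesignContext,
    RegressionResult,
)

LOGISTIC = "LOGISTIC"
FIRTH = "FIRTH"

# Newton convergence / Firth-fallback thresholds.
MAX_NEWTON_ITER = 25
SCORE_TOL = 1e-8
STEP_TOL = 1e-10
MAX_STEP_HALVINGS = 10
FALLBACK_BETA_MAX = 50.0
FALLBACK_MU_PIN = 1e-8


class ConvergenceError(Exception):
    """Newton iteration failed to converge; carries the objective trace."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(message)
        self.trace = trace


@dataclass
class ResidualizedPhenotype:
    """Covariate-model residuals with precomputed whole-cohort sums."""

    r: np.ndarray
    sum_r: float
    sum_r2: float
    n: int


@dataclass
class OffsetModel:
    """Frozen covariate-only linear predictor for binary-trait fast fits."""

    eta: np.ndarray
    converged: bool
    iterations: int
    gamma: np.ndarray
    engine: str = LOGISTIC


def qt_residualize(ctx: DesignContext, y: np.ndarray) -> ResidualizedPhenotype:
    """One upfront covariate regression; returns residuals and their sums."""
    y = np.asarray(y, dtype=float)
    if y.shape != (ctx.n,):
        raise ValueError("y must be a complete n-vector aligned to Xc")
    if not np.all(np.isfinite(y)):
        raise ValueError("y must contain no missing values (caller filters)")
    beta, *_ = linalg.lstsq(ctx.Xc, y)
    r = y - ctx.Xc @ beta
    return ResidualizedPhenotype(
        r=r, sum_r=math.fsum(r), sum_r2=math.fsum(r * r), n=ctx.n
    )


def sparse_p2_linreg(
    rp: ResidualizedPhenotype, sv: SparseVariantRecord
) -> RegressionResult:
    """O(k) intercept+genotype fit of the residuals with subtractive missingness.

    MISSING entries are handled by removing each flagged sample's
    contribution from the precomputed n, sum(r) and sum(r^2); genotype sums
    are accumulated over the remaining listed entries only. Equivalent to a
    dense regression of r on [1, g] restricted to non-missing rows.
    """
    idx, vals = sv.entry_arrays()
    miss = vals == MISSING
    n_used = rp.n - int(miss.sum())
    if n_used <= 2:
        return RegressionResult.singular(n_used)
    sum_r, sum_r2 = rp.sum_r, rp.sum_r2
    if miss.any():
        # Compensated subtraction: large k can make r-sums cancel badly.
        rm = rp.r[idx[miss]]
        sum_r = sum_r - math.fsum(rm)
        sum_r2 = sum_r2 - math.fsum(rm * rm)
    g = vals[~miss].astype(float)
    rg = rp.r[idx[~miss]]
    sum_g = float(g.sum())
    sum_g2 = float(g @ g)
    sum_gr = float(g @ rg)
    sxx = sum_g2 - sum_g * sum_g / n_used
    if sxx <= 1e-12 * max(sum_g2, 1.0):
        return RegressionResult.singular(n_used)
    sxy = sum_gr - sum_g * sum_r / n_used
    syy = sum_r2 - sum_r * sum_r / n_used
    beta = sxy / sxx
    rss = max(syy - beta * sxy, 0.0)
    df = n_used - 2
    se2 = (rss / df) / sxx
    if se2 <= 0 or not np.isfinite(se2):
        return RegressionResult.singular(n_used)
    se = math.sqrt(se2)
    t = beta / se
    p = float(2.0 * stats.t.sf(abs(t), df))
    return RegressionResult(beta, se, t, p, rss, n_used)


# ---------------------------------------------------------------------------
# Logistic / Firth machinery
# ---------------------------------------------------------------------------

@dataclass
class LogisticFit:
    beta: np.ndarray
    cov: np.ndarray
    converged: bool
    iterations: int
    mu: np.ndarray
    trace: list = field(default_factory=list)  # (penalized) log-likelihood path


def _loglik(eta: np.ndarray, y: np.ndarray) -> float:
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    offset: np.ndarray | None = None,
    firth: bool = False,
    max_iter: int = MAX_NEWTON_ITER,
) -> LogisticFit:
    """Newton fit of a logistic model, optionally Firth-penalized.

    Maximizes l(b) (plain) or l*(b) = l(b) + 1/2 log|X'WX| (Firth), with
    step-halving whenever a full Newton step would decrease the objective.
    The Firth score is X'(y - mu + h (1/2 - mu)) with h the hat diagonals of
    W^(1/2) X (X'WX)^-1 X' W^(1/2).
    """
    with warnings.catch_warnings():
        # Diverging fits drive X'WX toward singularity; solver warnings are
        # expected there and the outcome is handled by the fallback triggers.
        warnings.simplefilter("ignore", linalg.LinAlgWarning)
        return _fit_logistic_impl(X, y, offset, firth, max_iter)


def _fit_logistic_impl(X, y, offset, firth, max_iter) -> LogisticFit:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    off = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)
    beta = np.zeros(p)

    def objective_parts(b):
        eta = off + X @ b
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-300, None)
        M = (X * w[:, None]).T @ X
        obj = _loglik(eta, y)
        if firth:
            sign, logdet = np.linalg.slogdet(M)
            if sign <= 0:
                return eta, mu, w, M, -np.inf
            obj += 0.5 * logdet
        return eta, mu, w, M, obj

    eta, mu, w, M, obj = objective_parts(beta)
    trace = [obj]
    converged = False
    it = 0
    cov = np.full((p, p), np.nan)
    for it in range(1, max_iter + 1):
        if firth:
            try:
                XMinv = linalg.solve(M, X.T, assume_a="pos").T
            except linalg.LinAlgError:
                break
            h = w * np.einsum("ij,ij->i", XMinv, X)
            score = X.T @ (y - mu + h * (0.5 - mu))
        else:
            score = X.T @ (y - mu)
        if np.max(np.abs(score)) < SCORE_TOL:
            converged = True
            break
        try:
            step = linalg.solve(M, score, assume_a="pos")
        except linalg.LinAlgError:
            break
        # Step-halving on objective decrease.
        scale = 1.0
        for _ in range(MAX_STEP_HALVINGS + 1):
            cand = beta + scale * step
            parts = objective_parts(cand)
            if parts[4] >= obj or not np.isfinite(obj):
                break
            scale *= 0.5
        beta = cand
        prev_obj = trace[-1]
        eta, mu, w, M, obj = parts
        trace.append(obj)
        if np.max(np.abs(scale * step)) < STEP_TOL:
            converged = True
            break
        # Objective plateau at machine precision: the penalized problem can
        # stall with a tiny residual score because Newton uses the
        # unpenalized information as its Hessian.
        if np.isfinite(prev_obj) and obj - prev_obj <= 1e-11 * (1.0 + abs(obj)):
            converged = True
            break
    try:
        cov = linalg.inv(M)
    except linalg.LinAlgError:
        pass
    return LogisticFit(beta, cov, converged, it, mu, trace)


def cc_fit_offset(
    ctx: DesignContext, y_binary: np.ndarray, engine: str = LOGISTIC
) -> OffsetModel:
    """Fit the covariate-only binary model once; freeze eta = Xc gamma."""
    y = np.asarray(y_binary, dtype=float)
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("y_binary must be coded 0/1")
    if y.min() == y.max():
        raise ValueError("both case and control classes must be present")
    fit = fit_logistic(ctx.Xc, y, firth=(engine == FIRTH))
    diverged = engine == LOGISTIC and (
        np.max(np.abs(fit.beta)) > FALLBACK_BETA_MAX
        or np.any(fit.mu < FALLBACK_MU_PIN)
        or np.any(fit.mu > 1.0 - FALLBACK_MU_PIN)
    )
    if not fit.converged or diverged:
        raise ConvergenceError(
            f"covariate-only {engine} fit "
            + ("diverged (separation?)" if diverged else "did not converge")
            + f" after {fit.iterations} iterations",
            fit.trace,
        )
    eta = ctx.Xc @ fit.beta
    return OffsetModel(
        eta=eta, converged=True, iterations=fit.iterations,
        gamma=fit.beta, engine=engine,
    )


def _densify(sv) -> np.ndarray:
    if isinstance(sv, SparseVariantRecord):
        return sv.to_dense()
    return sv.codes


def _wald_result(fit: LogisticFit, n_used: int, engine: str) -> RegressionResult:
    if not fit.converged:
        nan = float("nan")
        return RegressionResult(
            nan, nan, nan, nan, nan, n_used, status=NONCONVERGED, engine=engine
        )
    beta_g = float(fit.beta[-1])
    var = float(fit.cov[-1, -1])
    if not np.isfinite(var) or var <= 0:
        return RegressionResult.singular(n_used, engine=engine)
    se = math.sqrt(var)
    z = beta_g / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return RegressionResult(
        beta_g, se, z, p, float("nan"), n_used, status=OK, engine=engine
    )


def _needs_firth(fit: LogisticFit) -> bool:
    return (
        not fit.converged
        or np.max(np.abs(fit.beta)) > FALLBACK_BETA_MAX
        or np.any(fit.mu < FALLBACK_MU_PIN)
        or np.any(fit.mu > 1.0 - FALLBACK_MU_PIN)
    )


def cc_residualize_variant(
    om: OffsetModel,
    sv,
    y_binary: np.ndarray,
    engine: str = LOGISTIC,
    firth_fallback: bool = True,
) -> RegressionResult:
    """2-parameter offset logistic fit logit(mu) = eta + b0 + bg g.

    With ``firth_fallback`` (the default, mirroring firth-fallback semantics
    at p = 2) a plain fit that fails to converge, diverges, or pins fitted
    probabilities is refitted with the Firth penalty.
    """
    y = np.asarray(y_binary, dtype=float)
    g = _densify(sv).astype(float)
    keep = g != MISSING
    n_used = int(keep.sum())
    gk = g[keep]
    if n_used <= 2 or np.ptp(gk) == 0:
        return RegressionResult.singular(n_used, engine=engine)
    X = np.column_stack([np.ones(n_used), gk])
    fit = fit_logistic(X, y[keep], offset=om.eta[keep], firth=(engine == FIRTH))
    if engine == LOGISTIC and firth_fallback and _needs_firth(fit):
        fit = fit_logistic(X, y[keep], offset=om.eta[keep], firth=True)
        return _wald_result(fit, n_used, FIRTH)
    return _wald_result(fit, n_used, engine)


def firth_fallback_variant(
    ctx: DesignContext, sv, y_binary: np.ndarray
) -> RegressionResult:
    """Full-covariate per-variant logistic fit with automatic Firth refit.

    The Firth penalty engages when the plain fit fails to converge, any
    |beta_j| exceeds 50, or a fitted probability pins to 0/1.
    """
    y = np.asarray(y_binary, dtype=float)
    g = _densify(sv).astype(float)
    keep = g != MISSING
    n_used = int(keep.sum())
    gk = g[keep]
    if n_used <= ctx.p or np.ptp(gk) == 0:
        return RegressionResult.singular(n_used, engine=LOGISTIC)
    X = np.column_stack([ctx.Xc[keep], gk])
    yk = y[keep]
    fit = fit_logistic(X, yk)
    if _needs_firth(fit):
        fit = fit_logistic(X, yk, firth=True)
        return _wald_result(fit, n_used, FIRTH)
    return _wald_result(fit, n_used, LOGISTIC)


# ---------------------------------------------------------------------------
# Whole-fileset scans
# ---------------------------------------------------------------------------

def _sparse_entries(rec) -> SparseVariantRecord:
    """View any record as a difflist (dense records scanned once, O(n))."""
    if isinstance(rec, SparseVariantRecord):
        return rec
    nz = np.flatnonzero(rec.codes)
    return SparseVariantRecord(rec.n_samples, nz, rec.codes[nz])


def scan_qt(ctx: DesignContext, y: np.ndarray, fileset: GenoFileset,
            keep: np.ndarray | None = None, tally: dict | None = None):
    """qt-residualize scan: one covariate fit, then O(k) per-variant fits."""
    from .genostore import subset_record

    rp = qt_residualize(ctx, y)
    for i, rec in fileset.iter_variants(mode="AS_STORED"):
        if keep is not None:
            rec = subset_record(rec, keep)
        if tally is not None:
            key = "sparse" if isinstance(rec, SparseVariantRecord) else "dense"
            tally[key] = tally.get(key, 0) + 1
        yield i, sparse_p2_linreg(rp, _sparse_entries(rec))


def scan_cc(ctx: DesignContext, y_binary: np.ndarray, fileset: GenoFileset,
            mode: str = "cc-residualize", keep: np.ndarray | None = None,
            tally: dict | None = None):
    """Binary-trait scan in cc-residualize or firth-fallback mode.

    In cc-residualize mode each variant gets the 2-parameter offset fit; a
    variant whose plain fit does not converge is retried with the Firth
    penalty, mirroring firth-fallback semantics at p = 2.
    """
    from .genostore import subset_record

    if mode not in ("cc-residualize", "firth-fallback"):
        raise ValueError(f"unknown binary-scan mode {mode!r}")
    om = cc_fit_offset(ctx, y_binary) if mode == "cc-residualize" else None
    for i, rec in fileset.iter_variants(mode="AS_STORED"):
        if keep is not None:
            rec = subset_record(rec, keep)
        if mode == "cc-residualize":
            res = cc_residualize_variant(om, rec, y_binary)
        else:
            res = firth_fallback_variant(ctx, rec, y_binary)
        if tally is not None:
            tally[res.engine or "NA"] = tally.get(res.engine or "NA", 0) + 1
        yield i, res
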