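"""qt/cc residualization: subtractive missingness, logistic and Firth fits."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import expit

from conftest import make_design, random_sparse_variant
from sparsegwas import (
    SparseVariantRecord,
    build_cache,
    cc_fit_offset,
    cc_residualize_variant,
    dense_linreg,
    firth_fallback_variant,
    fit_logistic,
    qt_residualize,
    sparse_p2_linreg,
)
from sparsegwas.glm_core import SINGULAR, DesignContext
from sparsegwas.residualize import FIRTH, LOGISTIC, ConvergenceError


# -- qt-residualize ----------------------------------------------------------

def test_residualize_intercept_only_is_centering(rng):
    y = rng.standard_normal(40)
    rp = qt_residualize(DesignContext(np.ones((40, 1))), y)
    assert np.allclose(rp.r, y - y.mean())
    assert rp.sum_r == pytest.approx(0.0, abs=1e-10)


def test_residualize_exact_linear_and_oracle(rng):
    ctx = make_design(rng, 100, 3)
    coef = rng.standard_normal(4)
    rp = qt_residualize(ctx, ctx.Xc @ coef)
    assert rp.sum_r2 == pytest.approx(0.0, abs=1e-16)
    y = rng.standard_normal(100)
    rp = qt_residualize(ctx, y)
    beta = np.linalg.lstsq(ctx.Xc, y, rcond=None)[0]
    assert np.allclose(rp.r, y - ctx.Xc @ beta, atol=1e-10)
    # residuals orthogonal to every covariate column
    assert np.max(np.abs(ctx.Xc.T @ rp.r)) < 1e-8 * np.linalg.norm(y)


def test_sparse_p2_no_missing_matches_dense(rng):
    ctx = make_design(rng, 150, 4)
    y = rng.standard_normal(150)
    rp = qt_residualize(ctx, y)
    sv = random_sparse_variant(rng, 150, 12)
    res = sparse_p2_linreg(rp, sv)
    ctx2 = DesignContext(np.ones((150, 1)))
    oracle = dense_linreg(ctx2, build_cache(ctx2, rp.r), sv.to_dense())
    assert res.beta_g == pytest.approx(oracle.beta_g, rel=1e-8)
    assert res.se_g == pytest.approx(oracle.se_g, rel=1e-8)
    assert res.p_value == pytest.approx(oracle.p_value, rel=1e-6)


def test_sparse_p2_subtractive_missingness_equals_subset_oracle(rng):
    """Subtracting missing-sample sums == refitting on the non-missing subset."""
    for _ in range(50):
        n = int(rng.integers(30, 200))
        ctx = make_design(rng, n, int(rng.integers(1, 5)))
        y = rng.standard_normal(n)
        rp = qt_residualize(ctx, y)
        k = int(rng.integers(1, max(n // 4, 2)))
        sv = random_sparse_variant(rng, n, k, allow_missing=True)
        res = sparse_p2_linreg(rp, sv)
        g = sv.to_dense()
        keep = g != 3
        gk = g[keep].astype(float)
        if res.status != "OK":
            assert keep.sum() <= 2 or np.ptp(gk) == 0
            continue
        fit = sm.OLS(rp.r[keep], sm.add_constant(gk)).fit()
        assert res.n_used == int(keep.sum())
        assert res.beta_g == pytest.approx(fit.params[-1], rel=1e-8, abs=1e-12)
        assert res.se_g == pytest.approx(fit.bse[-1], rel=1e-8)
        assert res.rss == pytest.approx(fit.ssr, rel=1e-8, abs=1e-12)


def test_sparse_p2_all_carriers_missing_is_singular(rng):
    ctx = DesignContext(np.ones((50, 1)))
    rp = qt_residualize(ctx, rng.standard_normal(50))
    sv = SparseVariantRecord(50, np.array([4, 9]), np.array([3, 3], np.uint8))
    assert sparse_p2_linreg(rp, sv).status == SINGULAR


# -- logistic / Firth machinery ---------------------------------------------

def test_offset_fit_intercept_only_closed_form():
    y = np.array([1.0] * 30 + [0.0] * 70)
    om = cc_fit_offset(DesignContext(np.ones((100, 1))), y)
    assert np.allclose(om.eta, np.log(30 / 70), atol=1e-8)


def test_logistic_matches_statsmodels_with_offset(rng):
    n = 300
    ctx = make_design(rng, n, 4)
    y = (rng.random(n) < expit(ctx.Xc @ rng.normal(0, 0.5, 5))).astype(float)
    om = cc_fit_offset(ctx, y)
    smfit = sm.Logit(y, ctx.Xc).fit(disp=0)
    assert np.allclose(om.gamma, smfit.params, atol=1e-6)
    # offset fit: 2-parameter model with frozen eta
    g = rng.binomial(2, 0.1, n).astype(float)
    X2 = np.column_stack([np.ones(n), g])
    ours = fit_logistic(X2, y, offset=om.eta)
    smoff = sm.GLM(
        y, X2, family=sm.families.Binomial(), offset=om.eta
    ).fit()
    assert np.allclose(ours.beta, smoff.params, atol=1e-6)
    assert np.allclose(
        np.sqrt(np.diag(ours.cov)), smoff.bse, atol=1e-6
    )


def test_separable_covariate_logistic_fails_firth_succeeds():
    x = np.linspace(-2, 2, 80)
    y = (x > 0).astype(float)
    ctx = DesignContext(np.column_stack([np.ones(80), x]))
    with pytest.raises(ConvergenceError):
        cc_fit_offset(ctx, y, engine=LOGISTIC)
    om = cc_fit_offset(ctx, y, engine=FIRTH)
    assert np.all(np.isfinite(om.gamma)) and np.all(np.isfinite(om.eta))


def test_firth_penalized_loglik_nondecreasing_under_separation():
    x = np.linspace(-3, 3, 50)
    y = (x > 0.5).astype(float)
    fit = fit_logistic(np.column_stack([np.ones(50), x]), y, firth=True)
    assert np.all(np.isfinite(fit.beta))
    assert np.all(np.diff(fit.trace) >= -1e-9)


def test_firth_matches_direct_penalized_likelihood_maximization(rng):
    """Independent oracle: numerically maximize l(b) + 1/2 log|I(b)|."""
    n = 60
    X = np.column_stack([np.ones(n), rng.standard_normal(n)])
    y = (rng.random(n) < 0.4).astype(float)

    def neg_penalized(b):
        eta = X @ b
        mu = expit(eta)
        ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
        M = (X * (mu * (1 - mu))[:, None]).T @ X
        sign, logdet = np.linalg.slogdet(M)
        return -(ll + 0.5 * logdet) if sign > 0 else np.inf

    ours = fit_logistic(X, y, firth=True)
    direct = minimize(neg_penalized, np.zeros(2), method="Nelder-Mead",
                      options={"xatol": 1e-10, "fatol": 1e-12})
    assert np.allclose(ours.beta, direct.x, atol=1e-5)


# -- per-variant binary fits --------------------------------------------------

def test_firth_fallback_well_behaved_matches_irls_oracle(rng):
    n = 400
    ctx = make_design(rng, n, 3)
    y = (rng.random(n) < 0.35).astype(float)
    sv = random_sparse_variant(rng, n, 40)
    sv.values[:] = np.minimum(sv.values, 2)
    res = firth_fallback_variant(ctx, sv, y)
    assert res.engine == LOGISTIC
    smfit = sm.Logit(
        y, np.column_stack([ctx.Xc, sv.to_dense().astype(float)])
    ).fit(disp=0)
    assert res.beta_g == pytest.approx(smfit.params[-1], abs=1e-6)
    assert res.se_g == pytest.approx(smfit.bse[-1], abs=1e-6)
    assert res.p_value == pytest.approx(smfit.pvalues[-1], abs=1e-6)


def test_firth_fallback_engages_on_quasi_separation(rng):
    n = 300
    ctx = make_design(rng, n, 2)
    y = (rng.random(n) < 0.3).astype(float)
    sv = random_sparse_variant(rng, n, 6)
    sv.values[:] = 1
    y[sv.indices] = 1.0  # every carrier a case
    res = firth_fallback_variant(ctx, sv, y)
    assert res.engine == FIRTH
    assert np.isfinite(res.beta_g) and res.status == "OK"


def test_cc_residualize_missing_rows_dropped_and_monomorphic(rng):
    n = 200
    ctx = make_design(rng, n, 2)
    y = (rng.random(n) < 0.3).astype(float)
    om = cc_fit_offset(ctx, y)
    mono = SparseVariantRecord(n, np.array([], int), np.array([], np.uint8))
    assert cc_residualize_variant(om, mono, y).status == SINGULAR
    sv = random_sparse_variant(rng, n, 15, allow_missing=True)
    if not np.any(sv.values == 3):
        sv.values[0] = 3
    res = cc_residualize_variant(om, sv, y)
    assert res.n_used == n - int((sv.values == 3).sum())


def test_offset_consistency_with_zero_covariates(rng):
    """Intercept-only offset model == direct 2-parameter logistic fit."""
    n = 250
    ctx = DesignContext(np.ones((n, 1)))
    y = (rng.random(n) < 0.4).astype(float)
    om = cc_fit_offset(ctx, y)
    sv = random_sparse_variant(rng, n, 25)
    sv.values[:] = np.minimum(sv.values, 2)
    res = cc_residualize_variant(om, sv, y)
    direct = sm.Logit(
        y, np.column_stack([np.ones(n), sv.to_dense().astype(float)])
    ).fit(disp=0)
    assert res.beta_g == pytest.approx(direct.params[-1], abs=1e-6)
    assert res.p_value == pytest.approx(direct.pvalues[-1], abs=1e-5)
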