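import numpy as np
import pytest

from sparsegwas import CohortSpec, DesignContext, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20250929)


@pytest.fixture(scope="session")
def small_cohort():
    """A reusable 400-sample, 150-variant rare-skewed cohort."""
    return simulate_cohort(
        CohortSpec(n_samples=400, n_variants=150, n_covariates=4, seed=314)
    )


def make_design(rng, n, q):
    """Random full-rank design with intercept first."""
    return DesignContext(
        np.column_stack([np.ones(n), rng.standard_normal((n, q))])
    )


def random_sparse_variant(rng, n, k, allow_missing=False):
    from sparsegwas import SparseVariantRecord

    idx = np.sort(rng.choice(n, size=k, replace=False))
    hi = 4 if allow_missing else 3
    vals = rng.integers(1, hi, size=k).astype(np.uint8)
    return SparseVariantRecord(n, idx, vals)
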