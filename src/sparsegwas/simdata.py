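"""Synthetic biobank-style cohorts with known ground truth.

Emulates the inputs a population-scale sequencing association study sees: a
panel of biallelic variants whose site-frequency spectrum is heavily skewed
toward rare alleles (most variants have minor-allele count k << n), drawn
per-variant as independent binomial(2, MAF) genotypes under Hardy-Weinberg
equilibrium with no linkage disequilibrium; uniformly random (MCAR)
genotype missingness; Gaussian covariates; a quantitative phenotype that is
a linear combination of covariates, planted genotype effects and Gaussian
noise; and a binary phenotype from a logistic model whose intercept is
tuned by bisection to hit a requested expected case fraction.

Default frequencies span [5e-4, 0.05] with a Beta(1, 3) skew on the log
scale — steeper than log-uniform, as sequencing site-frequency spectra are —
plus a small common-variant admixture, so the bulk of variants land on the
sparse storage/regression fast paths, mirroring the real-data regime where
the overwhelming majority of discovered variants are rare.

Everything is driven by a single integer seed; identical seeds produce
byte-identical filesets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .genostore import GenoFileset, MISSING


class SpecError(ValueError):
    """A cohort specification parameter is out of its valid range."""


@dataclass
class CohortSpec:
    """Parameters of one simulated cohort; the seed fully determines output."""

    n_samples: int = 2000
    n_variants: int = 5000
    maf_range: tuple = (5e-4, 0.05)
    maf_skew: float = 3.0  # Beta(1, skew) on the log-MAF scale; 1 = log-uniform
    common_variant_fraction: float = 0.02
    common_maf_range: tuple = (0.05, 0.5)
    missing_rate_genotype: float = 0.01
    n_covariates: int = 10
    covariate_effect_sd: float = 0.5
    n_causal: int = 10
    causal_beta: float = 0.5
    noise_sd: float = 1.0
    case_fraction: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 2 or self.n_variants < 1:
            raise SpecError("need at least 2 samples and 1 variant")
        for name in ("missing_rate_genotype", "common_variant_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SpecError(f"{name}={v} outside [0, 1]")
        if not 0.0 < self.case_fraction < 1.0:
            raise SpecError(
                f"case_fraction={self.case_fraction} infeasible (must be in (0,1))"
            )
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise SpecError(f"maf_range={self.maf_range} invalid")
        if self.n_causal > self.n_variants:
            raise SpecError("n_causal exceeds n_variants")
        if self.noise_sd <= 0:
            raise SpecError("noise_sd must be positive")
        if self.maf_skew <= 0:
            raise SpecError("maf_skew must be positive")


class SimulatedCohort(NamedTuple):
    fileset: GenoFileset
    covariates: pd.DataFrame  # FID IID COV1..COVq
    phenotypes: pd.DataFrame  # FID IID QT BIN
    truth: pd.DataFrame  # id, variant_index, maf, beta
    mafs: np.ndarray


def simulate_cohort(spec: CohortSpec) -> SimulatedCohort:
    """Draw genotypes, covariates and phenotypes per the cohort spec.

    Phenotypes are generated from the *true* genotypes; missingness is then
    applied to the stored copy only (missing-when-causal contributes as the
    reference genotype would, i.e. effects use the observed allele count).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_samples, spec.n_variants

    lo, hi = spec.maf_range
    u = rng.beta(1.0, spec.maf_skew, size=m)
    mafs = np.exp(np.log(lo) + u * (np.log(hi) - np.log(lo)))
    common = rng.random(m) < spec.common_variant_fraction
    if common.any():
        clo, chi = spec.common_maf_range
        mafs[common] = rng.uniform(clo, chi, size=int(common.sum()))

    G = rng.binomial(2, mafs[:, None], size=(m, n)).astype(np.uint8)

    q = spec.n_covariates
    Z = rng.standard_normal((n, q)) if q else np.empty((n, 0))
    gamma = rng.normal(0.0, spec.covariate_effect_sd, size=q)

    causal_idx = np.sort(rng.choice(m, size=spec.n_causal, replace=False))
    betas = np.full(spec.n_causal, float(spec.causal_beta))
    genetic = betas @ G[causal_idx].astype(float) if spec.n_causal else np.zeros(n)

    lin = Z @ gamma + genetic
    y_qt = lin + rng.normal(0.0, spec.noise_sd, size=n)

    # Intercept such that the expected case fraction matches the request.
    c0 = brentq(
        lambda c: expit(c + lin).mean() - spec.case_fraction, -60.0, 60.0,
        xtol=1e-10,
    )
    y_bin = (rng.random(n) < expit(c0 + lin)).astype(np.int64)

    codes = G.copy()
    if spec.missing_rate_genotype > 0:
        codes[rng.random((m, n)) < spec.missing_rate_genotype] = MISSING

    ids = [f"S{i + 1:06d}" for i in range(n)]
    samples = pd.DataFrame(
        {"fid": ids, "iid": ids, "pat": "0", "mat": "0", "sex": 0, "pheno": -9}
    )
    variants = pd.DataFrame(
        {
            "chrom": "1",
            "id": [f"V{i + 1}" for i in range(m)],
            "cm": 0.0,
            "pos": np.arange(1, m + 1, dtype=np.int64),
            "a1": "A",
            "a2": "C",
        }
    )
    fileset = GenoFileset.from_matrix(codes, variants=variants, samples=samples)

    covariates = pd.DataFrame(
        {"FID": ids, "IID": ids}
        | {f"COV{j + 1}": Z[:, j] for j in range(q)}
    )
    phenotypes = pd.DataFrame({"FID": ids, "IID": ids, "QT": y_qt, "BIN": y_bin})
    truth = pd.DataFrame(
        {
            "id": [f"V{i + 1}" for i in causal_idx],
            "variant_index": causal_idx,
            "maf": mafs[causal_idx],
            "beta": betas,
        }
    )
    return SimulatedCohort(fileset, covariates, phenotypes, truth, mafs)


def null_cohort(spec: CohortSpec) -> SimulatedCohort:
    """Same generator with every genotype effect zeroed (type-I calibration)."""
    return simulate_cohort(replace(spec, n_causal=0))
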