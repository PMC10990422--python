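"""Parameter-recovery and calibration experiments.

These are the package's verification experiments: simulate cohorts at the
published effect sizes (0.14 paternally and 0.025 maternally phased STR DNMs
per year of parental age; +0.0023 per year in the paternal fraction alpha),
refit the corresponding model, and summarize the recovered coefficients over
replicates, plus null calibrations of the age-effect and paired-Spearman
tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .agemodels import fit_age_model, fit_alpha_model
from .postzygotic import simulate_postzygotic

COHORT_SIZE = 1593  # children with phased DNM counts in the study cohort
PATERNAL_SLOPE = 0.14  # mutations per year of paternal age
MATERNAL_SLOPE = 0.025  # mutations per year of maternal age
ALPHA_SLOPE = 0.0023  # increase in paternal fraction per year


@dataclass
class RecoveryResult:
    mean_estimate: float
    mc_se: float  # Monte-Carlo standard error of the mean estimate
    n_reps: int
    n_children: int
    generating_value: float

    @property
    def bias(self) -> float:
        return self.mean_estimate - self.generating_value


def _truncated_normal(rng, mean, sd, bounds, size):
    out = rng.normal(mean, sd, size)
    bad = (out < bounds[0]) | (out > bounds[1])
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < bounds[0]) | (out > bounds[1])
    return out


def recover_age_slope(
    slope: float,
    intercept: float,
    seed: int,
    n_children: int = COHORT_SIZE,
    n_reps: int = 200,
    age_mean: float = 33.0,
    age_sd: float = 5.5,
    age_bounds: tuple[float, float] = (18.0, 50.0),
) -> RecoveryResult:
    """Identity-link Poisson slope recovery at a given generating effect.

    Per replicate: draw parental ages from a truncated normal, simulate
    per-child phased DNM counts as Poisson(intercept + slope * age), fit the
    identity-link Poisson GLM, record the slope.
    """
    rng = np.random.default_rng(seed)
    estimates = np.empty(n_reps)
    for rep in range(n_reps):
        ages = _truncated_normal(rng, age_mean, age_sd, age_bounds, n_children)
        counts = rng.poisson(intercept + slope * ages)
        estimates[rep] = fit_age_model(counts, ages).coef("age").estimate
    return RecoveryResult(
        mean_estimate=float(estimates.mean()),
        mc_se=float(estimates.std(ddof=1) / np.sqrt(n_reps)),
        n_reps=n_reps,
        n_children=n_children,
        generating_value=slope,
    )


def recover_alpha_slope(
    slope: float = ALPHA_SLOPE,
    seed: int = 3,
    n_children: int = COHORT_SIZE,
    n_reps: int = 500,
    alpha_at_mean: float = 0.72,
    age_mean: float = 33.0,
    age_sd: float = 5.5,
    age_bounds: tuple[float, float] = (20.0, 48.0),
    mean_phased: float = 7.0,
) -> RecoveryResult:
    """Quasi-binomial identity-link recovery of the alpha-vs-age slope.

    Per replicate: per child, total phased DNMs n ~ Poisson(mean_phased) + 1
    and paternal count ~ Binomial(n, alpha_at_mean + slope * (age - mean));
    fit the paternal fraction on age and record the slope.
    """
    rng = np.random.default_rng(seed)
    estimates = np.empty(n_reps)
    for rep in range(n_reps):
        ages = _truncated_normal(rng, age_mean, age_sd, age_bounds, n_children)
        n = rng.poisson(mean_phased, n_children) + 1
        p = alpha_at_mean + slope * (ages - age_mean)
        pat = rng.binomial(n, p)
        fit = fit_alpha_model(pat, n - pat, ages)
        estimates[rep] = fit.coef("age").estimate
    return RecoveryResult(
        mean_estimate=float(estimates.mean()),
        mc_se=float(estimates.std(ddof=1) / np.sqrt(n_reps)),
        n_reps=n_reps,
        n_children=n_children,
        generating_value=slope,
    )


def age_test_null_rejection_rate(
    seed: int,
    n_reps: int = 1000,
    n_children: int = COHORT_SIZE,
    mean_count: float = 5.8,
    alpha: float = 0.05,
) -> float:
    """Type-I error of the identity-link age-effect Wald test under a flat
    (age-independent) Poisson null."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        ages = _truncated_normal(rng, 33.0, 5.5, (18.0, 50.0), n_children)
        counts = rng.poisson(mean_count, n_children)
        fit = fit_age_model(counts, ages)
        rejections += fit.coef("age").p_value < alpha
    return rejections / n_reps


def spearman_test_null_rejection_rate(
    seed: int,
    n_reps: int = 1000,
    n_children: int = COHORT_SIZE,
    beta: tuple[float, float, float] = (1.18, 0.14, 0.025),
) -> float:
    """Type-I error of the paired-children postzygotic test at f_z = 0."""
    rng = np.random.default_rng(seed)
    pat_ages = _truncated_normal(rng, 33.0, 5.5, (18.0, 50.0), n_children)
    mat_ages = _truncated_normal(rng, 31.0, 4.5, (18.0, 50.0), n_children)
    point = simulate_postzygotic(pat_ages, mat_ages, beta, f_z=0.0,
                                 n_reps=n_reps, seed=seed + 1)
    return point.power
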