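"""Simulation configuration for the synthetic quad-family cohort.

The defaults describe the cohort the analysis is designed for: 1,593 quad
families sequenced to ~35x, with paternally phased STR DNM counts rising
linearly at 0.14 mutations per year of paternal age and maternally phased
counts at 0.025 per year of maternal age.  Intercepts are back-derived from
the observed phased means (5.80 paternal DNMs at mean paternal age 33 and
1.43 maternal DNMs at mean maternal age 31).  Noise parameters (stutter,
allelic dropout) have no published point estimates and are set to values
typical of short-read STR genotyping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigurationError

AGE_SUPPORT = (15.0, 60.0)


@dataclass
class SimulationConfig:
    """Parameters for the synthetic panel, cohort, read, and candidate generators.

    All randomness is driven by ``seed``: identical configurations produce
    byte-identical outputs.
    """

    seed: int = 0
    n_families: int = 1593
    n_loci: int = 2000

    # panel composition
    period_range: tuple[int, int] = (2, 6)
    at_fraction: float = 0.5  # mixture weight of AT-only motifs
    ref_repeat_range: tuple[int, int] = (8, 15)
    hotspot_fraction: float = 0.05
    s_zero_fraction: float = 0.5  # fraction of loci with selection coefficient 0

    # sequencing model
    depth: float = 35.0  # mean passing spanning reads per locus per sample
    stutter_rate: float = 0.05  # probability a read's repeat count is perturbed
    stutter_geom_p: float = 0.8  # geometric parameter for perturbation size
    dropout_rate: float = 0.02  # per parental allele per locus, genotype call and read pool

    # germline mutation model (phased-count scale, per child)
    beta0_pat: float = 1.18  # paternal intercept, mutations per child
    beta1_pat: float = 0.14  # paternal slope, mutations per year of paternal age
    beta0_mat: float = 0.66  # maternal intercept
    beta1_mat: float = 0.025  # maternal slope, mutations per year of maternal age
    gc_rate_multiplier_pat: float = 1.5  # relative paternal mutability of GC-containing loci
    at_slope_multiplier_mat: float = 2.0  # relative maternal age-slope at AT-only loci
    f_z: float = 0.0  # postzygotic fraction of maternal-age-associated mutations
    mutation_size_weights: tuple[float, float, float] = (0.85, 0.10, 0.05)  # |i| = 1, 2, 3

    # parental age distributions (years)
    father_age_mean: float = 33.0
    father_age_sd: float = 5.5
    mother_age_mean: float = 31.0
    mother_age_sd: float = 4.5
    age_bounds: tuple[float, float] = (18.0, 50.0)
    sibling_gap: tuple[float, float] = (1.5, 4.0)  # uniform age gap between children

    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_loci < 1:
            raise ConfigurationError("n_loci must be >= 1")
        if self.n_families < 1:
            raise ConfigurationError("n_families must be >= 1")
        lo, hi = self.period_range
        if not (2 <= lo <= hi <= 6):
            raise ConfigurationError(f"period_range must lie within [2, 6], got {self.period_range}")
        for name in ("at_fraction", "stutter_rate", "stutter_geom_p", "dropout_rate",
                     "f_z", "hotspot_fraction", "s_zero_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be a probability in [0, 1], got {v}")
        if self.depth <= 0:
            raise ConfigurationError("depth must be positive")
        a, b = self.ref_repeat_range
        if not (2 <= a <= b):
            raise ConfigurationError("ref_repeat_range must satisfy 2 <= lo <= hi")
        if abs(sum(self.mutation_size_weights) - 1.0) > 1e-9:
            raise ConfigurationError("mutation_size_weights must sum to 1")
        lo_a, hi_a = self.age_bounds
        if not (AGE_SUPPORT[0] <= lo_a < hi_a <= AGE_SUPPORT[1]):
            raise ConfigurationError(f"age_bounds must lie within {AGE_SUPPORT}")
        # expected counts must stay nonnegative across the simulated age support
        for b0, b1, label in ((self.beta0_pat, self.beta1_pat, "paternal"),
                              (self.beta0_mat, self.beta1_mat, "maternal")):
            for age in self.age_bounds:
                if b0 + b1 * age < 0:
                    raise ConfigurationError(
                        f"{label} Poisson mean is negative at age {age}: "
                        f"{b0} + {b1} * {age} < 0")
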