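"""Paired-children test for a postzygotic maternal-age effect, with power.

If a fraction ``f_z`` of maternal-age-associated STR mutations arises after
zygote formation, those mutations land on a random parental haplotype, so
the count of *paternally* phased DNMs should covary with maternal age after
conditioning on paternal age.  The test pairs children born to fathers of
(nearly) the same age and asks, with a one-sided Spearman rank correlation,
whether the child of the older mother carries more paternally phased DNMs.

The power analysis simulates paternally derived DNM counts as
``Poisson(beta0_p + beta1_p * age_p + beta1_m * f_z * age_m)``, runs the
paired test per replicate, and reports the fraction of replicates rejecting
at the 5% level.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import scipy.stats

from .errors import ConfigurationError

PATERNAL_AGE_TOLERANCE_YEARS = 0.5  # "same age" tolerance on the data path


@dataclass(slots=True)
class PairedChildDiff:
    pair_id: int
    child_younger: int  # index of the child with the younger mother
    child_older: int
    delta_maternal_age: float  # older-mother child minus younger; >= 0
    delta_paternal_dnms: int | None = None


def pair_children(
    paternal_ages,
    maternal_ages,
    seed: int,
    mode: str = "tolerance",
    tolerance: float = PATERNAL_AGE_TOLERANCE_YEARS,
) -> list[PairedChildDiff]:
    """Randomly form maximal nonoverlapping pairs of paternal-age-matched
    children, each oriented from younger to older mother.

    ``mode="tolerance"`` matches fathers within ``tolerance`` years (the
    real-data convention); ``mode="rounded"`` matches identical integer-
    rounded paternal ages (the simulation convention).  No child appears in
    more than one pair; unmatched children are left out.
    """
    pat = np.asarray(paternal_ages, dtype=float)
    mat = np.asarray(maternal_ages, dtype=float)
    if pat.shape != mat.shape:
        raise ConfigurationError("paternal and maternal age arrays must align")
    rng = np.random.default_rng(seed)
    order = rng.permutation(pat.size)
    pairs: list[PairedChildDiff] = []
    if mode == "rounded":
        buckets: dict[int, list[int]] = defaultdict(list)
        for idx in order:
            buckets[int(round(pat[idx]))].append(int(idx))
        mates = itertools.chain.from_iterable(
            zip(b[0::2], b[1::2]) for b in buckets.values())
    elif mode == "tolerance":
        unpaired: list[int] = []
        collected = []
        for idx in order:
            idx = int(idx)
            for k, other in enumerate(unpaired):
                if abs(pat[idx] - pat[other]) <= tolerance:
                    collected.append((other, idx))
                    unpaired.pop(k)
                    break
            else:
                unpaired.append(idx)
        mates = collected
    else:
        raise ConfigurationError(f"unknown pairing mode: {mode}")
    for pair_id, (i, j) in enumerate(mates):
        if mat[i] <= mat[j]:
            younger, older = i, j
        else:
            younger, older = j, i
        pairs.append(PairedChildDiff(
            pair_id=pair_id,
            child_younger=younger,
            child_older=older,
            delta_maternal_age=float(mat[older] - mat[younger]),
        ))
    return pairs


def attach_counts(pairs: list[PairedChildDiff], paternal_dnms) -> list[PairedChildDiff]:
    counts = np.asarray(paternal_dnms)
    for p in pairs:
        p.delta_paternal_dnms = int(counts[p.child_older] - counts[p.child_younger])
    return pairs


def paired_spearman_test(pairs: list[PairedChildDiff],
                         exact: bool = False) -> tuple[float, float]:
    """One-sided (positive) Spearman test of Delta maternal age vs Delta
    paternal DNMs over the pairs.

    Ties get average ranks with the usual asymptotic p-value; with ``exact``
    and at most 7 pairs the p is computed by full permutation enumeration,
    otherwise by 10,000 random permutations.
    """
    if len(pairs) < 3:
        raise ConfigurationError("need >= 3 pairs")
    dx = np.array([p.delta_maternal_age for p in pairs], dtype=float)
    dy = np.array([p.delta_paternal_dnms for p in pairs], dtype=float)
    if np.all(dx == dx[0]) or np.all(dy == dy[0]):
        return 0.0, 1.0  # degenerate: no rank variation
    if not exact:
        res = scipy.stats.spearmanr(dx, dy, alternative="greater")
        return float(res.statistic), float(res.pvalue)
    rho_obs = float(scipy.stats.spearmanr(dx, dy).statistic)
    n = len(dx)
    if n <= 7:
        perms = itertools.permutations(range(n))
        rhos = [float(scipy.stats.spearmanr(dx, dy[list(p)]).statistic) for p in perms]
    else:
        rng = np.random.default_rng(0)
        rhos = [float(scipy.stats.spearmanr(dx, rng.permutation(dy)).statistic)
                for _ in range(10_000)]
    rhos = np.asarray(rhos)
    p = float((np.sum(rhos >= rho_obs - 1e-12) + (0 if n <= 7 else 1))
              / (len(rhos) + (0 if n <= 7 else 1)))
    return rho_obs, p


@dataclass
class PowerPoint:
    f_z: float
    power: float
    n_replicates: int
    seed: int


def simulate_postzygotic(
    paternal_ages,
    maternal_ages,
    beta: tuple[float, float, float],
    f_z: float,
    n_reps: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> PowerPoint:
    """Power of the paired-children test at one postzygotic fraction.

    ``beta`` is (beta0_p, beta1_p, beta1_m).  Per replicate, paternally
    derived DNM counts are drawn from the stated Poisson, children are
    paired on rounded paternal age, and the one-sided Spearman p is
    recorded; power is the fraction of replicates with p < ``alpha``.
    """
    pat = np.asarray(paternal_ages, dtype=float)
    mat = np.asarray(maternal_ages, dtype=float)
    b0p, b1p, b1m = beta
    lam = b0p + b1p * pat + b1m * f_z * mat
    if (lam <= 0).any():
        raise ConfigurationError("Poisson mean must be positive at every age")
    rng = np.random.default_rng(seed)
    rejections = 0
    n_tested = 0
    for rep in range(n_reps):
        counts = rng.poisson(lam)
        pairs = pair_children(pat, mat, seed=int(rng.integers(2 ** 31)), mode="rounded")
        if len(pairs) < 3:
            continue
        attach_counts(pairs, counts)
        _, p = paired_spearman_test(pairs)
        n_tested += 1
        if p < alpha:
            rejections += 1
    if n_tested == 0:
        raise ConfigurationError("no replicate produced >= 3 pairs")
    return PowerPoint(f_z=f_z, power=rejections / n_tested,
                      n_replicates=n_tested, seed=seed)


def power_curve(paternal_ages, maternal_ages, beta, f_z_grid,
                n_reps: int = 1000, seed: int = 0) -> list[PowerPoint]:
    """Power at each value of the postzygotic fraction grid."""
    return [
        simulate_postzygotic(paternal_ages, maternal_ages, beta, fz,
                             n_reps=n_reps, seed=seed + k)
        for k, fz in enumerate(f_z_grid)
    ]
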