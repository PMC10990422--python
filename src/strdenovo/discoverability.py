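"""Discoverability-aware mutation-rate denominators.

At noisy or allele-diverse sites only some mutation sizes could ever pass
the read-based filter.  For a mutation of size ``i`` repeat units, a site is
fully discoverable for a couple iff for every called parental allele ``a``
no parental read supports an allele of size ``a - i`` or ``a + i``.  The
per-child mutation rate sums, over sizes i in {1, 2, 3}, the count of
validated DNMs of size i at discoverable sites divided by the number of
sites discoverable for size i.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, StrDenovoError
from .validation import SampleAlleleSupport

RATE_SIZES = (1, 2, 3)


@dataclass
class DiscoverabilityRecord:
    family_id: str
    locus_id: str
    discoverable: dict[int, bool]  # size i -> fully discoverable


@dataclass
class RateEstimate:
    child_id: str
    numerator: dict[int, int]
    denominator: dict[int, int]

    @property
    def rate(self) -> float:
        total = 0.0
        for i, num in self.numerator.items():
            den = self.denominator.get(i, 0)
            if num and not den:
                raise StrDenovoError(
                    f"size-{i} mutations observed with zero discoverable sites")
            if den:
                total += num / den
        return total


def is_discoverable(
    father_support: SampleAlleleSupport,
    mother_support: SampleAlleleSupport,
    parental_alleles: set[int],
    i: int,
) -> bool:
    """True iff no parental read supports ``a + i`` or ``a - i`` for any
    called parental allele ``a``."""
    if i < 1:
        raise ConfigurationError("mutation size i must be >= 1")
    if not parental_alleles:
        raise ConfigurationError("parental allele set A must be nonempty")
    for a in parental_alleles:
        for target in (a - i, a + i):
            if father_support.count(target) >= 1 or mother_support.count(target) >= 1:
                return False
    return True


def discoverability_record(
    family_id: str,
    locus_id: str,
    father_support: SampleAlleleSupport,
    mother_support: SampleAlleleSupport,
    parental_alleles: set[int],
    sizes: tuple[int, ...] = RATE_SIZES,
) -> DiscoverabilityRecord:
    return DiscoverabilityRecord(
        family_id=family_id,
        locus_id=locus_id,
        discoverable={i: is_discoverable(father_support, mother_support,
                                         parental_alleles, i)
                      for i in sizes},
    )


def mutation_rate(
    validated_dnms: pd.DataFrame,
    records: list[DiscoverabilityRecord],
    child_id: str,
    sizes: tuple[int, ...] = RATE_SIZES,
) -> RateEstimate:
    """Size-stratified rate for one child.

    ``validated_dnms`` needs columns ``child``, ``locus_id``, ``size``
    (absolute repeat units).  DNMs of size i at loci not discoverable for i,
    and sizes outside ``sizes``, are excluded from the numerator.
    """
    disc = {(r.locus_id, i): ok for r in records for i, ok in r.discoverable.items()}
    numerator = {i: 0 for i in sizes}
    denominator = {i: sum(1 for r in records if r.discoverable.get(i, False))
                   for i in sizes}
    sub = validated_dnms[validated_dnms["child"] == child_id]
    for _, row in sub.iterrows():
        i = abs(int(row["size"]))
        if i in numerator and disc.get((row["locus_id"], i), False):
            numerator[i] += 1
    return RateEstimate(child_id=child_id, numerator=numerator, denominator=denominator)


def discoverable_rate_regression(estimates: list[RateEstimate],
                                 father_age: dict[str, float],
                                 mother_age: dict[str, float]):
    """Poisson log-link GLM of fully discoverable DNM counts on parental
    ages, with an offset of log total discoverable sites.

    Children with a zero total denominator are dropped (counted in the
    result's ``n_dropped``).  Returns an :class:`~strdenovo.agemodels.AgeModelFit`.
    """
    from .agemodels import fit_poisson_glm  # deferred: avoids import cycle

    rows = []
    n_dropped = 0
    for est in estimates:
        denom = sum(est.denominator.values())
        if denom <= 0:
            n_dropped += 1
            continue
        rows.append((sum(est.numerator.values()), father_age[est.child_id],
                     mother_age[est.child_id], denom))
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} children with zero discoverable sites")
    if len(rows) < 2:
        raise StrDenovoError("need >= 2 children with nonzero denominators")
    arr = np.asarray(rows, dtype=float)
    fit = fit_poisson_glm(
        counts=arr[:, 0],
        covariates={"father_age": arr[:, 1], "mother_age": arr[:, 2]},
        link="log",
        offset=np.log(arr[:, 3]),
        formula="discoverable_dnms ~ father_age + mother_age + offset(log(discoverable_sites))",
    )
    fit.n_dropped = n_dropped
    return fit


def records_to_frame(records: list[DiscoverabilityRecord]) -> pd.DataFrame:
    rows = [{"family": r.family_id, "locus_id": r.locus_id,
             **{f"d{i}": int(ok) for i, ok in r.discoverable.items()}}
            for r in records]
    return pd.DataFrame(rows)
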