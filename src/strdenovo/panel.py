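"""STR locus panel: the genotyped set of repeat loci and its simulation.

Coordinates are 0-based half-open throughout: a locus occupies
``[start, start + ref_repeat_count * period)`` on its chromosome, with
exactly 10 bp of reference flank recorded on each side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import SimulationConfig
from .errors import ConfigurationError

_BASES = "ACGT"
_FLANK_LEN = 10
_LOCUS_SPACING = 1000  # bp between simulated locus starts; keeps windows disjoint


@dataclass
class STRLocus:
    """A short tandem repeat locus.

    ``motif`` is the repeat unit as it appears on the reference strand at the
    locus; ``ref_repeat_count`` is the number of copies in the reference.
    ``s_coefficient`` is a per-locus selection coefficient (fitness cost per
    repeat unit of deviation from the major allele); ``None`` when not
    inferred.  Period-1 loci are homopolymers and excluded from default
    analyses.
    """

    locus_id: str
    chrom: str
    start: int
    period: int
    motif: str
    ref_repeat_count: int
    flank_left: str
    flank_right: str
    s_coefficient: float | None = None
    hotspot: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.period <= 6:
            raise ConfigurationError(f"period must be in [1, 6], got {self.period}")
        if len(self.motif) != self.period:
            raise ConfigurationError("motif length must equal period")
        if len(self.flank_left) != _FLANK_LEN or len(self.flank_right) != _FLANK_LEN:
            raise ConfigurationError("flanks must be exactly 10 bp")
        if self.s_coefficient is not None and self.s_coefficient < 0:
            raise ConfigurationError("s_coefficient must be nonnegative")

    @property
    def end(self) -> int:
        return self.start + self.ref_repeat_count * self.period

    @property
    def is_homopolymer(self) -> bool:
        return self.period == 1 or len(set(self.motif)) == 1


def _is_primitive(motif: str) -> bool:
    """True if the motif is not a repetition of a shorter unit."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def _random_motif(rng: np.random.Generator, period: int, at_only: bool) -> str:
    alphabet = "AT" if at_only else _BASES
    while True:
        motif = "".join(rng.choice(list(alphabet), size=period))
        if len(set(motif)) == 1 or not _is_primitive(motif):
            continue
        if not at_only and not (set(motif) & {"G", "C"}):
            continue
        return motif


def _random_flanks(rng: np.random.Generator, motif: str) -> tuple[str, str]:
    """Draw 10-bp flanks free of embedded motif copies.

    The left flank must not contain a motif occurrence that would shift the
    anchor of the repeat run (the allele extractor scans for the first motif
    copy from 10 bp upstream), and the right flank must not extend the run.
    """
    period = len(motif)
    while True:
        left = "".join(rng.choice(list(_BASES), size=_FLANK_LEN))
        if (left + motif).find(motif) == _FLANK_LEN:
            break
    while True:
        right = "".join(rng.choice(list(_BASES), size=_FLANK_LEN))
        if motif not in right and not right.startswith(motif[: period]):
            break
    return left, right


def simulate_panel(config: SimulationConfig) -> list[STRLocus]:
    """Generate a deterministic panel of non-homopolymer STR loci.

    Motifs mix AT-only and GC-containing units across the configured period
    range; selection coefficients are a zero-inflated exponential (point mass
    at s = 0 for neutral loci) and a ``hotspot_fraction`` of loci is flagged
    as lying in maternal-age hotspot intervals.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(0,)))
    lo, hi = config.period_range
    loci: list[STRLocus] = []
    pos = _LOCUS_SPACING
    for idx in range(config.n_loci):
        period = int(rng.integers(lo, hi + 1))
        at_only = bool(rng.random() < config.at_fraction)
        motif = _random_motif(rng, period, at_only)
        flank_left, flank_right = _random_flanks(rng, motif)
        ref_count = int(rng.integers(config.ref_repeat_range[0], config.ref_repeat_range[1] + 1))
        if rng.random() < config.s_zero_fraction:
            s = 0.0
        else:
            s = round(float(rng.exponential(0.05)), 6)
        loci.append(STRLocus(
            locus_id=f"L{idx:06d}",
            chrom="chr1",
            start=pos,
            period=period,
            motif=motif,
            ref_repeat_count=ref_count,
            flank_left=flank_left,
            flank_right=flank_right,
            s_coefficient=s,
            hotspot=bool(rng.random() < config.hotspot_fraction),
        ))
        pos += _LOCUS_SPACING
    return loci
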