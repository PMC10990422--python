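"""Compositional annotation of STR loci.

Nucleotide-content class (AT-only vs GC-containing), canonical motif under
rotation and reverse complementation, compositional proxies for H-DNA and
Z-DNA propensity, hotspot-interval membership, and selection-coefficient
bins for DFE analyses.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}

S_EXCLUSION_THRESHOLD = 0.3  # posterior s above this indicates poor model fit
CONSTRAINED_PERCENTILE = 90.0


class GCClass(enum.Enum):
    AT_ONLY = "AT_only"
    GC_CONTAINING = "GC_containing"


class SBin(enum.Enum):
    NEUTRAL = "neutral"
    INTERMEDIATE = "intermediate"
    CONSTRAINED = "constrained"
    EXCLUDED = "excluded"


@dataclass
class LocusAnnotation:
    locus_id: str
    gc_class: GCClass
    canonical_motif: str
    hdna: bool
    zdna: bool
    hotspot: bool
    s_bin: SBin


def classify_gc(motif: str) -> GCClass:
    """AT-only iff every base is A or T."""
    if len(motif) < 2:
        raise ValueError("motif must have length >= 2")
    return GCClass.AT_ONLY if set(motif) <= {"A", "T"} else GCClass.GC_CONTAINING


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_motif(motif: str) -> str:
    """Lexicographic minimum over all rotations of the motif and of its
    reverse complement (so AC, CA, GT, and TG collapse to AC)."""
    rc = reverse_complement(motif)
    candidates = [m[i:] + m[:i] for m in (motif, rc) for i in range(len(m))]
    return min(candidates)


def classify_nonb(motif: str, require_g_on_reference: bool = False) -> tuple[bool, bool]:
    """Compositional (hdna, zdna) propensity flags.

    H-DNA: the motif is polypurine or polypyrimidine.  Z-DNA: strict
    purine-pyrimidine alternation along the repeated tract (evaluated on the
    doubled motif, so the alternation must continue across copy boundaries)
    with a G on one strand; a C on the reference strand puts a G on the
    other, unless ``require_g_on_reference`` demands a literal G.
    """
    bases = set(motif)
    hdna = bases <= _PURINES or bases <= _PYRIMIDINES
    doubled = motif + motif
    alternating = all(
        (doubled[k] in _PURINES) != (doubled[k + 1] in _PURINES)
        for k in range(len(doubled) - 1)
    )
    has_g = "G" in bases if require_g_on_reference else bool(bases & {"G", "C"})
    return hdna, alternating and has_g


def bin_selection(s: float | None, percentile_90_threshold: float) -> SBin:
    """Bin a selection coefficient for DFE contrasts.

    ``excluded`` above the model-fit cutoff (s > 0.3); ``neutral`` at s = 0;
    ``constrained`` at or above the 90th-percentile threshold of retained s
    values; otherwise ``intermediate``.
    """
    if s is None:
        return SBin.EXCLUDED
    if s > S_EXCLUSION_THRESHOLD:
        return SBin.EXCLUDED
    if s == 0:
        return SBin.NEUTRAL
    if s >= percentile_90_threshold:
        return SBin.CONSTRAINED
    return SBin.INTERMEDIATE


def constrained_threshold(s_values) -> float:
    """90th percentile of s values after the s > 0.3 exclusion."""
    s = np.asarray([v for v in s_values if v is not None and v <= S_EXCLUSION_THRESHOLD],
                   dtype=float)
    if s.size == 0:
        return float("inf")
    return float(np.percentile(s, CONSTRAINED_PERCENTILE))


def in_hotspot(locus_start: int, intervals: list[tuple[int, int]],
               chrom: str | None = None,
               interval_chroms: list[str] | None = None) -> bool:
    """True iff the locus start lies in any 0-based half-open interval."""
    for k, (lo, hi) in enumerate(intervals):
        if interval_chroms is not None and chrom is not None:
            if interval_chroms[k] != chrom:
                continue
        if lo <= locus_start < hi:
            return True
    return False


def annotate_panel(panel, hotspot_intervals: list[tuple[int, int]] | None = None) -> list[LocusAnnotation]:
    """Annotate every locus; the constrained-s threshold is computed on the
    panel itself after the s > 0.3 exclusion."""
    threshold = constrained_threshold([loc.s_coefficient for loc in panel])
    out = []
    for loc in panel:
        hdna, zdna = classify_nonb(loc.motif)
        if hotspot_intervals is None:
            hotspot = loc.hotspot
        else:
            hotspot = in_hotspot(loc.start, hotspot_intervals)
        out.append(LocusAnnotation(
            locus_id=loc.locus_id,
            gc_class=classify_gc(loc.motif),
            canonical_motif=canonical_motif(loc.motif),
            hdna=hdna,
            zdna=zdna,
            hotspot=hotspot,
            s_bin=bin_selection(loc.s_coefficient, threshold),
        ))
    return out
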