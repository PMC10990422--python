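"""Read-based validation of candidate STR de novo mutations.

The filter reimplements a strict, realignment-free approach to allelic
dropout: select primary, high-MAPQ reads that fully span the repeat plus
10 bp of flank on each side (excluding soft-clipped bases), extract a
per-read allele length by counting uninterrupted motif copies anchored at
the first motif occurrence, and classify each candidate against the read
support in child and parents.

Classification precedence: a candidate with zero child reads supporting the
de novo allele is a false positive; otherwise one or more supporting reads
in either parent makes it inherited; otherwise it is a true de novo event.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field

from .errors import UndefinedRateError
from .panel import STRLocus
from .reads import ReadRecord

FLANK = 10
DEFAULT_MAPQ_MIN = 60
DEFAULT_FLANK_MISMATCH_MAX = 1


class ReadOutcome(enum.Enum):
    ALLELE = "allele"
    REJECTED_NONSPANNING = "rejected_nonspanning"
    REJECTED_MAPQ = "rejected_mapq"
    REJECTED_NONPRIMARY = "rejected_nonprimary"
    REJECTED_INTERRUPTED = "rejected_interrupted"
    REJECTED_FLANK_MISMATCH = "rejected_flank_mismatch"


@dataclass(slots=True)
class ReadAlleleCall:
    read_id: str
    outcome: ReadOutcome
    length_ru: int | None = None


class Verdict(enum.Enum):
    TRUE_DE_NOVO = "true_de_novo"
    INHERITED = "inherited"
    FALSE_POSITIVE = "false_positive"


@dataclass
class SampleAlleleSupport:
    """Histogram of passing-read allele lengths for one sample at one locus."""

    sample_id: str
    locus_id: str
    support: dict[int, int] = field(default_factory=dict)

    def count(self, allele_ru: int) -> int:
        return self.support.get(allele_ru, 0)

    @property
    def total(self) -> int:
        return sum(self.support.values())


def select_reads(
    reads: list[ReadRecord],
    locus: STRLocus,
    longest_family_allele_ru: int,
    mapq_min: int = DEFAULT_MAPQ_MIN,
) -> list[ReadRecord]:
    """Keep primary reads with MAPQ >= ``mapq_min`` whose aligned span
    (soft clips excluded) covers the repeat window plus 10 bp flanks.

    The window is ``[locus.start - 10, locus.start +
    longest_family_allele_ru * period + 10)``, sized by the longest allele
    observed anywhere in the family so that a read supporting any family
    allele could in principle be counted.  Order is preserved.
    """
    if longest_family_allele_ru < 1:
        raise ValueError("longest_family_allele_ru must be >= 1")
    win_lo = locus.start - FLANK
    win_hi = locus.start + longest_family_allele_ru * locus.period + FLANK
    return [r for r in reads
            if r.is_primary
            and r.mapq >= mapq_min
            and r.aligned_start <= win_lo
            and r.aligned_end >= win_hi]


def extract_allele_length(
    read: ReadRecord,
    locus: STRLocus,
    flank_mismatch_max: int = DEFAULT_FLANK_MISMATCH_MAX,
) -> ReadAlleleCall:
    """Extract the repeat length supported by one spanning read.

    Scans the query sequence from the position aligned at
    ``locus.start - 10``, anchors at the first exact occurrence of the
    motif, counts maximal consecutive exact copies, and compares the 10
    bases on each side of the run to the reference flanks.  The call is an
    allele iff the run is uninterrupted and the total number of flank
    mismatches is at most ``flank_mismatch_max``; an interruption shifts
    the downstream flank window and is caught as flank mismatch.
    """
    seq = read.seq
    motif = locus.motif
    period = locus.period
    q0 = read.query_index(locus.start - FLANK)
    if q0 < 0:
        return ReadAlleleCall(read.read_id, ReadOutcome.REJECTED_NONSPANNING)
    idx = seq.find(motif, q0)
    if idx < 0:
        return ReadAlleleCall(read.read_id, ReadOutcome.REJECTED_INTERRUPTED)
    n = 0
    j = idx
    while seq.startswith(motif, j):
        n += 1
        j += period
    if idx < FLANK or j + FLANK > len(seq):
        return ReadAlleleCall(read.read_id, ReadOutcome.REJECTED_NONSPANNING)
    mismatches = sum(a != b for a, b in zip(seq[idx - FLANK:idx], locus.flank_left))
    if mismatches <= flank_mismatch_max:
        mismatches += sum(a != b for a, b in zip(seq[j:j + FLANK], locus.flank_right))
    if mismatches > flank_mismatch_max:
        return ReadAlleleCall(read.read_id, ReadOutcome.REJECTED_FLANK_MISMATCH)
    return ReadAlleleCall(read.read_id, ReadOutcome.ALLELE, length_ru=n)


def build_support(
    reads: list[ReadRecord],
    locus: STRLocus,
    longest_family_allele_ru: int,
    sample_id: str | None = None,
    mapq_min: int = DEFAULT_MAPQ_MIN,
    flank_mismatch_max: int = DEFAULT_FLANK_MISMATCH_MAX,
) -> SampleAlleleSupport:
    """Histogram of extracted allele lengths from passing reads of one sample."""
    if sample_id is None:
        sample_id = reads[0].sample if reads else ""
    passing = select_reads(reads, locus, longest_family_allele_ru, mapq_min=mapq_min)
    counts: Counter[int] = Counter()
    for read in passing:
        call = extract_allele_length(read, locus, flank_mismatch_max=flank_mismatch_max)
        if call.outcome is ReadOutcome.ALLELE:
            counts[call.length_ru] += 1
    return SampleAlleleSupport(sample_id=sample_id, locus_id=locus.locus_id,
                               support=dict(counts))


def classify_dnm(
    denovo_ru: int,
    child_support: SampleAlleleSupport,
    father_support: SampleAlleleSupport,
    mother_support: SampleAlleleSupport,
) -> Verdict:
    """Verdict for one candidate, in the filter's fixed precedence order."""
    if child_support.count(denovo_ru) == 0:
        return Verdict.FALSE_POSITIVE
    if father_support.count(denovo_ru) >= 1 or mother_support.count(denovo_ru) >= 1:
        return Verdict.INHERITED
    return Verdict.TRUE_DE_NOVO


@dataclass
class PositiveCoupleResult:
    """Sensitivity probe: how often would the filter wrongly call a true DNM
    inherited, judged from couples with the same genotypes whose children do
    not carry the putative de novo allele."""

    n_couples: int
    n_with_support: int

    @property
    def false_negative_rate(self) -> float:
        if self.n_couples == 0:
            raise UndefinedRateError("no positive couples: rate undefined")
        return self.n_with_support / self.n_couples


def _couple_key(gt_a, gt_b) -> frozenset:
    """Sex-nonspecific multiset of the two parental diploid genotypes."""
    return frozenset(Counter([tuple(sorted(map(int, gt_a))),
                              tuple(sorted(map(int, gt_b)))]).items())


def estimate_filter_false_negative_rate(
    target_parent_genotypes: tuple,
    denovo_ru: int,
    couples: list[dict],
) -> PositiveCoupleResult:
    """Estimate the probability that a true de novo allele would be filtered
    as inherited, from "positive couples".

    ``couples`` holds, per candidate couple, the called parental genotypes
    (``father_gt``, ``mother_gt``), the alleles carried by their children
    (``child_alleles``), and the parental read support at the locus
    (``father_support``, ``mother_support``).  A couple is positive when its
    genotype multiset matches the target couple's (sex nonspecific) and no
    child carries the putative de novo allele; the rate is the fraction of
    positive couples with >= 1 passing parental read supporting that allele.
    """
    target_key = _couple_key(*target_parent_genotypes)
    n_pos = 0
    n_support = 0
    for couple in couples:
        if _couple_key(couple["father_gt"], couple["mother_gt"]) != target_key:
            continue
        if denovo_ru in set(couple.get("child_alleles", ())):
            continue
        n_pos += 1
        fsup: SampleAlleleSupport = couple["father_support"]
        msup: SampleAlleleSupport = couple["mother_support"]
        if fsup.count(denovo_ru) >= 1 or msup.count(denovo_ru) >= 1:
            n_support += 1
    return PositiveCoupleResult(n_couples=n_pos, n_with_support=n_support)


@dataclass
class FilterMetrics:
    accuracy: float
    sensitivity: float
    specificity: float
    n_candidates: int
    confusion: dict[tuple[str, str], int]


def evaluate_filter(verdicts: list[Verdict], truths: list[str]) -> FilterMetrics:
    """Confusion-matrix metrics with true de novo as the positive class.

    ``truths`` holds per-candidate ground truth labels (``true_de_novo`` for
    injected mutations, anything else negative).  Predicted positive means a
    ``TRUE_DE_NOVO`` verdict.
    """
    if not verdicts:
        raise UndefinedRateError("no candidates: metrics undefined")
    if len(verdicts) != len(truths):
        raise ValueError("verdicts and truths must align")
    tp = fn = fp = tn = 0
    confusion: Counter = Counter()
    for v, t in zip(verdicts, truths):
        pred_pos = v is Verdict.TRUE_DE_NOVO
        true_pos = t == "true_de_novo"
        confusion[(t, v.value)] += 1
        if true_pos and pred_pos:
            tp += 1
        elif true_pos:
            fn += 1
        elif pred_pos:
            fp += 1
        else:
            tn += 1
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    acc = (tp + tn) / len(verdicts)
    return FilterMetrics(accuracy=acc, sensitivity=sens, specificity=spec,
                         n_candidates=len(verdicts), confusion=dict(confusion))
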