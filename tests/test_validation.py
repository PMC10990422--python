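"""Read selection, allele extraction, candidate classification, and the
positive-couples sensitivity probe."""

import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strdenovo.errors import UndefinedRateError
from strdenovo.panel import STRLocus
from strdenovo.validation import (ReadOutcome, Verdict, build_support,
                                  classify_dnm, estimate_filter_false_negative_rate,
                                  evaluate_filter, extract_allele_length,
                                  select_reads)
from conftest import make_read, support_of


def regex_allele_oracle(seq, locus, q0=0, flank_mismatch_max=1):
    """Independent reference implementation of allele extraction: regex for
    the first maximal motif run at or after q0, then literal flank checks."""
    m = re.compile(f"(?:{re.escape(locus.motif)})+").search(seq, q0)
    if m is None:
        return None  # no motif occurrence
    start, end = m.start(), m.end()
    n = (end - start) // locus.period
    if start < 10 or end + 10 > len(seq):
        return None
    mm = sum(a != b for a, b in zip(seq[start - 10:start], locus.flank_left))
    mm += sum(a != b for a, b in zip(seq[end:end + 10], locus.flank_right))
    if mm > flank_mismatch_max:
        return None
    return n


class TestSelectReads:
    def test_mapq_threshold(self, locus_at):
        reads = [make_read(locus_at, 10, mapq=59), make_read(locus_at, 10, mapq=60)]
        kept = select_reads(reads, locus_at, 10)
        assert kept == [reads[1]]

    def test_secondary_alignment_excluded(self, locus_at):
        reads = [make_read(locus_at, 10, primary=False)]
        assert select_reads(reads, locus_at, 10) == []

    def test_softclip_excluded_from_span(self, locus_at):
        """A read whose soft-clipped tail is needed to reach the window edge
        does not span: aligned span arithmetic excludes clipped bases."""
        full = make_read(locus_at, 10)
        # clip the last 3 bases: aligned end retreats inside the window
        clipped = make_read(locus_at, 10, softclip_right=3)
        win_hi = locus_at.start + 10 * locus_at.period + 10
        assert full.aligned_end == win_hi
        assert clipped.aligned_end == win_hi - 3
        assert select_reads([full, clipped], locus_at, 10) == [full]

    def test_window_scales_with_longest_family_allele(self, locus_at):
        read = make_read(locus_at, 10)
        assert select_reads([read], locus_at, 10) == [read]
        # a family allele of 12 repeat units widens the window past this read
        assert select_reads([read], locus_at, 12) == []

    def test_empty_input(self, locus_at):
        assert select_reads([], locus_at, 10) == []

    def test_invalid_longest_allele(self, locus_at):
        with pytest.raises(ValueError):
            select_reads([], locus_at, 0)


class TestExtractAllele:
    def test_exact_reference_read(self, locus_at):
        call = extract_allele_length(make_read(locus_at, 10), locus_at)
        assert call.outcome is ReadOutcome.ALLELE
        assert call.length_ru == 10

    def test_one_flank_mismatch_tolerated(self, locus_at):
        fr = list(locus_at.flank_right)
        fr[4] = "A" if fr[4] != "A" else "T"
        seq = locus_at.flank_left + locus_at.motif * 12 + "".join(fr)
        call = extract_allele_length(make_read(locus_at, 12, seq=seq), locus_at)
        assert call.outcome is ReadOutcome.ALLELE
        assert call.length_ru == 12

    def test_two_flank_mismatches_rejected(self, locus_at):
        fl = list(locus_at.flank_left)
        fr = list(locus_at.flank_right)
        fl[0] = "A"
        fr[0] = "A"
        seq = "".join(fl) + locus_at.motif * 10 + "".join(fr)
        call = extract_allele_length(make_read(locus_at, 10, seq=seq), locus_at)
        assert call.outcome is ReadOutcome.REJECTED_FLANK_MISMATCH

    def test_interrupted_repeat_rejected(self, locus_at):
        """An interruption truncates the run; the shifted right-flank window
        then mismatches and the read is discarded."""
        seq = locus_at.flank_left + "ATATACATAT" + locus_at.flank_right
        call = extract_allele_length(make_read(locus_at, 0, seq=seq), locus_at)
        assert call.outcome in (ReadOutcome.REJECTED_FLANK_MISMATCH,
                                ReadOutcome.REJECTED_INTERRUPTED)
        oracle = regex_allele_oracle(seq, locus_at)
        assert oracle is None

    def test_motif_absent(self, locus_at):
        seq = "G" * 40
        call = extract_allele_length(make_read(locus_at, 0, seq=seq), locus_at)
        assert call.outcome is ReadOutcome.REJECTED_INTERRUPTED

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.data())
    def test_agrees_with_regex_oracle(self, data):
        """Property: extraction equals a brute-force regex repeat counter on
        randomly constructed reads (motifs, mutations, and truncations)."""
        rng_bases = "ACGT"
        period = data.draw(st.integers(2, 4))
        motif = "".join(data.draw(st.sampled_from(rng_bases)) for _ in range(period))
        if len(set(motif)) == 1:
            motif = motif[:-1] + ("A" if motif[0] != "A" else "C")
        flank_len = 10
        fl = "".join(data.draw(st.sampled_from(rng_bases)) for _ in range(flank_len))
        fr = "".join(data.draw(st.sampled_from(rng_bases)) for _ in range(flank_len))
        n = data.draw(st.integers(1, 15))
        seq = list(fl + motif * n + fr)
        # random point mutations anywhere in the read
        for _ in range(data.draw(st.integers(0, 3))):
            k = data.draw(st.integers(0, len(seq) - 1))
            seq[k] = data.draw(st.sampled_from(rng_bases))
        seq = "".join(seq)
        locus = STRLocus(locus_id="LX", chrom="chr1", start=1000, period=period,
                         motif=motif, ref_repeat_count=max(n, 1),
                         flank_left=fl, flank_right=fr)
        call = extract_allele_length(make_read(locus, n, seq=seq), locus)
        expected = regex_allele_oracle(seq, locus)
        if expected is None:
            assert call.outcome is not ReadOutcome.ALLELE
        else:
            assert call.outcome is ReadOutcome.ALLELE
            assert call.length_ru == expected


class TestBuildSupport:
    def test_empty(self, locus_at):
        sup = build_support([], locus_at, 10, sample_id="S")
        assert sup.support == {}
        assert sup.total == 0

    def test_histogram_counts_only_allele_calls(self, locus_at):
        reads = [make_read(locus_at, 10, read_id=f"r{k}") for k in range(3)]
        reads.append(make_read(locus_at, 10, mapq=10, read_id="bad"))
        sup = build_support(reads, locus_at, 10, sample_id="S")
        assert sup.support == {10: 3}


class TestClassify:
    def test_true_de_novo(self):
        v = classify_dnm(11, support_of({11: 3}), support_of({10: 20}),
                         support_of({10: 18}))
        assert v is Verdict.TRUE_DE_NOVO

    def test_single_parental_read_inherits(self):
        v = classify_dnm(11, support_of({11: 3}), support_of({10: 19, 11: 1}),
                         support_of({10: 18}))
        assert v is Verdict.INHERITED

    def test_no_child_support_false_positive(self):
        """Zero child reads takes precedence even over parental support."""
        v = classify_dnm(11, support_of({10: 30}), support_of({11: 5}),
                         support_of({}))
        assert v is Verdict.FALSE_POSITIVE

    def test_partition_and_monotonicity_exhaustive(self):
        """Over all small supports on alleles 8-14: every candidate gets
        exactly one verdict, and adding one parental read of the de novo
        allele can only move a verdict from true_de_novo to inherited."""
        alleles = range(8, 15)
        for denovo in alleles:
            for child_has in (0, 1, 3):
                child = support_of({denovo: child_has} if child_has else {10: 5})
                for f_near in (denovo - 1, denovo, denovo + 1):
                    for f_n in (0, 1, 2):
                        for m_n in (0, 1):
                            father = support_of({f_near: f_n} if f_n else {})
                            mother = support_of({denovo: m_n} if m_n else {})
                            v = classify_dnm(denovo, child, father, mother)
                            assert v in (Verdict.TRUE_DE_NOVO, Verdict.INHERITED,
                                         Verdict.FALSE_POSITIVE)
                            # monotonicity: add one paternal read at denovo
                            father2 = support_of(
                                {**father.support,
                                 denovo: father.count(denovo) + 1})
                            v2 = classify_dnm(denovo, child, father2, mother)
                            if v is Verdict.TRUE_DE_NOVO:
                                assert v2 is Verdict.INHERITED
                            else:
                                assert v2 is v


class TestPositiveCouples:
    def _couple(self, fgt, mgt, children, fsup, msup):
        return {"father_gt": fgt, "mother_gt": mgt, "child_alleles": children,
                "father_support": support_of(fsup),
                "mother_support": support_of(msup)}

    def test_fraction_counts_supporting_couples(self):
        couples = [
            self._couple((10, 10), (10, 10), (10,), {10: 30}, {10: 28}),
            self._couple((10, 10), (10, 10), (10,), {10: 25, 11: 2}, {10: 30}),
            self._couple((10, 10), (10, 10), (10,), {10: 30}, {10: 30, 11: 1}),
            self._couple((10, 10), (10, 10), (10,), {10: 30}, {10: 30}),
            self._couple((10, 11), (10, 10), (10,), {11: 9}, {10: 9}),  # wrong gts
            self._couple((10, 10), (10, 10), (10, 11), {11: 9}, {10: 9}),  # child has 11
        ]
        res = estimate_filter_false_negative_rate(((10, 10), (10, 10)), 11, couples)
        assert res.n_couples == 4
        assert res.false_negative_rate == pytest.approx(0.5)

    def test_sex_nonspecific_matching(self):
        couples = [self._couple((12, 12), (10, 11), (10,), {}, {})]
        res = estimate_filter_false_negative_rate(((10, 11), (12, 12)), 13, couples)
        assert res.n_couples == 1
        assert res.false_negative_rate == 0.0

    def test_no_positive_couples_is_undefined(self):
        res = estimate_filter_false_negative_rate(((10, 10), (10, 10)), 11, [])
        assert res.n_couples == 0
        with pytest.raises(UndefinedRateError):
            _ = res.false_negative_rate


class TestEvaluateFilter:
    def test_perfect_and_inverted(self):
        verdicts = [Verdict.TRUE_DE_NOVO, Verdict.INHERITED]
        m = evaluate_filter(verdicts, ["true_de_novo", "inherited"])
        assert (m.accuracy, m.sensitivity, m.specificity) == (1.0, 1.0, 1.0)
        m2 = evaluate_filter(verdicts[::-1], ["true_de_novo", "inherited"])
        assert m2.sensitivity == 0.0

    def test_empty_undefined(self):
        with pytest.raises(UndefinedRateError):
            evaluate_filter([], [])
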