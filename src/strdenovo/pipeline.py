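"""End-to-end synthetic analysis: simulate, validate, phase, summarize.

Reads are simulated lazily, only at (family, locus) pairs that carry
candidate DNMs — the per-locus random streams are independent, so the reads
produced for a subset are identical to those of a full-panel run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .panel import STRLocus, simulate_panel
from .phasing import Phase, phase_dnm
from .reads import simulate_locus_reads
from .simulate import MISSING, QuadFamily, emit_candidate_dnms, simulate_families
from .validation import (FilterMetrics, Verdict, build_support, classify_dnm,
                         evaluate_filter)

VALIDATED_COLUMNS = ["family", "child", "locus_id", "denovo_ru", "inherited_ru",
                     "truth", "verdict", "phase", "size",
                     "child_support", "father_support", "mother_support"]


@dataclass
class PipelineResult:
    config: SimulationConfig
    panel: list[STRLocus]
    families: list[QuadFamily]
    candidates: pd.DataFrame  # with verdict / phase / support columns
    metrics: FilterMetrics | None


def observed_longest_allele(family: QuadFamily, locus_idx: int) -> int:
    """Longest allele among called parental and child genotypes at a locus."""
    alleles = [family.child_true[:, locus_idx].max()]
    for called in (family.father_called[locus_idx], family.mother_called[locus_idx]):
        valid = called[called != MISSING]
        if valid.size:
            alleles.append(valid.max())
    return int(max(alleles))


def validate_candidates(
    families: list[QuadFamily],
    panel: list[STRLocus],
    config: SimulationConfig,
    candidates: pd.DataFrame,
) -> pd.DataFrame:
    """Run the read filter and allele-based phasing over a candidate table.

    Returns the table with verdict, phase, signed mutation size (relative to
    the nearest called parental allele), and per-member support counts for
    the de novo allele.
    """
    if candidates.empty:
        return pd.DataFrame(columns=VALIDATED_COLUMNS)
    locus_index = {loc.locus_id: k for k, loc in enumerate(panel)}
    fam_by_id = {f.family_id: f for f in families}
    child_idx = {}
    for fam in families:
        child_idx[fam.child_id(0)] = 0
        child_idx[fam.child_id(1)] = 1
    rows = []
    for (fam_id, locus_id), group in candidates.groupby(["family", "locus_id"], sort=False):
        fam = fam_by_id[fam_id]
        li = locus_index[locus_id]
        locus = panel[li]
        reads = simulate_locus_reads(fam, locus, li, config)
        longest = observed_longest_allele(fam, li)
        supports = {s: build_support(reads[s], locus, longest, sample_id=s)
                    for s in reads}
        father_sup = supports[fam.father_id]
        mother_sup = supports[fam.mother_id]
        for _, cand in group.iterrows():
            c = child_idx[cand["child"]]
            child_sup = supports[fam.child_id(c)]
            denovo = int(cand["denovo_ru"])
            verdict = classify_dnm(denovo, child_sup, father_sup, mother_sup)
            child_gt = fam.child_true[c, li]
            phase = phase_dnm(fam.father_called[li], fam.mother_called[li],
                              child_gt, denovo)
            parental = np.concatenate([fam.father_called[li], fam.mother_called[li]])
            parental = parental[parental != MISSING]
            size = int(denovo - parental[np.argmin(np.abs(parental - denovo))])
            rows.append({
                **{k: cand[k] for k in ["family", "child", "locus_id",
                                        "denovo_ru", "inherited_ru", "truth"]},
                "verdict": verdict.value,
                "phase": phase.value,
                "size": size,
                "child_support": child_sup.count(denovo),
                "father_support": father_sup.count(denovo),
                "mother_support": mother_sup.count(denovo),
            })
    return pd.DataFrame(rows, columns=VALIDATED_COLUMNS)


def run_end_to_end(config: SimulationConfig) -> PipelineResult:
    """Simulate a cohort, emit candidates, validate them against reads."""
    panel = simulate_panel(config)
    families = simulate_families(panel, config)
    candidates = emit_candidate_dnms(families, panel)
    validated = validate_candidates(families, panel, config, candidates)
    metrics = None
    if not validated.empty:
        metrics = evaluate_filter([Verdict(v) for v in validated["verdict"]],
                                  list(validated["truth"]))
    return PipelineResult(config=config, panel=panel, families=families,
                          candidates=validated, metrics=metrics)


def phased_counts(validated: pd.DataFrame, families: list[QuadFamily]) -> pd.DataFrame:
    """Per-child table of validated, phased DNM counts and parental ages.

    Counts only candidates the filter passed (verdict ``true_de_novo``).
    Every cohort child appears, including those with zero validated DNMs.
    """
    passed = validated[validated["verdict"] == Verdict.TRUE_DE_NOVO.value] \
        if not validated.empty else validated
    rows = []
    for fam in families:
        for c in range(2):
            child = fam.child_id(c)
            sub = passed[passed["child"] == child] if not passed.empty else passed
            n_pat = int((sub["phase"] == Phase.PATERNAL.value).sum()) if len(sub) else 0
            n_mat = int((sub["phase"] == Phase.MATERNAL.value).sum()) if len(sub) else 0
            n_un = int((sub["phase"] == Phase.UNPHASED.value).sum()) if len(sub) else 0
            rows.append({
                "family": fam.family_id,
                "child": child,
                "role": fam.child_role(c),
                "father_age": fam.father_age[c],
                "mother_age": fam.mother_age[c],
                "n_paternal": n_pat,
                "n_maternal": n_mat,
                "n_unphased": n_un,
                "n_validated": n_pat + n_mat + n_un,
            })
    return pd.DataFrame(rows)
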