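"""Allele-based phasing of de novo STR mutations.

A DNM is assigned to a parental lineage from observed alleles alone: the
child's non-de-novo allele is the inherited allele, and if it can be
attributed unambiguously to one parent (present in that parent's genotype
and absent from the other's), the de novo allele is phased to the opposite
parent's lineage.  No haplotype reconstruction is attempted.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .errors import UndefinedRateError


class Phase(enum.Enum):
    PATERNAL = "paternal"
    MATERNAL = "maternal"
    UNPHASED = "unphased"


def phase_dnm(father_gt, mother_gt, child_gt, denovo_ru: int) -> Phase:
    """Phase one candidate DNM from the four genotypes.

    The child must carry ``denovo_ru``; a child homozygous for the de novo
    allele has no observable inherited allele and is unphasable.
    """
    child = [int(a) for a in child_gt]
    if denovo_ru not in child:
        raise ValueError(f"de novo allele {denovo_ru} not in child genotype {child_gt}")
    child.remove(denovo_ru)
    inherited = child[0]
    if inherited == denovo_ru:
        return Phase.UNPHASED  # homozygous de novo: no informative inherited allele
    in_father = inherited in {int(a) for a in father_gt}
    in_mother = inherited in {int(a) for a in mother_gt}
    if in_father and not in_mother:
        return Phase.MATERNAL  # inherited allele is paternal, so the DNM is maternal
    if in_mother and not in_father:
        return Phase.PATERNAL
    return Phase.UNPHASED


@dataclass
class AlphaEstimate:
    """Per-child paternal fraction of phased DNMs."""

    child_id: str
    n_paternal: int
    n_maternal: int
    n_unphased: int

    @property
    def alpha(self) -> float:
        phased = self.n_paternal + self.n_maternal
        if phased == 0:
            raise UndefinedRateError("no phased DNMs: alpha undefined")
        return self.n_paternal / phased


def alpha_per_child(phases: list[Phase], child_id: str = "") -> AlphaEstimate:
    """Count phases and form alpha = paternal / (paternal + maternal)."""
    n_pat = sum(p is Phase.PATERNAL for p in phases)
    n_mat = sum(p is Phase.MATERNAL for p in phases)
    n_un = sum(p is Phase.UNPHASED for p in phases)
    return AlphaEstimate(child_id=child_id, n_paternal=n_pat,
                         n_maternal=n_mat, n_unphased=n_un)
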