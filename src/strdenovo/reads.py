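"""Simulated spanning reads over STR loci.

A read is represented by its query sequence plus the SAM-like fields the
validation filter consumes: 0-based alignment start of the first non-clipped
base, mapping quality, primary flag, and soft-clip lengths.  Simulated reads
always span the family's longest-allele window (left flank + repeat + right
flank, padded on the right); rejected read classes are produced by tests and
by real SAM input, not by the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import SimulationConfig
from .panel import STRLocus
from .simulate import QuadFamily

_BASES = "ACGT"


@dataclass(slots=True)
class ReadRecord:
    read_id: str
    sample: str
    locus_id: str
    pos: int  # 0-based reference coordinate of the first aligned base
    seq: str  # full query sequence including soft-clipped bases
    mapq: int = 60
    is_primary: bool = True
    softclip_left: int = 0
    softclip_right: int = 0

    @property
    def aligned_start(self) -> int:
        return self.pos

    @property
    def aligned_end(self) -> int:
        """End (exclusive) of the aligned span, excluding soft-clipped bases."""
        return self.pos + len(self.seq) - self.softclip_left - self.softclip_right

    def query_index(self, ref_coord: int) -> int:
        """Query index of the base aligned at a reference coordinate."""
        return self.softclip_left + (ref_coord - self.pos)


def _locus_rng(config: SimulationConfig, family_index: int, locus_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(
        entropy=config.seed, spawn_key=(2, family_index, locus_index)))


def simulate_locus_reads(
    family: QuadFamily,
    locus: STRLocus,
    locus_index: int,
    config: SimulationConfig,
    samples: list[str] | None = None,
) -> dict[str, list[ReadRecord]]:
    """Simulate the read pool for one family at one locus.

    Per sample, read count ~ Poisson(depth); each read is drawn from one
    parental-origin allele copy, perturbed by stutter with probability
    ``stutter_rate`` (geometric magnitude, uniform sign).  In parent samples
    each allele copy independently drops out of the read pool with
    probability ``dropout_rate`` and then contributes no reads.  Reads are
    emitted at ``locus.start - 10`` and padded to span the longest family
    allele.  Deterministic given config seed, family, and locus.
    """
    rng = _locus_rng(config, family.index, locus_index)
    longest = family.longest_allele(locus_index)
    allele_sets: dict[str, tuple[np.ndarray, bool]] = {
        family.father_id: (family.father_true[locus_index], True),
        family.mother_id: (family.mother_true[locus_index], True),
        family.child_id(0): (family.child_true[0, locus_index], False),
        family.child_id(1): (family.child_true[1, locus_index], False),
    }
    wanted = samples if samples is not None else list(allele_sets)
    out: dict[str, list[ReadRecord]] = {}
    for sample in list(allele_sets):
        # consume randomness for every member in a fixed order so that
        # restricting `samples` never changes another sample's reads
        alleles, is_parent = allele_sets[sample]
        if is_parent:
            surviving = alleles[rng.random(2) >= config.dropout_rate]
        else:
            surviving = alleles
        n = int(rng.poisson(config.depth))
        # one random pad pool per sample-locus; reads slice what they need
        pool_len = (longest + 8) * locus.period
        pad_pool = "".join(_BASES[b] for b in rng.integers(0, 4, size=pool_len))
        records: list[ReadRecord] = []
        if len(surviving) and n:
            origins = rng.integers(0, len(surviving), size=n)
            stutter = rng.random(n) < config.stutter_rate
            mags = rng.geometric(config.stutter_geom_p, size=n)
            signs = np.where(rng.random(n) < 0.5, 1, -1)
            for k in range(n):
                count = int(surviving[origins[k]])
                if stutter[k]:
                    count = max(1, count + int(signs[k]) * int(mags[k]))
                pad_n = max(0, longest - count) * locus.period
                seq = locus.flank_left + locus.motif * count + locus.flank_right + pad_pool[:pad_n]
                records.append(ReadRecord(
                    read_id=f"{sample}:{locus.locus_id}:{k}",
                    sample=sample,
                    locus_id=locus.locus_id,
                    pos=locus.start - 10,
                    seq=seq,
                ))
        if samples is None or sample in wanted:
            out[sample] = records
    return out


def simulate_reads(
    family: QuadFamily,
    panel: list[STRLocus],
    config: SimulationConfig,
    loci: list[int] | None = None,
    samples: list[str] | None = None,
) -> dict[str, list[ReadRecord]]:
    """Simulate reads for a family across the panel (or a subset of loci).

    Returns per-sample read lists.  The per-locus random streams are
    independent, so simulating a subset of loci yields exactly the reads
    that a full run would produce at those loci.
    """
    indices = loci if loci is not None else range(len(panel))
    out: dict[str, list[ReadRecord]] = {}
    for li in indices:
        per_sample = simulate_locus_reads(family, panel[li], li, config, samples=samples)
        for sample, recs in per_sample.items():
            out.setdefault(sample, []).extend(recs)
    return out
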