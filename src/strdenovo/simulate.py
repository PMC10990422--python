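"""Synthetic quad-family cohorts with known de novo STR mutations.

Each family has two parents and two children (proband and unaffected
sibling).  Per child, paternally derived prezygotic DNM counts follow
``Poisson(beta0_pat + beta1_pat * father_age)`` and maternally derived counts
``Poisson(beta0_mat + beta1_mat * mother_age)``, on the phased-count scale.
A fraction ``f_z`` of the maternal-age-associated mutations is relabeled
postzygotic and lands on a uniformly random parental haplotype, which is the
mechanism the paired-children power analysis is designed to detect.

Mutations are assigned to loci with probability proportional to locus
mutability (reference repeat count, times a GC multiplier for paternal
mutations and an AT-only multiplier for the maternal age-dependent
component).  Mutation sizes are +/-1, 2, 3 repeat units with configurable
weights.

Allelic dropout is modeled at genotype-calling time: with probability
``dropout_rate`` per parental allele per locus, the called genotype misses
that allele (appearing homozygous for the other), so a child who inherited
it acquires an apparent de novo allele.  The raw read pool may still carry
the dropped allele; that is the artifact the read-based validation filter
exists to catch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .errors import ConfigurationError
from .panel import STRLocus

MISSING = -1

_ALLELE_OFFSETS = np.array([-2, -1, 0, 1, 2])
_ALLELE_OFFSET_P = np.array([0.05, 0.2, 0.5, 0.2, 0.05])


@dataclass
class TrueDNM:
    """One injected de novo mutation (the truth ledger entry)."""

    family_id: str
    child: str
    locus_id: str
    haplotype: str  # chromosome of residence: "paternal" | "maternal"
    postzygotic: bool
    source_ru: int
    denovo_ru: int
    size: int  # signed, repeat units


@dataclass
class QuadFamily:
    """Two parents and two children with true and called STR genotypes.

    ``*_true`` arrays hold the real diploid genotypes in repeat units; called
    parental genotypes reflect allelic dropout (``MISSING`` marks a locus the
    caller could not genotype).  Child haplotype order in ``child_true`` is
    (paternal-origin, maternal-origin).  ``truth`` lists the injected DNMs.
    """

    family_id: str
    index: int
    father_age: tuple[float, float]  # at each child's birth
    mother_age: tuple[float, float]
    father_true: np.ndarray  # (n_loci, 2)
    mother_true: np.ndarray
    child_true: np.ndarray  # (2, n_loci, 2)
    father_called: np.ndarray  # (n_loci, 2), MISSING-coded, sorted
    mother_called: np.ndarray
    truth: list[TrueDNM] = field(default_factory=list)

    @property
    def father_id(self) -> str:
        return f"{self.family_id}_fa"

    @property
    def mother_id(self) -> str:
        return f"{self.family_id}_mo"

    def child_id(self, c: int) -> str:
        return f"{self.family_id}_{'p1' if c == 0 else 's1'}"

    def child_role(self, c: int) -> str:
        return "proband" if c == 0 else "sibling"

    @property
    def member_ids(self) -> list[str]:
        return [self.father_id, self.mother_id, self.child_id(0), self.child_id(1)]

    def longest_allele(self, locus_idx: int) -> int:
        """Longest true allele (repeat units) at a locus across all members."""
        return int(max(self.father_true[locus_idx].max(),
                       self.mother_true[locus_idx].max(),
                       self.child_true[:, locus_idx].max()))


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      bounds: tuple[float, float], size: int) -> np.ndarray:
    out = rng.normal(mean, sd, size=size)
    bad = (out < bounds[0]) | (out > bounds[1])
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < bounds[0]) | (out > bounds[1])
    return out


def _locus_weights(panel: list[STRLocus], config: SimulationConfig) -> dict[str, np.ndarray]:
    ref = np.array([loc.ref_repeat_count for loc in panel], dtype=float)
    at_only = np.array([set(loc.motif) <= {"A", "T"} for loc in panel])
    w_pat = ref * np.where(at_only, 1.0, config.gc_rate_multiplier_pat)
    w_mat_base = ref.copy()
    w_mat_age = ref * np.where(at_only, config.at_slope_multiplier_mat, 1.0)
    return {
        "pat": w_pat / w_pat.sum(),
        "mat_base": w_mat_base / w_mat_base.sum(),
        "mat_age": w_mat_age / w_mat_age.sum(),
    }


def simulate_families(panel: list[STRLocus], config: SimulationConfig) -> list[QuadFamily]:
    """Simulate the quad cohort: ages, genotypes, injected DNMs, dropout.

    Deterministic under ``config.seed``.  Raises ``ConfigurationError`` on an
    empty panel or a Poisson mean that goes negative over the age support.
    """
    if not panel:
        raise ConfigurationError("panel must be nonempty")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(1,)))
    nf, nl = config.n_families, len(panel)
    ref = np.array([loc.ref_repeat_count for loc in panel])
    weights = _locus_weights(panel, config)

    # ages: base age at first child's birth, sibling born a uniform gap later
    gap = rng.uniform(*config.sibling_gap, size=nf)
    fa0 = _truncated_normal(rng, config.father_age_mean, config.father_age_sd,
                            config.age_bounds, nf)
    mo0 = _truncated_normal(rng, config.mother_age_mean, config.mother_age_sd,
                            config.age_bounds, nf)
    fa_age = np.stack([fa0, np.minimum(fa0 + gap, config.age_bounds[1])], axis=1)
    mo_age = np.stack([mo0, np.minimum(mo0 + gap, config.age_bounds[1])], axis=1)

    # parental genotypes: reference repeat count plus a small population offset
    def draw_gt() -> np.ndarray:
        off = rng.choice(_ALLELE_OFFSETS, size=(nf, nl, 2), p=_ALLELE_OFFSET_P)
        return np.maximum(ref[None, :, None] + off, 2).astype(np.int16)

    father = draw_gt()
    mother = draw_gt()

    # transmission: which parental haplotype each child inherits, per locus
    pat_pick = rng.integers(0, 2, size=(nf, 2, nl))
    mat_pick = rng.integers(0, 2, size=(nf, 2, nl))
    child = np.empty((nf, 2, nl, 2), dtype=np.int16)
    fam_idx = np.arange(nf)[:, None, None]
    loc_idx = np.arange(nl)[None, None, :]
    child[..., 0] = father[fam_idx, loc_idx, pat_pick]
    child[..., 1] = mother[fam_idx, loc_idx, mat_pick]

    # expected phased DNM counts per child
    lam_pat = config.beta0_pat + config.beta1_pat * fa_age
    lam_mat_base = np.full_like(mo_age, config.beta0_mat)
    lam_mat_age = config.beta1_mat * mo_age
    if (lam_pat < 0).any() or (lam_mat_age < 0).any():
        raise ConfigurationError("negative Poisson mean over the simulated ages")
    n_pat = rng.poisson(lam_pat)
    n_mat_base = rng.poisson(lam_mat_base)
    n_mat_age = rng.poisson(lam_mat_age)

    size_mag = np.array([1, 2, 3])
    truth_by_family: list[list[TrueDNM]] = [[] for _ in range(nf)]

    def inject(f: int, c: int, locus_pool: np.ndarray, pool_pos: int,
               haplotype: int, postzygotic: bool, mutated: set) -> int:
        """Apply one DNM; returns the updated pool cursor."""
        for _ in range(20):
            l = int(locus_pool[pool_pos % len(locus_pool)])
            pool_pos += 1
            if (c, l) not in mutated:
                break
        else:
            return pool_pos  # pathological collision density; skip silently
        mutated.add((c, l))
        mag = int(rng.choice(size_mag, p=config.mutation_size_weights))
        sign = 1 if rng.random() < 0.5 else -1
        source = int(child[f, c, l, haplotype])
        new = source + sign * mag
        if new < 2:
            sign, new = -sign, source + mag
        child[f, c, l, haplotype] = new
        fam_id = f"F{f:05d}"
        truth_by_family[f].append(TrueDNM(
            family_id=fam_id,
            child=f"{fam_id}_{'p1' if c == 0 else 's1'}",
            locus_id=panel[l].locus_id,
            haplotype="paternal" if haplotype == 0 else "maternal",
            postzygotic=postzygotic,
            source_ru=source,
            denovo_ru=new,
            size=sign * mag,
        ))
        return pool_pos

    # pre-draw locus assignments in bulk for speed
    pools = {
        "pat": rng.choice(nl, size=max(1, int(n_pat.sum())), p=weights["pat"]),
        "mat_base": rng.choice(nl, size=max(1, int(n_mat_base.sum())), p=weights["mat_base"]),
        "mat_age": rng.choice(nl, size=max(1, int(n_mat_age.sum())), p=weights["mat_age"]),
    }
    cursors = {k: 0 for k in pools}
    for f in range(nf):
        mutated: set = set()
        for c in range(2):
            for _ in range(int(n_pat[f, c])):
                cursors["pat"] = inject(f, c, pools["pat"], cursors["pat"], 0, False, mutated)
            for _ in range(int(n_mat_base[f, c])):
                cursors["mat_base"] = inject(f, c, pools["mat_base"], cursors["mat_base"],
                                             1, False, mutated)
            for _ in range(int(n_mat_age[f, c])):
                postzygotic = bool(rng.random() < config.f_z)
                hap = int(rng.integers(0, 2)) if postzygotic else 1
                cursors["mat_age"] = inject(f, c, pools["mat_age"], cursors["mat_age"],
                                            hap, postzygotic, mutated)

    # genotype-calling dropout in parents
    def call(gt: np.ndarray) -> np.ndarray:
        drop = rng.random(size=gt.shape) < config.dropout_rate
        called = gt.astype(np.int16).copy()
        one = drop[..., 0] & ~drop[..., 1]
        called[one, 0] = called[one, 1]
        other = drop[..., 1] & ~drop[..., 0]
        called[other, 1] = called[other, 0]
        both = drop[..., 0] & drop[..., 1]
        called[both] = MISSING
        return np.sort(called, axis=-1)

    father_called = call(father)
    mother_called = call(mother)

    families = []
    for f in range(nf):
        families.append(QuadFamily(
            family_id=f"F{f:05d}",
            index=f,
            father_age=(float(fa_age[f, 0]), float(fa_age[f, 1])),
            mother_age=(float(mo_age[f, 0]), float(mo_age[f, 1])),
            father_true=father[f],
            mother_true=mother[f],
            child_true=child[f],
            father_called=father_called[f],
            mother_called=mother_called[f],
            truth=truth_by_family[f],
        ))
    return families


def truth_table(families: list[QuadFamily]) -> pd.DataFrame:
    """Flatten the per-family truth ledgers into one DataFrame."""
    rows = [vars(t) for fam in families for t in fam.truth]
    cols = ["family_id", "child", "locus_id", "haplotype", "postzygotic",
            "source_ru", "denovo_ru", "size"]
    return pd.DataFrame(rows, columns=cols)


def emit_candidate_dnms(families: list[QuadFamily], panel: list[STRLocus]) -> pd.DataFrame:
    """Emulate the upstream caller: emit child alleles absent from the called
    parental genotypes as candidate DNMs, keeping truth labels for evaluation.

    Loci where either parent has no genotype call are skipped (a caller
    cannot nominate a DNM without both parental genotypes).  Candidates are
    labeled ``true_de_novo`` when they match an injected mutation and
    ``inherited`` when induced by parental allelic dropout.
    """
    locus_ids = np.array([loc.locus_id for loc in panel])
    frames = []
    for fam in families:
        truth_key = {(t.child, t.locus_id, t.denovo_ru) for t in fam.truth}
        parents_ok = (fam.father_called[:, 0] != MISSING) & (fam.mother_called[:, 0] != MISSING)
        parental = np.stack([fam.father_called[:, 0], fam.father_called[:, 1],
                             fam.mother_called[:, 0], fam.mother_called[:, 1]], axis=1)
        for c in range(2):
            child_id = fam.child_id(c)
            gts = fam.child_true[c]  # (nl, 2)
            novel = (gts[:, :, None] != parental[:, None, :]).all(axis=2)
            novel &= parents_ok[:, None]
            if not novel.any():
                continue
            li, hi = np.where(novel)
            seen = set()
            rows = []
            for l, h in zip(li.tolist(), hi.tolist()):
                denovo = int(gts[l, h])
                key = (l, denovo)
                if key in seen:
                    continue
                seen.add(key)
                lid = locus_ids[l]
                rows.append((fam.family_id, child_id, lid, denovo,
                             int(gts[l, 1 - h]),
                             "true_de_novo" if (child_id, lid, denovo) in truth_key
                             else "inherited"))
            if rows:
                frames.append(pd.DataFrame(
                    rows, columns=["family", "child", "locus_id", "denovo_ru",
                                   "inherited_ru", "truth"]))
    if not frames:
        return pd.DataFrame(columns=["family", "child", "locus_id", "denovo_ru",
                                     "inherited_ru", "truth"])
    return pd.concat(frames, ignore_index=True)
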