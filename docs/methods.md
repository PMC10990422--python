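# Methods

## The statistical model

Per child, the expected number of phased STR DNMs is linear in the relevant
parent's age at the child's birth:

    n_paternal ~ Poisson(β₀,p + β₁,p · age_p)
    n_maternal ~ Poisson(β₀,m + β₁,m · age_m)

fitted as Poisson GLMs with an **identity** link, so β₁ is directly
"mutations per year". The exponential alternative is the same GLM with a
log link, compared by AIC. Rate contrasts between locus classes of unequal
panel size (AT-only vs GC-containing, non-B DNA, constrained vs neutral)
use the log link with an offset `log(#loci in class)` whose coefficient is
fixed at 1, plus an age × class interaction where the question is whether
the age effect differs. The paternal fraction α = paternal/(paternal +
maternal) is regressed on paternal age as a quasi-binomial identity-link
GLM: binomial variance, scale estimated from the Pearson χ², denominator
(total phased DNMs) as variance weights. A postzygotic fraction f_z of
maternal-age-associated mutations lands on a random parental haplotype, so
paternally phased counts follow Poisson(β₀,p + β₁,p·age_p + β₁,m·f_z·age_m);
the paired-children design (same-aged fathers, one-sided Spearman on
Δ maternal age vs Δ paternal DNMs) isolates that term.

## The read-based filter

Candidates are child alleles absent from the *called* parental genotypes.
The filter re-examines raw reads: keep primary alignments with MAPQ ≥ 60
whose aligned span (soft clips excluded) covers
`[start − 10, start + longest_family_allele·period + 10)`; anchor at the
first exact motif occurrence scanning from 10 bp upstream; count maximal
consecutive exact copies; require the 10 bp on each side of the run to
match the reference flanks with ≤ 1 mismatch total (an interruption shifts
the downstream window and fails this check). Verdicts, in fixed precedence:
no child read with the de novo allele → false positive; ≥ 1 parental read
with it → inherited; otherwise true de novo. A site is *fully discoverable*
for size i iff no parental read supports a ± i for any called parental
allele a; the per-child rate is Σ_{i∈{1,2,3}} nᵢ/Dᵢ. Mutation size is
measured to the nearest called parental allele (the parsimony convention;
the reference allele for size is otherwise unstated).

Choices worth flagging:

- **MAPQ ≥ 60**, not > 60: common aligners cap MAPQ at 60, so a strict
  inequality would discard everything. Exposed as `mapq_min`.
- **Flank mismatch budget is total** across both flanks (≤ 1), exposed as
  `flank_mismatch_max`; a per-flank reading is equally defensible.
- Motif matching is exact and unrotated: the 10 bp upstream scan fixes the
  register, and rotated occurrences upstream count as flank content.
- No local realignment; extraction operates on the query sequence anchored
  at the first motif occurrence.
- Coordinates are 0-based half-open throughout.

## The synthetic cohort

The generator emulates the study conditions: 1,593 quad families (proband +
sibling), ~35× spanning-read depth, phased-count-scale mutation parameters
β₀,p = 1.18, β₁,p = 0.14, β₀,m = 0.66, β₁,m = 0.025 (intercepts back-derived
from the observed phased means, 5.80 paternal DNMs at mean paternal age 33
and 1.43 maternal at mean maternal age 31). Father ages ~ Normal(33, 5.5),
mother ages ~ Normal(31, 4.5), truncated to [18, 50]; sibling born a
Uniform(1.5, 4) years later. Mutation sizes are ±1, 2, 3 repeat units with
weights (0.85, 0.10, 0.05), so sizes 1–3 dominate as they do in real
callsets (~98%). Per-locus mutability is proportional to the reference
repeat count, times a ×1.5 GC multiplier for paternal mutations and a ×2
AT-only multiplier on the maternal age-dependent component — direction
taken from the observed contrasts, magnitudes unpublished and chosen once
as plausible. Stutter perturbs a read's repeat count with probability 0.05
by a Geometric(0.8) magnitude with uniform sign (geometric-tailed stutter is
the standard model). Panels default to 2,000 loci, periods 2–6, an equal
AT-only/GC-containing mix, no homopolymers; selection coefficients are a
50/50 mix of s = 0 and Exponential(mean 0.05).

**Allelic dropout** is the artifact the filter exists for: with probability
0.02 per parental allele per locus the *genotype call* misses the allele
(the parent appears homozygous), and, independently at the same rate, the
allele contributes no reads to the simulated pool. The two draws are
independent because the genotyper and the validation step see different
processings of the locus; the common case is therefore a dropout-induced
candidate whose de novo allele is still read-supported in a parent — which
is exactly what the filter rescues as "inherited". Child read pools are
complete (the artifact under study is parental). No published dropout rate
exists; 0.02 is a placeholder suitable for sensitivity sweeps.

Simulated reads always span the window (left flank + repeat + right flank +
right pad sized to the longest family allele); the rejection paths
(non-spanning, low MAPQ, secondary, soft-clip arithmetic, interruptions,
flank mismatches) are exercised by constructed reads in the tests. The
generator does not model mapping error, indel realignment, flank
sequencing error beyond what tests construct, reference bias, or child
genotyping error — so passing end-to-end tests demonstrate correctness of
the *logic* under the stated noise model, not performance on real BAMs.

## What the models stand on

- Identity-link Poisson fits start IRLS from a least-squares solution
  shifted into the positive-mean region; if IRLS exits the feasible region
  (strongly convex mean curves), the model is refit by direct likelihood
  maximization under a positivity barrier (Nelder–Mead), with expected-
  information standard errors. A fit with nonpositive means is never
  returned.
- Overdispersion: Cameron–Trivedi auxiliary regression
  ((y − μ)² − y)/μ on μ, one-sided, plus Pearson χ²/df. The specific test
  behind published "overdispersion test" statements is unnamed; both
  numbers are reported.
- AIC comparisons refuse to mix responses (n_obs must agree) and list
  quasi-likelihood fits with an explanatory note instead of a rank.
- Per-motif subgroup models require > 20 DNMs per group and use Bonferroni
  (not BH) across tested groups, matching the original analysis choice.
- Spearman ties get average ranks with the asymptotic p; exact enumeration
  is available for ≤ 7 pairs, Monte-Carlo permutation otherwise.
- Pairing: the simulation path matches identical *rounded* paternal ages;
  the data path matches within ±6 months. Both are exposed.
- Phasing is allele-identity only (no haplotype reconstruction); a child
  homozygous for the de novo allele is unphasable, and when both child
  alleles are novel both are emitted as unphased candidates.
- Z-DNA alternation is evaluated on the doubled motif so period-2 motifs
  like GC qualify; "G on one strand" accepts a reference C (G on the
  complement), with a strict-G flag for the narrower reading.
- The constrained-s bin is the top decile of s values retained after the
  s > 0.3 exclusion; hotspot membership is by locus start.

## Problem sizes

Verification experiments run at the cohort scale that matters for the
estimates (1,593 children; 200 replicates for Poisson slopes, 500 for α;
1,000 replicates for null calibrations) but on panels scaled to thousands
of loci rather than the hundreds of thousands in a real genome-wide panel —
locus count affects runtime, not the per-child count distributions the
regressions consume. The end-to-end validation run uses 500 families ×
5,000 loci with reads simulated only at candidate loci, which is exact
because each (family, locus) has an independent random stream.

## Known limitations

- Parental ages are drawn independently (no assortative correlation).
- The candidate emitter assumes children are genotyped correctly; child-
  side dropout would add false negatives the filter cannot see.
- Dropout-complete events (no genotype call *and* no reads) are labeled
  true de novo by design — with real data these are irreducible without
  orthogonal (long-read) evidence.
- The per-locus mutability model (∝ reference repeat count) is a
  convenience; real mutability rises superlinearly with allele length and
  varies by motif.
- Selection coefficients are simulation inputs, not inferences; DFE tests
  consume them as given.
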