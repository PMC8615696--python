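# Methods

## Overview

`sigmatch` implements a transcriptional reversal screen: disease
up-regulated genes are matched against drug down-regulated genes across a
multi-condition drug signature library, the ranked shortlist is tested
for mechanism-of-action (MOA) enrichment, and candidates are re-ranked by
blood–brain-barrier (BBB) penetration probability. This note records the
model, the parameters that matter, the synthetic data the tests run on,
and the design decisions taken where more than one reasonable choice
existed.

## Characteristic-direction signatures

For one perturbation experiment with p genes, n₁ control and n₂
treatment replicates, the signature direction is

    b ∝ Σ_γ⁻¹ (μ_t − μ_c),   Σ_γ = (1−γ)·Σ̂ + γ·ν·I,   ν = tr(Σ̂)/p,

where Σ̂ is the pooled within-class covariance (n₁+n₂−2 degrees of
freedom). b is returned with unit Euclidean norm, oriented so
b·(μ_t − μ_c) ≥ 0: a positive coefficient means the gene is higher under
treatment. Geometrically this is a regularized linear-discriminant
direction; γ interpolates between plain LDA (γ=0, only valid when Σ̂ has
full rank, i.e. more samples than genes) and the normalized mean
difference (γ=1).

With p ≫ n the inverse is never formed in gene space. Σ̂ has rank at
most n−2; writing its nonzero eigenpairs (λ_i, v_i) from the thin SVD of
the within-class-centered data, the Woodbury identity gives

    Σ_γ⁻¹ d = [ d − Σ_i (1−γ)λ_i / ((1−γ)λ_i + γν) · v_i (v_iᵀ d) ] / (γν),

exact and O(n²p). Numerical edge cases: singular values below 1e-12 of
the largest are treated as zero; a pooled covariance that is exactly zero
(noise-free replicates, or n₁=n₂=1) makes ν=0, and since Σ_γ is then a
scalar matrix whose scale cancels in the direction, ν is replaced by 1 so
the γ→1 mean-difference limit stays well defined. A zero mean difference
raises a degenerate-signal error; γ=0 with rank-deficient Σ̂ raises an
error instructing γ>0.

**Default γ = 0.5.** The method's behavior at the study conditions used
here (near-spherical noise) is insensitive to γ — the γ=1 limit is kept
as a closed-form test anchor — so the default sits mid-range rather than
at either degenerate end.

## DEG calling

Up/down differentially expressed gene (DEG) sets are called from the
coefficients by a z-test across genes: z_g = (b_g − mean(b))/sd(b),
p_g = 2(1−Φ(|z_g|)), gene g enters the up set iff p_g < α and b_g > 0
(down set analogously). Default α = 0.01, two-sided. The statistic is
self-contained (no replicate-level variance enters at this stage), which
matches the common post-processing of characteristic-direction
coefficients; under pure-noise inputs the coefficient distribution across
genes is approximately normal and the call rate is calibrated at α
(verified by label-permutation tests). When true DEGs are present they
inflate sd(b), so the test is conservative on the nulls.

## Reversal scoring

Per disease signature and drug signature, the score is the Jaccard index
between the disease up set and the drug down set. Two sets that are both
empty have no defined score and raise an error rather than returning 0;
a drug signature with an empty down set contributes 0.

Aggregation is fixed in this order: (1) per drug and per disease
signature, the maximum over the drug's conditions (cell line, dose,
time); (2) per drug, the arithmetic mean over disease signatures; (3)
ranks 1..n by descending average, ties broken lexicographically by drug
id so top-k lists are reproducible. The order matters (max-then-average
≠ average-then-max) and is covered by a test with a discriminating case.

Before each comparison both sets are restricted to the intersection of
the disease and drug gene universes; otherwise a universe mismatch
deflates the union asymmetrically. A drug whose comparable universe is
empty for some disease signature scores 0 there but is never dropped. A
symmetric variant (adding the disease-down vs drug-up term, averaged) is
available behind an off-by-default flag.

## Enrichment

All overlap questions use the upper tail of the hypergeometric
distribution: P(X ≥ k) for X ~ Hypergeom(N, K, n). Only over-enrichment
is offered. For term enrichment, each term's member set is first
intersected with the background; terms sharing no member with the query
are excluded (they carry no evidence of over-representation), and
Benjamini–Hochberg adjustment runs over the tested (k ≥ 1) terms.
MOA enrichment of the top-k drugs uses all scored drugs as background —
the only defensible universe available in-pipeline. Gene-set enrichment
of DEG/overlap lists uses the same core against a user-supplied GMT.

## BBB screen

The BBB-penetration classifier is consumed, not reimplemented: any
table of scores in [−1, 1] honoring the contract works. Candidates from
the reversal top-k are sorted by BBB probability (ties: higher average
reversal score, then drug id) and truncated to n (default 10). The
composition order is fixed — reversal shortlist first, BBB second — and
tested with a case where the orders disagree. A candidate missing from
the score table is excluded with a logged warning, never silently: a
missing prediction is not evidence of impermeability.

## Synthetic data

The generator emulates the screen's inputs at desk scale with planted
ground truth. Defaults: 978 genes (landmark-probe scale), 3 control + 3
treatment replicates, 5% DEGs per signature (49 genes each way), mean
shift 2.0 noise-SDs, unit Gaussian noise, 300 drugs × 4 conditions
(1,200 signatures — the same structure as a production-scale library at
minutes of runtime), 5 planted reversal drugs, reversal overlap 0.3 vs
background 0.02, two disease signatures sharing 50% of their up genes.

Details that matter:

- The two disease signatures stand in for a disease profiled in two
  related settings; the planted overlap fraction is taken of the *union*
  of their up sets, so both see elevated overlap.
- Reversal is a drug-level property: every condition of a planted
  reverser carries the elevated overlap, with the overlapping genes drawn
  independently per condition. Condition-to-condition variability comes
  from the noise model (and the per-condition draw), not from switching
  the mechanism off; the max-over-conditions rule then selects the
  condition where DEG recovery happened to be best. At these effect
  sizes per-gene DEG recall is only ~0.2–0.3 (even an oracle per-gene
  t-test has ~20% power at α=0.01 with 3v3 replicates and a 2-SD shift),
  so recovery of the planted ranking leans on having several conditions
  per drug — as the real screen's max rule does.
- The planted MOA class is, by default, exactly the planted reversers
  (`planted_moa_size=None`); padding it with random drugs dilutes the
  class, since at desk scale the shortlist is a third of the background.
- BBB scores partition the range: planted-permeable compounds uniform in
  [0.8, 1.0], all others uniform in [−1, 0.8), so planted status is
  recoverable from scores alone. The planted-permeable set is the
  reversers plus random fill to `n_bbb_high`.
- The config rejects `reversal_overlap ≤ background_overlap` (the signal
  would not be identifiable) and DEG sets that would round to zero genes.
- Determinism contract: one `numpy` Generator seeded from the mandatory
  config seed drives every draw in a fixed order; the same config yields
  byte-identical emitted files.

What the generator does **not** emulate: plate/batch effects,
dose-response monotonicity, gene-gene correlation, heavy-tailed noise,
and real compound chemistry. Passing tests therefore demonstrate that the
machinery recovers planted structure under idealized Gaussian
conditions, not that the screen's operating characteristics transfer to
real L1000 data.

## Pipeline

`run_screen` composes the stages (load/build signatures → score → top-k
→ MOA enrichment → BBB screen), writes each table as deterministic
UTF-8 TSV, logs stage counts to stderr, and records a manifest (config
hash, version, per-stage status and timings). Stage failures propagate
with the stage name; the manifest marks incomplete runs. Re-running the
same config produces byte-identical tables. The per-candidate overlap
report analyzes the candidate's best-scoring condition per disease
signature: overlap counts and hypergeometric p for candidate-down ∩
disease-up (and the mimicry direction candidate-up ∩ disease-down) over
the shared universe, plus optional gene-set enrichment of the overlap.

## Problem sizes used in tests

Unit tests run on reduced universes (tens of genes, tens of drugs) where
oracle comparisons are exact. The study-condition checks run the full
default generator (978 genes, 300 drugs, 1,200 signatures) across 50
seeds for planted-signal recovery and 100 label permutations for DEG
calibration; `scripts/acceptance.py` reports one full default run plus a
10-seed recovery rate and a 20-permutation calibration, keeping a
single-CPU run in the tens of seconds.

## Known limitations

- The z-test on standardized coefficients is conservative when many true
  DEGs are present (they inflate the scale estimate); moderated or
  replicate-aware alternatives are out of scope.
- Jaccard reversal ignores effect magnitude and rank information;
  weighted connectivity statistics (KS/tau, cosine) are out of scope.
- No significance is attached to Jaccard scores (ranking only), matching
  the screen's design.
- GCTX/HDF5 binary matrices are not parsed; GCT text (1.2/1.3) only.
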