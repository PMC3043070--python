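# Methods

## Overview

`mirmint` implements an integrated analysis of paired miRNA and mRNA
expression cohorts built around two exact, distribution-free statistics:

* **TNoM** (Threshold Number of Misclassifications) for two-class
  differential expression, with an exact combinatorial null;
* **mHG** (minimum hypergeometric) for gene-set enrichment over ranked
  gene lists, with an exact p-value that requires no correction for the
  threshold optimization.

These feed a pivot-miRNA framework: for each miRNA the whole mRNA
universe is ranked by Spearman correlation to that miRNA across the
cohort, gene sets are tested for enrichment in both orientations, and
the resulting signed scores are compared with the miRNA's own
differential expression (e.g. between highly and weakly proliferative
tumors) to associate miRNAs with biological processes.

## TNoM

For a feature with values x_1..x_N and binary labels with class sizes
n1 and n0, TNoM is the minimum number of misclassified samples over all
single expression thresholds and both label orientations. Cuts are
allowed at the two extremes and between consecutive *distinct* sorted
values; samples with tied expression are never split. Restricting cuts
at ties can only increase the observed k, so the continuous-data null
remains valid (conservative) under ties.

The null distributes the n1 labels uniformly over all C(N, n1)
arrangements. Writing b for the number of class-1 labels in a length-n
prefix of the sorted sequence, the two orientation errors at cut n are
`n + n1 - 2b` and `n0 - n + 2b`; an arrangement has TNoM > k iff its
lattice path (n, b) avoids every cell where either error is <= k. The
number of avoiding monotone paths is counted by dynamic programming in
exact integer arithmetic (Python big ints; O(n1*n0) cells per k), and
P(TNoM <= k) = 1 - avoiding/C(N, n1). The full CDF is cached per
(n1, n0). A closed-form anchor used in tests: exactly two arrangements
(all ones first or last) attain k = 0, so P(TNoM <= 0) = 2/C(N, n1).

Companion statistics in the differential-expression table: Welch
(unequal-variance) two-sided t-test; log2 fold change as the difference
of class means on the log2 scale; Benjamini–Hochberg step-up q-values
across features, computed from the exact TNoM p-values. Tables sort
ascending by p, ties by feature id, for determinism.

## Hypergeometric tail and mHG

HGT(b; N, B, n) = P(X >= b) for X hypergeometric with population N, B
successes and n draws. Tails are accumulated in log space from log
binomial coefficients (lgamma), top down, so values far below double
underflow thresholds in linear space remain exact on the log scale.

Given a ranked universe carrying a binary membership vector λ with
prefix counts b_n, the mHG score is s = min over n = 1..N of
HGT(b_n; N, B, n) (the n = N term is 1 and never harms). For fixed b
the tail strictly increases with n, so the minimum is attained at
positions where λ_n = 1; only those cells are evaluated, with ties
resolved to the smallest n.

The exact p-value P(mHG <= s) is computed by a forward pass over the
(n, b) lattice: alive[b] carries the probability that a random
arrangement reaches (n, b) without having entered the rejection region
{cells with tail <= s}; mass entering the region is moved into an event
accumulator at its first hit. Accumulating the event mass directly
(rather than 1 minus the surviving mass) keeps very small p-values
accurate. Within each row the rejection boundary is found by one
top-down log-sum-exp sweep that stops at the first cell above the
threshold; the pass ends early once all path mass is absorbed. A
log-scale tolerance of 1e-9 decides threshold attainment, absorbing
double rounding in tail evaluation. The kernels are JIT-compiled with
numba (a pure-Python fallback keeps the package importable without it).

Two guarantees hold analytically and are enforced/tested: s <= p
(the optimizing cut's tail event has probability exactly s) and
p <= N*s (union bound). p-values are floored at the smallest positive
normal double and never reported as zero.

An exact big-rational mode (`mhg_exact_pvalue_rational`, Fraction
arithmetic with integer path counting) serves as an independent oracle
for moderate N; enumeration over all C(N, B) arrangements covers
N <= 12 in the tests.

Because both exact tests are discrete, P(p <= α) under the null equals
the largest attainable p-value below α, which can sit well under α
(e.g. 0.0346 for TNoM at 30 vs 30). `mhg.attainable_level` computes
this level exactly for mHG by bisecting the attainable tail values
against the DP; calibration tests center their binomial envelopes on
these exact levels rather than on the nominal cutoff.

## Ranking schemes and pivot integration

* **Differential expression**: features ordered by signed score
  (-log10 p if up-regulated, +log10 p if down), most up-regulated first.
* **Correlation to a pivot miRNA**: Spearman rho of every gene against
  the pivot across all shared samples (average ranks at ties; genes
  with zero rank variance get rho = 0 so the universe stays stable
  across pivots). The positively correlated ranking sorts by
  descending rho with lexicographic tie-break; the anti-correlated
  ranking is its exact reverse.
* **Target prediction**: genes ranked ascending by context score (more
  negative = stronger predicted targeting); genes absent from the score
  table are excluded. Duplicate (miRNA, gene) score rows collapse to
  the most negative score on input.

Target anti-correlation: H = the pivot's top 2000 predicted targets
(all of them when fewer exist) tested by mHG within the anti-correlated
ranking; enrichment indicates the pivot's predicted targets track its
expression negatively, as expected under direct repression.

The association matrix tests every (pivot, gene set) pair in both
orientations and stores a signed score: +(-log10 p) when the set is
better supported among positively correlated genes, -(-log10 p)
otherwise; when both directions are significant the smaller p wins the
sign. Base 10 is a display choice; any base preserves order.
BH correction is applied within one ranked-list analysis (one pivot,
one direction set), not across pivots.

Concordance between differential expression and enrichment is the
Pearson correlation between per-miRNA signed DE scores and signed
enrichment scores for one gene set over the shared miRNAs (>= 3
required).

## Preprocessing

Order of operations: average replicate arrays (arithmetic mean on the
linear scale; detection = OR over replicates) → scale each sample so
its 75th percentile equals a constant c → log2 with an intensity floor.
Multiplicative per-sample scaling is only meaningful on the linear
scale, which fixes the order. The default c is the median of the
per-sample 75th percentiles: it coincides with any pooled-dataset
location for exchangeable samples and guarantees unit scale factors
when all samples are identical. Percentiles interpolate linearly
between order statistics (the common "type 7" convention). The log2
floor defaults to 1.0 intensity unit (sub-unit microarray intensities
are noise floor). Features detected in fewer than 10% of samples are
dropped (a feature at exactly 10% is kept). Top-variance selection
uses the unbiased (n-1) variance with lexicographic tie-break at the
cutoff. Probe-to-gene collapse, when a mapping is supplied, keeps the
most variable probe per gene.

## Phenotype rules

Ki67 immunostaining bins: negative (<= 1% stained cells), moderate
(1-10%], high (> 10%); mitotic index bins: low (0-5 mitoses), moderate
(6-11), high (> 11). Discrepant multi-core measurements resolve to the
highest category at annotation reading. Proliferation classes: HP for
(high, high), (high, moderate), (moderate, high); LP for (negative,
low), (negative, moderate), (moderate, low); every other combination -
including (moderate, moderate) and missing markers - is unassigned,
since the two rules cover only those cells.

LMA screen: readouts are z-scored against negative-control replicates
(z = (signal - mean(controls)) / sd(controls), per cell line and time
point; at least two controls with nonzero spread required). A miRNA is
a proliferation hit iff at least one |z| > 2, both |z| > 1 at 48 h and
72 h, and the two time points agree in sign; the sign-agreement clause
is this package's resolution of mixed-sign pairs, which the bare
threshold rule leaves undefined — calling a hit from contradictory
directions would be uninterpretable. Concordance with the tumor
contrast labels a screened miRNA matching (HP-up and increase, or
HP-down and decrease), opposite (hit with the reverse pairing) or none
(no hit).

## Synthetic cohorts

The generator emulates the statistical shape the analyses assume, on
the log2 scale: per-feature baselines ~ N(8, 1.5^2), sample noise
~ N(0, 1), replicate arrays sharing the sample signal with independent
N(0, 0.5^2) replicate noise, and intensities 2^(log2 signal). Default
cohort scale is 100 samples, 300 miRNAs, 3000 mRNAs, duplicate
hybridizations, with subtype proportions mirroring a breast-tumor
cohort (basal-like 0.15, luminal-A 0.40, luminal-B 0.15,
ERBB2-enriched 0.11, normal-like 0.07, unclassified 0.12) and ER/TP53
status drawn conditionally on subtype. Ki67 percents and mitotic
counts are drawn from a latent proliferation state (HP/LP/intermediate
at 0.25/0.35/0.40) so the HP/LP rule recovers it.

Planted structure:

* **Differential miRNAs**: a level-A shift of `effect_sd` noise-SD
  units on randomly chosen non-pivot miRNAs for a named annotation
  contrast.
* **Modules**: one latent factor ~ N(0, 1) per module (optionally
  shifted ±delta between two annotation levels); module genes load
  with coefficient `loading` jittered uniformly by ±20%; designated
  pivot miRNAs load on the same factor with signed couplings — the
  minimal structure that makes correlation-ranked enrichment
  meaningful.
* **Targets**: target genes receive -gamma * standardized pivot signal
  with gamma = noise_sd * |rho| / sqrt(1 - rho^2), producing the
  requested Spearman-scale anti-correlation in expectation.

Detection dropout follows a logistic curve in log2 intensity,
P(absent) = sigmoid((midpoint - x)/slope) with midpoint 4.0 and slope
1.0, so dropout rises as intensity falls. A single seed drives named
sub-streams (annotations, factors/assignments, miRNA noise, mRNA
noise, dropout), making cohorts bit-reproducible.

Companion generators emit a GMT collection (planted modules plus
random decoy sets drawn from non-module genes) and a context-score
table (planted pairs ~ N(-0.55, 0.05^2), background pairs
~ N(-0.15, 0.08^2), all clipped below zero), plus a long-format truth
manifest for recovery scoring.

What the generator does **not** emulate: probe-level physics,
copy-number or methylation structure, isomiRs, heavy-tailed or
correlated noise, batch effects. Passing recovery tests therefore
demonstrates correctness of the statistical machinery under the stated
model, not robustness to every artifact of real microarray data.

## Problem sizes used in the automated checks

The statistical acceptance checks run at reduced but representative
scale, chosen so the full suite completes in minutes: exact-test
oracles enumerate all arrangements up to 12 samples; the sandwich
bound is checked on 1000 random instances with universes up to 2000
genes; null calibration pools 1500 TNoM features and 1200 random gene
sets over 3 seeds; planted-DE recovery uses 30-vs-30 samples, 10 of
500 miRNAs at 2 SD over 20 seeds; pivot-module recovery uses 100
samples, 50 pivots, a 100-gene module in a 1000-gene universe with 50
decoy sets over 10 seeds; target recovery uses 100 samples and 2000
genes over 20 seeds.

## Known limitations

* TNoM p-values assume continuous data; under heavy ties they are
  conservative (documented tie rule above).
* The float-precision mHG DP is validated against exact rational and
  enumeration oracles up to moderate N; beyond that its accuracy rests
  on the log-space formulation and the enforced analytic bounds.
* The pivot framework quantifies association, not causality; module
  couplings and target anti-correlation in the generator are by
  construction, and real-data inference needs orthogonal evidence.
* BH-FDR across features assumes the usual positive-dependence
  conditions; planted-recovery tests measure the realized FDR directly.
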