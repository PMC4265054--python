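# Methods

## Signature model

The compendium is a genes × strains matrix `M` of log2 expression ratios
(M-values) against a common wild-type reference. The recurrent
slow-growth signature is defined as the first mode of the singular value
decomposition `M = U S Vᵀ`: gene loadings `U₁`, strain loadings `V₁`,
singular value `s₁`, with `variance_fraction = s₁²/Σₖ sₖ²`. The
*signature profile* is the largest-norm column of `M⁽¹⁾ = s₁U₁V₁ᵀ`, i.e.
`s₁·v₁[j*]·U₁` with `j* = argmax|v₁|` (ties broken toward the smallest
column index).

Numerical conventions:

* **Sign.** Singular vectors are sign-ambiguous; we orient so the entry
  of `U₁` with the largest absolute value is positive, and flip `V₁`
  together with it. This is deterministic and basis-independent.
* **Centering.** Off by default. M-values are already ratios against a
  shared reference, and with uncentered data the per-strain similarity
  score `⟨profile, U₁⟩` is a plain projection (proportional to the
  covariance only when the data are centered). A `center=True` flag
  subtracts column means first.
* **Removal.** For the compendium itself, `M* = M − s₁U₁V₁ᵀ`; every
  column of `M*` is orthogonal to `U₁` and `M⁽¹⁾ + M*` reconstructs `M`
  to machine precision. For an external profile, only the genes shared
  with the model are touched: `U₁` is re-normalised on the shared subset
  (`û`) and `profile − ⟨profile, û⟩û` replaces the shared entries, the
  rest passing through unchanged. Gene matching is always by identifier
  with re-alignment; positional matching is deliberately unsupported
  because cross-platform misregistration is silent and catastrophic.
* The robust-strain filter keeps samples with **strictly more than**
  `min_transcripts` (default 3) genes at |fold| **strictly greater than**
  1.7 and p **strictly below** 0.05, matching the usual statement of the
  criterion.

## Deconvolution

The target profile is modelled as `series.values @ w` with `w` a
length-T probability vector over the timepoints of a synchronised
cell-cycle time course (M-values relative to t = 0). `w` is generated by
a single interpolating cubic spline through four control points whose
x-positions are fixed at 0.2/0.4/0.6/0.8 of the cycle duration (78, 156,
234, 312 min for the default 390-min series); only the four ordinates
are optimised, unconstrained. The spline is evaluated at the T
timepoints (extrapolating outside the control range), negative values
are clamped to zero, and the vector is normalised to sum to one — the
simplest map from unconstrained ordinates onto the stated simplex. The
ordinates themselves carry no meaning beyond the weights they induce.

With exactly four control points the Forsythe–Malcolm–Moler end
conditions (end derivatives from the cubic through the four points
nearest each end) make the spline identical to the unique interpolating
cubic polynomial, which is how it is implemented; for more control
points the end derivatives are imposed on a standard cubic spline. A
`natural` end-condition mode is available in the configuration.

The objective — Pearson correlation between the virtual profile and the
target — is maximised by Nelder–Mead with default tolerances, restarted
with ordinates drawn uniformly from [0, 1). At least 10 restarts are
run; the fit is converged when the best three restarts have a
correlation coefficient of variation ≤ 0.01 **and** all three pairwise
Pearson correlations among their weight vectors are ≥ 0.95, continuing
to at most `max_restarts` (default 100) otherwise. A restart whose
clamped weights are all zero is scored −∞ and excluded. Non-convergence
is reported in the results object (`converged = False`), not raised.
Restart initialisations are drawn from a single generator seeded by
`config.seed`, so a fit is bit-reproducible.

Degeneracies worth knowing about: the t = 0 column of an M-value series
is identically zero, so its weight affects only the normalisation; the
same holds for a t = cycle-duration column in an exactly periodic
series. The spline couples these weights to the informative ones, which
is what makes the reported `w` well-defined in practice.

Controls: `randomize_gene_labels_control` permutes the target's gene
assignment and re-fits; `randomize_matrix_control` permutes each
time-point column independently; `cross_validate` fits the control
points on a random half of the genes and scores the induced virtual
profile on the held-out half. All three use the protocol above with a
fresh permutation per replicate from the seeded generator.

## Cell-cycle population simulator

The population is a circular array of 1-minute slots — G1 21, S 14, G2
14, M 21, M.G1 7, total 77 — holding the *relative* number of cells;
each step rotates every slot's mass forward one slot, wrapping the last
slot to the first. There is deliberately no doubling term at division:
the state is a density, and the uniform density (the unsynchronised
population) is then an exact fixed point.

A shock at t = 0 erects a barrier at the START checkpoint between slots
14 and 15 for a 25-minute recovery: the 14→15 transition is blocked for
the 25 steps producing states t = 1…25, so slot 14 accumulates
("piles up") one steady-state slot-mass per minute while the slots
beyond START empty out. Two release rules are implemented: **cohort**
(default) simply drops the barrier, so the accumulated mass advances as
one synchronised block; **drain** lets at most one steady-state
slot-mass (1/77) cross per minute until the pile is gone. Cohort is the
simplest rule that produces synchronised-cohort snapshots; the
deterministic model never disperses a cohort (no stochastic slippage),
which is a known limitation after release.

Observables: the 1N fraction is the mass in slots 1–28 (cells before
S-phase completion); consequently it stays at 28/77 until the emptying
wave reaches slot 28 at t = 14 and rises by 1/77 per minute to 39/77 at
t = 25 — the delayed-1N-rise prediction, reproduced exactly by an
independent bookkeeping oracle in the tests. For display and for the
magnitude model the 77 slots are averaged into 11 bins of 7 minutes.
The expression-magnitude model takes the population-average expression
change of phase-specific genes as proportional to the per-bin fold
change in cell numbers relative to t = 0, counts only bins beyond
1.7-fold (up) or below 1/1.7 (down), averages log2 fold changes over the
qualifying bins, and normalises each series to its own maximum — the
output is a shape; the proportionality constant is unidentifiable
without matched expression data. Empty bins are floored at 1e-6 before
the ratio.

All interfaces index slots 1-based ("slots 1 till 28"); the arrays
underneath are 0-based.

## Enrichment and growth statistics

Changed-gene selection uses strict inequalities on both thresholds
(|M| > log2 1.7, p < 0.05), directionally or two-sided. Enrichment is
the exact upper-tail hypergeometric probability P(X ≥ k) for the overlap
between the selection and a gene set, both restricted to the
caller-supplied universe first (genes outside the universe are dropped
with a logged count — platform mismatches are routine). Bonferroni is
`min(1, p·m)`. The test agrees with exhaustive enumeration for every
(N ≤ 12, K, n) in the suite.

Doubling time is `1/slope` of a least-squares fit of log2(OD600) versus
time. The default window is the trailing half of the supplied points —
the exponential stretch just prior to harvest is ordinarily a manual
choice, and an explicit window overrides the default. Non-positive OD or
a non-positive slope is an error. Relative growth is reported as
log2(dt_mutant/dt_wildtype).

## Missing data

K-nearest-neighbour row imputation (default k = 10): candidate
neighbours are ranked by root-mean-square distance over the columns
observed in both rows (normalising by the number of co-observed columns
so sparsely overlapping pairs are not favoured), and each hole takes the
mean of the k nearest neighbours' observed values in that column,
falling back to the column mean when no neighbour observes it or when
fewer than k usable neighbours exist (with a logged warning). Observed
entries are never altered; a fully missing row is an error. The
implementation is checked against a brute-force exhaustive-distance
oracle.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *statistical structure* the analysis
relies on, with ground truth attached:

* **Compendium** (2000 genes × 200 strains by default): a planted
  signature vector with 300 genes at +1 and 300 at −1; per-strain log2
  relative doubling times g ~ Uniform(−0.1, 1.0), spanning slightly
  faster than wild-type to twice-slower — the realistic range for viable
  deletion strains; profile = g·σ plus, for 40 strains, 20
  strain-specific ±2.0 spikes (mimicking genuine regulon effects), plus
  N(0, 0.25²) noise, a typical replicate-level M-value dispersion.
  P-values are two-sided z-tests of each M-value against the known
  noise scale — cheap and exactly consistent with the planted noise,
  but not a model of array-level error estimation.
* **Cycle series** (400 genes, 14 timepoints at 30-min intervals over a
  390-min cycle): each gene is a sum of three random-phase harmonics of
  the cycle (relative amplitude of the higher harmonics
  Uniform(0.2, 0.6)), shifted so t = 0 is exactly zero. The higher
  harmonics are essential, not decorative: with pure first-harmonic
  cosines every possible mixture profile collapses into a
  two-dimensional gene-vector space, so a perfect correlation can be
  achieved by weight vectors unrelated to the truth and the mixture
  weights are structurally unidentifiable. Real cycle transcript
  waveforms are sharply non-sinusoidal, which is precisely what makes
  deconvolution informative on real data.
* **Mixture targets**: spline weights from known control-point ordinates
  (default (0.1, 0.9, 0.3, 0.2) — a G1-weighted population) applied to
  the series, plus optional per-gene noise.
* **Enrichment scenario**: a perturbation profile with a 50-gene planted
  responsive set at +1.5 (drawn from genes outside the signature
  support, so the direct response and the growth confounder are
  separable), contaminated by 0.8·σ — a mid-range slow-growth loading —
  plus noise, alongside a 1000 × 100 compendium sharing σ from which the
  signature is estimated. Selection p-values after removal are
  recomputed from the transformed M-values with the same z-model,
  since removal changes the effect sizes.
* **Growth curves**: OD(t) = 0.05·2^(t/dt) with optional multiplicative
  log-normal noise.

What passing these tests does **not** show about real data: generators
contain no dye bias, spatial artefacts, intensity-dependent variance,
gene–gene correlation beyond the planted structure, synchrony loss in
time courses, or annotation error; the planted signature is exactly
rank-1 where the biological one is only approximately so. Recovery
results here certify the algorithms, not the biology.

## Problem sizes and determinism

The test suite and the acceptance script run the full protocol at the
generators' default sizes (2000 × 200 compendium; 400-gene, 14-point
series). Randomisation and cross-validation summaries use 20 replicates,
and the null-control fits cap the restart budget at 15 (permuted data
rarely satisfies the convergence rule, and the null correlation is flat
in the number of restarts beyond the protocol's minimum of ten). All
randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical seeds give bit-identical results,
including byte-identical CLI outputs.

## Known limitations

* The deconvolution assumes the time course spans exactly one cycle and
  that phase-specific profiles add linearly in the population average.
* The simulator's cohort never disperses; real populations desynchronise
  within a cycle or two after release.
* The enrichment module implements Bonferroni only; no FDR variants.
* Signature removal is a single-mode (rank-1) correction by design;
  profiles dominated by several recurrent modes need a different tool.
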