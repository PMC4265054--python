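# popshift

Much of what bulk expression profiling reports as "stress response" or
"mutant signature" in budding yeast can be explained without any change in
per-cell transcription: when growth slows or cells transiently arrest at
the START checkpoint, the *composition* of the asynchronous population
shifts between cell-cycle phases, and phase-specific transcripts rise and
fall in the population average. `popshift` packages the analysis toolkit
for testing that interpretation:

* **Signature extraction and removal.** A compendium of deletion-strain
  profiles (genes × strains, log2 ratios *M* versus wild-type) is
  decomposed by SVD, `M = U S Vᵀ`. The first mode
  `M⁽¹⁾ = s₁·U₁V₁ᵀ` is the recurrent *slow-growth signature*; its
  per-strain strength (the projection `⟨profile, U₁⟩`) scales with the
  strain's log2 relative doubling time. Subtracting the first mode
  (`M* = M − M⁽¹⁾`), or Gram-Schmidt-removing the projection onto `U₁`
  from any external profile, leaves the perturbation-specific changes.
* **Cell-cycle deconvolution.** A stress profile is modelled as a weighted
  sum of cell-cycle phase-specific profiles (a synchronised time course of
  T timepoints). The T weights — population fractions in [0, 1] summing
  to 1 — are governed by a single cubic spline through four control points
  at 0.2/0.4/0.6/0.8 of the cycle; only the four ordinates are free, and
  they are fitted by restarted Nelder–Mead to maximise the Pearson
  correlation of the virtual (mixed) profile with the target.
  Gene-label/matrix randomisation controls and half-split cross-validation
  guard against overfitting.
* **Checkpoint-arrest population simulator.** A circular array of
  1-minute slots (G1 21, S 14, G2 14, M 21, M.G1 7 → 77 min) holds the
  relative cell density. A shock erects a barrier at START (between slots
  14 and 15) for a 25-min recovery: the slot before START piles up, the
  slots beyond empty out, and the model predicts the delayed rise of the
  1N (pre-replication) fraction and the transient in population-average
  expression magnitudes (1.7-fold threshold on per-bin cell-number
  changes).
* **Enrichment and growth statistics.** Strictly thresholded changed-gene
  selection (|fold| > 1.7, p < 0.05), upper-tail hypergeometric gene-set
  enrichment with Bonferroni correction, and doubling-time estimation from
  the slope of log2(OD600) versus time.
* **Synthetic data with ground truth.** Seeded generators for a compendium
  with a planted rank-1 signature tied to planted doubling times, a
  periodic cycle time course, known spline mixtures, a
  signature-contaminated enrichment scenario, and exponential growth
  curves — so every recovery claim is testable against known truth.

## Worked example

```python
import numpy as np
from popshift import synthetic, extract_signature, similarity_scores, fit_deconvolution
from popshift.deconvolution import DeconvolutionConfig

# compendium with a planted slow-growth signature
compendium, truth = synthetic.make_compendium(seed=1)
model = extract_signature(compendium)
print(f"variance explained by first mode: {model.variance_fraction:.1%}")
scores = similarity_scores(compendium, model)
r = np.corrcoef(scores, truth.planted_growth_rates)[0, 1]
print(f"projection score vs planted growth rate: r = {r:.3f}")

# deconvolve a known spline mixture of cycle profiles
series, _ = synthetic.make_cycle_series(seed=7)
target, mix = synthetic.make_mixture_target(series, seed=7)
fit = fit_deconvolution(series, target, DeconvolutionConfig(seed=7))
print(f"achieved r = {fit.correlation:.4f}, "
      f"weight recovery r = {np.corrcoef(fit.weights, mix.true_weights)[0,1]:.4f}")
```

prints

```
variance explained by first mode: 55.1%
projection score vs planted growth rate: r = 0.999
achieved r = 1.0000, weight recovery r = 1.0000
```

The compendium's first SVD mode carries 55% of the variance (the planted
signature dominates the noise at the default settings), its per-strain
projection recovers the planted growth-rate confounder almost perfectly,
and the deconvolution recovers the planted mixture weights exactly in the
noiseless case.

The same stages are available from a shell:

```bash
popshift synth compendium --seed 1 --out data/
popshift extract-signature data/compendium.tsv --out model.json
popshift transform data/compendium.tsv --model model.json --out transformed.tsv
popshift simulate --t-end 115 --out trace.csv
```

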