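# Methods

## Data model

All computation happens on probes × samples matrices of log2-scale
expression with a binary clinical label per sample (`control` / `disease`;
disease is always the positive class). Ingestion enforces: unique probe and
sample IDs, finite values, a label for every sample; rows with any missing
value are dropped (the count is logged) rather than imputed. A scale
advisory flags matrices whose global range leaves [−5, 30], since log2
microarray intensities live roughly in [2, 16] and a maximum in the tens of
thousands almost always means linear-scale data leaked in; the check never
mutates data.

### Reference normalization

Reference-transcript normalization uses a stable transcript (GUSB-like) to
remove per-sample level differences: on the log2 scale each sample s is
shifted by `r̄ − r_s`, where `r_s` is the sample's reference value and `r̄`
the cohort mean, which equals division by the reference on the linear
scale. The operation is invertible, preserves every within-sample contrast
`x_gs − x_hs`, and makes the reference row constant. Whether the original
convention in whole-cohort reports was linear-scale division or log-scale
subtraction is not recoverable — the two differ only by exponentiation —
so the log-scale convention is declared here and used throughout.

### Cross-cohort matching

Within a manufacturer, transcripts are matched by exact probe-ID equality
and rows are emitted in lexicographic probe order so both cohorts carry
identical feature lists. Across manufacturers, probe IDs are not
comparable; probes are collapsed to genes by averaging (log2 scale) all
probes sharing an EntrezID, with EntrezID taking precedence over gene
symbol when annotations conflict. Gene-symbol comparisons elsewhere
(panel matching) are case-insensitive and split slash-composite
identifiers ("PITHD1/C1orf128") into aliases, because published panel
tables print such composites.

### Train/test splitting

Stratified splits draw, per class, `round(test_fraction × class size)`
samples (round half away from zero, floor of one) uniformly without
replacement under a seed. The floor guarantees a usable test set even for
very small disease cohorts.

## Random-forest transcript selection

Trees are standard binary CART classifiers grown on a bootstrap (n draws
with replacement from n training samples). At each node, f features are
drawn without replacement and the split maximizing the Gini impurity
decrease — parent impurity minus the child-size-weighted mean child
impurity, thresholds at midpoints between consecutive distinct values — is
taken; growth stops at purity, the depth cap, or when no positive-decrease
split respects the minimum leaf occupancy. Defaults: depth ≤ 20, ≥ 1
observation per leaf, f = ⌊√F⌋. The √F rule is the canonical bagged-forest
default and is configurable (`log2`, `fixed:k`) because the subset size
actually used by historical implementations of this protocol is not
documented. Ties between equally good splits go to the first feature in
draw order, making each tree a pure function of its seed.

Feature importance is the weighted Gini importance: for feature j,
`I(j) = (1/T) Σ over nodes splitting on j of (n_node / n) · Δgini`, where
`n_node` counts in-bag (multiset) occurrences. Ranking is by descending
importance with ties broken by ascending feature ID; per-feature sums are
accumulated with exact (compensated) summation so the ranking is invariant
to tree order. Prediction is by majority vote over trees (each tree votes
its leaf majority); exact ties at either level go to disease, a fixed rule
that favors sensitivity. Out-of-bag error is the misclassification rate of
majority votes restricted, per training sample, to trees whose bootstrap
excluded it. OOB error is a diagnostic only: no per-tree culling or
"best-tree" selection is performed, since selecting trees on OOB
performance would undermine the variance reduction that bagging provides.

### The four-step session and the multi-session sweep

One session: (1) forest of `n_trees_stage1` on all features; (2) restrict
to the `top_k_stage2` features by stage-1 importance; (3) forest of
`n_trees_stage3` on the survivors; (4) save the `top_k_final` panel by
stage-3 importance together with the stage-3 forest's confusion matrix
(sensitivity, specificity) on an independent test set and its OOB error.
The full profile is 1000/500/5000 trees, top 20, 100 sessions; the reduced
profile (200/100/500 trees, 10 sessions) keeps a desk-scale run in the
minutes range and is the default for the command-line `run`. Session i
uses seed `base_seed + i` — deterministic rather than wall-clock — and the
winning session maximizes test sensitivity, with ties broken by higher
specificity and then lower session index. Sensitivity-first selection
matches the screening intent: a blood screen's value is ruling disease in
for follow-up, so missing cases is the costlier error.

Stage-3 and later computations see only features that survived stage 2,
so final panels are always nested in the stage-2 set.

## Discriminant validation

Fisher's two-class LDA: weights `w ∝ S_w⁻¹ (m₁ − m₀)` with `S_w` the
pooled within-class covariance; scores are `w·x`; the threshold is the
midpoint of the projected class means (equal priors, prior-free and
symmetric — the ROC operating point at this threshold is reported so the
convention is transparent). When `S_w` is ill-conditioned (condition
number > 1e12, expected for 20-feature panels on small cohorts) a
diagonal ridge `ε·tr(S)/p` is added, ε starting at 1e-6 and escalating
tenfold until conditioning passes — deterministic and minimally
distorting.

ROC curves sweep the decision threshold over distinct score values; the
trapezoid AUC equals the Mann–Whitney statistic with tied scores credited
one half. Wilks' Λ = |E| / |H + E| uses the within-class (E) and
between-class (H) cross-product matrices over the panel; for two groups
the exact transform `F = ((N − p − 1)/p)(1 − Λ)/Λ` on `(p, N − p − 1)`
degrees of freedom is used instead of Bartlett's χ² approximation, because
it is exact at g = 2 and reduces to the squared pooled-variance t
statistic at p = 1. Panels wider than a cohort supports (N ≤ p + 1) are
rejected with instructions to truncate to the top-ranked usable features;
the pipeline truncates automatically and records that it did.

Two evaluation modes exist because they answer different questions.
*Holdout* (default) fits on a training split and scores a reserved test
split: an unbiased estimate of panel generalization. *Resubstitution* fits
and scores the same cohort, the convention of classic whole-cohort
discriminant reports; for p = 20 features on cohorts of a few hundred
samples its training-score AUC is optimistically biased (≈ 0.65–0.70 on
pure-noise data at N = 200 — consistent with published observations that
randomly drawn 20-transcript panels can reach AUC ≈ 0.7 on real cohorts).
The random-panel baseline therefore defaults to holdout, where null data
centers on AUC 0.5; resubstitution mode is available to reproduce the
inflated whole-cohort baseline. One stratified split is drawn per baseline
call and shared by all repetitions (so a degenerate draw of the full
feature set gives identical repetitions); the repetitions are therefore
correlated through the split, and the baseline mean carries split-level
variability of roughly ±0.05 at N = 200 — average over several seeded
calls when a tighter estimate is needed.

Cross-cohort panel application intersects the panel with the target's
features (probe ID first, symbol aliases as fallback), refuses evaluation
when fewer than `min_features` (default 5) members are measurable, and
otherwise reports the sub-panel size alongside AUC and Wilks statistics —
partial panels are the norm when moving between platforms.

## Synthetic data

The generator emulates normalized whole-blood microarray matrices
directly on the log2 scale (no raw-intensity model — the pipeline only
ever sees normalized data): per-probe baselines uniform on [6, 14] log2
units, Gaussian noise with constant SD 1.0 by default (a heteroscedastic
option draws per-probe SDs from Uniform(0.1, 1)), a reference probe at
the mid-range intensity with SD 0.05 in all samples, and a planted set of
informative probes receiving an additive `effect_size` (default 1.5 log2
units, i.e. 1.5σ at the default noise) in disease samples only. Defaults
— 2000 probes, 15 informative, 100–150 samples per class — mirror the
scale at which a 20-transcript panel is a meaningful target while keeping
a full protocol run in seconds. Optional structure: a fraction of genes
get two probes (for probe-collapsing tests), a balanced two-batch shift
(second half of each class), and a two-platform split sharing a chosen
fraction of probes with values copied, never re-noised. Everything is a
pure function of the seed.

What the generator does **not** emulate: cell-type composition, probe
cross-hybridization, intensity-dependent variance, dye or array-image
artifacts, correlated gene modules, or confounded batch/label designs.
Passing tests therefore demonstrate that the protocol recovers additive
planted signal under independent Gaussian noise — necessary, not
sufficient, for performance on real cohorts, where platform and
preanalytical variation dominate.

## Numerical and design choices

* Splits compare values with `<=` against midpoint thresholds; decreases
  must be strictly positive for a split to be taken.
* Determinism everywhere: per-tree seeds derive from a session seed, per
  session seeds from a base seed, pipeline stage seeds from one global
  seed via fixed named offsets; reruns of the pipeline produce
  byte-identical metrics JSON (timings live in a separate file).
* Leaf votes use raw class counts with no class weighting, including for
  imbalanced cohorts.
* The tree kernels are compiled with numba for speed; their semantics are
  pinned by pure-Python oracles in the test suite (exhaustive split
  search, pairwise AUC, t²/F identities).
* The pipeline's paired-cohort mode uses the same session seeds in both
  train/test directions so identical inputs give identical panels.

## Known limitations

Two-class only (multiclass forests and >2-group LDA are out of scope);
no probability calibration, permutation importance, covariate adjustment,
or batch correction (ComBat-style) — batch effects are simulated only to
let users observe their impact. GEO ingestion is limited to
series-matrix-like TSV; no SOFT parsing or network access.
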