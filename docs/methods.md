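# Methods

This note documents the models, parameters and numerical choices behind
`hievox`, and what the synthetic experiments do and do not demonstrate.

## The classification problem

Given segmented calls of one call type from a known set of callers, assign
each call to its source individual. Supervised training data usually carry
more labels than identity — here, the caller's sex — and the package's
central design is to exploit that: classify sex first (two classes), then
identity within the predicted or known sex (half as many classes). Because
the per-sex identity class lists are disjoint, a call routed to the wrong
sex is irrecoverably misclassified; the hierarchy is therefore only useful
when the first layer is substantially better than chance.

Two evaluation modes exist for the hierarchy and are reported side by side:

- **Composed mode** (default): each layer is evaluated on its own task with
  out-of-fold predictions, and a caller's final precision (recall) is the
  product `Y(sex) × Y(ind | sex)` of the layer scores. This treats the
  layers as independent filters and is how summary tables are built.
- **Routed mode**: calls are actually routed by the predicted sex and the
  end-to-end confusion matrix is evaluated. This is the deployable
  behaviour; it is reported as `routed` in experiment reports.

Composed precision is bounded by each layer's precision, and the two modes
agree exactly when the sex layer is perfect.

## Synthetic colonies

The generator emulates the acoustics that matter to the pipeline, not
marmoset perception. Calls are tonal frequency tracks, phase-integrated
into a waveform, shaped with a raised-cosine onset/offset (10% of duration
each, preventing spectral splatter), mixed with white Gaussian noise at a
configured SNR (default 20 dB) and peak-normalized.

Per call type the nominal tracks are:

| call type | track | band | duration |
|---|---|---|---|
| trill | carrier 6.5 kHz, sinusoidal FM at 30 Hz, depth 1.2 kHz | 5–8 kHz | 0.3–0.8 s |
| phee | 7 kHz tone with slow drift (±125 Hz at 1.5 Hz) and a shallow random glide | 6–8 kHz | 0.5–2 s |
| food call | linear downsweep 10 → 6 kHz | — | ~0.05 s |

Caller identity is a per-individual parameter signature drawn once per
individual: an additive f0 offset (sd 150 Hz, truncated so nominal
frequencies stay inside the call band), log-normal duration, FM-depth and
sweep-rate scales (sd 0.12 / 0.15 / 0.10 on the log scale) and an FM-rate
offset (sd 3 Hz). Call-to-call jitter re-draws each parameter around the
signature with smaller sds (40 Hz f0, 0.05 log-scale, 1 Hz FM rate), so
every individual is a cloud, not a point.

The sex cue is an additive shift of the mean f0 offset: females +250 Hz,
males −250 Hz (a 500 Hz separation, ~3× the within-sex per-call f0 spread
of ~155 Hz). This was chosen so that a single call carries a strongly
recoverable sex cue — the regime in which a sex-first hierarchy can help —
while leaving a few percent of calls genuinely ambiguous. Setting
`sex_effect_hz = 0` removes the cue entirely (the two sexes' parameter
distributions coincide); `signature_scale = 0` removes individual identity.

Twin pairs are planted by interpolating two same-sex signatures toward
their midpoint: at similarity *s*, each endpoint moves *s*/2 of the way to
the other, so *s* = 1 makes the signatures identical and *s* = 0 changes
nothing. No quantitative acoustic-similarity data for real twins exist to
calibrate against; the knob is a modelling stand-in, and twin results are
directional only.

What the generator does **not** emulate: formant structure, amplitude
modulation patterns, bout structure, context- or time-dependent drift of
call structure, reverberation, or colored background noise. Passing tests
on synthetic colonies therefore demonstrates that the pipeline's machinery
is correct and that its comparisons point the documented way under
controlled conditions — not that any particular accuracy will be attained
on field recordings.

Determinism: a colony spec (including its seed) maps to bit-identical
waveforms via a spawned seed tree (one stream per individual profile, one
per individual × call type for call synthesis).

## Feature bank

The bank plays the role of a "highly comparative" time-series feature
library: enough generic descriptors that data-driven selection, not the
analyst, decides what matters. Parity with any particular toolbox is not
claimed. Version `hievox-bank-1.0-full` applies ~150 per-series operators
to four views of each call — raw waveform, first difference, second
difference, amplitude envelope (|Hilbert analytic signal|) — plus
spectrogram-trajectory statistics (Hann window 512, hop 256, scaled down
for very short calls) and Daubechies-4 wavelet band energies, for 621 named
features. The `reduced` profile (158 features) keeps moments, a quantile
subset, short-lag autocorrelation, crossing/entropy/stationarity summaries
and all spectral summaries on the raw waveform and envelope; it exists for
large sweeps where extraction dominates runtime.

Numerical conventions:

- Operators that are undefined on a call (spectral moments of silence,
  skewness of a constant) return NaN rather than raising; the common-
  feature filter then keeps exactly the features finite in *every* call of
  the dataset, recording what was dropped. This mirrors per-call-type
  common-feature selection across individuals.
- Calls are analyzed whole; no fixed-length cropping. Windowed operators
  scale their windows down for calls shorter than the nominal window.
- Autocorrelations are FFT-based; partial autocorrelations and AR
  coefficients come from a Levinson–Durbin recursion on them.
- Welch spectra use segments of min(4096, n) samples; band energies are 16
  equal bands from 0 to Nyquist, as fractions of total power.
- Features are extracted from raw (unfiltered) audio.

## Balancing

The recipe is: drop classes with < `min_calls` (default 25) → optionally
undersample classes above a cap to exactly the cap (uniform, without
replacement) → SMOTE every class up to the post-cap majority count.
SMOTE draws, per synthetic row, an observation (uniform with replacement),
one of its `k = 5` nearest same-class neighbours, and a single scalar
`u ~ U(0,1)` applied to all features. Choices worth noting:

- **Neighbour pool = same class.** Interpolating across classes would
  synthesize points with wrong labels; a `cross_class_neighbours` flag
  exposes the alternative reading for anyone who wants it (off by default).
- **Distances on z-scored features.** Raw feature scales differ by orders
  of magnitude, which would let a few features own the neighbour graph.
  The scaler is fit on the pre-SMOTE data and recorded; interpolation
  itself happens in the original space (it is affine, so the choice of
  space only affects neighbour selection).
- **One scalar u per row** (canonical SMOTE); a per-feature-u variant is
  available but off by default.
- **Balancing precedes cross-validation** by default, which means synthetic
  rows derived from a training-fold call can land in a test fold. This
  faithfully reproduces the evaluated protocol and its optimism; balancing
  inside training folds only is the leakage-safe alternative and can be
  assembled from the estimator pieces (`RandomUndersampler`,
  `SmoteOversampler` have imblearn-style `fit_resample`).
- Classes smaller than k+1 reduce k with a warning; single-row classes are
  an error naming the class.

Synthetic rows are flagged `origin="synthetic"` and are never eligible for
undersampling; every synthetic row lies in the convex hull (hence the
axis-aligned bounding box) of its class.

## Classifiers

Weak learners are depth-limited CART trees (default depth 3) boosted
sequentially with SAMME reweighting — the multi-class generalization used
as the open analog of AdaBoostM2-style multi-class boosting; for two
classes it reduces to discrete AdaBoost. Defaults: learning rate 0.1;
500 trees for the sex task and 2500 for identity tasks, the points where
the staged held-out loss plateaus; both are configurable, and the recorded
`staged_loss_` (held-out misclassification after each boosting round, per
fold, held flat if boosting terminates early) is the tool for re-inspecting
that choice on new data.

Cross-validation is stratified 10-fold (stratification keeps every class
in every fold; a class smaller than the fold count is an error suggesting
more data or fewer folds). Per fold the wrapper records held-out accuracy,
staged loss and impurity-gain feature importances. Prediction uses the
most accurate fold's ensemble (ties → lowest fold index); a voting mode
over all folds is available. Both the mean of the 10 fold accuracies and
the pooled out-of-fold accuracy are reported, since summary accuracies of
CV ensembles can mean either. Feature rankings come from the best fold's
importances, descending, ties stable by feature name; each hierarchy
component ranks its own features independently.

## Evaluation and feature-importance testing

Precision and recall are computed per class from the confusion matrix
(rows = true, columns = predicted); a class never predicted gets precision
0 with a flag rather than NaN, keeping summaries defined and conservative.
Report invariants (row sums = supports, trace/total = accuracy, recall =
diagonal/row sum) are asserted on construction. One-vs-rest ROC-AUC uses
midrank tie handling; classes without positives are excluded with a flag.
Flat-versus-hierarchical comparisons use the two-sided Wilcoxon signed-rank
test paired by class (zero differences dropped; exact distribution for
≤ 25 effective pairs, else normal approximation with continuity
correction).

The feature-selection quality test embeds calls with Barnes–Hut t-SNE
(trade-off 0.5, exaggeration 4, perplexity n/100, learning rate n/12 —
large-dataset heuristics that require n ≥ 300 unless overridden;
affinities use squared Euclidean distances, and the sklearn backend with
`metric='euclidean'` does exactly that) restricted to the top-20 ranked
features, scores the embedding with the mean silhouette over callers, and
compares against 100 embeddings of 20 uniformly random features (no
exclusions — top features may be redrawn by chance). The Gaussian null is
fit by sample mean and sd of the null scores — a moment fit is
deterministic and binning-free, unlike fitting a curve to a histogram —
and the p-value is the Gaussian upper tail. Silhouettes on the 2-D
embedding use plain Euclidean distance (squared Euclidean would only
rescale the embedding's own metric; the choice is switchable via
`metric='sqeuclidean'`). Singleton classes contribute silhouette 0 with a
flag. Each null draw embeds with a fresh seed derived from the master
seed, so the whole test is reproducible.

## Problem sizes used by the test and acceptance runs

The synthetic experiments are sized for a single CPU:

- Colony experiments use 8 females + 8 males with 25–70 trills per
  individual at 25 kHz sampling (trill energy sits far below that
  Nyquist), the reduced feature bank, and boosting configs of 40 trees ×
  depth 2 × 5 folds. These are the package's chosen study sizes for
  directional comparisons; the defaults (62.5 kHz, full bank, 500/2500
  trees, 10 folds) remain what a real analysis would use.
- The hierarchical-advantage check runs 10 seeds and requires the
  composed hierarchical precision to beat flat precision in a majority of
  seeds at full sample size, with the mean advantage shrinking when
  classes are capped at 50 calls.
- The twin ablation plants one female pair at similarity 0.95 in an
  8F + 8M colony (30 trills each) and checks both directions: twins score
  below non-twin females, and removing the pair raises the remaining mean
  precision.
- Dataset-construction arithmetic uses deterministic class-count vectors
  with the published structure (see `design_imbalanced_counts`): totals
  1207/1374/4419 over 16/10/18 classes with majority classes 283/335/854
  and all classes ≥ 25. The balanced totals these produce
  (4528/3350/15372, 3152/1970/3546, 1584/990/1782, 800/500/900 for caps
  none/197/99/50) are arithmetic consequences of the recipe and hold for
  any feature values.

## Known limitations

- The hierarchy's advantage on synthetic colonies is a divide-and-conquer
  effect contingent on an accurate first layer; with no sex cue the
  advantage disappears (and first-layer errors propagate). The ablation
  test checks the contrast, not an absolute.
- Default-protocol SMOTE-before-CV inflates absolute metrics; comparisons
  between approaches share the inflation.
- The feature bank is generic: it contains no marmoset-specific acoustic
  knowledge, and its reduced profile trades coverage for speed.
- Segmentation is assumed done; the package never detects calls in
  continuous audio.
- t-SNE embeddings are seed-dependent; silhouette conclusions are about
  the test statistic's direction, not about any particular layout.
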