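# hievox

**Hierarchical source identification from animal vocalizations.**

`hievox` answers the question *"which individual produced this call?"* for
bioacoustic recordings — developed around the three major call types of the
common marmoset (*Callithrix jacchus*): trills (sinusoidal frequency
modulation within 5–8 kHz, 0.3–0.8 s), phees (narrowband 6–8 kHz tones,
0.5–2 s) and food calls (~0.05 s downsweeps from 10 to 6 kHz). It is aimed
at researchers who have a modest set of manually labelled calls and want to
attribute the rest of their recordings to individuals, e.g. for group-level
communication studies.

The pipeline has four stages:

1. **Plentiful feature extraction** (`hievox.features`). Each call is
   treated as a time series of pressure points and passed through a
   registered bank of >600 generic descriptors (distribution moments and
   quantiles, autocorrelation/partial autocorrelation, AR fits, entropy and
   complexity measures, crossing and run statistics, stationarity summaries,
   Welch-spectrum summaries and band energies on the waveform, its
   differences and its envelope, plus spectrogram-trajectory and wavelet
   features). Features that are not finite for every call of a dataset are
   dropped (*common-feature filtering*); the classifier chooses among the
   rest.
2. **Balancing** (`hievox.balance`). Callers with fewer than 25 calls of a
   type are removed, classes above a cap are randomly undersampled, and
   SMOTE raises every class to the majority count by interpolating
   same-class nearest-neighbour pairs: `x_new = x + u · (x_nn − x)`,
   `u ~ U(0,1)`.
3. **Boosted classification** (`hievox.model`). Adaptively boosted
   decision trees (SAMME reweighting) under stratified 10-fold
   cross-validation, as a flat multi-class classifier and as a **hierarchy**:
   a binary sex classifier followed by one identity classifier per sex. A
   caller's final precision/recall composes multiplicatively through the
   layers:

   ```
   Y_final(sex, ind) = Y(sex) × Y(ind | sex),   Y ∈ {precision, recall}
   ```

4. **Evaluation** (`hievox.evaluate`, `hievox.importance`). Per-class
   precision = TP/(TP+FP) and recall = TP/(TP+FN), one-vs-rest ROC-AUC,
   Wilcoxon signed-rank comparison of the flat and hierarchical approaches
   paired by class, sample-size sweeps, and a feature-selection quality
   test: mean silhouette of a Barnes–Hut t-SNE embedding (perplexity n/100,
   learning rate n/12, exaggeration 4) on the top-20 ranked features versus
   a Gaussian null built from 100 random-20 draws.

A synthetic-colony generator (`hievox.synth`) produces marmoset-like calls
with controllable per-individual signatures, sex dimorphism and planted
"twin" pairs, so the entire pipeline is testable without any recordings.

## Worked example

Run a small synthetic experiment end to end (3 females + 3 males, 40 trills
each, reduced feature bank, light training config):

```python
import hievox as hv
from hievox.pipeline import ExperimentConfig

cfg = ExperimentConfig.model_validate(dict(
    seed=0, call_types=["trill"],
    synth={"n_females": 3, "n_males": 3,
           "calls_per_type": {"trill": 40}, "sample_rate_hz": 31250},
    features={"profile": "reduced"},
    model_sex={"n_trees": 40, "max_depth": 2, "n_folds": 5},
    model_id={"n_trees": 40, "max_depth": 2, "n_folds": 5},
))
report = hv.run_experiment(cfg)
sec = report["call_types"]["trill"]
print(sec["n_calls"], sec["n_features_common"])
print(sec["chance_pct"])
print(sec["flat"]["accuracy"], sec["flat"]["summary"]["precision_mean"])
print(sec["hierarchical"]["sex"]["accuracy"])
print(sec["hierarchical"]["composed_summary"]["precision_mean"])
```

prints (to 4 decimals):

```
240 157
16.666666666666668
0.9708 0.9716
0.9875
0.9798
```

240 calls were reduced to 157 always-finite features; chance level for six
callers is 16.7%. The flat six-way classifier reaches 97.1% mean out-of-fold
precision; the sex layer is 98.75% accurate, and the composed hierarchical
precision is 98.0%. At this small, easy scale the two approaches are
statistically indistinguishable (the report's Wilcoxon p is 0.31); the
hierarchical advantage emerges on harder colonies — larger numbers of
callers and noisier signatures — which is what `tests/test_acceptance.py`
and the acceptance script measure.

The same experiment is available from the shell:

```bash
hievox synth --out colony --females 3 --males 3 --calls 40 --seed 0
hievox extract --manifest colony/manifest.csv --out feats --profile reduced
hievox run --config exp.yaml --out results_dir
```

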