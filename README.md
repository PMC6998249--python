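# imgsurv

Discrete-time survival modelling directly from masked tumor CT slices.

Radiomics pipelines predict cancer prognosis by extracting hand-crafted
texture features from a contoured region of interest (ROI) and feeding them
to a Cox proportional-hazards (CPH) model. Both steps are limiting: the
feature bank invites multiple-testing false positives, and CPH assumes the
covariates act linearly on the log hazard. `imgsurv` implements the
alternative: a small convolutional network that maps the masked grayscale
slice straight to a vector of discrete-time hazards, trained with a
survival likelihood instead of a classification loss, plus the
freeze-and-finetune transfer-learning recipe that makes this workable on
small cohorts (pretrain on a large cohort from a common cancer, then adapt
only the dense layers to the small target cohort). The package is aimed at
quantitative-imaging researchers who want a fully testable, CPU-only
reference implementation of this pipeline, including its evaluation stack
and a synthetic-data generator with a known image-to-hazard link.

## The model

Follow-up is cut into `J` intervals `[t_{j-1}, t_j)`. For subject `i` the
network emits hazards `h_j^i = P(T in interval j | T >= t_{j-1}, x_i)` and
the survival curve is `S_j = prod_{k<=j} (1 - h_k)`. Training minimizes the
negative log likelihood of the observed (event `d`, at-risk `r`) patterns,

    loss = sum_j [ -sum_{i failed in j} ln(h_j^i) - sum_{i survived j} ln(1 - h_j^i) ],

summed over intervals, with subjects leaving the sums once censored or
failed. Evaluation uses the concordance index over the order graph of
comparable pairs (strict-tie convention by default) and the index of
prediction accuracy, `IPA = (1 - Brier_model/Brier_null) * 100`, with
IPCW-weighted Brier scores at an 18-month horizon.

The architecture is six 3x3 convolutions (32 filters, batch-normalized) in
three blocks with max pools 2/3/3 and dropout 0.5, global average pooling,
a 19-unit dense feature layer (627 parameters — the "transfer-learning
features"), and a sigmoid hazard head. A Breslow-ties Cox solver with a
cross-validated LASSO path (`imgsurv.cox`) reproduces the classical
baseline over any feature table, including the network's own 19 features.

## Worked example

```python
from imgsurv import (CNNSurvival, RiskPrediction, SyntheticConfig, TrainConfig,
                     concordance_index, simulate_cohort, survival_at)
from imgsurv.imaging import standardize
from imgsurv.metrics import evaluation_report

train = simulate_cohort(SyntheticConfig(n_subjects=150, seed=1, image_side=48,
                                        beta_signal=1.5))
test = simulate_cohort(SyntheticConfig(n_subjects=80, seed=2, image_side=48,
                                       beta_signal=1.5))
train_slices = [standardize(s, side=48) for s in train.samples]
test_slices = [standardize(s, side=48) for s in test.samples]

model = CNNSurvival(train_slices, train.records, n_intervals=8,
                    config=TrainConfig(seed=0))
results = model.fit(epochs=30)
print(results.summary())

curves = results.predict_survival(test_slices)
horizon = min(548.0, float(results.grid.boundaries[-1]))
preds = [RiskPrediction(c.subject_id, survival_at(c, horizon),
                        survival_at(c, horizon)) for c in curves]
report = evaluation_report(preds, test.records, t_star=horizon)
```

Output:

```
CNN survival model
==================================================
stage:                pretrained
input:                48x48x1
intervals (J):        8
grid boundaries:      [   0.    26.5   53.9  116.4  182.9  269.2  365.6  567.5 1795.3]
feature dimension:    19
total parameters:     47731
feature-layer params:  627
trainable parameters: 47731
epochs trained:       30
final epoch loss:     254.1911

ci: 0.7821
brier: 0.2209
brier_null: 0.2217
ipa_percent: 0.3524
n_pairs: 2437
```

The synthetic cohort's images carry a latent prognostic score through
their bright-blob fraction, and exponential event times depend on that
score with log-hazard coefficient 1.5. The held-out concordance of 0.78
means the network's predicted 18-month survival ranks patients nearly as
well as the latent truth itself (~0.78 at this effect size); the IPA just
above 0 says its *calibration* only matches the Kaplan-Meier null at this
small training scale — discrimination emerges long before calibrated
absolute probabilities do. `results.finetune(slices, records)` adapts a
pretrained model to a new cohort while keeping every convolutional
parameter bit-identical, and `results.extract_features(...)` yields the 19
dense-layer features for the Cox baseline:

```python
from imgsurv import CoxPH
feats = results.extract_features(train_slices).drop(columns=["slice_index"])
sel = CoxPH(feats, train.records).fit_regularized_path(seed=0)
```

The same pipeline is scriptable from the shell: `imgsurv simulate`,
`imgsurv train`, `imgsurv finetune`, `imgsurv predict`,
`imgsurv evaluate` (see `imgsurv --help`).

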