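# boldfusion

Two-stage task decoding of BOLD fMRI time series with fused hand-crafted
and learned features.

## What problem this solves

Given 1-D ROI-averaged BOLD signals acquired under different experimental
paradigms — an emotion (social-support) task, a face–name memory task, a
finger-tapping motor task, and resting state — the package answers two
questions, in order:

1. **Which task produced this signal?** (Stage I, 4 classes)
2. **Which sub-phase does each segment of the run belong to?** (Stage II:
   high / medium / low support for emotion thirds; encode / recall for
   memory design blocks)

It is aimed at researchers studying brain decoding of multi-task fMRI who
want a reproducible, dependency-light reference pipeline, plus a synthetic
block-design generator to exercise it end to end without scanner data.

## The method

Every signal `x ∈ R^T` (zero-mean, detrended, zero-padded to T = 600) is
mapped to three feature branches:

* `f_L ∈ R^100` — last hidden state of a two-layer LSTM (150, 100 units)
  with the standard gate equations
  `i_t = σ(W_i[h_{t−1}, x_t] + b_i)`, `f_t = σ(W_f[h_{t−1}, x_t] + b_f)`,
  `o_t = σ(W_o[h_{t−1}, x_t] + b_o)`, `c_t = i_t ⊙ c̃_t + f_t ⊙ c_{t−1}`,
  `h_t = o_t ⊙ tanh(c_t)`, trained on the training folds with a temporary
  softmax head;
* `f_R ∈ R^2048` — global-pooled output of a fixed-weight 50-layer
  bottleneck residual CNN applied to the signal's CWT scalogram rendered
  as a 224×224 image;
* `f_F ∈ R^607` — 4 FFT summary scalars + the 8-level Haar periodized DWT
  coefficient vector (603 coefficients).

The fusion `f = [f_L; f_R; f_F] ∈ R^2755` is reduced to 512 features by
greedy minimum-redundancy-maximum-relevance selection — first feature
`argmax_j I(Y; F_j)`, then repeatedly

```
MID:  argmax_{j ∉ S}  I(Y; F_j) − (1/|S|) Σ_{i∈S} I(F_i; F_j)
MIQ:  argmax_{j ∉ S}  I(Y; F_j) / ((1/|S|) Σ_{i∈S} I(F_i; F_j))
```

with plug-in MI on quantile-binned features — and classified by a
two-layer fully-connected softmax network. Stage II re-runs the same
module on 200-sample sub-phase segments with adapted presets (6 DWT
levels, 256 selected features, LSTM dropout 0.2/0.1).

See `docs/methods.md` for assumptions, presets, and limitations.

## Worked example

```python
import boldfusion as bf

# default study conditions: 4 classes x 150 signals, 12 subjects
pool = bf.generate_pool(n_per_class=150, n_subjects=12, seed=0)

report = bf.evaluate_system(
    pool, k=6, mode="by-subject", fold_indices=[0],
    stages=("stage1", "stage2_emotion"), lstm_epochs=8, seed=0,
)
for stage in ("stage1", "stage2_emotion"):
    accs = {m: round(e["accuracy"], 1) for m, e in report[stage]["metrics"].items()}
    print(stage, accs)
print("stage1 diversity (ffm vs lstm):",
      report["stage1"]["diversity"]["ffm_vs_lstm"].as_dict())
```

prints (one held-out-subjects fold: 10 subjects train, 2 test):

```
stage1 {'lstm': 73.0, 'cnn': 100.0, 'ffm': 100.0}
stage2_emotion {'lstm': 81.3, 'cnn': 85.3, 'ffm': 88.0}
stage1 diversity (ffm vs lstm): {'both_hit': 73, 'a_only': 27, 'b_only': 0, 'both_miss': 0}
```

Read: on 100 held-out signals the fused FFM classifies every task
correctly while the briefly trained LSTM-only baseline reaches 73%; the
diversity table shows the fused model recovering all 27 signals the LSTM
misses. On held-out emotion thirds (75 segments) the fused model reaches
88.0% against a 33.3% chance level. Accuracies are percentages; the fused
model should never trail a single branch by more than a couple of points,
while absolute levels depend on the synthetic noise settings.

The same pipeline is scriptable from the shell:

```
boldfusion simulate --out pool.csv --n-per-class 25 --n-subjects 4 --seed 1
boldfusion train    --pool pool.csv --out model.pkl --lstm-epochs 4
boldfusion predict  --model model.pkl --pool pool.csv --out predictions.json
boldfusion evaluate --pool pool.csv --out report.json --k 2 --folds 0
```

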