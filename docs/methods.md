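# Methods

## Problem and model

`boldfusion` decodes which experimental task produced a 1-D BOLD time
series (one sample per TR, extracted from a region of interest), and for
the two temporally structured tasks, which sub-phase each segment of the
run belongs to. The system is a two-stage cascade:

1. **Stage I — task classification.** Every signal is normalised to zero
   mean, linearly detrended, zero-padded at the tail to T = 600 samples,
   and classified into emotion / memory / motor / resting.
2. **Stage II — sub-phase classification.** Signals labelled *emotion* are
   cut into three equal 200-sample thirds (the support phases are
   sequential and equally spaced by design) and each third is classified
   into high / medium / low support. Signals labelled *memory* are cut at
   their design-block boundaries and each non-rest block is classified
   into encode / recall. Stage II re-runs the same feature machinery with
   presets adapted to 200-sample inputs.

Both stages use the same feature fusion module (FFM). Per input signal it
concatenates, in fixed order:

* `fL ∈ R^100` — the final hidden state of a two-layer LSTM
  (150 then 100 units) trained on the training-fold signals with a
  temporary softmax head that is discarded after training;
* `fR ∈ R^2048` — the global-average-pooled output of a 50-layer
  bottleneck residual CNN applied to the signal's CWT scalogram rendered
  as a 224×224 RGB image;
* `fF ∈ R^607` — four FFT summary scalars (total power, spectral
  centroid, peak frequency, spectral entropy over non-DC bins) plus the
  full 8-level Haar DWT coefficient vector with periodized boundaries
  (603 coefficients for T = 600).

The fused 2755-vector is reduced to 512 features by greedy
minimum-redundancy-maximum-relevance selection (MID criterion by default)
fitted on training folds only, then classified by a two-layer
fully-connected network (128 ReLU units, softmax output, Adam,
cross-entropy) with internal feature standardisation.

## Design choices in the open parts

* **Composition of the 607-dim frequency block.** The block is defined
  here as 4 FFT summary scalars + the complete 8-level Haar periodized
  DWT vector (603), which hits 607 exactly with standard, reproducible
  components. Both sub-blocks are independently configurable; only this
  preset guarantees 607.
* **Padding.** Zero-padding is appended *after* the signal and *after*
  conditioning, so the pad value equals the signal mean (zero) and task
  onsets keep their temporal alignment. Padding never truncates; an
  over-long signal is a hard error.
* **Detrending** removes the least-squares straight line; the operation is
  idempotent to 1e-9.
* **LSTM details.** The candidate cell is the standard
  `tanh(W_c[h_{t-1}, x_t] + b_c)`. Stage I uses no dropout; Stage II uses
  dropout 0.2 / 0.1 between layers, active during training only. `fL` is
  the top layer's last-time-step hidden state, which fixes its
  dimensionality at 100. Training uses full backpropagation through time,
  Adam (lr 1e-3), batch size 256, gradient-norm clipping at 5, and a
  forget-gate bias initialised to 1.
* **CNN weights.** No trained image-network weights ship with the
  package; the residual CNN is a *fixed random-feature extractor*: He
  initialised from a seed and frozen, with the batch-norm stages folded to
  identity. Multi-scale pooled random convolutional features are a
  well-understood representation for texture-like inputs such as
  scalograms; the downstream selector and classifier do the learning. The
  architecture (not the weights) fixes `fR` at 2048.
* **Scalograms.** Analytic Morlet (`cmor1.5-1.0`), 64 geometric scales
  spanning [2, T/4] samples, magnitude min-max normalised, viridis
  colormap, bilinear resize to 224×224. All deterministic.
* **MRMR estimation.** Continuous features are quantile-binned into 8
  bins before plug-in MI (log base 2). Redundancy follows the literal
  ordered-pair double sum including i = j, and the selection loop caches
  pairwise MI so m-of-K selection costs O(K·m) MI evaluations. Ties break
  toward the lowest feature index; a zero MIQ denominator falls back to
  the MID score for that candidate.
* **Stage II presets.** 200-sample segments use 6 DWT levels (the deepest
  valid periodized chain), giving fF ∈ R^207 and a fused width of 2355;
  the MRMR target scales down to 256. Stage II heads are separate 3-class
  (emotion) and 2-class (memory) classifiers by default; a combined
  5-class mode over all sub-phase segments is available
  (`stage2_mode="combined"`) since either reading of "five sub-phase
  classes" is defensible.
* **Fold plans.** Plain k-fold assigns exactly ⌊n/k⌋ samples to each test
  fold and keeps the remainder permanently in training — the only rule
  consistent with testing 1,601 of 19,221 signals per fold at k = 12
  while training on 17,620. By-subject mode partitions subjects across
  folds and is the scientific default for multi-participant pools, since
  plain k-fold lets a subject straddle train and test.

## The synthetic generator

The generator emulates the block structure of the four acquisition
paradigms: resting (180 samples, TR 3 s, no stimulus), motor (200
samples, TR 2 s, ten 20 s rest / 20 s tapping cycles), emotion (600
samples, TR 3 s, three equal support phases), memory (600 samples, TR
3 s, rest/encode/rest/recall). Each signal is a boxcar stimulus train
convolved with a canonical double-gamma HRF (shapes 6 and 16, scale 1 s,
undershoot ratio 1/6, peak normalised to 1), plus AR(1) noise (ρ = 0.3),
white Gaussian noise (σ = 0.5) and a random low-order polynomial/cosine
drift (amplitude 0.3) — standard surrogates for scanner noise. Within the
emotion run the game rounds are periodic 10-on/10-off blocks whose
response amplitude decreases monotonically across phases
(1.0 / 0.6 / 0.3), so sub-phase classification is learnable but not
trivial under the noise; memory encode and recall blocks differ in both
amplitude and block period, giving them distinct spectral signatures.
Subjects receive a fixed lognormal response gain (sd 0.15) and signals
are assigned to subjects round-robin within class.

What the generator does **not** emulate: spatial structure, physiological
confounds (cardiac/respiratory aliasing), motion artefacts, inter-session
drift of real scanners, or genuine inter-subject variability in HRF shape
and network topology. Passing tests on synthetic pools therefore
demonstrate that the pipeline's machinery is correct and that its ordering
properties (fusion ≥ single branches) hold under controlled conditions —
not that the accuracy levels transfer to scanner data.

## Problem sizes and numerical choices

The package's reference experiment uses the default synthetic pool — 4
classes × 150 signals, 12 subjects, seed 0 — evaluated on one
held-out-subjects fold of a 6-fold by-subject plan (10 subjects train,
2 test), with LSTM branches trained for 8 epochs. These sizes keep the
full comparison (LSTM-only vs CNN-only vs fused FFM, Stage I and emotion
Stage II) at desk scale; accuracies are reported as percentages averaged
over the folds that are run. Degenerate inputs fail loudly rather than
silently: single-class training sets, unpadded signals entering a fitted
Stage I, non-divisible phase splits, over-long signals, and malformed
pool files all raise errors naming the problem.

## Known limitations

* The CNN branch is untrained; with trained weights its standalone
  accuracy would likely rise, which could only raise the fused system's
  bar in the branch-ordering comparison.
* The plug-in MI estimator is biased upward at small n; selection is
  rank-based so this mostly cancels, but MI *values* should not be read
  as unbiased estimates.
* LSTM training at desk-scale epoch counts is deliberately brief; the
  LSTM-only baseline is therefore conservative.
* The pool CSV stores design segments as label:start:end triples;
  generator-side stimulus amplitudes are not persisted (they are a
  simulation concept, not a property of an acquired signal).
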