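# Methods

## Forward model

The simulated study is a median-nerve motor conduction setup: stimulation
at the elbow, recording over the abductor pollicis brevis. Two straight
segments are modeled — 70 mm from wrist to muscle and 200 mm from wrist
to elbow. Conduction is healthy in the distal segment (each axon at its
normal CV) and demyelinated in the forearm segment (each axon at a
reassigned, generally slower CV). Latency is distance/velocity, so mm
divided by m/s gives ms directly.

### The sMUP template

Every conducting axon contributes the same unit waveform. The template
lives on a uniform 0.1 ms grid over the half-open interval [0, 15.0) ms —
150 samples at t = 0.0 … 14.9 ms. (A closed 0–15 ms interval would hold
151 points; the half-open grid is used so the sample count is exactly 150
and composes with the 251-point CMAP window.) Amplitudes are forced to
exactly 0 mV for t < 3.5 ms and t ≥ 12.1 ms, which excludes stimulus
artifact and baseline noise from the superposition; no separate noise
model is added.

Because digitized human sMUP recordings are not redistributable, the
default template is a synthetic surrogate: two opposed Gaussian lobes
(negative peak then a smaller positive one, the surface-EMG convention),
with lobe delays/widths jittered deterministically by a seed and the
whole shape scaled linearly to a requested peak amplitude. The default
peak is 0.1 mV, which puts the healthy 200-axon CMAP in the tens-of-mV
range typical of thenar recordings. Any two-column CSV
(time ms, amplitude mV) can be loaded instead; loaded points are smoothed
with a natural cubic spline (second derivative zero at the ends — the
standard default when the original smoothing flavor is unknown),
resampled to the grid, and gated identically.

### CV distribution and demyelination

The healthy population is 200 axons distributed over odd CVs 63…37 m/s
as (1, 2, 2, 6, 18, 30, 42, 39, 27, 17, 9, 4, 2, 1) — a prototypical
normal median-nerve histogram at a motor-unit-number-estimate population
size. Labels use 28 bins: {0, 11, 13, …, 63} m/s. The 0 m/s bin holds
axons in conduction block; this keeps every label summing to the
population size and makes the block frequency itself inferable.

Six slowing patterns reassign each conducting axon's forearm CV,
independently and uniformly at random over a pattern-specific allowed
set (an optional weight table supports non-uniform draws):

| pattern | allowed forearm CVs for an axon with normal CV v |
|---|---|
| 1 entire range | v, v−2, …, 11 |
| 2 severe | 11–19 |
| 3 moderate | 21–35 |
| 4 mild | v, …, v−8 |
| 5 moderate 2 | v, …, v−20 |
| 6 two distributions | {v, …, v−8} ∪ {11–19} |

Conduction block, when present, then flags each axon independently with
probability 0.4; blocked axons keep their CVs (they still count in bin 0)
but contribute zero waveform. Slowing always precedes block.

### Superposition

Each conducting axon's latency shift is computed relative to a reference
axon at 63 m/s in both segments, so the fastest possible axon is
unshifted and the template's own onset (≈3.5 ms) plays the role of the
fastest axon's physiological latency. Shifts are rounded to the nearest
0.1 ms grid step (no sub-sample interpolation — the whole pipeline is
grid-based), and template samples pushed past the 25.0 ms window end are
discarded; the slowest axons' tails are therefore truncated, which is
implied by the fixed 251-point window. The corpus is 12 groups (six
patterns × block absent/present) × 1,000 sets by default; a normal,
undemyelinated group can be generated but is not part of the default
corpus. The 80/20 train/test split is a uniform random partition without
stratification.

## Inverse model

### Architectures

A regressor consumes the 251-sample waveform as a univariate sequence
and emits 28 unconstrained real outputs. The architecture family is:
simple RNN (single layer, unidirectional only), LSTM and GRU with 1–3
recurrent layers, each optionally bidirectional (concatenating forward
and time-reversed features; intermediate layers return full sequences),
dropout after every recurrent layer (rate 0.5 by default), and a dense
projection to 28. The comparison grid therefore holds 13 networks. The
reference configuration uses 1,000 hidden units; scaled-down runs use
the same topology with fewer units.

The layers are implemented in NumPy within the package: float32
throughout, Glorot-uniform input kernels, orthogonal recurrent kernels
(per-gate blocks), zero biases except the LSTM forget gate (1.0). The
GRU uses the classic formulation (reset gate multiplying the hidden
projection inside the candidate, one bias per gate). Backpropagation
through time is analytic and is verified against central finite
differences in the test suite; the only Python loop is over time steps,
so training cost is dominated by BLAS matmuls.

### Training

MSE loss over the 28 outputs, Adam (default rate 1e-3, β₁ 0.9, β₂ 0.999,
ε 1e-7), default batch size 2,048, up to 1,000 epochs, early stopping
monitoring the *training* loss with patience 2 (patience 0 stops at the
first non-improving epoch). The held-out 20% partition doubles as the
validation set — no third split. All randomness (initialization,
shuffling, dropout masks) derives from explicit seeds, so runs are
bit-reproducible on a fixed BLAS.

**Target conditioning.** Optimization runs on per-bin z-scored targets
by default (`TrainConfig.scale_targets`), inverted inside `predict`, and
every reported loss/metric is on the raw axon-count scale. Rationale:
raw counts reach ~80 in block-present labels while Adam's per-step
update is bounded near the learning rate, so with narrow networks the
output head would spend thousands of steps just reaching the targets'
magnitude; wide (1,000-unit) networks mask this by summing many small
weights. Standardizing the regression targets is a pure conditioning
device — the model family and the loss semantics are unchanged. An
analogous optional input z-scoring flag exists and defaults off; the
waveform is otherwise fed unnormalized.

### Metrics and predictions

"Accuracy" is dominant-bin accuracy: the fraction of cases where
argmax(prediction) equals argmax(label), first index winning ties. It is
the natural argmax-agreement reading of a generic accuracy metric for a
multi-output regression, and it is interpretable clinically (does the
model find the modal CV class, including the blocked class?). Discrete
histograms round half away from zero, then clip at 0; the rounded
prediction is *not* renormalized to 200 axons — conservation of the
predicted total is itself a quality signal worth observing.

Per-group evaluation applies one globally trained model to each
(pattern, block) subset; group metrics recombine exactly to the overall
metrics under set-count weighting (tested). Grid reports rank by
validation accuracy, then validation loss.

## Problem sizes used in the checks

The test suite exercises the full 12,000-set corpus generation and split,
a brute-force superposition oracle on 100 random populations, 10,000-draw
uniformity and block-rate estimates, and a scaled-down inverse-model
recovery: 2-layer bidirectional LSTM, 64 hidden units, 1,200 sets
(100/group), batch 64, learning rate 3e-3, at most 20 epochs with the
standard early stopping. Under those conditions held-out dominant-bin
accuracy lands around 0.56 (chance 1/28 ≈ 0.036; a constant
corpus-mean predictor reaches 0.47 because block-present labels share
the bin-0 argmax) and the rounded predictions' mean per-bin absolute
error is ~1.9 axons versus ~7.1 for the mean-histogram baseline. The
full-scale 13-network comparison at 1,000 hidden units and up to 1,000
epochs is orders of magnitude more compute and is left to users with the
budget for it; the library runs it unchanged via `run_network_grid` or
the `cmapcv grid` command.

## Limitations

* Every axon contributes an identical sMUP; real motor units vary widely
  in size, and a few large units dominate real CMAP amplitude. Phase
  cancellation between unlike waveforms is therefore under-represented.
* Two straight segments, no far-field potentials, no electrode/volume
  conduction model, no recording noise: passing tests show the inverse
  mapping is learnable for this generator, not that it transfers to
  clinical recordings.
* Slowing draws are uniform over the allowed sets; real neuropathies
  concentrate severity non-uniformly. The weight-table hook exists for
  such scenarios but no clinical weighting is shipped.
* The 25 ms window truncates the slowest contributions (forearm CV
  11 m/s arrives near the window edge), exactly as a fixed acquisition
  window would.
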