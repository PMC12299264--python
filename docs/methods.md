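# Methods

This note documents the models, conventions and design choices behind
`dynhar`, the assumptions they rest on, and what the synthetic
experiments do and do not demonstrate.

## Data model and preprocessing

A sample is a 3 s window of 6-channel inertial data at 100 Hz (300 ×
6 values; channel order acc X/Y/Z, gyr X/Y/Z). The preprocessing
chain is fixed:

1. **Zero-row exclusion.** Any window containing a time row that is
   exactly zero on all six channels is removed (the sentinel for
   corrupted or disconnected segments). Whole windows are removed, not
   rows, so the window length NT stays constant; the exclusion report
   lists removed window ids.
2. **Class balancing** by truncation to the minority-class count, via
   a seeded uniform draw without replacement.
3. **Split** 70/15/15 into train/validation/test, stratified by class
   (floor for train and validation, remainder to test).
4. **Per-class Z-score.** Each value is standardized as
   x_norm = (x − μ_ic)/σ_ic, where μ_ic and σ_ic are the mean and
   *population* standard deviation of all data points of class c on
   channel i. Population rather than sample SD is used because the
   statistic is defined over the complete class data, not a sample
   from it. A zero-variance (class, channel) pair raises an error
   naming it.

Two caveats are inherent to this normalization and are surfaced
rather than silently resolved. First, computing statistics over the
full class data (before splitting) leaks label information across the
split; `train_only_stats=True` (CLI `--train-only-stats`) computes
them from the training partition only. Second, per-class
normalization at inference time requires the true label; the pipeline
applies it as defined, and the concern is noted here.

## Network architectures

All three networks share one hidden layer of NH units consuming the
last ND samples of a window, a dense softmax readout over NC classes
from the final hidden vector, logistic sigmoid (Ψ_S) gates and
sigmoid/tanh (Ψ_T) nonlinearities. ND means FIR tap count for the
FIRNN and consumed sequence length for LSTM/GRU. Hidden and gate
biases are subtracted (pre-activation = Σ − b); the readout uses the
conventional additive bias. Softmax subtracts the max logit for
stability.

* **FIRNN**: hidden unit h computes
  Ψ_S(Σ_{i=1..NI} Σ_{j=1..ND} w_ijh x_i(n−j+1) − b_h) once, at the
  readout time n = NT. The per-channel tap convention is the only
  reading consistent with the NI×ND×NH weight tensor and with the
  weight-count column of the complexity table.
* **LSTM**: gates and candidate are separate affine maps of the
  current input and previous hidden state (W_x ∈ R^{NI×NH},
  W_h ∈ R^{NH×NH}, bias per gate), the standard Hochreiter–Schmidhuber
  form; cell and hidden states start at zero.
* **GRU**: update/reset gates and a candidate whose recurrent operand
  is reset-gated, the standard Cho form; zero initial state.

Readout from the final hidden state was chosen over mean pooling
because the recurrences already integrate the window; mean pooling
remains an easy extension point.

Initialization draws every weight and bias i.i.d. from N(0, 0.001),
read as *variance* 0.001 (σ ≈ 0.0316), the standard distribution
notation.

`ForwardTrace` exposes every intermediate (gate activations,
candidate pre-activations, cell/hidden sequences, logits,
probabilities) so relevance propagation never re-runs the forward
pass.

## Complexity accounting

For one recall at dimensions (NI, ND, NH, NC):

| network | additions N2Σ | multiplications N2Π | activations NΨ | weights NW |
|---|---|---|---|---|
| FIRNN | NI·ND + NI·NH + NH | NI·ND + NI·NH + NH | NH + 1 | NH(NI·ND+1) + NC(NH+1) |
| GRU | 3NH·ND(NI+ND) + ND | 3NI·NH(NI+ND·NH) | 4ND·NH + 1 | 3NH(NI+NH+1) + NC(NH+1) |
| LSTM | 4NH·ND(NI+ND) + ND | 4NI·NH(NI+ND·NH) | 6ND·NH + 1 | 4NH(NI+NH+1) + NC(NH+1) |

The LSTM multiplication count is written as the four-gate analogue of
the GRU row (gate prefactor 4 instead of 3); an alternative published
form with an ND·ND prefactor is inconsistent with the corresponding
numeric value at (6, 100, 10, 3) and with the structural analogy, so
the form above is used. The NW column is an exact cross-module
identity: it equals the scalar count of `init_params` for every
architecture and dimension (property-tested).

## Training

The optimization recipe is a repository choice (no part of the model
definition): categorical cross-entropy, Adam, hand-derived gradients
(backpropagation through the FIR taps; BPTT for LSTM/GRU), validated
against central finite differences at 1e-5 relative tolerance.

Defaults: learning rate 5e-3, batch size 32, max 200 epochs, early
stopping on validation accuracy with patience 30, best-validation
parameters restored. The patience window is sized deliberately: with
the N(0, 0.001) initialization, validation accuracy sits at chance
for the first tens of epochs before learning onset, and a short
patience (e.g. 10) aborts nearly every run during that plateau. A
learning rate of 5e-3 shortens the plateau substantially compared to
1e-3 at no observed stability cost for these small models. A
non-finite loss raises a divergence error; the grid driver records
such runs as flagged rows rather than retrying, keeping the run count
exact.

The factorial grid is architectures × delays × hidden sizes ×
repetitions, with the delay grid {1, 10, 20, …, 100} (11 values) and
hidden sizes {2, 4, 6, 8, 10} by default. Per-run seeds derive from
`SeedSequence([base_seed, arch, ND, NH, repetition])`, making the
whole results table a pure function of (grid spec, split, train
config). Best-per-architecture selection maximizes validation
accuracy, with ties broken toward fewer parameters, then lower seed.

## Relevance propagation

Relevance is seeded at the target-class *logit* (not the softmax
probability): logit seeding keeps the redistribution rule linear and
is the common convention. Each linear (sub-)layer redistributes by
the ε-rule with a **signed** stabilizer, ε·sign(denominator), which
avoids sign flips when a pre-activation is negative; the plain +ε
variant is recovered in the limit for positive denominators.
ε defaults to 1e-6.

Architecture adaptations:

* **FIRNN** — output→hidden through the readout weights, then each
  hidden unit's relevance is redistributed over its NI×ND tap
  contributions w_ijh·x_i(n−j+1), placing signed relevance on the
  original (time, channel) grid.
* **LSTM/GRU** — relevance is unrolled backward through time.
  Additive junctions (cell update; GRU convex combination) split
  relevance proportionally to each addend's contribution,
  ε-stabilized. Multiplicative gate×signal junctions follow the
  **signal-takes-all** policy by default: the signal operand
  (cell/candidate path) receives everything, the gate receives zero —
  the established convention for LRP in gated recurrent networks. An
  alternative **proportional** policy is provided, defined here as an
  equal split between gate and signal with the gate share propagated
  through the gate's own affine layer; published work does not fix
  this rule, so it is a package definition, not a reconstruction.

Two quantities are tracked explicitly per map: the **bias-absorbed
share** (bias terms join each denominator, and their slice of the
relevance is absorbed rather than redistributed) and the **ε-leak**
(the small amount the stabilizer withholds at each junction). With
both ledgered, input relevance + bias share + leak equals the seeded
output score to machine precision, and the leak is shown to shrink
monotonically as ε → 0. Conservation statements in the tests are
always made against this closed ledger.

Normalizations use absolute values: temporal shares
T_h(n) = |R_h(n)| / Σ_c Σ_t |R_c(t)| (all entries of a map sum to 1)
and global shares V_h = Σ_n |R_h(n)| / Σ_c Σ_n |R_c(n)| (sum to 1).
Signed maps are preserved for visualization. Class-conditional
summaries average V over correctly classified samples only, then
re-normalize each class column to 1; classes with no correct
predictions are excluded with a warning.

## Downstream analytics

* **Zero-crossing rate**: strict sign changes per second, zeros
  continuing the previous sign, duration n/fs.
* **Relevance counts**: per channel, the number of time points
  strictly above the top-30% threshold, the threshold being the 0.70
  quantile of all (channel × time) values of the sample jointly
  (computed with the 'higher' quantile method so the strict count
  respects the 30% budget at any sample size).
* **Quadrants**: Q1 high-count/high-ZCR, Q2 low/high, Q3 high/low,
  Q4 low/low, with "high" strictly above the (by default median)
  thresholds, so ties fall low — deterministic and documented. The
  labeling is configurable because published quadrant conventions are
  not fully self-consistent.
* **Hidden-unit matrices**: per-class ℓ1-normalized hidden relevance
  columns, rows sorted by a chosen class (default the first), and a
  highlight set — the smallest prefix of the all-class accumulated
  ranking whose cumulative share exceeds 0.55.

## Synthetic data

Each activity class is a sum of 1–3 harmonics of a class fundamental
(defaults: sit-up-like 0.5 Hz, walk-like 2 Hz, stairs-like 1.5 Hz)
rendered on six channels with per-channel amplitudes/phases, plus
i.i.d. Gaussian noise (default SD 0.3) and an optional uniform
per-window time shift emulating arbitrary window starts. Corrupted
all-zero rows can be injected into a seeded fraction of windows.
Generation is a pure function of (config, seed).

The **planted-channel** configuration makes exactly one channel
(default gyr Y, index 4) discriminative: five channels carry one
shared 1.0 Hz carrier, literally identical across classes, while the
planted channel carries a class-specific fundamental (0.5/2.0/1.5 Hz)
via a per-channel frequency override. Frequency is the planted cue
because amplitude differences cannot survive the per-class Z-score.
Planted experiments run phase-locked (`random_phase=False`): under a
random per-window phase, a model restricted to a 0.3 s context cannot
in general resolve these low frequencies — in particular the
near-linear FIRNN cannot separate random-phase sinusoids of nearby
frequencies at all — whereas the phase-locked task is separable by
all three architectures, which is precisely the property a
ground-truth attribution test needs.

What the synthetic experiments show: that the training stack learns
genuinely discriminative structure, and that the LRP implementation
attributes relevance to the channel that carries it, across all three
architectures and seeds. What they do not show: performance or
attribution behavior on real inertial recordings, which have
subject-level heterogeneity, orientation drift, aperiodic transients
and cross-channel correlations the generator does not emulate.
Headline accuracies reported for real recordings are therefore out of
scope here.

## Numerical choices and degenerate inputs

* Tie-breaks: argmax prediction resolves ties to the lowest class id;
  best-model selection ties resolve to fewer parameters, then lower
  seed; quadrant/threshold ties fall to the "low" side.
* Degenerate inputs raise typed errors: empty datasets, zero-variance
  class-channels, all-zero relevance maps, classes with no windows.
  A degenerate all-equal relevance map yields zero counts with a
  warning rather than an error.
* All randomness flows through `numpy.random.default_rng` /
  `SeedSequence`; every seed is derived, recorded, and below 2^31.
* Experiment problem sizes used in the shipped tests are scaled to
  desk scale (e.g. attribution recovery: 300 windows, ND=30, NH=4, 10
  seeds; grid smoke runs with 1–2 repetitions); the full 16,500-run
  factorial design is enumerated and seeded but not trained in the
  test suite.

## Known limitations

* The proportional gate policy is one reasonable definition among
  several; conclusions that depend on gate-relevance assignment
  should be checked under both policies.
* Per-class normalization at inference uses the label (see above);
  deployment would need class-agnostic statistics.
* Single hidden layer only; no stacking, bidirectionality, dropout or
  attention.
* The synthetic generator is stationary and quasi-periodic; it is a
  verification instrument, not a substitute for real HAR data.
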