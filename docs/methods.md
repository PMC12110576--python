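# Methods

## Problem setting

Motor imagery (MI) of the left or right hand suppresses mu-band
(8–13 Hz) power over the *contralateral* sensorimotor cortex
(event-related desynchronization, ERD) and enhances it ipsilaterally
(event-related synchronization, ERS). Decoding left vs right MI from a
three-channel montage (C3, Cz, C4) therefore amounts to localizing the
hemisphere in which mu power drops after the cue. The hard version of
the problem is *subject-independent*: train on one group of people,
decode a new person, despite substantial inter-subject variability in
mu frequency, amplitude and ERD depth.

## Model

The network maps a trial `X ∈ R^{T×C}` (microvolts) to class
probabilities and an embedding:

1. **Convolutional front end.** A temporal convolution (kernel 25×1,
   stride 1, valid) acts as a learned filter bank; a spatial
   convolution (1×C) collapses the channel axis, acting as a learned
   spatial filter; batch normalization follows, with no intervening
   nonlinearity. Output: `d_model` features × `L' = T − 24` steps.
2. **Windowed multi-head self-attention.** `n_blocks` pairs of
   pre-norm transformer blocks (LN → attention → residual, LN → MLP
   with GELU → residual). The first block of each pair restricts
   attention to contiguous temporal windows of length `M = 8`; the
   second cyclically shifts the window grid by `M/2` (implemented as a
   cyclic roll of the sequence before partitioning and the inverse
   roll after), letting neighbouring windows communicate. No attention
   mask is applied across the cyclic wrap, and no positional encoding
   is added — temporal order is already encoded by the convolutional
   front end. Cost per windowed pair is `8LD² + 4MLD` multiply–adds,
   linear in `L'`, against `4LD² + 2L²D` for one global-attention
   block; both counts are verified empirically by instrumenting every
   matrix product the attention layers execute.
3. **Band-power head.** Elementwise square → average pooling over time
   (kernel 75, stride 15) → natural log → flatten. This
   square/pool/log cascade computes smoothed log-variance, i.e. log
   band power of the learned filters, the classical Shallow-ConvNet
   readout. The flattened vector is the trial **embedding**; a fully
   connected layer and softmax produce `[p_left, p_right]`. Pooled
   squares are clamped at `1e−6` before the log (they are ≥ 0 and can
   be 0 for degenerate inputs).

### Mirror trials, loss, fusion

A **mirror trial** swaps the data between left/right electrode pairs
(C3↔C4; midline fixed; the channel-name list is untouched — data moves
between fixed electrode positions) and flips the label. Mirroring is
an involution and, by the contralateral organization of ERD, converts
a physically plausible left trial into a physically plausible right
trial.

Training on a batch of `n` originals always uses the mirror-augmented
batch of `2n`. The objective is

    L = L_c + w_o·L_o + w_m·L_m

with `L_c` the cross-entropy over all `2n` trials and the contrastive
terms hinges on Euclidean embedding distances `D`:

    loss(D, g) = max(α + g·(D − β), 0),  g = +1 same label, −1 different.

`L_o` runs over all unordered pairs of originals, `L_m` over every
(mirror, original) combination; a trial and its own mirror always form
a negative pair. Defaults α = 0.2, β = 1.2, w_o = 0.2, w_m = 0.3. The
hinge is parenthesized as `α + g·(D − β)`: the alternative reading
`α + g·D − β` makes every negative-pair term vanish for α < β,
contradicting the intended push-apart behaviour. Pair aggregation is
the mean by default (keeps the loss scale independent of batch size);
`sum` is available. Unordered pairs are counted once; the mean/sum
switch absorbs the constant factor an ordered-pair reading would
introduce.

At inference, **mirror fusion** averages a trial's probabilities with
the class-swapped probabilities of its mirrored copy:
`p_left ← (p_left^o + p_right^m)/2`, and symmetrically. This enforces
`fused(mirror(X)) = swap(fused(X))` exactly, for any weights.

### Training

Adam (β₁ = 0.9, β₂ = 0.999) with weight decay 0.05 applied as
decoupled decay on matrix-shaped parameters (gains/biases exempt); a
coupled-L2 mode exists. Learning rate 1e−3 and batch size 64 by
default (neither is dictated by the architecture; both exposed in
config). One epoch is one pass over the *original* trials; mirrors are
constructed per batch and not counted. The checkpoint is the weight
snapshot at the epoch of minimum training loss. Train/test subject
sets are checked for disjointness (the subject-independent contract)
and overlap triggers a warning.

Batch normalization uses batch statistics during training and running
statistics at inference, so inference outputs are independent of batch
composition.

## Numerical engine

No deep-learning framework is used: the network, its gradients and
Adam run on a small tape-based reverse-mode autodiff engine over NumPy
(`mclswt.autodiff`). Convolution and pooling are expressed as strided
sliding-window extraction plus matrix products; layer norm is a fused
op with the closed-form backward. Every op's gradient is verified
against central finite differences in the test suite. Default
parameter dtype is float32 (float64 available via `ModelConfig.dtype`).
Gradient buffers use copy-on-write accumulation, which is safe because
reverse-topological execution finalizes each node's gradient before
its backward runs.

## Preprocessing

For continuous recordings: volts→microvolts, 3rd-order Butterworth
band-pass applied forward–backward (zero phase; `low = 0` degenerates
to a pure low-pass), per-channel exponential moving standardization
(`factor_new = 0.001`, `init_block_size = 1000`, `eps = 1e−4`),
polyphase resampling to 250 Hz, and cue-locked epoching over
[−0.5 s, +3.98 s), giving 1120 samples. The standardization recurrence
is `m_t = (1−f)m_{t−1} + f·x_t`, `v_t = (1−f)v_{t−1} + f(x_t−m_t)²`,
output `(x_t−m_t)/max(√v_t, eps)`, initialized with `m = x_0`, `v = 0`;
the first `init_block_size` samples are standardized by that block's
own mean/std instead, which removes the burn-in bias of the
recurrence. Standardization is applied on the continuous signal by
default; whether it should instead be applied per epoch is genuinely
ambiguous, so a config switch (`standardize_stage`) offers both.
Epochs are half-open, 0-based: `[cue + round(t₀·fs), … + n)` with
`n = round((t₁−t₀)·fs)` — unambiguous at negative offsets and exactly
1120 samples at the defaults.

## Synthetic ERD/ERS data

Each channel is `env(t)·A·sin(2πf t + φ) + 1/f^γ noise`, with `A` the
mu amplitude (default 10 µV), `f` the subject's mu frequency
(10 ± 1 Hz), γ = 1, and noise RMS 8 µV — a typical sensorimotor
background level that leaves the mu peak clearly visible, as in real
EEG. After the cue (0.5 s into the 4.48 s trial) the envelope of the
channel contralateral to the imagined hand falls to `1 − d` and the
ipsilateral one rises to `1 + e` (defaults d = 0.5, e = 0.2); Cz is
unmodulated. Per-subject parameters are jittered once per subject
(relative σ = 0.1). The onset uses a 200 ms raised-cosine ramp by
default to avoid spectral edge artifacts; validation oracles disable
it.

Because `d` scales amplitude, band power scales by `(1−d)²`, giving
the exact oracle ERD% = 100·((1−d)² − 1): −75% at d = 0.5. ERD% is
quantified as in standard ERD protocols: baseline mu power from
−500…−100 ms before the cue, non-overlapping 300 ms epochs over
0–1500 ms after it, per-trial percentage change averaged over trials.
Band power is the integrated boxcar periodogram over 8–13 Hz; at the
default geometry 10 Hz falls on an exact DFT bin of both window
lengths, so the noise-free recovery is exact to float precision.

What the generator does **not** emulate: volume conduction and channel
covariance, non-stationary background spectra, eye/muscle artifacts,
BCI-illiterate subjects, and realistic class overlap. Passing tests on
this data demonstrate that the pipeline is implemented correctly and
that the model can localize lateralized band-power changes across
simulated subjects — not that the reported accuracies transfer to real
EEG.

## Desk-scale study sizes

The standard simulation study used by the heavier tests and by
`scripts/acceptance.py` generates trials at 125 Hz (560 samples over
the same 4.48 s window; L' = 536 remains divisible by M = 8) and uses
a compact network (d_model = 16, H = 4, MLP width 32, one block pair)
— the full-rate, d_model = 40 configuration remains the library
default. The study uses 6 training and 2 held-out subjects with 100
trials each at d = 0.5. At these settings the task is strongly
separable: both MCL-SWT and plain SWT typically reach 100% held-out
accuracy within a few epochs, so the accuracy comparison between them
saturates into a tie and the effect of the mirror contrastive loss is
instead visible in the embedding geometry (originals pushed away from
their mirrors relative to within-class spread). Tail ("average")
accuracy for short runs is taken over the final fifth of the history,
the proportional generalization of the 100-of-500-epoch convention.

## Known limitations

- Only 2-class (left/right) decoding: mirroring is undefined for
  feet/tongue imagery, so 4-class montages are out of scope.
- The attention blocks do not mask across the cyclic wrap in shifted
  windows; tokens at the sequence edges may attend to each other.
  With a convolutional front end and short windows this is benign,
  but it is a modelling choice, not a necessity.
- CPU-only by design; training wall-time grows linearly in trial
  length and dataset size.
- GDF/EDF reading requires the optional `mne` dependency and is a
  thin untested wrapper (no binary fixtures ship with the package).
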