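# Methods

## The physical model

The sensing element is a piezoelectric thin-film microbalance: a clamped
PVDF diaphragm (default: 28 μm film, 5 mm active diameter) driven through
the converse piezoelectric effect, resonating at an unloaded fundamental
f₀ = 8.5 kHz with quality factor Q = 27.6 (half-power bandwidth f₀/Q ≈
308 Hz). Mass adsorbed on the active surface increases the effective
vibrating mass and pulls the resonance down.

Two closed-form shift relations are implemented in `ptfm.physics`:

* **Sauerbrey** (rigid crystal substrate): Δf = −2f₀²Δm / (A√(ρ_q μ_q)),
  with substrate density ρ_q (g·cm⁻³) and shear modulus μ_q (g·cm⁻¹·s⁻²).
  The theoretical sensitivity S_M = 2f₀²/(A√(ρ_q μ_q)) follows by dividing
  out the mass; the empirical sensitivity S_m = −Δf/Δm comes from
  calibration data instead.
* **Thin polymer film** (the PVDF device): Δf = −f₀·Δm_A/(2ρt) for areal
  loading Δm_A ≪ ρt, i.e. direct in f₀ and inverse in both density ρ and
  thickness t. We read the flattened one-line form of this relation as
  −f₀·Δm_A/(2ρt) because that is the unique reading consistent with the
  stated scaling laws (direct in f₀, inverse in ρ and t); a −f₀²·(…)
  reading would contradict them. When the load exceeds 10% of ρt the
  function emits a `ValidityWarning` rather than an error — the threshold
  for "substantially smaller" is a package choice, as only the qualitative
  assumption is physically fixed.

All internal computation is CGS (g, cm, s, Hz). Public mass interfaces are
in micrograms, geometry in mm/μm, because those are the bench units; unit
conversion is covered by dedicated tests.

PVDF's density is not a device measurement; the package default is the
literature value ρ = 1.78 g·cm⁻³. Every number derived through it (e.g.
the −4.343 Hz/μg slope of the default device) is a model output, not a
measured constant.

The 0–9 μg class labels are interpreted as total deposited mass (not
per-step increments).

## The signal simulator

`ptfm.simulator` stands in for the hardware chain (signal generator →
film vibration → acoustic emission → 48 kHz smartphone microphone). The
generative model is a second-order resonator in steady state:

* the loaded resonance is f_r = f₀ + film_shift(Δm/A);
* the drive waveform (sine, square or triangle) is expanded in its Fourier
  harmonics, truncated at Nyquist; each harmonic is scaled and phase-shifted
  by H(f) = 1/((1 − (f/f_r)²) + i(f/f_r)/Q), which has unit DC gain, peak
  gain Q at f_r, and half-power width ≈ f_r/Q;
* the harmonic sum is scaled to unit peak, Gaussian noise (white with an
  optional 1/f fraction) is added at exactly the requested SNR for each
  realization, and the result is re-normalized to peak 1 (so 16-bit WAV
  export never clips).

Ring-down transients are omitted: a 0.1 s window of a continuously driven
sensor is quasi-steady. The microphone is assumed flat; propagation and
enclosure effects are folded into the single SNR parameter (default
30 dB). Per-segment seeds are derived from the master seed through
`numpy.random.SeedSequence(master, index)`, so datasets are bit-reproducible
and any single segment can be regenerated in isolation; generation order is
shuffled to emulate a randomized mass-load sequence per session.

**Default sizes are the study conditions**: 0.1 s mono segments at 48 kHz
(4800 points), 10 classes at 0–9 μg, 60/20/20 stratified train/val/test.
The full study scale is 2500 segments per class; tests and the benchmark
run at 250 per class, a deliberate desk-scale choice.

### What carries the mass information, and the benchmark design

With the physical constants, one microgram shifts the resonance by only
≈ 4.3 Hz — less than half of the 10 Hz bin spacing of a single 0.1 s
window. Under a fixed sine drive at f₀, the shift appears only in the
response amplitude and phase, and per-segment peak normalization removes
the amplitude cue. The simulator therefore exposes two knobs:

* `separation_scale` multiplies the physical per-class shift. It is a
  benchmark-construction knob for building easier or harder synthetic
  problems, never a statement about the device.
* the **harmonic-probe configuration**: a square-wave drive at f₀/3 places
  the third harmonic on the resonance. The *ratios* between harmonic
  amplitudes then encode f_r, survive normalization, and are monotone in
  mass — this is what the "well-separated benchmark" (separation_scale 40,
  30 dB SNR) uses, and on noiseless probe data the spectral centroid is
  strictly monotone in class.

Passing the benchmark therefore shows that the training/evaluation
machinery can extract a genuinely present spectral cue; it does not show
that the real device's 0.1 s recordings are separable at physical scale —
those recordings are not available, and the reference headline accuracies
(96.9 / 97.3 / 99.5%) are treated as metric worked examples recomputed
from reference confusion matrices, not as dataset benchmarks to reproduce.

## Features

* `dual_channel_input`: (4800, 2) — the z-scored raw waveform and its
  one-sided FFT magnitude linearly resampled from 2401 bins to 4800
  points and z-scored. One tensor, two channels; chosen over a dual-branch
  network for simplicity. Magnitude (not power or dB) scaling is used.
  Z-scoring uses a 1e-12 floor so constant segments map to zero.
* `frame_sequence`: the dual-channel input folded into non-overlapping
  48-sample frames → a (100, 96) timestep sequence. This is the recurrent
  model's input; running an LSTM over 4800 raw timesteps is numerically
  equivalent but ~50× slower, and the framing preserves both channels.
* `patchify`: sliding windows over the standardized raw waveform (defaults
  T = 48, stride = 48 → 100 tokens, C = 1) for the Transformer.

## Models

All three classifiers are built on `ptfm.nn`, a compact reverse-mode
autograd toolkit on numpy (float32 parameters, seeded Glorot/He-uniform
init, Adam). Gradients of every structured op (conv, pooling, batch norm,
LSTM, attention, layer norm, cross-entropy) are verified against central
finite differences in float64.

* **CNN**: [conv(k=9, 'same') → batch-norm → ReLU → max-pool] × n_blocks,
  then global average pooling, dropout (0.3), one FC layer, softmax.
  Channel widths double from 16 (cap 128); lengths are zero-padded to the
  pool multiple at each stage, and a configuration that would pool the
  input away entirely is rejected with the offending block named.
* **LSTM**: one recurrent layer with n_units memory blocks (standard
  forget/input/candidate/output gates, forget bias 1), dropout 0.2 on the
  last hidden state, one FC layer, softmax. The sweep axis is 20–160
  units in steps of 20.
* **Transformer**: linear patch embedding to d_model (X_emb), learnable
  additive positional encoding (X_pos = X_emb + PE), L post-norm encoder
  layers (MHSA + FFN, each with residual and layer norm), global average
  pooling over tokens (H_pooled from H_final), one FC layer, softmax.
  Defaults: d_model 64, 4 heads, FFN 128, dropout 0.1.

Hyperparameters not fixed by the architecture descriptions (kernel sizes,
channel widths, d_model, head count, FFN width) are recorded defaults
sized for desk-scale training, not inferred values. Softmax temperature is
1; argmax ties break to the lowest class index.

## Training and evaluation

Cross-entropy with Adam (lr 1e-3, batch 64, ≤ 50 epochs, early stop on
validation accuracy with patience 10) for all three architectures — Adam
is adopted uniformly. The checkpoint returned is the best-validation
epoch; the snapshot includes batch-norm running statistics along with the
weights, because restoring weights without their matching normalization
statistics produces an inconsistent model (this failure mode is real and
was the motivation for snapshotting buffers).

Splits are stratified per class with rounded val/test fractions and the
remainder assigned to train; a fixed seed reproduces the assignment
exactly. Metrics come from the K×K confusion matrix: accuracy =
trace/total, macro-recall and macro-F1 as unweighted per-class means.
For exactly balanced row sums macro-recall equals accuracy identically
(asserted to 1e-12 in tests); classes with empty rows are excluded from
macro averages with a warning. Architecture sweeps (blocks 1–9, units
20–160, depth L) aggregate n_reps seeded runs per value and record failed
runs rather than dropping them.

The benchmark configurations used by the accuracy checks (CNN 3 blocks /
8 base channels / pool 4, LSTM 32 units, Transformer L=2 / d_model 32,
8 epochs at lr 3e-3) are reduced-scale package choices; the full-scale
defaults (7 blocks, 140 units, L=18) remain available and are what the
CLI uses when no sweep value is given.

## Calibration

`ptfm.calibration` fits ordinary least squares (intercept fitted by
default; a through-origin variant is available) of shift against mass over
a 0–9 μg ladder and reports R² = 1 − SS_res/SS_tot, with R² defined as 0
for a constant response. The empirical sensitivity is −slope (Hz/μg) and
`predict_mass` inverts the line.

Shifts come from either route:

* **analytic** — the film-shift relation plus Gaussian frequency noise
  (readout jitter). With noise sd equal to 1% of the full-scale shift, the
  median R² over 200 replicates exceeds 0.99.
* **acoustic** — 1 s segments (1 Hz bins, ten times finer than the
  classification window) driven at the loaded resonance, read back through
  the spectral-peak estimator with 8× zero-padding and parabolic
  interpolation. Driving at the loaded resonance mirrors a swept/locked
  resonance measurement and avoids the Q-dependent peak-pull bias
  (≈ f_r/(8Q²) ≈ 1–3 Hz here) that a broadband estimate would carry.
  Noiseless round-trip mass recovery is within 0.01 μg.

## Numerical choices and degenerate inputs

* Peak interpolation uses the 3-point parabola; peaks on edge bins (DC,
  Nyquist) and flat spectra are returned flagged as unreliable.
* Pooling requires divisibility; maps are zero-padded per stage.
* The chance-floor check uses a physically-scaled dataset (sine drive at
  f₀, separation_scale 1): its class cue is far below what an untrained
  network can expose, so untrained accuracy is binomial around 0.1. On
  strongly separated data the per-class features are nearly deterministic
  and an untrained network maps whole classes together, which makes the
  binomial band the wrong reference.

## Known limitations

* The simulator's noise is stationary and Gaussian; real smartphone
  captures have room reverberation, transient interference, and a
  non-flat microphone response.
* Steady-state synthesis omits ring-down and drive transients.
* The classifiers' accuracy on the benchmark measures machinery, not the
  physical device's resolution; at physical separation the 0.1 s window
  fundamentally under-resolves the per-microgram shift.
* The LSTM consumes framed sequences, not raw 4800-step sequences; the
  architecture is identical, the tokenization is a tractability choice.
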