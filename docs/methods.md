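# Methods

This note documents the models, numerical choices and known limitations of
the scrumforce pipeline, stage by stage.

## Signal model and preprocessing

Each engagement trial consists of two players' C7/lumbar landmark tracks
(2-D metric coordinates, video rate 50 Hz; pixel-to-metre calibration is
assumed done upstream) and one shoulder's contact-force trace (500 Hz).
Preprocessing choices:

- **Filtering.** Second-order Butterworth low-pass, 20 Hz for landmarks and
  100 Hz for force, applied forward-backward (`scipy.signal.filtfilt`).
  The dual pass is a deliberate choice: it cancels phase so the engagement
  window is not lagged, at the cost of squaring the magnitude response
  (documented in the filter's docstring and asserted in tests via the
  closed-form dual-pass gain). A 20 Hz cutoff at a 50 Hz video rate is 80%
  of Nyquist; it is allowed but logged, because the bilinear-transform
  response there is strongly warped.
- **Differentiation.** Midpoint speed is the Euclidean norm of the
  finite-difference derivative of the C7-lumbar midpoint: central
  differences on interior frames, one-sided at the ends (`np.gradient`).
- **Windowing.** On the force clock: first sample strictly above 10 N up to
  the global force maximum (first occurrence on ties, for determinism).
  Window endpoints are mapped to video frames by rounding to the nearest
  frame; both channels are then independently resampled (linear
  interpolation) to 101 points of normalised time, which makes the 10:1
  rate mismatch irrelevant downstream. Windows spanning fewer than two
  samples on either clock are rejected as degenerate rather than
  interpolated.
- **Cleaning.** Peak plausibility bounds 2.5-4.5 m/s and 1-4 kN, inclusive
  on both ends (the weaker reading of "within the ranges"), applied after
  filtering. Every rejection is logged with the violated rule.

The resulting `VelocityForcePair` (101 samples per channel, force maximum
at the final sample, non-negative speed) is the interchange currency of all
later stages, stored as CSV (t_norm, velocity_ms, force_n) plus a JSON
metadata sidecar. GAN-generated pairs, and Mixup pairs that may inherit
GAN parents, are exempt from the two structural invariants since a neural
emitter cannot guarantee them pointwise.

## Synthetic data: what it emulates and what it does not

The simulator provides the study conditions for all tests. A trial draws

- peak engagement speed `v_peak ~ U(2.5, 4.5) m/s`; the speed profile is a
  Gaussian bump peaking at 55-80% of normalised time (width 0.18-0.28);
- a force curve `F(t) = 15 N + (F_peak - 15 N) * s(t)^gamma`, where `s` is
  a sigmoid ramp (steepness 6-10, midpoint 0.45-0.6 of normalised time)
  rescaled to [0, 1] and `gamma ~ U(1, 2)` — a monotone rise ending at its
  peak, starting just above the 10 N contact threshold;
- the deterministic peak-force mapping
  `F_peak = 700 N/(m/s) * v_peak - 500 N`, scaled by 0.85 for PreBind
  trials (the pre-bound engagement produces lower impact forces), clipped
  to 1.05-3.95 kN;
- additive N(0, 350 N) noise on the observed peak plus 2% smooth
  multiplicative noise on the curve (three low-order Fourier components
  under a sin(pi t) envelope that vanishes at the window ends).

The slope/intercept/noise values were chosen once so that defaults stay
inside the cleaning bounds and the peak-speed/peak-force correlation is
moderate (~0.6-0.8) — a positive but noisy association, reflecting that
pack mass and technique, which the predictor never observes, also drive
force. The *noise-free* curve (deterministic mapping, no epsilon) is
retained as ground truth so prediction error can be measured without the
irreducible observation noise.

Raw-trial inversion produces a 0.6 s quiet approach (force < 2 N), an
engagement of 0.9-1.3 s (snapped to the video-frame grid so the force
window's endpoints fall on whole frames), and a sub-peak exponential decay
tail. The midpoint tracks follow the analytic speed profile with optional
white positional jitter; two players move in opposite directions so the
pair mean equals the profile. Preprocessing recovers the source pair to
within 0.5% (speed) and 0.3% (peak force) at zero jitter.

Deliberately not modelled: the sustained pushing phase after the peak,
per-player asymmetries, sensor drift or saturation, pose variation, and
any real biomechanics of the collision. Passing tests therefore demonstrate
that the pipeline recovers the statistical structure it assumes —
smooth unimodal speed, monotone force rise, noisy positive coupling — not
that it is accurate on real scrums; that check requires the deposited
measured dataset (see README).

## Adversarial augmentation

Architecture (generator: dense 50->26x128, batch norm, transposed conv
64/SELU, batch norm, transposed conv 2/tanh (26->52->104 steps), dense 202
tanh; discriminator: conv 64 and 128, LeakyReLU 0.2, 40% dropout, dense 1
sigmoid; kernel 5, stride 2, zero padding throughout) and optimiser (Adam,
1e-3, for both networks) follow the published design. Points the
publication leaves open were resolved as follows:

- The 202 generator outputs are packed velocity[0..100] then force[0..100];
  curves enter the tanh range via per-channel max-abs constants computed on
  the training set and stored with the model.
- Loss: standard non-saturating binary cross-entropy, one discriminator
  step per generator step; one-sided label smoothing (real label 0.9) and
  instance noise (SD 0.05 on discriminator inputs, decaying linearly to
  zero by mid-training) stabilise training on desk-scale datasets.
- Training controls default to 3000 epochs, batch 32, and are routinely
  reduced in tests and scripted runs; a single seed drives weight init,
  batching, latent draws and dropout, making runs bitwise reproducible.
- Fidelity is reported by matching each generated curve to the measured
  curve with the highest Pearson correlation per channel and averaging the
  matched correlations and RMSEs — the matching rule is recorded in the
  report because other pairings are defensible.

Even stabilised, adversarial training on tens to hundreds of curves shows
partial **amplitude collapse**: generated shapes are faithful (matched
correlations ~0.98-0.99) but peak amplitudes under-disperse relative to
the data, and the collapse point wanders between runs. Because downstream
the regressor must see realistic amplitude variation, the generated pool
is passed through **peak recalibration**: per channel, curve peaks are
quantile-matched to the measured peak distribution by rescaling each curve
(the i-th smallest generated peak maps to the corresponding empirical
quantile of measured peaks). Both maps are monotone, so within-pair rank
coupling between speed and force amplitude is preserved, and Pearson shape
fidelity is unchanged (correlation is scale-invariant). Recalibration is
on by default in `build_augmented_dataset` and can be disabled.

Mixup forms convex combinations (fixed coefficient 0.5) of two distinct
pairs drawn from the generated pool; drawing parents from the measured set
instead is available behind a flag.

## Sequence regressor

Two stacked LSTM layers (128, 64 cells; forget-gate bias 1, Glorot init)
and a per-time-step dense ReLU head; MSE on max-abs-scaled force; Adam at
0.002; batch 32; early stopping on validation MSE (patience 50 by default)
with best-weight restoration. The width-1 ReLU head is initialised with a
small positive bias (0.1): an all-negative initial pre-activation would
zero every gradient and leave the network permanently dead.

Normalisation constants (max absolute value per channel) come from the
training split actually fitted and are persisted with the model; inference
applies the stored constants and returns newtons, so physical-unit inputs
can never be scaled twice.

The hyperparameter grid — layers {1,2,3} x cells {32,64,128} x learning
rate {0.001,0.002,0.01}, 27 candidates — is searched with k-fold
cross-validation (5 folds by default) on mean validation MSE; a candidate
uses one cell width for all layers, since the stated grid cannot produce
mixed widths. The mixed-width [128, 64] network remains the package
default regardless of local grid results, as the published final model.

## Evaluation

- Correlation bands: poor <= 0.5 < moderate <= 0.75 < good <= 0.9 <
  excellent. The published band edges overlap, so shared endpoints go to
  the lower band (0.9 is "good").
- Bland-Altman differences are predicted minus measured (positive bias =
  overestimation); limits use the n-1 SD. Peak differences are reported as
  absolute values in tables while signed values feed Bland-Altman.
- Per-trial percentages normalise by that trial's maximum measured force;
  grouped tables renormalise by the maximum force across the group's
  measured curves.

## Protocol and leakage guard

`run_end_to_end` hard-codes the published protocol: the regressor trains
and validates on augmented data only (80/20 split) and is tested on the
measured pairs, which never enter training. The guard is structural —
every pair carries a provenance label (measured / synthetic / gan /
mixup), and an augmented label in the test set aborts the run — rather
than a convention.

## Problem sizes and numerical tolerances

Scripted runs and the test suite use a 60-trial simulated cohort, a
400-pair GAN + 200-pair Mixup augmented set, 500 GAN epochs (batch 16) and
up to 100 regressor epochs (patience 25); these budgets were chosen from
training-loss convergence on the synthetic cohort. Under them the
end-to-end run scores mean r ~0.98 and nRMSE ~11-13% against noise-free
ground truth across seeds. Oracle comparisons use 1e-9 (exact for index
arithmetic); preprocessing round-trips allow 2% (speed) and 1% (peak
force); the Bland-Altman large-sample check allows 2% at n = 1e5.

## Known limitations

- The NumPy backend is CPU-only and flops-bound on the LSTM; it is sized
  for hundreds-to-thousands of 101-point curves, not larger corpora.
- GAN amplitude statistics rely on the recalibration step; the raw
  generator under-disperses amplitudes on small datasets.
- The regressor sees only the engagement-speed curve: technique- and
  mass-driven force differences are irreducible error by construction.
- Grid-search cross-validation on the augmented set inherits whatever bias
  the augmentation introduced; it is a model-selection tool, not an
  unbiased performance estimate.
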