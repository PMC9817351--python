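# Methods

This note documents the models, the synthetic study conditions, the
numerical choices, and what the validation suite does and does not
establish.

## State-space decoder

A scalar latent pain state follows a stationary AR(1) process,
`z_k = a z_{k-1} + eps_k` with `eps_k ~ N(0, sigma^2)` and `0 < |a| < 1`;
the three binned band amplitudes are a linear-Gaussian readout,
`y_k = c z_k + d + v_k`, `v_k ~ N(0, Sigma)`.  The latent state is a
*common input* assumption: one process modulates low gamma, high gamma and
spiking-band power together.  Nothing in the model is specific to pain —
selectivity comes entirely from the choice of bands and the stimulus-locked
analysis windows.

**Filtering.** The Kalman recursions are implemented in the standard
predict/update form.  Because the state is scalar, the gain is computed
with the matrix-inversion lemma, `G_k = [Q_p/(1 + Q_p s)] c^T Sigma^{-1}`
with `s = c^T Sigma^{-1} c`, after one Cholesky factorization of `Sigma`;
each step is O(m) and the innovations-form log-likelihood comes out of the
same quantities.  A singular `Sigma` is rejected (`SingularCovarianceError`)
rather than regularized silently.  The filter prior is `z_0 = 0` with
`Q_0 = sigma^2/(1 - a^2)` (the stationary variance), so the prediction for
the first bin is already stationary.

**EM.** The E-step uses the full Rauch–Tung–Striebel smoother; the M-step
needs the smoothed lag-one covariances, which the backward pass provides,
including the smoothed initial state.  Updates for `a`, `(c, d)` and
`Sigma` are the usual closed forms.  Two deliberate choices:

* *Scale fixing.* The latent scale is unidentifiable (`c z` is invariant
  under `z -> alpha z`, `c -> c/alpha`), so `sigma^2` is held at 1 and `c`
  absorbs the scale.  Every reported quantity (Z-scores, latencies,
  the stationary observation covariance `c c^T sigma^2/(1-a^2) + Sigma`)
  is invariant under this convention, and the test suite asserts that
  invariance explicitly.
* *Fixed initial prior.* The initial-state prior is frozen at the starting
  parameters across iterations, so every iteration maximizes the same
  likelihood and the log-likelihood trace is non-decreasing by
  construction; a decrease beyond 1e-9 raises an internal-consistency
  error.  Convergence: absolute log-likelihood change below 1e-6, capped
  at 500 iterations (on 5000-bin series EM typically needs ~450 iterations
  to push the autoregressive coefficient to its final value; truncating at
  200 leaves a visible bias in `a`).

Initialization is moment-based: `d` = feature means, `c` along the first
principal direction of the centered features scaled to the implied
stationary variance, `Sigma` = diagonal residual covariance, `a = 0.5`.

**Z-scoring and detection.** The *filtered* (not smoothed) state is
standardized against the pre-stimulus baseline bins — the decoder is meant
to be causal at deployment time.  The CI half-width is
`Phi^{-1}((1+level)/2) * sqrt(Q_{k|k}) / SD(z_baseline)`: dividing by the
baseline SD puts the posterior uncertainty on the same Z scale as the
standardized state, which is the only reading under which "Z − CI >
threshold" is well-typed.  The threshold 3.38 is treated as an opaque
configurable constant.  The Z-peak latency uses the absolute Z value
uniformly for both modalities, and bin *start* times are reported, so
latencies are quantized at the 100 ms bin width.

**Per-trial fitting.** The pipeline fits the model independently per trial
on the 0.5 s pre-stimulus baseline plus the response window (0.5 s for
mechanical; onset-to-withdrawal for thermal).  Mechanical trials therefore
give only 10 bins — enough for the decoder to track a strong band-power
transient, but the fitted `a` on such short windows is noisy and should not
be interpreted.  Fitting per trial keeps trials statistically independent
for the paired test and mirrors per-trial Z-scoring.

## ERP latency

Trials are cut from the channel average after zero-phase 4–100 Hz
band-pass filtering (4th-order Butterworth, forward–backward), preserving
latencies exactly.  Candidate peaks are local extrema of either sign in a
±2-sample neighborhood (plateaus resolve to their first sample) whose
absolute deviation from the baseline mean exceeds 3 baseline SDs; the
latency is the earliest candidate.  This deterministic first-peak rule
replaces a manual replot-and-select step; the suite checks it against an
exhaustive scan of all supra-criterion extrema.  Trials with no candidate
report an absent latency and are dropped pairwise from comparisons (and
counted).  Whether the 3 SD criterion should be signed is ambiguous;
absolute deviation is used because raw-LFP ERPs can be negative-going.

## Synthetic sessions

The generator produces the study conditions; its defaults are fixed, not
tuning knobs.

* **Background.**  Each channel is 1/f Gaussian noise (spectral exponent
  beta = 1 from 1 Hz to Nyquist, exact RMS = `noise_level`, default 50 µV)
  plus an ongoing theta-range oscillation: constant amplitude
  3 × `noise_level`, instantaneous frequency wandering slowly in 4–7 Hz.
  The rhythm matters: rodent cortical LFP baselines are oscillation-
  dominated, and a "3 SD from baseline" single-trial criterion is only
  selective in that regime.  On rhythm-free 1/f noise the criterion's
  false-candidate rate in a 150–250 ms pre-peak window is ~10–18%
  regardless of the noise level (the threshold is scale-free), which would
  make single-trial first-peak latency estimation unusable — on real data
  as well as simulated.  With the constant-envelope rhythm the baseline SD
  is dominated by a component whose extrema never reach 3 SD, and the
  false-candidate rate drops below ~0.5%.
* **ERP.**  A 10 Hz cosine under a narrow Gaussian window (SD 6 ms),
  peaking exactly at onset + planted latency, added coherently to all
  channels (default 700 µV).  The width is chosen so the pulse is
  effectively monophasic *after* the 4–100 Hz filter: wider pulses contain
  enough sub-4 Hz energy that zero-phase high-passing synthesizes an
  anticipatory undershoot tens of ms before the peak, which a first-peak
  rule will latch onto.  With the 6 ms width the precursor is ~12% of the
  peak; ERP amplitudes must therefore sit between ~5 and ~25 baseline SDs
  for clean recovery, and the defaults do.
* **Band-power transients.**  The recording's own band-limited components
  are amplitude-modulated (so injection is exactly local in time and an
  identity at gain 1): mechanical = step to `gain` then exponential decay
  (time constant 0.5 s over a 0.5 s support); thermal = linear ramp from
  onset + latency to the trial's withdrawal time, then off.  Default gain 4
  in all three bands.
* **Trial structure.**  Mechanical: 96 trials, 3 s spacing, planted
  latencies S1 = 150 ms / ACC = 250 ms, per-trial latency jitter SD 30 ms.
  Thermal: 48 trials, 10 s spacing, equal planted latencies (200 ms),
  jitter SD 50 ms, withdrawal = 4.0 ± 0.3 s truncated to [3, 5] s,
  no ERP (slow ramps evoke none).  Latency jitter is drawn independently
  per trial and region and recorded in the ground-truth table.
* **Determinism.**  One master seed per session; per-trial draws come from
  fixed-counter substreams (`[seed, purpose, trial, region]`), so adding
  trials never reshuffles earlier ones and identical protocols are
  bit-identical.

What the generator does **not** emulate: spikes, movement/locomotion
artifacts, electrode drift, volume conduction between regions, cross-band
phase coupling, or any biophysical (conductance-based) LFP mechanism.
Passing tests on these sessions shows the estimators are correct under the
planted-effect model, not that real recordings satisfy that model.

## Validation design

* Filter and smoother moments are checked against dense joint-Gaussian
  conditioning (an O(K^3) oracle that never uses the recursions) to 1e-8
  relative error over random stable systems.
* EM is checked for monotone likelihood ascent and for recovery of the
  identifiable quantities only: `a` (to ±0.05) and the stationary
  observation covariance (to 10% relative Frobenius) at K = 5000.
* Detector calibration uses a long stimulus-free simulation from the
  fitted model with a 30 s baseline; the confidence-bound criterion must
  fire in fewer than 1% of 10,000 one-second windows.  A 300-bin baseline
  is used here (rather than the per-trial 5 bins) to measure the
  threshold's intrinsic false-alarm rate without small-sample baseline
  noise.
* The mechanical re-enactment requires ERP latency recovery within 10 ms
  on ≥ 95% of trials and both paired tests to reject at p < 0.01 with the
  ACC-longer direction; the thermal re-enactment requires the paired
  Z-peak test *not* to reject in ≥ 90% of 20 replicate sessions, plus a
  type-I calibration of the paired test itself (0.05 ± 0.02 over 1000
  simulated null tables).

Problem sizes in the suite (96 mechanical trials; 20 × 48 thermal trials;
K = 5000 × 20 EM replicates; 10,000 calibration windows) were chosen to
match the re-enacted designs while keeping the full suite in the
ten-minute range on a single CPU.

## Known limitations

* Latencies from the decoder are quantized at the 100 ms bin; sub-bin
  timing comes only from the ERP estimator.
* The paired test pools trials; rat-level clustering (several animals
  contributing trials) is not modelled — a mixed-effects extension would
  be needed for real multi-animal data.
* No multiple-testing correction across the ERP and Z-peak measures, which
  are reported separately by design.
* The decoder assumes Gaussian observation noise on band amplitudes;
  amplitude envelopes are non-negative and right-skewed, so the model is
  at best a working approximation (it is the same approximation the
  analysis it implements makes).
* Channel selection implements the artifact and SNR criteria only; a
  spike-activity criterion would require spike data the sessions do not
  contain.
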