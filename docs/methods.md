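# Methods

## Problem and model

Steady-state visual evoked potentials (ssVEPs) are oscillatory EEG
responses phase-locked to a periodically modulated stimulus — here a
grating whose contrast reverses every 100 ms, driving a second-harmonic
response at 10 Hz. Sensor EEG is modeled as an instantaneous linear
mixture `x(t) = A s(t) + n(t)` of cortical sources; the goal is a single
unmixing vector `w` such that `w^T x` isolates the ssVEP source, whose
trial-wise amplitude is then correlated with BOLD fMRI voxel series
recorded simultaneously.

## Functional Source Separation

Plain ICA chooses `w` purely by a statistical criterion
(non-Gaussianity), which on band-limited EEG is easily captured by
ongoing alpha-band activity. Functional Source Separation adds a
*functional* term encoding when the source of interest should be
active. The contrast maximized here is

    F(w) = Σ_phases [ J(w) + λ · ψ(R_stim(w), k) ]

with, per experimental phase (habituation / acquisition / extinction):

* `J(w) = (E{G(w^T x)} − E{G(v)})²`, the log-cosh negentropy
  approximation used by fastICA; `G(u) = log cosh(a₁u)/a₁`, `a₁ = 1`,
  `v` standard normal. The projection is renormalized to unit variance
  before every evaluation, so `F` is scale- and sign-invariant.
  `E{G(v)}` (≈ 0.37457 for `a₁ = 1`) is computed once by adaptive
  quadrature and cached.
* `R_stim(w)`: the evoked average `EA(t)` (trial average of `w^T x` on
  the −1…+7 s epoch window) is passed through `abs(Hilbert(·))`; the
  mean envelope over the stimulation window `[t_s, t_e] = [0, 5]` s
  minus the mean over the baseline `[t_b, 0] = [−1, 0]` s.
* `ψ(r, k) = r/k` for `r ≤ k`, else 1: a saturation that makes the
  functional term an admissibility constraint — above the required
  minimum response `k`, optimization is driven by `J` alone.
* `k` per phase: the maximum `R_stim` over a plain fastICA
  decomposition of that phase's data; clamped to a 1e−6 floor on null
  data so `ψ` stays defined.
* `λ = 10` for ssVEP recovery; `λ = 0` reduces the method to
  single-component ICA and is the built-in comparison mode.

Before extraction, data are band-passed 10 ± 0.5 Hz with a 4th-order
Butterworth applied forward–backward (zero phase, so phase-locked
averaging is unaffected). Expectations in `J` are sample means over all
samples of the phase's narrowband recording; per-phase terms are summed
over the three phases ("joint optimization"), with a concatenation
variant exposed as `combine="concat"`.

### Optimization

`ψ` is non-differentiable at `r = k`, so the contrast is maximized by
simulated annealing on the unit sphere of channel weights:

* warm start at the fastICA component (over all phases) with the
  highest joint contrast, plus one random restart;
* Gaussian proposals (scale 0.3, shrinking with the square root of
  temperature) followed by renormalization;
* initial temperature auto-calibrated from the spread of contrast
  changes under initial proposals; geometric cooling (factor 0.85,
  10 proposals per level) down to 1% of the start temperature;
* a 100-step greedy small-step polish from the best point;
* deterministic given the schedule seed.

Two engineering choices keep a full three-phase extraction at a few
seconds without changing the estimator: fastICA (used only for `k` and
warm starts) runs on 8×-decimated narrowband samples — the 1 Hz-wide
band is far oversampled at 250 Hz — and the annealer scores proposals
on 2×-strided samples, while every reported diagnostic (`J`, `R_stim`,
`H`, the final contrast) and the extracted source use the full data.
fastICA's fixed-point iteration rarely meets sklearn's tolerance on
narrowband (temporally dependent) data even when the unmixing is
accurate; the decomposition is therefore accepted with a warning flag
rather than rejected (`strict=True` restores hard failure).

The sign of `w` is fixed so the largest-|weight| channel is positive;
source polarity is not physically recoverable and all downstream
statistics are sign-invariant.

## Evaluation metrics

* `snr_evoked`: mean power of the trial-averaged source in 0–5 s over
  mean power in −1–0 s. Averaging before squaring rewards phase-locked
  activity; a `single_trial` flag switches to mean single-trial power.
* `snr_offset_check`: same ratio against 5.6–7 s, a window the
  extraction objective never sees — a validity check that the
  oscillation attenuates after stimulus offset.
* `snr_raw`: trial-averaged power spectrum of a raw channel (default
  Oz); 10 Hz bin over the mean of the 0.5–30 Hz bins excluding the
  target bin ± 1 (leakage guard).
* `ssvep_amp`: 1 s moving windows (10 cycles) stepped by 100 ms over
  the trial-averaged 0–5 s trace are averaged in the time domain and
  Fourier-transformed; the 2/N-scaled 10 Hz amplitude is returned.
  Integer-cycle windows make the estimate leakage-free, and the 100 ms
  step is itself one full cycle, so window averaging preserves the
  10 Hz phase.

## ssVEP–BOLD fusion

The extracted source's instantaneous amplitude (Hilbert envelope, 1 s
mirror padding) is averaged within each scan's [onset, onset + TR)
interval — averaging the raw 10 Hz oscillation over a 1.98 s scan
cancels to ≈ 2A/(2πfT) ≈ 0.016A — standardized, and shifted forward by
`round(4 s / TR) = 2` scans, the consensus hemodynamic latency applied
as an integer-scan shift. The map statistic per voxel is the absolute
Pearson correlation (bivariate xMCC). Zero-variance voxels are reported
as missing, never as zero, to keep null calibration honest.

Per-participant inference: a null distribution from circular shifts of
the neural series (minimum offset 10 scans, preserving its
autocorrelation, unlike naive relabeling), add-one p-values
`(1 + #{null ≥ obs}) / (1 + n_perm)`, threshold `p < 0.05`; a
max-statistic variant is available. Group level: per-voxel counts of
individually significant participants are compared with a
Binomial(n_participants, 0.05) null, Bonferroni-corrected over the
in-mask voxel count; the overlap threshold is the smallest count whose
corrected tail probability is below 0.05 and is computed from the
actual mask size rather than hard-coded. Clusters are 26-connected
components on the 3-D grid.

## Co-simulator

The generator emulates the study conditions end to end: 31 channels
(extended 10–20 montage) at 250 Hz; 3 phases × 40 trials; 5.1 s
stimulus; inter-trial interval uniform(0, 8) s plus a 3 s fixation
cross; BOLD at TR = 1.98 s on a 512-voxel grid (8×8×8) of which a
4×4×3 block of 48 voxels is coupled.

* ssVEP source: 10 Hz sinusoid phase-locked to each onset, gated by
  100 ms cosine ramps (smooth rise/fall avoids spectral splatter),
  per-trial amplitude log-normal with σ = 0.4 — the fluctuation law is
  not empirically constrained; log-normality gives strictly positive,
  right-skewed single-trial amplitudes. Topography peaks at Oz.
* distractor: amplitude-modulated narrowband noise centered at 10.5 Hz
  (inside the analysis band's edge) with a log-normal slow envelope
  (σ = 1.0), making it the *most non-Gaussian* in-band source — the
  condition under which a purely statistical criterion is drawn away
  from the ssVEP and the functional constraint earns its keep. Its
  topography is parieto-central, distinct from the ssVEP's.
* 10 broadband (0.5–30 Hz) noise sources with random topographies,
  plus sensor white noise at unit signal-to-noise RMS ratio.
* BOLD: coupled voxels are `ρ·z + sqrt(1−ρ²)·ε` with `z` the
  standardized neural regressor — by default the canonical double-gamma
  HRF (peak 6 s, undershoot 16 s, ratio 1/6) convolved with the
  continuous ssVEP amplitude envelope, so the fixed 4 s shift used by
  fusion is a deliberate approximation of the "true" hemodynamics; a
  pure-shift coupling mode exposes the lag itself. Coupling ρ = 0.5 by
  default — a strong-coupling regime chosen so per-participant
  detection is near ceiling and group overlap exercises the binomial
  threshold rather than per-voxel power; the true ssVEP–BOLD coupling
  strength is a free simulator parameter, not an empirical claim.
  Uncoupled voxels are white Gaussian noise (AR(1) optional).

What the simulator does **not** emulate: MR gradient and
ballistocardiogram artifacts, eye blinks, volume-conduction head
models, spatially correlated BOLD noise, scanner drift. Passing tests
therefore show that the estimator chain is correct under its own
assumptions (linear mixing, narrowband target, lagged linear coupling),
not that those artifacts are handled — the pipeline expects cleaned
input.

## Numerical choices and degenerate inputs

* `log cosh x` is evaluated as `|x| + log1p(e^{−2|x|}) − log 2`
  (overflow-free for any `x`).
* Epochs include both endpoint samples (length `(t_max−t_min)·fs + 1`);
  trial onsets are aligned to the sample grid so `t = 0` is exact.
* The epoch window is −1…+7 s everywhere (superset of all uses:
  stimulation integral to 5 s, offset check to 7 s); `R_stim`
  integrates 0–5 s only.
* Hilbert transforms mirror-pad by 1 s so envelope edge artifacts stay
  outside every integration window.
* Zero-variance projections raise; constant per-scan summaries raise
  (relative tolerance 1e−9); degenerate voxels become missing values.
* An annealing run that accepts no move returns a warning flag rather
  than failing.

## Problem sizes used by the shipped checks

The acceptance tests run 20 seeded three-phase co-simulations for the
FSS-vs-ICA comparison and 5 seeded six-participant studies (500
permutations each) for the group overlap check; the permutation
calibration uses 2000 null voxels × 200 permutations. These sizes give
stable pass/fail margins at desk scale and are the package's chosen
defaults for its own verification.

## Known limitations

* Single-component extraction only; no deflation for multiple sources.
* The group binomial test assumes exchangeable participants and
  voxel-wise independence under the null (Bonferroni is conservative
  under spatial smoothness).
* The integer-scan lag ignores sub-TR latency differences;
  HRF-convolved coupling attenuates the measured correlation relative
  to its generative value.
* Real-recording readers (BrainVision/EDF) pass data through unchanged;
  artifact removal must happen upstream.
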