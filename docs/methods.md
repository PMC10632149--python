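# Methods

This note documents the models and procedures synckit implements, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was open.

## Time conventions

All times are seconds on one session clock starting at 0. Bins are
half-open `[t, t + dt)`; a spike exactly at a bin edge belongs to the later
bin. Cross-device clock alignment (sync-pulse calibration) is assumed done
upstream and is not modelled.

## Wavelet spectrogram and syncope detection

Power is computed with analytic generalized Morse wavelets, implemented
directly in the frequency domain: Ψ(ω) ∝ ω^β e^(−ω^γ) on ω > 0, peak
frequency ω_p = (β/γ)^(1/γ), with γ = 3 and β = 20 (time–bandwidth
γβ = 60, the common default of MATLAB-style continuous wavelet analysis).
Eighty filters are log-spaced from exactly 0.5 to 120 Hz. Each frequency
row is divided by its mean over the pre-stimulus baseline window, so
baseline power is 1 per row by construction; normalization is idempotent.
The spectrogram time axis is block-averaged by a configurable factor
(default 10) before thresholding — the syncope statistic works at ~50 Hz
resolution, and this keeps permutation testing tractable.

Syncope onset is the first post-laser time at which the 8–100 Hz row
average, smoothed by a centred 1-s moving mean, falls below 0.5; the
offset is the first later time it exceeds 0.8. The smoothing window is the
main knob: it trades detection jitter (≈ ±0.1 s at the default) against
robustness to brief power dips. The smoothing window itself is a design
choice (the operation is described qualitatively in the field as
"smoothening"); 1 s matches the seconds-scale bouts being detected.

### Cluster permutation test

Light-on vs light-off freq × time maps are compared by shuffling condition
labels (default 1000 permutations; 500 in the calibration experiments).
The per-pixel permutation distribution sets a two-sided cluster-forming
threshold (default p = 0.05); supra-threshold pixels form 4-connected
clusters. Cluster size is the pixel *area*, as is conventional for this
analysis family — but a pure integer area gives the null maximum heavy
atoms and makes the test badly conservative on small maps (measured
family-wise error ≈ 0 at nominal 5%). Each cluster's statistic therefore
adds a sub-unit tie-break, mass/(1 + mass) with mass the summed exceedance,
which preserves the area ordering while making the null effectively
continuous; measured null calibration is then 4–7.5% against the nominal
5% (0.025 per tail). Empirical p-values use (1 + #{null ≥ obs})/(n_perm+1).
Whether baselines are per-trial or pooled is configurable; per-trial is the
default.

## Spike statistics

*Curation.* Firing rates in 100-ms bins are smoothed with a Gaussian of
σ = 30 s ("width" read as σ, switchable); a unit drifts if max/min of the
smoothed rate exceeds 5, with the minimum floored at 10⁻³ Hz so part-silent
units are flagged. Units under 0.25 Hz (strictly) are excluded. Curation
order is fixed: drift, then rate, then all downstream statistics.

*Inactivity at syncope.* For baseline rate λ (computed excluding the
encoding-model test segments), the silent run needed for chance probability
1% is k = ⌈−ln 0.01/(λ dt)⌉ bins of dt = 1 ms, capped at 4000 bins (4 s).
Silent runs are the intervals between consecutive spikes. A unit is
inactive when a run of ≥ k bins begins in the 250 ms *preceding* the
syncope onset (default `sided="pre"`): suppression that starts at onset
leaves the run's first silent bin just before it, so this reading keeps
full sensitivity to programmed silencing while halving the null rate
relative to a two-sided window — under a two-sided reading a stationary
unit at rate λ is false-flagged with probability ≈ 1 − e^(−0.005λ), which
exceeds 5% for typical awake rates by construction. Both alternatives
("two", "post") remain configurable. Time-off is the fraction of the
syncope window's 1-ms bins inside qualifying runs, computed only for
inactive units; when the bout offset is undefined the window ends at the
stimulation end. A random-window control applies the same criterion at a
uniformly drawn onset that avoids laser and syncope periods, and the
per-region inactive fractions are compared with a paired t-test.

*Laser-response latency.* Windows [onset, onset + t) grow in 1-ms steps up
to 1 s (configurable cap; no upper bound is inherent to the statistic).
The pooled count n across the N = 4 aligned windows is scored with the
Poisson tail P(≥ n | Nλt) (scipy's survival function, log-space stable);
the latency is the first t below 10⁻⁶. Because the statistic must
accumulate ~6–13 spikes of evidence beyond chance, its resolution is set
by the evoked rate: a sustained step of a few tens of Hz cannot be located
to 10 ms, whereas a realistic onset burst (hundreds of Hz for tens of ms,
as strong opto-evoked responses show) can. The generator therefore
programs responses as a 400-Hz, 30-ms burst followed by a sustained
50-Hz step.

*Activation classification.* A unit is laser-activated when (1) its mean
behaviour-prediction residual over the four 0.8-s laser-onset windows is
strictly positive, (2) the onset residual strictly exceeds the 0.8-s
pre-laser residual for every train, and (3) its latency is under 250 ms.
Region summaries report the median latency of activated units, the
percentage inactive at syncope, and mean time-off.

## Behaviour features

Motion energy is |frame_t − frame_{t−1}| with the first frame's energy set
to 0. SVD is computed in temporal segments (default 1000 frames); the
per-segment bases, weighted by singular values, are stacked and reduced by
a second SVD — on desk-scale inputs the resulting top-10 subspace agrees
with a direct SVD to < 5° principal angle. Whisking is the L2 norm of the
top-10 whisker motion components. Pupil keypoint coordinates are median
filtered over 5 frames; area = π(a/2)(b/2) from the vertical and
horizontal axes; frames with confidence < 0.75, a blink (dark-pixel count
below a configurable threshold, one value per animal cohort), or a
degenerate axis are undefined and propagate as missing — never
interpolated by default. Baseline normalization divides by the mean over
−30…0 s before laser onset (−6…−4 s before syncope for whisking), with
summaries over +5 s post-laser and +2 s post-syncope.

## Encoding model

The split tiles the session into 50-s non-test segments (80/20
train/validation by seeded draw) after carving out one 63-s laser-free
control segment and one 63-s window (−3…+60 s) per laser; lasers never
touch train or validation, and the segment length is deliberately long
relative to the behaviour autocorrelation (~2 s) to prevent leakage.

The network is linear (input → 200) → temporal convolution (kernel 15
frames ≈ 0.5 s, 100 channels, evaluated at the frames aligned with each
100-ms bin centre, i.e. the 30-Hz conv output subsampled at 10 Hz) → ReLU
→ linear bottleneck (32, the latents) → linear output, trained full-batch
with AdamW (lr 10⁻³, weight decay 10⁻⁴) under MSE on the binned rates in
Hz, early-stopped on validation MSE (patience 10, best weights restored).
Widths, kernel, latent dimension, loss and schedule are configuration
defaults chosen for desk-scale stability; the architecture shape and the
optimizer are fixed. The implementation is plain numpy with hand-written
backpropagation — the model is small enough that no autodiff framework is
needed — and all initialization is seeded.

The nearest-neighbour prediction finds, for each test latent, the 50
nearest training latents (Euclidean; ties broken toward the earlier
training time via a stable sort) and averages the *recorded* activity at
those times — not the model outputs; averaging model outputs could never
beat the direct prediction, whereas averaging recorded activity acts as a
nonparametric regression in latent space and does. Residual = recorded −
nearest-neighbour prediction, exactly, bin-wise; positive residual means
the model underpredicts. Variance explained and 1-s-binned correlations
are reported per unit on the control and laser segments separately.

The kNN average inherits the usual density-gradient bias: with few
training bins its neighbourhood radius grows and predictions are pulled
toward high-density (low-rate) states. The validation experiments
therefore use sessions long enough for ~8 training segments, where the
measured pre-laser residual is ~4% of the mean rate.

## Physiology

ECG is band-passed 10–50 Hz (zero-phase); R peaks are detected with
adaptive prominence (4× the MAD of the filtered trace), a 70-ms refractory
distance, and a second pass that keeps only peaks above half the typical
candidate height — band-limited impulse trains otherwise yield inter-beat
ripple peaks. Instantaneous bpm = 60/RR assigned to interval midpoints,
interpolated to the sample grid and smoothed with a 1-s moving mean; each
stimulation is normalized to its 30-s pre-laser baseline ("30 s to 1 min"
read as 30 s, configurable). Respiration uses a 1–10 Hz band (a mouse
breathing range; the extraction parameters are this package's choice) and
the same rate pipeline. Quantification windows: heart rate 6–24 s (centre
of stimulation) and 30–60 s (post-onset); respiration 6–15 s and 36–45 s.
Adaptation isolation subtracts the trace shifted by 10 s (PBG) or 40 s
(PE): output(t) = x(t) − x(t − shift).

LDF is normalized to the 30-s pre-stimulation baseline, median filtered
over 500 ms. Metrics: (1) latency to fall below 0.5; (2) minimum during
the 30-s stimulation; (3) transit width — the contiguous stretch around
the trial minimum below (1 + min)/2, reading "full width at half-minima"
as halfway between baseline and minimum; (4) mean over the final 100 s of
the trial; (5) time after the stimulus window to regain baseline; (6) rate
coefficient = ascending / |descending| least-squares slope, with the limbs
delimited by the last/first at-baseline samples around the stimulation
minimum (this makes a symmetric V dip give exactly 1.0 and a time-reversed
dip the reciprocal, and keeps the fits on the dip itself rather than on
flat shoulders). Searches for the latency and recovery crossings are
restricted to the trial extent so a later trial's dip cannot leak in.
Syncope-aligned averaging re-references trials to the detected 50%
power-drop time and emits the per-trial event-sequence table (heart-rate
minimum, LDF minimum, power drop, optional eye-roll annotation).

## Synthetic sessions and what passing tests show

Latent behaviour factors are white noise low-passed at 0.5 Hz (a proxy for
the slow Gaussian-process-like autocorrelation of facial behaviour). Movie
and motion SVD streams are rectified linear mixtures of the latents; unit
rates are softplus mixtures scaled to a base rate drawn from 5–25 Hz —
moderately active awake units, the regime where the 250-ms silence
criterion is informative (for slower units the last pre-onset spike is
typically too far from onset for any onset-anchored criterion). Spikes are
inhomogeneous Poisson on a 1-ms grid. Each 20-Hz laser is followed after a
uniform 4–8 s delay by a syncope bout (uniform 10–18 s): the 8–100 Hz LFP
component is multiplicatively attenuated (amplitude ×0.3, i.e. power
×0.09), a designated 80% of units in non-protected regions fall silent,
and non-protected laser responses are interrupted while protected-region
(PVZ-like) units stay driven. ECG is a train of 10-ms-wide Gaussian
R peaks following a programmed bpm curve with early asystole (4.7 s) so
the detected heart-rate minimum (the R-R-gap midpoint) precedes the LDF
minimum, which precedes the 50% power drop — the programmed event
sequence. LDF follows a piecewise-linear dip (deeper at 20 Hz than at
5/10 Hz); pupil keypoints sit on a circle whose radius dilates 1.5× at
20-Hz onset, with Poisson blink dropouts.

The generator reproduces the *statistical structure the analyses assume*,
not realistic waveforms: no ECG P/QRS/T morphology, no 1/f behaviour
spectra, no video pixels beyond a toy blob movie, linear-Gaussian
behaviour→rate coupling rather than real nonlinear motor drive. Passing
recovery tests therefore demonstrates that the estimators are correct and
calibrated under their stated assumptions — not that those assumptions
hold in any particular recording.

## Problem sizes

Validation and acceptance experiments run at the repetition counts stated
for them (20 sessions, 200 null repetitions × 500 permutations, 100 seeds
per latency, 50 units, 10 encoding sessions) on sessions scaled in
duration and channel count for single-CPU use: syncope-recovery sessions
are 150 s with one 20-Hz laser; encoding sessions are 960 s with 4 lasers,
20 SVD components per stream, 16 units and a 64/32/8 network. These sizes
are the package's own choices and are configurable.

## Known limitations

- The Morse β, the band-power smoothing window, the cluster-forming
  threshold and connectivity are defaults for quantities the analysis
  family leaves unspecified; conclusions sensitive to them should be
  checked across settings.
- The latency statistic is undefined (returns none) for units whose
  response never reaches the 10⁻⁶ tail within the 1-s cap.
- `random_window_control` draws a single control onset; averaging over
  many draws would tighten the comparison.
- The encoding network is full-batch; very long sessions would need
  mini-batching.
- Eye-roll events are consumed as optional annotations, never computed.
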