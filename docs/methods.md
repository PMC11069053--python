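# Methods

This note documents the models and estimators implemented in `spikefield`,
the defaults they ship with, and what the synthetic benchmark does and does
not establish about real recordings.

## Session model

A session bundles up to five modalities on one clock (seconds, t = 0 at
session start): LFP (µV), sorted spike units (times + mean waveform),
calcium fluorescence (neurons × frames, raw a.u., baseline ≈ 0), treadmill
speed (cm/s) and an open-field trajectory (cm). Modalities are nullable —
"not recorded" is distinct from "recorded nothing". Validation returns the
full list of invariant violations as data rather than failing on the first.
Storage is one HDF5 file per session with a flat documented layout; the
sampling rate of every series is stored explicitly and never assumed.

## LFP analysis

**Band split.** 4th-order Butterworth band-passes (1–300 Hz for LFP,
300–5000 Hz for spike band) applied forward–backward (`sosfiltfilt`), so
filtering is zero-phase and spike–field timing is preserved. The spike band
is omitted (with a warning) below 10 kHz sampling; the LFP band requires
≥ 600 Hz.

**Power spectra.** DPSS multitaper periodograms averaged over
50%-overlapping windows. Defaults: 2 s windows, time–bandwidth 3, 5 tapers.
These are conventional values for hippocampal LFP — 0.5 Hz grid resolution
and ±1.5 Hz spectral concentration, enough to separate the four bands —
and are recorded in the spectrum's metadata. Tapers are normalised to unit
energy and segments demeaned, so the one-sided density integrates to the
signal variance (Parseval; verified to 5% for tones and 10% for white
noise in the tests). Band powers are trapezoidal integrals over delta
(1–4 Hz), theta (5–12 Hz), beta (13–30 Hz), gamma (30–80 Hz), reported
both absolute (µV²) and relative to total 1–80 Hz power; group comparisons
default to absolute.

## Spike analysis

**RS/FS classification** is width-primary: trough-to-peak > 0.45 ms → RS,
else FS. The published rate ranges (RS < 15/s, FS 15–50/s) overlap at
their boundary, so rate is only a consistency check that logs a warning
when violated. Missing waveforms yield `unclassified`.

**Spike–field coherence.** For one unit: restrict spikes to locomotion
(median-smoothed speed over 0.5 s above 1 cm/s — threshold configurable,
as the defining criterion is conventional); drop spikes whose centred
300 ms window crosses a record edge; subsample exactly `n_spikes` without
replacement (seeded); average the windows into the STA; compute the power
spectrum of the STA and of every window with the same single
Hann-periodogram estimator (300 ms windows are too short for multitaper
averaging; the ≈ 3.3 Hz resolution suffices to localise a 5–12 Hz peak);
report `100 · P_STA / mean(P_i)` clipped to [0, 100] %. Clipping is a
documented choice — finite-sample ratios can exceed 100%. Peak search
excludes DC and breaks ties toward the lowest frequency. Theta SFC is the
maximum over 5–12 Hz. Comparisons across units equalise `n_spikes` to the
eligible count of the sparsest unit; in the end-to-end summary, units
below 50 eligible spikes are dropped instead of degrading every unit.

Two analytic limits calibrate the statistic: identical windows give 100%
at every frequency with power, and independent windows give an STA whose
power shrinks as 1/N, hence coherence ≈ 100/N % — both are asserted in the
acceptance tests.

## Calcium analysis

**Detection** uses `scipy.signal.find_peaks` on the raw trace with
height = 20, distance = 10 frames, prominence = 20 (frame units at 10 Hz;
10 frames = 1 s). A brute-force peak-enumeration oracle (strict local
maxima → height → greedy-by-height distance suppression → topographic
prominence) is held in the test suite and must agree exactly.

**Isolation.** Transient isolation is scored as the minimum frame gap to
any neighbouring transient (single-ended at the edges); the 10 best are
kept, ties broken by amplitude then earlier frame. The gap score is our
operationalisation of "best isolated" — it is simple, deterministic and
matches the intent (minimal contamination of the decay segment).

**Decay.** Each selected transient's post-peak segment (to the next
selected transient or 3 s) is fit as `A·gⁿ` by least squares on the log of
the *initial contiguous run* of positive samples; the first non-positive
sample marks the noise floor and ends the fit. (Fitting all positive
samples would keep isolated positive noise excursions from the tail and
bias τ long — at τ = 0.5 s the bias exceeded +60% in simulation; the
truncated fit recovers τ ∈ [0.5, 2] s within ~5% at the default noise.)
Per-neuron `g` is the amplitude-weighted mean across transients (larger
transients carry higher SNR), τ = −Δt/ln g, and τ > 2.5 s marks a failed
extraction: the neuron is excluded from decay summaries only — its
transients still count toward rate and amplitude. Weighted log-LS (weights
∝ observed y) was evaluated and rejected: the weights are endogenous
(noise raises both the weight and the log), biasing τ upward by 10–70%.

**Standardisation.** Traces are z-scored per neuron; constant traces are
excluded with a logged id rather than propagating NaNs.

## Correlations

Pearson, and Spearman as Pearson on average ranks; computed on z-scored
traces. Fisher z = atanh(r) with r clipped at |r| ≤ 1 − 10⁻⁶ (atanh
diverges at ±1). Group comparisons use Fisher z — variance stabilisation is
the transform's purpose. Speed is aligned to the calcium clock by linear
interpolation; at 10 Hz frames against 50 Hz speed this is exact to well
under a frame. Speed correlations are computed with both methods; Pearson
is the default comparison. Empirical CDFs are right-continuous step
functions used for the distributional group summaries.

## Behaviour and statistics

Open-field distance is the sum of Euclidean steps (no smoothing by
default — synthetic paths are smooth; a smoothing option exists for real
tracking). The centre region is the concentric rectangle with half the
arena's sides — exactly 25% of the area for any arena; time in centre is
reported as a percentage. The group harness applies Student t-tests for
single-factor designs and 2×2 group × treatment ANOVA with Šídák-adjusted
(p' = 1 − (1 − p)^m) post-hoc vehicle-vs-MK801 contrasts per treatment,
via scipy/statsmodels; cells report mean ± SD. Its type-I error is
calibrated in the acceptance suite (null rejection rate within [2%, 9%]
at α = 0.05 over 50 replicates).

## Synthetic sessions

The generator produces the statistical structure the analyses assume, with
known ground truth:

- **LFP**: Σ_b A_b sin(2π f_b t + φ_b) over delta/theta/beta/gamma
  components (defaults 2/8/20/40 Hz at 30/40/15/10 µV) plus FFT-shaped
  Gaussian noise with power ∝ f^(−1) scaled to 10 µV SD; 1 kHz, ≥ 10 s.
  Theta phase is known analytically from the generated component (ground
  truth, never re-estimated).
- **Spikes**: inhomogeneous Poisson with intensity
  r₀·exp(κ·cos(θ(t) − φ₀))/I₀(κ), sampled by exact thinning. The I₀
  normalisation makes the time-averaged rate equal r₀ for any κ, so
  synchrony and rate are decoupled by construction. RS units draw r₀ from
  1–15/s with 0.8 ms templates; FS from 15–50/s at half the width.
  Default κ = 2.
- **Calcium**: per-frame Poisson events with log-rate
  const + a·L(t) + β·z(speed), L a standardized AR(1) latent (ρ = 0.9 at
  10 Hz) shared across neurons, z(·) session-standardised speed. β acts on
  standardised speed so coupling strength is dimensionless (like the
  loading a) and independent of locomotion vigor. The constant is set so
  the realised mean event rate equals `transient_rate_hz` (default
  0.1 Hz). Amplitudes are Normal(60, 15) truncated at 0 (clearing the
  detection height of 20); events are convolved with exp(−t/τ), unit value
  at the event frame, τ = 1 s; measurement noise SD 5. Defaults a = 0.6,
  β = 0.4, 30 neurons.
- **Speed**: a mean-reverting process in normalised units (target 1 during
  move bouts, 0 at rest; relaxation 0.5/s, relative volatility
  0.5/√s) gated by exponential move/rest bouts (60% moving, 8 s mean
  cycle), rectified at 0 and scaled by the mean speed (6 cm/s). Simulating
  in normalised units makes path length exactly linear in the mean-speed
  parameter. Bout statistics are configurable defaults, not claims about
  real treadmill behaviour.
- **Trajectory**: heading random walk (diffusion 1.5 rad/√s) driven by the
  speed process inside the 55 × 40 cm arena with reflecting walls.
- **Between-session variability**: log-normal multipliers (CV 0.15 on
  oscillation amplitudes, transient rate/amplitude and mean speed; 0.10 on
  τ) emulate between-animal differences. Without it the synthetic
  population has near-zero between-session variance and any nanoscale
  systematic (e.g. multitaper sidelobe leakage of a large theta tone into
  the beta band) produces a spuriously large standardized effect.

**Condition presets** encode directions of effect with documented effect
sizes (free parameters — the underlying experiments report test statistics,
not generative effect sizes): MK801 = theta and gamma amplitude ×1.5,
κ ×0.35, transient rate ×1.4, transient amplitude ×1.25, latent loading
×0.58, speed coupling ×0.4, mean speed ×1.8; delta/beta amplitude and τ
unchanged. `MK801_ARI` sets every altered parameter to the midpoint
between MK-801 and vehicle; `VEHICLE_ARI` equals `VEHICLE`. All generators
are pure functions of (config, seed); per-modality random streams are
spawned from the seed, so matched seeds yield matched realisations across
presets (a parameter change in one modality does not perturb the others,
and the variability multipliers are identical within a matched pair).

## Problem sizes

The verification suite runs sessions of 120–240 s (1 kHz LFP, 10 Hz
calcium), 10 matched seed pairs for the direction-of-effect comparison and
20 seeds for Monte-Carlo recoveries — sizes chosen so the whole suite
completes in well under a minute per property while every check retains a
comfortable margin. The generator defaults target 600 s sessions for
interactive use.

## What passing tests do and do not show

The synthetic benchmark establishes that each estimator recovers the
generating parameters of its own model class, that the analytic limits of
the SFC statistic hold, and that the preset machinery produces the intended
ordering of conditions. It does not establish performance on real data:
the generator has stationary sinusoidal rhythms (no theta frequency drift
or phase slips, no cross-frequency coupling), Poisson spiking (no
refractoriness or bursts), linear-Gaussian calcium noise (no neuropil
contamination, bleaching or motion artefacts), and no place-field or
task structure. Sorting quality, ROI extraction and motion correction are
upstream of this pipeline and out of scope.

## Known limitations

- SFC values near the 100% clip are insensitive to further increases in
  locking; comparisons should use the theta-band CDFs, as the group
  summaries do.
- The decay estimator assumes a single exponential per neuron; mixtures of
  indicators or saturating transients violate this.
- NWB container support is not built in; sessions use the documented HDF5
  layout (the `nwb` format flag raises a clear error).
- The Šídák post-hoc contrasts assume independent contrasts; with two
  treatment levels this is the conventional, slightly conservative choice.
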