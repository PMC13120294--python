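# Methods

This note documents the models, conventions and numerical choices behind
`ppgreserve`, in the order data flows through the pipeline.

## LBNP protocol and reserve ground truth

A graded lower-body-negative-pressure run is modelled as ordered
`(pressure, duration)` steps: a 5-min baseline at 0 mmHg, −15 mmHg steps
every 5 min to −60 mmHg, then −10 mmHg steps to −100 mmHg. A run ends at
`stop_time` — the end of the decompensation step by default, or a
configurable fraction into it to model presyncope under medical-monitor
stops. The reserve ground truth is linear in pressure magnitude,

    CRM_GT(t) = 100 · (1 − |LBNP(t)| / |LBNP_HDD|),

piecewise constant on steps and clipped to [0, 100]; `LBNP_HDD ≠ 0` is the
decompensation pressure. Times outside `[0, stop_time]` are rejected rather
than extrapolated.

## Synthetic recordings

The simulator provides the study conditions for every downstream test. It
is a phenomenological signal model, not a hemodynamic one:

- **Beats.** An inhomogeneous point process with rate
  `HR(t) = HR_base + HR_gain · (1 − reserve(t))`; defaults HR_base = 70 bpm
  (a typical resting rate for healthy adults), HR_gain = 50 bpm, so the rate
  climbs to 120 bpm at decompensation — the tachycardic compensation the
  physiology implies. Inter-beat intervals get 1% multiplicative Gaussian
  jitter by default (ordinary short-term rate variability); jitter can be
  zeroed for exact fixtures.
- **Pulse shape.** Each beat adds two asymmetric Gaussians: a systolic peak
  at the beat time (rise σ = 0.08·IBI, fall σ = 0.14·IBI) and a dicrotic
  bump at +0.35·IBI with 25% relative amplitude. Any smooth single-dominant-
  peak template satisfies the downstream contracts; this one gives
  physiologically plausible morphology. Peak amplitude scales as
  `decay + (1 − decay)·reserve`, so pulsatility falls as reserve falls.
- **Artifacts**, per site profile: baseline wander (random sum of four
  sub-0.5 Hz sinusoids scaled to a peak amplitude), a DC offset, broadband
  white noise, motion bursts (Poisson-timed exponential transients of
  0.5–2 s with Laplace-distributed amplitude — heavy-tailed, like real
  motion artifacts), and coupling dropouts that zero the pulsatile component
  in 5-s blocks.
- **Seeding.** One root seed is split (`numpy.random.SeedSequence.spawn`)
  into child streams per component — beats, wander, noise, motion, dropout —
  so toggling one source leaves the others bit-identical. Equal inputs give
  byte-identical recordings.

Three presets encode the cross-site contrast of interest. *finger*: clean
(pulse 1.0, wander 0.05, noise 0.01). *triceps*: strong pulse under heavy
drift (wander 50, DC 15) — raw beat morphology is destroyed, but the drift
is out-of-band and filtering recovers it; the wander band extends to
0.4 Hz, close to the 0.5 Hz filter edge, which is why the 40 dB stopband of
Chebyshev II recovers this site more completely than the gentler Butterworth
roll-off. *clavicle*: weak pulse (0.12) under broadband noise (0.5) with
frequent motion bursts and dropouts — the in-band noise floor exceeds the
pulse, so no linear filter can recover it.

What the generator does **not** emulate: real PPG morphology families and
their drift with vasoconstriction, sensor-specific optical coupling,
correlated (pink) noise, respiration coupling, or any stroke-volume/pressure
dynamics — the reference heart rate is the configured rate law itself, not a
simulated ECG. Passing tests therefore demonstrate that the *analysis chain*
recovers known structure under controlled degradation, not that any
particular hardware performs well.

Surrogate reserve predictions are lagged, biased, noisy copies of the
ground truth, `clip(gt(t − lag) + bias + N(0, σ), 0, 100)` at 1 Hz. The
per-site defaults (finger −10%/σ10/0 s, triceps −16%/σ20/10 s, clavicle
−20%/σ40/30 s) encode the qualitative ordering that prediction quality
degrades with signal quality; they are package conventions for exercising
the evaluation stage, not measured device properties. Near the 0% floor,
clipping compresses the recovered bias below the injected one — visible in
the noisiest profile — which is a property of evaluating clipped percent
scales, not an estimator defect.

## Preprocessing

- **Decimation by selection** keeps every k-th sample with *no* anti-alias
  filter, reproducing the stated resampling of 1 kHz reference waveforms to
  100 Hz exactly; a warning is logged because content above the new Nyquist
  aliases.
- **IIR band-passes** (Butterworth and Chebyshev II, 4th order, 0.5–8 Hz)
  are applied forward–backward (`sosfiltfilt`): zero net phase, squared
  magnitude response. For Chebyshev II the band edges follow the
  conventional design semantics — the critical frequencies where attenuation
  first reaches 40 dB (scipy's `cheby2` contract). A `passband`
  interpretation (the stated band as 3 dB edges, solved numerically) is
  selectable since the prose convention is ambiguous. Note an even-order
  type II band-pass has no transmission zero at DC: DC sits at the stopband
  floor, −80 dB after the double pass (residual 1e−4), whereas Butterworth
  zeros DC exactly.
- **FIR path**: constant edge replication, full convolution, shift-back by
  the declared group delay so output sample k aligns with input sample k.
  The shipped kernel is a synthetic stand-in — a 1001-tap Hamming-windowed
  sinc band-pass at 100 Hz (delay 500), mean-subtracted to force an exact DC
  zero — with the identical application contract as a device-supplied
  coefficient set.
- Zero-phase edge transients occupy roughly the first/last 2 s of filtered
  output; tolerance checks in the tests exclude those spans.

## Signal quality

- **SNR.** The recording is AC-coupled with a 4th-order 0.5 Hz high-pass
  (cutoff chosen to match the band-pass low edge; the procedure itself does
  not fix it) and split at 5 Hz into cardiac/noise components with 4th-order
  Butterworth low/high-passes. Windows are 5 s, stride 1 s, sample-aligned,
  left-closed, fully contained; `n_windows = floor((N − 5fs)/fs) + 1`. The
  decomposition filters run once over the full recording and windows slice
  the filtered components: filtering each 5-s window separately injects
  zero-phase edge transients that dominate window RMS (measured at several
  dB on band-swap constructions), and the global application preserves the
  windowing/aggregation contract while matching the analytic oracles.
  Zero-noise windows record +∞ and are excluded from the subject median
  with a logged count.
- **Peak detection.** Two-moving-average event detection: clip at zero,
  square, compare a short (111 ms) moving average against a long (667 ms)
  one plus an offset proportional (β = 0.02) to the mean squared signal;
  blocks narrower than the short window are rejected and each block yields
  its maximum. Parameters follow the method's published defaults and are
  exposed as arguments.
- **SQI.** Beats are segmented midpoint-to-midpoint around each peak (both
  neighbours required), resampled to 100 points, averaged into a template;
  SQI is the mean per-beat Pearson correlation with the template, negative
  correlations clipped to 0 so the score lives on [0, 1]. A window scores 0
  when fewer than two usable beats remain, the template is degenerate, or
  the detected rhythm is implausible as a pulse — mean rate outside
  40–180 bpm, any inter-beat gap over 3 s, or a max/min IBI ratio above 2.2
  (the plausibility gates of the template-matching method this follows).
  The gates are what make unstructured noise score 0 rather than its chance
  correlation. Per-window peaks are re-detected on the window's own samples.

## Heart rate

HR = 60/IBI at inter-beat midpoints, linearly interpolated onto a uniform
1 Hz grid (matching the 1 Hz reserve cadence and giving well-defined metric
denominators). Only the reference series is screened (30–200 bpm,
*inclusive* bounds — values "outside the range" are excluded, so endpoints
stay); the PPG-derived series is deliberately unscreened so detector
failures surface in the metrics. Pairing intersects the two 1 Hz grids
after an optional known clock-offset correction and drops incomplete pairs
with logged counts.

## Reserve evaluation

- Model-input windows are 500 samples (5 s at 100 Hz), min–max normalized
  to attain 0 and 1 exactly; constant windows are degenerate and skipped
  with a logged count.
- Smoothing is a 20-sample centered moving average covering samples
  [i−10, i+9] — the convention of `pandas.rolling(20, center=True)`, and as
  close to a symmetric 10 s/10 s span as an even window allows. Edges use
  shrinking windows. Because the window is even, a linear series is
  reproduced with an exact half-sample-slope offset, not identically.
- Trend detection slides a 5-min window at 1 s stride over the (by default
  smoothed) 1 Hz predictions; the window "drops" when its OLS-fitted trend
  falls ≥15 points across the nominal 300 s span (OLS is robust to
  single-sample noise; a raw endpoint-difference mode is selectable).
  Detection time is window start + 300 s; the reported lead time is
  `(stop_time − detection)/60` minutes, so larger is earlier warning and
  never-detected runs score 0.
- R² defaults to the squared sample correlation (scatterplot agreement,
  insensitive to affine miscalibration); an identity-line convention
  (1 − SSE/SST) is available where bias should be penalized. Zero-variance
  inputs report an absent value with a logged reason.
- MdE/MdAE are plain medians of signed/absolute differences; ANSI-style
  accuracy uses the per-pair threshold `max(5 bpm, 10% of reference)`.

## Study sizes and determinism

The shipped study is 3 subjects (decompensating at −60/−70/−80 mmHg,
bracketing the typical final step) × 3 site profiles × 4 filter conditions
at 100 Hz, chosen so the full grid exercises every code path with clearly
separated site behaviour. Subject and per-site surrogate seeds derive from
the root seed through fixed integer maps and a CRC of the site label, so
reruns are byte-identical and no seed depends on Python's randomized string
hashing.

## Known limitations

- The reserve predictor itself is out of scope: predictions are inputs
  (or surrogates); only the windowing/normalization contract a pluggable
  predictor needs is implemented.
- Group-comparison statistics (normality gates, rank-based omnibus/post hoc
  tests) are reporting-stage concerns delegated to standard statistical
  libraries, not part of the method surface.
- Absolute SNR/SQI levels depend on profile parameters that are package
  conventions; only contrasts and recoveries carry meaning.
- The decimation stage aliases by design; the simulator's native 100 Hz
  output never passes through it unless explicitly requested.
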