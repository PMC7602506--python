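# Methods

This note records the models, parameter choices and numerical decisions
behind `navload`, in the order the pipeline applies them, and what the
synthetic-trial generator does and does not emulate.

## Stream model and synchronization

Every modality is a timestamped stream (LSL-style): `values` (samples ×
channels) plus one epoch-anchored timestamp per sample, stored in one HDF5
container (group per stream, datasets `time`/`values`, attributes `rate_hz`,
`labels`).  Annotations live in a sidecar CSV (`event,timestamp`, Unix
seconds) and must contain exactly one `Start` and one `Stop` bracketing all
other events.  All analysis windows are half-open `[t0, t1)`.

Alignment to the reference (video) timeline trims overruns from the tail and
pads shortfalls with NaN — the reserved missing-value sentinel, which is
propagated, never imputed.  Filters run per contiguous finite segment and
leave gaps untouched; power windows with more than 10% missing samples are
marked invalid.  A stream overlapping the reference by less than 50% raises
(gross clock error).  Only constant-offset alignment is supported; clock
*drift* between acquisition devices is out of scope and flagged, never
silently corrected, when a residual exceeds one sample.

## EEG conditioning

* Band-pass 0.5–100 Hz and per-band filters: 4th-order Butterworth applied
  forward and backward (zero net phase).  The 0.5 Hz corner has a transient
  lasting seconds, so filtering pads with an even (mirror) extension over
  `3·rate/lo` samples; an even extension is continuous at the boundary and
  keeps the slow corner's ringing in the padding.  Attenuation contracts
  (≥30 dB one octave out, ≤1 dB in-band; ≥30 dB at the 50 Hz notch, Q=25)
  are asserted on steady-state RMS in the tests.
* Band edges: delta [0.5,4), theta [4,7), alpha [8,13), alpha1 [7,10),
  alpha2 [10,13), beta [13,30), gamma [30,45) Hz.  Gamma is capped at 45 Hz
  to stay clear of the 50 Hz mains notch.  The alpha family is the only
  overlap `band_decompose` accepts; "total power over all bands" always uses
  the disjoint set (delta, theta, alpha1, alpha2, beta, gamma).
* Artifact removal: per channel, a Savitzky–Golay smooth (window 0.511 s —
  odd sample count at 512 Hz — polynomial order 3); samples whose residual
  exceeds 5× the MAD residual scale are flagged.  The flagged region is
  dilated by ~5% of the window to catch artifact tails, bridged by linear
  interpolation, re-smoothed, and only flagged samples are replaced — the
  artifact itself therefore cannot drag its own replacement, and unflagged
  samples are returned bit-identical.  The detector is causal-window
  equivalent; offline analysis is the use case.
* Baseline normalization: two modes.  The pipeline default operates on log
  band power (subtract the resting-state mean of ln P per channel and band),
  because every downstream statistic is power-based; a literal time-series
  mode (subtract the per-channel resting mean amplitude) is retained.

## Band power

Band power per 1 s window (50% overlap) is the windowed mean square of the
band-filtered signal — by Parseval, the integral of the periodogram over the
band.  An explicit spectral estimate at 1 Hz resolution was rejected: the
Hann-tapered periodogram of a 9 Hz tone leaks ~1/6 of its power into the bin
at 10 Hz, i.e. out of alpha1 [7,10), whereas the filtered-variance estimate
recovers a calibrated tone's power a²/2 to within 0.2%.  White-noise band
power tracks bandwidth to within ~15% across bands (Butterworth transition
widths account for the spread).  The 1 s window resolves the alpha1/alpha2
split while tracking dynamics; for delta the per-window estimate is noisy
but its time-average is unbiased, which is all the statistics consume.

## Cognitive load

AI = (ln P_L − ln P_R) / ln(P_L + P_R), natural logs throughout (the
customary base-free "log" is read as ln everywhere in the package).  AI is
exactly antisymmetric but *not* invariant to rescaling both powers — the
denominator changes — so powers must stay in µV²; a regression test pins
this.  When total power ≈ 1 µV² the denominator vanishes; windows with
|ln(P_L+P_R)| < 1e-6 are marked invalid (NaN) rather than returning an
exploding index.  The CL series is −|AI| so workload rises plot as negative
fluctuations.  Both frontal pairs (F3/F4 and Fp1/Fp2) are computed and
reported; neither is privileged.

TCL per electrode is defined operationally as
mean_w ln P_task(w) − mean_w ln P_rest(w) over total band power — a
baselined log-activation: 0 at resting level, 1 when total power is e× rest.
This reads "total" as summed over bands and averaged over time; it is one
defensible operationalization of a per-electrode activation summary and is
used consistently for the global CL distribution (median, linear-interpolated
quartiles, Tukey 1.5·IQR whiskers, sample skewness) and the O1/O2
visual-cortex analysis.

Asymmetry envelopes join local maxima by linear interpolation with the
series endpoints as extra supports (a constant series has a flat envelope);
collision events are projected onto the nearest window center.

## Valence

VS = ln(PS_R/PS_L) per (right, left) pair — T8-T7 (most relevant for
affect), C4-C3, P4-P3, F4-F3 — in alpha, beta and gamma.  Trial-level VS is
the mean of the windowed values (not the VS of mean powers; for stationary
synthetic trials the two differ by Jensen-gap terms well below the reporting
precision, and the windowed mean is robust to nonstationarity).  Aggregation
order is windows → trial → bands.  Qualitative labels use symmetric
thresholds, explicit in config: |VS| < 0.05 neutral, 0.05–0.25 "low
positive/negative", above 0.25 "positive/negative".  The thresholds are
reporting conveniences, not claims about affect magnitudes.

## Electrodermal and heart-rate processing

* Calibration y = p1·x + p2 (µS); p1, p2 are range-setting-specific sensor
  constants supplied via config, default identity.  (µS is a conductance
  unit; the calibrated signal is treated as conductance throughout.)
* Low-pass: 4th-order zero-phase Butterworth, default cutoff 1 Hz — the
  lowest of the defensible 1–5 Hz range, since 16 Hz sampling leaves little
  headroom below the 8 Hz Nyquist and the electrodermal response itself is
  far slower.
* Tonic/phasic: tonic is a sliding 25th-percentile trend over 30 s; phasic
  is the residual, so tonic + phasic reconstructs the input exactly.  The
  window is long against the seconds-scale SCR and short against the
  minutes-scale baseline drift.  A *low* percentile is used instead of the
  median because superimposed SCRs (rise ~1 s, decay ~4 s, so ~8 s above
  baseline) occupy enough of any practical window to drag a median up and
  clip recovered amplitudes; over 20 seeded trials the percentile trend
  recovers injected 0.2 µS amplitudes with ≤5% error versus ~10% for a 30 s
  median.  This is a deliberate, documented divergence from
  deconvolution-based decomposition (e.g. Ledalab): the indices consumed
  downstream depend only on phasic peak geometry, not on a driver function.
  Known boundary behavior: an SCR whose decay runs into the recording edge
  is partially absorbed by the edge-replicated trend, so responses in the
  last ~10 s are attenuated.
* SCR detection: local-minimum→local-maximum excursions on the phasic
  component, rise ≥ 0.05 µS completed within 5 s, 1 s refractory — standard
  electrodermal practice.  The SCR index is the mean amplitude of detected
  responses (0 when none); count and rate/min are reported alongside so a
  frequency-based reading of the index stays recoverable.
* RMSSD = sqrt(mean of squared successive IBI differences), ms; task vs
  rest as 100·(task−rest)/rest (percent change is intentionally asymmetric
  in its arguments).  A beat-wise HR series converts via IBI = 60000/HR.

## Synthetic trials: what they emulate, and what they do not

Each EEG channel is one sinusoid per band at fixed synthesis frequencies
(delta 2, theta 6, alpha1 9, alpha2 11.5, beta 20, gamma 38 Hz) so analytic
power checks are exact, over a 1/f background (default SD 2 µV) with
raised-cosine 400 ms blinks on Fp1/Fp2 (default 12/min, 200 µV — large
enough to trigger the artifact detector deterministically).  Default band
amplitudes (20/10/10/8/5/2 µV) are typical awake ambulatory scalp values.
Hemispheric ratios are injected as amplitude factors ρ^(±1/4) on homologous
pairs, preserving the pair's geometric-mean power.  EDA is tonic level
(default 5 µS) + drift (0.05 µS/min) + unit-peak bi-exponential SCR kernels
(τ_rise 0.75 s, τ_decay 4 s) at scheduled and Poisson-spontaneous times
(default 2/min, amplitudes 0.1–0.5 µS) + white sensor noise (0.005 µS).
IBIs are mean 800 ms with 30 ms i.i.d. Gaussian jitter (analytic RMSSD
σ√2), plus a deterministic alternating test mode with RMSSD exactly 2d.
The resting-state companion recording defaults to 60 s (a parameter, since
no canonical value exists) with all effects nulled.

All randomness flows from one seed through fixed per-signal substreams, so
adding a stream never perturbs another and identical configs are
bit-reproducible.

The generator does **not** emulate volume conduction or any forward head
model, inter-channel correlation structure, nonstationary band power,
heteroscedastic HRV, PPG waveforms, or realistic motion artifacts.  Passing
the recovery tests therefore demonstrates that the *statistics and pipeline*
are implemented correctly and are sensitive at realistic effect sizes — not
that the physiological interpretations hold on real recordings.

## Montage note

The acquisition montage lists sixteen 10-20 sites; the published list
contains C4 twice and omits T7, which the temporal-pair analyses require.
The default montage therefore substitutes T7 for the duplicate — an
inference, overridable via `channel_labels`.

## Problem sizes

The test suite and acceptance script run on deliberately small but
statistically adequate problems: 10–60 s recordings, 12–16 channels,
20-seed recovery loops, and 20 paired-condition suites of four 60 s trials
each (two per condition, reduced 12-channel montage).  These sizes give ≥20
analysis windows per estimate and Monte-Carlo margins several times smaller
than the tolerances being checked.

## Known limitations

- Constant-offset synchronization only; no clock-drift model.
- TCL and the SCR index implement one defensible operational definition
  each; alternatives (per-band TCL, SCR frequency index) are recoverable
  from the persisted per-band powers and SCR counts.
- The envelope is a support-point interpolant: between supports it can dip
  below the underlying series; it dominates the series at every local
  maximum by construction.
- No inferential statistics anywhere, by design: condition comparisons are
  descriptive.
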