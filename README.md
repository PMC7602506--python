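# navload

Cognitive-load, affect and autonomic analysis of multimodal mobility trials.

When visually impaired users navigate an obstacle course — with a white cane,
or guided by a sensory-substitution device that encodes the scene as audio,
haptic or combined (multimodal) cues — the mental effort and affective state
the navigation induces can be read out from synchronized physiological
streams: 16-channel 10-20 EEG at 512 Hz (ear reference), skin conductance at
16 Hz, a beat-wise heart-rate stream, and a video-annotated event log
(Start / Collision / Find / Lost / TouchCane / Stop).  `navload` implements
that readout as a tested, reusable pipeline, together with a synthetic trial
generator with known ground truth so every stage can be validated without
access to participant recordings.

## The statistics at the core

For a homologous left/right electrode pair with band powers
$P_L, P_R$ (µV²) in a window:

- **Asymmetry index (cognitive load).**
  $\mathrm{AI} = \dfrac{\ln P_L - \ln P_R}{\ln (P_L + P_R)}$ — higher |AI|
  reflects stronger workload.  The reported CL series is $-|\mathrm{AI}|$, so
  rising workload appears as a negative fluctuation.  Computed on the frontal
  pairs (F3/F4, Fp1/Fp2), resolved in the lower and upper alpha sub-bands
  (alpha1 7–10 Hz: attentional demand; alpha2 10–13 Hz: task difficulty).
- **Total cognitive load (TCL)** per electrode: the time-average of log total
  band power, baselined against a resting-state recording — activation
  relative to rest, in natural-log units.  Applied to O1/O2 for visual-cortex
  analysis.
- **Valence state.**  $\mathrm{VS} = \ln(PS_R / PS_L)$ for the (right, left)
  pairs T8-T7, C4-C3, P4-P3, F4-F3 in the alpha, beta and gamma bands;
  the sign encodes approach/withdrawal affect, and amplifier gain cancels.
- **Autonomic indices.**  Skin conductance is calibrated
  ($y = p_1 x + p_2$ µS), low-passed, split into a tonic trend and phasic
  remainder; skin-conductance responses (SCRs) are onset→peak rises
  ≥ 0.05 µS, summarized by the SCR index (mean amplitude) plus count and
  rate.  Heart-rate variability is RMSSD
  $= \sqrt{\overline{(\Delta \mathrm{IBI})^2}}$ (ms), compared to rest as a
  percent change.
- **Behavioral metrics.**  Per trial: duration, collisions, cane contacts and
  walked path length, aggregated per (codification, scenario).

EEG conditioning before any statistic: 0.5–100 Hz zero-phase band-pass,
50 Hz notch, Savitzky–Golay artifact flagging/repair, per-band decomposition,
1 s windows with 50% overlap.

## Worked example

```sh
navload analyze --config demo.yaml
```

with a config that simulates one null white-cane trial and one audio-guided
trial carrying a left:right alpha power ratio of 2, three collisions' worth
of arousal (spontaneous SCR rate 3/min) and two annotated collisions:

```
scratch/demo/trial-000-cane-A:  CL median -0.000, valence neutral (+0.007), SCR index 0.284, RMSSD change -1.8%
scratch/demo/trial-001-audio-A: CL median -0.039, valence low negative (-0.240), SCR index 0.407, RMSSD change +15.1%
```

`navload report scratch/demo/trial-001-audio-A/report.json` expands the
second trial:

```
Trial scratch/demo/trial-001-audio-A [audio/A]
  global CL: median -0.039  IQR [-0.072, +0.093]  skew -0.186
  frontal F3-F4/alpha1: mean CL -0.1472
  frontal F3-F4/alpha2: mean CL -0.1658
  frontal Fp1-Fp2/alpha1: mean CL -0.1507
  frontal Fp1-Fp2/alpha2: mean CL -0.1696
  visual cortex: mean asymmetry +0.1334, ln(O1/O2) +0.1611
  valence (T8-T7): -0.240 -> low negative
  autonomic: RMSSD 45.9 ms (+15.1% vs rest), 2 SCRs, index 0.407
  behavior: 60 s, 2 collisions, 0 cane contacts
```

Reading the numbers: the injected alpha ratio of 2 drives the frontal CL
series to a mean of about $-\ln 2 / \ln(P_L+P_R) \approx -0.15$ per pair and
sub-band (the null trial sits near 0); the same ratio read through the
right/left valence statistic on the temporal pair gives
$\mathrm{VS} \approx -\ln 2 / 3 = -0.24$ after averaging the unaffected beta
and gamma bands in, i.e. a "low negative" valence; and the simulated arousal
shows up as detected SCRs with a higher SCR index than the null trial.
`navload compare` then reduces any set of reports to per-codification
descriptive rows (median / IQR / whiskers / skewness of CL, valence means,
autonomic indices) — descriptive only, no hypothesis tests.

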