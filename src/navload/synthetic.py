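"""Synthetic multimodal mobility trials with known ground truth.

Emulates the acquisition setup of the navigation experiments — 16-channel
10-20 EEG at 512 Hz against an ear reference, skin conductance at 16 Hz over
Bluetooth, a beat-wise heart-rate stream, and a video-annotated event log —
so every downstream stage is testable without any external recordings.

EEG channels are sums of one band-limited sinusoid per classical band (at the
band-center frequencies) over a 1/f background, with configurable hemispheric
power ratios per homologous pair and raised-cosine blink transients on the
prefrontal channels.  EDA is a drifting tonic level plus bi-exponential
skin-conductance responses at scheduled and Poisson-spontaneous times.  The
inter-beat series has configurable mean and jitter with an analytic RMSSD.

All randomness flows from one seed through fixed per-signal substreams, so
adding or removing one signal never perturbs another and identical configs
produce bit-identical trials.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autonomic import EDARecording, IBISeries
from .preprocess import DEFAULT_MONTAGE, HOMOLOGOUS_PAIRS, EEGRecording
from .streams import EventLog, TimestampedStream, write_annotations, write_container

#: Synthesis frequency (Hz) of the single sinusoid standing for each band;
#: one tone per band keeps analytic power checks exact.
BAND_CENTERS = {
    "delta": 2.0, "theta": 6.0, "alpha1": 9.0,
    "alpha2": 11.5, "beta": 20.0, "gamma": 38.0,
}

#: Typical scalp amplitudes (uV) for an awake ambulatory recording.
DEFAULT_BAND_AMPLITUDES = {
    "delta": 20.0, "theta": 10.0, "alpha1": 10.0,
    "alpha2": 8.0, "beta": 5.0, "gamma": 2.0,
}

_KNOWN_1020 = set(DEFAULT_MONTAGE) | {
    "Fz", "Cz", "Pz", "Oz", "AFz", "FC5", "FC2", "AF4", "PO4",
}

#: SCR kernel time constants (s): standard bi-exponential electrodermal shape.
SCR_TAU_RISE = 0.75
SCR_TAU_DECAY = 4.0

_BLINK_WIDTH = 0.4   # seconds, raised-cosine

# fixed substream indices: adding a stream never perturbs another
_SUB_PHASES, _SUB_NOISE, _SUB_BLINK, _SUB_SCR, _SUB_EDANOISE, _SUB_IBI = range(6)
_SUB_REST = 99


@dataclass
class TrialConfig:
    """Everything needed to synthesize one trial (and its resting baseline)."""

    duration: float = 120.0
    eeg_rate: float = 512.0
    eda_rate: float = 16.0
    channel_labels: list[str] = field(default_factory=lambda: list(DEFAULT_MONTAGE))
    band_amplitudes: dict = field(default_factory=dict)   # band or (channel, band) -> uV
    asym_ratios: dict = field(default_factory=dict)       # band -> left:right power ratio
    blink_rate: float = 12.0          # blinks / min on Fp1+Fp2
    blink_amplitude: float = 200.0    # uV
    scr_times: tuple = ()             # seconds, scheduled responses
    scr_amplitudes: tuple = ()        # uS, one per scheduled time
    spontaneous_scr_rate: float = 2.0  # events / min
    tonic_level: float = 5.0          # uS
    tonic_drift: float = 0.05         # uS / min
    eda_noise_sd: float = 0.005       # uS, motion/sensor noise
    mean_ibi: float = 800.0           # ms
    ibi_jitter_sd: float = 30.0       # ms
    ibi_pattern: str = "random"       # "random" | "alternating" (test mode)
    event_schedule: list | None = None  # [(label, seconds from Start)]
    noise_sd: float = 2.0             # uV, 1/f EEG background
    resting_duration: float = 60.0    # s, baseline recording length
    start_time: float = 0.0           # epoch anchor, seconds
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.duration <= 0 or self.resting_duration <= 0:
            raise ValueError("durations must be positive")
        if self.eeg_rate <= 0 or self.eda_rate <= 0:
            raise ValueError("sampling rates must be positive")
        unknown = set(self.channel_labels) - _KNOWN_1020
        if unknown:
            raise ValueError(f"unknown channel label(s): {sorted(unknown)}")
        for key, amp in self.band_amplitudes.items():
            band = key[1] if isinstance(key, tuple) else key
            if band not in BAND_CENTERS:
                raise ValueError(f"unknown band {band!r} in band_amplitudes")
            if amp < 0:
                raise ValueError("band amplitudes must be >= 0")
        for band, f in BAND_CENTERS.items():
            if f >= self.eeg_rate / 2:
                raise ValueError(f"band {band!r} center {f} Hz at or above Nyquist")
        if len(self.scr_times) != len(self.scr_amplitudes):
            raise ValueError("scr_times and scr_amplitudes must have equal length")
        if any(not 0 <= t < self.duration for t in self.scr_times):
            raise ValueError("scr_times must lie within [0, duration)")
        if any(a < 0 for a in self.scr_amplitudes):
            raise ValueError("SCR amplitudes must be >= 0")
        if self.tonic_level < 0:
            raise ValueError("tonic level must be >= 0")
        if self.blink_rate < 0 or self.spontaneous_scr_rate < 0:
            raise ValueError("event rates must be >= 0")
        if self.mean_ibi <= 0:
            raise ValueError("mean IBI must be positive")
        if self.noise_sd < 0 or self.eda_noise_sd < 0 or self.ibi_jitter_sd < 0:
            raise ValueError("noise scales must be >= 0")
        if self.ibi_pattern not in ("random", "alternating"):
            raise ValueError(f"unknown ibi_pattern {self.ibi_pattern!r}")

    def _rng(self, substream: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(substream,))
        )

    def amplitude(self, channel: str, band: str) -> float:
        """Resolve the oscillation amplitude for (channel, band)."""
        if (channel, band) in self.band_amplitudes:
            return self.band_amplitudes[(channel, band)]
        if band in self.band_amplitudes:
            return self.band_amplitudes[band]
        return DEFAULT_BAND_AMPLITUDES[band]

    def asym_ratio(self, band: str) -> float:
        """Left:right power ratio for a band ('alpha' covers both sub-bands)."""
        if band in self.asym_ratios:
            return self.asym_ratios[band]
        if band in ("alpha1", "alpha2") and "alpha" in self.asym_ratios:
            return self.asym_ratios["alpha"]
        return 1.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["band_amplitudes"] = {
            (k if isinstance(k, str) else "/".join(k)): v
            for k, v in self.band_amplitudes.items()
        }
        return d


@dataclass
class GroundTruth:
    """What was injected, for closing the loop on downstream estimates."""

    asym_ratios: dict
    scr_times: list
    scr_amplitudes: list
    analytic_rmssd: float
    event_counts: dict

    @property
    def scr_count(self) -> int:
        return len(self.scr_times)

    def to_dict(self) -> dict:
        return {
            "asym_ratios": dict(self.asym_ratios),
            "scr_times": list(map(float, self.scr_times)),
            "scr_amplitudes": list(map(float, self.scr_amplitudes)),
            "scr_count": self.scr_count,
            "analytic_rmssd": self.analytic_rmssd,
            "event_counts": dict(self.event_counts),
        }


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------

def _pink_noise(rng: np.random.Generator, n: int, rate: float, sd: float) -> np.ndarray:
    """1/f-power background noise with standard deviation ``sd``."""
    if sd == 0 or n < 2:
        return np.zeros(n)
    spectrum = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, d=1 / rate)
    shaping = np.zeros_like(f)
    shaping[1:] = 1 / np.sqrt(f[1:])
    x = np.fft.irfft(spectrum * shaping, n)
    return sd * x / np.std(x)


def _hemisphere_factor(channel: str, ratio: float) -> float:
    """Amplitude factor realizing a left:right power ratio across a pair."""
    if ratio == 1.0:
        return 1.0
    if channel in HOMOLOGOUS_PAIRS:           # left member
        return ratio ** 0.25
    if channel in HOMOLOGOUS_PAIRS.values():  # right member
        return ratio ** -0.25
    return 1.0


def generate_eeg(config: TrialConfig, *, duration: float | None = None) -> EEGRecording:
    """Synthesize the EEG stream of one trial.

    Per channel: one sinusoid per band (configured amplitude, hemispheric
    ratio factor, random phase) + 1/f background + blink transients on
    Fp1/Fp2.  Homologous left/right band-power ratios match ``asym_ratios``
    in expectation.
    """
    duration = config.duration if duration is None else duration
    n = int(round(duration * config.eeg_rate))
    t = np.arange(n) / config.eeg_rate
    phase_rng = config._rng(_SUB_PHASES)
    noise_rng = config._rng(_SUB_NOISE)
    values = np.zeros((len(config.channel_labels), n))
    for ci, ch in enumerate(config.channel_labels):
        x = np.zeros(n)
        for band, f0 in BAND_CENTERS.items():
            amp = config.amplitude(ch, band) * _hemisphere_factor(ch, config.asym_ratio(band))
            phase = phase_rng.uniform(0, 2 * np.pi)
            if amp > 0:
                x += amp * np.sin(2 * np.pi * f0 * t + phase)
        x += _pink_noise(noise_rng, n, config.eeg_rate, config.noise_sd)
        values[ci] = x
    if config.blink_rate > 0 and config.blink_amplitude > 0:
        blink_rng = config._rng(_SUB_BLINK)
        n_blinks = blink_rng.poisson(config.blink_rate * duration / 60.0)
        times = np.sort(blink_rng.uniform(0, max(duration - _BLINK_WIDTH, 0), n_blinks))
        width = int(round(_BLINK_WIDTH * config.eeg_rate))
        shape = 0.5 * config.blink_amplitude * (1 - np.cos(2 * np.pi * np.arange(width) / width))
        for bt in times:
            a = int(round(bt * config.eeg_rate))
            b = min(a + width, n)
            for ch in ("Fp1", "Fp2"):
                if ch in config.channel_labels:
                    values[config.channel_labels.index(ch), a:b] += shape[: b - a]
    return EEGRecording(values, config.eeg_rate, list(config.channel_labels))


# ---------------------------------------------------------------------------
# EDA
# ---------------------------------------------------------------------------

def scr_kernel(t: np.ndarray, tau_rise: float = SCR_TAU_RISE,
               tau_decay: float = SCR_TAU_DECAY) -> np.ndarray:
    """Bi-exponential SCR shape, normalized to unit peak, zero for t < 0."""
    k = np.where(t >= 0, np.exp(-np.maximum(t, 0) / tau_decay)
                 - np.exp(-np.maximum(t, 0) / tau_rise), 0.0)
    t_peak = np.log(tau_decay / tau_rise) / (1 / tau_rise - 1 / tau_decay)
    peak = np.exp(-t_peak / tau_decay) - np.exp(-t_peak / tau_rise)
    return k / peak


def generate_eda(config: TrialConfig, *, duration: float | None = None,
                 ) -> tuple[EDARecording, dict]:
    """Synthesize the skin-conductance stream; returns (recording, scr truth).

    Tonic level + linear drift, one unit-peak bi-exponential kernel scaled to
    each scheduled amplitude, Poisson spontaneous responses, and white motion
    noise.  The truth dict lists every response actually injected.
    """
    duration = config.duration if duration is None else duration
    n = int(round(duration * config.eda_rate))
    t = np.arange(n) / config.eda_rate
    tonic = config.tonic_level + config.tonic_drift * t / 60.0
    scr_times = [float(x) for x in config.scr_times]
    scr_amps = [float(a) for a in config.scr_amplitudes]
    if config.spontaneous_scr_rate > 0:
        rng = config._rng(_SUB_SCR)
        k = rng.poisson(config.spontaneous_scr_rate * duration / 60.0)
        scr_times += sorted(rng.uniform(0, duration, k))
        scr_amps += list(rng.uniform(0.1, 0.5, k))
    phasic = np.zeros(n)
    for st, amp in zip(scr_times, scr_amps):
        phasic += amp * scr_kernel(t - st)
    noise = (config._rng(_SUB_EDANOISE).standard_normal(n) * config.eda_noise_sd
             if config.eda_noise_sd > 0 else 0.0)
    values = np.maximum(tonic + phasic + noise, 0.0)
    order = np.argsort(scr_times)
    truth = {
        "scr_times": [scr_times[i] for i in order],
        "scr_amplitudes": [scr_amps[i] for i in order],
    }
    return EDARecording(values, config.eda_rate, t), truth


# ---------------------------------------------------------------------------
# Inter-beat intervals
# ---------------------------------------------------------------------------

def generate_ibi(config: TrialConfig, *, duration: float | None = None) -> IBISeries:
    """Synthesize the inter-beat series covering the trial duration.

    ``random`` mode draws i.i.d. Gaussian jitter around the mean IBI
    (analytic RMSSD = jitter_sd * sqrt(2)); ``alternating`` is a
    deterministic test mode m+d, m-d, m+d, ... whose RMSSD is exactly 2d.
    """
    duration = config.duration if duration is None else duration
    n = int(np.ceil(duration * 1000.0 / config.mean_ibi)) + 2
    if config.ibi_pattern == "alternating":
        d = config.ibi_jitter_sd
        intervals = config.mean_ibi + d * np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
    else:
        jitter = (config._rng(_SUB_IBI).standard_normal(n) * config.ibi_jitter_sd
                  if config.ibi_jitter_sd > 0 else np.zeros(n))
        intervals = config.mean_ibi + jitter
    if np.any(intervals <= 0):
        raise ValueError("IBI jitter produced a nonpositive interval")
    onsets = np.cumsum(intervals) / 1000.0
    keep = onsets <= duration
    keep[0] = True
    return IBISeries(intervals[keep], onsets[keep])


def analytic_rmssd(config: TrialConfig) -> float:
    """Expected RMSSD implied by the jitter model (ms)."""
    if config.ibi_jitter_sd == 0:
        return 0.0
    if config.ibi_pattern == "alternating":
        return 2.0 * config.ibi_jitter_sd
    return float(config.ibi_jitter_sd * np.sqrt(2.0))


# ---------------------------------------------------------------------------
# Full trial
# ---------------------------------------------------------------------------

def _event_log(config: TrialConfig) -> EventLog:
    schedule = config.event_schedule
    if schedule is None:
        schedule = [("Start", 0.0), ("Stop", config.duration)]
    labels = [lab for lab, _ in schedule]
    if "Start" not in labels or "Stop" not in labels:
        raise ValueError("event schedule must include Start and Stop")
    times = np.array([config.start_time + t for _, t in schedule], dtype=float)
    order = np.argsort(times, kind="stable")
    return EventLog([labels[i] for i in order], times[order])


def rest_config(config: TrialConfig) -> TrialConfig:
    """The companion resting-state configuration: null effects, same montage."""
    rest_seed = int(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(_SUB_REST,))
        .generate_state(1)[0] % (2**31)
    )
    return dataclasses.replace(
        config,
        duration=config.resting_duration,
        asym_ratios={},
        scr_times=(), scr_amplitudes=(),
        spontaneous_scr_rate=min(config.spontaneous_scr_rate, 1.0),
        event_schedule=[("Start", 0.0), ("Stop", config.resting_duration)],
        seed=rest_seed,
    )


def generate_trial(config: TrialConfig, out_dir) -> GroundTruth:
    """Write one synthetic trial to ``out_dir`` and return its ground truth.

    Files written: ``trial.h5`` (eeg/eda/hr streams), ``rest.h5`` (resting
    baseline), ``events.csv`` (Unix-epoch annotations) and
    ``ground_truth.json``.  Identical (config, seed) produce identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log = _event_log(config)

    eeg = generate_eeg(config)
    eda, scr_truth = generate_eda(config)
    ibi = generate_ibi(config)
    write_container(out_dir / "trial.h5", _streams(config, eeg, eda, ibi))

    rc = rest_config(config)
    write_container(
        out_dir / "rest.h5",
        _streams(rc, generate_eeg(rc), generate_eda(rc)[0], generate_ibi(rc)),
    )

    write_annotations(out_dir / "events.csv", log)
    truth = GroundTruth(
        asym_ratios={b: config.asym_ratio(b) for b in BAND_CENTERS},
        scr_times=scr_truth["scr_times"],
        scr_amplitudes=scr_truth["scr_amplitudes"],
        analytic_rmssd=analytic_rmssd(config),
        event_counts={lab: log.count(lab) for lab in set(log.labels)},
    )
    (out_dir / "ground_truth.json").write_text(
        json.dumps(truth.to_dict(), indent=1, sort_keys=True)
    )
    return truth


def _streams(config: TrialConfig, eeg: EEGRecording, eda: EDARecording,
             ibi: IBISeries) -> list[TimestampedStream]:
    t0 = config.start_time
    n_eeg = eeg.n_samples
    beat_times = t0 + ibi.onsets_s
    beat_rate = 1.0 / float(np.median(np.diff(beat_times))) if len(ibi) > 1 else 1.0
    return [
        TimestampedStream("eeg", config.eeg_rate,
                          t0 + np.arange(n_eeg) / config.eeg_rate,
                          eeg.values.T, list(eeg.labels)),
        TimestampedStream("eda", config.eda_rate, t0 + eda.timestamps,
                          eda.values[:, None], ["eda"]),
        TimestampedStream("hr", beat_rate, beat_times,
                          ibi.intervals_ms[:, None], ["ibi_ms"]),
    ]
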