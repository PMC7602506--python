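"""Electrodermal and heart-rate processing: calibration, SCRs, RMSSD.

The skin-conductance channel arrives as raw sensor ADC counts sampled at
16 Hz; an affine range calibration turns counts into microsiemens.  After
low-pass filtering (motion artifacts ride above a few Hz while electrodermal
responses are slow), the signal splits into a tonic level (sliding-median
trend) and a phasic remainder on which skin-conductance responses (SCRs) --
abrupt conductance rises signalling sympathetic arousal -- are detected as
local-minimum-to-local-maximum excursions.

Heart-rate variability is summarized by RMSSD, the root mean square of
successive inter-beat-interval differences (ms); task recordings are compared
to rest via the percent change of RMSSD, negative meaning reduced variability
(stronger concentration, emotion or effort).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.ndimage import percentile_filter


@dataclass(frozen=True)
class ADCCalibration:
    """Affine ADC -> conductance map: y[uS] = p1 * x + p2 (range-specific)."""

    p1: float = 1.0
    p2: float = 0.0
    range_setting: str = "identity"

    def __post_init__(self) -> None:
        if self.p1 == 0:
            raise ValueError("calibration slope p1 must be nonzero")


@dataclass
class EDARecording:
    """Skin conductance in microsiemens at a nominal 16 Hz."""

    values: np.ndarray
    rate: float = 16.0
    timestamps: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.rate <= 0:
            raise ValueError("EDA rate must be positive")
        if self.timestamps is None:
            self.timestamps = np.arange(self.values.size) / self.rate
        if np.any(self.values[np.isfinite(self.values)] < 0):
            raise ValueError("conductance must be non-negative")

    @property
    def duration(self) -> float:
        return self.values.size / self.rate


@dataclass(frozen=True)
class SCREvent:
    """One skin-conductance response: onset -> peak rise of >= threshold."""

    onset: float
    peak: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.onset >= self.peak:
            raise ValueError("SCR onset must precede its peak")


@dataclass
class IBISeries:
    """Inter-beat intervals (ms) with beat-onset times (s)."""

    intervals_ms: np.ndarray
    onsets_s: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.intervals_ms = np.asarray(self.intervals_ms, dtype=float)
        if np.any(self.intervals_ms <= 0):
            raise ValueError("inter-beat intervals must be positive")
        if self.onsets_s is None:
            self.onsets_s = np.cumsum(self.intervals_ms) / 1000.0
        else:
            self.onsets_s = np.asarray(self.onsets_s, dtype=float)

    def __len__(self) -> int:
        return self.intervals_ms.size


@dataclass
class SCRSummary:
    """SCR index (mean amplitude, uS) with count and rate for context."""

    index: float
    count: int
    rate_per_min: float
    amplitudes: list[float] = field(default_factory=list)


@dataclass
class AutonomicSummary:
    rmssd_ms: float
    rmssd_pct_change: float | None
    scr_count: int
    scr_index: float
    mean_tonic_us: float


def adc_to_conductance(x, cal: ADCCalibration) -> np.ndarray:
    """Calibrate raw ADC counts to conductance: y = p1 * x + p2."""
    return cal.p1 * np.asarray(x, dtype=float) + cal.p2


def lowpass_eda(rec: EDARecording, cutoff: float = 1.0) -> EDARecording:
    """Zero-phase low-pass removing motion/high-frequency noise.

    Default cutoff 1 Hz -- the electrodermal response itself is much slower,
    and the 16 Hz sampling leaves little headroom below the 8 Hz Nyquist.
    """
    nyq = rec.rate / 2
    if not 0 < cutoff < nyq:
        raise ValueError(f"cutoff must be in (0, {nyq}) Hz")
    sos = signal.butter(4, cutoff, btype="lowpass", fs=rec.rate, output="sos")
    values = signal.sosfiltfilt(sos, rec.values)
    # zero-phase filtering can undershoot 0 by ringing; conductance is >= 0
    return EDARecording(np.maximum(values, 0.0), rec.rate, rec.timestamps)


def decompose_tonic_phasic(
    rec: EDARecording, trend_window: float = 30.0, percentile: float = 25.0
) -> tuple[np.ndarray, np.ndarray]:
    """Split conductance into tonic trend and phasic remainder.

    Tonic is a sliding low-percentile trend (default: 25th percentile over
    30 s).  The window is long against the seconds-scale SCR and short
    against the minutes-scale baseline drift; tracking a low percentile
    rather than the median keeps superimposed responses from dragging the
    trend up, so phasic peak amplitudes stay faithful.  Phasic is the
    residual: tonic + phasic reconstructs the input exactly.
    """
    if rec.duration < trend_window:
        raise ValueError(
            f"recording of {rec.duration:.3g}s shorter than the {trend_window}s trend window"
        )
    size = int(round(trend_window * rec.rate)) | 1
    tonic = percentile_filter(rec.values, percentile, size=size, mode="nearest")
    return tonic, rec.values - tonic


def detect_scrs(
    phasic: np.ndarray,
    rate: float,
    min_amplitude: float = 0.05,
    max_rise: float = 5.0,
    refractory: float = 1.0,
) -> list[SCREvent]:
    """Detect SCRs as onset-to-peak excursions on the phasic component.

    A peak counts when the rise from the preceding local minimum (within
    ``max_rise`` seconds) reaches ``min_amplitude`` uS; peaks closer than
    ``refractory`` seconds are merged into the larger one.  Events come back
    non-overlapping in time order; an empty list is a valid result.
    """
    phasic = np.asarray(phasic, dtype=float)
    peaks, _ = signal.find_peaks(phasic, distance=max(1, int(round(refractory * rate))))
    events: list[SCREvent] = []
    prev_peak = 0
    for p in peaks:
        lo = max(prev_peak, p - int(round(max_rise * rate)))
        if lo >= p:
            continue
        onset = lo + int(np.argmin(phasic[lo:p]))
        amplitude = phasic[p] - phasic[onset]
        if amplitude >= min_amplitude and onset < p:
            events.append(SCREvent(onset / rate, p / rate, float(amplitude)))
            prev_peak = p
    return events


def scr_index(events: list[SCREvent], duration: float) -> SCRSummary:
    """Global SCR index: mean amplitude of detected responses (0 if none).

    Count and rate per minute are reported alongside so a frequency-based
    reading of the index stays recoverable.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    amps = [e.amplitude for e in events]
    return SCRSummary(
        index=float(np.mean(amps)) if amps else 0.0,
        count=len(amps),
        rate_per_min=60.0 * len(amps) / duration,
        amplitudes=amps,
    )


def rmssd(ibi: IBISeries) -> float:
    """Root mean square of successive inter-beat-interval differences (ms)."""
    if len(ibi) < 2:
        raise ValueError("RMSSD needs at least 2 intervals")
    d = np.diff(ibi.intervals_ms)
    return float(np.sqrt(np.mean(d**2)))


def rmssd_pct_change(task_rmssd: float, rest_rmssd: float) -> float:
    """Percent change of RMSSD vs rest: 100*(task-rest)/rest (negative = decrease)."""
    if rest_rmssd <= 0:
        raise ValueError("resting RMSSD must be positive")
    return 100.0 * (task_rmssd - rest_rmssd) / rest_rmssd


def hr_to_ibi(hr_bpm) -> IBISeries:
    """Convert a beat-wise heart-rate series (bpm) to inter-beat intervals.

    Each HR sample maps to one interval IBI = 60000/HR (ms); onset times are
    the cumulative sum, i.e. the series is resampled onto beat onsets.
    """
    hr = np.asarray(hr_bpm, dtype=float)
    if np.any(hr <= 0):
        raise ValueError("heart rate must be positive")
    return IBISeries(60000.0 / hr)


def ibi_to_hr(ibi: IBISeries) -> np.ndarray:
    """Inverse of hr_to_ibi: instantaneous HR (bpm) per beat."""
    return 60000.0 / ibi.intervals_ms
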