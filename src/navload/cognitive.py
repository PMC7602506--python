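"""Band power and hemispheric-asymmetry cognitive-load statistics.

The workload statistic is a frontal hemispheric asymmetry of band power: for a
homologous left/right electrode pair with band powers ``P_L``, ``P_R`` (uV^2),

    AI = (ln P_L - ln P_R) / ln(P_L + P_R)

Higher |AI| reflects stronger workload; the reported cognitive-load (CL) series
is -|AI| so that rising workload appears as a negative fluctuation.  Per
electrode, total cognitive load (TCL) is the time-average of baseline-
normalized log total band power: activation relative to the resting state.

Note that AI is *not* invariant to rescaling both powers by a common gain (the
``ln(P_L + P_R)`` denominator changes); powers must stay in uV^2.  A window
whose total power is ~1 uV^2 makes the denominator vanish; such windows are
marked invalid (NaN) because the index is undefined there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .preprocess import (
    DEFAULT_BANDS,
    HOMOLOGOUS_PAIRS,
    BandDefinition,
    EEGRecording,
    band_decompose,
)
from .streams import EventLog

#: |ln(P_L + P_R)| below this marks the window invalid (index undefined).
SINGULARITY_EPS = 1e-6

FRONTAL_PAIRS = (("F3", "F4"), ("Fp1", "Fp2"))

#: Disjoint band set used for "total power over all bands" (avoids double
#: counting alpha against its sub-bands).
_TOTAL_POWER_BANDS = ("delta", "theta", "alpha1", "alpha2", "beta", "gamma")


@dataclass
class PowerSeries:
    """Windowed band power: (n_windows, n_channels, n_bands), NaN = invalid."""

    windows: np.ndarray          # (n_windows, 2) [t0, t1) seconds
    channels: list[str]
    bands: list[str]
    powers: np.ndarray

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    @property
    def centers(self) -> np.ndarray:
        return self.windows.mean(axis=1)

    def get(self, channel: str, band: str) -> np.ndarray:
        if channel not in self.channels:
            raise KeyError(f"channel {channel!r} not in power series")
        if band not in self.bands:
            raise KeyError(f"band {band!r} not in power series")
        return self.powers[:, self.channels.index(channel), self.bands.index(band)]

    def total(self, channel: str, bands: tuple[str, ...] | None = None) -> np.ndarray:
        """Total power per window at one electrode, summed over disjoint bands."""
        if bands is None:
            bands = tuple(b for b in _TOTAL_POWER_BANDS if b in self.bands) or tuple(self.bands)
        return np.sum([self.get(channel, b) for b in bands], axis=0)


@dataclass
class AsymmetrySeries:
    """One asymmetry value per window for a homologous (left, right) pair."""

    pair: tuple[str, str]
    band: str
    times: np.ndarray            # window centers, seconds
    values: np.ndarray

    def mean(self) -> float:
        return float(np.nanmean(self.values))


@dataclass
class EnvelopeSeries:
    """Upper envelope of an asymmetry series with projected event markers."""

    times: np.ndarray
    values: np.ndarray
    markers: list[tuple[str, float]] = field(default_factory=list)


@dataclass
class CLSummary:
    """Per-electrode TCL plus the box-plot summary of their distribution."""

    tcl: dict[str, float]
    median: float
    q1: float
    q3: float
    whisker_lo: float
    whisker_hi: float
    skewness: float


# ---------------------------------------------------------------------------
# Band power
# ---------------------------------------------------------------------------

def band_power(
    rec: EEGRecording,
    bands: list[BandDefinition] | None = None,
    window: float = 1.0,
    overlap: float = 0.5,
    max_missing: float = 0.1,
) -> PowerSeries:
    """Windowed band power per channel.

    Each band is isolated with the zero-phase band filter and its power taken
    as the windowed mean square (the Parseval-equivalent of integrating the
    periodogram over the band): an amplitude-``a`` sinusoid in the band yields
    ~a^2/2.  Windows are ``window`` seconds with fractional ``overlap``;
    windows with more than ``max_missing`` missing samples are invalid (NaN).
    """
    if bands is None:
        bands = [DEFAULT_BANDS[n] for n in _TOTAL_POWER_BANDS]
    if window <= 0 or not 0 <= overlap < 1:
        raise ValueError("need window > 0 and 0 <= overlap < 1")
    if window > rec.duration:
        raise ValueError(
            f"window of {window}s longer than recording of {rec.duration:.3g}s"
        )
    per_band = band_decompose(rec, bands)
    wlen = int(round(window * rec.rate))
    step = max(1, int(round(wlen * (1 - overlap))))
    starts = np.arange(0, rec.n_samples - wlen + 1, step)
    windows = np.column_stack([starts / rec.rate, (starts + wlen) / rec.rate])
    powers = np.full((len(starts), rec.n_channels, len(bands)), np.nan)
    raw_finite = np.isfinite(rec.values)
    for w, s in enumerate(starts):
        ok = np.mean(raw_finite[:, s:s + wlen], axis=1) >= 1 - max_missing
        if not ok.any():
            continue
        for bi, band in enumerate(bands):
            seg = per_band[band.name].values[np.flatnonzero(ok), s:s + wlen]
            finite = np.isfinite(seg)
            sums = np.where(finite, seg, 0.0) ** 2
            counts = finite.sum(axis=1)
            good = counts > 0
            vals = np.full(seg.shape[0], np.nan)
            vals[good] = sums.sum(axis=1)[good] / counts[good]
            powers[w, np.flatnonzero(ok), bi] = vals
    return PowerSeries(windows, list(rec.labels), [b.name for b in bands], powers)


# ---------------------------------------------------------------------------
# Asymmetry / cognitive load
# ---------------------------------------------------------------------------

def asymmetry_index(p_left, p_right):
    """Hemispheric asymmetry: (ln P_L - ln P_R) / ln(P_L + P_R).

    Exactly antisymmetric in its arguments.  Raises on nonpositive power;
    returns NaN where |ln(P_L + P_R)| < SINGULARITY_EPS (the index is
    undefined when total power is ~1 uV^2).
    """
    p_left = np.asarray(p_left, dtype=float)
    p_right = np.asarray(p_right, dtype=float)
    if np.any(p_left <= 0) or np.any(p_right <= 0):
        raise ValueError("band powers must be strictly positive")
    denom = np.log(p_left + p_right)
    with np.errstate(divide="ignore", invalid="ignore"):
        ai = np.where(np.abs(denom) < SINGULARITY_EPS, np.nan,
                      (np.log(p_left) - np.log(p_right)) / denom)
    return float(ai) if ai.ndim == 0 else ai


def _check_pair(pair: tuple[str, str]) -> None:
    left, right = pair
    if HOMOLOGOUS_PAIRS.get(left) != right:
        raise ValueError(f"({left}, {right}) is not a (left, right) homologous 10-20 pair")


def asymmetry_series(power: PowerSeries, pair: tuple[str, str], band: str) -> AsymmetrySeries:
    """Windowed asymmetry index for one homologous pair in one band."""
    _check_pair(pair)
    pl, pr = power.get(pair[0], band), power.get(pair[1], band)
    values = np.full(power.n_windows, np.nan)
    ok = np.isfinite(pl) & np.isfinite(pr) & (pl > 0) & (pr > 0)
    if np.any(ok):
        values[ok] = asymmetry_index(pl[ok], pr[ok])
    return AsymmetrySeries(pair, band, power.centers, values)


def cl_index(frontal_asym: AsymmetrySeries) -> AsymmetrySeries:
    """Cognitive-load series: CL = -|AI| per window (frontal pairs only).

    The sign convention makes rising workload a *negative* fluctuation.
    """
    if frontal_asym.pair not in FRONTAL_PAIRS:
        raise ValueError(
            f"cognitive load is defined on frontal pairs {FRONTAL_PAIRS}, "
            f"got {frontal_asym.pair}"
        )
    return AsymmetrySeries(
        frontal_asym.pair, frontal_asym.band,
        frontal_asym.times, -np.abs(frontal_asym.values),
    )


def normalize_log_power(power: PowerSeries, resting: PowerSeries) -> PowerSeries:
    """Baseline log band power against the resting state (pipeline default mode).

    Returns a PowerSeries whose entries are ln P_task(w) minus the resting
    mean of ln P_rest per (channel, band) — dimensionless activation relative
    to rest.  A resting series normalized against itself has per-channel,
    per-band mean zero.  Raises naming any channel missing from the reference.
    """
    missing = set(power.channels) - set(resting.channels)
    if missing:
        raise ValueError(f"resting reference lacks channel(s): {sorted(missing)}")
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(power.powers > 0, np.log(power.powers), np.nan)
    ref = np.full((len(power.channels), len(power.bands)), np.nan)
    for ci, ch in enumerate(power.channels):
        for bi, band in enumerate(power.bands):
            r = resting.get(ch, band)
            r = r[np.isfinite(r) & (r > 0)]
            if r.size:
                ref[ci, bi] = np.mean(np.log(r))
    return PowerSeries(power.windows, list(power.channels), list(power.bands),
                       logp - ref[None, :, :])


def total_cl(power: PowerSeries, electrode: str, resting: PowerSeries) -> float:
    """Total cognitive load at one electrode (natural-log units).

    Time-average of the log total band power, baselined against the resting
    state: mean_w ln P_task(w) - mean_w ln P_rest(w).  Zero means activation
    at resting level; 1 means total power e times resting.
    """
    task = power.total(electrode)
    rest = resting.total(electrode)
    task, rest = task[task > 0], rest[rest > 0]
    if task.size == 0 or rest.size == 0:
        raise ValueError(f"no valid windows for electrode {electrode!r}")
    return float(np.nanmean(np.log(task)) - np.nanmean(np.log(rest)))


def global_cl(power: PowerSeries, resting: PowerSeries) -> CLSummary:
    """Per-electrode TCL plus its box-plot distribution over electrodes.

    Quartiles use linear interpolation; whiskers are the Tukey adjacent values
    (the extreme data within 1.5 IQR of the quartiles); skewness is the
    biased sample skewness.
    """
    if not power.channels:
        raise ValueError("power series has no channels")
    tcl = {ch: total_cl(power, ch, resting) for ch in power.channels}
    vals = np.array(list(tcl.values()))
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    iqr = q3 - q1
    in_lo = vals[vals >= q1 - 1.5 * iqr]
    in_hi = vals[vals <= q3 + 1.5 * iqr]
    return CLSummary(
        tcl=tcl, median=float(med), q1=float(q1), q3=float(q3),
        whisker_lo=float(in_lo.min()), whisker_hi=float(in_hi.max()),
        skewness=_skew(vals),
    )


def _skew(vals: np.ndarray) -> float:
    if vals.size <= 2 or np.ptp(vals) < 1e-12:
        return 0.0
    return float(stats.skew(vals))


def asymmetry_envelope(series: AsymmetrySeries, events: EventLog | None = None) -> EnvelopeSeries:
    """Upper envelope of an asymmetry series with collision markers.

    Local maxima are joined by linear interpolation (endpoints always act as
    supports, so a constant series has a flat envelope).  Collision events are
    projected onto the nearest window center.
    """
    values, times = series.values, series.times
    if values.size < 3:
        raise ValueError("envelope needs at least 3 windows")
    from scipy.signal import find_peaks

    peaks, _ = find_peaks(values)
    supports = np.unique(np.concatenate(([0], peaks, [values.size - 1])))
    envelope = np.interp(times, times[supports], values[supports])
    markers = []
    if events is not None:
        for t in events.times_of("Collision"):
            markers.append(("Collision", float(times[np.argmin(np.abs(times - t))])))
    return EnvelopeSeries(times, envelope, markers)


def vc_asymmetry(
    power: PowerSeries, resting: PowerSeries
) -> tuple[AsymmetrySeries, dict[str, float]]:
    """Visual-cortex analysis: (O1, O2) asymmetry per window plus each TCL."""
    for ch in ("O1", "O2"):
        if ch not in power.channels:
            raise ValueError(f"occipital channel {ch!r} missing")
    series = asymmetry_series(power, ("O1", "O2"), _pick_band(power))
    tcl = {ch: total_cl(power, ch, resting) for ch in ("O1", "O2")}
    return series, tcl


def _pick_band(power: PowerSeries) -> str:
    for band in ("alpha", "alpha1"):
        if band in power.bands:
            return band
    return power.bands[0]
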