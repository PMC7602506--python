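"""EEG conditioning chain: band-pass, notch, artifact removal, band split, baselining.

The recordings come from a 16-electrode 10-20 montage with an ear reference at
512 Hz.  All filters are zero-phase (applied forward and backward) so that
event-locked timing downstream is preserved.  Missing samples (the alignment
padding sentinel, NaN) are propagated, never imputed: filters run on each
contiguous finite segment and leave the gaps untouched.

Band edges: the classical delta/theta/alpha/beta/gamma split, with the lower
and upper alpha sub-bands (alpha1 7-10 Hz, attentional demand; alpha2 10-13 Hz,
task difficulty) resolved separately, and gamma capped at 45 Hz to stay clear
of the 50 Hz mains notch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

#: Default montage.  The acquisition montage of the study hardware; T7 fills
#: the slot the acquisition sheet listed twice as C4 (the temporal-pair
#: analyses require T7/T8).
DEFAULT_MONTAGE = [
    "Fp1", "F7", "F3", "C3", "P3", "P7", "T7", "O1",
    "O2", "Fp2", "F8", "F4", "C4", "P4", "T8", "P8",
]

#: Left -> right homologous 10-20 pairs (overridable in configs).
HOMOLOGOUS_PAIRS = {
    "Fp1": "Fp2", "F7": "F8", "F3": "F4", "C3": "C4",
    "T7": "T8", "P3": "P4", "P7": "P8", "O1": "O2",
}


@dataclass(frozen=True)
class BandDefinition:
    """A half-open frequency band [lo, hi) in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not 0 < self.lo < self.hi:
            raise ValueError(f"band {self.name!r}: need 0 < lo < hi, got [{self.lo}, {self.hi})")

    def overlaps(self, other: "BandDefinition") -> bool:
        return self.lo < other.hi and other.lo < self.hi


#: Default analysis bands.  alpha1/alpha2 deliberately overlap alpha; that is
#: the only overlap band_decompose accepts.
DEFAULT_BANDS = {
    "delta": BandDefinition("delta", 0.5, 4.0),
    "theta": BandDefinition("theta", 4.0, 7.0),
    "alpha": BandDefinition("alpha", 8.0, 13.0),
    "alpha1": BandDefinition("alpha1", 7.0, 10.0),
    "alpha2": BandDefinition("alpha2", 10.0, 13.0),
    "beta": BandDefinition("beta", 13.0, 30.0),
    "gamma": BandDefinition("gamma", 30.0, 45.0),
}

_ALPHA_FAMILY = {"alpha", "alpha1", "alpha2"}


@dataclass
class EEGRecording:
    """channels x samples EEG in microvolts with 10-20 labels."""

    values: np.ndarray
    rate: float
    labels: list[str]
    reference: str = "ear"

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if len(self.labels) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.values.shape[0]} channels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.values[self.labels.index(label)]
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None


@dataclass
class ArtifactMask:
    """Boolean per (channel, sample): True where an artifact was flagged."""

    mask: np.ndarray
    labels: list[str] = field(default_factory=list)

    @property
    def fraction(self) -> float:
        return float(np.mean(self.mask))


# ---------------------------------------------------------------------------
# NaN-segment-aware zero-phase filtering
# ---------------------------------------------------------------------------

def _finite_runs(finite: np.ndarray):
    """Yield (start, stop) index pairs of contiguous True runs."""
    idx = np.flatnonzero(np.diff(np.concatenate(([False], finite, [False])).astype(int)))
    return zip(idx[::2], idx[1::2])


def _sosfiltfilt_nan(sos: np.ndarray, values: np.ndarray,
                     padlen: int | None = None) -> np.ndarray:
    """Zero-phase filter each channel, segment-wise over finite runs.

    ``padlen`` should cover the filter's slowest transient (several periods of
    the lowest corner frequency), else start-up ringing leaks into the output.
    Runs too short for the edge padding stay untouched as missing.
    """
    out = np.full_like(values, np.nan)
    if padlen is None:
        padlen = 3 * (2 * sos.shape[0] + 1)
    for ch in range(values.shape[0]):
        x = values[ch]
        for a, b in _finite_runs(np.isfinite(x)):
            n = b - a
            if n > 3 * (2 * sos.shape[0] + 1):
                # even extension: continuous at the boundary, so the slow
                # corner's transient stays in the padding, not the signal
                out[ch, a:b] = signal.sosfiltfilt(sos, x[a:b], padtype="even",
                                                  padlen=min(padlen, n - 1))
    return out


def bandpass(rec: EEGRecording, lo: float = 0.5, hi: float = 100.0) -> EEGRecording:
    """Zero-phase 4th-order Butterworth band-pass (default 0.5-100 Hz)."""
    nyq = rec.rate / 2
    if not 0 < lo < hi < nyq:
        raise ValueError(f"need 0 < lo < hi < Nyquist ({nyq} Hz), got [{lo}, {hi}]")
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=rec.rate, output="sos")
    # pad over several periods of the low corner so its transient dies out
    padlen = int(3 * rec.rate / lo)
    return replace(rec, values=_sosfiltfilt_nan(sos, rec.values, padlen))


def notch(rec: EEGRecording, f0: float = 50.0, q: float = 25.0) -> EEGRecording:
    """Zero-phase IIR notch removing mains contamination at f0 (default 50 Hz)."""
    if not 0 < f0 < rec.rate / 2:
        raise ValueError(f"notch frequency {f0} Hz outside (0, Nyquist)")
    b, a = signal.iirnotch(f0, q, fs=rec.rate)
    sos = signal.tf2sos(b, a)
    return replace(rec, values=_sosfiltfilt_nan(sos, rec.values))


def remove_artifacts(
    rec: EEGRecording,
    window: float = 0.511,
    order: int = 3,
    k: float = 5.0,
) -> tuple[EEGRecording, ArtifactMask]:
    """Flag and replace transient artifacts against a Savitzky-Golay smooth.

    Per channel the signal is smoothed with a Savitzky-Golay filter (window in
    seconds, odd sample count, polynomial ``order``); samples whose residual
    exceeds ``k`` times the robust (MAD) residual scale are flagged as
    artifacts (blinks, muscle bursts, saturations).  The flagged region is
    slightly dilated to catch the artifact's tails, then replaced by a smooth
    fitted over the artifact-free neighbourhood (flagged samples are bridged
    by interpolation before re-smoothing, so the artifact itself does not
    drag the replacement).  Unflagged samples are returned bit-identical.
    """
    from scipy.ndimage import binary_dilation

    wlen = int(round(window * rec.rate))
    if wlen % 2 == 0:
        wlen += 1
    if wlen <= order:
        raise ValueError(f"window of {wlen} samples must exceed polynomial order {order}")
    grow = max(1, wlen // 20)
    out = rec.values.copy()
    mask = np.zeros_like(out, dtype=bool)
    for ch in range(rec.n_channels):
        x = rec.values[ch]
        for a, b in _finite_runs(np.isfinite(x)):
            if b - a <= wlen:
                continue
            seg = x[a:b]
            smooth = signal.savgol_filter(seg, wlen, order)
            resid = seg - smooth
            scale = 1.4826 * np.median(np.abs(resid - np.median(resid)))
            if scale <= 0:
                continue
            bad = np.abs(resid) > k * scale
            if not bad.any():
                continue
            bad = binary_dilation(bad, iterations=grow)
            idx = np.arange(seg.size)
            bridged = seg.copy()
            if bad.all():
                continue  # nothing clean to anchor a replacement on
            bridged[bad] = np.interp(idx[bad], idx[~bad], seg[~bad])
            resmooth = signal.savgol_filter(bridged, wlen, order)
            repaired = out[ch, a:b]
            repaired[bad] = resmooth[bad]
            out[ch, a:b] = repaired
            mask[ch, a:b] = bad
    return replace(rec, values=out), ArtifactMask(mask, list(rec.labels))


def band_decompose(
    rec: EEGRecording, bands: list[BandDefinition] | None = None
) -> dict[str, EEGRecording]:
    """Split a recording into per-band filtered copies.

    Requested bands must be pairwise disjoint, except within the alpha family
    (alpha vs alpha1/alpha2), whose overlap is intentional.
    """
    if bands is None:
        bands = list(DEFAULT_BANDS.values())
    nyq = rec.rate / 2
    for band in bands:
        if band.hi > nyq:
            raise ValueError(f"band {band.name!r} upper edge {band.hi} Hz exceeds Nyquist")
    for i, b1 in enumerate(bands):
        for b2 in bands[i + 1:]:
            if b1.overlaps(b2) and not ({b1.name, b2.name} <= _ALPHA_FAMILY):
                raise ValueError(f"bands {b1.name!r} and {b2.name!r} overlap")
    return {b.name: bandpass(rec, b.lo, b.hi) for b in bands}


def baseline_normalize(
    rec: EEGRecording, resting: EEGRecording
) -> EEGRecording:
    """Literal baselining: subtract each channel's resting-state mean amplitude.

    This is the time-series reading of baseline normalization; the pipeline
    default baselines log band power instead (see cognitive.total_cl), since
    every downstream statistic is power-based.
    """
    missing = set(rec.labels) - set(resting.labels)
    if missing:
        raise ValueError(f"resting reference lacks channel(s): {sorted(missing)}")
    ref = np.array(
        [np.nanmean(resting.channel(l)) for l in rec.labels]
    )
    return replace(rec, values=rec.values - ref[:, None])
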