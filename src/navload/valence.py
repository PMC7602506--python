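"""Valence-state statistic from right/left hemispheric band-power ratios.

For a homologous (right, left) electrode pair with band powers PS_R, PS_L,

    VS = ln(PS_R / PS_L)

Left-hemisphere inactivation (VS > 0 with these conventions for the temporal
pair) indicates withdrawal / negative affect; right inactivation indicates an
approach response.  The statistic is exactly antisymmetric in its arguments
and invariant to any common rescaling of both powers, so amplifier gain
cancels.  Computed on the alpha, beta and gamma bands over the central,
temporal, parietal and frontal pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cognitive import PowerSeries
from .preprocess import HOMOLOGOUS_PAIRS

#: (right, left) pairs considered for affect: temporal first (most relevant).
VALENCE_PAIRS = (("T8", "T7"), ("C4", "C3"), ("P4", "P3"), ("F4", "F3"))

VALENCE_BANDS = ("alpha", "beta", "gamma")

#: Classification thresholds on |VS| (natural-log units).
NEUTRAL_BAND = 0.05
STRONG_BAND = 0.25


@dataclass
class ValenceSeries:
    """Windowed valence state for one (right, left) pair in one band."""

    pair: tuple[str, str]        # (right, left)
    band: str
    times: np.ndarray
    values: np.ndarray

    @property
    def mean(self) -> float:
        """Trial-level VS: the mean of the windowed values."""
        return float(np.nanmean(self.values))


def valence_state(ps_right, ps_left):
    """VS = ln(PS_R / PS_L); antisymmetric and scale-invariant."""
    ps_right = np.asarray(ps_right, dtype=float)
    ps_left = np.asarray(ps_left, dtype=float)
    if np.any(ps_right <= 0) or np.any(ps_left <= 0):
        raise ValueError("band powers must be strictly positive")
    vs = np.log(ps_right) - np.log(ps_left)
    return float(vs) if vs.ndim == 0 else vs


def valence_over_time(
    power: PowerSeries,
    pairs: tuple[tuple[str, str], ...] = VALENCE_PAIRS,
    bands: tuple[str, ...] = VALENCE_BANDS,
) -> list[ValenceSeries]:
    """Windowed VS for every (pair, band) combination.

    Raises KeyError naming the first missing channel or band.
    """
    out = []
    for right, left in pairs:
        if HOMOLOGOUS_PAIRS.get(left) != right:
            raise ValueError(f"({right}, {left}) is not a (right, left) homologous pair")
        for band in bands:
            pr, pl = power.get(right, band), power.get(left, band)
            values = np.full(power.n_windows, np.nan)
            ok = np.isfinite(pr) & np.isfinite(pl) & (pr > 0) & (pl > 0)
            if np.any(ok):
                values[ok] = valence_state(pr[ok], pl[ok])
            out.append(ValenceSeries((right, left), band, power.centers, values))
    return out


def classify_valence(
    mean_vs: float,
    neutral_band: float = NEUTRAL_BAND,
    strong_band: float = STRONG_BAND,
) -> str:
    """Qualitative label for a trial-level VS under symmetric thresholds.

    |VS| < neutral_band -> "neutral"; up to strong_band -> "low positive" /
    "low negative"; beyond -> "positive" / "negative".
    """
    if not np.isfinite(mean_vs):
        raise ValueError("valence state must be finite")
    mag = abs(mean_vs)
    if mag < neutral_band:
        return "neutral"
    side = "positive" if mean_vs > 0 else "negative"
    return f"low {side}" if mag < strong_band else side


def valence_table(series: list[ValenceSeries]):
    """Trial-level VS per (pair, band) as a pairs x bands table with aggregate.

    Rows are pairs, columns are bands plus an 'aggregate' column (mean over
    bands of the trial-level means; window -> trial -> band aggregation order).
    """
    import pandas as pd

    rows: dict[str, dict[str, float]] = {}
    for s in series:
        rows.setdefault("-".join(s.pair), {})[s.band] = s.mean
    df = pd.DataFrame(rows).T
    df["aggregate"] = df.mean(axis=1)
    df.index.name = "pair"
    return df
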