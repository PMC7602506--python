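"""Behavioral navigation metrics and their cumulative aggregation.

Each trial is one traversal of a test scenario (A..E, easiest to hardest)
under one codification — white cane, or the assistive device with audio,
haptic or multimodal encoding.  From the annotated event log and (optional)
walked path the per-trial metrics are duration, collision count, cane-contact
count and path length; trials aggregate into a cumulative table per
(codification, scenario) plus per-scenario averages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .streams import EventLog

CODIFICATIONS = ("audio", "haptic", "multimodal", "cane")
SCENARIOS = ("A", "B", "C", "D", "E")


@dataclass
class TrialRecord:
    """One navigation trial: its events and, when measured, the walked path."""

    codification: str
    scenario: str
    events: EventLog
    path: np.ndarray | None = None          # (n, 2) positions in metres
    path_times: np.ndarray | None = None    # seconds, within [Start, Stop]

    def __post_init__(self) -> None:
        if self.codification not in CODIFICATIONS:
            raise ValueError(f"unknown codification {self.codification!r}")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.path is not None:
            self.path = np.asarray(self.path, dtype=float)
            if self.path.ndim != 2 or self.path.shape[1] != 2:
                raise ValueError("path must be an (n, 2) array of positions")
        if self.path_times is not None:
            t = np.asarray(self.path_times, dtype=float)
            if np.any(t < self.events.t_start) or np.any(t > self.events.t_stop):
                raise ValueError("path timestamps must lie within [Start, Stop]")


def path_length(path: np.ndarray | None) -> float | None:
    """Total Euclidean length of an ordered 2-D path; None when unmeasured."""
    if path is None:
        return None
    return float(np.sum(np.linalg.norm(np.diff(path, axis=0), axis=1)))


def trial_metrics(trial: TrialRecord) -> dict:
    """Per-trial metrics: duration, collisions, cane contacts, path length.

    Path length is None (missing, never 0) when no path was recorded.
    """
    ev = trial.events
    return {
        "codification": trial.codification,
        "scenario": trial.scenario,
        "duration_s": ev.duration,
        "collisions": ev.count("Collision"),
        "cane_contacts": ev.count("TouchCane"),
        "finds": ev.count("Find"),
        "losts": ev.count("Lost"),
        "path_length_m": path_length(trial.path),
    }


@dataclass
class MetricsTable:
    """Cumulative per-(codification, scenario) metrics and per-scenario averages."""

    cumulative: pd.DataFrame
    scenario_means: pd.DataFrame

    def to_csv(self, path) -> None:
        """Export the cumulative table with the report-style column names.

        Cane contacts are blank (not zero) for device codifications, where a
        cane was not carried.
        """
        df = self.cumulative.reset_index()
        out = pd.DataFrame(
            {
                "Codification": df["codification"],
                "Scenario Type": df["scenario"],
                "Collisions Total Number": df["collisions"],
                "Path Total Distance (m)": df["path_length_m"],
                "Total Time (s)": df["duration_s"],
                "Cane Contacts": [
                    c if cod == "cane" else ""
                    for cod, c in zip(df["codification"], df["cane_contacts"])
                ],
            }
        )
        out.to_csv(path, index=False)


def aggregate_metrics(trials: list[TrialRecord]) -> MetricsTable:
    """Aggregate trial metrics: cumulative sums per cell, means per scenario.

    Sums are exact (integer counts, exact-sum distances) and permutation-
    invariant over trials; a missing path length stays missing (NaN) in cells
    where no trial measured a path.
    """
    if not trials:
        raise ValueError("need at least one trial")
    df = pd.DataFrame([trial_metrics(t) for t in trials])
    agg = {
        "duration_s": "sum",
        "collisions": "sum",
        "cane_contacts": "sum",
        "finds": "sum",
        "losts": "sum",
        "path_length_m": lambda s: s.sum(min_count=1),
    }
    cumulative = df.groupby(["codification", "scenario"], sort=True).agg(agg)
    scenario_means = df.groupby("scenario", sort=True)[
        ["duration_s", "collisions", "cane_contacts", "path_length_m"]
    ].mean()
    return MetricsTable(cumulative, scenario_means)
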