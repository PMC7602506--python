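"""Timestamped stream containers, event annotations and trial-timeline alignment.

Recordings are stored LSL-style: every modality is a timestamped stream in one
HDF5 container (one group per stream with ``time``/``values`` datasets), and
navigation events annotated on the trial video live in a sidecar CSV with
Unix-epoch timestamps.  This module reads and validates both, and aligns the
streams to a common reference timeline (the video length) by trimming overruns
and padding shortfalls with NaN, reporting what it did.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

#: Navigation event vocabulary used by the trial annotations.
EVENT_LABELS = ("Start", "Collision", "Find", "Lost", "TouchCane", "Stop")

#: Sentinel for padded / missing samples (propagated, never imputed).
MISSING = np.nan


class SchemaError(ValueError):
    """Container or annotation file does not match the expected layout."""


@dataclass
class TimestampedStream:
    """One modality's samples on an absolute (epoch-anchored) timebase.

    ``values`` is samples x channels; ``timestamps`` holds one time (seconds,
    double) per sample and must be monotone non-decreasing and consistent with
    ``nominal_rate`` to within 1%.
    """

    name: str
    nominal_rate: float
    timestamps: np.ndarray
    values: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] == 1 and self.timestamps.size > 1:
            self.values = self.values.T
        self.validate()

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.nominal_rate

    def validate(self) -> None:
        if self.nominal_rate <= 0:
            raise ValueError(f"stream {self.name!r}: nominal_rate must be > 0")
        if self.timestamps.shape[0] != self.values.shape[0]:
            raise ValueError(
                f"stream {self.name!r}: {self.timestamps.shape[0]} timestamps "
                f"for {self.values.shape[0]} samples"
            )
        if np.any(np.diff(self.timestamps) < 0):
            raise ValueError(f"stream {self.name!r}: timestamps not monotone non-decreasing")
        if self.labels and len(self.labels) != self.n_channels:
            raise ValueError(f"stream {self.name!r}: label/channel count mismatch")
        if self.timestamps.size > 1:
            dt = float(np.median(np.diff(self.timestamps)))
            if dt > 0 and abs(dt - 1.0 / self.nominal_rate) > 0.01 / self.nominal_rate:
                raise ValueError(
                    f"stream {self.name!r}: median timestamp spacing {dt:.6g}s "
                    f"inconsistent with nominal rate {self.nominal_rate} Hz"
                )


@dataclass
class EventLog:
    """Validated navigation events: exactly one Start and one Stop bracket all rows."""

    labels: list[str]
    times: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.validate()

    def validate(self) -> None:
        unknown = set(self.labels) - set(EVENT_LABELS)
        if unknown:
            raise ValueError(f"unknown event label(s): {sorted(unknown)}")
        if self.labels.count("Start") != 1 or self.labels.count("Stop") != 1:
            raise ValueError("event log must contain exactly one Start and one Stop")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("event timestamps must be non-decreasing")
        t0, t1 = self.t_start, self.t_stop
        if np.any(self.times < t0) or np.any(self.times > t1):
            raise ValueError("all event timestamps must lie within [Start, Stop]")

    @property
    def t_start(self) -> float:
        return float(self.times[self.labels.index("Start")])

    @property
    def t_stop(self) -> float:
        return float(self.times[self.labels.index("Stop")])

    @property
    def duration(self) -> float:
        return self.t_stop - self.t_start

    def __len__(self) -> int:
        return len(self.labels)

    def count(self, label: str) -> int:
        return self.labels.count(label)

    def times_of(self, label: str) -> np.ndarray:
        return self.times[[i for i, l in enumerate(self.labels) if l == label]]

    def relative_to_start(self) -> "EventLog":
        """Re-express all timestamps relative to the Start event."""
        return EventLog(list(self.labels), self.times - self.t_start)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"event": self.labels, "timestamp": self.times})


@dataclass
class StreamAlignment:
    """What align_streams did to one stream (seconds, non-negative)."""

    name: str
    trimmed: float = 0.0
    padded: float = 0.0
    residual_offset: float = 0.0
    flags: list[str] = field(default_factory=list)


@dataclass
class AlignmentReport:
    entries: dict[str, StreamAlignment] = field(default_factory=dict)

    def __getitem__(self, name: str) -> StreamAlignment:
        return self.entries[name]


# ---------------------------------------------------------------------------
# HDF5 container I/O
# ---------------------------------------------------------------------------

def write_container(path, streams: list[TimestampedStream]) -> None:
    """Write streams to an HDF5 container, one group per stream."""
    with h5py.File(path, "w") as f:
        for s in streams:
            g = f.create_group(s.name)
            g.create_dataset("time", data=s.timestamps, dtype="f8")
            g.create_dataset("values", data=s.values, dtype="f8")
            g.attrs["rate_hz"] = float(s.nominal_rate)
            g.attrs["labels"] = [str(l) for l in s.labels] if s.labels else []


def read_container(path) -> list[TimestampedStream]:
    """Read and validate every stream group in an HDF5 container."""
    streams = []
    with h5py.File(path, "r") as f:
        for name in sorted(f.keys()):
            g = f[name]
            for ds in ("time", "values"):
                if ds not in g:
                    raise SchemaError(f"group {name!r}: missing dataset {ds!r}")
            if "rate_hz" not in g.attrs:
                raise SchemaError(f"group {name!r}: missing attribute 'rate_hz'")
            labels = [str(l) for l in g.attrs.get("labels", [])]
            streams.append(
                TimestampedStream(
                    name=name,
                    nominal_rate=float(g.attrs["rate_hz"]),
                    timestamps=g["time"][...],
                    values=g["values"][...],
                    labels=labels,
                )
            )
    return streams


def write_annotations(path, log: EventLog) -> None:
    log.to_frame().to_csv(path, index=False)


def read_annotations(path) -> EventLog:
    """Read an ``event,timestamp`` CSV into a validated EventLog."""
    df = pd.read_csv(path)
    if list(df.columns) != ["event", "timestamp"]:
        raise SchemaError(f"annotation CSV must have header 'event,timestamp', got {list(df.columns)}")
    return EventLog(list(df["event"].astype(str)), df["timestamp"].to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# Alignment and slicing
# ---------------------------------------------------------------------------

def align_streams(
    streams: list[TimestampedStream], reference_duration: float
) -> tuple[list[TimestampedStream], AlignmentReport]:
    """Trim or pad each stream so it spans exactly the reference timeline.

    Overruns are trimmed from the tail; shortfalls are padded with the
    missing-value sentinel (NaN), never imputed.  A stream overlapping the
    reference by less than 50% signals a gross clock error and raises.
    """
    if reference_duration <= 0:
        raise ValueError("reference_duration must be > 0")
    out, report = [], AlignmentReport()
    for s in streams:
        target_n = int(round(reference_duration * s.nominal_rate))
        n = s.n_samples
        entry = StreamAlignment(name=s.name)
        if n < 0.5 * target_n:
            raise ValueError(
                f"stream {s.name!r} covers {n / s.nominal_rate:.1f}s, less than 50% "
                f"of the {reference_duration:.1f}s reference: gross clock error"
            )
        if n > target_n:
            entry.trimmed = (n - target_n) / s.nominal_rate
            values = s.values[:target_n]
            times = s.timestamps[:target_n]
        elif n < target_n:
            entry.padded = (target_n - n) / s.nominal_rate
            entry.flags.append(f"{target_n - n} samples padded as missing")
            pad = np.full((target_n - n, s.n_channels), MISSING)
            values = np.vstack([s.values, pad])
            t0 = s.timestamps[-1] if n else 0.0
            times = np.concatenate(
                [s.timestamps, t0 + np.arange(1, target_n - n + 1) / s.nominal_rate]
            )
        else:
            values, times = s.values, s.timestamps
        entry.residual_offset = abs(values.shape[0] - reference_duration * s.nominal_rate) / s.nominal_rate
        if entry.residual_offset > 1.0 / s.nominal_rate:
            entry.flags.append("residual misalignment exceeds one sample")
        out.append(
            TimestampedStream(s.name, s.nominal_rate, times, values, list(s.labels))
        )
        report.entries[s.name] = entry
    return out, report


def slice_by_events(
    stream: TimestampedStream, log: EventLog
) -> tuple[TimestampedStream, EventLog]:
    """Restrict a stream to the half-open trial window [Start, Stop).

    Returns the sliced stream (timestamps rebased to 0 at Start) and the event
    log re-expressed relative to Start.
    """
    t0, t1 = log.t_start, log.t_stop
    keep = (stream.timestamps >= t0) & (stream.timestamps < t1)
    if not np.any(keep):
        raise ValueError(
            f"empty window: no samples of {stream.name!r} in [{t0}, {t1})"
        )
    sliced = TimestampedStream(
        stream.name,
        stream.nominal_rate,
        stream.timestamps[keep] - t0,
        stream.values[keep],
        list(stream.labels),
    )
    return sliced, log.relative_to_start()
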