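"""End-to-end orchestration: simulate -> ingest -> preprocess -> analyze -> report.

A trial directory holds ``trial.h5`` (eeg/eda/hr streams), ``rest.h5`` (the
resting baseline), and ``events.csv`` (annotations).  ``run_trial`` turns one
such directory into a TrialReport: cognitive-load summaries, alpha sub-band
asymmetry envelopes with collision markers, visual-cortex asymmetry, the
valence table, autonomic indices and behavioral metrics, stamped with the
config hash and seed for provenance.  ``compare_conditions`` reduces a set of
reports to descriptive per-codification statistics (no hypothesis tests, by
design: the analysis is descriptive).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import autonomic as auto
from . import behavior, cognitive, valence
from .preprocess import DEFAULT_BANDS, EEGRecording
from .preprocess import bandpass, notch, remove_artifacts
from .streams import EventLog, read_annotations, read_container, slice_by_events
from .synthetic import TrialConfig, generate_trial

_ANALYSIS_BANDS = [DEFAULT_BANDS[n] for n in
                   ("delta", "theta", "alpha", "alpha1", "alpha2", "beta", "gamma")]


class PipelineError(RuntimeError):
    """A stage failure, prefixed with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Validated pipeline settings; unknown keys in a config file are rejected."""

    out_dir: str = "navload-out"
    window: float = 1.0
    overlap: float = 0.5
    baseline_mode: str = "power"           # "power" | "literal"
    eda_cutoff: float = 1.0
    scr_min_amplitude: float = 0.05
    scr_max_rise: float = 5.0
    valence_neutral: float = 0.05
    valence_strong: float = 0.25
    seed: int = 0
    trials: list = field(default_factory=list)   # [{dir, codification, scenario}]
    simulate: list = field(default_factory=list)  # [{codification, scenario, config overrides}]

    def __post_init__(self) -> None:
        if self.baseline_mode not in ("power", "literal"):
            raise ValueError(f"unknown baseline_mode {self.baseline_mode!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class TrialReport:
    """Per-trial analysis output; every section traces to one analysis stage."""

    trial_dir: str
    codification: str
    scenario: str
    cognitive_load: dict
    envelopes: dict
    visual_cortex: dict
    valence: dict
    autonomic: dict
    behavior: dict
    provenance: dict

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True, indent=1,
                          default=_jsonable)


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")


def _require_stream(streams, name: str, stage: str):
    for s in streams:
        if s.name == name:
            return s
    raise PipelineError(stage, f"stream {name!r} missing from container")


def _eeg_power(stream, log: EventLog | None, config: PipelineConfig) -> cognitive.PowerSeries:
    """Slice (when a log is given), condition, and window-power an EEG stream."""
    if log is not None:
        stream, _ = slice_by_events(stream, log)
    rec = EEGRecording(stream.values.T, stream.nominal_rate, list(stream.labels))
    rec = notch(bandpass(rec))
    rec, _ = remove_artifacts(rec)
    return cognitive.band_power(rec, _ANALYSIS_BANDS,
                                window=config.window, overlap=config.overlap)


def run_trial(trial_dir, config: PipelineConfig,
              codification: str = "cane", scenario: str = "A") -> TrialReport:
    """Analyze one trial directory into a TrialReport."""
    trial_dir = Path(trial_dir)
    try:
        streams = read_container(trial_dir / "trial.h5")
        rest_streams = read_container(trial_dir / "rest.h5")
        log = read_annotations(trial_dir / "events.csv")
    except FileNotFoundError as e:
        raise PipelineError("ingest", str(e)) from e

    eeg = _require_stream(streams, "eeg", "ingest")
    eda_stream = _require_stream(streams, "eda", "ingest")
    hr_stream = _require_stream(streams, "hr", "ingest")
    rest_eeg = _require_stream(rest_streams, "eeg", "ingest")
    rest_hr = _require_stream(rest_streams, "hr", "ingest")

    # --- EEG power (task sliced to [Start, Stop); rest used whole) ---------
    try:
        power = _eeg_power(eeg, log, config)
        rest_power = _eeg_power(rest_eeg, None, config)
    except (ValueError, KeyError) as e:
        raise PipelineError("eeg", str(e)) from e

    # --- cognitive load ----------------------------------------------------
    try:
        cl: dict = {"frontal": {}}
        for pair in cognitive.FRONTAL_PAIRS:
            if pair[0] in power.channels and pair[1] in power.channels:
                for band in ("alpha1", "alpha2"):
                    series = cognitive.cl_index(
                        cognitive.asymmetry_series(power, pair, band))
                    cl["frontal"][f"{pair[0]}-{pair[1]}/{band}"] = {
                        "mean_cl": float(np.nanmean(series.values)),
                        "mean_abs_asym": float(np.nanmean(-series.values)),
                    }
        summary = cognitive.global_cl(power, rest_power)
        cl["global"] = {
            "tcl": {k: float(v) for k, v in summary.tcl.items()},
            "median": summary.median, "q1": summary.q1, "q3": summary.q3,
            "whisker_lo": summary.whisker_lo, "whisker_hi": summary.whisker_hi,
            "skewness": summary.skewness,
        }

        rel_log = log.relative_to_start()
        envelopes = {}
        for band in ("alpha1", "alpha2"):
            series = cognitive.asymmetry_series(power, ("F3", "F4"), band)
            env = cognitive.asymmetry_envelope(series, rel_log)
            envelopes[band] = {
                "times": env.times.tolist(),
                "values": [None if not np.isfinite(v) else float(v) for v in env.values],
                "markers": env.markers,
            }

        vc_series, vc_tcl = cognitive.vc_asymmetry(power, rest_power)
        with np.errstate(invalid="ignore", divide="ignore"):
            o1, o2 = power.total("O1"), power.total("O2")
            ok = (o1 > 0) & (o2 > 0)
            ln_ratio = float(np.nanmean(np.log(o1[ok]) - np.log(o2[ok]))) if ok.any() else float("nan")
        visual_cortex = {
            "mean_asymmetry": vc_series.mean(),
            "mean_ln_power_ratio": ln_ratio,
            "tcl": {k: float(v) for k, v in vc_tcl.items()},
        }
    except (ValueError, KeyError) as e:
        raise PipelineError("cognitive", str(e)) from e

    # --- valence ------------------------------------------------------------
    try:
        vs_series = valence.valence_over_time(power)
        table = valence.valence_table(vs_series)
        t8t7 = float(table.loc["T8-T7", "aggregate"])
        val = {
            "table": {r: {c: float(table.loc[r, c]) for c in table.columns}
                      for r in table.index},
            "t8_t7_aggregate": t8t7,
            "label": valence.classify_valence(
                t8t7, config.valence_neutral, config.valence_strong),
        }
    except (ValueError, KeyError) as e:
        raise PipelineError("valence", str(e)) from e

    # --- autonomic ----------------------------------------------------------
    try:
        eda_sliced, _ = slice_by_events(eda_stream, log)
        eda_rec = auto.EDARecording(eda_sliced.values[:, 0],
                                    eda_sliced.nominal_rate, eda_sliced.timestamps)
        eda_lp = auto.lowpass_eda(eda_rec, config.eda_cutoff)
        tonic, phasic = auto.decompose_tonic_phasic(eda_lp)
        events = auto.detect_scrs(phasic, eda_lp.rate,
                                  min_amplitude=config.scr_min_amplitude,
                                  max_rise=config.scr_max_rise)
        scr = auto.scr_index(events, eda_rec.duration)

        task_ibi = auto.IBISeries(hr_stream.values[:, 0])
        rest_ibi = auto.IBISeries(rest_hr.values[:, 0])
        task_rmssd = auto.rmssd(task_ibi)
        rest_rmssd = auto.rmssd(rest_ibi)
        autonomic_section = {
            "rmssd_ms": task_rmssd,
            "rest_rmssd_ms": rest_rmssd,
            "rmssd_pct_change": auto.rmssd_pct_change(task_rmssd, rest_rmssd),
            "scr_count": scr.count,
            "scr_index": scr.index,
            "scr_rate_per_min": scr.rate_per_min,
            "mean_tonic_us": float(np.mean(tonic)),
        }
    except (ValueError, KeyError) as e:
        raise PipelineError("autonomic", str(e)) from e

    # --- behavior -----------------------------------------------------------
    try:
        record = behavior.TrialRecord(codification, scenario, log)
        metrics = behavior.trial_metrics(record)
    except ValueError as e:
        raise PipelineError("behavior", str(e)) from e

    return TrialReport(
        trial_dir=str(trial_dir),
        codification=codification,
        scenario=scenario,
        cognitive_load=cl,
        envelopes=envelopes,
        visual_cortex=visual_cortex,
        valence=val,
        autonomic=autonomic_section,
        behavior=metrics,
        provenance={"config_hash": config.hash(), "seed": config.seed},
    )


def simulate_trials(config: PipelineConfig, out_dir=None) -> list[dict]:
    """Generate every trial in config.simulate; returns trial specs with dirs."""
    out_dir = Path(out_dir if out_dir is not None else config.out_dir)
    specs = []
    for i, spec in enumerate(config.simulate):
        spec = dict(spec)
        codification = spec.pop("codification", "cane")
        scenario = spec.pop("scenario", "A")
        spec.setdefault("seed", config.seed + i)
        tdir = out_dir / f"trial-{i:03d}-{codification}-{scenario}"
        generate_trial(TrialConfig(**spec), tdir)
        specs.append({"dir": str(tdir), "codification": codification,
                      "scenario": scenario})
    return specs


def run_pipeline(config: PipelineConfig) -> list[TrialReport]:
    """Simulate (if configured), analyze every trial, persist reports."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    trials = list(config.trials)
    if config.simulate:
        trials += simulate_trials(config, out_dir)
    if not trials:
        raise PipelineError("ingest", "no trials configured")
    reports = []
    for spec in trials:
        report = run_trial(spec["dir"], config,
                           codification=spec.get("codification", "cane"),
                           scenario=spec.get("scenario", "A"))
        (Path(spec["dir"]) / "report.json").write_text(report.to_json())
        reports.append(report)
    return reports


def compare_conditions(reports: list[TrialReport]) -> pd.DataFrame:
    """Descriptive per-codification comparison of CL, valence and autonomic indices.

    One row per codification: median/quartiles/whiskers/skewness of the
    per-trial global-CL medians, mean valence aggregate, mean RMSSD percent
    change and mean SCR index.  Purely descriptive: no hypothesis tests.
    """
    groups: dict[str, list[TrialReport]] = {}
    for r in reports:
        groups.setdefault(r.codification, []).append(r)
    if len(groups) < 2:
        raise ValueError("need at least 2 codification groups to compare")
    rows = {}
    for cod, rs in sorted(groups.items()):
        if not rs:
            raise ValueError(f"group {cod!r} has zero trials")
        cl = np.array([r.cognitive_load["global"]["median"] for r in rs])
        frontal = np.array([
            np.mean([v["mean_cl"] for v in r.cognitive_load["frontal"].values()])
            for r in rs
        ])
        q1, med, q3 = np.percentile(cl, [25, 50, 75])
        iqr = q3 - q1
        from .cognitive import _skew
        rows[cod] = {
            "n_trials": len(rs),
            "cl_median": med, "cl_q1": q1, "cl_q3": q3, "cl_iqr": iqr,
            "cl_whisker_lo": cl[cl >= q1 - 1.5 * iqr].min(),
            "cl_whisker_hi": cl[cl <= q3 + 1.5 * iqr].max(),
            "cl_skewness": _skew(cl),
            "frontal_cl_median": float(np.median(frontal)),
            "frontal_cl_iqr": float(np.subtract(*np.percentile(frontal, [75, 25]))),
            "valence_mean": float(np.mean([r.valence["t8_t7_aggregate"] for r in rs])),
            "rmssd_pct_change_mean": float(np.mean(
                [r.autonomic["rmssd_pct_change"] for r in rs])),
            "scr_index_mean": float(np.mean([r.autonomic["scr_index"] for r in rs])),
            "collisions_total": int(sum(r.behavior["collisions"] for r in rs)),
        }
    df = pd.DataFrame(rows).T
    df.index.name = "codification"
    return df
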