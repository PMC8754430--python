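"""File formats: trace TSV + JSON sidecar, event JSON, results tables.

A trace is stored as a two-column TSV (``time_s``, ``intensity``) next to
a JSON sidecar carrying acquisition metadata (sampling rate, pH, genotype,
optics, seed, efficiency class). Ground truth and detected events are
stored as JSON documents with a schema tag, so round trips restore the
original dataclasses. Summary tables go to CSV via pandas.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .analyze import DatasetSummary, TransientDwellEvent
from .simulate import (
    AnnotatedTrajectory,
    CatalyticDwell,
    IntensityTrace,
    PowerStroke,
    TransientDwellTruth,
)

__all__ = [
    "SchemaError",
    "save_trace",
    "load_trace",
    "save_events",
    "load_events",
    "save_trajectory",
    "load_trajectory",
    "save_tables",
]


class SchemaError(ValueError):
    """A file does not match the documented schema (names the offender)."""


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def save_trace(trace: IntensityTrace, path: str | Path) -> Path:
    """Write a trace as TSV (time_s, intensity) plus a JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame({"time_s": trace.time, "intensity": trace.intensity})
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    sidecar = {
        "sampling_rate": trace.sampling_rate,
        "ph": trace.ph,
        "genotype": trace.genotype,
        "meta": _jsonable(trace.meta),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return path


def load_trace(path: str | Path) -> IntensityTrace:
    """Read a trace TSV and its sidecar back into an `IntensityTrace`."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    for col in ("time_s", "intensity"):
        if col not in df.columns:
            raise SchemaError(f"trace file {path.name} is missing column {col!r}")
    sidecar_file = _sidecar_path(path)
    if sidecar_file.exists():
        sidecar = json.loads(sidecar_file.read_text())
    else:
        dt = float(np.median(np.diff(df["time_s"].to_numpy()))) if len(df) > 1 else 1.0
        sidecar = {"sampling_rate": 1.0 / dt, "ph": float("nan"), "genotype": "unknown", "meta": {}}
    t = df["time_s"].to_numpy()
    if len(t) > 2:
        dts = np.diff(t)
        if np.max(np.abs(dts - dts[0])) > 1e-6 * max(dts[0], 1e-12):
            raise SchemaError(f"trace file {path.name}: time_s is not a uniform grid")
    return IntensityTrace(
        intensity=df["intensity"].to_numpy(),
        sampling_rate=float(sidecar["sampling_rate"]),
        ph=float(sidecar["ph"]),
        genotype=sidecar.get("genotype", "unknown"),
        meta=sidecar.get("meta", {}),
    )


_EVENT_TYPES = {
    "transient_dwell": TransientDwellEvent,
    "transient_dwell_truth": TransientDwellTruth,
    "power_stroke": PowerStroke,
    "catalytic_dwell": CatalyticDwell,
}
_TYPE_TAGS = {cls: tag for tag, cls in _EVENT_TYPES.items()}


def save_events(events: list, path: str | Path) -> Path:
    """Serialize a list of event dataclasses to JSON, preserving order."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = []
    for ev in events:
        tag = _TYPE_TAGS.get(type(ev))
        if tag is None:
            raise SchemaError(f"cannot serialize event of type {type(ev).__name__}")
        payload.append({"type": tag, **_jsonable(dataclasses.asdict(ev))})
    path.write_text(json.dumps(payload, indent=1))
    return path


def load_events(path: str | Path) -> list:
    path = Path(path)
    out = []
    for row in json.loads(path.read_text()):
        if "type" not in row:
            raise SchemaError(f"event record in {path.name} is missing field 'type'")
        tag = row.pop("type")
        cls = _EVENT_TYPES.get(tag)
        if cls is None:
            raise SchemaError(f"unknown event type {tag!r} in {path.name}")
        try:
            out.append(cls(**row))
        except TypeError as exc:
            raise SchemaError(f"bad {tag} record in {path.name}: {exc}") from exc
    return out


def save_trajectory(traj: AnnotatedTrajectory, path: str | Path) -> Path:
    """Serialize a full annotated trajectory (breakpoints + labels) to JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = {
        "time_bp": [float(x) for x in traj.time_bp],
        "angle_bp": [float(x) for x in traj.angle_bp],
        "dwells": [_jsonable(dataclasses.asdict(d)) for d in traj.dwells],
        "strokes": [_jsonable(dataclasses.asdict(s)) for s in traj.strokes],
        "tds": [_jsonable(dataclasses.asdict(t)) for t in traj.tds],
        "duration": traj.duration,
        "ph": traj.ph,
        "seed": traj.seed,
        "efficiency_multiplier": traj.efficiency_multiplier,
    }
    path.write_text(json.dumps(doc, indent=1))
    return path


def load_trajectory(path: str | Path) -> AnnotatedTrajectory:
    doc = json.loads(Path(path).read_text())
    try:
        return AnnotatedTrajectory(
            time_bp=np.asarray(doc["time_bp"], float),
            angle_bp=np.asarray(doc["angle_bp"], float),
            dwells=[CatalyticDwell(**d) for d in doc["dwells"]],
            strokes=[PowerStroke(**s) for s in doc["strokes"]],
            tds=[TransientDwellTruth(**t) for t in doc["tds"]],
            duration=float(doc["duration"]),
            ph=float(doc["ph"]),
            seed=doc.get("seed"),
            efficiency_multiplier=float(doc.get("efficiency_multiplier", 1.0)),
        )
    except KeyError as exc:
        raise SchemaError(f"trajectory file {Path(path).name} is missing field {exc}") from exc


def summaries_to_frame(summaries: list[DatasetSummary], extra: list[dict] | None = None) -> pd.DataFrame:
    """Flatten per-data-set summaries into a tidy table."""
    rows = []
    for i, s in enumerate(summaries):
        row = {
            "n_power_strokes": s.n_power_strokes,
            "percent_with_td": s.percent_with_td,
            "n_tds": s.n_tds,
            "percent_td_with_step": s.percent_td_with_step,
            "mean_td_duration_us": float(np.mean(s.td_durations_us)) if s.td_durations_us else float("nan"),
            "mean_td_spacing_deg": float(np.mean(s.td_spacings_deg)) if s.td_spacings_deg else float("nan"),
            "mean_step_extent_deg": float(np.mean(s.step_extents_deg)) if s.step_extents_deg else float("nan"),
        }
        if extra is not None:
            row.update(extra[i])
        rows.append(row)
    return pd.DataFrame(rows)


def save_tables(tables: dict[str, pd.DataFrame], outdir: str | Path) -> list[Path]:
    """Write each named DataFrame as ``<name>.csv`` under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        written.append(p)
    return written


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj
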