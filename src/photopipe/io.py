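"""Plain-text file formats and provenance manifests.

Everything is CSV plus JSON sidecars: recordings as ``time_s,f465,f405``
with a ``.meta.json`` sidecar (rate, identifiers), schedules and ground
truth as JSON, dF/F traces as ``time_s,dff`` with method/fit sidecar, and
response tables as CSV.  Small, diff-able, reviewable files — photometry
sessions at 120 Hz are only megabytes.  ``RunManifest`` records config,
seeds and SHA-256 hashes of every output so a run can be re-executed and
checked byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field, is_dataclass
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd

from .recording import DffTrace, EventSchedule, PhotometryRecording
from .simulate import AmplitudeMap, GroundTruth, SimConfig

__all__ = [
    "read_recording", "write_recording",
    "read_schedule", "write_schedule",
    "read_dff", "write_dff",
    "write_ground_truth",
    "read_response_table", "write_response_table",
    "RunManifest", "sha256_file", "RaggedCsvError",
]


class RaggedCsvError(ValueError):
    """A CSV row has the wrong number of fields; carries the line number."""


def _meta_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def _read_csv_strict(path: Path, n_cols: int, header: list[str]) -> np.ndarray:
    rows = []
    with open(path) as fh:
        first = fh.readline().strip()
        if first.split(",") != header:
            raise ValueError(f"{path}: expected header {','.join(header)!r}, got {first!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.strip().split(",")
            if len(parts) != n_cols:
                raise RaggedCsvError(
                    f"{path}: line {lineno} has {len(parts)} fields, expected {n_cols}"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError as e:
                raise RaggedCsvError(f"{path}: line {lineno}: {e}") from None
    return np.asarray(rows, dtype=float)


# ---------------------------------------------------------------------
# recordings
# ---------------------------------------------------------------------

def write_recording(rec: PhotometryRecording, path: str | Path) -> Path:
    path = Path(path)
    rec.to_frame().to_csv(path, index=False, float_format="%.10g")
    meta = dict(rate=rec.rate, subject_id=rec.subject_id, session_id=rec.session_id)
    _meta_path(path).write_text(json.dumps(meta, indent=2))
    return path


def read_recording(path: str | Path) -> PhotometryRecording:
    """Read a ``time_s,f465,f405`` CSV; rate comes from the sidecar or,
    absent one, is inferred as 1/median(time step)."""
    path = Path(path)
    arr = _read_csv_strict(path, 3, ["time_s", "f465", "f405"])
    meta_p = _meta_path(path)
    meta = json.loads(meta_p.read_text()) if meta_p.exists() else {}
    time = arr[:, 0]
    if len(time) >= 2:
        dt = np.diff(time)
        med = float(np.median(dt))
        dev = float(np.max(np.abs(dt - med)))
        if np.any(dt <= 0) or dev > 1e-6:
            raise ValueError(
                f"{path}: non-uniform time base (max step deviation {dev:.3g} s)"
            )
        rate = meta.get("rate", 1.0 / med)
    else:
        rate = meta.get("rate", 1.0)
    return PhotometryRecording(
        time=time, f465=arr[:, 1], f405=arr[:, 2], rate=float(rate),
        subject_id=meta.get("subject_id", "subject"),
        session_id=meta.get("session_id", "session"),
    )


# ---------------------------------------------------------------------
# schedules / ground truth
# ---------------------------------------------------------------------

def _jsonable(x: Any) -> Any:
    if isinstance(x, float) and math.isnan(x):
        return None
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.bool_):
        return bool(x)
    return x


def write_schedule(schedule: EventSchedule, path: str | Path) -> Path:
    path = Path(path)
    events = [
        {k: _jsonable(v) for k, v in row.items()}
        for row in schedule.events.to_dict("records")
    ]
    doc = dict(duration=schedule.duration, protocol=schedule.protocol, events=events)
    path.write_text(json.dumps(doc, indent=2))
    return path


def read_schedule(path: str | Path) -> EventSchedule:
    doc = json.loads(Path(path).read_text())
    ev = pd.DataFrame(doc["events"])
    if "intensity" in ev.columns:
        ev["intensity"] = ev["intensity"].astype(float)
    return EventSchedule(events=ev, duration=float(doc["duration"]),
                         protocol=doc.get("protocol", ""))


def _config_dict(config: SimConfig) -> dict:
    d = asdict(config)
    amap = config.amplitude_map
    if isinstance(amap, AmplitudeMap):
        d["amplitude_map"] = amap.to_table()
    elif isinstance(amap, dict):
        d["amplitude_map"] = {
            k: (v.to_table() if isinstance(v, AmplitudeMap) else [list(p) for p in v])
            for k, v in amap.items()
        }
    return d


def write_ground_truth(truth: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    doc = dict(
        treatment=truth.treatment,
        config=_config_dict(truth.config),
        transients=[{k: _jsonable(v) for k, v in r.items()}
                    for r in truth.transients.to_dict("records")],
        motion=[{k: _jsonable(v) for k, v in r.items()}
                for r in truth.motion.to_dict("records")],
    )
    path.write_text(json.dumps(doc, indent=2, default=_jsonable))
    return path


# ---------------------------------------------------------------------
# dF/F traces and response tables
# ---------------------------------------------------------------------

def write_dff(trace: DffTrace, path: str | Path) -> Path:
    path = Path(path)
    trace.to_frame().to_csv(path, index=False, float_format="%.10g")
    meta = dict(method=trace.method, rate=trace.rate, fit=trace.fit,
                baseline_window=trace.baseline_window,
                subject_id=trace.subject_id, session_id=trace.session_id)
    _meta_path(path).write_text(json.dumps(meta, indent=2))
    return path


def read_dff(path: str | Path) -> DffTrace:
    path = Path(path)
    arr = _read_csv_strict(path, 2, ["time_s", "dff"])
    meta = json.loads(_meta_path(path).read_text())
    fit = tuple(meta["fit"]) if meta.get("fit") else None
    bw = tuple(meta["baseline_window"]) if meta.get("baseline_window") else None
    return DffTrace(time=arr[:, 0], dff=arr[:, 1], method=meta["method"],
                    rate=float(meta["rate"]), fit=fit, baseline_window=bw,
                    subject_id=meta.get("subject_id", "subject"),
                    session_id=meta.get("session_id", "session"))


def write_response_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False, float_format="%.10g")
    return path


def read_response_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------

def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record of one pipeline run.

    Re-running the same manifest (same config snapshot and seed) must
    reproduce byte-identical outputs for every deterministic stage.
    """

    config: dict
    seed: int
    stages: list[str] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    exclusions: dict[str, Any] = field(default_factory=dict)
    version: str = ""

    def record_output(self, path: str | Path) -> None:
        p = Path(path)
        self.outputs[p.name] = sha256_file(p)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2, default=_jsonable))
        return path

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        doc = json.loads(Path(path).read_text())
        return cls(**doc)
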