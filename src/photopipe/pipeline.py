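"""End-to-end pipeline: simulate -> preprocess -> extract -> analyze.

A run is described by a plain config mapping (YAML on disk), executed
stage by stage with intermediates persisted to the output directory and a
:class:`~photopipe.io.RunManifest` recording the config snapshot, seed and
SHA-256 of every output.  All randomness flows from the manifest seed.
Exclusion bookkeeping (trials in / excluded / analyzed) is logged per
stage — that is where photometry analyses silently go wrong.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .preprocess import compute_baseline_zscore_dff, compute_dff
from .protocols import ProtocolSpec, build_protocol
from .recording import EventSchedule
from .simulate import DreaddParams, SimConfig, simulate_dreadd_session, simulate_recording
from .stats import dose_response_summary, paired_t
from .trials import event_response_table

__all__ = ["run_pipeline", "StageError", "load_config", "DEFAULT_CONFIG"]

log = logging.getLogger("photopipe")

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "protocol": {"name": "tfc_train"},
    "sim": {},
    "treatment": None,
    "preprocess": {"method": "isosbestic", "baseline": None},
    "extract": {"events": ["tone_on", "tone_off", "shock_on"],
                "window": [20.0, 5.0], "width": 2.0, "z_thresh": 8.0,
                "baseline_window": None},
}


class StageError(RuntimeError):
    """A pipeline stage failed; names the stage and chains the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def load_config(path: str | Path) -> dict:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: pipeline config must be a mapping")
    return doc


def _merged_config(config: dict) -> dict:
    out = {k: (dict(v) if isinstance(v, dict) else v)
           for k, v in DEFAULT_CONFIG.items()}
    for k, v in (config or {}).items():
        if k not in DEFAULT_CONFIG:
            raise ValueError(f"unknown pipeline config key {k!r}")
        if isinstance(v, dict):
            out[k].update(v)
        else:
            out[k] = v
    return out


def _build_sim_config(cfg: dict, duration: float, seed: int) -> SimConfig:
    known = {f.name for f in dataclasses.fields(SimConfig)}
    bad = set(cfg) - known
    if bad:
        raise ValueError(f"unknown sim config keys: {sorted(bad)}")
    merged = dict(duration=duration, seed=seed)
    merged.update(cfg)
    sim = SimConfig(**merged)
    sim.validate()
    return sim


def run_pipeline(config: dict, outdir: str | Path) -> pio.RunManifest:
    """Execute all stages of a synthetic run and write a manifest.

    Returns the manifest; raises :class:`StageError` naming the first
    failing stage.  Outputs: ``recording.csv``, ``schedule.json``,
    ``ground_truth.json``, ``dff.csv``, ``responses.csv``,
    ``analysis.json``, ``manifest.json`` (each CSV with its sidecar).
    """
    cfg = _merged_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest = pio.RunManifest(config=cfg, seed=seed)

    # -- simulate ------------------------------------------------------
    try:
        pcfg = dict(cfg["protocol"])
        name = pcfg.pop("name")
        spec = ProtocolSpec(name=name, **pcfg)
        schedule = build_protocol(spec, seed=seed)
        sim = _build_sim_config(cfg["sim"], duration=schedule.duration, seed=seed)
        if cfg["treatment"]:
            rec, truth = simulate_dreadd_session(sim, cfg["treatment"], schedule)
        else:
            rec, truth = simulate_recording(sim, schedule)
        manifest.record_output(pio.write_recording(rec, outdir / "recording.csv"))
        manifest.record_output(pio.write_schedule(schedule, outdir / "schedule.json"))
        manifest.record_output(pio.write_ground_truth(truth, outdir / "ground_truth.json"))
        manifest.stages.append("simulate")
        log.info("simulate: %d samples, %d events", rec.n_samples, len(schedule))
    except Exception as e:
        raise StageError("simulate", e) from e

    # -- preprocess ----------------------------------------------------
    try:
        method = cfg["preprocess"]["method"]
        if method == "isosbestic":
            trace = compute_dff(rec)
        elif method == "zscore":
            baseline = cfg["preprocess"].get("baseline")
            if baseline is None:
                inj = schedule.times("injection")
                if len(inj) == 0:
                    raise ValueError(
                        "zscore preprocessing needs an explicit baseline window "
                        "or an injection event to anchor the default 5 min window"
                    )
                baseline = [float(inj[0]) - 300.0, float(inj[0])]
            trace = compute_baseline_zscore_dff(rec, tuple(baseline))
        else:
            raise ValueError(f"unknown preprocess method {method!r}")
        manifest.record_output(pio.write_dff(trace, outdir / "dff.csv"))
        manifest.stages.append("preprocess")
        log.info("preprocess: method=%s", trace.method)
    except StageError:
        raise
    except Exception as e:
        raise StageError("preprocess", e) from e

    # -- extract -------------------------------------------------------
    try:
        ex = cfg["extract"]
        table, tensors = event_response_table(
            trace, schedule, rec=rec, events=tuple(ex["events"]),
            window=tuple(ex["window"]),
            baseline_window=(tuple(ex["baseline_window"])
                             if ex.get("baseline_window") else None),
            width=float(ex["width"]), z_thresh=float(ex["z_thresh"]),
        )
        manifest.record_output(pio.write_response_table(table, outdir / "responses.csv"))
        n_in = sum(t.n_trials for t in tensors.values())
        n_exc = sum(int(t.excluded.sum()) for t in tensors.values())
        manifest.exclusions = {
            "trials_in": n_in, "trials_excluded": n_exc,
            "reasons": {lbl: [r for r in t.exclusion_reasons if r]
                        for lbl, t in tensors.items()},
        }
        manifest.stages.append("extract")
        log.info("extract: %d trials in, %d excluded, %d analyzed",
                 n_in, n_exc, n_in - n_exc)
    except StageError:
        raise
    except Exception as e:
        raise StageError("extract", e) from e

    # -- analyze -------------------------------------------------------
    try:
        analysis: dict[str, Any] = {"events": {}}
        for event in table["event"].unique():
            sub = table[table["event"] == event]
            pre = sub[sub["phase"] == "pre"].set_index("trial")["peak_dff"]
            post = sub[sub["phase"] == "post"].set_index("trial")["peak_dff"]
            joined = pd.concat([pre, post], axis=1, join="inner")
            entry: dict[str, Any] = {"n_trials": int(len(joined))}
            if len(joined) >= 2 and joined.iloc[:, 1].sub(joined.iloc[:, 0]).std() > 0:
                t = paired_t(joined.iloc[:, 0].to_numpy(), joined.iloc[:, 1].to_numpy())
                entry.update(t=t.t, df=t.df, p=t.p)
            analysis["events"][str(event)] = entry
        dose = dose_response_summary(table, subject="subject_id")
        analysis["dose_response"] = dose.to_dict("records")
        out = outdir / "analysis.json"
        out.write_text(json.dumps(analysis, indent=2, default=float))
        manifest.record_output(out)
        manifest.stages.append("analyze")
        log.info("analyze: %d events", len(analysis["events"]))
    except StageError:
        raise
    except Exception as e:
        raise StageError("analyze", e) from e

    manifest.write(outdir / "manifest.json")
    return manifest
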