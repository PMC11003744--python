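"""Peri-event trace figures and peak-response tables.

Styling is deliberately plain; figures show the across-trial (or
across-subject) mean with a +/- SEM band around each alignment event,
with the event onset marked — the standard way photometry responses are
reported.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .trials import TrialTensor

__all__ = ["plot_event_traces", "plot_dose_response", "write_report"]


def plot_event_traces(tensors: Mapping[str, TrialTensor],
                      ax_title: Optional[str] = None):
    """One panel per alignment event: mean +/- SEM across retained trials."""
    n = len(tensors)
    fig, axes = plt.subplots(1, n, figsize=(4 * n, 3), squeeze=False, sharey=True)
    for ax, (label, tensor) in zip(axes[0], tensors.items()):
        rows = tensor.data[tensor.retained]
        mean = rows.mean(axis=0)
        sem = (rows.std(axis=0, ddof=1) / np.sqrt(rows.shape[0])
               if rows.shape[0] > 1 else np.zeros_like(mean))
        ax.plot(tensor.rel_time, mean, lw=1.2)
        ax.fill_between(tensor.rel_time, mean - sem, mean + sem, alpha=0.3)
        ax.axvline(0.0, ls="--", c="k", lw=0.8)
        ax.set_xlabel(f"time from {label} (s)")
        ax.set_title(f"{label} (n={rows.shape[0]} trials)")
    axes[0][0].set_ylabel(f"dF/F ({next(iter(tensors.values())).units})")
    if ax_title:
        fig.suptitle(ax_title)
    fig.tight_layout()
    return fig


def plot_dose_response(summary: pd.DataFrame, xlabel: str = "intensity"):
    """Mean +/- SEM peak response against stimulus intensity."""
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.errorbar(summary.iloc[:, 0], summary["mean"], yerr=summary["sem"],
                marker="o", capsize=3)
    ax.set_xlabel(xlabel)
    ax.set_ylabel("peak dF/F")
    fig.tight_layout()
    return fig


def write_report(tensors: Mapping[str, TrialTensor], responses: pd.DataFrame,
                 outdir: str | Path) -> list[Path]:
    """Render trace plots and a peak table into ``outdir``; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    fig = plot_event_traces(tensors)
    p = outdir / "event_traces.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)
    peaks = (responses[responses["phase"] == "post"]
             .groupby(["event"], observed=True)["peak_dff"]
             .agg(["mean", "sem", "count"]).reset_index())
    p = outdir / "peak_table.csv"
    peaks.to_csv(p, index=False)
    written.append(p)
    return written
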