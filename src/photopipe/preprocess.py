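"""Normalization of raw two-channel recordings to dF/F traces.

Two methods, matching the two regimes in which photometry sessions are
analyzed:

* **Isosbestic regression** — an ordinary-least-squares fit predicts the
  465 nm signal channel from the 405 nm isosbestic channel over the whole
  recording; dF/F = 100 x (F465 - pred) / pred.  Because the isosbestic
  channel shares motion and (proportional) bleaching with the signal
  channel but carries no sensor response, this removes common-mode
  artifacts while preserving event transients.
* **Baseline z-scoring** — for hour-long pharmacology sessions where the
  two channels bleach at different rates and the regression is no longer
  trustworthy, the 465 channel alone is z-scored against a baseline
  window (default: the 5 min before the injection).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .recording import DffTrace, PhotometryRecording

__all__ = [
    "IsosbesticModel",
    "IsosbesticResult",
    "fit_isosbestic",
    "compute_dff",
    "compute_baseline_zscore_dff",
    "bin_timecourse",
    "SingularFitError",
    "PredictionFloorError",
]


class SingularFitError(ValueError):
    """The isosbestic regressor is constant; the OLS fit is singular."""


class PredictionFloorError(ValueError):
    """Predicted 465 values pass below the division-safety floor."""


class IsosbesticModel:
    """OLS model predicting the 465 nm channel from the 405 nm channel.

    Usage follows the model/results convention::

        res = IsosbesticModel(rec).fit()
        trace = res.dff_trace()

    The fit is taken over the entire recording, so a single (slope,
    intercept) pair describes the session; artifact-trial screening
    downstream relies on this whole-session prediction.
    """

    def __init__(self, rec: PhotometryRecording):
        if rec.n_samples < 3:
            raise ValueError("need at least 3 samples to fit the isosbestic regression")
        self.rec = rec

    def fit(self) -> "IsosbesticResult":
        x, y = self.rec.f405, self.rec.f465
        sx = float(np.ptp(x))
        if sx == 0.0:
            raise SingularFitError(
                "405 nm channel is constant; cannot regress 465 on 405"
            )
        # normal equations in centered form for numerical stability
        xm, ym = x.mean(), y.mean()
        xc = x - xm
        slope = float(np.dot(xc, y - ym) / np.dot(xc, xc))
        intercept = float(ym - slope * xm)
        return IsosbesticResult(model=self, slope=slope, intercept=intercept)


@dataclass
class IsosbesticResult:
    """Fitted isosbestic regression with dF/F construction and diagnostics."""

    model: IsosbesticModel
    slope: float
    intercept: float

    @property
    def predicted(self) -> np.ndarray:
        return self.slope * self.model.rec.f405 + self.intercept

    @property
    def resid(self) -> np.ndarray:
        return self.model.rec.f465 - self.predicted

    @property
    def rsquared(self) -> float:
        y = self.model.rec.f465
        sst = float(np.sum((y - y.mean()) ** 2))
        return 1.0 - float(np.sum(self.resid**2)) / sst if sst > 0 else np.nan

    def dff_trace(self, pred_floor_frac: float = 0.01) -> DffTrace:
        """dF/F(t) = 100 x (F465 - pred) / pred, in percent.

        ``pred_floor_frac`` guards the division: if |pred| drops below
        that fraction of its session mean at any sample, the computation
        refuses rather than silently blowing up on a bleached tail.
        """
        rec = self.model.rec
        pred = self.predicted
        floor = pred_floor_frac * abs(float(pred.mean()))
        low = np.abs(pred) < floor
        if low.any():
            i = int(np.argmax(low))
            raise PredictionFloorError(
                f"|predicted 465| falls below the safety floor ({floor:.4g}) "
                f"first at t = {rec.time[i]:.3f} s"
            )
        dff = 100.0 * (rec.f465 - pred) / pred
        return DffTrace(time=rec.time, dff=dff, method="isosbestic_regression",
                        rate=rec.rate, fit=(self.slope, self.intercept),
                        subject_id=rec.subject_id, session_id=rec.session_id)

    def summary(self) -> str:
        rec = self.model.rec
        lines = [
            "Isosbestic regression (OLS: F465 ~ F405)",
            f"  subject/session : {rec.subject_id}/{rec.session_id}",
            f"  n samples       : {rec.n_samples} at {rec.rate:g} Hz",
            f"  slope           : {self.slope:.6g}",
            f"  intercept       : {self.intercept:.6g}",
            f"  R^2             : {self.rsquared:.4f}",
        ]
        return "\n".join(lines)


def fit_isosbestic(rec: PhotometryRecording) -> tuple[float, float]:
    """Whole-recording OLS coefficients (slope, intercept) of F465 ~ F405."""
    res = IsosbesticModel(rec).fit()
    return res.slope, res.intercept


def compute_dff(rec: PhotometryRecording, pred_floor_frac: float = 0.01) -> DffTrace:
    """Isosbestic-regression dF/F of a recording, in percent."""
    return IsosbesticModel(rec).fit().dff_trace(pred_floor_frac=pred_floor_frac)


def compute_baseline_zscore_dff(rec: PhotometryRecording,
                                baseline_window: tuple[float, float],
                                min_baseline_s: float = 10.0) -> DffTrace:
    """Z-score the 465 channel against a baseline window; 405 is ignored.

    dff(t) = (F465(t) - mean_baseline) / sd_baseline.  The baseline window
    is half-open [start, end) in session seconds and must lie inside the
    recording and span at least ``min_baseline_s``.
    """
    start, end = float(baseline_window[0]), float(baseline_window[1])
    if end - start < min_baseline_s:
        raise ValueError(
            f"baseline window [{start}, {end}) shorter than {min_baseline_s} s"
        )
    if start < rec.time[0] or end > rec.time[-1] + 1.0 / rec.rate:
        raise ValueError(
            f"baseline window [{start}, {end}) outside recording "
            f"[{rec.time[0]}, {rec.duration})"
        )
    m = (rec.time >= start) & (rec.time < end)
    base = rec.f465[m]
    mu = float(base.mean())
    sd = float(base.std(ddof=0))
    if sd == 0.0:
        raise ValueError("baseline SD is zero; cannot z-score a constant channel")
    dff = (rec.f465 - mu) / sd
    return DffTrace(time=rec.time, dff=dff, method="baseline_zscore",
                    rate=rec.rate, baseline_window=(start, end),
                    subject_id=rec.subject_id, session_id=rec.session_id)


def bin_timecourse(trace: DffTrace, bin_width: float,
                   start: Optional[float] = None,
                   end: Optional[float] = None) -> pd.DataFrame:
    """Mean dF/F in consecutive non-overlapping half-open time bins.

    Returns a frame with columns ``bin_start_s``, ``dff_mean``, ``n``; a
    final partial bin is dropped and recorded in ``frame.attrs``.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    t0 = float(trace.time[0]) if start is None else float(start)
    t1 = float(trace.time[-1] + 1.0 / trace.rate) if end is None else float(end)
    n_bins = int(np.floor((t1 - t0) / bin_width + 1e-9))
    rows = []
    for k in range(n_bins):
        a, b = t0 + k * bin_width, t0 + (k + 1) * bin_width
        m = (trace.time >= a) & (trace.time < b)
        rows.append(dict(bin_start_s=a, dff_mean=float(trace.dff[m].mean()),
                         n=int(m.sum())))
    out = pd.DataFrame(rows, columns=["bin_start_s", "dff_mean", "n"])
    out.attrs["dropped_partial_s"] = float((t1 - t0) - n_bins * bin_width)
    out.attrs["units"] = trace.units
    return out
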