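"""Core data containers for two-channel fiber-photometry sessions.

A recording holds the demodulated 465 nm (signal) and 405 nm (isosbestic)
channels on one uniform time base.  An event schedule holds the labeled,
timed events (tone onset/offset, shock, injection, session markers) that
define a behavioral protocol.  A ``DffTrace`` is the normalized output of
preprocessing, tagged with the method that produced it so that percent
dF/F and baseline z-units are never mixed downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "PhotometryRecording",
    "EventSchedule",
    "DffTrace",
    "TIME_UNIFORMITY_TOL",
]

#: maximum absolute deviation (s) of any time step from the median step
TIME_UNIFORMITY_TOL = 1e-6

EVENT_COLUMNS = ["label", "time_s", "trial", "intensity", "signaled"]


class NonUniformTimeError(ValueError):
    """Raised when a recording's time base is not uniformly sampled."""


@dataclass
class PhotometryRecording:
    """Paired 465/405 traces on a shared, uniformly sampled time base.

    Parameters
    ----------
    time : array of float
        Sample times in seconds, strictly increasing and uniform.
    f465, f405 : array of float
        Fluorescence of the signal (465 nm) and isosbestic (405 nm)
        channels, in arbitrary units, one value per time sample.
    rate : float
        Nominal sampling rate in samples/second (120 Hz for the
        demodulated photometry stream this package models).
    subject_id, session_id : str
        Provenance identifiers carried through the pipeline.
    """

    time: np.ndarray
    f465: np.ndarray
    f405: np.ndarray
    rate: float
    subject_id: str = "subject"
    session_id: str = "session"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.f465 = np.asarray(self.f465, dtype=float)
        self.f405 = np.asarray(self.f405, dtype=float)
        if not (len(self.time) == len(self.f465) == len(self.f405)):
            raise ValueError(
                "time, f465 and f405 must have equal length; got "
                f"{len(self.time)}, {len(self.f465)}, {len(self.f405)}"
            )
        if len(self.time) >= 2:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                i = int(np.argmax(dt <= 0))
                raise NonUniformTimeError(
                    f"time must be strictly increasing; violation at sample {i + 1}"
                )
            med = float(np.median(dt))
            dev = float(np.max(np.abs(dt - med)))
            if dev > TIME_UNIFORMITY_TOL:
                raise NonUniformTimeError(
                    f"time base not uniform: max step deviation {dev:.3g} s "
                    f"exceeds {TIME_UNIFORMITY_TOL:g} s"
                )
            if abs(self.rate * med - 1.0) > 1e-3:
                raise ValueError(
                    f"rate {self.rate} samples/s does not match median time step "
                    f"{med:.6g} s within 0.1%"
                )

    @property
    def n_samples(self) -> int:
        return len(self.time)

    @property
    def duration(self) -> float:
        """Session span in seconds (one sample period past the last sample)."""
        return float(self.n_samples / self.rate)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.time, "f465": self.f465, "f405": self.f405}
        )


@dataclass
class EventSchedule:
    """Labeled, timed events defining a session's protocol.

    ``events`` is a long-format table with columns
    ``label, time_s, trial, intensity, signaled``.  ``trial`` is -1 for
    session-level markers (``session_start``/``session_end``), and
    ``intensity`` is NaN where a stimulus has no graded intensity.
    """

    events: pd.DataFrame
    duration: float
    protocol: str = ""

    def __post_init__(self) -> None:
        ev = pd.DataFrame(self.events).copy()
        for col in EVENT_COLUMNS:
            if col not in ev.columns:
                ev[col] = (
                    np.nan if col == "intensity" else (-1 if col == "trial" else False)
                )
        ev = ev[EVENT_COLUMNS].reset_index(drop=True)
        ev["time_s"] = ev["time_s"].astype(float)
        ev["trial"] = ev["trial"].astype(int)
        if (ev["time_s"] < 0).any() or (ev["time_s"] > self.duration).any():
            bad = ev.loc[(ev["time_s"] < 0) | (ev["time_s"] > self.duration)]
            raise ValueError(
                f"event times outside [0, {self.duration}]: "
                f"{bad[['label', 'time_s']].to_dict('records')}"
            )
        if not ev["time_s"].is_monotonic_increasing:
            raise ValueError("event times must be non-decreasing")
        self.events = ev

    def times(self, label: str) -> np.ndarray:
        """Times (s) of all events carrying ``label``, in session order."""
        return self.events.loc[self.events["label"] == label, "time_s"].to_numpy()

    def subset(self, label: str) -> pd.DataFrame:
        return self.events.loc[self.events["label"] == label].reset_index(drop=True)

    @property
    def labels(self) -> list[str]:
        return list(dict.fromkeys(self.events["label"]))

    def __len__(self) -> int:
        return len(self.events)


@dataclass
class DffTrace:
    """Normalized fluorescence trace.

    ``dff`` is in percent when ``method == "isosbestic_regression"``
    (the 100 x (F465 - pred)/pred convention) and in baseline z-units
    when ``method == "baseline_zscore"``.  The two are deliberately kept
    apart by the method tag and must not be pooled in one analysis.
    """

    time: np.ndarray
    dff: np.ndarray
    method: str
    rate: float
    fit: Optional[tuple[float, float]] = None  # (slope, intercept)
    baseline_window: Optional[tuple[float, float]] = None
    subject_id: str = "subject"
    session_id: str = "session"

    VALID_METHODS = ("isosbestic_regression", "baseline_zscore")

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.dff = np.asarray(self.dff, dtype=float)
        if self.method not in self.VALID_METHODS:
            raise ValueError(
                f"method must be one of {self.VALID_METHODS}, got {self.method!r}"
            )
        if len(self.time) != len(self.dff):
            raise ValueError("time and dff must have equal length")
        if self.method == "isosbestic_regression" and self.fit is None:
            raise ValueError("isosbestic_regression traces must carry fit coefficients")
        if self.method == "baseline_zscore" and self.baseline_window is None:
            raise ValueError("baseline_zscore traces must carry their baseline window")

    @property
    def units(self) -> str:
        return "%dF/F" if self.method == "isosbestic_regression" else "z"

    def crop(self, start: float, end: float) -> "DffTrace":
        """Half-open time crop [start, end)."""
        m = (self.time >= start) & (self.time < end)
        return replace(self, time=self.time[m], dff=self.dff[m])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_s": self.time, "dff": self.dff})
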