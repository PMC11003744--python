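"""Event-aligned trial segmentation, artifact exclusion, and peak responses.

The session-level dF/F trace is cut into per-trial, event-aligned rows on
a common sample grid, each row re-baselined by subtracting its own
pre-event mean (20 s pre-tone for conditioning sessions, 2 s pre-event for
stimulus-curve sessions).  Trials containing large *simultaneous*
deflections in both raw channels — motion artifacts rather than sensor
signal — are excluded by a robust (median/MAD) z-score rule.  The scalar
statistic carried into statistics is the peak dF/F in the first 2 s of
each stimulus period, paired with the peak in the 2 s before the event.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .recording import DffTrace, EventSchedule, PhotometryRecording

__all__ = [
    "TrialTensor",
    "segment_trials",
    "detect_artifact_trials",
    "peak_response",
    "pre_event_peaks",
    "event_response_table",
    "phase_freezing_scores",
    "default_baseline_window",
    "RESPONSE_COLUMNS",
]

RESPONSE_COLUMNS = ["subject_id", "session_id", "trial", "event", "phase",
                    "peak_dff", "intensity", "signaled", "units"]

#: per-trial baseline convention by protocol: conditioning-style sessions
#: use the 20 s preceding tone delivery, stimulus-curve sessions the 2 s
#: preceding the event.
_BASELINE_BY_PROTOCOL = {
    "tfc_train": (-20.0, 0.0),
    "tone_test": (-20.0, 0.0),
    "extinction": (-20.0, 0.0),
    "signaled_unsignaled": (-20.0, 0.0),
    "shock_curve": (-2.0, 0.0),
    "tone_curve": (-2.0, 0.0),
}


def default_baseline_window(protocol: str) -> tuple[float, float]:
    return _BASELINE_BY_PROTOCOL.get(protocol, (-2.0, 0.0))


@dataclass
class TrialTensor:
    """Per-trial, event-aligned dF/F segments with exclusion bookkeeping.

    ``data`` holds the baseline-normalized rows, ``raw`` the rows before
    per-trial mean subtraction (for round-trip checks); ``rel_time`` is the
    shared within-trial grid relative to the alignment event.  ``excluded``
    plus ``exclusion_reasons`` make dropped trials explicit — excluded rows
    never reach averages or statistics downstream.
    """

    data: np.ndarray
    raw: np.ndarray
    rel_time: np.ndarray
    align_label: str
    window: tuple[float, float]
    baseline_window: tuple[float, float]
    meta: pd.DataFrame  # trial, time_s (aligned event time), intensity, signaled
    excluded: np.ndarray
    exclusion_reasons: list[Optional[str]]
    units: str
    subject_id: str = "subject"
    session_id: str = "session"

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def retained(self) -> np.ndarray:
        return ~self.excluded

    def exclude(self, index: int, reason: str) -> None:
        self.excluded[index] = True
        self.exclusion_reasons[index] = reason

    def mean_trace(self) -> np.ndarray:
        """Across-trial mean of the retained, normalized rows."""
        if not self.retained.any():
            raise ValueError("no retained trials")
        return self.data[self.retained].mean(axis=0)

    def sample_window(self, rel_start: float, rel_end: float) -> slice:
        """Half-open column slice [rel_start, rel_end) on the trial grid."""
        dt = float(self.rel_time[1] - self.rel_time[0])
        pre = self.window[0]
        i0 = int(round((rel_start + pre) / dt))
        i1 = int(round((rel_end + pre) / dt))
        if i0 < 0 or i1 > len(self.rel_time) or i1 <= i0:
            raise ValueError(
                f"window [{rel_start}, {rel_end}) s outside trial span "
                f"[{-pre}, {self.window[1]}) s"
            )
        return slice(i0, i1)


def _snap_index(t: float, rate: float) -> int:
    """Index of the nearest sample at or after nominal time ``t``."""
    return int(np.ceil(t * rate - 1e-9))


def segment_trials(trace: DffTrace, schedule: EventSchedule, align_on: str,
                   window: tuple[float, float],
                   baseline_window: Optional[tuple[float, float]] = None,
                   ) -> TrialTensor:
    """Cut the trace into rows aligned on every ``align_on`` event.

    ``window`` is (pre, post) in seconds; each row covers the half-open
    sample window [t_event - pre, t_event + post).  Each row is normalized
    by subtracting its mean over ``baseline_window`` (seconds relative to
    the event; defaults to the protocol's convention, or the full pre
    period).  Events whose window leaves the recording are kept but
    flagged excluded with reason ``window_out_of_bounds``.
    """
    events = schedule.subset(align_on)
    if len(events) == 0:
        raise ValueError(f"no events labeled {align_on!r} in schedule")
    pre, post = float(window[0]), float(window[1])
    if pre < 0 or post <= 0:
        raise ValueError("window must be (pre >= 0, post > 0) seconds")
    if baseline_window is None:
        baseline_window = default_baseline_window(schedule.protocol)
        baseline_window = (max(baseline_window[0], -pre), baseline_window[1])
    b0, b1 = float(baseline_window[0]), float(baseline_window[1])
    if b0 < -pre or b1 > post:
        raise ValueError(
            f"baseline window [{b0}, {b1}) not covered by trial window "
            f"[-{pre}, {post})"
        )

    rate = trace.rate
    n_pre = int(round(pre * rate))
    n_row = int(round((pre + post) * rate))
    rel_time = (np.arange(n_row) - n_pre) / rate

    rows_raw, meta_rows, excluded, reasons = [], [], [], []
    for _, e in events.iterrows():
        i_ev = _snap_index(float(e["time_s"]), rate)
        i0, i1 = i_ev - n_pre, i_ev - n_pre + n_row
        if i0 < 0 or i1 > len(trace.dff):
            rows_raw.append(np.full(n_row, np.nan))
            excluded.append(True)
            reasons.append("window_out_of_bounds")
        else:
            rows_raw.append(trace.dff[i0:i1].copy())
            excluded.append(False)
            reasons.append(None)
        meta_rows.append(dict(trial=int(e["trial"]), time_s=float(e["time_s"]),
                              intensity=float(e["intensity"]),
                              signaled=bool(e["signaled"])))

    raw = np.asarray(rows_raw)
    bsel = (rel_time >= b0) & (rel_time < b1)
    if not bsel.any():
        raise ValueError("baseline window contains no samples")
    # out-of-bounds rows are all-NaN; skip them when taking baseline means
    ok = ~np.asarray(excluded)
    bmeans = np.zeros((raw.shape[0], 1))
    if ok.any():
        bmeans[ok, 0] = raw[np.ix_(ok, bsel)].mean(axis=1)
    data = raw - bmeans
    return TrialTensor(
        data=data, raw=raw, rel_time=rel_time, align_label=align_on,
        window=(pre, post), baseline_window=(b0, b1),
        meta=pd.DataFrame(meta_rows), excluded=np.asarray(excluded, dtype=bool),
        exclusion_reasons=reasons, units=trace.units,
        subject_id=trace.subject_id, session_id=trace.session_id,
    )


def robust_z(x: np.ndarray) -> np.ndarray:
    """(x - median) / (1.4826 * MAD): robust z-scores over a session."""
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0.0:
        mad = np.finfo(float).tiny
    return (x - med) / (1.4826 * mad)


def detect_artifact_trials(rec: PhotometryRecording, tensor: TrialTensor,
                           z_thresh: float = 8.0) -> np.ndarray:
    """Flag trials containing large simultaneous deflections in both channels.

    Robust z-scores (median/MAD over the whole session) are computed per
    raw channel; a trial is excluded iff some sample inside its window has
    |z465| and |z405| both above ``z_thresh`` with matching sign — the
    signature of a motion artifact, which a genuine 465-only sensor
    transient cannot produce.  The tensor's mask is updated in place with
    reason ``simultaneous_deflection@t=...`` and also returned.
    """
    z465 = robust_z(rec.f465)
    z405 = robust_z(rec.f405)
    joint = ((np.abs(z465) > z_thresh) & (np.abs(z405) > z_thresh)
             & (np.sign(z465) == np.sign(z405)))
    rate = rec.rate
    n_pre = int(round(tensor.window[0] * rate))
    n_row = len(tensor.rel_time)
    for i, (_, e) in enumerate(tensor.meta.iterrows()):
        if tensor.excluded[i]:
            continue
        i0 = _snap_index(float(e["time_s"]), rate) - n_pre
        i1 = i0 + n_row
        sel = joint[max(i0, 0):min(i1, len(joint))]
        if sel.any():
            t_hit = rec.time[max(i0, 0) + int(np.argmax(sel))]
            tensor.exclude(i, f"simultaneous_deflection@t={t_hit:.3f}s")
    return tensor.excluded.copy()


def _peaks_frame(tensor: TrialTensor, sl: slice, phase: str,
                 event: Optional[str]) -> pd.DataFrame:
    rows = []
    for i in range(tensor.n_trials):
        if tensor.excluded[i]:
            continue
        rows.append(dict(
            subject_id=tensor.subject_id, session_id=tensor.session_id,
            trial=int(tensor.meta["trial"].iloc[i]),
            event=event or tensor.align_label, phase=phase,
            peak_dff=float(np.max(tensor.data[i, sl])),
            intensity=float(tensor.meta["intensity"].iloc[i]),
            signaled=bool(tensor.meta["signaled"].iloc[i]),
            units=tensor.units,
        ))
    return pd.DataFrame(rows, columns=RESPONSE_COLUMNS)


def peak_response(tensor: TrialTensor, event_offset: float = 0.0,
                  width: float = 2.0,
                  event: Optional[str] = None) -> pd.DataFrame:
    """Peak (signed maximum) dF/F in [offset, offset + width) s post-event.

    One long-format row per retained trial, phase ``post``.  The default
    window is the first 2 s of the stimulus period.
    """
    sl = tensor.sample_window(event_offset, event_offset + width)
    return _peaks_frame(tensor, sl, "post", event)


def pre_event_peaks(tensor: TrialTensor, width: float = 2.0,
                    event: Optional[str] = None) -> pd.DataFrame:
    """Peak dF/F in the [-width, 0) s window before the event (phase ``pre``)."""
    if width > tensor.window[0] + 1e-9:
        raise ValueError(
            f"pre window of {width} s exceeds the {tensor.window[0]} s of "
            "pre-event samples in the tensor"
        )
    sl = tensor.sample_window(-width, 0.0)
    return _peaks_frame(tensor, sl, "pre", event)


def event_response_table(trace: DffTrace, schedule: EventSchedule,
                         rec: Optional[PhotometryRecording] = None,
                         events: Sequence[str] = ("tone_on", "tone_off", "shock_on"),
                         window: tuple[float, float] = (20.0, 5.0),
                         baseline_window: Optional[tuple[float, float]] = None,
                         width: float = 2.0, z_thresh: float = 8.0,
                         ) -> tuple[pd.DataFrame, dict[str, TrialTensor]]:
    """Pre/post peak table across several alignment events of one session.

    Convenience wrapper used by the pipeline: segments once per event
    label present in the schedule, runs artifact exclusion when the raw
    recording is supplied, and stacks pre- and post-event peaks into one
    long-format response table.
    """
    frames, tensors = [], {}
    for label in events:
        if len(schedule.subset(label)) == 0:
            continue
        tensor = segment_trials(trace, schedule, label, window, baseline_window)
        if rec is not None:
            detect_artifact_trials(rec, tensor, z_thresh=z_thresh)
        tensors[label] = tensor
        frames.append(peak_response(tensor, width=width))
        frames.append(pre_event_peaks(tensor, width=width))
    if not frames:
        raise ValueError(f"none of the labels {tuple(events)} occur in the schedule")
    return pd.concat(frames, ignore_index=True), tensors


def phase_freezing_scores(freezing: pd.DataFrame,
                          phases: Sequence[str] = ("baseline", "tone", "trace"),
                          ) -> pd.DataFrame:
    """Per-subject phase means of pre-scored percent freezing.

    ``freezing`` is long-format with columns (subject, trial, phase,
    percent_freezing).  Freezing is scored upstream (video-based); here it
    is only averaged across trials within each phase type for each animal.
    Raises if any subject is missing one of the requested phases.
    """
    required = {"subject", "trial", "phase", "percent_freezing"}
    missing_cols = required - set(freezing.columns)
    if missing_cols:
        raise ValueError(f"freezing table missing columns {sorted(missing_cols)}")
    sub = freezing[freezing["phase"].isin(phases)]
    got = sub.groupby("subject")["phase"].agg(lambda s: set(s))
    incomplete = [s for s, ph in got.items() if not set(phases) <= ph]
    if incomplete:
        raise ValueError(f"subjects missing phases: {incomplete}")
    out = (sub.groupby(["subject", "phase"], observed=True)["percent_freezing"]
           .mean().rename("mean_freezing").reset_index())
    order = pd.CategoricalDtype(list(phases), ordered=True)
    out["phase"] = out["phase"].astype(order)
    return out.sort_values(["subject", "phase"]).reset_index(drop=True)
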