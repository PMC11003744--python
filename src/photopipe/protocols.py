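"""Behavioral protocol definitions and event-schedule construction.

The protocols model standard trace-fear-conditioning (TFC) session designs:
a tone conditional stimulus (CS) and a foot-shock unconditional stimulus
(US) separated by a stimulus-free trace interval, plus the stimulus-response
curve, extinction, signaled/unsignaled and chemogenetic (DREADD) session
layouts used alongside it.  ``build_protocol`` turns a validated
``ProtocolSpec`` into a concrete :class:`~photopipe.recording.EventSchedule`
with labeled, strictly ordered event times.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .recording import EventSchedule

__all__ = ["ProtocolSpec", "build_protocol", "ProtocolTimingError", "PROTOCOL_NAMES"]

PROTOCOL_NAMES = (
    "tfc_train",
    "tone_test",
    "extinction",
    "shock_curve",
    "tone_curve",
    "signaled_unsignaled",
    "dreadd_session",
)

SHOCK_CURVE_INTENSITIES = (0.0, 0.05, 0.1, 0.2, 0.4, 0.6, 0.8)  # mA
TONE_CURVE_INTENSITIES = (55.0, 65.0, 75.0, 85.0, 95.0)  # dB


class ProtocolTimingError(ValueError):
    """Events overflow the session duration; carries the offending trial."""

    def __init__(self, message: str, trial: int):
        super().__init__(message)
        self.trial = trial


@dataclass
class ProtocolSpec:
    """Timing parameterization of one behavioral session.

    Defaults mirror the photometry variants of each design: 10-trial TFC
    training with a 20 s tone, 20 s trace and 2 s shock; a 10-tone test at
    140 s inter-trial interval (ITI); 20-tone extinction at 90 s ITI; a
    3-block x 7-intensity shock response curve; a 25-tone loudness curve;
    10 half-signaled conditioning trials; and a 60 min DREADD session with
    the injection at the end of a 10 min baseline.
    """

    name: str
    n_trials: int = 10
    pre_exposure_s: float = 180.0
    post_s: float = 180.0
    tone_s: float = 20.0
    trace_s: float = 20.0
    shock_s: float = 2.0
    iti_s: float | Sequence[float] = 120.0
    tone_db: float = 85.0
    shock_ma: float = 0.2
    intensities: Optional[Sequence[float]] = None
    n_blocks: int = 1
    inter_block_s: float = 180.0
    injection_time_s: float = 600.0
    duration_s: Optional[float] = None  # dreadd only; else derived
    max_duration_s: Optional[float] = None

    # ---- canonical constructors -------------------------------------

    @classmethod
    def tfc_train(cls, n_trials: int = 10, iti_s: float | Sequence[float] = 120.0,
                  shock_ma: float = 0.2, **kw) -> "ProtocolSpec":
        return cls(name="tfc_train", n_trials=n_trials, iti_s=iti_s,
                   shock_ma=shock_ma, **kw)

    @classmethod
    def tone_test(cls, n_trials: int = 10, iti_s: float = 140.0, **kw) -> "ProtocolSpec":
        return cls(name="tone_test", n_trials=n_trials, iti_s=iti_s, **kw)

    @classmethod
    def extinction(cls, n_trials: int = 20, iti_s: float = 90.0, **kw) -> "ProtocolSpec":
        return cls(name="extinction", n_trials=n_trials, iti_s=iti_s, **kw)

    @classmethod
    def shock_curve(cls, intensities: Sequence[float] = SHOCK_CURVE_INTENSITIES,
                    n_blocks: int = 3, iti_s: float = 30.0, shock_s: float = 1.0,
                    **kw) -> "ProtocolSpec":
        return cls(name="shock_curve", intensities=tuple(intensities),
                   n_blocks=n_blocks, iti_s=iti_s, shock_s=shock_s,
                   n_trials=n_blocks * len(tuple(intensities)), **kw)

    @classmethod
    def tone_curve(cls, intensities: Sequence[float] = TONE_CURVE_INTENSITIES,
                   n_repeats: int = 5, iti_s: float = 60.0, post_s: float = 60.0,
                   **kw) -> "ProtocolSpec":
        ints = tuple(intensities)
        return cls(name="tone_curve", intensities=ints, n_blocks=n_repeats,
                   iti_s=iti_s, post_s=post_s, n_trials=n_repeats * len(ints), **kw)

    @classmethod
    def signaled_unsignaled(cls, n_trials: int = 10, iti_s: float = 120.0,
                            **kw) -> "ProtocolSpec":
        return cls(name="signaled_unsignaled", n_trials=n_trials, iti_s=iti_s, **kw)

    @classmethod
    def dreadd_session(cls, duration_s: float = 3600.0,
                       injection_time_s: float = 600.0, **kw) -> "ProtocolSpec":
        return cls(name="dreadd_session", n_trials=0, duration_s=duration_s,
                   injection_time_s=injection_time_s, **kw)

    # ---- validation --------------------------------------------------

    def validate(self) -> None:
        if self.name not in PROTOCOL_NAMES:
            raise ValueError(f"unknown protocol {self.name!r}; choose from {PROTOCOL_NAMES}")
        for attr in ("pre_exposure_s", "post_s", "tone_s", "trace_s", "shock_s"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be >= 0")
        if self.n_trials < 0:
            raise ValueError("n_trials must be >= 0")
        for iti in np.atleast_1d(np.asarray(self.iti_s, dtype=float)):
            if iti < 0:
                raise ValueError("iti_s must be >= 0")
        if self.name == "shock_curve":
            bad = set(self.intensities or ()) - set(SHOCK_CURVE_INTENSITIES)
            if bad:
                raise ValueError(
                    f"shock_curve intensities {sorted(bad)} outside the "
                    f"calibrated set {SHOCK_CURVE_INTENSITIES}"
                )
        if self.name == "dreadd_session":
            if self.duration_s is None or self.duration_s <= self.injection_time_s:
                raise ValueError("dreadd_session needs duration_s > injection_time_s")
        if self.name == "signaled_unsignaled" and self.n_trials % 2:
            raise ValueError("signaled_unsignaled needs an even trial count")

    def iti_for_trial(self, i: int) -> float:
        itis = np.atleast_1d(np.asarray(self.iti_s, dtype=float))
        return float(itis[i % len(itis)])


# ---------------------------------------------------------------------
# pseudorandom ordering
# ---------------------------------------------------------------------

def _is_sorted_run(order: Sequence[float]) -> bool:
    a = np.asarray(order)
    return bool(np.all(np.diff(a) >= 0) or np.all(np.diff(a) <= 0))


def _pseudorandom_blocks(intensities: Sequence[float], n_blocks: int,
                         rng: np.random.Generator,
                         max_tries: int = 10_000) -> list[tuple[float, ...]]:
    """Seeded rejection sampling of per-block intensity orders.

    Constraints: no block is in ascending or descending intensity order,
    and no two blocks share the same order.
    """
    base = tuple(intensities)
    blocks: list[tuple[float, ...]] = []
    for _ in range(n_blocks):
        for _try in range(max_tries):
            perm = tuple(rng.permutation(base).tolist())
            if len(base) > 2 and _is_sorted_run(perm):
                continue
            if n_blocks > 1 and perm in blocks:
                continue
            blocks.append(perm)
            break
        else:  # pragma: no cover - astronomically unlikely for these sizes
            raise RuntimeError("could not sample a block order meeting the constraints")
    return blocks


# ---------------------------------------------------------------------
# schedule construction
# ---------------------------------------------------------------------

def _tone_trial(t: float, spec: ProtocolSpec, trial: int, with_shock: bool,
                shock_ma: Optional[float] = None,
                signaled: bool = True) -> tuple[list[dict], float]:
    """Events of one tone(-shock) trial starting at ``t``; returns end time."""
    ev = []
    if signaled:
        ev.append(dict(label="tone_on", time_s=t, trial=trial,
                       intensity=spec.tone_db, signaled=signaled))
        ev.append(dict(label="tone_off", time_s=t + spec.tone_s, trial=trial,
                       intensity=spec.tone_db, signaled=signaled))
    t_end = t + spec.tone_s + (spec.trace_s if with_shock else 0.0)
    if with_shock:
        ma = spec.shock_ma if shock_ma is None else shock_ma
        ev.append(dict(label="shock_on", time_s=t_end, trial=trial,
                       intensity=ma, signaled=signaled))
        ev.append(dict(label="shock_off", time_s=t_end + spec.shock_s, trial=trial,
                       intensity=ma, signaled=signaled))
        t_end += spec.shock_s
    return ev, t_end


def build_protocol(spec: ProtocolSpec, seed: int = 0) -> EventSchedule:
    """Construct the event schedule for one session of ``spec``.

    ``seed`` drives only the pseudorandom components (stimulus-curve block
    orders, the signaled/unsignaled assignment); fixed-timing protocols are
    unaffected by it.  Raises :class:`ProtocolTimingError` if a trial would
    overflow ``spec.max_duration_s``.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    events: list[dict] = []
    t = spec.pre_exposure_s

    if spec.name in ("tfc_train", "tone_test", "extinction"):
        with_shock = spec.name == "tfc_train"
        for i in range(spec.n_trials):
            ev, t_end = _tone_trial(t, spec, i, with_shock)
            events += ev
            t = t_end + spec.iti_for_trial(i)
        duration = (t - (spec.iti_for_trial(spec.n_trials - 1) if spec.n_trials else 0.0)
                    + spec.post_s)

    elif spec.name == "signaled_unsignaled":
        half = spec.n_trials // 2
        signaled_mask = np.zeros(spec.n_trials, dtype=bool)
        signaled_mask[rng.permutation(spec.n_trials)[:half]] = True
        for i in range(spec.n_trials):
            if signaled_mask[i]:
                ev, t_end = _tone_trial(t, spec, i, with_shock=True, signaled=True)
            else:
                # same trial length, but the 40 s of tone + trace pass in silence
                t_shock = t + spec.tone_s + spec.trace_s
                ev = [dict(label="shock_on", time_s=t_shock, trial=i,
                           intensity=spec.shock_ma, signaled=False),
                      dict(label="shock_off", time_s=t_shock + spec.shock_s, trial=i,
                           intensity=spec.shock_ma, signaled=False)]
                t_end = t_shock + spec.shock_s
            events += ev
            t = t_end + spec.iti_for_trial(i)
        duration = t - spec.iti_for_trial(spec.n_trials - 1) + spec.post_s

    elif spec.name == "shock_curve":
        blocks = _pseudorandom_blocks(spec.intensities or SHOCK_CURVE_INTENSITIES,
                                      spec.n_blocks, rng)
        trial = 0
        for b, block in enumerate(blocks):
            for j, ma in enumerate(block):
                events.append(dict(label="shock_on", time_s=t, trial=trial,
                                   intensity=ma, signaled=False))
                events.append(dict(label="shock_off", time_s=t + spec.shock_s,
                                   trial=trial, intensity=ma, signaled=False))
                t += spec.shock_s
                if j < len(block) - 1:
                    t += spec.iti_for_trial(trial)
                trial += 1
            if b < len(blocks) - 1:
                t += spec.inter_block_s
        duration = t + spec.post_s

    elif spec.name == "tone_curve":
        blocks = _pseudorandom_blocks(spec.intensities or TONE_CURVE_INTENSITIES,
                                      spec.n_blocks, rng)
        order = [db for block in blocks for db in block]
        for i, db in enumerate(order):
            events.append(dict(label="tone_on", time_s=t, trial=i,
                               intensity=db, signaled=True))
            events.append(dict(label="tone_off", time_s=t + spec.tone_s, trial=i,
                               intensity=db, signaled=True))
            t += spec.tone_s
            if i < len(order) - 1:
                t += spec.iti_for_trial(i)
        duration = t + spec.post_s

    elif spec.name == "dreadd_session":
        duration = float(spec.duration_s)
        events.append(dict(label="injection", time_s=spec.injection_time_s,
                           trial=-1, intensity=np.nan, signaled=False))

    else:  # pragma: no cover - guarded by validate()
        raise AssertionError(spec.name)

    if spec.max_duration_s is not None:
        for e in events:
            if e["time_s"] > spec.max_duration_s:
                raise ProtocolTimingError(
                    f"trial {e['trial']} event {e['label']!r} at "
                    f"{e['time_s']:.1f} s exceeds max duration "
                    f"{spec.max_duration_s:.1f} s",
                    trial=int(e["trial"]),
                )
        duration = min(duration, spec.max_duration_s)

    markers = [dict(label="session_start", time_s=0.0, trial=-1,
                    intensity=np.nan, signaled=False),
               dict(label="session_end", time_s=duration, trial=-1,
                    intensity=np.nan, signaled=False)]
    ev = pd.DataFrame(events + markers).sort_values(
        "time_s", kind="stable").reset_index(drop=True)
    return EventSchedule(events=ev, duration=duration, protocol=spec.name)
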