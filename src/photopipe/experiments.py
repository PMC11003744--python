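"""Simulation studies: detector operating point, calibration, power.

These are the package's own verification experiments, built entirely from
the synthetic generator so every answer can be checked against ground
truth: the artifact detector's sensitivity/false-exclusion operating
point, type-I error calibration of the test statistics under Gaussian
nulls at the small cohort sizes typical of photometry studies (4-11
subjects), and the power of the binned-timecourse mixed ANOVA to detect a
chemogenetic treatment x time interaction.

All randomness derives from a single integer seed via
``numpy.random.SeedSequence`` spawning, so every study is reproducible.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional

import numpy as np
import pandas as pd

from .preprocess import bin_timecourse, compute_baseline_zscore_dff
from .protocols import ProtocolSpec, build_protocol
from .recording import EventSchedule
from .simulate import DreaddParams, SimConfig, simulate_dreadd_session, simulate_recording
from .stats import mixed_anova_matrix, paired_t, rm_anova_matrix
from .trials import detect_artifact_trials, segment_trials

__all__ = [
    "artifact_detector_operating_point",
    "type_i_error_paired_t",
    "type_i_error_rm_anova",
    "type_i_error_mixed_anova",
    "dreadd_cohort_table",
    "dreadd_interaction_rejection_rate",
]


def _child_seeds(seed: int, n: int) -> list[int]:
    """n reproducible 31-bit child seeds derived from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) >> 1]


# ---------------------------------------------------------------------
# artifact detector operating point
# ---------------------------------------------------------------------

def artifact_detector_operating_point(seed: int, n_sessions: int = 100,
                                      deflection_mads: float = 10.0,
                                      z_thresh: float = 8.0,
                                      rate: float = 60.0) -> dict[str, float]:
    """Sensitivity and false-exclusion rate of the simultaneous-deflection rule.

    Each synthetic session has 8 trials on a trend-free background: two
    trials contain a shared motion bump of ``deflection_mads`` robust-SD
    units in both channels, two contain a 465-only sensor transient of the
    same magnitude (genuine signal), and four are clean.  Sensitivity is
    the exclusion rate of bump trials; the false-exclusion rate pools the
    signal-only and clean trials.
    """
    noise = 0.3
    amp = deflection_mads * noise  # robust SD of Gaussian noise ~= its SD
    hits = bumps = false = benign = 0
    for s in _child_seeds(seed, n_sessions):
        rng = np.random.default_rng(s)
        times = 20.0 + 20.0 * np.arange(8)
        order = rng.permutation(8)
        bump_trials, transient_trials = set(order[:2]), set(order[2:4])
        ev = pd.DataFrame([dict(label="tone_on", time_s=t, trial=i,
                                intensity=95.0 if i in transient_trials else 55.0)
                           for i, t in enumerate(times)])
        sched = EventSchedule(events=ev, duration=200.0, protocol="tone_curve")
        cfg = SimConfig(
            duration=200.0, rate=rate, bleach_465=(), bleach_405=(),
            motion_events=tuple((times[i] + float(rng.uniform(0.5, 8.0)), amp, 0.3)
                                for i in bump_trials),
            amplitude_map=[(55.0, 0.0), (95.0, amp)],
            noise_sd_465=noise, noise_sd_405=noise, seed=s,
        )
        rec, _ = simulate_recording(cfg, sched)
        trace_stub = compute_baseline_zscore_dff(rec, (0.0, 15.0))
        tensor = segment_trials(trace_stub, sched, "tone_on", (2.0, 10.0))
        detect_artifact_trials(rec, tensor, z_thresh=z_thresh)
        for i in range(8):
            if i in bump_trials:
                bumps += 1
                hits += bool(tensor.excluded[i])
            else:
                benign += 1
                false += bool(tensor.excluded[i])
    return dict(sensitivity=hits / bumps, false_exclusion_rate=false / benign,
                n_sessions=n_sessions)


# ---------------------------------------------------------------------
# type-I error calibration under Gaussian nulls
# ---------------------------------------------------------------------

def type_i_error_paired_t(seed: int, n_sims: int = 10_000,
                          alpha: float = 0.05) -> float:
    """Null rejection rate of the paired t-test, n drawn from 4..11."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sims):
        n = int(rng.integers(4, 12))
        res = paired_t(rng.normal(size=n), rng.normal(size=n))
        rejections += res.p < alpha
    return rejections / n_sims


def type_i_error_rm_anova(seed: int, n_sims: int = 10_000,
                          alpha: float = 0.05) -> float:
    """Null rejection rate of the one-way RM-ANOVA, 4-11 subjects, 3-7 levels."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sims):
        n = int(rng.integers(4, 12))
        k = int(rng.integers(3, 8))
        Y = rng.normal(size=(n, k)) + rng.normal(size=(n, 1))  # subject effects
        rejections += rm_anova_matrix(Y).p < alpha
    return rejections / n_sims


def type_i_error_mixed_anova(seed: int, n_sims: int = 10_000,
                             alpha: float = 0.05) -> dict[str, float]:
    """Null rejection rates (between/within/interaction) of the mixed ANOVA."""
    rng = np.random.default_rng(seed)
    rej = dict(between=0, within=0, interaction=0)
    for _ in range(n_sims):
        n1, n2 = int(rng.integers(4, 12)), int(rng.integers(4, 12))
        b = int(rng.integers(3, 6))
        Y = rng.normal(size=(n1 + n2, b)) + rng.normal(size=(n1 + n2, 1))
        groups = np.repeat([0, 1], [n1, n2])
        for eff in mixed_anova_matrix(Y, groups):
            rej[eff.effect] += eff.p < alpha
    return {k: v / n_sims for k, v in rej.items()}


# ---------------------------------------------------------------------
# chemogenetic (DREADD) timecourse power study
# ---------------------------------------------------------------------

#: hour-long session conditions: LED power is kept low in long recordings,
#: so bleaching is mild, and bin-scale variability is dominated by slow
#: physiological state fluctuations (OU process) rather than shot noise
DREADD_SESSION_CONDITIONS = dict(
    bleach_465=((0.04, 1200.0), (0.02, 180.0)),
    bleach_405=((0.03, 1500.0), (0.015, 200.0)),
    noise_slow_sd_465=3.0,
    noise_slow_sd_405=1.0,
    noise_slow_tau_s=30.0,
)

def dreadd_cohort_table(seed: int, n_per_group: int = 5, rate: float = 10.0,
                        bin_width: float = 600.0,
                        params: Optional[DreaddParams] = None,
                        disable_slow: bool = False) -> pd.DataFrame:
    """Binned post-injection timecourse for a vehicle vs CNO cohort.

    Each subject gets an independent 3600 s session (injection at 600 s),
    is z-scored against the final 5 min of baseline, and binned into
    ``bin_width`` bins from the injection to session end.  Returns a long
    table (subject_id, group, time_bin, dff_mean) ready for the mixed
    ANOVA.  ``disable_slow`` zeroes the CNO slow component, making the two
    groups generatively identical (the null).
    """
    params = params or DreaddParams()
    if disable_slow:
        params = replace(params, cno_amplitude_frac=0.0)
    schedule = build_protocol(ProtocolSpec.dreadd_session(), seed=0)
    seeds = _child_seeds(seed, 2 * n_per_group)
    rows = []
    for i, s in enumerate(seeds):
        group = "vehicle" if i < n_per_group else "cno"
        cfg = SimConfig(duration=3600.0, rate=rate, kernel=(0.5, 4.0), seed=s,
                        subject_id=f"{group}{i}", **DREADD_SESSION_CONDITIONS)
        rec, _ = simulate_dreadd_session(cfg, group, schedule, params)
        trace = compute_baseline_zscore_dff(rec, (300.0, 600.0))
        bins = bin_timecourse(trace, bin_width, start=600.0, end=3600.0)
        for _, r in bins.iterrows():
            rows.append(dict(subject_id=cfg.subject_id, group=group,
                             time_bin=float(r["bin_start_s"]),
                             dff_mean=float(r["dff_mean"])))
    return pd.DataFrame(rows)


def dreadd_interaction_rejection_rate(seed: int, n_reps: int,
                                      alpha: float = 0.05,
                                      disable_slow: bool = False,
                                      n_per_group: int = 5,
                                      rate: float = 10.0) -> float:
    """Rejection rate of the treatment x time interaction over replicate cohorts.

    With the slow CNO component at its default size this estimates power;
    with ``disable_slow`` it estimates the type-I error of the whole
    simulate -> normalize -> bin -> mixed-ANOVA chain.
    """
    rejections = 0
    for s in _child_seeds(seed, n_reps):
        table = dreadd_cohort_table(s, n_per_group=n_per_group, rate=rate,
                                    disable_slow=disable_slow)
        wide = table.pivot_table(index="subject_id", columns="time_bin",
                                 values="dff_mean")
        groups = (table.groupby("subject_id")["group"].first()
                  .loc[wide.index].to_numpy())
        inter = mixed_anova_matrix(wide.to_numpy(), groups)[2]
        rejections += inter.p < alpha
    return rejections / n_reps
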