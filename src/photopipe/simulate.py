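"""Ground-truth synthetic two-channel photometry generator.

The generative model mirrors what a fiber-photometry rig actually records
after demodulation: each channel has a slow double-exponential bleaching
trend on top of its baseline fluorescence, motion artifacts appear as
Gaussian deflections *shared* across the 465 nm and 405 nm channels (with
per-channel gains near one), and sensor transients — difference-of-
exponentials kernels with fast calcium-indicator or slow neuromodulator-
sensor time constants — appear only in the 465 nm channel, with amplitudes
set by a monotone map from stimulus intensity.  Additive Gaussian noise is
independent per channel.  Every injected transient and motion event is
returned as ground truth so the preprocessing, artifact-exclusion and
response-extraction stages can be verified against known answers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .recording import EventSchedule, PhotometryRecording

__all__ = [
    "AmplitudeMap",
    "SimConfig",
    "DreaddParams",
    "GroundTruth",
    "kernel_peak_time",
    "transient_kernel",
    "simulate_recording",
    "simulate_dreadd_session",
]

# kernel presets: (tau_rise s, tau_decay s)
GCAMP_KERNEL = (0.2, 1.5)
GRAB_KERNEL = (0.5, 4.0)

#: event labels that trigger a 465-only sensor transient by default
DEFAULT_TRANSIENT_LABELS = ("tone_on", "tone_off", "shock_on")

# default intensity -> raw-amplitude tables (fluorescence units on a
# baseline of 100), saturating with intensity as sensor responses do
DEFAULT_SHOCK_MAP = ((0.0, 0.0), (0.05, 0.6), (0.1, 1.2), (0.2, 2.5),
                     (0.4, 4.0), (0.6, 5.0), (0.8, 5.8))
DEFAULT_TONE_MAP = ((55.0, 0.6), (65.0, 1.1), (75.0, 1.8), (85.0, 2.5), (95.0, 3.1))
DEFAULT_TONE_OFF_MAP = tuple((db, 0.8 * a) for db, a in DEFAULT_TONE_MAP)


class AmplitudeMap:
    """Tabulated monotone non-decreasing map: stimulus intensity -> amplitude.

    Intermediate intensities are linearly interpolated; intensities beyond
    the table are clamped to the end values.  Events with no graded
    intensity (NaN) receive ``default``.
    """

    def __init__(self, table: Sequence[tuple[float, float]],
                 default: Optional[float] = None):
        tab = sorted((float(x), float(a)) for x, a in table)
        if not tab:
            raise ValueError("amplitude map needs at least one (intensity, amplitude)")
        amps = [a for _, a in tab]
        if any(b < a for a, b in zip(amps, amps[1:])):
            raise ValueError("amplitude map must be non-decreasing in intensity")
        self.x = np.array([x for x, _ in tab])
        self.a = np.array(amps)
        self.default = float(default) if default is not None else float(amps[-1])

    def __call__(self, intensity: float) -> float:
        if intensity is None or (isinstance(intensity, float) and math.isnan(intensity)):
            return self.default
        return float(np.interp(intensity, self.x, self.a))

    def to_table(self) -> list[list[float]]:
        return [[float(x), float(a)] for x, a in zip(self.x, self.a)]


MapLike = Union[AmplitudeMap, Sequence[tuple[float, float]]]


def _as_map(m: MapLike) -> AmplitudeMap:
    return m if isinstance(m, AmplitudeMap) else AmplitudeMap(m)


def default_amplitude_maps() -> dict[str, AmplitudeMap]:
    return {
        "shock_on": AmplitudeMap(DEFAULT_SHOCK_MAP),
        "tone_on": AmplitudeMap(DEFAULT_TONE_MAP),
        "tone_off": AmplitudeMap(DEFAULT_TONE_OFF_MAP),
    }


def transient_kernel(t: np.ndarray, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Unit-peak difference-of-exponentials transient, zero for t < 0.

    k(t) = (1 - exp(-t/tau_rise)) * exp(-t/tau_decay), rescaled so its
    maximum is exactly 1; the analytic peak time is
    ``tau_rise * log(1 + tau_decay/tau_rise)``.
    """
    t = np.asarray(t, dtype=float)
    k = np.where(t >= 0, (1.0 - np.exp(-np.maximum(t, 0) / tau_rise))
                 * np.exp(-np.maximum(t, 0) / tau_decay), 0.0)
    tp = kernel_peak_time(tau_rise, tau_decay)
    peak = (1.0 - np.exp(-tp / tau_rise)) * np.exp(-tp / tau_decay)
    return k / peak


def kernel_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Analytic time-to-peak of the difference-of-exponentials kernel."""
    return tau_rise * math.log1p(tau_decay / tau_rise)


@dataclass
class SimConfig:
    """Full generative parameterization of a synthetic session.

    ``bleach_465``/``bleach_405`` are pairs of (fractional amplitude,
    time-constant s); the channel trend is
    ``baseline * (1 + a1*exp(-t/tau1) + a2*exp(-t/tau2))``, so amplitude 0
    gives a flat channel.  ``motion_events`` are (time s, amplitude, width s)
    Gaussian bumps added to both channels, scaled by the per-channel gains.
    ``amplitude_map`` may be a single intensity table applied to every
    transient label or a dict label -> table; tone (dB) and shock (mA)
    intensities live on different scales, hence the per-label option.
    """

    duration: float = 600.0
    rate: float = 120.0
    baseline_465: float = 100.0
    baseline_405: float = 80.0
    bleach_465: tuple[tuple[float, float], ...] = ((0.08, 900.0), (0.04, 120.0))
    bleach_405: tuple[tuple[float, float], ...] = ((0.05, 1400.0), (0.025, 160.0))
    motion_events: tuple[tuple[float, float, float], ...] = ()
    motion_gain_465: float = 1.0
    motion_gain_405: float = 0.95
    kernel: tuple[float, float] = GCAMP_KERNEL
    amplitude_map: Union[MapLike, Mapping[str, MapLike], None] = None
    transient_labels: tuple[str, ...] = DEFAULT_TRANSIENT_LABELS
    noise_sd_465: float = 0.3
    noise_sd_405: float = 0.25
    # slow physiological fluctuation (Ornstein-Uhlenbeck): stationary SD in
    # raw units and correlation time; off by default, relevant for hour-long
    # sessions where state fluctuations dominate bin-scale variability
    noise_slow_sd_465: float = 0.0
    noise_slow_sd_405: float = 0.0
    noise_slow_tau_s: float = 60.0
    amp_jitter_sd: float = 0.0  # lognormal sigma of per-trial amplitude jitter
    seed: int = 0
    subject_id: str = "subject"
    session_id: str = "session"

    def validate(self) -> None:
        if self.rate <= 0 or self.duration <= 0:
            raise ValueError("rate and duration must be > 0")
        if min(self.kernel) <= 0:
            raise ValueError("kernel time constants must be > 0")
        for pairs in (self.bleach_465, self.bleach_405):
            for _, tau in pairs:
                if tau <= 0:
                    raise ValueError("bleach time constants must be > 0")
        if (self.noise_sd_465 < 0 or self.noise_sd_405 < 0
                or self.noise_slow_sd_465 < 0 or self.noise_slow_sd_405 < 0
                or self.amp_jitter_sd < 0):
            raise ValueError("noise/jitter SDs must be >= 0")
        if self.noise_slow_tau_s <= 0:
            raise ValueError("noise_slow_tau_s must be > 0")
        self.resolve_maps()  # raises on a non-monotone table

    def resolve_maps(self) -> dict[str, AmplitudeMap]:
        """Per-label amplitude maps, broadcasting a single table if given."""
        if self.amplitude_map is None:
            maps = default_amplitude_maps()
        elif isinstance(self.amplitude_map, Mapping):
            maps = {k: _as_map(v) for k, v in self.amplitude_map.items()}
        else:
            one = _as_map(self.amplitude_map)
            maps = {lbl: one for lbl in self.transient_labels}
        return maps


@dataclass
class DreaddParams:
    """Chemogenetic session components added on top of ``SimConfig``.

    ``cno_amplitude`` is the sustained raw-fluorescence elevation of the
    465 channel reached at full effect, as a fraction of its baseline
    (default 10%); the elevation is a logistic ramp whose midpoint sits
    ``cno_latency_s`` after the injection (default 600 s, i.e. the ~10 min
    onset latency of systemic CNO), with timescale ``cno_ramp_s``.  The
    injection itself adds a brief handling transient in every treatment.
    """

    injection_amplitude: float = 3.0
    cno_amplitude_frac: float = 0.10
    cno_latency_s: float = 600.0
    cno_ramp_s: float = 120.0

    def validate(self) -> None:
        if self.cno_latency_s < 0 or self.cno_ramp_s <= 0:
            raise ValueError("cno latency must be >= 0 and ramp > 0")


@dataclass
class GroundTruth:
    """Everything the generator injected, for verification downstream."""

    transients: pd.DataFrame  # label, trial, time_s, intensity, amplitude, peak_time_s
    motion: pd.DataFrame      # time_s, amplitude, width_s
    config: SimConfig
    treatment: Optional[str] = None


def _bleach_trend(t: np.ndarray, baseline: float,
                  pairs: Sequence[tuple[float, float]]) -> np.ndarray:
    trend = np.ones_like(t)
    for amp, tau in pairs:
        trend = trend + amp * np.exp(-t / tau)
    return baseline * trend


def _ou_trace(n: int, dt: float, sd: float, tau: float,
              rng: np.random.Generator) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck path: slow state fluctuations."""
    from scipy.signal import lfilter

    a = math.exp(-dt / tau)
    w = rng.normal(0.0, sd * math.sqrt(1.0 - a * a), size=n)
    w[0] = rng.normal(0.0, sd)  # stationary start
    return lfilter([1.0], [1.0, -a], w)


def _motion_trace(t: np.ndarray,
                  events: Sequence[tuple[float, float, float]]) -> np.ndarray:
    m = np.zeros_like(t)
    for t0, amp, width in events:
        m += amp * np.exp(-0.5 * ((t - t0) / width) ** 2)
    return m


def _transient_sum(t: np.ndarray, schedule: EventSchedule, config: SimConfig,
                   rng: np.random.Generator) -> tuple[np.ndarray, pd.DataFrame]:
    maps = config.resolve_maps()
    tau_r, tau_d = config.kernel
    tp = kernel_peak_time(tau_r, tau_d)
    out = np.zeros_like(t)
    rows = []
    ev = schedule.events
    for _, e in ev[ev["label"].isin(config.transient_labels)].iterrows():
        amap = maps.get(e["label"])
        if amap is None:
            continue
        amp = amap(e["intensity"])
        if config.amp_jitter_sd > 0:
            amp *= float(rng.lognormal(0.0, config.amp_jitter_sd))
        if amp != 0.0:
            out += amp * transient_kernel(t - e["time_s"], tau_r, tau_d)
        rows.append(dict(label=e["label"], trial=int(e["trial"]),
                         time_s=float(e["time_s"]), intensity=float(e["intensity"]),
                         amplitude=float(amp), peak_time_s=float(e["time_s"] + tp)))
    cols = ["label", "trial", "time_s", "intensity", "amplitude", "peak_time_s"]
    return out, pd.DataFrame(rows, columns=cols)


def simulate_recording(config: SimConfig,
                       schedule: EventSchedule) -> tuple[PhotometryRecording, GroundTruth]:
    """Render a schedule into a two-channel recording plus its ground truth.

    465 = baseline*bleach + sensor transients + gain*motion + noise;
    405 = baseline*bleach + gain*motion + noise (the isosbestic channel
    carries no sensor transients by construction).  Identical
    (config, schedule) inputs produce bit-identical outputs.
    """
    config.validate()
    if schedule.events["time_s"].max() > config.duration:
        raise ValueError(
            f"schedule (last event at {schedule.events['time_s'].max():.1f} s) "
            f"does not fit within config.duration = {config.duration:.1f} s"
        )
    n = int(round(config.duration * config.rate))
    t = np.arange(n) / config.rate
    rng = np.random.default_rng(config.seed)

    transients, truth_tr = _transient_sum(t, schedule, config, rng)
    motion = _motion_trace(t, config.motion_events)
    f465 = (_bleach_trend(t, config.baseline_465, config.bleach_465)
            + transients + config.motion_gain_465 * motion)
    f405 = (_bleach_trend(t, config.baseline_405, config.bleach_405)
            + config.motion_gain_405 * motion)
    if config.noise_slow_sd_465 > 0:
        f465 = f465 + _ou_trace(n, 1.0 / config.rate, config.noise_slow_sd_465,
                                config.noise_slow_tau_s, rng)
    if config.noise_slow_sd_405 > 0:
        f405 = f405 + _ou_trace(n, 1.0 / config.rate, config.noise_slow_sd_405,
                                config.noise_slow_tau_s, rng)
    if config.noise_sd_465 > 0:
        f465 = f465 + rng.normal(0.0, config.noise_sd_465, size=n)
    if config.noise_sd_405 > 0:
        f405 = f405 + rng.normal(0.0, config.noise_sd_405, size=n)

    rec = PhotometryRecording(time=t, f465=f465, f405=f405, rate=config.rate,
                              subject_id=config.subject_id,
                              session_id=config.session_id)
    truth_mo = pd.DataFrame(list(config.motion_events),
                            columns=["time_s", "amplitude", "width_s"])
    return rec, GroundTruth(transients=truth_tr, motion=truth_mo, config=config)


TREATMENTS = ("vehicle", "cno", "cno_antagonist")


def simulate_dreadd_session(config: SimConfig, treatment: str,
                            schedule: EventSchedule,
                            params: Optional[DreaddParams] = None,
                            ) -> tuple[PhotometryRecording, GroundTruth]:
    """Simulate a chemogenetic activation session.

    All treatments share the session-long bleaching decay and a brief
    injection-locked handling transient.  Under ``cno`` the 465 channel
    additionally shows a slow logistic elevation beginning roughly
    ``params.cno_latency_s`` after the injection, emulating sustained
    sensor activation; ``cno_antagonist`` nulls the sensor response, so
    its trace matches vehicle up to noise.
    """
    if treatment not in TREATMENTS:
        raise ValueError(f"treatment must be one of {TREATMENTS}")
    params = params or DreaddParams()
    params.validate()
    inj = schedule.times("injection")
    if len(inj) == 0:
        raise ValueError("dreadd schedule must contain an 'injection' event")
    t_inj = float(inj[0])

    rec, truth = simulate_recording(config, schedule)
    t = rec.time
    tau_r, tau_d = GRAB_KERNEL
    handling = params.injection_amplitude * transient_kernel(t - t_inj, tau_r, tau_d)
    f465 = rec.f465 + handling
    extra = [dict(label="injection", trial=-1, time_s=t_inj, intensity=np.nan,
                  amplitude=params.injection_amplitude,
                  peak_time_s=t_inj + kernel_peak_time(tau_r, tau_d))]
    if treatment == "cno":
        midpoint = t_inj + params.cno_latency_s
        slow = (params.cno_amplitude_frac * config.baseline_465
                / (1.0 + np.exp(-(t - midpoint) / params.cno_ramp_s)))
        slow[t < t_inj] = 0.0
        f465 = f465 + slow
        extra.append(dict(label="cno_slow", trial=-1, time_s=midpoint,
                          intensity=np.nan,
                          amplitude=params.cno_amplitude_frac * config.baseline_465,
                          peak_time_s=float(t[-1])))

    rec = PhotometryRecording(time=t, f465=f465, f405=rec.f405, rate=rec.rate,
                              subject_id=rec.subject_id, session_id=rec.session_id)
    extra_df = pd.DataFrame(extra)
    transients = (extra_df if truth.transients.empty else
                  pd.concat([truth.transients, extra_df], ignore_index=True))
    return rec, GroundTruth(transients=transients, motion=truth.motion,
                            config=config, treatment=treatment)
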