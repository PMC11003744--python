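"""Trial segmentation, artifact exclusion, peak extraction, freezing means."""

import numpy as np
import pandas as pd
import pytest

from photopipe import (
    ProtocolSpec,
    SimConfig,
    build_protocol,
    compute_dff,
    detect_artifact_trials,
    event_response_table,
    peak_response,
    phase_freezing_scores,
    pre_event_peaks,
    segment_trials,
    simulate_recording,
)
from photopipe.recording import DffTrace, EventSchedule, PhotometryRecording
from photopipe.trials import TrialTensor, default_baseline_window


def _trace(dff, rate=10.0, method="baseline_zscore"):
    n = len(dff)
    kw = (dict(baseline_window=(0.0, n / rate)) if method == "baseline_zscore"
          else dict(fit=(1.0, 0.0)))
    return DffTrace(time=np.arange(n) / rate, dff=np.asarray(dff, float),
                    method=method, rate=rate, **kw)


def _schedule(times, label="tone_on", duration=None, protocol="tone_curve",
              intensities=None):
    duration = duration or (max(times) + 30.0)
    rows = [dict(label=label, time_s=t, trial=i,
                 intensity=(intensities[i] if intensities is not None else 85.0))
            for i, t in enumerate(times)]
    return EventSchedule(events=pd.DataFrame(rows), duration=duration,
                         protocol=protocol)


def _manual_tensor(rows, rate=10.0, pre=2.0):
    rows = np.asarray(rows, float)
    n = rows.shape[1]
    rel = (np.arange(n) - int(pre * rate)) / rate
    return TrialTensor(
        data=rows, raw=rows.copy(), rel_time=rel, align_label="tone_on",
        window=(pre, n / rate - pre), baseline_window=(-pre, 0.0),
        meta=pd.DataFrame(dict(trial=range(len(rows)),
                               time_s=np.zeros(len(rows)),
                               intensity=np.nan, signaled=True)),
        excluded=np.zeros(len(rows), bool),
        exclusion_reasons=[None] * len(rows), units="z",
    )


class TestSegmentTrials:
    def test_constant_trace_normalizes_to_zero(self):
        trace = _trace(np.full(600, 4.2))
        tensor = segment_trials(trace, _schedule([10.0, 30.0]), "tone_on",
                                (2.0, 5.0))
        np.testing.assert_allclose(tensor.data, 0.0, atol=1e-12)

    def test_tfc_window_spans_tone_trace_shock(self):
        sched = build_protocol(ProtocolSpec.tfc_train(n_trials=10), seed=2)
        cfg = SimConfig(duration=sched.duration, seed=2)
        rec, _ = simulate_recording(cfg, sched)
        trace = compute_dff(rec)
        tensor = segment_trials(trace, sched, "tone_on", (20.0, 62.0))
        assert tensor.data.shape == (10, int(82.0 * cfg.rate))
        assert tensor.baseline_window == (-20.0, 0.0)  # conditioning convention
        assert tensor.rel_time[0] == pytest.approx(-20.0)

    def test_transient_on_single_trial_dominates_its_row(self):
        # tone at 95 dB only on trial 3; map gives the others zero amplitude
        times = [20.0, 60.0, 100.0, 140.0, 180.0]
        ints = [55.0, 55.0, 55.0, 95.0, 55.0]
        sched = _schedule(times, duration=240.0, intensities=ints)
        cfg = SimConfig(duration=240.0, rate=60.0,
                        bleach_465=((0.05, 200.0),), bleach_405=((0.05, 200.0),),
                        noise_sd_465=0.0, noise_sd_405=0.0,
                        amplitude_map=[(55.0, 0.0), (95.0, 3.0)], seed=0)
        rec, _ = simulate_recording(cfg, sched)
        trace = compute_dff(rec)
        tensor = segment_trials(trace, sched, "tone_on", (2.0, 10.0))
        maxima = tensor.data.max(axis=1)
        assert np.argmax(maxima) == 3
        assert maxima[3] > 10 * np.max(np.delete(maxima, 3))

    def test_round_trip_reproduces_source_samples(self):
        rng = np.random.default_rng(5)
        trace = _trace(rng.normal(size=800))
        sched = _schedule([20.0, 40.0, 60.0])
        tensor = segment_trials(trace, sched, "tone_on", (2.0, 6.0))
        for i, t_ev in enumerate(sched.times("tone_on")):
            i0 = int(np.ceil(t_ev * trace.rate)) - 20
            np.testing.assert_array_equal(tensor.raw[i],
                                          trace.dff[i0:i0 + 80])

    def test_missing_label_errors(self):
        with pytest.raises(ValueError, match="shock_on"):
            segment_trials(_trace(np.zeros(100)), _schedule([5.0]), "shock_on",
                           (1.0, 2.0))

    def test_short_coverage_flags_not_drops(self):
        trace = _trace(np.zeros(100))  # 10 s at 10 Hz
        tensor = segment_trials(trace, _schedule([1.0, 5.0], duration=12.0),
                                "tone_on", (2.0, 3.0))
        assert tensor.n_trials == 2
        assert tensor.excluded[0] and not tensor.excluded[1]
        assert tensor.exclusion_reasons[0] == "window_out_of_bounds"

    def test_baseline_convention_by_protocol(self):
        assert default_baseline_window("tfc_train") == (-20.0, 0.0)
        assert default_baseline_window("shock_curve") == (-2.0, 0.0)


class TestArtifactDetector:
    def _session(self, motion=(), transient_amp=0.0, seed=0):
        times = [20.0, 60.0, 100.0, 140.0]
        sched = _schedule(times, duration=180.0)
        amp_map = [(85.0, transient_amp)]
        cfg = SimConfig(duration=180.0, rate=60.0, bleach_465=(), bleach_405=(),
                        motion_events=tuple(motion), amplitude_map=amp_map,
                        noise_sd_465=0.3, noise_sd_405=0.3, seed=seed)
        rec, _ = simulate_recording(cfg, sched)
        trace = compute_dff(rec)
        tensor = segment_trials(trace, sched, "tone_on", (2.0, 10.0))
        return rec, tensor

    def test_clean_session_keeps_all_trials(self):
        rec, tensor = self._session()
        detect_artifact_trials(rec, tensor, z_thresh=8.0)
        assert not tensor.excluded.any()

    def test_shared_bump_excludes_exactly_that_trial(self):
        # 20-sigma shared bump inside trial 1's window (tone at 60 s)
        rec, tensor = self._session(motion=[(63.0, 6.0, 0.3)])
        detect_artifact_trials(rec, tensor, z_thresh=8.0)
        assert list(np.flatnonzero(tensor.excluded)) == [1]
        assert "simultaneous_deflection" in tensor.exclusion_reasons[1]

    def test_signal_only_transient_is_retained(self):
        # a genuine 465-only transient of the same magnitude is not an artifact
        rec, tensor = self._session(transient_amp=6.0)
        detect_artifact_trials(rec, tensor, z_thresh=8.0)
        assert not tensor.excluded.any()


class TestPeaks:
    def test_zero_row_peaks_at_zero(self):
        tensor = _manual_tensor(np.zeros((2, 50)))
        out = peak_response(tensor)
        assert (out["peak_dff"] == 0.0).all()
        assert (out["phase"] == "post").all()

    def test_single_sample_spike_is_the_peak(self):
        rows = np.zeros((1, 50))
        rows[0, 25] = 7.0  # 0.5 s after the event at 10 Hz
        out = peak_response(_manual_tensor(rows), width=2.0)
        assert out["peak_dff"].iloc[0] == 7.0

    def test_peak_is_signed_maximum(self):
        rows = np.zeros((1, 50))
        rows[0, 22] = -9.0
        rows[0, 30] = 1.5
        out = peak_response(_manual_tensor(rows), width=2.0)
        assert out["peak_dff"].iloc[0] == 1.5

    def test_pre_peaks_mirror_and_validate_width(self):
        rows = np.zeros((1, 50))
        rows[0, 10] = 2.5  # 1 s before the event
        out = pre_event_peaks(_manual_tensor(rows), width=2.0)
        assert out["phase"].iloc[0] == "pre"
        assert out["peak_dff"].iloc[0] == 2.5
        with pytest.raises(ValueError, match="pre window"):
            pre_event_peaks(_manual_tensor(rows), width=5.0)

    def test_window_outside_span_errors(self):
        with pytest.raises(ValueError, match="outside trial span"):
            peak_response(_manual_tensor(np.zeros((1, 50))), event_offset=2.5,
                          width=2.0)

    def test_excluded_trials_emit_no_rows(self):
        tensor = _manual_tensor(np.zeros((3, 50)))
        tensor.exclude(1, "simultaneous_deflection@t=1.0s")
        out = pd.concat([peak_response(tensor), pre_event_peaks(tensor)])
        # retained trials x 1 event x 2 phases
        assert len(out) == 2 * 2
        assert 1 not in out["trial"].values

    def test_mean_peaks_monotone_in_intensity(self):
        sched = build_protocol(ProtocolSpec.shock_curve(n_blocks=3), seed=9)
        cfg = SimConfig(duration=sched.duration, rate=60.0,
                        noise_sd_465=0.0, noise_sd_405=0.0, seed=9)
        rec, _ = simulate_recording(cfg, sched)
        tensor = segment_trials(compute_dff(rec), sched, "shock_on", (2.0, 5.0))
        out = peak_response(tensor)
        means = out.groupby("intensity")["peak_dff"].mean()
        assert (np.diff(means.loc[sorted(means.index)]) >= -1e-9).all()


class TestEventResponseTable:
    def test_row_count_matches_retained_trials(self, tfc_session):
        rec, truth, sched, cfg = tfc_session
        trace = compute_dff(rec)
        table, tensors = event_response_table(trace, sched, rec=rec)
        for label, tensor in tensors.items():
            n_ret = int(tensor.retained.sum())
            assert len(table[table["event"] == label]) == 2 * n_ret  # pre+post

    def test_unknown_labels_error(self, tfc_session):
        rec, truth, sched, cfg = tfc_session
        trace = compute_dff(rec)
        with pytest.raises(ValueError, match="none of the labels"):
            event_response_table(trace, sched, events=("lever_press",))


class TestPhaseFreezing:
    def _table(self):
        rows = []
        for subj in ("m1", "m2"):
            for trial in range(2):
                for phase, val in [("baseline", 10.0), ("tone", 40.0 + 20 * trial),
                                   ("trace", 30.0)]:
                    rows.append(dict(subject=subj, trial=trial, phase=phase,
                                     percent_freezing=val))
        return pd.DataFrame(rows)

    def test_two_trial_average(self):
        out = phase_freezing_scores(self._table())
        tone = out[(out["subject"] == "m1") & (out["phase"] == "tone")]
        assert tone["mean_freezing"].iloc[0] == 50.0  # mean of 40 and 60

    def test_single_trial_equals_raw_values(self):
        t = self._table()
        t = t[t["trial"] == 0]
        out = phase_freezing_scores(t)
        assert set(out["mean_freezing"]) == {10.0, 40.0, 30.0}

    def test_matches_brute_force_groupby(self):
        rng = np.random.default_rng(3)
        rows = [dict(subject=f"m{s}", trial=tr, phase=ph,
                     percent_freezing=float(rng.uniform(0, 100)))
                for s in range(3) for tr in range(6)
                for ph in ("baseline", "tone", "trace")]
        t = pd.DataFrame(rows)
        out = phase_freezing_scores(t)
        for _, r in out.iterrows():
            expect = t[(t["subject"] == r["subject"]) &
                       (t["phase"] == r["phase"])]["percent_freezing"].mean()
            assert r["mean_freezing"] == pytest.approx(expect)

    def test_missing_phase_names_subject(self):
        t = self._table()
        t = t[~((t["subject"] == "m2") & (t["phase"] == "trace"))]
        with pytest.raises(ValueError, match="m2"):
            phase_freezing_scores(t)
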