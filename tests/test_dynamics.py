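"""Trace segmentation, phase tiling and dynamic-instability statistics."""

import numpy as np
import pytest

from mtbundle import (
    DynamicsError,
    DynamicsTrace,
    Phase,
    event_statistics,
    gen_traces,
    segment_trace,
    traces_from_frame,
)
from mtbundle.dynamics import window_velocity
from mtbundle.synthetic import traces_to_frame


def ramp_trace(slope, duration=120.0, dt=1.0, intercept=0.0):
    t = np.arange(0.0, duration + dt / 2, dt)
    return DynamicsTrace(t, np.maximum(intercept + slope * t, 0.0))


class TestSegmentTrace:
    def test_pure_ramp_is_single_growth_phase(self):
        phases = segment_trace(ramp_trace(14.73))
        assert [p.kind for p in phases] == ["growth"]
        assert phases[0].velocity_nm_s == pytest.approx(14.73, abs=1e-9)

    def test_flat_trace_is_single_pause(self):
        t = np.arange(0.0, 61.0)
        phases = segment_trace(DynamicsTrace(t, np.full(len(t), 500.0)))
        assert [p.kind for p in phases] == ["pause"]

    def test_growth_then_shrinkage_is_one_catastrophe(self):
        t = np.arange(0.0, 81.0)
        y = np.where(t <= 60, 14.73 * t, np.maximum(14.73 * 60 - 40.0 * (t - 60), 0.0))
        phases = segment_trace(DynamicsTrace(t, y))
        kinds = [p.kind for p in phases]
        assert kinds[0] == "growth" and "shrinkage" in kinds
        s = event_statistics([phases])
        assert s.n_catastrophes == 1

    def test_phases_tile_trace(self, rng):
        traces, _ = gen_traces(v_g=10.0, v_s=-300.0, f_cat=0.01, f_res=0.05,
                               pause_entry_rate=0.005, pause_exit_rate=0.01,
                               duration_s=300.0, n_traces=5, seed=3)
        for tr in traces:
            phases = segment_trace(tr)
            total = sum(p.duration_s for p in phases)
            assert total == pytest.approx(tr.time_s[-1] - tr.time_s[0])
            for a, b in zip(phases[:-1], phases[1:]):
                assert a.end_s == pytest.approx(b.start_s)

    def test_too_short_trace_error(self):
        with pytest.raises(DynamicsError):
            DynamicsTrace(np.arange(5.0), np.arange(5.0))

    def test_noise_shuffle_does_not_change_phase_count(self, rng):
        # well-separated velocities: |v| >= 5x the pause band
        t = np.arange(0.0, 201.0)
        clean = np.where(t <= 120, 10.0 * t, 1200.0)
        noise = rng.normal(0, 5.0, len(t))
        k1 = [p.kind for p in segment_trace(DynamicsTrace(t, np.maximum(clean + noise, 0)))]
        k2 = [p.kind for p in segment_trace(DynamicsTrace(t, np.maximum(clean + rng.permutation(noise), 0)))]
        assert k1 == k2 == ["growth", "pause"]


class TestWindowVelocity:
    def test_constant_slope_everywhere(self):
        v = window_velocity(ramp_trace(3.0), window=5)
        np.testing.assert_allclose(v, 3.0, atol=1e-9)


class TestEventStatistics:
    def test_hand_built_catastrophe_frequency(self):
        phases = [
            Phase("growth", 0.0, 60.0, 10.0),
            Phase("shrinkage", 60.0, 65.0, -200.0),
            Phase("growth", 65.0, 100.0, 10.0),
            Phase("pause", 100.0, 105.0, 0.0),
            Phase("shrinkage", 105.0, 110.0, -200.0),
        ]
        s = event_statistics([phases])
        assert s.n_catastrophes == 2
        assert s.total_growth_pause_s == pytest.approx(100.0)
        assert s.f_cat_per_s == pytest.approx(0.02)
        assert s.n_rescues == 1

    def test_no_shrinkage_gives_undefined_rescue_rate(self):
        phases = [Phase("growth", 0.0, 100.0, 5.0)]
        s = event_statistics([phases])
        assert not s.f_res_defined
        assert s.f_res_per_s is None

    def test_adding_catastrophe_increases_f_cat(self):
        base = [Phase("growth", 0.0, 100.0, 10.0)]
        more = [Phase("growth", 0.0, 50.0, 10.0),
                Phase("shrinkage", 50.0, 52.0, -200.0),
                Phase("growth", 52.0, 102.0, 10.0)]
        assert event_statistics([more]).f_cat_per_s > event_statistics([base]).f_cat_per_s


class TestRecovery:
    def test_growth_rate_recovered_from_simulation(self):
        traces, truth = gen_traces(v_g=14.73, v_s=-300.0, f_cat=0.005,
                                   f_res=0.02, duration_s=600.0, n_traces=25,
                                   length_noise_nm=20.0, seed=11)
        s = event_statistics([segment_trace(tr) for tr in traces])
        assert s.growth_rate_nm_s == pytest.approx(truth.params["v_g"], rel=0.05)

    def test_catastrophe_frequency_within_counting_error(self):
        traces, truth = gen_traces(v_g=14.73, v_s=-300.0, f_cat=0.005,
                                   f_res=0.02, duration_s=600.0, n_traces=50,
                                   length_noise_nm=20.0, seed=11)
        s = event_statistics([segment_trace(tr) for tr in traces])
        assert s.f_cat_per_s == pytest.approx(truth.params["f_cat"], rel=0.25)

    def test_slow_growth_with_pauses_recovered(self):
        traces, truth = gen_traces(v_g=1.71, v_s=-300.0, f_cat=0.001,
                                   f_res=0.02, pause_entry_rate=0.01,
                                   pause_exit_rate=0.005, duration_s=600.0,
                                   n_traces=25, length_noise_nm=20.0, seed=12)
        s = event_statistics([segment_trace(tr) for tr in traces])
        assert s.growth_rate_nm_s == pytest.approx(truth.params["v_g"], rel=0.12)
        assert s.n_pauses > 0


class TestTraceIO:
    def test_frame_round_trip(self):
        traces, _ = gen_traces(v_g=5.0, v_s=-100.0, f_cat=0.01, f_res=0.05,
                               duration_s=60.0, n_traces=3, seed=2)
        again = traces_from_frame(traces_to_frame(traces))
        assert len(again) == 3
        for a, b in zip(sorted(again, key=lambda x: x.trace_id), traces):
            np.testing.assert_allclose(a.length_nm, b.length_nm)
            assert a.condition == b.condition
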