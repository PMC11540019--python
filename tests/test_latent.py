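"""Latent need/motivation trace construction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from needmot import (
    Event,
    EventKind,
    EventSchedule,
    LatentTrace,
    MotivationParams,
    NeedParams,
    build_inverted_trace,
    build_motivation_trace,
    build_need_trace,
    build_test_model,
)
from needmot.errors import ParameterShapeError, ScheduleError

from conftest import euler_motivation


def step_sum_oracle(schedule, params, t):
    """Independent evaluation of the need value at time t by summing steps."""
    if schedule.abandon_time is not None and t >= schedule.abandon_time:
        return params.N0
    value = params.N0
    for R, ev in zip(params.steps, schedule.step_events):
        if t >= ev.time:
            value -= R
    return value


class TestNeedTrace:
    def test_no_events_is_constant_baseline(self, simple_window):
        sched = EventSchedule([], simple_window)
        trace = build_need_trace(sched, NeedParams(N0=1.0))
        assert np.all(trace.values == 1.0)
        assert len(trace) == 2000

    def test_single_gain_steps_down_at_event(self, simple_window):
        sched = EventSchedule([Event(5.0, "g", EventKind.GAIN)], simple_window)
        trace = build_need_trace(sched, NeedParams(N0=1.0, steps=(0.4,)))
        t = trace.times
        assert np.allclose(trace.values[t < 5.0], 1.0)
        assert np.allclose(trace.values[t >= 5.0], 0.6)

    def test_loss_then_abandon_returns_to_baseline(self):
        sched = EventSchedule(
            [Event(3.0, "loss", EventKind.LOSS), Event(8.0, "ab", EventKind.ABANDON)],
            (0.0, 12.0),
        )
        trace = build_need_trace(sched, NeedParams(N0=0.0, steps=(-0.7,)))
        t = trace.times
        assert np.allclose(trace.values[t < 3.0], 0.0)
        assert np.allclose(trace.values[(t >= 3.0) & (t < 8.0)], 0.7)
        assert np.allclose(trace.values[t >= 8.0], 0.0)

    def test_matches_step_sum_oracle(self, multi_schedule):
        params = NeedParams(N0=2.0, steps=(0.5, 0.5, 0.5, 2.5, -1.5))
        trace = build_need_trace(multi_schedule, params)
        for t in (0.0, 11.0, 13.0, 17.0, 20.0, 30.0, 39.0):
            assert trace.values[trace.index_of(t)] == pytest.approx(
                step_sum_oracle(multi_schedule, params, t)
            )

    def test_one_discontinuity_per_step_event(self, multi_schedule):
        params = NeedParams(N0=2.0, steps=(0.5, 0.5, 0.5, 2.5, -1.5))
        trace = build_need_trace(multi_schedule, params)
        jumps = np.flatnonzero(np.diff(trace.values) != 0)
        assert jumps.size == len(multi_schedule.step_events)

    def test_clip_floor(self, simple_window):
        sched = EventSchedule([Event(5.0, "g", EventKind.GAIN)], simple_window)
        trace = build_need_trace(sched, NeedParams(N0=0.5, steps=(2.0,), clip_floor=0.0))
        assert trace.values.min() == 0.0

    def test_wrong_step_count_raises(self, simple_window):
        sched = EventSchedule([Event(5.0, "g", EventKind.GAIN)], simple_window)
        with pytest.raises(ParameterShapeError):
            build_need_trace(sched, NeedParams(N0=1.0, steps=(0.4, 0.1)))

    def test_sign_convention_enforced(self, simple_window):
        sched = EventSchedule([Event(5.0, "g", EventKind.GAIN)], simple_window)
        with pytest.raises(ParameterShapeError):
            build_need_trace(sched, NeedParams(N0=1.0, steps=(-0.4,)))

    def test_event_outside_window_raises(self):
        with pytest.raises(ScheduleError):
            EventSchedule([Event(25.0, "g", EventKind.GAIN)], (0.0, 20.0))


class TestMotivationTrace:
    def test_constant_need_linear_growth(self):
        sched = EventSchedule(
            [Event(0.0, "a", EventKind.ACCESSIBILITY)], (0.0, 10.0)
        )
        need = build_need_trace(sched, NeedParams(N0=2.0))
        mot = build_motivation_trace(
            sched, need, MotivationParams(M0=0.0, a=0.5, Leak=0.0, t0=0.0)
        )
        # slope a*N = 1 => M(t) = t
        assert np.allclose(mot.values, mot.times, atol=1e-9)

    def test_pure_leak(self):
        sched = EventSchedule(
            [Event(0.0, "a", EventKind.ACCESSIBILITY)], (0.0, 10.0)
        )
        need = build_need_trace(sched, NeedParams(N0=0.0))
        mot = build_motivation_trace(
            sched, need, MotivationParams(M0=1.0, a=0.0, Leak=0.1, t0=0.0)
        )
        assert np.allclose(mot.values, 1.0 - 0.1 * mot.times, atol=1e-9)

    def test_stepwise_need_matches_euler_oracle(self):
        sched = EventSchedule(
            [
                Event(0.0, "a", EventKind.ACCESSIBILITY),
                Event(5.0, "g", EventKind.GAIN),
            ],
            (0.0, 10.0),
        )
        np_params = NeedParams(N0=1.0, steps=(0.5,))
        mp = MotivationParams(M0=0.0, a=0.2, Leak=0.05, t0=0.0)
        need = build_need_trace(sched, np_params, rate=100)
        mot = build_motivation_trace(sched, need, mp)
        t_e, m_e = euler_motivation(sched, np_params, mp, dt=0.001)
        # compare on the shared 100 Hz grid
        assert np.allclose(mot.values, m_e[::10], atol=1e-6)

    def test_slope_equals_aN_minus_leak_on_each_interval(self, multi_schedule, multi_params):
        need_params, mot_params = multi_params
        need = build_need_trace(multi_schedule, need_params)
        mot = build_motivation_trace(multi_schedule, need, mot_params)
        i0 = need.index_of(multi_schedule.accessibility_time)
        i_loss = need.index_of(multi_schedule.first_loss_time)
        slopes = np.diff(mot.values) * need.rate
        expected = mot_params.a * need.values - mot_params.Leak
        assert np.allclose(slopes[i0:i_loss - 1], expected[i0:i_loss - 1], atol=1e-9)

    def test_frozen_after_loss_event(self, multi_schedule, multi_params):
        need_params, mot_params = multi_params
        need = build_need_trace(multi_schedule, need_params)
        mot = build_motivation_trace(multi_schedule, need, mot_params)
        i_loss = mot.index_of(multi_schedule.first_loss_time)
        assert np.all(mot.values[i_loss:] == mot.values[i_loss])

    def test_abandon_reset_baseline_vs_zero(self, loss_abandon_schedule):
        np_params = NeedParams(N0=1.0, steps=(0.5,))
        mp = MotivationParams(M0=0.3, a=0.2, Leak=0.0)
        need = build_need_trace(loss_abandon_schedule, np_params)
        for reset, value in (("baseline", 0.3), ("zero", 0.0)):
            mot = build_motivation_trace(
                loss_abandon_schedule, need, mp, abandon_reset=reset
            )
            i_ab = mot.index_of(loss_abandon_schedule.abandon_time)
            assert np.all(mot.values[i_ab:] == value)

    def test_baseline_conservation(self, multi_schedule):
        """All R_i = 0, a = 0, Leak = 0: need == N0 and motivation == M0."""
        need_params = NeedParams(N0=1.7, steps=(0.0,) * 5)
        need = build_need_trace(multi_schedule, need_params)
        mot = build_motivation_trace(
            multi_schedule, need, MotivationParams(M0=-0.4, a=0.0, Leak=0.0, t0=10.0)
        )
        i_loss = need.index_of(multi_schedule.first_loss_time)
        assert np.all(need.values[:i_loss] == 1.7)
        assert np.all(mot.values == -0.4)


class TestInversion:
    def test_constant_trace_unchanged(self):
        trace = LatentTrace(np.full(100, 2.5))
        assert np.array_equal(build_inverted_trace(trace).values, trace.values)

    def test_step_reflects_about_initial_value(self):
        values = np.where(np.arange(200) < 100, 1.0, 0.6)
        inv = build_inverted_trace(LatentTrace(values))
        assert np.allclose(inv.values[:100], 1.0)
        assert np.allclose(inv.values[100:], 1.4)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(-10, 10), min_size=1, max_size=50))
    def test_involution_and_initial_value(self, values):
        trace = LatentTrace(np.asarray(values))
        inv = build_inverted_trace(trace)
        assert inv.values[0] == trace.values[0]
        back = build_inverted_trace(inv)
        assert np.allclose(back.values, trace.values)

    def test_empty_trace_raises(self):
        with pytest.raises(ValueError):
            build_inverted_trace(LatentTrace(np.array([])))


class TestBuildTestModel:
    def test_loss1_need_rises_stepwise(self):
        sched = EventSchedule([Event(8.0, "inacc", EventKind.LOSS)], (0.0, 20.0))
        trace = build_test_model("loss1", sched, "need", NeedParams(N0=0.0, steps=(-1.0,)))
        t = trace.times
        assert np.allclose(trace.values[t < 8.0], 0.0)
        assert np.allclose(trace.values[t >= 8.0], 1.0)

    def test_loss1_motivation_is_flat(self):
        """Inaccessibility blocks access, so motivation never accumulates."""
        sched = EventSchedule([Event(8.0, "inacc", EventKind.LOSS)], (0.0, 20.0))
        trace = build_test_model(
            "loss1", sched, "motivation",
            NeedParams(N0=0.0, steps=(-1.0,)),
            MotivationParams(M0=0.2, a=0.5, Leak=0.1),
        )
        assert np.all(trace.values == 0.2)

    def test_delay_equals_manual_schedule_edit(self, multi_schedule, multi_params):
        need_params, mot_params = multi_params
        delayed = build_test_model(
            "multi_gain_loss", multi_schedule, "need", need_params, delay=2.0
        )
        manual = multi_schedule.shift_kind(EventKind.CONSUMPTION_END, 2.0)
        reference = build_test_model("multi_gain_loss", manual, "need", need_params)
        assert np.array_equal(delayed.values, reference.values)

    def test_unknown_test_id_raises(self, multi_schedule, multi_params):
        with pytest.raises(ScheduleError):
            build_test_model("gain7", multi_schedule, "need", multi_params[0])

    def test_missing_required_kind_raises(self, gain_schedule):
        with pytest.raises(ScheduleError):
            build_test_model(
                "multi_gain_loss", gain_schedule, "need", NeedParams(N0=1.0, steps=(0.5,))
            )

    def test_forbidden_kind_raises(self, loss_abandon_schedule):
        with pytest.raises(ScheduleError):
            build_test_model(
                "gain1", loss_abandon_schedule, "need", NeedParams(N0=1.0, steps=(0.5,))
            )
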