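import numpy as np
import pytest

from needmot import (
    Event,
    EventKind,
    EventSchedule,
    KernelSpec,
    MotivationParams,
    NeedParams,
)


@pytest.fixture
def simple_window():
    return (0.0, 20.0)


@pytest.fixture
def gain_schedule(simple_window):
    """Accessibility then a single predicted-gain event."""
    return EventSchedule(
        [
            Event(3.0, "door_removed", EventKind.ACCESSIBILITY),
            Event(5.0, "seeking_initiation", EventKind.GAIN),
        ],
        simple_window,
    )


@pytest.fixture
def loss_abandon_schedule(simple_window):
    """Loss-test-2 style: gain followed by a voluntary abandon."""
    return EventSchedule(
        [
            Event(2.0, "door_removed", EventKind.ACCESSIBILITY),
            Event(3.0, "eating_initiation", EventKind.GAIN),
            Event(8.0, "eating_abandon", EventKind.ABANDON),
        ],
        simple_window,
    )


@pytest.fixture
def multi_schedule():
    """Multi-gain/loss template: three gains, consumption end, inaccessibility."""
    return EventSchedule(
        [
            Event(10.0, "door_removed", EventKind.ACCESSIBILITY),
            Event(12.0, "seeking_initiation", EventKind.GAIN),
            Event(15.0, "proximate_to_food", EventKind.GAIN),
            Event(18.0, "food_contact", EventKind.GAIN),
            Event(26.0, "consumption_end", EventKind.CONSUMPTION_END),
            Event(32.0, "inaccessibility", EventKind.LOSS),
        ],
        (0.0, 40.0),
    )


@pytest.fixture
def kernel_spec():
    return KernelSpec()


@pytest.fixture
def multi_params():
    return (
        NeedParams(N0=2.0, steps=(0.5, 0.5, 0.5, 2.5, -1.5)),
        MotivationParams(M0=0.0, a=0.25, Leak=0.05),
    )


def euler_motivation(schedule, need_params, mot_params, dt=0.001,
                     freeze_at_loss=True, abandon_reset="baseline"):
    """Independent forward-Euler oracle for the motivation integral.

    Integrates dM/dt = a*N(t) - Leak from t0 on a fine grid, with the same
    event semantics as the closed form (freeze at the first loss event,
    reset to baseline at abandon).  Step times are assumed to sit on the
    dt grid.
    """
    start, end = schedule.trial_window
    n = int(round((end - start) / dt))
    t = start + np.arange(n) * dt

    # piecewise-constant need evaluated directly from the events
    N = np.full(n, need_params.N0)
    for R, ev in zip(need_params.steps, schedule.step_events):
        N[t >= ev.time - 1e-12] -= R
    if schedule.abandon_time is not None:
        N[t >= schedule.abandon_time - 1e-12] = need_params.N0

    t0 = schedule.accessibility_time
    M = np.full(n, mot_params.M0)
    if t0 is not None:
        i0 = int(round((t0 - start) / dt))
        for i in range(i0, n - 1):
            M[i + 1] = M[i] + (mot_params.a * N[i] - mot_params.Leak) * dt
    if freeze_at_loss and schedule.first_loss_time is not None:
        iL = int(round((schedule.first_loss_time - start) / dt))
        M[iL:] = M[iL]
    if schedule.abandon_time is not None:
        iA = int(round((schedule.abandon_time - start) / dt))
        M[iA:] = mot_params.M0 if abandon_reset == "baseline" else 0.0
    return t, M
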