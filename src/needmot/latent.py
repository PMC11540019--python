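"""Latent need and motivation time courses implied by an event schedule.

The need latent ``N(t)`` is piecewise constant: it starts at a baseline
``N0`` and changes by ``-R_i`` at each step-inducing event (predicted-gain
events carry ``R_i >= 0``, predicted-loss events ``R_i <= 0``).  At an
``abandon`` event the trace resets instantaneously to the pre-trial
baseline and holds there.

The motivation latent ``M(t)`` is the leaky accumulation of need from the
accessibility moment ``t0``::

    M(t) = M0 + integral_{t0}^{t} [ a * N(s) - Leak ] ds      (t >= t0)

Because ``N`` is piecewise constant, ``M`` is continuous piecewise linear
with slope ``a*N - Leak`` on each interval; the builder evaluates this
closed form exactly on the sample grid.  Accumulation freezes at the first
``loss`` (inaccessibility) event — a blocked target stops driving
goal-directed motivation — and an ``abandon`` event resets the trace to its
pre-trial baseline (configurable to zero).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .errors import AlignmentError, ParameterShapeError, ScheduleError
from .schedule import Event, EventKind, EventSchedule, STEP_KINDS

__all__ = [
    "LatentTrace",
    "NeedParams",
    "MotivationParams",
    "TEST_IDS",
    "MODEL_NAMES",
    "build_need_trace",
    "build_motivation_trace",
    "build_inverted_trace",
    "build_test_model",
    "step_sign",
]

TEST_IDS = (
    "gain1",
    "gain2",
    "loss1",
    "loss2",
    "loss3",
    "multi_gain",
    "multi_gain_loss",
)

MODEL_NAMES = ("need", "motivation", "inverted_need", "inverted_motivation")


@dataclass(frozen=True)
class LatentTrace:
    """Uniformly sampled latent time series."""

    values: np.ndarray
    rate: float = 100.0
    t_start: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1:
            raise ValueError("LatentTrace values must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("LatentTrace values must be finite")
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return self.t_start + np.arange(self.values.size) / self.rate

    def index_of(self, t: float) -> int:
        """Nearest sample index for time ``t`` (events snap to the grid)."""
        return int(round((t - self.t_start) * self.rate))


def step_sign(kind: EventKind) -> int:
    """Sign convention for a step magnitude: gains carry R >= 0, losses R <= 0."""
    if kind in (EventKind.GAIN, EventKind.CONSUMPTION_END):
        return 1
    if kind is EventKind.LOSS:
        return -1
    raise ScheduleError(f"{kind} is not a step-inducing event kind")


@dataclass(frozen=True)
class NeedParams:
    """Parameters of the stepwise need model.

    ``steps`` holds one magnitude R_i per step-inducing event, in schedule
    order.  The sign convention follows the predicted-gain/loss semantics:
    R_i >= 0 for gain-type events (need decreases), R_i <= 0 for loss events
    (need increases).
    """

    N0: float
    steps: tuple[float, ...] = ()
    clip_floor: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "steps", tuple(float(s) for s in self.steps))

    def validate_against(self, schedule: EventSchedule) -> None:
        step_events = schedule.step_events
        if len(self.steps) != len(step_events):
            raise ParameterShapeError(
                f"{len(self.steps)} step magnitudes supplied for "
                f"{len(step_events)} step-inducing events"
            )
        for R, ev in zip(self.steps, step_events):
            if step_sign(ev.kind) * R < -1e-12:
                raise ParameterShapeError(
                    f"step magnitude {R} violates the sign convention for "
                    f"a {ev.kind.value} event at t={ev.time}"
                )


@dataclass(frozen=True)
class MotivationParams:
    """Parameters of the leaky need-accumulation model.

    ``t0`` is the accumulation onset (the accessibility moment); ``None``
    means the target is never accessible and motivation stays at ``M0``.
    """

    M0: float = 0.0
    a: float = 0.0
    Leak: float = 0.0
    t0: float | None = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.a) and self.a >= 0):
            raise ParameterShapeError("accumulation gain a must be finite and >= 0")
        if not (math.isfinite(self.Leak) and self.Leak >= 0):
            raise ParameterShapeError("Leak must be finite and >= 0")


def _window_samples(schedule: EventSchedule, rate: float) -> int:
    start, end = schedule.trial_window
    return int(round((end - start) * rate))


def build_need_trace(
    schedule: EventSchedule, params: NeedParams, rate: float = 100.0
) -> LatentTrace:
    """Construct the piecewise-constant need latent for a schedule.

    The value is ``N0`` before the first step event; each step event i
    changes it by ``-R_i``; an abandon event resets it to the pre-trial
    baseline ``N0`` for the remainder of the trial.
    """
    params.validate_against(schedule)
    start, _ = schedule.trial_window
    n = _window_samples(schedule, rate)
    values = np.full(n, params.N0, dtype=float)
    for R, ev in zip(params.steps, schedule.step_events):
        idx = int(round((ev.time - start) * rate))
        if 0 <= idx < n:
            values[idx:] -= R
        # events snapped past the window end have no effect
    t_ab = schedule.abandon_time
    if t_ab is not None:
        idx = int(round((t_ab - start) * rate))
        if idx < n:
            values[max(idx, 0):] = params.N0
    if params.clip_floor is not None:
        np.maximum(values, params.clip_floor, out=values)
    return LatentTrace(values, rate=rate, t_start=start)


def build_motivation_trace(
    schedule: EventSchedule,
    need: LatentTrace,
    params: MotivationParams,
    *,
    freeze_at_loss: bool = True,
    abandon_reset: Literal["baseline", "zero"] = "baseline",
) -> LatentTrace:
    """Accumulate a need trace into the motivation latent, in closed form.

    The left-Riemann cumulative sum of ``a*N - Leak`` is exact for a
    piecewise-constant need whose steps sit on the sample grid, and equals
    the piecewise-linear closed form of the integral.
    """
    start, _ = schedule.trial_window
    if abs(need.rate) <= 0 or abs(need.t_start - start) * need.rate > 0.5:
        raise AlignmentError("need trace window does not match the schedule")
    rate = need.rate
    n = len(need)
    dt = 1.0 / rate
    values = np.full(n, params.M0, dtype=float)
    if params.t0 is not None:
        i0 = max(int(round((params.t0 - start) * rate)), 0)
        if i0 < n:
            slope = params.a * need.values[i0:] - params.Leak
            # M[i0] = M0; M[i+1] = M[i] + slope[i] * dt  (exact on the grid)
            values[i0 + 1:] = params.M0 + np.cumsum(slope[:-1]) * dt
    if freeze_at_loss:
        t_loss = schedule.first_loss_time
        if t_loss is not None:
            idx = int(round((t_loss - start) * rate))
            if 0 <= idx < n:
                values[idx:] = values[idx]
    t_ab = schedule.abandon_time
    if t_ab is not None:
        idx = int(round((t_ab - start) * rate))
        if idx < n:
            reset_value = params.M0 if abandon_reset == "baseline" else 0.0
            values[max(idx, 0):] = reset_value
    return LatentTrace(values, rate=rate, t_start=start)


def build_inverted_trace(trace: LatentTrace) -> LatentTrace:
    """Reflect a latent about its initial value (inverted-sign control).

    The initial value is preserved and every excursion is flipped, so the
    inverted model shares baseline semantics with the direct one.  The
    operation is an involution.
    """
    if len(trace) == 0:
        raise ValueError("cannot invert an empty trace")
    v0 = trace.values[0]
    return LatentTrace(2.0 * v0 - trace.values, rate=trace.rate, t_start=trace.t_start)


_TEST_VOCABULARY: dict[str, dict] = {
    "gain1": dict(require={EventKind.GAIN}, forbid={EventKind.LOSS, EventKind.ABANDON}),
    "gain2": dict(require={EventKind.GAIN}, forbid={EventKind.LOSS, EventKind.ABANDON}),
    "loss1": dict(
        require={EventKind.LOSS},
        forbid={EventKind.GAIN, EventKind.ABANDON, EventKind.ACCESSIBILITY},
    ),
    "loss2": dict(require={EventKind.ABANDON}, forbid={EventKind.LOSS}),
    "loss3": dict(require={EventKind.ABANDON}, forbid={EventKind.LOSS}),
    "multi_gain": dict(require={EventKind.GAIN}, forbid={EventKind.LOSS, EventKind.ABANDON}),
    "multi_gain_loss": dict(
        require={EventKind.GAIN, EventKind.CONSUMPTION_END, EventKind.LOSS},
        forbid={EventKind.ABANDON},
    ),
}


def validate_test_schedule(test_id: str, schedule: EventSchedule) -> None:
    if test_id not in _TEST_VOCABULARY:
        raise ScheduleError(f"unknown test id {test_id!r}; expected one of {TEST_IDS}")
    vocab = _TEST_VOCABULARY[test_id]
    kinds = {e.kind for e in schedule.events}
    missing = vocab["require"] - kinds
    if missing:
        raise ScheduleError(
            f"test {test_id!r} requires event kinds {sorted(k.value for k in missing)}"
        )
    illegal = vocab["forbid"] & kinds
    if illegal:
        raise ScheduleError(
            f"test {test_id!r} forbids event kinds {sorted(k.value for k in illegal)}"
        )


def apply_consumption_delay(schedule: EventSchedule, delay: float) -> EventSchedule:
    """Shift the consumption_end event by ``delay`` seconds (0-8 s grid).

    The measured consumption-end moment can lag the true end of consummatory
    behavior (food remaining in the mouth), so the latent is built with the
    event moved later by the fitted delay.  The shifted time is capped just
    before the next event (consumption cannot outlast the subsequent
    inaccessibility) and before the window end, preserving event order.
    """
    if delay == 0.0:
        return schedule
    if not 0.0 <= delay <= 8.0:
        raise ScheduleError(f"consumption-end delay must lie in [0, 8] s, got {delay}")
    events = list(schedule.events)
    margin = 0.05
    for i, e in enumerate(events):
        if e.kind is EventKind.CONSUMPTION_END:
            t_new = e.time + delay
            if i + 1 < len(events):
                t_new = min(t_new, events[i + 1].time - margin)
            t_new = min(t_new, schedule.trial_window[1] - margin)
            t_new = max(t_new, e.time)
            events[i] = Event(t_new, e.label, e.kind)
    return EventSchedule(events, schedule.trial_window)


def build_test_model(
    test_id: str,
    schedule: EventSchedule,
    model: str,
    need_params: NeedParams,
    motivation_params: MotivationParams | None = None,
    *,
    rate: float = 100.0,
    delay: float = 0.0,
    abandon_reset: Literal["baseline", "zero"] = "baseline",
) -> LatentTrace:
    """Dispatch to the latent builders with test-specific constraints.

    ``model`` is one of ``need``, ``motivation``, ``inverted_need``,
    ``inverted_motivation``.  For motivation-family models the accumulation
    onset defaults to the schedule's accessibility event; a schedule without
    one (predicted-loss test 1) yields a flat motivation trace, since an
    inaccessible target never starts the accumulation.
    """
    if model not in MODEL_NAMES:
        raise ValueError(f"unknown model {model!r}; expected one of {MODEL_NAMES}")
    validate_test_schedule(test_id, schedule)
    if delay != 0.0:
        if test_id != "multi_gain_loss":
            raise ScheduleError("a consumption-end delay applies only to multi_gain_loss")
        schedule = apply_consumption_delay(schedule, delay)
    need = build_need_trace(schedule, need_params, rate=rate)
    if model in ("need", "inverted_need"):
        out = need
    else:
        mp = motivation_params if motivation_params is not None else MotivationParams()
        # accumulation is gated on target accessibility: t0 is the schedule's
        # accessibility moment, and without one the trace stays flat at M0
        mp = MotivationParams(
            M0=mp.M0, a=mp.a, Leak=mp.Leak, t0=schedule.accessibility_time
        )
        out = build_motivation_trace(
            schedule, need, mp, abandon_reset=abandon_reset
        )
    if model.startswith("inverted_"):
        out = build_inverted_trace(out)
    return out
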