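"""Event schedules: the labeled, ordered trial events that drive the latent models.

A trial is described by an :class:`EventSchedule` — a time window plus an
ordered list of labeled events.  Event *kinds* carry the model semantics:

- ``accessibility``: the moment the target becomes reachable; motivation
  starts accumulating here.
- ``gain``: an event signalling a predicted gain (need steps down).
- ``loss``: an event signalling a predicted loss, e.g. the target becoming
  inaccessible (need steps up; motivation accumulation is frozen).
- ``abandon``: voluntary disengagement; both latents reset to baseline.
- ``consumption_end``: completion of the predicted gain (a gain-signed step;
  this is the event an optional consumption-end delay shifts).
- ``trial_start`` / ``trial_end``: structural markers, no model effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

from .errors import ScheduleError

__all__ = [
    "EventKind",
    "Event",
    "EventSchedule",
    "STEP_KINDS",
    "read_event_table",
    "write_event_table",
]


class EventKind(str, Enum):
    ACCESSIBILITY = "accessibility"
    GAIN = "gain"
    LOSS = "loss"
    ABANDON = "abandon"
    CONSUMPTION_END = "consumption_end"
    TRIAL_START = "trial_start"
    TRIAL_END = "trial_end"


#: Kinds that contribute one free step magnitude each to the need model.
#: ``consumption_end`` is gain-signed (it completes a predicted gain);
#: ``abandon`` is a reset, not a step, so it carries no free parameter.
STEP_KINDS = frozenset(
    {EventKind.GAIN, EventKind.LOSS, EventKind.CONSUMPTION_END}
)


@dataclass(frozen=True)
class Event:
    time: float
    label: str
    kind: EventKind

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", EventKind(self.kind))


@dataclass(frozen=True)
class EventSchedule:
    """Ordered labeled event times defining a trial's structure."""

    events: tuple[Event, ...]
    trial_window: tuple[float, float]

    def __init__(
        self,
        events: Iterable[Event | tuple],
        trial_window: tuple[float, float],
    ) -> None:
        evs = tuple(e if isinstance(e, Event) else Event(*e) for e in events)
        object.__setattr__(self, "events", evs)
        object.__setattr__(self, "trial_window", (float(trial_window[0]), float(trial_window[1])))
        self._validate()

    def _validate(self) -> None:
        start, end = self.trial_window
        if not start < end:
            raise ScheduleError(f"trial_window start must precede end, got {self.trial_window}")
        times = [e.time for e in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ScheduleError(f"event times must be strictly increasing, got {times}")
        if any(not (start <= t <= end) for t in times):
            raise ScheduleError(f"event times {times} fall outside trial window {self.trial_window}")
        access = [e for e in self.events if e.kind is EventKind.ACCESSIBILITY]
        if len(access) > 1:
            raise ScheduleError("at most one accessibility event is allowed")
        if access:
            first_gain = next((e.time for e in self.events if e.kind is EventKind.GAIN), None)
            if first_gain is not None and access[0].time > first_gain:
                raise ScheduleError("the accessibility event must precede all gain events")

    # -- queries -------------------------------------------------------------

    def of_kind(self, kind: EventKind) -> tuple[Event, ...]:
        return tuple(e for e in self.events if e.kind is EventKind(kind))

    @property
    def step_events(self) -> tuple[Event, ...]:
        """Events that induce one free step each in the need model."""
        return tuple(e for e in self.events if e.kind in STEP_KINDS)

    @property
    def accessibility_time(self) -> float | None:
        ev = self.of_kind(EventKind.ACCESSIBILITY)
        return ev[0].time if ev else None

    @property
    def abandon_time(self) -> float | None:
        ev = self.of_kind(EventKind.ABANDON)
        return ev[0].time if ev else None

    @property
    def first_loss_time(self) -> float | None:
        ev = self.of_kind(EventKind.LOSS)
        return ev[0].time if ev else None

    # -- transforms ----------------------------------------------------------

    def shift_kind(self, kind: EventKind, delta: float) -> "EventSchedule":
        """Return a schedule with every event of ``kind`` moved by ``delta`` s."""
        kind = EventKind(kind)
        moved = [
            Event(e.time + delta, e.label, e.kind) if e.kind is kind else e
            for e in self.events
        ]
        moved.sort(key=lambda e: e.time)
        return EventSchedule(moved, self.trial_window)

    def shifted(self, delta: float) -> "EventSchedule":
        """Return a schedule with all times (and window) shifted by ``delta``."""
        start, end = self.trial_window
        return EventSchedule(
            [Event(e.time + delta, e.label, e.kind) for e in self.events],
            (start + delta, end + delta),
        )

    def to_frame(self, trial_id: int | str = 0) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial_id": trial_id,
                "event_label": [e.label for e in self.events],
                "event_kind": [e.kind.value for e in self.events],
                "time_s": [e.time for e in self.events],
            }
        )


def write_event_table(
    schedules: Sequence[EventSchedule], path, *, sep: str = ","
) -> None:
    """Write schedules as a tidy event table (trial_id, event_label, event_kind, time_s)."""
    frames = [s.to_frame(i) for i, s in enumerate(schedules)]
    pd.concat(frames, ignore_index=True).to_csv(path, sep=sep, index=False)


def read_event_table(
    path, trial_window: tuple[float, float], *, sep: str = ","
) -> list[EventSchedule]:
    """Read an event table into one :class:`EventSchedule` per trial.

    The table needs columns ``trial_id``, ``event_label``, ``event_kind`` and
    ``time_s`` (seconds, 0 = trial-window start).  The trial window is not
    stored in the table and must be supplied.
    """
    df = pd.read_csv(path, sep=sep)
    required = {"trial_id", "event_label", "event_kind", "time_s"}
    missing = required - set(df.columns)
    if missing:
        raise ScheduleError(f"event table is missing columns: {sorted(missing)}")
    schedules = []
    for _, group in df.groupby("trial_id", sort=True):
        group = group.sort_values("time_s")
        events = [
            Event(row.time_s, row.event_label, EventKind(row.event_kind))
            for row in group.itertuples()
        ]
        schedules.append(EventSchedule(events, trial_window))
    return schedules
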