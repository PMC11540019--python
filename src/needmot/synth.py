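"""Ground-truth-labeled synthetic photometry sessions and behavior rasters.

Every generated artifact follows the package's own forward models, so the
fitting and comparison machinery can be exercised closed-loop: a session is
a set of trials whose latent follows the need or motivation model (or an
inverted-sign control) for one of the behavioral tests, convolved with the
calcium kernel and observed under additive Gaussian noise; a behavior
session draws Bernoulli bins from one of the stimulation models.

Template schedules encode the trial structures of the tests (e.g. a 10-s
initial inaccessibility before the accessibility moment of the multi-gain
tests, 30-40 s trial windows); per-trial event times are jittered with a
truncated Gaussian that preserves event order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np

from .behavior import (
    BehaviorRaster,
    MotivationBehaviorParams,
    NeedBehaviorParams,
    motivation_behavior_model,
    need_behavior_model,
)
from .errors import ScheduleError
from .latent import (
    LatentTrace,
    MODEL_NAMES,
    MotivationParams,
    NeedParams,
    TEST_IDS,
    build_test_model,
)
from .photometry import KernelSpec, PhotometryTrial, make_gcamp_kernel, predict_signal, zscore
from .schedule import Event, EventKind, EventSchedule

__all__ = [
    "SessionSpec",
    "TEMPLATE_SCHEDULES",
    "default_true_params",
    "generate_schedule",
    "generate_photometry_session",
    "generate_behavior_session",
]


def _tmpl(window, events) -> EventSchedule:
    return EventSchedule([Event(t, lbl, EventKind(kind)) for t, lbl, kind in events], window)


#: Template trial structures, one per test.  Times are seconds from the
#: trial-window start; multi-gain tests begin with a 10-s inaccessibility
#: segment before the door opens (the accessibility moment).
TEMPLATE_SCHEDULES: dict[str, EventSchedule] = {
    "gain1": _tmpl((0.0, 20.0), [
        (3.0, "door_removed", "accessibility"),
        (8.0, "seeking_initiation", "gain"),
    ]),
    "gain2": _tmpl((0.0, 20.0), [
        (3.0, "door_removed", "accessibility"),
        (8.0, "food_contact", "gain"),
    ]),
    "loss1": _tmpl((0.0, 20.0), [
        (8.0, "inaccessibility", "loss"),
    ]),
    "loss2": _tmpl((0.0, 25.0), [
        (3.0, "door_removed", "accessibility"),
        (7.0, "eating_initiation", "gain"),
        (14.0, "eating_abandon", "abandon"),
    ]),
    "loss3": _tmpl((0.0, 25.0), [
        (3.0, "food_cue", "accessibility"),
        (7.0, "seeking_initiation", "gain"),
        (14.0, "eating_abandon", "abandon"),
    ]),
    "multi_gain": _tmpl((0.0, 30.0), [
        (10.0, "door_removed", "accessibility"),
        (12.0, "seeking_initiation", "gain"),
        (15.0, "proximate_to_food", "gain"),
        (18.0, "food_contact", "gain"),
    ]),
    "multi_gain_loss": _tmpl((0.0, 40.0), [
        (10.0, "door_removed", "accessibility"),
        (12.0, "seeking_initiation", "gain"),
        (15.0, "proximate_to_food", "gain"),
        (18.0, "food_contact", "gain"),
        (26.0, "consumption_end", "consumption_end"),
        (32.0, "inaccessibility", "loss"),
    ]),
}


def default_true_params(test_id: str) -> dict:
    """Generating parameters used as the study conditions for each test.

    Step magnitudes are in latent units of the same order as the z-scored
    signals they produce (O(1)); the accumulation gain and leak are chosen
    so the motivation latent rises over seconds and declines sharply after
    consumption, matching the qualitative trial structure of the tests.
    """
    if test_id not in TEMPLATE_SCHEDULES:
        raise ScheduleError(f"unknown test id {test_id!r}; expected one of {TEST_IDS}")
    n_steps = len(TEMPLATE_SCHEDULES[test_id].step_events)
    steps = {
        "gain1": (1.5,),
        "gain2": (1.5,),
        "loss1": (-1.5,),
        "loss2": (1.0,),
        "loss3": (1.0,),
        "multi_gain": (0.6, 0.6, 0.8),
        # three gains, a large consumption-end completion, then a loss rebound
        "multi_gain_loss": (0.5, 0.5, 0.5, 2.5, -1.5),
    }[test_id]
    assert len(steps) == n_steps
    return {
        "need": NeedParams(N0=2.0, steps=steps),
        "motivation": MotivationParams(M0=0.0, a=0.25, Leak=0.05, t0=None),
        "offset": 0.0,
    }


@dataclass(frozen=True)
class SessionSpec:
    """Recipe for one synthetic photometry session."""

    test_id: str
    n_trials: int = 15
    generating_model: str = "need"
    true_params: Mapping | None = None
    event_jitter_sd: float = 0.5
    noise_sd: float = 0.3
    kernel: KernelSpec = field(default_factory=KernelSpec)
    seed: int = 0
    rate: float = 100.0
    zscore: bool = True
    delay: float = 0.0
    ar1: float = 0.0  # optional AR(1) noise autocorrelation, 0 = white

    def __post_init__(self) -> None:
        if self.test_id not in TEMPLATE_SCHEDULES:
            raise ScheduleError(f"unknown test id {self.test_id!r}")
        if self.generating_model not in MODEL_NAMES:
            raise ValueError(f"unknown generating model {self.generating_model!r}")
        if self.n_trials < 1 or self.noise_sd < 0 or self.event_jitter_sd < 0:
            raise ValueError("n_trials >= 1 and non-negative noise/jitter required")


def generate_schedule(
    test_id: str,
    n_trials: int,
    jitter_sd: float,
    seed: int,
    *,
    min_start_gap: float = 1.0,
    min_separation: float = 0.5,
) -> list[EventSchedule]:
    """Per-trial schedules: template event times with seeded Gaussian jitter.

    Draws are resampled until events stay ordered (with ``min_separation``
    seconds between consecutive events), keep their distance from the window
    edges, and any accessibility event still precedes all gains.
    """
    template = TEMPLATE_SCHEDULES.get(test_id)
    if template is None:
        raise ScheduleError(f"unknown test id {test_id!r}")
    rng = np.random.default_rng(seed)
    start, end = template.trial_window
    base_times = np.array([e.time for e in template.events])
    schedules: list[EventSchedule] = []
    for _ in range(n_trials):
        for _attempt in range(1000):
            times = base_times + rng.normal(0.0, jitter_sd, size=base_times.size)
            if times.size and times[0] < start + min_start_gap:
                continue
            if times.size and times[-1] > end - min_start_gap:
                continue
            if np.any(np.diff(times) < min_separation):
                continue
            break
        else:
            raise ScheduleError("could not draw an ordered jittered schedule")
        events = [
            Event(t, e.label, e.kind) for t, e in zip(times, template.events)
        ]
        schedules.append(EventSchedule(events, template.trial_window))
    return schedules


@dataclass(frozen=True)
class SessionTruth:
    """Ground-truth bundle accompanying a generated session."""

    spec: SessionSpec
    schedules: tuple[EventSchedule, ...]
    latents: tuple[LatentTrace, ...]
    need_params: NeedParams
    motivation_params: MotivationParams
    offset: float


def generate_photometry_session(
    spec: SessionSpec,
) -> tuple[list[PhotometryTrial], SessionTruth]:
    """Generate one session of photometry trials plus its ground truth.

    For each trial the true latent is built from the jittered schedule,
    convolved with the calcium kernel (mean-padded boundary), shifted by the
    true offset, and observed under additive Gaussian noise; trials are then
    z-scored unless the spec disables it (parameter-recovery harnesses keep
    raw units so fitted magnitudes are directly comparable to the truth).
    """
    rng = np.random.default_rng(spec.seed)
    params = dict(spec.true_params) if spec.true_params else default_true_params(spec.test_id)
    need_params: NeedParams = params["need"]
    mot_params: MotivationParams = params.get("motivation", MotivationParams())
    offset: float = params.get("offset", 0.0)
    schedules = generate_schedule(
        spec.test_id, spec.n_trials, spec.event_jitter_sd, seed=spec.seed
    )
    kernel = make_gcamp_kernel(spec.kernel)
    trials: list[PhotometryTrial] = []
    latents: list[LatentTrace] = []
    for schedule in schedules:
        latent = build_test_model(
            spec.test_id,
            schedule,
            spec.generating_model,
            need_params,
            mot_params,
            rate=spec.rate,
            delay=spec.delay,
        )
        clean = predict_signal(latent, kernel, offset, "pad_mean", rate=spec.rate)
        noise = rng.normal(0.0, spec.noise_sd, size=clean.size)
        if spec.ar1 > 0.0:
            for i in range(1, noise.size):
                noise[i] += spec.ar1 * noise[i - 1]
            noise *= np.sqrt(1.0 - spec.ar1**2)
        values = clean + noise
        if spec.zscore:
            values = zscore(values)
        trials.append(
            PhotometryTrial(
                values=values,
                rate=spec.rate,
                schedule=schedule,
                t_align=0.0,
                zscored=spec.zscore,
            )
        )
        latents.append(latent)
    truth = SessionTruth(
        spec=spec,
        schedules=tuple(schedules),
        latents=tuple(latents),
        need_params=need_params,
        motivation_params=mot_params,
        offset=offset,
    )
    return trials, truth


def generate_behavior_session(
    model: Literal["need", "motivation"],
    params: NeedBehaviorParams | MotivationBehaviorParams,
    n_trials: int,
    *,
    stim_window: tuple[float, float] = (5.0, 15.0),
    bin_s: float = 0.1,
    total_s: float = 35.0,
    seed: int = 0,
) -> BehaviorRaster:
    """Draw Bernoulli behavior bins from one of the stimulation models."""
    t_on, t_off = stim_window
    n_bins = int(round(total_s / bin_s))
    t_grid = (np.arange(n_bins) + 0.5) * bin_s
    if model == "need":
        curve = need_behavior_model(params, t_grid, t_on, t_off)
    elif model == "motivation":
        curve = motivation_behavior_model(params, t_grid, t_on, t_off)
    else:
        raise ValueError("model must be 'need' or 'motivation'")
    rng = np.random.default_rng(seed)
    trials = (rng.random((n_trials, n_bins)) < curve).astype(float)
    return BehaviorRaster(trials=trials, bin_s=bin_s, t_on=t_on, t_off=t_off)
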