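"""Agent-based go/no-go foraging simulation: direct need vs. accumulated need.

A single agent on a 1-D track decides each time step whether to move toward
food (``go``) or stay (``stop``).  Its homeostatic deficit projects into a
normalized sum of discounted deficit (SDD); predicted-gain information
compensates most of that projection, leaving a residual fraction ``e`` while
the prediction is active.  Two policies are compared:

- **direct need**: act whenever the instantaneous need exceeds a threshold.
  Under the "prediction changes when the agent stops" condition the
  predicted gain is tied to the agent's own motion, so moving collapses the
  need below threshold and stopping restores it — the policy dithers and
  food acquisition is delayed.
- **accumulated need (motivation)**: integrate need (gain ``a``, constant
  ``leak``) from the moment food is accessible and act when the accumulated
  motivation exceeds the threshold; once moving, motivation keeps
  accumulating and the approach is sustained.

Action switches respect dwell-time holds (at least 50 steps in stop, 10 in
go after a switch); deficit, need and motivation are floored at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AgentParams",
    "AgentTrajectory",
    "sdd",
    "compute_need",
    "step_agent",
    "run_simulation",
    "parameter_sweep",
    "POLICIES",
    "CONDITIONS",
]

POLICIES = ("direct_need", "accumulated_need")
CONDITIONS = (
    "pred_changes_on_stop",
    "pred_independent",
    "always_accessible",
    "with_inaccessible",
)
DEFICIT_MODES = ("ID", "NID")

#: with_inaccessible deficit schedule: zero deficit, then a linear rise to 1.
_FREEZE_STEPS = 100
_RISE_STEPS = 500


@dataclass(frozen=True)
class AgentParams:
    """Simulation parameters.

    ``e`` is the residual fraction of the discounted deficit left
    uncompensated while a predicted gain is active (an active prediction
    cancels the fraction ``1 - e`` of the projected deficit).  ``horizon``
    of ``None`` means the infinite-horizon geometric projection.
    """

    gamma: float = 0.99
    e: float = 0.1
    a: float = 0.0015
    leak: float = 0.001
    threshold: float = 0.5
    hold_stop: int = 50
    hold_go: int = 10
    deficit_increment: float = 1e-5
    eat_rate: float = 0.012
    horizon: int | None = None
    nid_noise: float = 0.001

    def __post_init__(self) -> None:
        if not 0.0 < self.gamma < 1.0:
            raise ValueError("gamma must lie in (0, 1)")
        for name in ("e", "a", "leak", "deficit_increment", "eat_rate", "nid_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @classmethod
    def defaults(cls, deficit_mode: str = "ID", **overrides) -> "AgentParams":
        """Stated defaults; the NID condition uses a smaller leak (0.0008)."""
        if deficit_mode == "NID" and "leak" not in overrides:
            overrides["leak"] = 0.0008
        return cls(**overrides)


def sdd(
    deficit: float,
    gamma: float,
    horizon: int | None = None,
    *,
    normalized: bool = True,
) -> float:
    """Sum of discounted deficit under a constant-deficit projection.

    ``sum_{k=0}^{horizon} gamma^k * deficit``; with ``normalized`` the sum is
    multiplied by (1 - gamma) so an infinite-horizon constant deficit d maps
    to exactly d, making magnitudes comparable to the action threshold.
    """
    if deficit < 0:
        raise ValueError("deficit must be non-negative")
    if horizon is None:
        if gamma >= 1.0:
            raise ValueError("infinite horizon requires gamma < 1")
        total = deficit / (1.0 - gamma)
    else:
        total = deficit * (1.0 - gamma ** (horizon + 1)) / (1.0 - gamma)
    return total * (1.0 - gamma) if normalized else total


def compute_need(
    deficit: float, prediction_active: bool, params: AgentParams
) -> float:
    """Need = residual normalized SDD after predicted-gain compensation.

    An active predicted gain compensates the fraction ``1 - e`` of the
    projected deficit, so need drops to ``e * SDD``; with no active
    prediction the full projection remains.  Floored at zero.
    """
    s = sdd(deficit, params.gamma, params.horizon, normalized=True)
    if prediction_active:
        s *= params.e
    return max(s, 0.0)


@dataclass
class AgentState:
    t: int = 0
    deficit: float = 0.0
    need: float = 0.0
    motivation: float = 0.0
    action: str = "stop"
    position: int = 0
    steps_in_action: int = 10**9  # free to switch at t = 0
    state: str = "accessible"
    eaten: bool = False


@dataclass(frozen=True)
class AgentTrajectory:
    """Per-step record of one simulated foraging episode."""

    t: np.ndarray
    deficit: np.ndarray
    sdd: np.ndarray
    need: np.ndarray
    motivation: np.ndarray
    action: np.ndarray  # "go"/"stop"
    position: np.ndarray
    state: np.ndarray
    acquisition_time: int | None
    policy: str
    condition: str
    deficit_mode: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "deficit": self.deficit,
                "sdd": self.sdd,
                "need": self.need,
                "motivation": self.motivation,
                "action": self.action,
                "position": self.position,
                "state": self.state,
            }
        )

    @property
    def n_go_bouts(self) -> int:
        go = self.action == "go"
        return int(np.sum(go[1:] & ~go[:-1]) + int(go[0]))

    @property
    def total_go_steps(self) -> int:
        return int(np.sum(self.action == "go"))


def _accessible(condition: str, t: int) -> bool:
    if condition == "with_inaccessible":
        return not (_FREEZE_STEPS <= t < _FREEZE_STEPS + _RISE_STEPS)
    return True


def _update_deficit(
    deficit: float,
    t: int,
    condition: str,
    deficit_mode: str,
    eating: bool,
    params: AgentParams,
    rng: np.random.Generator,
) -> float:
    if eating:
        return max(deficit - params.eat_rate, 0.0)
    if condition == "with_inaccessible" and t < _FREEZE_STEPS + _RISE_STEPS and not eating:
        # environment-imposed schedule dominates until food access
        if t < _FREEZE_STEPS:
            return 0.0
        return min((t - _FREEZE_STEPS + 1) / _RISE_STEPS, 1.0)
    if deficit_mode == "ID":
        return deficit + params.deficit_increment
    if deficit_mode == "NID":
        return max(deficit + rng.uniform(-params.nid_noise, params.nid_noise), 0.0)
    raise ValueError(f"unknown deficit mode {deficit_mode!r}")


def _prediction_active(
    policy: str, condition: str, action: str, accessible: bool
) -> bool:
    if not accessible:
        return False
    if policy == "direct_need":
        if condition == "pred_changes_on_stop":
            return action == "go"
        # prediction independent of the agent's motion
        return True
    # accumulated-need policy: the predicted gain is consumed by the
    # accumulation process itself (integration is gated on accessibility),
    # not subtracted from the instantaneous need signal.
    return False


def step_agent(
    state: AgentState,
    params: AgentParams,
    policy: str,
    condition: str,
    deficit_mode: str,
    food_distance: int,
    rng: np.random.Generator,
) -> AgentState:
    """Advance the agent by one time step; returns the new state."""
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}")
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    t = state.t
    accessible = _accessible(condition, t)
    eating = state.eaten and state.deficit > 0.0 and accessible
    deficit = _update_deficit(
        state.deficit, t, condition, deficit_mode, eating, params, rng
    )
    active = _prediction_active(policy, condition, state.action, accessible)
    need = compute_need(deficit, active, params)
    if accessible:
        motivation = max(state.motivation + params.a * need - params.leak, 0.0)
    else:
        motivation = state.motivation  # a blocked target freezes accumulation
    drive = need if policy == "direct_need" else motivation
    desired = "go" if drive > params.threshold else "stop"
    action = state.action
    steps_in_action = state.steps_in_action + 1
    if desired != action:
        hold = params.hold_stop if action == "stop" else params.hold_go
        if state.steps_in_action >= hold:
            action = desired
            steps_in_action = 1
    position = state.position
    eaten = state.eaten
    if eating:
        env = "eating"
    else:
        if action == "go" and accessible and not eaten:
            position = min(position + 1, food_distance)
            if position >= food_distance:
                eaten = True
        env = "accessible" if accessible else "inaccessible"
    return AgentState(
        t=t + 1,
        deficit=deficit,
        need=need,
        motivation=motivation,
        action=action,
        position=position,
        steps_in_action=steps_in_action,
        state=env,
        eaten=eaten,
    )


def run_simulation(
    policy: str,
    condition: str,
    deficit_mode: str = "ID",
    params: AgentParams | None = None,
    *,
    food_distance: int = 300,
    n_steps: int = 5000,
    seed: int = 0,
) -> AgentTrajectory:
    """Run one episode and record the full trajectory.

    ``acquisition_time`` is the first step at which the agent's position
    reaches the food while it is accessible.  Under ``with_inaccessible``
    the episode is extended to track 1000 steps past the first consumption.
    """
    if params is None:
        params = AgentParams.defaults(deficit_mode)
    rng = np.random.default_rng(seed)
    state = AgentState(
        deficit=0.0 if condition == "with_inaccessible" else 1.0,
        steps_in_action=max(params.hold_stop, params.hold_go),
    )
    rec: list[AgentState] = []
    acquisition: int | None = None
    t = 0
    while True:
        state = step_agent(
            state, params, policy, condition, deficit_mode, food_distance, rng
        )
        rec.append(state)
        if acquisition is None and state.eaten:
            acquisition = state.t
        t = state.t
        if condition == "with_inaccessible" and acquisition is not None:
            if t >= acquisition + 1000:
                break
            continue
        if t >= n_steps:
            break
        if t > 10 * n_steps:  # safety net
            break
    return AgentTrajectory(
        t=np.array([s.t for s in rec]),
        deficit=np.array([s.deficit for s in rec]),
        sdd=np.array(
            [sdd(s.deficit, params.gamma, params.horizon, normalized=True) for s in rec]
        ),
        need=np.array([s.need for s in rec]),
        motivation=np.array([s.motivation for s in rec]),
        action=np.array([s.action for s in rec]),
        position=np.array([s.position for s in rec]),
        state=np.array([s.state for s in rec]),
        acquisition_time=acquisition,
        policy=policy,
        condition=condition,
        deficit_mode=deficit_mode,
    )


def parameter_sweep(
    thresholds: Sequence[float],
    a_values: Sequence[float],
    gammas: Sequence[float],
    policies: Sequence[str] = POLICIES,
    conditions: Sequence[str] = ("pred_changes_on_stop", "always_accessible"),
    *,
    deficit_mode: str = "ID",
    food_distance: int = 300,
    n_steps: int = 5000,
    seed: int = 0,
    base_params: AgentParams | None = None,
) -> pd.DataFrame:
    """Grid sweep over threshold, accumulation gain and discount factor.

    Returns one row per (policy, condition, threshold, a, gamma) cell with
    the acquisition time, number of go bouts and total go steps; rows are
    deterministic given the seed.
    """
    base = base_params or AgentParams.defaults(deficit_mode)
    rows = []
    for policy in policies:
        for condition in conditions:
            for thr in thresholds:
                for a in a_values:
                    for gamma in gammas:
                        params = replace(base, threshold=thr, a=a, gamma=gamma)
                        traj = run_simulation(
                            policy,
                            condition,
                            deficit_mode,
                            params,
                            food_distance=food_distance,
                            n_steps=n_steps,
                            seed=seed,
                        )
                        rows.append(
                            {
                                "policy": policy,
                                "condition": condition,
                                "threshold": thr,
                                "a": a,
                                "gamma": gamma,
                                "acquisition_time": traj.acquisition_time,
                                "n_go_bouts": traj.n_go_bouts,
                                "total_go_steps": traj.total_go_steps,
                            }
                        )
    return pd.DataFrame(rows)
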