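"""Optogenetic behavior-probability models and their raster preprocessing.

Stimulating need-encoding neurons drives behavior through accumulation: the
probability ramps up during the stimulus, saturates at 1, and decays only
slowly after stimulus offset (persistent behavior).  Stimulating
motivation-encoding neurons produces a delayed boxcar: probability jumps by
``A_stim`` for the stimulation window and returns to baseline immediately
after (time-locked behavior).  Both curves are clipped to [0, 1].

Rasters are binary behavior annotations in fixed-width bins (default 0.1 s);
they are averaged across trials, normalized, and smoothed with a centered
moving average before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterShapeError
from .fitting import FitResult, fit_model

__all__ = [
    "BehaviorRaster",
    "NeedBehaviorParams",
    "MotivationBehaviorParams",
    "raster_to_probability",
    "need_behavior_model",
    "motivation_behavior_model",
    "BehaviorModelBuilder",
    "make_behavior_builder",
    "fit_behavior",
    "persistence_bins",
]


@dataclass(frozen=True)
class BehaviorRaster:
    """Binary behavior bins per trial, with the stimulation window."""

    trials: np.ndarray  # (n_trials, n_bins) of 0/1
    bin_s: float = 0.1
    t_on: float = 5.0
    t_off: float = 15.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.trials, dtype=float)
        if arr.ndim != 2 or arr.size == 0:
            raise ParameterShapeError("raster must be a non-empty (trials x bins) array")
        if not np.isin(arr, (0.0, 1.0)).all():
            raise ParameterShapeError("raster bins must be 0 or 1")
        if not self.t_on < self.t_off:
            raise ParameterShapeError("t_on must precede t_off")
        object.__setattr__(self, "trials", arr)

    @property
    def n_bins(self) -> int:
        return self.trials.shape[1]

    @property
    def bin_centers(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.bin_s

    def to_frame(self) -> pd.DataFrame:
        n_trials, n_bins = self.trials.shape
        return pd.DataFrame(
            {
                "trial_id": np.repeat(np.arange(n_trials), n_bins),
                "bin_index": np.tile(np.arange(n_bins), n_trials),
                "value": self.trials.reshape(-1).astype(int),
            }
        )


@dataclass(frozen=True)
class NeedBehaviorParams:
    """Accumulation (need-activation) behavior model parameters.

    The post-offset decay rate is capped at one quarter of the on-stimulus
    rise rate (``Leaky <= A / 4``), reflecting the slow washout of the
    accumulated drive.
    """

    BN0: float
    A: float
    Leaky: float
    t_delay: float = 0.0
    gen_threshold: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.BN0 <= 1.0:
            raise ParameterShapeError("BN0 must lie in [0, 1]")
        if self.A < 0 or self.Leaky < 0 or self.t_delay < 0:
            raise ParameterShapeError("A, Leaky and t_delay must be non-negative")
        if self.Leaky > self.A / 4.0 + 1e-12:
            raise ParameterShapeError(
                f"Leaky={self.Leaky} exceeds A/4={self.A / 4.0}: the decay rate "
                "may not exceed one quarter of the rise rate"
            )
        if not 0.0 <= self.gen_threshold <= 1.0:
            raise ParameterShapeError("gen_threshold must lie in [0, 1]")


@dataclass(frozen=True)
class MotivationBehaviorParams:
    """Boxcar (motivation-activation) behavior model parameters."""

    BM0: float
    A_stim: float
    t_delay: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.BM0 <= 1.0:
            raise ParameterShapeError("BM0 must lie in [0, 1]")
        if self.A_stim < 0 or self.t_delay < 0:
            raise ParameterShapeError("A_stim and t_delay must be non-negative")


def raster_to_probability(raster: BehaviorRaster, smooth_bins: int = 10) -> np.ndarray:
    """Per-bin mean across trials, normalized to [0, 1], then moving-averaged.

    Normalization only rescales when the mean exceeds 1 (a no-op for a
    well-formed binary raster).  Smoothing uses a centered window that
    shrinks at the edges, so no padding values leak in.
    """
    if smooth_bins < 1:
        raise ParameterShapeError("smooth_bins must be >= 1")
    p = raster.trials.mean(axis=0)
    if p.max() > 1.0:
        p = p / p.max()
    half_lo = (smooth_bins - 1) // 2
    half_hi = smooth_bins // 2
    cumsum = np.concatenate([[0.0], np.cumsum(p)])
    n = p.size
    lo = np.maximum(np.arange(n) - half_lo, 0)
    hi = np.minimum(np.arange(n) + half_hi + 1, n)
    return (cumsum[hi] - cumsum[lo]) / (hi - lo)


def need_behavior_model(
    params: NeedBehaviorParams,
    t_grid: np.ndarray,
    t_on: float,
    t_off: float,
    *,
    decay_anchor: Literal["on", "off"] = "on",
) -> np.ndarray:
    """Piecewise accumulation curve: baseline, ramp, leaky decay; clipped to [0, 1].

    As printed, the decay branch is anchored at the stimulus onset,
    ``BN0 + A*(t_off - t_on) - Leaky*(t - t_on)``, which is discontinuous at
    the offset boundary whenever ``Leaky > 0``; ``decay_anchor='off'``
    selects a continuity-preserving variant anchored at the offset.
    Values below ``gen_threshold`` are reported as 0 (no generated behavior).
    """
    t = np.asarray(t_grid, dtype=float)
    if not t_on < t_off:
        raise ParameterShapeError("t_on must precede t_off")
    d = params.t_delay
    out = np.full(t.shape, params.BN0, dtype=float)
    rising = (t >= t_on + d) & (t < t_off + d)
    out[rising] = params.BN0 + params.A * (t[rising] - t_on)
    after = t >= t_off + d
    anchor = t_on if decay_anchor == "on" else t_off
    out[after] = (
        params.BN0
        + params.A * (t_off - t_on)
        - params.Leaky * (t[after] - anchor)
    )
    np.clip(out, 0.0, 1.0, out=out)
    if params.gen_threshold > 0.0:
        out[out < params.gen_threshold] = 0.0
    return out


def motivation_behavior_model(
    params: MotivationBehaviorParams,
    t_grid: np.ndarray,
    t_on: float,
    t_off: float,
) -> np.ndarray:
    """Delayed boxcar of height ``A_stim`` over the stimulation window, clipped."""
    t = np.asarray(t_grid, dtype=float)
    if not t_on < t_off:
        raise ParameterShapeError("t_on must precede t_off")
    d = params.t_delay
    out = np.full(t.shape, params.BM0, dtype=float)
    stim = (t >= t_on + d) & (t < t_off + d)
    out[stim] = params.BM0 + params.A_stim
    return np.clip(out, 0.0, 1.0)


@dataclass(frozen=True)
class BehaviorModelBuilder:
    """Adapter exposing a behavior model to the generic multi-start fitter.

    For the need model the leak is fit as a fraction of its cap,
    ``Leaky = leak_frac * A / 4``, so every point within the [0, 1] bounds
    respects the rate-ratio constraint.
    """

    model_name: str
    t_grid: np.ndarray
    t_on: float
    t_off: float
    decay_anchor: str = "on"

    @property
    def param_names(self) -> tuple[str, ...]:
        if self.model_name == "need":
            return ("BN0", "A", "leak_frac", "t_delay", "gen_threshold")
        return ("BM0", "A_stim", "t_delay")

    @property
    def bounds(self) -> tuple[tuple[float, float], ...]:
        return tuple((0.0, 1.0) for _ in self.param_names)

    def predict(self, theta: np.ndarray) -> np.ndarray:
        if self.model_name == "need":
            BN0, A, leak_frac, t_delay, thr = (float(v) for v in theta)
            params = NeedBehaviorParams(
                BN0=BN0, A=A, Leaky=leak_frac * A / 4.0,
                t_delay=t_delay, gen_threshold=thr,
            )
            return need_behavior_model(
                params, self.t_grid, self.t_on, self.t_off,
                decay_anchor=self.decay_anchor,
            )
        BM0, A_stim, t_delay = (float(v) for v in theta)
        params = MotivationBehaviorParams(BM0=BM0, A_stim=A_stim, t_delay=t_delay)
        return motivation_behavior_model(params, self.t_grid, self.t_on, self.t_off)


def make_behavior_builder(
    model: Literal["need", "motivation"],
    t_grid: np.ndarray,
    t_on: float,
    t_off: float,
    *,
    decay_anchor: Literal["on", "off"] = "on",
) -> BehaviorModelBuilder:
    if model not in ("need", "motivation"):
        raise ValueError("model must be 'need' or 'motivation'")
    return BehaviorModelBuilder(
        model_name=model,
        t_grid=np.asarray(t_grid, dtype=float),
        t_on=t_on,
        t_off=t_off,
        decay_anchor=decay_anchor,
    )


def fit_behavior(
    prob: np.ndarray,
    t_grid: np.ndarray,
    t_on: float,
    t_off: float,
    model: Literal["need", "motivation"],
    *,
    n_starts: int = 30,
    seed: int = 0,
    decay_anchor: Literal["on", "off"] = "on",
) -> FitResult:
    """Multi-start bounded fit of one behavior model to a probability curve."""
    prob = np.asarray(prob, dtype=float)
    if prob.min() < -1e-9 or prob.max() > 1.0 + 1e-9:
        raise ParameterShapeError("behavior probabilities must lie in [0, 1]")
    builder = make_behavior_builder(model, t_grid, t_on, t_off, decay_anchor=decay_anchor)
    return fit_model(prob, builder, n_starts=n_starts, seed=seed)


def persistence_bins(
    prob: np.ndarray,
    t_grid: np.ndarray,
    t_off: float,
    t_delay: float,
    threshold: float,
    bin_s: float,
) -> int:
    """Number of consecutive bins the curve stays above ``threshold`` past t_off + t_delay."""
    t = np.asarray(t_grid, dtype=float)
    after = t >= t_off + t_delay - 1e-9
    vals = np.asarray(prob, dtype=float)[after]
    above = vals > threshold
    if not above.any():
        return 0
    below = np.flatnonzero(~above)
    return int(below[0]) if below.size else int(above.size)
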