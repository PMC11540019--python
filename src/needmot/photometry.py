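"""Forward model from latent traces to photometry, and trial preprocessing.

A latent trace is convolved with a calcium-indicator impulse response (a
double-exponential GCaMP6s kernel) and shifted by a free offset to predict a
z-scored fluorescence signal.  Raw trials are aligned to a named event,
cropped, resampled to a common 100 samples/s grid and z-scored before any
model fitting or trial averaging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy.signal import fftconvolve

from .errors import AlignmentError, WindowError
from .schedule import Event, EventKind, EventSchedule

__all__ = [
    "KernelSpec",
    "PhotometryTrial",
    "RawTrial",
    "make_gcamp_kernel",
    "predict_signal",
    "preprocess_trials",
    "average_trials",
    "zscore",
]

#: Samples prepended before trial start in ``pad_mean`` boundary handling.
PAD_SAMPLES = 125
#: Number of post-start samples averaged to form the pad value.
PAD_BASIS_SAMPLES = 50


@dataclass(frozen=True)
class KernelSpec:
    """Double-exponential calcium kernel, k(t) = c*(1-exp(-t/tau_rise))*exp(-t/tau_decay).

    Defaults follow published GCaMP6s kinetics (slow indicator: ~0.2 s rise,
    ~2.6 s half-decay scale), truncated at 10 s and normalized to unit peak.
    """

    tau_rise: float = 0.2
    tau_decay: float = 2.6
    duration: float = 10.0
    rate: float = 100.0
    peak_amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.tau_rise <= 0:
            raise ValueError("tau_rise must be positive")
        if self.tau_decay <= self.tau_rise:
            raise ValueError("tau_decay must exceed tau_rise")
        if self.duration <= 0 or self.rate <= 0 or self.peak_amplitude <= 0:
            raise ValueError("duration, rate and peak_amplitude must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.rate))

    @property
    def peak_time(self) -> float:
        """Analytic peak location: tau_rise * ln(1 + tau_decay/tau_rise)."""
        return self.tau_rise * np.log1p(self.tau_decay / self.tau_rise)


def make_gcamp_kernel(spec: KernelSpec) -> np.ndarray:
    t = np.arange(spec.n_samples) / spec.rate
    k = (1.0 - np.exp(-t / spec.tau_rise)) * np.exp(-t / spec.tau_decay)
    peak = k.max()
    if peak <= 0:
        raise ValueError("kernel is degenerate; increase duration or rate")
    return k * (spec.peak_amplitude / peak)


def predict_signal(
    latent,
    kernel: np.ndarray,
    offset: float = 0.0,
    mode: Literal["pad_mean", "crop_last5s"] = "pad_mean",
    *,
    rate: float | None = None,
    crop_s: float = 5.0,
) -> np.ndarray:
    """Predict a photometry signal from a latent trace.

    The discrete convolution is scaled by the sample interval so the output
    approximates the continuous integral and is rate-independent.

    - ``pad_mean`` prepends ``PAD_SAMPLES`` samples equal to the mean of the
      first ``PAD_BASIS_SAMPLES`` post-start samples, so the kernel sees a
      plausible pre-trial history instead of zeros.
    - ``crop_last5s`` convolves with a zero history and then discards the
      first ``crop_s`` seconds of output (used where the trial begins with a
      long inaccessibility segment whose onset transient is not analyzed).
    """
    values = np.asarray(getattr(latent, "values", latent), dtype=float)
    if rate is None:
        rate = float(getattr(latent, "rate", 100.0))
    kernel = np.asarray(kernel, dtype=float)
    if values.size < kernel.size:
        raise WindowError(
            f"latent ({values.size} samples) is shorter than the kernel ({kernel.size})"
        )
    dt = 1.0 / rate
    if mode == "pad_mean":
        pad_value = values[:PAD_BASIS_SAMPLES].mean()
        padded = np.concatenate([np.full(PAD_SAMPLES, pad_value), values])
        full = fftconvolve(padded, kernel)[: padded.size] * dt
        out = full[PAD_SAMPLES:]
    elif mode == "crop_last5s":
        full = fftconvolve(values, kernel)[: values.size] * dt
        out = full[int(round(crop_s * rate)):]
    else:
        raise ValueError(f"unknown boundary mode {mode!r}")
    return out + offset


def zscore(values: np.ndarray) -> np.ndarray:
    """Z-score a series; a zero-variance input maps to zeros with a warning."""
    values = np.asarray(values, dtype=float)
    sd = values.std()
    scale = np.abs(values).max(initial=0.0) + 1.0
    if sd <= 1e-12 * scale or not np.isfinite(sd):
        warnings.warn("zero-variance trace: z-score is degenerate, returning zeros")
        return np.zeros_like(values)
    return (values - values.mean()) / sd


@dataclass(frozen=True)
class PhotometryTrial:
    """One observed (or synthetic) trial on a uniform grid.

    ``t_align`` is the time of the alignment event on the trial's own clock
    (0 after preprocessing); ``schedule`` carries the trial's events on the
    same clock as ``values``.
    """

    values: np.ndarray
    rate: float
    schedule: EventSchedule
    t_align: float = 0.0
    zscored: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trial values must be finite")
        if self.rate <= 0:
            raise ValueError("rate must be positive")

    def __len__(self) -> int:
        return self.values.size

    @property
    def t_start(self) -> float:
        return self.schedule.trial_window[0]

    @property
    def times(self) -> np.ndarray:
        return self.t_start + np.arange(self.values.size) / self.rate


@dataclass(frozen=True)
class RawTrial:
    """An unprocessed recording: sample times, values and the trial's events."""

    times: np.ndarray
    values: np.ndarray
    schedule: EventSchedule

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.times.shape != self.values.shape:
            raise AlignmentError("times and values must have equal length")


def preprocess_trials(
    raw_trials: Sequence[RawTrial],
    align_label: str,
    window: tuple[float, float],
    *,
    rate: float = 100.0,
) -> list[PhotometryTrial]:
    """Align, crop, resample to ``rate`` (linear interpolation) and z-score.

    Each trial is shifted so that t = 0 at its ``align_label`` event, cropped
    to ``window`` (seconds relative to the event), resampled onto a uniform
    grid and z-scored over the window.
    """
    t_lo, t_hi = window
    if not t_lo < t_hi:
        raise WindowError(f"invalid window {window}")
    out: list[PhotometryTrial] = []
    n = int(round((t_hi - t_lo) * rate))
    grid = t_lo + np.arange(n) / rate
    for raw in raw_trials:
        match = [e for e in raw.schedule.events if e.label == align_label]
        if not match:
            raise AlignmentError(f"trial has no event labeled {align_label!r}")
        t_event = match[0].time
        rel = raw.times - t_event
        if rel[0] > t_lo + 1e-9 or rel[-1] < t_hi - 1e-9 - 1.0 / rate:
            raise WindowError(
                f"window {window} exceeds the recording span "
                f"[{rel[0]:.3f}, {rel[-1]:.3f}] around {align_label!r}"
            )
        resampled = np.interp(grid, rel, raw.values)
        shifted = raw.schedule.shifted(-t_event)
        events = [e for e in shifted.events if t_lo <= e.time <= t_hi]
        schedule = EventSchedule(events, (t_lo, t_hi))
        out.append(
            PhotometryTrial(
                values=zscore(resampled),
                rate=rate,
                schedule=schedule,
                t_align=0.0,
                zscored=True,
            )
        )
    return out


def average_trials(trials: Sequence[PhotometryTrial]) -> PhotometryTrial:
    """Pointwise mean across trials; the schedule carries consensus event times.

    Consensus events are the mean time per (label, kind) pair across trials.
    """
    if not trials:
        raise AlignmentError("cannot average an empty trial list")
    first = trials[0]
    for t in trials[1:]:
        if len(t) != len(first) or t.rate != first.rate:
            raise AlignmentError("trials must share length and rate to be averaged")
        if t.schedule.trial_window != first.schedule.trial_window:
            raise AlignmentError("trials must share the trial window to be averaged")
    mean_values = np.mean([t.values for t in trials], axis=0)
    groups: dict[tuple[str, EventKind], list[float]] = {}
    order: list[tuple[str, EventKind]] = []
    for t in trials:
        for e in t.schedule.events:
            key = (e.label, e.kind)
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append(e.time)
    events = sorted(
        (Event(float(np.mean(groups[key])), key[0], key[1]) for key in order),
        key=lambda e: e.time,
    )
    schedule = EventSchedule(events, first.schedule.trial_window)
    return PhotometryTrial(
        values=mean_values,
        rate=first.rate,
        schedule=schedule,
        t_align=first.t_align,
        zscored=all(t.zscored for t in trials),
    )
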