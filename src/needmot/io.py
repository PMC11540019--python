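"""Plain-text and array-container I/O for traces, rasters and fit results."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .behavior import BehaviorRaster
from .fitting import FitResult
from .photometry import PhotometryTrial
from .schedule import EventSchedule

__all__ = [
    "save_trace_csv",
    "load_trace_csv",
    "save_trials_npz",
    "load_trials_npz",
    "save_raster_csv",
    "load_raster_csv",
    "fit_result_to_dict",
    "save_fit_json",
]


def save_trace_csv(path, values: np.ndarray, rate: float, t_start: float = 0.0) -> None:
    t = t_start + np.arange(np.asarray(values).size) / rate
    pd.DataFrame({"time_s": t, "value": values}).to_csv(path, index=False)


def load_trace_csv(path) -> tuple[np.ndarray, float, float]:
    """Returns (values, rate, t_start); the rate is inferred from the time column."""
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    dt = np.median(np.diff(t)) if t.size > 1 else 0.01
    return df["value"].to_numpy(), float(1.0 / dt), float(t[0])


def save_trials_npz(path, trials: Sequence[PhotometryTrial]) -> None:
    """Binary array container: one values array per trial plus rate metadata."""
    arrays = {f"trial_{i}": t.values for i, t in enumerate(trials)}
    arrays["rate"] = np.array([trials[0].rate])
    arrays["window"] = np.array(trials[0].schedule.trial_window)
    np.savez_compressed(path, **arrays)


def load_trials_npz(path) -> tuple[list[np.ndarray], float, tuple[float, float]]:
    with np.load(path) as data:
        rate = float(data["rate"][0])
        window = tuple(data["window"])
        values = [data[k] for k in sorted(data.files, key=str) if k.startswith("trial_")]
    return values, rate, window


def save_raster_csv(path, raster: BehaviorRaster) -> None:
    df = raster.to_frame()
    df.attrs = {}
    with open(path, "w") as fh:
        fh.write(f"# bin_s={raster.bin_s} t_on={raster.t_on} t_off={raster.t_off}\n")
        df.to_csv(fh, index=False)


def load_raster_csv(path) -> BehaviorRaster:
    with open(path) as fh:
        header = fh.readline()
        meta = dict(kv.split("=") for kv in header.lstrip("# ").split())
        df = pd.read_csv(fh)
    n_trials = df["trial_id"].nunique()
    n_bins = df["bin_index"].max() + 1
    trials = np.zeros((n_trials, n_bins))
    for tid, group in df.groupby("trial_id"):
        trials[tid, group["bin_index"].to_numpy()] = group["value"].to_numpy()
    return BehaviorRaster(
        trials=trials,
        bin_s=float(meta["bin_s"]),
        t_on=float(meta["t_on"]),
        t_off=float(meta["t_off"]),
    )


def fit_result_to_dict(fit: FitResult) -> dict:
    return {
        "model_name": fit.model_name,
        "params": fit.params,
        "rmse": fit.rmse,
        "rss": fit.rss,
        "n": fit.n,
        "k": fit.k,
        "aic": fit.aic,
        "n_starts": fit.n_starts,
        "seed": fit.seed,
        "converged": fit.converged,
    }


def save_fit_json(path, fit: FitResult) -> None:
    Path(path).write_text(json.dumps(fit_result_to_dict(fit), indent=2))
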