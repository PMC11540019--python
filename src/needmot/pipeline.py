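"""Run configuration and the end-to-end model-comparison pipeline."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .builders import make_photometry_builder
from .errors import ConfigError
from .fitting import ComparisonResult, FitResult, fit_model, friedman_on_aic, permutation_test
from .io import fit_result_to_dict
from .photometry import KernelSpec, PhotometryTrial, average_trials

__all__ = ["RunConfig", "load_config", "save_config", "run_compare"]

logger = logging.getLogger(__name__)

COMMANDS = ("generate", "fit", "behavior-fit", "simulate", "compare", "sweep")
_ALLOWED_KEYS = {"command", "paths", "parameters", "seed", "log_level"}


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration with strict (unknown keys rejected) schema."""

    command: str
    seed: int
    paths: dict = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return {
            "command": self.command,
            "seed": self.seed,
            "paths": dict(self.paths),
            "parameters": dict(self.parameters),
            "log_level": self.log_level,
        }

    @property
    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _validate(raw: Mapping) -> RunConfig:
    if not isinstance(raw, Mapping):
        raise ConfigError("config root must be a mapping")
    unknown = set(raw) - _ALLOWED_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    command = raw.get("command")
    if command not in COMMANDS:
        raise ConfigError(f"field 'command' must be one of {COMMANDS}, got {command!r}")
    if "seed" not in raw:
        raise ConfigError(f"field 'seed' is required for command {command!r}")
    seed = raw["seed"]
    if not isinstance(seed, int):
        raise ConfigError("field 'seed' must be an integer")
    paths = raw.get("paths", {}) or {}
    parameters = raw.get("parameters", {}) or {}
    if not isinstance(paths, Mapping) or not isinstance(parameters, Mapping):
        raise ConfigError("fields 'paths' and 'parameters' must be mappings")
    return RunConfig(
        command=command,
        seed=seed,
        paths=dict(paths),
        parameters=dict(parameters),
        log_level=str(raw.get("log_level", "INFO")),
    )


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except Exception as exc:  # noqa: BLE001 - surface parse errors as config errors
        raise ConfigError(f"could not parse config {path}: {exc}") from exc
    config = _validate(raw)
    digest = hashlib.sha256(path.read_bytes()).hexdigest()[:16]
    logger.info("loaded config %s (sha256 %s)", path, digest)
    return config


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def run_compare(
    trials: Sequence[PhotometryTrial],
    models: Sequence[str],
    test_id: str,
    *,
    kernel_spec: KernelSpec | None = None,
    n_starts: int = 20,
    seed: int = 0,
    average: bool = True,
    per_trial: bool = False,
    permutation: bool = False,
    n_perm: int = 200,
    out_dir=None,
    config: RunConfig | None = None,
    plot: bool = False,
) -> ComparisonResult:
    """Fit every candidate model and compare AICs.

    With ``average`` the candidates are fit to the trial-averaged trace (the
    consensus schedule carries the mean event times); with ``per_trial`` an
    AIC matrix (trials x models) is additionally assembled and passed to the
    Friedman rank test.  Reports (JSON + CSV, optional figure) are written
    under ``out_dir`` and embed the seed and config digest.
    """
    if len(models) < 2:
        raise ValueError("model comparison needs at least 2 candidate models")
    target = average_trials(trials) if average else trials[0]
    fits: list[FitResult] = []
    predictions: dict[str, np.ndarray] = {}
    for model in models:
        builder = make_photometry_builder(
            test_id, target.schedule, model, kernel_spec, rate=target.rate
        )
        fit = fit_model(target, builder, n_starts=n_starts, seed=seed)
        fits.append(fit)
        predictions[model] = builder.predict(fit.theta)
    friedman_stat = p_value = None
    if per_trial and len(trials) >= 2:
        matrix = np.empty((len(trials), len(models)))
        for i, trial in enumerate(trials):
            for j, model in enumerate(models):
                builder = make_photometry_builder(
                    test_id, trial.schedule, model, kernel_spec, rate=trial.rate
                )
                matrix[i, j] = fit_model(
                    trial, builder, n_starts=n_starts, seed=seed + i
                ).aic
        friedman_stat, p_value = friedman_on_aic(matrix)
    elif permutation:
        best = min(fits, key=lambda f: f.aic)
        builder = make_photometry_builder(
            test_id, target.schedule, best.model_name, kernel_spec, rate=target.rate
        )
        p_value = permutation_test(
            target, builder, n_perm=n_perm, seed=seed, n_starts=max(n_starts // 2, 2)
        )
    result = ComparisonResult(
        fits=tuple(fits), friedman_stat=friedman_stat, p_value=p_value
    )
    if out_dir is not None:
        _write_report(out_dir, result, target, predictions, seed, config, plot)
    return result


def _write_report(out_dir, result, target, predictions, seed, config, plot) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = {
        "seed": seed,
        "config_digest": config.digest if config is not None else None,
        "winner": result.winner,
        "delta_aic": result.delta_aic,
        "friedman_stat": result.friedman_stat,
        "p_value": result.p_value,
        "fits": [fit_result_to_dict(f) for f in result.fits],
    }
    (out / "comparison.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    table = {"time_s": target.times, "observed": target.values}
    table.update({f"pred_{m}": v for m, v in predictions.items()})
    pd.DataFrame(table).to_csv(out / "traces.csv", index=False)
    if plot:
        try:
            import matplotlib
            matplotlib.use("Agg")
            import matplotlib.pyplot as plt
        except ImportError:  # plotting is a soft dependency
            logger.warning("matplotlib unavailable; skipping figure")
            return
        fig, ax = plt.subplots(figsize=(8, 4))
        ax.plot(target.times, target.values, color="0.6", label="observed")
        for model, pred in predictions.items():
            ax.plot(target.times, pred, label=model)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("z-scored signal")
        ax.legend(frameon=False)
        fig.tight_layout()
        fig.savefig(out / "comparison.png", dpi=120)
        plt.close(fig)
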