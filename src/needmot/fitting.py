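"""Multi-start RMSE fitting, AIC model comparison and the statistical tests.

Every candidate model is wrapped in a *builder* exposing ``param_names``,
``bounds`` and ``predict(theta) -> ndarray``; :func:`fit_model` minimizes
the RMSE between prediction and data from ``n_starts`` uniform-random
initial points with a bound-constrained quasi-Newton optimizer (L-BFGS-B,
finite-difference gradients) and reports the best restart.

Model comparison uses the Akaike information criterion

    AIC = N * ln(RSS / N) + 2 * K

with N the number of samples, RSS the residual sum of squares and K the
number of free parameters actually optimized.  Across subjects, AIC values
are compared with a Friedman rank test; on a single trace, a block-permutation
test yields an empirical p-value against surrogate data.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import AlignmentError, FitError
from .photometry import PhotometryTrial

__all__ = [
    "ModelBuilder",
    "FitResult",
    "ComparisonResult",
    "rmse",
    "aic",
    "fit_model",
    "fit_with_delay",
    "loo_cv",
    "permutation_test",
    "friedman_on_aic",
]

logger = logging.getLogger(__name__)


class ModelBuilder(Protocol):
    """Minimal surface a fittable model must expose."""

    model_name: str
    param_names: Sequence[str]
    bounds: Sequence[tuple[float, float]]

    def predict(self, theta: np.ndarray) -> np.ndarray: ...


def rmse(pred: np.ndarray, data: np.ndarray) -> float:
    pred = np.asarray(pred, dtype=float)
    data = np.asarray(data, dtype=float)
    if pred.shape != data.shape:
        raise AlignmentError(f"length mismatch: {pred.shape} vs {data.shape}")
    if pred.size == 0:
        raise AlignmentError("cannot compute RMSE of empty series")
    return float(np.sqrt(np.mean((pred - data) ** 2)))


def aic(rss: float, n: int, k: int) -> float:
    """AIC = n*ln(rss/n) + 2k; a perfect fit (rss == 0) returns -inf with a warning."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if rss < 0:
        raise ValueError("rss must be non-negative")
    if rss == 0.0:
        warnings.warn("rss is exactly zero: degenerate perfect fit, AIC = -inf")
        return float("-inf")
    return float(n * math.log(rss / n) + 2 * k)


@dataclass(frozen=True)
class FitResult:
    """Best fit of one model to one trace, with AIC bookkeeping."""

    model_name: str
    params: dict[str, float]
    rmse: float
    n: int
    k: int
    n_starts: int
    seed: int
    converged: bool
    extra: dict = field(default_factory=dict)

    @property
    def rss(self) -> float:
        return self.rmse**2 * self.n

    @property
    def aic(self) -> float:
        return aic(self.rss, self.n, self.k)

    @property
    def theta(self) -> np.ndarray:
        return np.array(list(self.params.values()), dtype=float)


@dataclass(frozen=True)
class ComparisonResult:
    """AIC comparison of several fitted models; the winner has minimal AIC."""

    fits: tuple[FitResult, ...]
    friedman_stat: float | None = None
    p_value: float | None = None

    @property
    def winner(self) -> str:
        return min(self.fits, key=lambda f: f.aic).model_name

    @property
    def delta_aic(self) -> float:
        """AIC margin of the winner over the runner-up."""
        ordered = sorted(f.aic for f in self.fits)
        return ordered[1] - ordered[0] if len(ordered) > 1 else 0.0


def _data_of(trace) -> np.ndarray:
    return np.asarray(getattr(trace, "values", trace), dtype=float)


def _check_bounds(builder: ModelBuilder) -> np.ndarray:
    bounds = np.asarray(builder.bounds, dtype=float)
    if bounds.ndim != 2 or bounds.shape[1] != 2 or bounds.shape[0] != len(builder.param_names):
        raise FitError("builder bounds must give one (lo, hi) pair per parameter")
    if not np.all(np.isfinite(bounds)):
        raise FitError("all parameters must be bounded for multi-start fitting")
    return bounds


def fit_model(
    trace,
    builder: ModelBuilder,
    *,
    n_starts: int = 100,
    seed: int = 0,
    maxiter: int = 200,
) -> FitResult:
    """Multi-start bounded RMSE minimization; returns the best restart.

    Deterministic given (builder, data, n_starts, seed): initial points are
    drawn uniformly within the builder's bounds from a seeded generator.
    """
    data = _data_of(trace)
    bounds = _check_bounds(builder)
    rng = np.random.default_rng(seed)

    def objective(theta: np.ndarray) -> float:
        return rmse(builder.predict(theta), data)

    best = None
    n_ok = 0
    for _ in range(n_starts):
        x0 = rng.uniform(bounds[:, 0], bounds[:, 1])
        res = optimize.minimize(
            objective,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter},
        )
        if np.isfinite(res.fun):
            n_ok += res.success
            if best is None or res.fun < best.fun:
                best = res
    if best is None:
        raise FitError(f"all {n_starts} restarts failed for model {builder.model_name}")
    params = dict(zip(builder.param_names, (float(v) for v in best.x)))
    logger.debug(
        "fit %s: seed=%d n_starts=%d rmse=%.6g converged=%d/%d",
        builder.model_name, seed, n_starts, best.fun, n_ok, n_starts,
    )
    return FitResult(
        model_name=builder.model_name,
        params=params,
        rmse=float(best.fun),
        n=data.size,
        k=len(builder.param_names),
        n_starts=n_starts,
        seed=seed,
        converged=bool(n_ok > 0),
    )


def fit_with_delay(
    trace,
    builder_factory: Callable[[float], ModelBuilder],
    delay_grid: Sequence[float],
    *,
    n_starts: int = 100,
    seed: int = 0,
) -> FitResult:
    """Grid search over a consumption-end delay, refitting at each delay.

    The chosen delay is recorded as a fitted parameter and counted in K, so
    the returned AIC reflects the extra degree of freedom.
    """
    delays = list(delay_grid)
    if not delays:
        raise ValueError("delay grid must not be empty")
    best: FitResult | None = None
    best_delay = delays[0]
    for delay in delays:
        fit = fit_model(trace, builder_factory(delay), n_starts=n_starts, seed=seed)
        fit_d = FitResult(
            model_name=fit.model_name,
            params={**fit.params, "delay_s": float(delay)},
            rmse=fit.rmse,
            n=fit.n,
            k=fit.k + 1,
            n_starts=fit.n_starts,
            seed=fit.seed,
            converged=fit.converged,
        )
        if best is None or fit_d.aic < best.aic:
            best, best_delay = fit_d, delay
    logger.debug("fit_with_delay %s: chose delay %.3f s", best.model_name, best_delay)
    return best


def loo_cv(
    trials: Sequence[PhotometryTrial],
    builder_factory: Callable[[PhotometryTrial], ModelBuilder],
    *,
    n_starts: int = 20,
    seed: int = 0,
) -> tuple[list[float], float]:
    """Leave-one-out cross-validation with shared parameters across trials.

    For each held-out trial the remaining trials are fit jointly (one shared
    parameter vector minimizing the summed RSS across training trials), and
    the held-out trial's AIC is evaluated with those parameters.  Returns
    (per-trial test AICs, their mean).
    """
    if len(trials) < 3:
        raise ValueError("LOO-CV needs at least 3 trials")
    builders = [builder_factory(t) for t in trials]
    ref = builders[0]
    bounds = _check_bounds(ref)
    k = len(ref.param_names)
    test_aics: list[float] = []
    for i, held_out in enumerate(trials):
        train = [(builders[j], _data_of(trials[j])) for j in range(len(trials)) if j != i]

        def objective(theta: np.ndarray) -> float:
            return sum(
                float(np.sum((b.predict(theta) - y) ** 2)) for b, y in train
            )

        rng = np.random.default_rng(seed + i)
        best = None
        for _ in range(n_starts):
            x0 = rng.uniform(bounds[:, 0], bounds[:, 1])
            res = optimize.minimize(
                objective, x0, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": 200},
            )
            if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
                best = res
        if best is None:
            raise FitError("all restarts failed in a LOO-CV training fold")
        y_test = _data_of(held_out)
        pred = builders[i].predict(best.x)
        rss = float(np.sum((pred - y_test) ** 2))
        test_aics.append(aic(rss, y_test.size, k))
    return test_aics, float(np.mean(test_aics))


def permutation_test(
    trace,
    builder: ModelBuilder,
    *,
    n_parts: int = 20,
    n_perm: int = 1000,
    seed: int = 0,
    n_starts: int = 10,
) -> float:
    """Empirical p-value of a model fit against block-permuted surrogates.

    The trace is divided into ``n_parts`` contiguous blocks; each surrogate
    rearranges the blocks without replacement (preserving within-block
    structure), the model is refit, and the observed AIC is ranked within
    the surrogate AIC distribution: p = fraction of surrogates with
    AIC <= observed.  A p of 0 should be reported as < 1/n_perm.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    data = _data_of(trace)
    observed = fit_model(data, builder, n_starts=n_starts, seed=seed).aic
    blocks = np.array_split(data, n_parts)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for p in range(n_perm):
        order = rng.permutation(len(blocks))
        surrogate = np.concatenate([blocks[i] for i in order])
        null[p] = fit_model(surrogate, builder, n_starts=n_starts, seed=seed).aic
    return float(np.mean(null <= observed))


def _friedman_statistic(ranks: np.ndarray) -> float:
    """Friedman chi-square from a (subjects x models) mid-rank matrix."""
    n, k = ranks.shape
    col_sums = ranks.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * float(np.sum(col_sums**2)) - 3.0 * n * (k + 1)
    # tie correction (mid-ranks): divide by 1 - sum(t^3 - t) / (n k (k^2 - 1))
    tie_term = 0.0
    for row in ranks:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float(np.sum(counts**3 - counts))
    denom = 1.0 - tie_term / (n * k * (k**2 - 1))
    if denom <= 0:
        return 0.0
    return stat / denom


def _friedman_exact_p(n: int, k: int, observed: float) -> float:
    """Exact p by dynamic programming over all k!^n within-subject rankings."""
    perms = [np.array(p) for p in itertools.permutations(range(1, k + 1))]
    # distribution over column-sum vectors (store first k-1 sums; last is implied)
    dist: dict[tuple[int, ...], float] = {tuple([0] * (k - 1)): 1.0}
    w = 1.0 / len(perms)
    for _ in range(n):
        new: dict[tuple[int, ...], float] = {}
        for sums, prob in dist.items():
            for perm in perms:
                key = tuple(s + int(r) for s, r in zip(sums, perm[: k - 1]))
                new[key] = new.get(key, 0.0) + prob * w
        dist = new
    total_rank = n * k * (k + 1) // 2
    p = 0.0
    for sums, prob in dist.items():
        col = np.array(list(sums) + [total_rank - sum(sums)], dtype=float)
        stat = 12.0 / (n * k * (k + 1)) * float(np.sum(col**2)) - 3.0 * n * (k + 1)
        if stat >= observed - 1e-12:
            p += prob
    return p


def friedman_on_aic(aic_matrix: np.ndarray) -> tuple[float, float]:
    """Friedman rank test on a (subjects x models) AIC matrix.

    Ties take mid-ranks; all-equal rows are flagged with a warning (they
    carry no ranking information).  The p-value comes from exact enumeration
    of within-subject rankings for small problems (models <= 3 and subjects
    <= 8, no ties), otherwise from the chi-square approximation.
    """
    X = np.asarray(aic_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 subjects and 2 models")
    n, k = X.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, X)
    if any(np.unique(row).size == 1 for row in X):
        warnings.warn("some subjects rank all models equally; they add no information")
    statistic = _friedman_statistic(ranks)
    has_ties = any(np.unique(row).size < k for row in X)
    if k <= 3 and n <= 8 and not has_ties:
        p = _friedman_exact_p(n, k, statistic)
    else:
        p = float(stats.chi2.sf(statistic, df=k - 1))
    return float(statistic), p
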