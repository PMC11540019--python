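"""RMSE/AIC machinery, multi-start fitting, LOO-CV, permutation and Friedman tests."""

import itertools

import numpy as np
import pytest
from scipy import stats

import needmot as nm
from needmot.builders import (
    make_photometry_builder,
    physical_to_reduced,
)
from needmot.errors import AlignmentError, FitError
from needmot.fitting import (
    aic,
    fit_model,
    fit_with_delay,
    friedman_on_aic,
    loo_cv,
    permutation_test,
    rmse,
)
from needmot.photometry import average_trials


class TestRmseAic:
    @pytest.mark.parametrize(
        "pred, data, expected",
        [
            ([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], 0.0),
            ([2.0, 3.0, 4.0], [1.0, 2.0, 3.0], 1.0),
            ([0.0, 0.0], [3.0, 4.0], np.sqrt(25.0 / 2.0)),  # sqrt((9+16)/2)
        ],
    )
    def test_rmse_examples(self, pred, data, expected):
        assert rmse(np.array(pred), np.array(data)) == pytest.approx(expected)

    def test_rmse_length_mismatch_raises(self):
        with pytest.raises(AlignmentError):
            rmse(np.zeros(3), np.zeros(4))

    @pytest.mark.parametrize(
        "rss, n, k, expected",
        [
            (100.0, 100, 2, 4.0),  # ln(1) = 0
            (50.0, 100, 3, 100.0 * np.log(0.5) + 6.0),
        ],
    )
    def test_aic_examples(self, rss, n, k, expected):
        assert aic(rss, n, k) == pytest.approx(expected)

    def test_aic_linear_in_k(self):
        assert aic(37.0, 200, 5) - aic(37.0, 200, 2) == pytest.approx(6.0)

    def test_zero_rss_returns_minus_inf_with_warning(self):
        with pytest.warns(UserWarning, match="perfect fit"):
            assert aic(0.0, 10, 1) == -np.inf


class ConstantModel:
    """k = 1 constant model: least-squares solution is the sample mean."""

    model_name = "constant"
    param_names = ("offset",)
    bounds = ((-5.0, 5.0),)

    def __init__(self, n):
        self.n = n

    def predict(self, theta):
        return np.full(self.n, theta[0])


class TestFitModel:
    def test_constant_fit_recovers_mean(self):
        rng = np.random.default_rng(0)
        data = rng.normal(0.7, 0.5, 400)
        fit = fit_model(data, ConstantModel(400), n_starts=5, seed=1)
        assert fit.params["offset"] == pytest.approx(data.mean(), abs=1e-5)
        assert fit.k == 1

    def test_determinism_same_seed_identical_result(self, multi_schedule, multi_params):
        trials, _ = nm.generate_photometry_session(
            nm.SessionSpec(test_id="multi_gain_loss", n_trials=3, seed=7)
        )
        avg = average_trials(trials)
        builder = make_photometry_builder("multi_gain_loss", avg.schedule, "need")
        a = fit_model(avg, builder, n_starts=5, seed=11)
        b = fit_model(avg, builder, n_starts=5, seed=11)
        assert a == b  # bit-identical FitResult

    def test_noiseless_need_recovery(self, multi_schedule, multi_params):
        need_params, mot_params = multi_params
        trials, truth = nm.generate_photometry_session(
            nm.SessionSpec(
                test_id="multi_gain_loss", n_trials=1, noise_sd=0.0,
                event_jitter_sd=0.0, zscore=False, seed=3,
            )
        )
        builder = make_photometry_builder(
            "multi_gain_loss", trials[0].schedule, "need"
        )
        fit = fit_model(trials[0], builder, n_starts=8, seed=0)
        assert fit.rmse < 1e-3
        est = np.array([fit.params[n] for n in builder.param_names[2:]])
        true = np.abs(truth.need_params.steps)
        assert np.all(np.abs(est - true) / true < 0.01)

    def test_aic_identity_fields(self):
        fit = fit_model(np.zeros(50) + 0.2, ConstantModel(50), n_starts=3, seed=0)
        assert fit.rss == pytest.approx(fit.rmse**2 * fit.n)
        assert fit.aic == pytest.approx(fit.n * np.log(fit.rss / fit.n) + 2 * fit.k)

    def test_unbounded_parameter_rejected(self):
        class Unbounded(ConstantModel):
            bounds = ((-np.inf, np.inf),)

        with pytest.raises(FitError):
            fit_model(np.zeros(10), Unbounded(10), n_starts=1, seed=0)


class TestDualRoute:
    """The basis-path builders must equal the explicit latent-then-convolve route."""

    @pytest.mark.parametrize("model", nm.MODEL_NAMES)
    def test_builder_matches_explicit_forward_model(
        self, model, multi_schedule, multi_params
    ):
        need_params, mot_params = multi_params
        spec = nm.KernelSpec()
        builder = make_photometry_builder("multi_gain_loss", multi_schedule, model, spec)
        theta = physical_to_reduced(
            builder, multi_schedule, need_params, mot_params, offset=0.3
        )
        latent = nm.build_test_model(
            "multi_gain_loss", multi_schedule, model, need_params, mot_params
        )
        explicit = nm.predict_signal(latent, nm.make_gcamp_kernel(spec), 0.3)
        assert np.allclose(builder.predict(theta), explicit, atol=1e-9)


class TestFitWithDelay:
    def _session(self, delay, seed=0):
        trials, _ = nm.generate_photometry_session(
            nm.SessionSpec(
                test_id="multi_gain_loss", n_trials=10, delay=delay,
                noise_sd=0.2, seed=seed,
            )
        )
        return average_trials(trials)

    def test_recovers_true_delay(self):
        avg = self._session(delay=4.0, seed=5)
        fit = fit_with_delay(
            avg,
            lambda d: make_photometry_builder(
                "multi_gain_loss", avg.schedule, "need", delay=d
            ),
            delay_grid=np.arange(9.0),
            n_starts=5,
            seed=0,
        )
        assert fit.params["delay_s"] == 4.0

    def test_degenerate_grid_adds_one_parameter(self):
        avg = self._session(delay=0.0, seed=6)
        builder = make_photometry_builder("multi_gain_loss", avg.schedule, "need")
        plain = fit_model(avg, builder, n_starts=5, seed=0)
        delayed = fit_with_delay(
            avg,
            lambda d: make_photometry_builder(
                "multi_gain_loss", avg.schedule, "need", delay=d
            ),
            delay_grid=[0.0],
            n_starts=5,
            seed=0,
        )
        assert delayed.k == plain.k + 1
        assert delayed.rmse == pytest.approx(plain.rmse)
        assert delayed.aic == pytest.approx(plain.aic + 2.0)

    def test_best_over_grid_at_most_delay0_plus_parameter_cost(self):
        avg = self._session(delay=4.0, seed=7)
        factory = lambda d: make_photometry_builder(
            "multi_gain_loss", avg.schedule, "need", delay=d
        )
        best = fit_with_delay(avg, factory, np.arange(9.0), n_starts=5, seed=0)
        at_zero = fit_model(avg, factory(0.0), n_starts=5, seed=0)
        assert best.aic <= at_zero.aic + 2.0 + 1e-9

    def test_empty_grid_raises(self):
        avg = self._session(delay=0.0, seed=8)
        with pytest.raises(ValueError):
            fit_with_delay(avg, lambda d: None, [])


class TestLooCv:
    def _trials(self, n=4, seed=0, noise=0.2):
        trials, _ = nm.generate_photometry_session(
            nm.SessionSpec(
                test_id="multi_gain_loss", n_trials=n, noise_sd=noise, seed=seed
            )
        )
        return trials

    def _factory(self, model="need"):
        return lambda trial: make_photometry_builder(
            "multi_gain_loss", trial.schedule, model
        )

    def test_identical_trials_give_equal_test_aics(self):
        base = self._trials(n=1, seed=1, noise=0.1)[0]
        trials = [base] * 4
        aics, mean = loo_cv(trials, self._factory(), n_starts=4, seed=0)
        assert np.allclose(aics, aics[0])
        assert mean == pytest.approx(aics[0])

    def test_order_invariance(self):
        trials = self._trials(n=4, seed=2)
        aics, _ = loo_cv(trials, self._factory(), n_starts=4, seed=0)
        # reversing trials permutes which fold index gets which rng stream,
        # so compare the sets at a tolerance dominated by restart variation
        aics_rev, _ = loo_cv(trials[::-1], self._factory(), n_starts=4, seed=0)
        assert np.allclose(sorted(aics), sorted(aics_rev), rtol=1e-3, atol=0.5)

    def test_generating_model_wins_mean_test_aic(self):
        trials = self._trials(n=4, seed=3)
        _, mean_need = loo_cv(trials, self._factory("need"), n_starts=4, seed=0)
        _, mean_mot = loo_cv(trials, self._factory("motivation"), n_starts=4, seed=0)
        assert mean_need < mean_mot

    def test_too_few_trials_raises(self):
        with pytest.raises(ValueError):
            loo_cv(self._trials(n=2, seed=4), self._factory())


class StepModel:
    """Two-parameter time-structured model for permutation calibration."""

    model_name = "step"
    param_names = ("offset", "height")
    bounds = ((-5.0, 5.0), (-5.0, 5.0))

    def __init__(self, n, at):
        self.template = np.zeros(n)
        self.template[at:] = 1.0

    def predict(self, theta):
        return theta[0] + theta[1] * self.template


class TestPermutationTest:
    def test_degenerate_single_permutation(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=200)
        p = permutation_test(
            data, StepModel(200, 100), n_parts=10, n_perm=1, seed=0, n_starts=2
        )
        assert p in (0.0, 1.0)

    def test_structured_signal_beats_all_surrogates(self):
        rng = np.random.default_rng(1)
        data = np.where(np.arange(400) < 200, 0.0, 3.0) + rng.normal(0, 0.3, 400)
        p = permutation_test(
            data, StepModel(400, 200), n_parts=20, n_perm=50, seed=0, n_starts=2
        )
        assert p == 0.0  # reported as < 1/n_perm

    def test_invalid_n_perm_raises(self):
        with pytest.raises(ValueError):
            permutation_test(np.zeros(100), StepModel(100, 50), n_perm=0)


def brute_force_friedman(matrix):
    """Rank-sum Friedman statistic computed longhand (no ties assumed)."""
    n, k = matrix.shape
    ranks = np.zeros_like(matrix)
    for i, row in enumerate(matrix):
        order = np.argsort(row)
        for rank, j in enumerate(order, start=1):
            ranks[i, j] = rank
    Rj = ranks.sum(axis=0)
    return 12.0 / (n * k * (k + 1)) * np.sum(Rj**2) - 3.0 * n * (k + 1)


class TestFriedman:
    def test_identical_columns_statistic_zero(self):
        X = np.tile(np.arange(5.0)[:, None], (1, 3))
        with pytest.warns(UserWarning):
            stat, _ = friedman_on_aic(X)
        assert stat == pytest.approx(0.0)

    def test_column_permutation_invariance(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(6, 3))
        stat, p = friedman_on_aic(X)
        stat2, p2 = friedman_on_aic(X[:, [2, 0, 1]])
        assert stat == pytest.approx(stat2)
        assert p == pytest.approx(p2)

    def test_perfect_separation_two_models(self):
        # model A strictly better for all 6 subjects: maximal rank separation
        X = np.column_stack([np.zeros(6), np.ones(6)])
        stat, p = friedman_on_aic(X)
        assert stat == pytest.approx(brute_force_friedman(X))
        assert stat == pytest.approx(6.0)  # k=2, n=6 closed-form maximum
        assert p == pytest.approx(2.0 / 2**6)  # two one-sided extremes

    @pytest.mark.parametrize("n_subjects", [2, 3, 4, 5, 6])
    def test_matches_brute_force_on_random_two_model_matrices(self, n_subjects):
        rng = np.random.default_rng(n_subjects)
        X = rng.normal(size=(n_subjects, 2))
        stat, _ = friedman_on_aic(X)
        assert stat == pytest.approx(brute_force_friedman(X))

    def test_matches_scipy_three_models(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(12, 3))
        stat, p = friedman_on_aic(X)
        ref = stats.friedmanchisquare(*(X[:, j] for j in range(3)))
        assert stat == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)  # n > 8: chi-square branch

    def test_exact_p_matches_enumeration_small_case(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(4, 3))
        stat, p = friedman_on_aic(X)
        # brute force: enumerate all 6^4 within-subject rankings
        count = total = 0
        for combo in itertools.product(
            list(itertools.permutations([1, 2, 3])), repeat=4
        ):
            R = np.array(combo, dtype=float)
            s = brute_force_friedman_from_ranks(R)
            total += 1
            count += s >= stat - 1e-12
        assert p == pytest.approx(count / total)

    def test_too_small_matrix_raises(self):
        with pytest.raises(ValueError):
            friedman_on_aic(np.zeros((1, 2)))


def brute_force_friedman_from_ranks(ranks):
    n, k = ranks.shape
    Rj = ranks.sum(axis=0)
    return 12.0 / (n * k * (k + 1)) * np.sum(Rj**2) - 3.0 * n * (k + 1)
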