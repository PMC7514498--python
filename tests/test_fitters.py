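import numpy as np
import pytest

from speechlaws import (
    DegenerateSampleError,
    FitError,
    bin_log,
    fit_exponential,
    fit_loglog,
    fit_lognormal,
    fit_menzerath,
    fit_power_law,
    fit_yule,
    rescale_log,
)
from speechlaws.fitters import _powerlaw_nll, _yule_norm, yule_rank_probs


class TestRescaleLog:
    def test_geometric_triplet(self):
        out = rescale_log([1.0, np.e, np.e**2])
        np.testing.assert_allclose(out.values, [-1.0, 0.0, 1.0], atol=1e-12)

    def test_constant_sample_is_degenerate(self):
        with pytest.raises(DegenerateSampleError):
            rescale_log([2.0, 2.0, 2.0])

    def test_non_positive_values_rejected(self):
        with pytest.raises(FitError):
            rescale_log([0.5, -1.0, 2.0])

    def test_standardization_contract(self, rng):
        x = rng.lognormal(-1, 0.7, 500)
        out = rescale_log(x).values
        assert abs(out.mean()) < 1e-10
        assert abs(out.std(ddof=1) - 1) < 1e-10


class TestLognormal:
    def test_closed_form_on_known_logs(self):
        x = np.exp([0.0, 1.0, 2.0] * 4)
        fit = fit_lognormal(x)
        assert fit.mu == pytest.approx(1.0)
        assert fit.sigma == pytest.approx(np.std([0, 1, 2] * 4), abs=1e-12)

    def test_scale_invariance(self, rng):
        x = rng.lognormal(-2, 0.5, 200)
        f1, f2 = fit_lognormal(x), fit_lognormal(3.0 * x)
        assert f2.mu - f1.mu == pytest.approx(np.log(3.0), abs=1e-12)
        assert f2.sigma == pytest.approx(f1.sigma, abs=1e-12)
        assert f2.ks_to_gaussian == pytest.approx(f1.ks_to_gaussian, abs=1e-12)

    def test_degenerate_sample_rejected(self):
        with pytest.raises(FitError):
            fit_lognormal([np.e] * 12)

    def test_small_samples_rejected(self):
        with pytest.raises(FitError):
            fit_lognormal([0.1] * 5)


class TestPowerLaw:
    def test_matches_grid_search_oracle_on_small_instance(self, rng):
        # 30-type toy corpus: brute-force likelihood grid is the oracle
        p = np.arange(1, 31.0) ** -1.6
        counts = rng.multinomial(2000, p / p.sum())
        counts = counts[counts > 0]
        fit = fit_power_law(counts, max_xmin=1)  # same tail as the oracle
        ranks = np.arange(1, counts.size + 1)
        f = np.sort(counts)[::-1].astype(float)
        grid = np.arange(1.01, 4.0, 1e-3)
        nll = [_powerlaw_nll(a, ranks, f) for a in grid]
        assert fit.alpha == pytest.approx(grid[int(np.argmin(nll))], abs=2e-3)

    def test_uniform_counts_have_no_tail(self):
        with pytest.raises(DegenerateSampleError):
            fit_power_law([7] * 20)

    def test_too_few_types_rejected(self):
        with pytest.raises(FitError):
            fit_power_law([10, 5, 2])

    def test_xmin_one_for_clean_zipf(self, rng):
        p = np.arange(1, 501.0) ** -1.5
        counts = rng.multinomial(30_000, p / p.sum())
        fit = fit_power_law(counts[counts > 0])
        assert fit.xmin == 1
        assert fit.alpha == pytest.approx(1.5, abs=0.05)


class TestYule:
    def test_self_consistency_recovery(self, rng):
        # generate from the fitted family with known parameters, refit
        a, b = 0.25, 0.96
        probs = yule_rank_probs(a, b, 2000)
        counts = rng.multinomial(100_000, probs / probs.sum())
        fit = fit_yule(counts[counts > 0])
        assert fit.b == pytest.approx(b, abs=0.01)
        assert fit.a == pytest.approx(a, abs=0.15)

    def test_mle_is_a_local_optimum(self, rng):
        probs = yule_rank_probs(0.5, 0.9, 500)
        counts = rng.multinomial(20_000, probs / probs.sum())
        counts = np.sort(counts[counts > 0])[::-1].astype(float)
        fit = fit_yule(counts)
        ranks = np.arange(1, counts.size + 1)

        def loglik(a, b):
            return float(
                (counts * (-a * np.log(ranks) + ranks * np.log(b))).sum()
                - counts.sum() * np.log(_yule_norm(a, b))
            )

        assert loglik(fit.a, fit.b) == pytest.approx(fit.loglik, rel=1e-9)
        for da, db in [(0.05, 0), (-0.05, 0), (0, 0.005), (0, -0.005)]:
            assert loglik(fit.a + da, fit.b + db) <= fit.loglik + 1e-6

    def test_degenerate_sample_rejected(self):
        with pytest.raises(FitError):
            fit_yule([4] * 15)


class TestExponential:
    def test_exact_exponential(self):
        ell = np.array([1.0, 2.0, 3.0])
        fit = fit_exponential(ell, np.exp(-ell))
        assert fit.lambda_rate == pytest.approx(1.0, abs=1e-10)
        assert fit.prefactor == pytest.approx(1.0, abs=1e-10)

    def test_strictly_decreasing_gives_perfect_anticorrelation(self):
        ell = np.arange(1.0, 11.0)
        fit = fit_exponential(ell, 100.0 / ell)
        assert fit.spearman_rho == pytest.approx(-1.0)

    def test_zero_frequencies_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="excluding"):
            fit = fit_exponential([1, 2, 3, 4.0], [np.e**-1, np.e**-2, np.e**-3, 0.0])
        assert fit.n == 3
        assert fit.lambda_rate == pytest.approx(1.0, abs=1e-10)

    def test_too_few_usable_points_rejected(self):
        with pytest.raises(FitError):
            fit_exponential([1.0, 2.0], [3.0, 1.0])


class TestMenzerath:
    ENGLISH = (0.364, -0.227, -0.0067)

    def test_noiseless_recovery_to_four_decimals(self):
        a, b, c = self.ENGLISH
        n = np.arange(1, 41.0)
        y = a * n**b * np.exp(-c * n)
        fit = fit_menzerath(n, y)
        assert fit.a == pytest.approx(a, abs=1e-4)
        assert fit.b == pytest.approx(b, abs=1e-4)
        assert fit.c == pytest.approx(c, abs=1e-4)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)

    def test_constant_data_gives_flat_fit(self):
        n = np.arange(1, 21.0)
        fit = fit_menzerath(n, np.full_like(n, 0.25))
        assert fit.b == pytest.approx(0.0, abs=1e-5)
        assert fit.c == pytest.approx(0.0, abs=1e-5)
        assert fit.r2 == 1.0

    def test_extremum_matches_numeric_argmax(self):
        # for b, c > 0 the fitted curve peaks at n = b/c
        n = np.arange(1, 41.0)
        y = 1.0 * n**0.5 * np.exp(-0.05 * n)
        fit = fit_menzerath(n, y)
        grid = np.linspace(1, 40, 40_000)
        curve = fit.a * grid**fit.b * np.exp(-fit.c * grid)
        assert grid[np.argmax(curve)] == pytest.approx(fit.b / fit.c, abs=2e-3)
        assert fit.inversion_n == pytest.approx(10.0, abs=1e-6)

    def test_too_few_sizes_rejected(self):
        with pytest.raises(FitError):
            fit_menzerath([1, 2, 3.0], [1, 1, 1.0])


class TestLoglog:
    def test_exact_power_law_over_three_decades(self):
        x = np.geomspace(1, 1000, 40)
        fit = fit_loglog(x, x**0.63)
        assert fit.slope == pytest.approx(0.63, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0)

    def test_constant_y_gives_zero_slope(self):
        fit = fit_loglog([1.0, 10.0, 100.0], [5.0, 5.0, 5.0])
        assert fit.slope == 0.0

    def test_slope_invariant_under_x_rescaling(self, rng):
        x = np.geomspace(1, 100, 30)
        y = x**0.8 * np.exp(rng.normal(0, 0.05, 30))
        f1, f2 = fit_loglog(x, y), fit_loglog(7.5 * x, y)
        assert f2.slope == pytest.approx(f1.slope, abs=1e-12)

    def test_non_positive_rejected(self):
        with pytest.raises(FitError):
            fit_loglog([1.0, 0.0, 3.0], [1.0, 2.0, 3.0])


class TestBinLog:
    def test_single_occupied_bin_returns_overall_mean(self):
        centers, means, counts = bin_log([2.0, 2.0, 2.0], [1.0, 2.0, 6.0], n_bins=4)
        assert len(centers) == 1
        assert means[0] == pytest.approx(3.0)

    def test_monotone_y_gives_monotone_bin_means(self):
        x = np.geomspace(1, 1000, 200)
        _, means, _ = bin_log(x, np.log(x), n_bins=8)
        assert (np.diff(means) > 0).all()

    def test_matches_hand_computed_means(self):
        x = np.geomspace(1.0, 100.0, 100)
        y = np.arange(100.0)
        edges = np.geomspace(1.0, 100.0, 5)
        expected = []
        idx = np.clip(np.digitize(x, edges) - 1, 0, 3)
        for b in range(4):
            if (idx == b).any():
                expected.append(y[idx == b].mean())
        _, means, counts = bin_log(x, y, n_bins=4)
        np.testing.assert_allclose(means, expected)
        assert counts.sum() == 100
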