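"""Spline bases, knot rules, and continuous-phenotype regression."""

import numpy as np
import pytest
from scipy import stats

from phenoinfer import (
    ContinuousSpec,
    build_continuous_predictor,
    deserialize_predictor,
    make_spline_basis,
    predict_continuous,
    select_regions_continuous,
    serialize_predictor,
    simulate_continuous_dataset,
)
from phenoinfer.continuous import continuous_association_stats, squared_correlation
from phenoinfer.moderation import log_variance_moments, prior_from_moments


class TestKnotPlacement:
    def test_uniform_grid_quantile_knots(self):
        basis = make_spline_basis(np.arange(1.0, 101.0), l=5)
        np.testing.assert_allclose(basis.knots, [1.0, 25.75, 50.5, 75.25, 100.0])

    def test_zero_inflation_pins_first_knot_at_zero(self):
        rng = np.random.default_rng(0)
        values = np.concatenate([np.zeros(60), rng.uniform(0.001, 10, 40)])
        basis = make_spline_basis(values, l=5)
        assert basis.knots[0] == 0.0
        assert np.all(basis.knots[1:] > 0.0)
        assert basis.n_basis == 5

    def test_few_distinct_values_reduce_basis_with_warning(self):
        values = np.array([1.0, 1.0, 2.0, 2.0, 3.0, 3.0, 3.0])
        with pytest.warns(UserWarning, match="reduced"):
            basis = make_spline_basis(values, l=5)
        # quantile knots (1, 1.5, 2, 3, 3) deduplicate to 4
        assert basis.n_basis == 4

    def test_constant_values_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            make_spline_basis(np.full(10, 2.0), l=5)


class TestNaturalSplineBasis:
    def test_cardinal_interpolation(self):
        basis = make_spline_basis(np.arange(1.0, 101.0), l=5)
        B = basis.evaluate(basis.knots)
        np.testing.assert_allclose(B, np.eye(5), atol=1e-12)

    def test_linear_tails_second_derivative_zero(self):
        """Beyond the boundary knots the basis is linear (f'' = 0)."""
        basis = make_spline_basis(np.arange(1.0, 101.0), l=5)
        for x0 in (-20.0, 150.0):
            h = 0.5
            f = basis.evaluate(np.array([x0 - h, x0, x0 + h]))
            second = (f[0] - 2 * f[1] + f[2]) / h**2
            np.testing.assert_allclose(second, 0.0, atol=1e-6)

    def test_partition_of_unity(self):
        """Cardinal natural splines sum to one everywhere (constants in span)."""
        basis = make_spline_basis(np.arange(1.0, 101.0), l=5)
        x = np.linspace(-50, 200, 101)
        np.testing.assert_allclose(basis.evaluate(x).sum(axis=1), 1.0, atol=1e-10)

    def test_in_range_flags(self):
        basis = make_spline_basis(np.arange(1.0, 101.0), l=5)
        np.testing.assert_array_equal(
            basis.in_range([0.0, 1.0, 50.0, 100.0, 101.0]),
            [False, True, True, True, False],
        )


class TestContinuousSelection:
    def test_signal_region_outranks_noise(self):
        """Expression = 2y + noise ranks above 99 pure-noise regions."""
        rng = np.random.default_rng(13)
        n = 200
        y = rng.uniform(0, 5, n)
        E = np.abs(rng.normal(3, 1, size=(100, n)))
        E[0] = 2.0 * y + rng.normal(0, 0.1, n)
        stats_df = continuous_association_stats(E, y, 5)
        assert int(np.argmin(stats_df["p"])) == 0

    def test_null_f_statistics_match_reference_distribution(self):
        """y independent of expression: moderated F follows F(k, d + d0)."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n, R = 100, 200
            y = rng.uniform(20, 70, n)
            sd = rng.lognormal(0, 0.4, size=(R, 1))
            E = np.abs(rng.normal(3, 1, size=(R, n)) * sd)
            st = continuous_association_stats(E, y, 5)
            df = st["df"].iloc[0]
            prior = prior_from_moments(
                log_variance_moments(st["s2"].to_numpy(), df)
            )
            ks = stats.kstest(st["F"], stats.f(4, df + prior.df).cdf)
            assert ks.pvalue > 0.01, f"seed {seed}: KS p = {ks.pvalue}"

    def test_n_equal_total_selects_all(self):
        m, pheno, _ = simulate_continuous_dataset(ContinuousSpec(seed=1, n_regions=30))
        y = pheno.values("trait").astype(float)
        sel = select_regions_continuous(m, y, 30)
        assert len(sel) == 30


class TestContinuousPredictor:
    def test_realizable_signal_interpolated(self):
        """y an exact spline function of one region's expression: RMSE ~ 0."""
        rng = np.random.default_rng(3)
        n = 120
        x = rng.uniform(0, 10, n)
        basis = make_spline_basis(x, l=5)
        y = basis.evaluate(x) @ np.array([1.0, -2.0, 0.5, 3.0, 1.5])
        from phenoinfer import ExpressionMatrix, Region
        from phenoinfer.selection import SelectedRegionSet

        region = Region("chr1", 0, 100)
        m = ExpressionMatrix([region], [f"s{i}" for i in range(n)], x[None, :], True)
        sel = SelectedRegionSet("t", ["spline"], 1, {"spline": [region]})
        model = build_continuous_predictor(m, y, sel)
        assert model.training_rmse < 1e-8

    def test_training_predictions_reproduce_fit(self):
        m, pheno, _ = simulate_continuous_dataset(ContinuousSpec(seed=5))
        y = pheno.values("trait").astype(float)
        sel = select_regions_continuous(m, y, 15)
        model = build_continuous_predictor(m, y, sel)
        pred = predict_continuous(m, model, y_reported=y)
        ok = np.isfinite(y)
        rmse = float(np.sqrt(np.mean((y[ok] - pred.predicted[ok]) ** 2)))
        assert rmse == pytest.approx(model.training_rmse, abs=1e-10)

    def test_extrapolation_flag(self):
        m, pheno, _ = simulate_continuous_dataset(ContinuousSpec(seed=5))
        y = pheno.values("trait").astype(float)
        sel = select_regions_continuous(m, y, 5)
        model = build_continuous_predictor(m, y, sel)
        from phenoinfer import ExpressionMatrix

        k = len(model.regions)
        far = np.full((k, 1), 1e4)
        em = ExpressionMatrix(model.regions, ["far"], far, True)
        pred = predict_continuous(em, model)
        assert pred.extrapolated[0]
        assert np.isfinite(pred.predicted[0])
        at_knots = np.array([[b.knots[1]] for b in model.bases()])
        em2 = ExpressionMatrix(model.regions, ["in"], at_knots, True)
        assert not predict_continuous(em2, model).extrapolated[0]

    def test_null_and_recovery_heldout_r2(self):
        """No signal: held-out R^2 small; linear low-noise signal: large."""
        for seed in range(20):
            spec = ContinuousSpec(seed=seed, shape="none")
            m, pheno, _ = simulate_continuous_dataset(spec)
            y = pheno.values("trait").astype(float)
            half = spec.n_samples // 2
            mt = m.subset_samples(m.samples[:half])
            mh = m.subset_samples(m.samples[half:])
            sel = select_regions_continuous(mt, y[:half], 20)
            model = build_continuous_predictor(mt, y[:half], sel)
            pred = predict_continuous(mh, model, y_reported=y[half:])
            assert pred.r2 <= 0.05, f"null seed {seed}: R^2 = {pred.r2}"

            spec_s = ContinuousSpec(seed=seed, shape="linear", noise=0.1)
            m2, p2, _ = simulate_continuous_dataset(spec_s)
            y2 = p2.values("trait").astype(float)
            m2t = m2.subset_samples(m2.samples[:half])
            m2h = m2.subset_samples(m2.samples[half:])
            sel2 = select_regions_continuous(m2t, y2[:half], 20)
            model2 = build_continuous_predictor(m2t, y2[:half], sel2)
            pred2 = predict_continuous(m2h, model2, y_reported=y2[half:])
            assert pred2.r2 >= 0.9, f"signal seed {seed}: R^2 = {pred2.r2}"

    def test_monotone_information_loss(self):
        """Held-out R^2 decreases (on average) as noise grows."""
        sigmas = [0.1, 0.5, 2.0, 8.0]
        mean_r2 = []
        for sigma in sigmas:
            vals = []
            for seed in range(5):
                spec = ContinuousSpec(seed=seed, shape="linear", noise=sigma)
                m, pheno, _ = simulate_continuous_dataset(spec)
                y = pheno.values("trait").astype(float)
                half = spec.n_samples // 2
                mt = m.subset_samples(m.samples[:half])
                mh = m.subset_samples(m.samples[half:])
                sel = select_regions_continuous(mt, y[:half], 15)
                model = build_continuous_predictor(mt, y[:half], sel)
                pred = predict_continuous(mh, model, y_reported=y[half:])
                vals.append(pred.r2)
            mean_r2.append(np.mean(vals))
        assert all(a >= b - 0.05 for a, b in zip(mean_r2, mean_r2[1:]))

    def test_serialization_round_trip(self, tmp_path):
        m, pheno, _ = simulate_continuous_dataset(ContinuousSpec(seed=5))
        y = pheno.values("trait").astype(float)
        sel = select_regions_continuous(m, y, 10)
        model = build_continuous_predictor(m, y, sel)
        serialize_predictor(model, tmp_path / "model")
        again = deserialize_predictor(tmp_path / "model", expect_kind="continuous")
        p1 = predict_continuous(m, model)
        p2 = predict_continuous(m, again)
        assert np.array_equal(p1.predicted, p2.predicted)


def test_squared_correlation_basics():
    y = np.array([1.0, 2.0, 3.0, 4.0])
    assert squared_correlation(y, 2 * y + 1) == pytest.approx(1.0)
    assert squared_correlation(y, np.full(4, 2.0)) == 0.0
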