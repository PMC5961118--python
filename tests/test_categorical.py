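"""Constrained mean model, non-negative projection, and the unassigned rule."""

import numpy as np
import pytest

from phenoinfer.categorical import test_predictor as resubstitute
from phenoinfer import (
    ExpressionMatrix,
    Region,
    SimulationSpec,
    UNASSIGNED,
    build_predictor,
    deserialize_predictor,
    extract_data,
    predict_pheno,
    project_samples,
    select_regions,
    serialize_predictor,
    simulate_categorical_dataset,
)
from phenoinfer.categorical import (
    CategoricalModel,
    fit_nonneg_means,
    labels_from_memberships,
    project_memberships,
)

from conftest import split_halves


def projected_gradient_nnls(A, b, iters=40000, lr=None):
    """Independent constrained-LS oracle: projected gradient descent."""
    A = np.asarray(A, float)
    b = np.asarray(b, float)
    if lr is None:
        lr = 1.0 / np.linalg.norm(A.T @ A, 2)
    x = np.zeros(A.shape[1])
    for _ in range(iters):
        x = np.maximum(0.0, x - lr * (A.T @ (A @ x - b)))
    return x


class TestConstrainedMeanFit:
    def test_disjoint_indicators_give_level_means(self):
        """With disjoint 0/1 indicators the constrained optimum is the mean."""
        D = np.array([[1, 0], [1, 0], [0, 1], [0, 1.0]])
        E = np.array([[1.0, 3.0, 4.0, 6.0]])
        coef = fit_nonneg_means(E, D)
        np.testing.assert_allclose(coef, [[2.0, 5.0]], atol=1e-10)

    def test_all_zero_region_gets_zero_row(self):
        D = np.array([[1, 0], [1, 0], [0, 1], [0, 1.0]])
        E = np.zeros((1, 4))
        coef = fit_nonneg_means(E, D)
        np.testing.assert_array_equal(coef, [[0.0, 0.0]])

    def test_matches_projected_gradient_oracle(self):
        """Random 6-region, 3-level fixture vs an independent solver."""
        rng = np.random.default_rng(9)
        labels = rng.integers(0, 3, 30)
        D = np.column_stack([(labels == j).astype(float) for j in range(3)])
        E = np.abs(rng.normal(3, 2, size=(6, 30)))
        coef = fit_nonneg_means(E, D)
        for r in range(6):
            oracle = projected_gradient_nnls(D, E[r])
            np.testing.assert_allclose(coef[r], oracle, atol=1e-6)


class TestProjection:
    def test_exact_match_recovers_unit_vector(self):
        coef = np.array([[2.0, 0.5], [0.1, 3.0], [1.0, 1.0]])
        gamma, resid = project_memberships(coef, coef[:, [1]])
        np.testing.assert_allclose(gamma, [[0.0, 1.0]], atol=1e-10)
        assert resid[0] == pytest.approx(0.0, abs=1e-10)

    def test_zero_sample_gets_zero_gamma(self):
        coef = np.array([[2.0, 0.5], [0.1, 3.0]])
        gamma, _ = project_memberships(coef, np.zeros((2, 1)))
        np.testing.assert_array_equal(gamma, [[0.0, 0.0]])

    def test_matches_grid_search_oracle(self):
        """3-region/2-level projection vs exhaustive grid at step 1e-3."""
        rng = np.random.default_rng(17)
        coef = np.abs(rng.normal(2, 1, size=(3, 2)))
        E = np.abs(rng.normal(2, 1, size=(3, 4)))
        gamma, _ = project_memberships(coef, E)
        grid = np.arange(0.0, 3.0 + 1e-9, 1e-3)
        G1, G2 = np.meshgrid(grid, grid, indexing="ij")
        for j in range(E.shape[1]):
            e = E[:, j]
            rss = (
                np.sum(e * e)
                - 2 * (G1 * (coef[:, 0] @ e) + G2 * (coef[:, 1] @ e))
                + G1**2 * (coef[:, 0] @ coef[:, 0])
                + 2 * G1 * G2 * (coef[:, 0] @ coef[:, 1])
                + G2**2 * (coef[:, 1] @ coef[:, 1])
            )
            best = np.unravel_index(np.argmin(rss), rss.shape)
            oracle = np.array([grid[best[0]], grid[best[1]]])
            np.testing.assert_allclose(gamma[j], oracle, atol=2e-3)

    def test_kkt_perturbation_never_improves(self):
        """+-1e-4 single-coordinate moves (respecting gamma >= 0) never help."""
        rng = np.random.default_rng(23)
        coef = np.abs(rng.normal(2, 1, size=(8, 3)))
        E = np.abs(rng.normal(2, 1, size=(8, 12)))
        gamma, _ = project_memberships(coef, E)
        for j in range(E.shape[1]):
            base = np.sum((E[:, j] - coef @ gamma[j]) ** 2)
            for l in range(3):
                for eps in (1e-4, -1e-4):
                    cand = gamma[j].copy()
                    cand[l] += eps
                    if cand[l] < 0:
                        continue
                    rss = np.sum((E[:, j] - coef @ cand) ** 2)
                    assert rss >= base - 1e-9

    def test_scale_equivariance(self):
        """Scaling a sample by c > 0 scales gamma by c; labels unchanged."""
        rng = np.random.default_rng(31)
        coef = np.abs(rng.normal(2, 1, size=(5, 2)))
        e = np.abs(rng.normal(2, 1, size=(5, 1)))
        gamma, _ = project_memberships(coef, e)
        for c in (0.1, 2.0, 37.5):
            gamma_c, _ = project_memberships(coef, c * e)
            np.testing.assert_allclose(gamma_c, c * gamma, rtol=1e-8, atol=1e-10)
            assert (
                labels_from_memberships(gamma_c, ["a", "b"])[0]
                == labels_from_memberships(gamma, ["a", "b"])[0]
            )


class TestUnassignedRule:
    @pytest.mark.parametrize(
        "gamma,expected",
        [
            ([0.9, 0.1], "a"),
            ([0.1, 0.9], "b"),
            ([0.5, 0.5], UNASSIGNED),
            ([0.0, 0.0], UNASSIGNED),
            ([1.0, 1.0, 0.2], UNASSIGNED),
            ([0.0, 1e-12], "b"),
            ([2.0, 2.0 * (1 - 1e-12)], UNASSIGNED),   # inside tolerance
            ([2.0, 2.0 * (1 - 1e-6)], "a"),           # outside tolerance
        ],
    )
    def test_exhaustive_constructed_vectors(self, gamma, expected):
        levels = ["a", "b", "c"][: len(gamma)]
        out = labels_from_memberships(np.array([gamma]), levels, tie_tol=1e-8)
        assert out[0] == expected

    def test_total_over_random_vectors(self):
        rng = np.random.default_rng(2)
        gamma = np.abs(rng.normal(size=(200, 4)))
        out = labels_from_memberships(gamma, ["a", "b", "c", "d"])
        assert set(out) <= {"a", "b", "c", "d", UNASSIGNED}


class TestExtractData:
    def _model(self, regions):
        coef = np.arange(1, 2 * len(regions) + 1, dtype=float).reshape(-1, 2)
        return CategoricalModel("sex", ["female", "male"], regions, coef)

    def test_scrambled_order_restored(self, tiny_matrix):
        model = self._model([tiny_matrix.regions[2], tiny_matrix.regions[0]])
        out = extract_data(tiny_matrix, model)
        assert out.regions == model.regions
        np.testing.assert_array_equal(out.values[1], tiny_matrix.values[0])

    def test_strict_missing_region_errors(self, tiny_matrix):
        missing = Region("chr9", 0, 10)
        model = self._model([tiny_matrix.regions[0], missing])
        with pytest.raises(ValueError, match="chr9:0-10"):
            extract_data(tiny_matrix, model)

    def test_lenient_zero_fills_and_records(self, tiny_matrix):
        missing = Region("chr9", 0, 10)
        model = self._model([tiny_matrix.regions[0], missing])
        out = extract_data(tiny_matrix, model, mode="lenient")
        np.testing.assert_array_equal(out.values[1], 0.0)
        assert out.meta["zero_filled_regions"] == 1


class TestEndToEnd:
    def test_resubstitution_extremes(self):
        """Perfect agreement gives RE = 0; full disagreement gives RE = 100."""
        rng = np.random.default_rng(4)
        m, pheno, _ = simulate_categorical_dataset(
            SimulationSpec(seed=4, n_samples=100, n_regions=100, messy_fraction=0.0)
        )
        sel = select_regions(m, pheno, "phenotype", 10)
        model = build_predictor(m, pheno, "phenotype", sel)
        report = resubstitute(m, pheno, model)
        assert report.resubstitution_error == pytest.approx(0.0)
        # swap the level order in the coefficient matrix -> everything wrong
        flipped = CategoricalModel(
            model.phenotype, model.levels[::-1], model.regions, model.coef
        )
        bad = resubstitute(m, pheno, flipped)
        assert bad.resubstitution_error == pytest.approx(100.0)

    def test_heldout_accuracy_on_planted_signal(self, planted_dataset):
        m, pheno, truth = planted_dataset
        mt, pt, mh, ph, tr, te = split_halves(m, pheno, seed=1)
        sel = select_regions(mt, pt, "phenotype", 20)
        model = build_predictor(mt, pt, "phenotype", sel)
        result = predict_pheno(mh, model)
        acc = np.mean(result.labels == truth.true_labels[te])
        assert acc >= 0.95

    def test_prediction_covers_unlabeled_samples(self, planted_dataset):
        m, pheno, _ = planted_dataset
        sel = select_regions(m, pheno, "phenotype", 10)
        model = build_predictor(m, pheno, "phenotype", sel)
        result = predict_pheno(m, model)
        assert len(result.labels) == len(m.samples)

    def test_noise_samples_can_be_unassigned(self):
        """Level-free noise yields a strictly positive abstention rate.

        Near-ties under the 1e-3 relative tolerance are rare (~5e-4 per
        sample), so the check draws enough samples to observe them.
        """
        rng = np.random.default_rng(1)
        m, pheno, _ = simulate_categorical_dataset(SimulationSpec(seed=44))
        sel = select_regions(m, pheno, "phenotype", 20)
        model = build_predictor(m, pheno, "phenotype", sel, tie_tol=1e-3)
        k = len(model.regions)
        n = 4000
        noise = np.abs(rng.normal(0, 0.01, size=(k, n)))
        em = ExpressionMatrix(model.regions, [f"n{i}" for i in range(n)], noise, True)
        result = project_samples(em, model)
        assert np.mean(result.labels == UNASSIGNED) > 0

    def test_parameter_recovery(self):
        """Fitted profiles approach planted means (no zero inflation)."""
        worst = 0.0
        for seed in range(20):
            m, pheno, truth = simulate_categorical_dataset(
                SimulationSpec(seed=seed, n_samples=1000, zero_inflation=0.0)
            )
            sel = select_regions(m, pheno, "phenotype", 20)
            model = build_predictor(m, pheno, "phenotype", sel)
            true_means = truth.level_means.loc[
                [r.id for r in model.regions], model.levels
            ].to_numpy()
            worst = max(worst, float(np.abs(model.coef - true_means).mean()))
        assert worst < 0.05


class TestSerialization:
    def test_round_trip_preserves_predictions(self, tmp_path, planted_dataset):
        m, pheno, _ = planted_dataset
        sel = select_regions(m, pheno, "phenotype", 10)
        model = build_predictor(m, pheno, "phenotype", sel)
        serialize_predictor(model, tmp_path / "model")
        again = deserialize_predictor(tmp_path / "model")
        r1 = predict_pheno(m, model)
        r2 = predict_pheno(m, again)
        assert np.array_equal(r1.gamma, r2.gamma)
        assert np.array_equal(r1.labels, r2.labels)

    def test_missing_coefficients_rejected(self, tmp_path, planted_dataset):
        m, pheno, _ = planted_dataset
        sel = select_regions(m, pheno, "phenotype", 5)
        model = build_predictor(m, pheno, "phenotype", sel)
        serialize_predictor(model, tmp_path / "model")
        (tmp_path / "model" / "coefficients.tsv").unlink()
        with pytest.raises(FileNotFoundError, match="coefficients"):
            deserialize_predictor(tmp_path / "model")

    def test_kind_mismatch_rejected(self, tmp_path, planted_dataset):
        m, pheno, _ = planted_dataset
        sel = select_regions(m, pheno, "phenotype", 5)
        model = build_predictor(m, pheno, "phenotype", sel)
        serialize_predictor(model, tmp_path / "model")
        with pytest.raises(ValueError, match="categorical"):
            deserialize_predictor(tmp_path / "model", expect_kind="continuous")
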