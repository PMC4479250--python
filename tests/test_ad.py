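import numpy as np
import pytest
import scipy.linalg
import scipy.spatial.distance

from qdbkit import fit_ad, leverage, mahalanobis, similar_compounds, williams_data
from qdbkit.core import ValuesTable
from qdbkit.errors import DimensionMismatch, InsufficientTraining

from conftest import archive_from_matrix


def params_for(X, **kwargs):
    archive = archive_from_matrix(np.asarray(X, dtype=float), **kwargs)
    return archive, fit_ad(archive, archive.models["m"])


class TestFitAd:
    def test_saturated_two_point_design_leverages_one(self):
        # X'X = [[2,1],[1,1]], inverse [[1,-1],[-1,2]]: both hat values are 1
        _, params = params_for([[0.0], [1.0]])
        assert not params.singular
        assert leverage(params, [0.0]) == pytest.approx(1.0)
        assert leverage(params, [1.0]) == pytest.approx(1.0)

    def test_identical_rows_pseudo_inverse_half_leverage(self):
        _, params = params_for([[1.0], [1.0]])
        assert params.singular
        assert leverage(params, [1.0]) == pytest.approx(0.5)

    def test_single_complete_row_insufficient(self):
        archive = archive_from_matrix([[1.0], [2.0], [3.0]])
        table = archive.descriptors["x1"].values_table()
        table.set("c2", None)
        table.set("c3", None)
        archive.descriptors["x1"].set_values(table)
        with pytest.raises(InsufficientTraining):
            fit_ad(archive, archive.models["m"])

    def test_warning_leverage_convention(self):
        _, params = params_for(np.arange(10.0).reshape(5, 2))
        assert params.warning_leverage == pytest.approx(3 * 3 / 5)


class TestLeverage:
    def test_centroid_of_centered_design_is_one_over_n(self):
        X = np.array([[-2.0], [-1.0], [0.0], [1.0], [2.0]])
        _, params = params_for(X)
        assert leverage(params, [0.0]) == pytest.approx(1.0 / 5.0)

    def test_midpoint_of_two_point_design(self):
        _, params = params_for([[0.0], [2.0]])
        assert leverage(params, [1.0]) == pytest.approx(0.5)

    def test_hat_trace_equals_rank(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            n, d = int(rng.integers(5, 20)), int(rng.integers(1, 4))
            X = rng.normal(size=(n, d))
            _, params = params_for(X)
            trace = sum(leverage(params, row) for row in X)
            assert trace == pytest.approx(params.rank, abs=1e-8)

    def test_dimension_mismatch(self):
        _, params = params_for([[0.0], [1.0], [2.0]])
        with pytest.raises(DimensionMismatch):
            leverage(params, [1.0, 2.0])


class TestMahalanobis:
    def test_zero_at_centroid(self):
        _, params = params_for(np.random.default_rng(0).normal(size=(8, 2)))
        assert mahalanobis(params, params.centroid) == pytest.approx(0.0)

    def test_square_design_hand_value(self):
        # covariance of the 2x2 grid is diag(4/3, 4/3); corner distance sqrt(1.5)
        X = np.array([[0.0, 0.0], [2.0, 0.0], [0.0, 2.0], [2.0, 2.0]])
        _, params = params_for(X)
        assert mahalanobis(params, [0.0, 0.0]) == pytest.approx(np.sqrt(1.5))

    def test_sum_of_squares_identity(self):
        # sum of squared training distances = (n-1) d for full-rank covariance
        X = np.array([[0.0, 0.0], [2.0, 0.0], [0.0, 2.0], [2.0, 2.0]])
        _, params = params_for(X)
        total = sum(mahalanobis(params, row) ** 2 for row in X)
        assert total == pytest.approx(6.0)

    def test_translation_invariance(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(9, 3))
        shift = rng.normal(size=3) * 10
        _, params = params_for(X)
        _, shifted = params_for(X + shift)
        x = rng.normal(size=3)
        assert mahalanobis(shifted, x + shift) == pytest.approx(
            mahalanobis(params, x), rel=1e-9)
        assert leverage(shifted, shifted.centroid) == pytest.approx(
            leverage(params, params.centroid), rel=1e-9)


def test_oracle_equivalence_dense_solve():
    """leverage/mahalanobis match an independent dense linear-solve oracle."""
    rng = np.random.default_rng(11)
    for _ in range(20):
        n, d = int(rng.integers(5, 21)), int(rng.integers(1, 5))
        X = rng.normal(size=(n, d))
        _, params = params_for(X)
        X_aug = np.column_stack([np.ones(n), X])
        cov = np.cov(X, rowvar=False, ddof=1).reshape(d, d)
        centroid = X.mean(axis=0)
        for _ in range(3):
            x = rng.normal(size=d)
            v = np.concatenate([[1.0], x])
            h_oracle = float(v @ scipy.linalg.solve(X_aug.T @ X_aug, v,
                                                    assume_a="sym"))
            m_oracle = scipy.spatial.distance.mahalanobis(
                x, centroid, scipy.linalg.inv(cov))
            assert leverage(params, x) == pytest.approx(h_oracle, rel=1e-10)
            assert mahalanobis(params, x) == pytest.approx(m_oracle, rel=1e-10)


class TestWilliamsData:
    def test_noise_free_fixture_std_residuals_zero(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(10, 2))
        archive = archive_from_matrix(X)  # y identical to predictions
        profiles = williams_data(archive, archive.models["m"])
        assert len(profiles) == 10
        # a perfect model has zero training RMSE, so std residuals are undefined
        assert all(p.residual == pytest.approx(0.0) for p in profiles)

    def test_outlier_has_largest_std_residual(self, archive):
        prop = archive.properties["activity"]
        table = prop.values_table()
        model = archive.models["model1"]
        params = fit_ad(archive, model)
        victim = params.compound_ids[0]
        table.set(victim, table.get(victim) + 10 * params.training_rmse)
        prop.set_values(table)
        profiles = williams_data(archive, model)
        worst = max(profiles, key=lambda p: abs(p.std_residual or 0))
        assert worst.compound_id == victim

    def test_compound_without_experimental_is_insubria_point(self, archive):
        prop = archive.properties["activity"]
        table = prop.values_table()
        testing = archive.predictions["testing"].values_table()
        orphan = next(iter(testing.keys()))
        table.set(orphan, None)
        prop.set_values(table)
        profiles = {p.compound_id: p for p in williams_data(archive,
                                                            archive.models["model1"])}
        point = profiles[orphan]
        assert point.leverage > 0 and point.mahalanobis >= 0
        assert point.residual is None and point.std_residual is None
        assert point.set_kind == "testing"

    def test_profiles_follow_registry_order(self, archive):
        profiles = williams_data(archive, archive.models["model1"])
        order = archive.compounds.ids()
        indices = [order.index(p.compound_id) for p in profiles]
        assert indices == sorted(indices)


class TestSimilarCompounds:
    def test_exact_match_first_at_zero_distance(self):
        X = np.array([[0.0], [3.0], [7.0]])
        archive = archive_from_matrix(X)
        ranked = similar_compounds(archive, archive.models["m"], [3.0], k=2)
        assert ranked[0][0] == "c2" and ranked[0][1] == 0.0

    def test_hand_distances_and_order(self):
        archive = archive_from_matrix(np.array([[0.0], [3.0]]))
        ranked = similar_compounds(archive, archive.models["m"], [1.0], k=2)
        assert [(r[0], r[1]) for r in ranked] == [("c1", 1.0), ("c2", 2.0)]

    def test_k_larger_than_dataset_clamps(self):
        archive = archive_from_matrix(np.array([[0.0], [1.0]]))
        assert len(similar_compounds(archive, archive.models["m"], [0.0], k=99)) == 2

    def test_ties_break_by_registry_order(self):
        archive = archive_from_matrix(np.array([[1.0], [-1.0], [1.0]]))
        ranked = similar_compounds(archive, archive.models["m"], [0.0], k=3)
        assert [r[0] for r in ranked] == ["c1", "c2", "c3"]

    def test_carries_experimental_and_predicted(self, archive):
        model = archive.models["model1"]
        params = fit_ad(archive, model)
        ranked = similar_compounds(archive, model, params.training_matrix[0], k=1)
        cid, distance, experimental, predicted = ranked[0]
        assert distance == pytest.approx(0.0)
        assert isinstance(experimental, float) and isinstance(predicted, float)

    def test_scaled_mode_changes_metric(self):
        # one dominant-variance column: scaling rebalances the ranking
        X = np.array([[0.0, 0.0], [100.0, 1.0], [10.0, 10.0]])
        archive = archive_from_matrix(X)
        raw = similar_compounds(archive, archive.models["m"], [0.0, 9.0], k=1)
        scaled = similar_compounds(archive, archive.models["m"], [0.0, 9.0], k=1,
                                   scaled=True)
        assert raw[0][0] != scaled[0][0]
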