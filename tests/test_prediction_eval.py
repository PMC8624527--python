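"""One-step prediction, error metrics and model serialization."""

import numpy as np
import pytest

from pwasoft.data_model import build_regression_vectors
from pwasoft.prediction_eval import (
    PWARXModel,
    error_metrics,
    evaluate_model,
    fit_global_arx,
    predict_one_step,
    rmse_by_test_size,
)
from pwasoft.region_partition import DividingSurface
from pwasoft.synthetic_data import (
    gen_fermentation_batches,
    FermentationSpec,
    make_three_phase_fixture,
)
from pwasoft.data_model import assign_split_labels


def _three_region_model(rng):
    """Synthetic S = 3 model in a 2-d regressor space with explicit surfaces."""
    thetas = rng.normal(size=(3, 3))
    centers = np.array([
        [-2.0, 0.0, 0.0], [0.0, 0.0, 0.0], [2.0, 0.0, 0.0],
    ])
    surfaces = [
        DividingSurface(0, 1, w=np.array([-1.0, 0.0]), v=-1.0),
        DividingSurface(1, 2, w=np.array([-1.0, 0.0]), v=1.0),
    ]
    return PWARXModel(
        n_y=1, n_u=1, p=0, r=1, target="y",
        thetas=thetas, centers=centers, surfaces=surfaces,
    )


class TestPredictOneStep:
    def test_single_region_reduces_to_global_arx(self, rng):
        theta = np.array([[0.4, -0.2, 0.1]])
        model = PWARXModel(
            n_y=1, n_u=1, p=0, r=1, target="y",
            thetas=theta, centers=np.zeros((1, 3)),
        )
        X = rng.normal(size=(20, 2))
        expected = np.column_stack([X, np.ones(20)]) @ theta[0]
        assert np.allclose(predict_one_step(model, X), expected)

    def test_boundary_point_uses_lower_region(self, rng):
        model = _three_region_model(rng)
        X = np.array([[1.0, 0.5]])  # exactly on the 1|2 surface
        pred = predict_one_step(model, X)
        expected = np.array([1.0, 0.5, 1.0]) @ model.thetas[1]
        assert pred[0] == pytest.approx(expected)

    def test_matches_indicator_sum_oracle(self, rng):
        model = _three_region_model(rng)
        X = rng.normal(size=(100, 2)) * 2
        regions = model.regions(X)
        pred = predict_one_step(model, X)
        for k, x in enumerate(X):
            acc = 0.0
            for i in range(3):
                delta = 1.0 if regions[k] == i else 0.0
                acc += (np.concatenate([x, [1.0]]) @ model.thetas[i]) * delta
            assert pred[k] == pytest.approx(acc)

    def test_dimension_mismatch_raises(self, rng):
        model = _three_region_model(rng)
        with pytest.raises(ValueError):
            predict_one_step(model, rng.normal(size=(4, 5)))


class TestErrorMetrics:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0])
        rep = error_metrics(y, y)
        assert rep.mape == 0.0 and rep.rmse == 0.0

    def test_known_mape_value(self):
        rep = error_metrics([1.0, 2.0, 4.0], [1.1, 1.8, 4.4])
        assert rep.mape == pytest.approx(0.1)

    def test_scale_homogeneity(self, rng):
        y = rng.uniform(1, 5, size=50)
        yp = y + rng.normal(size=50) * 0.2
        a, b = error_metrics(y, yp), error_metrics(3 * y, 3 * yp)
        assert b.mape == pytest.approx(a.mape)
        assert b.rmse == pytest.approx(3 * a.rmse)

    def test_small_y_excluded_from_mape(self):
        rep = error_metrics([0.0, 2.0], [1.0, 2.2], small_y_floor=1e-8)
        assert rep.n_excluded_small_y == 1
        assert rep.mape == pytest.approx(0.1)
        # RMSE keeps every sample
        assert rep.rmse == pytest.approx(np.sqrt((1.0 + 0.04) / 2))

    def test_all_excluded_raises(self):
        with pytest.raises(ValueError, match="excluded"):
            error_metrics([0.0, 0.0], [1.0, 1.0])

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            error_metrics([1.0], [1.0, 2.0])


class TestEvaluateModel:
    def test_truth_model_on_own_noiseless_data(self):
        batches, truth = make_three_phase_fixture(seed=5, noise_sd=0.0)
        assign_split_labels(batches)
        spec = truth["spec"]
        # the true model with the true threshold partition encoded as surfaces
        surfaces = [
            DividingSurface(0, 1, w=np.array([-1.0] + [0.0] * 6), v=0.30),
            DividingSurface(1, 2, w=np.array([-1.0] + [0.0] * 6), v=0.65),
        ]
        ds = build_regression_vectors(batches, "y", 1, 1)
        centers = np.vstack([
            ds.z[truth["labels"] == i].mean(axis=0) for i in range(3)
        ])
        model = PWARXModel(
            n_y=1, n_u=1, p=0, r=6, target="y",
            thetas=spec.thetas, centers=centers, surfaces=surfaces,
        )
        rep = evaluate_model(model, batches, split="test")
        assert rep.mape < 1e-10
        assert rep.rmse < 1e-10

    def test_rmse_table_structure_for_180_samples(self):
        y = np.random.default_rng(0).uniform(1, 2, 180)
        rows = rmse_by_test_size(y, y + 0.01, step=20)
        assert [r[0] for r in rows] == [20, 40, 60, 80, 100, 120, 140, 160, 180]

    def test_report_matches_recomputation(self, rng):
        batches, _ = make_three_phase_fixture(seed=7)
        assign_split_labels(batches)
        ds = build_regression_vectors(batches, "y", 1, 1)
        theta = fit_global_arx(ds.split("train"))
        model = PWARXModel(
            n_y=1, n_u=1, p=0, r=6, target="y",
            thetas=theta[None, :], centers=np.zeros((1, 8)),
        )
        rep = evaluate_model(model, batches, split="test")
        te = ds.split("test")
        yhat = np.column_stack([te.X, np.ones(len(te))]) @ theta
        ok = np.abs(te.y) >= 1e-8
        assert rep.mape == pytest.approx(
            np.mean(np.abs((te.y[ok] - yhat[ok]) / te.y[ok]))
        )
        assert rep.rmse == pytest.approx(np.sqrt(np.mean((te.y - yhat) ** 2)))

    def test_empty_split_raises(self):
        batches, _ = make_three_phase_fixture(seed=3)
        assign_split_labels(batches)
        model = PWARXModel(
            n_y=1, n_u=1, p=0, r=6, target="y",
            thetas=np.zeros((1, 8)), centers=np.zeros((1, 8)),
        )
        with pytest.raises(ValueError):
            evaluate_model(model, batches, split="nope")

    def test_physical_scale_metrics_reported(self):
        spec = FermentationSpec(
            n_batches=2, samples_per_batch=48, split_sizes=(48, 24, 24), seed=1
        )
        batches, transform = gen_fermentation_batches(spec)
        ds = build_regression_vectors(batches, "X", 1, 1)
        theta = fit_global_arx(ds.split("train"))
        model = PWARXModel(
            n_y=1, n_u=1, p=0, r=6, target="X",
            thetas=theta[None, :], centers=np.zeros((1, 8)),
            scaling=transform,
        )
        rep = evaluate_model(model, batches, split="test")
        assert rep.mape_physical is not None
        assert rep.rmse_physical is not None and rep.rmse_physical > 0


class TestModelSerialization:
    def test_round_trip_lossless(self, rng, tmp_path):
        model = _three_region_model(rng)
        model.metadata = {"seed": 1}
        path = tmp_path / "m.json"
        model.to_json(path)
        back = PWARXModel.from_json(path)
        assert np.array_equal(back.thetas, model.thetas)
        assert np.array_equal(back.centers, model.centers)
        assert back.target == model.target and back.S == model.S
        assert len(back.surfaces) == len(model.surfaces)
        for a, b in zip(model.surfaces, back.surfaces):
            assert np.array_equal(a.w, b.w) and a.v == b.v

    def test_json_text_is_deterministic(self, rng):
        m1 = _three_region_model(np.random.default_rng(4))
        m2 = _three_region_model(np.random.default_rng(4))
        assert m1.to_json() == m2.to_json()

    def test_inconsistent_dimensions_rejected(self):
        with pytest.raises(ValueError):
            PWARXModel(
                n_y=1, n_u=1, p=0, r=1, target="y",
                thetas=np.zeros((2, 5)), centers=np.zeros((2, 3)),
            )


def test_global_arx_baseline_is_least_squares(rng):
    batches, _ = make_three_phase_fixture(seed=2, n_batches=2,
                                          n_samples=60)
    ds = build_regression_vectors(batches, "y", 1, 1)
    theta = fit_global_arx(ds)
    Phi = np.column_stack([ds.X, np.ones(len(ds))])
    expected, *_ = np.linalg.lstsq(Phi, ds.y, rcond=None)
    assert np.allclose(theta, expected)
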