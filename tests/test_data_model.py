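"""Containers, interpolation, normalization and regressor construction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pwasoft.data_model import (
    BatchTimeSeries,
    ScalingTransform,
    assign_split_labels,
    build_regression_vectors,
    interpolate_outputs,
    minmax_normalize,
    read_batches_csv,
    regressor_window,
    write_batches_csv,
)


def _single_channel_batch(values, mask=None, n_u=1):
    v = np.asarray(values, dtype=float)
    m = np.ones(len(v), dtype=bool) if mask is None else np.asarray(mask, bool)
    return BatchTimeSeries(
        batch_id="b",
        u=np.zeros((len(v), n_u)),
        y=v[:, None],
        y_observed_mask=m,
        u_names=tuple(f"u{i}" for i in range(n_u)),
        y_names=("y",),
    )


class TestNormalization:
    def test_endpoints_map_to_plus_minus_one(self):
        b = _single_channel_batch([2.0, 4.0, 6.0])
        scaled, tr = minmax_normalize([b])
        assert np.allclose(scaled[0].y[:, 0], [-1.0, 0.0, 1.0])

    def test_constant_channel_maps_to_zero_and_is_flagged(self):
        b = _single_channel_batch([7.0, 7.0, 7.0])
        scaled, tr = minmax_normalize([b])
        assert np.allclose(scaled[0].y, 0.0)
        assert np.allclose(scaled[0].u, 0.0)
        assert tr.constant.all()
        # inverse restores the constant
        assert np.allclose(tr.inverse(scaled[0].y * 0.0)[..., -1], 7.0)

    def test_round_trip_is_identity(self, random_batch):
        scaled, tr = minmax_normalize([random_batch])
        full = np.hstack([scaled[0].u, scaled[0].y])
        back = tr.inverse(full)
        orig = np.hstack([random_batch.u, random_batch.y])
        assert np.allclose(back, orig, atol=1e-12)

    def test_normalizing_normalized_data_is_identity(self, random_batch):
        scaled, _ = minmax_normalize([random_batch])
        rescaled, tr2 = minmax_normalize(scaled)
        assert np.allclose(rescaled[0].u, scaled[0].u, atol=1e-12)
        assert np.allclose(rescaled[0].y, scaled[0].y, atol=1e-12)

    def test_training_image_lies_in_unit_box(self, rng):
        batches = [
            BatchTimeSeries(
                batch_id=f"b{i}",
                u=rng.normal(size=(30, 6)) * 10 + 5,
                y=rng.normal(size=(30, 2)),
                y_observed_mask=np.ones(30, bool),
            )
            for i in range(3)
        ]
        scaled, _ = minmax_normalize(batches)
        for s in scaled:
            assert np.all(np.abs(s.u) <= 1 + 1e-12)
            assert np.all(np.abs(s.y) <= 1 + 1e-12)

    def test_empty_collection_raises(self):
        with pytest.raises(ValueError, match="empty"):
            minmax_normalize([])

    def test_non_finite_value_names_channel(self):
        b = _single_channel_batch([1.0, np.nan, 2.0], mask=[True, False, True])
        with pytest.raises(ValueError, match="'y'"):
            minmax_normalize([b])

    def test_out_of_range_values_are_not_clipped(self):
        b = _single_channel_batch([0.0, 1.0])
        _, tr = minmax_normalize([b])
        wide = _single_channel_batch([2.0, -1.0])
        out = tr.apply_batches([wide])[0]
        assert out.y[0, 0] == pytest.approx(3.0)
        assert out.y[1, 0] == pytest.approx(-3.0)

    def test_serialization_round_trip(self, random_batch):
        _, tr = minmax_normalize([random_batch])
        tr2 = ScalingTransform.from_dict(tr.to_dict())
        x = np.linspace(-1, 1, 8 * 3).reshape(3, 8)
        assert np.allclose(tr.inverse(x), tr2.inverse(x))


class TestInterpolation:
    def test_linear_fill_matches_closed_form(self):
        # hourly observations 0 and 12 on a 5-min grid: interior = 1..11
        y = np.full(13, np.nan)
        y[0], y[12] = 0.0, 12.0
        mask = np.zeros(13, bool)
        mask[[0, 12]] = True
        b = _single_channel_batch(y, mask)
        out = interpolate_outputs(b)
        assert np.allclose(out.y[:, 0], np.arange(13.0))

    def test_fully_observed_is_identity(self, random_batch):
        out = interpolate_outputs(random_batch)
        assert np.array_equal(out.y, random_batch.y)

    def test_matches_independent_interpolator(self, rng):
        from scipy.interpolate import interp1d

        n = 60
        mask = np.zeros(n, bool)
        mask[::6] = True
        mask[-1] = True
        y = np.full((n, 1), np.nan)
        y[mask, 0] = rng.normal(size=mask.sum())
        b = _single_channel_batch(y[:, 0], mask)
        out = interpolate_outputs(b)
        t = b.time_minutes
        f = interp1d(t[mask], y[mask, 0])
        assert np.allclose(out.y[:, 0], f(t), atol=1e-12)

    def test_observed_values_preserved_exactly(self, rng):
        n = 25
        mask = np.zeros(n, bool)
        mask[[0, 7, 13, 24]] = True
        y = np.full(n, np.nan)
        y[mask] = rng.normal(size=4)
        b = _single_channel_batch(y, mask)
        out = interpolate_outputs(b, method="cubic")
        assert np.array_equal(out.y[mask, 0], y[mask])

    def test_too_few_observations_raise(self):
        b = _single_channel_batch([1.0, np.nan, np.nan], [True, False, False])
        with pytest.raises(ValueError, match=">= 2 observed"):
            interpolate_outputs(b)

    def test_extrapolation_requires_flag(self):
        y = np.array([np.nan, 1.0, 2.0, np.nan])
        mask = np.array([False, True, True, False])
        b = _single_channel_batch(y, mask)
        with pytest.raises(ValueError, match="extrapolat"):
            interpolate_outputs(b)
        out = interpolate_outputs(b, allow_extrapolation=True)
        assert np.allclose(out.y[:, 0], [0.0, 1.0, 2.0, 3.0])


class TestRegressionVectors:
    def test_constant_series_pairs(self):
        n = 12
        b = BatchTimeSeries(
            batch_id="c", u=np.full((n, 1), 3.0), y=np.full((n, 1), 5.0),
            y_observed_mask=np.ones(n, bool), u_names=("u0",), y_names=("y",),
        )
        ds = build_regression_vectors(b, "y", n_y=1, n_u=1)
        assert len(ds) == n - 1
        assert np.allclose(ds.X, [[5.0, 3.0]] * (n - 1))
        assert np.allclose(ds.y, 5.0)

    def test_six_input_one_lag_gives_eight_parameters(self, random_batch):
        # r=6 with one output and one input lag: regressor dim 7, so the
        # affine local parameter vector has 8 entries
        ds = build_regression_vectors(random_batch, "X", n_y=1, n_u=1)
        assert ds.n == 7
        assert ds.z.shape[1] == 8

    def test_matches_bookkeeping_oracle(self, rng):
        n, r, n_y, n_u, p = 10, 2, 2, 1, 1
        u = rng.normal(size=(n, r))
        y = rng.normal(size=n)
        b = BatchTimeSeries(
            batch_id="o", u=u, y=y[:, None],
            y_observed_mask=np.ones(n, bool),
            u_names=("a", "b"), y_names=("y",),
        )
        ds = build_regression_vectors(b, "y", n_y, n_u, p)
        w = max(n_y, p + n_u)
        rows = []
        for k in range(w, n):
            row = []
            for i in range(1, n_y + 1):
                row.append(y[k - i])
            for j in range(1, n_u + 1):
                row.extend(u[k - p - j])
            rows.append(row)
        assert np.allclose(ds.X, rows)
        assert np.allclose(ds.y, y[w:])
        assert np.allclose(ds.z, np.column_stack([rows, y[w:]]))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        lengths=st.lists(st.integers(1, 12), min_size=1, max_size=4),
        n_y=st.integers(0, 3),
        n_u=st.integers(1, 3),
        p=st.integers(0, 2),
    )
    def test_pair_count_conservation(self, lengths, n_y, n_u, p):
        rng = np.random.default_rng(7)
        batches = [
            BatchTimeSeries(
                batch_id=f"b{i}", u=rng.normal(size=(m, 1)),
                y=rng.normal(size=(m, 1)),
                y_observed_mask=np.ones(m, bool),
                u_names=("u0",), y_names=("y",),
            )
            for i, m in enumerate(lengths)
        ]
        w = regressor_window(n_y, n_u, p)
        expected = sum(max(0, m - w) for m in lengths)
        if expected == 0:
            with pytest.raises(ValueError):
                build_regression_vectors(batches, "y", n_y, n_u, p)
        else:
            ds = build_regression_vectors(batches, "y", n_y, n_u, p)
            assert len(ds) == expected

    def test_windows_never_cross_batches(self, rng):
        batches = [
            BatchTimeSeries(
                batch_id=f"b{i}", u=rng.normal(size=(8, 1)),
                y=rng.normal(size=(8, 1)), y_observed_mask=np.ones(8, bool),
                u_names=("u0",), y_names=("y",),
            )
            for i in range(2)
        ]
        ds = build_regression_vectors(batches, "y", n_y=2, n_u=2)
        assert (ds.time_indices >= 2).all()
        for bid in ("b0", "b1"):
            sub = ds.subset(ds.batch_ids == bid)
            src = batches[0] if bid == "b0" else batches[1]
            for Xk, k in zip(sub.X, sub.time_indices):
                assert Xk[0] == src.y[k - 1, 0]


class TestSplitsAndCsv:
    def test_split_labels_by_global_index(self, rng):
        batches = [
            _single_channel_batch(rng.normal(size=10)) for _ in range(3)
        ]
        assign_split_labels(batches, sizes=(15, 10, 5))
        flat = np.concatenate([b.split_labels for b in batches])
        assert (flat[:15] == "train").all()
        assert (flat[15:25] == "val").all()
        assert (flat[25:] == "test").all()

    def test_bad_split_sizes_raise(self):
        b = _single_channel_batch(np.zeros(4))
        with pytest.raises(ValueError, match="sum"):
            assign_split_labels([b], sizes=(2, 1, 2))

    def test_csv_round_trip(self, tmp_path, rng):
        batches = [
            BatchTimeSeries(
                batch_id=f"b{i}", u=rng.normal(size=(12, 6)),
                y=rng.normal(size=(12, 2)),
                y_observed_mask=(np.arange(12) % 3 == 0),
            )
            for i in range(2)
        ]
        for b in batches:
            b.y[~b.y_observed_mask] = np.nan
        assign_split_labels(batches, sizes=(12, 6, 6))
        path = tmp_path / "batches.csv"
        write_batches_csv(batches, path)
        back = read_batches_csv(path)
        assert len(back) == 2
        for a, c in zip(batches, back):
            assert a.batch_id == c.batch_id
            assert np.allclose(a.u, c.u)
            assert np.allclose(a.y, c.y, equal_nan=True)
            assert np.array_equal(a.y_observed_mask, c.y_observed_mask)
            assert np.array_equal(a.split_labels, c.split_labels)
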