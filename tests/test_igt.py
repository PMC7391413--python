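import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import jensenshannon, pdist, squareform

import tempovar as tv
from tempovar.igt import classical_mds

from conftest import make_table, random_prob_vector


def prob_vectors(k):
    return st.lists(
        st.floats(1e-6, 1.0), min_size=k, max_size=k
    ).map(lambda v: np.array(v) / np.sum(v))


class TestJSD:
    def test_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = random_prob_vector(rng, 8)
            assert tv.jsd(p, p) == 0.0

    def test_disjoint_supports_give_one(self):
        assert abs(tv.jsd([1, 0], [0, 1]) - 1.0) < 1e-12
        assert abs(tv.jsd([0.5, 0.5, 0, 0], [0, 0, 0.5, 0.5]) - 1.0) < 1e-12

    def test_matches_term_by_term_formula(self):
        # independent oracle: explicit base-2 JS formula
        p, q = np.array([0.5, 0.5]), np.array([0.25, 0.75])
        m = (p + q) / 2
        expected = np.sqrt(
            0.5 * sum(pi * np.log2(pi / mi) for pi, mi in zip(p, m))
            + 0.5 * sum(qi * np.log2(qi / mi) for qi, mi in zip(q, m))
        )
        got = tv.jsd(p, q)
        assert abs(got - expected) < 1e-14
        assert 0 < got < 1

    def test_matches_scipy_cross_check(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            k = int(rng.integers(2, 12))
            p, q = random_prob_vector(rng, k), random_prob_vector(rng, k)
            assert abs(tv.jsd(p, q) - jensenshannon(p, q, base=2)) < 1e-10

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(prob_vectors(5), prob_vectors(5), prob_vectors(5))
    def test_metric_properties(self, p, q, r):
        """Symmetry, boundedness and the triangle inequality."""
        d_pq, d_qp = tv.jsd(p, q), tv.jsd(q, p)
        assert abs(d_pq - d_qp) <= 1e-12
        assert 0 <= d_pq <= 1
        assert d_pq <= tv.jsd(p, r) + tv.jsd(r, q) + 1e-12

    def test_zero_iff_equal(self):
        rng = np.random.default_rng(1)
        p = random_prob_vector(rng, 6)
        q = p.copy()
        q[[0, 1]] = q[[1, 0]] + np.array([0.01, -0.01])
        q = np.abs(q) / np.abs(q).sum()
        assert tv.jsd(p, p) < 1e-12
        assert tv.jsd(p, q) > 0

    def test_input_validation(self):
        with pytest.raises(ValueError, match="length"):
            tv.jsd([1, 0], [1, 0, 0])
        with pytest.raises(ValueError, match="normalized"):
            tv.jsd([0.7, 0.7], [0.5, 0.5])
        with pytest.raises(ValueError, match="non-negative"):
            tv.jsd([1.5, -0.5], [0.5, 0.5])


class TestDissimilarityMatrix:
    def test_identical_rows_all_zero(self):
        table = make_table(["2001-01-05", "2001-02-05"], ["A", "A"])
        dtm = tv.estimate_data_temporal_map(table, "dx")
        dm = tv.dissimilarity_matrix(dtm)
        assert (dm.values == 0).all()

    def test_symmetry_zero_diagonal_and_oracle(self):
        rng = np.random.default_rng(9)
        dates, values = [], []
        for m in range(1, 4):
            for _ in range(60):
                dates.append(dt.date(2012, m, int(rng.integers(1, 28))))
                values.append(str(rng.choice(list("ABC"), p=[0.5, 0.3, 0.2])))
        dtm = tv.estimate_data_temporal_map(make_table(dates, values), "dx")
        dm = tv.dissimilarity_matrix(dtm)
        assert np.array_equal(dm.values, dm.values.T)
        assert (np.diag(dm.values) == 0).all()
        for i in range(3):
            for j in range(3):
                expected = tv.jsd(dtm.probabilities[i], dtm.probabilities[j])
                assert dm.values[i, j] == expected

    def test_missing_batches_excluded(self):
        table = make_table(["2001-01-05", "2001-03-05"], ["A", "B"])
        dtm = tv.estimate_data_temporal_map(table, "dx", missing_policy="zeros")
        dm = tv.dissimilarity_matrix(dtm)
        assert dm.n == 2
        assert dm.batch_dates == [dt.date(2001, 1, 1), dt.date(2001, 3, 1)]

    def test_too_few_batches(self):
        table = make_table(["2001-01-05"], ["A"])
        dtm = tv.estimate_data_temporal_map(table, "dx")
        with pytest.raises(ValueError, match="at least 2"):
            tv.dissimilarity_matrix(dtm)


class TestConsecutiveSeries:
    def test_constant_distribution_gives_zeros(self):
        dates = [dt.date(2010, m, d) for m in range(1, 6) for d in (3, 17)]
        values = ["A", "B"] * 5
        dtm = tv.estimate_data_temporal_map(make_table(dates, values), "dx")
        series = tv.consecutive_dissimilarity_series(dtm)
        assert len(series) == 4
        assert all(v == 0 for _, v in series)

    def test_single_abrupt_change_spikes_once(self):
        dates, values = [], []
        for m in range(1, 7):
            for _ in range(30):
                dates.append(dt.date(2010, m, 10))
                values.append("A" if m < 4 else "B")
        dtm = tv.estimate_data_temporal_map(make_table(dates, values), "dx")
        series = tv.consecutive_dissimilarity_series(dtm)
        nonzero = [i for i, (_, v) in enumerate(series) if v > 0]
        assert nonzero == [2]  # between batches 2 and 3
        assert series[2][0] == dt.date(2010, 4, 1)

    def test_equals_pairwise_oracle(self):
        rng = np.random.default_rng(21)
        dates = [dt.date(2011, m, int(rng.integers(1, 28)))
                 for m in range(1, 9) for _ in range(40)]
        values = [str(rng.choice(list("ABCD"))) for _ in dates]
        dtm = tv.estimate_data_temporal_map(make_table(dates, values), "dx")
        series = tv.consecutive_dissimilarity_series(dtm)
        for i, (_, v) in enumerate(series):
            assert v == tv.jsd(dtm.probabilities[i], dtm.probabilities[i + 1])


class TestClassicalMDS:
    def test_equilateral_triangle(self):
        D = np.ones((3, 3)) - np.eye(3)
        coords, var, _ = classical_mds(D, dims=2)
        got = squareform(pdist(coords))
        np.testing.assert_allclose(got, D, atol=1e-8)

    def test_identical_points_at_origin(self):
        coords, var, _ = classical_mds(np.zeros((4, 4)), dims=2)
        np.testing.assert_allclose(coords, 0, atol=1e-12)
        assert (var == 0).all()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_planar_distance_recovery(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(int(rng.integers(10, 50)), 2))
        D = squareform(pdist(pts))
        coords, var, neg = classical_mds(D / D.max(), dims=2)
        np.testing.assert_allclose(squareform(pdist(coords)), D / D.max(),
                                   atol=1e-8)
        assert neg < 1e-8

    def test_dims_too_large(self):
        with pytest.raises(ValueError, match="dims"):
            classical_mds(np.ones((3, 3)) - np.eye(3), dims=3)

    def test_orientation_first_nonzero_positive(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(12, 2))
        D = squareform(pdist(pts))
        coords, _, _ = classical_mds(D / D.max(), dims=2)
        for j in range(2):
            nz = coords[np.abs(coords[:, j]) > 1e-12, j]
            assert nz[0] > 0


class TestIGTProjection:
    @pytest.fixture
    def trend_dtm(self):
        truth = tv.realize_distributions(tv.scenario_presets(seed=3)["trend"])
        table = tv.sample_records(truth)
        return tv.estimate_data_temporal_map(table, "code")

    def test_variance_explained_non_increasing_and_bounded(self, trend_dtm):
        proj = tv.estimate_igt_projection(trend_dtm, dims=3)
        ve = proj.variance_explained
        assert (np.diff(ve) <= 1e-12).all()
        assert ve.sum() <= 1 + 1e-12

    def test_embedding_approximates_dissimilarities(self, trend_dtm):
        proj = tv.estimate_igt_projection(trend_dtm, dims=3)
        dm = tv.dissimilarity_matrix(trend_dtm)
        approx = squareform(pdist(proj.embedding))
        # leading components dominate, so distances correlate strongly
        corr = np.corrcoef(approx.ravel(), dm.values.ravel())[0, 1]
        assert corr > 0.95

    def test_permutation_equivariance(self):
        """Row order of the data does not change per-batch coordinates."""
        rng = np.random.default_rng(8)
        dates = [dt.date(2015, m, int(rng.integers(1, 28)))
                 for m in range(1, 13) for _ in range(50)]
        values = [str(rng.choice(list("ABCDE"))) for _ in dates]
        table = make_table(dates, values)
        perm = rng.permutation(len(dates))
        shuffled = make_table([dates[i] for i in perm], [values[i] for i in perm])
        p1 = tv.estimate_igt_projection(
            tv.estimate_data_temporal_map(table, "dx"), dims=2)
        p2 = tv.estimate_igt_projection(
            tv.estimate_data_temporal_map(shuffled, "dx"), dims=2)
        np.testing.assert_allclose(p1.embedding, p2.embedding, atol=1e-10)

    def test_labels_and_seasons(self, trend_dtm):
        proj = tv.estimate_igt_projection(trend_dtm, dims=2)
        assert proj.labels[0] == "08J"  # Jan 2008
        assert proj.season_indices[0] == 1

    def test_dims_validation(self, trend_dtm):
        with pytest.raises(ValueError, match="dims"):
            tv.estimate_igt_projection(trend_dtm, dims=200)


class TestBatchLabels:
    @pytest.mark.parametrize("period,granularity,expected", [
        (dt.date(1998, 10, 1), "month", "98O"),
        (dt.date(2002, 7, 1), "month", "02x"),
        (dt.date(2010, 1, 1), "year", "10"),
        (2010, "year", "10"),
    ])
    def test_examples(self, period, granularity, expected):
        assert tv.format_batch_label(period, granularity) == expected

    def test_full_month_letter_cycle(self):
        letters = [tv.format_batch_label(dt.date(2005, m, 1), "month")[2]
                   for m in range(1, 13)]
        assert letters == ["J", "F", "M", "A", "m", "j", "x", "a", "S", "O", "N", "D"]

    def test_week_label_has_iso_week(self):
        lab = tv.format_batch_label(dt.date(2021, 1, 4), "week")
        assert lab == "21Jw01"

    def test_season_index(self):
        assert tv.season_index(dt.date(1998, 10, 1), "month") == 10
        assert tv.season_index(dt.date(2002, 1, 1), "month") == 1
        assert tv.season_index(dt.date(2021, 1, 4), "week") == 1
        with pytest.raises(ValueError, match="not applicable"):
            tv.season_index(dt.date(2000, 1, 1), "year")


class TestTrajectory:
    def _proj(self, coords):
        n = coords.shape[0]
        dates = [dt.date(2010, 1, 1) + dt.timedelta(days=31 * i) for i in range(n)]
        dates = [d.replace(day=1) for d in dates]
        return tv.IGTProjection(
            embedding=coords,
            variance_explained=np.array([0.6, 0.3]),
            batch_dates=dates, granularity="month",
            labels=["x"] * n, season_indices=[1] * n,
        )

    def test_constant_points_unchanged(self):
        coords = np.tile([1.0, 2.0], (8, 1))
        traj = tv.smooth_trajectory(self._proj(coords))
        np.testing.assert_allclose(traj, coords, atol=1e-12)

    def test_linear_points_reproduced(self):
        t = np.arange(10, dtype=float)
        coords = np.column_stack([2 * t + 1, -0.5 * t])
        traj = tv.smooth_trajectory(self._proj(coords))
        np.testing.assert_allclose(traj, coords, atol=1e-8)

    def test_noisy_sinusoid_is_denoised(self):
        rng = np.random.default_rng(12)
        t = np.arange(48, dtype=float)
        clean = np.column_stack([np.sin(2 * np.pi * t / 24), np.cos(2 * np.pi * t / 24)])
        noisy = clean + rng.normal(0, 0.08, size=clean.shape)
        traj = tv.smooth_trajectory(self._proj(noisy))
        mse_raw = np.mean((noisy - clean) ** 2)
        mse_smooth = np.mean((traj - clean) ** 2)
        assert mse_smooth < mse_raw

    def test_too_few_batches(self):
        coords = np.random.default_rng(0).normal(size=(4, 2))
        with pytest.raises(ValueError, match="at least"):
            tv.smooth_trajectory(self._proj(coords))


class TestIGTSerialization:
    def test_round_trip(self, tmp_path):
        truth = tv.realize_distributions(tv.scenario_presets(seed=2)["abrupt"])
        dtm = tv.estimate_data_temporal_map(tv.sample_records(truth), "code")
        proj = tv.estimate_igt_projection(dtm, dims=3, with_trajectory=True)
        tv.save_igt(proj, tmp_path / "igt")
        back = tv.load_igt(tmp_path / "igt")
        np.testing.assert_allclose(back.embedding, proj.embedding, atol=1e-12)
        np.testing.assert_allclose(back.trajectory, proj.trajectory, atol=1e-12)
        np.testing.assert_allclose(back.variance_explained,
                                   proj.variance_explained, atol=1e-12)
        assert back.batch_dates == proj.batch_dates
        assert back.labels == proj.labels
        assert back.season_indices == proj.season_indices
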