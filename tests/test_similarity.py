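"""Shift metrics against brute-force oracles; ratio and DC behavior."""

import numpy as np
import pytest

import oodhar as oh
from oodhar.similarity import DEGENERACY_EPS, dc, distance_ratio, set_distance


def _mmd_triple_loop(X, Y):
    """Independent oracle: literal double sums of the unbiased estimator."""
    n, m = len(X), len(Y)
    xx = sum(X[i] @ X[j] for i in range(n) for j in range(n) if i != j)
    yy = sum(Y[i] @ Y[j] for i in range(m) for j in range(m) if i != j)
    xy = sum(X[i] @ Y[j] for i in range(n) for j in range(m))
    return xx / (n * (n - 1)) + yy / (m * (m - 1)) - 2 * xy / (n * m)


def _w1_sorted_oracle(x, y):
    """Equal-size 1-D Wasserstein-1: mean |sorted(x) - sorted(y)|."""
    return np.abs(np.sort(x) - np.sort(y)).mean()


class TestMMD:
    def test_matches_triple_loop_oracle(self, rng):
        for _ in range(50):
            X = rng.normal(size=(20, 5))
            Y = rng.normal(size=(15, 5)) + rng.normal()
            assert oh.linear_mmd(X, Y) == pytest.approx(_mmd_triple_loop(X, Y),
                                                        abs=1e-9)

    def test_unit_basis_example(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert oh.linear_mmd(X, X) == pytest.approx(-1.0)

    def test_needs_two_rows(self):
        with pytest.raises(ValueError):
            oh.linear_mmd(np.ones((1, 2)), np.ones((3, 2)))


class TestWasserstein:
    def test_matches_sorted_sample_oracle(self, rng):
        for _ in range(50):
            X = rng.normal(size=(30, 4))
            Y = rng.normal(size=(30, 4)) * rng.uniform(0.5, 2.0)
            oracle = np.mean([_w1_sorted_oracle(X[:, j], Y[:, j])
                              for j in range(4)])
            assert oh.mean_wasserstein(X, Y) == pytest.approx(oracle, abs=1e-12)

    def test_point_masses(self):
        assert set_distance("wasserstein", [[0.0]], [[1.0]]) == pytest.approx(1.0)
        A = np.arange(8.0).reshape(4, 2)
        assert set_distance("wasserstein", A, A) == 0.0


class TestCentroidMetrics:
    def test_identical_sets(self, rng):
        A = rng.normal(size=(10, 3))
        assert set_distance("euclidean", A, A) == 0.0
        assert set_distance("cosine", A, A) == pytest.approx(1.0)

    def test_row_permutation_invariance(self, rng):
        A, B = rng.normal(size=(12, 6)), rng.normal(size=(9, 6))
        perm = rng.permutation(12)
        for metric in oh.METRICS:
            assert set_distance(metric, A, B) == pytest.approx(
                set_distance(metric, A[perm], B), abs=1e-12)

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError):
            set_distance("euclidean", rng.normal(size=(3, 2)),
                         rng.normal(size=(3, 4)))


class TestDistanceRatio:
    def test_same_distribution_near_one(self, rng):
        # at representation width (192 dims) the ratio concentrates near 1
        X, Y = rng.normal(size=(150, 192)), rng.normal(size=(70, 192))
        r = distance_ratio("wasserstein", X, Y, n_repeats=30, seed=5)
        assert 0.85 <= r.mean <= 1.25
        assert r.subset_size == 35

    def test_large_shift_inflates_ratio(self, rng):
        X = rng.normal(size=(100, 5))
        Y = rng.normal(size=(60, 5)) + 10.0
        r = distance_ratio("wasserstein", X, Y, n_repeats=30, seed=5)
        assert r.mean > 3.0

    def test_self_ratio_band_for_stable_metrics(self, rng):
        X = rng.normal(size=(120, 10))
        for metric in ("wasserstein", "euclidean"):
            r = distance_ratio(metric, X, X, n_repeats=30, seed=2)
            assert 0.8 <= r.mean <= 1.25, metric

    def test_self_ratio_cosine_on_uncentered_data(self, rng):
        # cosine between centroids is only informative when the centroid
        # is away from the origin (true of raw handcrafted features)
        X = rng.normal(loc=3.0, size=(120, 10))
        r = distance_ratio("cosine", X, X, n_repeats=30, seed=2)
        assert 0.8 <= r.mean <= 1.25

    def test_self_ratio_mmd_finite_and_deterministic(self, rng):
        # the unbiased MMD is mean-zero between same-distribution subsets,
        # so its self-ratio is heavy-tailed; only determinism is contractual
        X = rng.normal(size=(120, 10))
        a = distance_ratio("mmd", X, X, n_repeats=30, seed=2)
        b = distance_ratio("mmd", X, X, n_repeats=30, seed=2)
        assert np.isfinite(a.mean) and a == b

    def test_deterministic(self, rng):
        X, Y = rng.normal(size=(50, 4)), rng.normal(size=(40, 4))
        assert distance_ratio("wasserstein", X, Y, seed=7) == \
            distance_ratio("wasserstein", X, Y, seed=7)

    def test_too_few_rows(self, rng):
        with pytest.raises(ValueError):
            distance_ratio("euclidean", rng.normal(size=(3, 2)),
                           rng.normal(size=(10, 2)))

    def test_degenerate_denominator_rejected(self):
        X = np.zeros((10, 3))
        Y = np.ones((10, 3))
        with pytest.raises(ValueError):
            distance_ratio("euclidean", X, Y, seed=0)


class TestDC:
    def test_identical_subset_gives_p_one(self, rng):
        T = rng.normal(size=(30, 4))
        V = T[:5].copy()
        res = dc(T, V, B=49, seed=0)
        assert res.observed_delta == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == 1.0

    def test_null_calibration_small(self, rng):
        ps = []
        for i in range(50):
            T, V = rng.normal(size=(50, 5)), rng.normal(size=(20, 5))
            ps.append(dc(T, V, B=99, seed=i).p_value)
        ps = np.array(ps)
        assert 0.35 <= ps.mean() <= 0.65
        assert np.mean(ps <= 0.05) <= 0.12

    def test_shift_detected(self, rng):
        T = rng.normal(size=(50, 5))
        V = rng.normal(size=(20, 5)) + 5.0
        assert dc(T, V, B=99, seed=1).p_value <= 0.05

    def test_cosine_base_distance(self, rng):
        T = rng.normal(size=(40, 5))
        V = rng.normal(size=(15, 5))
        res = dc(T, V, d="cosine", B=19, seed=0)
        assert 0.0 < res.p_value <= 1.0 and res.base_distance == "cosine"

    def test_preconditions(self, rng):
        T, V = rng.normal(size=(10, 3)), rng.normal(size=(12, 3))
        with pytest.raises(ValueError):
            dc(T, V)  # |V| >= |T|
        with pytest.raises(ValueError):
            dc(V, T[:5], B=10)  # B too small


class TestShiftReport:
    def test_structure_and_avg_ood(self, tasks, windowset, handcrafted):
        picked = {s: tasks[s][:1] for s in ("ID", "OOD-U", "OOD-MD")}
        picked["OOD-SD"] = tasks["OOD-SD"][:2]
        reps = {}
        pos = {wid: i for i, wid in enumerate(windowset.ids)}
        for ts in picked.values():
            for t in ts:
                tr = [pos[w] for w in t.train_ids]
                te = [pos[w] for w in t.test_ids]
                reps[t] = (handcrafted.values[tr], handcrafted.values[te])
        report = oh.shift_report(picked, reps, metrics=("wasserstein",),
                                 n_repeats=5, dc_permutations=19, seed=0)
        assert list(report.columns) == ["ID", "OOD-U", "OOD-MD", "OOD-SD",
                                        "Avg. OOD"]
        assert set(report.index) == {"wasserstein", "dc_euclidean", "dc_cosine"}
        text = oh.format_shift_report(report)
        assert "±" in text
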