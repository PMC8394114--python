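"""Unit and property tests for the five entropy estimators.

The exact-equivalence tests pit each estimator against an independent
brute-force oracle written with naive loops.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import digamma
from scipy.stats import chi2

from tebench import EmbeddedData, EmbeddingSpec, build_embedding, estimate_te
from tebench.estimators import (
    PartitionCell,
    binned_conditional_entropy,
    binned_entropy,
    chi2_split_stat,
    dv_partition,
    kde_bandwidth,
    kde_entropy,
    knn_entropy,
    partition_conditional_entropy,
    rank_transform,
    te_dvp,
    te_fbr,
    te_kde,
    te_knn,
    te_linear,
)


def _random_embedded(seed, R=60, coupled=True):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(R + 1)
    y = rng.standard_normal(R + 1)
    if coupled:
        y[1:] += 0.5 * x[:-1]
    return build_embedding(x, y, EmbeddingSpec(tau=1))


# ---------------------------------------------------------------------------
# ordinal sampling
# ---------------------------------------------------------------------------

class TestRankTransform:
    def test_basic_example(self):
        assert list(rank_transform([0.3, -1.2, 5.0])) == [2, 1, 3]

    def test_sorted_input_is_identity(self):
        n = 17
        assert list(rank_transform(np.arange(n) * 0.5 - 3)) == list(range(1, n + 1))

    def test_ties_resolved_by_first_occurrence(self):
        assert list(rank_transform([5.0, 5.0, 1.0])) == [2, 3, 1]

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=200))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_ranks_are_permutation(self, values):
        ranks = rank_transform(values)
        assert sorted(ranks) == list(range(1, len(values) + 1))

    def test_order_preserving_on_distinct_values(self):
        rng = np.random.default_rng(5)
        v = rng.standard_normal(80)
        r = rank_transform(v)
        assert np.array_equal(np.argsort(v, kind="stable"), np.argsort(r))


# ---------------------------------------------------------------------------
# LIN
# ---------------------------------------------------------------------------

class TestLinear:
    def test_matches_ols_residual_variance_oracle(self):
        """LIN equals 0.5*log(SSR_restricted/SSR_full) from explicit
        normal-equation OLS fits, to 10 significant digits."""
        for seed in range(5):
            e = _random_embedded(seed)
            dep = e.target_present

            def ssr(X):
                A = np.column_stack([np.ones(len(dep)), X])
                beta = np.linalg.solve(A.T @ A, A.T @ dep)
                r = dep - A @ beta
                return r @ r

            oracle = 0.5 * np.log(
                ssr(e.target_past)
                / ssr(np.column_stack([e.driver_past, e.target_past]))
            )
            assert te_linear(e).value == pytest.approx(oracle, rel=1e-10)

    def test_uncoupled_median_near_zero(self):
        te = [te_linear(_random_embedded(s, R=199, coupled=False)).value
              for s in range(50)]
        assert 0 <= np.median(te) < 0.02

    def test_constant_driver_rejected(self):
        e = _random_embedded(0)
        e.driver_past[:] = 1.0
        with pytest.raises(ValueError, match="singular"):
            te_linear(e)

    def test_affine_invariance_exact(self):
        rng = np.random.default_rng(11)
        x, y = rng.standard_normal(120), rng.standard_normal(120)
        spec = EmbeddingSpec(tau=2)
        a = estimate_te(x, y, spec, "LIN").value
        b = estimate_te(3.5 * x - 2.0, -0.25 * y + 7.0, spec, "LIN").value
        assert a == pytest.approx(b, rel=1e-9)

    def test_nonnegative_up_to_roundoff(self):
        for s in range(20):
            assert te_linear(_random_embedded(s, coupled=False)).value > -1e-12


# ---------------------------------------------------------------------------
# KNN
# ---------------------------------------------------------------------------

def _brute_knn_entropy(points, k):
    """Loop-based Kozachenko-Leonenko entropy with max-norm distances."""
    R, d = points.shape
    log_eps = []
    for i in range(R):
        dists = sorted(
            max(abs(points[i, c] - points[j, c]) for c in range(d))
            for j in range(R) if j != i
        )
        log_eps.append(np.log(2.0 * dists[k - 1]))
    return -digamma(k) + digamma(R) + d * np.mean(log_eps)


def _brute_te_knn(e, k):
    """Loop-based Kraskov/Frenzel-Pompe conditional-MI transfer entropy."""
    joint = e.full_joint()
    R = joint.shape[0]
    m = e.driver_past.shape[1]
    cols = {"y_ypast": [0] + list(range(1 + m, joint.shape[1])),
            "pasts": list(range(1, joint.shape[1])),
            "ypast": list(range(1 + m, joint.shape[1]))}

    def dist(i, j, idx):
        return max(abs(joint[i, c] - joint[j, c]) for c in idx)

    total = 0.0
    for i in range(R):
        eps = sorted(dist(i, j, range(joint.shape[1]))
                     for j in range(R) if j != i)[k - 1]
        counts = {}
        for name, idx in cols.items():
            counts[name] = sum(
                1 for j in range(R) if j != i and dist(i, j, idx) < eps
            )
        total += (digamma(counts["y_ypast"] + 1) + digamma(counts["pasts"] + 1)
                  - digamma(counts["ypast"] + 1))
    return float(digamma(k) - total / R)


class TestKnn:
    def test_entropy_matches_brute_force(self):
        rng = np.random.default_rng(2)
        points = rng.standard_normal((20, 3))
        for k in (1, 3, 5):
            assert knn_entropy(points, k) == pytest.approx(
                _brute_knn_entropy(points, k), rel=1e-10
            )

    @pytest.mark.parametrize("seed,R,k", [(0, 30, 3), (1, 50, 5), (2, 40, 8)])
    def test_te_matches_brute_force_oracle(self, seed, R, k):
        e = _random_embedded(seed, R=R)
        assert te_knn(e, k=k, jitter=False).value == pytest.approx(
            _brute_te_knn(e, k), rel=1e-10
        )

    def test_k_must_be_smaller_than_rows(self):
        e = _random_embedded(0, R=30)
        with pytest.raises(ValueError):
            te_knn(e, k=30)
        with pytest.raises(ValueError):
            knn_entropy(np.random.default_rng(0).standard_normal((10, 2)), 10)

    def test_independent_median_near_zero(self, independent_medians):
        """KNN is approximately unbiased; single trials may be negative."""
        assert abs(independent_medians["KNN"]) < 0.05


# ---------------------------------------------------------------------------
# FBR
# ---------------------------------------------------------------------------

class TestFbr:
    def test_ranked_uniform_data_fills_bins_evenly(self):
        # a permutation of 1..R in every dimension: Q=4 equal-width bins in
        # rank space are equal-frequency bins
        R, Q = 200, 4
        perm = np.random.default_rng(0).permutation(R) + 1.0
        assert binned_entropy(perm.reshape(-1, 1), Q) == pytest.approx(np.log(Q))

    def test_hand_counted_conditional_entropy(self):
        # 12 points, Q=2: occupancies hand-counted from the construction
        u = np.arange(1.0, 13.0)                                   # 6 | 6
        v = np.array([1, 2, 3, 4, 5, 12, 6, 7, 8, 9, 10, 11.0])    # see below
        # u-bins: {1..6}, {7..12}; v-bins: {<=6}, {>6}
        # u-bin 1 holds v = [1,2,3,4,5,12] -> r=(5,1)
        # u-bin 2 holds v = [6,7,8,9,10,11] -> r=(1,5)
        hand = -(
            5 * np.log(5 / 6) + 1 * np.log(1 / 6)
            + 1 * np.log(1 / 6) + 5 * np.log(5 / 6)
        ) / 12
        got = binned_conditional_entropy(v.reshape(-1, 1), u.reshape(-1, 1), 2)
        assert got == pytest.approx(hand, rel=1e-12)

    def test_q_larger_than_rows_rejected(self):
        e = _random_embedded(0, R=30)
        with pytest.raises(ValueError):
            te_fbr(e, Q=31)
        with pytest.raises(ValueError):
            te_fbr(e, Q=1)

    def test_positive_bias_on_independent_pairs(self, independent_medians):
        assert independent_medians["FBR"] > 0.0


# ---------------------------------------------------------------------------
# KDE
# ---------------------------------------------------------------------------

class TestKde:
    def test_bandwidth_arithmetic(self):
        assert kde_bandwidth(1.0, 200, 1.0) == pytest.approx(0.3674, abs=5e-5)
        assert kde_bandwidth(2.0, 200, 1.5) == pytest.approx(
            1.06 * 1.5 * 2.0 * 200 ** -0.2
        )

    def test_entropy_matches_double_sum_oracle(self):
        rng = np.random.default_rng(4)
        points = rng.standard_normal((10, 2)) * [1.0, 3.0]
        alpha = 1.25
        R, d = points.shape
        h = 1.06 * alpha * points.std(axis=0, ddof=1) * R ** -0.2
        logp = []
        for i in range(R):
            dens = 0.0
            for j in range(R):
                k = 1.0
                for c in range(d):
                    u = (points[i, c] - points[j, c]) / h[c]
                    k *= np.exp(-0.5 * u * u) / (h[c] * np.sqrt(2 * np.pi))
                dens += k / R
            logp.append(np.log(dens))
        assert kde_entropy(points, alpha) == pytest.approx(-np.mean(logp), rel=1e-10)

    def test_zero_variance_dimension_rejected(self):
        e = _random_embedded(0)
        e.driver_past[:] = 2.0
        with pytest.raises(ValueError, match="variance"):
            te_kde(e, alpha=1.0)
        with pytest.raises(ValueError):
            te_kde(_random_embedded(1), alpha=-0.5)

    def test_positive_bias_on_independent_pairs(self, independent_medians):
        assert independent_medians["KDE"] > 0.0


# ---------------------------------------------------------------------------
# DVP
# ---------------------------------------------------------------------------

class TestChi2SplitStat:
    def test_even_counts_give_zero(self):
        assert chi2_split_stat([10] * 8) == 0.0

    def test_concentrated_counts_arithmetic(self):
        assert chi2_split_stat([80, 0, 0, 0, 0, 0, 0, 0]) == 5600.0

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            chi2_split_stat([1, 2, 3])

    def test_critical_value(self):
        assert chi2.ppf(0.95, 7) == pytest.approx(14.067, abs=5e-4)


class TestDvPartition:
    def test_even_occupancy_keeps_single_cell(self):
        # 8 octants x 10 points each: evenness statistic is exactly 0
        corners = np.array(
            [[i, j, k] for i in (1.0, 2.0) for j in (1.0, 2.0) for k in (1.0, 2.0)]
        )
        points = np.repeat(corners, 10, axis=0)
        cells = dv_partition(points)
        assert len(cells) == 1
        assert cells[0].count == 80

    def test_concentrated_points_force_root_split(self):
        rng = np.random.default_rng(0)
        cluster = rng.uniform(1, 10, size=(76, 3))
        far = rng.uniform(90, 99, size=(4, 3))
        cells = dv_partition(np.vstack([cluster, far]))
        assert len(cells) > 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            dv_partition(np.empty((0, 3)))

    @given(st.integers(0, 1000), st.integers(2, 3), st.integers(20, 150))
    @settings(deadline=None, max_examples=30, derandomize=True)
    def test_counts_conserved_and_cells_disjoint(self, seed, d, R):
        rng = np.random.default_rng(seed)
        pts = np.column_stack(
            [rng.permutation(R) + 1.0 for _ in range(d)]
        )
        cells = dv_partition(pts)
        assert sum(c.count for c in cells) == R
        membership = np.zeros(R, dtype=int)
        for cell in cells:
            inside = np.ones(R, dtype=bool)
            for j in range(d):
                inside &= (pts[:, j] >= cell.lower[j]) & (pts[:, j] < cell.upper[j])
            assert inside.sum() == cell.count
            membership += inside
        assert np.all(membership == 1)

    def test_children_mode_keeps_subcells(self):
        corners = np.array(
            [[i, j, k] for i in (1.0, 2.0) for j in (1.0, 2.0) for k in (1.0, 2.0)]
        )
        points = np.repeat(corners, 10, axis=0)
        cells = dv_partition(points, on_accept="children")
        assert len(cells) == 8


class TestTeDvp:
    def test_single_cell_conditional_entropy_is_zero(self):
        # one cell covering everything: p(v | rest) = 1 in every cell,
        # the analytic value for a partition that does not resolve V
        rng = np.random.default_rng(1)
        pts = np.column_stack([rng.permutation(40) + 1.0 for _ in range(2)])
        cell = PartitionCell(pts.min(0) - 0.5, pts.max(0) + 0.5, 40)
        assert partition_conditional_entropy(pts, [cell]) == 0.0

    def test_two_cell_partition_matches_hand_count(self):
        # 2-D points, partition split only along the conditioning axis:
        # conditional entropy follows from the per-cell counts directly
        v = np.array([1.0, 2, 3, 4, 5, 6, 7, 8])
        w = np.array([1.0, 5, 2, 6, 3, 7, 4, 8])
        pts = np.column_stack([v, w])
        cells = [
            PartitionCell([0.5, 0.5], [8.5, 4.5], 4),
            PartitionCell([0.5, 4.5], [8.5, 8.5], 4),
        ]
        # every cell: r = 4, conditioning count = 4 -> H = 0
        assert partition_conditional_entropy(pts, cells) == pytest.approx(0.0)
        # split along V instead: r=4 cells but conditioning counts are 8
        cells_v = [
            PartitionCell([0.5, 0.5], [4.5, 8.5], 4),
            PartitionCell([4.5, 0.5], [8.5, 8.5], 4),
        ]
        assert partition_conditional_entropy(pts, cells_v) == pytest.approx(np.log(2))

    def test_monotone_invariance_exact(self):
        rng = np.random.default_rng(9)
        x, y = rng.standard_normal(150), rng.standard_normal(150)
        spec = EmbeddingSpec(tau=1)
        a = estimate_te(x, y, spec, "DVP").value
        b = estimate_te(np.exp(x), y ** 3, spec, "DVP").value
        assert a == b

    def test_independent_median_near_zero(self, independent_medians):
        assert abs(independent_medians["DVP"]) < 0.05


# ---------------------------------------------------------------------------
# shared estimator properties
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "fn,params",
    [
        (te_linear, {}),
        (te_knn, {"k": 4, "jitter": False}),
        (te_fbr, {"Q": 4}),
        (te_kde, {"alpha": 1.0}),
        (te_dvp, {}),
    ],
)
def test_row_permutation_invariance(fn, params):
    """Every estimator is a function of the point cloud, not of row order."""
    e = _random_embedded(13, R=80)
    perm = np.random.default_rng(42).permutation(e.rows)
    shuffled = EmbeddedData(
        e.target_present[perm], e.driver_past[perm], e.target_past[perm]
    )
    assert fn(e, **params).value == pytest.approx(
        fn(shuffled, **params).value, rel=1e-9, abs=1e-12
    )


def test_bias_ordering_on_independent_pairs(independent_medians):
    """Binned and kernel plug-in estimators are positively biased; the
    linear and adaptive-partitioning ones are not."""
    m = independent_medians
    assert m["FBR"] > max(m["LIN"], m["DVP"])
    assert m["KDE"] > max(m["LIN"], m["DVP"])
    assert abs(m["LIN"]) < 0.05
    assert abs(m["DVP"]) < 0.05
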