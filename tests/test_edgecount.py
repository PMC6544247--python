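"""Within-group edge counts, exact null moments, statistic and p-values."""

import itertools

import numpy as np
import pytest
from scipy import stats

from edgescreen.edgecount import (
    GroupLabels,
    count_within_group_edges,
    null_moments,
    edge_count_statistic,
    permutation_pvalue,
    edge_count_test,
)
from edgescreen.graph import SimilarityGraph, kmst_1d
from conftest import (
    moments_by_enumeration,
    within_counts_bruteforce,
    enumerate_label_assignments,
)


class TestCountWithinGroupEdges:
    def test_labeled_path_hand_count(self, path5):
        R = count_within_group_edges(path5, [1, 1, 2, 2, 1])
        assert R.tolist() == [1, 1]

    def test_single_label_counts_all_edges(self, path5):
        R = count_within_group_edges(path5, [1, 1, 1, 1, 1])
        assert R.tolist() == [4]

    def test_matches_naive_double_loop(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 12))
            pairs = list(itertools.combinations(range(n), 2))
            m = int(rng.integers(1, len(pairs)))
            idx = rng.choice(len(pairs), size=m, replace=False)
            g = SimilarityGraph(n_nodes=n, edges=np.array([pairs[i] for i in idx]))
            y = rng.integers(0, 3, n)
            lab = GroupLabels.from_array(y)
            expected = within_counts_bruteforce(g.edges, lab.y, lab.J)
            assert np.array_equal(count_within_group_edges(g, lab), expected)

    def test_length_mismatch_rejected(self, path5):
        with pytest.raises(ValueError, match="match"):
            count_within_group_edges(path5, [0, 1, 0])


class TestNullMoments:
    def test_path5_expectation_hand_value(self, path5):
        m = null_moments(path5, [0, 0, 0, 1, 1])
        assert m.mean == pytest.approx([1.2, 0.4])

    def test_path5_matches_enumeration(self, path5):
        m = null_moments(path5, [0, 0, 0, 1, 1])
        mean_e, cov_e = moments_by_enumeration(path5, (3, 2))
        assert np.allclose(m.mean, mean_e, atol=1e-10)
        assert np.allclose(m.cov, cov_e, atol=1e-10)

    def test_singleton_group_degenerate(self, path5):
        m = null_moments(path5, [0, 0, 0, 0, 1])
        assert m.mean[1] == 0
        assert np.allclose(m.cov[1], 0, atol=1e-12)

    def test_random_graphs_match_enumeration(self, rng):
        """Analytic moments vs exhaustive label-permutation enumeration."""
        for _ in range(8):
            n = int(rng.integers(4, 8))
            pairs = list(itertools.combinations(range(n), 2))
            m_edges = int(rng.integers(n - 1, len(pairs)))
            idx = rng.choice(len(pairs), size=m_edges, replace=False)
            g = SimilarityGraph(n_nodes=n, edges=np.array([pairs[i] for i in idx]))
            n1 = int(rng.integers(1, n - 1))
            sizes = (n1, n - n1)
            y = np.repeat([0, 1], sizes)
            m = null_moments(g, y)
            mean_e, cov_e = moments_by_enumeration(g, sizes)
            assert np.allclose(m.mean, mean_e, atol=1e-10)
            assert np.allclose(m.cov, cov_e, atol=1e-10)

    def test_small_N_rejected(self):
        g = SimilarityGraph(n_nodes=3, edges=np.array([[0, 1], [1, 2]]))
        with pytest.raises(ValueError, match="N-3|N >= 4"):
            null_moments(g, [0, 0, 1])


class TestEdgeCountStatistic:
    def test_zero_deviation_gives_p_one(self, path5):
        m = null_moments(path5, [0, 0, 0, 1, 1])
        res = edge_count_statistic(m.mean, m)
        assert res.S == 0.0 and res.p_value == 1.0

    def test_two_by_two_hand_inverse(self):
        """S against the explicit 2x2 inverse algebra."""
        from edgescreen.edgecount import NullMoments

        mean = np.array([2.0, 1.0])
        cov = np.array([[2.0, 0.5], [0.5, 1.0]])
        R = np.array([4.0, 0.0])
        det = 2.0 * 1.0 - 0.5 * 0.5
        inv = np.array([[1.0, -0.5], [-0.5, 2.0]]) / det
        d = R - mean
        expected = float(d @ inv @ d)
        res = edge_count_statistic(R, NullMoments(mean=mean, cov=cov))
        assert res.S == pytest.approx(expected, rel=1e-12)
        assert res.p_value == pytest.approx(float(stats.chi2.sf(expected, 2)))

    def test_degenerate_cov_flagged(self):
        from edgescreen.edgecount import NullMoments

        res = edge_count_statistic(
            np.array([0.0, 0.0]),
            NullMoments(mean=np.zeros(2), cov=np.zeros((2, 2))),
        )
        assert res.degenerate and res.p_value == 1.0 and res.S == 0.0

    def test_null_statistic_close_to_chisq(self, rng):
        """Simulated null S distribution tracks chi-square with J=2 df."""
        y = np.repeat([0, 1], 100)
        S = np.array([
            edge_count_test(rng.normal(size=200), y, k=3, mode="asymptotic").S
            for _ in range(300)
        ])
        # compare empirical quantiles of S with chi2(2)
        qs = np.quantile(S, [0.25, 0.5, 0.75])
        expected = stats.chi2.ppf([0.25, 0.5, 0.75], 2)
        assert np.allclose(qs, expected, atol=0.45)


class TestPermutationPvalue:
    def test_exhaustive_balanced_enumeration(self, rng):
        """Monte-Carlo permutation p vs the exact p over all 20 assignments."""
        x = rng.normal(size=6)
        g = kmst_1d(x, 1)
        y = np.array([0, 0, 0, 1, 1, 1])
        m = null_moments(g, y)
        from edgescreen.edgecount import _invert_cov, _statistic_only

        vinv = _invert_cov(m.cov)
        S_obs = _statistic_only(count_within_group_edges(g, y), m.mean, vinv)
        exact_ge = 0
        assignments = enumerate_label_assignments(6, (3, 3))
        for ya in assignments:
            S = _statistic_only(
                within_counts_bruteforce(g.edges, ya, 2), m.mean, vinv
            )
            exact_ge += S >= S_obs
        p_exact = exact_ge / len(assignments)
        res = permutation_pvalue(g, y, B=4000, seed=0)
        assert res.p_value == pytest.approx(p_exact, abs=3 * 0.5 / np.sqrt(4000))

    def test_constant_feature_gives_p_one(self):
        res = edge_count_test(np.ones(12), np.repeat([0, 1], 6),
                              k=1, mode="permutation", B=50, seed=1)
        assert res.p_value == 1.0

    def test_reproducible_under_seed(self, rng):
        x = rng.normal(size=20)
        y = np.repeat([0, 1], 10)
        g = kmst_1d(x, 2)
        p1 = permutation_pvalue(g, y, B=200, seed=42).p_value
        p2 = permutation_pvalue(g, y, B=200, seed=42).p_value
        assert p1 == p2


class TestEdgeCountTest:
    def test_separated_groups_rejected(self, rng):
        x = np.concatenate([rng.normal(0, 1, 30), rng.normal(5, 1, 30)])
        y = np.repeat([0, 1], 30)
        assert edge_count_test(x, y, k=3).p_value < 0.01

    def test_null_pvalues_uniform(self, rng):
        """Shuffled labels give approximately U(0,1) p-values."""
        pvals = []
        y = np.repeat([0, 1], 50)
        for _ in range(250):
            x = rng.normal(size=100)
            pvals.append(edge_count_test(x, rng.permutation(y), k=3,
                                         mode="asymptotic").p_value)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_three_equal_groups_nominal_rate(self, rng):
        y = np.repeat([0, 1, 2], 30)
        rej = sum(
            edge_count_test(rng.normal(size=90), y, k=3,
                            mode="asymptotic").p_value < 0.05
            for _ in range(400)
        )
        assert 0.02 <= rej / 400 <= 0.08

    def test_auto_mode_small_groups_uses_permutation(self, rng):
        x = rng.normal(size=16)
        y = np.repeat([0, 1], 8)
        res = edge_count_test(x, y, k=2, mode="auto", B=99, seed=0)
        assert res.method == "permutation"
        res = edge_count_test(rng.normal(size=40), np.repeat([0, 1], 20),
                              k=2, mode="auto")
        assert res.method == "asymptotic"

    def test_multivariate_feature_set_supported(self, rng):
        x = np.vstack([rng.normal(0, 1, (25, 3)), rng.normal(2, 1, (25, 3))])
        y = np.repeat([0, 1], 25)
        assert edge_count_test(x, y, k=3).p_value < 0.01


class TestProperties:
    def test_edge_conservation(self, rng):
        """Within-group counts plus between-group edges equal |G|."""
        for _ in range(10):
            n = int(rng.integers(10, 40))
            x = rng.normal(size=n)
            k = int(rng.integers(1, 4))
            if k > n // 2:
                continue
            g = kmst_1d(x, k)
            y = rng.integers(0, 3, n)
            lab = GroupLabels.from_array(y)
            R = count_within_group_edges(g, lab)
            yu, yv = lab.y[g.edges[:, 0]], lab.y[g.edges[:, 1]]
            between = int(np.sum(yu != yv))
            assert R.sum() + between == g.n_edges

    def test_power_monotone_in_location_shift(self, rng):
        y = np.repeat([0, 1], 30)
        powers = []
        for shift in (0.3, 0.8, 1.5):
            rej = 0
            for _ in range(200):
                x = np.concatenate([rng.normal(0, 1, 30),
                                    rng.normal(shift, 1, 30)])
                rej += edge_count_test(x, y, k=3, mode="asymptotic").p_value < 0.05
            powers.append(rej / 200)
        assert powers[0] < powers[1] < powers[2]

    def test_asymptotic_permutation_agreement(self, rng):
        """Median |p_asym - p_perm| small for moderate group sizes."""
        y = np.repeat([0, 1], 50)
        diffs = []
        for _ in range(60):
            x = rng.normal(size=100)
            g = kmst_1d(x, 3)
            p_perm = permutation_pvalue(g, y, B=2000, seed=rng.integers(2**31)).p_value
            R = count_within_group_edges(g, GroupLabels.from_array(y))
            p_asym = edge_count_statistic(R, null_moments(g, y)).p_value
            diffs.append(abs(p_perm - p_asym))
        assert np.median(diffs) < 0.02
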