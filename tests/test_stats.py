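"""Statistics layer: Spearman, BH-FDR, networks, splits, rank tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from vitacyt import (
    CohortSpec,
    bh_adjust,
    classify_uc_activity,
    correlation_network,
    mann_whitney,
    median_split,
    shannon_diversity,
    simulate_cohort,
    spearman_rho,
)
from vitacyt.stats import kruskal_dunn


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        assert spearman_rho(x, x ** 3)[0] == pytest.approx(1.0)
        assert spearman_rho(x, -x)[0] == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # d^2 = (1,1,1,1,0) -> rho = 1 - 6*4/(5*24) = 0.8
        rho, _ = spearman_rho([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert rho == pytest.approx(0.8)

    def test_matches_rank_pearson_oracle_with_ties(self):
        """Mid-rank Pearson oracle agrees to 1e-12 on tied random vectors."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.integers(0, 5, size=30).astype(float)
            y = rng.integers(0, 5, size=30).astype(float) + 0.3 * x
            rho, _ = spearman_rho(x, y)
            oracle = np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1]
            assert rho == pytest.approx(oracle, abs=1e-12)

    def test_pairwise_complete_and_errors(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0, 6.0]
        y = [2.0, 3.0, 9.0, 5.0, np.nan, 7.0]
        rho, _ = spearman_rho(x, y)
        assert rho == pytest.approx(1.0)
        with pytest.raises(ValueError, match="zero variance"):
            spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])
        with pytest.raises(ValueError, match="complete pairs"):
            spearman_rho([1, 2], [3, 4])


class TestBhAdjust:
    @pytest.mark.parametrize("pvals,expected", [
        ([0.04], [0.04]),
        ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
        ([0.001, 0.5], [0.002, 0.5]),
    ])
    def test_hand_computed_triples(self, pvals, expected):
        assert bh_adjust(pvals) == pytest.approx(expected)

    def test_never_decreases_and_order_preserving(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=50)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestCorrelationNetwork:
    def test_duplicated_variable_perfect_edge(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"x": rng.normal(size=30)})
        df["x_copy"] = df["x"]
        df["noise"] = rng.normal(size=30)
        net = correlation_network(df, ["x", "x_copy", "noise"])
        pair = net.edges.set_index(["var_a", "var_b"])
        assert pair.loc[("x", "x_copy"), "rho"] == pytest.approx(1.0)
        assert net.graph.has_edge("x", "x_copy")

    def test_generator_correlation_detected(self):
        res = simulate_cohort(CohortSpec(n_subjects=100, seed=23))
        net = correlation_network(res.cohort, ["living_rate", "calprotectin"])
        assert len(net.edges) == 1
        assert net.edges.rho.iloc[0] < 0

    def test_null_edge_rate_controlled(self):
        """Across 200 seeded null replicates, edge frequency <= alpha + 2 SE."""
        rng = np.random.default_rng(3)
        alpha = 0.05
        hits = 0
        for _ in range(200):
            df = pd.DataFrame(rng.normal(size=(40, 2)), columns=["a", "b"])
            hits += len(correlation_network(df, ["a", "b"], alpha).edges) > 0
        assert hits / 200 <= alpha + 2 * np.sqrt(alpha * (1 - alpha) / 200)

    def test_missing_variable_rejected(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(ValueError, match="absent"):
            correlation_network(df, ["a", "zz"])


class TestMedianSplit:
    def test_boundary_goes_high(self):
        thr, low, high = median_split([40.0, 50.0, 60.0])
        assert thr == 50.0
        assert list(low) == [40.0]
        assert sorted(high) == [50.0, 60.0]

    def test_all_equal_low_empty(self):
        _, low, high = median_split([5.0, 5.0, 5.0])
        assert low.size == 0 and high.size == 3

    def test_cohort_split_uses_its_own_median(self, default_cohort):
        rates = default_cohort.cohort.living_rate.to_numpy()
        thr, low, high = median_split(rates)
        assert thr == np.median(rates)
        assert low.size + high.size == rates.size


class TestMannWhitney:
    def test_identical_samples_p_one(self):
        x = np.arange(8.0)
        _, p = mann_whitney(x, x)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_complete_separation_u_zero(self):
        u, p = mann_whitney([1.0, 2.0], [3.0, 4.0])
        assert u == 0.0
        assert p == pytest.approx(2 / 6, abs=1e-9)  # 2 of C(4,2) assignments as extreme

    def test_exact_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            x = rng.integers(0, 6, size=5).astype(float)
            y = rng.integers(0, 6, size=6).astype(float)
            u_obs, p = mann_whitney(x, y)
            pooled = np.concatenate([x, y])
            ranks = sps.rankdata(pooled)
            mu = len(x) * len(y) / 2
            d_obs = abs(u_obs - mu)
            hits = total = 0
            for idx in itertools.combinations(range(11), 5):
                u = ranks[list(idx)].sum() - 5 * 6 / 2
                total += 1
                hits += abs(u - mu) >= d_obs - 1e-12
            assert p == pytest.approx(hits / total, abs=1e-12)

    def test_normal_approximation_close_to_exact_small_n(self):
        """Continuity-corrected asymptotic p tracks exact enumeration over the
        whole U distribution at m = n = 6 (worst case 0.0155 by enumeration)."""
        m = n = 6
        ranks = np.arange(1, m + n + 1)
        us = np.array([ranks[list(idx)].sum() - m * (m + 1) / 2
                       for idx in itertools.combinations(range(m + n), m)])
        mu = m * n / 2
        sigma = np.sqrt(m * n * (m + n + 1) / 12.0)
        for u_obs in np.unique(us):
            d = abs(u_obs - mu)
            p_exact = (np.abs(us - mu) >= d - 1e-12).mean()
            p_norm = min(1.0, 2 * sps.norm.sf((d - 0.5) / sigma))
            assert abs(p_norm - p_exact) <= 0.016

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mann_whitney([], [1.0])

    def test_detects_generator_group_difference(self, default_cohort):
        """Median split by living rate separates calprotectin (negative
        coupling in the generator)."""
        df = default_cohort.cohort
        thr = np.median(df.living_rate)
        low = df.calprotectin[df.living_rate < thr]
        high = df.calprotectin[df.living_rate >= thr]
        _, p = mann_whitney(low, high)
        assert p < 0.05
        assert low.median() > high.median()


class TestShannonAndMayo:
    @pytest.mark.parametrize("abund,expected", [
        ([7.0], 0.0),
        ([1, 1, 1, 1], 2.0),
        ([0.5, 0.25, 0.25], 1.5),
        ([2, 1, 1, 0], 1.5),   # zeros dropped, counts normalised
    ])
    def test_shannon_bits(self, abund, expected):
        assert shannon_diversity(abund) == pytest.approx(expected)

    def test_shannon_errors(self):
        with pytest.raises(ValueError):
            shannon_diversity([0.0, 0.0])
        with pytest.raises(ValueError):
            shannon_diversity([-1.0, 2.0])

    @pytest.mark.parametrize("mayo,sub,expected", [
        (3, 1, "active"), (7, 3, "active"),
        (1, 1, "inactive"), (0, 0, "inactive"),
        (2, 1, "intermediate"), (1, 2, "intermediate"),
    ])
    def test_mayo_classification(self, mayo, sub, expected):
        assert classify_uc_activity(mayo, sub) == expected

    def test_mayo_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_uc_activity(-1, 0)


def test_kruskal_dunn_flags_shifted_group():
    rng = np.random.default_rng(6)
    groups = {
        "HA": rng.normal(10.9, 0.3, size=25),
        "inUC": rng.normal(10.8, 0.3, size=18),
        "aUC": rng.normal(10.3, 0.4, size=17),
    }
    out = kruskal_dunn(groups)
    assert out.attrs["kruskal_p"] < 0.01
    sig = out[out.q < 0.05]
    assert {"aUC"} <= set(sig.group_a) | set(sig.group_b)
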