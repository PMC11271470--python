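import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import squareform

import skbio.diversity.alpha as skalpha
from skbio import DistanceMatrix
from skbio.stats.distance import anosim as skbio_anosim

from enterodyn import diversity as dv


class TestChao1:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            # 10 taxa, no singletons or doubletons -> S_obs
            ([3] * 10, 10.0),
            # S_obs=10, F1=4, F2=2 -> 10 + 4*3/6
            ([1, 1, 1, 1, 2, 2, 3, 3, 3, 3], 12.0),
            # all five taxa singletons -> 5 + 5*4/2
            ([1, 1, 1, 1, 1], 15.0),
        ],
    )
    def test_closed_form(self, counts, expected):
        assert dv.chao1(counts) == pytest.approx(expected)

    def test_never_below_observed_richness(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            c = rng.integers(0, 5, size=30)
            if not (c > 0).any():
                continue
            assert dv.chao1(c) >= (c > 0).sum()

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            dv.chao1([0, 0, 0])


class TestShannon:
    @pytest.mark.parametrize(
        "p, base, expected",
        [
            ([1.0], None, 0.0),
            ([0.25] * 4, None, np.log(4)),
            ([0.5, 0.25, 0.25], None, 1.0397207708399179),
            ([0.25] * 4, 2, 2.0),
        ],
    )
    def test_reference_values(self, p, base, expected):
        assert dv.shannon(p, base=base) == pytest.approx(expected, abs=1e-9)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            dv.shannon([1.2, -0.2])

    def test_bounded_by_log_richness(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            p = rng.dirichlet(np.ones(12))
            assert 0.0 <= dv.shannon(p) <= np.log(12) + 1e-12


class TestBrayCurtis:
    def test_reference_values(self):
        tbl = pd.DataFrame(
            {"same1": [0.7, 0.3], "same2": [0.7, 0.3],
             "flip": [0.3, 0.7]},
            index=["a", "b"],
        )
        d = dv.bray_curtis(tbl)
        assert d["same1", "same2"] == pytest.approx(0.0)
        assert d["same1", "flip"] == pytest.approx(0.4)

    def test_disjoint_supports_are_maximally_distant(self):
        tbl = pd.DataFrame({"x": [1.0, 0.0], "y": [0.0, 1.0]}, index=["a", "b"])
        assert dv.bray_curtis(tbl)["x", "y"] == pytest.approx(1.0)


def test_alpha_and_beta_match_reference_implementation():
    """Chao1, Shannon and Bray-Curtis agree with scikit-bio on random tables."""
    rng = np.random.default_rng(42)
    for _ in range(20):
        counts = rng.integers(0, 40, size=12)
        if not (counts > 0).any():
            continue
        assert dv.chao1(counts) == pytest.approx(
            skalpha.chao1(counts, bias_corrected=True), abs=1e-9
        )
        p = counts / counts.sum()
        assert dv.shannon(p) == pytest.approx(
            skalpha.shannon(counts, base=np.e), abs=1e-9
        )
    tbl = pd.DataFrame(rng.dirichlet(np.ones(8), size=6).T,
                       index=[f"t{i}" for i in range(8)],
                       columns=[f"s{j}" for j in range(6)])
    import skbio.diversity as skdiv

    ours = dv.bray_curtis(tbl).data
    ref = skdiv.beta_diversity(
        "braycurtis", tbl.to_numpy().T, ids=list(tbl.columns)
    ).data
    np.testing.assert_allclose(ours, ref, atol=1e-9)


class TestKruskalDunn:
    def test_identical_groups_give_zero_h(self):
        res = dv.kruskal_dunn([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value > 0.9

    def test_three_group_rank_formula_oracle(self):
        # values 1..9 split 3/3/3 in order: rank sums 6/15/24 give
        # H = 12/(N(N+1)) * sum R_g^2/n_g - 3(N+1) = 7.2
        res = dv.kruskal_dunn(np.arange(1, 10), ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        assert res.statistic == pytest.approx(7.2)
        assert len(res.pairwise) == 3

    def test_adjusted_p_at_least_raw_and_capped(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=30)
        res = dv.kruskal_dunn(values, np.repeat(["a", "b", "c"], 10))
        for _, p_adj in res.pairwise.values():
            assert 0.0 <= p_adj <= 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            dv.kruskal_dunn([1.0, 2.0], ["a", "a"])


class TestAnosim:
    def test_perfect_separation_r_is_one(self):
        # 2+2 samples where every between-distance exceeds every within
        d = np.array(
            [[0.0, 1.0, 9.0, 9.5],
             [1.0, 0.0, 9.2, 9.1],
             [9.0, 9.2, 0.0, 1.1],
             [9.5, 9.1, 1.1, 0.0]]
        )
        res = dv.anosim(d, ["a", "a", "b", "b"], n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_null_r_centred_on_zero(self):
        rng = np.random.default_rng(7)
        rs = []
        for _ in range(50):
            x = rng.normal(size=(12, 3))
            d = squareform(np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1)),
                           checks=False)
            rs.append(dv.anosim_r(squareform(d), rng.permutation([0, 1] * 6)))
        assert abs(np.mean(rs)) < 0.05

    def test_p_matches_exact_enumeration_on_toy(self):
        d = np.array(
            [[0.0, 1.0, 8.0, 9.0],
             [1.0, 0.0, 7.0, 9.5],
             [8.0, 7.0, 0.0, 2.0],
             [9.0, 9.5, 2.0, 0.0]]
        )
        labels = np.array(["a", "a", "b", "b"])
        r_obs = dv.anosim_r(d, labels)
        perm_rs = [
            dv.anosim_r(d, np.array(perm))
            for perm in set(itertools.permutations(labels))
        ]
        p_exact = np.mean([r >= r_obs for r in perm_rs])
        res = dv.anosim(d, labels, n_perm=999, seed=1)
        assert res.p_value == pytest.approx(p_exact, abs=0.05)

    def test_agrees_with_reference_implementation(self):
        rng = np.random.default_rng(11)
        x = np.vstack([rng.normal(0, 1, (6, 4)), rng.normal(2, 1, (6, 4))])
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        np.fill_diagonal(d, 0.0)
        labels = ["g1"] * 6 + ["g2"] * 6
        ours = dv.anosim(DistanceMatrix(d), labels, n_perm=999, seed=2)
        ref = skbio_anosim(DistanceMatrix(d), grouping=labels, permutations=999)
        assert ours.statistic == pytest.approx(ref["test statistic"], abs=1e-9)
        assert ours.p_value == pytest.approx(ref["p-value"], abs=0.03)

    def test_singleton_group_rejected(self):
        d = np.ones((3, 3)) - np.eye(3)
        with pytest.raises(ValueError):
            dv.anosim(d, ["a", "a", "b"], n_perm=99)

    def test_sample_order_equivariance(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(10, 3))
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        np.fill_diagonal(d, 0.0)
        labels = np.array([0, 1] * 5)
        perm = rng.permutation(10)
        r1 = dv.anosim_r(d, labels)
        r2 = dv.anosim_r(d[np.ix_(perm, perm)], labels[perm])
        assert r1 == pytest.approx(r2, abs=1e-12)


class TestPermanova:
    def test_hand_computed_toy(self):
        # 1-D points 0,1,4,5 in groups (a,a,b,b): SS_T = 68/4 = 17,
        # SS_W = 1/2 + 1/2 = 1, F = ((17-1)/1)/(1/(4-2)) = 32, R^2 = 16/17
        pts = np.array([0.0, 1.0, 4.0, 5.0])
        d = np.abs(pts[:, None] - pts[None, :])
        f, r2 = dv._permanova_stats(d**2, np.array(["a", "a", "b", "b"]))
        assert f == pytest.approx(32.0)
        assert r2 == pytest.approx(16.0 / 17.0)

    def test_null_r_squared_expectation(self):
        # random labels: E[R^2] ~= (g-1)/(n-1)
        rng = np.random.default_rng(13)
        n, g = 20, 4
        r2s = []
        for _ in range(200):
            x = rng.normal(size=(n, 3))
            d2 = ((x[:, None] - x[None]) ** 2).sum(-1)
            labels = rng.permutation(np.repeat(np.arange(g), n // g))
            _, r2 = dv._permanova_stats(d2, labels)
            r2s.append(r2)
        assert np.mean(r2s) == pytest.approx((g - 1) / (n - 1), abs=0.03)

    def test_r_squared_grows_with_separation(self):
        rng = np.random.default_rng(17)
        base = rng.normal(size=(16, 3))
        labels = np.repeat(["a", "b"], 8)
        r2s = []
        for sep in (0.5, 2.0, 8.0):
            x = base + sep * (labels == "b")[:, None]
            d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
            np.fill_diagonal(d, 0.0)
            res = dv.permanova(d, labels, n_perm=99, seed=0)
            r2s.append(res.extra["r_squared"])
        assert r2s[0] < r2s[1] < r2s[2]
        assert r2s[2] > 0.9

    def test_single_level_factor_rejected(self):
        d = np.ones((4, 4)) - np.eye(4)
        with pytest.raises(ValueError):
            dv.permanova(d, ["a"] * 4, n_perm=99)


class TestOneWayAnova:
    def test_zero_f_when_group_means_equal(self):
        res = dv.one_way_anova([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_textbook_toy_closed_form(self):
        # groups {1,2,3} and {2,3,4}: SSB = 1.5, MSW = 1 -> F = 1.5
        res = dv.one_way_anova([1, 2, 3, 2, 3, 4], ["a"] * 3 + ["b"] * 3)
        assert res.statistic == pytest.approx(1.5)

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValueError):
            dv.one_way_anova([1.0, 2.0, 3.0], ["a", "a", "b"])


def test_permutation_p_reproducible_and_bounded():
    rng = np.random.default_rng(23)
    x = rng.normal(size=(12, 2))
    d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
    np.fill_diagonal(d, 0.0)
    labels = [0, 1] * 6
    a1 = dv.anosim(d, labels, n_perm=99, seed=9)
    a2 = dv.anosim(d, labels, n_perm=99, seed=9)
    assert a1.p_value == a2.p_value
    assert a1.p_value >= 1.0 / 100.0
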