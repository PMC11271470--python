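import itertools

import numpy as np
import pandas as pd
import pytest

from enterodyn import enterotype as et
from enterodyn import synth
from enterodyn.io import to_relative


def brute_force_pam_cost(d: np.ndarray, k: int) -> float:
    """Exhaustive minimum total distance over all k-subsets of medoids."""
    n = d.shape[0]
    best = np.inf
    for medoids in itertools.combinations(range(n), k):
        cost = d[:, medoids].min(axis=1).sum()
        best = min(best, cost)
    return best


class TestJsdDistance:
    def test_identical_compositions_are_at_zero(self):
        tbl = pd.DataFrame({"s1": [0.6, 0.4], "s2": [0.6, 0.4]}, index=["a", "b"])
        assert et.jsd_distance(tbl)["s1", "s2"] == pytest.approx(0.0, abs=1e-6)

    def test_disjoint_supports_approach_analytic_maximum(self):
        tbl = pd.DataFrame({"s1": [1.0, 0.0], "s2": [0.0, 1.0]}, index=["a", "b"])
        d = et.jsd_distance(tbl, pseudocount=1e-12)
        assert d["s1", "s2"] == pytest.approx(et.MAX_JSD_DISTANCE, abs=1e-4)

    def test_hand_computed_divergence(self):
        # direct KL evaluation for (0.5,0.5) vs (0.25,0.75)
        a, b = np.array([0.5, 0.5]), np.array([0.25, 0.75])
        m = (a + b) / 2
        kl = lambda p, q: float((p * np.log(p / q)).sum())
        expected = np.sqrt(0.5 * kl(a, m) + 0.5 * kl(b, m))
        tbl = pd.DataFrame({"s1": a, "s2": b}, index=["x", "y"])
        assert et.jsd_distance(tbl)["s1", "s2"] == pytest.approx(expected, abs=1e-6)

    def test_triangle_inequality_on_random_triples(self):
        rng = np.random.default_rng(0)
        comps = rng.dirichlet(np.full(10, 0.5), size=60).T
        tbl = pd.DataFrame(comps, columns=[f"s{j}" for j in range(60)])
        d = et.jsd_distance(tbl).data
        for _ in range(100):
            i, j, k = rng.choice(60, size=3, replace=False)
            assert d[i, k] <= d[i, j] + d[j, k] + 1e-12

    def test_non_positive_pseudocount_rejected(self):
        tbl = pd.DataFrame({"s1": [1.0, 0.0]}, index=["a", "b"])
        with pytest.raises(ValueError):
            et.jsd_distance(tbl, pseudocount=0.0)


class TestPam:
    def test_obvious_two_cluster_optimum(self, line_distance):
        res = et.pam(line_distance, k=2)
        groups = {tuple(np.nonzero(res.labels == c)[0]) for c in (1, 2)}
        assert groups == {(0, 1), (2, 3)}
        assert res.total_cost == pytest.approx(2.0)

    def test_k_n_minus_one_matches_exhaustive(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(6, 2))
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        np.fill_diagonal(d, 0.0)
        res = et.pam(d, k=5)
        assert res.total_cost == pytest.approx(brute_force_pam_cost(d, 5))

    @pytest.mark.parametrize("k", [2, 3])
    def test_matches_exhaustive_optimum_on_random_matrices(self, k):
        # PAM is a local optimiser: it must never beat the global optimum
        # and should reach it in the vast majority of random 7-point
        # problems (the rare misses here coincide exactly, medoids and
        # cost, with the reference R cluster::pam local optima)
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.uniform(size=(7, 3))
            d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
            np.fill_diagonal(d, 0.0)
            res = et.pam(d, k=k)
            best = brute_force_pam_cost(d, k)
            assert res.total_cost >= best - 1e-9
            hits += res.total_cost <= best + 1e-9
        assert hits >= 16

    def test_medoids_belong_to_their_clusters(self, line_distance):
        res = et.pam(line_distance, k=2)
        for cluster, m in enumerate(res.medoid_indices, start=1):
            assert res.labels[m] == cluster

    def test_deterministic(self, line_distance):
        a = et.pam(line_distance, k=2)
        b = et.pam(line_distance, k=2)
        assert a.medoid_indices == b.medoid_indices
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_invalid_k_rejected(self, line_distance):
        for k in (1, 4, 5):
            with pytest.raises(ValueError):
                et.pam(line_distance, k=k)


class TestChIndex:
    def test_tabulated_toy_equals_200(self, line_distance):
        assert et.ch_index(line_distance, [1, 1, 2, 2]) == pytest.approx(200.0)

    def test_null_labels_give_ch_near_one(self):
        rng = np.random.default_rng(2)
        chs = []
        for _ in range(50):
            x = rng.normal(size=(20, 5))
            d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
            np.fill_diagonal(d, 0.0)
            chs.append(et.ch_index(d, rng.permutation([1, 2] * 10)))
        assert 0.7 < np.mean(chs) < 1.4

    def test_ch_increases_as_clusters_tighten(self):
        chs = []
        for eps in (0.5, 0.2, 0.05):
            pts = np.array([0.0, eps, 10.0, 10.0 + eps])
            d = np.abs(pts[:, None] - pts[None, :])
            chs.append(et.ch_index(d, [1, 1, 2, 2]))
        assert chs[0] < chs[1] < chs[2]

    def test_degenerate_cluster_counts_rejected(self, line_distance):
        with pytest.raises(ValueError):
            et.ch_index(line_distance, [1, 1, 1, 1])
        with pytest.raises(ValueError):
            et.ch_index(line_distance, [1, 2, 3, 4])


class TestSelectK:
    def test_two_separated_clouds_give_two(self):
        rng = np.random.default_rng(3)
        x = np.vstack([rng.normal(0, 0.3, (10, 2)), rng.normal(5, 0.3, (10, 2))])
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        np.fill_diagonal(d, 0.0)
        assert et.select_k(d, 2, 6).best_k == 2

    def test_single_candidate_range(self, line_distance):
        assert et.select_k(line_distance, 2, 2).best_k == 2

    def test_empty_range_rejected(self, line_distance):
        with pytest.raises(ValueError):
            et.select_k(line_distance, 5, 3)

    def test_recovers_true_state_count_across_seeds(self):
        # four-state cohorts at default dominance/concentration: the CH
        # scan must recover K=4 in at least 9/10 seeds
        hits = 0
        for seed in range(1, 11):
            cfg = synth.CohortConfig(n_subjects=60, seed=seed)
            profiles = synth.make_profiles(G=40, K=4)
            traj = synth.simulate_trajectories(cfg)
            counts, _ = synth.simulate_counts(traj, profiles, cfg)
            d = et.jsd_distance(to_relative(counts))
            hits += et.select_k(d, 2, 8).best_k == 4
        assert hits >= 9


class TestDriverTaxa:
    def test_cluster_driver_matches_generating_state(self, small_cohort):
        _, profiles, _, counts, meta = small_cohort
        rel = to_relative(counts)
        drivers = et.driver_taxa(rel, meta["state"].to_numpy(), top_n=3)
        for state, frame in drivers.items():
            assert frame["taxon"].iloc[0] == profiles.dominant_taxon[state - 1]

    def test_single_cluster_is_global_ranking(self, toy_counts):
        rel = to_relative(toy_counts)
        drivers = et.driver_taxa(rel, [1, 1, 1, 1], top_n=3)
        expected = rel.mean(axis=1).sort_values(ascending=False).index[0]
        assert drivers[1]["taxon"].iloc[0] == expected

    def test_ties_break_by_taxon_id(self):
        tbl = pd.DataFrame({"s1": [0.5, 0.5], "s2": [0.5, 0.5]},
                           index=["zeta", "alpha"])
        drivers = et.driver_taxa(tbl, [1, 1], top_n=2)
        assert list(drivers[1]["taxon"]) == ["alpha", "zeta"]


class TestSignatureTaxa:
    def _two_cluster_table(self, high, low, n=8, jitter=1e-6):
        rng = np.random.default_rng(0)
        rows = {"marker": np.r_[np.full(n, high), np.full(n, low)]
                + rng.uniform(0, jitter, 2 * n),
                "flat": np.full(2 * n, 0.5)}
        tbl = pd.DataFrame(rows).T
        tbl.columns = [f"s{j}" for j in range(2 * n)]
        return tbl, np.r_[np.ones(n, int), np.full(n, 2, int)]

    def test_tenfold_difference_passes(self):
        tbl, labels = self._two_cluster_table(0.01, 0.001)
        sig = et.signature_taxa(tbl, labels)
        assert list(sig["taxon"]) == ["marker"]
        assert sig["score"].iloc[0] == pytest.approx(np.log10(9000), abs=0.01)
        assert sig["cluster"].iloc[0] == 1

    def test_constant_taxon_excluded(self):
        tbl, labels = self._two_cluster_table(0.01, 0.001)
        sig = et.signature_taxa(tbl, labels)
        assert "flat" not in set(sig["taxon"])

    def test_exact_score_boundary_excluded(self):
        # max |mean difference| of exactly 1e-4 -> score == 2 -> strict cut
        tbl, labels = self._two_cluster_table(2e-4, 1e-4, jitter=0.0)
        sig = et.signature_taxa(tbl, labels)
        assert sig.empty
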