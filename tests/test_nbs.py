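"""Network-based statistics: sign-test mask, edge t-tests, component
extraction, permutation FWE."""

import numpy as np
import pytest

from fconn.nbs import (EdgeComponent, NetworkBasedStatistic, edge_t_tests,
                       nonzero_mask, permutation_fwe, resolve_threshold,
                       sign_test_pvalues, suprathreshold_components)


def matrices_from_edge_values(values_by_edge, n_regions, n_subjects):
    """Symmetric z-matrices with given per-subject values on chosen edges
    and zeros elsewhere."""
    Z = np.zeros((n_subjects, n_regions, n_regions))
    for (i, j), vals in values_by_edge.items():
        Z[:, i, j] = vals
        Z[:, j, i] = vals
    return Z


class TestSignMask:
    def test_all_positive_edge_has_tiny_p(self):
        vals = np.ones((30, 1))
        p = sign_test_pvalues(vals)[0]
        assert p == pytest.approx(2.0 ** -30, rel=1e-9)

    def test_balanced_edge_not_significant(self):
        vals = np.array([1.0] * 15 + [-1.0] * 15)[:, None]
        p = sign_test_pvalues(vals)[0]
        # P(X >= 15), X ~ Binom(30, 1/2)
        assert p == pytest.approx(0.5722, abs=1e-4)
        assert p > 0.05

    def test_zeros_are_dropped(self):
        vals = np.array([1.0] * 8 + [0.0] * 22)[:, None]
        assert sign_test_pvalues(vals)[0] == pytest.approx(2.0 ** -8)

    def test_all_zero_edge_not_significant(self):
        assert sign_test_pvalues(np.zeros((10, 1)))[0] == 1.0

    def test_union_rule_includes_single_group_edge(self, rng):
        # edge 0: nonzero in controls only; edge 1: in neither
        n_pat, n_ctl = 12, 12
        Z = np.zeros((n_pat + n_ctl, 4, 4))
        groups = np.array([1] * n_pat + [0] * n_ctl)
        Z[groups == 0, 0, 1] = 0.5
        Z[groups == 0, 1, 0] = 0.5
        noise = rng.standard_normal(n_pat + n_ctl) * 1e-3
        Z[:, 2, 3] = noise * np.where(np.arange(n_pat + n_ctl) % 2, 1, -1)
        Z[:, 3, 2] = Z[:, 2, 3]
        mask = nonzero_mask(Z, groups, alpha=0.05)
        assert mask[0, 1] and mask[1, 0]
        assert not mask[2, 3]
        assert not mask.diagonal().any()


class TestEdgeTTests:
    def test_hand_computed_pooled_t(self):
        Z = matrices_from_edge_values({(0, 1): [1, 2, 3, 4, 5, 6]}, 3, 6)
        groups = np.array([1, 1, 1, 0, 0, 0])
        mask = np.ones((3, 3), bool)
        np.fill_diagonal(mask, False)
        stats_map = edge_t_tests(Z, groups, mask)
        assert stats_map["t"][0, 1] == pytest.approx(-3.6742, abs=1e-4)
        assert stats_map["df"] == 4

    def test_identical_groups_give_t_zero_p_half(self, rng):
        vals = np.tile(rng.standard_normal(4), 2)
        Z = matrices_from_edge_values({(0, 1): vals}, 3, 8)
        groups = np.array([1] * 4 + [0] * 4)
        mask = np.ones((3, 3), bool)
        np.fill_diagonal(mask, False)
        sm = edge_t_tests(Z, groups, mask)
        assert sm["t"][0, 1] == pytest.approx(0.0, abs=1e-12)
        assert sm["p_greater"][0, 1] == pytest.approx(0.5)
        assert sm["p_less"][0, 1] == pytest.approx(0.5)

    def test_swapping_labels_negates_t(self, rng):
        Z = rng.standard_normal((10, 5, 5))
        Z = (Z + Z.transpose(0, 2, 1)) / 2
        groups = np.array([1] * 5 + [0] * 5)
        mask = np.ones((5, 5), bool)
        np.fill_diagonal(mask, False)
        t1 = edge_t_tests(Z, groups, mask)["t"]
        t2 = edge_t_tests(Z, 1 - groups, mask)["t"]
        iu = np.triu_indices(5, 1)
        np.testing.assert_allclose(t1[iu], -t2[iu], atol=1e-10)

    def test_zero_variance_edge_dropped(self):
        Z = matrices_from_edge_values({(0, 1): [1.0] * 8}, 3, 8)
        groups = np.array([1] * 4 + [0] * 4)
        mask = np.ones((3, 3), bool)
        np.fill_diagonal(mask, False)
        with pytest.warns(UserWarning, match="zero pooled variance"):
            sm = edge_t_tests(Z, groups, mask)
        assert not sm["mask"][0, 1]


class TestComponents:
    def stat_map_for_edges(self, edges, n):
        t = np.zeros((n, n))
        for i, j in edges:
            t[i, j] = t[j, i] = 5.0
        mask = np.ones((n, n), bool)
        np.fill_diagonal(mask, False)
        return {"t": t, "mask": mask, "df": 20}

    def test_hand_graph_component_sizes(self):
        comps = suprathreshold_components(
            self.stat_map_for_edges([(1, 2), (2, 3), (4, 5)], 6))
        assert [c.size for c in comps] == [2, 1]
        assert comps[0].nodes == {1, 2, 3}

    def test_chain_is_single_component(self):
        k = 7
        edges = [(i, i + 1) for i in range(k - 1)]
        comps = suprathreshold_components(self.stat_map_for_edges(edges, k))
        assert len(comps) == 1 and comps[0].size == k - 1

    def test_no_suprathreshold_edges_empty_list(self):
        sm = self.stat_map_for_edges([], 4)
        assert suprathreshold_components(sm) == []

    def test_threshold_forms(self):
        from scipy import stats as sps
        assert resolve_threshold(("t", 3.0), 55) == 3.0
        assert resolve_threshold("t=3", 55) == 3.0
        assert resolve_threshold("p=0.05", 55) == pytest.approx(
            sps.t.isf(0.05, 55))

    def test_sizes_match_bruteforce_reachability(self, rng):
        """Component sizes agree with an exhaustive BFS oracle on random
        20-node graphs."""
        for _ in range(100):
            n = 20
            t = np.zeros((n, n))
            iu = np.triu_indices(n, 1)
            on = rng.random(iu[0].size) < 0.08
            t[iu[0][on], iu[1][on]] = 5.0
            t = t + t.T
            sm = {"t": t, "mask": ~np.eye(n, dtype=bool), "df": 20}
            comps = suprathreshold_components(sm)
            assert sorted(c.size for c in comps) == sorted(
                bruteforce_component_sizes(t > 3.0))


def bruteforce_component_sizes(adj):
    """Edge counts of connected components by plain BFS over an adjacency
    matrix — the independent oracle."""
    n = adj.shape[0]
    seen = set()
    sizes = []
    for start in range(n):
        if start in seen or not adj[start].any():
            continue
        queue, comp = [start], {start}
        while queue:
            u = queue.pop()
            for v in np.flatnonzero(adj[u]):
                if v not in comp:
                    comp.add(int(v))
                    queue.append(int(v))
        if not comp & seen:
            edge_count = int(adj[np.ix_(sorted(comp), sorted(comp))].sum()) // 2
            if edge_count:
                sizes.append(edge_count)
        seen |= comp
    return sizes


class TestPermutationFWE:
    def small_planted_study(self, rng, delta=3.0):
        n_pat, n_ctl, n = 10, 8, 12
        Z = rng.standard_normal((n_pat + n_ctl, n, n)) * 0.1 + 0.3
        Z = (Z + Z.transpose(0, 2, 1)) / 2
        for s in range(n_pat):
            for i, j in [(0, 1), (1, 2), (2, 3)]:
                Z[s, i, j] += delta
                Z[s, j, i] += delta
        for z in Z:
            np.fill_diagonal(z, 0)
        return Z, np.array([1] * n_pat + [0] * n_ctl)

    def test_boundary_p_is_one_over_nperm_plus_one(self, rng):
        Z, y = self.small_planted_study(rng, delta=50.0)
        comps, null = permutation_fwe(Z, y, n_perm=199, seed=3)
        big = max(comps, key=lambda c: c.size)
        assert big.p_fwe == pytest.approx(1.0 / 200.0)

    def test_component_no_larger_than_every_null_max_gets_p_one(self, rng):
        Z, y = self.small_planted_study(rng, delta=0.0)
        comps, null = permutation_fwe(Z, y, threshold=("t", 1.5),
                                      n_perm=100, seed=3)
        # every permutation yields at least one suprathreshold edge, so
        # size-1 observed components are matched by the whole null
        assert null.min() >= 1
        dominated = [c for c in comps if c.size <= null.min()]
        assert dominated, "expected at least one dominated component"
        assert all(c.p_fwe == 1.0 for c in dominated)

    def test_coarse_nperm_warns(self, rng):
        Z, y = self.small_planted_study(rng)
        with pytest.warns(UserWarning, match="coarse"):
            permutation_fwe(Z, y, n_perm=50, seed=0)

    def test_region_relabeling_preserves_sizes_and_p(self, rng):
        Z, y = self.small_planted_study(rng)
        perm = rng.permutation(Z.shape[1])
        Zp = Z[:, perm][:, :, perm]
        c1, _ = permutation_fwe(Z, y, n_perm=200, seed=11)
        c2, _ = permutation_fwe(Zp, y, n_perm=200, seed=11)
        assert sorted(c.size for c in c1) == sorted(c.size for c in c2)
        assert sorted(c.p_fwe for c in c1) == sorted(c.p_fwe for c in c2)

    def test_raising_threshold_never_grows_components(self, rng):
        Z, y = self.small_planted_study(rng)
        mask = ~np.eye(Z.shape[1], dtype=bool)
        sizes = []
        for thr in (1.0, 2.0, 3.0, 4.0):
            sm = edge_t_tests(Z, y, mask)
            comps = suprathreshold_components(sm, ("t", thr))
            sizes.append(max((c.size for c in comps), default=0))
        assert sizes == sorted(sizes, reverse=True)

    def test_fixed_seed_bit_reproducible(self, rng):
        Z, y = self.small_planted_study(rng)
        r1 = NetworkBasedStatistic(n_perm=150, random_state=9).fit(Z, y)
        r2 = NetworkBasedStatistic(n_perm=150, random_state=9).fit(Z, y)
        assert [(c.size, c.p_fwe, c.edges) for c in r1.components_] == \
               [(c.size, c.p_fwe, c.edges) for c in r2.components_]
        for tail in r1.null_max_sizes_:
            np.testing.assert_array_equal(r1.null_max_sizes_[tail],
                                          r2.null_max_sizes_[tail])

    def test_estimator_detects_planted_component(self, small_study):
        model = NetworkBasedStatistic(n_perm=300, tail="greater",
                                      random_state=1)
        model.fit(small_study.matrices, small_study.groups)
        sig = model.significant_components(0.05)
        assert sig, "planted component not detected"
        assert sig[0].size >= 15
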