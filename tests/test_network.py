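import numpy as np
import pytest
from statsmodels.stats.multitest import multipletests

from cravemap import synth
from cravemap.network import (NetworkError, bh_adjust, connectivity_matrix,
                              edge_permutation_pvalues, extract_beta_series,
                              link_fdr, nbs)

PLANTED_EDGES = [(i, j) for i in range(1, 6) for j in range(i + 1, 6)]


def _paired_matrices(n_subjects=20, n_rois=15, trials=60, delta_r=0.0, seed=0):
    data = synth.simulate_beta_series(n_subjects, n_rois, trials,
                                      PLANTED_EDGES if delta_r else [],
                                      delta_r, seed=seed)
    mats_p = [connectivity_matrix(data["positive"][s]) for s in range(n_subjects)]
    mats_n = [connectivity_matrix(data["negative"][s]) for s in range(n_subjects)]
    return mats_p, mats_n


class TestExtractBetaSeries:
    def _atlas(self):
        atlas = np.zeros((4, 4, 4), dtype=int)
        atlas[:2] = 1
        atlas[2:, :2] = 2
        atlas[2:, 2:] = 3
        return atlas

    def test_constant_beta_gives_constant_series(self):
        atlas = self._atlas()
        betas = np.full((5, 4, 4, 4), 2.5)
        series = extract_beta_series(betas, ["positive"] * 5, atlas)
        assert np.allclose(series["positive"], 2.5)

    def test_series_length_matches_trials_per_condition(self):
        atlas = self._atlas()
        conds = ["positive"] * 60 + ["negative"] * 60
        betas = np.random.default_rng(0).standard_normal((120, 4, 4, 4))
        series = extract_beta_series(betas, conds, atlas)
        assert series["positive"].shape == (60, 3)
        assert series["negative"].shape == (60, 3)

    def test_roi_mean_matches_voxel_loop_oracle(self, rng):
        atlas = self._atlas()
        betas = rng.standard_normal((7, 4, 4, 4))
        series = extract_beta_series(betas, ["now"] * 7, atlas)
        for t in range(7):
            for lab in (1, 2, 3):
                acc = [betas[t, i, j, k]
                       for i in range(4) for j in range(4) for k in range(4)
                       if atlas[i, j, k] == lab]
                assert series["now"][t, lab - 1] == pytest.approx(np.mean(acc))

    def test_empty_roi_rejected(self, rng):
        atlas = self._atlas()
        atlas[atlas == 3] = 2   # label 3 now empty but still counted via max
        atlas[0, 0, 0] = 4
        atlas[0, 0, 0] = 2      # leave labels {1,2} but max=2: make empty lab
        atlas = np.where(atlas == 2, 5, atlas)  # labels {1,5}: 2..4 empty
        with pytest.raises(NetworkError, match="empty"):
            extract_beta_series(rng.standard_normal((3, 4, 4, 4)),
                                ["now"] * 3, atlas)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(NetworkError, match="length"):
            extract_beta_series(rng.standard_normal((3, 4, 4, 4)),
                                ["now"] * 4, self._atlas())


class TestConnectivityMatrix:
    def test_duplicated_series_gives_unit_correlation(self, rng):
        base = rng.standard_normal(50)
        series = np.column_stack([base, base, rng.standard_normal(50)])
        corr = connectivity_matrix(series)
        assert corr[0, 1] == pytest.approx(1.0)
        assert np.allclose(np.diag(corr), 1.0)
        assert np.allclose(corr, corr.T, equal_nan=True)

    def test_independent_series_near_zero(self, rng):
        corr = connectivity_matrix(rng.standard_normal((20000, 3)))
        assert abs(corr[0, 1]) < 0.03

    def test_generator_target_recovered(self):
        data = synth.simulate_beta_series(1, 2, 10_000, [(1, 2)], 0.3,
                                          seed=5, base_r=0.2)
        corr = connectivity_matrix(data["positive"][0])
        assert 0.47 <= corr[0, 1] <= 0.53

    def test_zero_variance_flagged_nan(self, rng):
        series = rng.standard_normal((30, 3))
        series[:, 1] = 7.0
        corr = connectivity_matrix(series)
        assert np.isnan(corr[0, 1]) and np.isnan(corr[1, 2])
        assert np.isfinite(corr[0, 2])
        assert corr[1, 1] == 1.0

    def test_too_few_trials_rejected(self, rng):
        with pytest.raises(NetworkError, match="3 trials"):
            connectivity_matrix(rng.standard_normal((2, 4)))


class TestEdgePermutation:
    def test_full_flip_negates_statistics(self):
        mats_p, mats_n = _paired_matrices(n_subjects=8, n_rois=6, trials=30)
        t_ab, _, _ = edge_permutation_pvalues(mats_p, mats_n, n_perm=100, seed=0)
        t_ba, _, _ = edge_permutation_pvalues(mats_n, mats_p, n_perm=100, seed=0)
        np.testing.assert_allclose(t_ab, -t_ba, atol=1e-10)

    def test_min_permutations_enforced(self):
        mats_p, mats_n = _paired_matrices(n_subjects=8, n_rois=6, trials=30)
        with pytest.raises(NetworkError, match="n_perm"):
            edge_permutation_pvalues(mats_p, mats_n, n_perm=50)

    def test_pvalues_in_unit_interval(self):
        mats_p, mats_n = _paired_matrices(n_subjects=10, n_rois=8, trials=40)
        _, p, _ = edge_permutation_pvalues(mats_p, mats_n, n_perm=200, seed=1)
        assert ((p > 0) & (p <= 1)).all()


class TestNbs:
    def test_identical_conditions_yield_nothing(self):
        mats_p, _ = _paired_matrices(n_subjects=8, n_rois=8, trials=40)
        res = nbs(mats_p, [m.copy() for m in mats_p], n_perm=100, seed=0)
        assert res.supra_edges == []
        assert res.components == []

    def test_planted_component_recovered(self):
        mats_p, mats_n = _paired_matrices(delta_r=0.4, seed=3)
        res = nbs(mats_p, mats_n, link_alpha=0.001, n_perm=1000, seed=4)
        assert len(res.components) == 1
        comp = res.components[0]
        assert comp.p < 0.05
        recall = len(set(PLANTED_EDGES) & set(comp.edges)) / len(PLANTED_EDGES)
        assert recall > 0.8
        assert set(comp.nodes) >= {1, 2, 3, 4, 5}

    def test_component_edges_form_connected_graph(self):
        mats_p, mats_n = _paired_matrices(delta_r=0.4, seed=6)
        res = nbs(mats_p, mats_n, n_perm=500, seed=7)
        for comp in res.all_components:
            import networkx as nx
            g = nx.Graph(comp.edges)
            assert nx.is_connected(g)
            assert sorted(g.nodes) == sorted(comp.nodes)

    def test_unpaired_input_rejected(self):
        mats_p, mats_n = _paired_matrices(n_subjects=8, n_rois=6, trials=30)
        with pytest.raises(NetworkError, match="paired"):
            nbs(mats_p, mats_n[:-1])

    def test_too_few_subjects_rejected(self):
        mats_p, mats_n = _paired_matrices(n_subjects=8, n_rois=6, trials=30)
        with pytest.raises(NetworkError, match="subjects"):
            nbs(mats_p[:4], mats_n[:4])

    def test_seed_reproducible(self):
        mats_p, mats_n = _paired_matrices(delta_r=0.4, seed=8)
        a = nbs(mats_p, mats_n, n_perm=200, seed=9)
        b = nbs(mats_p, mats_n, n_perm=200, seed=9)
        np.testing.assert_array_equal(a.null_max_size, b.null_max_size)
        assert [c.edges for c in a.components] == [c.edges for c in b.components]


def brute_force_bh(p_values, q):
    """All-threshold scan oracle for BH step-up rejections."""
    p = np.asarray(p_values, float)
    m = len(p)
    best_k = 0
    sorted_p = np.sort(p)
    for k in range(1, m + 1):
        if sorted_p[k - 1] <= k * q / m:
            best_k = k
    return set(np.argsort(p, kind="stable")[:best_k])


class TestLinkFdr:
    def test_all_p_one_gives_empty_set(self):
        assert bh_adjust(np.ones(10)).min() == 1.0
        mats_p, _ = _paired_matrices(n_subjects=8, n_rois=6, trials=30)
        res = link_fdr(mats_p, [m.copy() for m in mats_p], q=0.05,
                       n_perm=100, seed=0)
        assert res.edges == []

    def test_bh_matches_brute_force_oracle(self, rng):
        for q in (0.001, 0.01, 0.05, 0.1):
            for _ in range(20):
                p = rng.random(rng.integers(1, 40))
                adj = bh_adjust(p)
                got = set(np.flatnonzero(adj <= q))
                assert got == brute_force_bh(p, q)

    def test_bh_matches_statsmodels(self, rng):
        p = rng.random(200)
        _, adj_ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_adjust(p), adj_ref, atol=1e-12)

    def test_stepup_on_literal_example(self):
        # hand-executed step-up on (0.0001, 0.0002, 0.04, 0.5) at q = 0.05:
        # k=2 is the largest k with p_(k) <= k q / m (0.04 > 3*0.05/4)
        p = np.array([0.0001, 0.0002, 0.04, 0.5])
        adj = bh_adjust(p)
        rejected = set(np.flatnonzero(adj <= 0.05))
        assert rejected == brute_force_bh(p, 0.05) == {0, 1}

    def test_planted_edges_detected(self):
        mats_p, mats_n = _paired_matrices(delta_r=0.4, seed=11)
        res = link_fdr(mats_p, mats_n, q=0.05, n_perm=1000, seed=12)
        recall = len(set(PLANTED_EDGES) & set(res.edges)) / len(PLANTED_EDGES)
        assert recall > 0.8

    def test_planted_edges_detected_at_strict_q(self):
        # q = 0.001 needs adjusted p below k*q/m ~ 1e-4, i.e. enough
        # permutations to resolve p values that small
        mats_p, mats_n = _paired_matrices(delta_r=0.4, seed=11)
        res = link_fdr(mats_p, mats_n, q=0.001, n_perm=12000, seed=12)
        recall = len(set(PLANTED_EDGES) & set(res.edges)) / len(PLANTED_EDGES)
        assert recall > 0.8

    def test_shares_edge_machinery_with_nbs(self):
        # at equal thresholds the supra-threshold edge set is identical
        mats_p, mats_n = _paired_matrices(delta_r=0.4, seed=13)
        res_nbs = nbs(mats_p, mats_n, link_alpha=0.01, n_perm=500, seed=14)
        res_fdr = link_fdr(mats_p, mats_n, q=1.0, n_perm=500, seed=14)
        supra_from_p = {e for e, p in
                        zip([(int(i), int(j)) for i, j in res_nbs.supra_edges],
                            [1] * len(res_nbs.supra_edges))}
        edges_below = set()
        iu, ju = np.triu_indices(15, k=1)
        for (i, j, p) in zip(iu, ju, res_fdr.p_obs):
            if p < 0.01:
                edges_below.add((int(i) + 1, int(j) + 1))
        assert supra_from_p == edges_below
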