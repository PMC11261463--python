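"""CPM engine: selection statistics, cross-validated prediction,
permutation inference, and hub bookkeeping."""

import numpy as np
import pytest
from scipy import stats as sps

from cpmtools import (
    CPMConfig, EdgeMask, consensus_and_degree, edge_behavior_correlation,
    network_strength, permutation_pvalue, permutation_test, run_cpm_edges,
    select_edges, summarize_mask_by_atlas, synthetic_atlas,
)


def brute_force_loocv(X, y, p_threshold, tail="positive"):
    """Independent oracle: explicit per-fold recomputation with
    scipy.stats.pearsonr and np.polyfit."""
    n, E = X.shape
    preds = np.empty(n)
    for i in range(n):
        tr = [k for k in range(n) if k != i]
        Xtr, ytr = X[tr], y[tr]
        rs, ps = zip(*(sps.pearsonr(Xtr[:, e], ytr) for e in range(E)))
        rs, ps = np.array(rs), np.array(ps)
        pos = (rs > 0) & (ps < p_threshold)
        neg = (rs < 0) & (ps < p_threshold)
        mask = pos if tail == "positive" else neg
        if tail == "both":
            s_tr = Xtr[:, pos].sum(1) - Xtr[:, neg].sum(1)
            s_te = X[i, pos].sum() - X[i, neg].sum()
        else:
            s_tr = Xtr[:, mask].sum(1)
            s_te = X[i, mask].sum()
        if np.ptp(s_tr) == 0:
            preds[i] = ytr.mean()
        else:
            slope, intercept = np.polyfit(s_tr, ytr, 1)
            preds[i] = intercept + slope * s_te
    return preds


class TestEdgeBehaviorCorrelation:
    def test_perfect_correlation(self):
        y = np.arange(10.0)
        X = np.column_stack([y, -y, np.ones(10)])
        r, p = edge_behavior_correlation(X, y)
        assert r[0] == pytest.approx(1.0)
        assert p[0] < 1e-12
        assert r[1] == pytest.approx(-1.0)
        assert (r[2], p[2]) == (0.0, 1.0)  # constant edge

    def test_pvalue_matches_t_cdf_oracle(self, rng):
        x = rng.standard_normal(10)
        y = rng.standard_normal(10)
        r, p = edge_behavior_correlation(x[:, None], y)
        r0 = np.corrcoef(x, y)[0, 1]
        t = r0 * np.sqrt(8 / (1 - r0**2))
        p_oracle = 2 * sps.t.sf(abs(t), 8)
        assert r[0] == pytest.approx(r0, abs=1e-12)
        assert p[0] == pytest.approx(p_oracle, abs=1e-10)

    def test_type_one_error_calibration(self):
        """Independent noise: ~5% of edges reach p < 0.05."""
        rng = np.random.default_rng(7)
        X = rng.standard_normal((59, 10_000))
        y = rng.standard_normal(59)
        _, p = edge_behavior_correlation(X, y)
        assert np.mean(p < 0.05) == pytest.approx(0.05, abs=0.01)

    def test_constant_behavior_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            edge_behavior_correlation(rng.standard_normal((8, 3)), np.ones(8))


class TestSelectEdges:
    def test_degenerate_threshold_selects_all_positive(self, rng):
        r = rng.uniform(-1, 1, 50)
        p = rng.uniform(0, 1, 50)
        pos, neg = select_edges(r, p, p_threshold=1 - 1e-12)
        np.testing.assert_array_equal(pos, r > 0)
        np.testing.assert_array_equal(neg, r < 0)
        assert not np.any(pos & neg)

    def test_all_above_threshold_gives_empty_masks(self):
        pos, neg = select_edges(np.array([0.5, -0.5]), np.array([0.2, 0.9]),
                                p_threshold=0.1)
        assert not pos.any() and not neg.any()


class TestNetworkStrength:
    def test_empty_mask_and_additivity(self):
        vec = np.array([0.2, 0.3, -0.1])
        assert network_strength(vec, np.zeros(3, bool)) == 0.0
        assert network_strength(vec, np.array([True, True, False])) == \
            pytest.approx(0.5)

    def test_matches_masked_upper_triangle_sum(self, rng):
        n = 12
        m = rng.uniform(-1, 1, (n, n))
        m = np.clip((m + m.T) / 2, -1, 1)
        np.fill_diagonal(m, 1.0)
        sel = rng.random((n, n)) < 0.3
        sel = np.triu(sel, 1)
        sel = sel + sel.T
        mask = EdgeMask.from_matrix(sel.astype(int))
        expected = sum(m[i, j] for i in range(n) for j in range(i + 1, n)
                       if sel[i, j])
        from cpmtools import FCMatrix
        assert network_strength(FCMatrix(m), mask) == pytest.approx(expected)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="disagree"):
            network_strength(np.zeros(3), np.zeros(4, bool))


class TestRunCpm:
    def test_noiseless_recovery(self, rng):
        """Behavior an exact linear function of one edge: near-perfect CV."""
        n = 20
        X = rng.standard_normal((n, 15))
        y = 3.0 + 2.0 * X[:, 4]
        res = run_cpm_edges(X, y, CPMConfig(p_threshold=1e-4))
        assert res.r_obs > 0.99
        assert res.mse < 1e-3

    def test_loocv_matches_brute_force(self, rng):
        X = rng.standard_normal((8, 10))
        y = rng.standard_normal(8) + X[:, 0]
        for thr in (0.5, 0.05):
            res = run_cpm_edges(X, y, CPMConfig(p_threshold=thr))
            np.testing.assert_allclose(res.predictions.to_numpy(),
                                       brute_force_loocv(X, y, thr),
                                       atol=1e-10)

    def test_both_tails_matches_brute_force(self, rng):
        X = rng.standard_normal((12, 8))
        y = X[:, 1] - X[:, 5] + 0.3 * rng.standard_normal(12)
        res = run_cpm_edges(X, y, CPMConfig(p_threshold=0.3, tail="both"))
        np.testing.assert_allclose(res.predictions.to_numpy(),
                                   brute_force_loocv(X, y, 0.3, "both"),
                                   atol=1e-10)

    def test_subject_order_invariance(self, rng):
        X = rng.standard_normal((10, 20))
        y = rng.standard_normal(10) + X[:, 2]
        ids = [f"p{k}" for k in range(10)]
        res = run_cpm_edges(X, y, CPMConfig(p_threshold=0.1), subject_ids=ids)
        perm = rng.permutation(10)
        res2 = run_cpm_edges(X[perm], y[perm], CPMConfig(p_threshold=0.1),
                             subject_ids=[ids[k] for k in perm])
        for sid in ids:
            assert res.predictions[sid] == pytest.approx(res2.predictions[sid],
                                                         abs=1e-12)

    def test_no_test_set_leakage(self, rng):
        """Corrupting a held-out subject's behavior never changes its
        prediction."""
        X = rng.standard_normal((9, 12))
        y = rng.standard_normal(9) + X[:, 3]
        base = run_cpm_edges(X, y, CPMConfig(p_threshold=0.2))
        for i in (0, 4, 8):
            y2 = y.copy()
            y2[i] += 100.0  # fold i's model never sees y2[i]
            res = run_cpm_edges(X, y2, CPMConfig(p_threshold=0.2))
            assert res.predictions.iloc[i] == pytest.approx(
                base.predictions.iloc[i], abs=1e-10)

    def test_null_r_is_not_anticonservative(self):
        """Shuffled behavior: mean observed-vs-predicted r must not be
        systematically positive. (It is in fact negatively biased —
        LOOCV predictions of an uninformative model anticorrelate with
        the held-out score — which the permutation test absorbs because
        the null distribution shares the bias.)"""
        rs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((15, 30))
            y = rng.permutation(15).astype(float)
            res = run_cpm_edges(X, y, CPMConfig(p_threshold=0.1))
            rs.append(res.r_obs)
        assert np.mean(rs) < 0.05
        assert np.mean(rs) > -0.6  # finite, not degenerate

    def test_too_few_subjects(self, rng):
        with pytest.raises(ValueError, match="at least 6"):
            run_cpm_edges(rng.standard_normal((5, 4)), np.arange(5.0))

    def test_kfold_runs_and_predicts_everyone(self, rng):
        X = rng.standard_normal((20, 15))
        y = X[:, 0] + 0.1 * rng.standard_normal(20)
        res = run_cpm_edges(X, y, CPMConfig(p_threshold=0.05, cv="kfold", k=4))
        assert len(res.predictions) == 20
        assert res.r_obs > 0.5


class TestPermutationTest:
    def test_pvalue_floor_and_ceiling(self):
        null = np.linspace(-0.5, 0.5, 199)
        assert permutation_pvalue(0.9, null) == pytest.approx(1 / 200)
        assert permutation_pvalue(-0.9, null) == pytest.approx(1.0)

    def test_ties_count_as_exceedances(self):
        assert permutation_pvalue(0.5, np.array([0.5, 0.1])) == \
            pytest.approx(2 / 3)

    def test_bounds_and_monotonicity(self, rng):
        null = rng.uniform(-1, 1, 50)
        ps = [permutation_pvalue(r, null) for r in (-2, 0.0, 0.3, 2)]
        assert all(1 / 51 <= p <= 1 for p in ps)
        assert ps == sorted(ps, reverse=True)

    def test_seeded_reproducibility(self, rng):
        X = rng.standard_normal((12, 20))
        y = rng.standard_normal(12)
        cfg = CPMConfig(p_threshold=0.1, n_permutations=25, seed=5)
        a = permutation_test(X, cfg, behavior=y)
        b = permutation_test(X, cfg, behavior=y)
        np.testing.assert_array_equal(a.null_distribution, b.null_distribution)
        assert a.p_perm == b.p_perm

    def test_planted_signal_is_significant(self, rng):
        X = rng.standard_normal((25, 40))
        y = X[:, :5].sum(1) + 0.5 * rng.standard_normal(25)
        cfg = CPMConfig(p_threshold=0.01, n_permutations=99, seed=1)
        res = permutation_test(X, cfg, behavior=y)
        assert res.p_perm == pytest.approx(1 / 100)


class TestConsensusAndDegree:
    def _mask_with_degrees(self, n_nodes, edges):
        m = np.zeros((n_nodes, n_nodes), dtype=int)
        for i, j in edges:
            m[i, j] = m[j, i] = 1
        return EdgeMask.from_matrix(m)

    def test_hub_at_seven_edges_threshold_five(self):
        edges = [(0, j) for j in range(1, 8)] + [(9, 10)]
        mask = self._mask_with_degrees(12, edges)
        consensus, recs = consensus_and_degree([mask], hub_threshold=5)
        assert recs[0].node == 0 and recs[0].degree == 7 and recs[0].is_hub
        assert consensus == mask

    def test_four_edges_is_not_a_hub(self):
        mask = self._mask_with_degrees(8, [(0, j) for j in range(1, 5)])
        _, recs = consensus_and_degree([mask], hub_threshold=5)
        assert recs[0].degree == 4 and not recs[0].is_hub

    def test_degrees_equal_row_sums_and_conservation(self, rng):
        n = 15
        sel = np.triu(rng.random((n, n)) < 0.25, 1)
        mask = EdgeMask.from_matrix((sel + sel.T).astype(int))
        consensus, recs = consensus_and_degree([mask])
        row_sums = mask.to_matrix().sum(1)
        for rec in recs:
            assert rec.degree == row_sums[rec.node]
        assert sum(r.degree for r in recs) == 2 * mask.n_selected

    def test_consensus_is_intersection_and_subset(self, rng):
        masks = []
        for _ in range(4):
            sel = np.triu(rng.random((10, 10)) < 0.5, 1)
            masks.append(EdgeMask.from_matrix((sel + sel.T).astype(int)))
        consensus, _ = consensus_and_degree(masks)
        for m in masks:
            assert consensus.issubset(m)
        expected = masks[0].flat & masks[1].flat & masks[2].flat & masks[3].flat
        np.testing.assert_array_equal(consensus.flat, expected)

    def test_sort_order_ties_by_node_index(self):
        mask = self._mask_with_degrees(6, [(0, 1), (2, 3)])
        _, recs = consensus_and_degree([mask])
        assert [r.node for r in recs[:4]] == [0, 1, 2, 3]


class TestAtlasSummary:
    def test_empty_mask_all_zero(self):
        atlas = synthetic_atlas(48)
        mask = EdgeMask(np.zeros(48 * 47 // 2, bool), 48)
        out = summarize_mask_by_atlas(mask, atlas, "lobe")
        assert (out.to_numpy() == 0).all()

    def test_single_within_lobe_edge_on_diagonal(self):
        atlas = synthetic_atlas(48)
        lobes = atlas.labels("lobe")
        i, j = np.flatnonzero(lobes == "Frontal")[:2]
        m = np.zeros((48, 48), int)
        m[i, j] = m[j, i] = 1
        out = summarize_mask_by_atlas(EdgeMask.from_matrix(m), atlas, "lobe")
        assert out.loc["Frontal", "Frontal"] == 1
        assert out.to_numpy().sum() == 1

    def test_edge_count_conservation(self, rng):
        atlas = synthetic_atlas(48)
        sel = np.triu(rng.random((48, 48)) < 0.1, 1)
        mask = EdgeMask.from_matrix((sel + sel.T).astype(int))
        for level in ("lobe", "gyrus"):
            out = summarize_mask_by_atlas(mask, atlas, level).to_numpy()
            upper = np.triu(out).sum()
            assert upper == mask.n_selected
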