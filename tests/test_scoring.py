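import math

import numpy as np
import pytest

import knowclust as kc
from knowclust.preprocess import log_normalize
from knowclust.scoring import (
    KnowledgebaseAligner, MatchResult, aggregate, bss_tss, fisher_z, inv_fisher,
    match_cluster, partition_score, pseudo_bulk, spearman,
)


def spearman_oracle(x, y):
    """Brute-force: explicit average ranks, explicit Pearson."""
    def ranks(v):
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v))
        sv = np.asarray(v)[order]
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            r[order[i:j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return r
    rx, ry = ranks(x), ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / math.sqrt((rx**2).sum() * (ry**2).sum()))


class TestSpearman:
    @pytest.mark.parametrize("x,y,expected", [
        ([1, 2, 3, 4, 5], [2, 4, 6, 8, 10], 1.0),
        ([1, 2, 3], [3, 2, 1], -1.0),
        ([1, 2, 3, 4, 5], [1, 3, 2, 5, 4], 0.8),  # 1 - 6*4/(5*24)
    ])
    def test_known_values(self, x, y, expected):
        rho, degen = spearman(np.array(x, float), np.array(y, float))
        assert not degen
        assert rho == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_degenerate(self):
        rho, degen = spearman(np.ones(5), np.arange(5.0))
        assert degen and rho == 0.0

    def test_matches_oracle_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            x = rng.normal(size=20)
            y = rng.normal(size=20)
            assert spearman(x, y)[0] == pytest.approx(spearman_oracle(x, y), abs=1e-12)

    def test_matches_oracle_with_ties(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            x = rng.integers(0, 4, size=15).astype(float)
            y = rng.integers(0, 4, size=15).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            assert spearman(x, y)[0] == pytest.approx(spearman_oracle(x, y), abs=1e-12)


class TestFisher:
    def test_zero_rho_gives_zero_z(self):
        assert fisher_z(0.0, 0.7) == 0.0

    def test_closed_form_value(self):
        assert fisher_z(0.5, 1.0) == pytest.approx(math.atanh(0.5), abs=1e-12)
        assert fisher_z(0.5, 1.0) == pytest.approx(0.549306, abs=1e-6)

    def test_round_trip_identity(self):
        for rho in np.arange(-0.9, 0.95, 0.1):
            assert inv_fisher(fisher_z(rho, 1.0)) == pytest.approx(rho, abs=1e-9)

    def test_clamping_at_unit_correlation(self):
        assert math.isfinite(fisher_z(1.0, 1.0))
        assert math.isfinite(fisher_z(-1.0, 1.0))


class TestAggregate:
    def _m(self, rho, weight=1.0):
        return MatchResult(0, "T", rho, weight, 10, fisher_z(rho, weight))

    def test_single_match_is_identity(self):
        _, p = aggregate([self._m(0.6)])
        assert p == pytest.approx(0.6, abs=1e-9)

    def test_antisymmetric_pair_cancels(self):
        z_bar, p = aggregate([self._m(0.5), self._m(-0.5)])
        assert z_bar == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_saturated_matches_give_near_unit_p(self):
        _, p = aggregate([self._m(1.0), self._m(1.0)])
        assert p > 0.999999

    def test_all_zero_weight_gives_zero(self):
        _, p = aggregate([self._m(0.9, weight=0.0)])
        assert p == 0.0

    def test_alternative_variant_runs(self):
        z_bar, p = aggregate([self._m(0.5)], variant="tanh_of_weighted_rho")
        assert p == pytest.approx(0.5, abs=1e-9)


class TestBssTss:
    def test_single_cluster_is_zero(self):
        Z = np.random.default_rng(0).normal(size=(20, 3))
        assert bss_tss(Z, np.zeros(20, int)) == 0.0

    def test_singletons_give_one(self):
        Z = np.random.default_rng(1).normal(size=(10, 2))
        assert bss_tss(Z, np.arange(10)) == pytest.approx(1.0, rel=1e-12)

    def test_hand_computed_example(self):
        Z = np.array([[0.0], [2.0], [4.0], [6.0]])
        labels = np.array([0, 0, 1, 1])
        assert bss_tss(Z, labels) == pytest.approx(0.8, abs=1e-12)

    def test_identical_points_give_zero(self):
        assert bss_tss(np.ones((6, 2)), np.array([0, 0, 1, 1, 2, 2])) == 0.0

    def test_bss_plus_wss_equals_tss(self):
        rng = np.random.default_rng(2)
        Z = rng.normal(size=(100, 5))
        labels = rng.integers(0, 4, 100)
        center = Z.mean(axis=0)
        tss = ((Z - center) ** 2).sum()
        wss = sum(((Z[labels == c] - Z[labels == c].mean(axis=0)) ** 2).sum()
                  for c in np.unique(labels))
        ratio = bss_tss(Z, labels)
        assert ratio * tss + wss == pytest.approx(tss, rel=1e-9)


class TestPseudoBulk:
    def test_singleton_cluster_is_its_cell(self, tiny_counts):
        logn = log_normalize(tiny_counts)
        profiles = pseudo_bulk(logn, np.array([0, 1, 2]))
        np.testing.assert_allclose(profiles[1].profile, logn.values[1])

    def test_two_cell_mean(self):
        expr = kc.ExpressionMatrix(np.array([[0.0, 2.0], [2.0, 0.0]]),
                                   ["a", "b"], ["g1", "g2"], state="lognorm")
        profiles = pseudo_bulk(expr, np.array([0, 0]))
        np.testing.assert_allclose(profiles[0].profile, [1.0, 1.0])

    def test_size_weighted_mean_conserved(self):
        rng = np.random.default_rng(0)
        expr = kc.ExpressionMatrix(rng.normal(size=(30, 4)),
                                   [f"c{i}" for i in range(30)],
                                   [f"g{i}" for i in range(4)], state="lognorm")
        labels = rng.integers(0, 3, 30)
        profiles = pseudo_bulk(expr, labels)
        grand = sum(p.size * p.profile for p in profiles) / 30
        np.testing.assert_allclose(grand, expr.values.mean(axis=0), atol=1e-12)


class TestMatchCluster:
    def test_self_match_is_perfect(self, small_split, small_kb):
        ref, _ = small_split
        logn = log_normalize(ref.rna)
        lab = np.asarray(ref.labels)
        t = small_kb.types[1]
        sub = logn.subset_cells(np.nonzero(lab == t)[0])
        profile = pseudo_bulk(sub, np.zeros(sub.n_cells, int))[0]
        m = match_cluster(profile, small_kb, top_gene_fraction=0.10)
        assert m.best_type == t
        assert m.rho > 0.9

    def test_disjoint_gene_space_unassigned(self, small_kb):
        expr = kc.ExpressionMatrix(np.ones((4, 3)), [f"c{i}" for i in range(4)],
                                   ["zz1", "zz2", "zz3"], state="lognorm")
        profile = pseudo_bulk(expr, np.zeros(4, int))[0]
        m = match_cluster(profile, small_kb, 0.10)
        assert m.best_type == "unassigned"
        assert m.weight == 0.0 and m.rho == 0.0

    def test_query_cluster_matches_its_type(self, small_split, small_kb):
        _, query = small_split
        logn = log_normalize(query.rna)
        lab = np.asarray(query.labels)
        for t in small_kb.types:
            sub = logn.subset_cells(np.nonzero(lab == t)[0])
            profile = pseudo_bulk(sub, np.zeros(sub.n_cells, int))[0]
            assert match_cluster(profile, small_kb, 0.10).best_type == t


class TestPartitionScore:
    def test_score_is_product_and_tanh_consistent(self, small_split, small_kb, small_config):
        _, query = small_split
        logn = log_normalize(query.rna)
        rng = np.random.default_rng(0)
        Z = rng.normal(size=(query.rna.n_cells, 4))
        truth = np.unique(np.asarray(query.labels), return_inverse=True)[1]
        ps = partition_score(Z, logn, truth, small_kb, small_config)
        assert ps.score == ps.bss_tss * ps.p_k
        assert ps.p_k == pytest.approx(math.tanh(ps.z_bar), abs=1e-12)
        assert ps.valid

    def test_small_cluster_invalidates(self, small_split, small_kb, small_config):
        _, query = small_split
        logn = log_normalize(query.rna)
        Z = np.random.default_rng(0).normal(size=(query.rna.n_cells, 4))
        labels = np.zeros(query.rna.n_cells, int)
        labels[:10] = 1  # 10-cell cluster < min_cells=15
        ps = partition_score(Z, logn, labels, small_kb, small_config)
        assert not ps.valid

    def test_invariant_to_relabeling_and_cell_order(self, small_split, small_kb, small_config):
        _, query = small_split
        logn = log_normalize(query.rna)
        rng = np.random.default_rng(1)
        Z = rng.normal(size=(query.rna.n_cells, 4))
        truth = np.unique(np.asarray(query.labels), return_inverse=True)[1]
        ps1 = partition_score(Z, logn, truth, small_kb, small_config)
        perm = rng.permutation(query.rna.n_cells)
        ps2 = partition_score(Z[perm], logn.subset_cells(perm), 2 - truth[perm],
                              small_kb, small_config)
        assert ps1.score == pytest.approx(ps2.score, abs=1e-12)
        assert ps1.p_k == pytest.approx(ps2.p_k, abs=1e-12)

    def test_true_partition_outscores_merged(self, small_split, small_kb, small_config):
        """Knowledge guidance: merging two true types must lower the score."""
        _, query = small_split
        logn = log_normalize(query.rna)
        truth = np.unique(np.asarray(query.labels), return_inverse=True)[1]
        # embed cells at their type centroids plus small noise so the
        # geometry reflects the true structure
        rng = np.random.default_rng(2)
        centers = rng.normal(0, 5, size=(3, 4))
        Z = centers[truth] + rng.normal(0, 0.3, size=(len(truth), 4))
        merged = np.where(truth == 2, 1, truth)
        s_true = partition_score(Z, logn, truth, small_kb, small_config)
        s_merged = partition_score(Z, logn, merged, small_kb, small_config)
        assert s_true.score > s_merged.score


class TestAligner:
    def test_matches_direct_spearman(self, small_split, small_kb):
        _, query = small_split
        logn = log_normalize(query.rna)
        al = KnowledgebaseAligner(logn, small_kb)
        rows = np.arange(25)
        t = small_kb.types[0]
        x = logn.subset_features(al.genes).values[rows].mean(axis=0)
        y = small_kb.profiles.loc[t, al.genes].to_numpy(float)
        assert al.rho(rows, t) == pytest.approx(spearman(x, y)[0], abs=1e-12)
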