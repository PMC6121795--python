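"""Topological overlap, module detection, eigengenes, and overlap tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from obpdiv.coexpression import (
    CoexpressionConfig,
    adjacency_tom,
    detect_modules,
    eigengene_group_test,
    module_eigengene,
    module_overlap_fisher,
    ModuleAssignment,
)


def _expr(mat, genes=None, samples=None):
    mat = np.asarray(mat, dtype=float)
    genes = genes or [f"g{i}" for i in range(mat.shape[0])]
    samples = samples or [f"s{j}" for j in range(mat.shape[1])]
    return pd.DataFrame(mat, index=genes, columns=samples)


def _blocks(rng, n_blocks=2, block_size=20, n_samples=50, cor=0.9, noise=0.4):
    """Latent-factor blocks: gene = factor + noise gives within-block
    correlation about cor when noise is tuned accordingly."""
    rows, labels = [], []
    for b in range(n_blocks):
        factor = rng.normal(size=n_samples)
        for _ in range(block_size):
            rows.append(factor + rng.normal(scale=noise, size=n_samples))
            labels.append(f"block{b}")
    return _expr(np.array(rows)), labels


class TestAdjacencyTom:
    def test_perfectly_correlated_genes_have_unit_adjacency_and_tom(self):
        x = np.arange(10.0)
        expr = _expr([x, 2 * x + 1, -x])
        tom = adjacency_tom(expr, CoexpressionConfig(beta=6))
        assert tom.iloc[0, 1] == pytest.approx(1.0)
        assert tom.iloc[0, 2] == pytest.approx(1.0)  # unsigned network

    def test_entries_bounded_diagonal_one_symmetric(self):
        rng = np.random.default_rng(3)
        expr = _expr(rng.normal(size=(15, 12)))
        tom = adjacency_tom(expr)
        t = tom.to_numpy()
        assert np.allclose(t, t.T)
        assert np.all((t >= 0) & (t <= 1))
        assert np.allclose(np.diag(t), 1.0)

    def test_three_gene_toy_matches_hand_evaluated_formula(self):
        rng = np.random.default_rng(11)
        expr = _expr(rng.normal(size=(3, 30)))
        beta = 6
        tom = adjacency_tom(expr, CoexpressionConfig(beta=beta))
        cor = np.corrcoef(expr.to_numpy())
        a = np.abs(cor) ** beta
        np.fill_diagonal(a, 0.0)
        k = a.sum(axis=1)
        for i in range(3):
            for j in range(3):
                if i == j:
                    continue
                num = sum(a[i, u] * a[u, j] for u in range(3)) + a[i, j]
                den = min(k[i], k[j]) + 1 - a[i, j]
                assert tom.iloc[i, j] == pytest.approx(num / den, abs=1e-12)

    def test_gene_order_permutation_invariance(self):
        rng = np.random.default_rng(5)
        expr = _expr(rng.normal(size=(10, 20)))
        tom = adjacency_tom(expr)
        perm = list(rng.permutation(expr.index))
        tom_p = adjacency_tom(expr.loc[perm])
        assert np.allclose(tom.loc[perm, perm].to_numpy(), tom_p.to_numpy())

    def test_constant_gene_removed_with_warning(self):
        rng = np.random.default_rng(7)
        mat = rng.normal(size=(5, 10))
        mat[2] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            tom = adjacency_tom(_expr(mat))
        assert "g2" not in tom.index


class TestDetectModules:
    def test_two_planted_blocks_recovered_exactly(self):
        rng = np.random.default_rng(21)
        expr, labels = _blocks(rng)
        assign = detect_modules(adjacency_tom(expr),
                                CoexpressionConfig(min_module_size=10))
        assert len(assign.modules()) == 2
        for module in assign.modules():
            block_labels = {labels[expr.index.get_loc(g)]
                            for g in assign.genes_in(module)}
            assert len(block_labels) == 1  # each module is one planted block
        assert (assign.labels != "unassigned").all()

    def test_independent_genes_stay_unassigned(self):
        rng = np.random.default_rng(22)
        expr = _expr(rng.normal(size=(30, 100)))
        assign = detect_modules(adjacency_tom(expr),
                                CoexpressionConfig(min_module_size=10))
        assert assign.modules() == []

    def test_planted_partition_adjusted_rand_index(self):
        from sklearn.metrics import adjusted_rand_score
        rng = np.random.default_rng(23)
        expr, labels = _blocks(rng, n_blocks=3, block_size=15, n_samples=40,
                               noise=0.5)
        assign = detect_modules(adjacency_tom(expr),
                                CoexpressionConfig(min_module_size=10))
        assert adjusted_rand_score(labels, list(assign.labels)) >= 0.9


class TestModuleEigengene:
    def _assign(self, expr, genes, module="M1"):
        labels = pd.Series("unassigned", index=expr.index, dtype=object)
        labels[genes] = module
        return ModuleAssignment(labels)

    def test_single_gene_module_is_standardized_profile(self):
        rng = np.random.default_rng(31)
        expr = _expr(rng.normal(size=(4, 12)))
        assign = self._assign(expr, ["g1"])
        eg = module_eigengene(expr, assign, "M1")
        z = stats.zscore(expr.loc["g1"], ddof=1)
        ref = z / np.linalg.norm(z)
        assert np.allclose(np.abs(eg.scores), np.abs(ref))
        assert np.dot(eg.scores, z) > 0  # orientation follows module mean

    def test_two_identical_genes_explain_all_variance(self):
        rng = np.random.default_rng(32)
        x = rng.normal(size=15)
        expr = _expr([x, x, rng.normal(size=15)])
        assign = self._assign(expr, ["g0", "g1"])
        eg = module_eigengene(expr, assign, "M1")
        assert eg.variance_explained == pytest.approx(1.0)

    def test_latent_factor_recovered(self):
        rng = np.random.default_rng(33)
        factor = rng.normal(size=30)
        expr = _expr([factor + rng.normal(scale=0.5, size=30)
                      for _ in range(30)])
        assign = self._assign(expr, list(expr.index))
        eg = module_eigengene(expr, assign, "M1")
        assert abs(np.corrcoef(eg.scores, factor)[0, 1]) > 0.9

    def test_variance_explained_at_least_any_single_gene_share(self):
        rng = np.random.default_rng(34)
        expr, _ = _blocks(rng, n_blocks=1, block_size=10, n_samples=25)
        assign = self._assign(expr, list(expr.index))
        eg = module_eigengene(expr, assign, "M1")
        for g in expr.index:
            r2 = np.corrcoef(eg.scores, expr.loc[g])[0, 1] ** 2
            assert eg.variance_explained >= r2 / len(expr) - 1e-9


class TestEigengeneGroupTest:
    def _eigengenes(self, shift=0.0, n=8, seed=41):
        rng = np.random.default_rng(seed)
        samples = [f"s{i}" for i in range(2 * n)]
        scores = rng.normal(size=2 * n)
        scores[:n] += shift
        scores /= np.linalg.norm(scores)
        from obpdiv.coexpression import Eigengene
        eg = Eigengene("M1", pd.Series(scores, index=samples), 0.5)
        groups = pd.Series(["a"] * n + ["b"] * n, index=samples)
        return [eg], groups

    def test_identical_groups_not_significant(self):
        egs, groups = self._eigengenes(shift=0.0)
        out = eigengene_group_test(egs, groups, "a", "b")
        assert not out["significant"].any()

    def test_planted_shift_detected_in_most_replicates(self):
        # a 2-SD eigengene shift at 8 vs 8 has ~0.95 two-sided t power
        hits = 0
        for seed in range(20):
            egs, groups = self._eigengenes(shift=2.0, seed=100 + seed)
            out = eigengene_group_test(egs, groups, "a", "b")
            hits += bool(out["significant"].iloc[0])
        assert hits >= 16

    def test_small_group_skipped_with_warning(self):
        egs, groups = self._eigengenes()
        groups[:] = "a"
        groups.iloc[0] = "b"
        with pytest.warns(UserWarning, match="too small"):
            out = eigengene_group_test(egs, groups, "a", "b")
        assert len(out) == 0


class TestModuleOverlapFisher:
    def _assignment(self, labels):
        return ModuleAssignment(pd.Series(labels, dtype=object))

    def test_identical_partitions_overlap_on_diagonal(self):
        labels = pd.Series(["M1"] * 10 + ["M2"] * 10,
                           index=[f"g{i}" for i in range(20)])
        a = self._assignment(labels)
        out = module_overlap_fisher(a, a)
        diag = out[out.module_a == out.module_b]
        off = out[out.module_a != out.module_b]
        assert (diag.overlap == 10).all()
        assert (off.overlap == 0).all()
        assert diag.significant.all()

    def test_toy_table_matches_hypergeometric_summation(self):
        # 2x2 table (both=10, only_a=2, only_b=3, neither=85)
        genes = [f"g{i}" for i in range(100)]
        la = pd.Series("unassigned", index=genes, dtype=object)
        lb = pd.Series("unassigned", index=genes, dtype=object)
        la[genes[:12]] = "A1"
        lb[genes[:10] + genes[12:15]] = "B1"
        out = module_overlap_fisher(self._assignment(la), self._assignment(lb))
        row = out.iloc[0]
        assert row.overlap == 10
        oracle = stats.hypergeom(100, 12, 13)
        # two-sided Fisher p: sum of all tables as or less probable
        p_obs = oracle.pmf(10)
        p_two = sum(oracle.pmf(k) for k in range(14)
                    if oracle.pmf(k) <= p_obs * (1 + 1e-9))
        assert row.p_value == pytest.approx(p_two, rel=1e-6)

    def test_disjoint_universes_raise(self):
        a = self._assignment(pd.Series(["M1"] * 3, index=["a", "b", "c"]))
        b = self._assignment(pd.Series(["M1"] * 3, index=["x", "y", "z"]))
        with pytest.raises(ValueError):
            module_overlap_fisher(a, b)
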