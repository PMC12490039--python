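"""Co-expression network: adjacency, scale-free fit, TOM, modules, proximity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from coexnet import coexpr
from coexnet.containers import ExpressionMatrix, ModulePartition
from coexnet.simulate import SimulationConfig, simulate_dataset


def _expr(values, prefix="g"):
    values = np.asarray(values, dtype=float)
    frame = pd.DataFrame(
        values,
        index=[f"{prefix}{i}" for i in range(values.shape[0])],
        columns=[f"s{j}" for j in range(values.shape[1])],
    )
    half = values.shape[1] // 2
    cond = pd.Series(
        ["A"] * half + ["B"] * (values.shape[1] - half), index=frame.columns
    )
    return ExpressionMatrix(frame, cond)


class TestPearsonAdjacency:
    def test_perfect_correlation_gives_one(self):
        x = np.arange(10.0)
        m = _expr([x, 2 * x + 1])
        adj = coexpr.pearson_adjacency(m, power=6)
        assert adj.values.iloc[0, 1] == pytest.approx(1.0)

    def test_soft_threshold_power(self):
        # r = 0.5 at beta = 6 -> 0.5^6
        rng = np.random.default_rng(0)
        z = rng.normal(size=4000)
        x = z
        y = 0.5 * z + np.sqrt(1 - 0.25) * rng.normal(size=4000)
        r = np.corrcoef(x, y)[0, 1]
        adj = coexpr.pearson_adjacency(_expr([x, y]), power=6)
        assert adj.values.iloc[0, 1] == pytest.approx(abs(r) ** 6)
        assert adj.values.iloc[0, 1] == pytest.approx(0.5**6, rel=0.25)

    def test_unsigned_mode_ignores_sign(self):
        x = np.arange(12.0)
        pos = coexpr.pearson_adjacency(_expr([x, x]), power=6)
        neg = coexpr.pearson_adjacency(_expr([x, -x]), power=6)
        assert pos.values.iloc[0, 1] == pytest.approx(neg.values.iloc[0, 1])

    def test_zero_variance_gene_removed_with_warning(self):
        m = _expr([np.arange(8.0), np.ones(8), np.arange(8.0) ** 2])
        with pytest.warns(UserWarning, match="zero-variance"):
            adj = coexpr.pearson_adjacency(m, power=2)
        assert adj.values.shape == (2, 2)


class TestScaleFreeIndex:
    def test_power_law_degrees_fit_well(self):
        rng = np.random.default_rng(1)
        k = rng.pareto(2.0, size=4000) + 1.0
        assert coexpr.scale_free_index(k) >= 0.95

    def test_uniform_random_adjacency_fits_poorly(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(size=(300, 300))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        adj = coexpr.AdjacencyMatrix(
            values=pd.DataFrame(a), power=1.0
        )
        assert coexpr.scale_free_fit(adj) < 0.5

    def test_too_few_genes_rejected(self):
        adj = coexpr.AdjacencyMatrix(values=pd.DataFrame(np.zeros((2, 2))), power=1)
        with pytest.raises(ValueError):
            coexpr.scale_free_fit(adj)

    def test_constant_degrees_report_zero(self):
        with pytest.warns(UserWarning, match="constant connectivity"):
            assert coexpr.scale_free_index(np.full(50, 3.0)) == 0.0


class TestPickSoftPower:
    def test_zero_threshold_returns_smallest(self, small_dataset):
        matrix, _ = small_dataset
        scan = coexpr.pick_soft_power(matrix, candidate_powers=(2, 4, 6),
                                      fit_threshold=0.0)
        assert scan.power == 2
        assert list(scan.table["power"]) == [2, 4, 6]

    def test_fallback_to_argmax_with_warning(self, small_dataset):
        matrix, _ = small_dataset
        with pytest.warns(UserWarning, match="falling back"):
            scan = coexpr.pick_soft_power(
                matrix, candidate_powers=(2, 4), fit_threshold=0.999
            )
        best = scan.table.loc[scan.table["fit_index"].idxmax(), "power"]
        assert scan.power == best and not scan.reached_threshold

    def test_empty_candidates_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            coexpr.pick_soft_power(small_dataset[0], candidate_powers=())


def _adj_from(array):
    a = np.asarray(array, dtype=float)
    return coexpr.AdjacencyMatrix(values=pd.DataFrame(a), power=1.0)


class TestTomSimilarity:
    def test_triangle_of_ones_is_one(self):
        a = np.ones((3, 3)) - np.eye(3)
        tom = coexpr.tom_similarity(_adj_from(a))
        off = tom.similarity.to_numpy()[np.triu_indices(3, 1)]
        assert np.allclose(off, 1.0)

    def test_path_graph_hand_value(self):
        # a12 = a23 = 1, a13 = 0: TOM13 = (1 + 0)/(min(1,1) + 1 - 0) = 0.5
        a = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        tom = coexpr.tom_similarity(_adj_from(a))
        assert tom.similarity.iloc[0, 2] == pytest.approx(0.5)

    def test_empty_adjacency_gives_zero_overlap(self):
        tom = coexpr.tom_similarity(_adj_from(np.zeros((4, 4))))
        off = tom.similarity.to_numpy()[np.triu_indices(4, 1)]
        assert np.allclose(off, 0.0)
        assert np.allclose(np.diag(tom.similarity), 1.0)

    def test_duplicated_node_in_binary_graph_scores_one(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            n = 8
            a = (rng.uniform(size=(n, n)) < 0.4).astype(float)
            a = np.triu(a, 1)
            a = a + a.T
            # clone node 0 as node n with identical neighborhood and a=1 link
            full = np.zeros((n + 1, n + 1))
            full[:n, :n] = a
            full[n, :n] = a[0]
            full[:n, n] = a[0]
            full[0, n] = full[n, 0] = 1.0
            tom = coexpr.tom_similarity(_adj_from(full))
            assert tom.similarity.iloc[0, n] == pytest.approx(1.0)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_tom_and_adjacency_bounded_and_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(8, 12))
        adj = coexpr.pearson_adjacency(_expr(x), power=rng.integers(1, 9))
        a = adj.values.to_numpy()
        assert ((a >= 0) & (a <= 1)).all() and np.allclose(a, a.T)
        t = coexpr.tom_similarity(adj).similarity.to_numpy()
        assert ((t >= 0) & (t <= 1 + 1e-12)).all() and np.allclose(t, t.T)


def _two_block_matrix(n_per=20, n_samples=30, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    z1, z2 = rng.normal(size=(2, n_samples))
    rows = [z1 * rng.uniform(0.8, 1.2) + noise * rng.normal(size=n_samples)
            for _ in range(n_per)]
    rows += [z2 * rng.uniform(0.8, 1.2) + noise * rng.normal(size=n_samples)
             for _ in range(n_per)]
    return _expr(rows), np.repeat([1, 2], n_per)


class TestClusterModules:
    def test_noise_free_two_modules_recovered_exactly(self):
        m, truth = _two_block_matrix(noise=0.0)
        adj = coexpr.pearson_adjacency(m, power=6)
        part = coexpr.cluster_modules(coexpr.tom_similarity(adj), min_module_size=5)
        assert adjusted_rand_score(truth, part.assignment.to_numpy()) == pytest.approx(1.0)

    def test_default_synthetic_recovery(self, default_dataset):
        from coexnet import ingest

        matrix, truth = default_dataset
        matrix = ingest.mad_filter(matrix)
        adj = coexpr.pearson_adjacency(matrix, power=6)
        part = coexpr.cluster_modules(coexpr.tom_similarity(adj))
        part = coexpr.merge_modules(matrix, coexpr.module_eigengenes(matrix, part))
        labels = [truth.membership[g] for g in part.assignment.index]
        assert adjusted_rand_score(labels, part.assignment.to_numpy()) >= 0.8
        # detected eigengenes track the planted factors
        for mod in part.module_labels:
            genes = part.module_genes(mod)
            true_mod = pd.Series([truth.membership[g] for g in genes]).mode()[0]
            if true_mod == 0:
                continue
            r = np.corrcoef(
                part.eigengenes.loc[mod],
                truth.factor_values.loc[true_mod, part.eigengenes.columns],
            )[0, 1]
            assert abs(r) >= 0.9

    def test_pure_noise_leaves_most_genes_unassigned(self):
        frac_unassigned = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            m = _expr(rng.normal(size=(80, 25)))
            adj = coexpr.pearson_adjacency(m, power=6)
            part = coexpr.cluster_modules(coexpr.tom_similarity(adj),
                                          min_module_size=10)
            frac_unassigned.append((part.assignment == 0).mean())
        assert np.mean(frac_unassigned) >= 0.9

    def test_fewer_genes_than_min_size_all_unassigned(self):
        m, _ = _two_block_matrix(n_per=3)
        tom = coexpr.tom_similarity(coexpr.pearson_adjacency(m, power=2))
        with pytest.warns(UserWarning, match="fewer genes"):
            part = coexpr.cluster_modules(tom, min_module_size=30)
        assert (part.assignment == 0).all()


class TestModuleEigengenes:
    def test_perfect_module_explains_all_variance(self):
        m, truth = _two_block_matrix(noise=0.0)
        part = ModulePartition(
            assignment=pd.Series(truth, index=m.values.index)
        )
        out = coexpr.module_eigengenes(m, part)
        for mod in (1, 2):
            assert out.variance_explained[mod] == pytest.approx(1.0)
            gene = out.module_genes(mod)[0]
            r = np.corrcoef(out.eigengenes.loc[mod], m.values.loc[gene])[0, 1]
            assert abs(r) == pytest.approx(1.0)

    def test_sign_aligned_with_module_mean(self, small_dataset):
        matrix, truth = small_dataset
        part = ModulePartition(
            assignment=pd.Series(
                [truth.membership[g] for g in matrix.genes], index=matrix.genes
            )
        )
        out = coexpr.module_eigengenes(matrix, part)
        for mod in out.module_labels:
            sub = matrix.values.loc[out.module_genes(mod)]
            std = (sub.sub(sub.mean(axis=1), axis=0)).div(sub.std(axis=1, ddof=0), axis=0)
            r = np.corrcoef(out.eigengenes.loc[mod], std.mean(axis=0))[0, 1]
            assert r >= 0

    def test_recovers_planted_factor(self, small_dataset):
        matrix, truth = small_dataset
        part = ModulePartition(
            assignment=pd.Series(
                [truth.membership[g] for g in matrix.genes], index=matrix.genes
            )
        )
        out = coexpr.module_eigengenes(matrix, part)
        for mod in out.module_labels:
            r = np.corrcoef(
                out.eigengenes.loc[mod], truth.factor_values.loc[mod]
            )[0, 1]
            assert abs(r) >= 0.9

    def test_constant_gene_raises_naming_module(self):
        values = np.vstack([np.ones(10), np.arange(10.0), np.arange(10.0) * 2])
        m = _expr(values)
        part = ModulePartition(assignment=pd.Series([1, 1, 1], index=m.values.index))
        with pytest.raises(ValueError, match="module 1"):
            coexpr.module_eigengenes(m, part)


def _correlated_factor_matrix(r, n_per=10, n=400, seed=0):
    """Two modules whose eigengenes correlate at ~r."""
    rng = np.random.default_rng(seed)
    z1 = rng.normal(size=n)
    z2 = r * z1 + np.sqrt(1 - r**2) * rng.normal(size=n)
    rows = [z1 * rng.uniform(0.9, 1.1) for _ in range(n_per)]
    rows += [z2 * rng.uniform(0.9, 1.1) for _ in range(n_per)]
    m = _expr(rows)
    part = ModulePartition(
        assignment=pd.Series(np.repeat([1, 2], n_per), index=m.values.index)
    )
    return m, part


class TestMergeModules:
    def test_dissimilarity_below_threshold_merges(self):
        m, part = _correlated_factor_matrix(0.8)
        out = coexpr.merge_modules(m, coexpr.module_eigengenes(m, part))
        assert out.module_labels == [1]

    def test_dissimilarity_above_threshold_kept(self):
        m, part = _correlated_factor_matrix(0.7)
        out = coexpr.merge_modules(m, coexpr.module_eigengenes(m, part))
        assert len(out.module_labels) == 2

    def test_three_similar_modules_collapse_order_independent(self):
        rng = np.random.default_rng(8)
        n = 400
        z = rng.normal(size=n)
        rows = [
            0.9 * z + np.sqrt(1 - 0.81) * rng.normal(size=n) for _ in range(30)
        ]
        m = _expr(rows)
        for perm in ([1, 2, 3], [3, 1, 2], [2, 3, 1]):
            assignment = pd.Series(np.repeat(perm, 10), index=m.values.index)
            out = coexpr.merge_modules(
                m, coexpr.module_eigengenes(m, ModulePartition(assignment=assignment))
            )
            assert out.module_labels == [1]

    def test_fixed_point_when_all_dissimilar(self, small_dataset):
        matrix, truth = small_dataset
        part = ModulePartition(
            assignment=pd.Series(
                [truth.membership[g] for g in matrix.genes], index=matrix.genes
            )
        )
        once = coexpr.merge_modules(matrix, coexpr.module_eigengenes(matrix, part))
        twice = coexpr.merge_modules(matrix, once)
        pd.testing.assert_series_equal(once.assignment, twice.assignment)


class TestModuleProximity:
    @staticmethod
    def _partition(sizes):
        labels = np.concatenate([[i + 1] * s for i, s in enumerate(sizes)])
        return ModulePartition(
            assignment=pd.Series(labels, index=[f"g{i}" for i in range(labels.size)])
        )

    def test_constant_adjacency_gives_all_ones(self):
        n = 12
        a = np.full((n, n), 0.4)
        np.fill_diagonal(a, 0)
        adj = coexpr.AdjacencyMatrix(
            values=pd.DataFrame(a, index=[f"g{i}" for i in range(n)],
                                columns=[f"g{i}" for i in range(n)]),
            power=1,
        )
        res = coexpr.module_proximity(adj, self._partition([4, 4, 4]), 1)
        assert np.allclose(res.relative.to_numpy(), 1.0)
        assert res.reference == 1.0

    def test_block_adjacency_hand_computation(self):
        # focal block 1 <-> block 2 at 0.4; every other cross pair at 0.1
        sizes = [5, 5, 5]
        n = sum(sizes)
        a = np.full((n, n), 0.1)
        a[0:5, 5:10] = 0.4
        a[5:10, 0:5] = 0.4
        np.fill_diagonal(a, 0)
        adj = coexpr.AdjacencyMatrix(
            values=pd.DataFrame(a, index=[f"g{i}" for i in range(n)],
                                columns=[f"g{i}" for i in range(n)]),
            power=1,
        )
        res = coexpr.module_proximity(adj, self._partition(sizes), 1)
        reference = (0.4 + 0.1) / 2  # equal-size blocks
        assert res.relative[2] == pytest.approx(0.4 / reference)
        assert res.relative[3] == pytest.approx(0.1 / reference)

    def test_invariant_to_uniform_scaling(self, small_dataset):
        matrix, truth = small_dataset
        part = ModulePartition(
            assignment=pd.Series(
                [truth.membership[g] for g in matrix.genes], index=matrix.genes
            )
        )
        adj = coexpr.pearson_adjacency(matrix, power=6)
        res1 = coexpr.module_proximity(adj, part, 1)
        scaled = coexpr.AdjacencyMatrix(values=adj.values * 0.25, power=6)
        res2 = coexpr.module_proximity(scaled, part, 1)
        pd.testing.assert_series_equal(res1.relative, res2.relative)

    def test_single_module_rejected(self):
        a = np.ones((6, 6)) - np.eye(6)
        adj = coexpr.AdjacencyMatrix(
            values=pd.DataFrame(a, index=[f"g{i}" for i in range(6)],
                                columns=[f"g{i}" for i in range(6)]),
            power=1,
        )
        with pytest.raises(ValueError):
            coexpr.module_proximity(adj, self._partition([6]), 1)


def test_export_edges_keeps_strong_pairs():
    a = np.array([[0, 0.5, 0.1], [0.5, 0, 0.35], [0.1, 0.35, 0]])
    adj = coexpr.AdjacencyMatrix(
        values=pd.DataFrame(a, index=list("xyz"), columns=list("xyz")), power=1
    )
    edges = coexpr.export_edges(adj, min_weight=0.3)
    assert set(zip(edges["source"], edges["target"])) == {("x", "y"), ("y", "z")}
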