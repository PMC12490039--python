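"""Gene-set statistics against independent enumeration and hand-trace oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from coexnet import enrich
from coexnet.containers import ExpressionMatrix
from coexnet.enrich import GeneSetCollection, Ontology
from coexnet.simulate import default_config, simulate_dataset


def _hypergeom_tail_oracle(n_univ, set_size, module_size, k):
    """P(overlap >= k) by exhaustive enumeration of module draws."""
    universe = range(n_univ)
    members = set(range(set_size))
    total = hits = 0
    for draw in itertools.combinations(universe, module_size):
        total += 1
        if len(members & set(draw)) >= k:
            hits += 1
    return hits / total


class TestGsoa:
    @pytest.mark.parametrize(
        "n_univ,set_size,module_size,k",
        [(10, 5, 5, 5), (6, 3, 3, 2), (8, 4, 3, 1), (12, 6, 4, 2), (9, 2, 5, 0)],
    )
    def test_matches_exhaustive_enumeration(self, n_univ, set_size, module_size, k):
        universe = [f"g{i}" for i in range(n_univ)]
        collection = GeneSetCollection(sets={"S": universe[:set_size]})
        module = universe[: k] + universe[set_size: set_size + module_size - k]
        assert len(module) == module_size
        res = enrich.gsoa(module, collection, universe)
        expected = _hypergeom_tail_oracle(n_univ, set_size, module_size, k)
        assert res.loc[0, "p"] == pytest.approx(expected, abs=1e-12)
        assert res.loc[0, "overlap"] == k
        assert res.loc[0, "gene_ratio"] == pytest.approx(k / module_size)

    def test_all_module_inside_set(self):
        # N=10, K=5, n=5, k=5 -> 1/C(10,5) = 1/252
        universe = [f"g{i}" for i in range(10)]
        collection = GeneSetCollection(sets={"S": universe[:5]})
        res = enrich.gsoa(universe[:5], collection, universe)
        assert res.loc[0, "p"] == pytest.approx(1 / 252, abs=1e-12)

    def test_empty_set_gives_p_one(self):
        universe = [f"g{i}" for i in range(6)]
        collection = GeneSetCollection(sets={"S": []})
        res = enrich.gsoa(universe[:3], collection, universe)
        assert res.loc[0, "p"] == 1.0

    def test_empty_inputs_rejected(self):
        collection = GeneSetCollection(sets={"S": ["a"]})
        with pytest.raises(ValueError):
            enrich.gsoa([], collection, ["a", "b"])
        with pytest.raises(ValueError):
            enrich.gsoa(["a"], collection, [])


class TestCes:
    @pytest.mark.parametrize(
        "best_p,expected", [(0.001, 3.0), (1.0, 0.0), (0.05, 1.3010299957)]
    )
    def test_known_values(self, best_p, expected):
        frame = pd.DataFrame({"adj_p": [best_p, 1.0]})
        assert enrich.ces(frame) == pytest.approx(expected, abs=1e-9)

    def test_zero_p_capped_with_warning(self):
        with pytest.warns(UserWarning, match="capped"):
            value = enrich.ces(pd.DataFrame({"adj_p": [0.0]}))
        assert np.isfinite(value) and value > 300


def _ks_oracle(genes_in_order, gene_set):
    """Unweighted two-sample ECDF statistic, signed by direction."""
    hits = np.array([g in gene_set for g in genes_in_order])
    n_hit = hits.sum()
    n_miss = (~hits).sum()
    path = np.cumsum(np.where(hits, 1.0 / n_hit, -1.0 / n_miss))
    return path[np.argmax(np.abs(path))]


class TestGsea:
    def test_top_hits_weight_zero_reach_one(self):
        ranked = pd.Series([4.0, 3.0, 2.0, 1.0], index=list("abcd"))
        res = enrich.gsea(ranked, ["a", "b"], weight_p=0.0, n_perm=100, seed=0)
        assert res["es"] == pytest.approx(1.0)

    def test_hand_traced_weighted_running_sum(self):
        # r = (2, 1, -1, -2), set = {gene1, gene4}, weight 1:
        # steps +2/4, -1/2, -1/2, +2/4 -> path (0.5, 0, -0.5, 0) -> ES = +0.5
        ranked = pd.Series([2.0, 1.0, -1.0, -2.0], index=list("abcd"))
        res = enrich.gsea(ranked, ["a", "d"], weight_p=1.0, n_perm=100, seed=0)
        assert res["es"] == pytest.approx(0.5)

    def test_weight_zero_equals_ks_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = 12
            genes = [f"g{i}" for i in range(n)]
            scores = np.sort(rng.normal(size=n))[::-1]
            ranked = pd.Series(scores, index=genes)
            gene_set = list(rng.choice(genes, size=4, replace=False))
            res = enrich.gsea(ranked, gene_set, weight_p=0.0, n_perm=100, seed=1)
            assert res["es"] == pytest.approx(_ks_oracle(genes, set(gene_set)))

    def test_permutation_p_matches_exhaustive_null(self):
        # 8 genes, K=2: the null has C(8,2)=28 equally likely hit placements
        genes = [f"g{i}" for i in range(8)]
        scores = np.array([3.0, 2.5, 2.0, 1.0, -0.5, -1.0, -2.0, -3.0])
        ranked = pd.Series(scores, index=genes)
        gene_set = ["g0", "g2"]
        res = enrich.gsea(ranked, gene_set, weight_p=1.0, n_perm=4000, seed=3)
        null = []
        for pos in itertools.combinations(range(8), 2):
            hits = np.zeros(8, dtype=bool)
            hits[list(pos)] = True
            null.append(enrich._running_sum(scores, hits, 1.0)[0])
        null = np.array(null)
        same = null[np.sign(null) == np.sign(res["es"])]
        exact_tail = (np.abs(same) >= abs(res["es"])).sum() / same.size
        # sampled (smoothed) estimate within a binomial envelope of the truth
        envelope = 3 * math.sqrt(exact_tail * (1 - exact_tail) / 2000) + 2 / 2000
        assert res["p"] == pytest.approx(exact_tail, abs=envelope)

    def test_disjoint_set_rejected(self):
        ranked = pd.Series([1.0, -1.0], index=["a", "b"])
        with pytest.raises(ValueError):
            enrich.gsea(ranked, ["zzz"], n_perm=100)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_es_always_within_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        scores = rng.normal(size=n)
        k = int(rng.integers(1, n))
        hits = np.zeros(n, dtype=bool)
        hits[rng.choice(n, size=k, replace=False)] = True
        es, _ = enrich._running_sum(np.sort(scores)[::-1], hits, rng.uniform(0, 2))
        assert -1.0 - 1e-9 <= es <= 1.0 + 1e-9


class TestPartitionOverlap:
    def test_jaccard_examples(self):
        pa = pd.Series([1, 1, 1], index=["A", "B", "C"])
        pb = pd.Series([1, 1, 1], index=["B", "C", "D"])
        out = enrich.partition_overlap(pa, pb)
        assert out.loc[0, "jaccard"] == pytest.approx(0.5)

    def test_identical_modules_score_one(self):
        pa = pd.Series([1, 1, 2, 2], index=list("abcd"))
        out = enrich.partition_overlap(pa, pa)
        same = out[(out["module_a"] == out["module_b"])]
        assert (same["jaccard"] == 1.0).all()

    def test_disjoint_hypergeometric_matches_enumeration(self):
        genes = [f"g{i}" for i in range(10)]
        pa = pd.Series(1, index=genes[:4])
        pb = pd.Series(1, index=genes[4:9])
        out = enrich.partition_overlap(pa, pb)
        assert out.loc[0, "jaccard"] == 0.0
        expected = _hypergeom_tail_oracle(9, 5, 4, 0)
        assert out.loc[0, "p"] == pytest.approx(expected, abs=1e-12)


def _toy_ontology():
    # root -> {t1 (6 genes), t2 (2 genes)}; t2 -> t3 (1 gene); 8 genes total
    parents = {"root": set(), "t1": {"root"}, "t2": {"root"}, "t3": {"t2"}}
    term_genes = {
        "root": set(),
        "t1": {f"g{i}" for i in range(6)},
        "t2": {"g6"},
        "t3": {"g7"},
    }
    return Ontology(parents=parents, term_genes=term_genes)


class TestSemanticSimilarity:
    def test_identical_single_term_is_one(self):
        onto = _toy_ontology()
        assert enrich.semantic_similarity(["t1"], ["t1"], onto) == pytest.approx(1.0)

    def test_root_only_common_ancestor_is_zero(self):
        onto = _toy_ontology()
        assert enrich.semantic_similarity(["t1"], ["t2"], onto) == pytest.approx(0.0)

    def test_hand_computed_best_match_average(self):
        onto = _toy_ontology()
        # IC = -log(n/8): t2 has 2 annotated (g6 + t3's g7), t3 has 1
        ic_t2, ic_t3 = -math.log(2 / 8), -math.log(1 / 8)
        lin_t2_t3 = 2 * ic_t2 / (ic_t2 + ic_t3)  # MICA(t2, t3) = t2
        # row best-matches: (lin(t2,t3), 1.0); column best-match for t3: 1.0
        expected = 0.5 * (np.mean([lin_t2_t3, 1.0]) + 1.0)
        got = enrich.semantic_similarity(["t2", "t3"], ["t3"], onto)
        assert got == pytest.approx(expected)

    def test_symmetric(self):
        onto = _toy_ontology()
        a = enrich.semantic_similarity(["t1", "t2"], ["t3"], onto)
        b = enrich.semantic_similarity(["t3"], ["t1", "t2"], onto)
        assert a == pytest.approx(b)

    def test_unknown_term_rejected(self):
        with pytest.raises(KeyError, match="nope"):
            enrich.semantic_similarity(["nope"], ["t1"], _toy_ontology())

    def test_resnik_normalized_variant(self):
        onto = _toy_ontology()
        val = enrich.semantic_similarity(["t3"], ["t3"], onto, measure="resnik")
        assert val == pytest.approx(1.0)  # t3 carries the maximum IC


class TestSignatureScore:
    def test_uniform_shift_recovered(self):
        rng = np.random.default_rng(0)
        values = pd.DataFrame(
            rng.normal(size=(60, 10)),
            index=[f"g{i}" for i in range(60)],
            columns=[f"s{j}" for j in range(10)],
        )
        sig = [f"g{i}" for i in range(10)]
        values.loc[sig] += 2.5
        cond = pd.Series(["A"] * 5 + ["B"] * 5, index=values.columns)
        score = enrich.signature_score(
            ExpressionMatrix(values, cond), sig, n_bins=4, n_ctrl=10, seed=0
        )
        # bin-matched controls sit at the top of the null distribution, so a
        # small downward bias is expected; the shift still dominates
        assert np.allclose(score, 2.5, atol=1.0)
        assert score.min() > 1.0

    def test_whole_universe_scores_near_zero(self, small_dataset):
        matrix, _ = small_dataset
        score = enrich.signature_score(matrix, matrix.genes, seed=0)
        assert np.allclose(score, 0.0, atol=0.05)

    @pytest.mark.parametrize("seed", range(5))
    def test_planted_shift_separates_conditions(self, seed):
        matrix, truth = simulate_dataset(default_config(seed=100 + seed))
        score = enrich.signature_score(matrix, truth.module_genes(1), seed=seed)
        a = score[matrix.samples_in("A")]
        b = score[matrix.samples_in("B")]
        p = stats.mannwhitneyu(b, a, alternative="greater").pvalue
        assert p < 0.01

    def test_missing_set_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            enrich.signature_score(small_dataset[0], ["nope"])


class TestGmtRoundTrip:
    def test_write_then_read(self, tmp_path, small_dataset):
        from coexnet.simulate import simulate_genesets

        _, truth = small_dataset
        coll = simulate_genesets(truth, seed=0)
        path = tmp_path / "sets.gmt"
        enrich.write_gmt(coll, path)
        back = enrich.read_gmt(path)
        assert back.sets == {k: list(v) for k, v in coll.sets.items()}

    def test_malformed_line_rejected(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("name_only\tdesc\n")
        with pytest.raises(ValueError):
            enrich.read_gmt(path)
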