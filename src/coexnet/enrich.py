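"""Gene-set statistics: overrepresentation, CES, GSEA, overlap, semantic
similarity, and expression-matched signature scoring.

The cluster enrichment score (CES) of a module is the absolute base-10 log
of its best BH-adjusted gene-set p-value, so CES > 3 is equivalent to an
adjusted p below 0.001.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix

__all__ = [
    "Ontology",
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "gsoa",
    "ces",
    "gsea",
    "partition_overlap",
    "semantic_similarity",
    "signature_score",
]


@dataclass
class Ontology:
    """A rooted term DAG (child -> parents) with direct gene annotations.

    Information content of a term is ``-log(f_t)`` where ``f_t`` is the
    fraction of root-annotated genes annotated at or below the term
    (annotations propagate to ancestors).
    """

    parents: dict[str, set[str]]
    term_genes: dict[str, set[str]]

    def __post_init__(self) -> None:
        roots = [t for t, ps in self.parents.items() if not ps]
        if len(roots) != 1:
            raise ValueError(f"ontology must have exactly one root, found {roots}")
        self.root = roots[0]
        self._validate_acyclic()
        self._propagated: dict[str, frozenset] = {}

    def _validate_acyclic(self) -> None:
        import networkx as nx

        g = nx.DiGraph()
        for child, ps in self.parents.items():
            g.add_node(child)
            for p in ps:
                g.add_edge(child, p)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("ontology contains a cycle")
        self._children: dict[str, set[str]] = {t: set() for t in self.parents}
        for child, ps in self.parents.items():
            for p in ps:
                self._children.setdefault(p, set()).add(child)

    @property
    def terms(self) -> list[str]:
        return sorted(self.parents)

    def ancestors(self, term: str) -> set[str]:
        """All ancestors of ``term`` including itself."""
        if term not in self.parents:
            raise KeyError(f"term {term!r} not in ontology")
        out, stack = {term}, [term]
        while stack:
            for p in self.parents[stack.pop()]:
                if p not in out:
                    out.add(p)
                    stack.append(p)
        return out

    def annotated_genes(self, term: str) -> frozenset:
        if term not in self._propagated:
            genes = set(self.term_genes.get(term, set()))
            for c in self._children.get(term, set()):
                genes |= self.annotated_genes(c)
            self._propagated[term] = frozenset(genes)
        return self._propagated[term]

    def ic(self, term: str) -> float:
        total = len(self.annotated_genes(self.root))
        if total == 0:
            raise ValueError("ontology has no annotated genes")
        n = len(self.annotated_genes(term))
        if n == 0:
            return float("inf")
        return float(-np.log(n / total))

    def max_ic(self) -> float:
        vals = [self.ic(t) for t in self.terms if np.isfinite(self.ic(t))]
        return max(vals) if vals else 0.0

    @classmethod
    def from_edges(
        cls, edges: list[tuple[str, str]], term_genes: dict[str, set[str]]
    ) -> "Ontology":
        parents: dict[str, set[str]] = {}
        for child, parent in edges:
            parents.setdefault(child, set()).add(parent)
            parents.setdefault(parent, set())
        return cls(parents=parents, term_genes={t: set(g) for t, g in term_genes.items()})

    def to_edge_frame(self) -> pd.DataFrame:
        rows = [(c, p) for c, ps in sorted(self.parents.items()) for p in sorted(ps)]
        return pd.DataFrame(rows, columns=["child", "parent"])


@dataclass
class GeneSetCollection:
    """Named gene sets with an optional annotation ontology."""

    sets: dict[str, list[str]]
    ontology: Ontology | None = None

    def __post_init__(self) -> None:
        self.sets = {name: list(genes) for name, genes in self.sets.items()}

    def names(self) -> list[str]:
        return sorted(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        name = parts[0]
        if name in sets:
            raise ValueError(f"duplicate gene-set name {name!r}")
        sets[name] = [g for g in parts[2:] if g]
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([name, "na", *collection.sets[name]])
        for name in collection.names()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def gsoa(
    module_genes: list[str],
    collection: GeneSetCollection,
    universe: list[str],
) -> pd.DataFrame:
    """Hypergeometric overrepresentation of each set in a gene module.

    One-sided upper-tail p: with universe size N, set size K (after
    intersection with the universe), module size n, and overlap k, the
    p-value is P(X >= k) for X ~ Hypergeom(N, K, n). BH adjustment is
    applied across all tested sets.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty universe")
    module = set(module_genes) & universe_set
    if not set(module_genes):
        raise ValueError("empty module")
    if not module:
        raise ValueError("module does not intersect the universe")
    n_univ, n_mod = len(universe_set), len(module)
    rows = []
    for name in collection.names():
        members = set(collection.sets[name]) & universe_set
        k = len(members & module)
        p = float(stats.hypergeom.sf(k - 1, n_univ, len(members), n_mod))
        rows.append(
            {
                "term": name,
                "set_size": len(members),
                "overlap": k,
                "gene_ratio": k / n_mod,
                "p": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows)
    out["adj_p"] = multipletests(out["p"], method="fdr_bh")[1]
    return out.sort_values(["p", "term"]).reset_index(drop=True)


def ces(results: pd.DataFrame) -> float:
    """Cluster enrichment score: |log10| of the best BH-adjusted p-value."""
    if len(results) == 0:
        raise ValueError("ces needs at least one enrichment result")
    best = float(results["adj_p"].min())
    if best <= 0:
        warnings.warn("adjusted p of 0 capped at machine precision", stacklevel=2)
        best = float(np.finfo(float).tiny)
    return float(abs(np.log10(best)))


def _running_sum(
    scores: np.ndarray, hits: np.ndarray, weight_p: float
) -> tuple[float, np.ndarray]:
    """Weighted KS-style running sum; returns (ES, full path)."""
    n = scores.size
    n_hits = int(hits.sum())
    if n_hits == 0 or n_hits == n:
        raise ValueError("gene set must hit a strict subset of the ranking")
    w = np.abs(scores) ** weight_p
    hit_total = w[hits].sum()
    steps = np.where(hits, np.where(hit_total > 0, w / max(hit_total, 1e-300), 0.0),
                     -1.0 / (n - n_hits))
    if hit_total == 0:  # all hit weights zero (possible at weight_p > 0)
        steps[hits] = 1.0 / n_hits
    path = np.cumsum(steps)
    es = float(path[np.argmax(np.abs(path))])
    return es, path


def gsea(
    ranked: pd.DataFrame | pd.Series,
    gene_set: list[str],
    weight_p: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Rank-based enrichment of a gene set in a signed ranking.

    ``ranked`` is either a differential table with ``gene`` and ``log2fc``
    columns or a Series mapping gene to score; it is sorted descending.
    Hit increments are ``|r|^p / sum_hits |r|^p``; misses decrement
    ``1/(G - K)``. The enrichment score is the maximum deviation from zero.
    NES and the p-value come from a gene-label permutation null: NES is the
    ES divided by the mean |null ES| of the same sign.
    """
    if isinstance(ranked, pd.DataFrame):
        series = pd.Series(ranked["log2fc"].to_numpy(), index=ranked["gene"].to_numpy())
    else:
        series = ranked
    series = series.sort_values(ascending=False, kind="mergesort")
    genes = np.array(series.index)
    scores = series.to_numpy(dtype=float)
    hit_mask = np.isin(genes, list(gene_set))
    n_hits = int(hit_mask.sum())
    if n_hits == 0:
        raise ValueError("gene set is disjoint from the ranking")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    es, _ = _running_sum(scores, hit_mask, weight_p)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    n = genes.size
    for i in range(n_perm):
        perm = np.zeros(n, dtype=bool)
        perm[rng.choice(n, size=n_hits, replace=False)] = True
        null[i], _ = _running_sum(scores, perm, weight_p)
    same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
    if same_sign.size == 0:
        nes = np.nan
        p = 1.0 / (n_perm + 1)
    else:
        denom = np.abs(same_sign).mean()
        nes = float(es / denom) if denom > 0 else np.nan
        p = float((1 + (np.abs(same_sign) >= abs(es)).sum()) / (1 + same_sign.size))
    return {"es": es, "nes": nes, "p": p, "n_hits": n_hits, "n_genes": int(n)}


def partition_overlap(partition_a, partition_b) -> pd.DataFrame:
    """Jaccard index and hypergeometric p for every module pair.

    Accepts two gene->label Series (label 0 ignored). The hypergeometric
    universe is the union of assigned genes across both partitions; BH is
    applied over all tested pairs.
    """
    pa = partition_a.assignment if hasattr(partition_a, "assignment") else partition_a
    pb = partition_b.assignment if hasattr(partition_b, "assignment") else partition_b
    mods_a = {m: set(pa.index[pa == m]) for m in sorted(set(pa) - {0})}
    mods_b = {m: set(pb.index[pb == m]) for m in sorted(set(pb) - {0})}
    universe = set().union(*mods_a.values(), *mods_b.values()) if mods_a and mods_b else set()
    n_univ = len(universe)
    rows = []
    for ma, a_genes in mods_a.items():
        for mb, b_genes in mods_b.items():
            inter = len(a_genes & b_genes)
            union = len(a_genes | b_genes)
            if union == 0:
                rows.append(
                    {"module_a": ma, "module_b": mb, "jaccard": 0.0, "p": 1.0,
                     "empty": True}
                )
                continue
            p = float(stats.hypergeom.sf(inter - 1, n_univ, len(b_genes), len(a_genes)))
            rows.append(
                {
                    "module_a": ma,
                    "module_b": mb,
                    "jaccard": inter / union,
                    "p": min(p, 1.0),
                    "empty": False,
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["adj_p"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def _lin(t1: str, t2: str, ontology: Ontology) -> float:
    common = ontology.ancestors(t1) & ontology.ancestors(t2)
    mica_ic = max(ontology.ic(t) for t in common)
    ic1, ic2 = ontology.ic(t1), ontology.ic(t2)
    if ic1 + ic2 == 0:
        return 0.0
    return float(2.0 * mica_ic / (ic1 + ic2))


def semantic_similarity(
    terms_a: list[str],
    terms_b: list[str],
    ontology: Ontology,
    measure: str = "lin",
) -> float:
    """Between-set term similarity via best-match average.

    Pairwise similarity uses Lin's measure
    ``2 IC(MICA) / (IC(t1) + IC(t2))`` by default (Resnik, normalized by
    the ontology's maximum IC, behind ``measure='resnik'``). Term pairs
    whose only shared ancestor is the root score 0.
    """
    for t in list(terms_a) + list(terms_b):
        if t not in ontology.parents:
            raise KeyError(f"term {t!r} not in ontology")
    if not terms_a or not terms_b:
        raise ValueError("both term sets must be non-empty")
    if measure == "lin":
        pair = lambda a, b: _lin(a, b, ontology)
    elif measure == "resnik":
        max_ic = ontology.max_ic()
        if max_ic == 0:
            return 0.0
        pair = lambda a, b: float(
            max(ontology.ic(t) for t in ontology.ancestors(a) & ontology.ancestors(b))
            / max_ic
        )
    else:
        raise ValueError("measure must be 'lin' or 'resnik'")
    sim = np.array([[pair(a, b) for b in terms_b] for a in terms_a])
    bma = 0.5 * (sim.max(axis=1).mean() + sim.max(axis=0).mean())
    return float(np.clip(bma, 0.0, 1.0))


def signature_score(
    matrix: ExpressionMatrix | pd.DataFrame,
    gene_set: list[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Per-sample signature score against expression-matched controls.

    Genes are binned by average expression into ``n_bins`` equal-count
    bins; for every signature gene, ``n_ctrl`` control genes are drawn from
    the non-signature genes of its bin. The score is mean signature
    expression minus mean control expression, per sample.
    """
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    present = [g for g in gene_set if g in values.index]
    if not present:
        raise ValueError("gene set does not intersect the matrix")
    rng = np.random.default_rng(seed)
    avg = values.mean(axis=1)
    n_bins = min(n_bins, len(values))
    ranks = avg.rank(method="first")
    bins = np.ceil(ranks / len(values) * n_bins).astype(int)
    sig_set = set(present)
    ctrl_rows = []
    warned = False
    for g in present:
        pool = [x for x in values.index[bins == bins[g]] if x not in sig_set]
        if not pool:  # bin holds only signature genes; match within the bin
            pool = list(values.index[bins == bins[g]])
        replace = len(pool) < n_ctrl
        if replace and not warned:
            warnings.warn(
                "expression bin smaller than n_ctrl; sampling with replacement",
                stacklevel=2,
            )
            warned = True
        ctrl_rows.extend(rng.choice(pool, size=n_ctrl, replace=replace))
    sig_mean = values.loc[present].mean(axis=0)
    ctrl_mean = values.loc[ctrl_rows].mean(axis=0)
    return (sig_mean - ctrl_mean).rename("signature_score")
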