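"""Regulator prioritization for a target module.

Two independent gene-regulatory-network reconstructions — a tree-ensemble
importance method (GENIE3-style) and a mutual-information method with
data-processing-inequality pruning (ARACNe-style) — are each summarized by
weighted node degree into the target module, and their top-k rankings are
intersected and then filtered by a motif-support table to yield consensus
regulators with provenance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesRegressor

from .containers import EdgeTable, ExpressionMatrix

__all__ = [
    "genie3_weights",
    "mi_matrix",
    "dpi_prune",
    "rank_tfs",
    "consensus_tfs",
    "regulon_subnetwork",
    "ConsensusResult",
]


@dataclass
class ConsensusResult:
    """Two-stage consensus: GRN-intersection TFs, then motif-supported TFs."""

    stage1: list[str]
    stage2: list[str]
    provenance: pd.DataFrame  # tf, rank_a, rank_b, max_nes, n_motif_targets


def genie3_weights(
    matrix: ExpressionMatrix | pd.DataFrame,
    regulators: list[str],
    targets: list[str] | None = None,
    n_trees: int = 1000,
    max_features: str | float = "sqrt",
    seed: int = 0,
) -> pd.DataFrame:
    """Tree-ensemble regulator importances per target gene.

    Each target is regressed on all regulators (excluding itself) with an
    extra-trees ensemble; total-variance-reduction importances are
    normalized to sum to 1 per target. Returns a regulator-by-target weight
    frame with zero self-edges.
    """
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    missing = [r for r in regulators if r not in values.index]
    if missing:
        raise ValueError(f"regulators absent from the matrix: {missing[:5]}")
    if len(regulators) < 2:
        raise ValueError("need at least 2 regulators")
    if targets is None:
        targets = list(values.index)
    regulators = list(regulators)
    x_all = values.loc[regulators].to_numpy().T  # samples x regulators
    weights = pd.DataFrame(0.0, index=regulators, columns=targets)
    rng = np.random.default_rng(seed)
    for target in targets:
        y = values.loc[target].to_numpy()
        if y.std() == 0:
            warnings.warn(f"target {target!r} has zero variance; skipped", stacklevel=2)
            continue
        if target in regulators:
            cols = [i for i, r in enumerate(regulators) if r != target]
        else:
            cols = list(range(len(regulators)))
        model = ExtraTreesRegressor(
            n_estimators=n_trees,
            max_features=max_features,
            random_state=int(rng.integers(2**31)),
            n_jobs=1,
        )
        model.fit(x_all[:, cols], y)
        imp = model.feature_importances_
        total = imp.sum()
        if total > 0:
            imp = imp / total
        for i, c in enumerate(cols):
            weights.iloc[c, weights.columns.get_loc(target)] = imp[i]
    return weights


def mi_matrix(
    matrix: ExpressionMatrix | pd.DataFrame, n_bins: int | None = None
) -> pd.DataFrame:
    """Pairwise mutual information (nats) from equal-frequency binning.

    Discretization uses ceil(n^(1/3)) bins by default — with sqrt-many
    bins the joint table is too sparse for the Miller-Madow correction to
    remove the plug-in bias, and independent pairs score far from zero.
    The corrected estimate is clipped at zero. Diagonal is 0; constant
    genes get an all-zero row.
    """
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    n = values.shape[1]
    if n < 8:
        raise ValueError("mutual information needs at least 8 samples")
    if n_bins is None:
        n_bins = max(2, int(np.ceil(np.cbrt(n))))
    genes = list(values.index)
    x = values.to_numpy(dtype=float)
    constant = x.std(axis=1) == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant gene(s); their MI rows set to 0",
            stacklevel=2,
        )
    # equal-frequency codes via ranks
    order = np.argsort(x, axis=1, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(x.shape[0])[:, None]
    ranks[rows, order] = np.arange(n)[None, :]
    codes = (ranks * n_bins // n).astype(np.int64)

    g = len(genes)
    mi = np.zeros((g, g))
    log_counts = {}
    marg_h = np.zeros(g)
    marg_m = np.zeros(g, dtype=int)
    for i in range(g):
        c = np.bincount(codes[i], minlength=n_bins)
        nz = c[c > 0]
        marg_h[i] = -np.sum(nz / n * np.log(nz / n))
        marg_m[i] = len(nz)
    for i in range(g):
        if constant[i]:
            continue
        for j in range(i + 1, g):
            if constant[j]:
                continue
            joint = np.bincount(
                codes[i] * n_bins + codes[j], minlength=n_bins * n_bins
            )
            nz = joint[joint > 0]
            h_xy = -np.sum(nz / n * np.log(nz / n))
            plug_in = marg_h[i] + marg_h[j] - h_xy
            correction = (marg_m[i] + marg_m[j] - len(nz) - 1) / (2.0 * n)
            mi[i, j] = mi[j, i] = max(plug_in + correction, 0.0)
    return pd.DataFrame(mi, index=genes, columns=genes)


def dpi_prune(
    mi: pd.DataFrame, regulators: list[str] | None = None, epsilon: float = 0.0
) -> pd.DataFrame:
    """Data-processing-inequality pruning of an MI network.

    In every fully connected triangle, the smallest edge is removed when it
    is below ``(1 - epsilon)`` times the smaller of the other two (likely
    an indirect interaction). Removals are decided on the original matrix
    and applied at the end, so a second application is a no-op. On an exact
    tie among a triangle's smallest edges, the lexicographically smallest
    gene pair is removed. If ``regulators`` is given, the result is
    restricted to regulator rows (all genes remain as columns).
    """
    w = mi.to_numpy().astype(float).copy()
    np.fill_diagonal(w, 0.0)
    genes = list(mi.index)
    g = len(genes)
    pos = w > 0
    # thr_ij = max over k of min(w_ik, w_jk) across triangles containing (i, j)
    thr = np.zeros_like(w)
    for i in range(g):
        m = np.minimum(w[i][None, :], w)  # (j, k)
        m[~(pos[i][None, :] & pos)] = 0.0
        thr[i] = m.max(axis=1)
    remove = set()
    strict = pos & (w < (1.0 - epsilon) * thr)
    for i, j in zip(*np.nonzero(np.triu(strict, k=1))):
        remove.add((int(i), int(j)))
    if epsilon == 0.0:
        # exact ties: within a triangle whose two smallest edges are equal,
        # drop the lexicographically smallest of the tied pairs
        tie = pos & ~strict & (w == thr) & (thr > 0)
        for i, j in zip(*np.nonzero(np.triu(tie, k=1))):
            ks = np.flatnonzero(pos[i] & pos[j])
            for k in ks:
                if np.minimum(w[i, k], w[j, k]) != w[i, j]:
                    continue
                tied = [(int(i), int(j))]
                if w[min(i, k), max(i, k)] == w[i, j]:
                    tied.append((int(min(i, k)), int(max(i, k))))
                if w[min(j, k), max(j, k)] == w[i, j]:
                    tied.append((int(min(j, k)), int(max(j, k))))
                remove.add(min(tied))
    for i, j in remove:
        w[i, j] = w[j, i] = 0.0
    pruned = pd.DataFrame(w, index=genes, columns=genes)
    if regulators is not None:
        missing = [r for r in regulators if r not in pruned.index]
        if missing:
            raise ValueError(f"regulators absent from MI matrix: {missing[:5]}")
        pruned = pruned.loc[regulators]
        for r in regulators:
            if r in pruned.columns:
                pruned.loc[r, r] = 0.0
    return pruned


def rank_tfs(
    weights: pd.DataFrame, target_set: list[str], top_k: int = 100
) -> pd.DataFrame:
    """Rank regulators by weighted node degree into a target gene set.

    Node degree is the sum of a regulator's edge weights into the target
    set; ties break alphabetically. Returns the top ``top_k`` rows with
    1-based ranks.
    """
    if not target_set:
        raise ValueError("target_set must be non-empty")
    cols = [g for g in target_set if g in weights.columns]
    if not cols:
        warnings.warn("no regulator touches the target set", stacklevel=2)
        return pd.DataFrame(columns=["tf", "node_degree", "rank"])
    sub = weights[cols]
    degree = sub.sum(axis=1)
    for tf in degree.index:
        if tf in cols:
            degree[tf] -= sub.loc[tf, tf] if tf in sub.columns else 0.0
    out = (
        degree.rename("node_degree")
        .rename_axis("tf")
        .reset_index()
        .sort_values(["node_degree", "tf"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    out = out[out["node_degree"] > 0].head(top_k).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    if len(out) == 0:
        warnings.warn("no regulator touches the target set", stacklevel=2)
    return out


def consensus_tfs(
    ranking_a: pd.DataFrame,
    ranking_b: pd.DataFrame,
    motif_table: pd.DataFrame | None = None,
    nes_floor: float = 3.0,
    module_genes: list[str] | None = None,
) -> ConsensusResult:
    """Two-stage consensus of regulator rankings plus motif support.

    Stage 1 intersects the two rankings' TF lists. Stage 2 keeps stage-1
    TFs with motif-table NES >= ``nes_floor`` for at least one target
    (restricted to ``module_genes`` when given). Per-TF provenance records
    both method ranks, the best NES, and the motif target count.
    """
    set_a = dict(zip(ranking_a["tf"], ranking_a["rank"]))
    set_b = dict(zip(ranking_b["tf"], ranking_b["rank"]))
    stage1 = sorted(set(set_a) & set(set_b))
    if motif_table is None or len(motif_table) == 0:
        if motif_table is not None and len(motif_table) == 0:
            warnings.warn("empty motif table; stage 2 is empty", stacklevel=2)
        motif_table = pd.DataFrame(columns=["tf", "target", "nes"])
    motif = motif_table[motif_table["nes"] >= nes_floor]
    if module_genes is not None:
        motif = motif[motif["target"].isin(set(module_genes))]
    rows, stage2 = [], []
    for tf in stage1:
        hits = motif[motif["tf"] == tf]
        supported = len(hits) > 0
        if supported:
            stage2.append(tf)
        rows.append(
            {
                "tf": tf,
                "rank_a": set_a[tf],
                "rank_b": set_b[tf],
                "max_nes": float(hits["nes"].max()) if supported else np.nan,
                "n_motif_targets": int(len(hits)),
                "motif_supported": supported,
            }
        )
    provenance = pd.DataFrame(
        rows,
        columns=["tf", "rank_a", "rank_b", "max_nes", "n_motif_targets", "motif_supported"],
    )
    return ConsensusResult(stage1=stage1, stage2=stage2, provenance=provenance)


def regulon_subnetwork(
    weights: pd.DataFrame,
    consensus: list[str],
    module_genes: list[str],
    motif_table: pd.DataFrame,
) -> tuple[EdgeTable, float]:
    """Edges from consensus TFs to motif-supported module genes.

    Edge weight comes from the GRN weight matrix; coverage is the fraction
    of module genes reached by at least one consensus TF.
    """
    if not consensus:
        raise ValueError("consensus TF list is empty")
    pairs = {
        (t.tf, t.target)
        for t in motif_table.itertuples(index=False)
        if t.tf in set(consensus) and t.target in set(module_genes)
    }
    rows = []
    for tf, target in sorted(pairs):
        weight = 0.0
        if tf in weights.index and target in weights.columns:
            weight = float(weights.loc[tf, target])
        rows.append({"source": tf, "target": target, "weight": weight})
    edges = pd.DataFrame(rows, columns=["source", "target", "weight"])
    covered = len(set(edges["target"])) if len(edges) else 0
    coverage = covered / len(module_genes) if module_genes else 0.0
    return EdgeTable(edges=edges, directed=True), coverage
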