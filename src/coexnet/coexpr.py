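"""Weighted co-expression network construction and module detection.

Implements the standard unsigned pipeline: soft-thresholded Pearson
adjacency ``a_ij = |cor(x_i, x_j)|^beta``, scale-free topology fit for
power selection, topological overlap (TOM), average-linkage clustering of
``1 - TOM`` with a static tree cut, first-principal-component module
eigengenes, eigengene-dissimilarity merging, and the module-proximity
statistic (average adjacency of every module to a focal module, normalized
so the all-module reference equals 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .containers import ExpressionMatrix, ModulePartition

__all__ = [
    "AdjacencyMatrix",
    "TomMatrix",
    "SoftPowerScan",
    "ProximityResult",
    "pearson_adjacency",
    "scale_free_index",
    "scale_free_fit",
    "pick_soft_power",
    "tom_similarity",
    "cluster_modules",
    "module_eigengenes",
    "merge_modules",
    "module_proximity",
    "export_edges",
]


@dataclass
class AdjacencyMatrix:
    """Symmetric gene-by-gene adjacency in [0, 1]; diagonal stored as 0."""

    values: pd.DataFrame
    power: float
    signed: bool = False

    @property
    def genes(self) -> list:
        return list(self.values.index)

    def connectivity(self) -> pd.Series:
        """Node degree k_i = sum_j a_ij (diagonal excluded)."""
        return self.values.sum(axis=1)


@dataclass
class TomMatrix:
    """Topological overlap similarity; diagonal 1, dissimilarity = 1 - TOM."""

    similarity: pd.DataFrame

    @property
    def dissimilarity(self) -> pd.DataFrame:
        return 1.0 - self.similarity


@dataclass
class SoftPowerScan:
    power: int
    table: pd.DataFrame  # columns: power, fit_index, mean_k
    reached_threshold: bool


@dataclass
class ProximityResult:
    focal_module: int
    relative: pd.Series  # module label -> reference-normalized mean adjacency
    reference: float = 1.0


def pearson_adjacency(
    matrix: ExpressionMatrix | pd.DataFrame, power: float = 6.0, signed: bool = False
) -> AdjacencyMatrix:
    """Soft-thresholded correlation adjacency.

    Unsigned mode (default): ``a_ij = |cor|^power``. Signed mode maps the
    correlation to ``(1 + cor)/2`` before raising to the power. Genes with
    zero variance carry no correlation information and are removed with a
    warning.
    """
    if power < 1:
        raise ValueError("soft-thresholding power must be >= 1")
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    sd = values.std(axis=1, ddof=0)
    if (sd == 0).any():
        dropped = list(values.index[sd == 0])
        warnings.warn(
            f"removed {len(dropped)} zero-variance gene(s): {dropped[:5]}",
            stacklevel=2,
        )
        values = values.loc[sd > 0]
    cor = np.corrcoef(values.to_numpy())
    cor = np.clip(np.nan_to_num(cor), -1.0, 1.0)
    if signed:
        adj = ((1.0 + cor) / 2.0) ** power
    else:
        adj = np.abs(cor) ** power
    np.fill_diagonal(adj, 0.0)
    frame = pd.DataFrame(adj, index=values.index, columns=values.index)
    return AdjacencyMatrix(values=frame, power=power, signed=signed)


def scale_free_index(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log-log degree-distribution regression.

    Degrees are grouped into ``n_bins`` equal-width bins; log10 frequency is
    regressed on log10 mean degree per bin. The R^2 is signed by the slope:
    a negative slope (heavier low-degree tail, the scale-free signature)
    yields a positive index, so positively sloped fits cannot pass a
    threshold.
    """
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if k.size < 2 or float(k.max()) == float(k.min()):
        warnings.warn("constant connectivity; scale-free index reported as 0", stacklevel=2)
        return 0.0
    # equal-width degree bins, as in the standard scale-free topology criterion
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, n_bins - 1)
    log_k, log_f = [], []
    total = k.size
    for b in range(n_bins):
        members = k[idx == b]
        if members.size == 0:
            continue
        log_k.append(np.log10(members.mean()))
        log_f.append(np.log10(members.size / total))
    if len(log_k) < 3:
        warnings.warn("too few occupied degree bins; index reported as 0", stacklevel=2)
        return 0.0
    slope, _ = np.polyfit(log_k, log_f, 1)
    r = np.corrcoef(log_k, log_f)[0, 1]
    r2 = float(r * r)
    return r2 if slope < 0 else -r2


def scale_free_fit(adjacency: AdjacencyMatrix, n_bins: int = 10) -> float:
    """Scale-free topology fit index of a network's connectivity profile."""
    if len(adjacency.values) < 10:
        raise ValueError("scale-free fit needs at least 10 genes")
    return scale_free_index(adjacency.connectivity().to_numpy(), n_bins=n_bins)


def pick_soft_power(
    matrix: ExpressionMatrix | pd.DataFrame,
    candidate_powers: tuple[int, ...] = tuple(range(1, 13)),
    fit_threshold: float = 0.8,
    n_bins: int = 10,
) -> SoftPowerScan:
    """Smallest candidate power whose fit index reaches the threshold.

    If none qualifies, the argmax is returned with a warning, mirroring the
    standard soft-threshold selection heuristic.
    """
    if not candidate_powers:
        raise ValueError("candidate_powers must be non-empty")
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    sd = values.std(axis=1, ddof=0)
    values = values.loc[sd > 0]
    cor = np.abs(np.clip(np.nan_to_num(np.corrcoef(values.to_numpy())), -1, 1))
    np.fill_diagonal(cor, 0.0)
    rows = []
    for beta in candidate_powers:
        adj = cor**beta
        k = adj.sum(axis=1)
        rows.append(
            {
                "power": beta,
                "fit_index": scale_free_index(k, n_bins=n_bins),
                "mean_k": float(k.mean()),
            }
        )
    table = pd.DataFrame(rows)
    passing = table[table["fit_index"] >= fit_threshold]
    if len(passing):
        chosen = int(passing.iloc[0]["power"])
        reached = True
    else:
        chosen = int(table.loc[table["fit_index"].idxmax(), "power"])
        reached = False
        warnings.warn(
            f"no candidate power reached fit index {fit_threshold}; "
            f"falling back to argmax beta={chosen}",
            stacklevel=2,
        )
    return SoftPowerScan(power=chosen, table=table, reached_threshold=reached)


def tom_similarity(adjacency: AdjacencyMatrix) -> TomMatrix:
    """Unsigned topological overlap.

    ``TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` with
    ``l_ij = sum_{u != i,j} a_iu * a_uj``; diagonal set to 1.
    """
    a = adjacency.values.to_numpy()
    k = a.sum(axis=1)
    # with a zero diagonal, (A @ A)_ij already sums over u not in {i, j}
    l = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (l + a) / denom
    tom = np.nan_to_num(tom)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(tom, 1.0)
    frame = pd.DataFrame(tom, index=adjacency.values.index, columns=adjacency.values.columns)
    return TomMatrix(similarity=frame)


def cluster_modules(
    tom: TomMatrix,
    min_module_size: int = 30,
    cut_height: float | None = None,
) -> ModulePartition:
    """Average-linkage clustering of TOM dissimilarity with a static cut.

    The dendrogram is cut at ``cut_height`` (default 0.90 x the maximum
    merge height — the top of the tree is dominated by unassignable noise
    genes joining at near-maximal dissimilarity); clusters below
    ``min_module_size`` are set to label 0 (unassigned). Labels are
    ordered by decreasing module size.
    """
    if min_module_size < 3:
        raise ValueError("min_module_size must be >= 3")
    genes = list(tom.similarity.index)
    if len(genes) < min_module_size:
        warnings.warn("fewer genes than min_module_size; all unassigned", stacklevel=2)
        return ModulePartition(assignment=pd.Series(0, index=genes))
    diss = tom.dissimilarity.to_numpy()
    diss = (diss + diss.T) / 2.0
    np.fill_diagonal(diss, 0.0)
    z = hierarchy.linkage(squareform(diss, checks=False), method="average")
    height = cut_height if cut_height is not None else 0.90 * float(z[:, 2].max())
    raw = hierarchy.fcluster(z, t=height, criterion="distance")
    assignment = _relabel_by_size(pd.Series(raw, index=genes), min_module_size)
    return ModulePartition(assignment=assignment)


def _relabel_by_size(raw: pd.Series, min_module_size: int) -> pd.Series:
    counts = raw.value_counts()
    keep = [lab for lab in counts.index if counts[lab] >= min_module_size]
    keep.sort(key=lambda lab: (-counts[lab], lab))
    mapping = {lab: i + 1 for i, lab in enumerate(keep)}
    return raw.map(lambda lab: mapping.get(lab, 0)).astype(int)


def module_eigengenes(
    matrix: ExpressionMatrix | pd.DataFrame, partition: ModulePartition
) -> ModulePartition:
    """First principal component per module, sign-aligned and unit-norm.

    Each module's submatrix is standardized gene-wise; the eigengene is the
    leading right singular vector over samples, flipped if needed so it
    correlates positively with the module's mean expression profile.
    ``variance_explained`` is the leading singular value's share of total
    variance.
    """
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    labels = partition.module_labels
    me_rows, ve = {}, {}
    for m in labels:
        genes = partition.module_genes(m)
        if len(genes) < 3:
            raise ValueError(f"module {m} has fewer than 3 genes")
        sub = values.loc[genes].to_numpy()
        sd = sub.std(axis=1, ddof=0)
        if (sd == 0).any():
            bad = [g for g, s in zip(genes, sd) if s == 0]
            raise ValueError(f"module {m} contains constant gene(s): {bad[:5]}")
        std = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
        _, s, vt = np.linalg.svd(std, full_matrices=False)
        me = vt[0]
        mean_profile = std.mean(axis=0)
        if np.corrcoef(me, mean_profile)[0, 1] < 0:
            me = -me
        me_rows[m] = me
        ve[m] = float(s[0] ** 2 / (s**2).sum())
    eigengenes = pd.DataFrame(me_rows, index=values.columns).T
    eigengenes.index.name = "module"
    return ModulePartition(
        assignment=partition.assignment.copy(),
        eigengenes=eigengenes,
        variance_explained=pd.Series(ve, name="variance_explained"),
    )


def merge_modules(
    matrix: ExpressionMatrix | pd.DataFrame,
    partition: ModulePartition,
    me_diss_threshold: float = 0.25,
) -> ModulePartition:
    """Iteratively merge the closest eigengene pair while below threshold.

    Dissimilarity is ``1 - cor(ME_a, ME_b)``. After each merge, eigengenes
    are recomputed. The final labels are re-ordered by decreasing size, so
    the result does not depend on the input label order.
    """
    part = partition
    if part.eigengenes is None:
        part = module_eigengenes(matrix, part)
    assignment = part.assignment.copy()
    while True:
        labels = sorted(set(assignment) - {0})
        if len(labels) < 2:
            break
        me = part.eigengenes.loc[labels].to_numpy()
        cor = np.corrcoef(me)
        diss = 1.0 - cor
        best = None
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                key = (diss[i, j], labels[i], labels[j])
                if best is None or key < best:
                    best = key
        if best is None or best[0] >= me_diss_threshold:
            break
        _, a, b = best
        assignment[assignment == b] = a
        part = module_eigengenes(matrix, ModulePartition(assignment=assignment))
        assignment = part.assignment
    counts = assignment[assignment != 0].value_counts()
    order = sorted(counts.index, key=lambda lab: (-counts[lab], lab))
    mapping = {lab: i + 1 for i, lab in enumerate(order)}
    relabeled = assignment.map(lambda lab: mapping.get(lab, 0)).astype(int)
    return module_eigengenes(matrix, ModulePartition(assignment=relabeled))


def module_proximity(
    adjacency: AdjacencyMatrix, partition: ModulePartition, focal_module: int
) -> ProximityResult:
    """Relative average adjacency of every module to a focal module.

    For each module m != focal, the mean adjacency over cross pairs
    (i in focal, j in m) is divided by the overall mean adjacency between
    the focal module and all other assigned genes, so the all-module
    reference is exactly 1.
    """
    labels = partition.module_labels
    if focal_module not in labels:
        raise ValueError(f"focal module {focal_module} not present")
    others = [m for m in labels if m != focal_module]
    if not others:
        raise ValueError("module_proximity needs at least one non-focal module")
    a = adjacency.values
    focal_genes = partition.module_genes(focal_module)
    rest_genes = [g for m in others for g in partition.module_genes(m)]
    reference = float(a.loc[focal_genes, rest_genes].to_numpy().mean())
    if reference == 0:
        raise ValueError("reference average adjacency is zero")
    rel = {}
    for m in others:
        block = a.loc[focal_genes, partition.module_genes(m)].to_numpy()
        rel[m] = float(block.mean()) / reference
    return ProximityResult(
        focal_module=focal_module, relative=pd.Series(rel).sort_index()
    )


def export_edges(
    adjacency: AdjacencyMatrix, min_weight: float = 0.3
) -> pd.DataFrame:
    """Edge list keeping pairs whose adjacency exceeds ``min_weight``."""
    a = adjacency.values.to_numpy()
    genes = adjacency.genes
    ii, jj = np.where(np.triu(a, k=1) > min_weight)
    return pd.DataFrame(
        {
            "source": [genes[i] for i in ii],
            "target": [genes[j] for j in jj],
            "weight": a[ii, jj],
        }
    )


def to_graphml(edges: pd.DataFrame, path) -> None:
    """Write an edge table (source, target, weight) as GraphML."""
    g = nx.Graph()
    for row in edges.itertuples(index=False):
        g.add_edge(row.source, row.target, weight=float(row.weight))
    nx.write_graphml(g, path)
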