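"""Directed Bayesian networks over module eigengenes.

Score-based structure learning with a Gaussian BIC score: greedy hill
climbing over add/delete/reverse moves with random restarts, an exhaustive
enumerator for up to four nodes (the test oracle), and bootstrap
aggregation with arc strength / direction summaries and threshold
filtering.

The BIC of a DAG decomposes into per-node local scores

    local(j | P) = -n/2 (log(2 pi s2_j) + 1) - (|P| + 2)/2 log(n)

where s2_j is the MLE residual variance of node j regressed on its parent
set P (intercept included). Residual variances are floored at 1e-12 so
near-deterministic relations remain scorable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

__all__ = [
    "DagStructure",
    "BootstrapNetwork",
    "select_bn_inputs",
    "hc_search",
    "exhaustive_dag_search",
    "bootstrap_network",
]

_VAR_FLOOR = 1e-12


@dataclass
class DagStructure:
    nodes: list
    edges: frozenset  # of (from, to) node-label pairs
    score: float

    def parent_sets(self) -> dict:
        parents = {n: [] for n in self.nodes}
        for u, v in self.edges:
            parents[v].append(u)
        return {n: tuple(sorted(ps)) for n, ps in parents.items()}


@dataclass
class BootstrapNetwork:
    """Aggregated bootstrap network.

    ``edges`` holds the retained arcs with their strength (fraction of
    bootstrap DAGs containing the edge in either direction) and direction
    (fraction of those supporting the reported orientation, always >= 0.5).
    ``support`` tallies every undirected pair observed in any replicate.
    """

    edges: pd.DataFrame
    support: pd.DataFrame
    n_boot: int


class _BicScorer:
    """Cached Gaussian-BIC local scores from a column-centered data matrix."""

    def __init__(self, data: np.ndarray):
        data = np.asarray(data, dtype=float)
        self.n = data.shape[0]
        centered = data - data.mean(axis=0)
        self.s = centered.T @ centered / self.n
        self._cache: dict[tuple[int, tuple[int, ...]], float] = {}
        for j in range(data.shape[1]):
            if self.s[j, j] <= 0 and data[:, j].std() == 0:
                raise ValueError(f"node {j} is constant")

    def local(self, j: int, parents: tuple[int, ...]) -> float:
        key = (j, parents)
        if key in self._cache:
            return self._cache[key]
        if parents:
            p = list(parents)
            spp = self.s[np.ix_(p, p)]
            spj = self.s[p, j]
            try:
                beta = np.linalg.solve(spp, spj)
            except np.linalg.LinAlgError:
                beta = np.linalg.lstsq(spp, spj, rcond=None)[0]
            var = self.s[j, j] - spj @ beta
        else:
            var = self.s[j, j]
        var = max(float(var), _VAR_FLOOR)
        n = self.n
        ll = -n / 2.0 * (np.log(2 * np.pi * var) + 1.0)
        score = ll - (len(parents) + 2) / 2.0 * np.log(n)
        self._cache[key] = score
        return score

    def total(self, parent_sets: dict[int, tuple[int, ...]]) -> float:
        return sum(self.local(j, ps) for j, ps in parent_sets.items())


def select_bn_inputs(
    ces_scores: pd.Series | dict,
    eigengenes: pd.DataFrame,
    ces_threshold: float = 3.0,
) -> pd.DataFrame:
    """Restrict the eigengene matrix to modules with CES strictly above
    the threshold, preserving row order."""
    scores = pd.Series(ces_scores)
    missing = [m for m in eigengenes.index if m not in scores.index]
    if missing:
        raise ValueError(f"CES missing for modules: {missing}")
    keep = [m for m in eigengenes.index if scores[m] > ces_threshold]
    if not keep:
        raise ValueError(
            f"no module has CES > {ces_threshold}; lower the threshold"
        )
    return eigengenes.loc[keep]


def _creates_cycle(adj: np.ndarray, u: int, v: int) -> bool:
    """Would adding u->v create a cycle? (is u reachable from v?)"""
    n = adj.shape[0]
    seen = np.zeros(n, dtype=bool)
    stack = [v]
    while stack:
        w = stack.pop()
        if w == u:
            return True
        if seen[w]:
            continue
        seen[w] = True
        stack.extend(np.flatnonzero(adj[w]))
    return False


def _prune_parents(scorer: _BicScorer, n_nodes: int, adj: np.ndarray) -> np.ndarray:
    """Backward parent selection per node (order-preserving deletions)."""
    adj = adj.copy()
    for j in range(n_nodes):
        parents = list(np.flatnonzero(adj[:, j]))
        best = scorer.local(j, tuple(sorted(parents)))
        improved = True
        while improved and parents:
            improved = False
            for p in list(parents):
                trial = tuple(sorted(q for q in parents if q != p))
                score = scorer.local(j, trial)
                if score > best + 1e-9:
                    best = score
                    parents.remove(p)
                    adj[p, j] = 0
                    improved = True
    return adj


def _hill_climb(
    scorer: _BicScorer, n_nodes: int, init_adj: np.ndarray
) -> tuple[np.ndarray, float]:
    adj = init_adj.copy()
    parents = {j: tuple(sorted(np.flatnonzero(adj[:, j]))) for j in range(n_nodes)}
    local = {j: scorer.local(j, parents[j]) for j in range(n_nodes)}
    while True:
        best_delta, best_move = 1e-9, None
        for u in range(n_nodes):
            for v in range(n_nodes):
                if u == v:
                    continue
                if adj[u, v]:
                    # delete u->v
                    new_pv = tuple(p for p in parents[v] if p != u)
                    delta = scorer.local(v, new_pv) - local[v]
                    if delta > best_delta:
                        best_delta, best_move = delta, ("del", u, v)
                    # reverse u->v
                    adj[u, v] = 0
                    ok = not _creates_cycle(adj, v, u)
                    adj[u, v] = 1
                    if ok:
                        new_pu = tuple(sorted(parents[u] + (v,)))
                        delta = (
                            scorer.local(v, new_pv)
                            - local[v]
                            + scorer.local(u, new_pu)
                            - local[u]
                        )
                        if delta > best_delta:
                            best_delta, best_move = delta, ("rev", u, v)
                elif not _creates_cycle(adj, u, v):
                    new_pv = tuple(sorted(parents[v] + (u,)))
                    delta = scorer.local(v, new_pv) - local[v]
                    if delta > best_delta:
                        best_delta, best_move = delta, ("add", u, v)
        if best_move is None:
            break
        kind, u, v = best_move
        if kind == "add":
            adj[u, v] = 1
        elif kind == "del":
            adj[u, v] = 0
        else:
            adj[u, v] = 0
            adj[v, u] = 1
        for j in (u, v):
            parents[j] = tuple(sorted(np.flatnonzero(adj[:, j])))
            local[j] = scorer.local(j, parents[j])
    return adj, sum(local.values())


def _random_dag(n_nodes: int, rng: np.random.Generator, p_edge: float = 0.3) -> np.ndarray:
    order = rng.permutation(n_nodes)
    adj = np.zeros((n_nodes, n_nodes), dtype=np.int8)
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_edge:
                adj[order[i], order[j]] = 1
    return adj


def hc_search(
    data: pd.DataFrame | np.ndarray,
    seed: int = 0,
    n_restarts: int = 10,
) -> DagStructure:
    """Greedy hill climbing over add/delete/reverse moves with restarts.

    The first climb starts from the empty graph; subsequent restarts
    alternate between complete DAGs over random topological orders (greedy
    deletion escapes collider traps that single-edge additions cannot
    reach) and sparse random DAGs. Moves are accepted only when they
    strictly improve the BIC; candidate moves are scanned in a fixed
    lexicographic order so ties resolve deterministically under a fixed
    seed.
    """
    frame = data if isinstance(data, pd.DataFrame) else pd.DataFrame(np.asarray(data))
    nodes = list(frame.columns)
    n_nodes = len(nodes)
    x = frame.to_numpy(dtype=float)
    if x.shape[0] < 3 * n_nodes:
        warnings.warn(
            f"only {x.shape[0]} samples for {n_nodes} nodes; "
            "structure estimates may be unstable",
            stacklevel=2,
        )
    scorer = _BicScorer(x)
    rng = np.random.default_rng(seed)
    best_adj, best_score = None, -np.inf
    for r in range(max(1, n_restarts)):
        if r == 0:
            init = np.zeros((n_nodes, n_nodes), dtype=np.int8)
        elif r <= n_nodes:
            # complete DAG over a random order forced to end at node r-1:
            # greedy deletion can then uncover any collider sinking there
            order = list(rng.permutation(n_nodes))
            order.remove(r - 1)
            order.append(r - 1)
            init = np.zeros((n_nodes, n_nodes), dtype=np.int8)
            for i in range(n_nodes):
                for j in range(i + 1, n_nodes):
                    init[order[i], order[j]] = 1
            init = _prune_parents(scorer, n_nodes, init)
        else:
            init = _random_dag(n_nodes, rng, p_edge=0.5)
        adj, score = _hill_climb(scorer, n_nodes, init)
        if score > best_score + 1e-12:
            best_adj, best_score = adj, score
    edges = frozenset(
        (nodes[u], nodes[v]) for u, v in zip(*np.nonzero(best_adj))
    )
    return DagStructure(nodes=nodes, edges=edges, score=float(best_score))


@lru_cache(maxsize=None)
def _all_dags(n_nodes: int) -> list[tuple[tuple[int, int], ...]]:
    """Every labeled DAG on ``n_nodes`` nodes as sorted edge tuples."""
    pairs = [(u, v) for u in range(n_nodes) for v in range(n_nodes) if u != v]
    dags = []
    for mask in range(1 << len(pairs)):
        edges = tuple(pairs[i] for i in range(len(pairs)) if mask >> i & 1)
        adj = np.zeros((n_nodes, n_nodes), dtype=np.int8)
        skip = False
        for u, v in edges:
            if adj[v, u]:
                skip = True
                break
            adj[u, v] = 1
        if skip:
            continue
        if _is_acyclic(adj):
            dags.append(edges)
    return dags


def _is_acyclic(adj: np.ndarray) -> bool:
    n = adj.shape[0]
    indeg = adj.sum(axis=0).astype(int)
    queue = [i for i in range(n) if indeg[i] == 0]
    seen = 0
    while queue:
        u = queue.pop()
        seen += 1
        for v in np.flatnonzero(adj[u]):
            indeg[v] -= 1
            if indeg[v] == 0:
                queue.append(v)
    return seen == n


def exhaustive_dag_search(data: pd.DataFrame | np.ndarray) -> DagStructure:
    """Globally BIC-optimal DAG by enumeration; refuses above 4 nodes."""
    frame = data if isinstance(data, pd.DataFrame) else pd.DataFrame(np.asarray(data))
    nodes = list(frame.columns)
    n_nodes = len(nodes)
    if n_nodes > 4:
        raise ValueError("exhaustive search is limited to 4 nodes")
    scorer = _BicScorer(frame.to_numpy(dtype=float))
    best_edges, best_score = (), -np.inf
    for edges in _all_dags(n_nodes):
        parents: dict[int, list[int]] = {j: [] for j in range(n_nodes)}
        for u, v in edges:
            parents[v].append(u)
        score = sum(
            scorer.local(j, tuple(sorted(ps))) for j, ps in parents.items()
        )
        if score > best_score + 1e-12:
            best_edges, best_score = edges, score
    edges = frozenset((nodes[u], nodes[v]) for u, v in best_edges)
    return DagStructure(nodes=nodes, edges=edges, score=float(best_score))


def bootstrap_network(
    data: pd.DataFrame,
    n_boot: int = 1000,
    aggregate_threshold: float = 0.85,
    strength_floor: float = 0.7,
    seed: int = 0,
    n_restarts: int = 2,
    mode: str = "strength",
) -> BootstrapNetwork:
    """Bootstrap-aggregated hill-climbing network with threshold filtering.

    Samples (rows) are resampled with replacement ``n_boot`` times and a
    DAG is learned per replicate. For every node pair, strength is the
    fraction of replicates containing the edge in either direction and
    direction is the majority orientation's share of those. With
    ``mode='strength'`` (default) the averaged network keeps pairs whose
    strength reaches ``aggregate_threshold``, oriented by majority; with
    ``mode='directed'`` the threshold applies to the directed support
    (strength x direction). Edges with strength below ``strength_floor``
    are then removed, and any residual cycle is broken by iteratively
    dropping its lowest-support arc.
    """
    if not 0 < aggregate_threshold <= 1:
        raise ValueError("aggregate_threshold must be in (0, 1]")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if mode not in ("strength", "directed"):
        raise ValueError("mode must be 'strength' or 'directed'")
    nodes = list(data.columns)
    n = len(data)
    rng = np.random.default_rng(seed)
    counts: dict[tuple, int] = {}
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        sample = data.iloc[idx]
        if any(sample[c].std() == 0 for c in nodes):
            continue
        dag = hc_search(sample, seed=int(rng.integers(2**31)), n_restarts=n_restarts)
        for e in dag.edges:
            counts[e] = counts.get(e, 0) + 1

    rows = []
    pairs = {tuple(sorted((u, v))) for (u, v) in counts}
    for a, b in sorted(pairs):
        fwd = counts.get((a, b), 0)
        rev = counts.get((b, a), 0)
        strength = (fwd + rev) / n_boot
        if fwd >= rev:
            u, v, direction = a, b, fwd / (fwd + rev)
        else:
            u, v, direction = b, a, rev / (fwd + rev)
        rows.append(
            {"from": u, "to": v, "strength": strength, "direction": direction}
        )
    support = pd.DataFrame(rows, columns=["from", "to", "strength", "direction"])

    kept = support.copy()
    if len(kept):
        if mode == "strength":
            kept = kept[kept["strength"] >= aggregate_threshold]
        else:
            kept = kept[kept["strength"] * kept["direction"] >= aggregate_threshold]
        kept = kept[kept["strength"] >= strength_floor]
    kept = kept.reset_index(drop=True)
    kept = _break_cycles(kept)
    return BootstrapNetwork(edges=kept, support=support, n_boot=n_boot)


def _break_cycles(edges: pd.DataFrame) -> pd.DataFrame:
    import networkx as nx

    frame = edges.copy()
    while True:
        g = nx.DiGraph()
        for u, v, s in frame[["from", "to", "strength"]].itertuples(index=False, name=None):
            g.add_edge(u, v, strength=s)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            return frame.reset_index(drop=True)
        weakest = min(
            cycle, key=lambda e: g.edges[e[0], e[1]]["strength"]
        )
        mask = ~((frame["from"] == weakest[0]) & (frame["to"] == weakest[1]))
        frame = frame[mask]
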