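"""Synthetic data with known ground truth for the module-network pipeline.

The generator emulates the statistical structure the downstream stages
assume: genes loading on latent module factors, a linear-Gaussian DAG among
the factors, a condition-specific mean shift on selected modules,
regulator->target effects confined to one module, module-aligned gene-set
annotations under a toy ontology, and drug rank profiles that mimic or
reverse a query signature.

Model
-----
For sample i the module factors follow a structural equation model

    z_j = sum_{k in pa(j)} b_jk * z_k + eps_j,    eps_j ~ N(0, sigma_z^2)

in topological order of the factor DAG. Samples in condition B additionally
receive ``z_m += delta_m`` for every shifted module m (added after the SEM
pass, so the shift does not propagate to child factors and the planted
differential signal stays confined to the shifted modules). A gene g
assigned to module m is

    x_g = lambda_g * z_m + N(0, sigma_g^2)

with loading lambda_g drawn uniformly from ``loading_range``. Designated
regulator ("TF") genes live in one module; their targets additionally
receive ``sum_t w_t * x_t`` over their regulators. Background genes are
pure N(0, 1) noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "DrugSignatureLibrary",
    "simulate_dataset",
    "simulate_genesets",
    "simulate_drug_profiles",
    "simulate_motif_table",
    "simulate_regulator_list",
    "default_config",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the study design at desk scale: 1000 genes of which 750
    load on five modules (sizes 250..50), 16 reference (A) and 27 case (B)
    samples, a four-edge factor DAG, and a condition shift of +2 log units
    on module 1, which also hosts the five planted regulators.
    """

    n_genes: int = 1000
    module_sizes: tuple[int, ...] = (250, 200, 150, 100, 50)
    n_samples_per_condition: tuple[int, int] = (16, 27)
    # directed (parent, child, coefficient) triples over 1-based module labels
    factor_dag: tuple[tuple[int, int, float], ...] = (
        (1, 2, 0.6),
        (1, 3, 0.6),
        (2, 4, 0.6),
        (3, 5, 0.6),
    )
    condition_shift: tuple[tuple[int, float], ...] = ((1, 2.0),)
    loading_range: tuple[float, float] = (0.6, 1.0)
    gene_noise_sd: float = 0.3
    factor_noise_sd: float = 1.0
    n_tfs: int = 5
    tf_module: int = 1
    tf_effect_sd: float = 1.0
    tf_target_frac: float = 0.4
    random_loading_sign: bool = False
    # per-gene baseline log2 intensity, uniform over this range; makes
    # average-expression bins a realistic mix of genes (set to (0, 0) for
    # exactly factor-proportional module genes)
    baseline_range: tuple[float, float] = (4.0, 12.0)
    seed: int = 0

    @property
    def n_background(self) -> int:
        return self.n_genes - sum(self.module_sizes)

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    def validate(self) -> None:
        if any(s < 3 for s in self.module_sizes):
            raise ValueError("every module must have at least 3 genes")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("module_sizes sum above n_genes")
        lo, hi = self.loading_range
        if lo > hi:
            raise ValueError("loading_range must satisfy lambda_min <= lambda_max")
        if self.baseline_range[0] > self.baseline_range[1]:
            raise ValueError("baseline_range must be (low, high)")
        if min(self.gene_noise_sd, self.factor_noise_sd, self.tf_effect_sd) < 0:
            raise ValueError("noise standard deviations must be >= 0")
        g = nx.DiGraph()
        g.add_nodes_from(range(1, self.n_modules + 1))
        g.add_edges_from((p, c) for p, c, _ in self.factor_dag)
        if set(g.nodes) - set(range(1, self.n_modules + 1)):
            raise ValueError("factor_dag references unknown module labels")
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("factor_dag must be acyclic")
        if not (1 <= self.tf_module <= self.n_modules):
            raise ValueError("tf_module out of range")
        if self.n_tfs >= self.module_sizes[self.tf_module - 1]:
            raise ValueError("n_tfs must be smaller than the host module")
        for m, _ in self.condition_shift:
            if not (1 <= m <= self.n_modules):
                raise ValueError(f"condition_shift references unknown module {m}")


@dataclass
class SyntheticTruth:
    """Planted ground truth accompanying a simulated dataset."""

    membership: dict[str, int]  # gene -> module label, 0 = background
    factor_values: pd.DataFrame  # module x sample
    dag_edges: list[tuple[int, int, float]]
    tf_edges: list[tuple[str, str, float]]
    tf_genes: list[str]
    shifted_modules: dict[int, float]
    loadings: dict[str, float]
    condition: pd.Series | None = None
    drug_classes: dict[str, str] = field(default_factory=dict)

    def module_genes(self, label: int) -> list[str]:
        return [g for g, m in self.membership.items() if m == label]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "membership": self.membership,
            "factor_values": self.factor_values.to_dict(),
            "dag_edges": self.dag_edges,
            "tf_edges": self.tf_edges,
            "tf_genes": self.tf_genes,
            "shifted_modules": {str(k): v for k, v in self.shifted_modules.items()},
            "loadings": self.loadings,
            "drug_classes": self.drug_classes,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


@dataclass
class DrugSignatureLibrary:
    """Per-drug full gene rankings with signed differential scores.

    ``scores`` is gene-by-drug; each column ranks the same gene universe.
    """

    scores: pd.DataFrame

    @property
    def drugs(self) -> list[str]:
        return list(self.scores.columns)

    def profile(self, drug: str) -> pd.Series:
        return self.scores[drug]


def default_config(**overrides) -> SimulationConfig:
    """The package's reference simulation conditions, optionally overridden."""
    return SimulationConfig(**overrides)


def simulate_dataset(config: SimulationConfig) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Draw one expression matrix plus its ground truth from ``config``.

    Deterministic under a fixed ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_a, n_b = config.n_samples_per_condition
    n_samples = n_a + n_b
    samples = [f"A{i + 1:02d}" for i in range(n_a)] + [f"B{i + 1:02d}" for i in range(n_b)]
    condition = pd.Series(["A"] * n_a + ["B"] * n_b, index=samples, name="condition")

    k = config.n_modules
    g = nx.DiGraph()
    g.add_nodes_from(range(1, k + 1))
    g.add_weighted_edges_from(config.factor_dag)
    order = list(nx.topological_sort(g))

    z = pd.DataFrame(0.0, index=range(1, k + 1), columns=samples)
    eps = rng.normal(0.0, config.factor_noise_sd, size=(k, n_samples))
    for j in order:
        row = eps[j - 1].copy()
        for p in g.predecessors(j):
            row = row + g.edges[p, j]["weight"] * z.loc[p].to_numpy()
        z.loc[j] = row
    shifted = dict(config.condition_shift)
    b_cols = [s for s in samples if condition[s] == "B"]
    for m, delta in shifted.items():
        z.loc[m, b_cols] += delta

    genes: list[str] = []
    membership: dict[str, int] = {}
    loadings: dict[str, float] = {}
    rows: list[np.ndarray] = []
    lo, hi = config.loading_range
    for m, size in enumerate(config.module_sizes, start=1):
        for i in range(size):
            name = f"M{m}G{i + 1:03d}"
            lam = rng.uniform(lo, hi)
            if config.random_loading_sign and rng.random() < 0.5:
                lam = -lam
            x = lam * z.loc[m].to_numpy() + rng.normal(0.0, config.gene_noise_sd, n_samples)
            genes.append(name)
            membership[name] = m
            loadings[name] = float(lam)
            rows.append(x)
    for i in range(config.n_background):
        name = f"BG{i + 1:04d}"
        genes.append(name)
        membership[name] = 0
        loadings[name] = 0.0
        rows.append(rng.normal(0.0, 1.0, n_samples))

    values = pd.DataFrame(np.vstack(rows), index=genes, columns=samples)

    # regulator effects inside the designated module
    host = [g_ for g_ in genes if membership[g_] == config.tf_module]
    tf_genes = host[: config.n_tfs]
    candidates = host[config.n_tfs:]
    n_targets = max(1, round(config.tf_target_frac * len(candidates)))
    tf_edges: list[tuple[str, str, float]] = []
    for tf in tf_genes:
        targets = rng.choice(candidates, size=n_targets, replace=False)
        for t in targets:
            # half-normal weights: regulator effects reinforce the module
            # factor, so the planted condition shift keeps its sign in targets
            w = abs(rng.normal(0.0, config.tf_effect_sd))
            tf_edges.append((tf, str(t), float(w)))
    for tf, target, w in tf_edges:
        values.loc[target] = values.loc[target] + w * values.loc[tf]

    b_lo, b_hi = config.baseline_range
    if (b_lo, b_hi) != (0.0, 0.0):
        baselines = rng.uniform(b_lo, b_hi, size=len(genes))
        values = values.add(pd.Series(baselines, index=genes), axis=0)

    truth = SyntheticTruth(
        membership=membership,
        factor_values=z,
        dag_edges=[tuple(e) for e in config.factor_dag],
        tf_edges=tf_edges,
        tf_genes=tf_genes,
        shifted_modules=shifted,
        loadings=loadings,
        condition=condition,
    )
    return ExpressionMatrix(values, condition), truth


def simulate_genesets(
    truth: SyntheticTruth,
    overlap_frac: float = 0.8,
    n_decoys: int = 20,
    seed: int = 0,
):
    """Module-aligned gene sets plus decoys under a small rooted ontology.

    Each module gets one "matched" set of the same size that shares
    ``round(overlap_frac * size)`` of the module's genes (the remainder is
    filled from outside the module). Decoy sets are random draws from the
    whole gene universe. The ontology is a rooted DAG whose leaves are the
    sets, with direct annotations enabling information-content computation.
    """
    from .enrich import GeneSetCollection, Ontology

    if not 0 < overlap_frac <= 1:
        raise ValueError("overlap_frac must be in (0, 1]")
    rng = np.random.default_rng(seed)
    universe = list(truth.membership)
    modules = sorted({m for m in truth.membership.values() if m != 0})

    sets: dict[str, list[str]] = {}
    for m in modules:
        mod_genes = truth.module_genes(m)
        n_keep = round(overlap_frac * len(mod_genes))
        if n_keep < 1:
            raise ValueError(f"overlap_frac too small for module {m}")
        keep = list(rng.choice(mod_genes, size=n_keep, replace=False))
        pool = [g for g in universe if truth.membership[g] != m]
        filler = list(rng.choice(pool, size=len(mod_genes) - n_keep, replace=False))
        sets[f"SET_M{m}"] = sorted(keep + filler)
    for i in range(n_decoys):
        size = int(rng.integers(10, 51))
        sets[f"DECOY{i + 1:02d}"] = sorted(rng.choice(universe, size=size, replace=False))

    # rooted term DAG: root -> 3 branches -> leaf terms; a few leaves get a
    # second parent so the structure is a genuine DAG, not a tree
    parents: dict[str, set[str]] = {"ROOT": set()}
    branches = ["BRANCH1", "BRANCH2", "BRANCH3"]
    for b in branches:
        parents[b] = {"ROOT"}
    term_genes: dict[str, set[str]] = {t: set() for t in parents}
    for i, (name, members) in enumerate(sorted(sets.items())):
        parents[name] = {branches[i % 3]}
        if i % 5 == 4:
            parents[name].add(branches[(i + 1) % 3])
        term_genes[name] = set(members)
    ontology = Ontology(parents=parents, term_genes=term_genes)
    return GeneSetCollection(sets=sets, ontology=ontology)


def simulate_drug_profiles(
    query_up: list[str],
    query_down: list[str],
    universe: list[str],
    n_per_class: int = 10,
    noise_swaps: int = 0,
    seed: int = 0,
    n_neutral: int | None = None,
) -> tuple[DrugSignatureLibrary, dict[str, str]]:
    """Drug rank profiles planted as reversers, mimickers, and neutrals.

    A reverser places ``query_up`` genes at the bottom of its ranking and
    ``query_down`` genes at the top (a drug that pushes the signature back);
    a mimicker does the opposite; neutrals are uniform permutations. After
    placement, ``noise_swaps`` random transpositions are applied. Signed
    differential scores decrease linearly down the ranking.
    """
    up, down = set(query_up), set(query_down)
    if up & down:
        raise ValueError("query_up and query_down must be disjoint")
    missing = (up | down) - set(universe)
    if missing:
        raise ValueError(f"query genes outside universe: {sorted(missing)[:5]}")
    if noise_swaps < 0:
        raise ValueError("noise_swaps must be >= 0")

    rng = np.random.default_rng(seed)
    n_genes = len(universe)
    score_grid = np.linspace(3.0, -3.0, n_genes)
    rest = [g for g in universe if g not in up and g not in down]

    def ranked(kind: str) -> list[str]:
        mid = list(rng.permutation(rest))
        top_up = list(rng.permutation(sorted(up)))
        top_down = list(rng.permutation(sorted(down)))
        if kind == "reverser":
            order = top_down + mid + top_up
        elif kind == "mimicker":
            order = top_up + mid + top_down
        else:
            order = list(rng.permutation(universe))
        for _ in range(noise_swaps):
            i, j = rng.integers(0, n_genes, size=2)
            order[i], order[j] = order[j], order[i]
        return order

    columns: dict[str, pd.Series] = {}
    classes: dict[str, str] = {}
    per_class = {"reverser": n_per_class, "mimicker": n_per_class,
                 "neutral": n_per_class if n_neutral is None else n_neutral}
    for kind in ("reverser", "mimicker", "neutral"):
        for i in range(per_class[kind]):
            drug = f"{kind[:3].upper()}{i + 1:03d}"
            order = ranked(kind)
            columns[drug] = pd.Series(score_grid, index=order).reindex(universe)
            classes[drug] = kind
    library = DrugSignatureLibrary(scores=pd.DataFrame(columns))
    return library, classes


def simulate_motif_table(
    truth: SyntheticTruth,
    n_supported: int = 3,
    nes_range: tuple[float, float] = (4.0, 8.0),
    n_decoy_rows: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """A motif-support table (tf, target, nes) standing in for a motif scan.

    The first ``n_supported`` planted regulators get high-NES rows for their
    true targets; decoy rows pair random genes at sub-threshold NES so a
    floor of 3 separates supported from unsupported regulators.
    """
    rng = np.random.default_rng(seed)
    supported = truth.tf_genes[:n_supported]
    rows = []
    for tf, target, _ in truth.tf_edges:
        if tf in supported:
            rows.append((tf, target, float(rng.uniform(*nes_range))))
    universe = list(truth.membership)
    for _ in range(n_decoy_rows):
        tf, target = rng.choice(universe, size=2, replace=False)
        rows.append((str(tf), str(target), float(rng.uniform(0.5, 2.5))))
    return pd.DataFrame(rows, columns=["tf", "target", "nes"])


def simulate_regulator_list(
    truth: SyntheticTruth, n_decoys: int = 15, seed: int = 0
) -> list[str]:
    """Candidate-regulator list: planted TFs plus decoys from other modules
    and the background — regulators that are expressed but do not drive the
    target module, emulating a TF catalog intersected with the data."""
    rng = np.random.default_rng(seed)
    tf_module = truth.membership[truth.tf_genes[0]]
    pool = [g for g, m in truth.membership.items() if m != tf_module]
    decoys = list(rng.choice(pool, size=n_decoys, replace=False))
    return sorted(truth.tf_genes) + sorted(map(str, decoys))


def write_dataset(
    matrix: ExpressionMatrix, truth: SyntheticTruth, outdir: str | Path
) -> dict[str, Path]:
    """Persist a simulated dataset in the package's text formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "condition": outdir / "condition.tsv",
        "truth": outdir / "truth.json",
    }
    mat = matrix.values.copy()
    mat.index.name = "gene"
    mat.to_csv(paths["expression"], sep="\t")
    cond = matrix.condition.rename_axis("sample").reset_index()
    cond.to_csv(paths["condition"], sep="\t", index=False)
    truth.to_json(paths["truth"])
    return paths
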