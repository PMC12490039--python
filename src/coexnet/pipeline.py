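"""Stage orchestration: a single config, derived per-stage seeds, JSON
manifests with input/output hashes, and text-format artifacts per stage.

Stages and their order::

    simulate -> preprocess -> wgcna -> enrich -> bn
                                    -> proximity
                                    -> grn -> score -> connect -> report

Each stage writes its outputs plus ``manifest_<stage>.json`` recording
parameters, the derived seed, and SHA-256 hashes of inputs and outputs.
A dependent stage verifies its inputs against the producer's recorded
hashes, so a tampered intermediate fails loudly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bayesnet, coexpr, connectivity, enrich, grn, ingest, simulate
from .containers import ModulePartition

__all__ = ["PipelineConfig", "run_stage", "run_all", "STAGES"]

STAGES = [
    "simulate",
    "preprocess",
    "wgcna",
    "enrich",
    "proximity",
    "bn",
    "grn",
    "score",
    "connect",
    "report",
]


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end run, with study-default values."""

    seed: int = 0
    # simulation
    n_genes: int = 1000
    module_sizes: tuple[int, ...] = (250, 200, 150, 100, 50)
    n_samples_per_condition: tuple[int, int] = (16, 27)
    gene_noise_sd: float = 0.3
    condition_delta: float = 2.0
    n_tfs: int = 5
    n_decoy_regulators: int = 15
    geneset_overlap_frac: float = 0.8
    n_decoy_sets: int = 20
    # wgcna
    soft_power: int | None = 6  # None -> scan candidate_powers
    candidate_powers: tuple[int, ...] = tuple(range(1, 13))
    fit_threshold: float = 0.8
    min_module_size: int = 30
    me_diss_threshold: float = 0.25
    edge_min_weight: float = 0.3
    # enrichment
    gsea_n_perm: int = 1000
    ces_threshold: float = 3.0
    # bayesian network
    n_boot: int = 1000
    aggregate_threshold: float = 0.85
    strength_floor: float = 0.7
    bn_restarts: int = 2
    # grn
    n_trees: int = 1000
    top_k: int = 100
    nes_floor: float = 3.0
    # connectivity
    n_drugs_per_class: int = 10
    drug_noise_swaps: int = 5
    connectivity_threshold: float = -0.7
    focal_module: int | None = None  # None -> module with highest CES

    def validate(self) -> None:
        if not (0 < self.aggregate_threshold <= 1):
            raise ValueError("aggregate_threshold must be in (0, 1]")
        if self.me_diss_threshold < 0:
            raise ValueError("me_diss_threshold must be >= 0")
        if self.n_boot < 100:
            raise ValueError("n_boot must be >= 100")
        if self.top_k < 1 or self.n_trees < 1 or self.min_module_size < 3:
            raise ValueError("parameter out of documented bounds")

    def stage_seed(self, stage: str) -> int:
        idx = STAGES.index(stage)
        return int((self.seed * 1_000_003 + 7919 * (idx + 1)) % 2**31)

    def to_yaml(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        for key, val in payload.items():
            if isinstance(val, tuple):
                payload[key] = list(val)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(payload) - set(fields)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key, val in payload.items():
            if isinstance(val, list):
                payload[key] = tuple(val)
        return cls(**payload)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(
    workdir: Path, stage: str, config: PipelineConfig,
    inputs: list[Path], outputs: list[Path], extra: dict | None = None
) -> Path:
    manifest = {
        "stage": stage,
        "seed": config.stage_seed(stage),
        "params": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "inputs": {p.name: _sha256(p) for p in inputs},
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    if extra:
        manifest["extra"] = extra
    path = workdir / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path


def _require(workdir: Path, producer: str, names: list[str]) -> list[Path]:
    paths = []
    manifest_path = workdir / f"manifest_{producer}.json"
    if not manifest_path.exists():
        raise FileNotFoundError(
            f"missing outputs of stage '{producer}'; run it first"
        )
    recorded = json.loads(manifest_path.read_text())["outputs"]
    for name in names:
        path = workdir / name
        if not path.exists():
            raise FileNotFoundError(
                f"missing '{name}' from stage '{producer}'; run it first"
            )
        if name in recorded and _sha256(path) != recorded[name]:
            raise ValueError(
                f"hash mismatch for '{name}': file changed since stage "
                f"'{producer}' produced it"
            )
        paths.append(path)
    return paths


def _read_modules(workdir: Path) -> ModulePartition:
    assignment = pd.read_csv(workdir / "modules.tsv", sep="\t", index_col=0)["module"]
    eigengenes = pd.read_csv(workdir / "eigengenes.tsv", sep="\t", index_col=0)
    eigengenes.index = eigengenes.index.astype(int)
    return ModulePartition(assignment=assignment, eigengenes=eigengenes)


def _focal_module(config: PipelineConfig, workdir: Path) -> int:
    if config.focal_module is not None:
        return config.focal_module
    ces_table = pd.read_csv(workdir / "ces.tsv", sep="\t", index_col=0)
    return int(ces_table["ces"].idxmax())


# ---------------------------------------------------------------------------
# stage implementations


def _stage_simulate(config: PipelineConfig, workdir: Path) -> list[Path]:
    seed = config.stage_seed("simulate")
    n_modules = len(config.module_sizes)
    default_dag = simulate.SimulationConfig.__dataclass_fields__["factor_dag"].default
    dag = tuple(e for e in default_dag if e[0] <= n_modules and e[1] <= n_modules)
    sim = simulate.SimulationConfig(
        n_genes=config.n_genes,
        module_sizes=tuple(config.module_sizes),
        factor_dag=dag,
        n_samples_per_condition=tuple(config.n_samples_per_condition),
        gene_noise_sd=config.gene_noise_sd,
        condition_shift=((1, config.condition_delta),),
        n_tfs=config.n_tfs,
        seed=seed,
    )
    matrix, truth = simulate.simulate_dataset(sim)
    paths = simulate.write_dataset(matrix, truth, workdir)
    collection = simulate.simulate_genesets(
        truth, overlap_frac=config.geneset_overlap_frac,
        n_decoys=config.n_decoy_sets, seed=seed + 1,
    )
    enrich.write_gmt(collection, workdir / "genesets.gmt")
    collection.ontology.to_edge_frame().to_csv(
        workdir / "ontology.tsv", sep="\t", index=False
    )
    motif = simulate.simulate_motif_table(truth, seed=seed + 2)
    motif.to_csv(workdir / "motif_table.tsv", sep="\t", index=False)
    regulators = simulate.simulate_regulator_list(
        truth, n_decoys=config.n_decoy_regulators, seed=seed + 3
    )
    (workdir / "regulators.txt").write_text("\n".join(regulators) + "\n")
    return [
        paths["expression"], paths["condition"], paths["truth"],
        workdir / "genesets.gmt", workdir / "ontology.tsv",
        workdir / "motif_table.tsv", workdir / "regulators.txt",
    ]


def _stage_preprocess(config: PipelineConfig, workdir: Path) -> list[Path]:
    _require(workdir, "simulate", ["expression.tsv", "condition.tsv"])
    matrix = ingest.read_expression(
        workdir / "expression.tsv", workdir / "condition.tsv"
    )
    matrix = ingest.collapse_transcripts(matrix)
    matrix = ingest.mad_filter(matrix)
    filtered = matrix.values.copy()
    filtered.index.name = "gene"
    filtered.to_csv(workdir / "filtered.tsv", sep="\t")
    diff = ingest.differential_ranking(matrix)
    diff.to_csv(workdir / "differential.tsv", sep="\t", index=False)
    return [workdir / "filtered.tsv", workdir / "differential.tsv"]


def _stage_wgcna(config: PipelineConfig, workdir: Path) -> list[Path]:
    _require(workdir, "preprocess", ["filtered.tsv"])
    values = pd.read_csv(workdir / "filtered.tsv", sep="\t", index_col=0)
    if config.soft_power is None:
        scan = coexpr.pick_soft_power(
            values, candidate_powers=tuple(config.candidate_powers),
            fit_threshold=config.fit_threshold,
        )
        power = scan.power
        scan.table.to_csv(workdir / "power_scan.tsv", sep="\t", index=False)
    else:
        power = config.soft_power
        pd.DataFrame({"power": [power]}).to_csv(
            workdir / "power_scan.tsv", sep="\t", index=False
        )
    adjacency = coexpr.pearson_adjacency(values, power=power)
    tom = coexpr.tom_similarity(adjacency)
    partition = coexpr.cluster_modules(tom, min_module_size=config.min_module_size)
    partition = coexpr.module_eigengenes(values, partition)
    partition = coexpr.merge_modules(
        values, partition, me_diss_threshold=config.me_diss_threshold
    )
    partition.assignment.rename("module").rename_axis("gene").to_csv(
        workdir / "modules.tsv", sep="\t"
    )
    partition.eigengenes.to_csv(workdir / "eigengenes.tsv", sep="\t")
    adjacency.values.to_csv(workdir / "adjacency.tsv", sep="\t")
    edges = coexpr.export_edges(adjacency, min_weight=config.edge_min_weight)
    edges.to_csv(workdir / "network_edges.tsv", sep="\t", index=False)
    return [
        workdir / "power_scan.tsv", workdir / "modules.tsv",
        workdir / "eigengenes.tsv", workdir / "adjacency.tsv",
        workdir / "network_edges.tsv",
    ]


def _stage_enrich(config: PipelineConfig, workdir: Path) -> list[Path]:
    _require(workdir, "wgcna", ["modules.tsv"])
    _require(workdir, "preprocess", ["filtered.tsv", "differential.tsv"])
    _require(workdir, "simulate", ["genesets.gmt"])
    partition = _read_modules(workdir)
    values = pd.read_csv(workdir / "filtered.tsv", sep="\t", index_col=0)
    collection = enrich.read_gmt(workdir / "genesets.gmt")
    universe = list(values.index)
    all_rows, ces_rows = [], []
    for m in partition.module_labels:
        res = enrich.gsoa(partition.module_genes(m), collection, universe)
        res.insert(0, "module", m)
        all_rows.append(res)
        ces_rows.append({"module": m, "ces": enrich.ces(res)})
    pd.concat(all_rows).to_csv(workdir / "gsoa.tsv", sep="\t", index=False)
    pd.DataFrame(ces_rows).set_index("module").to_csv(workdir / "ces.tsv", sep="\t")

    diff = pd.read_csv(workdir / "differential.tsv", sep="\t")
    seed = config.stage_seed("enrich")
    gsea_rows = []
    for m in partition.module_labels:
        genes = [g for g in partition.module_genes(m) if g in set(diff["gene"])]
        if not genes:
            continue
        res = enrich.gsea(diff, genes, n_perm=config.gsea_n_perm, seed=seed + m)
        gsea_rows.append({"module": m, **res})
    pd.DataFrame(gsea_rows).to_csv(workdir / "gsea.tsv", sep="\t", index=False)
    return [workdir / "gsoa.tsv", workdir / "ces.tsv", workdir / "gsea.tsv"]


def _stage_proximity(config: PipelineConfig, workdir: Path) -> list[Path]:
    _require(workdir, "wgcna", ["adjacency.tsv", "modules.tsv"])
    _require(workdir, "enrich", ["ces.tsv"])
    partition = _read_modules(workdir)
    values = pd.read_csv(workdir / "adjacency.tsv", sep="\t", index_col=0)
    adjacency = coexpr.AdjacencyMatrix(values=values, power=np.nan)
    focal = _focal_module(config, workdir)
    result = coexpr.module_proximity(adjacency, partition, focal)
    out = result.relative.rename("relative_adjacency").rename_axis("module").reset_index()
    out["focal_module"] = focal
    out.to_csv(workdir / "proximity.tsv", sep="\t", index=False)
    return [workdir / "proximity.tsv"]


def _stage_bn(config: PipelineConfig, workdir: Path) -> list[Path]:
    _require(workdir, "wgcna", ["eigengenes.tsv"])
    _require(workdir, "enrich", ["ces.tsv"])
    partition = _read_modules(workdir)
    ces_table = pd.read_csv(workdir / "ces.tsv", sep="\t", index_col=0)["ces"]
    try:
        selected = bayesnet.select_bn_inputs(
            ces_table, partition.eigengenes, ces_threshold=config.ces_threshold
        )
    except ValueError as err:
        warnings.warn(f"bn stage skipped: {err}", stacklevel=2)
        pd.DataFrame(columns=["from", "to", "strength", "direction"]).to_csv(
            workdir / "bn_edges.tsv", sep="\t", index=False
        )
        return [workdir / "bn_edges.tsv"]
    if len(selected) < 2:
        warnings.warn("fewer than 2 modules pass CES; bn stage empty", stacklevel=2)
        pd.DataFrame(columns=["from", "to", "strength", "direction"]).to_csv(
            workdir / "bn_edges.tsv", sep="\t", index=False
        )
        return [workdir / "bn_edges.tsv"]
    net = bayesnet.bootstrap_network(
        selected.T,
        n_boot=config.n_boot,
        aggregate_threshold=config.aggregate_threshold,
        strength_floor=config.strength_floor,
        seed=config.stage_seed("bn"),
        n_restarts=config.bn_restarts,
    )
    net.edges.to_csv(workdir / "bn_edges.tsv", sep="\t", index=False)
    net.support.to_csv(workdir / "bn_support.tsv", sep="\t", index=False)
    return [workdir / "bn_edges.tsv", workdir / "bn_support.tsv"]


def _stage_grn(config: PipelineConfig, workdir: Path) -> list[Path]:
    _require(workdir, "preprocess", ["filtered.tsv"])
    _require(workdir, "wgcna", ["modules.tsv"])
    _require(workdir, "enrich", ["ces.tsv"])
    _require(workdir, "simulate", ["regulators.txt", "motif_table.tsv"])
    partition = _read_modules(workdir)
    values = pd.read_csv(workdir / "filtered.tsv", sep="\t", index_col=0)
    regulators = [
        r for r in (workdir / "regulators.txt").read_text().split()
        if r in values.index
    ]
    focal = _focal_module(config, workdir)
    module_genes = partition.module_genes(focal)
    targets = [g for g in module_genes if g not in set(regulators)]
    seed = config.stage_seed("grn")

    g3 = grn.genie3_weights(
        values, regulators, targets=targets, n_trees=config.n_trees, seed=seed
    )
    mi = grn.mi_matrix(values.loc[sorted(set(regulators) | set(targets))])
    aracne = grn.dpi_prune(mi, regulators=regulators)
    rank_a = grn.rank_tfs(g3, targets, top_k=config.top_k)
    rank_b = grn.rank_tfs(aracne, targets, top_k=config.top_k)
    motif = pd.read_csv(workdir / "motif_table.tsv", sep="\t")
    consensus = grn.consensus_tfs(
        rank_a, rank_b, motif, nes_floor=config.nes_floor, module_genes=module_genes
    )
    rank_a.to_csv(workdir / "grn_rank_trees.tsv", sep="\t", index=False)
    rank_b.to_csv(workdir / "grn_rank_mi.tsv", sep="\t", index=False)
    consensus.provenance.to_csv(workdir / "consensus_tfs.tsv", sep="\t", index=False)
    if consensus.stage2:
        regulon, coverage = grn.regulon_subnetwork(
            g3, consensus.stage2, module_genes, motif
        )
        regulon.edges.to_csv(workdir / "regulon_edges.tsv", sep="\t", index=False)
    else:
        coverage = 0.0
        pd.DataFrame(columns=["source", "target", "weight"]).to_csv(
            workdir / "regulon_edges.tsv", sep="\t", index=False
        )
    (workdir / "regulon_coverage.txt").write_text(f"{coverage:.6f}\n")
    return [
        workdir / "grn_rank_trees.tsv", workdir / "grn_rank_mi.tsv",
        workdir / "consensus_tfs.tsv", workdir / "regulon_edges.tsv",
        workdir / "regulon_coverage.txt",
    ]


def _stage_score(config: PipelineConfig, workdir: Path) -> list[Path]:
    _require(workdir, "preprocess", ["filtered.tsv"])
    _require(workdir, "wgcna", ["modules.tsv"])
    _require(workdir, "enrich", ["ces.tsv"])
    _require(workdir, "simulate", ["condition.tsv"])
    partition = _read_modules(workdir)
    matrix = ingest.read_expression(workdir / "filtered.tsv", workdir / "condition.tsv")
    focal = _focal_module(config, workdir)
    scores = enrich.signature_score(
        matrix, partition.module_genes(focal), seed=config.stage_seed("score")
    )
    out = scores.rename_axis("sample").reset_index()
    out["condition"] = matrix.condition.loc[out["sample"]].to_numpy()
    out.to_csv(workdir / "signature_scores.tsv", sep="\t", index=False)
    return [workdir / "signature_scores.tsv"]


def _stage_connect(config: PipelineConfig, workdir: Path) -> list[Path]:
    _require(workdir, "preprocess", ["filtered.tsv", "differential.tsv"])
    _require(workdir, "wgcna", ["modules.tsv"])
    _require(workdir, "enrich", ["ces.tsv"])
    partition = _read_modules(workdir)
    diff = pd.read_csv(workdir / "differential.tsv", sep="\t").set_index("gene")
    focal = _focal_module(config, workdir)
    module_genes = partition.module_genes(focal)
    up = [g for g in module_genes if diff.loc[g, "log2fc"] > 0]
    down = [g for g in module_genes if diff.loc[g, "log2fc"] < 0]
    query = connectivity.QuerySignature(up_genes=up, down_genes=down)
    universe = list(diff.index)
    library, classes = simulate.simulate_drug_profiles(
        query.up_genes, query.down_genes, universe,
        n_per_class=config.n_drugs_per_class,
        noise_swaps=config.drug_noise_swaps,
        seed=config.stage_seed("connect"),
    )
    results = connectivity.score_library(library, query)
    results["planted_class"] = results["drug"].map(classes)
    results.to_csv(workdir / "connectivity.tsv", sep="\t", index=False)
    hits = connectivity.screen_drugs(results, threshold=config.connectivity_threshold)
    hits.to_csv(workdir / "drug_screen.tsv", sep="\t", index=False)
    return [workdir / "connectivity.tsv", workdir / "drug_screen.tsv"]


def _stage_report(config: PipelineConfig, workdir: Path) -> list[Path]:
    lines = ["# Pipeline report", ""]
    ces_table = pd.read_csv(workdir / "ces.tsv", sep="\t", index_col=0)
    lines += ["## Module enrichment (CES)", "", ces_table.to_markdown(), ""]
    prox = pd.read_csv(workdir / "proximity.tsv", sep="\t")
    lines += ["## Module proximity", "", prox.to_markdown(index=False), ""]
    bn_edges = pd.read_csv(workdir / "bn_edges.tsv", sep="\t")
    lines += [
        "## Eigengene Bayesian network",
        "",
        f"{len(bn_edges)} retained arcs",
        bn_edges.to_markdown(index=False),
        "",
    ]
    cons = pd.read_csv(workdir / "consensus_tfs.tsv", sep="\t")
    lines += ["## Consensus regulators", "", cons.to_markdown(index=False), ""]
    screen = pd.read_csv(workdir / "drug_screen.tsv", sep="\t")
    lines += ["## Drug screen candidates", "", screen.to_markdown(index=False), ""]
    (workdir / "report.md").write_text("\n".join(lines))
    return [workdir / "report.md"]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "wgcna": _stage_wgcna,
    "enrich": _stage_enrich,
    "proximity": _stage_proximity,
    "bn": _stage_bn,
    "grn": _stage_grn,
    "score": _stage_score,
    "connect": _stage_connect,
    "report": _stage_report,
}


def run_stage(name: str, config: PipelineConfig, workdir: str | Path) -> Path:
    """Run one stage; returns the manifest path."""
    if name not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {name!r}; choose from {STAGES}")
    config.validate()
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    outputs = _STAGE_FUNCS[name](config, workdir)
    return _write_manifest(workdir, name, config, inputs=[], outputs=outputs)


def run_all(
    config: PipelineConfig, workdir: str | Path, skip_bn: bool = False
) -> Path:
    """Execute every stage in order; returns the report path."""
    workdir = Path(workdir)
    for stage in STAGES:
        if skip_bn and stage == "bn":
            pd.DataFrame(columns=["from", "to", "strength", "direction"]).to_csv(
                Path(workdir) / "bn_edges.tsv", sep="\t", index=False
            )
            continue
        run_stage(stage, config, workdir)
    return Path(workdir) / "report.md"
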