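"""End-to-end pipeline: select -> synergy -> network -> enrich -> associate
-> differential-correlation baseline.

Every stage writes a TSV under the output directory; a manifest records
the configuration, seed, package versions and per-stage counts, so a run
is fully reproducible from its output directory alone.  Stage seeds are
the root seed plus fixed offsets, so re-running a single stage matches the
full run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import networkx
import numpy as np
import pandas as pd
import scipy
import yaml

from . import io as io_mod
from .datasets import ExpressionDataset, GeneSetCollection
from .diffcorr import build_diffcorr_network
from .network import annotate_patterns, build_network, topology_report
from .pathways import associate_neighbors, enrich_pathways
from .selection import select_genes
from .synergy import SynergyEstimator, synergy_scan

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]

log = logging.getLogger(__name__)

# fixed per-stage seed offsets (root seed + offset)
STAGE_SEEDS = {"synergy": 101, "topology": 202}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    """Flat key-value configuration of a pipeline run."""

    expression: str
    metadata: str
    gene_sets: str
    out_dir: str
    alpha_select: float = 0.05
    estimator: str = "cluster"
    n_states: int = 3
    permutations: int = 1000
    null_model: str = "pooled"
    alpha_edge: float = 0.05
    alpha_enrich: float = 0.05
    alpha_assoc: float = 0.05
    min_connections: int = 3
    diffcorr_method: str = "pearson"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("alpha_select", "alpha_edge", "alpha_enrich", "alpha_assoc"):
            a = getattr(self, name)
            if not 0 < a < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {a}")
        if self.permutations < 1:
            raise ValueError("permutations must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: expected a flat key-value mapping")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage; returns the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    logging.basicConfig(level=config.log_level)
    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root_logger = logging.getLogger("synergynet")
    root_logger.addHandler(handler)
    root_logger.setLevel(config.log_level)

    counts: dict[str, int] = {}
    try:
        dataset, gene_sets = _load(config)
        counts["genes_input"] = dataset.n_genes
        counts["samples"] = dataset.n_samples

        selected, report = _select(config, dataset)
        io_mod.write_table(report, out / "selection.tsv")
        counts["genes_selected"] = len(selected)
        log.info("selected %d / %d genes", len(selected), dataset.n_genes)

        results = _synergy(config, dataset, selected)
        counts["pairs_tested"] = len(results)

        net = _network(config, results)
        results = annotate_patterns(
            results, dataset.subset_genes(selected), config.alpha_edge
        )
        io_mod.write_table(results, out / "synergy_pairs.tsv")
        edges = net.edge_table()
        io_mod.write_table(edges, out / "network_edges.tsv")
        io_mod.write_sif(edges, out / "network.sif")
        counts["network_genes"] = len(net.nodes)
        counts["network_edges"] = net.n_edges
        log.info("synergy network: %d genes, %d edges", len(net.nodes), net.n_edges)

        if net.n_edges:
            topo = _topology(config, net)
            topo_df = pd.DataFrame(
                {
                    "degree": topo["degrees"],
                    "er_degree": topo["er_degrees"],
                }
            )
            topo_df["ks_stat"] = topo["ks_stat"]
            topo_df["ks_p"] = topo["ks_p"]
            io_mod.write_table(topo_df, out / "topology.tsv")

        enrichment = _enrich(config, net, selected, gene_sets)
        io_mod.write_table(enrichment, out / "enrichment.tsv")
        counts["pathways_tested"] = len(enrichment)
        counts["pathways_significant"] = (
            int(enrichment["significant"].sum()) if len(enrichment) else 0
        )

        assoc = _associate(config, net, gene_sets, enrichment)
        io_mod.write_table(assoc, out / "association.tsv")
        counts["neighbors_tested"] = len(assoc)

        dc_net, dc_results = _diffcorr(config, dataset, selected)
        io_mod.write_table(dc_results, out / "diffcorr_pairs.tsv")
        dc_edges = dc_net.edge_table()
        io_mod.write_table(dc_edges, out / "diffcorr_edges.tsv")
        counts["diffcorr_edges"] = dc_net.n_edges

        manifest = {
            "config": config.to_dict(),
            "seed": config.seed,
            "stage_seeds": {k: config.seed + v for k, v in STAGE_SEEDS.items()},
            "counts": counts,
            "versions": {
                "numpy": np.__version__,
                "scipy": scipy.__version__,
                "pandas": pd.__version__,
                "networkx": networkx.__version__,
            },
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
    finally:
        root_logger.removeHandler(handler)
        handler.close()
    return out


@_stage("load")
def _load(config: PipelineConfig) -> tuple[ExpressionDataset, GeneSetCollection]:
    dataset = io_mod.read_expression(config.expression, config.metadata)
    gene_sets = io_mod.read_gene_sets(config.gene_sets)
    return dataset, gene_sets


@_stage("select")
def _select(config: PipelineConfig, dataset: ExpressionDataset):
    return select_genes(dataset, alpha=config.alpha_select)


@_stage("synergy")
def _synergy(config: PipelineConfig, dataset: ExpressionDataset, selected):
    if len(selected) < 2:
        raise ValueError(f"only {len(selected)} genes selected; need >= 2")
    est = SynergyEstimator(
        method=config.estimator,
        n_states=config.n_states,
        seed=config.seed + STAGE_SEEDS["synergy"],
    )
    return synergy_scan(
        dataset.subset_genes(selected),
        estimator=est,
        B=config.permutations,
        seed=config.seed + STAGE_SEEDS["synergy"],
        null_model=config.null_model,
    )


@_stage("network")
def _network(config: PipelineConfig, results):
    return build_network(results, alpha=config.alpha_edge)


@_stage("topology")
def _topology(config: PipelineConfig, net):
    return topology_report(net, seed=config.seed + STAGE_SEEDS["topology"])


@_stage("enrich")
def _enrich(config: PipelineConfig, net, selected, gene_sets):
    return enrich_pathways(
        net.nodes, selected, gene_sets, alpha=config.alpha_enrich
    )


@_stage("associate")
def _associate(config: PipelineConfig, net, gene_sets, enrichment):
    frames = []
    tested = (
        enrichment[enrichment["significant"]]["pathway"]
        if len(enrichment)
        else []
    )
    for name in tested:
        df = associate_neighbors(
            net,
            gene_sets.members(name),
            min_connections=config.min_connections,
            alpha=config.alpha_assoc,
        )
        df.insert(0, "pathway", name)
        frames.append(df)
    if frames:
        return pd.concat(frames, ignore_index=True)
    return pd.DataFrame(
        columns=["pathway", "gene", "x", "N", "n", "k", "p", "p_adj", "rank",
                 "significant"]
    )


@_stage("diffcorr")
def _diffcorr(config: PipelineConfig, dataset: ExpressionDataset, selected):
    return build_diffcorr_network(
        dataset.subset_genes(selected),
        alpha=config.alpha_edge,
        method=config.diffcorr_method,
    )
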