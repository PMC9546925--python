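"""End-to-end disease-signature pipeline.

Stages, in order: seed mapping → connectivity-significance expansion →
biological boundary on the ranking → batch correction → differential
expression → correlation network → clustering/cartography → switch-gene
calling → candidate filtering and intersection → module significance of
the assembled (seeds ∪ signature) gene set.  Every stage writes its table
under the output directory and logs its counts; a single master seed
drives all randomized stages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import biocriterion, core_data, diamond, swim
from .module_significance import ModuleSignificanceReport, module_significance

logger = logging.getLogger("netmedsig")


@dataclass
class PipelineConfig:
    """Flat configuration for one pipeline run.

    Paths name the five inputs; the parameters default to the standard
    study settings: 500 expansion iterations, window equal to the number of
    in-network seeds, seed-term enrichment at adjusted p <= 0.05, boundary
    at enrichment p <= 0.01, fold-change threshold 1 (inert on the linear
    scale), FDR 0.001, correlation threshold at the 83rd percentile of
    |r|, 1000 degree-matched randomizations.
    """

    network: str = ""
    seeds: str = ""
    expression: str = ""
    metadata: str = ""
    gene_sets: str = ""
    outdir: str = "netmedsig_out"

    iterations: int = 500
    window: int | None = None           # None -> number of in-network seeds
    enrichment_alpha: float = 0.05
    boundary_threshold: float = 0.01
    fc_threshold: float = 1.0
    fdr_threshold: float = 0.001
    correlation_percentile: float = 83.0
    correlation_samples: str = "case"
    n_clusters: int | None = None       # None -> elbow choice
    switch_direction: str = "up"
    cluster_rule: str = "majority"      # or "all", or "cluster:<id>"
    batch_correction: bool = True
    parametric_eb: bool = True
    assume_log_scale: bool = True
    n_randomizations: int = 1000
    master_seed: int = 0
    diamond_alpha: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


@dataclass
class DiseaseSignature:
    """Result of one pipeline run.

    The signature is the intersection of the boundary-limited expansion
    candidates with the filtered switch genes (seeds excluded); the
    assembled module is seeds ∪ signature and carries the randomization
    report.
    """

    seeds: set[str]
    diamond_candidates: set[str]
    switch_candidates: set[str]
    signature: list[str]
    assembled_module: set[str]
    significance: ModuleSignificanceReport
    boundary: biocriterion.BoundaryReport
    stage_counts: dict = field(default_factory=dict)

    def validate(self) -> None:
        assert set(self.signature) <= self.diamond_candidates
        assert set(self.signature) <= self.switch_candidates
        assert not set(self.signature) & self.seeds
        assert self.assembled_module >= self.seeds


def filter_switch_candidates(cartography: pd.DataFrame, deg_table: pd.DataFrame,
                             direction: str = "up",
                             cluster_rule: str = "majority") -> set[str]:
    """Restrict switch genes to a coherent expression pattern and cluster.

    ``direction`` keeps switch genes whose differential-expression direction
    matches ("both" disables the filter).  ``cluster_rule`` = "majority"
    keeps only the single cluster holding the most direction-matching
    switch genes; "all" disables cluster filtering; "cluster:<id>" names a
    cluster explicitly.  An empty result is returned with a warning, not an
    error.
    """
    if direction not in {"up", "down", "both"}:
        raise ValueError(f"direction must be up/down/both, got {direction!r}")
    switch = cartography.index[cartography["is_switch"]]
    if direction != "both":
        in_deg = [g for g in switch if g in deg_table.index]
        switch = [g for g in in_deg if deg_table.loc[g, "direction"] == direction]
    switch = list(switch)
    if not switch:
        logger.warning("filter_switch_candidates: no switch gene matches "
                       "direction %r", direction)
        return set()
    if cluster_rule == "all":
        return set(switch)
    clusters = cartography.loc[switch, "cluster"]
    if cluster_rule == "majority":
        # ties broken toward the smaller cluster label for determinism
        counts = clusters.value_counts().sort_index()
        chosen = int(counts.idxmax())
    elif cluster_rule.startswith("cluster:"):
        chosen = int(cluster_rule.split(":", 1)[1])
    else:
        raise ValueError(f"unknown cluster_rule {cluster_rule!r}")
    kept = {g for g in switch if int(cartography.loc[g, "cluster"]) == chosen}
    if not kept:
        logger.warning("filter_switch_candidates: cluster %d holds no "
                       "matching switch gene", chosen)
    return kept


def intersect_candidates(diamond_set, switch_set, seeds=()) -> list[str]:
    """Signature = sorted intersection of the two candidate sets, seeds excluded."""
    return sorted((set(diamond_set) & set(switch_set)) - set(seeds))


def run_pipeline(config: PipelineConfig) -> DiseaseSignature:
    """Execute all stages; writes intermediates under ``config.outdir``."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict = {}

    def stage(name):
        logger.info("pipeline stage: %s", name)
        return name

    try:
        name = stage("load inputs")
        net = core_data.read_edge_list(config.network)
        seed_list = core_data.read_gene_list(config.seeds)
        expr = core_data.read_expression(config.expression, config.metadata)
        collection = core_data.read_gmt(config.gene_sets)
        counts["network_nodes"] = net.n_nodes
        counts["network_edges"] = net.n_edges

        name = stage("seed mapping")
        seeds = diamond.SeedSet.from_genes(seed_list, net)
        if not seeds.in_network:
            raise ValueError("no seed gene maps into the interactome")
        counts["seeds"] = len(seeds.genes)
        counts["seeds_in_network"] = len(seeds.in_network)

        name = stage("connectivity-significance expansion")
        ranking = diamond.run_diamond(net, seeds, n_iter=config.iterations,
                                      alpha=config.diamond_alpha)
        ranking.to_csv(out / "diamond_ranking.tsv", sep="\t", index=False)
        counts["iterations_run"] = len(ranking)

        name = stage("biological boundary")
        background = net.nodes & collection.annotated_genes()
        boundary = biocriterion.evaluate_boundary(
            ranking, seeds.in_network, collection, background,
            window=config.window, alpha=config.enrichment_alpha,
            threshold=config.boundary_threshold)
        boundary.to_frame().to_csv(out / "boundary_report.tsv", sep="\t",
                                   index=False)
        counts["boundary_iteration"] = boundary.cutoff
        diamond_set = set(ranking["gene"].iloc[:boundary.cutoff])

        name = stage("batch correction")
        if config.batch_correction and expr.batch.nunique() > 1:
            expr = core_data.batch_correct(expr, parametric_eb=config.parametric_eb)

        name = stage("switch-gene analysis")
        deg_table, cartography, corr_net = swim.swim_analysis(
            expr, fc_threshold=config.fc_threshold,
            fdr_threshold=config.fdr_threshold,
            percentile=config.correlation_percentile,
            k=config.n_clusters, seed=config.master_seed,
            samples=config.correlation_samples)
        deg_table.to_csv(out / "deg_table.tsv", sep="\t", index_label="gene")
        cartography.to_csv(out / "cartography.tsv", sep="\t", index_label="gene")
        corr_net.write_edges(out / "correlation_edges.tsv")
        counts["degs"] = len(deg_table)
        counts["correlation_threshold"] = corr_net.threshold
        counts["correlation_nodes"] = corr_net.n_nodes
        counts["clusters"] = int(cartography["cluster"].nunique())
        counts["switch_genes"] = int(cartography["is_switch"].sum())

        name = stage("candidate filtering and intersection")
        switch_set = filter_switch_candidates(cartography, deg_table,
                                              direction=config.switch_direction,
                                              cluster_rule=config.cluster_rule)
        counts["filtered_switch_genes"] = len(switch_set)
        signature = intersect_candidates(diamond_set, switch_set,
                                         seeds=seeds.in_network)
        counts["signature_size"] = len(signature)
        (out / "signature.txt").write_text("\n".join(signature) + "\n")

        name = stage("module significance")
        assembled = seeds.in_network | set(signature)
        report = module_significance(
            net, assembled, n_rep=config.n_randomizations,
            seed=config.master_seed)
        report.to_frame().to_csv(out / "module_significance.tsv", sep="\t",
                                 index_label="metric")
    except Exception as exc:
        raise RuntimeError(f"pipeline aborted at stage {name!r}: {exc}") from exc

    for key, val in counts.items():
        logger.info("pipeline count: %s = %s", key, val)
    result = DiseaseSignature(
        seeds=seeds.in_network, diamond_candidates=diamond_set,
        switch_candidates=switch_set, signature=signature,
        assembled_module=assembled, significance=report, boundary=boundary,
        stage_counts=counts)
    result.validate()
    return result
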