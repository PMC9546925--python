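"""Synthetic interactomes and expression matrices with planted structure.

Every stage of the pipeline is scored against ground truth: a densely
wired module planted in a sparse background interactome stands in for the
disease neighbourhood; an expression matrix with correlated gene blocks,
case-shifted genes, batch effects and anti-correlated "connector" hubs
stands in for the case/control microarray data.  Connectors are built as
the negated mixture of several block factors, so in the correlation
network their neighbours span blocks and correlate negatively with them —
exactly the topology the switch-gene cartography is designed to find.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .core_data import ExpressionMatrix, GeneSetCollection, Interactome


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generators."""

    planted_module: set[str] = field(default_factory=set)
    planted_degs: dict[str, float] = field(default_factory=dict)  # gene -> true logFC
    planted_clusters: dict[str, int] = field(default_factory=dict)
    planted_connectors: set[str] = field(default_factory=set)
    batch_effects: dict[str, tuple[float, float]] = field(default_factory=dict)

    def merge(self, other: "SyntheticTruth") -> "SyntheticTruth":
        return SyntheticTruth(
            planted_module=self.planted_module | other.planted_module,
            planted_degs={**self.planted_degs, **other.planted_degs},
            planted_clusters={**self.planted_clusters, **other.planted_clusters},
            planted_connectors=self.planted_connectors | other.planted_connectors,
            batch_effects={**self.batch_effects, **other.batch_effects})


def _symbol(i: int) -> str:
    return f"G{i:04d}"


def generate_interactome(n_nodes: int, mean_degree: float, module_size: int,
                         module_density: float, seed: int,
                         module_nodes: list[str] | None = None,
                         model: str = "er",
                         weight_range: tuple[float, float] = (2.0, 32.0),
                         module_weight_range: tuple[float, float] | None = None,
                         ) -> tuple[Interactome, SyntheticTruth]:
    """Sparse random background graph with a planted dense module.

    With ``model="er"`` the background is an Erdős–Rényi graph with the
    requested mean degree.  With ``model="broad"`` it is a Chung–Lu graph
    whose expected degrees are log-uniform over ``weight_range`` (and
    ``mean_degree`` is ignored): every doubling degree bin is then
    populated, which real interactomes satisfy through their heavy tail
    and which degree-matched null sampling relies on.  The first
    ``module_size`` nodes (or ``module_nodes``) are additionally wired
    among themselves with probability ``module_density``, which must
    exceed the background density.  ``module_weight_range`` (broad model
    only) restricts the module members' background expected degrees: a
    disease module is locally dense through its internal wiring, not
    because its members are global hubs.  Reproducible from ``seed``.
    """
    if module_size > n_nodes:
        raise ValueError("module_size exceeds n_nodes")
    rng = np.random.default_rng(seed)
    names = [_symbol(i) for i in range(n_nodes)]
    g = nx.Graph()
    g.add_nodes_from(names)
    iu = np.triu_indices(n_nodes, k=1)
    if model == "er":
        p_bg = mean_degree / (n_nodes - 1)
        if not 0 <= p_bg < 1:
            raise ValueError("infeasible background density")
        p_edge = np.full(len(iu[0]), p_bg)
    elif model == "broad":
        lo, hi = weight_range
        w = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_nodes))
        if module_weight_range is not None and module_size > 0:
            mlo, mhi = module_weight_range
            w[:module_size] = np.exp(rng.uniform(np.log(mlo), np.log(mhi),
                                                 size=module_size))
        p_edge = np.minimum(w[iu[0]] * w[iu[1]] / w.sum(), 1.0)
        p_bg = float(p_edge.mean())
    else:
        raise ValueError(f"unknown background model {model!r}")
    if module_size > 1 and module_density <= p_bg:
        raise ValueError(f"module_density {module_density} must exceed the "
                         f"background density {p_bg:.4f}")
    mask = rng.random(len(iu[0])) < p_edge
    for i, j in zip(iu[0][mask], iu[1][mask]):
        g.add_edge(names[i], names[j])
    truth = SyntheticTruth()
    if module_size > 0:
        members = module_nodes if module_nodes is not None else names[:module_size]
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                if rng.random() < module_density:
                    g.add_edge(members[a], members[b])
        truth.planted_module = set(members)
    g.remove_nodes_from(list(nx.isolates(g)))
    return Interactome(g), truth


def generate_expression(n_genes: int, n_case: int, n_control: int,
                        n_batches: int = 2,
                        block_spec: list[tuple[list[str], float]] | None = None,
                        deg_spec: dict[str, float] | None = None,
                        connector_spec: dict[str, list[int]] | None = None,
                        noise_sd: float = 1.0, seed: int = 0,
                        connector_strength: float = 4.0,
                        connector_noise_sd: float = 1.0,
                        batch_shift_sd: float = 0.5,
                        batch_shift_mean: float = 1.0,
                        gene_names: list[str] | None = None,
                        ) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Genes × samples log-scale matrix with planted blocks, DEGs, connectors
    and batch effects.

    * ``block_spec``: list of (gene list, factor loading); genes of a block
      share a latent standard-normal factor scaled by the loading, which
      sets the within-block correlation loading²/(loading²+noise_sd²).
    * ``deg_spec``: gene -> additive mean shift applied to case samples
      (the true logFC on the log scale).
    * ``connector_spec``: gene -> list of block indices; the connector's
      profile is the negated mean of those blocks' factors times
      ``connector_strength`` plus ``connector_noise_sd`` noise, making its
      network neighbours span blocks with negative correlation to it.
    * batch effects: per (batch, gene) additive shifts drawn around
      ``batch_shift_mean`` (batch 0 is the reference); applied last.

    Reproducible from ``seed``; ``noise_sd`` must be positive.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    rng = np.random.default_rng(seed)
    names = gene_names if gene_names is not None else [_symbol(i) for i in range(n_genes)]
    if len(names) != n_genes:
        raise ValueError("gene_names length must equal n_genes")
    name_idx = {g: i for i, g in enumerate(names)}
    block_spec = block_spec or []
    deg_spec = deg_spec or {}
    connector_spec = connector_spec or {}
    n_block_genes = sum(len(genes) for genes, _ in block_spec)
    if n_block_genes > n_genes:
        raise ValueError("block genes exceed n_genes")
    for g in list(deg_spec) + list(connector_spec):
        if g not in name_idx:
            raise ValueError(f"planted gene {g!r} not among generated genes")
    for g, blocks in connector_spec.items():
        if any(b >= len(block_spec) for b in blocks):
            raise ValueError(f"connector {g!r} references a missing block")
        if len(blocks) < 2:
            raise ValueError(f"connector {g!r} must mix at least 2 blocks")

    n_samples = n_case + n_control
    samples = [f"S{i:03d}" for i in range(n_samples)]
    group = np.array(["case"] * n_case + ["control"] * n_control)
    # interleave batches over samples so each batch holds both groups
    batch = np.array([f"batch{i % n_batches}" for i in range(n_samples)])

    baseline = rng.normal(7.0, 1.0, size=n_genes)  # log2-intensity baselines
    x = baseline[:, None] + rng.normal(0.0, noise_sd, size=(n_genes, n_samples))

    factors = rng.standard_normal((max(len(block_spec), 1), n_samples))
    truth = SyntheticTruth()
    for b, (genes, loading) in enumerate(block_spec):
        idx = [name_idx[g] for g in genes]
        x[idx, :] += loading * factors[b][None, :]
        for g in genes:
            truth.planted_clusters[g] = b

    for g, blocks in connector_spec.items():
        i = name_idx[g]
        signal = -connector_strength * factors[list(blocks)].mean(axis=0)
        x[i, :] = baseline[i] + signal + rng.normal(
            0.0, connector_noise_sd, size=n_samples)
        truth.planted_connectors.add(g)

    case_cols = np.flatnonzero(group == "case")
    for g, shift in deg_spec.items():
        x[name_idx[g], case_cols] += shift
        truth.planted_degs[g] = shift

    for b in range(1, n_batches):
        cols = np.flatnonzero(batch == f"batch{b}")
        shifts = rng.normal(batch_shift_mean, batch_shift_sd, size=n_genes)
        x[:, cols] += shifts[:, None]
        truth.batch_effects[f"batch{b}"] = (batch_shift_mean, batch_shift_sd)

    values = pd.DataFrame(x, index=pd.Index(names, name="gene"), columns=samples)
    expr = ExpressionMatrix(values=values,
                            group=pd.Series(group, index=samples),
                            batch=pd.Series(batch, index=samples))
    return expr, truth


# ---------------------------------------------------------------------------
# Coherent study bundle
# ---------------------------------------------------------------------------

@dataclass
class SyntheticBundle:
    """A complete, mutually consistent input set for the whole pipeline."""

    interactome: Interactome
    seeds: list[str]
    expression: ExpressionMatrix
    gene_sets: GeneSetCollection
    truth: SyntheticTruth
    overlap_genes: set[str]   # planted-module genes that are also connectors

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "network": outdir / "edges.tsv",
            "seeds": outdir / "seeds.txt",
            "expression": outdir / "expr.tsv",
            "metadata": outdir / "meta.tsv",
            "gene_sets": outdir / "sets.gmt",
            "truth": outdir / "truth.json",
        }
        self.interactome.write_edge_list(paths["network"])
        paths["seeds"].write_text("\n".join(self.seeds) + "\n")
        self.expression.write(paths["expression"], paths["metadata"])
        self.gene_sets.write_gmt(paths["gene_sets"])
        import json
        truth = {
            "planted_module": sorted(self.truth.planted_module),
            "planted_degs": dict(sorted(self.truth.planted_degs.items())),
            "planted_clusters": dict(sorted(self.truth.planted_clusters.items())),
            "planted_connectors": sorted(self.truth.planted_connectors),
            "overlap_genes": sorted(self.overlap_genes),
        }
        paths["truth"].write_text(json.dumps(truth, indent=1))
        return paths


def paper_small_bundle(seed: int = 0, n_nodes: int = 500, mean_degree: float = 6.0,
                       module_size: int = 40, module_density: float = 0.3,
                       n_seeds: int = 15, n_overlap: int = 10,
                       n_genes: int = 800, n_case: int = 100,
                       n_control: int = 100, block_size: int = 100,
                       n_blocks: int = 3, n_extra_degs: int = 125,
                       deg_shift: float = 2.0, loading: float = 2.0,
                       n_decoy_terms: int = 20) -> SyntheticBundle:
    """Scaled-down study bundle with a planted end-to-end signature.

    The interactome holds a dense ``module_size``-gene module; the first
    ``n_seeds`` members are the seed list and ``n_overlap`` further members
    double as expression connectors (anti-correlated inter-block hubs that
    are up-regulated in cases).  Three correlated blocks plus independent
    shifted genes make up the DEG population, so the correlation-network
    percentile threshold falls between the block correlations and noise.
    One annotation term covers the planted module (driving the boundary
    criterion); decoy terms are random draws.
    """
    rng = np.random.default_rng(seed)
    net, net_truth = generate_interactome(n_nodes, mean_degree, module_size,
                                          module_density, seed=seed + 1,
                                          model="broad",
                                          module_weight_range=(2.0, 8.0))
    module = sorted(net_truth.planted_module)
    seeds = module[:n_seeds]
    overlap = set(module[n_seeds:n_seeds + n_overlap])

    names = [_symbol(i) for i in range(n_genes)]
    blocks = []
    start = 100
    for b in range(n_blocks):
        blocks.append((names[start:start + block_size], loading))
        start += block_size
    connector_spec = {g: list(range(n_blocks)) for g in sorted(overlap)}
    deg_genes = ([g for genes, _ in blocks for g in genes]
                 + sorted(overlap)
                 + names[500:500 + n_extra_degs])
    deg_spec = {g: deg_shift for g in deg_genes}
    expr, expr_truth = generate_expression(
        n_genes=n_genes, n_case=n_case, n_control=n_control, n_batches=2,
        block_spec=blocks, deg_spec=deg_spec, connector_spec=connector_spec,
        noise_sd=1.0, seed=seed + 2, gene_names=names)

    terms = {"planted_module_pathway": set(module)}
    net_nodes = sorted(net.nodes)
    for t in range(n_decoy_terms):
        size = int(rng.integers(15, 40))
        idx = rng.choice(len(net_nodes), size=size, replace=False)
        terms[f"decoy_{t:02d}"] = {net_nodes[i] for i in idx}
    gene_sets = GeneSetCollection(terms=terms)

    truth = net_truth.merge(expr_truth)
    return SyntheticBundle(interactome=net, seeds=seeds, expression=expr,
                           gene_sets=gene_sets, truth=truth,
                           overlap_genes=overlap)
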