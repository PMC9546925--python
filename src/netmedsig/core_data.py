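"""Containers and I/O for interactomes, expression matrices and gene sets.

The pipeline operates on three kinds of data: an undirected protein–protein
interaction network keyed by gene symbol, a genes × samples log-scale
expression matrix with case/control and batch labels, and a GMT collection
of annotation gene sets.  This module owns reading, writing and the
preprocessing that turns raw probe-level matrices into a single
batch-corrected, symbol-keyed matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("netmedsig")

GROUP_CASE = "case"
GROUP_CONTROL = "control"


# ---------------------------------------------------------------------------
# Interactome
# ---------------------------------------------------------------------------

@dataclass
class Interactome:
    """Undirected simple graph of gene symbols (no self-loops, no multi-edges)."""

    graph: nx.Graph

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset(e) for e in self.graph.edges}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, node: str) -> int:
        return self.graph.degree[node]

    def write_edge_list(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for u, v in sorted(tuple(sorted(e)) for e in self.graph.edges):
                fh.write(f"{u}\t{v}\n")


def _looks_like_header(tokens: list[str]) -> bool:
    """Heuristic header detection: common column-name words in the first row."""
    first = tokens[0].strip().lower()
    return first in {"gene1", "gene_a", "genea", "source", "from", "node1",
                     "protein1", "proteina", "symbol1", "gene", "interactor_a"}


def read_edge_list(path: str | Path) -> Interactome:
    """Read a two-column whitespace/tab-delimited edge list of gene symbols.

    Self-loops are removed and duplicate (including reversed) edges collapsed;
    the counts of dropped records are logged.  An optional header row is
    auto-detected.  Empty files and single-column rows are hard errors.
    """
    path = Path(path)
    g = nx.Graph()
    n_self = n_dup = 0
    with open(path) as fh:
        lines = [ln for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"edge list {path} is empty")
    start = 0
    tokens0 = lines[0].split()
    if len(tokens0) >= 2 and _looks_like_header(tokens0):
        start = 1
        if len(lines) == 1:
            raise ValueError(f"edge list {path} contains only a header")
    for i, ln in enumerate(lines[start:], start=start + 1):
        tokens = ln.split()
        if len(tokens) < 2:
            raise ValueError(f"line {i} of {path} has fewer than 2 columns: {ln!r}")
        u, v = tokens[0], tokens[1]
        if u == v:
            n_self += 1
            continue
        if g.has_edge(u, v):
            n_dup += 1
            continue
        g.add_edge(u, v)
    logger.info("read_edge_list: %d nodes, %d edges (%d self-loops and %d "
                "duplicates dropped)", g.number_of_nodes(), g.number_of_edges(),
                n_self, n_dup)
    return Interactome(g)


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes × samples matrix of log-scale intensities with sample labels.

    ``values`` is a DataFrame indexed by gene symbol with sample-id columns;
    ``group`` and ``batch`` are Series aligned to the columns, ``group``
    taking values in {"case", "control"}.
    """

    values: pd.DataFrame
    group: pd.Series
    batch: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.batch is None:
            self.batch = pd.Series("batch0", index=self.values.columns)
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene symbols in expression matrix")
        if not self.group.index.equals(self.values.columns):
            self.group = self.group.reindex(self.values.columns)
        if self.group.isna().any():
            missing = list(self.group.index[self.group.isna()])
            raise ValueError(f"samples without a group label: {missing[:5]}")
        bad = set(self.group.unique()) - {GROUP_CASE, GROUP_CONTROL}
        if bad:
            raise ValueError(f"group labels must be case/control, got {bad}")
        self.batch = self.batch.reindex(self.values.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def case_samples(self) -> list[str]:
        return list(self.group.index[self.group == GROUP_CASE])

    def control_samples(self) -> list[str]:
        return list(self.group.index[self.group == GROUP_CONTROL])

    def write(self, expr_path: str | Path, meta_path: str | Path) -> None:
        self.values.to_csv(expr_path, sep="\t", index_label="gene")
        meta = pd.DataFrame({"sample_id": self.values.columns,
                             "group": self.group.values,
                             "batch": self.batch.values})
        meta.to_csv(meta_path, sep="\t", index=False)


def read_expression(expr_path: str | Path, meta_path: str | Path) -> ExpressionMatrix:
    """Read expression TSV (first column gene id) plus sample metadata TSV
    with columns sample_id, group, batch."""
    values = pd.read_csv(expr_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", dtype=str).set_index("sample_id")
    missing = [s for s in values.columns if s not in meta.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing[:5]}")
    meta = meta.loc[values.columns]
    batch = meta["batch"] if "batch" in meta.columns else None
    return ExpressionMatrix(values=values, group=meta["group"], batch=batch)


def collapse_probes(values: pd.DataFrame, probe_map: dict[str, str],
                    uppercase: bool = False) -> pd.DataFrame:
    """Collapse a probes × samples matrix to genes × samples by per-gene mean.

    Probes absent from ``probe_map`` are dropped (count logged).  Gene order
    in the result is lexicographic.  Raises if no probe maps to a symbol.
    """
    mapped = values.index.map(probe_map.get)
    n_unmapped = int(pd.isna(mapped).sum())
    if n_unmapped:
        logger.info("collapse_probes: dropping %d unmapped probes", n_unmapped)
    keep = ~pd.isna(mapped)
    if not keep.any():
        raise ValueError("no probe maps to a gene symbol")
    sub = values.loc[keep]
    symbols = pd.Index([probe_map[p] for p in sub.index], name="gene")
    if uppercase:
        symbols = symbols.str.upper()
    collapsed = sub.groupby(symbols).mean().sort_index()
    return collapsed


def merge_batches(a: ExpressionMatrix, b: ExpressionMatrix,
                  batch_names: tuple[str, str] = ("batch1", "batch2")) -> ExpressionMatrix:
    """Merge two symbol-collapsed matrices on the intersection of gene symbols.

    Sample columns are concatenated (ids must be disjoint) and batch labels
    set to the source dataset.
    """
    common = a.values.index.intersection(b.values.index).sort_values()
    if len(common) == 0:
        raise ValueError("no gene symbols shared between the two datasets")
    overlap = set(a.sample_ids) & set(b.sample_ids)
    if overlap:
        raise ValueError(f"sample ids present in both datasets: {sorted(overlap)[:5]}")
    values = pd.concat([a.values.loc[common], b.values.loc[common]], axis=1)
    group = pd.concat([a.group, b.group])
    batch = pd.Series(
        [batch_names[0]] * a.n_samples + [batch_names[1]] * b.n_samples,
        index=values.columns)
    logger.info("merge_batches: %d shared genes, %d samples", len(common),
                values.shape[1])
    return ExpressionMatrix(values=values, group=group, batch=batch)


# ---------------------------------------------------------------------------
# ComBat batch correction
# ---------------------------------------------------------------------------

def _combat_it_sol(z: np.ndarray, g_hat: np.ndarray, d_hat: np.ndarray,
                   g_bar: float, t2: float, a: float, b: float,
                   conv: float = 1e-4) -> tuple[np.ndarray, np.ndarray]:
    """Iterative EB shrinkage of per-gene batch location/scale (parametric)."""
    n = z.shape[1]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    change = 1.0
    while change > conv:
        g_new = (n * t2 * g_hat + d_old * g_bar) / (n * t2 + d_old)
        ssq = ((z - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (0.5 * ssq + b) / (n / 2 + a - 1)
        change = max(np.abs(g_new - g_old).max() / np.abs(g_old).max(),
                     np.abs(d_new - d_old).max() / np.abs(d_old).max())
        g_old, d_old = g_new, d_new
    return g_old, d_old


def batch_correct(expr: ExpressionMatrix, parametric_eb: bool = True) -> ExpressionMatrix:
    """Remove additive and multiplicative batch effects per gene (ComBat).

    Implements the parametric empirical-Bayes location/scale adjustment of
    Johnson et al. (2007): genes are standardized against the grand mean and
    pooled variance, per-batch gene means and variances are shrunk toward
    batch-level priors (normal prior on locations, inverse-gamma on scales),
    and the shrunk effects are removed.  ``parametric_eb=False`` skips the
    shrinkage and removes the raw per-batch per-gene location and scale,
    which equalizes per-batch gene means exactly.

    A single batch is returned unchanged.  A batch with one sample is a hard
    error; genes with zero pooled variance receive a location-only
    adjustment with a logged warning.  The operation is deterministic and
    preserves the matrix shape and all sample labels.
    """
    batches = list(pd.unique(expr.batch))
    if len(batches) < 2:
        logger.info("batch_correct: single batch, returning input unchanged")
        return ExpressionMatrix(values=expr.values.copy(), group=expr.group.copy(),
                                batch=expr.batch.copy())
    x = expr.values.to_numpy(dtype=float).copy()
    batch_idx = [np.flatnonzero((expr.batch == b).to_numpy()) for b in batches]
    for b, idx in zip(batches, batch_idx):
        if len(idx) < 2:
            raise ValueError(f"batch {b!r} has a single sample; cannot estimate scale")
    n_total = x.shape[1]
    n_per = np.array([len(idx) for idx in batch_idx], dtype=float)

    batch_means = np.column_stack([x[:, idx].mean(axis=1) for idx in batch_idx])
    grand_mean = batch_means @ (n_per / n_total)
    # residual variance around per-batch means, pooled over all samples
    var_pooled = np.zeros(x.shape[0])
    for i, idx in enumerate(batch_idx):
        var_pooled += ((x[:, idx] - batch_means[:, [i]]) ** 2).sum(axis=1)
    var_pooled /= n_total

    degenerate = var_pooled <= 0
    if degenerate.any():
        logger.warning("batch_correct: %d zero-variance genes get location-only "
                       "adjustment", int(degenerate.sum()))
    scale = np.sqrt(np.where(degenerate, 1.0, var_pooled))

    z = (x - grand_mean[:, None]) / scale[:, None]
    out = z.copy()
    for i, idx in enumerate(batch_idx):
        zb = z[:, idx]
        g_hat = zb.mean(axis=1)
        d_hat = zb.var(axis=1, ddof=1)
        d_hat = np.where(d_hat <= 0, 1e-8, d_hat)
        if parametric_eb:
            g_bar = float(g_hat.mean())
            t2 = float(g_hat.var(ddof=1))
            m, s2 = float(d_hat.mean()), float(d_hat.var(ddof=1))
            # method-of-moments inverse-gamma hyperparameters
            a = (2 * s2 + m ** 2) / s2 if s2 > 0 else 2.0
            b = (m * s2 + m ** 3) / s2 if s2 > 0 else m
            g_star, d_star = _combat_it_sol(zb, g_hat, d_hat, g_bar, t2, a, b)
        else:
            g_star, d_star = g_hat, d_hat
        d_star = np.where(degenerate, 1.0, d_star)
        out[:, idx] = (zb - g_star[:, None]) / np.sqrt(d_star)[:, None]
    corrected = out * scale[:, None] + grand_mean[:, None]
    values = pd.DataFrame(corrected, index=expr.values.index,
                          columns=expr.values.columns)
    return ExpressionMatrix(values=values, group=expr.group.copy(),
                            batch=expr.batch.copy())


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named gene sets (GMT terms) with an optional background universe."""

    terms: dict[str, set[str]]
    universe: set[str] | None = None

    def __post_init__(self):
        for name, genes in self.terms.items():
            if not genes:
                raise ValueError(f"term {name!r} is empty")

    def __len__(self) -> int:
        return len(self.terms)

    def annotated_genes(self) -> set[str]:
        out: set[str] = set()
        for genes in self.terms.values():
            out |= genes
        return out

    def write_gmt(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name in sorted(self.terms):
                genes = "\t".join(sorted(self.terms[name]))
                fh.write(f"{name}\tna\t{genes}\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: term, description, genes (tab-delimited).

    Duplicate genes within a term are deduplicated; a duplicated term name
    or a line with fewer than 3 fields is a hard error.
    """
    terms: dict[str, set[str]] = {}
    with open(path) as fh:
        for i, ln in enumerate(fh, start=1):
            if not ln.strip():
                continue
            fields = ln.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {i} has {len(fields)} fields (need >=3)")
            name = fields[0]
            if name in terms:
                raise ValueError(f"duplicate term name {name!r} at line {i}")
            terms[name] = {g for g in fields[2:] if g}
    return GeneSetCollection(terms=terms)


def read_gene_list(path: str | Path) -> list[str]:
    """One gene symbol per line; blank lines ignored; order preserved."""
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip()]
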