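"""Functional-annotation boundary for the ranked candidate list.

The connectivity-significance ranking alone cannot say where the disease
module ends: the p values of successive iterations are not comparable
because the module they are computed against keeps growing.  The boundary
is therefore set biologically — terms enriched among the seed genes define
a "true positive" annotation set, and a sliding window across the ranking
is tested (hypergeometric upper tail) for containing more true positives
than chance.  The module boundary is the last iteration whose window is
still significant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .core_data import GeneSetCollection

logger = logging.getLogger("netmedsig")


def hypergeometric_enrichment(query: set[str], collection: GeneSetCollection,
                              background: set[str]) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per term, BH-adjusted.

    Each term is first intersected with the background; query genes outside
    the background are dropped with a warning.  Returns a DataFrame sorted
    by p with columns term, overlap_count, term_size, query_size,
    background_size, p, adjusted_p.
    """
    if not query:
        raise ValueError("empty query gene set")
    if not background:
        raise ValueError("empty background gene set")
    stray = set(query) - set(background)
    if stray:
        logger.warning("enrichment: dropping %d query genes outside the "
                       "background", len(stray))
    query = set(query) & set(background)
    if not query:
        raise ValueError("no query gene lies in the background")
    n_bg, n_q = len(background), len(query)
    rows = []
    for name, genes in collection.terms.items():
        term_bg = genes & background
        if not term_bg:
            continue
        overlap = len(term_bg & query)
        p = 1.0 if overlap == 0 else float(
            hypergeom.sf(overlap - 1, n_bg, len(term_bg), n_q))
        rows.append({"term": name, "overlap_count": overlap,
                     "term_size": len(term_bg), "query_size": n_q,
                     "background_size": n_bg, "p": p})
    if not rows:
        raise ValueError("no term overlaps the background")
    table = pd.DataFrame(rows)
    table["adjusted_p"] = multipletests(table["p"], method="fdr_bh")[1]
    return table.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)


def seed_enriched_terms(seeds: set[str], collection: GeneSetCollection,
                        background: set[str], alpha: float = 0.05) -> set[str]:
    """Terms over-represented among the seeds at BH-adjusted p <= alpha."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    table = hypergeometric_enrichment(seeds, collection, background)
    hits = set(table.loc[table["adjusted_p"] <= alpha, "term"])
    if not hits:
        raise ValueError("no term is enriched among the seeds at adjusted "
                         f"p <= {alpha}; the boundary criterion is undefined "
                         "for this collection — try a different gene-set "
                         "collection or a looser alpha")
    return hits


@dataclass
class BoundaryReport:
    """Per-iteration sliding-window enrichment and the chosen cutoff."""

    p_values: np.ndarray          # aligned to ranking iterations (1-based)
    true_positives: np.ndarray    # annotated genes in each window
    window: int
    threshold: float
    cutoff: int                   # last significant iteration, 0 if none

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "iteration": np.arange(1, len(self.p_values) + 1),
            "window_true_positives": self.true_positives,
            "enrichment_p": self.p_values,
        })


def sliding_window_significance(ranking: pd.DataFrame, enriched_genes: set[str],
                                window: int, background: set[str]) -> pd.DataFrame:
    """Hypergeometric enrichment of annotated genes in a window sliding
    down the ranking.

    At iteration t the window holds the ranked genes at positions
    max(1, t-window+1)..t (a shrinking head window before it fills).  The
    test draws |window| genes from the background and asks for at least the
    observed number of annotated ("true positive") members.  Returns a
    DataFrame with iteration, window_true_positives, enrichment_p.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if len(ranking) < 1:
        raise ValueError("empty ranking")
    genes = list(ranking["gene"])
    annotated = set(enriched_genes) & set(background)
    n_bg, n_ann = len(background), len(annotated)
    is_tp = np.array([g in annotated for g in genes])
    p_vals, tps = [], []
    for t in range(1, len(genes) + 1):
        lo = max(0, t - window)
        tp = int(is_tp[lo:t].sum())
        draws = t - lo
        p = 1.0 if tp == 0 else float(hypergeom.sf(tp - 1, n_bg, n_ann, draws))
        p_vals.append(p)
        tps.append(tp)
    return pd.DataFrame({"iteration": np.arange(1, len(genes) + 1),
                         "window_true_positives": tps,
                         "enrichment_p": p_vals})


def select_module_boundary(p_values, threshold: float = 0.01) -> int:
    """Last iteration (1-based) whose enrichment p is <= threshold; 0 if none.

    The plateau of candidates with direct biological support ends where the
    window stops being significant; the cutoff is the largest iteration
    still meeting the threshold.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value sequence")
    sig = np.flatnonzero(p <= threshold)
    return int(sig[-1] + 1) if sig.size else 0


def evaluate_boundary(ranking: pd.DataFrame, seeds: set[str],
                      collection: GeneSetCollection, background: set[str],
                      window: int | None = None, alpha: float = 0.05,
                      threshold: float = 0.01) -> BoundaryReport:
    """Full biological criterion: seed enrichment -> sliding window -> cutoff."""
    if window is None:
        window = len(set(seeds) & set(background)) or len(seeds)
    terms = seed_enriched_terms(set(seeds), collection, background, alpha=alpha)
    enriched_genes: set[str] = set()
    for t in terms:
        enriched_genes |= collection.terms[t]
    report = sliding_window_significance(ranking, enriched_genes, window,
                                         background)
    cutoff = select_module_boundary(report["enrichment_p"].to_numpy(), threshold)
    logger.info("boundary: %d enriched terms, %d annotated genes, cutoff at "
                "iteration %d", len(terms), len(enriched_genes), cutoff)
    return BoundaryReport(p_values=report["enrichment_p"].to_numpy(),
                          true_positives=report["window_true_positives"].to_numpy(),
                          window=window, threshold=threshold, cutoff=cutoff)
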