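"""Disease-module expansion by hypergeometric connectivity significance.

Starting from a set of seed genes mapped onto the interactome, each
iteration scores every outside protein that touches the growing module by
the probability that a node of its degree would have at least its observed
number of links into the module if neighbours were drawn at random from the
network (a hypergeometric upper tail).  The lowest-probability protein is
admitted, and the procedure repeats for a fixed number of iterations,
yielding a ranked candidate list (the DIAMOnD ranking).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom

from .core_data import Interactome

logger = logging.getLogger("netmedsig")


@dataclass
class SeedSet:
    """Seed genes and the subset actually present in the interactome."""

    genes: set[str]
    in_network: set[str]

    @classmethod
    def from_genes(cls, genes, net: Interactome) -> "SeedSet":
        genes = set(genes)
        in_net = genes & net.nodes
        dropped = genes - in_net
        if dropped:
            logger.warning("SeedSet: %d of %d seeds absent from the interactome",
                           len(dropped), len(genes))
        return cls(genes=genes, in_network=in_net)


def connectivity_significance(n_population: int, n_seeds: int, k: int,
                              ks: int) -> float:
    """Upper-tail probability that a degree-``k`` node has >= ``ks`` links
    to the current ``n_seeds``-gene module in an ``n_population``-node network.

    P(X >= ks) for X ~ Hypergeometric(N=n_population, K=n_seeds, n=k),
    evaluated in log space by scipy for numerical stability.
    """
    if ks > k:
        raise ValueError(f"ks={ks} exceeds candidate degree k={k}")
    if n_seeds > n_population:
        raise ValueError(f"seed count {n_seeds} exceeds population {n_population}")
    if ks > n_seeds:
        raise ValueError(f"ks={ks} exceeds seed count {n_seeds}")
    if ks < 0 or k < 0:
        raise ValueError("k and ks must be non-negative")
    if ks == 0:
        return 1.0
    return float(hypergeom.sf(ks - 1, n_population, n_seeds, k))


def run_diamond(net: Interactome, seeds: SeedSet, n_iter: int = 500,
                alpha: float = 1.0) -> pd.DataFrame:
    """Iteratively expand the seed module, one gene per iteration.

    Returns a DataFrame with columns ``iteration`` (1-based), ``gene``,
    ``degree`` (total degree k), ``links_to_module`` (ks at admission) and
    ``p_value`` (connectivity significance at admission).  Ties on p are
    broken by larger ks, then lexicographic gene symbol, so the ranking is
    deterministic.  If the module exhausts its neighbourhood before
    ``n_iter`` iterations the ranking stops early with a warning.

    ``alpha`` is the seed weight of the original algorithm: every link to an
    *original* seed counts alpha times, and the population and seed counts
    grow by (alpha-1)·|seeds| accordingly.  alpha = 1 is plain counting.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if alpha < 1 or alpha != int(alpha):
        raise ValueError("alpha must be a positive integer >= 1")
    alpha = int(alpha)
    if not seeds.in_network:
        raise ValueError("no seed gene maps into the interactome")
    g = net.graph
    module = set(seeds.in_network)
    n_population = g.number_of_nodes() + (alpha - 1) * len(module)
    # bookkeeping per frontier node: links into the module, and links to
    # original seeds (the alpha-weighted subset)
    ks_count: dict[str, int] = {}
    ks_seed: dict[str, int] = {}
    for s in module:
        for nb in g.neighbors(s):
            if nb not in module:
                ks_count[nb] = ks_count.get(nb, 0) + 1
                ks_seed[nb] = ks_seed.get(nb, 0) + 1

    records = []
    for it in range(1, n_iter + 1):
        if not ks_count:
            logger.warning("run_diamond: candidate frontier exhausted at "
                           "iteration %d of %d", it, n_iter)
            break
        s = len(module) + (alpha - 1) * len(seeds.in_network)
        cache: dict[tuple[int, int], float] = {}
        best = None  # (p, -ks, gene)
        for gene, ks in ks_count.items():
            extra = (alpha - 1) * ks_seed.get(gene, 0)
            k_w = g.degree[gene] + extra
            ks_w = ks + extra
            key = (k_w, ks_w)
            p = cache.get(key)
            if p is None:
                p = connectivity_significance(n_population, s, k_w, ks_w)
                cache[key] = p
            cand = (p, -ks_w, gene)
            if best is None or cand < best:
                best = cand
        p, neg_ks, gene = best
        records.append({"iteration": it, "gene": gene, "degree": g.degree[gene],
                        "links_to_module": ks_count[gene], "p_value": p})
        module.add(gene)
        del ks_count[gene]
        ks_seed.pop(gene, None)
        for nb in g.neighbors(gene):
            if nb not in module:
                ks_count[nb] = ks_count.get(nb, 0) + 1
    return pd.DataFrame(records,
                        columns=["iteration", "gene", "degree",
                                 "links_to_module", "p_value"])
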