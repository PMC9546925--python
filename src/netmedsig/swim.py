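"""Switch-gene detection in a case/control co-expression network.

Differentially expressed genes are wired into a correlation network (edges
where |Pearson r| exceeds a percentile-derived threshold), communities are
found by k-means on the signed correlation profiles, and every node is
placed on a "heat cartography" map by two coordinates: the within-module
degree z (how much of a hub it is inside its own cluster) and the
clusterphobic coefficient Kπ = 1 − (κ/k)² (how much it reaches outside).
Hubs (degree > 5) are classed by the average Pearson correlation with
their neighbours (APCC): party (strongly positive), date (moderately
positive) and fight-club (negative).  Switch genes are fight-club hubs
that are not local hubs (low z) and interact mainly outside their cluster
(high Kπ) — anti-correlated connectors between co-expression modules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .core_data import ExpressionMatrix

logger = logging.getLogger("netmedsig")

HUB_DEGREE = 5          # hub iff degree strictly greater
PARTY_APCC = 0.5        # party iff APCC >= this; fight-club iff APCC < 0
KPI_THRESHOLD = 0.8     # switch needs Kpi strictly above
Z_THRESHOLD = 2.5       # switch needs within-module degree strictly below
LOG_BASE = 2.0          # expression values are log2-scale intensities


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------

def differential_expression(expr: ExpressionMatrix, fc_threshold: float = 1.0,
                            fdr_threshold: float = 0.001,
                            filtered: bool = True) -> pd.DataFrame:
    """Per-gene Welch t-test (case vs control) on log-scale values with BH FDR.

    Returns a DataFrame indexed by gene with mean_case, mean_control, logFC
    (case − control on the log scale), p, FDR and direction (up iff
    logFC > 0).  With ``filtered`` (default) only genes passing both the
    linear fold-change magnitude >= ``fc_threshold`` and FDR <=
    ``fdr_threshold`` are kept; a threshold of 1 leaves the fold-change
    filter inert.
    """
    case = expr.case_samples()
    ctrl = expr.control_samples()
    if len(case) < 2 or len(ctrl) < 2:
        raise ValueError("each group needs at least 2 samples "
                         f"(case={len(case)}, control={len(ctrl)})")
    xc = expr.values[case].to_numpy(dtype=float)
    xt = expr.values[ctrl].to_numpy(dtype=float)
    mean_case = xc.mean(axis=1)
    mean_ctrl = xt.mean(axis=1)
    logfc = mean_case - mean_ctrl
    t, p = stats.ttest_ind(xc, xt, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance genes: no evidence
    fdr = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame({
        "mean_case": mean_case, "mean_control": mean_ctrl, "logFC": logfc,
        "p": p, "FDR": fdr,
        "direction": np.where(logfc > 0, "up", "down"),
    }, index=expr.values.index)
    if filtered:
        linear_fc = LOG_BASE ** np.abs(logfc)
        keep = (table["FDR"] <= fdr_threshold) & (linear_fc >= fc_threshold)
        table = table.loc[keep]
        logger.info("differential_expression: %d DEGs at FC>=%g, FDR<=%g",
                    len(table), fc_threshold, fdr_threshold)
    return table


# ---------------------------------------------------------------------------
# Correlation network
# ---------------------------------------------------------------------------

def _correlation_matrix(expr: ExpressionMatrix, genes: list[str],
                        samples: str = "case") -> pd.DataFrame:
    if samples == "case":
        cols = expr.case_samples()
    elif samples == "control":
        cols = expr.control_samples()
    elif samples == "all":
        cols = expr.sample_ids
    else:
        raise ValueError(f"unknown sample selection {samples!r}")
    if len(cols) < 3:
        raise ValueError("need at least 3 samples to estimate correlations")
    x = expr.values.loc[genes, cols].to_numpy(dtype=float)
    r = np.corrcoef(x)
    r = np.nan_to_num(r, nan=0.0)  # constant genes have undefined r
    return pd.DataFrame(r, index=genes, columns=genes)


@dataclass
class CorrelationNetwork:
    """Thresholded signed-correlation graph over differentially expressed genes."""

    graph: nx.Graph              # edge attribute "r" holds the signed coefficient
    threshold: float
    percentile: float
    corr: pd.DataFrame           # signed correlation matrix over retained nodes

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def write_edges(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("gene1\tgene2\tr\n")
            for u, v, d in sorted(self.graph.edges(data=True)):
                fh.write(f"{u}\t{v}\t{d['r']:.6f}\n")


def build_correlation_network(expr: ExpressionMatrix, deg_genes,
                              percentile: float = 83.0,
                              samples: str = "case") -> CorrelationNetwork:
    """Wire DEGs whose |Pearson r| exceeds the given percentile of all
    pairwise |r| values.

    The threshold is the ``percentile``-th percentile (linear interpolation
    on the sorted population) of |r| over all unordered DEG pairs; edges
    keep the signed r.  Correlations are computed over the case samples by
    default.  Isolated genes are dropped from the network.
    """
    if not 0 < percentile < 100:
        raise ValueError("percentile must be in (0, 100)")
    genes = sorted(set(deg_genes) & set(expr.values.index))
    if len(genes) < 2:
        raise ValueError("need at least 2 DEGs present in the expression matrix")
    corr = _correlation_matrix(expr, genes, samples=samples)
    iu = np.triu_indices(len(genes), k=1)
    abs_r = np.abs(corr.to_numpy()[iu])
    threshold = float(np.percentile(abs_r, percentile, method="linear"))
    g = nx.Graph()
    if threshold >= abs_r.max():
        # degenerate tie (e.g. all pairs equally correlated): keep the ties,
        # otherwise the network would be empty at any percentile
        edge_mask = np.abs(corr.to_numpy()) >= threshold
    else:
        edge_mask = np.abs(corr.to_numpy()) > threshold
    rows, cols = np.where(edge_mask)
    for i, j in zip(rows, cols):
        if i < j:
            g.add_edge(genes[i], genes[j], r=float(corr.iat[i, j]))
    kept = sorted(g.nodes)
    logger.info("correlation network: threshold %.4f (%.0fth pct), %d/%d nodes, "
                "%d edges", threshold, percentile, len(kept), len(genes),
                g.number_of_edges())
    return CorrelationNetwork(graph=g, threshold=threshold,
                              percentile=percentile,
                              corr=corr.loc[kept, kept])


def connectivity_profile(expr: ExpressionMatrix, deg_genes, thresholds,
                         samples: str = "case") -> pd.DataFrame:
    """Fraction of DEGs in the largest connected component as |r| threshold
    varies.

    For each threshold the |r|-thresholded graph is built over all DEGs
    (isolated genes count as singleton components) and the LCC fraction
    over all DEGs is reported.  Used to pick a threshold that keeps the
    network intact yet manageable.
    """
    thresholds = list(thresholds)
    if not thresholds:
        raise ValueError("empty threshold list")
    genes = sorted(set(deg_genes) & set(expr.values.index))
    if len(genes) < 2:
        raise ValueError("need at least 2 DEGs")
    corr = _correlation_matrix(expr, genes, samples=samples).to_numpy()
    abs_r = np.abs(corr)
    np.fill_diagonal(abs_r, 0.0)
    rows = []
    for thr in thresholds:
        adj = abs_r > thr
        n_comp, labels = _connected_components(adj)
        largest = np.bincount(labels).max()
        rows.append({"threshold": float(thr),
                     "lcc_fraction": largest / len(genes)})
    return pd.DataFrame(rows)


def _connected_components(adj: np.ndarray) -> tuple[int, np.ndarray]:
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components
    return connected_components(csr_matrix(adj), directed=False)


# ---------------------------------------------------------------------------
# Clustering and cartography
# ---------------------------------------------------------------------------

def cluster_network(net: CorrelationNetwork, k: int | None = None,
                    seed: int = 0, k_range: tuple[int, int] = (2, 10)) -> pd.Series:
    """k-means communities on the signed correlation profiles of the nodes.

    Each node is represented by its vector of signed correlations to all
    network nodes.  When ``k`` is not given it is chosen by the elbow of
    the within-cluster dispersion curve over ``k_range`` (largest distance
    from the inertia curve to its end-to-end chord).  The RNG seed makes
    labels deterministic.
    """
    nodes = net.nodes
    if not nodes:
        raise ValueError("empty correlation network")
    x = net.corr.loc[nodes, nodes].to_numpy(dtype=float)
    if k is not None:
        if k < 2:
            raise ValueError("k must be >= 2")
        if k > len(nodes):
            raise ValueError(f"k={k} exceeds node count {len(nodes)}")
        best_k = k
    else:
        lo, hi = k_range
        hi = min(hi, len(nodes))
        ks = list(range(lo, hi + 1))
        inertias = [KMeans(n_clusters=kk, random_state=seed, n_init=10)
                    .fit(x).inertia_ for kk in ks]
        best_k = ks[_elbow_index(np.asarray(inertias))]
        logger.info("cluster_network: elbow chose k=%d", best_k)
    labels = KMeans(n_clusters=best_k, random_state=seed, n_init=10).fit_predict(x)
    return pd.Series(labels, index=nodes, name="cluster")


def _elbow_index(inertias: np.ndarray) -> int:
    """Index of the point farthest from the chord joining the curve's ends."""
    n = len(inertias)
    if n <= 2:
        return 0
    xs = np.arange(n, dtype=float)
    x0, y0, x1, y1 = 0.0, inertias[0], n - 1.0, inertias[-1]
    num = np.abs((y1 - y0) * xs - (x1 - x0) * inertias + x1 * y0 - y1 * x0)
    den = np.hypot(y1 - y0, x1 - x0)
    return int(np.argmax(num / den))


def compute_apcc(net: CorrelationNetwork) -> pd.Series:
    """Average signed Pearson correlation between each hub and its neighbours.

    Defined only for hubs (degree > 5); non-hubs are absent from the result.
    """
    out = {}
    for node in net.nodes:
        nbrs = list(net.graph.neighbors(node))
        if len(nbrs) > HUB_DEGREE:
            out[node] = float(np.mean([net.graph[node][nb]["r"] for nb in nbrs]))
    return pd.Series(out, name="APCC", dtype=float)


def classify_hubs(apcc: pd.Series, degree: pd.Series,
                  party_boundary: float = PARTY_APCC) -> pd.Series:
    """Date / party / fight-club classification of hubs by APCC.

    fight-club: APCC < 0; party: APCC >= party_boundary; date: in between.
    Nodes with degree <= 5 are non-hubs regardless of APCC.
    """
    classes = {}
    for node, k in degree.items():
        if k <= HUB_DEGREE:
            classes[node] = "non-hub"
        else:
            a = apcc[node]
            if a < 0:
                classes[node] = "fight-club"
            elif a >= party_boundary:
                classes[node] = "party"
            else:
                classes[node] = "date"
    return pd.Series(classes, name="hub_class")


def compute_cartography(net: CorrelationNetwork, labels: pd.Series) -> pd.DataFrame:
    """Within-module degree z and clusterphobic coefficient Kπ per node.

    κ is the number of a node's edges inside its own cluster; z standardizes
    κ against the κ distribution of the node's cluster (z = 0 where the
    cluster is κ-degenerate); Kπ = 1 − (κ/k)² is 0 for purely intra-cluster
    nodes and approaches 1 for nodes wired almost entirely outward.
    """
    nodes = net.nodes
    missing = [n for n in nodes if n not in labels.index]
    if missing:
        raise ValueError(f"unlabelled network nodes: {missing[:5]}")
    k = pd.Series({n: net.graph.degree[n] for n in nodes}, dtype=float)
    kappa = pd.Series({
        n: sum(1 for nb in net.graph.neighbors(n) if labels[nb] == labels[n])
        for n in nodes}, dtype=float)
    z = pd.Series(0.0, index=pd.Index(nodes))
    for cl, members in pd.Series(nodes).groupby(labels.loc[nodes].values):
        kv = kappa[members.values]
        sd = kv.std(ddof=0)
        if sd > 0:
            z[members.values] = (kv - kv.mean()) / sd
    kpi = 1.0 - (kappa / k) ** 2
    return pd.DataFrame({"cluster": labels.loc[nodes].astype(int),
                         "degree": k.astype(int), "kappa": kappa.astype(int),
                         "z": z, "Kpi": kpi})


def call_switch_genes(cartography: pd.DataFrame,
                      kpi_threshold: float = KPI_THRESHOLD,
                      z_threshold: float = Z_THRESHOLD) -> set[str]:
    """Switch genes: fight-club hubs with Kπ > kpi_threshold and z < z_threshold."""
    required = {"hub_class", "Kpi", "z"}
    if not required <= set(cartography.columns):
        raise ValueError(f"cartography missing columns {required - set(cartography.columns)}")
    mask = ((cartography["hub_class"] == "fight-club")
            & (cartography["Kpi"] > kpi_threshold)
            & (cartography["z"] < z_threshold))
    return set(cartography.index[mask])


def swim_analysis(expr: ExpressionMatrix, fc_threshold: float = 1.0,
                  fdr_threshold: float = 0.001, percentile: float = 83.0,
                  k: int | None = None, seed: int = 0,
                  samples: str = "case",
                  party_boundary: float = PARTY_APCC,
                  kpi_threshold: float = KPI_THRESHOLD,
                  z_threshold: float = Z_THRESHOLD,
                  ) -> tuple[pd.DataFrame, pd.DataFrame, CorrelationNetwork]:
    """Full switch-gene workflow; returns (deg_table, cartography, network).

    The cartography frame carries cluster, degree, kappa, z, Kpi, APCC,
    hub_class and is_switch for every node of the correlation network.
    """
    deg = differential_expression(expr, fc_threshold, fdr_threshold)
    if len(deg) < 2:
        raise ValueError(f"only {len(deg)} DEGs; cannot build a network")
    net = build_correlation_network(expr, list(deg.index), percentile,
                                    samples=samples)
    labels = cluster_network(net, k=k, seed=seed)
    carto = compute_cartography(net, labels)
    apcc = compute_apcc(net)
    carto["APCC"] = apcc.reindex(carto.index)
    carto["hub_class"] = classify_hubs(apcc, carto["degree"], party_boundary)
    switch = call_switch_genes(carto, kpi_threshold, z_threshold)
    carto["is_switch"] = carto.index.isin(switch)
    logger.info("swim_analysis: %d DEGs, %d network nodes, %d clusters, "
                "%d switch genes", len(deg), net.n_nodes,
                labels.nunique(), len(switch))
    return deg, carto, net
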