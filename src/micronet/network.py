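"""Bacteria-fungi co-occurrence networks and per-sample complexity indices.

Per crop, the merged bacterial + fungal ASV table is screened: taxa below
0.01% of the grand total are removed, pairwise Spearman correlations (on
relative abundances by default) are tested two-sided, p-values are
Benjamini-Hochberg adjusted over the upper triangle, and an undirected edge
is kept where |rho| >= 0.7 and q < 0.001.  Seven topological parameters of
each sample's induced subgraph — node number n, average connectivity
(2|E|/n), Freeman centralization of betweenness and degree, global
clustering coefficient, density, and average path length over reachable
pairs — are condensed by PCA into the network complexity indices (PC1, PC2)
used as SOC predictors.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import math

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import AsvCounts

TOPO_COLUMNS = ("n", "avg_k", "cb", "cc", "cd", "den", "avg_l")


def merge_counts(bacteria: AsvCounts, fungi: AsvCounts) -> AsvCounts:
    """Merge the two domain tables over their shared samples (order of bacteria)."""
    if bacteria.sample_ids != fungi.sample_ids:
        common = [s for s in bacteria.sample_ids if s in set(fungi.sample_ids)]
        if not common:
            raise ValueError("no shared samples between the two tables")
        b_idx = [bacteria.sample_ids.index(s) for s in common]
        f_idx = [fungi.sample_ids.index(s) for s in common]
        b_mat, f_mat = bacteria.matrix[b_idx], fungi.matrix[f_idx]
    else:
        common = list(bacteria.sample_ids)
        b_mat, f_mat = bacteria.matrix, fungi.matrix
    return AsvCounts(
        matrix=np.hstack([b_mat, f_mat]),
        taxa_ids=bacteria.taxa_ids + fungi.taxa_ids,
        taxonomy=bacteria.taxonomy + fungi.taxonomy,
        sample_ids=common,
        domain="merged",
        taxon_domains=["bacteria"] * len(bacteria.taxa_ids) + ["fungi"] * len(fungi.taxa_ids),
    )


def filter_taxa(counts: AsvCounts, min_fraction: float = 1e-4) -> AsvCounts:
    """Drop taxa whose total count is below ``min_fraction`` of the grand total.

    The default 1e-4 is the 0.01%-of-all-sequences screen; a taxon at
    exactly the threshold is retained.  Column order is preserved.
    """
    totals = counts.matrix.sum(axis=0)
    grand = counts.matrix.sum()
    keep = totals >= min_fraction * grand
    if not np.any(keep):
        raise ValueError("abundance filter removed every taxon")
    idx = np.flatnonzero(keep)
    return dataclasses.replace(
        counts,
        matrix=counts.matrix[:, idx],
        taxa_ids=[counts.taxa_ids[i] for i in idx],
        taxonomy=[counts.taxonomy[i] for i in idx],
        taxon_domains=[counts.taxon_domains[i] for i in idx] if counts.taxon_domains else None,
    )


@dataclass
class CorrelationScreen:
    """Spearman rho with raw and BH-adjusted p-values over all taxon pairs."""

    taxa: list[str]
    rho: np.ndarray
    p_raw: np.ndarray
    q_fdr: np.ndarray
    taxon_domains: list[str] | None = None


def correlation_screen(counts: AsvCounts, *, use_relative: bool = True) -> CorrelationScreen:
    """All-pairs Spearman correlations with BH FDR over the upper triangle.

    Correlates relative abundances by default (identical rho to raw counts
    sample-wise except when library sizes differ).  Ties get average ranks;
    two-sided p-values use the t approximation.  Pairs involving a constant
    taxon have undefined rho, recorded as NaN and never eligible as edges.
    """
    n_samples = len(counts.sample_ids)
    if n_samples < 5:
        raise ValueError("need at least 5 samples for the correlation screen")
    data = counts.relative_abundance() if use_relative else counts.matrix.astype(float)
    # rank-transform (average ranks for ties) then Pearson; p from the
    # two-sided t approximation with n-2 df
    ranks = np.apply_along_axis(stats.rankdata, 0, data)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
        t = rho * np.sqrt((n_samples - 2) / np.clip(1.0 - rho**2, 1e-300, None))
        p = 2.0 * stats.t.sf(np.abs(t), n_samples - 2)
    p[np.abs(rho) >= 1.0] = 0.0
    constant = data.std(axis=0) == 0
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan
    p[constant, :] = np.nan
    p[:, constant] = np.nan
    np.fill_diagonal(rho, 1.0)
    m = rho.shape[0]
    iu = np.triu_indices(m, k=1)
    p_upper = p[iu]
    q_upper = np.full_like(p_upper, np.nan)
    ok = np.isfinite(p_upper)
    if ok.any():
        q_upper[ok] = stats.false_discovery_control(p_upper[ok], method="bh")
    q = np.full_like(p, np.nan)
    q[iu] = q_upper
    q[(iu[1], iu[0])] = q_upper
    return CorrelationScreen(list(counts.taxa_ids), rho, p, q, counts.taxon_domains)


@dataclass
class CooccurrenceNetwork:
    """Undirected taxon graph; edges carry the Spearman rho that admitted them."""

    graph: nx.Graph
    crop: str = ""

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def edge_list(self) -> pd.DataFrame:
        rows = [
            {"taxon_i": u, "taxon_j": v, "rho": d["rho"], "q": d["q"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["taxon_i", "taxon_j", "rho", "q"])


def build_network(
    screen: CorrelationScreen,
    rho_min: float = 0.7,
    q_max: float = 0.001,
    *,
    crop: str = "",
    positive_only: bool = False,
) -> CooccurrenceNetwork:
    """Threshold the screen into a network: |rho| >= rho_min and q < q_max.

    Strong negative correlations qualify unless ``positive_only``.  Isolated
    taxa are dropped from the node set; a zero-edge result is returned as a
    valid empty network with a warning.
    """
    g = nx.Graph()
    m = len(screen.taxa)
    strength = screen.rho if positive_only else np.abs(screen.rho)
    iu = np.triu_indices(m, k=1)
    qual = (strength[iu] >= rho_min) & (screen.q_fdr[iu] < q_max)
    qual &= np.isfinite(screen.rho[iu])
    for i, j in zip(iu[0][qual], iu[1][qual]):
        g.add_edge(
            screen.taxa[i],
            screen.taxa[j],
            rho=float(screen.rho[i, j]),
            q=float(screen.q_fdr[i, j]),
        )
    if screen.taxon_domains:
        domains = dict(zip(screen.taxa, screen.taxon_domains))
        nx.set_node_attributes(g, {n: domains[n] for n in g.nodes}, "domain")
    if g.number_of_edges() == 0:
        warnings.warn("no taxon pair passed the correlation/FDR thresholds; empty network")
    return CooccurrenceNetwork(g, crop)


@dataclass
class TopoMetrics:
    """The seven per-sample topological parameters (NaN + defined=False if n < 2)."""

    n: int
    avg_k: float
    cb: float
    cc: float
    cd: float
    den: float
    avg_l: float
    defined: bool = True
    n_components: int = 1

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                "n": self.n, "avg_k": self.avg_k, "cb": self.cb, "cc": self.cc,
                "cd": self.cd, "den": self.den, "avg_l": self.avg_l,
            }
        )


def _degree_centralization(g: nx.Graph) -> float:
    """Freeman degree centralization, 1 for a star (n>=3; 0 below)."""
    n = g.number_of_nodes()
    if n < 3:
        return 0.0
    degrees = np.array([d for _, d in g.degree()])
    return float((degrees.max() - degrees).sum() / ((n - 1) * (n - 2)))


def _betweenness_centralization(g: nx.Graph) -> float:
    """Freeman centralization of (normalized) betweenness; star graph gives 1."""
    n = g.number_of_nodes()
    if n < 3:
        return 0.0
    bc = np.array(list(nx.betweenness_centrality(g, normalized=True).values()))
    return float((bc.max() - bc).sum() / (n - 1))


def _average_path_length(g: nx.Graph) -> tuple[float, int]:
    """Mean shortest-path length over reachable pairs; also the component count."""
    comps = list(nx.connected_components(g))
    total, pairs = 0.0, 0
    for comp in comps:
        if len(comp) < 2:
            continue
        sub = g.subgraph(comp)
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            total += sum(dists.values())
            pairs += len(dists) - 1
    if pairs == 0:
        return math.nan, len(comps)
    return total / pairs, len(comps)


def sample_subgraph_metrics(net: CooccurrenceNetwork, present) -> TopoMetrics:
    """Topological parameters of the subgraph induced by one sample's taxa.

    ``present`` maps taxon id -> truthy presence (dict, Series, or a set of
    present taxa); it must cover every network node.  Subgraphs with fewer
    than 2 nodes are reported undefined.
    """
    if isinstance(present, (set, frozenset, list, tuple)):
        present = {t: (t in set(present)) for t in net.nodes}
    missing = [t for t in net.nodes if t not in present]
    if missing:
        raise ValueError(f"presence undefined for {len(missing)} network taxa, e.g. {missing[:3]}")
    keep = [t for t in net.nodes if present[t]]
    sub = net.graph.subgraph(keep)
    n = sub.number_of_nodes()
    if n < 2:
        return TopoMetrics(n, math.nan, math.nan, math.nan, math.nan, math.nan, math.nan,
                           defined=False, n_components=n)
    e = sub.number_of_edges()
    avg_k = 2.0 * e / n
    den = 2.0 * e / (n * (n - 1))
    cc = nx.transitivity(sub)
    cd = _degree_centralization(sub)
    cb = _betweenness_centralization(sub)
    avg_l, n_comp = _average_path_length(sub)
    return TopoMetrics(n, avg_k, cb, cc, cd, den, avg_l, defined=True, n_components=n_comp)


def metrics_table(
    net: CooccurrenceNetwork, counts: AsvCounts, *, presence_threshold: int = 0
) -> pd.DataFrame:
    """Per-sample TopoMetrics for every sample in a count table.

    A taxon is present in a sample when its count exceeds
    ``presence_threshold`` (default 0, i.e. count > 0).  Taxa absent from
    the count table are treated as absent everywhere.
    """
    col = {t: i for i, t in enumerate(counts.taxa_ids)}
    rows = {}
    defined = {}
    for i, sid in enumerate(counts.sample_ids):
        present = {
            t: (counts.matrix[i, col[t]] > presence_threshold) if t in col else False
            for t in net.nodes
        }
        m = sample_subgraph_metrics(net, present)
        rows[sid] = m.as_series()
        defined[sid] = m.defined
    out = pd.DataFrame(rows).T
    out.index.name = "site_id"
    out["defined"] = pd.Series(defined)
    return out


@dataclass
class ComplexityIndex:
    """PC1/PC2 scores of the Z-scored topological parameters."""

    scores: pd.DataFrame            # sites x (net_pc1, net_pc2)
    variance_explained: np.ndarray  # fractions for PC1, PC2
    loadings: pd.DataFrame          # metric x (net_pc1, net_pc2)


def complexity_index(metrics: pd.DataFrame) -> ComplexityIndex:
    """PCA of the seven per-sample topological parameters.

    Columns are Z-scored; constant columns are dropped with a warning.  The
    sign of each component is fixed by making its largest-|loading| element
    positive, so results are deterministic.  Samples flagged undefined get
    NaN scores.
    """
    cols = [c for c in TOPO_COLUMNS if c in metrics.columns]
    X = metrics[cols].astype(float)
    ok = np.isfinite(X.to_numpy()).all(axis=1)
    if "defined" in metrics.columns:
        ok &= metrics["defined"].astype(bool).to_numpy()
    if ok.sum() < 3:
        raise ValueError("need at least 3 samples with defined metrics")
    Xd = X.loc[ok]
    sds = Xd.std(ddof=1)
    constant = [c for c in Xd.columns if sds[c] == 0 or not np.isfinite(sds[c])]
    if constant:
        warnings.warn(f"dropping constant metric column(s) before PCA: {constant}")
        Xd = Xd.drop(columns=constant)
        sds = sds.drop(constant)
    if Xd.shape[1] < 2:
        raise ValueError("fewer than 2 varying metric columns; PCA is meaningless")
    Z = (Xd - Xd.mean()) / sds
    cov = np.cov(Z.to_numpy(), rowvar=False, ddof=1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    for j in range(eigvecs.shape[1]):
        k = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[k, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    scores_ok = Z.to_numpy() @ eigvecs[:, :2]
    scores = pd.DataFrame(np.nan, index=metrics.index, columns=["net_pc1", "net_pc2"])
    scores.loc[Z.index, "net_pc1"] = scores_ok[:, 0]
    scores.loc[Z.index, "net_pc2"] = scores_ok[:, 1]
    var = eigvals[:2] / eigvals.sum()
    loadings = pd.DataFrame(eigvecs[:, :2], index=Xd.columns, columns=["net_pc1", "net_pc2"])
    return ComplexityIndex(scores, var, loadings)


@dataclass
class ModulePartition:
    assignment: dict[str, int]  # node -> module id (0 = largest module)
    modularity: float


def detect_modules(net: CooccurrenceNetwork, seed: int = 0) -> ModulePartition:
    """Greedy modularity maximization; modules numbered by decreasing size."""
    if net.graph.number_of_edges() == 0:
        raise ValueError("cannot partition a network with no edges")
    communities = nx.algorithms.community.greedy_modularity_communities(net.graph)
    communities = sorted(communities, key=lambda c: (-len(c), sorted(c)[0]))
    assignment = {node: i for i, comm in enumerate(communities) for node in comm}
    q = nx.algorithms.community.modularity(net.graph, communities)
    return ModulePartition(assignment, float(q))


def degree_distribution_summary(net: CooccurrenceNetwork) -> tuple[float, float]:
    """Slope and R² of the log-log degree-frequency regression.

    A descriptive scale-free check: OLS of log(count) on log(degree) over
    the observed degree histogram (zero-count bins dropped).  Needs at
    least 5 distinct positive degrees.
    """
    degrees = np.array([d for _, d in net.graph.degree()])
    degrees = degrees[degrees > 0]
    uniq, counts = np.unique(degrees, return_counts=True)
    if len(uniq) < 5:
        raise ValueError(f"only {len(uniq)} distinct degrees; log-log fit undefined")
    x = np.log(uniq.astype(float))
    y = np.log(counts.astype(float))
    res = stats.linregress(x, y)
    return float(res.slope), float(res.rvalue**2)
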