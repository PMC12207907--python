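"""Co-occurrence networks: abundance filtering, Spearman edges with FDR,
random-matrix-theory (RMT) threshold selection, topology features,
per-sample subnetworks, and robustness to random node loss.

Edges are Spearman correlations between per-sample relative abundances of
retained taxa, kept when the BH-adjusted two-sided p-value is below
``fdr_alpha`` and |rho| reaches the similarity threshold. The threshold can
be chosen by an RMT scan: the smallest cutoff at which the thresholded
correlation matrix's nearest-neighbour eigenvalue spacing becomes
consistent with the Poisson (exponential) law — the signature that random
noise correlations have been removed. The survey this package emulates
reports RMT-selected thresholds of 0.76 (whole network) and 0.86 (regional
networks); both ship as documented presets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.interpolate import UnivariateSpline
from scipy.stats import kstest, rankdata
from scipy.stats import t as student_t
from statsmodels.stats.multitest import multipletests

from continuum_assembly.datamodel import CommunityTable

logger = logging.getLogger(__name__)

RMT_PRESET_WHOLE = 0.76
RMT_PRESET_REGIONAL = 0.86

TOPOLOGY_COLUMNS = (
    "nodes", "edges", "average_degree", "clustering_coefficient",
    "average_path_length", "modularity", "density", "diameter",
    "betweenness_centralization", "degree_centralization",
    "mean_closeness_centrality",
)


@dataclass
class CooccurrenceNetwork:
    """Signed, weighted, undirected co-occurrence graph over taxa."""

    graph: nx.Graph
    threshold: float
    flags: dict = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def edge_table(self) -> pd.DataFrame:
        rows = [(u, v, d["rho"], d.get("p_adj", np.nan),
                 "positive" if d["rho"] > 0 else "negative")
                for u, v, d in self.graph.edges(data=True)]
        return pd.DataFrame(rows, columns=["i", "j", "rho", "p_adj", "sign"])


def filter_taxa(table: CommunityTable, min_rel_abund: float = 0.0001,
                min_occurrence: float = 0.20) -> CommunityTable:
    """Keep taxa above overall relative abundance and occurrence cutoffs.

    A taxon is retained when taxon total / grand total > ``min_rel_abund``
    (default 0.01%) AND it occurs in more than ``min_occurrence`` of the
    samples (default 20%). Both inequalities strict.
    """
    if not (0 < min_rel_abund < 1) or not (0 < min_occurrence < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    totals = table.data.sum(axis=0)
    rel = totals / totals.sum()
    occ = (table.data > 0).mean(axis=0)
    keep = table.data.columns[(rel > min_rel_abund) & (occ > min_occurrence)]
    if len(keep) == 0:
        raise ValueError("no taxa pass the abundance/occurrence filters")
    return CommunityTable(table.data[keep], drop_empty=True)


def spearman_matrix(table: CommunityTable, relative: bool = True):
    """Spearman rho and two-sided p matrices over taxa.

    Average ranks for ties; p-values use the t approximation on n - 2
    degrees of freedom (the same convention scipy applies pairwise).
    Constant taxa get NaN rows/columns and are skipped downstream.
    """
    data = (table.relative_abundance() if relative else table.data).to_numpy(float)
    n, m = data.shape
    constant = np.array([np.all(col == col[0]) for col in data.T])
    rho = np.full((m, m), np.nan)
    p = np.full((m, m), np.nan)
    ok = np.where(~constant)[0]
    if constant.any():
        logger.warning("%d constant taxa; their correlations skipped",
                       int(constant.sum()))
    if len(ok) >= 2:
        ranks = np.apply_along_axis(rankdata, 0, data[:, ok])
        r = np.clip(np.corrcoef(ranks, rowvar=False), -1.0, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = r * np.sqrt((n - 2) / (1.0 - r ** 2))
            pv = 2.0 * student_t.sf(np.abs(tstat), n - 2)
        pv[np.isclose(np.abs(r), 1.0)] = 0.0
        rho[np.ix_(ok, ok)] = r
        p[np.ix_(ok, ok)] = pv
    return rho, p


def correlation_edges(table: CommunityTable, threshold: float,
                      fdr_alpha: float = 0.05,
                      relative: bool = True) -> CooccurrenceNetwork:
    """Build the network: |rho| >= threshold AND BH-adjusted p < fdr_alpha."""
    if table.n_samples < 4:
        raise ValueError("need >= 4 samples for correlation edges")
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    rho, p = spearman_matrix(table, relative=relative)
    taxa = table.taxon_ids
    iu = np.triu_indices(len(taxa), k=1)
    pvals = p[iu]
    ok = ~np.isnan(pvals)
    p_adj = np.full_like(pvals, np.nan)
    if ok.sum():
        p_adj[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
    g = nx.Graph()
    g.add_nodes_from(taxa)
    for (u, v), r, q in zip(zip(*iu), rho[iu], p_adj):
        if np.isnan(r) or np.isnan(q):
            continue
        if abs(r) >= threshold and q < fdr_alpha:
            g.add_edge(taxa[u], taxa[v], rho=float(r), p_adj=float(q),
                       weight=abs(float(r)))
    return CooccurrenceNetwork(graph=g, threshold=threshold)


# ----------------------------------------------------------------------
# RMT threshold selection
# ----------------------------------------------------------------------

def _nn_spacings(eigvals: np.ndarray):
    """Unfolded nearest-neighbour spacings of an eigenvalue spectrum.

    Degenerate eigenvalues (within 1e-8) are collapsed first — exact
    multiplicities carry no spacing information. Unfolding fits a
    smoothing spline to the cumulative spectral function so the mean
    spacing is 1.
    """
    vals = np.sort(eigvals)
    keep = [vals[0]]
    for v in vals[1:]:
        if v - keep[-1] > 1e-8:
            keep.append(v)
    vals = np.asarray(keep)
    if len(vals) < 10:
        return None
    cum = np.arange(1, len(vals) + 1, dtype=float)
    spline = UnivariateSpline(vals, cum, k=3,
                              s=max(len(vals) * 0.5, 4.0))
    unfolded = spline(vals)
    spacings = np.diff(unfolded)
    spacings = spacings[spacings > 0]
    if len(spacings) < 5:
        return None
    return spacings / spacings.mean()


def rmt_threshold(table: CommunityTable, scan=None, relative: bool = True,
                  alpha: float = 0.05) -> dict:
    """Scan correlation cutoffs for the Poisson transition of the spectrum.

    For each candidate threshold, |rho| entries below it are zeroed, the
    eigenvalues of the thresholded matrix are unfolded, and the
    nearest-neighbour spacing distribution is tested against Exp(1) by a
    Kolmogorov–Smirnov test. Returns the smallest threshold whose spacing
    is Poisson-consistent (p > ``alpha``); degenerate spectra and an empty
    hit set produce flagged results, never exceptions.
    """
    if scan is None:
        scan = np.round(np.arange(0.30, 0.995, 0.01), 2)
    scan = np.asarray(list(scan), float)
    if scan.size == 0:
        raise ValueError("empty scan grid")
    if table.n_taxa < 10:
        raise ValueError("need >= 10 taxa for an RMT scan")
    rho, _ = spearman_matrix(table, relative=relative)
    rho = np.nan_to_num(rho)
    np.fill_diagonal(rho, 1.0)
    diagnostics = []
    selected, flag = None, None
    for t in np.sort(scan):
        m = np.where(np.abs(rho) >= t, rho, 0.0)
        np.fill_diagonal(m, 1.0)
        eig = np.linalg.eigvalsh(m)
        spacings = _nn_spacings(eig)
        if spacings is None:
            diagnostics.append((t, np.nan, "degenerate"))
            continue
        p = kstest(spacings, "expon").pvalue
        diagnostics.append((t, p, "poisson" if p > alpha else "goe"))
        if p > alpha and selected is None:
            selected = float(t)
    diag = pd.DataFrame(diagnostics, columns=["threshold", "ks_p", "regime"])
    if selected is None:
        if (diag["regime"] == "degenerate").all():
            selected, flag = float(np.sort(scan)[0]), "all_degenerate"
        else:
            selected, flag = float(np.sort(scan)[-1]), "no_poisson_transition"
        logger.warning("RMT scan degenerate (%s); returning %.2f", flag, selected)
    return {"threshold": selected, "flag": flag, "diagnostics": diag}


# ----------------------------------------------------------------------
# topology
# ----------------------------------------------------------------------

def _centralization_degree(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 3:
        return np.nan
    deg = np.array([d for _, d in g.degree()])
    return float((deg.max() - deg).sum() / ((n - 1) * (n - 2)))


def _centralization_betweenness(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 3:
        return np.nan
    bc = np.array(list(nx.betweenness_centrality(g, normalized=True).values()))
    return float((bc.max() - bc).sum() / (n - 1))


def network_topology(net) -> pd.Series:
    """The 11-feature topology vector of a network.

    Path-based metrics (average path length, diameter, mean closeness) are
    computed on the largest connected component; a multi-component graph is
    flagged. Modularity uses greedy agglomerative (CNM) community
    detection, which is deterministic for a fixed graph. Centralizations
    use Freeman's normalization. Edgeless graphs get missing path metrics.
    """
    g = net.graph if isinstance(net, CooccurrenceNetwork) else net
    n, e = g.number_of_nodes(), g.number_of_edges()
    feats = dict.fromkeys(TOPOLOGY_COLUMNS, np.nan)
    feats["nodes"], feats["edges"] = float(n), float(e)
    if n == 0:
        raise ValueError("empty network")
    feats["average_degree"] = 2.0 * e / n
    feats["density"] = nx.density(g) if n > 1 else np.nan
    feats["clustering_coefficient"] = nx.average_clustering(g) if n > 1 else np.nan
    feats["degree_centralization"] = _centralization_degree(g)
    feats["betweenness_centralization"] = _centralization_betweenness(g)
    if e > 0:
        comms = nx.community.greedy_modularity_communities(g)
        feats["modularity"] = nx.community.modularity(g, comms)
        lcc_nodes = max(nx.connected_components(g), key=len)
        lcc = g.subgraph(lcc_nodes)
        if lcc.number_of_nodes() > 1:
            feats["average_path_length"] = nx.average_shortest_path_length(lcc)
            feats["diameter"] = float(nx.diameter(lcc))
            feats["mean_closeness_centrality"] = float(
                np.mean(list(nx.closeness_centrality(lcc).values())))
    return pd.Series(feats)


def sample_subnetwork_features(net: CooccurrenceNetwork,
                               table: CommunityTable) -> pd.DataFrame:
    """Topology of each sample's induced subnetwork ("interaction indices").

    For every sample, the subgraph induced on network taxa present
    (count > 0) in that sample is extracted and the 11-feature vector is
    computed. Samples with fewer than 2 present network taxa keep their
    row with mostly-missing features.
    """
    missing = [t for t in net.nodes if t not in set(table.taxon_ids)]
    if missing:
        raise ValueError(f"network taxa absent from table: {missing[:5]}")
    presence = table.presence()
    rows = {}
    for sid in table.data.index:
        present = [t for t in net.nodes if presence.loc[sid, t]]
        sub = net.graph.subgraph(present)
        if sub.number_of_nodes() == 0:
            rows[sid] = pd.Series(dict.fromkeys(TOPOLOGY_COLUMNS, np.nan))
            rows[sid]["nodes"] = 0.0
            rows[sid]["edges"] = 0.0
        else:
            rows[sid] = network_topology(sub)
    return pd.DataFrame(rows).T.loc[table.data.index]


def robustness(net: CooccurrenceNetwork, removal_fraction: float = 0.5,
               reps: int = 100, seed: int = 0) -> dict:
    """Random species-removal robustness with secondary extinction.

    Per repetition, ``floor(removal_fraction * n)`` nodes are removed
    uniformly at random, then nodes left without any edge are removed
    iteratively; robustness is surviving nodes / initial nodes. Reports
    the mean and SD over repetitions (seeded).
    """
    if not (0 < removal_fraction < 1):
        raise ValueError("removal_fraction must be in (0, 1)")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    g0 = net.graph
    n = g0.number_of_nodes()
    if n == 0:
        raise ValueError("empty network")
    rng = np.random.default_rng(seed)
    n_remove = int(np.floor(removal_fraction * n))
    nodes = list(g0.nodes)
    values = np.empty(reps)
    for r in range(reps):
        removed = rng.choice(n, size=n_remove, replace=False)
        g = g0.copy()
        g.remove_nodes_from([nodes[i] for i in removed])
        while True:
            isolated = [v for v, d in g.degree() if d == 0]
            if not isolated:
                break
            g.remove_nodes_from(isolated)
        values[r] = g.number_of_nodes() / n
    return {"mean": float(values.mean()), "sd": float(values.std(ddof=0)),
            "values": values}
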