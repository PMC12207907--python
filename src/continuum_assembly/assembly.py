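"""Bin-based phylogenetic null-model classification of assembly processes.

The framework follows the iCAMP logic: taxa are partitioned into
phylogenetic bins (clades of at least ``bin_size_limit`` tips); within each
bin and for each sample pair a standardized phylogenetic turnover z-score
(beta-NRI from beta-MPD, or beta-NTI from beta-MNTD) is computed against a
tip-shuffling null, and a Raup–Crick index on Bray–Curtis (RC_bray) against
a richness- and abundance-preserving null. Each (pair, bin) is then
assigned one of five processes:

* z > +1.96           -> heterogeneous selection
* z < -1.96           -> homogeneous selection
* |z| <= 1.96, RC > +0.95  -> dispersal limitation
* |z| <= 1.96, RC < -0.95  -> homogenizing dispersal
* |z| <= 1.96, |RC| <= 0.95 -> drift

Per pair, bins are weighted by the mean relative abundance of their taxa in
the two samples (renormalized across bins), giving per-pair process
fractions that sum to 1; group-level fractions are means over pairs.

Null randomizations are generated once per bin and shared across all sample
pairs (the iCAMP convention), which also makes large pair sets cheap: the
beta-MPD null for every pair is a batched quadratic form against the same
stack of permuted patristic matrices.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

from continuum_assembly.datamodel import CommunityTable

logger = logging.getLogger(__name__)

Z_THRESHOLD = 1.96
RC_THRESHOLD = 0.95

PROCESS_LABELS = (
    "heterogeneous_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "drift",
    "unclassified",
)


@dataclass
class PhyloBin:
    bin_id: int
    taxa: list[str]

    def __len__(self) -> int:
        return len(self.taxa)


# ----------------------------------------------------------------------
# binning
# ----------------------------------------------------------------------

def _node_depths(tree: TreeNode) -> dict[int, float]:
    depth = {id(tree): 0.0}
    for node in tree.preorder(include_self=False):
        depth[id(node)] = depth[id(node.parent)] + float(node.length or 0.0)
    return depth


def _node_distance(u: TreeNode, v: TreeNode, depth: dict[int, float]) -> float:
    ancestors_u = set()
    node = u
    while node is not None:
        ancestors_u.add(id(node))
        node = node.parent
    node = v
    while id(node) not in ancestors_u:
        node = node.parent
    return depth[id(u)] + depth[id(v)] - 2 * depth[id(node)]


def phylo_bins(tree: TreeNode, bin_size_limit: int = 64) -> list[PhyloBin]:
    """Partition the tree's tips into phylogenetic bins.

    Post-order traversal: a clade becomes a bin the first time its count of
    not-yet-assigned tips reaches ``bin_size_limit``. Tips left unassigned
    at the root are grouped into maximal unassigned clades and merged into
    the bin whose MRCA is nearest by patristic distance. Deterministic for
    a fixed tree.
    """
    if bin_size_limit < 1:
        raise ValueError("bin_size_limit must be >= 1")
    all_tips = list(tree.tips())
    n = len(all_tips)
    if bin_size_limit > n:
        logger.warning("bin_size_limit %d exceeds %d taxa; single bin",
                       bin_size_limit, n)
        return [PhyloBin(1, [t.name for t in all_tips])]

    assigned: set[str] = set()
    raw_bins: list[tuple[list[str], TreeNode]] = []
    for node in tree.postorder(include_self=True):
        members = [node] if node.is_tip() else list(node.tips())
        unassigned = [t for t in members if t.name not in assigned]
        if len(unassigned) >= bin_size_limit:
            assigned.update(t.name for t in unassigned)
            raw_bins.append(([t.name for t in unassigned], node))

    leftover = [t for t in all_tips if t.name not in assigned]
    if leftover:
        depth = _node_depths(tree)
        # maximal clades consisting entirely of unassigned tips
        clades: dict[int, tuple[TreeNode, list[str]]] = {}
        for tip in leftover:
            node = tip
            while node.parent is not None:
                parent_tips = list(node.parent.tips())
                if any(t.name in assigned for t in parent_tips):
                    break
                node = node.parent
            key = id(node)
            if key not in clades:
                clades[key] = (node, [])
            clades[key][1].append(tip.name)
        for mrca, names in clades.values():
            dists = [_node_distance(mrca, bnode, depth) for _, bnode in raw_bins]
            raw_bins[int(np.argmin(dists))][0].extend(names)
            logger.debug("merged leftover clade of %d tips into nearest bin",
                         len(names))
    return [PhyloBin(i + 1, taxa) for i, (taxa, _) in enumerate(raw_bins)]


# ----------------------------------------------------------------------
# phylogenetic turnover metrics
# ----------------------------------------------------------------------

def patristic_matrix(tree: TreeNode):
    """Tip-to-tip patristic distance matrix; returns (ndarray, tip names)."""
    dm = tree.tip_tip_distances()
    return np.asarray(dm.data, float), list(dm.ids)


def _beta_mpd(fa: np.ndarray, fb: np.ndarray, d: np.ndarray) -> float:
    return float(fa @ d @ fb)


def _beta_mntd(fa: np.ndarray, fb: np.ndarray, d: np.ndarray) -> float:
    ia, ib = np.nonzero(fa)[0], np.nonzero(fb)[0]
    sub = d[np.ix_(ia, ib)]
    return 0.5 * (float(fa[ia] @ sub.min(axis=1)) + float(fb[ib] @ sub.min(axis=0)))


def beta_phylo_metric(table: CommunityTable, tree_or_d, pair,
                      metric: str = "beta_mpd", weighted: bool = True,
                      taxa=None) -> float:
    """Observed beta-MPD or beta-MNTD between two samples.

    ``tree_or_d`` may be a TreeNode or a precomputed ``(D, names)`` pair.
    ``taxa`` restricts the computation to a subset (e.g. one bin); relative
    abundances are renormalized within the subset.
    """
    d, names = (patristic_matrix(tree_or_d)
                if isinstance(tree_or_d, TreeNode) else tree_or_d)
    cols = list(taxa) if taxa is not None else table.taxon_ids
    idx = [names.index(t) for t in cols]
    dsub = d[np.ix_(idx, idx)]
    fa = _freq(table, pair[0], cols, weighted)
    fb = _freq(table, pair[1], cols, weighted)
    if fa is None or fb is None:
        raise ValueError("a sample has zero total counts in the taxon subset")
    fn = _beta_mpd if metric == "beta_mpd" else _beta_mntd
    if metric not in ("beta_mpd", "beta_mntd"):
        raise ValueError(f"unknown metric {metric!r}")
    return fn(fa, fb, dsub)


def _freq(table: CommunityTable, sample: str, cols, weighted: bool):
    x = table.data.loc[sample, list(cols)].to_numpy(float)
    if weighted:
        tot = x.sum()
        return None if tot == 0 else x / tot
    pres = (x > 0).astype(float)
    tot = pres.sum()
    return None if tot == 0 else pres / tot


def null_z(table: CommunityTable, tree_or_d, pair, metric: str = "beta_mpd",
           n_rand: int = 999, seed: int = 0, weighted: bool = True,
           taxa=None) -> float:
    """Standardized effect size (beta-NRI / beta-NTI) for one sample pair.

    The null shuffles tip labels within the evaluated taxon subset
    ``n_rand`` times. Returns NaN when the null distribution is degenerate
    (zero standard deviation).
    """
    d, names = (patristic_matrix(tree_or_d)
                if isinstance(tree_or_d, TreeNode) else tree_or_d)
    cols = list(taxa) if taxa is not None else table.taxon_ids
    idx = [names.index(t) for t in cols]
    dsub = d[np.ix_(idx, idx)]
    fa = _freq(table, pair[0], cols, weighted)
    fb = _freq(table, pair[1], cols, weighted)
    if fa is None or fb is None:
        raise ValueError("a sample has zero total counts in the taxon subset")
    fn = _beta_mpd if metric == "beta_mpd" else _beta_mntd
    obs = fn(fa, fb, dsub)
    rng = np.random.default_rng(seed)
    k = len(cols)
    nulls = np.empty(n_rand)
    for r in range(n_rand):
        perm = rng.permutation(k)
        nulls[r] = fn(fa, fb, dsub[np.ix_(perm, perm)])
    sd = nulls.std(ddof=0)
    if sd <= 1e-12 * max(abs(nulls.mean()), 1.0):
        logger.info("degenerate null (sd=0) for pair %s; z missing", (pair,))
        return np.nan
    return (obs - nulls.mean()) / sd


# ----------------------------------------------------------------------
# Raup-Crick on Bray-Curtis
# ----------------------------------------------------------------------

def _bray(x: np.ndarray, y: np.ndarray) -> float:
    denom = x.sum() + y.sum()
    return float(np.abs(x - y).sum() / denom)


def _null_community_draws(counts: np.ndarray, occupancy_p: np.ndarray,
                          abundance_p: np.ndarray, n_rand: int, rng):
    """Null assemblages preserving one sample's richness and read total.

    Membership is drawn without replacement with probability proportional
    to metacommunity occupancy; one read guarantees each member's presence
    and the remaining reads are assigned multinomially proportional to
    metacommunity relative abundance.
    """
    k = int((counts > 0).sum())
    n_reads = int(counts.sum())
    m = len(counts)
    out = np.zeros((n_rand, m), dtype=np.int64)
    for r in range(n_rand):
        chosen = rng.choice(m, size=k, replace=False, p=occupancy_p)
        out[r, chosen] = 1
        extra = n_reads - k
        if extra > 0:
            q = abundance_p[chosen]
            q = q / q.sum()
            out[r, chosen] += rng.multinomial(extra, q)
    return out


def raup_crick_bray(table: CommunityTable, pair, n_rand: int = 999,
                    seed: int = 0, taxa=None) -> float:
    """RC_bray for one sample pair against the whole-table metacommunity."""
    cols = list(taxa) if taxa is not None else table.taxon_ids
    sub = table.data[cols]
    meta_occ = (sub > 0).sum(axis=0).to_numpy(float)
    meta_ab = sub.sum(axis=0).to_numpy(float)
    if (meta_ab > 0).sum() < 2:
        raise ValueError("metacommunity has fewer than 2 taxa")
    occ_p = meta_occ / meta_occ.sum()
    ab_p = meta_ab / meta_ab.sum()
    xa = sub.loc[pair[0]].to_numpy()
    xb = sub.loc[pair[1]].to_numpy()
    if xa.sum() == 0 or xb.sum() == 0:
        raise ValueError("a sample has zero total counts in the taxon subset")
    obs = _bray(xa, xb)
    rng = np.random.default_rng(seed)
    na = _null_community_draws(xa, occ_p, ab_p, n_rand, rng)
    nb = _null_community_draws(xb, occ_p, ab_p, n_rand, rng)
    null_bc = np.abs(na - nb).sum(axis=1) / (na.sum(axis=1) + nb.sum(axis=1))
    less = int(np.sum(null_bc < obs - 1e-12))
    equal = int(np.sum(np.abs(null_bc - obs) <= 1e-12))
    return 2.0 * (less + 0.5 * equal) / n_rand - 1.0


# ----------------------------------------------------------------------
# classification and aggregation
# ----------------------------------------------------------------------

def classify_process(z: float, rc: float) -> str:
    """Five-process decision rule from (beta-NRI z, RC_bray)."""
    z_missing = z is None or (isinstance(z, float) and np.isnan(z))
    rc_missing = rc is None or (isinstance(rc, float) and np.isnan(rc))
    if z_missing and rc_missing:
        return "unclassified"
    if not z_missing:
        if z > Z_THRESHOLD:
            return "heterogeneous_selection"
        if z < -Z_THRESHOLD:
            return "homogeneous_selection"
    else:
        logger.info("z missing; classifying by RC_bray only")
    if rc_missing:
        return "unclassified"
    if rc > RC_THRESHOLD:
        return "dispersal_limitation"
    if rc < -RC_THRESHOLD:
        return "homogenizing_dispersal"
    return "drift"


def pair_fractions(pair_bin_table: pd.DataFrame) -> pd.DataFrame:
    """Per-pair process fractions (bin weights summed by label)."""
    rows = {}
    for (i, j), grp in pair_bin_table.groupby(["i", "j"], sort=False):
        w = grp["weight"].to_numpy(float)
        fr = {lab: 0.0 for lab in PROCESS_LABELS}
        for lab, wt in zip(grp["label"], w):
            fr[lab] += wt
        rows[(i, j)] = fr
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index = pd.MultiIndex.from_tuples(out.index, names=["i", "j"])
    return out


def aggregate_processes(pair_bin_table: pd.DataFrame,
                        grouping=None) -> pd.DataFrame:
    """Group-level process fractions: mean of per-pair fractions.

    ``grouping`` maps each pair (i, j) to a group label; by default all
    pairs form one group named 'all'. Fractions sum to 1 per group.
    """
    fr = pair_fractions(pair_bin_table)
    if grouping is None:
        labels = pd.Series("all", index=fr.index)
    else:
        labels = pd.Series([grouping[(i, j)] for i, j in fr.index], index=fr.index)
    if (labels.value_counts() == 0).any() or len(fr) == 0:
        raise ValueError("empty pair group")
    return fr.groupby(labels).mean()


# ----------------------------------------------------------------------
# batch driver
# ----------------------------------------------------------------------

def assembly_analysis(table: CommunityTable, tree: TreeNode, pairs=None,
                      metric: str = "beta_mpd", weighted: bool = True,
                      bin_size_limit: int = 64, n_rand: int = 999,
                      seed: int = 0, shuffle_scope: str = "bin",
                      bins: list[PhyloBin] | None = None,
                      compute_rc: bool = True) -> pd.DataFrame:
    """Per-pair, per-bin z, RC_bray, process label, and abundance weight.

    ``shuffle_scope='bin'`` (default, iCAMP convention) permutes tip labels
    within each bin's subtree; ``'tree'`` permutes across the whole tree.
    Null randomizations are generated once per bin and reused for every
    pair. ``compute_rc=False`` skips the Raup–Crick nulls (selection vs
    non-selection classification only — cheap when only the z-based
    labels are needed). Returns a long-form frame with columns
    ``i, j, bin_id, z, rc, label, weight``.
    """
    if metric not in ("beta_mpd", "beta_mntd"):
        raise ValueError(f"unknown metric {metric!r}")
    if shuffle_scope not in ("bin", "tree"):
        raise ValueError("shuffle_scope must be 'bin' or 'tree'")
    d_full, names = patristic_matrix(tree)
    name_pos = {t: i for i, t in enumerate(names)}
    missing = [t for t in table.taxon_ids if t not in name_pos]
    if missing:
        raise ValueError(f"taxa absent from tree: {missing[:5]}")
    if bins is None:
        bins = phylo_bins(tree, bin_size_limit)
    # restrict bins to taxa present in the table
    table_taxa = set(table.taxon_ids)
    bins = [PhyloBin(b.bin_id, [t for t in b.taxa if t in table_taxa])
            for b in bins]
    bins = [b for b in bins if len(b) > 0]

    samples = table.sample_ids
    if pairs is None:
        pairs = list(itertools.combinations(samples, 2))
    pairs = [(str(a), str(b)) for a, b in pairs]
    pair_samples = sorted({s for p in pairs for s in p})
    sample_pos = {s: i for i, s in enumerate(samples)}

    counts = table.counts.astype(float)
    sample_tot = counts.sum(axis=1)

    # per-sample relative abundance mass per bin (for pair weights)
    bin_mass = np.zeros((len(samples), len(bins)))
    col_pos = {t: i for i, t in enumerate(table.taxon_ids)}
    for bi, b in enumerate(bins):
        cols = [col_pos[t] for t in b.taxa]
        bin_mass[:, bi] = counts[:, cols].sum(axis=1) / sample_tot

    records = []
    if shuffle_scope == "tree":
        whole_rng = np.random.default_rng([int(seed), 900])
        global_idx = np.array([name_pos[t] for t in table.taxon_ids])
        tree_perms = [whole_rng.permutation(len(global_idx))
                      for _ in range(n_rand)]

    for bi, b in enumerate(bins):
        cols = b.taxa
        ccols = np.array([col_pos[t] for t in cols])
        k = len(cols)
        dsub = d_full[np.ix_([name_pos[t] for t in cols],
                             [name_pos[t] for t in cols])]
        sub_counts = counts[:, ccols]
        sub_tot = sub_counts.sum(axis=1)

        # frequency vectors per sample within the bin
        with np.errstate(invalid="ignore", divide="ignore"):
            if weighted:
                freq = sub_counts / sub_tot[:, None]
            else:
                pres = (sub_counts > 0).astype(float)
                freq = pres / pres.sum(axis=1)[:, None]

        if shuffle_scope == "bin":
            rng_perm = np.random.default_rng([int(seed), 10 + bi])
            null_d = (dsub[np.ix_(p, p)]
                      for p in (rng_perm.permutation(k)
                                for _ in range(n_rand)))
        else:
            # taxa may swap tips with other bins: permute table-wide, then
            # look up this bin's shuffled positions in the full matrix
            null_d = (d_full[np.ix_(global_idx[p[ccols]], global_idx[p[ccols]])]
                      for p in tree_perms)

        pair_idx = [(sample_pos[a], sample_pos[b_]) for a, b_ in pairs]
        fa_mat = np.array([freq[a] for a, _ in pair_idx])
        fb_mat = np.array([freq[b_] for _, b_ in pair_idx])
        valid = ~(np.isnan(fa_mat).any(axis=1) | np.isnan(fb_mat).any(axis=1))

        if metric == "beta_mpd":
            obs = np.einsum("ai,ij,aj->a", np.nan_to_num(fa_mat), dsub,
                            np.nan_to_num(fb_mat), optimize=True)
            nulls = np.empty((n_rand, len(pairs)))
            fa_z = np.nan_to_num(fa_mat)
            fb_z = np.nan_to_num(fb_mat)
            for r, dp in enumerate(null_d):
                nulls[r] = ((fa_z @ dp) * fb_z).sum(axis=1)
        else:
            obs = np.full(len(pairs), np.nan)
            nulls = np.full((n_rand, len(pairs)), np.nan)
            dps = list(null_d)
            for pi, (a, b_) in enumerate(pair_idx):
                if not valid[pi]:
                    continue
                obs[pi] = _beta_mntd(freq[a], freq[b_], dsub)
                for r, dp in enumerate(dps):
                    nulls[r, pi] = _beta_mntd(freq[a], freq[b_], dp)

        mean_null = nulls.mean(axis=0)
        sd_null = nulls.std(axis=0, ddof=0)
        degenerate = sd_null <= 1e-12 * np.maximum(np.abs(mean_null), 1.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(~degenerate, (obs - mean_null) / sd_null, np.nan)
        z[~valid] = np.nan

        # RC_bray within the bin: null draws per sample, reused across pairs
        rng_rc = np.random.default_rng([int(seed), 500 + bi])
        occ = (sub_counts > 0).sum(axis=0)
        ab = sub_counts.sum(axis=0)
        rc = np.full(len(pairs), np.nan)
        if compute_rc and (ab > 0).sum() >= 2:
            occ_p = occ / occ.sum()
            ab_p = ab / ab.sum()
            null_by_sample = {}
            for s in pair_samples:
                si = sample_pos[s]
                if sub_tot[si] > 0:
                    null_by_sample[si] = _null_community_draws(
                        sub_counts[si].astype(np.int64), occ_p, ab_p,
                        n_rand, rng_rc)
            for pi, (a, b_) in enumerate(pair_idx):
                if a not in null_by_sample or b_ not in null_by_sample:
                    continue
                na, nb = null_by_sample[a], null_by_sample[b_]
                obs_bc = _bray(sub_counts[a], sub_counts[b_])
                null_bc = (np.abs(na - nb).sum(axis=1)
                           / (na.sum(axis=1) + nb.sum(axis=1)))
                less = int(np.sum(null_bc < obs_bc - 1e-12))
                equal = int(np.sum(np.abs(null_bc - obs_bc) <= 1e-12))
                rc[pi] = 2.0 * (less + 0.5 * equal) / n_rand - 1.0

        for pi, (a, b_) in enumerate(pairs):
            ai, bj = pair_idx[pi]
            w = 0.5 * (bin_mass[ai, bi] + bin_mass[bj, bi])
            records.append({
                "i": a, "j": b_, "bin_id": b.bin_id,
                "z": z[pi], "rc": rc[pi],
                "label": classify_process(z[pi], rc[pi]),
                "weight": w,
            })

    out = pd.DataFrame(records)
    # renormalize weights across bins within each pair
    wsum = out.groupby(["i", "j"])["weight"].transform("sum")
    out["weight"] = out["weight"] / wsum
    return out
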