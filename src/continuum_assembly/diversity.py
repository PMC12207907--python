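"""Rarefaction and alpha diversity (Shannon, richness, Pielou, Faith PD).

Shannon entropy is reported in nats. Faith's phylogenetic diversity uses
the MRCA-spanning convention by default: the total branch length of the
minimal subtree connecting a sample's observed tips to their most recent
common ancestor. ``include_root=True`` adds the path from the MRCA to the
tree root, matching tools that anchor PD at the root.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.special import gammaln
from skbio import TreeNode

from continuum_assembly.datamodel import CommunityTable

logger = logging.getLogger(__name__)


def rarefy(table: CommunityTable, depth: int, seed: int) -> CommunityTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped with a logged
    warning. Deterministic for a fixed seed.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.data.sum(axis=1)
    keep = totals[totals >= depth].index
    dropped = [str(s) for s in totals.index[totals < depth]]
    if dropped:
        logger.warning("rarefy: dropping %d sample(s) below depth %d: %s",
                       len(dropped), depth, dropped)
    if len(keep) == 0:
        raise ValueError(f"no sample reaches rarefaction depth {depth}")
    rows = []
    for sid in keep:
        counts = table.data.loc[sid].to_numpy()
        if counts.sum() == depth:
            rows.append(counts)
        else:
            rows.append(rng.multivariate_hypergeometric(counts, depth))
    return CommunityTable(
        pd.DataFrame(np.array(rows), index=keep, columns=table.data.columns))


def _faith_pd(tree_index, present_tips: set[str], include_root: bool) -> float:
    """Branch length of the minimal subtree spanning ``present_tips``."""
    parent, length, tip_node = tree_index
    if not present_tips:
        raise ValueError("empty sample has no phylogenetic diversity")
    if len(present_tips) == 1 and not include_root:
        return 0.0
    # union of root-ward paths, then subtract the shared stem above the MRCA
    counts: dict[int, int] = {}
    total = 0.0
    n = len(present_tips)
    for name in present_tips:
        node = tip_node[name]
        while node is not None:
            nid = id(node)
            if nid in counts:
                counts[nid] += 1
                node = parent[nid]
                continue
            counts[nid] = 1
            total += length[nid]
            node = parent[nid]
    if not include_root:
        # drop branches on the path where all present tips pass (MRCA stem)
        node = tip_node[next(iter(present_tips))]
        while node is not None:
            if counts[id(node)] == n:
                total -= length[id(node)]
            node = parent[id(node)]
    return total


def _index_tree(tree: TreeNode):
    parent, length, tip_node = {}, {}, {}
    for node in tree.traverse(include_self=True):
        parent[id(node)] = node.parent
        length[id(node)] = float(node.length or 0.0)
        if node.is_tip():
            tip_node[node.name] = node
    return parent, length, tip_node


def alpha_diversity(table: CommunityTable,
                    tree: TreeNode | None = None,
                    include_root: bool = False) -> pd.DataFrame:
    """Per-sample Shannon (nats), observed richness, Pielou evenness, Faith PD.

    Pielou is H'/ln(observed) and reported missing for samples with a single
    observed taxon. ``faith_pd`` is only computed when a tree is supplied.
    """
    counts = table.counts.astype(float)
    totals = counts.sum(axis=1)
    if np.any(totals == 0):
        raise ValueError("empty sample in alpha_diversity input")
    p = counts / totals[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    shannon = -plogp.sum(axis=1)
    observed = (counts > 0).sum(axis=1)
    pielou = np.where(observed >= 2, shannon / np.log(np.maximum(observed, 2)), np.nan)

    result = pd.DataFrame({
        "shannon": shannon,
        "observed": observed,
        "pielou": pielou,
    }, index=table.data.index)

    if tree is not None:
        tips = {t.name for t in tree.tips()}
        missing = [t for t in table.taxon_ids if t not in tips]
        if missing:
            raise ValueError(f"taxa absent from tree: {missing[:5]}"
                             + ("..." if len(missing) > 5 else ""))
        index = _index_tree(tree)
        presence = table.presence()
        result["faith_pd"] = [
            _faith_pd(index, set(presence.columns[presence.loc[sid]]), include_root)
            for sid in table.data.index
        ]
    return result


def rarefaction_curve(table: CommunityTable, depths, reps: int = 200,
                      seed: int = 0, mode: str = "analytic") -> pd.DataFrame:
    """Expected observed richness per sample at each depth.

    ``mode='analytic'`` uses the hypergeometric expectation
    ``E[S] = sum_i 1 - C(T - n_i, d) / C(T, d)``; ``mode='monte_carlo'``
    averages ``reps`` seeded rarefactions. Returns samples × depths.
    """
    depths = [int(d) for d in depths]
    if not depths:
        raise ValueError("empty depth grid")
    if sorted(depths) != depths:
        raise ValueError("depths must be increasing")
    totals = table.data.sum(axis=1)
    if max(depths) > totals.min():
        raise ValueError("every depth must be <= each sample's total count")
    out = pd.DataFrame(index=table.data.index, columns=depths, dtype=float)
    if mode == "analytic":
        for sid in table.data.index:
            n = table.data.loc[sid].to_numpy()
            T = n.sum()
            for d in depths:
                # log C(T-n_i, d) - log C(T, d), with C=0 when T-n_i < d
                with np.errstate(invalid="ignore"):
                    logp = (gammaln(T - n + 1) - gammaln(d + 1) - gammaln(T - n - d + 1)
                            - (gammaln(T + 1) - gammaln(d + 1) - gammaln(T - d + 1)))
                p_absent = np.where(T - n >= d, np.exp(logp), 0.0)
                out.loc[sid, d] = float(np.sum((n > 0) * (1.0 - p_absent)))
    elif mode == "monte_carlo":
        if reps < 1:
            raise ValueError("reps must be >= 1")
        acc = np.zeros((table.n_samples, len(depths)))
        for r in range(reps):
            for k, d in enumerate(depths):
                sub = rarefy(table, d, seed=int(np.random.default_rng(
                    [seed, r, k]).integers(2 ** 31)))
                acc[:, k] += (sub.counts > 0).sum(axis=1)
        out.iloc[:, :] = acc / reps
    else:
        raise ValueError("mode must be 'analytic' or 'monte_carlo'")
    return out
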