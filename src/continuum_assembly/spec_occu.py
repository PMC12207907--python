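"""Specificity–occupancy (SPEC-OCCU) statistics and specialist calling.

For a taxon *S* and a sample class *H* (region, habitat, or lifestyle):

* specificity(S, H) = mean count of S over all samples of H, divided by the
  sum of those mean counts across all classes — how concentrated the taxon's
  abundance is in H;
* occupancy(S, H) = fraction of H's samples that contain S — how prevalent
  the taxon is within H.

A taxon is a specialist of H when both statistics reach the cutoff
(0.7 by default, both comparisons inclusive).

The per-class mean is taken over *all* samples of the class, zeros
included. Specificity is computed from raw mean counts by default, so it is
deliberately sensitive to library-size differences between classes;
``relative=True`` switches to per-sample relative abundances, which removes
that sensitivity.
"""

from __future__ import annotations

import logging

import pandas as pd

from continuum_assembly.datamodel import CommunityTable

logger = logging.getLogger(__name__)


def spec_occu_table(table: CommunityTable, groups, top_n: int = 1000,
                    relative: bool = False) -> pd.DataFrame:
    """Specificity and occupancy for each class's ``top_n`` most abundant taxa.

    ``groups`` maps every sample ID to exactly one class. Per class, the
    ``top_n`` taxa by summed counts are selected (boundary ties all kept,
    with a log message); the union of selections is scored, and each
    selected taxon gets one record per class — its specificity denominator
    always spans all classes. Taxa absent everywhere are excluded.

    Returns a long-form frame with columns ``taxon_id, group_id,
    specificity, occupancy, specialist`` (specialist initialized False).
    """
    groups = pd.Series(groups)
    groups.index = groups.index.astype(str)
    missing = [s for s in table.sample_ids if s not in groups.index]
    if missing:
        raise ValueError(f"samples without a group assignment: {missing}")
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    groups = groups.loc[table.sample_ids]
    data = table.relative_abundance() if relative else table.data.astype(float)

    group_sizes = groups.value_counts()
    if (group_sizes == 0).any():
        raise ValueError("every group must contain at least one sample")

    means = data.groupby(groups).mean()            # groups × taxa
    occ = (table.data > 0).groupby(groups).mean()  # groups × taxa

    selected: set[str] = set()
    totals = table.data.groupby(groups).sum()
    for g in totals.index:
        row = totals.loc[g]
        row = row[row > 0].sort_values(ascending=False)
        if len(row) <= top_n:
            picked = set(row.index)
        else:
            cut = row.iloc[top_n - 1]
            picked = set(row[row >= cut].index)
            n_ties = len(picked) - top_n
            if n_ties > 0:
                logger.info("group %s: %d taxa tied at the top_n boundary kept",
                            g, n_ties)
        selected |= picked
    selected = [t for t in table.taxon_ids if t in selected]

    denom = means[selected].sum(axis=0)
    records = []
    for g in means.index:
        spec = means.loc[g, selected] / denom
        for t in selected:
            records.append({
                "taxon_id": t,
                "group_id": g,
                "specificity": float(spec[t]),
                "occupancy": float(occ.loc[g, t]),
                "specialist": False,
            })
    return pd.DataFrame(records)


def call_specialists(records: pd.DataFrame, cutoff: float = 0.7) -> pd.DataFrame:
    """Flag records with specificity >= cutoff AND occupancy >= cutoff."""
    if not (0 < cutoff <= 1):
        raise ValueError("cutoff must be in (0, 1]")
    out = records.copy()
    out["specialist"] = (out["specificity"] >= cutoff) & (out["occupancy"] >= cutoff)
    return out
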