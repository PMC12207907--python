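"""Dissimilarity matrices, Jaccard beta-diversity partitioning, geographic
distances, and distance–decay of community similarity.

Total Jaccard dissimilarity between presence sets decomposes additively
(Podani family) into a species-replacement and a richness-difference
component. With ``a`` shared presences and ``b``, ``c`` taxa unique to each
sample:

    beta_total = (b + c) / (a + b + c)
    beta_repl  = 2 min(b, c) / (a + b + c)
    beta_rich  = |b - c| / (a + b + c)

so ``beta_total = beta_repl + beta_rich`` exactly. "Horizontal" beta
compares the pooled (union) presence set of a base site — the most upstream
site of a transect — against each other site's pooled set.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import linregress, rankdata, spearmanr
from skbio import DistanceMatrix

EARTH_RADIUS_KM = 6371.0088


def dissimilarity_matrix(table, metric: str = "bray_curtis") -> DistanceMatrix:
    """Pairwise Bray–Curtis (on counts) or binary Jaccard dissimilarity."""
    counts = table.counts.astype(float)
    if table.n_samples < 2:
        raise ValueError("need >= 2 samples")
    if np.any(counts.sum(axis=1) == 0):
        raise ValueError("all-zero sample: dissimilarity undefined")
    if metric == "bray_curtis":
        condensed = pdist(counts, metric="braycurtis")
    elif metric == "jaccard_binary":
        condensed = pdist(counts > 0, metric="jaccard")
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(squareform(condensed), ids=table.sample_ids)


def _podani_jaccard(x: np.ndarray, y: np.ndarray):
    a = int(np.sum(x & y))
    b = int(np.sum(x & ~y))
    c = int(np.sum(~x & y))
    n = a + b + c
    if n == 0:
        raise ValueError("pair shares no taxa and has none unique (a=b=c=0)")
    return ((b + c) / n, 2 * min(b, c) / n, abs(b - c) / n)


def partition_beta(table, mode: str = "pairwise",
                   site_groups=None, base_site=None) -> pd.DataFrame:
    """Replacement/richness partition of Jaccard beta diversity.

    ``mode='pairwise'`` partitions every pair of samples.
    ``mode='horizontal'`` pools presence sets by site (``site_groups`` maps
    sample -> site) and partitions the base site's pooled set against every
    other site's pooled set.

    Returns columns ``i, j, beta_total, beta_repl, beta_rich``.
    """
    presence = table.presence().to_numpy()
    ids = table.sample_ids
    rows = []
    if mode == "pairwise":
        for u in range(len(ids)):
            for v in range(u + 1, len(ids)):
                tot, repl, rich = _podani_jaccard(presence[u], presence[v])
                rows.append((ids[u], ids[v], tot, repl, rich))
    elif mode == "horizontal":
        if site_groups is None or base_site is None:
            raise ValueError("horizontal mode requires site_groups and base_site")
        site_groups = pd.Series(site_groups)
        pooled = {}
        for site, members in site_groups.groupby(site_groups).groups.items():
            idx = [ids.index(str(s)) for s in members]
            pooled[site] = presence[idx].any(axis=0)
        if base_site not in pooled:
            raise ValueError(f"base site {base_site!r} not found")
        base = pooled[base_site]
        for site, vec in pooled.items():
            if site == base_site:
                continue
            tot, repl, rich = _podani_jaccard(base, vec)
            rows.append((base_site, site, tot, repl, rich))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return pd.DataFrame(rows, columns=["i", "j", "beta_total", "beta_repl",
                                       "beta_rich"])


def geographic_distance_matrix(meta: pd.DataFrame) -> DistanceMatrix:
    """Haversine great-circle distances (km) between sample coordinates."""
    for col in ("latitude", "longitude"):
        if col not in meta.columns:
            raise ValueError(f"metadata lacks {col!r}")
        bad = meta.index[meta[col].isna()]
        if len(bad):
            raise ValueError(f"missing coordinates for samples: {list(bad)}")
    lat = np.radians(meta["latitude"].to_numpy(float))
    lon = np.radians(meta["longitude"].to_numpy(float))
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = (np.sin(dlat / 2) ** 2
         + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2)
    km = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
    np.fill_diagonal(km, 0.0)
    km = (km + km.T) / 2
    return DistanceMatrix(km, ids=[str(s) for s in meta.index])


def _upper(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def mantel_permutation_p(m1: np.ndarray, m2: np.ndarray, statistic,
                         n_perm: int, rng,
                         alternative: str = "two-sided") -> float:
    """Permutation p-value for a matrix-correlation statistic.

    Rows/columns of ``m2`` are permuted jointly; p uses the
    (count + 1) / (n_perm + 1) convention.
    """
    obs = statistic(_upper(m1), _upper(m2))
    count = 0
    n = m1.shape[0]
    for _ in range(n_perm):
        perm = rng.permutation(n)
        val = statistic(_upper(m1), _upper(m2[np.ix_(perm, perm)]))
        if alternative == "two-sided":
            count += abs(val) >= abs(obs) - 1e-12
        elif alternative == "greater":
            count += val >= obs - 1e-12
        elif alternative == "less":
            count += val <= obs + 1e-12
        else:
            raise ValueError(f"unknown alternative {alternative!r}")
    return (count + 1) / (n_perm + 1)


def distance_decay(dist_km: DistanceMatrix, diss: DistanceMatrix,
                   groups=None, n_perm: int = 999, seed: int = 0,
                   alternative: str = "two-sided") -> dict:
    """Distance–decay of similarity: OLS fit and Spearman–Mantel test.

    Fits similarity (1 - dissimilarity) on geographic distance over
    upper-triangle pairs and reports the Spearman correlation between
    similarity and distance with a Mantel-style permutation p-value
    (two-sided by default). ``groups`` optionally restricts to
    within-group pairs.
    """
    if list(dist_km.ids) != list(diss.ids):
        diss = diss.filter(dist_km.ids)
    km = np.asarray(dist_km.data, float).copy()
    sim = 1.0 - np.asarray(diss.data, float)
    if groups is not None:
        groups = pd.Series(groups).loc[list(dist_km.ids)].to_numpy()
        mask = groups[:, None] != groups[None, :]
        km[mask] = np.nan
        sim[mask] = np.nan
    x, y = _upper(km), _upper(sim)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need >= 3 pairs for distance-decay")
    fit = linregress(x, y)
    if np.allclose(y, y[0]) or np.allclose(x, x[0]):
        rho, p = np.nan, np.nan
    else:
        rho = spearmanr(x, y).statistic
        if groups is None:
            rng = np.random.default_rng(seed)
            stat = lambda a, b: spearmanr(a, b).statistic
            p = mantel_permutation_p(km, sim, stat, n_perm, rng, alternative)
        else:
            # masked matrices break joint row/column permutation; fall back
            # to permuting the within-group pair vector
            rng = np.random.default_rng(seed)
            count = 0
            for _ in range(n_perm):
                val = spearmanr(x, rng.permutation(y)).statistic
                if alternative == "two-sided":
                    count += abs(val) >= abs(rho) - 1e-12
                elif alternative == "greater":
                    count += val >= rho - 1e-12
                else:
                    count += val <= rho + 1e-12
            p = (count + 1) / (n_perm + 1)
    return {
        "slope": fit.slope,
        "intercept": fit.intercept,
        "r_squared": fit.rvalue ** 2,
        "spearman_rho": rho,
        "p_value": p,
        "n_pairs": int(len(x)),
    }
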