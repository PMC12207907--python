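"""PERMANOVA, Mantel / partial Mantel, CCA, VIF selection, and two-matrix
variation partitioning (abiotic environment vs biotic interaction indices).

Variation partitioning uses redundancy analysis on Hellinger-transformed
counts with Ezekiel-adjusted R²: with explanatory matrices X (environment)
and W (biotic),

    pure_env    = adjR2(X ∪ W) - adjR2(W)
    pure_biotic = adjR2(X ∪ W) - adjR2(X)
    joint       = adjR2(X) + adjR2(W) - adjR2(X ∪ W)
    unexplained = 1 - adjR2(X ∪ W)

which closes to 1 by construction. Adjusted fractions may be slightly
negative; they are reported as computed and flagged, never clamped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from skbio import DistanceMatrix

logger = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# PERMANOVA
# ----------------------------------------------------------------------

@dataclass
class PermanovaResult:
    factor: str
    r_squared: float
    pseudo_f: float
    p_value: float
    n_perm: int


def permanova(diss: DistanceMatrix, groups, n_perm: int = 999,
              seed: int = 0, factor: str = "factor") -> PermanovaResult:
    """One-factor PERMANOVA on a dissimilarity matrix.

    Sums of squares follow the standard identity SS = sum of squared
    distances / group size; the p-value counts permuted pseudo-F values
    reaching the observed one, with the (count + 1)/(n_perm + 1)
    convention.
    """
    ids = list(diss.ids)
    groups = pd.Series(groups).loc[ids]
    labels, counts = np.unique(groups.to_numpy(), return_counts=True)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    if (counts < 2).any():
        small = labels[counts < 2]
        raise ValueError(f"groups of size 1: {list(small)}")
    d2 = np.asarray(diss.data, float) ** 2
    n = len(ids)
    a = len(labels)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    membership = np.array([np.array(groups) == g for g in labels])

    def ss_within(member_rows: np.ndarray) -> float:
        # member_rows: (a, n) boolean
        out = 0.0
        for g in range(a):
            m = member_rows[g]
            ng = m.sum()
            out += d2[np.ix_(m, m)].sum() / (2 * ng)
        return out

    ss_w = ss_within(membership)
    ss_b = ss_total - ss_w
    with np.errstate(divide="ignore"):
        f_obs = (ss_b / (a - 1)) / (ss_w / (n - a))
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            ss_w_p = ss_within(membership[:, perm])
            f_p = ((ss_total - ss_w_p) / (a - 1)) / (ss_w_p / (n - a))
            if f_p >= f_obs - 1e-12:
                count += 1
    return PermanovaResult(
        factor=factor,
        r_squared=ss_b / ss_total,
        pseudo_f=f_obs,
        p_value=(count + 1) / (n_perm + 1),
        n_perm=n_perm,
    )


# ----------------------------------------------------------------------
# Mantel
# ----------------------------------------------------------------------

def _upper(m: np.ndarray) -> np.ndarray:
    return m[np.triu_indices(m.shape[0], k=1)]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xs = x - x.mean()
    ys = y - y.mean()
    denom = np.sqrt((xs ** 2).sum() * (ys ** 2).sum())
    return float(xs @ ys / denom) if denom > 0 else np.nan


def mantel(d1: DistanceMatrix, d2: DistanceMatrix, method: str = "spearman",
           n_perm: int = 999, seed: int = 0,
           alternative: str = "two-sided"):
    """Mantel correlation between two distance matrices with permutation p."""
    if list(d1.ids) != list(d2.ids):
        d2 = d2.filter(d1.ids)
    m1 = np.asarray(d1.data, float)
    m2 = np.asarray(d2.data, float)
    if method == "spearman":
        transform = lambda v: rankdata(v)
    elif method == "pearson":
        transform = lambda v: v
    else:
        raise ValueError(f"unknown method {method!r}")
    x = transform(_upper(m1))
    if np.allclose(x, x[0]) or np.allclose(_upper(m2), _upper(m2)[0]):
        return np.nan, np.nan
    r_obs = _pearson(x, transform(_upper(m2)))
    rng = np.random.default_rng(seed)
    n = m1.shape[0]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r = _pearson(x, transform(_upper(m2[np.ix_(perm, perm)])))
        if alternative == "two-sided":
            count += abs(r) >= abs(r_obs) - 1e-12
        elif alternative == "greater":
            count += r >= r_obs - 1e-12
        else:
            count += r <= r_obs + 1e-12
    return r_obs, (count + 1) / (n_perm + 1)


def mantel_partial(d1: DistanceMatrix, d2: DistanceMatrix,
                   d_control: DistanceMatrix, method: str = "spearman",
                   n_perm: int = 999, seed: int = 0,
                   alternative: str = "two-sided"):
    """Partial Mantel: correlation of d1 and d2 with d_control held fixed.

    The upper-triangle vectors (rank-transformed for spearman) of d1 and d2
    are each regressed on the control vector; their residuals are
    correlated. Permutations shuffle d1's rows/columns jointly and
    recompute its residual against the fixed control.
    """
    for other in (d2, d_control):
        if list(d1.ids) != list(other.ids):
            raise ValueError("matrices must share the same sample order")
    m1 = np.asarray(d1.data, float)
    transform = (lambda v: rankdata(v)) if method == "spearman" else (lambda v: v)
    vc = transform(_upper(np.asarray(d_control.data, float)))
    v2 = transform(_upper(np.asarray(d2.data, float)))

    def residual(v: np.ndarray) -> np.ndarray:
        X = np.column_stack([np.ones_like(vc), vc])
        beta, *_ = np.linalg.lstsq(X, v, rcond=None)
        res = v - X @ beta
        # a matrix fully explained by the control leaves only numerical
        # noise; its partial correlation is 0 by convention
        scale = np.linalg.norm(v - v.mean())
        if scale > 0 and np.linalg.norm(res) <= 1e-8 * scale:
            res[:] = 0.0
        return res

    def corr(a: np.ndarray, b: np.ndarray) -> float:
        if np.allclose(a, 0.0) or np.allclose(b, 0.0):
            return 0.0
        return _pearson(a, b)

    r2 = residual(v2)
    r_obs = corr(residual(transform(_upper(m1))), r2)
    rng = np.random.default_rng(seed)
    n = m1.shape[0]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r = corr(residual(transform(_upper(m1[np.ix_(perm, perm)]))), r2)
        if alternative == "two-sided":
            count += abs(r) >= abs(r_obs) - 1e-12
        elif alternative == "greater":
            count += r >= r_obs - 1e-12
        else:
            count += r <= r_obs + 1e-12
    return r_obs, (count + 1) / (n_perm + 1)


# ----------------------------------------------------------------------
# CCA
# ----------------------------------------------------------------------

@dataclass
class CcaResult:
    total_inertia: float
    constrained_inertia: float
    eigenvalues: np.ndarray
    site_scores: pd.DataFrame
    species_scores: pd.DataFrame
    biplot_scores: pd.DataFrame


def cca(table, env: pd.DataFrame) -> CcaResult:
    """Canonical correspondence analysis of counts constrained by env.

    Chi-square standardizes the count matrix, regresses it onto the
    (row-weighted) environmental variables, and eigen-decomposes the fitted
    values. Constrained inertia never exceeds total inertia.
    """
    env = env.loc[table.data.index]
    X = env.to_numpy(float)
    for k, col in enumerate(env.columns):
        if np.allclose(X[:, k], X[0, k]):
            raise ValueError(f"constant environmental column: {col!r}")
    n, q = X.shape
    if q >= n:
        raise ValueError("more environmental columns than samples - 1")
    Y = table.counts.astype(float)
    total = Y.sum()
    P = Y / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    if np.any(c == 0):
        raise ValueError("taxon with zero total count")
    Qbar = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    total_inertia = float((Qbar ** 2).sum())

    # weighted regression of Qbar on env (row weights r)
    sqrt_r = np.sqrt(r)
    Xc = X - (r @ X)  # weighted centering
    Xw = Xc * sqrt_r[:, None]
    B, *_ = np.linalg.lstsq(Xw, Qbar, rcond=None)
    fitted = Xw @ B
    u, s, vt = np.linalg.svd(fitted, full_matrices=False)
    eig = s ** 2
    keep = eig > 1e-12 * max(eig.max(), 1.0)
    eig, u, vt = eig[keep], u[:, keep], vt[keep]
    axes = [f"CCA{i + 1}" for i in range(len(eig))]
    site = pd.DataFrame((u / sqrt_r[:, None]), index=table.data.index,
                        columns=axes)
    species = pd.DataFrame((vt.T / np.sqrt(c)[:, None]) * s[keep],
                           index=table.taxon_ids, columns=axes)
    # biplot scores: weighted correlations of env with the site axes
    Xstd = Xw / np.sqrt((Xw ** 2).sum(axis=0))
    biplot = pd.DataFrame(Xstd.T @ (u / np.sqrt((u ** 2).sum(axis=0))),
                          index=env.columns, columns=axes)
    return CcaResult(
        total_inertia=total_inertia,
        constrained_inertia=float(eig.sum()),
        eigenvalues=eig,
        site_scores=site,
        species_scores=species,
        biplot_scores=biplot,
    )


# ----------------------------------------------------------------------
# VIF selection and variation partitioning
# ----------------------------------------------------------------------

def _vif(X: np.ndarray) -> np.ndarray:
    n, q = X.shape
    out = np.empty(q)
    for k in range(q):
        y = X[:, k]
        others = np.delete(X, k, axis=1)
        A = np.column_stack([np.ones(n), others])
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        if ss_tot == 0:
            out[k] = np.inf
            continue
        r2 = 1.0 - ss_res / ss_tot
        out[k] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def vif_select(env: pd.DataFrame, threshold: float = 10.0):
    """Drop the largest-VIF variable until all VIFs fall below threshold.

    Perfectly collinear variables have infinite VIF and go first; ties
    break by column order. Returns ``(retained columns, elimination trace)``
    where the trace lists (dropped column, its VIF) in order.
    """
    if env.shape[1] < 2:
        raise ValueError("need >= 2 variables")
    cols = list(env.columns)
    trace = []
    while len(cols) > 1:
        vifs = _vif(env[cols].to_numpy(float))
        worst = int(np.argmax(vifs))
        if vifs[worst] < threshold:
            break
        trace.append((cols[worst], float(vifs[worst])))
        cols.pop(worst)
    return cols, trace


def hellinger(counts: np.ndarray) -> np.ndarray:
    """Hellinger transform: square root of per-sample relative abundances."""
    totals = counts.sum(axis=1, keepdims=True)
    return np.sqrt(counts / totals)


def _rda_r2(Y: np.ndarray, X: np.ndarray) -> float:
    """Redundancy-analysis R²: fraction of centered Y variance fit by X."""
    Yc = Y - Y.mean(axis=0)
    A = np.column_stack([np.ones(len(Y)), X])
    beta, *_ = np.linalg.lstsq(A, Yc, rcond=None)
    fitted = A @ beta
    ss_tot = float((Yc ** 2).sum())
    return float((fitted ** 2).sum()) / ss_tot


def _adjust_r2(r2: float, n: int, p: int) -> float:
    if n - p - 1 <= 0:
        raise ValueError("too many explanatory columns for the sample size")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


@dataclass
class VpaResult:
    pure_env: float
    pure_biotic: float
    joint: float
    unexplained: float
    negative_fractions: list

    def as_dict(self) -> dict:
        return {"pure_env": self.pure_env, "pure_biotic": self.pure_biotic,
                "joint": self.joint, "unexplained": self.unexplained}


def variation_partition(table, X_env: pd.DataFrame,
                        W_biotic: pd.DataFrame | None) -> VpaResult:
    """Partition community variation between two explanatory matrices.

    RDA on Hellinger-transformed counts; Ezekiel-adjusted R² fractions.
    An empty/None biotic matrix reduces to a single-matrix fit with
    pure_biotic = joint = 0.
    """
    Y = hellinger(table.counts.astype(float))
    n = Y.shape[0]
    X = X_env.loc[table.data.index].to_numpy(float)
    if W_biotic is None or W_biotic.shape[1] == 0:
        adj_x = _adjust_r2(_rda_r2(Y, X), n, X.shape[1])
        return VpaResult(pure_env=adj_x, pure_biotic=0.0, joint=0.0,
                         unexplained=1.0 - adj_x,
                         negative_fractions=["pure_env"] if adj_x < 0 else [])
    W = W_biotic.loc[table.data.index].to_numpy(float)
    if X.shape[1] + W.shape[1] >= n - 1:
        raise ValueError("combined explanatory columns must be < samples - 1")
    adj_x = _adjust_r2(_rda_r2(Y, X), n, X.shape[1])
    adj_w = _adjust_r2(_rda_r2(Y, W), n, W.shape[1])
    both = np.column_stack([X, W])
    adj_xw = _adjust_r2(_rda_r2(Y, both), n, both.shape[1])
    pure_env = adj_xw - adj_w
    pure_biotic = adj_xw - adj_x
    joint = adj_x + adj_w - adj_xw
    unexplained = 1.0 - adj_xw
    fractions = {"pure_env": pure_env, "pure_biotic": pure_biotic,
                 "joint": joint, "unexplained": unexplained}
    negative = [k for k, v in fractions.items() if v < 0]
    if negative:
        logger.info("negative adjusted fractions (reported, not clamped): %s",
                    negative)
    return VpaResult(**fractions, negative_fractions=negative)
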