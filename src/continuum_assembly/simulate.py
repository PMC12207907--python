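"""Synthetic gradient metacommunities with known assembly regimes.

The generator emulates an amplicon survey of ~50 sites along a one-dimensional
river–estuary–sea transect with a monotone salinity-like gradient
(0–33.7 PSU by default) sampled in up to three fractions (free-living,
particle-associated, sediment) that differ only in dispersal scale.

Model
-----
Taxa arise on a pure-birth (Yule) phylogeny scaled to depth 1. Each taxon
carries a niche optimum ``mu_i`` evolved as Brownian motion on the tree and
affinely mapped onto the environmental gradient, so optima are
phylogenetically conserved (``phylo_signal='shuffled'`` permutes optima
across tips afterwards, destroying the signal but preserving the marginal
distribution). Expected relative abundance of taxon *i* at site *s* is

    p_i(s)  ∝  exp(-(E_s - mu_i)^2 / (2 sigma^2))^lambda  *  m_i(s)

where ``E_s`` is the site environment (linear in transect position),
``sigma`` the niche breadth, ``lambda`` the selection strength
(``lambda = 0`` is the neutral limit), and

    m_i(s)  =  sum_t exp(-d_st / delta_f) * A_i(t)

is distance-decaying immigration from a fixed latent regional pool ``A``
(independent log-normal abundances per taxon per site), with the dispersal
scale ``delta_f = delta * fraction multiplier``. Small ``delta`` confines
each site to its local pool (dispersal limitation); ``delta → ∞`` mixes all
sites uniformly. Observed counts are a single multinomial draw of
``read_depth`` reads per sample, which is the model's only drift term.

The latent-pool and multinomial random streams are decoupled from the
parameter values, so changing ``lambda`` alone leaves the pool and the
sampling noise identical — the handle the monotonicity properties rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from continuum_assembly.datamodel import CommunityTable

EARTH_KM_PER_DEG = 111.19492664455873  # 6371.0088 * pi / 180

DEFAULT_FRACTIONS = {"FL": 1.0, "PA": 0.5, "sediment": 0.2}


@dataclass
class SimulationParams:
    """Knobs of the gradient-metacommunity generator.

    Defaults describe the emulated survey: 50 transect sites over 1900 km,
    a 0–33.7 PSU salinity-like gradient, niche breadth 5 PSU (~0.15 of the
    gradient span), moderate selection, basin-scale dispersal, and 2000
    reads per sample.
    """

    n_sites: int = 50
    n_taxa: int = 200
    gradient_range: tuple[float, float] = (0.0, 33.7)
    niche_breadth: float = 5.0
    selection_strength: float = 1.0
    dispersal_scale: float = 400.0
    read_depth: int = 2000
    transect_length: float = 1900.0
    fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FRACTIONS))
    phylo_signal: str = "brownian"
    seed: int = 0
    # regime-label bookkeeping thresholds (not science claims)
    selection_lambda_min: float = 2.0
    neutral_lambda_max: float = 0.5
    limited_dispersal_frac: float = 0.1

    def __post_init__(self):
        if self.n_sites < 2:
            raise ValueError("n_sites must be >= 2")
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        if self.niche_breadth <= 0 and self.selection_strength > 0:
            raise ValueError("niche_breadth must be > 0 when selection acts")
        if self.selection_strength < 0:
            raise ValueError("selection_strength must be >= 0")
        if self.dispersal_scale <= 0:
            raise ValueError("dispersal_scale must be > 0")
        if self.read_depth < 1:
            raise ValueError("read_depth must be >= 1")
        if self.phylo_signal not in ("brownian", "shuffled"):
            raise ValueError("phylo_signal must be 'brownian' or 'shuffled'")
        unknown = set(self.fractions) - set(DEFAULT_FRACTIONS)
        if unknown:
            raise ValueError(f"unknown fractions: {sorted(unknown)}")

    @property
    def regime(self) -> str:
        """Ground-truth regime label, a pure function of (lambda, delta)."""
        if self.selection_strength >= self.selection_lambda_min:
            return "selection_dominated"
        if (self.selection_strength < self.neutral_lambda_max
                and self.dispersal_scale
                <= self.limited_dispersal_frac * self.transect_length):
            return "dispersal_limited"
        return "drift_dominated"


@dataclass
class GroundTruth:
    """What the generator knows and the analysis must recover."""

    niche_optima: pd.Series        # per taxon, gradient units
    site_environment: pd.Series    # per sample, gradient units
    site_position_km: pd.Series    # per sample
    regime: str
    params: SimulationParams


def simulate_phylogeny(n_taxa: int, seed: int,
                       gradient_range: tuple[float, float] = (0.0, 1.0),
                       phylo_signal: str = "brownian"):
    """Simulate a Yule tree of depth 1 and Brownian niche optima on it.

    Returns ``(tree, optima)`` where ``optima`` is a Series indexed by tip
    name, affinely mapped onto ``gradient_range`` (min trait -> range min,
    max trait -> range max). ``phylo_signal='shuffled'`` permutes optima
    across tips after simulation.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = np.random.default_rng([int(seed), 101])

    root = TreeNode(length=0.0)
    left, right = TreeNode(), TreeNode()
    root.extend([left, right])
    active = [left, right]          # lineages alive, in birth order
    birth = {id(left): 0.0, id(right): 0.0}
    t = 0.0
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / len(active))
        k = rng.integers(len(active))
        parent = active.pop(k)
        parent.length = t - birth[id(parent)]
        c1, c2 = TreeNode(), TreeNode()
        parent.extend([c1, c2])
        birth[id(c1)] = birth[id(c2)] = t
        active.extend([c1, c2])
    t_end = t + rng.exponential(1.0 / len(active))
    for node in active:
        node.length = t_end - birth[id(node)]
    # scale so every tip sits at depth exactly 1
    for node in root.traverse(include_self=False):
        node.length /= t_end
    width = len(str(n_taxa))
    for i, tip in enumerate(root.tips()):
        tip.name = f"T{i + 1:0{width}d}"

    # Brownian walk: child trait = parent trait + N(0, branch length)
    trait = {id(root): 0.0}
    for node in root.preorder(include_self=False):
        parent_val = trait[id(node.parent)]
        trait[id(node)] = parent_val + rng.normal(0.0, np.sqrt(max(node.length, 0.0)))
    tips = list(root.tips())
    values = np.array([trait[id(tip)] for tip in tips])
    lo, hi = float(values.min()), float(values.max())
    gmin, gmax = gradient_range
    if hi > lo:
        values = gmin + (values - lo) * (gmax - gmin) / (hi - lo)
    else:
        values = np.full_like(values, 0.5 * (gmin + gmax))
    if phylo_signal == "shuffled":
        values = rng.permutation(values)
    elif phylo_signal != "brownian":
        raise ValueError("phylo_signal must be 'brownian' or 'shuffled'")
    optima = pd.Series(values, index=[tip.name for tip in tips], name="niche_optimum")
    return root, optima


def _environmental_covariates(rng, salinity, position_km, transect_length):
    """Plausible correlated covariates for the metadata table (not ground truth)."""
    n = len(salinity)
    frac = position_km / transect_length
    return {
        "salinity": salinity,
        "temperature": 28.0 - 8.0 * frac + rng.normal(0, 0.4, n),
        "pH": 7.6 + 0.015 * salinity + rng.normal(0, 0.05, n),
        "DO": 260.0 - 2.0 * salinity + rng.normal(0, 8.0, n),
        "chl_a": np.exp(rng.normal(0.5, 0.5, n) - 1.5 * frac),
        "NH4": np.exp(rng.normal(1.0, 0.3, n) - 1.0 * frac),
        "NO3": np.exp(rng.normal(2.5, 0.3, n) - 1.5 * frac),
        "NO2": np.exp(rng.normal(-0.5, 0.3, n) - 0.5 * frac),
        "PO4": np.exp(rng.normal(0.0, 0.3, n) - 0.8 * frac),
        "SiO3": np.exp(rng.normal(3.0, 0.3, n) - 1.8 * frac),
    }


def simulate_metacommunity(params: SimulationParams,
                           tree: TreeNode | None = None,
                           optima: pd.Series | None = None):
    """Simulate counts, metadata, and ground truth for one metacommunity.

    Returns ``(table, metadata, tree, truth)``. If ``tree``/``optima`` are
    not supplied they are simulated from ``params``. One sample is emitted
    per site per requested fraction; every sample's counts sum to exactly
    ``read_depth``.
    """
    if tree is None or optima is None:
        tree, optima = simulate_phylogeny(
            params.n_taxa, params.seed,
            gradient_range=params.gradient_range,
            phylo_signal=params.phylo_signal)
    tip_names = [t.name for t in tree.tips()]
    if len(tip_names) != params.n_taxa:
        raise ValueError(
            f"tree has {len(tip_names)} tips but params.n_taxa={params.n_taxa}")
    mu = optima.loc[tip_names].to_numpy()

    pos = np.linspace(0.0, params.transect_length, params.n_sites)
    gmin, gmax = params.gradient_range
    env = gmin + (gmax - gmin) * pos / params.transect_length

    # latent regional pool and sampling noise use parameter-independent streams
    rng_pool = np.random.default_rng([int(params.seed), 1])
    rng_draw = np.random.default_rng([int(params.seed), 2])
    rng_meta = np.random.default_rng([int(params.seed), 3])
    pool = rng_pool.lognormal(0.0, 1.0, size=(params.n_sites, params.n_taxa))

    dist = np.abs(pos[:, None] - pos[None, :])
    lam, sigma = params.selection_strength, params.niche_breadth
    if lam > 0:
        fitness = np.exp(-lam * (env[:, None] - mu[None, :]) ** 2 / (2 * sigma ** 2))
    else:
        fitness = np.ones((params.n_sites, params.n_taxa))

    # region by transect thirds: freshwater, transition, coastal
    thirds = np.minimum((3 * pos / params.transect_length).astype(int), 2)
    region = np.array(["FR", "TR", "CR"])[thirds]
    lat0, lon0 = 20.0, 120.0
    lat = lat0 + pos / EARTH_KM_PER_DEG

    covariates = _environmental_covariates(rng_meta, env, pos, params.transect_length)

    rows, meta_rows, sample_ids = [], [], []
    for fraction, mult in params.fractions.items():
        delta_f = params.dispersal_scale * mult
        migration = np.exp(-dist / delta_f) @ pool
        p = fitness * migration
        row_sums = p.sum(axis=1)
        if not np.all(np.isfinite(p)) or np.any(row_sums <= 0):
            raise ValueError(
                "degenerate expected abundances (all-zero or non-finite); "
                "use niche_breadth > 0 large enough for the gradient")
        p = p / row_sums[:, None]
        for s in range(params.n_sites):
            counts = rng_draw.multinomial(params.read_depth, p[s])
            sid = f"S{s + 1:02d}_{fraction}"
            sample_ids.append(sid)
            rows.append(counts)
            meta_rows.append({
                "sample_id": sid,
                "site": s + 1,
                "region": region[s],
                "habitat": "sediment" if fraction == "sediment" else "water",
                "lifestyle": np.nan if fraction == "sediment" else fraction,
                "latitude": lat[s],
                "longitude": lon0,
                "position_km": pos[s],
                **{k: v[s] for k, v in covariates.items()},
            })

    table = CommunityTable(
        pd.DataFrame(np.array(rows), index=sample_ids, columns=tip_names),
        drop_empty=False)
    metadata = pd.DataFrame(meta_rows).set_index("sample_id")
    truth = GroundTruth(
        niche_optima=optima,
        site_environment=pd.Series(
            metadata["salinity"].to_numpy(), index=metadata.index, name="E"),
        site_position_km=metadata["position_km"].copy(),
        regime=params.regime,
        params=params,
    )
    return table, metadata, tree, truth
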