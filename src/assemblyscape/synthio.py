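"""Synthetic phylogenies, niche traits, environments and communities.

The generator emulates a depth-stratified grassland soil survey: sites along
a south-north precipitation gradient, three depth layers per site with
nutrient stocks declining downward, a phylogeny with Brownian-conserved
environmental niches, and communities assembled under named regimes so that
every downstream inference has a known ground truth:

``homogeneous_selection``
    all samples filtered toward one shared environmental optimum (Gaussian
    niche kernel of breadth sigma);
``variable_selection``
    samples filtered toward site-specific optima spanning the niche range;
``neutral_drift``
    Sloan-style source-sink sampling: each read immigrates from the
    metacommunity with probability m, otherwise copies a resident read
    (sequential Polya urn);
``dispersal_limitation``
    neutral drift with small m from spatially autocorrelated local pools;
``mixed``
    a depth series — strong selection in topsoil (T), weak selection in the
    middle layer (M), dispersal-limited drift in subsoil (S) — mirroring a
    deterministic-to-stochastic shift with depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .datamodel import CommunityTable, validate_env

REGIMES = (
    "homogeneous_selection",
    "variable_selection",
    "dispersal_limitation",
    "neutral_drift",
    "mixed",
)

#: Depth-layer multipliers applied to nutrient stocks (SOC, TN, TP, TC, AN):
#: topsoil / middle / subsoil.
LAYER_NUTRIENT_MULTIPLIERS = {"T": 1.0, "M": 0.6, "S": 0.35}


@dataclass
class SimConfig:
    """Configuration of one synthetic dataset."""

    n_taxa: int = 2000
    n_sites: int = 66
    n_layers: int = 3
    reads_per_sample: int = 16611
    regime: str = "mixed"
    sigma: float = 0.3          # niche breadth (selection strength = 1/sigma)
    migration: float = 0.1      # Sloan immigration probability m
    phylo_signal: float = 1.0   # Brownian rate of niche-optimum evolution
    spatial_extent: float = 450.0  # north-south extent of the site transect, km
    within_noise: float = 3.0   # lognormal sd of per-sample clade-level drift
    immigration_frac: float = 0.05  # mass-effect read fraction from the raw pool
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}; one of {REGIMES}")
        if not (0 < self.migration <= 1):
            raise ValueError("migration m must lie in (0, 1]")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        for name in ("n_taxa", "n_sites", "n_layers", "reads_per_sample"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SimTruth:
    """Ground truth underlying a simulated dataset."""

    tree: TreeNode
    niche_optima: pd.Series          # per taxon
    env_value: pd.Series             # per sample: realized niche axis value
    coordinates: pd.DataFrame        # per sample: latitude, longitude
    regime_by_layer: dict[str, str]
    migration: float | None
    pool: pd.Series                  # metacommunity relative abundances


# ---------------------------------------------------------------------- #
# Tree and trait simulation
# ---------------------------------------------------------------------- #

def simulate_tree(n_taxa: int, seed: int) -> TreeNode:
    """Yule (pure-birth) tree on ``n_taxa`` tips, ultrametric, depth scaled to 1.

    Lineages split at unit rate; at each event a uniformly chosen extant
    lineage bifurcates. Tips are named ``t0001`` ... in birth order.
    """
    if n_taxa < 3:
        raise ValueError("n_taxa must be >= 3")
    rng = np.random.default_rng(seed)
    root = TreeNode(name=None)
    a, b = TreeNode(), TreeNode()
    root.extend([a, b])
    active = [(a, 0.0), (b, 0.0)]  # (node, birth time)
    t = 0.0
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / len(active))
        i = rng.integers(len(active))
        node, birth = active.pop(i)
        node.length = t - birth
        c1, c2 = TreeNode(), TreeNode()
        node.extend([c1, c2])
        active.extend([(c1, t), (c2, t)])
    t += rng.exponential(1.0 / len(active))
    depth = t if t > 0 else 1.0
    for k, (node, birth) in enumerate(active):
        node.length = t - birth
    for node in root.traverse(include_self=False):
        node.length /= depth
    root.length = None
    for k, tip in enumerate(root.tips()):
        tip.name = f"t{k + 1:04d}"
    return root


def simulate_niches(tree: TreeNode, phylo_signal: float, seed: int) -> pd.Series:
    """Brownian-motion niche optima on the tree, root value 0.

    Each branch adds a Normal(0, rate * length) increment, so tip values are
    jointly Gaussian with covariance equal to shared root-to-node path
    length times the rate.
    """
    rng = np.random.default_rng(seed)
    values: dict[int, float] = {id(tree): 0.0}
    for node in tree.preorder(include_self=False):
        parent_value = values[id(node.parent)]
        sd = np.sqrt(max(phylo_signal, 0.0) * (node.length or 0.0))
        values[id(node)] = parent_value + (rng.normal(0.0, sd) if sd > 0 else 0.0)
    tips = list(tree.tips())
    return pd.Series({t.name: values[id(t)] for t in tips}, name="niche_optimum")


# ---------------------------------------------------------------------- #
# Environment simulation
# ---------------------------------------------------------------------- #

def _simulate_environment(cfg: SimConfig, rng: np.random.Generator):
    """Site coordinates on a south-north transect plus depth-resolved soil data.

    MAP declines from ~600 mm in the south to ~150 mm in the north (as a
    linear gradient with noise); grassland type follows the gradient
    (AM wettest .. GD driest); nutrients decline with depth by the layer
    multipliers; remaining soil variables are weakly structured noise.
    """
    lat0, km_per_deg = 35.2, 111.0
    lats = np.sort(lat0 + rng.uniform(0, cfg.spatial_extent / km_per_deg, cfg.n_sites))
    lons = 104.3 + rng.uniform(0, 3.0, cfg.n_sites)
    frac = (lats - lats.min()) / max(lats.max() - lats.min(), 1e-9)
    map_site = 600.0 - 450.0 * frac + rng.normal(0, 20, cfg.n_sites)
    map_site = np.clip(map_site, 50.0, None)
    mat_site = 5.0 + 4.0 * frac + rng.normal(0, 0.5, cfg.n_sites)
    gtypes = np.array(["AM", "TG", "DG", "GD"])[
        np.minimum((frac * 4).astype(int), 3)
    ]
    layers = ["T", "M", "S"][: cfg.n_layers] or ["T"]

    rows = []
    for s in range(cfg.n_sites):
        # site-level nutrient baselines scale with moisture
        soc0 = 8.0 + 14.0 * (map_site[s] / 600.0) + rng.normal(0, 1.0)
        tn0 = soc0 / 11.0 + rng.normal(0, 0.05)
        tp0 = 0.6 + rng.normal(0, 0.05)
        for layer in layers:
            mult = LAYER_NUTRIENT_MULTIPLIERS.get(layer, 1.0)
            rows.append({
                "sample": f"S{s + 1:03d}_{layer}",
                "site": f"S{s + 1:03d}",
                "layer": layer,
                "grassland": gtypes[s],
                "latitude": lats[s],
                "longitude": lons[s],
                "MAP": map_site[s],
                "MAT": mat_site[s],
                "SWC": np.clip(5 + 25 * map_site[s] / 600.0 * mult
                               + rng.normal(0, 2), 1, 60),
                "pH": np.clip(8.6 - 1.5 * map_site[s] / 600.0 + rng.normal(0, 0.15),
                              4.5, 10.5),
                "SOC": max(soc0 * mult + rng.normal(0, 0.5), 0.1),
                "TN": max(tn0 * mult + rng.normal(0, 0.03), 0.01),
                "TP": max(tp0 * mult + rng.normal(0, 0.03), 0.01),
                "TC": max(soc0 * 1.4 * mult + rng.normal(0, 0.8), 0.1),
                "AN": max(60 * tn0 * mult + rng.normal(0, 3), 0.5),
                "AP": max(5 + rng.normal(0, 1), 0.1),
                "AK": max(150 * mult ** 0.5 + rng.normal(0, 15), 1.0),
                "BD": np.clip(1.15 + 0.25 * (1 - mult) + rng.normal(0, 0.05),
                              0.8, 1.9),
                "EC": max(120 + 250 * frac[s] + rng.normal(0, 30), 5.0),
            })
    env = pd.DataFrame(rows).set_index("sample")
    metadata = env[["site", "layer", "grassland"]].copy()
    env = env.drop(columns=["site", "layer", "grassland"])
    return validate_env(env), metadata


# ---------------------------------------------------------------------- #
# Community assembly
# ---------------------------------------------------------------------- #

def _selection_weights(pool, optima, e_star, sigma):
    w = pool * np.exp(-((optima - e_star) ** 2) / (2.0 * sigma ** 2))
    total = w.sum()
    if total <= 0:  # kernel underflow: fall back to nearest-optimum taxon
        w = np.where(np.abs(optima - e_star) == np.abs(optima - e_star).min(), pool, 0)
        total = w.sum()
    return w / total


def _selection_sample_weights(pool, opt, clades, e_star, sigma, tau,
                              immigration_frac, rng, clade_tau=0.0):
    """Per-sample taxon weights under niche selection with clade-level drift.

    Selection acts on shallow clades (ecologically coherent units under the
    Brownian niche model): a clade's weight is its pooled abundance times
    the Gaussian kernel at the clade's mean optimum. Which member dominates
    a clade varies sample-to-sample (lognormal drift of sd ``tau``), so
    turnover between samples happens among close relatives while the clade
    profile — the phylogenetic footprint — is held by selection. A small
    ``immigration_frac`` of mass-effect immigrants from the raw pool keeps
    phylogenetically scattered transients in the observed pool. Under weak
    selection the clade profile itself drifts too (``clade_tau`` > 0),
    eroding the phylogenetic clustering signature.
    """
    n_clades = clades.max() + 1
    clade_pool = np.bincount(clades, weights=pool, minlength=n_clades)
    clade_opt = np.bincount(clades, weights=pool * opt,
                            minlength=n_clades) / np.maximum(clade_pool, 1e-300)
    v = clade_pool * np.exp(-((clade_opt - e_star) ** 2) / (2.0 * sigma ** 2))
    if v.sum() <= 0:
        v = np.where(np.abs(clade_opt - e_star)
                     == np.abs(clade_opt - e_star).min(), clade_pool, 0.0)
    if clade_tau > 0:
        v = v * np.exp(rng.normal(0.0, clade_tau, n_clades))
    v = v / v.sum()
    u = pool * np.exp(rng.normal(0.0, tau, len(pool)))
    within = u / np.maximum(np.bincount(clades, weights=u,
                                        minlength=n_clades)[clades], 1e-300)
    w = v[clades] * within
    w = w / w.sum()
    return (1 - immigration_frac) * w + immigration_frac * pool


def _neutral_stationary_sample(pool_p, n_reads, m, rng):
    """Draw one local community from the neutral stationary distribution.

    In the Sloan diffusion limit, a neutral local community of J
    individuals receiving immigrants from a metacommunity with relative
    abundances ``pool_p`` at per-birth immigration probability m has
    stationary frequencies x ~ Dirichlet(J * m * pool_p); the sampled
    community is Multinomial(J, x). Sampling the stationary law directly
    is exact and O(taxa) — no generation-by-generation dynamics are
    needed. m = 1 reduces to an iid multinomial draw from the
    metacommunity.
    """
    if m >= 1.0 - 1e-12:
        return rng.multinomial(n_reads, pool_p)
    conc = m * n_reads
    g = rng.gamma(np.maximum(conc * pool_p, 1e-12))
    total = g.sum()
    if total <= 0:  # extreme underflow: fall back to the single largest alpha
        g = (pool_p == pool_p.max()).astype(float)
        total = g.sum()
    return rng.multinomial(n_reads, g / total)


def _spatial_fields(coords_km, n_taxa, length_scale, rng):
    """Spatially autocorrelated Gaussian fields (sites x taxa), exp kernel."""
    d = np.sqrt(((coords_km[:, None, :] - coords_km[None, :, :]) ** 2).sum(-1))
    cov = np.exp(-d / length_scale) + 1e-8 * np.eye(len(coords_km))
    chol = np.linalg.cholesky(cov)
    return chol @ rng.standard_normal((len(coords_km), n_taxa))


def simulate_dataset(cfg: SimConfig):
    """Generate one dataset: (CommunityTable, PhyloTree, EnvTable, SimTruth)."""
    ss = np.random.SeedSequence(cfg.seed).spawn(4)
    tree = simulate_tree(cfg.n_taxa, ss[0])
    optima = simulate_niches(tree, cfg.phylo_signal, ss[1])
    rng_env = np.random.default_rng(ss[2])
    env, metadata = _simulate_environment(cfg, rng_env)
    rng = np.random.default_rng(ss[3])

    taxa = list(optima.index)
    opt = optima.to_numpy()
    pool = rng.lognormal(0.0, 1.5, cfg.n_taxa)
    pool /= pool.sum()
    clades = _cut_clades(tree, taxa, 0.8)  # shallow, niche-coherent units

    # niche axis: standardized MAP per sample (site-level, shared by layers)
    zmap = (env["MAP"] - env["MAP"].mean()) / env["MAP"].std()
    opt_scale = np.std(opt) if np.std(opt) > 0 else 1.0

    samples = list(env.index)
    layers = metadata["layer"]
    coords_km = np.column_stack([
        env["latitude"].to_numpy() * 111.0,
        env["longitude"].to_numpy() * 88.0,  # ~cos(37 deg) * 111
    ])

    regime_by_layer: dict[str, str] = {}
    sigma_by_layer: dict[str, float] = {}
    clade_tau_by_layer: dict[str, float] = {}
    if cfg.regime == "mixed":
        avail = ["T", "M", "S"][: cfg.n_layers]
        for i, lay in enumerate(avail):
            if i == 0:
                regime_by_layer[lay] = "homogeneous_selection"
                sigma_by_layer[lay] = cfg.sigma
                clade_tau_by_layer[lay] = 0.0
            elif i == 1:
                # weakened selection: wider niche kernel and a drifting
                # clade profile (selection no longer pins clade weights)
                regime_by_layer[lay] = "homogeneous_selection"
                sigma_by_layer[lay] = cfg.sigma * 6.0
                clade_tau_by_layer[lay] = 1.5
            else:
                regime_by_layer[lay] = "dispersal_limitation"
                sigma_by_layer[lay] = np.inf
                clade_tau_by_layer[lay] = 0.0
    else:
        for lay in set(layers):
            regime_by_layer[lay] = cfg.regime
            sigma_by_layer[lay] = cfg.sigma
            clade_tau_by_layer[lay] = 0.0

    # pre-compute spatially autocorrelated local pools where needed
    needs_spatial = any(r == "dispersal_limitation" for r in regime_by_layer.values())
    local_pools = None
    if needs_spatial:
        fields = _spatial_fields(coords_km, cfg.n_taxa,
                                 max(cfg.spatial_extent / 6.0, 1.0), rng)
        lp = pool[None, :] * np.exp(1.5 * fields)
        local_pools = lp / lp.sum(axis=1, keepdims=True)

    counts = np.zeros((len(samples), cfg.n_taxa), dtype=np.int64)
    env_value = pd.Series(0.0, index=samples, name="env_value")
    for i, sid in enumerate(samples):
        lay = layers.loc[sid]
        regime = regime_by_layer[lay]
        sigma = sigma_by_layer[lay] * opt_scale
        if regime == "homogeneous_selection":
            e_star = 0.0
            w = _selection_sample_weights(pool, opt, clades, e_star, sigma,
                                          cfg.within_noise,
                                          cfg.immigration_frac, rng,
                                          clade_tau=clade_tau_by_layer[lay])
            counts[i] = rng.multinomial(cfg.reads_per_sample, w / w.sum())
            env_value.iloc[i] = e_star
        elif regime == "variable_selection":
            e_star = float(zmap.loc[sid]) * opt_scale * 2.0
            w = _selection_sample_weights(pool, opt, clades, e_star, sigma,
                                          cfg.within_noise,
                                          cfg.immigration_frac, rng)
            counts[i] = rng.multinomial(cfg.reads_per_sample, w / w.sum())
            env_value.iloc[i] = e_star
        elif regime == "neutral_drift":
            counts[i] = _neutral_stationary_sample(pool, cfg.reads_per_sample,
                                                   cfg.migration, rng)
        elif regime == "dispersal_limitation":
            # low immigration from a spatially autocorrelated local pool
            counts[i] = _neutral_stationary_sample(
                local_pools[i], cfg.reads_per_sample,
                min(cfg.migration, 0.05), rng)
        else:  # pragma: no cover - guarded in SimConfig
            raise ValueError(f"unknown regime {regime!r}")

    counts_df = pd.DataFrame(counts, index=samples, columns=taxa)
    # coarse taxonomy: phylum by deep clade, genus by shallow clade
    taxonomy = _clade_taxonomy(tree, taxa)
    table = CommunityTable(counts_df, metadata, taxonomy)
    truth = SimTruth(
        tree=tree,
        niche_optima=optima,
        env_value=env_value,
        coordinates=env[["latitude", "longitude"]].copy(),
        regime_by_layer=regime_by_layer,
        migration=cfg.migration,
        pool=pd.Series(pool, index=taxa, name="pool"),
    )
    return table, tree, env, truth


def _cut_clades(tree: TreeNode, taxa: list[str], threshold: float
                ) -> np.ndarray:
    """Group tips into clades by cutting the (ultrametric) tree at a depth.

    Returns integer clade ids aligned with ``taxa``; a tip whose entire
    path is shallower than the threshold forms its own clade.
    """
    depth = {id(tree): 0.0}
    for node in tree.preorder(include_self=False):
        depth[id(node)] = depth[id(node.parent)] + (node.length or 0.0)
    groups: dict[str, int] = {}
    gid = 0
    assigned: set[int] = set()
    for node in tree.preorder(include_self=False):
        if id(node) in assigned:
            continue
        parent_d = depth[id(node.parent)]
        if parent_d <= threshold < depth[id(node)] or (
            node.is_tip() and depth[id(node)] <= threshold
        ):
            members = [node.name] if node.is_tip() else [
                t.name for t in node.tips()
            ]
            for mname in members:
                groups[mname] = gid
            gid += 1
            for sub in node.traverse(include_self=True):
                assigned.add(id(sub))
    return np.array([groups[t] for t in taxa], dtype=np.int64)


def _clade_taxonomy(tree: TreeNode, taxa: list[str]) -> pd.DataFrame:
    """Assign a coarse taxonomy by cutting the ultrametric tree at two depths.

    Tips in the same deep clade share a phylum; tips in the same shallow
    clade share a genus. Gives network construction realistic rank structure.
    """
    phyla = _cut_clades(tree, taxa, 0.25)
    genera = _cut_clades(tree, taxa, 0.75)
    return pd.DataFrame({
        "phylum": [f"p{p + 1:03d}" for p in phyla],
        "genus": [f"g{g + 1:04d}" for g in genera],
    }, index=pd.Index(taxa, name="taxon"))
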