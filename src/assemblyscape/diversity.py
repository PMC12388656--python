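"""Alpha diversity, beta diversity, ordination and permutation tests.

Alpha metrics follow the usual community-ecology definitions: observed
richness, bias-corrected Chao1, Shannon entropy in nats, Pielou evenness,
Good's coverage and Faith's phylogenetic diversity. Beta diversity supports
Bray-Curtis (taxonomic) and normalized weighted UniFrac (phylogenetic).
Group-structure tests are ANOSIM and PERMANOVA with label permutations.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform
from scipy.stats import rankdata
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity
from skbio.diversity.alpha import faith_pd
from sklearn.manifold import MDS

from .datamodel import CommunityTable, as_distance_matrix


def alpha_diversity(table: CommunityTable, tree: TreeNode | None = None
                    ) -> pd.DataFrame:
    """Per-sample alpha diversity.

    Columns: ``Sobs``, ``Chao1`` (bias-corrected), ``Shannon`` (nats),
    ``Pielou``, ``Goods_coverage`` and, when a tree is given, ``Faith_PD``
    (total branch length of the subtree spanning the present taxa and the
    root).
    """
    counts = table.counts.to_numpy()
    if (counts.sum(axis=1) == 0).any():
        bad = table.counts.index[counts.sum(axis=1) == 0][0]
        raise ValueError(f"sample {bad!r} has zero total count")
    records = []
    for i, sid in enumerate(table.samples):
        x = counts[i]
        present = x[x > 0]
        n = present.sum()
        sobs = len(present)
        f1 = int((present == 1).sum())
        f2 = int((present == 2).sum())
        chao1 = sobs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
        p = present / n
        shannon = float(-(p * np.log(p)).sum())
        pielou = shannon / np.log(sobs) if sobs > 1 else np.nan
        goods = 1.0 - f1 / n
        rec = {"Sobs": sobs, "Chao1": chao1, "Shannon": shannon,
               "Pielou": pielou, "Goods_coverage": goods}
        if tree is not None:
            rec["Faith_PD"] = faith_pd(x, table.taxa, tree)
        records.append(rec)
    return pd.DataFrame(records, index=pd.Index(table.samples, name="sample"))


def beta_matrix(table: CommunityTable, metric: str = "bray_curtis",
                tree: TreeNode | None = None) -> DistanceMatrix:
    """Pairwise sample dissimilarity under Bray-Curtis or weighted UniFrac.

    Weighted UniFrac is the normalized variant (values in [0, 1]),
    computed on relative abundances.
    """
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    counts = table.counts.to_numpy()
    if metric == "bray_curtis":
        return beta_diversity("braycurtis", counts, ids=table.samples)
    if metric == "weighted_unifrac":
        if tree is None:
            raise ValueError("weighted UniFrac requires a tree")
        tips = {t.name for t in tree.tips()}
        missing = [t for t in table.taxa if t not in tips]
        if missing:
            raise ValueError(f"taxa missing from tree: {missing[:5]}")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return beta_diversity(
                "weighted_unifrac", counts, ids=table.samples,
                taxa=table.taxa, tree=tree, normalized=True,
            )
    raise ValueError(f"unknown metric {metric!r}")


def nmds(dm: DistanceMatrix, k: int = 2, n_starts: int = 4,
         seed: int = 0, max_iter: int = 300):
    """Non-metric MDS by SMACOF majorization with isotonic regression.

    Returns ``(coordinates DataFrame, stress)`` where stress is Kruskal's
    stress-1 of the best of ``n_starts`` random initializations.
    """
    n = dm.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than n_samples={n}")
    model = MDS(n_components=k, metric=False, n_init=n_starts,
                max_iter=max_iter, random_state=seed,
                dissimilarity="precomputed", normalized_stress=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        coords = model.fit_transform(dm.data)
    cols = [f"NMDS{i + 1}" for i in range(k)]
    return (pd.DataFrame(coords, index=list(dm.ids), columns=cols),
            float(model.stress_))


def _group_masks(dm: DistanceMatrix, groups) -> tuple[np.ndarray, np.ndarray]:
    groups = pd.Series(groups)
    if not set(groups.index) >= set(dm.ids):
        # positional grouping
        g = np.asarray(groups)
    else:
        g = groups.loc[list(dm.ids)].to_numpy()
    counts = pd.Series(g).value_counts()
    if (counts >= 2).sum() < 2:
        raise ValueError("need >= 2 groups with >= 2 members")
    singletons = counts[counts < 2].index.tolist()
    if singletons:
        warnings.warn(f"groups with a single member excluded: {singletons}")
    return g, np.isin(g, counts[counts >= 2].index)


def anosim(dm: DistanceMatrix, groups, n_perm: int = 999, seed: int = 0):
    """ANOSIM R statistic and permutation p-value.

    R = (mean between-group rank - mean within-group rank) / (M / 2) with
    M = n(n-1)/2 pairwise distances, ranked with midranks for ties. The
    p-value permutes group labels; the observed statistic is included in
    the null (p >= 1/(n_perm+1)).
    """
    g, keep = _group_masks(dm, groups)
    ids = np.asarray(dm.ids)[keep]
    d = dm.filter(ids).condensed_form()
    g = g[keep]
    n = len(g)
    ranks = rankdata(d)
    m = n * (n - 1) / 2
    i_idx, j_idx = np.triu_indices(n, k=1)

    def stat(labels):
        within = labels[i_idx] == labels[j_idx]
        if within.all() or not within.any():
            return np.nan
        return (ranks[~within].mean() - ranks[within].mean()) / (m / 2.0)

    r_obs = stat(g)
    if np.isnan(r_obs) or np.all(d == d[0]):
        warnings.warn("degenerate distances/groups; ANOSIM R set to 0")
        return 0.0, 1.0
    rng = np.random.default_rng(seed)
    count = 1
    for _ in range(n_perm):
        r = stat(rng.permutation(g))
        if not np.isnan(r) and r >= r_obs - 1e-12:
            count += 1
    return float(r_obs), count / (n_perm + 1)


def permanova(dm: DistanceMatrix, groups, n_perm: int = 999, seed: int = 0):
    """PERMANOVA pseudo-F, R^2 and permutation p-value.

    SS_total = sum of squared distances / n; SS_within pools, for each
    group, the squared within-group distances divided by the group size;
    pseudo-F = (SS_between/(g-1)) / (SS_within/(n-g)). Labels are permuted
    for the p-value with the observed statistic included in the null.
    """
    g, keep = _group_masks(dm, groups)
    ids = np.asarray(dm.ids)[keep]
    d2 = dm.filter(ids).condensed_form() ** 2
    g = g[keep]
    n = len(g)
    uniq, g_codes = np.unique(g, return_inverse=True)
    n_groups = len(uniq)
    i_idx, j_idx = np.triu_indices(n, k=1)
    ss_total = d2.sum() / n

    def pseudo_f(codes):
        sizes = np.bincount(codes, minlength=n_groups)
        within = codes[i_idx] == codes[j_idx]
        pair_group = np.where(within, codes[i_idx], -1)
        ss_within = 0.0
        for k in range(n_groups):
            mask = pair_group == k
            if sizes[k] > 1:
                ss_within += d2[mask].sum() / sizes[k]
        ss_between = ss_total - ss_within
        if ss_within <= 0:
            return np.inf, 1.0
        f = (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))
        return f, ss_between / ss_total if ss_total > 0 else 0.0

    f_obs, r2 = pseudo_f(g_codes)
    rng = np.random.default_rng(seed)
    count = 1
    for _ in range(n_perm):
        f_perm, _ = pseudo_f(rng.permutation(g_codes))
        if f_perm >= f_obs - 1e-12:
            count += 1
    return float(f_obs), float(r2), count / (n_perm + 1)


def bray_curtis_condensed(counts: np.ndarray) -> np.ndarray:
    """Condensed Bray-Curtis distances for a dense count matrix (helper)."""
    from scipy.spatial.distance import pdist
    return pdist(counts, metric="braycurtis")
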