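"""Null-model inference of community assembly processes.

The framework classifies each pair of communities into one of five
ecological processes by combining two null-model statistics:

* **βMNTD / βNTI** — the abundance-weighted mean phylogenetic distance from
  each taxon to its nearest relative in the paired community, compared to a
  null in which taxon labels are shuffled across the tips of the phylogeny.
  The z-score (βNTI) below -2 indicates homogeneous selection; above +2,
  variable (heterogeneous) selection.
* **RC-bray** — the rank of the observed Bray-Curtis dissimilarity within a
  probabilistic null that reassembles each community preserving its
  richness and total reads, drawing occurrences in proportion to regional
  occupancy and reads in proportion to regional relative abundance,
  rescaled to [-1, 1]. Among pairs with |βNTI| < 2, RC-bray < -0.95 is
  homogeneous dispersal, RC-bray > 0.95 dispersal limitation, and
  |RC-bray| <= 0.95 drift.

Boundary values (βNTI exactly ±2, |RC| exactly 0.95) fall to the
stochastic/drift side: the inequalities are strict.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode

from .datamodel import CommunityTable, patristic_distances

PROCESSES = (
    "homogeneous_selection",
    "variable_selection",
    "homogeneous_dispersal",
    "dispersal_limitation",
    "drift",
)


@dataclass
class AssemblyResult:
    """Pairwise assembly statistics and per-group process fractions."""

    pairs: pd.DataFrame       # sample_i, sample_j, group, betaMNTD, betaNTI, RC_bray, process
    fractions: pd.DataFrame   # group x process fractions (rows sum to 1)
    n_excluded: int           # pairs dropped for undefined betaNTI


# ---------------------------------------------------------------------- #
# betaMNTD / betaNTI
# ---------------------------------------------------------------------- #

def _beta_mntd_from_distances(freq: np.ndarray, dist: np.ndarray,
                              present: list[np.ndarray]) -> np.ndarray:
    """betaMNTD for all sample pairs given taxon frequencies and distances.

    ``freq``: samples x taxa relative abundances; ``present``: per-sample
    arrays of present-taxon indices. For pair (k, l), each taxon present in
    k contributes its frequency times the distance to its nearest taxon in
    l, and vice versa; the two directions are averaged.
    """
    n_samples, n_taxa = freq.shape
    # nearest[i, l] = min distance from taxon i to any taxon present in sample l
    nearest = np.empty((n_taxa, n_samples))
    for l, idx in enumerate(present):
        nearest[:, l] = dist[:, idx].min(axis=1)
    g = freq @ nearest          # g[k, l] = sum_i freq[k,i] * nearest[i, l]
    return 0.5 * (g + g.T)


def beta_mntd(table: CommunityTable, tree: TreeNode,
              weighted: bool = True) -> pd.DataFrame:
    """Observed between-community mean nearest taxon distance (βMNTD).

    ``weighted=True`` weights each taxon by its relative abundance;
    ``weighted=False`` uses uniform weights over present taxa.
    Returned as a labelled square DataFrame (branch-length units).
    """
    counts = table.counts.to_numpy(dtype=float)
    if (counts.sum(axis=1) == 0).any():
        bad = table.counts.index[counts.sum(axis=1) == 0][0]
        raise ValueError(f"empty community {bad!r}")
    dist = patristic_distances(tree, table.taxa)
    freq, present = _frequencies(counts, weighted)
    b = _beta_mntd_from_distances(freq, dist, present)
    np.fill_diagonal(b, 0.0)
    return pd.DataFrame(b, index=table.samples, columns=table.samples)


def _frequencies(counts: np.ndarray, weighted: bool):
    present = [np.flatnonzero(row > 0) for row in counts]
    if weighted:
        freq = counts / counts.sum(axis=1, keepdims=True)
    else:
        freq = (counts > 0).astype(float)
        freq /= freq.sum(axis=1, keepdims=True)
    return freq, present


def beta_nti(table: CommunityTable, tree: TreeNode, n_null: int = 999,
             seed: int = 0, weighted: bool = True,
             return_obs: bool = False):
    """βNTI: z-score of observed βMNTD against a tip-label-shuffle null.

    Each null iteration applies one random permutation of taxon labels
    across the tree tips (equivalently, of rows/columns of the patristic
    distance matrix) — the same permutation for every sample pair — and
    recomputes βMNTD. Pairs whose null standard deviation is zero yield
    NaN with a warning (degenerate phylogenies, e.g. star trees).
    """
    if n_null < 99:
        raise ValueError("n_null must be >= 99")
    counts = table.counts.to_numpy(dtype=float)
    if (counts.sum(axis=1) == 0).any():
        raise ValueError("empty community present")
    dist = patristic_distances(tree, table.taxa)
    freq, present = _frequencies(counts, weighted)
    obs = _beta_mntd_from_distances(freq, dist, present)

    rng = np.random.default_rng(seed)
    n_taxa = dist.shape[0]
    mean = np.zeros_like(obs)
    m2 = np.zeros_like(obs)
    for it in range(n_null):
        perm = rng.permutation(n_taxa)
        null_b = _beta_mntd_from_distances(freq, dist[np.ix_(perm, perm)],
                                           present)
        delta = null_b - mean
        mean += delta / (it + 1)
        m2 += delta * (null_b - mean)
    sd = np.sqrt(m2 / (n_null - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (obs - mean) / sd
    np.fill_diagonal(z, 0.0)
    off_diag_sd = sd[np.triu_indices_from(sd, k=1)]
    if (off_diag_sd == 0).any():
        warnings.warn("null betaMNTD sd is zero for some pairs; betaNTI set "
                      "to NaN (degenerate tree or <=2 taxa)")
        z[sd == 0] = np.nan
        np.fill_diagonal(z, 0.0)
    znti = pd.DataFrame(z, index=table.samples, columns=table.samples)
    if return_obs:
        return znti, pd.DataFrame(obs, index=table.samples,
                                  columns=table.samples)
    return znti


# ---------------------------------------------------------------------- #
# RC-bray
# ---------------------------------------------------------------------- #

def rc_bray(table: CommunityTable, n_null: int = 999, seed: int = 0,
            tie_tol: float = 1e-9) -> pd.DataFrame:
    """Bray-Curtis-based Raup-Crick metric, rescaled to [-1, 1].

    For every null iteration, each sample is reassembled preserving its
    observed richness and total reads: occurring taxa are drawn without
    replacement with probability proportional to regional occupancy
    (fraction of samples containing the taxon); each drawn taxon receives
    one read and the remaining reads are allocated multinomially in
    proportion to regional relative abundance. RC for a pair is
    ``2 * ((#null < obs) + 0.5 * (#null == obs)) / n_null - 1``.
    """
    counts = table.counts.to_numpy()
    n_samples, n_taxa = counts.shape
    if n_samples < 2:
        raise ValueError("need >= 2 samples")
    richness = (counts > 0).sum(axis=1)
    totals = counts.sum(axis=1)
    occupancy = (counts > 0).mean(axis=0).astype(float)
    regional = counts.sum(axis=0).astype(float)
    pool = np.flatnonzero(regional > 0)
    if (richness > len(pool)).any():
        bad = table.counts.index[richness > len(pool)][0]
        raise ValueError(f"sample {bad!r} richness exceeds regional pool size")
    regional_p = regional / regional.sum()

    obs = pdist(counts, metric="braycurtis")
    n_pairs = len(obs)
    less = np.zeros(n_pairs)
    equal = np.zeros(n_pairs)
    rng = np.random.default_rng(seed)
    occ_w = occupancy[pool]
    reg_w = regional_p[pool]
    log_occ = np.log(occ_w)
    null_counts = np.zeros((n_samples, n_taxa), dtype=np.int64)
    for _ in range(n_null):
        for s in range(n_samples):
            k = richness[s]
            # weighted sampling without replacement via Gumbel top-k
            keys = log_occ + rng.gumbel(size=len(pool))
            chosen = pool[np.argpartition(-keys, k - 1)[:k]]
            row = np.zeros(n_taxa, dtype=np.int64)
            row[chosen] = 1
            rem = totals[s] - k
            if rem > 0:
                p = regional_p[chosen]
                row[chosen] += rng.multinomial(rem, p / p.sum())
            null_counts[s] = row
        null_d = pdist(null_counts, metric="braycurtis")
        less += null_d < obs - tie_tol
        equal += np.abs(null_d - obs) <= tie_tol
    rc = 2.0 * ((less + 0.5 * equal) / n_null) - 1.0
    mat = squareform(rc)
    return pd.DataFrame(mat, index=table.samples, columns=table.samples)


# ---------------------------------------------------------------------- #
# Process classification
# ---------------------------------------------------------------------- #

def classify_pair(bnti: float, rc: float) -> str:
    """Map one (βNTI, RC-bray) pair to its assembly process (strict thresholds)."""
    if np.isnan(bnti):
        raise ValueError("betaNTI is NaN; exclude pair before classification")
    if bnti < -2:
        return "homogeneous_selection"
    if bnti > 2:
        return "variable_selection"
    if rc < -0.95:
        return "homogeneous_dispersal"
    if rc > 0.95:
        return "dispersal_limitation"
    return "drift"


def classify_processes(betanti: pd.DataFrame, rc: pd.DataFrame,
                       groups: pd.Series | None = None) -> AssemblyResult:
    """Classify every pair and summarize process fractions per group.

    ``groups`` maps sample id to a group label (e.g. depth layer x
    grassland type); when given, only within-group pairs are classified,
    matching the convention of reporting assembly processes within habitat
    groups. Pairs with undefined (NaN) βNTI are excluded and counted.
    """
    if list(betanti.index) != list(rc.index):
        raise ValueError("betaNTI and RC matrices have mismatched labels")
    samples = list(betanti.index)
    records = []
    n_excluded = 0
    for a in range(len(samples)):
        for b in range(a + 1, len(samples)):
            si, sj = samples[a], samples[b]
            if groups is not None:
                if groups.loc[si] != groups.loc[sj]:
                    continue
                group = groups.loc[si]
            else:
                group = "all"
            z = betanti.iloc[a, b]
            r = rc.iloc[a, b]
            if np.isnan(z):
                n_excluded += 1
                continue
            records.append({
                "sample_i": si, "sample_j": sj, "group": group,
                "betaNTI": z, "RC_bray": r,
                "process": classify_pair(z, r),
            })
    pairs = pd.DataFrame(records,
                         columns=["sample_i", "sample_j", "group",
                                  "betaNTI", "RC_bray", "process"])
    if len(pairs):
        frac = (pairs.groupby("group")["process"]
                .value_counts(normalize=True)
                .unstack(fill_value=0.0)
                .reindex(columns=PROCESSES, fill_value=0.0))
    else:
        frac = pd.DataFrame(columns=PROCESSES)
    if n_excluded:
        warnings.warn(f"{n_excluded} pairs excluded (undefined betaNTI)")
    return AssemblyResult(pairs=pairs, fractions=frac, n_excluded=n_excluded)
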