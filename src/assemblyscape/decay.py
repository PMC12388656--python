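"""Distance-decay of community dissimilarity.

The decay model is the log-log regression

    ln C = alpha + beta * ln(E/G)

where C is community dissimilarity and E/G environmental or geographic
distance between a pair of samples. Significance uses a Mantel-style
permutation of one matrix's sample labels (whole rows/columns together),
never independent pair shuffling, because pairs sharing a sample are not
independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .datamodel import as_distance_matrix

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088


@dataclass
class DistanceDecayFit:
    alpha: float
    beta: float
    beta_se: float
    r2: float
    p: float
    n_pairs: int
    n_excluded: int
    predictor: str


def geographic_distance(env: pd.DataFrame) -> DistanceMatrix:
    """Great-circle (haversine) distances in km from latitude/longitude."""
    lat = env["latitude"].to_numpy()
    lon = env["longitude"].to_numpy()
    if np.any(np.abs(lat) > 90):
        raise ValueError("latitude outside [-90, 90]")
    if np.any(np.abs(lon) > 180):
        raise ValueError("longitude outside [-180, 180]")
    phi = np.radians(lat)
    lam = np.radians(lon)
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    a = (np.sin(dphi / 2) ** 2
         + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2) ** 2)
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
    return as_distance_matrix(d, env.index)


def environmental_distance(env: pd.DataFrame, variables=None,
                           standardize: bool = True) -> DistanceMatrix:
    """Euclidean distance on (z-scored) environmental variables."""
    cols = variables or [c for c in env.columns
                         if c not in ("latitude", "longitude")]
    x = env[cols].to_numpy(dtype=float)
    if standardize:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x = (x - x.mean(axis=0)) / sd
    from scipy.spatial.distance import squareform, pdist
    return as_distance_matrix(squareform(pdist(x)), env.index)


def fit_decay(community_dm: DistanceMatrix, predictor_dm: DistanceMatrix,
              n_perm: int = 999, seed: int = 0,
              predictor: str = "geographic_km",
              on_similarity: bool = False) -> DistanceDecayFit:
    """OLS of ln(dissimilarity) on ln(predictor distance) over usable pairs.

    Pairs with zero predictor distance or zero (dis)similarity are excluded
    (no pseudo-count) and counted. ``on_similarity`` regresses
    ln(1 - C) instead.
    """
    if list(community_dm.ids) != list(predictor_dm.ids):
        predictor_dm = predictor_dm.filter(community_dm.ids)
    c = community_dm.condensed_form()
    if on_similarity:
        c = 1.0 - c
    x = predictor_dm.condensed_form()
    usable = (c > 0) & (x > 0)
    n_excluded = int((~usable).sum())
    if usable.sum() < 3:
        raise ValueError("fewer than 3 usable pairs for the decay fit")
    if n_excluded:
        logger.info("distance-decay: excluded %d zero pairs", n_excluded)
    ln_c = np.log(c[usable])
    ln_x = np.log(x[usable])

    def ols_beta(yv, xv):
        xm, ym = xv.mean(), yv.mean()
        sxx = ((xv - xm) ** 2).sum()
        sxy = ((xv - xm) * (yv - ym)).sum()
        b = sxy / sxx
        return ym - b * xm, b

    alpha, beta = ols_beta(ln_c, ln_x)
    resid = ln_c - (alpha + beta * ln_x)
    sst = ((ln_c - ln_c.mean()) ** 2).sum()
    r2 = 1.0 - (resid ** 2).sum() / sst if sst > 0 else np.nan
    dof = max(len(ln_c) - 2, 1)
    beta_se = float(np.sqrt((resid ** 2).sum() / dof
                            / ((ln_x - ln_x.mean()) ** 2).sum()))

    # Mantel-style permutation of the community matrix's sample labels
    # (n_perm = 0 skips the test; note pairs sharing a sample are dependent,
    # hence whole-label permutation rather than pair shuffling)
    rng = np.random.default_rng(seed)
    n = community_dm.shape[0]
    cmat = community_dm.data.copy()
    if on_similarity:
        cmat = 1.0 - cmat
        np.fill_diagonal(cmat, 0.0)
    iu = np.triu_indices(n, k=1)
    count = 1
    for _ in range(n_perm):
        perm = rng.permutation(n)
        cp = cmat[np.ix_(perm, perm)][iu]
        ok = (cp > 0) & (x > 0)
        if ok.sum() < 3:
            continue
        _, b = ols_beta(np.log(cp[ok]), np.log(x[ok]))
        if abs(b) >= abs(beta) - 1e-15:
            count += 1
    p_val = count / (n_perm + 1) if n_perm > 0 else np.nan
    return DistanceDecayFit(alpha=float(alpha), beta=float(beta),
                            beta_se=beta_se,
                            r2=float(r2), p=p_val,
                            n_pairs=int(usable.sum()),
                            n_excluded=n_excluded, predictor=predictor)
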