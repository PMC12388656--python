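"""Sloan neutral community model fit.

The model predicts the occurrence frequency of a taxon across local
communities from its mean relative abundance in the metacommunity, under
neutral birth-death dynamics with immigration. With community size N
(reads per sample) and immigration rate m, the local relative abundance of
a taxon with metacommunity abundance p is Beta(N*m*p, N*m*(1-p))
distributed, so the probability of detecting it above the limit d = 1/N is

    f_pred(p) = 1 - BetaCDF(d; N*m*p, N*m*(1-p)).

m is estimated by least squares of observed frequencies on predicted
frequencies across taxa; the fit quality R^2 = 1 - SSE/SST may be negative
when the neutral expectation fits worse than a constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datamodel import CommunityTable


@dataclass
class NCMFit:
    m: float
    Nm: float
    R2: float
    N: float
    taxa: pd.DataFrame  # per-taxon: p, f_obs, f_pred, lower, upper, class


def _predicted_frequency(p: np.ndarray, m: float, N: float) -> np.ndarray:
    d = 1.0 / N
    a = N * m * p
    b = N * m * (1.0 - p)
    with np.errstate(invalid="ignore"):
        f = 1.0 - stats.beta.cdf(d, a, b)
    return np.where(p <= 0, 0.0, np.clip(f, 0.0, 1.0))


def fit_ncm(table: CommunityTable, N: float | None = None) -> NCMFit:
    """Fit the neutral community model to occurrence frequency vs abundance.

    ``N`` defaults to the mean sample total (reads per sample after
    rarefaction). Taxa with zero total count are dropped. The 95%
    above/within/below band uses Wilson score intervals on the predicted
    frequency at the number of samples.
    """
    counts = table.counts.to_numpy(dtype=float)
    totals = counts.sum(axis=1)
    if N is None:
        N = float(totals.mean())
    rel = counts / totals[:, None]
    p = rel.mean(axis=0)
    f_obs = (counts > 0).mean(axis=0)
    keep = p > 0
    if keep.sum() < 10:
        raise ValueError("need >= 10 taxa observed at least once")
    p, f_obs = p[keep], f_obs[keep]
    taxa_ids = np.asarray(table.taxa)[keep]
    n_samples = counts.shape[0]
    if np.all((f_obs == 0) | (f_obs == 1)):
        warnings.warn("all occurrence frequencies are 0 or 1; fit is "
                      "uninformative")

    def sse(m):
        return float(((f_obs - _predicted_frequency(p, m, N)) ** 2).sum())

    # coarse log-grid scan then bounded refinement (the SSE surface can be
    # flat in m over wide ranges when most taxa are saturated)
    grid = np.logspace(-6, 0, 61)
    losses = [sse(m) for m in grid]
    i_best = int(np.argmin(losses))
    lo = grid[max(i_best - 1, 0)]
    hi = grid[min(i_best + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(sse, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-8})
    if not res.success:
        raise RuntimeError(f"m optimization failed: {res.message}")
    m_hat = float(res.x)
    f_pred = _predicted_frequency(p, m_hat, N)
    sse_val = float(((f_obs - f_pred) ** 2).sum())
    sst = float(((f_obs - f_obs.mean()) ** 2).sum())
    r2 = 1.0 - sse_val / sst if sst > 0 else np.nan

    # 95% acceptance band: binomial quantiles of the predicted frequency
    # at the number of samples (a taxon seen in all samples stays "within"
    # whenever the prediction makes that outcome plausible)
    lower = stats.binom.ppf(0.025, n_samples, f_pred) / n_samples
    upper = stats.binom.ppf(0.975, n_samples, f_pred) / n_samples
    cls = np.where(f_obs > upper, "above",
                   np.where(f_obs < lower, "below", "within"))
    taxa = pd.DataFrame({
        "p": p, "f_obs": f_obs, "f_pred": f_pred,
        "lower": lower, "upper": upper, "class": cls,
    }, index=pd.Index(taxa_ids, name="taxon"))
    return NCMFit(m=m_hat, Nm=N * m_hat, R2=r2, N=N, taxa=taxa)
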