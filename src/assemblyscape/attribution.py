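"""Variance attribution for phylogenetic turnover.

Two complementary tools decompose pairwise βNTI variation into
environmental, spatial and biotic components:

* **MRM** — multiple regression on distance matrices: lower triangles are
  vectorized, an OLS is fit, and significance comes from jointly permuting
  the response matrix's row/column labels and refitting (the pairs are not
  independent, so ordinary OLS p-values would be anticonservative).
* **PLS-PM** — partial least squares path modeling with latent variables
  measured by indicator blocks (mode A outer estimation, centroid inner
  scheme). Path coefficients are OLS regressions of each endogenous latent
  on its predecessors; goodness of fit is
  GOF = sqrt(mean communality x mean R^2); bootstrap resampling gives
  percentile intervals for the paths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix


@dataclass
class MRMResult:
    coefficients: pd.Series       # per predictor (plus intercept)
    tstats: pd.Series
    r2: float
    p_coefficients: pd.Series     # permutation p per predictor
    p_model: float                # permutation p for the full-model R^2
    n_perm: int


@dataclass
class PathModel:
    blocks: dict
    inner: pd.DataFrame                 # predecessors (cols) -> targets (rows), 0/1
    outer_weights: dict
    loadings: dict
    scores: pd.DataFrame
    paths: pd.DataFrame                 # path coefficient matrix (target rows)
    total_effects: pd.DataFrame
    r2: pd.Series
    gof: float
    boot_ci: pd.DataFrame | None = None


# ---------------------------------------------------------------------- #
# MRM
# ---------------------------------------------------------------------- #

def _lower(values: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu]


def _as_matrix(dm) -> np.ndarray:
    if isinstance(dm, DistanceMatrix):
        return dm.data
    if isinstance(dm, pd.DataFrame):
        return dm.to_numpy(dtype=float)
    return np.asarray(dm, dtype=float)


def mrm(response_dm, predictor_dms: dict, n_perm: int = 999,
        seed: int = 0) -> MRMResult:
    """Multiple regression on distance matrices with Legendre permutations.

    ``predictor_dms`` maps predictor name to a square matrix sharing the
    response's label order. Pairs with NaN response (e.g. undefined βNTI)
    are dropped. The permutation test shuffles the response matrix's
    rows/columns jointly, recomputes the pseudo-t of each coefficient, and
    compares to the observed pseudo-t two-sidedly.
    """
    y_mat = _as_matrix(response_dm)
    names = list(predictor_dms)
    x_mats = [_as_matrix(predictor_dms[k]) for k in names]
    for x in x_mats:
        if x.shape != y_mat.shape:
            raise ValueError("all matrices must share shape/labels")
    y = _lower(y_mat)
    X = np.column_stack([np.ones_like(y)] + [_lower(x) for x in x_mats])
    ok = np.isfinite(y) & np.isfinite(X).all(axis=1)

    cond = np.linalg.cond(X[ok][:, 1:]) if X.shape[1] > 2 else 0.0
    if cond > 1e8:
        warnings.warn(f"predictor matrices nearly collinear "
                      f"(condition number {cond:.2e})")

    def fit(yv, mask):
        Xo, yo = X[mask], yv[mask]
        coef, _, _, _ = np.linalg.lstsq(Xo, yo, rcond=None)
        resid = yo - Xo @ coef
        dof = max(len(yo) - Xo.shape[1], 1)
        s2 = (resid ** 2).sum() / dof
        xtx_inv = np.linalg.pinv(Xo.T @ Xo)
        se = np.sqrt(np.clip(np.diag(xtx_inv) * s2, 1e-300, None))
        sst = ((yo - yo.mean()) ** 2).sum()
        r2 = 1 - (resid ** 2).sum() / sst if sst > 0 else 0.0
        return coef, coef / se, r2

    coef, t_obs, r2_obs = fit(y, ok)
    rng = np.random.default_rng(seed)
    n = y_mat.shape[0]
    count_t = np.ones(len(coef))
    count_r2 = 1
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = _lower(y_mat[np.ix_(perm, perm)])
        okp = np.isfinite(yp) & np.isfinite(X).all(axis=1)
        _, t_p, r2_p = fit(yp, okp)
        count_t += np.abs(t_p) >= np.abs(t_obs) - 1e-12
        count_r2 += r2_p >= r2_obs - 1e-12
    labels = ["intercept"] + names
    return MRMResult(
        coefficients=pd.Series(coef, index=labels),
        tstats=pd.Series(t_obs, index=labels),
        r2=float(r2_obs),
        p_coefficients=pd.Series(count_t / (n_perm + 1), index=labels),
        p_model=count_r2 / (n_perm + 1),
        n_perm=n_perm,
    )


# ---------------------------------------------------------------------- #
# PLS path modeling
# ---------------------------------------------------------------------- #

def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (x - x.mean(axis=0)) / sd


def pls_pm(data: pd.DataFrame, blocks: dict, inner: pd.DataFrame,
           n_boot: int = 0, seed: int = 0, max_iter: int = 300,
           tol: float = 1e-6) -> PathModel:
    """PLS path model: mode A outer estimation, centroid inner scheme.

    Parameters
    ----------
    data : DataFrame
        Observations x indicator variables (standardized internally).
    blocks : dict
        Latent name -> list of indicator column names.
    inner : DataFrame
        Square 0/1 matrix, ``inner.loc[target, source] = 1`` for a directed
        path source -> target; must be acyclic (lower-triangular in some
        ordering of the latents).
    n_boot : int
        Bootstrap resamples for percentile CIs of the path coefficients
        (0 disables).
    """
    latents = list(blocks)
    inner = inner.reindex(index=latents, columns=latents, fill_value=0)
    _check_acyclic(inner)
    X = {b: _standardize(data[cols].to_numpy(dtype=float))
         for b, cols in blocks.items()}
    model = _pls_core(X, blocks, inner, latents, max_iter, tol)
    (weights, loadings, scores, paths, r2, gof) = model
    scores_df = pd.DataFrame(scores, index=data.index if len(data.index) ==
                             next(iter(X.values())).shape[0] else None,
                             columns=latents)
    total = _total_effects(paths)
    boot_ci = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        n = len(data)
        records = {}
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            Xb = {b: _standardize(X[b][idx]) for b in blocks}
            try:
                _, _, _, pb, _, _ = _pls_core(Xb, blocks, inner, latents,
                                              max_iter, tol)
            except RuntimeError:
                continue
            for tgt in latents:
                for src in latents:
                    if inner.loc[tgt, src]:
                        records.setdefault((src, tgt), []).append(
                            pb.loc[tgt, src])
        rows = []
        for (src, tgt), vals in records.items():
            lo, hi = np.percentile(vals, [2.5, 97.5])
            rows.append({"source": src, "target": tgt,
                         "estimate": paths.loc[tgt, src],
                         "ci_low": lo, "ci_high": hi,
                         "n_boot": len(vals)})
        boot_ci = pd.DataFrame(rows)
    return PathModel(blocks=blocks, inner=inner, outer_weights=weights,
                     loadings=loadings, scores=scores_df, paths=paths,
                     total_effects=total, r2=r2, gof=gof, boot_ci=boot_ci)


def _check_acyclic(inner: pd.DataFrame) -> None:
    import networkx as nx
    g = nx.DiGraph()
    g.add_nodes_from(inner.index)
    for tgt in inner.index:
        for src in inner.columns:
            if inner.loc[tgt, src]:
                g.add_edge(src, tgt)
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("inner path matrix contains a cycle")


def _pls_core(X: dict, blocks: dict, inner: pd.DataFrame, latents, max_iter,
              tol):
    adj = (inner + inner.T).clip(upper=1)  # undirected adjacency for inner step
    n = next(iter(X.values())).shape[0]
    weights = {b: np.ones(X[b].shape[1]) / np.sqrt(X[b].shape[1])
               for b in latents}
    scores = np.column_stack([
        _norm(X[b] @ weights[b]) for b in latents])
    for it in range(max_iter):
        # inner estimation: centroid scheme
        corr = np.corrcoef(scores, rowvar=False)
        if corr.ndim == 0:
            corr = np.array([[1.0]])
        inner_scores = np.zeros_like(scores)
        for i, b in enumerate(latents):
            nbrs = [j for j, b2 in enumerate(latents) if adj.loc[b, b2]]
            if not nbrs:
                inner_scores[:, i] = scores[:, i]
                continue
            z = np.zeros(n)
            for j in nbrs:
                z += np.sign(corr[i, j] if corr[i, j] != 0 else 1.0) \
                    * scores[:, j]
            inner_scores[:, i] = _norm(z)
        # outer estimation: mode A (weights = correlations with inner score)
        max_change = 0.0
        new_scores = np.empty_like(scores)
        for i, b in enumerate(latents):
            w = X[b].T @ inner_scores[:, i] / n
            w = w / np.sqrt((w ** 2).sum())
            # orientation: positive correlation with the block's first indicator
            if (X[b][:, 0] @ (X[b] @ w)) < 0:
                w = -w
            max_change = max(max_change, np.abs(w - weights[b]).max())
            weights[b] = w
            new_scores[:, i] = _norm(X[b] @ w)
        scores = new_scores
        if max_change < tol:
            break
    else:
        raise RuntimeError(f"PLS-PM outer weights did not converge in "
                           f"{max_iter} iterations")
    loadings = {b: X[b].T @ scores[:, i] / n for i, b in enumerate(latents)}
    # path coefficients: OLS of each endogenous latent on its predecessors
    paths = pd.DataFrame(0.0, index=latents, columns=latents)
    r2 = {}
    for i, tgt in enumerate(latents):
        preds = [j for j, src in enumerate(latents) if inner.loc[tgt, src]]
        if not preds:
            continue
        Xp = scores[:, preds]
        coef, _, _, _ = np.linalg.lstsq(Xp, scores[:, i], rcond=None)
        for c, j in zip(coef, preds):
            paths.iloc[i, j] = c
        resid = scores[:, i] - Xp @ coef
        r2[tgt] = 1.0 - (resid ** 2).sum() / (scores[:, i] ** 2).sum()
    r2 = pd.Series(r2, dtype=float)
    communality = np.array([np.mean(loadings[b] ** 2) for b in latents])
    gof = float(np.sqrt(communality.mean() * r2.mean())) if len(r2) else np.nan
    return weights, loadings, scores, paths, r2, gof


def _total_effects(paths: pd.DataFrame) -> pd.DataFrame:
    """Total (direct + indirect) effects as the geometric series of paths."""
    p = paths.to_numpy()
    total = np.zeros_like(p)
    power = np.eye(len(p))
    for _ in range(len(p)):
        power = power @ p.T      # walk source -> ... -> target
        total += power.T
        if not power.any():
            break
    return pd.DataFrame(total, index=paths.index, columns=paths.columns)


def _norm(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=0)
    return (v - v.mean()) / (sd if sd > 0 else 1.0)


def taxa_association_distance(table, window: str = "correlation"
                              ) -> pd.DataFrame:
    """Biotic 'taxa association' distance between samples.

    Each sample is described by the profile of element-wise products of
    genus relative abundances with every other genus (its row of the
    sample-specific association structure); the distance between two
    samples is the Euclidean distance between their profiles. This is one
    concrete reading of an association-based biotic distance; it is
    configurable because the construction is genuinely open.
    """
    rel = table.relative_abundance().to_numpy()
    n = rel.shape[0]
    if window == "correlation":
        # leave-one-out perturbation of the genus correlation structure:
        # sample i's profile is rel_i weighted by the overall genus-genus
        # Spearman correlation matrix
        from scipy.stats import rankdata
        ranks = np.apply_along_axis(rankdata, 0, rel)
        ranks = _standardize(ranks)
        corr = ranks.T @ ranks / n
        profiles = rel @ corr
    else:
        profiles = rel
    from scipy.spatial.distance import pdist, squareform
    d = squareform(pdist(profiles))
    return pd.DataFrame(d, index=table.samples, columns=table.samples)
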