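"""Attribute βNTI variation to environment, space and biotic structure.

Per depth layer: multiple regression on distance matrices (MRM) of the
pairwise βNTI on environmental distance, geographic distance and a
taxa-association distance; then a PLS path model with environment and
space acting on turnover directly and through the biotic block.
"""

import importlib
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).parent))
cfg = importlib.import_module("00_config")

import pandas as pd

from assemblyscape import (beta_nti, environmental_distance,
                           geographic_distance, mrm, pls_pm, read_community,
                           read_env, read_tree, taxa_association_distance)

table = read_community(cfg.DATA_DIR / "counts.tsv",
                       cfg.DATA_DIR / "metadata.csv").drop_empty_taxa()
tree = read_tree(cfg.DATA_DIR / "tree.nwk")
env = read_env(cfg.DATA_DIR / "env.csv")

inner = pd.DataFrame(0, index=["environment", "space", "biotic", "turnover"],
                     columns=["environment", "space", "biotic", "turnover"])
inner.loc["biotic", ["environment", "space"]] = 1
inner.loc["turnover", ["environment", "space", "biotic"]] = 1

rows = {}
for lay in ("T", "M", "S"):
    ids = list(table.metadata.index[table.metadata["layer"] == lay])
    sub = table.subset_samples(ids).drop_empty_taxa()
    bnti = beta_nti(sub, tree, n_null=cfg.N_NULL, seed=cfg.SEED)
    env_l = env.loc[ids]
    geo = geographic_distance(env_l)
    envd = environmental_distance(env_l)
    biotic = taxa_association_distance(sub)
    res = mrm(bnti, {
        "environment": pd.DataFrame(envd.data, index=ids, columns=ids),
        "space": pd.DataFrame(geo.data, index=ids, columns=ids),
        "biotic": biotic,
    }, n_perm=cfg.N_PERM, seed=cfg.SEED)
    iu = np.triu_indices(len(ids), k=1)
    pairs = pd.DataFrame({
        "env_dist": envd.data[iu], "geo_dist": geo.data[iu],
        "biotic_dist": biotic.to_numpy()[iu],
        "betaNTI": bnti.to_numpy()[iu],
    }).dropna()
    pm = pls_pm(pairs, {"environment": ["env_dist"], "space": ["geo_dist"],
                        "biotic": ["biotic_dist"], "turnover": ["betaNTI"]},
                inner, seed=cfg.SEED)
    rows[lay] = {
        "mrm_r2": res.r2, "mrm_p_model": res.p_model,
        **{f"coef_{k}": v for k, v in res.coefficients.items()
           if k != "intercept"},
        "plspm_gof": pm.gof,
        **{f"path_{s}": pm.paths.loc["turnover", s]
           for s in ("environment", "space", "biotic")},
        "indirect_env_via_biotic": pm.total_effects.loc["turnover",
                                                        "environment"]
        - pm.paths.loc["turnover", "environment"],
    }

out = pd.DataFrame(rows).T
out.to_csv(cfg.OUT_DIR / "attribution.csv", index_label="layer")
print("attribution of betaNTI per layer:")
print(out.round(3).to_string())
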