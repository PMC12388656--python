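"""End-to-end orchestration of the depth-stratified assembly analysis.

A run proceeds: simulate (or load) -> rarefy -> alpha/beta diversity ->
ordination and group tests -> null-model assembly inference per depth
layer -> neutral-model fits per layer -> co-occurrence and
taxon-environment networks per layer -> distance-decay -> MRM and PLS-PM
attribution. Every stage writes CSV/JSON under the output directory and
is recorded, with its seed and parameters, in a JSON run manifest so a
rerun with the same config is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assembly, attribution, decay, diversity, networks, neutral
from .datamodel import CommunityTable, rarefy, read_community, read_env, read_tree
from .synthio import SimConfig, simulate_dataset

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run."""

    out_dir: str = "results/run"
    seed: int = 0
    # either simulate ...
    simulate: dict | None = None
    # ... or load from files
    counts_path: str | None = None
    metadata_path: str | None = None
    taxonomy_path: str | None = None
    tree_path: str | None = None
    env_path: str | None = None
    # stage parameters
    rarefaction_depth: int | None = None
    n_null: int = 999
    n_perm: int = 999
    rho_min: float = 0.8
    p_max_taxa: float = 0.05
    p_max_env: float = 0.01
    top_genera: int = 200
    stages: tuple = ("diversity", "assembly", "ncm", "networks", "decay",
                     "attribution")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw["stages"] = tuple(raw.get("stages", cls.stages))
        return cls(**raw)

    def validate(self) -> None:
        if self.simulate is None and self.counts_path is None:
            raise ValueError("config must either simulate or give counts_path")
        if self.simulate is None:
            needs_tree = "assembly" in self.stages or "diversity" in self.stages
            if needs_tree and self.tree_path is None:
                raise ValueError(
                    "tree_path is required for the requested stages")
            if self.metadata_path is None:
                raise ValueError("metadata_path is required")


def _config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all configured stages; return the run manifest."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(cfg.seed)
    stage_seeds = {name: int(s.generate_state(1)[0] % (2 ** 31))
                   for name, s in zip(
                       ("rarefy", "diversity", "assembly", "ncm", "networks",
                        "decay", "attribution"), ss.spawn(7))}
    manifest = {"config": asdict(cfg), "config_hash": _config_hash(cfg),
                "stage_seeds": stage_seeds, "stages": {}}

    # ---------------- inputs ---------------- #
    if cfg.simulate is not None:
        sim = SimConfig(**{**cfg.simulate, "seed": cfg.seed})
        table, tree, env, truth = simulate_dataset(sim)
        manifest["stages"]["simulate"] = {"ok": True,
                                          "regimes": truth.regime_by_layer}
    else:
        table = read_community(cfg.counts_path, cfg.metadata_path,
                               cfg.taxonomy_path)
        tree = read_tree(cfg.tree_path) if cfg.tree_path else None
        env = read_env(cfg.env_path) if cfg.env_path else None

    depth = cfg.rarefaction_depth or int(table.counts.sum(axis=1).min())
    table = rarefy(table, depth, stage_seeds["rarefy"])
    manifest["stages"]["rarefy"] = {"ok": True, "depth": depth}
    work = table.drop_empty_taxa()
    layers = sorted(work.metadata["layer"].unique())
    groups = (work.metadata["layer"].astype(str) + "/"
              + work.metadata["grassland"].astype(str))

    def _per_layer(fn):
        res = {}
        for lay in layers:
            ids = work.metadata.index[work.metadata["layer"] == lay]
            res[lay] = fn(work.subset_samples(ids).drop_empty_taxa(), lay)
        return res

    try:
        if "diversity" in cfg.stages:
            alpha = diversity.alpha_diversity(work, tree)
            alpha.to_csv(out / "alpha_diversity.csv")
            bc = diversity.beta_matrix(work, "bray_curtis")
            pd.DataFrame(bc.data, index=list(bc.ids),
                         columns=list(bc.ids)).to_csv(out / "bray_curtis.csv")
            coords, stress = diversity.nmds(bc, seed=stage_seeds["diversity"])
            coords.to_csv(out / "nmds.csv")
            r, p_anosim = diversity.anosim(bc, work.metadata["layer"],
                                           n_perm=cfg.n_perm,
                                           seed=stage_seeds["diversity"])
            f, r2, p_adonis = diversity.permanova(bc, work.metadata["layer"],
                                                  n_perm=cfg.n_perm,
                                                  seed=stage_seeds["diversity"])
            manifest["stages"]["diversity"] = {
                "ok": True, "nmds_stress": stress,
                "anosim_R": r, "anosim_p": p_anosim,
                "permanova_F": f, "permanova_R2": r2, "permanova_p": p_adonis,
            }

        if "assembly" in cfg.stages:
            bnti = assembly.beta_nti(work, tree, n_null=cfg.n_null,
                                     seed=stage_seeds["assembly"])
            rc = assembly.rc_bray(work, n_null=cfg.n_null,
                                  seed=stage_seeds["assembly"] + 1)
            result = assembly.classify_processes(bnti, rc, groups=groups)
            bnti.to_csv(out / "betaNTI.csv")
            rc.to_csv(out / "RC_bray.csv")
            result.pairs.to_csv(out / "assembly_pairs.csv", index=False)
            result.fractions.to_csv(out / "process_fractions.csv")
            manifest["stages"]["assembly"] = {
                "ok": True, "n_pairs": len(result.pairs),
                "n_excluded": result.n_excluded,
            }

        if "ncm" in cfg.stages:
            rows = {}
            for lay, fit in _per_layer(
                    lambda t, lay: neutral.fit_ncm(t)).items():
                rows[lay] = {"m": fit.m, "Nm": fit.Nm, "R2": fit.R2}
                fit.taxa.to_csv(out / f"ncm_taxa_{lay}.csv")
            pd.DataFrame(rows).T.to_csv(out / "ncm_fits.csv",
                                        index_label="layer")
            manifest["stages"]["ncm"] = {"ok": True, "fits": rows}

        if "networks" in cfg.stages and work.taxonomy is not None:
            topo = {}
            for lay in layers:
                ids = work.metadata.index[work.metadata["layer"] == lay]
                sub = work.subset_samples(ids).drop_empty_taxa()
                genus = networks.select_taxa(sub, top_n=cfg.top_genera)
                net = networks.correlation_network(
                    genus, rho_min=cfg.rho_min, p_max=cfg.p_max_taxa,
                    seed=stage_seeds["networks"])
                net.edges.to_csv(out / f"network_edges_{lay}.csv",
                                 index=False)
                topo[lay] = net.topology
                if env is not None:
                    bip = networks.taxon_env_network(
                        genus, env, rho_min=cfg.rho_min,
                        p_max=cfg.p_max_env)
                    bip.edges.to_csv(out / f"taxon_env_edges_{lay}.csv",
                                     index=False)
            pd.DataFrame(topo).T.to_csv(out / "network_topology.csv",
                                        index_label="layer")
            manifest["stages"]["networks"] = {"ok": True, "topology": topo}

        if "decay" in cfg.stages and env is not None:
            geo = decay.geographic_distance(env)
            envd = decay.environmental_distance(env)
            fits = {}
            for lay in layers:
                ids = list(work.metadata.index[work.metadata["layer"] == lay])
                sub = work.subset_samples(ids).drop_empty_taxa()
                bc_l = diversity.beta_matrix(sub, "bray_curtis")
                for name, dmx in (("geographic_km", geo),
                                  ("environmental_euclidean", envd)):
                    fit = decay.fit_decay(bc_l, dmx.filter(ids),
                                          n_perm=cfg.n_perm,
                                          seed=stage_seeds["decay"],
                                          predictor=name)
                    fits[f"{lay}/{name}"] = asdict(fit)
            pd.DataFrame(fits).T.to_csv(out / "distance_decay.csv")
            manifest["stages"]["decay"] = {"ok": True, "fits": fits}

        if "attribution" in cfg.stages and env is not None:
            attr = {}
            for lay in layers:
                ids = list(work.metadata.index[work.metadata["layer"] == lay])
                sub = work.subset_samples(ids).drop_empty_taxa()
                bnti_l = assembly.beta_nti(sub, tree, n_null=cfg.n_null,
                                           seed=stage_seeds["attribution"])
                env_l = env.loc[ids]
                geo_l = decay.geographic_distance(env_l)
                env_d = decay.environmental_distance(env_l)
                biotic = attribution.taxa_association_distance(sub)
                res = attribution.mrm(
                    bnti_l,
                    {"environment": pd.DataFrame(env_d.data, index=ids,
                                                 columns=ids),
                     "space": pd.DataFrame(geo_l.data, index=ids,
                                           columns=ids),
                     "biotic": biotic},
                    n_perm=cfg.n_perm, seed=stage_seeds["attribution"])
                attr[lay] = {
                    "mrm_r2": res.r2,
                    "mrm_p_model": res.p_model,
                    **{f"mrm_coef_{k}": v
                       for k, v in res.coefficients.items()},
                }
                # pair-level PLS-PM: betaNTI ~ env + space + biotic distances
                iu = np.triu_indices(len(ids), k=1)
                pair_df = pd.DataFrame({
                    "env_dist": env_d.data[iu],
                    "geo_dist": geo_l.data[iu],
                    "biotic_dist": biotic.to_numpy()[iu],
                    "betaNTI": bnti_l.to_numpy()[iu],
                }).dropna()
                inner = pd.DataFrame(
                    0, index=["environment", "space", "biotic", "turnover"],
                    columns=["environment", "space", "biotic", "turnover"])
                inner.loc["biotic", ["environment", "space"]] = 1
                inner.loc["turnover", ["environment", "space", "biotic"]] = 1
                pm = attribution.pls_pm(
                    pair_df,
                    blocks={"environment": ["env_dist"],
                            "space": ["geo_dist"],
                            "biotic": ["biotic_dist"],
                            "turnover": ["betaNTI"]},
                    inner=inner, seed=stage_seeds["attribution"])
                attr[lay]["plspm_gof"] = pm.gof
                for src in ("environment", "space", "biotic"):
                    attr[lay][f"path_{src}_turnover"] = \
                        pm.paths.loc["turnover", src]
            pd.DataFrame(attr).T.to_csv(out / "attribution.csv",
                                        index_label="layer")
            manifest["stages"]["attribution"] = {"ok": True, "results": attr}
    except Exception as exc:  # record the failed stage, keep prior outputs
        manifest["stages"]["failed"] = repr(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      default=str))
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
    return manifest
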