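"""Genus-level co-occurrence and taxon-environment correlation networks.

Construction follows common soil-microbiome practice: counts are collapsed
to genus, genera are restricted to phyla with mean relative abundance above
1%, the 200 most abundant genera are kept, and an edge connects two genera
when their Spearman correlation is both strong (|rho| > 0.8) and
significant (p < 0.05, t-approximation; raw p-values — no multiple-testing
correction, with an optional Benjamini-Hochberg flag). Taxon-environment
networks use the same machinery bipartitely at p < 0.01.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import CommunityTable


@dataclass
class NetworkGraph:
    graph: nx.Graph
    edges: pd.DataFrame       # source, target, rho, p, sign
    topology: dict = field(default_factory=dict)
    bipartite: bool = False


def select_taxa(table: CommunityTable, phylum_min_frac: float = 0.01,
                top_n: int = 200) -> CommunityTable:
    """Collapse to genus and keep the dominant genera of dominant phyla.

    Counts are summed within genus; genera are kept only if their phylum's
    mean relative abundance across samples exceeds ``phylum_min_frac``;
    the ``top_n`` genera by summed counts are retained, ties at the cutoff
    broken lexicographically by genus id.
    """
    if table.taxonomy is None or "genus" not in table.taxonomy.columns:
        raise ValueError("taxonomy to genus rank is required")
    tax = table.taxonomy.loc[table.taxa]
    rel = table.relative_abundance()
    phylum_mean = rel.T.groupby(tax["phylum"]).sum().T.mean(axis=0)
    keep_phyla = phylum_mean[phylum_mean > phylum_min_frac].index
    in_phyla = tax["phylum"].isin(keep_phyla)
    genus_counts = (table.counts.loc[:, in_phyla.to_numpy()]
                    .T.groupby(tax.loc[in_phyla.to_numpy(), "genus"]).sum().T)
    totals = genus_counts.sum(axis=0)
    ranked = sorted(genus_counts.columns, key=lambda g: (-totals[g], g))
    kept = ranked[:top_n]
    if len(kept) < 2:
        raise ValueError("fewer than 2 genera survive selection")
    genus_counts = genus_counts[kept]
    genus_tax = pd.DataFrame(
        {"phylum": tax.drop_duplicates("genus").set_index("genus")
         .loc[kept, "phylum"]},
        index=pd.Index(kept, name="taxon"))
    return CommunityTable(genus_counts, table.metadata.copy(), genus_tax)


def _spearman_edges(x: pd.DataFrame, y: pd.DataFrame, rho_min: float,
                    p_max: float, bh_correct: bool):
    """All significant-pair edges between columns of x and columns of y."""
    const_x = x.columns[x.nunique(axis=0) <= 1]
    const_y = y.columns[y.nunique(axis=0) <= 1]
    if len(const_x) or len(const_y):
        warnings.warn(
            f"constant vectors excluded: {list(const_x) + list(const_y)}")
        x = x.drop(columns=const_x)
        y = y.drop(columns=const_y)
    if x.shape[1] < 1 or y.shape[1] < 1:
        raise ValueError("no non-constant vectors left for correlation")
    bipartite = x is not y and not x.columns.equals(y.columns)
    rho, p = stats.spearmanr(pd.concat([x, y], axis=1).to_numpy())
    if np.ndim(rho) == 0:  # scipy collapses the 2-column case to scalars
        rho = np.array([[1.0, rho], [rho, 1.0]])
        p = np.array([[0.0, p], [p, 0.0]])
    nx_, ny_ = x.shape[1], y.shape[1]
    rho_xy = rho[:nx_, nx_:nx_ + ny_] if bipartite else rho[:nx_, :nx_]
    p_xy = p[:nx_, nx_:nx_ + ny_] if bipartite else p[:nx_, :nx_]
    rows = []
    cols_x, cols_y = list(x.columns), list(y.columns)
    if bipartite:
        it = ((i, j) for i in range(nx_) for j in range(ny_))
    else:
        it = ((i, j) for i in range(nx_) for j in range(i + 1, nx_))
    for i, j in it:
        rows.append((cols_x[i], (cols_y if bipartite else cols_x)[j],
                     rho_xy[i, j], p_xy[i, j]))
    edges = pd.DataFrame(rows, columns=["source", "target", "rho", "p"])
    if bh_correct and len(edges):
        from statsmodels.stats.multitest import multipletests
        edges["p"] = multipletests(edges["p"], method="fdr_bh")[1]
    mask = (edges["rho"].abs() > rho_min) & (edges["p"] < p_max)
    edges = edges[mask].reset_index(drop=True)
    edges["sign"] = np.where(edges["rho"] > 0, "positive", "negative")
    return edges, list(x.columns), list(y.columns)


def correlation_network(table: CommunityTable, rho_min: float = 0.8,
                        p_max: float = 0.05, bh_correct: bool = False,
                        seed: int = 0) -> NetworkGraph:
    """Genus-genus co-occurrence network on relative abundances."""
    if table.n_samples < 4:
        raise ValueError("need >= 4 samples for correlation inference")
    rel = table.relative_abundance()
    edges, cols, _ = _spearman_edges(rel, rel, rho_min, p_max, bh_correct)
    g = nx.Graph()
    mean_rel = rel.mean(axis=0)
    for c in cols:
        g.add_node(c, abundance=float(mean_rel.get(c, 0.0)))
    for _, e in edges.iterrows():
        g.add_edge(e["source"], e["target"], rho=float(e["rho"]),
                   p=float(e["p"]), sign=e["sign"])
    net = NetworkGraph(graph=g, edges=edges)
    net.topology = topology(net, seed=seed)
    return net


def taxon_env_network(table: CommunityTable, env: pd.DataFrame,
                      rho_min: float = 0.8, p_max: float = 0.01,
                      bh_correct: bool = False) -> NetworkGraph:
    """Bipartite genus-environment network (stricter default p < 0.01)."""
    env = env.loc[table.samples]
    env_num = env.select_dtypes("number").drop(
        columns=[c for c in ("latitude", "longitude") if c in env.columns])
    rel = table.relative_abundance()
    edges, genera, variables = _spearman_edges(rel, env_num, rho_min, p_max,
                                               bh_correct)
    g = nx.Graph()
    mean_rel = rel.mean(axis=0)
    for c in genera:
        g.add_node(c, kind="genus", abundance=float(mean_rel.get(c, 0.0)))
    for v in variables:
        g.add_node(v, kind="environment")
    for _, e in edges.iterrows():
        g.add_edge(e["source"], e["target"], rho=float(e["rho"]),
                   p=float(e["p"]), sign=e["sign"])
    return NetworkGraph(graph=g, edges=edges, bipartite=True)


def topology(net: NetworkGraph, seed: int = 0) -> dict:
    """Topology summary of an (unsigned) undirected network.

    Clustering is the mean local clustering coefficient over nodes of
    degree >= 2; average path length is over the largest connected
    component; modularity comes from greedy modularity maximization.
    """
    g = net.graph
    n, e = g.number_of_nodes(), g.number_of_edges()
    if n == 0 or e == 0:
        warnings.warn("empty graph; topology metrics set to 0")
        return {"n_nodes": n, "n_edges": e, "average_degree": 0.0,
                "clustering_coefficient": 0.0, "average_path_length": 0.0,
                "modularity": 0.0, "positive_edge_fraction": 0.0,
                "largest_component": 0}
    local = nx.clustering(g)
    deg2 = [v for v, d in g.degree() if d >= 2]
    clustering = float(np.mean([local[v] for v in deg2])) if deg2 else 0.0
    components = sorted(nx.connected_components(g), key=len, reverse=True)
    giant = g.subgraph(components[0])
    apl = (nx.average_shortest_path_length(giant)
           if giant.number_of_nodes() > 1 else 0.0)
    communities = nx.community.greedy_modularity_communities(g)
    q = nx.community.modularity(g, communities)
    signs = nx.get_edge_attributes(g, "sign")
    pos_frac = (np.mean([s == "positive" for s in signs.values()])
                if signs else 1.0)
    return {
        "n_nodes": n, "n_edges": e,
        "average_degree": 2.0 * e / n,
        "clustering_coefficient": clustering,
        "average_path_length": float(apl),
        "modularity": float(q),
        "positive_edge_fraction": float(pos_frac),
        "largest_component": giant.number_of_nodes(),
    }
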