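"""Core data containers and I/O for community tables, trees and environment tables.

Conventions used throughout the package:

* community tables are samples-as-rows, taxa-as-columns, non-negative integer
  counts;
* taxon and sample identifiers are opaque strings;
* distance matrices are :class:`skbio.DistanceMatrix` objects (symmetric,
  zero-diagonal, labelled);
* phylogenies are rooted :class:`skbio.TreeNode` objects with branch lengths.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

logger = logging.getLogger(__name__)

DEPTH_LAYERS = ("T", "M", "S")
GRASSLAND_TYPES = ("AM", "TG", "DG", "GD")

TAXONOMY_RANKS = ("phylum", "class", "order", "family", "genus")


class ValidationError(ValueError):
    """Raised when a table violates its structural invariants."""


@dataclass
class CommunityTable:
    """Site-by-taxon count matrix with per-sample metadata.

    Parameters
    ----------
    counts : pandas.DataFrame
        Samples (rows) by taxa (columns), non-negative integers.
    metadata : pandas.DataFrame
        Indexed by sample id; expected columns ``site``, ``layer``
        (one of ``T``/``M``/``S``) and ``grassland`` (``AM``/``TG``/``DG``/``GD``).
    taxonomy : pandas.DataFrame, optional
        Indexed by taxon id; columns are taxonomic ranks (phylum .. genus).
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame
    taxonomy: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------ #
    def validate(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            raise ValidationError("duplicated sample ids in count table")
        if c.columns.has_duplicates:
            raise ValidationError("duplicated taxon ids in count table")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                bad = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
                raise ValidationError(
                    f"non-integer count at sample {c.index[bad[0]]!r}, "
                    f"taxon {c.columns[bad[1]]!r}"
                )
            self.counts = c = c.round().astype(np.int64)
            arr = c.to_numpy()
        if (arr < 0).any():
            bad = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count at sample {c.index[bad[0]]!r}, "
                f"taxon {c.columns[bad[1]]!r}"
            )
        missing = set(self.metadata.index) - set(c.index)
        extra = set(c.index) - set(self.metadata.index)
        if missing or extra:
            raise ValidationError(
                "sample ids mismatch between counts and metadata; "
                f"metadata-only: {sorted(missing)}; counts-only: {sorted(extra)}"
            )
        # align metadata row order to the count table
        self.metadata = self.metadata.loc[c.index]
        n_empty = int((arr.sum(axis=0) == 0).sum())
        if n_empty:
            logger.info("community table retains %d all-zero taxa", n_empty)

    # ------------------------------------------------------------------ #
    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.counts.shape[1]

    def relative_abundance(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=1)
        return self.counts.div(totals, axis=0)

    def drop_empty_taxa(self) -> "CommunityTable":
        """Return a copy without all-zero taxa (used before diversity/null work)."""
        keep = self.counts.columns[self.counts.sum(axis=0) > 0]
        return CommunityTable(
            self.counts[keep].copy(),
            self.metadata.copy(),
            None if self.taxonomy is None else self.taxonomy.loc[
                self.taxonomy.index.intersection(keep)
            ].copy(),
        )

    def subset_samples(self, sample_ids) -> "CommunityTable":
        sample_ids = list(sample_ids)
        return CommunityTable(
            self.counts.loc[sample_ids].copy(),
            self.metadata.loc[sample_ids].copy(),
            None if self.taxonomy is None else self.taxonomy.copy(),
        )

    # ------------------------------------------------------------------ #
    def write(self, counts_path, metadata_path, taxonomy_path=None) -> None:
        sep = "\t" if str(counts_path).endswith((".tsv", ".txt")) else ","
        self.counts.to_csv(counts_path, sep=sep, index_label="sample")
        self.metadata.to_csv(metadata_path, index_label="sample")
        if taxonomy_path is not None and self.taxonomy is not None:
            self.taxonomy.to_csv(taxonomy_path, index_label="taxon")


def read_community(path, metadata_path, taxonomy_path=None) -> CommunityTable:
    """Read a delimited count table (samples as rows) plus CSV metadata."""
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    counts = pd.read_csv(path, sep=sep, index_col=0)
    counts.index = counts.index.astype(str)
    counts.columns = counts.columns.astype(str)
    metadata = pd.read_csv(metadata_path, index_col=0)
    metadata.index = metadata.index.astype(str)
    taxonomy = None
    if taxonomy_path is not None:
        taxonomy = pd.read_csv(taxonomy_path, index_col=0)
        taxonomy.index = taxonomy.index.astype(str)
    return CommunityTable(counts, metadata, taxonomy)


# ---------------------------------------------------------------------- #
# Phylogenetic trees
# ---------------------------------------------------------------------- #

def read_tree(path_or_str) -> TreeNode:
    """Read a rooted, branch-lengthed newick tree.

    Unrooted trees (basal polytomy of degree > 2 at small size, or an
    explicitly unrooted shape) are midpoint-rooted with a loud log message.
    Missing branch lengths are a hard error.
    """
    s = str(path_or_str)
    if s.rstrip().endswith(";") and "(" in s:
        tree = TreeNode.read([s])
    else:
        tree = TreeNode.read(s)
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise ValidationError(
                f"tree node {node.name!r} lacks a branch length"
            )
        if node.length < 0:
            raise ValidationError(f"negative branch length at {node.name!r}")
    tips = [t.name for t in tree.tips()]
    if len(tips) != len(set(tips)):
        raise ValidationError("duplicate tip labels in tree")
    if len(tree.children) > 2:
        logger.warning("input tree is unrooted (basal polytomy); midpoint rooting")
        tree = tree.root_at_midpoint()
    return tree


def prune_tree_to_table(tree: TreeNode, table: CommunityTable) -> TreeNode:
    """Prune the tree to the table's taxa; error on taxa missing from the tree."""
    tip_names = {t.name for t in tree.tips()}
    missing = [t for t in table.taxa if t not in tip_names]
    if missing:
        raise ValidationError(
            f"{len(missing)} taxa absent from tree tips, e.g. {missing[:5]}"
        )
    extra = tip_names - set(table.taxa)
    if extra:
        warnings.warn(f"pruning {len(extra)} tree tips absent from the table")
        tree = tree.shear(set(table.taxa))
        tree.prune()
    return tree


def patristic_distances(tree: TreeNode, taxa: list[str]) -> np.ndarray:
    """Dense patristic (tip-to-tip path length) matrix in the given taxon order."""
    dm = tree.tip_tip_distances()
    idx = [dm.index(t) for t in taxa]
    return dm.data[np.ix_(idx, idx)]


# ---------------------------------------------------------------------- #
# Environment tables
# ---------------------------------------------------------------------- #

ENV_VARIABLES = (
    "SWC", "pH", "SOC", "TN", "TP", "TC", "AN", "AP", "AK", "BD", "EC",
    "MAT", "MAP",
)


def validate_env(env: pd.DataFrame) -> pd.DataFrame:
    """Validate a per-sample environment table (soil + climate + coordinates)."""
    if env.index.has_duplicates:
        raise ValidationError("duplicated sample ids in environment table")
    if "pH" in env and not env["pH"].between(0, 14, inclusive="neither").all():
        raise ValidationError("pH outside (0, 14)")
    if "MAP" in env and (env["MAP"] < 0).any():
        raise ValidationError("negative MAP")
    if "latitude" in env and not env["latitude"].abs().le(90).all():
        raise ValidationError("latitude outside [-90, 90]")
    if "longitude" in env and not env["longitude"].abs().le(180).all():
        raise ValidationError("longitude outside [-180, 180]")
    return env


def read_env(path) -> pd.DataFrame:
    env = pd.read_csv(path, index_col=0)
    env.index = env.index.astype(str)
    return validate_env(env)


# ---------------------------------------------------------------------- #
# Rarefaction
# ---------------------------------------------------------------------- #

def rarefy(table: CommunityTable, depth: int, seed: int) -> CommunityTable:
    """Rarefy every sample to ``depth`` reads without replacement.

    Subsampling is a single multivariate-hypergeometric draw per sample.
    To make the result invariant to the order of taxon columns, each
    sample's draw is performed on taxa sorted by id and mapped back; child
    seeds are spawned per sample so samples are independently reproducible.
    """
    totals = table.counts.sum(axis=1)
    low = totals[totals < depth]
    if len(low):
        raise ValidationError(
            f"rarefaction depth {depth} exceeds sample total for "
            f"{low.index[0]!r} ({int(low.iloc[0])} reads)"
        )
    order = np.argsort(np.asarray(table.taxa, dtype=object))
    inverse = np.argsort(order)
    out = np.empty_like(table.counts.to_numpy())
    children = np.random.SeedSequence(seed).spawn(table.n_samples)
    for i, ss in enumerate(children):
        rng = np.random.default_rng(ss)
        row = table.counts.iloc[i].to_numpy()[order]
        drawn = rng.multivariate_hypergeometric(row, depth)
        out[i] = drawn[inverse]
    counts = pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns)
    return CommunityTable(counts, table.metadata.copy(),
                          None if table.taxonomy is None else table.taxonomy.copy())


def as_distance_matrix(values: np.ndarray, labels) -> DistanceMatrix:
    """Build a validated skbio DistanceMatrix, symmetrizing tiny asymmetries."""
    values = np.asarray(values, dtype=float)
    values = 0.5 * (values + values.T)
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(values, ids=list(labels))
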