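"""Reading, validation, normalization and harmonization of the three input files.

The tool takes (1) a taxa-by-samples abundance table (TSV, raw counts or
normalized), (2) a Newick phylogenetic tree whose tips match the table's
taxa — or, alternatively, a precomputed sample-by-sample dissimilarity
matrix — and (3) a mapping file assigning each sample to groups.  This
module parses and validates all of them, harmonizes their sample/taxon
universes, and writes every tabular output as TSV.

In-memory containers: the abundance table is a thin wrapper around a pandas
DataFrame (taxa as rows), trees are :class:`skbio.TreeNode`, distance
matrices are :class:`skbio.DistanceMatrix`, and sample metadata is a pandas
DataFrame indexed by sample id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

logger = logging.getLogger("divcom")

__all__ = [
    "DivComError",
    "ValidationError",
    "AbundanceTable",
    "read_abundance_table",
    "write_abundance_table",
    "normalize",
    "read_tree",
    "read_metadata",
    "write_metadata",
    "harmonize",
    "read_distance_matrix",
    "write_distance_matrix",
    "write_table",
]


class DivComError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(DivComError):
    """Invalid or inconsistent user input."""


def _check_unique(ids, what: str) -> None:
    seen, dups = set(), []
    for i in ids:
        if i in seen and i not in dups:
            dups.append(i)
        seen.add(i)
    if dups:
        raise ValidationError(f"duplicate {what}: {', '.join(map(str, dups))}")


@dataclass
class AbundanceTable:
    """Taxa-by-samples matrix of nonnegative counts or abundances.

    ``df`` has taxa as the index and samples as columns.  Validation happens
    on construction: unique labels, numeric nonnegative values.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.df.index, "taxon ids")
        _check_unique(self.df.columns, "sample ids")
        values = self.df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            for j, col in enumerate(self.df.columns):
                bad = pd.to_numeric(self.df[col], errors="coerce")
                if bad.isna().any():
                    row = self.df.index[int(np.argmax(bad.isna().to_numpy()))]
                    raise ValidationError(
                        f"non-numeric value at taxon {row!r}, sample {col!r}"
                    )
            self.df = self.df.astype(float)
            values = self.df.to_numpy()
        if np.isnan(values).any():
            i, j = np.argwhere(np.isnan(values))[0]
            raise ValidationError(
                f"missing value at taxon {self.df.index[i]!r}, "
                f"sample {self.df.columns[j]!r}"
            )
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative value at taxon {self.df.index[i]!r}, "
                f"sample {self.df.columns[j]!r}"
            )

    @property
    def taxon_ids(self) -> list:
        return list(self.df.index)

    @property
    def sample_ids(self) -> list:
        return list(self.df.columns)

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy(dtype=float)

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        return isinstance(other, AbundanceTable) and self.df.equals(other.df)


def read_abundance_table(path) -> AbundanceTable:
    """Read a TSV abundance table (taxa rows, sample columns).

    The first header cell is ignored; the first column holds taxon ids.
    Duplicate ids, negative or non-numeric cells are hard errors.
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    _check_unique(header[1:], "sample ids")
    df = pd.read_csv(path, sep="\t", index_col=0, encoding="utf-8")
    df.index = df.index.astype(str)
    df.columns = [str(c) for c in header[1:]]
    return AbundanceTable(df)


def write_abundance_table(table: AbundanceTable, path) -> None:
    df = table.df.copy()
    df.index.name = "#OTUId"
    df.to_csv(path, sep="\t", encoding="utf-8")


def normalize(table: AbundanceTable, target_depth="min") -> AbundanceTable:
    """Rescale every sample column to a common total.

    By default the target is the minimum observed column sum, which keeps
    values on a count-like scale; any positive constant can be given
    instead.  Relative proportions within each sample are unchanged, and
    the operation is idempotent.
    """
    sums = table.df.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValidationError(
            f"sample(s) with zero total abundance: {', '.join(map(str, zero.index))}"
        )
    if isinstance(target_depth, str):
        if target_depth != "min":
            raise ValidationError(f"unknown normalization target {target_depth!r}")
        target = float(sums.min())
    else:
        target = float(target_depth)
        if target <= 0:
            raise ValidationError("normalization target must be positive")
    return AbundanceTable(table.df * (target / sums))


def read_tree(path, default_branch_length=None) -> TreeNode:
    """Read a Newick tree; midpoint-root it when the root is not bifurcating.

    Missing branch lengths are a hard error unless ``default_branch_length``
    is given (silent zeros would distort UniFrac distances); negative
    lengths are always an error.
    """
    tree = TreeNode.read(str(path), format="newick")
    tip_names = [t.name for t in tree.tips()]
    _check_unique(tip_names, "tree tip labels")
    for node in tree.postorder(include_self=False):
        if node.length is None:
            if default_branch_length is None:
                name = node.name or "internal node"
                raise ValidationError(f"missing branch length above {name}")
            node.length = float(default_branch_length)
        elif node.length < 0:
            raise ValidationError(
                f"negative branch length above {node.name or 'internal node'}"
            )
    if len(tree.children) > 2:
        logger.warning("input tree is unrooted; applying midpoint rooting")
        tree = tree.root_at_midpoint()
    return tree


def read_metadata(path) -> pd.DataFrame:
    """Read the mapping file: first column sample id, remaining categorical."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, encoding="utf-8")
    df.index = df.index.astype(str)
    _check_unique(df.index, "mapping sample ids")
    return df


def write_metadata(metadata: pd.DataFrame, path) -> None:
    out = metadata.copy()
    out.index.name = out.index.name or "#SampleId"
    out.to_csv(path, sep="\t", encoding="utf-8")


def harmonize(
    table: AbundanceTable,
    tree: TreeNode | None,
    metadata: pd.DataFrame,
    drop_missing_taxa: bool = False,
):
    """Restrict all inputs to a common sample set and matching taxa.

    Samples are intersected between table columns and mapping rows (dropped
    ids are logged).  The tree is pruned to the table's taxa; taxa missing
    from the tree are a hard error unless ``drop_missing_taxa`` asks for
    them to be removed from the table instead.  Returned objects share an
    identical sample ordering (the table's column order).
    """
    meta_ids = set(metadata.index)
    shared = [s for s in table.sample_ids if s in meta_ids]
    if not shared:
        raise ValidationError("no samples shared between table and mapping file")
    dropped = sorted(set(table.sample_ids).symmetric_difference(meta_ids))
    if dropped:
        logger.warning(
            "dropping samples absent from table or mapping: %s", ", ".join(dropped)
        )
    df = table.df[shared]
    if tree is not None:
        tips = {t.name for t in tree.tips()}
        missing = [t for t in df.index if t not in tips]
        if missing:
            if not drop_missing_taxa:
                raise ValidationError(
                    "taxa absent from the tree: " + ", ".join(map(str, missing))
                )
            logger.warning(
                "dropping taxa absent from the tree: %s", ", ".join(map(str, missing))
            )
            df = df.drop(index=missing)
        extra = tips.difference(df.index)
        if extra:
            tree = tree.shear(list(df.index))
    empty = df.columns[(df.sum(axis=0) <= 0).to_numpy()]
    if len(empty):
        raise ValidationError(
            "sample(s) left with zero total abundance after harmonization: "
            + ", ".join(map(str, empty))
        )
    out_table = AbundanceTable(df)
    out_meta = metadata.loc[shared]
    return out_table, tree, out_meta


def read_distance_matrix(path) -> DistanceMatrix:
    """Read a labeled square TSV dissimilarity matrix.

    Row and column labels must match.  Asymmetry up to 1e-8 is symmetrized
    by averaging (with a warning); larger asymmetry and any nonzero
    diagonal are hard errors.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, encoding="utf-8")
    df.index = df.index.astype(str)
    df.columns = [str(c) for c in df.columns]
    if list(df.index) != list(df.columns):
        raise ValidationError("distance matrix row and column labels differ")
    _check_unique(df.index, "distance matrix sample ids")
    values = df.to_numpy(dtype=float)
    if np.diag(values).any():
        raise ValidationError("distance matrix diagonal must be exactly zero")
    asym = np.abs(values - values.T).max()
    if asym > 1e-8:
        raise ValidationError(f"distance matrix asymmetric (max deviation {asym:g})")
    if asym > 0:
        logger.warning("symmetrizing distance matrix (max asymmetry %g)", asym)
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 0.0)
    if (values < 0).any():
        raise ValidationError("distance matrix contains negative entries")
    return DistanceMatrix(values, ids=list(df.index))


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    df = pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))
    df.index.name = ""
    df.to_csv(path, sep="\t", encoding="utf-8")


def write_table(obj, path) -> None:
    """Write any supported tabular object as TSV."""
    if isinstance(obj, AbundanceTable):
        write_abundance_table(obj, path)
    elif isinstance(obj, DistanceMatrix):
        write_distance_matrix(obj, path)
    elif isinstance(obj, pd.DataFrame):
        obj.to_csv(path, sep="\t", encoding="utf-8")
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
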