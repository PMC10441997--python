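"""Reading, writing and hygiene of the pipeline's tabular and tree inputs.

The central in-memory container is a plain :class:`pandas.DataFrame` of
non-negative integer counts with taxa (ASVs) as the index and samples as the
columns.  Every downstream stage accepts tables in this orientation;
:func:`validate_asv_table` enforces the contract once at the boundary.

Trees are :class:`dendropy.Tree` objects read from Newick with branch
lengths; sample metadata is a ``sample_id -> group`` mapping held as a
:class:`pandas.Series`.
"""

from __future__ import annotations

import logging
from typing import Iterable

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "validate_asv_table",
    "read_asv_table",
    "write_asv_table",
    "read_metadata",
    "rarefy",
    "to_relative_abundance",
    "read_tree",
    "write_tree",
]

# serialization precision for all TSV writers
_FLOAT_FMT = "%.10g"


def validate_asv_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the count-table contract and return the table unchanged.

    Raises ``ValueError`` naming the offending identifier or cell when the
    table has duplicate identifiers, negative or non-integral counts, or
    fewer than 2 taxa / 2 samples.
    """
    if table.index.duplicated().any():
        dup = table.index[table.index.duplicated()][0]
        raise ValueError(f"duplicate taxon identifier: {dup!r}")
    if table.columns.duplicated().any():
        dup = table.columns[table.columns.duplicated()][0]
        raise ValueError(f"duplicate sample identifier: {dup!r}")
    values = table.to_numpy()
    if values.size == 0 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError(
            f"ASV table must have at least 2 taxa and 2 samples, got shape {table.shape}"
        )
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("ASV table contains non-numeric values")
    bad = ~np.isfinite(values) | (values < 0) | (values != np.floor(values))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"invalid count at taxon {table.index[i]!r}, sample {table.columns[j]!r}: "
            f"{values[i, j]!r} (counts must be non-negative integers)"
        )
    return table


def read_asv_table(path, orientation: str = "taxa_rows") -> pd.DataFrame:
    """Read a tab-separated count table into taxa x samples orientation.

    Parameters
    ----------
    path : str or pathlib.Path
        TSV file whose first column holds row identifiers and first row the
        column identifiers.
    orientation : {"taxa_rows", "samples_rows"}
        Which axis of the *file* holds taxa; the returned table always has
        taxa as rows.
    """
    if orientation not in ("taxa_rows", "samples_rows"):
        raise ValueError(f"unknown orientation: {orientation!r}")
    # pandas mangles duplicate header names, so check them verbatim first
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen: set[str] = set()
    for name in header:
        if name in seen:
            raise ValueError(f"duplicate identifier in header: {name!r}")
        seen.add(name)
    raw = pd.read_csv(path, sep="\t", header=0, index_col=0)
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    if orientation == "samples_rows":
        raw = raw.T
    table = validate_asv_table(raw)
    return table.astype(np.int64)


def write_asv_table(table: pd.DataFrame, path) -> None:
    """Write a taxa x samples count table as TSV (UTF-8)."""
    validate_asv_table(table)
    table.to_csv(path, sep="\t", encoding="utf-8")


def read_metadata(path) -> pd.Series:
    """Read a sample metadata TSV with columns ``sample_id`` and ``group``.

    Returns a Series indexed by sample_id.  Duplicate sample ids are an
    error: each sample must carry exactly one group label.
    """
    meta = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in meta.columns:
            raise ValueError(f"metadata file lacks required column {col!r}")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id in metadata: {dup!r}")
    return meta.set_index("sample_id")["group"]


def rarefy(table: pd.DataFrame, depth: int, seed: int) -> pd.DataFrame:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples whose total is below ``depth`` are dropped (and logged).  Taxa
    rows are retained even when rarefaction reduces them to zero, so the
    taxon identity set is preserved.  Deterministic given ``seed``.
    """
    validate_asv_table(table)
    if depth < 1:
        raise ValueError(f"rarefaction depth must be >= 1, got {depth}")
    rng = np.random.default_rng(seed)
    totals = table.sum(axis=0)
    keep = totals.index[totals >= depth]
    dropped = totals.index.difference(keep)
    if len(keep) == 0:
        raise ValueError(f"all samples have fewer than {depth} reads; cannot rarefy")
    if len(dropped):
        logger.warning(
            "rarefy: dropping %d sample(s) below depth %d: %s",
            len(dropped), depth, list(dropped),
        )
    out = {}
    counts = table.to_numpy()
    col_of = {s: k for k, s in enumerate(table.columns)}
    for sample in keep:
        col = counts[:, col_of[sample]]
        total = int(col.sum())
        if total == depth:
            out[sample] = col.copy()
            continue
        # multivariate hypergeometric draw = sampling reads w/o replacement
        out[sample] = rng.multivariate_hypergeometric(col, depth)
    result = pd.DataFrame(out, index=table.index, dtype=np.int64)
    return result


def to_relative_abundance(table: pd.DataFrame) -> pd.DataFrame:
    """Column-normalize counts to per-sample proportions.

    Every sample must have a positive total; a zero-total sample is a hard
    error naming the sample (it should have been dropped upstream).
    """
    totals = table.sum(axis=0)
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValueError(f"sample {zero[0]!r} has zero total count; cannot normalize")
    return table / totals


def read_tree(path, taxon_namespace: Iterable[str] | None = None) -> dendropy.Tree:
    """Read a rooted Newick tree with branch lengths.

    Every edge except the root's must carry a branch length.  When
    ``taxon_namespace`` is given, leaf labels are cross-checked against it
    and an unknown leaf raises ``ValueError``.
    """
    tree = dendropy.Tree.get(
        path=str(path), schema="newick",
        preserve_underscores=True, rooting="default-rooted",
    )
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValueError("tree has an edge without a branch length")
    if taxon_namespace is not None:
        allowed = set(taxon_namespace)
        for leaf in tree.leaf_node_iter():
            if leaf.taxon.label not in allowed:
                raise ValueError(
                    f"tree leaf {leaf.taxon.label!r} absent from the taxon table"
                )
    return tree


def write_tree(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)
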