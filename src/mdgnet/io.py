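"""Readers and writers for the pipeline's plain-text formats.

Expression matrices are genes-as-rows TSV files with a header row of
sample ids and the gene id in the first column. Sample-to-cohort maps
are two-column TSV files. Gene sets use the GMT dialect (term name,
description, then tab-separated gene ids, one term per line).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .enrichment import GeneSetCollection

__all__ = [
    "read_expression",
    "read_expression_pair",
    "write_expression",
    "read_groups",
    "read_gmt",
    "write_gmt",
]


class FormatError(ValueError):
    """A file violates its expected dialect."""


def _read_matrix(path) -> pd.DataFrame:
    matrix = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    matrix.index = matrix.index.astype(str)
    matrix.index.name = "gene_id"
    if matrix.index.duplicated().any():
        dupes = matrix.index[matrix.index.duplicated()].unique().to_list()
        raise FormatError(f"{path}: duplicated gene ids {dupes[:5]}")
    if matrix.shape[1] == 0:
        raise FormatError(f"{path}: no sample columns")
    try:
        return matrix.astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric expression values") from exc


def read_groups(path) -> pd.Series:
    """Sample-to-cohort map from a two-column TSV (sample, group)."""
    table = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if table.shape[1] != 2:
        raise FormatError(f"{path}: expected exactly two columns (sample, group)")
    groups = pd.Series(table[1].to_numpy(), index=table[0].to_numpy())
    if groups.index.duplicated().any():
        raise FormatError(f"{path}: duplicated sample ids")
    return groups


def read_expression(path, groups_path, control_label="C", experimental_label="E"):
    """One expression table plus a group map -> (matrix_c, matrix_e).

    Every sample column must be assigned to exactly one of the two
    cohort labels; genes keep file order in both outputs.
    """
    matrix = _read_matrix(path)
    groups = read_groups(groups_path)
    missing = [s for s in matrix.columns if s not in groups.index]
    if missing:
        raise FormatError(f"samples without a group assignment: {missing[:5]}")
    labels = groups.loc[list(matrix.columns)]
    known = {control_label, experimental_label}
    stray = sorted(set(labels) - known)
    if stray:
        raise FormatError(f"unknown group labels {stray}; expected {sorted(known)}")
    matrix_c = matrix.loc[:, (labels == control_label).to_numpy()]
    matrix_e = matrix.loc[:, (labels == experimental_label).to_numpy()]
    if matrix_c.shape[1] == 0 or matrix_e.shape[1] == 0:
        raise FormatError("both cohorts must contain at least one sample")
    return matrix_c, matrix_e


def read_expression_pair(path_c, path_e):
    """Two per-cohort expression tables sharing the same gene ids."""
    matrix_c = _read_matrix(path_c)
    matrix_e = _read_matrix(path_e)
    if not matrix_c.index.equals(matrix_e.index):
        raise FormatError("cohort files must list identical gene ids in order")
    return matrix_c, matrix_e


def write_expression(matrix: pd.DataFrame, path):
    """Write a genes x samples table as TSV (gene id first column)."""
    matrix = matrix.copy()
    matrix.index = matrix.index.astype(str)
    matrix.index.name = "gene_id"
    # %.17g keeps doubles exact under write-then-read
    matrix.to_csv(path, sep="\t", float_format="%.17g")


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file into a collection (universe = union of genes)."""
    sets, descriptions = {}, {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT lines need term, description and >= 1 gene"
                )
            term, description, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise FormatError(f"{path}:{lineno}: term {term!r} has no genes")
            if term in sets:
                raise FormatError(f"{path}:{lineno}: duplicated term {term!r}")
            sets[term] = frozenset(genes)
            descriptions[term] = description
    if not sets:
        raise FormatError(f"{path}: empty GMT file")
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path):
    """Write a collection as GMT with sorted terms and members."""
    path = Path(path)
    with open(path, "w") as handle:
        for term in sorted(collection.sets):
            genes = "\t".join(sorted(collection.sets[term]))
            description = collection.descriptions.get(term, "")
            handle.write(f"{term}\t{description}\t{genes}\n")
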