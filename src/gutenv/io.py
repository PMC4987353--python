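"""Readers and writers for the four standard inputs and tabular outputs.

Formats: classic OTU-table TSV (rows = OTUs, header row = sample ids,
optional trailing ``taxonomy`` column), Newick with branch lengths,
taxonomy TSV (otu_id <tab> lineage string), and metadata TSV with columns
sample_id / compartment / site / host_species. All tabular outputs are
tab-separated with a single header row; floats are printed with 6
significant digits.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import skbio

from .model import (
    RANKS,
    UNCLASSIFIED,
    CountTable,
    PhyloTree,
    SampleFrame,
    TaxonomyMap,
    ValidationReport,
)

PathLike = Union[str, Path]

FLOAT_FORMAT = "%.6g"

__all__ = [
    "read_count_table",
    "write_count_table",
    "read_tree",
    "write_tree",
    "read_taxonomy",
    "write_taxonomy",
    "parse_lineage",
    "format_lineage",
    "read_metadata",
    "write_metadata",
    "read_distance_matrix",
    "write_distance_matrix",
    "validate_dataset",
    "prune_tree_to_table",
]


# ---------------------------------------------------------------- count table

def read_count_table(
    path: PathLike, return_taxonomy: bool = False
) -> Union[CountTable, tuple[CountTable, Optional[TaxonomyMap]]]:
    """Parse a classic OTU-table TSV.

    A trailing column named ``taxonomy`` (any case) is split off and, when
    ``return_taxonomy`` is true, returned as a side-channel
    :class:`TaxonomyMap`. Row and column order are preserved.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, comment=None)
    df.index = df.index.astype(str)
    taxonomy: Optional[TaxonomyMap] = None
    tax_cols = [c for c in df.columns if str(c).lower() == "taxonomy"]
    if tax_cols:
        dup = df.index[df.index.duplicated()]
        if len(dup):
            raise ValueError(f"duplicate OTU id: {dup[0]!r}")
        taxonomy = TaxonomyMap(
            {otu: parse_lineage(s) for otu, s in df[tax_cols[0]].items()}
        )
        df = df.drop(columns=tax_cols)
    numeric = pd.DataFrame(index=df.index)
    for col in df.columns:
        try:
            numeric[col] = pd.to_numeric(df[col])
        except ValueError as exc:
            raise ValueError(f"non-numeric count in sample column {col!r}: {exc}") from exc
    table = CountTable(numeric)
    if return_taxonomy:
        return table, taxonomy
    return table


def write_count_table(
    table: CountTable, path: PathLike, taxonomy: Optional[TaxonomyMap] = None
) -> None:
    df = table.data.copy()
    df.index.name = "#OTU ID"
    if taxonomy is not None:
        df["taxonomy"] = [format_lineage(taxonomy.lineages[o]) for o in table.otu_ids]
    df.to_csv(path, sep="\t")


# ----------------------------------------------------------------------- tree

def read_tree(path: PathLike) -> PhyloTree:
    """Read a rooted Newick tree; missing branch lengths default to 0."""
    try:
        tree = skbio.TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises format-specific errors
        raise ValueError(f"unparseable Newick in {path}: {exc}") from exc
    return PhyloTree(tree)


def write_tree(tree: PhyloTree, path: PathLike) -> None:
    tree.tree.write(str(path), format="newick")


# ------------------------------------------------------------------- taxonomy

_PREFIXES = tuple(f"{r[0]}__" for r in RANKS)


def parse_lineage(lineage: str) -> tuple[str, ...]:
    """Parse a semicolon-delimited lineage into kingdom..genus names.

    Accepts both the Greengenes-style ``k__Bacteria;p__Firmicutes`` dialect
    and the plain ``Bacteria;Firmicutes`` dialect; rank prefixes are stripped
    on ingest. Missing or empty trailing ranks become ``"unclassified"``.
    """
    names: list[str] = []
    if lineage is None or (isinstance(lineage, float) and np.isnan(lineage)):
        lineage = ""
    for part in str(lineage).split(";"):
        part = part.strip()
        for pref in _PREFIXES:
            if part.lower().startswith(pref):
                part = part[len(pref):]
                break
        names.append(part if part else UNCLASSIFIED)
    names = names[: len(RANKS)]
    names += [UNCLASSIFIED] * (len(RANKS) - len(names))
    return tuple(names)


def format_lineage(names: tuple[str, ...]) -> str:
    return ";".join(
        f"{rank[0]}__{'' if name == UNCLASSIFIED else name}"
        for rank, name in zip(RANKS, names)
    )


def read_taxonomy(path: PathLike) -> TaxonomyMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("taxonomy file needs at least two columns (otu_id, lineage)")
    otus = df.iloc[:, 0].astype(str)
    dup = otus[otus.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate OTU id in taxonomy: {dup.iloc[0]!r}")
    return TaxonomyMap(
        {otu: parse_lineage(lin) for otu, lin in zip(otus, df.iloc[:, 1])}
    )


def write_taxonomy(taxonomy: TaxonomyMap, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("otu_id\ttaxonomy\n")
        for otu, names in taxonomy.lineages.items():
            fh.write(f"{otu}\t{format_lineage(names)}\n")


# ------------------------------------------------------------------- metadata

def read_metadata(path: PathLike) -> SampleFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df.columns = [c.lstrip("#") for c in df.columns]
    return SampleFrame(df)


def write_metadata(samples: SampleFrame, path: PathLike) -> None:
    samples.data.to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------ distance matrix

def write_distance_matrix(ids: list[str], d: np.ndarray, path: PathLike) -> None:
    pd.DataFrame(d, index=ids, columns=ids).to_csv(
        path, sep="\t", float_format=FLOAT_FORMAT, index_label=""
    )


def read_distance_matrix(path: PathLike) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return list(df.index.astype(str)), df.to_numpy(dtype=float)


# ----------------------------------------------------------------- validation

def validate_dataset(
    table: CountTable,
    tree: Optional[PhyloTree],
    taxonomy: Optional[TaxonomyMap],
    samples: Optional[SampleFrame],
) -> ValidationReport:
    """Cross-check ids across the four inputs.

    OTUs absent from the tree and sample/metadata mismatches are hard errors
    for tree-based metrics; extra tree tips are merely prunable (see
    :func:`prune_tree_to_table`).
    """
    report = ValidationReport()
    otus = set(table.otu_ids)
    if tree is not None:
        tips = set(tree.tip_names)
        report.otus_missing_from_tree = sorted(otus - tips)
        report.extra_tree_tips = sorted(tips - otus)
    if taxonomy is not None:
        report.otus_missing_from_taxonomy = sorted(
            o for o in table.otu_ids if o not in taxonomy
        )
    if samples is not None:
        meta = set(samples.sample_ids)
        cols = set(table.sample_ids)
        report.samples_missing_metadata = sorted(cols - meta)
        report.metadata_without_samples = sorted(meta - cols)
    return report


def prune_tree_to_table(tree: PhyloTree, table: CountTable) -> PhyloTree:
    """Drop tree tips that do not appear in the table.

    Pruning extra tips never changes any between-sample distance because no
    counted OTU maps to them.
    """
    keep = set(table.otu_ids) & set(tree.tip_names)
    if not keep:
        raise ValueError("no overlap between table OTUs and tree tips")
    return tree.sheared(keep)
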