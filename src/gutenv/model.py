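"""Typed containers shared by every pipeline stage.

The analysis unit throughout is the OTU (operational taxonomic unit): a
97%-identity cluster of 16S rRNA sequences. Counts live in a classic
OTU-by-sample table; phylogeny is a rooted tree whose tips are OTU ids;
sample metadata assigns each sample to a compartment (host gut ``pika``,
``plant`` surface, or ``soil``), a site, and — for gut samples — a host
species.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import skbio

RANKS: tuple[str, ...] = ("kingdom", "phylum", "class", "order", "family", "genus")
UNCLASSIFIED = "unclassified"
COMPARTMENTS: tuple[str, ...] = ("pika", "plant", "soil")

__all__ = [
    "RANKS",
    "UNCLASSIFIED",
    "COMPARTMENTS",
    "CountTable",
    "AbundanceTable",
    "TaxonomyMap",
    "PhyloTree",
    "SampleFrame",
    "PipelineConfig",
    "ValidationReport",
]


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} id: {i!r}")
        seen.add(i)


class CountTable:
    """OTU x sample matrix of non-negative integer read counts.

    Rows are OTUs, columns are samples; both id vectors are ordered and
    unique. A zero column sum is permitted (flagged via :attr:`empty_samples`)
    so that readers can surface the problem instead of silently dropping it.
    """

    def __init__(self, data: pd.DataFrame):
        _check_unique(list(data.index), "OTU")
        _check_unique(list(data.columns), "sample")
        values = data.to_numpy()
        if values.size:
            if not np.issubdtype(values.dtype, np.number):
                raise ValueError("counts must be numeric")
            if np.any(values < 0):
                r, c = np.argwhere(values < 0)[0]
                raise ValueError(
                    f"negative count at OTU {data.index[r]!r}, sample {data.columns[c]!r}"
                )
            if not np.allclose(values, np.round(values)):
                r, c = np.argwhere(~np.isclose(values, np.round(values)))[0]
                raise ValueError(
                    f"non-integer count at OTU {data.index[r]!r}, sample {data.columns[c]!r}"
                )
        self.data = data.astype(np.int64)

    # -- accessors -------------------------------------------------------
    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_otus(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def column_sums(self) -> pd.Series:
        return self.data.sum(axis=0)

    @property
    def empty_samples(self) -> list[str]:
        sums = self.column_sums()
        return list(sums.index[sums == 0])

    def select_samples(self, sample_ids: Iterable[str]) -> "CountTable":
        ids = list(sample_ids)
        missing = [s for s in ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"unknown samples: {missing}")
        return CountTable(self.data[ids])

    def sample_counts(self, sample_id: str) -> pd.Series:
        return self.data[sample_id]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CountTable) and self.data.equals(other.data)

    def __repr__(self) -> str:
        return f"CountTable({self.n_otus} OTUs x {self.n_samples} samples)"


class AbundanceTable:
    """OTU x sample matrix of within-sample proportions (columns sum to 1)."""

    TOL = 1e-9

    def __init__(self, data: pd.DataFrame):
        _check_unique(list(data.index), "OTU")
        _check_unique(list(data.columns), "sample")
        values = data.to_numpy(dtype=float)
        if values.size:
            if np.any(values < -self.TOL) or np.any(values > 1 + self.TOL):
                raise ValueError("proportions must lie in [0, 1]")
            sums = values.sum(axis=0)
            bad = np.where(np.abs(sums - 1.0) > self.TOL)[0]
            if bad.size:
                j = bad[0]
                raise ValueError(
                    f"column {data.columns[j]!r} sums to {sums[j]!r}, expected 1"
                )
        self.data = data.astype(float)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def proportions(self) -> np.ndarray:
        return self.data.to_numpy()

    def select_samples(self, sample_ids: Iterable[str]) -> "AbundanceTable":
        return AbundanceTable(self.data[list(sample_ids)])

    def __repr__(self) -> str:
        return f"AbundanceTable({self.data.shape[0]} OTUs x {self.data.shape[1]} samples)"


@dataclass
class TaxonomyMap:
    """otu_id -> lineage, each lineage an ordered (rank, name) list.

    Ranks run kingdom..genus; ranks absent from the source string are filled
    with the sentinel ``"unclassified"``.
    """

    lineages: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for otu, names in self.lineages.items():
            if len(names) != len(RANKS):
                raise ValueError(
                    f"lineage for {otu!r} has {len(names)} ranks, expected {len(RANKS)}"
                )

    def lineage(self, otu_id: str) -> list[tuple[str, str]]:
        return list(zip(RANKS, self.lineages[otu_id]))

    def name_at(self, otu_id: str, rank: str) -> str:
        return self.lineages[otu_id][RANKS.index(rank)]

    def best_label(self, otu_id: str) -> str:
        """Deepest resolved rank name, or 'Unclassified <kingdom>' fallback."""
        names = self.lineages[otu_id]
        for name in reversed(names):
            if name != UNCLASSIFIED:
                return name
        return "Unclassified"

    def __contains__(self, otu_id: str) -> bool:
        return otu_id in self.lineages

    def __len__(self) -> int:
        return len(self.lineages)


class PhyloTree:
    """Rooted tree over OTU tips with non-negative branch lengths.

    Thin wrapper around :class:`skbio.TreeNode` that enforces unique tip
    labels and defaults missing branch lengths to zero (with a warning),
    so downstream branch arithmetic never meets ``None``.
    """

    def __init__(self, tree: skbio.TreeNode, warn_missing_lengths: bool = True):
        n_defaulted = 0
        for node in tree.traverse(include_self=True):
            if node.length is None:
                node.length = 0.0
                if not node.is_root():
                    n_defaulted += 1
            elif node.length < 0:
                raise ValueError(f"negative branch length on node {node.name!r}")
        if n_defaulted and warn_missing_lengths:
            warnings.warn(
                f"{n_defaulted} branch length(s) missing; defaulted to 0",
                stacklevel=2,
            )
        tips = [t.name for t in tree.tips()]
        _check_unique(tips, "tip")
        self.tree = tree

    @property
    def tip_names(self) -> list[str]:
        return [t.name for t in self.tree.tips()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.tips())

    def total_length(self) -> float:
        return sum(
            node.length for node in self.tree.traverse(include_self=False)
        )

    def sheared(self, keep: Iterable[str]) -> "PhyloTree":
        """Prune to the given tip set; single-child chains are collapsed,
        summing lengths, so tip-to-tip path lengths are preserved."""
        keep = set(keep)
        missing = keep - set(self.tip_names)
        if missing:
            raise KeyError(f"tips not in tree: {sorted(missing)}")
        sub = self.tree.shear(keep)
        sub.prune()
        return PhyloTree(sub, warn_missing_lengths=False)

    def __repr__(self) -> str:
        return f"PhyloTree({self.n_tips} tips)"


class SampleFrame:
    """Per-sample metadata: compartment, site, and host species for gut samples."""

    COLUMNS = ("sample_id", "compartment", "site", "host_species")

    def __init__(self, data: pd.DataFrame):
        df = data.copy()
        for col in self.COLUMNS:
            if col not in df.columns:
                raise ValueError(f"metadata missing column {col!r}")
        df = df[list(self.COLUMNS)]
        df["host_species"] = df["host_species"].fillna("").astype(str)
        df["site"] = df["site"].astype(str)
        _check_unique(list(df["sample_id"]), "sample")
        bad = df.loc[~df["compartment"].isin(COMPARTMENTS), "compartment"]
        if len(bad):
            raise ValueError(
                f"unknown compartment {bad.iloc[0]!r}; expected one of {COMPARTMENTS}"
            )
        pika = df["compartment"] == "pika"
        if (pika & (df["host_species"] == "")).any():
            sid = df.loc[pika & (df["host_species"] == ""), "sample_id"].iloc[0]
            raise ValueError(f"gut sample {sid!r} lacks a host species")
        if (~pika & (df["host_species"] != "")).any():
            sid = df.loc[~pika & (df["host_species"] != ""), "sample_id"].iloc[0]
            raise ValueError(f"non-gut sample {sid!r} must not carry a host species")
        self.data = df.set_index("sample_id", drop=False)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    @property
    def sites(self) -> list[str]:
        return sorted(self.data["site"].unique())

    @property
    def host_species(self) -> list[str]:
        vals = self.data.loc[self.data["compartment"] == "pika", "host_species"]
        return sorted(vals.unique())

    def select(
        self,
        compartment: Optional[str] = None,
        site: Optional[str] = None,
        host_species: Optional[str] = None,
    ) -> list[str]:
        mask = pd.Series(True, index=self.data.index)
        if compartment is not None:
            mask &= self.data["compartment"] == compartment
        if site is not None:
            mask &= self.data["site"] == str(site)
        if host_species is not None:
            mask &= self.data["host_species"] == host_species
        return list(self.data.loc[mask, "sample_id"])

    def compartment_of(self, sample_id: str) -> str:
        return self.data.loc[sample_id, "compartment"]

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class PipelineConfig:
    """Tunable thresholds for the full analysis.

    Defaults follow the study design this pipeline reproduces: rarefaction to
    4058 reads per sample, core prevalence 80%, environmental-abundance
    threshold 0.1%, phylum display cut 0.04%, genus dominance cut 1%.
    """

    rarefaction_depth: int = 4058
    core_prevalence: float = 0.80
    abundance_threshold: float = 0.001
    display_phylum_threshold: float = 0.0004
    dominant_threshold: float = 0.01
    anosim_permutations: int = 999
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.rarefaction_depth < 1:
            raise ValueError("rarefaction_depth must be a positive integer")
        if not 0 < self.core_prevalence <= 1:
            raise ValueError("core_prevalence must lie in (0, 1]")
        for name in ("abundance_threshold", "display_phylum_threshold", "dominant_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.anosim_permutations < 1:
            raise ValueError("anosim_permutations must be positive")


@dataclass
class ValidationReport:
    """Cross-consistency report for (table, tree, taxonomy, metadata).

    ``otus_missing_from_tree`` and sample mismatches are hard errors for any
    tree-based metric; ``extra_tree_tips`` merely invites pruning.
    """

    otus_missing_from_tree: list[str] = field(default_factory=list)
    extra_tree_tips: list[str] = field(default_factory=list)
    otus_missing_from_taxonomy: list[str] = field(default_factory=list)
    samples_missing_metadata: list[str] = field(default_factory=list)
    metadata_without_samples: list[str] = field(default_factory=list)

    @property
    def is_clean(self) -> bool:
        return not any(
            (
                self.otus_missing_from_tree,
                self.extra_tree_tips,
                self.otus_missing_from_taxonomy,
                self.samples_missing_metadata,
                self.metadata_without_samples,
            )
        )

    @property
    def blocks_tree_metrics(self) -> bool:
        return bool(
            self.otus_missing_from_tree
            or self.samples_missing_metadata
            or self.metadata_without_samples
        )
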