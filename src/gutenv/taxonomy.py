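"""Rank-level aggregation and dominance summaries.

Aggregation sums per-sample proportions within each taxon name at a chosen
rank; OTUs unresolved at that rank pool under ``"unclassified"``, so column
mass is conserved (every aggregated column still sums to 1).
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .model import RANKS, UNCLASSIFIED, AbundanceTable, TaxonomyMap

__all__ = ["aggregate_by_rank", "dominant_taxa", "shared_taxa_breakdown"]


def _rank_labels(taxonomy: TaxonomyMap, otu_ids: Sequence[str], rank: str) -> pd.Series:
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    missing = [o for o in otu_ids if o not in taxonomy]
    if missing:
        raise KeyError(f"OTU {missing[0]!r} has no taxonomy assignment")
    pos = RANKS.index(rank)
    return pd.Series({o: taxonomy.lineages[o][pos] for o in otu_ids})


def aggregate_by_rank(
    ab: AbundanceTable, taxonomy: TaxonomyMap, rank: str
) -> AbundanceTable:
    """Sum proportions within each taxon at ``rank``; mass is conserved."""
    labels = _rank_labels(taxonomy, ab.otu_ids, rank)
    grouped = ab.data.groupby(labels).sum()
    return AbundanceTable(grouped)


def dominant_taxa(mean_abundance: pd.Series, threshold: float) -> list[tuple[str, float]]:
    """Taxa whose mean abundance strictly exceeds ``threshold``, sorted descending."""
    if not 0 <= threshold < 1:
        raise ValueError("threshold must lie in [0, 1)")
    kept = mean_abundance[mean_abundance > threshold]
    kept = kept.sort_values(ascending=False)
    return list(kept.items())


def shared_taxa_breakdown(
    shared: Iterable[str],
    taxonomy: TaxonomyMap,
    ab: AbundanceTable,
    sample_ids: Sequence[str],
    rank: str,
) -> tuple[pd.DataFrame, int]:
    """Taxonomic composition of a shared-OTU set at one rank.

    Returns a table with two complementary compositions — ``mass`` weights
    each shared OTU by its mean abundance over ``sample_ids`` (normalized to
    the shared mass) and ``count`` weights every shared OTU equally — plus
    the number of distinct taxa represented (quantifying how taxonomically
    diverse the shared set is).
    """
    shared = sorted(set(shared))
    if not shared:
        raise ValueError("shared OTU set is empty")
    labels = _rank_labels(taxonomy, shared, rank)
    mean_ab = ab.data.loc[shared, list(sample_ids)].mean(axis=1)
    mass = mean_ab.groupby(labels).sum()
    total = mass.sum()
    mass = mass / total if total > 0 else mass
    count = labels.value_counts() / len(shared)
    out = pd.DataFrame({"mass": mass, "count": count}).fillna(0.0)
    out = out.sort_values("mass", ascending=False)
    return out, int(labels.nunique())
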