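"""Host–environment OTU overlap analysis.

These are the study's central selection objects: per-compartment presence
sets and their Venn partition at each site, unique/shared gut-OTU fractions,
prevalence-defined core microbiomes per host species, the most-abundant
environmental OTU sets, and the 2x2 cross-tabulation of shared-OTU
abundances in gut vs. environment (with its headline "rare in the
environment" fraction and a Spearman rank correlation).

Boundary conventions follow the wording they implement: core membership is
inclusive ("at least 80% of samples" -> prevalence >= tau); the abundant
environmental set is strict (">0.1% relative abundance" -> mean > a*);
the rare-shared statistic is inclusive ("0.1% or less" -> mean <= a*).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .model import AbundanceTable, CountTable, SampleFrame, TaxonomyMap

__all__ = [
    "PresenceSets",
    "VennPartition",
    "CoreSet",
    "CrossTab",
    "CoreSummary",
    "presence_sets",
    "venn_partition",
    "unique_fraction",
    "shared_fraction",
    "core_otus",
    "core_overlap",
    "abundant_env_otus",
    "core_vs_abundant",
    "abundance_crosstab",
    "core_summary_table",
]


# ------------------------------------------------------------- presence sets

@dataclass
class PresenceSets:
    """Per-compartment OTU detection sets at one site."""

    site: str
    sets: dict[str, frozenset[str]]

    def __getitem__(self, compartment: str) -> frozenset[str]:
        return self.sets[compartment]

    @property
    def environment(self) -> frozenset[str]:
        """Union of the non-gut compartments."""
        env: set[str] = set()
        for comp, s in self.sets.items():
            if comp != "pika":
                env |= s
        return frozenset(env)


def presence_sets(
    table: CountTable,
    samples: SampleFrame,
    site: str,
    compartments: Sequence[str] = ("pika", "plant", "soil"),
) -> PresenceSets:
    """Detection sets per compartment at one site.

    An OTU is detected in a group if it has count > 0 in at least one sample
    of that group (post-rarefaction singletons count).
    """
    sets: dict[str, frozenset[str]] = {}
    for comp in compartments:
        ids = samples.select(compartment=comp, site=site)
        if not ids:
            raise ValueError(f"site {site!r} has no {comp!r} samples")
        sub = table.data[ids]
        detected = sub.index[(sub > 0).any(axis=1)]
        sets[comp] = frozenset(detected)
    return PresenceSets(str(site), sets)


# ------------------------------------------------------------ venn partition

@dataclass
class VennPartition:
    """Counts of the 7 disjoint regions of a three-set Venn diagram."""

    a_only: int
    b_only: int
    c_only: int
    ab_only: int
    ac_only: int
    bc_only: int
    abc: int
    labels: tuple[str, str, str] = ("pika", "plant", "soil")

    @property
    def union_size(self) -> int:
        return (self.a_only + self.b_only + self.c_only
                + self.ab_only + self.ac_only + self.bc_only + self.abc)

    def as_dict(self) -> dict[str, int]:
        a, b, c = self.labels
        return {
            a: self.a_only,
            b: self.b_only,
            c: self.c_only,
            f"{a}&{b}": self.ab_only,
            f"{a}&{c}": self.ac_only,
            f"{b}&{c}": self.bc_only,
            f"{a}&{b}&{c}": self.abc,
        }


def venn_partition(
    a: Iterable[str],
    b: Iterable[str],
    c: Iterable[str],
    labels: tuple[str, str, str] = ("pika", "plant", "soil"),
) -> VennPartition:
    A, B, C = set(a), set(b), set(c)
    return VennPartition(
        a_only=len(A - B - C),
        b_only=len(B - A - C),
        c_only=len(C - A - B),
        ab_only=len((A & B) - C),
        ac_only=len((A & C) - B),
        bc_only=len((B & C) - A),
        abc=len(A & B & C),
        labels=labels,
    )


# --------------------------------------------------------- unique and shared

def unique_fraction(
    pika_set: Iterable[str], plant_set: Iterable[str], soil_set: Iterable[str]
) -> tuple[float, int, int]:
    """Fraction of gut OTUs found in neither environmental compartment.

    Returns ``(fraction, n_unique, n_total)`` so the printed "x of y total
    OTUs" form can be reproduced.
    """
    P = set(pika_set)
    if not P:
        raise ValueError("gut OTU set is empty")
    env = set(plant_set) | set(soil_set)
    unique = P - env
    return len(unique) / len(P), len(unique), len(P)


def shared_fraction(pika_set: Iterable[str], env_set: Iterable[str]) -> tuple[float, int, int]:
    """Fraction of gut OTUs also detected in one environmental set."""
    P = set(pika_set)
    if not P:
        raise ValueError("gut OTU set is empty")
    shared = P & set(env_set)
    return len(shared) / len(P), len(shared), len(P)


# ------------------------------------------------------------------ core set

@dataclass
class CoreSet:
    """Prevalence-thresholded core microbiome for one host species."""

    host_species: str
    threshold: float
    otus: frozenset[str]
    prevalence: pd.Series  # over members, fraction of samples with count > 0
    n_samples: int = 0


def core_otus(
    table: CountTable,
    samples: SampleFrame,
    host_species: str,
    threshold: float,
) -> CoreSet:
    """Core OTUs of one host species: prevalence >= threshold.

    Prevalence is the fraction of that species' gut samples (pooled across
    all of its sites) in which the OTU has count > 0. Membership is
    inclusive at the boundary ("at least").
    """
    if not 0 < threshold <= 1:
        raise ValueError("prevalence threshold must lie in (0, 1]")
    ids = samples.select(compartment="pika", host_species=host_species)
    if len(ids) < 2:
        raise ValueError(
            f"host species {host_species!r} has {len(ids)} gut sample(s); need >= 2"
        )
    prev = (table.data[ids] > 0).mean(axis=1)
    members = prev.index[prev >= threshold]
    return CoreSet(
        host_species=host_species,
        threshold=threshold,
        otus=frozenset(members),
        prevalence=prev.loc[members],
        n_samples=len(ids),
    )


def core_overlap(core_a: CoreSet, core_b: CoreSet) -> tuple[int, int, int]:
    """(|A|, |B|, |A ∩ B|) for two core sets."""
    inter = core_a.otus & core_b.otus
    return len(core_a.otus), len(core_b.otus), len(inter)


# ---------------------------------------------------- abundant env / overlap

def abundant_env_otus(mean_abundance: pd.Series, threshold: float) -> frozenset[str]:
    """OTUs whose group mean relative abundance strictly exceeds ``threshold``."""
    total = float(mean_abundance.sum())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"mean abundance vector sums to {total}, expected 1")
    return frozenset(mean_abundance.index[mean_abundance > threshold])


def core_vs_abundant(sets: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """All pairwise and higher-order intersection sizes among named OTU sets.

    The classic use pits each host species' core set against the abundant
    plant and soil sets. Rows are '&'-joined set-name combinations.
    """
    named = {k: set(v) for k, v in sets.items()}
    rows = []
    names = list(named)
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inter = set.intersection(*(named[n] for n in combo))
            rows.append({"sets": "&".join(combo), "size": len(inter)})
    return pd.DataFrame(rows).set_index("sets")


# ------------------------------------------------------------------ crosstab

@dataclass
class CrossTab:
    """2x2 abundance cross-tabulation of gut-environment shared OTUs.

    Cells split the shared OTUs at the same threshold ``a*`` on both axes:
    gut mean abundance (rows: <= a*, > a*) by environment mean abundance
    (columns). ``rare_in_env`` — the fraction of shared OTUs at <= a* in the
    environment — is the headline statistic; ``spearman_rho`` quantifies the
    rank relationship between gut and environmental abundance (average ranks
    for ties).
    """

    threshold: float
    n_shared: int
    fractions: dict[str, float]
    rare_in_env: float
    spearman_rho: float
    gut: pd.Series = field(repr=False, default=None)
    env: pd.Series = field(repr=False, default=None)


def abundance_crosstab(
    shared: Iterable[str],
    gut_mean: pd.Series,
    env_mean: pd.Series,
    threshold: float,
) -> CrossTab:
    shared = sorted(set(shared))
    if not shared:
        raise ValueError("shared OTU set is empty")
    missing = [o for o in shared if o not in gut_mean.index or o not in env_mean.index]
    if missing:
        raise KeyError(f"abundance vectors do not cover shared OTU {missing[0]!r}")
    g = gut_mean.loc[shared].astype(float)
    e = env_mean.loc[shared].astype(float)
    g_low = g <= threshold
    e_low = e <= threshold
    n = len(shared)
    fractions = {
        "gut_low_env_low": float((g_low & e_low).sum()) / n,
        "gut_low_env_high": float((g_low & ~e_low).sum()) / n,
        "gut_high_env_low": float((~g_low & e_low).sum()) / n,
        "gut_high_env_high": float((~g_low & ~e_low).sum()) / n,
    }
    if n > 1 and (g.nunique() > 1 and e.nunique() > 1):
        rho = float(spearmanr(g, e).statistic)
    else:
        rho = float("nan")
    return CrossTab(
        threshold=threshold,
        n_shared=n,
        fractions=fractions,
        rare_in_env=float(e_low.mean()),
        spearman_rho=rho,
        gut=g,
        env=e,
    )


# ---------------------------------------------------------- core summary

@dataclass
class CoreSummary:
    """Taxon-level core abundance table plus environmental-prevalence flags."""

    taxon_table: pd.DataFrame         # taxon x (group label) summed mean abundance
    otu_counts: pd.Series             # core OTUs per taxon row
    plant_prevalence: pd.Series       # per core OTU
    sporadic_in_plant: frozenset[str]  # core OTUs below tau prevalence in plant
    never_in_environment: frozenset[str]


def core_summary_table(
    core: CoreSet,
    taxonomy: TaxonomyMap,
    group_means: Mapping[str, pd.Series],
    table: CountTable,
    samples: SampleFrame,
) -> CoreSummary:
    """Aggregate a species' core OTUs by taxonomic unit across sample groups.

    ``group_means`` maps a column label (e.g. ``"3694/plant"``) to that
    group's mean relative-abundance vector; each taxon row holds the summed
    mean abundance of its core OTUs in that group. Each core OTU is labelled
    by its deepest resolved rank (falling back to "Unclassified Bacteria").
    Also reports every core OTU's prevalence across plant samples — flagging
    OTUs that are only sporadically seen there (< the core threshold) — and
    the core OTUs never observed in any environmental (plant or soil) sample.
    """
    members = sorted(core.otus)
    labels = pd.Series(
        {o: taxonomy.best_label(o) if o in taxonomy else "Unclassified Bacteria"
         for o in members}
    )
    cols = {}
    for name, mean_vec in group_means.items():
        vals = mean_vec.reindex(members).fillna(0.0)
        cols[name] = vals.groupby(labels).sum()
    taxon_table = pd.DataFrame(cols).fillna(0.0).sort_index()
    otu_counts = labels.value_counts().reindex(taxon_table.index).astype(int)

    plant_ids = samples.select(compartment="plant")
    if plant_ids:
        plant_prev = (table.data.loc[members, plant_ids] > 0).mean(axis=1)
    else:
        plant_prev = pd.Series(0.0, index=members)
    sporadic = frozenset(plant_prev.index[plant_prev < core.threshold])

    env_ids = samples.select(compartment="plant") + samples.select(compartment="soil")
    if env_ids:
        seen_env = (table.data.loc[members, env_ids] > 0).any(axis=1)
        never = frozenset(seen_env.index[~seen_env])
    else:
        never = frozenset(members)
    return CoreSummary(
        taxon_table=taxon_table,
        otu_counts=otu_counts,
        plant_prevalence=plant_prev,
        sporadic_in_plant=sporadic,
        never_in_environment=never,
    )
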