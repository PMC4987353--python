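"""End-to-end orchestration: rarefaction through the headline report.

``run_pipeline`` executes every stage in order — rarefy, relative
abundance, alpha diversity, UniFrac distance matrices, PCoA, ANOSIM
(compartments; host species; sites within species), per-site presence sets
and Venn partitions, core detection per host species, abundant-environment
sets, core-vs-abundant overlap, the abundance cross-tabulation (per site
and pooled), the core summary table, and rank-level taxonomy summaries —
optionally writing every tabular output plus a machine-readable JSON report
of the headline numbers.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as gio
from .diversity import alpha_diversity, anosim, distance_matrix, pcoa
from .model import (
    CountTable,
    PhyloTree,
    PipelineConfig,
    SampleFrame,
    TaxonomyMap,
)
from .normalize import group_mean_abundance, rarefy, relative_abundance
from .selection import (
    abundance_crosstab,
    abundant_env_otus,
    core_otus,
    core_overlap,
    core_summary_table,
    core_vs_abundant,
    presence_sets,
    shared_fraction,
    unique_fraction,
    venn_partition,
)
from .taxonomy import aggregate_by_rank, dominant_taxa, shared_taxa_breakdown

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "load_inputs"]


def load_inputs(
    table_path, tree_path, taxonomy_path, metadata_path
) -> tuple[CountTable, PhyloTree, Optional[TaxonomyMap], SampleFrame]:
    table, inline_tax = gio.read_count_table(table_path, return_taxonomy=True)
    tree = gio.read_tree(tree_path)
    taxonomy = (
        gio.read_taxonomy(taxonomy_path) if taxonomy_path is not None else inline_tax
    )
    samples = gio.read_metadata(metadata_path)
    return table, tree, taxonomy, samples


def _write(df: pd.DataFrame, out_dir: Optional[Path], name: str) -> None:
    if out_dir is not None:
        df.to_csv(out_dir / name, sep="\t", float_format=gio.FLOAT_FORMAT)


def run_pipeline(
    table: CountTable,
    tree: PhyloTree,
    taxonomy: TaxonomyMap,
    samples: SampleFrame,
    config: PipelineConfig = PipelineConfig(),
    out_dir: Optional[str | Path] = None,
) -> dict:
    """Run every stage and return the headline report as a nested dict."""
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    report = gio.validate_dataset(table, tree, taxonomy, samples)
    if report.blocks_tree_metrics:
        raise ValueError(
            "dataset inconsistent: "
            f"OTUs missing from tree={report.otus_missing_from_tree[:5]}, "
            f"samples without metadata={report.samples_missing_metadata[:5]}, "
            f"metadata without samples={report.metadata_without_samples[:5]}"
        )
    if report.extra_tree_tips:
        logger.info("pruning %d tree tip(s) absent from the table",
                    len(report.extra_tree_tips))
        tree = gio.prune_tree_to_table(tree, table)

    # --- normalization ----------------------------------------------------
    rare = rarefy(table, config.rarefaction_depth, config.rng_seed)
    kept = set(rare.sample_ids)
    samples_kept = SampleFrame(
        samples.data[samples.data["sample_id"].isin(kept)].reset_index(drop=True)
    )
    ab = relative_abundance(rare)

    # --- alpha diversity --------------------------------------------------
    alpha = alpha_diversity(rare, tree)
    _write(alpha, out, "alpha_diversity.tsv")

    # --- beta diversity ---------------------------------------------------
    results: dict = {"n_samples": rare.n_samples, "n_otus": rare.n_otus,
                     "anosim": {}, "sites": {}, "core": {}, "crosstab": {},
                     "taxonomy": {}}
    labels_comp = [samples_kept.compartment_of(s) for s in rare.sample_ids]
    dms = {}
    for metric in ("weighted_unifrac", "unweighted_unifrac"):
        dm = distance_matrix(rare, tree, metric)
        dms[metric] = dm
        if out is not None:
            gio.write_distance_matrix(dm.sample_ids, dm.d, out / f"{metric}.tsv")
        ord_res = pcoa(dm)
        if out is not None:
            with open(out / f"pcoa_{metric}.tsv", "w") as fh:
                fh.write("# eigenvalues\t" + "\t".join(
                    gio.FLOAT_FORMAT % v for v in ord_res.eigenvalues) + "\n")
                fh.write("# proportion_explained\t" + "\t".join(
                    gio.FLOAT_FORMAT % v for v in ord_res.proportion_explained) + "\n")
            ord_res.coordinates.to_csv(
                out / f"pcoa_{metric}.tsv", sep="\t",
                float_format=gio.FLOAT_FORMAT, mode="a",
            )

    dm_main = dms["weighted_unifrac"]

    def _safe_anosim(dm, labels, tag):
        labels = np.asarray(labels)
        uniq, counts = np.unique(labels, return_counts=True)
        if uniq.size < 2 or counts.min() < 2:
            logger.info("skipping ANOSIM %s: insufficient group structure", tag)
            return None
        res = anosim(dm, labels, config.anosim_permutations, config.rng_seed)
        return {"R": res.R, "p": res.p_value, "n_permutations": res.n_permutations}

    results["anosim"]["compartments"] = _safe_anosim(dm_main, labels_comp,
                                                     "compartments")
    pika_ids = [s for s in rare.sample_ids
                if samples_kept.compartment_of(s) == "pika"]
    if len(pika_ids) >= 4:
        dm_pika = dm_main.submatrix(pika_ids)
        sp_labels = [samples_kept.data.loc[s, "host_species"] for s in pika_ids]
        results["anosim"]["host_species"] = _safe_anosim(
            dm_pika, sp_labels, "host species")
        for sp in samples_kept.host_species:
            ids = [s for s, lab in zip(pika_ids, sp_labels) if lab == sp]
            site_labels = [samples_kept.data.loc[s, "site"] for s in ids]
            if len(ids) >= 4:
                results["anosim"][f"sites_within_{sp}"] = _safe_anosim(
                    dm_main.submatrix(ids), site_labels, f"sites within {sp}")

    # --- per-site presence, venn, fractions -------------------------------
    for site in samples_kept.sites:
        comps = set(samples_kept.data.loc[
            samples_kept.data["site"] == site, "compartment"])
        if not {"pika", "plant", "soil"} <= comps:
            logger.info("site %s lacks a compartment; skipping site analyses", site)
            continue
        ps = presence_sets(rare, samples_kept, site)
        venn = venn_partition(ps["pika"], ps["plant"], ps["soil"])
        if out is not None:
            pd.Series(venn.as_dict(), name="n_otus").to_csv(
                out / f"venn_{site}.tsv", sep="\t", index_label="region")
        uf, n_uniq, n_tot = unique_fraction(ps["pika"], ps["plant"], ps["soil"])
        sf_plant = shared_fraction(ps["pika"], ps["plant"])
        sf_soil = shared_fraction(ps["pika"], ps["soil"])
        results["sites"][site] = {
            "venn": venn.as_dict(),
            "unique_fraction": uf,
            "n_unique": n_uniq,
            "n_gut_otus": n_tot,
            "shared_with_plant": sf_plant[0],
            "shared_with_soil": sf_soil[0],
        }

        # per-site crosstab: gut vs combined environment means
        shared = set(ps["pika"]) & set(ps.environment)
        if shared:
            gut_mean = group_mean_abundance(
                ab, samples=samples_kept, compartment="pika", site=site)
            env_ids = (samples_kept.select(compartment="plant", site=site)
                       + samples_kept.select(compartment="soil", site=site))
            env_mean = group_mean_abundance(ab, env_ids)
            ct = abundance_crosstab(shared, gut_mean, env_mean,
                                    config.abundance_threshold)
            results["crosstab"][site] = {
                "n_shared": ct.n_shared,
                "rare_in_env": ct.rare_in_env,
                "spearman_rho": ct.spearman_rho,
                "fractions": ct.fractions,
            }
            if out is not None:
                pd.DataFrame({"gut_mean": ct.gut, "env_mean": ct.env}).to_csv(
                    out / f"crosstab_{site}.tsv", sep="\t",
                    float_format=gio.FLOAT_FORMAT, index_label="otu_id")

    # --- pooled crosstab --------------------------------------------------
    all_pika = samples_kept.select(compartment="pika")
    all_env = (samples_kept.select(compartment="plant")
               + samples_kept.select(compartment="soil"))
    pika_detect = set(rare.data.index[(rare.data[all_pika] > 0).any(axis=1)])
    env_detect = set(rare.data.index[(rare.data[all_env] > 0).any(axis=1)])
    shared_all = pika_detect & env_detect
    if shared_all:
        gut_mean_all = group_mean_abundance(ab, all_pika)
        env_mean_all = group_mean_abundance(ab, all_env)
        ct = abundance_crosstab(shared_all, gut_mean_all, env_mean_all,
                                config.abundance_threshold)
        results["crosstab"]["pooled"] = {
            "n_shared": ct.n_shared,
            "rare_in_env": ct.rare_in_env,
            "spearman_rho": ct.spearman_rho,
            "fractions": ct.fractions,
        }

    # --- core microbiomes -------------------------------------------------
    cores = {}
    for sp in samples_kept.host_species:
        try:
            cores[sp] = core_otus(rare, samples_kept, sp, config.core_prevalence)
        except ValueError as exc:
            logger.info("core detection skipped for %s: %s", sp, exc)
    for sp, core in cores.items():
        results["core"][sp] = {"size": len(core.otus), "n_samples": core.n_samples}
        if out is not None:
            pd.DataFrame({"prevalence": core.prevalence}).to_csv(
                out / f"core_{sp}.tsv", sep="\t",
                float_format=gio.FLOAT_FORMAT, index_label="otu_id")
    species = list(cores)
    if len(species) >= 2:
        a, b, inter = core_overlap(cores[species[0]], cores[species[1]])
        results["core"]["overlap"] = {
            "species": species[:2], "sizes": [a, b], "shared": inter}

    # --- abundant environmental OTUs & overlap with cores -----------------
    plant_mean = group_mean_abundance(ab, samples=samples_kept, compartment="plant")
    soil_mean = group_mean_abundance(ab, samples=samples_kept, compartment="soil")
    abundant = {
        "abundant_plant": abundant_env_otus(plant_mean, config.abundance_threshold),
        "abundant_soil": abundant_env_otus(soil_mean, config.abundance_threshold),
    }
    results["abundant_env"] = {k: len(v) for k, v in abundant.items()}
    overlap_sets = {f"core_{sp}": cores[sp].otus for sp in cores}
    overlap_sets.update(abundant)
    overlap_df = core_vs_abundant(overlap_sets)
    _write(overlap_df, out, "core_vs_abundant.tsv")
    results["core_vs_abundant"] = {
        idx: int(row["size"]) for idx, row in overlap_df.iterrows() if "&" in idx
    }

    # --- core summary tables ----------------------------------------------
    group_means = {}
    for site in samples_kept.sites:
        for comp in ("pika", "plant", "soil"):
            ids = samples_kept.select(compartment=comp, site=site)
            if ids:
                group_means[f"{site}/{comp}"] = group_mean_abundance(ab, ids)
    for sp, core in cores.items():
        if not core.otus:
            continue
        summary = core_summary_table(core, taxonomy, group_means, rare, samples_kept)
        _write(summary.taxon_table, out, f"core_summary_{sp}.tsv")
        results["core"][sp]["never_in_environment"] = len(summary.never_in_environment)
        results["core"][sp]["sporadic_in_plant"] = len(summary.sporadic_in_plant)

    # --- taxonomy summaries -----------------------------------------------
    phylum_ab = aggregate_by_rank(ab, taxonomy, "phylum")
    _write(phylum_ab.data, out, "phylum_abundance.tsv")
    for comp in ("pika", "plant", "soil"):
        ids = samples_kept.select(compartment=comp)
        if not ids:
            continue
        comp_mean = phylum_ab.data[ids].mean(axis=1)
        results["taxonomy"][f"dominant_phyla_{comp}"] = [
            [name, val] for name, val in
            dominant_taxa(comp_mean, config.display_phylum_threshold)
        ]
    genus_ab = aggregate_by_rank(ab, taxonomy, "genus")
    gut_ids = samples_kept.select(compartment="pika")
    if gut_ids:
        genus_mean = genus_ab.data[gut_ids].mean(axis=1)
        results["taxonomy"]["dominant_genera_pika"] = [
            [name, val] for name, val in
            dominant_taxa(genus_mean, config.dominant_threshold)
        ]
    if shared_all:
        breakdown, richness = shared_taxa_breakdown(
            shared_all, taxonomy, ab, all_pika, "phylum")
        _write(breakdown, out, "shared_taxa_phylum.tsv")
        results["taxonomy"]["shared_phylum_richness"] = richness

    # --- alpha summary + report ------------------------------------------
    results["alpha"] = {
        comp: {
            "observed_otus": float(alpha.loc[ids, "observed_otus"].mean()),
            "faith_pd": float(alpha.loc[ids, "faith_pd"].mean()),
        }
        for comp in ("pika", "plant", "soil")
        if (ids := samples_kept.select(compartment=comp))
    }
    results["config"] = {
        "rarefaction_depth": config.rarefaction_depth,
        "core_prevalence": config.core_prevalence,
        "abundance_threshold": config.abundance_threshold,
        "anosim_permutations": config.anosim_permutations,
        "rng_seed": config.rng_seed,
    }
    if out is not None:
        with open(out / "report.json", "w") as fh:
            json.dump(results, fh, indent=2, sort_keys=True)
    return results
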