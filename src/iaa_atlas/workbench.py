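"""Orchestration of the two surveys: genome atlas and root-environment quant.

The genome survey chains annotation -> classification -> per-phylum
summaries, coexistence histograms, chi-square preference tests and
rarefaction; the metagenome survey chains catalog QC -> gene abundance ->
KO/taxon profiles -> per-compartment group-relative abundances for the
Trp-catalyzing and IAA-producing (last-step) enzyme groups.  All
thresholds live in one config whose defaults are the published values, so
sensitivity analyses are one-flag changes; every filter logs its
input/output row counts to make attrition auditable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as atlas_io
from .annotation import FilterThresholds, read_outfmt6
from .catalog import PathwayCatalog, default_catalog, load_catalog
from .classify import (
    classify_cohort,
    phylum_preference_test,
    phylum_summary,
    rarefy_combinations,
    reports_to_frame,
)
from .quant import (
    compartment_mean_shares,
    gene_abundance,
    ko_profile,
    qc_catalog,
    taxon_profile,
)
from .synthetic import recover_profiles

logger = logging.getLogger("iaa_atlas")

__all__ = [
    "RunConfig",
    "GenomeSurveyResult",
    "MetagenomeSurveyResult",
    "run_genome_survey",
    "run_metagenome_survey",
    "trp_catalyzing_kos",
    "last_step_kos",
]


@dataclass
class RunConfig:
    """Paths, thresholds and seed for a survey run.

    Thresholds default to the published values: E-value < 1e-5 and score
    >= 60 for annotation; gene >= 150 bp and contig >= 500 bp for catalog
    QC; rarefaction is seeded and reproducible.
    """

    catalog_path: str | None = None
    manifest_path: str | None = None
    hits_path: str | None = None
    ko_map_path: str | None = None
    profiles_path: str | None = None
    gene_catalog_path: str | None = None
    counts_path: str | None = None
    samples_path: str | None = None
    out_dir: str | None = None
    max_evalue: float = 1e-5
    min_score: float = 60.0
    min_gene_len: int = 150
    min_contig_len: int = 500
    rarefaction_depths: tuple[int, ...] = ()
    rarefaction_replicates: int = 100
    taxon_rank: str = "phylum"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "rarefaction_depths" in data:
            data["rarefaction_depths"] = tuple(data["rarefaction_depths"])
        return cls(**data)

    def load_catalog(self) -> PathwayCatalog:
        if self.catalog_path:
            return load_catalog(self.catalog_path)
        return default_catalog()

    def thresholds(self) -> FilterThresholds:
        return FilterThresholds(max_evalue=self.max_evalue, min_score=self.min_score)


@dataclass
class GenomeSurveyResult:
    reports: pd.DataFrame
    summary: pd.DataFrame
    rarefaction: pd.DataFrame
    preference_tests: dict[str, dict]
    manifest_summary: pd.DataFrame


@dataclass
class MetagenomeSurveyResult:
    ko_profile: pd.DataFrame
    taxon_profile_trp: pd.DataFrame
    taxon_profile_producing: pd.DataFrame
    trp_group_shares: pd.DataFrame
    last_step_group_shares: pd.DataFrame


def trp_catalyzing_kos(catalog: PathwayCatalog) -> frozenset[str]:
    """KOs of roles consuming Trp (the first-step enzyme group)."""
    return frozenset(ko for role in catalog.trp_roles for ko in role.ko_ids)


def last_step_kos(catalog: PathwayCatalog) -> frozenset[str]:
    """KOs of roles producing IAA directly (the last-step enzyme group)."""
    return frozenset(
        ko
        for role in catalog.roles.values()
        if role.product == catalog.terminal
        for ko in role.ko_ids
    )


def _maybe_write(df: pd.DataFrame, out_dir: Path | None, name: str) -> None:
    if out_dir is not None:
        df.to_csv(out_dir / name, sep="\t", index=False)


def run_genome_survey(config: RunConfig) -> GenomeSurveyResult:
    """Classify a genome cohort and emit the atlas summary tables."""
    catalog = config.load_catalog()
    if config.profiles_path:
        profiles = atlas_io.read_profiles(config.profiles_path)
    else:
        if not (config.manifest_path and config.hits_path and config.ko_map_path):
            raise ValueError(
                "genome survey needs either profiles_path or "
                "manifest_path + hits_path + ko_map_path"
            )
        manifest = atlas_io.read_manifest(config.manifest_path)
        hits = read_outfmt6(config.hits_path)
        ko_map = atlas_io.read_ko_map(config.ko_map_path)
        logger.info("annotation: %d raw hits", len(hits))
        profiles = recover_profiles(
            hits,
            ko_map,
            dict(zip(manifest["genome_id"], manifest["phylum"])),
            thresholds=config.thresholds(),
        )
    logger.info("cohort: %d genome profiles", len(profiles))

    reports = classify_cohort(profiles, catalog)
    reports_df = reports_to_frame(reports)
    summary = phylum_summary(reports, catalog)

    manifest_summary = (
        reports_df.groupby("phylum", as_index=False)
        .size()
        .rename(columns={"size": "n_genomes"})
    )
    total = pd.DataFrame(
        [{"phylum": "total", "n_genomes": int(manifest_summary["n_genomes"].sum())}]
    )
    manifest_summary = pd.concat([manifest_summary, total], ignore_index=True)

    # chi-square preference tests on phylum x category count tables
    preference_tests: dict[str, dict] = {}
    for panel in ("trp_catalysis", "denovo", "from_intermediate_pathway"):
        sub = summary[summary["panel"] == panel]
        table = sub.pivot_table(
            index="phylum", columns="category", values="count", fill_value=0
        )
        table = table.loc[:, table.sum(axis=0) > 0]
        table = table.loc[table.sum(axis=1) > 0, :]
        if table.shape[0] >= 2 and table.shape[1] >= 2:
            stat, dof, p = phylum_preference_test(table)
            preference_tests[panel] = {
                "statistic": stat, "dof": dof, "p_value": p,
            }

    depths = config.rarefaction_depths
    if not depths:
        n = len(reports)
        depths = tuple(sorted({max(1, n // 10), max(1, n // 2), n}))
    frames = []
    by_phylum: dict[str, list] = {}
    for r in reports:
        by_phylum.setdefault(r.phylum, []).append(r)
    for phylum, grp in sorted(by_phylum.items()):
        usable = [d for d in depths if d <= len(grp)] or [len(grp)]
        curve = rarefy_combinations(
            grp, usable, replicates=config.rarefaction_replicates, seed=config.seed
        )
        curve.insert(0, "phylum", phylum)
        frames.append(curve)
    rarefaction = pd.concat(frames, ignore_index=True)

    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        _maybe_write(reports_df, out_dir, "genome_reports.tsv")
        _maybe_write(summary, out_dir, "phylum_summary.tsv")
        _maybe_write(rarefaction, out_dir, "rarefaction.tsv")
        _maybe_write(manifest_summary, out_dir, "manifest_summary.tsv")
        with open(out_dir / "preference_tests.json", "w") as fh:
            json.dump(preference_tests, fh, indent=2, sort_keys=True)

    return GenomeSurveyResult(
        reports=reports_df,
        summary=summary,
        rarefaction=rarefaction,
        preference_tests=preference_tests,
        manifest_summary=manifest_summary,
    )


def run_metagenome_survey(config: RunConfig) -> MetagenomeSurveyResult:
    """Quantify IAA-synthesis gene groups in RS/RP compartment samples."""
    catalog = config.load_catalog()
    if not (config.gene_catalog_path and config.counts_path and config.samples_path):
        raise ValueError(
            "metagenome survey needs gene_catalog_path + counts_path + samples_path"
        )
    genes = atlas_io.read_gene_catalog(config.gene_catalog_path)
    counts = atlas_io.read_counts(config.counts_path)
    samples = atlas_io.read_samples(config.samples_path)

    unknown = set(counts.columns) - set(samples["sample_id"])
    if unknown:
        raise ValueError(
            f"sample(s) in counts matrix absent from manifest: {sorted(unknown)[:5]}"
        )

    contig_lengths = None
    if "contig_length" in genes.columns:
        contig_lengths = dict(zip(genes["contig_id"], genes["contig_length"]))
    retained = qc_catalog(
        genes,
        contig_lengths,
        min_gene_len=config.min_gene_len,
        min_contig_len=config.min_contig_len,
    )
    logger.info("catalog QC: %d of %d genes retained", len(retained), len(genes))

    retained = retained.set_index("gene_id")
    counts = counts.reindex(retained.index).fillna(0).astype(int)
    abundance = gene_abundance(counts, retained["length"])

    gene_to_ko = retained["ko_id"].dropna() if "ko_id" in retained else pd.Series(dtype=object)
    ko_prof = ko_profile(abundance, gene_to_ko)

    comp = dict(zip(samples["sample_id"], samples["compartment"]))
    trp_group = trp_catalyzing_kos(catalog) & set(ko_prof.index)
    last_group = last_step_kos(catalog) & set(ko_prof.index)
    trp_shares = compartment_mean_shares(ko_prof, trp_group, comp) if trp_group else pd.DataFrame()
    last_shares = compartment_mean_shares(ko_prof, last_group, comp) if last_group else pd.DataFrame()

    lineages = (
        dict(zip(retained.index, retained["lineage"]))
        if "lineage" in retained
        else {}
    )

    def group_taxa(group: frozenset[str]) -> pd.DataFrame:
        group_genes = gene_to_ko[gene_to_ko.isin(group)].index
        if not len(group_genes):
            return pd.DataFrame(columns=abundance.columns)
        return taxon_profile(
            abundance.loc[group_genes], lineages, rank=config.taxon_rank
        )

    result = MetagenomeSurveyResult(
        ko_profile=ko_prof,
        taxon_profile_trp=group_taxa(trp_catalyzing_kos(catalog)),
        taxon_profile_producing=group_taxa(last_step_kos(catalog)),
        trp_group_shares=trp_shares,
        last_step_group_shares=last_shares,
    )

    if config.out_dir:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        result.ko_profile.to_csv(out_dir / "ko_profile.tsv", sep="\t")
        result.taxon_profile_trp.to_csv(out_dir / "taxon_trp.tsv", sep="\t")
        result.taxon_profile_producing.to_csv(out_dir / "taxon_producing.tsv", sep="\t")
        result.trp_group_shares.to_csv(out_dir / "trp_group_shares.tsv", sep="\t")
        result.last_step_group_shares.to_csv(
            out_dir / "last_step_group_shares.tsv", sep="\t"
        )
    return result
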