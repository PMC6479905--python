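"""Gene-catalog QC and abundance profiling for root-environment metagenomes.

Quantification follows the standard gene-catalog arithmetic: the abundance
of a gene in a sample is the number of reads mapped to it divided by its
length in bp; KO profiles sum gene abundances sharing a KO; taxon profiles
sum gene abundances sharing a phylum or class (genes without that rank
aggregate under ``Unknown``).  Catalog QC drops genes shorter than 150 bp
and genes on contigs shorter than 500 bp before any quantification.

Group-relative abundances (e.g. each Trp-catalyzing enzyme's share of all
Trp-catalyzing enzyme abundance) are computed per sample; compartment
summaries (rhizosphere RS vs rhizoplane RP) average the per-sample shares
by default, with a pooled-mass alternative behind a flag since both
conventions occur in practice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .lca import Lineage, format_lineage

__all__ = [
    "COMPARTMENTS",
    "LINEAGE_RANKS",
    "qc_catalog",
    "gene_abundance",
    "ko_profile",
    "taxon_profile",
    "group_relative_abundance",
    "compartment_mean_shares",
]

COMPARTMENTS = ("RS", "RP")

#: Rank order assumed for lineage tuples.
LINEAGE_RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

UNKNOWN_TAXON = "Unknown"


def qc_catalog(
    entries: pd.DataFrame,
    contig_lengths: Mapping[str, int] | pd.Series | None = None,
    min_gene_len: int = 150,
    min_contig_len: int = 500,
) -> pd.DataFrame:
    """Drop genes shorter than ``min_gene_len`` bp or on short contigs.

    ``entries`` needs columns ``gene_id`` and ``length``; contig filtering
    additionally needs a ``contig_id`` column plus the contig length map.
    A gene referencing a contig absent from the map is an error.
    """
    required = {"gene_id", "length"}
    missing = required - set(entries.columns)
    if missing:
        raise ValueError(f"gene catalog missing columns: {sorted(missing)}")
    if entries["gene_id"].duplicated().any():
        dup = entries.loc[entries["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"duplicate gene_id in catalog: {dup!r}")
    keep = entries["length"].astype(int) >= min_gene_len
    if contig_lengths is not None:
        if "contig_id" not in entries.columns:
            raise ValueError("contig filtering requested but no contig_id column")
        lengths = pd.Series(contig_lengths)
        unknown = set(entries["contig_id"]) - set(lengths.index)
        if unknown:
            raise ValueError(f"genes reference unknown contigs: {sorted(unknown)[:5]}")
        keep &= entries["contig_id"].map(lengths).astype(int) >= min_contig_len
    return entries.loc[keep].reset_index(drop=True)


def gene_abundance(
    read_counts: pd.DataFrame, lengths: Mapping[str, int] | pd.Series
) -> pd.DataFrame:
    """Per-gene per-sample abundance: reads mapped to the gene / gene length.

    ``read_counts`` is a gene x sample matrix of non-negative counts.
    """
    lengths = pd.Series(lengths, dtype=float)
    missing = read_counts.index.difference(lengths.index)
    if len(missing):
        raise ValueError(f"no length for gene(s): {list(missing[:5])}")
    if (read_counts.to_numpy() < 0).any():
        raise ValueError("read counts must be non-negative")
    div = lengths.reindex(read_counts.index)
    if (div <= 0).any():
        bad = div.index[div <= 0][0]
        raise ValueError(f"non-positive length for gene {bad!r}")
    return read_counts.div(div, axis=0)


def ko_profile(
    abundance: pd.DataFrame, gene_to_ko: Mapping[str, str] | pd.Series
) -> pd.DataFrame:
    """KO x sample profile: sum of abundances of genes mapped to each KO.

    Genes absent from the mapping (or mapped to null) are excluded, so the
    total KO mass is at most the total gene mass, with equality iff every
    gene is mapped.
    """
    ko = pd.Series(gene_to_ko).reindex(abundance.index)
    mapped = ko.notna()
    if not mapped.any():
        return pd.DataFrame(columns=abundance.columns, dtype=float)
    return abundance.loc[mapped].groupby(ko[mapped]).sum().sort_index()


def taxon_profile(
    abundance: pd.DataFrame,
    gene_to_lineage: Mapping[str, Lineage],
    rank: str = "phylum",
    ranks: Sequence[str] = LINEAGE_RANKS,
) -> pd.DataFrame:
    """Taxon x sample profile at a rank; lineages lacking it go to Unknown."""
    if rank not in ranks:
        raise ValueError(f"rank {rank!r} not in {tuple(ranks)}")
    level = list(ranks).index(rank)

    def taxon_of(gene: str) -> str:
        lineage = gene_to_lineage.get(gene)
        if lineage is None or len(lineage) <= level:
            return UNKNOWN_TAXON
        return lineage[level]

    labels = pd.Series([taxon_of(g) for g in abundance.index], index=abundance.index)
    return abundance.groupby(labels).sum().sort_index()


def group_relative_abundance(
    ko_prof: pd.DataFrame,
    group: Iterable[str],
    sample_compartment: Mapping[str, str] | pd.Series | None = None,
    aggregate_by_compartment: bool = False,
    pooled: bool = False,
) -> pd.DataFrame:
    """Within-group share of each group member, per sample or compartment.

    For every sample the share of each KO in ``group`` is its abundance
    divided by the group's total abundance in that sample; shares sum to 1
    except in zero-mass samples, which come back all-zero with a warning.
    With ``aggregate_by_compartment`` the per-sample shares are averaged
    within each compartment (or, with ``pooled=True``, computed from summed
    group masses instead).
    """
    group = sorted(set(group))
    if not group:
        raise ValueError("group of KO ids must be non-empty")
    sub = ko_prof.reindex(group).fillna(0.0)
    if aggregate_by_compartment:
        if sample_compartment is None:
            raise ValueError("compartment aggregation requires sample metadata")
        comp = pd.Series(sample_compartment).reindex(sub.columns)
        if comp.isna().any():
            missing = list(sub.columns[comp.isna()])
            raise ValueError(f"samples missing from manifest: {missing[:5]}")
        if pooled:
            pooled_mass = sub.T.groupby(comp).sum().T
            return _normalise_columns(pooled_mass)
        shares = _normalise_columns(sub)
        return shares.T.groupby(comp).mean().T
    return _normalise_columns(sub)


def _normalise_columns(mass: pd.DataFrame) -> pd.DataFrame:
    totals = mass.sum(axis=0)
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"zero group mass in column(s): {list(mass.columns[zero])[:5]}",
            stacklevel=3,
        )
    return mass.div(totals.where(~zero, 1.0), axis=1)


def compartment_mean_shares(
    ko_prof: pd.DataFrame,
    group: Iterable[str],
    sample_compartment: Mapping[str, str] | pd.Series,
) -> pd.DataFrame:
    """Convenience wrapper: per-compartment mean of per-sample group shares."""
    return group_relative_abundance(
        ko_prof, group, sample_compartment, aggregate_by_compartment=True
    )
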