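"""Plain-text readers and writers for the pipeline's tabular interfaces.

All formats are tab-separated with a header row unless noted: genome
manifests (genome_id, phylum), subject->KO maps, genome KO profiles
(KO sets semicolon-joined), per-gene capability reports, gene catalogs,
gene x sample count matrices (dense TSV or MatrixMarket triplets with
side-car label files), sample manifests, taxonomic hit tables, and the bin
QC tables.  Alignment hit tables use the BLAST/DIAMOND outfmt-6 column
order (no header), via :func:`iaa_atlas.annotation.read_outfmt6`.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import scipy.io
import scipy.sparse

from .annotation import AlignmentHit, GenomeProfile
from .binqc import BinRecord, PairwiseSim
from .lca import TaxHit, format_lineage, parse_lineage

__all__ = [
    "read_manifest",
    "read_ko_map",
    "write_profiles",
    "read_profiles",
    "write_hits_outfmt6",
    "read_gene_catalog",
    "write_gene_catalog",
    "read_counts",
    "write_counts",
    "read_samples",
    "read_tax_hits",
    "read_bins",
    "read_pairwise_sims",
]


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"genome_id", "phylum"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if df["genome_id"].duplicated().any():
        dup = df.loc[df["genome_id"].duplicated(), "genome_id"].iloc[0]
        raise ValueError(f"duplicate genome_id in manifest: {dup!r}")
    return df


def read_ko_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", header=None, names=["subject_id", "ko_id"], dtype=str)
    return dict(zip(df["subject_id"], df["ko_id"]))


def write_ko_map(ko_map: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(sorted(ko_map.items())).to_csv(
        path, sep="\t", header=False, index=False
    )


def write_profiles(profiles: Iterable[GenomeProfile], path: str | Path) -> None:
    rows = [
        {
            "genome_id": p.genome_id,
            "phylum": p.phylum,
            "n_genes": p.n_genes,
            "ko_set": ";".join(sorted(p.ko_set)),
        }
        for p in profiles
    ]
    pd.DataFrame(rows, columns=["genome_id", "phylum", "n_genes", "ko_set"]).to_csv(
        path, sep="\t", index=False
    )


def read_profiles(path: str | Path) -> list[GenomeProfile]:
    df = pd.read_csv(path, sep="\t", dtype={"genome_id": str, "phylum": str})
    profiles = []
    for row in df.itertuples(index=False):
        raw = "" if pd.isna(row.ko_set) else str(row.ko_set)
        kos = frozenset(k for k in raw.split(";") if k)
        profiles.append(
            GenomeProfile(
                genome_id=row.genome_id,
                phylum=row.phylum,
                ko_set=kos,
                n_genes=int(row.n_genes),
            )
        )
    return profiles


def write_hits_outfmt6(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    """Write hits as a 12-column outfmt-6 table (placeholder coordinates)."""
    rows = [
        (
            h.query_id, h.subject_id, round(h.identity * 100.0, 1),
            100, 0, 0, 1, 100, 1, 100,
            f"{h.evalue:.3g}", f"{h.score:.1f}",
        )
        for h in hits
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_gene_catalog(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "contig_id": str})
    missing = {"gene_id", "length"} - set(df.columns)
    if missing:
        raise ValueError(f"gene catalog missing columns: {sorted(missing)}")
    if "ko_id" in df.columns:
        df["ko_id"] = df["ko_id"].where(df["ko_id"].notna(), None)
    if "lineage" in df.columns:
        df["lineage"] = [
            parse_lineage(x) if isinstance(x, str) else ()
            for x in df["lineage"]
        ]
    return df


def write_gene_catalog(genes: pd.DataFrame, path: str | Path) -> None:
    out = genes.copy()
    if "lineage" in out.columns:
        out["lineage"] = [
            format_lineage(l) if not isinstance(l, str) else l
            for l in out["lineage"]
        ]
    out.to_csv(path, sep="\t", index=False)


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a gene x sample count matrix: dense TSV, or MTX with side cars.

    For ``matrix.mtx``, row labels are read from ``<stem>.genes.tsv`` and
    column labels from ``<stem>.samples.tsv`` next to it.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        mat = scipy.io.mmread(path)
        genes = pd.read_csv(path.with_suffix(".genes.tsv"), header=None)[0]
        samples = pd.read_csv(path.with_suffix(".samples.tsv"), header=None)[0]
        return pd.DataFrame(
            scipy.sparse.coo_matrix(mat).toarray(), index=genes, columns=samples
        )
    return pd.read_csv(path, sep="\t", index_col=0)


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".mtx":
        scipy.io.mmwrite(path, scipy.sparse.csr_matrix(counts.to_numpy()))
        counts.index.to_series().to_csv(
            path.with_suffix(".genes.tsv"), header=False, index=False
        )
        counts.columns.to_series().to_csv(
            path.with_suffix(".samples.tsv"), header=False, index=False
        )
    else:
        counts.to_csv(path, sep="\t")


def read_samples(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"sample_id", "compartment"} - set(df.columns)
    if missing:
        raise ValueError(f"sample manifest missing columns: {sorted(missing)}")
    bad = set(df["compartment"]) - {"RS", "RP"}
    if bad:
        raise ValueError(f"unknown compartment label(s): {sorted(bad)}")
    return df


def read_tax_hits(path: str | Path) -> dict[str, list[TaxHit]]:
    """Read (gene_id, lineage, identity, coverage[, score]) rows grouped by gene."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "lineage": str})
    out: dict[str, list[TaxHit]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.gene_id, []).append(
            TaxHit(
                lineage=parse_lineage(row.lineage),
                identity=float(row.identity),
                coverage=float(row.coverage),
                score=float(getattr(row, "score", 0.0)),
            )
        )
    return out


def read_bins(
    bins_path: str | Path,
    markers_path: str | Path | None = None,
    scaffolds_path: str | Path | None = None,
    genes_path: str | Path | None = None,
) -> list[BinRecord]:
    """Assemble BinRecords from the bin/marker/scaffold/gene-location tables."""
    bins_df = pd.read_csv(bins_path, sep="\t", dtype={"bin_id": str})
    markers: dict[str, dict[str, int]] = {}
    if markers_path is not None:
        mdf = pd.read_csv(markers_path, sep="\t", dtype={"bin_id": str, "marker_id": str})
        for row in mdf.itertuples(index=False):
            markers.setdefault(row.bin_id, {})[row.marker_id] = int(row.copy_number)
    scaffolds: dict[str, dict[str, str]] = {}
    if scaffolds_path is not None:
        sdf = pd.read_csv(scaffolds_path, sep="\t", dtype=str)
        for row in sdf.itertuples(index=False):
            scaffolds.setdefault(row.bin_id, {})[row.scaffold_id] = row.label
    genes: dict[str, dict[str, tuple[str, str | None]]] = {}
    if genes_path is not None:
        gdf = pd.read_csv(genes_path, sep="\t", dtype=str)
        for row in gdf.itertuples(index=False):
            role = None if pd.isna(row.role_id) else row.role_id
            genes.setdefault(row.bin_id, {})[row.gene_id] = (row.scaffold_id, role)
    records = []
    for row in bins_df.itertuples(index=False):
        records.append(
            BinRecord(
                bin_id=row.bin_id,
                completeness=float(row.completeness),
                contamination=float(row.contamination),
                marker_counts=markers.get(row.bin_id, {}),
                scaffold_labels=scaffolds.get(row.bin_id, {}),
                gene_locations=genes.get(row.bin_id, {}),
                phylum=getattr(row, "phylum", None),
            )
        )
    return records


def read_pairwise_sims(path: str | Path) -> list[PairwiseSim]:
    df = pd.read_csv(path, sep="\t", dtype={"bin_a": str, "bin_b": str})
    return [
        PairwiseSim(
            bin_a=row.bin_a,
            bin_b=row.bin_b,
            gani_ab=float(row.gani_ab),
            gani_ba=float(row.gani_ba),
            af_ab=float(row.af_ab),
            af_ba=float(row.af_ba),
        )
        for row in df.itertuples(index=False)
    ]
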