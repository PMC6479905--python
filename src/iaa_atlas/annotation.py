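"""Per-genome functional annotation from protein-vs-KEGG alignment tables.

The survey's genome atlas starts from DIAMOND/BLAST tabular output
(outfmt 6).  Hits are filtered with the thresholds E-value < 1e-5 and
alignment (bit) score >= 60, a single best hit is retained per query gene
(ties broken deterministically: score, then E-value, then subject id), and
the surviving subject identifiers are mapped to KEGG orthology (KO) labels
to yield one KO set per genome.  Genomes with no retained pathway KO stay
in every denominator downstream — they are incapable, not missing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "AlignmentHit",
    "FilterThresholds",
    "GenomeProfile",
    "filter_hits",
    "best_hit_per_query",
    "build_genome_profile",
    "build_genome_profiles",
    "annotation_concordance",
    "read_outfmt6",
    "OUTFMT6_COLUMNS",
]

#: BLAST/DIAMOND tabular default column order.
OUTFMT6_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)


@dataclass(frozen=True)
class AlignmentHit:
    query_id: str
    subject_id: str
    evalue: float
    score: float
    ko_id: str | None = None
    identity: float = 0.0
    coverage: float = 0.0

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"hit {self.query_id}->{self.subject_id}: evalue < 0")
        if self.score < 0:
            raise ValueError(f"hit {self.query_id}->{self.subject_id}: score < 0")


@dataclass(frozen=True)
class FilterThresholds:
    """Alignment retention thresholds.

    E-value is compared strictly (<), the score non-strictly (>=).
    """

    max_evalue: float = 1e-5
    min_score: float = 60.0

    def __post_init__(self) -> None:
        if self.max_evalue <= 0:
            raise ValueError("max_evalue must be > 0")
        if self.min_score < 0:
            raise ValueError("min_score must be >= 0")


@dataclass(frozen=True)
class GenomeProfile:
    """One genome's identity, phylum label and retained KO set."""

    genome_id: str
    phylum: str
    ko_set: frozenset[str]
    n_genes: int = 0


def filter_hits(
    hits: Iterable[AlignmentHit],
    thresholds: FilterThresholds = FilterThresholds(),
) -> list[AlignmentHit]:
    """Retain hits with evalue strictly below and score at or above threshold."""
    return [
        h for h in hits
        if h.evalue < thresholds.max_evalue and h.score >= thresholds.min_score
    ]


def _best_key(hit: AlignmentHit) -> tuple:
    return (-hit.score, hit.evalue, hit.subject_id)


def best_hit_per_query(hits: Iterable[AlignmentHit]) -> dict[str, AlignmentHit]:
    """One hit per query: highest score, then lowest E-value, then subject id.

    The tie-break chain makes the result invariant under permutation of the
    input.
    """
    best: dict[str, AlignmentHit] = {}
    for hit in hits:
        cur = best.get(hit.query_id)
        if cur is None or _best_key(hit) < _best_key(cur):
            best[hit.query_id] = hit
    return best


def build_genome_profile(
    genome_id: str,
    phylum: str,
    best_hits: Mapping[str, AlignmentHit] | Iterable[AlignmentHit],
    ko_map: Mapping[str, str] | None = None,
) -> GenomeProfile:
    """Collapse best hits into a genome's KO set.

    ``ko_map`` translates subject ids to KO labels; subjects absent from it
    (and hits whose own ``ko_id`` is unset) count toward ``n_genes`` but
    contribute nothing to the KO set.
    """
    if isinstance(best_hits, Mapping):
        hits = list(best_hits.values())
    else:
        hits = list(best_hits)
    kos = set()
    for hit in hits:
        ko = hit.ko_id
        if ko is None and ko_map is not None:
            ko = ko_map.get(hit.subject_id)
        if ko is not None:
            kos.add(ko)
    return GenomeProfile(
        genome_id=genome_id, phylum=phylum, ko_set=frozenset(kos), n_genes=len(hits)
    )


def build_genome_profiles(
    batches: Iterable[tuple[str, str, Mapping[str, AlignmentHit]]],
    ko_map: Mapping[str, str] | None = None,
) -> list[GenomeProfile]:
    """Profile a batch of genomes; duplicate genome ids are an error."""
    seen: set[str] = set()
    profiles = []
    for genome_id, phylum, best in batches:
        if genome_id in seen:
            raise ValueError(f"duplicate genome_id {genome_id!r} in batch")
        seen.add(genome_id)
        profiles.append(build_genome_profile(genome_id, phylum, best, ko_map))
    return profiles


def annotation_concordance(
    profile_a: Mapping[str, str], profile_b: Mapping[str, str]
) -> float:
    """Fraction of genes labeled in A that carry the same label in B.

    Used to compare two independent functional annotations of the same gene
    set (e.g. KEGG- vs COG-derived labels).  The denominator is all genes
    labeled in A; genes unlabeled in B count as discordant.
    """
    if not profile_a:
        warnings.warn("annotation_concordance: empty reference mapping", stacklevel=2)
        return 0.0
    agree = sum(
        1 for gene, label in profile_a.items() if profile_b.get(gene) == label
    )
    return agree / len(profile_a)


def read_outfmt6(path: str | Path) -> list[AlignmentHit]:
    """Read a BLAST/DIAMOND outfmt-6 table into hits.

    Extra trailing columns are ignored; a non-numeric evalue or bitscore is
    reported with its 1-based line number.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] < len(OUTFMT6_COLUMNS):
        raise ValueError(
            f"{path}: expected >= {len(OUTFMT6_COLUMNS)} tab-separated columns, "
            f"got {df.shape[1]}"
        )
    df = df.iloc[:, : len(OUTFMT6_COLUMNS)]
    df.columns = list(OUTFMT6_COLUMNS)
    hits = []
    for lineno, row in enumerate(df.itertuples(index=False), start=1):
        try:
            evalue = float(row.evalue)
            score = float(row.bitscore)
            identity = float(row.pident) / 100.0
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed numeric field: {exc}") from exc
        hits.append(
            AlignmentHit(
                query_id=row.qseqid,
                subject_id=row.sseqid,
                evalue=evalue,
                score=score,
                identity=identity,
            )
        )
    return hits
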