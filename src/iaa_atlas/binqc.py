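"""Quality control and dereplication of metagenome-assembled genomes (bins).

Bins are retained when CheckM-style completeness >= 70% and contamination
<= 10%; for phylogenetic work they must additionally carry at least 8 of
the 16 universal single-copy marker genes, each in exactly one copy.
Redundant bins across assemblies are collapsed by clustering pairs with
genome-wide average nucleotide identity (gANI) >= 99.9% and alignment
fraction (AF) >= 90%; since ANI tools report both directions, gANI is
combined as the mean of directions and AF as the minimum (conservative),
both configurable.  Plasmid-localisation summaries and gap-column trimming
of concatenated marker alignments round out the stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx

from .catalog import PathwayCatalog

__all__ = [
    "BinRecord",
    "PairwiseSim",
    "quality_filter",
    "marker_filter",
    "dereplicate",
    "plasmid_gene_fraction",
    "trim_alignment_columns",
]

SCAFFOLD_LABELS = ("plasmid", "chromosome", "unclassified")


@dataclass(frozen=True)
class BinRecord:
    """A metagenome-assembled genome with QC metrics and gene locations."""

    bin_id: str
    completeness: float
    contamination: float
    marker_counts: Mapping[str, int] = field(default_factory=dict)
    scaffold_labels: Mapping[str, str] = field(default_factory=dict)
    gene_locations: Mapping[str, tuple[str, str | None]] = field(default_factory=dict)
    phylum: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.completeness <= 100.0:
            raise ValueError(f"bin {self.bin_id}: completeness outside [0, 100]")
        if self.contamination < 0.0:
            raise ValueError(f"bin {self.bin_id}: negative contamination")
        bad = [l for l in self.scaffold_labels.values() if l not in SCAFFOLD_LABELS]
        if bad:
            raise ValueError(f"bin {self.bin_id}: unknown scaffold label {bad[0]!r}")


@dataclass(frozen=True)
class PairwiseSim:
    """Directional gANI (percent) and AF (fraction) between two bins."""

    bin_a: str
    bin_b: str
    gani_ab: float
    gani_ba: float
    af_ab: float
    af_ba: float


def quality_filter(
    bins: Iterable[BinRecord],
    min_completeness: float = 70.0,
    max_contamination: float = 10.0,
) -> list[BinRecord]:
    """Boundary-inclusive completeness/contamination retention."""
    return [
        b for b in bins
        if b.completeness >= min_completeness and b.contamination <= max_contamination
    ]


def marker_filter(bins: Iterable[BinRecord], min_markers: int = 8) -> list[BinRecord]:
    """Keep bins with >= ``min_markers`` markers present, all single-copy."""
    kept = []
    for b in bins:
        present = {m: c for m, c in b.marker_counts.items() if c > 0}
        if len(present) >= min_markers and all(c == 1 for c in present.values()):
            kept.append(b)
    return kept


def dereplicate(
    bins: Iterable[BinRecord | str],
    sims: Iterable[PairwiseSim],
    min_gani: float = 99.9,
    min_af: float = 0.90,
    gani_combine: Callable[[float, float], float] = lambda a, b: (a + b) / 2.0,
    af_combine: Callable[[float, float], float] = min,
) -> list[frozenset[str]]:
    """Cluster bins whose combined gANI and AF reach the thresholds.

    Clusters are connected components of the qualifying-pair graph; bins
    with no qualifying partner are singleton clusters.  Pairs absent from
    ``sims`` are non-edges.
    """
    ids = [b.bin_id if isinstance(b, BinRecord) else b for b in bins]
    graph = nx.Graph()
    graph.add_nodes_from(ids)
    known = set(ids)
    for s in sims:
        if s.bin_a not in known or s.bin_b not in known:
            continue
        if (
            gani_combine(s.gani_ab, s.gani_ba) >= min_gani
            and af_combine(s.af_ab, s.af_ba) >= min_af
        ):
            graph.add_edge(s.bin_a, s.bin_b)
    clusters = [frozenset(c) for c in nx.connected_components(graph)]
    return sorted(clusters, key=lambda c: sorted(c)[0])


def plasmid_gene_fraction(
    bin_record: BinRecord,
    catalog: PathwayCatalog,
    include_unclassified: bool = True,
) -> dict[str, float]:
    """Per-pathway fraction of pathway-role genes on plasmid scaffolds.

    A role shared by several pathways counts toward each of them.  Pathways
    with no genes in the bin are absent from the result (blank, not zero).
    ``include_unclassified=False`` drops unclassified scaffolds from the
    denominators as well.
    """
    totals: dict[str, int] = {}
    on_plasmid: dict[str, int] = {}
    for gene_id, (scaffold_id, role_id) in bin_record.gene_locations.items():
        if scaffold_id not in bin_record.scaffold_labels:
            raise ValueError(
                f"bin {bin_record.bin_id}: gene {gene_id!r} on unknown "
                f"scaffold {scaffold_id!r}"
            )
        if role_id is None:
            continue
        label = bin_record.scaffold_labels[scaffold_id]
        if label == "unclassified" and not include_unclassified:
            continue
        for pathway in catalog.pathways_of_role(role_id):
            totals[pathway] = totals.get(pathway, 0) + 1
            if label == "plasmid":
                on_plasmid[pathway] = on_plasmid.get(pathway, 0) + 1
    return {
        pathway: on_plasmid.get(pathway, 0) / total
        for pathway, total in sorted(totals.items())
    }


def trim_alignment_columns(
    rows: Sequence[str],
    max_gap_fraction: float = 0.70,
    gap_chars: str = "-.",
) -> list[str]:
    """Remove alignment columns whose gap fraction strictly exceeds the cap.

    ``rows`` are equal-length aligned sequences; row order is preserved and
    an all-gap alignment degenerates to rows of length zero.
    """
    rows = list(rows)
    if not rows:
        return []
    width = len(rows[0])
    for i, row in enumerate(rows):
        if len(row) != width:
            raise ValueError(
                f"alignment rows differ in length (row 0 is {width}, row {i} is {len(row)})"
            )
    n = len(rows)
    gaps = set(gap_chars)
    keep = [
        col for col in range(width)
        if sum(1 for row in rows if row[col] in gaps) / n <= max_gap_fraction
    ]
    return ["".join(row[col] for col in keep) for row in rows]
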