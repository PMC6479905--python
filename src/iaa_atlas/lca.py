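"""Lowest-common-ancestor taxonomy assignment for metagenomic genes.

A gene's alignment hits against a reference protein database each carry a
taxonomic lineage (semicolon-delimited ranks, domain outward).  Hits are
first filtered with coverage >= 0.8 and identity >= 0.65 (both inclusive,
as printed); the gene is then assigned the longest common rank prefix of
the surviving lineages.  No bit-score windowing is applied by default —
``score_window`` enables the common "within x% of the best score" heuristic
as a documented extension.

A lineage is a tuple of rank names truncated only at the tail; the empty
tuple renders as ``Unknown``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "TaxHit",
    "UNKNOWN",
    "parse_lineage",
    "format_lineage",
    "filter_tax_hits",
    "lca_assign",
]

Lineage = tuple[str, ...]

#: The unassignable lineage (no informative hits).
UNKNOWN: Lineage = ()

_UNKNOWN_NAMES = {"", "unknown", "unclassified", "na"}


@dataclass(frozen=True)
class TaxHit:
    lineage: Lineage
    identity: float
    coverage: float
    score: float = 0.0

    def __post_init__(self) -> None:
        for name, value in (("identity", self.identity), ("coverage", self.coverage)):
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")


def parse_lineage(text: str, sep: str = ";") -> Lineage:
    """Parse ``Bacteria;Proteobacteria;...`` into a rank tuple.

    Empty or placeholder tails are trimmed; internal empty ranks are not
    allowed (lineages truncate only at the tail).
    """
    parts = [p.strip() for p in text.split(sep)]
    while parts and parts[-1].lower() in _UNKNOWN_NAMES:
        parts.pop()
    if any(p.lower() in _UNKNOWN_NAMES for p in parts):
        raise ValueError(f"lineage {text!r} has an empty internal rank")
    return tuple(parts)


def format_lineage(lineage: Lineage, sep: str = ";") -> str:
    return sep.join(lineage) if lineage else "Unknown"


def filter_tax_hits(
    hits: Iterable[TaxHit],
    min_coverage: float = 0.8,
    min_identity: float = 0.65,
) -> list[TaxHit]:
    """Retain hits with coverage and identity at or above the thresholds."""
    return [
        h for h in hits
        if h.coverage >= min_coverage and h.identity >= min_identity
    ]


def lca_assign(
    hits: Sequence[TaxHit], score_window: float | None = None
) -> Lineage:
    """Longest common lineage prefix of the (filtered) hits.

    No hits -> ``UNKNOWN``; a single hit keeps its full lineage.  With
    ``score_window`` set (e.g. 0.1), only hits scoring within that relative
    margin of the best hit participate.
    """
    hits = list(hits)
    if score_window is not None and hits:
        top = max(h.score for h in hits)
        hits = [h for h in hits if h.score >= top * (1.0 - score_window)]
    if not hits:
        return UNKNOWN
    prefix = list(hits[0].lineage)
    for hit in hits[1:]:
        depth = 0
        for a, b in zip(prefix, hit.lineage):
            if a != b:
                break
            depth += 1
        del prefix[depth:]
        if not prefix:
            break
    return tuple(prefix)
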