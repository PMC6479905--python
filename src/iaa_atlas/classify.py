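"""Three-part IAA-capability classification of genomes and cohort summaries.

Each genome is scored against the pathway catalog in three parts:

1. *Trp-catalyzing step* — which enzyme roles consuming tryptophan are
   present, i.e. which first intermediates the genome can reach.
2. *De novo synthesis* — which pathways have at least one fully covered
   route from Trp to IAA.
3. *Synthesis from intermediates* — for each key intermediate (IPA, TPM,
   IAM, IAN), which routes to IAA are fully covered.

A role is "present" in a genome iff the genome's KO set intersects the
role's KO set.  A pathway is *complete* when a de novo route is covered and
*partial* when an intermediate route is covered but no de novo route is.
Per-genome calls collapse into a canonical combination signature; cohorts
collapse into per-phylum summary tables, chi-square preference tests and
rarefaction curves of distinct signatures.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GenomeProfile
from .catalog import PathwayCatalog, Route

__all__ = [
    "CapabilityReport",
    "CoexistenceCounts",
    "classify_genome",
    "classify_cohort",
    "coexistence_counts",
    "combination_signature",
    "phylum_summary",
    "phylum_preference_test",
    "rarefy_combinations",
    "reports_to_frame",
]

EMPTY_SIGNATURE = "none"


@dataclass(frozen=True)
class CapabilityReport:
    """Per-genome capability calls for the three pathway parts."""

    genome_id: str
    phylum: str
    trp_products: frozenset[tuple[str, str]]  # (role_id, product metabolite)
    denovo_pathways: frozenset[str]
    intermediate_routes: Mapping[str, tuple[Route, ...]]
    partial_pathways: frozenset[str]
    n_trp_enzymes: int
    n_complete_pathways: int
    combination_signature: str

    @property
    def pathway_statuses(self) -> dict[str, str]:
        statuses = {p: "complete" for p in self.denovo_pathways}
        statuses.update({p: "partial" for p in self.partial_pathways})
        return statuses

    @property
    def n_pathways_any(self) -> int:
        """Pathways with complete-or-partial status (the 'diverse pathways' count)."""
        return len(self.denovo_pathways | self.partial_pathways)


class CoexistenceCounts(NamedTuple):
    n_trp_enzymes: int
    n_complete_pathways: int
    n_partial_pathways: int


def _signature(statuses: Mapping[str, str]) -> str:
    if not statuses:
        return EMPTY_SIGNATURE
    return "|".join(f"{p}:{s}" for p, s in sorted(statuses.items()))


def classify_genome(
    profile: GenomeProfile, catalog: PathwayCatalog
) -> CapabilityReport:
    """Classify one genome's KO set against the catalog."""
    ko_set = profile.ko_set
    present = {
        role_id for role_id, role in catalog.roles.items() if ko_set & role.ko_ids
    }

    trp_products = frozenset(
        (r.role_id, r.product) for r in catalog.trp_roles if r.role_id in present
    )
    denovo = frozenset(
        route.pathway_id
        for route in catalog.denovo_routes()
        if all(step in present for step in route.steps)
    )
    intermediate_routes: dict[str, tuple[Route, ...]] = {}
    for met in catalog.intermediate_ids:
        covered = tuple(
            route for route in catalog.routes_from(met)
            if all(step in present for step in route.steps)
        )
        intermediate_routes[met] = covered
    partial = frozenset(
        catalog.pathway_of(met)
        for met, covered in intermediate_routes.items()
        if covered and catalog.pathway_of(met) not in denovo
    )

    statuses = {p: "complete" for p in denovo}
    statuses.update({p: "partial" for p in partial})
    return CapabilityReport(
        genome_id=profile.genome_id,
        phylum=profile.phylum,
        trp_products=trp_products,
        denovo_pathways=denovo,
        intermediate_routes=intermediate_routes,
        partial_pathways=partial,
        n_trp_enzymes=len(trp_products),
        n_complete_pathways=len(denovo),
        combination_signature=_signature(statuses),
    )


def classify_cohort(
    profiles: Iterable[GenomeProfile], catalog: PathwayCatalog
) -> list[CapabilityReport]:
    return [classify_genome(p, catalog) for p in profiles]


def coexistence_counts(report: CapabilityReport) -> CoexistenceCounts:
    """Counts of coexisting Trp-catalyzing roles and complete/partial pathways."""
    return CoexistenceCounts(
        n_trp_enzymes=report.n_trp_enzymes,
        n_complete_pathways=report.n_complete_pathways,
        n_partial_pathways=len(report.partial_pathways),
    )


def combination_signature(
    report: CapabilityReport, by_route: bool = False
) -> str:
    """Canonical encoding of which pathways are complete or partial.

    With ``by_route=True`` the signature lists the covered intermediate
    route variants instead of collapsing to pathway level.
    """
    if not by_route:
        return _signature(report.pathway_statuses)
    parts = sorted(
        route.route_id
        for covered in report.intermediate_routes.values()
        for route in covered
    )
    parts += sorted(f"denovo:{p}" for p in report.denovo_pathways)
    return "|".join(parts) if parts else EMPTY_SIGNATURE


def reports_to_frame(reports: Sequence[CapabilityReport]) -> pd.DataFrame:
    """Flatten reports to one row per genome (the per-genome output table)."""
    rows = []
    for r in reports:
        rows.append(
            {
                "genome_id": r.genome_id,
                "phylum": r.phylum,
                "trp_products": ";".join(
                    sorted(f"{role}->{met}" for role, met in r.trp_products)
                ),
                "denovo_pathways": ";".join(sorted(r.denovo_pathways)),
                "partial_pathways": ";".join(sorted(r.partial_pathways)),
                "n_trp_enzymes": r.n_trp_enzymes,
                "n_complete_pathways": r.n_complete_pathways,
                "n_pathways_any": r.n_pathways_any,
                "combination_signature": r.combination_signature,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "genome_id", "phylum", "trp_products", "denovo_pathways",
            "partial_pathways", "n_trp_enzymes", "n_complete_pathways",
            "n_pathways_any", "combination_signature",
        ],
    )


def phylum_summary(
    reports: Sequence[CapabilityReport], catalog: PathwayCatalog
) -> pd.DataFrame:
    """Per-phylum counts and percentages for every capability category.

    Returns a tidy table with columns ``phylum, panel, category, count,
    n_genomes, percentage``.  Panels:

    * ``trp_catalysis`` — genomes converting Trp into each first product.
    * ``trp_enzyme`` — genomes carrying each Trp-consuming role.
    * ``denovo`` — genomes with a complete route from Trp, per pathway.
    * ``from_intermediate`` — genomes covering each intermediate->IAA route
      variant.
    * ``from_intermediate_pathway`` — same, merged per pathway.
    * ``n_trp_enzymes`` / ``n_complete_pathways`` / ``n_pathways_any`` —
      coexistence histograms (category is the integer count).

    Denominators are all genomes of the phylum, including genomes with no
    pathway KO at all.
    """
    by_phylum: dict[str, list[CapabilityReport]] = {}
    for r in reports:
        by_phylum.setdefault(r.phylum, []).append(r)

    rows = []

    def emit(phylum: str, panel: str, category: str, count: int, n: int) -> None:
        rows.append(
            {
                "phylum": phylum,
                "panel": panel,
                "category": category,
                "count": count,
                "n_genomes": n,
                "percentage": 100.0 * count / n if n else 0.0,
            }
        )

    intermediate_pathway = {
        m: catalog.pathway_of(m) for m in catalog.intermediate_ids
    }
    for phylum in sorted(by_phylum):
        grp = by_phylum[phylum]
        n = len(grp)
        products = sorted({r.product for r in catalog.trp_roles})
        for met in products:
            count = sum(
                1 for r in grp if any(p == met for _, p in r.trp_products)
            )
            emit(phylum, "trp_catalysis", met, count, n)
        for role in sorted(catalog.trp_roles, key=lambda r: r.role_id):
            count = sum(
                1 for r in grp if any(rid == role.role_id for rid, _ in r.trp_products)
            )
            emit(phylum, "trp_enzyme", role.role_id, count, n)
        for pathway in catalog.pathway_ids:
            count = sum(1 for r in grp if pathway in r.denovo_pathways)
            emit(phylum, "denovo", pathway, count, n)
        for met in catalog.intermediate_ids:
            for route in catalog.routes_from(met):
                count = sum(
                    1 for r in grp
                    if any(
                        c.route_id == route.route_id
                        for c in r.intermediate_routes.get(met, ())
                    )
                )
                emit(phylum, "from_intermediate", route.route_id, count, n)
            count = sum(1 for r in grp if r.intermediate_routes.get(met))
            emit(
                phylum, "from_intermediate_pathway",
                intermediate_pathway[met], count, n,
            )
        for panel, getter in (
            ("n_trp_enzymes", lambda r: r.n_trp_enzymes),
            ("n_complete_pathways", lambda r: r.n_complete_pathways),
            ("n_pathways_any", lambda r: r.n_pathways_any),
        ):
            hist = Counter(getter(r) for r in grp)
            for value in sorted(hist):
                emit(phylum, panel, str(value), hist[value], n)
    return pd.DataFrame(
        rows,
        columns=["phylum", "panel", "category", "count", "n_genomes", "percentage"],
    )


def phylum_preference_test(
    table: pd.DataFrame | np.ndarray,
) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on a phylum x category table.

    No continuity correction is applied.  Returns (statistic, dof, p-value).
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (arr < 0).any():
        raise ValueError("contingency table contains negative counts")
    row_sums = arr.sum(axis=1)
    col_sums = arr.sum(axis=0)
    is_frame = isinstance(table, pd.DataFrame)
    for axis_name, sums, labels in (
        ("row", row_sums, table.index if is_frame else None),
        ("column", col_sums, table.columns if is_frame else None),
    ):
        zero = np.nonzero(sums == 0)[0]
        if zero.size:
            name = labels[zero[0]] if labels is not None else zero[0]
            raise ValueError(f"contingency table has zero-total {axis_name}: {name!r}")
    res = stats.chi2_contingency(arr, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def rarefy_combinations(
    reports: Sequence[CapabilityReport],
    depths: Sequence[int],
    replicates: int = 100,
    seed: int | np.random.Generator = 0,
    by_route: bool = False,
) -> pd.DataFrame:
    """Rarefaction of distinct combination signatures.

    For each depth, subsamples genomes without replacement ``replicates``
    times and counts distinct signatures; reports mean and (population)
    standard deviation per depth.  Fully seeded and reproducible.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    signatures = np.array(
        [combination_signature(r, by_route=by_route) for r in reports], dtype=object
    )
    n = len(signatures)
    rows = []
    for depth in depths:
        if depth < 1 or depth > n:
            raise ValueError(f"depth {depth} outside [1, {n}]")
        counts = np.empty(replicates)
        for i in range(replicates):
            idx = rng.choice(n, size=depth, replace=False)
            counts[i] = len(set(signatures[idx]))
        rows.append(
            {
                "depth": depth,
                "mean_distinct": float(counts.mean()),
                "sd_distinct": float(counts.std(ddof=0)),
                "replicates": replicates,
            }
        )
    return pd.DataFrame(rows, columns=["depth", "mean_distinct", "sd_distinct", "replicates"])
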