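"""Synthetic cohorts, alignment tables, metagenomes and bins with planted truth.

Every analysis stage of the package is testable without external downloads:
this module fabricates inputs whose ground truth is known by construction
and returned alongside the data.

* :func:`simulate_genomes` plants per-phylum pathway-capability patterns
  and emits genome KO sets plus a truth table of pre-noise capabilities.
* :func:`simulate_hit_table` wraps KO sets in noisy DIAMOND-style hits
  (decoys below the best hit, sub-threshold hits violating the filters) so
  filtering + best-hit retention must reconstruct the profiles exactly.
* :func:`simulate_metagenome` emits a gene catalog, a negative-binomial
  gene x sample count matrix whose expected read mass is proportional to
  planted KO share x gene length (so the reads/length correction removes
  length bias in expectation), lineages from a small synthetic taxonomy,
  and a handful of genes planted to fail catalog QC.
* :func:`simulate_bins` emits bins with planted QC outcomes, marker-gene
  copy tables, a planted dereplication partition realised in pairwise
  gANI/AF values, and plasmid/chromosome scaffold labels.

All draws flow from a single :class:`numpy.random.Generator` seeded by the
scenario, so identical seeds give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import AlignmentHit, GenomeProfile, best_hit_per_query, filter_hits
from .binqc import BinRecord, PairwiseSim
from .catalog import PathwayCatalog, default_catalog
from .classify import classify_genome, reports_to_frame
from .lca import Lineage

__all__ = [
    "CohortScenario",
    "MetagenomeScenario",
    "DEFAULT_PHYLUM_COUNTS",
    "DEFAULT_STATUS_PROBS",
    "simulate_genomes",
    "simulate_hit_table",
    "recover_profiles",
    "simulate_metagenome",
    "simulate_bins",
]

#: Desk-scale cohort preserving the published five-phylum shape
#: (114/923/281/1705/4259 genomes scaled to ~500 total).
DEFAULT_PHYLUM_COUNTS: dict[str, int] = {
    "Acidobacteria": 8,
    "Actinobacteria": 63,
    "Bacteroidetes": 19,
    "Firmicutes": 117,
    "Proteobacteria": 293,
}

#: Per-phylum, per-pathway probabilities of the planted capability status
#: (remaining mass is "none").  Values approximate the published per-phylum
#: capability percentages; they are conditions of the default scenario, not
#: fitted quantities.  IAN de novo stays 0 everywhere: no bacterial
#: Trp->IAOX orthologue is expected under the default catalog.
DEFAULT_STATUS_PROBS: dict[str, dict[str, dict[str, float]]] = {
    "Acidobacteria": {
        "IAM": {"denovo": 0.36, "partial": 0.20, "trp_only": 0.12},
        "TPM": {"denovo": 0.24, "partial": 0.15, "trp_only": 0.42},
        "IPA": {"denovo": 0.01, "partial": 0.30, "trp_only": 0.01},
        "IAN": {"partial": 0.35},
    },
    "Actinobacteria": {
        "IAM": {"denovo": 0.29, "partial": 0.25, "trp_only": 0.01},
        "TPM": {"denovo": 0.09, "partial": 0.20, "trp_only": 0.05},
        "IPA": {"denovo": 0.005, "partial": 0.32, "trp_only": 0.007},
        "IAN": {"partial": 0.55},
    },
    "Bacteroidetes": {
        "IAM": {"denovo": 0.07, "partial": 0.20, "trp_only": 0.06},
        "TPM": {"denovo": 0.09, "partial": 0.15, "trp_only": 0.08},
        "IPA": {"denovo": 0.01, "partial": 0.20, "trp_only": 0.02},
        "IAN": {"partial": 0.45},
    },
    "Firmicutes": {
        "IAM": {"denovo": 0.02, "partial": 0.25, "trp_only": 0.02},
        "TPM": {"denovo": 0.065, "partial": 0.20, "trp_only": 0.013},
        "IPA": {"denovo": 0.005, "partial": 0.22, "trp_only": 0.026},
        "IAN": {"partial": 0.40},
    },
    "Proteobacteria": {
        "IAM": {"denovo": 0.10, "partial": 0.30, "trp_only": 0.05},
        "TPM": {"denovo": 0.06, "partial": 0.20, "trp_only": 0.06},
        "IPA": {"denovo": 0.045, "partial": 0.15, "trp_only": 0.64},
        "IAN": {"partial": 0.60},
    },
}

_STATUSES = ("denovo", "partial", "trp_only")


@dataclass(frozen=True)
class CohortScenario:
    """Study conditions for a synthetic genome cohort."""

    phylum_counts: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_PHYLUM_COUNTS)
    )
    status_probs: Mapping[str, Mapping[str, Mapping[str, float]]] = field(
        default_factory=lambda: DEFAULT_STATUS_PROBS
    )
    decoy_rate: float = 0.2
    subthreshold_rate: float = 0.1
    ko_dropout: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for phylum, count in self.phylum_counts.items():
            if count < 0:
                raise ValueError(f"negative genome count for phylum {phylum!r}")
        for rate_name in ("decoy_rate", "subthreshold_rate", "ko_dropout"):
            rate = getattr(self, rate_name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{rate_name} outside [0, 1]: {rate}")
        for phylum, per_pathway in self.status_probs.items():
            for pathway, probs in per_pathway.items():
                for status, p in probs.items():
                    if status not in _STATUSES:
                        raise ValueError(f"unknown status {status!r}")
                    if not 0.0 <= p <= 1.0:
                        raise ValueError(
                            f"prevalence outside [0, 1]: {phylum}/{pathway}/{status}"
                        )
                if sum(probs.values()) > 1.0 + 1e-12:
                    raise ValueError(
                        f"status probabilities exceed 1 for {phylum}/{pathway}"
                    )


@dataclass(frozen=True)
class MetagenomeScenario:
    """Study conditions for a synthetic root-environment metagenome.

    The 27 rhizosphere + 19 rhizoplane sample design is the default; gene
    counts are drawn negative-binomially with variance m + dispersion*m^2.
    """

    n_rs: int = 27
    n_rp: int = 19
    n_genes: int = 2000
    n_background_kos: int = 50
    unannotated_fraction: float = 0.05
    qc_fail_fraction: float = 0.02
    unknown_lineage_fraction: float = 0.2
    sequencing_depth: float = 2e5
    dispersion: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rs < 1 or self.n_rp < 1:
            raise ValueError("both compartments need at least one sample")
        if self.sequencing_depth <= 0:
            raise ValueError("sequencing_depth must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


# ---------------------------------------------------------------------------
# genome cohort
# ---------------------------------------------------------------------------


def _draw_status(rng: np.random.Generator, probs: Mapping[str, float]) -> str:
    p = [probs.get(s, 0.0) for s in _STATUSES]
    p.append(max(0.0, 1.0 - sum(p)))
    return rng.choice([*_STATUSES, "none"], p=np.array(p) / sum(p))


def simulate_genomes(
    scenario: CohortScenario,
    catalog: PathwayCatalog | None = None,
    seed: int | None = None,
) -> tuple[list[GenomeProfile], pd.DataFrame]:
    """Plant per-pathway capability patterns and emit KO sets plus truth.

    For each genome and pathway a status is drawn (de novo / partial /
    Trp-step only / none) and a matching set of enzyme roles is planted,
    one KO per role.  Because some roles serve several pathways (the IAM
    hydrolase, the aldehyde dehydrogenase), planting one pathway can upgrade
    another; the truth table therefore records the *realised* pre-noise
    capability (the classification of the noise-free KO set), which the
    classifier must recover exactly at zero noise.  KO dropout, when
    enabled, then thins each KO independently.
    """
    catalog = catalog or default_catalog()
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    denovo_by_pathway: dict[str, list] = {}
    for route in catalog.denovo_routes():
        denovo_by_pathway.setdefault(route.pathway_id, []).append(route)
    pathway_intermediate = {
        catalog.pathway_of(m): m for m in catalog.intermediate_ids
    }
    trp_roles_by_pathway: dict[str, list] = {}
    for role in catalog.trp_roles:
        trp_roles_by_pathway.setdefault(
            catalog.pathway_of(role.product), []
        ).append(role)

    profiles: list[GenomeProfile] = []
    truth_rows = []
    idx = 0
    for phylum in sorted(scenario.phylum_counts):
        per_pathway = scenario.status_probs.get(phylum, {})
        for _ in range(scenario.phylum_counts[phylum]):
            genome_id = f"G{idx:05d}"
            idx += 1
            roles: set[str] = set()
            planted: dict[str, str] = {}
            for pathway in catalog.pathway_ids:
                status = _draw_status(rng, per_pathway.get(pathway, {}))
                planted[pathway] = status
                if status == "denovo":
                    options = denovo_by_pathway.get(pathway)
                    if not options:
                        raise ValueError(
                            f"no de novo route exists for pathway {pathway!r}"
                        )
                    route = options[rng.integers(len(options))]
                    roles.update(route.steps)
                elif status == "partial":
                    options = catalog.routes_from(pathway_intermediate[pathway])
                    route = options[rng.integers(len(options))]
                    roles.update(route.steps)
                elif status == "trp_only":
                    options = trp_roles_by_pathway.get(pathway)
                    if not options:
                        raise ValueError(
                            f"pathway {pathway!r} has no Trp-catalyzing role"
                        )
                    roles.add(options[rng.integers(len(options))].role_id)
            kos = set()
            for role_id in sorted(roles):
                choices = sorted(catalog.roles[role_id].ko_ids)
                kos.add(choices[rng.integers(len(choices))])
            clean = GenomeProfile(
                genome_id=genome_id,
                phylum=phylum,
                ko_set=frozenset(kos),
                n_genes=len(kos),
            )
            report = classify_genome(clean, catalog)
            truth_rows.append(
                {
                    "genome_id": genome_id,
                    "phylum": phylum,
                    "planted": "|".join(
                        f"{p}:{s}" for p, s in sorted(planted.items()) if s != "none"
                    ) or "none",
                    "trp_products": ";".join(
                        sorted(f"{r}->{m}" for r, m in report.trp_products)
                    ),
                    "denovo_pathways": ";".join(sorted(report.denovo_pathways)),
                    "partial_pathways": ";".join(sorted(report.partial_pathways)),
                    "n_trp_enzymes": report.n_trp_enzymes,
                    "n_complete_pathways": report.n_complete_pathways,
                    "combination_signature": report.combination_signature,
                }
            )
            if scenario.ko_dropout > 0:
                kos = {
                    ko for ko in sorted(kos)
                    if rng.random() >= scenario.ko_dropout
                }
            profiles.append(replace(clean, ko_set=frozenset(kos)))
    return profiles, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# alignment hit tables
# ---------------------------------------------------------------------------


def simulate_hit_table(
    profiles: Sequence[GenomeProfile],
    decoy_rate: float = 0.2,
    subthreshold_rate: float = 0.1,
    seed: int = 0,
) -> tuple[list[AlignmentHit], dict[str, str]]:
    """Wrap KO sets in a noisy alignment table plus a subject->KO map.

    Each planted KO yields one confident hit (E-value <= 1e-20, score >=
    90).  Decoys attach to the same query with a strictly lower — but still
    filter-passing — score and a wrong KO; sub-threshold hits violate
    either the E-value or score bound.  Filtering followed by best-hit
    retention must therefore reconstruct the KO sets exactly.  Query ids
    are ``<genome_id>::g<i>``.
    """
    rng = np.random.default_rng(seed)
    hits: list[AlignmentHit] = []
    ko_map: dict[str, str] = {}
    decoy_counter = 0
    for profile in profiles:
        for i, ko in enumerate(sorted(profile.ko_set)):
            query = f"{profile.genome_id}::g{i}"
            subject = f"{ko}|ref"
            ko_map[subject] = ko
            score = float(rng.uniform(90.0, 300.0))
            hits.append(
                AlignmentHit(
                    query_id=query,
                    subject_id=subject,
                    evalue=float(10.0 ** rng.uniform(-80, -20)),
                    score=score,
                    identity=float(rng.uniform(0.5, 1.0)),
                )
            )
            if rng.random() < decoy_rate:
                decoy_counter += 1
                decoy_subject = f"DECOY{decoy_counter:05d}|ref"
                ko_map[decoy_subject] = f"K9{decoy_counter:04d}"
                hits.append(
                    AlignmentHit(
                        query_id=query,
                        subject_id=decoy_subject,
                        evalue=float(10.0 ** rng.uniform(-18, -6)),
                        score=float(score - rng.uniform(5.0, 25.0)),
                        identity=float(rng.uniform(0.3, 0.8)),
                    )
                )
            if rng.random() < subthreshold_rate:
                decoy_counter += 1
                bad_subject = f"WEAK{decoy_counter:05d}|ref"
                ko_map[bad_subject] = f"K8{decoy_counter:04d}"
                if rng.random() < 0.5:  # fails the strict E-value bound
                    evalue, bad_score = float(10.0 ** rng.uniform(-5, -1)), 80.0
                else:  # fails the score bound
                    evalue, bad_score = 1e-30, float(rng.uniform(0.0, 59.9))
                hits.append(
                    AlignmentHit(
                        query_id=query,
                        subject_id=bad_subject,
                        evalue=evalue,
                        score=bad_score,
                        identity=float(rng.uniform(0.2, 0.6)),
                    )
                )
    order = rng.permutation(len(hits))
    return [hits[i] for i in order], ko_map


def recover_profiles(
    hits: Sequence[AlignmentHit],
    ko_map: Mapping[str, str],
    phylum_of_genome: Mapping[str, str],
    thresholds=None,
) -> list[GenomeProfile]:
    """Filter + best-hit + KO mapping, grouped by the ``genome::gene`` convention."""
    from .annotation import FilterThresholds, build_genome_profile

    thresholds = thresholds or FilterThresholds()
    best = best_hit_per_query(filter_hits(hits, thresholds))
    by_genome: dict[str, dict[str, AlignmentHit]] = {g: {} for g in phylum_of_genome}
    for query, hit in best.items():
        genome_id = query.split("::", 1)[0]
        if genome_id not in by_genome:
            raise ValueError(f"query {query!r} references unknown genome {genome_id!r}")
        by_genome[genome_id][query] = hit
    return [
        build_genome_profile(g, phylum_of_genome[g], by_genome[g], ko_map)
        for g in sorted(by_genome)
    ]


# ---------------------------------------------------------------------------
# metagenome
# ---------------------------------------------------------------------------

_TAX_PHYLA = (
    "Proteobacteria", "Actinobacteria", "Bacteroidetes", "Firmicutes", "Acidobacteria",
)


def _draw_lineage(rng: np.random.Generator) -> Lineage:
    phylum = _TAX_PHYLA[rng.integers(len(_TAX_PHYLA))]
    cls = f"{phylum}_c{rng.integers(1, 3)}"
    order = f"{cls}_o{rng.integers(1, 3)}"
    family = f"{order}_f{rng.integers(1, 3)}"
    return ("Bacteria", phylum, cls, order, family)


def _nb_counts(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    p = shape / (shape + mean)
    return rng.negative_binomial(shape, p)


def simulate_metagenome(
    scenario: MetagenomeScenario,
    catalog: PathwayCatalog | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict]:
    """Emit (gene catalog, gene x sample counts, sample manifest, truth).

    Planted per-compartment KO shares are Dirichlet draws over the catalog
    KOs plus background KOs; each KO's mass is split evenly over its genes
    and scaled by gene length, so dividing counts by length recovers the
    shares in expectation.  A small fraction of genes is planted to fail
    catalog QC (short gene or short contig) with inflated counts, and a
    fraction carries no KO or an unknown lineage.
    """
    scenario_seed = scenario.seed if seed is None else seed
    rng = np.random.default_rng(scenario_seed)
    catalog = catalog or default_catalog()

    # the Trp->IAOX oxidoreductase has no bacterial orthologue: plant no
    # abundance for roles reaching outside the intermediate/terminal set
    absent_kos = {
        ko
        for role in catalog.roles.values()
        if role.substrate == catalog.source
        and role.product != catalog.terminal
        and not catalog.metabolites[role.product].is_intermediate
        for ko in role.ko_ids
    }
    iaa_kos = sorted(catalog.all_ko_ids - absent_kos)
    background = [f"K7{i:04d}" for i in range(scenario.n_background_kos)]
    kos = iaa_kos + background
    n_kos = len(kos)

    shares = pd.DataFrame(
        {
            "RS": rng.dirichlet(np.ones(n_kos)),
            "RP": rng.dirichlet(np.ones(n_kos)),
        },
        index=kos,
    )

    n_pass = scenario.n_genes
    n_unannot = int(round(n_pass * scenario.unannotated_fraction))
    n_annot = n_pass - n_unannot
    # every KO gets at least one gene so shares are recoverable
    ko_of_gene = kos + [
        kos[rng.integers(n_kos)] for _ in range(max(0, n_annot - n_kos))
    ]
    ko_of_gene = ko_of_gene[:n_annot] + [None] * n_unannot
    genes_per_ko = pd.Series([k for k in ko_of_gene if k]).value_counts()

    rows = []
    weights = np.zeros((n_pass, 2))  # expected abundance mass per compartment
    for gi, ko in enumerate(ko_of_gene):
        length = int(rng.integers(150, 1500))
        lineage = (
            ()
            if rng.random() < scenario.unknown_lineage_fraction
            else _draw_lineage(rng)
        )
        if ko is None:
            w_rs = w_rp = float(rng.uniform(0.2, 1.0)) / max(1, n_unannot) * 0.05
        else:
            w_rs = shares.loc[ko, "RS"] / genes_per_ko[ko]
            w_rp = shares.loc[ko, "RP"] / genes_per_ko[ko]
        weights[gi] = (w_rs, w_rp)
        rows.append(
            {
                "gene_id": f"gene{gi:05d}",
                "contig_id": f"contig{gi:05d}",
                "length": length,
                "contig_length": length + int(rng.integers(350, 1000)),
                "ko_id": ko,
                "lineage": lineage,
            }
        )

    # genes planted to fail QC, with deliberately loud counts
    n_fail = int(round(n_pass * scenario.qc_fail_fraction))
    qc_fail_genes = []
    for fi in range(n_fail):
        gid = f"failgene{fi:05d}"
        qc_fail_genes.append(gid)
        if fi % 2 == 0:
            length, contig_length = int(rng.integers(60, 150)), 2000
        else:
            length, contig_length = int(rng.integers(150, 600)), int(rng.integers(200, 500))
        rows.append(
            {
                "gene_id": gid,
                "contig_id": f"failcontig{fi:05d}",
                "length": length,
                "contig_length": contig_length,
                "ko_id": kos[rng.integers(n_kos)],
                "lineage": _draw_lineage(rng),
            }
        )

    genes = pd.DataFrame(rows)
    samples = pd.DataFrame(
        {
            "sample_id": [f"RS{i + 1:02d}" for i in range(scenario.n_rs)]
            + [f"RP{i + 1:02d}" for i in range(scenario.n_rp)],
            "compartment": ["RS"] * scenario.n_rs + ["RP"] * scenario.n_rp,
        }
    )

    comp_idx = {"RS": 0, "RP": 1}
    lengths = genes["length"].to_numpy(float)
    counts = np.zeros((len(genes), len(samples)), dtype=np.int64)
    fail_weight = 5.0 / max(1, n_fail)
    for si, comp in enumerate(samples["compartment"]):
        w = np.concatenate([weights[:, comp_idx[comp]], np.full(n_fail, fail_weight)])
        mean = scenario.sequencing_depth * w * lengths / 1000.0
        counts[:, si] = _nb_counts(rng, mean, scenario.dispersion)
    counts_df = pd.DataFrame(
        counts, index=genes["gene_id"], columns=samples["sample_id"]
    )

    # planted taxon (phylum) shares among QC-passing genes, per compartment
    taxon_rows: dict[str, np.ndarray] = {}
    for gi in range(n_pass):
        lineage = rows[gi]["lineage"]
        phylum = lineage[1] if len(lineage) > 1 else "Unknown"
        taxon_rows.setdefault(phylum, np.zeros(2))
        taxon_rows[phylum] += weights[gi]
    taxon_shares = pd.DataFrame(taxon_rows).T
    taxon_shares.columns = ["RS", "RP"]
    taxon_shares = taxon_shares / taxon_shares.sum(axis=0)

    truth = {
        "ko_shares": shares,
        "taxon_shares": taxon_shares.sort_index(),
        "qc_fail_genes": qc_fail_genes,
        "seed": scenario_seed,
    }
    return genes, counts_df, samples, truth


# ---------------------------------------------------------------------------
# bins
# ---------------------------------------------------------------------------


def simulate_bins(
    n: int = 30,
    catalog: PathwayCatalog | None = None,
    completeness_range: tuple[float, float] = (50.0, 100.0),
    contamination_range: tuple[float, float] = (0.0, 15.0),
    plasmid_fraction: float = 0.2,
    unclassified_fraction: float = 0.1,
    cluster_sizes: Sequence[int] | None = None,
    seed: int = 0,
) -> tuple[list[BinRecord], list[PairwiseSim], dict]:
    """Emit bins, pairwise gANI/AF values realising a planted partition, truth.

    ``cluster_sizes`` lists the planted multi-bin clusters (default 2/3/5);
    remaining bins are singletons.  Within-cluster pairs get gANI ~99.9+
    and AF > 0.9, cross-cluster pairs stay clearly below both thresholds.
    ``plasmid_fraction`` is the probability that a pathway gene lands on a
    plasmid-labeled scaffold; truth records the realised per-pathway
    fractions and the QC/marker outcomes.
    """
    if n < 1:
        raise ValueError("need at least one bin")
    rng = np.random.default_rng(seed)
    catalog = catalog or default_catalog()
    cluster_sizes = list(cluster_sizes) if cluster_sizes is not None else [2, 3, 5]
    if sum(cluster_sizes) > n:
        raise ValueError("cluster sizes exceed the number of bins")

    bin_ids = [f"bin{i:03d}" for i in range(n)]
    clusters: list[list[str]] = []
    cursor = 0
    for size in cluster_sizes:
        clusters.append(bin_ids[cursor : cursor + size])
        cursor += size
    clusters.extend([[b] for b in bin_ids[cursor:]])

    markers = [f"M{i:02d}" for i in range(1, 17)]
    role_ids = sorted(catalog.roles)
    bins: list[BinRecord] = []
    plasmid_truth: dict[str, dict[str, list[int]]] = {}
    qc_pass, marker_pass = [], []
    for bin_id in bin_ids:
        completeness = float(rng.uniform(*completeness_range))
        contamination = float(rng.uniform(*contamination_range))
        n_markers = int(rng.integers(5, 17))
        chosen = rng.choice(markers, size=n_markers, replace=False)
        marker_counts = {
            m: (2 if rng.random() < 0.1 else 1) for m in sorted(chosen)
        }
        n_scaffolds = int(rng.integers(5, 12))
        scaffold_labels = {}
        for si in range(n_scaffolds):
            u = rng.random()
            if u < unclassified_fraction:
                label = "unclassified"
            elif u < unclassified_fraction + 0.3:
                label = "plasmid"
            else:
                label = "chromosome"
            scaffold_labels[f"{bin_id}_s{si}"] = label
        plasmids = [s for s, l in scaffold_labels.items() if l == "plasmid"]
        chromosomes = [
            s for s, l in scaffold_labels.items() if l == "chromosome"
        ] or list(scaffold_labels)
        if not plasmids:
            scaffold_labels[f"{bin_id}_sp"] = "plasmid"
            plasmids = [f"{bin_id}_sp"]

        gene_locations: dict[str, tuple[str, str | None]] = {}
        counters: dict[str, list[int]] = {}
        n_genes = int(rng.integers(3, 9))
        picked = rng.choice(role_ids, size=n_genes, replace=True)
        for gi, role_id in enumerate(picked):
            if rng.random() < plasmid_fraction:
                scaffold = plasmids[rng.integers(len(plasmids))]
            else:
                scaffold = chromosomes[rng.integers(len(chromosomes))]
            gene_locations[f"{bin_id}_g{gi}"] = (scaffold, str(role_id))
            is_plasmid = scaffold_labels[scaffold] == "plasmid"
            for pathway in catalog.pathways_of_role(str(role_id)):
                total, plas = counters.get(pathway, [0, 0])
                counters[pathway] = [total + 1, plas + (1 if is_plasmid else 0)]
        plasmid_truth[bin_id] = counters

        record = BinRecord(
            bin_id=bin_id,
            completeness=completeness,
            contamination=contamination,
            marker_counts=marker_counts,
            scaffold_labels=scaffold_labels,
            gene_locations=gene_locations,
        )
        bins.append(record)
        if completeness >= 70.0 and contamination <= 10.0:
            qc_pass.append(bin_id)
        present = {m: c for m, c in marker_counts.items() if c > 0}
        if len(present) >= 8 and all(c == 1 for c in present.values()):
            marker_pass.append(bin_id)

    sims: list[PairwiseSim] = []
    for cluster in clusters:
        for i in range(len(cluster)):
            for j in range(i + 1, len(cluster)):
                sims.append(
                    PairwiseSim(
                        bin_a=cluster[i],
                        bin_b=cluster[j],
                        gani_ab=float(rng.uniform(99.92, 100.0)),
                        gani_ba=float(rng.uniform(99.92, 100.0)),
                        af_ab=float(rng.uniform(0.92, 0.99)),
                        af_ba=float(rng.uniform(0.92, 0.99)),
                    )
                )
    # a sprinkling of clearly sub-threshold cross-cluster pairs
    for _ in range(min(50, n * 2)):
        a, b = rng.choice(n, size=2, replace=False)
        if any(bin_ids[a] in c and bin_ids[b] in c for c in clusters):
            continue
        sims.append(
            PairwiseSim(
                bin_a=bin_ids[a],
                bin_b=bin_ids[b],
                gani_ab=float(rng.uniform(80.0, 99.0)),
                gani_ba=float(rng.uniform(80.0, 99.0)),
                af_ab=float(rng.uniform(0.05, 0.6)),
                af_ba=float(rng.uniform(0.05, 0.6)),
            )
        )

    truth = {
        "clusters": [frozenset(c) for c in clusters],
        "qc_pass": qc_pass,
        "marker_pass": marker_pass,
        "plasmid_fractions": {
            bin_id: {
                pathway: plas / total
                for pathway, (total, plas) in counters.items()
            }
            for bin_id, counters in plasmid_truth.items()
        },
    }
    return bins, sims, truth
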