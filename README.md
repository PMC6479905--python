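# iaa-atlas

Genome- and metagenome-scale survey of **tryptophan-dependent indole-3-acetic
acid (IAA) biosynthesis** in bacteria.

IAA is the principal auxin phytohormone; many root-associated bacteria
synthesize it from tryptophan (Trp) through four canonical pathways named
after their first committed intermediate — indole-3-pyruvate (**IPA**),
tryptamine (**TPM**), indole-3-acetamide (**IAM**) and indole-3-acetonitrile
(**IAN**). This package answers, for any collection of annotated genomes or
for metagenomic samples, the questions a microbiome researcher asks about
that trait:

* **Which genomes can do what?** Each pathway is decomposed into three
  parts — the Trp-catalyzing first step, de novo synthesis (a complete
  enzyme chain Trp → IAA), and synthesis from an intermediate (a complete
  chain intermediate → IAA). A genome's KEGG-orthology (KO) set is scored
  against a declarative pathway catalog: a role is present iff the KO set
  intersects the role's KOs; a pathway is *complete* when some Trp → IAA
  route is fully covered and *partial* when only an intermediate → IAA
  route is.
* **How do pathways combine?** Coexisting complete/partial pathways
  collapse into canonical combination signatures; per-phylum summaries,
  chi-square preference tests and seeded rarefaction curves of distinct
  combinations quantify pathway preferences across taxa.
* **Who does it in the root environment?** For rhizosphere (RS) and
  rhizoplane (RP) metagenomes, gene abundance is reads-mapped ÷ gene
  length; KO and taxon profiles are additive roll-ups, gene taxonomy comes
  from a lowest-common-ancestor rule over filtered protein hits, and
  group-relative abundances compare enzyme groups between compartments.
* **Are the MAGs trustworthy, and where do the genes sit?** Bin quality
  and marker-gene filters, gANI/AF dereplication, plasmid-localisation
  fractions and gap-column trimming of marker alignments.

Every stage is testable without downloads: `iaa_atlas.synthetic` generates
genome cohorts, noisy alignment tables, metagenome count matrices and bins
with planted ground truth.

## Worked example

```python
from iaa_atlas import default_catalog, GenomeProfile, classify_genome, coexistence_counts

catalog = default_catalog()          # the four-pathway Trp -> IAA graph
genome = GenomeProfile(
    "Pa01", "Proteobacteria",
    frozenset({"K00466", "K01426", "K01501"}),  # iaaM, iaaH, nitrilase
    n_genes=3,
)
report = classify_genome(genome, catalog)
print(report.combination_signature)
print(sorted(report.trp_products))
print(coexistence_counts(report))
```

prints

```
IAM:complete|IAN:partial
[('trp_monooxygenase_iaaM', 'IAM')]
CoexistenceCounts(n_trp_enzymes=1, n_complete_pathways=1, n_partial_pathways=1)
```

meaning: the genome carries the tryptophan-2-monooxygenase (*iaaM*) first
step, completes the IAM pathway de novo (*iaaM* + *iaaH*), and could
additionally convert exogenous IAN to IAA via its nitrilase — a partial
IAN pathway, since no bacterial Trp → IAOX enzyme exists to feed it.

At cohort scale, on the default synthetic cohort of 500 genomes
(`CohortScenario(seed=1)`), the per-phylum summary reports e.g. that
209/293 (71.3%) of Proteobacteria catalyze Trp into IPA while only
34/293 (11.6%) complete the IAM pathway de novo — the same Fig-2-style
bubble-table the genome survey writes as `phylum_summary.tsv`.

The same analyses run from the shell:

```sh
atlas simulate hits --seed 5 --out sim/
atlas annotate --hits sim/hits.tsv --ko-map sim/ko_map.tsv \
               --manifest sim/manifest.tsv --out profiles.tsv
atlas profile --profiles profiles.tsv --out survey/
atlas quantify --genes genes.tsv --counts counts.tsv --samples samples.tsv --out fig3/
```

## Layout

| module | contents |
| --- | --- |
| `iaa_atlas.catalog` | declarative pathway catalog (metabolite/role graph, route enumeration) |
| `iaa_atlas.annotation` | alignment-hit filtering, best-hit retention, genome KO profiles |
| `iaa_atlas.classify` | three-part capability calls, signatures, summaries, chi-square, rarefaction |
| `iaa_atlas.lca` | hit filtering and prefix-LCA taxonomy assignment |
| `iaa_atlas.quant` | gene-catalog QC, abundance, KO/taxon profiles, group-relative shares |
| `iaa_atlas.binqc` | bin quality/marker filters, gANI/AF dereplication, plasmid fractions, alignment trimming |
| `iaa_atlas.synthetic` | seeded generators with planted truth for all of the above |
| `iaa_atlas.workbench` | end-to-end genome and metagenome surveys (`RunConfig`) |
| `iaa_atlas.cli` | the `atlas` command |

See `docs/methods.md` for the model, its assumptions, defaults and known
limitations.
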