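# Methods

## The pathway model

Bacterial Trp-dependent IAA synthesis is represented as a directed
multigraph: nodes are metabolites (Trp, IPA, TPM, IAM, IAN, IAOX, IAAld,
IAA), edges are enzyme roles, and each role carries the set of KEGG
orthology identifiers that evidences it. A *route* is a simple role-path
ending at IAA; routes are enumerated exhaustively (networkx
`all_simple_edge_paths`) at catalog construction, so classification never
hard-codes chemistry. A route belongs to the pathway of its first
intermediate (for Trp-rooted routes) or of its start metabolite; the
non-intermediate IAOX is pinned to the IAN pathway in the catalog config.

The default catalog encodes the canonical four-pathway graph:

* IAM: Trp →(iaaM, K00466) IAM →(iaaH/amidase, K01426) IAA.
* IPA: Trp →(aromatic aminotransferase K00838 or L-amino-acid oxidase
  K03334) IPA, then either one-step YUCCA-like monooxygenase (K11816) or
  ipdC decarboxylase (K04103) + aldehyde dehydrogenase (K00128/K14085).
* TPM: Trp →(aromatic-L-amino-acid decarboxylase K01593) TPM →(amine
  oxidase K00274) IAAld →(dehydrogenase) IAA.
* IAN: IAN →(nitrilase K01501) IAA, or IAN →(nitrile hydratase K01721)
  IAM →(iaaH) IAA. The Trp → IAOX oxidoreductase is representable (plant
  CYP79B-like KOs K11812/K11813) but has no known bacterial orthologue, so
  under the default catalog IAN is never completable de novo.

Shared roles legitimately serve several pathways: iaaH serves IAM and IAN
(via the hydratase), the aldehyde dehydrogenase serves IPA and TPM. The
Trp side-chain oxidase (TSO) shortcut is deliberately not modeled: it is
restricted to a few *Pseudomonas* strains and adds no classification
signal at phylum scale. KO rosters are configuration
(`data/default_catalog.yaml`), not code; users can swap in their own
lists without touching the classifier.

## Capability classification

A role is *present* in a genome iff the genome's KO set intersects the
role's KO set (one matching KO suffices — orthology groups are treated as
interchangeable evidence). Per genome we report:

* the Trp-catalyzing roles present and the intermediates they produce;
* *de novo* pathways: pathways with at least one fully covered Trp → IAA
  route (route variants merge for the completeness call but are reported
  separately in summaries);
* *from-intermediate* routes: for each of IPA/TPM/IAM/IAN, the fully
  covered routes to IAA; a pathway with such a route but no de novo route
  is *partial*;
* coexistence counts (distinct Trp-catalyzing roles, complete pathways,
  partial pathways) and a canonical combination signature
  (`IAM:complete|TPM:partial`, sorted, `none` when empty). A route-level
  signature variant distinguishes YUCCA- from ipdC-type completions.

Counting "disparate Trp-catalyzing enzymes" counts roles, not KOs: one
enzyme class may carry several orthology groups. Percentages are always
over *all* genomes of a phylum — genomes with zero pathway KOs are
incapable, not missing, and stay in every denominator.

Preference tests use Pearson's chi-square of independence without
continuity correction on phylum × category count tables; zero-margin rows
or columns are rejected by name rather than silently propagating NaNs.
Rarefaction subsamples genomes without replacement at each depth,
replicated with a seeded generator; it reports the per-depth mean and
population standard deviation of distinct signatures.

## Annotation

Alignment tables (DIAMOND/BLAST outfmt 6) are filtered with E-value
strictly below 1e-5 and bit score at or above 60 — the comparison
strictness mirrors how the thresholds are conventionally printed, and
"alignment score" is read as the bit-score column since that is what the
aligners emit. One best hit is retained per query, filtering first;
ties break deterministically by score, then E-value, then subject id, so
results are invariant under input permutation. Subjects then map to KOs;
genes without a KO count toward gene totals but not KO sets.
`annotation_concordance` compares any two gene→label maps (e.g. KEGG- vs
COG-derived) as the fraction of reference-labeled genes with an identical
label in the other map.

## Gene taxonomy (LCA)

Taxonomic hits are filtered with coverage ≥ 0.8 and identity ≥ 0.65, both
inclusive. The assignment is the longest common rank-prefix of the
surviving lineages: no hits → Unknown, one hit → its full lineage.
Lineages truncate only at the tail; internal gaps are rejected at parse
time. No bit-score windowing is applied by default — the plain rule is
what is implemented, and a `score_window` option exposes the common
"within x% of the best score" heuristic explicitly.

## Metagenome quantification

Catalog QC drops genes shorter than 150 bp and genes on contigs shorter
than 500 bp (both inclusive retention bounds). Gene abundance is reads
mapped ÷ gene length in bp, with no per-kilobase rescaling: the length
unit cancels in every relative quantity the package reports. KO and taxon
profiles are additive roll-ups; genes whose lineage lacks the requested
rank aggregate under `Unknown`. The pipeline is linear in the input
counts, and KO mass is conserved exactly over mapped genes.

Group-relative abundances (each member's share of its enzyme group's
total) are computed per sample; compartment summaries **average per-sample
shares** rather than pooling counts, because per-sample normalisation is
robust to library-size differences between samples — a pooled-mass mode
is available behind a flag since both conventions occur in practice.
Zero-mass samples return all-zero shares with a warning instead of NaNs.
The "last step" enzyme group (IAA-producing) is derived from the catalog
as all roles whose product is IAA (iaaH/amidase, nitrilase, aldehyde
dehydrogenase, YUCCA), so it tracks any user-supplied catalog.

## Bin QC and dereplication

Bins are retained at completeness ≥ 70% and contamination ≤ 10%
(inclusive); phylogenetic screening additionally requires ≥ 8 of the 16
universal single-copy markers, each in exactly one copy. Marker
identifiers are free-form labels. Dereplication clusters connected
components of the pair graph whose combined gANI ≥ 99.9% and AF ≥ 0.90;
because ANI tools report both directions, gANI combines as the mean of
directions and AF as the minimum — the conservative choice, since a low
alignment fraction in either direction undermines the comparison — and
both combiners are injectable. Plasmid fractions divide pathway-role
genes on plasmid-labeled scaffolds by all pathway-role genes; pathways
with no genes are absent from the result (a blank, not a zero), and
unclassified scaffolds count in denominators only (a flag excludes them
entirely). Alignment trimming removes columns whose gap fraction strictly
exceeds 0.70, so exactly-70% columns survive.

## Synthetic data: what it emulates, and what it does not

`CohortScenario` defaults to 500 genomes in the five-phylum proportions
of large public collections (8 Acidobacteria / 63 Actinobacteria / 19
Bacteroidetes / 117 Firmicutes / 293 Proteobacteria) with per-phylum,
per-pathway status probabilities (de novo / partial / Trp-step-only)
approximating the capability prevalences reported for such collections —
e.g. Trp→IPA conversion is common in Proteobacteria while its full IPA
pathway is rare, and IAN is never planted de novo. These are fixed study
conditions of the default scenario, not fitted quantities.

Genome construction plants one KO per chosen role. Because shared roles
serve several pathways, planting one pathway can upgrade another (e.g.
an IAN-partial genome using the hydratase route also becomes
IAM-partial); the truth table therefore records the *realised* pre-noise
capability — the classification of the noise-free KO set — which the
classifier must then recover exactly. KO dropout thins each planted KO
independently, giving the closed-form expectation
`prevalence x (1 - dropout)^k` for a k-step route built from single-KO
roles; the acceptance checks use a single-pathway scenario so no
cross-pathway rescue perturbs that expectation.

Hit tables give every planted KO one confident hit (score ≥ 90, E-value
≤ 1e-20); decoys share the query but sit strictly below the best score
while still passing the filters, and sub-threshold hits violate exactly
one bound — so reconstruction through filter + best-hit must be exact at
any decoy rate by construction.

`MetagenomeScenario` defaults to the 27 rhizosphere + 19 rhizoplane
design with a 2,000-gene catalog. Counts are negative-binomial
(variance m + dispersion·m², dispersion 0.1 by default; 0 gives Poisson)
with mean proportional to planted KO share × gene length, split evenly
over a KO's genes — so the reads÷length correction removes length bias in
expectation and per-compartment KO shares are recoverable. 5% of genes
are unannotated, 20% carry unknown lineages, and 2% are planted to fail
catalog QC with inflated counts (so skipping QC visibly distorts
profiles). Scale (desk-size catalogs, two-level taxonomy per rank) keeps
the default test run in seconds.

What the generators do **not** emulate: sequence-level realism (no reads,
no alignments, no homology structure), compositionality and zero
inflation of real count data, phylogenetic correlation of capabilities
within a phylum, strain mixtures within bins, or chimeric contigs.
Passing recovery tests therefore demonstrates correctness of the
bookkeeping and statistics under the stated noise model, not robustness
to every artefact of real sequencing.

`simulate_bins` realises a planted partition (default clusters of 2/3/5
plus singletons) in pairwise gANI/AF values with a wide margin on either
side of the thresholds, draws completeness/contamination uniformly over
ranges that straddle the QC bounds, and places pathway genes on
plasmid-labeled scaffolds with a configurable probability, recording the
realised per-pathway fractions.

## Numerical and design choices

* All randomness flows from `numpy.random.default_rng(seed)`; identical
  seeds give byte-identical outputs, including survey tables on disk.
* Rarefaction reports the population (ddof 0) standard deviation, which
  makes the depth-equals-n case exactly zero.
* Best-hit and signature orderings are lexicographic so that no output
  depends on dict or input order.
* The chi-square test delegates to `scipy.stats.chi2_contingency`
  (`correction=False`); the test suite cross-checks it against a direct
  Σ(O−E)²/E loop and the 2×2 closed form.
* Empty inputs degrade explicitly: empty hit lists filter to empty,
  all-gap alignments trim to zero-length rows, zero-mass share columns
  warn and return zeros, empty concordance references warn and return 0.

## Known limitations

* Capability calls are genetic potential, not expression or activity;
  a "complete" pathway proves nothing about in vivo IAA titres.
* Presence by KO intersection cannot distinguish promiscuous enzyme
  families (nitrilases especially) from pathway-dedicated ones.
* The default KO roster follows KEGG map00380 conventions and may differ
  from any particular annotation pipeline's; swap the catalog config to
  match yours.
* Prefix-LCA ignores hit scores unless `score_window` is set, and
  rank-aligned name equality assumes a consistent taxonomy across hits.
* Read counts are taken as given; multi-mapping reads and mapping bias
  are upstream concerns.
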