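import numpy as np
import pandas as pd
import pytest

from iaa_atlas.annotation import FilterThresholds
from iaa_atlas.binqc import dereplicate, marker_filter, plasmid_gene_fraction, quality_filter
from iaa_atlas.classify import classify_genome
from iaa_atlas.quant import (
    compartment_mean_shares,
    gene_abundance,
    ko_profile,
    qc_catalog,
)
from iaa_atlas.synthetic import (
    CohortScenario,
    MetagenomeScenario,
    recover_profiles,
    simulate_bins,
    simulate_genomes,
    simulate_hit_table,
    simulate_metagenome,
)


class TestGenomeCohort:
    def test_zero_noise_recovery_is_exact(self, catalog):
        scenario = CohortScenario(seed=7)
        profiles, truth = simulate_genomes(scenario, catalog)
        assert len(profiles) == 500
        by_id = truth.set_index("genome_id")
        for p in profiles:
            rep = classify_genome(p, catalog)
            row = by_id.loc[p.genome_id]
            assert rep.combination_signature == row.combination_signature
            assert rep.n_trp_enzymes == row.n_trp_enzymes
            assert rep.n_complete_pathways == row.n_complete_pathways

    def test_same_seed_identical_output(self, catalog):
        a_profiles, a_truth = simulate_genomes(CohortScenario(seed=3), catalog)
        b_profiles, b_truth = simulate_genomes(CohortScenario(seed=3), catalog)
        assert a_profiles == b_profiles
        assert a_truth.equals(b_truth)

    def test_dropout_thinning_matches_closed_form(self, catalog):
        """A two-step pathway planted at 0.5 with dropout 0.1 completes at
        ~0.5 * 0.9^2, within 3 binomial standard errors."""
        n, prevalence, dropout = 1000, 0.5, 0.1
        scenario = CohortScenario(
            phylum_counts={"Synthetic": n},
            status_probs={"Synthetic": {"IAM": {"denovo": prevalence}}},
            ko_dropout=dropout,
            seed=13,
        )
        profiles, _ = simulate_genomes(scenario, catalog)
        observed = np.mean([
            "IAM" in classify_genome(p, catalog).denovo_pathways for p in profiles
        ])
        expected = prevalence * (1.0 - dropout) ** 2
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(observed - expected) <= 3 * se

    def test_invalid_prevalence_rejected(self):
        with pytest.raises(ValueError, match="prevalence"):
            CohortScenario(status_probs={"P": {"IAM": {"denovo": 1.5}}})

    def test_ian_never_denovo_under_default_scenario(self, catalog):
        profiles, truth = simulate_genomes(CohortScenario(seed=21), catalog)
        assert not truth.denovo_pathways.str.contains("IAN").any()


class TestHitTable:
    def test_zero_noise_reconstruction_exact(self, catalog):
        profiles, _ = simulate_genomes(CohortScenario(seed=2), catalog)
        hits, ko_map = simulate_hit_table(profiles, 0.0, 0.0, seed=4)
        rec = recover_profiles(
            hits, ko_map, {p.genome_id: p.phylum for p in profiles}
        )
        assert {p.genome_id: p.ko_set for p in rec} == {
            p.genome_id: p.ko_set for p in profiles
        }

    def test_heavy_decoys_never_displace_best(self, catalog):
        profiles, _ = simulate_genomes(CohortScenario(seed=5), catalog)
        hits, ko_map = simulate_hit_table(profiles, 0.5, 0.3, seed=6)
        rec = recover_profiles(
            hits, ko_map, {p.genome_id: p.phylum for p in profiles}
        )
        assert {p.genome_id: p.ko_set for p in rec} == {
            p.genome_id: p.ko_set for p in profiles
        }

    def test_subthreshold_only_ko_absent(self):
        """A KO evidenced only by hits violating the filters is not recovered."""
        from iaa_atlas.annotation import AlignmentHit, best_hit_per_query, filter_hits, build_genome_profile

        hits = [
            AlignmentHit("G::g0", "good|ref", 1e-30, 120.0),
            AlignmentHit("G::g1", "weak|ref", 1e-4, 120.0),   # fails E-value
            AlignmentHit("G::g2", "weak2|ref", 1e-30, 59.0),  # fails score
        ]
        ko_map = {"good|ref": "K1", "weak|ref": "K2", "weak2|ref": "K2"}
        best = best_hit_per_query(filter_hits(hits, FilterThresholds()))
        prof = build_genome_profile("G", "P", best, ko_map)
        assert prof.ko_set == {"K1"}


@pytest.fixture(scope="module")
def sim(catalog):
    scenario = MetagenomeScenario(seed=11)
    return scenario, simulate_metagenome(scenario, catalog)


class TestMetagenome:
    def test_sample_design(self, sim):
        _, (genes, counts, samples, truth) = sim
        assert (samples.compartment == "RS").sum() == 27
        assert (samples.compartment == "RP").sum() == 19
        assert counts.shape[1] == 46

    def test_qc_drops_exactly_the_planted_failures(self, sim):
        _, (genes, counts, samples, truth) = sim
        retained = qc_catalog(genes, dict(zip(genes.contig_id, genes.contig_length)))
        dropped = set(genes.gene_id) - set(retained.gene_id)
        assert dropped == set(truth["qc_fail_genes"])

    def test_planted_ko_shares_recovered_within_3se(self, sim):
        scenario, (genes, counts, samples, truth) = sim
        retained = qc_catalog(
            genes, dict(zip(genes.contig_id, genes.contig_length))
        ).set_index("gene_id")
        ab = gene_abundance(counts.reindex(retained.index), retained["length"])
        prof = ko_profile(ab, retained["ko_id"].dropna())
        comp = dict(zip(samples.sample_id, samples.compartment))
        group = list(truth["ko_shares"].index)
        per_sample = prof.reindex(group).fillna(0.0)
        per_sample = per_sample / per_sample.sum(axis=0)
        for compartment, n in (("RS", 27), ("RP", 19)):
            cols = [s for s in per_sample.columns if comp[s] == compartment]
            est = per_sample[cols].mean(axis=1)
            sem = per_sample[cols].std(axis=1, ddof=1) / np.sqrt(len(cols))
            diff = (est - truth["ko_shares"][compartment]).abs()
            # 3 SE plus a hair of slack for the ratio-estimator bias
            assert (diff <= 3 * sem + 1e-3).all()

    def test_length_bias_removed_in_expectation(self, catalog):
        """Two genes of one KO with different lengths get equal abundance."""
        scenario = MetagenomeScenario(seed=8, dispersion=0.0, n_genes=300,
                                      sequencing_depth=2e6)
        genes, counts, samples, truth = simulate_metagenome(scenario, catalog)
        genes = genes.set_index("gene_id")
        ab = gene_abundance(counts, genes["length"])
        annotated = genes[genes.ko_id.notna() & ~genes.index.str.startswith("fail")]
        for ko, members in annotated.groupby("ko_id").groups.items():
            if len(members) < 2:
                continue
            means = ab.loc[members].mean(axis=1)
            assert means.std() / means.mean() < 0.25
            break

    def test_same_seed_identical_matrices(self, catalog):
        scenario = MetagenomeScenario(seed=19, n_genes=200)
        _, a, _, _ = simulate_metagenome(scenario, catalog)
        _, b, _, _ = simulate_metagenome(scenario, catalog)
        assert a.equals(b)


class TestBins:
    def test_planted_clusters_recovered(self, catalog):
        bins, sims, truth = simulate_bins(
            n=20, catalog=catalog, cluster_sizes=[2, 3, 5], seed=31
        )
        clusters = set(dereplicate(bins, sims))
        assert clusters == set(truth["clusters"])
        assert sum(len(c) > 1 for c in clusters) == 3

    def test_qc_and_marker_truth(self, catalog):
        bins, _, truth = simulate_bins(n=40, catalog=catalog, seed=33)
        assert {b.bin_id for b in quality_filter(bins)} == set(truth["qc_pass"])
        assert {b.bin_id for b in marker_filter(bins)} == set(truth["marker_pass"])

    def test_lenient_qc_distributions_retain_all(self, catalog):
        bins, _, _ = simulate_bins(
            n=15, catalog=catalog, completeness_range=(70, 100),
            contamination_range=(0, 10), seed=35,
        )
        assert len(quality_filter(bins)) == 15

    def test_plasmid_fraction_truth_recovered(self, catalog):
        bins, _, truth = simulate_bins(n=25, catalog=catalog, seed=37)
        for b in bins:
            fractions = plasmid_gene_fraction(b, catalog)
            assert fractions == pytest.approx(truth["plasmid_fractions"][b.bin_id])

    def test_zero_plasmid_fraction(self, catalog):
        bins, _, _ = simulate_bins(n=10, catalog=catalog, plasmid_fraction=0.0, seed=39)
        for b in bins:
            for fraction in plasmid_gene_fraction(b, catalog).values():
                assert fraction == 0.0

    def test_determinism(self, catalog):
        a = simulate_bins(n=12, catalog=catalog, seed=41)
        b = simulate_bins(n=12, catalog=catalog, seed=41)
        assert a[0] == b[0]
        assert a[1] == b[1]
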