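from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iaa_atlas.annotation import GenomeProfile
from iaa_atlas.classify import (
    classify_genome,
    coexistence_counts,
    combination_signature,
    phylum_preference_test,
    phylum_summary,
    rarefy_combinations,
)

from .conftest import make_reduced_catalog
from .oracles import chi_square_direct, exhaustive_rarefaction_mean, oracle_capabilities


def profile(kos, genome_id="G1", phylum="Proteobacteria"):
    return GenomeProfile(genome_id, phylum, frozenset(kos), len(kos))


class TestClassifyExamples:
    def test_trp_step_only(self, catalog):
        rep = classify_genome(profile({"K00466"}), catalog)
        assert rep.trp_products == {("trp_monooxygenase_iaaM", "IAM")}
        assert rep.denovo_pathways == frozenset()
        assert all(not v for v in rep.intermediate_routes.values())

    def test_iaam_plus_iaah_completes_iam(self, catalog):
        rep = classify_genome(profile({"K00466", "K01426"}), catalog)
        assert rep.denovo_pathways == {"IAM"}
        assert [r.steps for r in rep.intermediate_routes["IAM"]] == [
            ("iam_hydrolase_iaaH",)
        ]

    def test_three_intact_pathways_coexist(self, catalog):
        # full IPA (aminotransferase + YUCCA), IAM (iaaM + iaaH),
        # TPM (decarboxylase + amine oxidase + dehydrogenase)
        kos = {"K00838", "K11816", "K00466", "K01426", "K01593", "K00274", "K00128"}
        rep = classify_genome(profile(kos), catalog)
        assert rep.denovo_pathways == {"IPA", "IAM", "TPM"}
        assert rep.n_complete_pathways == 3

    def test_nitrilase_only_is_partial_ian(self, catalog):
        rep = classify_genome(profile({"K01501"}), catalog)
        assert coexistence_counts(rep) == (0, 0, 1)
        assert rep.partial_pathways == {"IAN"}

    def test_empty_genome(self, catalog):
        rep = classify_genome(profile(set()), catalog)
        assert coexistence_counts(rep) == (0, 0, 0)
        assert rep.combination_signature == "none"

    def test_three_disparate_trp_enzymes(self, catalog):
        kos = {"K00838", "K01593", "K00466"}  # aminotransferase, decarboxylase, iaaM
        rep = classify_genome(profile(kos), catalog)
        assert rep.n_trp_enzymes == 3

    def test_denovo_never_contains_ian_without_oxidoreductase(self, catalog):
        """Bacterial KO sets lack the Trp->IAOX step, so IAN is never de novo."""
        every_bacterial_ko = catalog.all_ko_ids - {"K11812", "K11813"}
        rep = classify_genome(profile(every_bacterial_ko), catalog)
        assert "IAN" not in rep.denovo_pathways
        assert rep.denovo_pathways == {"IPA", "TPM", "IAM"}
        assert "IAN" in rep.partial_pathways


class TestOracleEquivalence:
    def test_exhaustive_reduced_catalog(self, reduced_catalog):
        """All 2^10 KO subsets agree with the brute-force path oracle."""
        kos = sorted(reduced_catalog.all_ko_ids)
        assert len(kos) == 10
        for mask in range(1 << len(kos)):
            subset = frozenset(k for i, k in enumerate(kos) if mask >> i & 1)
            rep = classify_genome(profile(subset), reduced_catalog)
            trp, denovo, inter, partial = oracle_capabilities(
                reduced_catalog, subset
            )
            assert rep.trp_products == trp, subset
            assert rep.denovo_pathways == denovo, subset
            assert rep.partial_pathways == partial, subset
            got_paths = {
                m: {r.steps for r in routes}
                for m, routes in rep.intermediate_routes.items()
            }
            assert got_paths == inter, subset

    @given(st.sets(st.sampled_from([f"X{i:02d}" for i in range(1, 11)])),
           st.sampled_from([f"X{i:02d}" for i in range(1, 11)]))
    @settings(deadline=None, derandomize=True, max_examples=100)
    def test_monotone_in_ko_set(self, kos, extra):
        """Adding a KO never removes a capability."""
        cat = make_reduced_catalog()
        small = classify_genome(profile(frozenset(kos)), cat)
        big = classify_genome(profile(frozenset(kos) | {extra}), cat)
        assert small.denovo_pathways <= big.denovo_pathways
        assert small.trp_products <= big.trp_products
        for met in cat.intermediate_ids:
            assert {r.route_id for r in small.intermediate_routes[met]} <= {
                r.route_id for r in big.intermediate_routes[met]
            }


class TestSignatures:
    def test_canonical_ordering(self, catalog):
        rep = classify_genome(
            profile({"K00466", "K01426", "K00274", "K00128"}), catalog
        )
        # IAM complete; TPM partial via amine oxidase + dehydrogenase
        assert rep.combination_signature == "IAM:complete|TPM:partial"

    def test_identical_capability_identical_signature(self, catalog):
        a = classify_genome(profile({"K00466", "K01426"}, genome_id="A"), catalog)
        b = classify_genome(
            profile({"K01426", "K00466"}, genome_id="B", phylum="Firmicutes"), catalog
        )
        assert a.combination_signature == b.combination_signature

    def test_planted_patterns_give_distinct_signatures(self, catalog):
        patterns = [{"K00466", "K01426"}, {"K01501"}, {"K01426"}]
        sigs = {
            classify_genome(profile(kos, genome_id=f"G{i}{j}"), catalog
                            ).combination_signature
            for j, kos in enumerate(patterns)
            for i in range(2)
        }
        assert len(sigs) == 3

    def test_route_level_signature_distinguishes_variants(self, catalog):
        nit = classify_genome(profile({"K01501"}), catalog)
        nhase = classify_genome(profile({"K01721", "K01426"}), catalog)
        assert combination_signature(nit, by_route=True) != combination_signature(
            nhase, by_route=True
        )


class TestPhylumSummary:
    def test_percentage_arithmetic(self, catalog):
        reports = [
            classify_genome(
                profile(
                    {"K01593", "K00274", "K00128"} if i < 5 else set(),
                    genome_id=f"G{i}", phylum="Firmicutes",
                ),
                catalog,
            )
            for i in range(10)
        ]
        summary = phylum_summary(reports, catalog)
        row = summary[
            (summary.panel == "denovo") & (summary.category == "TPM")
        ].iloc[0]
        assert row["count"] == 5
        assert row.percentage == pytest.approx(50.0)
        assert row.n_genomes == 10

    def test_zero_capable_phylum_all_zero(self, catalog):
        reports = [
            classify_genome(profile(set(), genome_id=f"G{i}", phylum="Acidobacteria"), catalog)
            for i in range(4)
        ]
        summary = phylum_summary(reports, catalog)
        capability = summary[~summary.panel.str.startswith("n_")]
        assert (capability.percentage == 0).all()

    def test_prevalence_recovery_within_binomial_bound(self, catalog):
        rng = np.random.default_rng(11)
        p, n = 0.3, 500
        reports = []
        for i in range(n):
            kos = {"K00466", "K01426"} if rng.random() < p else set()
            reports.append(
                classify_genome(profile(kos, genome_id=f"G{i}", phylum="P"), catalog)
            )
        summary = phylum_summary(reports, catalog)
        est = summary[
            (summary.panel == "denovo") & (summary.category == "IAM")
        ].percentage.iloc[0] / 100.0
        assert abs(est - p) <= 3 * np.sqrt(p * (1 - p) / n)


class TestPreferenceTest:
    def test_perfect_independence(self):
        stat, dof, p = phylum_preference_test([[10, 10], [10, 10]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_2x2_closed_form(self):
        # n*(ad-bc)^2 / (row and column products) = 40*(400)^2/(20*20*20*20)
        stat, dof, p = phylum_preference_test([[20, 0], [0, 20]])
        assert stat == pytest.approx(40.0)
        assert dof == 1

    def test_matches_direct_loop_on_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            shape = (rng.integers(2, 5), rng.integers(2, 6))
            table = rng.integers(1, 50, size=shape)
            stat, dof, _ = phylum_preference_test(table)
            expected_stat, expected_dof = chi_square_direct(table.tolist())
            assert stat == pytest.approx(expected_stat)
            assert dof == expected_dof

    def test_zero_margin_named(self):
        with pytest.raises(ValueError, match="zero-total"):
            phylum_preference_test([[0, 0], [5, 5]])


class TestRarefaction:
    def make_reports(self, catalog):
        planted = [
            {"K00466", "K01426"},
            {"K00466", "K01426"},
            {"K01501"},
            {"K01501"},
            {"K01426"},
        ]
        return [
            classify_genome(profile(kos, genome_id=f"G{i}", phylum="P"), catalog)
            for i, kos in enumerate(planted)
        ]

    def test_full_depth_exact_with_zero_sd(self, catalog):
        reports = self.make_reports(catalog)
        table = rarefy_combinations(reports, [len(reports)], replicates=10, seed=3)
        assert table.mean_distinct.iloc[0] == 3.0
        assert table.sd_distinct.iloc[0] == 0.0

    def test_depth_one_is_exactly_one(self, catalog):
        reports = self.make_reports(catalog)
        table = rarefy_combinations(reports, [1], replicates=20, seed=3)
        assert table.mean_distinct.iloc[0] == 1.0

    def test_mean_matches_exhaustive_enumeration(self, catalog):
        """Depth-3 mean over many replicates approaches the C(5,3) average."""
        reports = self.make_reports(catalog)
        sigs = [r.combination_signature for r in reports]
        exact = exhaustive_rarefaction_mean(sigs, 3)
        table = rarefy_combinations(reports, [3], replicates=4000, seed=5)
        assert table.mean_distinct.iloc[0] == pytest.approx(exact, abs=0.05)

    def test_monotone_in_depth(self, catalog):
        reports = self.make_reports(catalog)
        table = rarefy_combinations(reports, [1, 2, 3, 4, 5], replicates=400, seed=9)
        means = table.mean_distinct.to_numpy()
        assert (np.diff(means) >= -1e-9).all()

    def test_seed_reproducibility_and_depth_errors(self, catalog):
        reports = self.make_reports(catalog)
        a = rarefy_combinations(reports, [2, 3], replicates=50, seed=42)
        b = rarefy_combinations(reports, [2, 3], replicates=50, seed=42)
        assert a.equals(b)
        with pytest.raises(ValueError, match="depth"):
            rarefy_combinations(reports, [6], replicates=5, seed=1)
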