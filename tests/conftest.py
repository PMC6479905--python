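import pytest

from iaa_atlas.catalog import EnzymeRole, Metabolite, PathwayCatalog, default_catalog


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


def make_reduced_catalog() -> PathwayCatalog:
    """A 10-KO catalog (one KO per role) spanning all four pathways.

    Small enough that every one of the 2^10 KO subsets can be classified
    exhaustively against a brute-force oracle.
    """
    metabolites = [
        Metabolite("Trp"),
        Metabolite("IPA", is_intermediate=True),
        Metabolite("TPM", is_intermediate=True),
        Metabolite("IAM", is_intermediate=True),
        Metabolite("IAN", is_intermediate=True),
        Metabolite("IAAld"),
        Metabolite("IAA"),
    ]
    roles = [
        EnzymeRole("aminotransferase", frozenset({"X01"}), "Trp", "IPA"),
        EnzymeRole("ipdC", frozenset({"X02"}), "IPA", "IAAld"),
        EnzymeRole("yucca", frozenset({"X03"}), "IPA", "IAA"),
        EnzymeRole("trp_decarboxylase", frozenset({"X04"}), "Trp", "TPM"),
        EnzymeRole("amine_oxidase", frozenset({"X05"}), "TPM", "IAAld"),
        EnzymeRole("dehydrogenase", frozenset({"X06"}), "IAAld", "IAA"),
        EnzymeRole("iaaM", frozenset({"X07"}), "Trp", "IAM"),
        EnzymeRole("iaaH", frozenset({"X08"}), "IAM", "IAA"),
        EnzymeRole("nitrilase", frozenset({"X09"}), "IAN", "IAA"),
        EnzymeRole("nhase", frozenset({"X10"}), "IAN", "IAM"),
    ]
    return PathwayCatalog(metabolites, roles, version="reduced-test")


@pytest.fixture(scope="session")
def reduced_catalog():
    return make_reduced_catalog()
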