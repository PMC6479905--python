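# Default catalog of the four bacterial Trp-dependent IAA synthesis pathways.
#
# Role -> KO assignments follow KEGG map00380 (tryptophan metabolism) style
# orthology groups and are deliberately user-overridable: classification logic
# is independent of the exact KO roster, only of the graph structure.
#
# The Trp -> IAOX oxidoreductase is representable (plant CYP79B-like KOs) but
# no bacterial orthologue is expected to match it, so under this catalog the
# IAN pathway is reachable only from the IAN intermediate, never de novo.
version: "1.0"
source: Trp
terminal: IAA
metabolites:
  - id: Trp
  - id: IPA
    intermediate: true
  - id: TPM
    intermediate: true
  - id: IAM
    intermediate: true
  - id: IAN
    intermediate: true
  - id: IAOX
    pathway: IAN
  - id: IAAld
  - id: IAA
roles:
  aminotransferase:
    ko_ids: [K00838]
    substrate: Trp
    product: IPA
  l_aa_oxidase:
    ko_ids: [K03334]
    substrate: Trp
    product: IPA
  ipdC_decarboxylase:
    ko_ids: [K04103]
    substrate: IPA
    product: IAAld
  yucca_monooxygenase:
    ko_ids: [K11816]
    substrate: IPA
    product: IAA
  trp_decarboxylase:
    ko_ids: [K01593]
    substrate: Trp
    product: TPM
  amine_oxidase:
    ko_ids: [K00274]
    substrate: TPM
    product: IAAld
  iaald_dehydrogenase:
    ko_ids: [K00128, K14085]
    substrate: IAAld
    product: IAA
  trp_monooxygenase_iaaM:
    ko_ids: [K00466]
    substrate: Trp
    product: IAM
  iam_hydrolase_iaaH:
    ko_ids: [K01426]
    substrate: IAM
    product: IAA
  oxidoreductase_iaox:
    ko_ids: [K11812, K11813]
    substrate: Trp
    product: IAOX
  iaox_dehydratase:
    ko_ids: [K20807]
    substrate: IAOX
    product: IAN
  nitrilase:
    ko_ids: [K01501]
    substrate: IAN
    product: IAA
  nitrile_hydratase:
    ko_ids: [K01721]
    substrate: IAN
    product: IAM
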