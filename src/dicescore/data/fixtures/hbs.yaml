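# Hemoglobin S / malaria resistance — positive-control dossier.
# The alternative-validation item is a reconstruction (the original
# implementation details were published only as supplementary material and
# are not available); it is encoded with an explicit significance call.
factor:
  name: Hemoglobin S
  factor_class: variant
  aliases: [HbS]
phenotype:
  name: malaria resistance
  description: resistance to severe malaria
items:
  - item_id: hbs-fine-mapping
    category: omic
    subtype: discovery
    result_key: jallow2009:hbs-locus
    significant_override: true
    source: >-
      Case-control GWAS of severe malaria (Jallow et al. 2009): the marker
      SNP missed genome-wide significance, but significance was attained by
      fine mapping at the Hemoglobin S locus.
    reviewed: true
  - item_id: hbs-alt-validation
    category: omic
    subtype: alternative_validation
    result_key: hbs-alternative-validation
    significant_override: true
    source: >-
      Reconstruction: alternative statistical validation of the HbS
      association (post hoc confirmation by a distinct analytic approach).
    reviewed: true
  - item_id: hbs-literature
    category: informatic
    subtype: literature
    result_key: pubmed:hemoglobin S and malaria
    source: >-
      Extensive literature linking sickle-cell trait to roughly ten-fold
      protection against severe malaria.
    reviewed: true
  - item_id: hbs-experimental
    category: experimental
    subtype: cell_molecular
    result_key: hbs-invitro-parasite-growth
    source: >-
      Laboratory evidence of impaired Plasmodium falciparum growth in
      HbS-containing erythrocytes.
    reviewed: true
notes: >-
  Positive control: a well-established protective allele that a single
  conservative GWAS criterion would have missed. Component evidence for the
  omic validation entry is a reconstruction of unavailable supplementary
  detail and is flagged as such in its source field.
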