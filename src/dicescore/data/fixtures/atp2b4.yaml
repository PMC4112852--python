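# ATP2B4 / malaria resistance — new lead with five genome-wide significant
# SNPs (Timmann et al.), plus database and laboratory support.  The
# alternative-validation item is a reconstruction of unavailable
# supplementary detail.
factor:
  name: ATP2B4
  factor_class: gene
  aliases: [PMCA4]
phenotype:
  name: malaria resistance
  description: resistance to severe malaria
items:
  - item_id: atp2b4-snp1
    category: omic
    subtype: discovery
    result_key: timmann:atp2b4-snp1
    p_value: 6.1e-9
    source: GWAS of severe malaria (Timmann et al.), SNP 1 in ATP2B4
    reviewed: true
  - item_id: atp2b4-snp2
    category: omic
    subtype: discovery
    result_key: timmann:atp2b4-snp2
    p_value: 1.5e-8
    source: GWAS of severe malaria (Timmann et al.), SNP 2 in ATP2B4
    reviewed: true
  - item_id: atp2b4-snp3
    category: omic
    subtype: discovery
    result_key: timmann:atp2b4-snp3
    p_value: 2.1e-8
    source: GWAS of severe malaria (Timmann et al.), SNP 3 in ATP2B4
    reviewed: true
  - item_id: atp2b4-snp4
    category: omic
    subtype: discovery
    result_key: timmann:atp2b4-snp4
    p_value: 5.1e-8
    source: GWAS of severe malaria (Timmann et al.), SNP 4 in ATP2B4
    reviewed: true
  - item_id: atp2b4-snp5
    category: omic
    subtype: discovery
    result_key: timmann:atp2b4-snp5
    p_value: 3.4e-8
    source: GWAS of severe malaria (Timmann et al.), SNP 5 in ATP2B4
    reviewed: true
  - item_id: atp2b4-alt-validation
    category: omic
    subtype: alternative_validation
    result_key: atp2b4-alternative-validation
    significant_override: true
    source: >-
      Reconstruction: alternative statistical validation of the ATP2B4
      association (post hoc confirmation by an alternative analytic
      approach).
    reviewed: true
  - item_id: atp2b4-informatic
    category: informatic
    subtype: literature
    result_key: pubmed:ATP2B4 and malaria
    source: >-
      ATP2B4 encodes the primary erythrocyte calcium pump; database and
      literature evidence links erythrocyte calcium handling to malaria
      pathophysiology.
    reviewed: true
  - item_id: atp2b4-experimental
    category: experimental
    subtype: cell_molecular
    result_key: atp2b4-laboratory
    source: >-
      Laboratory support for the involvement of the erythrocyte calcium pump
      in Plasmodium biology.
    reviewed: true
notes: >-
  New lead with strong convergent evidence; the validation entry is a
  reconstruction of unavailable supplementary detail.
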