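# MARVELD3 / malaria resistance — new lead resting on a single intergenic
# SNP near (not in) MARVELD3 and no corroborating evidence.
factor:
  name: MARVELD3
  factor_class: gene
  aliases: []
phenotype:
  name: malaria resistance
  description: resistance to severe malaria
items:
  - item_id: marveld3-snp
    category: omic
    subtype: discovery
    result_key: timmann:rs2334880
    p_value: 3.9e-8
    source: >-
      GWAS of severe malaria (Timmann et al.): rs2334880, an intergenic SNP
      between MARVELD3 and TAT, attributed here to MARVELD3.
    reviewed: true
notes: >-
  Attribution is positional guesswork: the SNP sits between MARVELD3 and TAT
  (head-to-head configuration), so the association may not involve MARVELD3
  at all.
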