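# TAT (tyrosine aminotransferase) / malaria — re-attribution of the
# intergenic SNP rs2334880 (between MARVELD3 and TAT) plus one literature
# hit from the query "tyrosine aminotransferase and malaria".
factor:
  name: TAT
  factor_class: gene
  aliases: [tyrosine aminotransferase]
phenotype:
  name: malaria
  description: malaria pathophysiology
items:
  - item_id: tat-snp
    category: omic
    subtype: discovery
    result_key: timmann:rs2334880:tat
    p_value: 3.9e-8
    source: >-
      rs2334880 (GWAS of severe malaria, Timmann et al.) re-attributed to
      TAT: the SNP is intergenic between MARVELD3 and TAT.
    reviewed: true
  - item_id: tat-literature
    category: informatic
    subtype: literature
    result_key: pubmed:tyrosine aminotransferase and malaria
    source: >-
      NCBI search for "tyrosine aminotransferase and malaria" identifies a
      paper implicating the enzyme in malaria pathophysiology.
    reviewed: true
notes: >-
  Alternative attribution of the MARVELD3-adjacent SNP; evidence limited to
  the discovery association and one literature link.
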