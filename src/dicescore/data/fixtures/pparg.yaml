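# PPARγ / type 2 diabetes — positive control.  rs1801282 (Pro12Ala) missed
# genome-wide significance in three 2007 scans (and one discovery scan gave
# the index SNP p = 0.83), but the odds ratios were consistent and a
# meta-analysis of the three studies gave p = 1.7e-6 — still short of the
# 5e-8 discovery threshold, so the omic components score zero and the strong
# call rests on informatic + experimental convergence.
factor:
  name: PPARG
  factor_class: gene
  aliases: [PPARgamma, peroxisome proliferator-activated receptor gamma]
phenotype:
  name: type 2 diabetes
  description: type 2 diabetes mellitus
items:
  - item_id: pparg-scan1
    category: omic
    subtype: discovery
    result_key: gwas2007:study1:rs1801282
    p_value: 0.019
    effect:
      odds_ratio: 1.09
      ci_lower: 1.01
      ci_upper: 1.16
      ci_level: 0.95
      label: study-1
    source: 2007 type 2 diabetes GWAS, study 1, rs1801282
    reviewed: true
  - item_id: pparg-scan2
    category: omic
    subtype: discovery
    result_key: gwas2007:study2:rs1801282
    p_value: 0.0013
    effect:
      odds_ratio: 1.23
      ci_lower: 1.09
      ci_upper: 1.41
      ci_level: 0.95
      label: study-2
    source: 2007 type 2 diabetes GWAS, study 2, rs1801282
    reviewed: true
  - item_id: pparg-scan3
    category: omic
    subtype: discovery
    result_key: gwas2007:study3:rs1801282
    p_value: 0.0014
    effect:
      odds_ratio: 1.20
      ci_lower: 1.07
      ci_upper: 1.33
      ci_level: 0.95
      label: study-3
    source: 2007 type 2 diabetes GWAS, study 3, rs1801282
    reviewed: true
  - item_id: pparg-index-snp
    category: omic
    subtype: discovery
    result_key: gwas2007:discovery-scan:index-snp
    p_value: 0.83
    source: index SNP p-value in one of the discovery scans
    reviewed: true
  - item_id: pparg-meta
    category: omic
    subtype: alternative_validation
    result_key: gwas2007:meta-analysis:rs1801282
    p_value: 1.7e-6
    source: fixed-effect meta-analysis of the three 2007 studies
    reviewed: true
  - item_id: pparg-informatic
    category: informatic
    subtype: pathway_db
    result_key: pathway:PPARG and type 2 diabetes
    source: >-
      Database and literature evidence establishing PPARG in adipocyte
      differentiation and insulin sensitization pathways.
    reviewed: true
  - item_id: pparg-experimental
    category: experimental
    subtype: treatment
    result_key: thiazolidinedione-target
    source: >-
      PPARγ is the molecular target of the thiazolidinedione class of type 2
      diabetes drugs; extensive cell and animal pharmacology.
    reviewed: true
notes: >-
  Positive control: under the genome-wide threshold none of the omic items
  qualify, so the score rests entirely on informatic and experimental
  convergence.
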