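# dicescore

Composite **Diverse Convergent Evidence** scoring for candidate disease risk
factors.

Agnostic omic screens (GWAS above all) routinely miss true risk factors that
fail a conservative significance threshold, and p-values alone cannot
separate two hits with near-identical significance but wildly different
biological support. `dicescore` is for genetic epidemiologists and
translational researchers triaging such candidates: it combines **omic**,
**informatic** (literature/database), and **experimental** evidence for a
(factor, phenotype) pair into a single composite score under a fixed point
rubric, and classifies the evidence as *strong* or *weak*.

## The rubric

For a dossier of evidence items the composite score is

    S = S_omic + S_informatic + S_experimental

with

* S_omic = 1 point for ≥1 discovery finding with p < 5×10⁻⁸ (or an explicit
  significance call, e.g. by fine mapping), **plus either** 3 points for
  standard statistical validation (independent sample, same analysis) **or**
  2 points for alternative statistical validation (meta-analysis, distinct
  analytic method, covariate accounting) — never both;
* S_informatic = 3 points for ≥1 reviewed database/literature item;
* S_experimental = 3 points for ≥1 reviewed laboratory item;

and **S ≥ 6 ⇒ strong evidence**. No single category can reach 6, so a strong
call always rests on convergent evidence from at least two categories. A
single underlying result is counted once even when it appears under several
categories. The supporting statistics — strict threshold calls and
fixed-effect inverse-variance meta-analysis of odds ratios
(wᵢ = 1/SEᵢ², SEᵢ back-calculated from the printed CI) — make the
alternative-validation pathway computable from published summary tables.

## Worked example

Score the shipped ATP2B4 / malaria-resistance dossier (five genome-wide
significant SNPs, an alternative statistical validation, database and
laboratory support):

```sh
dice score src/dicescore/data/fixtures/atp2b4.yaml --format markdown
```

```
# Evidence score: ATP2B4 / malaria resistance

| Component | Points | Contributing items |
|---|---|---|
| Omic: single significant finding | 1 | atp2b4-snp1, atp2b4-snp2, atp2b4-snp3, atp2b4-snp5 |
| Omic: statistical validation | 2 | atp2b4-alt-validation |
| Informatic (biological database) | 3 | atp2b4-informatic |
| Experimental | 3 | atp2b4-experimental |
| **Total** | **9** | |

**Verdict: strong** (strong-evidence cutoff: total ≥ 6; discovery threshold p < 5e-08)
```

Four of the five SNPs pass the strict 5×10⁻⁸ threshold (5.1×10⁻⁸ does not)
and earn the single-finding point; the alternative validation adds 2; the
informatic and experimental items add 3 each. Total 9 ≥ 6: strong evidence,
worth laboratory follow-up — while the MARVELD3 dossier, whose SNP has a
nearly identical p-value (3.9×10⁻⁸) but no other support, scores 1 and is
flagged for evidence gathering instead.

Pool the three published PPARγ / type-2-diabetes odds ratios:

```sh
dice meta --or-ci 1.09,1.01,1.16 --or-ci 1.23,1.09,1.41 --or-ci 1.20,1.07,1.33
```

```json
{
  "pooled_log_or": 0.1298028214508298,
  "pooled_or": 1.1386038529332598,
  "pooled_se": 0.027135770319864902,
  "z_statistic": 4.783458141072446,
  "p_two_sided": 1.7230478687107556e-06,
  "per_study_weights": [801.3953759388295, 231.89883561947622, 324.7555719696661]
}
```

The pooled p of 1.7×10⁻⁶ is convincing yet still short of genome-wide
significance — exactly the situation where the composite rubric (here:
0 + 0 + 3 + 3 = 6, strong) rescues a true positive that threshold-only
validation would discard.

Other entry points: `dice batch HITS.tsv --evidence-dir DIR` ranks a GWAS
hit table by composite score, `dice validate-schema PATH` checks a dossier
file against the shipped JSON schema, and `dice fixtures --out DIR --seed N`
writes the canonical and synthetic fixtures. The same functionality is
available from Python via `dicescore.score_dossier`,
`dicescore.fixed_effect_meta`, `dicescore.batch_score`, etc.

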