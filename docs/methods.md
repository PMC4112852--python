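# Methods

## The scoring model

`dicescore` operationalizes a composite evidence-triangulation heuristic for
candidate disease risk factors. For a (factor, phenotype) pair, evidence is
collected into a *dossier* of items in three categories, and points are
awarded per category:

| Component | Condition | Points (default) |
|---|---|---|
| Omic: single significant finding | ≥1 discovery item passes the significance threshold | 1 |
| Omic: standard statistical validation | ≥1 significant replication in an independent sample with the same analytic approach | 3 |
| Omic: alternative statistical validation | otherwise, ≥1 significant post hoc confirmation (meta-analysis, distinct analytic method, covariate accounting) | 2 |
| Informatic | ≥1 reviewed database/literature item | 3 |
| Experimental | ≥1 reviewed laboratory item | 3 |

Standard and alternative validation are mutually exclusive ("either/or"), so
the omic category contributes at most 1 + 3 = 4 points and the maximum total
is 10. The composite total classifies the factor as **strong** (total ≥ 6)
or **weak**. Because no single category can reach 6 on its own, a strong call
always requires convergence of at least two categories — the rubric's central
design property. Item counts within a category deliberately do not
accumulate: five literature hits are worth the same 3 points as one, since
within-category validation counts have no consistent relationship to the
truth of a finding.

### Parameters (`RubricConfig`)

* `discovery_threshold` (probability, default `5e-8`) — the significance
  threshold for omic items, defaulting to the conventional genome-wide
  multiple-testing-adjusted level. Threshold choice is a researcher judgment;
  the package enforces only that one value is used consistently per run
  (batch mode accepts e.g. a nominal `0.05` for sub-threshold triage).
  Comparison is strict (`p < threshold`), so `p = 5e-8` exactly does not
  pass.
* Point values (`points_single_finding=1`, `points_standard_validation=3`,
  `points_alternative_validation=2`, `points_informatic=3`,
  `points_experimental=3`) and `strong_cutoff=6` — the published rubric;
  configurable, with the constraint that alternative validation can never
  outscore standard validation.
* `validation_requires_discovery` (default `true`) — validation points are
  withheld when no qualifying discovery finding exists. The rubric's source
  never states this rule explicitly, but its worked type-2-diabetes example
  awards 0 validation points despite a pooled meta-analysis p of 1.7e-6,
  which is only consistent with gating; the flag makes the choice auditable
  and reversible.
* `require_reviewed` (default `true`) — machine-proposed items
  (`reviewed=false`) never contribute points until a human confirms them.

### Significance calls

An omic item is significant if its `significant_override` is `true`, or —
when no override is present — if `p_value < discovery_threshold`. The
override exists because some credits do not rest on a scan p-value at all
(e.g. significance attained by fine mapping at an already-known locus, the
Hemoglobin S case); when present it supersedes the p-value entirely.

### Single counting

A single underlying result reported under several categories must be counted
once. Items carry an author-supplied `result_key` (no fuzzy citation
matching — behavior stays deterministic and auditable), and `deduplicate`
keeps one item per key. When duplicates span categories, the survivor set is
the assignment that maximizes the dossier total under the active config, with
ties broken by category priority (omic > experimental > informatic) and then
lexicographic `item_id`. A per-key greedy rule ("keep the copy with the
highest individual potential") was considered and rejected: it can strip the
sole discovery item in favor of an experimental duplicate and thereby void
gated validation points, making the total *decrease* when evidence is added.
The maximizing rule preserves monotonicity (adding evidence never lowers the
total), which we treat as non-negotiable for a cumulative-evidence score. The
exhaustive search is capped at 4096 assignments (far beyond any realistic
dossier); past the cap the greedy rule applies.

## Supporting statistics

### Fixed-effect meta-analysis from printed ORs

Study effects arrive as an odds ratio with a 95% Wald CI, the form results
are printed in. The log-scale standard error is back-calculated from the
interval width, SE = (ln U − ln L) / (2·z₀.₉₇₅), and studies are pooled by
inverse-variance weighting: wᵢ = 1/SEᵢ², pooled logOR = Σwᵢ·logORᵢ / Σwᵢ,
pooled SE = (Σwᵢ)^(−1/2), z = pooled logOR / pooled SE, two-sided normal p.
Applied to the three published PPARγ odds ratios (1.09 [1.01–1.16],
1.23 [1.09–1.41], 1.20 [1.07–1.33]) this reproduces the published pooled
p = 1.7×10⁻⁶ to two significant figures (z ≈ 4.78) — the stated contract,
since whether the original pooling used genotype counts rather than
CI-derived SEs is unknowable from the printed record. Per-study printed
p-values (0.019, 0.0013, 0.0014) are *not* asserted against the Wald
back-calculation: the source studies' tests need not be Wald tests.

Numerical choices: a CI is rejected when ln(OR) deviates from the
log-midpoint of its bounds by more than 0.05 (beyond what 2-decimal rounding
of printed CIs can explain); degenerate (L = U) or inverted CIs are rejected
explicitly rather than allowed to dominate with infinite weight. Sums use
`math.fsum`. Random-effects models and heterogeneity statistics are out of
scope.

## Canonical case dossiers

Five dossiers ship as YAML files and reproduce the published component table:
Hemoglobin S/malaria (1,2,3,3 → 9, strong), ATP2B4/malaria (1,2,3,3 → 9,
strong), MARVELD3/malaria (1,0,0,0 → 1, weak), PPARγ/type 2 diabetes
(0,0,3,3 → 6, strong), and TAT/malaria (1,0,3,0 → 4, weak). The
alternative-validation items in the Hemoglobin S and ATP2B4 dossiers encode
the published component outcomes via explicit significance calls because the
original implementation details were published only as supplementary material
that is not available; both items and files are flagged as reconstructions.

## Synthetic generator

The generator emulates the *shape* of evidence dossiers, not GWAS data:
per-category presence is Bernoulli (defaults 0.7 omic / 0.5 informatic /
0.4 experimental — a mid-density regime where all score components are well
exercised); significant discovery p-values are log-uniform on
[10⁻¹², 5×10⁻⁸) and null p-values uniform on (0, 1], a minimal two-component
mixture sufficient for threshold logic; half of discoveries get a validation
attempt, split evenly between standard and alternative; non-omic items are
human-reviewed with probability 0.8. Alongside each dossier the generator
records the component points it *intended*, by bookkeeping entirely
independent of the scoring engine, so the two codepaths cross-check each
other (the suite does this on 1000 dossiers). What passing these tests does
**not** show: anything about linkage disequilibrium, winner's curse, effect
size distributions, correlated evidence across factors, or the realism of
any particular literature search — the generator has no model of any of
these.

## Batch mode

A GWAS hit table (variant_id, gene attribution, p-value, optional OR/CI) is
grouped by attributed gene; each group is merged into the gene's dossier as
omic discovery items and scored, and rows are ranked by (total desc, best p
asc), so near-identical p-values separate by evidence diversity — the
ATP2B4-vs-MARVELD3 situation. Gene attribution is always taken from the
input column, never inferred from coordinates; no genomic coordinates enter
the package at all. Next-step flags are advisory strings, not scores:
strong → "laboratory follow-up"; weak → "gather informatic/experimental
evidence", or "consider nearby-factor reattribution" when the hit is marked
intergenic in the input (the attribution-is-guesswork situation). The
`intergenic` column is this package's design choice for surfacing that case,
since attribution confidence cannot be derived from summary statistics.

## Known limitations

* The rubric is ordinal and heuristic; totals convey ranking information,
  not calibrated probabilities.
* `result_key` correctness is the author's responsibility; the package
  cannot detect two differently-keyed items that are really the same result.
* Only offline, table-backed retrieval providers are implemented; live
  database clients are a documented interface, not a feature.
* Evidence *quality* within a category (weak vs. strong animal model) does
  not modulate points; the source text of each item is recorded for human
  judgment but the rubric ignores it by design.
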