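"""Evidence dossier data model.

The unit of analysis is the *dossier*: every piece of evidence collected for
one (factor, phenotype) pair, where a factor may be a gene, variant, exposure,
or pathway and the phenotype is the pathophysiology of interest.  Each
:class:`EvidenceItem` belongs to one of three evidence categories:

``omic``
    findings from agnostic screening analyses (GWAS, other omic scans) and
    their statistical validations;
``informatic``
    support from literature or biological databases (PubMed, KEGG, GEO, GO);
``experimental``
    laboratory support (animal models, cell/molecular work, treatment
    experiments).

Domain objects are plain dataclasses and deliberately permissive: invalid
states can be constructed and are *reported* by :func:`validate_dossier`
rather than raised, so that a whole file's problems surface at once.  The
file-format layer (:mod:`dicescore.io`) enforces the schema strictly at parse
time.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from dicescore.meta import StudyEffect

__all__ = [
    "FactorClass",
    "Category",
    "OmicSubtype",
    "InformaticSubtype",
    "ExperimentalSubtype",
    "Factor",
    "Phenotype",
    "EvidenceItem",
    "Dossier",
    "RubricConfig",
    "validate_dossier",
    "deduplicate",
]


class FactorClass(str, Enum):
    gene = "gene"
    variant = "variant"
    exposure = "exposure"
    pathway = "pathway"
    other = "other"


class Category(str, Enum):
    omic = "omic"
    informatic = "informatic"
    experimental = "experimental"


class OmicSubtype(str, Enum):
    discovery = "discovery"
    standard_validation = "standard_validation"
    alternative_validation = "alternative_validation"


class InformaticSubtype(str, Enum):
    literature = "literature"
    pathway_db = "pathway_db"
    expression_db = "expression_db"
    other_db = "other_db"


class ExperimentalSubtype(str, Enum):
    animal_model = "animal_model"
    cell_molecular = "cell_molecular"
    treatment = "treatment"


SUBTYPES_BY_CATEGORY: dict[Category, frozenset[str]] = {
    Category.omic: frozenset(s.value for s in OmicSubtype),
    Category.informatic: frozenset(s.value for s in InformaticSubtype),
    Category.experimental: frozenset(s.value for s in ExperimentalSubtype),
}


@dataclass(frozen=True)
class Factor:
    """A candidate risk factor: gene, variant, exposure, or pathway."""

    name: str
    factor_class: FactorClass = FactorClass.other
    aliases: tuple[str, ...] = ()


@dataclass(frozen=True)
class Phenotype:
    name: str
    description: str = ""


@dataclass(frozen=True)
class EvidenceItem:
    """One piece of evidence linking the factor to the phenotype.

    ``result_key`` identifies the underlying result so that a single result
    appearing under several categories is counted only once.  ``reviewed``
    distinguishes human-confirmed evidence from machine-proposed candidates
    (the latter never score under the default rubric).
    ``significant_override`` is an explicit significance call for findings
    whose credit does not rest on a scan p-value (e.g. significance attained
    by fine mapping); when present it supersedes the p-value comparison.
    """

    item_id: str
    category: Category
    subtype: str
    result_key: str
    p_value: Optional[float] = None
    significant_override: Optional[bool] = None
    effect: Optional[StudyEffect] = None
    source: str = ""
    reviewed: bool = True


@dataclass
class Dossier:
    factor: Factor
    phenotype: Phenotype
    items: list[EvidenceItem] = field(default_factory=list)
    notes: str = ""


@dataclass(frozen=True)
class RubricConfig:
    """Point values and thresholds of the scoring rubric.

    Defaults encode the published rubric: 1 point for a single significant
    omic finding, 3 for standard statistical validation (independent sample,
    same analytic approach) or 2 for alternative statistical validation
    (meta-analysis, distinct analytic method, covariate accounting), 3 each
    for informatic and experimental support; a composite total >= 6 is
    classified as strong evidence.  The discovery significance threshold
    defaults to the conventional genome-wide 5e-8 but is deliberately
    configurable — threshold choice is left to the researcher, as long as one
    value is used consistently per run.
    """

    discovery_threshold: float = 5e-8
    points_single_finding: int = 1
    points_standard_validation: int = 3
    points_alternative_validation: int = 2
    points_informatic: int = 3
    points_experimental: int = 3
    strong_cutoff: int = 6
    require_reviewed: bool = True
    validation_requires_discovery: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.discovery_threshold < 1.0):
            raise ValueError("discovery_threshold must lie in (0, 1)")
        for name in (
            "points_single_finding",
            "points_standard_validation",
            "points_alternative_validation",
            "points_informatic",
            "points_experimental",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.points_alternative_validation > self.points_standard_validation:
            raise ValueError(
                "alternative validation cannot outscore standard validation"
            )
        if self.strong_cutoff > self.max_total:
            raise ValueError("strong_cutoff exceeds the maximum attainable total")

    @property
    def max_total(self) -> int:
        return (
            self.points_single_finding
            + self.points_standard_validation
            + self.points_informatic
            + self.points_experimental
        )


def item_is_significant(item: EvidenceItem, config: RubricConfig) -> bool:
    """Significance call for an omic item under the configured threshold.

    An explicit ``significant_override`` wins; otherwise the p-value is
    compared strictly (p < threshold).  An item with neither is not
    significant.
    """
    if item.significant_override is not None:
        return item.significant_override
    if item.p_value is not None:
        return item.p_value < config.discovery_threshold
    return False


def validate_dossier(dossier: Dossier) -> list[str]:
    """Check every dossier invariant; return human-readable violations.

    Returns an empty list iff the dossier is valid.  Violations name the
    offending item_id and field; nothing is raised.
    """
    violations: list[str] = []
    if not dossier.factor.name:
        violations.append("factor.name: must be non-empty")
    if dossier.factor.name in dossier.factor.aliases:
        violations.append("factor.aliases: must not contain the factor name")
    if not dossier.phenotype.name:
        violations.append("phenotype.name: must be non-empty")

    seen: set[str] = set()
    for item in dossier.items:
        iid = item.item_id or "<missing item_id>"
        if not item.item_id:
            violations.append(f"{iid}.item_id: must be non-empty")
        elif item.item_id in seen:
            violations.append(f"{iid}.item_id: duplicate item_id")
        seen.add(item.item_id)

        if not item.result_key:
            violations.append(f"{iid}.result_key: must be non-empty")
        if item.category not in SUBTYPES_BY_CATEGORY:
            violations.append(f"{iid}.category: unknown category {item.category!r}")
        elif item.subtype not in SUBTYPES_BY_CATEGORY[item.category]:
            violations.append(
                f"{iid}.subtype: {item.subtype!r} is not a "
                f"{item.category.value} subtype"
            )
        if item.p_value is not None and not (
            0.0 < item.p_value <= 1.0 and math.isfinite(item.p_value)
        ):
            violations.append(f"{iid}.p_value: {item.p_value!r} not in (0, 1]")
    return violations


# --- single-counting ---------------------------------------------------------

_CATEGORY_PRIORITY = {Category.omic: 0, Category.experimental: 1, Category.informatic: 2}

# Exhaustive assignment search is capped; beyond this the per-key greedy rule
# (highest individual potential, then category priority, then item_id) applies.
_MAX_ASSIGNMENTS = 4096


def _sort_key(item: EvidenceItem) -> tuple[int, str]:
    return (_CATEGORY_PRIORITY[item.category], item.item_id)


def _item_potential(item: EvidenceItem, config: RubricConfig) -> int:
    """Upper bound on the points this item alone could contribute."""
    if config.require_reviewed and not item.reviewed:
        return 0
    if item.category is Category.informatic:
        return config.points_informatic
    if item.category is Category.experimental:
        return config.points_experimental
    if not item_is_significant(item, config):
        return 0
    return {
        OmicSubtype.discovery.value: config.points_single_finding,
        OmicSubtype.standard_validation.value: config.points_standard_validation,
        OmicSubtype.alternative_validation.value: config.points_alternative_validation,
    }.get(item.subtype, 0)


def deduplicate(
    items: list[EvidenceItem], config: RubricConfig | None = None
) -> list[EvidenceItem]:
    """Enforce single counting: at most one item survives per ``result_key``.

    When one underlying result appears under several categories, the survivor
    is the one that credits the dossier most: among all assignments of
    duplicated keys, the one maximizing the dossier total under ``config``
    is kept, ties broken by category priority (omic > experimental >
    informatic) then lexicographic item_id.  Output order follows first
    appearance of each result_key; the operation is idempotent and
    order-invariant in the returned *set* of items.
    """
    from dicescore.scoring import _total_for_items  # deferred: avoids cycle

    config = config or RubricConfig()
    by_key: dict[str, list[EvidenceItem]] = {}
    for item in items:
        by_key.setdefault(item.result_key, []).append(item)

    # deterministic candidate order per key: tie-break order doubles as
    # preference order when totals are equal
    for key, group in by_key.items():
        group.sort(key=lambda it: (-_item_potential(it, config), *_sort_key(it)))

    # canonical key order keeps tie resolution independent of input order
    dup_keys = sorted(k for k, g in by_key.items() if len(g) > 1)
    chosen: dict[str, EvidenceItem] = {
        k: g[0] for k, g in by_key.items() if len(g) == 1
    }

    n_assignments = math.prod(len(by_key[k]) for k in dup_keys) if dup_keys else 0
    if dup_keys and n_assignments <= _MAX_ASSIGNMENTS:
        best: dict[str, EvidenceItem] | None = None
        best_total = -1
        for combo in itertools.product(*(by_key[k] for k in dup_keys)):
            candidate = dict(chosen)
            candidate.update(zip(dup_keys, combo))
            total = _total_for_items(list(candidate.values()), config)
            if total > best_total:
                best, best_total = candidate, total
        assert best is not None
        chosen = best
    else:
        for k in dup_keys:  # greedy fallback (and trivially for no duplicates)
            chosen[k] = by_key[k][0]

    first_seen: list[str] = []
    for item in items:
        if item.result_key not in first_seen:
            first_seen.append(item.result_key)
    return [chosen[k] for k in first_seen]
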