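"""The composite evidence scoring engine.

Applies the point rubric to a dossier: 1 point for a single significant omic
finding, plus either 3 (standard statistical validation) or 2 (alternative
statistical validation, e.g. meta-analysis or a distinct analytic method),
3 points for informatic support, 3 for experimental support.  The composite
total classifies the factor as ``strong`` (total >= cutoff, default 6) or
``weak``.  With default points no single category can reach the cutoff, so a
strong call always rests on convergent evidence from at least two categories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from dicescore.evidence_model import (
    Category,
    Dossier,
    EvidenceItem,
    OmicSubtype,
    RubricConfig,
    deduplicate,
    item_is_significant,
    validate_dossier,
)

__all__ = [
    "DiceScore",
    "InvalidDossierError",
    "score_omic",
    "score_informatic",
    "score_experimental",
    "score_dossier",
    "classify",
]


class InvalidDossierError(ValueError):
    """Raised when a dossier fails validation before scoring."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("invalid dossier: " + "; ".join(violations))


@dataclass(frozen=True)
class DiceScore:
    """Per-component points, composite total, and the strong/weak verdict.

    ``attribution`` maps each component to the item_ids that earned (or could
    equally have earned) its points; every awarded point is covered.
    """

    single_finding_points: int
    validation_points: int
    informatic_points: int
    experimental_points: int
    total: int
    classification: str
    attribution: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        # stable key order for serialization
        return {
            "single_finding_points": self.single_finding_points,
            "validation_points": self.validation_points,
            "informatic_points": self.informatic_points,
            "experimental_points": self.experimental_points,
            "total": self.total,
            "classification": self.classification,
            "attribution": {k: list(v) for k, v in sorted(self.attribution.items())},
        }


def _check_category(items: list[EvidenceItem], expected: Category) -> None:
    for item in items:
        if item.category is not expected:
            raise ValueError(
                f"item {item.item_id!r} has category {item.category.value!r}; "
                f"expected {expected.value!r}"
            )


def _eligible(items: list[EvidenceItem], config: RubricConfig) -> list[EvidenceItem]:
    if not config.require_reviewed:
        return items
    return [it for it in items if it.reviewed]


def score_omic(
    items: list[EvidenceItem], config: RubricConfig
) -> tuple[int, int, dict[str, tuple[str, ...]]]:
    """Score the omic category: (single-finding points, validation points).

    A significant discovery item earns the single-finding point.  Validation
    points go to the highest-ranking significant validation present: standard
    supersedes alternative, never both.  With ``validation_requires_discovery``
    (the default) validation points are withheld when no qualifying discovery
    exists — a post hoc confirmation cannot substitute for an initial finding.
    """
    _check_category(items, Category.omic)
    eligible = _eligible(items, config)

    discoveries = sorted(
        it.item_id
        for it in eligible
        if it.subtype == OmicSubtype.discovery.value and item_is_significant(it, config)
    )
    standard = sorted(
        it.item_id
        for it in eligible
        if it.subtype == OmicSubtype.standard_validation.value
        and item_is_significant(it, config)
    )
    alternative = sorted(
        it.item_id
        for it in eligible
        if it.subtype == OmicSubtype.alternative_validation.value
        and item_is_significant(it, config)
    )

    single = config.points_single_finding if discoveries else 0
    attribution: dict[str, tuple[str, ...]] = {}
    if discoveries:
        attribution["single_finding"] = tuple(discoveries)

    validation = 0
    if standard:
        validation = config.points_standard_validation
        validators = tuple(standard)
    elif alternative:
        validation = config.points_alternative_validation
        validators = tuple(alternative)
    else:
        validators = ()
    if config.validation_requires_discovery and not discoveries:
        validation = 0
        validators = ()
    if validation:
        attribution["validation"] = validators
    return single, validation, attribution


def _score_flat(
    items: list[EvidenceItem],
    config: RubricConfig,
    expected: Category,
    points: int,
) -> tuple[int, dict[str, tuple[str, ...]]]:
    _check_category(items, expected)
    eligible = sorted(it.item_id for it in _eligible(items, config))
    if not eligible:
        return 0, {}
    return points, {expected.value: tuple(eligible)}


def score_informatic(
    items: list[EvidenceItem], config: RubricConfig
) -> tuple[int, dict[str, tuple[str, ...]]]:
    """Flat award for informatic support; extra items do not accumulate."""
    return _score_flat(items, config, Category.informatic, config.points_informatic)


def score_experimental(
    items: list[EvidenceItem], config: RubricConfig
) -> tuple[int, dict[str, tuple[str, ...]]]:
    """Flat award for experimental support; extra items do not accumulate."""
    return _score_flat(items, config, Category.experimental, config.points_experimental)


def classify(total: int, config: RubricConfig) -> str:
    """``strong`` iff total >= the configured cutoff, else ``weak``."""
    if total < 0:
        raise ValueError("total must be non-negative")
    return "strong" if total >= config.strong_cutoff else "weak"


def _total_for_items(items: list[EvidenceItem], config: RubricConfig) -> int:
    """Composite total of an already-deduplicated item set (internal)."""
    by_cat: dict[Category, list[EvidenceItem]] = {c: [] for c in Category}
    for item in items:
        by_cat[item.category].append(item)
    single, validation, _ = score_omic(by_cat[Category.omic], config)
    informatic, _ = score_informatic(by_cat[Category.informatic], config)
    experimental, _ = score_experimental(by_cat[Category.experimental], config)
    return single + validation + informatic + experimental


def score_dossier(dossier: Dossier, config: RubricConfig | None = None) -> DiceScore:
    """Validate, deduplicate, and score a dossier under the rubric.

    Fully deterministic and invariant to item order.  Raises
    :class:`InvalidDossierError` listing every violation if the dossier fails
    validation.
    """
    config = config or RubricConfig()
    violations = validate_dossier(dossier)
    if violations:
        raise InvalidDossierError(violations)

    items = deduplicate(dossier.items, config)
    by_cat: dict[Category, list[EvidenceItem]] = {c: [] for c in Category}
    for item in items:
        by_cat[item.category].append(item)

    single, validation, omic_attr = score_omic(by_cat[Category.omic], config)
    informatic, info_attr = score_informatic(by_cat[Category.informatic], config)
    experimental, exp_attr = score_experimental(by_cat[Category.experimental], config)
    total = single + validation + informatic + experimental
    return DiceScore(
        single_finding_points=single,
        validation_points=validation,
        informatic_points=informatic,
        experimental_points=experimental,
        total=total,
        classification=classify(total, config),
        attribution={**omic_attr, **info_attr, **exp_attr},
    )
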