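"""File formats, report generation, and batch scoring of GWAS hit tables.

Dossiers live in YAML (or JSON) files with top-level keys ``factor``,
``phenotype``, ``items`` and ``notes``; the shipped ``dossier.schema.json``
documents the format and :func:`validate_schema` enforces it (via pydantic
parse models) with field-level error context.

Batch mode consumes a tab-delimited GWAS hit table (columns ``variant_id``,
``gene``, ``p_value``, optional ``or``/``ci_lower``/``ci_upper`` and
``intergenic``), merges each gene's hits into its evidence dossier as omic
discovery items, scores every dossier, and ranks the rows so that hits with
near-identical p-values separate by the diversity of their supporting
evidence.  Gene attribution is always taken from the input column, never
inferred from coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
import pydantic
import yaml

from dicescore.evidence_model import (
    Category,
    Dossier,
    EvidenceItem,
    Factor,
    FactorClass,
    OmicSubtype,
    Phenotype,
    RubricConfig,
    SUBTYPES_BY_CATEGORY,
)
from dicescore.meta import StudyEffect
from dicescore.scoring import DiceScore, score_dossier

__all__ = [
    "SchemaError",
    "GwasHit",
    "BatchRow",
    "BatchReport",
    "read_dossier",
    "write_dossier",
    "validate_schema",
    "schema_path",
    "write_report",
    "read_hits",
    "read_effects",
    "batch_score",
]


class SchemaError(ValueError):
    """A dossier file that does not conform to the published schema."""

    def __init__(self, path: str, errors: list[str]):
        self.path = path
        self.errors = errors
        super().__init__(f"{path}: " + "; ".join(errors))


# --- parse models (strict file-format layer) ---------------------------------


class _EffectModel(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")
    odds_ratio: float
    ci_lower: float
    ci_upper: float
    ci_level: float = 0.95
    label: str = ""


class _FactorModel(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")
    name: str = pydantic.Field(min_length=1)
    factor_class: Literal["gene", "variant", "exposure", "pathway", "other"] = "other"
    aliases: list[str] = []


class _PhenotypeModel(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")
    name: str = pydantic.Field(min_length=1)
    description: str = ""


class _ItemModel(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")
    item_id: str = pydantic.Field(min_length=1)
    category: Literal["omic", "informatic", "experimental"]
    subtype: str
    result_key: str = pydantic.Field(min_length=1)
    p_value: Optional[float] = pydantic.Field(default=None, gt=0.0, le=1.0)
    significant_override: Optional[bool] = None
    effect: Optional[_EffectModel] = None
    source: str = ""
    reviewed: bool = True

    @pydantic.model_validator(mode="after")
    def _subtype_matches_category(self):
        allowed = SUBTYPES_BY_CATEGORY[Category(self.category)]
        if self.subtype not in allowed:
            raise ValueError(
                f"subtype {self.subtype!r} not valid for category "
                f"{self.category!r} (allowed: {sorted(allowed)})"
            )
        return self


class _DossierModel(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")
    factor: _FactorModel
    phenotype: _PhenotypeModel
    items: list[_ItemModel] = []
    notes: str = ""

    @pydantic.model_validator(mode="after")
    def _unique_item_ids(self):
        seen: set[str] = set()
        for item in self.items:
            if item.item_id in seen:
                raise ValueError(f"duplicate item_id {item.item_id!r}")
            seen.add(item.item_id)
        return self


def _format_pydantic_errors(exc: pydantic.ValidationError) -> list[str]:
    out = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<root>"
        out.append(f"{loc}: {err['msg']}")
    return out


def _to_dossier(model: _DossierModel) -> Dossier:
    items = []
    for m in model.items:
        effect = StudyEffect(**m.effect.model_dump()) if m.effect else None
        items.append(
            EvidenceItem(
                item_id=m.item_id,
                category=Category(m.category),
                subtype=m.subtype,
                result_key=m.result_key,
                p_value=m.p_value,
                significant_override=m.significant_override,
                effect=effect,
                source=m.source,
                reviewed=m.reviewed,
            )
        )
    return Dossier(
        factor=Factor(
            name=model.factor.name,
            factor_class=FactorClass(model.factor.factor_class),
            aliases=tuple(model.factor.aliases),
        ),
        phenotype=Phenotype(
            name=model.phenotype.name, description=model.phenotype.description
        ),
        items=items,
        notes=model.notes,
    )


def read_dossier(path: str | Path) -> Dossier:
    """Parse and schema-check a YAML/JSON dossier file."""
    path = Path(path)
    try:
        data = yaml.safe_load(path.read_text())
    except (OSError, yaml.YAMLError) as exc:
        raise SchemaError(str(path), [f"unreadable: {exc}"]) from exc
    if not isinstance(data, dict):
        raise SchemaError(str(path), ["top level must be a mapping"])
    try:
        model = _DossierModel.model_validate(data)
        return _to_dossier(model)
    except pydantic.ValidationError as exc:
        raise SchemaError(str(path), _format_pydantic_errors(exc)) from exc
    except ValueError as exc:  # StudyEffect invariant failures
        raise SchemaError(str(path), [str(exc)]) from exc


def dossier_to_dict(dossier: Dossier) -> dict:
    """Canonical plain-dict form of a dossier (round-trip stable)."""
    items = []
    for it in dossier.items:
        d: dict = {
            "item_id": it.item_id,
            "category": it.category.value,
            "subtype": it.subtype,
            "result_key": it.result_key,
        }
        if it.p_value is not None:
            d["p_value"] = it.p_value
        if it.significant_override is not None:
            d["significant_override"] = it.significant_override
        if it.effect is not None:
            d["effect"] = {
                "odds_ratio": it.effect.odds_ratio,
                "ci_lower": it.effect.ci_lower,
                "ci_upper": it.effect.ci_upper,
                "ci_level": it.effect.ci_level,
                "label": it.effect.label,
            }
        if it.source:
            d["source"] = it.source
        d["reviewed"] = it.reviewed
        items.append(d)
    return {
        "factor": {
            "name": dossier.factor.name,
            "factor_class": dossier.factor.factor_class.value,
            "aliases": list(dossier.factor.aliases),
        },
        "phenotype": {
            "name": dossier.phenotype.name,
            "description": dossier.phenotype.description,
        },
        "items": items,
        "notes": dossier.notes,
    }


def write_dossier(dossier: Dossier, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(dossier_to_dict(dossier), sort_keys=False, allow_unicode=True)
    )


def schema_path() -> Path:
    """Location of the shipped JSON Schema for dossier files."""
    return Path(str(resources.files("dicescore") / "data" / "dossier.schema.json"))


def validate_schema(path: str | Path) -> list[str]:
    """Return schema violations for a dossier file; empty list iff valid."""
    try:
        read_dossier(path)
        return []
    except SchemaError as exc:
        return exc.errors


# --- reports -----------------------------------------------------------------


def write_report(
    score: DiceScore,
    dossier: Dossier,
    config: RubricConfig,
    format: str = "json",
) -> str:
    """Render a scored dossier as json, markdown, or tsv."""
    if format == "json":
        payload = {
            "factor": dossier.factor.name,
            "phenotype": dossier.phenotype.name,
            "score": score.to_dict(),
            "config": config.__dict__,
        }
        return json.dumps(payload, indent=2, sort_keys=False) + "\n"
    if format == "tsv":
        header = (
            "factor\tphenotype\tsingle_finding\tvalidation\tinformatic\t"
            "experimental\ttotal\tclassification\n"
        )
        row = (
            f"{dossier.factor.name}\t{dossier.phenotype.name}\t"
            f"{score.single_finding_points}\t{score.validation_points}\t"
            f"{score.informatic_points}\t{score.experimental_points}\t"
            f"{score.total}\t{score.classification}\n"
        )
        return header + row
    if format == "markdown":
        lines = [
            f"# Evidence score: {dossier.factor.name} / {dossier.phenotype.name}",
            "",
            "| Component | Points | Contributing items |",
            "|---|---|---|",
        ]
        for label, pts, key in [
            ("Omic: single significant finding", score.single_finding_points, "single_finding"),
            ("Omic: statistical validation", score.validation_points, "validation"),
            ("Informatic (biological database)", score.informatic_points, "informatic"),
            ("Experimental", score.experimental_points, "experimental"),
        ]:
            ids = ", ".join(score.attribution.get(key, ())) or "—"
            lines.append(f"| {label} | {pts} | {ids} |")
        lines += [
            f"| **Total** | **{score.total}** | |",
            "",
            f"**Verdict: {score.classification}** "
            f"(strong-evidence cutoff: total ≥ {config.strong_cutoff}; "
            f"discovery threshold p < {config.discovery_threshold:g})",
        ]
        if dossier.notes:
            lines += ["", f"Notes: {dossier.notes}"]
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown report format {format!r}")


# --- batch mode --------------------------------------------------------------


@dataclass(frozen=True)
class GwasHit:
    """One row of a GWAS summary-statistic table.

    ``gene`` is the attributed factor, which may differ from the nearest
    gene; ``intergenic`` marks hits whose attribution is positional guesswork
    (the flag feeds the next-step advice, never the score).
    """

    variant_id: str
    gene: str
    p_value: float
    effect: Optional[StudyEffect] = None
    intergenic: bool = False

    def __post_init__(self) -> None:
        if not self.variant_id:
            raise ValueError("variant_id must be non-empty")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(
                f"{self.variant_id}: p_value {self.p_value!r} not in (0, 1]"
            )


@dataclass(frozen=True)
class BatchRow:
    factor: str
    phenotype: str
    n_hits: int
    min_p: float
    single_finding_points: int
    validation_points: int
    informatic_points: int
    experimental_points: int
    total: int
    classification: str
    next_step: str
    error: str = ""


@dataclass
class BatchReport:
    rows: list[BatchRow]
    config: RubricConfig
    notes: str = ""

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.rows])

    def to_json(self) -> str:
        return (
            json.dumps(
                {
                    "rows": [r.__dict__ for r in self.rows],
                    "config": self.config.__dict__,
                    "notes": self.notes,
                },
                indent=2,
            )
            + "\n"
        )

    def to_tsv(self) -> str:
        cols = list(BatchRow.__dataclass_fields__)
        lines = ["\t".join(cols)]
        for r in self.rows:
            lines.append("\t".join(str(getattr(r, c)) for c in cols))
        return "\n".join(lines) + "\n"


def read_hits(path: str | Path) -> list[GwasHit]:
    """Read a tab-delimited GWAS hit table; duplicate variant ids are errors."""
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "gene": str})
    required = {"variant_id", "gene", "p_value"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(str(path), [f"missing columns: {sorted(missing)}"])
    dupes = df["variant_id"][df["variant_id"].duplicated()].tolist()
    if dupes:
        raise SchemaError(str(path), [f"duplicate variant_id: {sorted(set(dupes))}"])
    has_or = {"or", "ci_lower", "ci_upper"}.issubset(df.columns)
    hits = []
    for rec in df.to_dict("records"):
        effect = None
        if has_or and pd.notna(rec["or"]):
            effect = StudyEffect(
                odds_ratio=float(rec["or"]),
                ci_lower=float(rec["ci_lower"]),
                ci_upper=float(rec["ci_upper"]),
                label=str(rec["variant_id"]),
            )
        hits.append(
            GwasHit(
                variant_id=str(rec["variant_id"]),
                gene=str(rec["gene"]),
                p_value=float(rec["p_value"]),
                effect=effect,
                intergenic=bool(rec.get("intergenic", False)),
            )
        )
    return hits


def read_effects(path: str | Path) -> list[StudyEffect]:
    """Read study effects from a 4-column TSV: label, or, ci_lower, ci_upper."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["label", "or", "ci_lower", "ci_upper"],
        comment="#",
    )
    return [
        StudyEffect(
            odds_ratio=float(r["or"]),
            ci_lower=float(r["ci_lower"]),
            ci_upper=float(r["ci_upper"]),
            label=str(r["label"]),
        )
        for r in df.to_dict("records")
    ]


def _next_step(score: DiceScore, any_intergenic: bool) -> str:
    if score.classification == "strong":
        return "laboratory follow-up"
    if any_intergenic:
        return "consider nearby-factor reattribution"
    return "gather informatic/experimental evidence"


def batch_score(
    hits: list[GwasHit],
    evidence_dir: str | Path | None,
    config: RubricConfig | None = None,
    phenotype: str = "phenotype under study",
) -> BatchReport:
    """Score every attributed gene in a hit table against its dossier.

    Hits are grouped by gene; each group is merged into the gene's dossier
    (``<gene>.yaml`` in ``evidence_dir``; a missing file means an empty
    dossier) as omic discovery items keyed by variant id, then scored.  Rows
    sort by (total descending, best p ascending), so equally significant hits
    separate by the diversity of their evidence.  Unreadable dossier files
    yield per-row error entries; the run continues.
    """
    config = config or RubricConfig()
    seen: set[str] = set()
    for h in hits:
        if h.variant_id in seen:
            raise ValueError(f"duplicate variant_id {h.variant_id!r}")
        seen.add(h.variant_id)

    by_gene: dict[str, list[GwasHit]] = {}
    for h in hits:
        by_gene.setdefault(h.gene, []).append(h)

    rows: list[BatchRow] = []
    for gene, gene_hits in by_gene.items():
        dossier = Dossier(
            factor=Factor(name=gene, factor_class=FactorClass.gene),
            phenotype=Phenotype(name=phenotype),
        )
        error = ""
        if evidence_dir is not None:
            dossier_file = Path(evidence_dir) / f"{gene}.yaml"
            if dossier_file.exists():
                try:
                    dossier = read_dossier(dossier_file)
                except SchemaError as exc:
                    error = "; ".join(exc.errors)
        for h in gene_hits:
            dossier.items.append(
                EvidenceItem(
                    item_id=f"hit-{h.variant_id}",
                    category=Category.omic,
                    subtype=OmicSubtype.discovery.value,
                    result_key=h.variant_id,
                    p_value=h.p_value,
                    effect=h.effect,
                    source="batch hit table",
                )
            )
        score = score_dossier(dossier, config)
        any_intergenic = any(h.intergenic for h in gene_hits)
        rows.append(
            BatchRow(
                factor=gene,
                phenotype=dossier.phenotype.name,
                n_hits=len(gene_hits),
                min_p=min(h.p_value for h in gene_hits),
                single_finding_points=score.single_finding_points,
                validation_points=score.validation_points,
                informatic_points=score.informatic_points,
                experimental_points=score.experimental_points,
                total=score.total,
                classification=score.classification,
                next_step=_next_step(score, any_intergenic),
                error=error,
            )
        )
    rows.sort(key=lambda r: (-r.total, r.min_p, r.factor))
    return BatchReport(rows=rows, config=config)
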