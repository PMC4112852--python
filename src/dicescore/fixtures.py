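"""Canonical case-study dossiers and a seeded synthetic dossier generator.

Five canonical dossiers ship with the package, built from published case
studies of the rubric:

* **Hemoglobin S / malaria resistance** — a positive control: the marker SNP
  missed genome-wide significance in the discovery GWAS, but significance was
  attained by fine mapping, and informatic and experimental support abound.
* **ATP2B4 / malaria resistance** — a new lead with five genome-wide
  significant SNPs and convergent database and laboratory evidence.
* **MARVELD3 / malaria resistance** — a new lead resting on a single
  intergenic SNP and nothing else.
* **PPARγ / type 2 diabetes** — a second positive control: the known drug
  target never reached genome-wide significance in three scans, yet consistent
  odds ratios, a meta-analysis, and rich informatic/experimental evidence
  support it.
* **TAT / malaria** — tyrosine aminotransferase as the alternative attribution
  of the intergenic MARVELD3 SNP, plus one literature hit.

The alternative-validation items in the Hemoglobin S and ATP2B4 dossiers are
reconstructions of unpublished implementation details; each carries a
provenance note saying so.

The synthetic generator emulates the *shape* of such dossiers — category
presence, significant vs. null discovery p-values, validation and review
status — and records its own ground-truth component points alongside each
dossier, by bookkeeping entirely independent of the scoring engine.  It makes
no claim of GWAS realism (no LD, no genotypes, no effect-size model).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from dicescore.evidence_model import (
    Category,
    Dossier,
    EvidenceItem,
    ExperimentalSubtype,
    Factor,
    FactorClass,
    InformaticSubtype,
    OmicSubtype,
    Phenotype,
)
from dicescore.io import GwasHit, read_dossier

__all__ = [
    "CANONICAL_NAMES",
    "canonical_fixtures",
    "pparg_study_effects",
    "PValueMixture",
    "GeneratorSpec",
    "GroundTruth",
    "generate",
]

CANONICAL_NAMES = ("hbs", "atp2b4", "marveld3", "pparg", "tat")


def _fixture_dir() -> Path:
    return Path(str(resources.files("dicescore") / "data" / "fixtures"))


def canonical_fixtures() -> dict[str, Dossier]:
    """Load the five canonical dossiers shipped with the package."""
    return {
        name: read_dossier(_fixture_dir() / f"{name}.yaml")
        for name in CANONICAL_NAMES
    }


def pparg_study_effects() -> list:
    """The three published odds ratios behind the PPARγ meta-analysis."""
    dossier = canonical_fixtures()["pparg"]
    return [it.effect for it in dossier.items if it.effect is not None]


def provider_fixture_path() -> Path:
    """Shipped two-column (raw_query, record ids) provider table."""
    return _fixture_dir() / "provider_pubmed.tsv"


# --- synthetic generator -----------------------------------------------------


@dataclass(frozen=True)
class PValueMixture:
    """Two-component p-value model for synthetic omic findings.

    Significant p-values are log-uniform in [sig_low, threshold); null
    p-values uniform on (0, 1].  ``significant_fraction`` is the probability
    that a drawn omic finding comes from the significant component.  Minimal
    emulation sufficient for threshold logic, nothing more.
    """

    significant_fraction: float = 0.5
    threshold: float = 5e-8
    sig_low: float = 1e-12

    def __post_init__(self) -> None:
        if not (0.0 <= self.significant_fraction <= 1.0):
            raise ValueError("significant_fraction must lie in [0, 1]")
        if not (0.0 < self.sig_low < self.threshold < 1.0):
            raise ValueError("require 0 < sig_low < threshold < 1")

    def draw(self, rng: np.random.Generator) -> tuple[float, bool]:
        if rng.random() < self.significant_fraction:
            logp = rng.uniform(np.log10(self.sig_low), np.log10(self.threshold))
            p = float(10.0**logp)
            # log-uniform draws stay strictly below threshold; clip guards
            # against floating round-up at the boundary
            p = min(p, np.nextafter(self.threshold, 0.0))
            return p, True
        return float(rng.uniform(np.nextafter(0.0, 1.0), 1.0)), False


@dataclass(frozen=True)
class GeneratorSpec:
    seed: int = 0
    n_dossiers: int = 50
    category_presence_probs: dict = field(
        default_factory=lambda: {"omic": 0.7, "informatic": 0.5, "experimental": 0.4}
    )
    p_value_distribution: PValueMixture = field(default_factory=PValueMixture)
    fraction_with_validation: float = 0.5
    fraction_standard_validation: float = 0.5
    fraction_reviewed: float = 0.8
    fraction_override_significant: float = 0.0
    phenotype: str = "synthetic phenotype"

    def __post_init__(self) -> None:
        if self.n_dossiers < 0:
            raise ValueError("n_dossiers must be non-negative")
        for key in ("omic", "informatic", "experimental"):
            p = self.category_presence_probs.get(key, 0.0)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"presence probability for {key} must be in [0, 1]")
        for name in (
            "fraction_with_validation",
            "fraction_standard_validation",
            "fraction_reviewed",
            "fraction_override_significant",
        ):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    """Component points the generator *intended*, under the default rubric."""

    single_finding_points: int
    validation_points: int
    informatic_points: int
    experimental_points: int

    @property
    def total(self) -> int:
        return (
            self.single_finding_points
            + self.validation_points
            + self.informatic_points
            + self.experimental_points
        )


def generate(
    spec: GeneratorSpec,
) -> tuple[list[tuple[Dossier, GroundTruth]], pd.DataFrame, dict[str, tuple[str, ...]]]:
    """Generate seeded synthetic dossiers, a hit table, and a provider table.

    The returned ground truth assumes the default rubric (1/3/2/3/3 points,
    validation gated on a significant discovery, unreviewed items excluded);
    it is computed from the generator's own draws, never by calling the
    scoring engine, so the two can be cross-checked as independent codepaths.
    """
    rng = np.random.default_rng(spec.seed)
    probs = spec.category_presence_probs
    mix = spec.p_value_distribution

    out: list[tuple[Dossier, GroundTruth]] = []
    hit_rows: list[dict] = []
    provider_table: dict[str, tuple[str, ...]] = {}

    for i in range(spec.n_dossiers):
        gene = f"SYNG{i:04d}"
        items: list[EvidenceItem] = []
        single = validation = informatic = experimental = 0

        if rng.random() < probs.get("omic", 0.0):
            if rng.random() < spec.fraction_override_significant:
                p, sig = None, True
                override: bool | None = True
            else:
                p, sig = mix.draw(rng)
                override = None
            items.append(
                EvidenceItem(
                    item_id=f"{gene}-disc",
                    category=Category.omic,
                    subtype=OmicSubtype.discovery.value,
                    result_key=f"{gene}:discovery",
                    p_value=p,
                    significant_override=override,
                    source="synthetic discovery scan",
                )
            )
            if sig:
                single = 1
            variant = f"rs9{i:07d}"
            hit_rows.append(
                {
                    "variant_id": variant,
                    "gene": gene,
                    "p_value": p if p is not None else mix.sig_low,
                }
            )
            if rng.random() < spec.fraction_with_validation:
                standard = rng.random() < spec.fraction_standard_validation
                vp, vsig = mix.draw(rng)
                subtype = (
                    OmicSubtype.standard_validation.value
                    if standard
                    else OmicSubtype.alternative_validation.value
                )
                items.append(
                    EvidenceItem(
                        item_id=f"{gene}-val",
                        category=Category.omic,
                        subtype=subtype,
                        result_key=f"{gene}:validation",
                        p_value=vp,
                        source="synthetic validation study",
                    )
                )
                if vsig and sig:  # gated on a qualifying discovery
                    validation = 3 if standard else 2

        if rng.random() < probs.get("informatic", 0.0):
            reviewed = bool(rng.random() < spec.fraction_reviewed)
            query = f"{gene} and {spec.phenotype}"
            items.append(
                EvidenceItem(
                    item_id=f"{gene}-info",
                    category=Category.informatic,
                    subtype=InformaticSubtype.literature.value,
                    result_key=f"pubmed:{query}",
                    source=query,
                    reviewed=reviewed,
                )
            )
            provider_table[query] = (f"rec-{gene}-1",)
            if reviewed:
                informatic = 3

        if rng.random() < probs.get("experimental", 0.0):
            reviewed = bool(rng.random() < spec.fraction_reviewed)
            subtype = rng.choice([s.value for s in ExperimentalSubtype])
            items.append(
                EvidenceItem(
                    item_id=f"{gene}-exp",
                    category=Category.experimental,
                    subtype=str(subtype),
                    result_key=f"{gene}:experiment",
                    source="synthetic laboratory model",
                    reviewed=reviewed,
                )
            )
            if reviewed:
                experimental = 3

        dossier = Dossier(
            factor=Factor(name=gene, factor_class=FactorClass.gene),
            phenotype=Phenotype(name=spec.phenotype),
            items=items,
            notes="synthetic dossier",
        )
        out.append(
            (
                dossier,
                GroundTruth(single, validation, informatic, experimental),
            )
        )

    hit_table = pd.DataFrame(hit_rows, columns=["variant_id", "gene", "p_value"])
    return out, hit_table, provider_table


def write_all(out_dir: str | Path, spec: GeneratorSpec | None = None) -> None:
    """Write canonical fixtures plus one synthetic batch to ``out_dir``."""
    from dicescore.io import write_dossier

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, dossier in canonical_fixtures().items():
        write_dossier(dossier, out_dir / f"{name}.yaml")
    (out_dir / "provider_pubmed.tsv").write_text(
        provider_fixture_path().read_text()
    )
    if spec is not None:
        synth_dir = out_dir / "synthetic"
        synth_dir.mkdir(exist_ok=True)
        dossiers, hit_table, provider_table = generate(spec)
        for dossier, _ in dossiers:
            write_dossier(dossier, synth_dir / f"{dossier.factor.name}.yaml")
        hit_table.to_csv(synth_dir / "hits.tsv", sep="\t", index=False)
        lines = [f"{q}\t{','.join(ids)}" for q, ids in sorted(provider_table.items())]
        (synth_dir / "provider_pubmed.tsv").write_text("\n".join(lines) + "\n")
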