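"""Significance thresholds and fixed-effect meta-analysis of odds ratios.

Per-study effects arrive as an odds ratio with a Wald confidence interval, the
form in which GWAS results are usually printed.  The standard error is
back-calculated from the interval width on the log scale,

    SE = (ln U - ln L) / (2 * z_crit),

and studies are pooled by inverse-variance weighting of the log odds ratios:
w_i = 1/SE_i^2, pooled logOR = sum(w_i * logOR_i) / sum(w_i),
pooled SE = (sum w_i)^(-1/2), with a two-sided normal (Wald) p-value.

Random-effects models and heterogeneity statistics are out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.stats import norm

__all__ = [
    "StudyEffect",
    "MetaResult",
    "z_crit",
    "two_sided_p_from_z",
    "log_or_and_se",
    "fixed_effect_meta",
    "passes_threshold",
]

# |ln(OR) - midpoint of [ln L, ln U]| beyond this is treated as a data error
# rather than CI rounding (printed CIs carry ~2 decimals).
MIDPOINT_TOLERANCE = 0.05


@dataclass(frozen=True)
class StudyEffect:
    """One study's odds ratio with its confidence interval."""

    odds_ratio: float
    ci_lower: float
    ci_upper: float
    ci_level: float = 0.95
    label: str = ""

    def __post_init__(self) -> None:
        lab = f" (study {self.label!r})" if self.label else ""
        if not (0.0 < self.ci_level < 1.0):
            raise ValueError(f"ci_level must lie in (0, 1){lab}")
        for name in ("odds_ratio", "ci_lower", "ci_upper"):
            v = getattr(self, name)
            if not (v > 0.0 and math.isfinite(v)):
                raise ValueError(f"{name} must be positive and finite{lab}")
        if self.ci_lower >= self.ci_upper:
            raise ValueError(
                f"degenerate or inverted CI [{self.ci_lower}, {self.ci_upper}]{lab}"
            )
        if not (self.ci_lower <= self.odds_ratio <= self.ci_upper):
            raise ValueError(f"odds_ratio outside its own CI{lab}")
        midpoint = 0.5 * (math.log(self.ci_lower) + math.log(self.ci_upper))
        if abs(math.log(self.odds_ratio) - midpoint) > MIDPOINT_TOLERANCE:
            raise ValueError(
                f"odds_ratio inconsistent with CI midpoint beyond rounding "
                f"tolerance {MIDPOINT_TOLERANCE}{lab}"
            )


@dataclass(frozen=True)
class MetaResult:
    pooled_log_or: float
    pooled_se: float
    z_statistic: float
    p_two_sided: float
    per_study_weights: tuple[float, ...] = field(default=())

    @property
    def pooled_or(self) -> float:
        return math.exp(self.pooled_log_or)

    def to_dict(self) -> dict:
        return {
            "pooled_log_or": self.pooled_log_or,
            "pooled_or": self.pooled_or,
            "pooled_se": self.pooled_se,
            "z_statistic": self.z_statistic,
            "p_two_sided": self.p_two_sided,
            "per_study_weights": list(self.per_study_weights),
        }


def z_crit(level: float) -> float:
    """Two-sided normal critical value for a CI of the given coverage."""
    if not (0.0 < level < 1.0):
        raise ValueError("ci level must lie in (0, 1)")
    return float(norm.ppf(0.5 * (1.0 + level)))


def two_sided_p_from_z(z: float) -> float:
    """Two-sided tail probability 2*(1 - Phi(|z|)), via the survival function."""
    return float(min(1.0, 2.0 * norm.sf(abs(z))))


def log_or_and_se(effect: StudyEffect) -> tuple[float, float]:
    """Back-calculate (log odds ratio, standard error) from an OR and its CI."""
    log_or = math.log(effect.odds_ratio)
    se = (math.log(effect.ci_upper) - math.log(effect.ci_lower)) / (
        2.0 * z_crit(effect.ci_level)
    )
    return log_or, se


def fixed_effect_meta(effects: list[StudyEffect]) -> MetaResult:
    """Fixed-effect inverse-variance pooling of study odds ratios.

    Invariant to study order; pooling n identical studies shrinks the SE by
    sqrt(n); a single study is returned unchanged with its own Wald p.
    """
    if not effects:
        raise ValueError("meta-analysis requires at least one study effect")
    log_ors, weights = [], []
    for eff in effects:
        lo, se = log_or_and_se(eff)
        log_ors.append(lo)
        weights.append(1.0 / (se * se))
    w_sum = math.fsum(weights)
    pooled = math.fsum(w * lo for w, lo in zip(weights, log_ors)) / w_sum
    pooled_se = w_sum**-0.5
    z = pooled / pooled_se
    return MetaResult(
        pooled_log_or=pooled,
        pooled_se=pooled_se,
        z_statistic=z,
        p_two_sided=two_sided_p_from_z(z),
        per_study_weights=tuple(weights),
    )


def passes_threshold(p: float, threshold: float) -> bool:
    """Strict significance call: true iff p < threshold."""
    if not (0.0 < p <= 1.0):
        raise ValueError(f"p-value {p!r} not in (0, 1]")
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold {threshold!r} not in (0, 1)")
    return p < threshold
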