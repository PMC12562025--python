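"""Variance components, broad-sense heritability, and CV ratios.

From a balanced one-way ANOVA with k replicates the moment estimators are

    sigma_f2 = QMg / k            phenotypic variance (of genotype means)
    sigma_e2 = QMr / k            environmental variance
    sigma_g2 = (QMg - QMr) / k    genetic variance
    h2       = sigma_g2 / sigma_f2 = 1 - QMr/QMg
    CVg      = 100 * sqrt(sigma_g2) / m
    CVe      = 100 * sqrt(QMr) / m
    CVg/CVe  = sqrt((QMg - QMr) / (k * QMr))

Note the deliberate asymmetry: CVe uses the residual mean square on the
observation scale (sqrt(QMr)), not sqrt(QMr/k).  This is the convention of
the plant-breeding software lineage these estimators come from — it makes
CVe coincide with the experiment's ordinary CV% — and it is the only
reading consistent with published tables that report CVg/CVe and CV%
side by side.  A negative sigma_g2 (QMr > QMg) is reported as-is and
flagged, never truncated to zero, so that simulation studies see the raw
estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .anova_scott_knott import AnovaResult

__all__ = ["GeneticParameterSet", "genetic_parameters", "parameters_from_mean_squares"]


@dataclass(frozen=True)
class GeneticParameterSet:
    """Moment estimates of the genetic parameters for one trait.

    ``h2`` is stored as a fraction; exports render it as a percentage.
    ``flags`` marks degenerate estimates (negative genetic variance,
    infinite ratio, undefined CVs) instead of silently masking them.
    """

    trait: str
    k: int
    sigma_f2: float
    sigma_e2: float
    sigma_g2: float
    h2: float
    cvg_percent: float
    cve_percent: float
    cvg_cve_ratio: float
    flags: tuple[str, ...] = field(default=())

    @property
    def h2_percent(self) -> float:
        return 100.0 * self.h2


def parameters_from_mean_squares(
    trait: str, qmg: float, qmr: float, k: int, mean: float
) -> GeneticParameterSet:
    """Compute the parameter set directly from mean squares and a trait mean.

    This is the entry point for replaying published ANOVA summaries where
    only QMg, QMr, k and the trait mean are available.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if qmg < 0 or qmr < 0:
        raise ValueError("mean squares must be non-negative")
    flags: list[str] = []
    sigma_f2 = qmg / k
    sigma_e2 = qmr / k
    sigma_g2 = (qmg - qmr) / k

    if qmg > 0:
        h2 = sigma_g2 / sigma_f2  # == 1 - qmr/qmg
    else:
        h2 = math.nan
        flags.append("h2_undefined")
    if sigma_g2 < 0:
        flags.append("negative_sigma_g2")

    if mean == 0:
        cvg = cve = math.nan
        flags.append("cv_undefined_zero_mean")
    else:
        cvg = 100.0 * math.sqrt(sigma_g2) / mean if sigma_g2 >= 0 else math.nan
        cve = 100.0 * math.sqrt(qmr) / mean

    if qmr == 0:
        ratio = math.inf if sigma_g2 > 0 else 0.0
        if sigma_g2 > 0:
            flags.append("ratio_infinite")
    elif sigma_g2 < 0:
        ratio = math.nan
    else:
        ratio = math.sqrt((qmg - qmr) / (k * qmr))

    return GeneticParameterSet(
        trait=trait,
        k=k,
        sigma_f2=sigma_f2,
        sigma_e2=sigma_e2,
        sigma_g2=sigma_g2,
        h2=h2,
        cvg_percent=cvg,
        cve_percent=cve,
        cvg_cve_ratio=ratio,
        flags=tuple(flags),
    )


def genetic_parameters(anova: AnovaResult, k: int) -> GeneticParameterSet:
    """Parameter set for one trait from its ANOVA (k = replicates of the design)."""
    return parameters_from_mean_squares(
        anova.trait, anova.qmg, anova.qmr, k, anova.grand_mean
    )
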