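"""Synthetic balanced-CRD cohorts with known variance components.

The study's raw observations are not deposited, so every downstream stage
is exercised on simulated cohorts whose ground truth is known.  The model
is the one the ANOVA estimators assume:

    y_{ijt} = mu_t + g_{it} + e_{ijt}

with genotypic effect vectors g_i ~ MVN(0, D C D) (D = diag(sigma_g per
trait), C an optional cross-trait correlation) and residuals
e_{ijt} ~ N(0, sigma_e2_t) independent.  Under this model the one-way
expected mean squares are E[QMg] = sigma_e2 + r*sigma_g2 and
E[QMr] = sigma_e2, which is exactly what the moment estimators invert.

Default cohort scale mirrors the study design: G=160 mother plants,
r=4 replicates; tests use reduced G for speed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .trait_data import TraitTable

__all__ = ["TraitSpec", "CohortSpec", "simulate_cohort", "expected_parameters"]


@dataclass(frozen=True)
class TraitSpec:
    """Per-trait population parameters: grand mean and variance components."""

    name: str
    mean: float
    sigma_g2: float
    sigma_e2: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.mean):
            raise ValueError(f"{self.name}: grand mean must be finite")
        if self.sigma_g2 < 0:
            raise ValueError(f"{self.name}: sigma_g2 must be >= 0")
        if self.sigma_e2 <= 0:
            raise ValueError(f"{self.name}: sigma_e2 must be > 0")


@dataclass(frozen=True)
class CohortSpec:
    """Design and parameters of a simulated cohort.

    ``genetic_correlation`` (optional) is the T x T correlation of the
    genotypic effects; it must be symmetric PSD with unit diagonal.
    ``seed`` is mandatory — there is no global RNG state.
    """

    G: int
    r: int
    traits: tuple[TraitSpec, ...]
    seed: int
    genetic_correlation: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        if self.G < 2:
            raise ValueError("need at least 2 genotypes")
        if self.r < 2:
            raise ValueError("need at least 2 replicates")
        if not self.traits:
            raise ValueError("need at least one trait")
        object.__setattr__(self, "traits", tuple(self.traits))
        C = self.genetic_correlation
        if C is not None:
            C = np.asarray(C, dtype=float)
            T = len(self.traits)
            if C.shape != (T, T):
                raise ValueError(f"genetic_correlation must be {T}x{T}")
            if not np.allclose(C, C.T, atol=1e-12):
                raise ValueError("genetic_correlation must be symmetric")
            if not np.allclose(np.diag(C), 1.0, atol=1e-12):
                raise ValueError("genetic_correlation must have unit diagonal")
            if np.linalg.eigvalsh(C).min() < -1e-10:
                raise ValueError("genetic_correlation must be positive semidefinite")
            object.__setattr__(self, "genetic_correlation", C)

    @classmethod
    def from_config(cls, source) -> "CohortSpec":
        """Build from a YAML/JSON mapping (path or file object).

        Expected keys: G, r, seed, traits (list of {name, mean, sigma_g2,
        sigma_e2}), optional genetic_correlation (T x T nested list).
        """
        if hasattr(source, "read"):
            cfg = yaml.safe_load(source)
        else:
            with open(source) as fh:
                cfg = yaml.safe_load(fh)
        traits = tuple(TraitSpec(**t) for t in cfg["traits"])
        corr = cfg.get("genetic_correlation")
        return cls(
            G=int(cfg["G"]),
            r=int(cfg["r"]),
            traits=traits,
            seed=int(cfg["seed"]),
            genetic_correlation=None if corr is None else np.asarray(corr, float),
        )


def simulate_cohort(spec: CohortSpec) -> TraitTable:
    """Draw one balanced cohort; identical spec (incl. seed) -> identical table."""
    rng = np.random.default_rng(spec.seed)
    G, r, T = spec.G, spec.r, len(spec.traits)
    sg = np.array([np.sqrt(t.sigma_g2) for t in spec.traits])
    se = np.array([np.sqrt(t.sigma_e2) for t in spec.traits])
    mu = np.array([t.mean for t in spec.traits])

    z = rng.standard_normal((G, T))
    if spec.genetic_correlation is not None:
        # eigendecomposition square root: tolerates PSD-singular correlations
        w, V = np.linalg.eigh(spec.genetic_correlation)
        z = z @ (V * np.sqrt(np.clip(w, 0.0, None))) @ V.T
    g = z * sg  # (G, T) genotypic effects with marginal sd sigma_g

    e = rng.standard_normal((G, T, r)) * se[None, :, None]
    values = mu[None, :, None] + g[:, :, None] + e
    genotypes = [f"g{i + 1:03d}" for i in range(G)]
    return TraitTable(genotypes, [t.name for t in spec.traits], r, values)


def expected_parameters(spec: CohortSpec) -> pd.DataFrame:
    """Population-level recovery targets for each trait.

    Returns a frame indexed by trait with columns ``h2`` (heritability of
    genotype means, sigma_g2 / (sigma_g2 + sigma_e2/r)), ``cvg_percent``,
    ``cve_percent`` and ``cvg_cve_ratio`` — the values the moment
    estimators should recover on average.
    """
    rows = {}
    for t in spec.traits:
        if t.mean == 0 and (t.sigma_g2 > 0 or t.sigma_e2 > 0):
            raise ValueError(f"{t.name}: CV undefined for zero mean")
        h2 = t.sigma_g2 / (t.sigma_g2 + t.sigma_e2 / spec.r)
        rows[t.name] = {
            "h2": h2,
            "cvg_percent": 100.0 * np.sqrt(t.sigma_g2) / t.mean,
            "cve_percent": 100.0 * np.sqrt(t.sigma_e2) / t.mean,
            "cvg_cve_ratio": np.sqrt(t.sigma_g2 / t.sigma_e2),
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "trait"
    return df
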