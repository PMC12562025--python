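"""Generalized Mahalanobis divergence between genotypes.

The metric is the inverse of the pooled within-genotype (residual)
covariance of the raw observations,

    psi[t, u] = sum_i sum_j (y_ijt - ybar_it) (y_iju - ybar_iu) / (G (r-1)),

whose diagonal equals each trait's residual mean square QMr.  Distances
are computed between genotype MEAN vectors:

    D2(i, i') = d' psi^{-1} d,   d = ybar_i - ybar_i'.

Singh's criterion decomposes each pairwise D2 into additive per-trait
terms c_j = d_j * (psi^{-1} d)_j (so sum_j c_j = D2 exactly) and
aggregates them over all unordered pairs; a trait's relative contribution
is its share of the total.  With correlated traits individual c_j can be
negative; the signed values are kept because the decomposition identity
is the only self-consistent convention.

An optional ``scale="means"`` divides psi by r (covariance of genotype
means rather than of observations).  This multiplies every D2 by the
constant r and therefore changes no grouping, only absolute distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .trait_data import TraitTable

__all__ = [
    "PooledCovariance",
    "DistanceMatrix",
    "ContributionTable",
    "pooled_residual_covariance",
    "mahalanobis_matrix",
    "singh_contributions",
]

_COND_WARN = 1e12


class SingularCovarianceError(np.linalg.LinAlgError):
    """Pooled residual covariance is singular (collinear traits)."""


@dataclass(frozen=True)
class PooledCovariance:
    """Pooled residual covariance psi (T x T) with its pooling df G*(r-1)."""

    traits: tuple[str, ...]
    psi: np.ndarray = field(repr=False)
    df: int
    scale: str = "observations"

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.psi, index=self.traits, columns=self.traits)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric G x G matrix of generalized Mahalanobis D2 values."""

    genotypes: tuple[str, ...]
    d2: np.ndarray = field(repr=False)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d2, index=self.genotypes, columns=self.genotypes)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy's condensed (pdist) order."""
        iu = np.triu_indices(len(self.genotypes), k=1)
        return self.d2[iu]


@dataclass(frozen=True)
class ContributionTable:
    """Singh per-trait divergence totals S_j and percent contributions."""

    traits: tuple[str, ...]
    s_j: np.ndarray = field(repr=False)
    percent: np.ndarray = field(repr=False)

    def as_frame(self) -> pd.DataFrame:
        """Contributions sorted by descending percent (bar-chart order)."""
        df = pd.DataFrame({"trait": self.traits, "S_j": self.s_j, "percent": self.percent})
        return df.sort_values("percent", ascending=False, ignore_index=True)


def pooled_residual_covariance(table: TraitTable, scale: str = "observations") -> PooledCovariance:
    """Pool within-genotype cross-products over all genotypes.

    ``scale="observations"`` (default) divides by G*(r-1); ``scale="means"``
    additionally divides by r.  The diagonal (observation scale) equals each
    trait's QMr.  Raises :class:`SingularCovarianceError` when a trait is a
    linear combination of others; warns when df < T (underdetermined) or the
    condition number exceeds 1e12.
    """
    if scale not in ("observations", "means"):
        raise ValueError(f"scale must be 'observations' or 'means', got {scale!r}")
    G, T, r = table.values.shape
    df = G * (r - 1)
    if df < T:
        warnings.warn(
            f"pooling df={df} < number of traits T={T}: psi is rank-deficient "
            "or poorly estimated",
            stacklevel=2,
        )
    resid = table.values - table.values.mean(axis=2, keepdims=True)  # (G, T, r)
    flat = resid.transpose(0, 2, 1).reshape(G * r, T)
    psi = flat.T @ flat / df
    if scale == "means":
        psi = psi / r
    _check_invertible(psi)
    return PooledCovariance(tuple(table.traits), psi, df, scale)


def _check_invertible(psi: np.ndarray) -> None:
    try:
        cond = np.linalg.cond(psi)
    except np.linalg.LinAlgError:  # pragma: no cover - cond rarely fails
        cond = np.inf
    eps = np.finfo(float).eps
    if not np.isfinite(cond) or cond > 1.0 / eps:
        raise SingularCovarianceError(
            "pooled residual covariance is singular; remove collinear/constant "
            "traits (e.g. a duplicated or linearly dependent column)"
        )
    if cond > _COND_WARN:
        warnings.warn(
            f"pooled covariance condition number {cond:.3g} > 1e12; "
            "D2 values may be numerically unstable",
            stacklevel=3,
        )


def _solve_psi(psi: np.ndarray, b: np.ndarray) -> np.ndarray:
    """psi^{-1} b via Cholesky when PD, with a symmetric-solve fallback."""
    try:
        c = linalg.cho_factor(psi, lower=True, check_finite=False)
        return linalg.cho_solve(c, b, check_finite=False)
    except linalg.LinAlgError:
        try:
            return linalg.solve(psi, b, assume_a="sym", check_finite=False)
        except linalg.LinAlgError as exc:
            raise SingularCovarianceError(str(exc)) from exc


def mahalanobis_matrix(table: TraitTable, psi: PooledCovariance) -> DistanceMatrix:
    """All-pairs D2 between genotype mean vectors in the psi metric."""
    if tuple(table.traits) != psi.traits:
        raise ValueError("psi was computed for different traits")
    M = table.genotype_means().to_numpy()  # (G, T)
    # whiten: rows w_i with D2(i,i') = ||w_i - w_i'||^2
    W = _whiten(M, psi.psi)
    sq = (W**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (W @ W.T)
    np.clip(d2, 0.0, None, out=d2)
    np.fill_diagonal(d2, 0.0)
    d2 = (d2 + d2.T) / 2.0
    return DistanceMatrix(tuple(table.genotypes), d2)


def _whiten(M: np.ndarray, psi: np.ndarray) -> np.ndarray:
    try:
        L = linalg.cholesky(psi, lower=True, check_finite=False)
    except linalg.LinAlgError as exc:
        raise SingularCovarianceError(str(exc)) from exc
    return linalg.solve_triangular(L, M.T, lower=True, check_finite=False).T


def pairwise_trait_terms(
    table: TraitTable, psi: PooledCovariance, i: int, j: int
) -> np.ndarray:
    """Signed per-trait terms c of one pair's D2 (sum(c) == D2(i, j))."""
    M = table.genotype_means().to_numpy()
    d = M[i] - M[j]
    return d * _solve_psi(psi.psi, d)


def singh_contributions(table: TraitTable, psi: PooledCovariance) -> ContributionTable:
    """Per-trait divergence totals over all unordered genotype pairs.

    S_j = sum over pairs of d_j (psi^{-1} d)_j, computed through the
    pair-sum outer-product identity
    sum_{i<i'} d d' = G * sum_i (m_i - mbar)(m_i - mbar)',
    so S_j = row-sum of (A . psi^{-1}) without an explicit pair loop.
    """
    if tuple(table.traits) != psi.traits:
        raise ValueError("psi was computed for different traits")
    M = table.genotype_means().to_numpy()
    G = M.shape[0]
    Mc = M - M.mean(axis=0)
    A = G * (Mc.T @ Mc)  # sum over unordered pairs of d d'
    psi_inv = _solve_psi(psi.psi, np.eye(len(psi.traits)))
    s_j = (psi_inv * A).sum(axis=1)
    total = s_j.sum()
    if total <= 0:
        raise ValueError(
            "total divergence is zero: all genotype mean vectors are identical"
        )
    return ContributionTable(psi.traits, s_j, 100.0 * s_j / total)
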