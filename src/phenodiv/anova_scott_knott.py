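"""One-way CRD ANOVA and Scott-Knott grouping of genotype means.

The Scott-Knott test recursively splits the mean-ordered genotype list at
the contiguous cut that maximizes the between-group sum of squares B0 and
accepts the split when

    lambda = pi / (2*(pi - 2)) * B0 / sigma0_hat^2

exceeds the upper-alpha chi-square quantile with k/(pi-2) (non-integer)
degrees of freedom, where, for a node holding k means,

    sigma0_hat^2 = (sum_i (ybar_i - ybar)^2 + nu * s2_ybar) / (k + nu),

s2_ybar = QMr / r is the variance of a genotype mean and nu = G*(r-1) the
residual degrees of freedom of the trait's own ANOVA (reused at every
depth, as in the classical procedure).  Classes are therefore always
contiguous runs of the mean-ordered list and are labelled a, b, c, ... by
descending class mean.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .trait_data import TraitTable

__all__ = ["AnovaResult", "SKGrouping", "one_way_anova", "scott_knott"]

_SK_CONST = np.pi / (2.0 * (np.pi - 2.0))
_SK_DF_FACTOR = 1.0 / (np.pi - 2.0)


@dataclass(frozen=True)
class AnovaResult:
    """Per-trait one-way ANOVA summary (the bridge to the genetic parameters)."""

    trait: str
    qmg: float  # genotype (mother-plant) mean square
    qmr: float  # residual mean square
    df_g: int
    df_r: int
    f: float
    p: float
    grand_mean: float
    cv_percent: float  # 100*sqrt(QMr)/grand_mean; nan when the mean is 0

    @property
    def stars(self) -> str:
        """Significance marker: ** p<0.01, * p<0.05, ns otherwise."""
        return "**" if self.p < 0.01 else "*" if self.p < 0.05 else "ns"


@dataclass(frozen=True)
class SKGrouping:
    """Ordered partition of genotypes into homogeneous classes.

    ``groups`` lists classes by descending class mean; each class is a list
    of genotype ids.  ``letters`` maps genotype -> class label (a, b, ...).
    """

    trait: str
    alpha: float
    groups: tuple[tuple[str, ...], ...]
    means: dict[str, float]

    @property
    def letters(self) -> dict[str, str]:
        out: dict[str, str] = {}
        labels = _class_labels(len(self.groups))
        for label, cls in zip(labels, self.groups):
            for g in cls:
                out[g] = label
        return out

    @property
    def n_groups(self) -> int:
        return len(self.groups)


def _class_labels(n: int) -> list[str]:
    letters = string.ascii_lowercase
    labels = []
    for i in range(n):
        lab = ""
        j = i
        while True:
            lab = letters[j % 26] + lab
            j = j // 26 - 1
            if j < 0:
                break
        labels.append(lab)
    return labels


def one_way_anova(table: TraitTable, trait: str) -> AnovaResult:
    """Balanced one-way ANOVA for one trait.

    SSg = r * sum_i (ybar_i - ybar)^2,  SSr = sum_ij (y_ij - ybar_i)^2,
    QMg = SSg/(G-1), QMr = SSr/(G(r-1)), F = QMg/QMr with the upper-tail
    F probability.
    """
    y = table.trait_values(trait)
    G, r = y.shape
    if G < 2:
        raise ValueError("ANOVA needs at least 2 genotypes")
    gmeans = y.mean(axis=1)
    grand = y.mean()
    ssg = r * float(((gmeans - grand) ** 2).sum())
    ssr = float(((y - gmeans[:, None]) ** 2).sum())
    df_g, df_r = G - 1, G * (r - 1)
    qmg, qmr = ssg / df_g, ssr / df_r
    if qmr > 0:
        f = qmg / qmr
        p = float(stats.f.sf(f, df_g, df_r))
    else:
        f = np.inf if qmg > 0 else 0.0
        p = 0.0 if qmg > 0 else 1.0
    cv = 100.0 * np.sqrt(qmr) / grand if grand != 0 else np.nan
    return AnovaResult(trait, qmg, qmr, df_g, df_r, f, p, grand, cv)


def _best_split(means: np.ndarray) -> tuple[int, float]:
    """Leftmost contiguous split maximizing the between-group SS B0.

    Returns (cut, B0) where the left part is means[:cut].  Ties on B0 go to
    the smallest cut for determinism.
    """
    k = len(means)
    total = means.sum()
    csum = np.cumsum(means)[:-1]
    k1 = np.arange(1, k)
    b0 = csum**2 / k1 + (total - csum) ** 2 / (k - k1) - total**2 / k
    cut = int(np.argmax(b0))  # argmax takes the first maximum: leftmost tie
    return cut + 1, float(b0[cut])


def _sk_recurse(
    means: np.ndarray,
    order_ids: list[str],
    s2_ybar: float,
    nu: float,
    alpha: float,
    out: list[list[str]],
) -> None:
    k = len(means)
    if k == 1:
        out.append(list(order_ids))
        return
    cut, b0 = _best_split(means)
    centered_ss = float(((means - means.mean()) ** 2).sum())
    sigma02 = (centered_ss + nu * s2_ybar) / (k + nu)
    if sigma02 <= 0:
        lam = np.inf if b0 > 0 else 0.0
    else:
        lam = _SK_CONST * b0 / sigma02
    crit = stats.chi2.ppf(1.0 - alpha, k * _SK_DF_FACTOR)
    if lam > crit:
        _sk_recurse(means[:cut], order_ids[:cut], s2_ybar, nu, alpha, out)
        _sk_recurse(means[cut:], order_ids[cut:], s2_ybar, nu, alpha, out)
    else:
        out.append(list(order_ids))


def scott_knott(table: TraitTable, trait: str, alpha: float = 0.05) -> SKGrouping:
    """Scott-Knott clustering of one trait's genotype means at level alpha."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    y = table.trait_values(trait)
    G, r = y.shape
    anova = one_way_anova(table, trait)
    s2_ybar = anova.qmr / r
    nu = float(anova.df_r)
    gmeans = y.mean(axis=1)
    # descending means; stable sort keeps input order among exact ties
    order = np.argsort(-gmeans, kind="stable")
    ids = [table.genotypes[i] for i in order]
    out: list[list[str]] = []
    _sk_recurse(gmeans[order], ids, s2_ybar, nu, alpha, out)
    groups = tuple(tuple(cls) for cls in out)
    means = {g: float(m) for g, m in zip(table.genotypes, gmeans)}
    return SKGrouping(trait, alpha, groups, means)
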