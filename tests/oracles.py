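"""Independent brute-force oracles used only by the tests.

Each function here re-derives a quantity by the most literal possible
route (explicit loops, exhaustive enumeration, explicit matrix inverse)
so that the package's vectorized / library-backed implementations are
checked against genuinely independent code paths.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

SK_CONST = math.pi / (2.0 * (math.pi - 2.0))


def naive_upgma(dist: np.ndarray):
    """Textbook O(G^3) UPGMA on a full matrix.

    Inter-cluster distance is recomputed every step as the plain average of
    all cross-pair entries of the ORIGINAL matrix.  Returns the list of
    merge heights (sorted per step order) and a cophenetic matrix.
    """
    G = dist.shape[0]
    clusters: list[list[int]] = [[i] for i in range(G)]
    heights: list[float] = []
    coph = np.zeros((G, G))
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = np.mean([dist[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or d < best[0] - 1e-15:
                    best = (d, a, b)
        d, a, b = best
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = d
        heights.append(d)
        merged = clusters[a] + clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(merged)
    return heights, coph


def naive_cophenetic_correlation(dist: np.ndarray) -> float:
    """Pearson r between original and naive-UPGMA cophenetic distances."""
    _, coph = naive_upgma(dist)
    iu = np.triu_indices(dist.shape[0], k=1)
    x, y = dist[iu], coph[iu]
    x = x - x.mean()
    y = y - y.mean()
    return float((x * y).sum() / math.sqrt((x**2).sum() * (y**2).sum()))


def exhaustive_scott_knott(
    means: np.ndarray, ids: list[str], s2_ybar: float, nu: float, alpha: float
) -> list[list[str]]:
    """Scott-Knott by literal enumeration of every contiguous split.

    ``means`` must already be sorted descending; recursion mirrors the
    procedure's definition with B0 and lambda computed from first
    principles (explicit group sums, no incremental formulas).
    """
    k = len(means)
    if k == 1:
        return [list(ids)]
    best_b0, best_cut = -np.inf, None
    for cut in range(1, k):
        g1, g2 = means[:cut], means[cut:]
        b0 = (
            g1.sum() ** 2 / len(g1)
            + g2.sum() ** 2 / len(g2)
            - means.sum() ** 2 / k
        )
        if b0 > best_b0 + 1e-12:
            best_b0, best_cut = b0, cut
    sigma02 = (sum((m - means.mean()) ** 2 for m in means) + nu * s2_ybar) / (k + nu)
    lam = np.inf if sigma02 <= 0 and best_b0 > 0 else (
        0.0 if sigma02 <= 0 else SK_CONST * best_b0 / sigma02
    )
    crit = stats.chi2.ppf(1.0 - alpha, k / (math.pi - 2.0))
    if lam > crit:
        return exhaustive_scott_knott(
            means[:best_cut], ids[:best_cut], s2_ybar, nu, alpha
        ) + exhaustive_scott_knott(means[best_cut:], ids[best_cut:], s2_ybar, nu, alpha)
    return [list(ids)]


def brute_force_singh(means: np.ndarray, psi: np.ndarray):
    """Per-trait Singh totals via an explicit pair loop and explicit inverse.

    Returns (S_j vector, total sum of pairwise D2).
    """
    G, T = means.shape
    psi_inv = np.linalg.inv(psi)
    s_j = np.zeros(T)
    total_d2 = 0.0
    for i in range(G):
        for ip in range(i + 1, G):
            d = means[i] - means[ip]
            w = psi_inv @ d
            s_j += d * w
            total_d2 += float(d @ w)
    return s_j, total_d2


def brute_force_pooled_cov(values: np.ndarray) -> np.ndarray:
    """Pooled within-genotype cross products via explicit triple loop."""
    G, T, r = values.shape
    psi = np.zeros((T, T))
    for i in range(G):
        for t in range(T):
            for u in range(T):
                yt = values[i, t, :]
                yu = values[i, u, :]
                psi[t, u] += np.sum((yt - yt.mean()) * (yu - yu.mean()))
    return psi / (G * (r - 1))
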