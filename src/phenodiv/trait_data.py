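"""Replicated genotype x trait tables and seed-vigor indices.

The central container is :class:`TraitTable`: a balanced completely
randomized design (CRD) of G genotypes (mother plants) x T traits x r
replicates.  Everything downstream — per-trait ANOVA, variance components,
Mahalanobis divergence, UPGMA grouping — consumes this one structure.

Two seed-vigor indices are derived from daily emergence counts and then
enter the table as ordinary traits:

* Maguire's emergence speed index, ESI = sum_i n_i / t_i (seedlings/day)
* Edmond & Drapala's mean emergence time, MET = sum_i n_i t_i / sum_i n_i (days)

where n_i seedlings newly emerged on day t_i after sowing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TraitTable",
    "EmergenceCounts",
    "read_trait_table",
    "write_trait_table",
    "emergence_speed_index",
    "mean_emergence_time",
]

LONG_COLUMNS = ("genotype", "replicate", "trait", "value")


class TraitTableError(ValueError):
    """Raised when a trait table violates the balanced-CRD contract."""


@dataclass
class TraitTable:
    """Balanced replicated observations, indexed (genotype, trait, replicate).

    Parameters
    ----------
    genotypes : list of str
        Genotype identifiers in first-appearance order.
    traits : list of str
        Trait names in first-appearance order.
    r : int
        Replicates per (genotype, trait) cell; the design is balanced.
    values : ndarray of shape (G, T, r)
        Observations in original trait units.  No internal standardization
        is applied — the D² metric already scales by the residual covariance.
    """

    genotypes: list[str]
    traits: list[str]
    r: int
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        G, T = len(self.genotypes), len(self.traits)
        if self.r < 2:
            raise TraitTableError(f"need at least 2 replicates, got r={self.r}")
        if self.values.shape != (G, T, self.r):
            raise TraitTableError(
                f"values shape {self.values.shape} != (G={G}, T={T}, r={self.r})"
            )
        if len(set(self.genotypes)) != G:
            raise TraitTableError("duplicate genotype identifiers")
        if len(set(self.traits)) != T:
            raise TraitTableError("duplicate trait names")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise TraitTableError(
                "non-finite value at (genotype="
                f"{self.genotypes[bad[0]]}, trait={self.traits[bad[1]]}, "
                f"replicate={bad[2] + 1})"
            )

    @property
    def n_genotypes(self) -> int:
        return len(self.genotypes)

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    def trait_index(self, trait: str) -> int:
        try:
            return self.traits.index(trait)
        except ValueError:
            raise KeyError(f"unknown trait {trait!r}") from None

    def trait_values(self, trait: str) -> np.ndarray:
        """(G, r) array of observations for one trait."""
        return self.values[:, self.trait_index(trait), :]

    def genotype_means(self) -> pd.DataFrame:
        """G x T table of genotype means, the input to D²."""
        return pd.DataFrame(
            self.values.mean(axis=2), index=self.genotypes, columns=self.traits
        )

    def to_long(self) -> pd.DataFrame:
        """Long-format frame with columns genotype, replicate, trait, value."""
        G, T, r = self.values.shape
        return pd.DataFrame(
            {
                "genotype": np.repeat(self.genotypes, T * r),
                "replicate": np.tile(np.arange(1, r + 1), G * T),
                "trait": np.tile(np.repeat(self.traits, r), G),
                "value": self.values.reshape(-1),
            }
        )

    def with_trait(self, name: str, values: np.ndarray) -> "TraitTable":
        """Return a new table with an extra trait column (e.g. a vigor index)."""
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n_genotypes, self.r):
            raise TraitTableError(
                f"new trait values must have shape (G, r)={(self.n_genotypes, self.r)}"
            )
        if name in self.traits:
            raise TraitTableError(f"trait {name!r} already present")
        stacked = np.concatenate([self.values, values[:, None, :]], axis=1)
        return TraitTable(list(self.genotypes), list(self.traits) + [name], self.r, stacked)


@dataclass(frozen=True)
class EmergenceCounts:
    """Daily counts of newly emerged seedlings for one replicate.

    ``days`` are strictly increasing positive integers (days after sowing);
    ``counts[i]`` seedlings emerged on ``days[i]``; ``n_sown`` seeds were sown.
    """

    days: tuple[int, ...]
    counts: tuple[int, ...]
    n_sown: int

    def __post_init__(self) -> None:
        days = tuple(int(d) for d in self.days)
        counts = tuple(int(c) for c in self.counts)
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "counts", counts)
        if len(days) != len(counts):
            raise ValueError("days and counts must have equal length")
        if any(d <= 0 for d in days):
            raise ValueError("days must be positive (day 0 undefined for ESI)")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("days must be strictly increasing")
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative")
        if self.n_sown <= 0:
            raise ValueError("n_sown must be positive")
        if sum(counts) > self.n_sown:
            raise ValueError(
                f"total emergence {sum(counts)} exceeds n_sown={self.n_sown}"
            )


def emergence_speed_index(ec: EmergenceCounts) -> float:
    """Maguire's ESI = sum_i n_i / t_i, in seedlings per day.

    Zero when nothing emerged.  Additive over any partition of the daily
    counts, which is what makes it usable on pooled or split count records.
    """
    return float(sum(c / d for c, d in zip(ec.counts, ec.days)))


def mean_emergence_time(ec: EmergenceCounts) -> float:
    """Edmond-Drapala MET = sum_i n_i t_i / sum_i n_i, in days.

    Undefined (raises) when no seedling emerged; otherwise lies within
    [first day with emergence, last day with emergence].
    """
    total = sum(ec.counts)
    if total == 0:
        raise ValueError("mean emergence time undefined: no seedling emerged")
    return float(sum(c * d for c, d in zip(ec.counts, ec.days)) / total)


def _table_from_long(df: pd.DataFrame) -> TraitTable:
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise TraitTableError(f"long CSV missing column(s) {missing}")
    df = df.copy()
    df["genotype"] = df["genotype"].astype(str)
    df["trait"] = df["trait"].astype(str)

    values = pd.to_numeric(df["value"], errors="coerce")
    bad = values.isna() | ~np.isfinite(values)
    if bad.any():
        # +2: header row plus 1-based indexing of data rows
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise TraitTableError(f"non-numeric or missing value at CSV row {row}")
    df["value"] = values

    dup = df.duplicated(subset=["genotype", "trait", "replicate"])
    if dup.any():
        g, t, rep = df.loc[dup.idxmax(), ["genotype", "trait", "replicate"]]
        raise TraitTableError(
            f"duplicate observation for (genotype={g}, trait={t}, replicate={rep})"
        )

    genotypes = list(dict.fromkeys(df["genotype"]))
    traits = list(dict.fromkeys(df["trait"]))
    counts = df.groupby(["genotype", "trait"], sort=False).size()
    r = int(counts.iloc[0])
    full = pd.MultiIndex.from_product([genotypes, traits], names=["genotype", "trait"])
    counts = counts.reindex(full, fill_value=0)
    off = counts[counts != r]
    if len(off):
        (g, t), n = off.index[0], int(off.iloc[0])
        raise TraitTableError(
            f"unbalanced design: (genotype={g}, trait={t}) has {n} "
            f"replicate(s), expected {r}"
        )

    gi = {g: i for i, g in enumerate(genotypes)}
    ti = {t: i for i, t in enumerate(traits)}
    arr = np.empty((len(genotypes), len(traits), r))
    # replicate slot by within-cell appearance order, robust to arbitrary labels
    slot = df.groupby(["genotype", "trait"], sort=False).cumcount().to_numpy()
    arr[
        df["genotype"].map(gi).to_numpy(),
        df["trait"].map(ti).to_numpy(),
        slot,
    ] = df["value"].to_numpy()
    return TraitTable(genotypes, traits, r, arr)


def _table_from_wide(df: pd.DataFrame) -> TraitTable:
    for col in ("genotype", "replicate"):
        if col not in df.columns:
            raise TraitTableError(f"wide CSV missing column {col!r}")
    traits = [c for c in df.columns if c not in ("genotype", "replicate")]
    if not traits:
        raise TraitTableError("wide CSV has no trait columns")
    long = df.melt(
        id_vars=["genotype", "replicate"],
        value_vars=traits,
        var_name="trait",
        value_name="value",
    )
    # restore row-major (genotype block) ordering so appearance order matches
    long = long.sort_values(
        by=["genotype", "trait"],
        key=lambda s: s.map({v: i for i, v in enumerate(dict.fromkeys(s))}),
        kind="stable",
    )
    return _table_from_long(long.reset_index(drop=True))


def read_trait_table(path, dialect: str = "long") -> TraitTable:
    """Read and validate a trait CSV.

    ``dialect="long"`` expects columns ``genotype,replicate,trait,value``;
    ``dialect="wide"`` expects one row per (genotype, replicate) and one
    column per trait.  Genotype/trait order is first-appearance order.
    Unbalanced, duplicated or non-numeric cells raise with the offending
    genotype/trait or row number.
    """
    df = pd.read_csv(path)
    if dialect == "long":
        return _table_from_long(df)
    if dialect == "wide":
        return _table_from_wide(df)
    raise ValueError(f"dialect must be 'long' or 'wide', got {dialect!r}")


def write_trait_table(table: TraitTable, path) -> None:
    """Write the canonical long CSV (round-trips through read_trait_table)."""
    table.to_long().to_csv(path, index=False)
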