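"""One-command orchestration of the full divergence analysis.

Stages, in order: per-trait ANOVA -> Scott-Knott letters -> genetic
parameters -> pooled residual covariance -> Mahalanobis D2 -> Singh
contributions -> UPGMA -> cophenetic correlation -> Mojena cutoff ->
group assignment.  Each stage's table is written as CSV into the output
directory; the dendrogram additionally as Newick and (optionally) as a
plot.  A failure in any stage aborts the run, names the stage, and
removes the partial outputs so a bundle on disk is always complete.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, divergence
from .anova_scott_knott import one_way_anova, scott_knott
from .genetic_parameters import genetic_parameters, parameters_from_mean_squares
from .trait_data import TraitTable, read_trait_table

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "replay_mean_squares"]

logger = logging.getLogger("phenodiv")


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    """All numeric decisions of one run, logged verbatim into run.log."""

    input_path: Path | None = None
    dialect: str = "long"
    alpha: float = 0.05  # Scott-Knott significance level
    mojena_k: float = 1.25  # cutoff multiplier on sd of fusion levels
    cov_scale: str = "observations"  # or "means": psi/r, rescales all D2 by r
    out_dir: Path = Path("phenodiv_out")
    make_plot: bool = True
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.mojena_k < 0:
            raise ValueError("mojena_k must be >= 0")
        self.out_dir = Path(self.out_dir)
        if self.input_path is not None:
            self.input_path = Path(self.input_path)


@dataclass
class PipelineResult:
    """In-memory handles to everything the bundle contains."""

    anova: pd.DataFrame
    sk_groups: pd.DataFrame
    genetic_params: pd.DataFrame
    d2: divergence.DistanceMatrix
    contributions: divergence.ContributionTable
    tree: clustering.MergeTree
    cophenetic: float
    cutoff: float
    groups: clustering.GroupAssignment
    out_dir: Path = field(default=Path("."))


def _fmt(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(config: PipelineConfig, table: TraitTable | None = None) -> PipelineResult:
    """Execute the full analysis and write the report bundle.

    ``table`` may be passed directly (e.g. a simulated cohort); otherwise
    ``config.input_path`` is read.  Returns the in-memory results; all CSVs
    in the bundle are byte-identical across reruns of the same input.
    """
    logging.basicConfig(level=config.log_level)
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "read input"
    try:
        if table is None:
            if config.input_path is None:
                raise ValueError("either a table or config.input_path is required")
            table = read_trait_table(config.input_path, config.dialect)
        logger.info(
            "run: G=%d genotypes, T=%d traits, r=%d replicates; alpha=%g, "
            "mojena_k=%g, cov_scale=%s",
            table.n_genotypes, table.n_traits, table.r,
            config.alpha, config.mojena_k, config.cov_scale,
        )

        stage = "anova"
        anova_rows, sk_rows, gp_rows = [], [], []
        for trait in table.traits:
            a = one_way_anova(table, trait)
            anova_rows.append(
                {
                    "trait": trait, "QMg": a.qmg, "QMr": a.qmr,
                    "df_g": a.df_g, "df_r": a.df_r, "F": a.f, "p": a.p,
                    "mean": a.grand_mean, "cv_percent": a.cv_percent,
                    "signif": a.stars,
                }
            )
            stage = f"scott-knott ({trait})"
            sk = scott_knott(table, trait, config.alpha)
            letters = sk.letters
            for g in table.genotypes:
                sk_rows.append(
                    {"trait": trait, "genotype": g,
                     "mean": sk.means[g], "group_letter": letters[g]}
                )
            stage = f"genetic parameters ({trait})"
            p = genetic_parameters(a, table.r)
            gp_rows.append(
                {
                    "trait": trait, "sigma_f2": p.sigma_f2, "sigma_e2": p.sigma_e2,
                    "sigma_g2": p.sigma_g2, "h2_percent": p.h2_percent,
                    "cvg_percent": p.cvg_percent, "cve_percent": p.cve_percent,
                    "cvg_cve_ratio": p.cvg_cve_ratio, "flags": ";".join(p.flags),
                }
            )
        anova_df = pd.DataFrame(anova_rows)
        sk_df = pd.DataFrame(sk_rows)
        gp_df = pd.DataFrame(gp_rows)

        stage = "pooled covariance"
        psi = divergence.pooled_residual_covariance(table, scale=config.cov_scale)
        stage = "mahalanobis D2"
        d2 = divergence.mahalanobis_matrix(table, psi)
        stage = "singh contributions"
        contrib = divergence.singh_contributions(table, psi)
        stage = "upgma"
        tree = clustering.upgma(d2)
        stage = "cophenetic correlation"
        coph = (
            clustering.cophenetic_correlation(tree, d2)
            if table.n_genotypes >= 3 else np.nan
        )
        stage = "mojena cutoff"
        cutoff = clustering.mojena_cutoff(tree, config.mojena_k)
        stage = "cut tree"
        groups = clustering.cut_tree(tree, cutoff)
        logger.info(
            "cophenetic=%.4f mojena cutoff=%.4f -> %d groups",
            coph, cutoff, groups.n_groups,
        )

        stage = "write bundle"
        _fmt(anova_df, out / "anova.csv"); written.append(out / "anova.csv")
        _fmt(sk_df, out / "sk_groups.csv"); written.append(out / "sk_groups.csv")
        _fmt(gp_df, out / "genetic_params.csv"); written.append(out / "genetic_params.csv")
        d2_path = out / "d2_matrix.csv"
        d2.as_frame().to_csv(d2_path, float_format="%.10g"); written.append(d2_path)
        _fmt(contrib.as_frame(), out / "contributions.csv")
        written.append(out / "contributions.csv")
        fl = pd.DataFrame({"merge": np.arange(1, len(tree.fusion_levels) + 1),
                           "fusion_level": tree.fusion_levels})
        _fmt(fl, out / "fusion_levels.csv"); written.append(out / "fusion_levels.csv")
        gr = pd.DataFrame(
            {"genotype": list(groups.groups), "group": list(groups.groups.values())}
        )
        _fmt(gr, out / "groups.csv"); written.append(out / "groups.csv")
        (out / "dendrogram.newick").write_text(clustering.to_newick(tree) + "\n")
        written.append(out / "dendrogram.newick")
        summary = pd.DataFrame(
            [{"n_genotypes": table.n_genotypes, "n_traits": table.n_traits,
              "replicates": table.r, "alpha": config.alpha,
              "mojena_k": config.mojena_k, "cov_scale": config.cov_scale,
              "cophenetic_correlation": coph, "mojena_cutoff": cutoff,
              "n_groups": groups.n_groups}]
        )
        _fmt(summary, out / "summary.csv"); written.append(out / "summary.csv")
        log_lines = [
            f"input: {config.input_path if config.input_path else '<in-memory table>'}",
            f"design: G={table.n_genotypes} genotypes, T={table.n_traits} traits, "
            f"r={table.r} replicates (balanced CRD)",
            f"scott_knott_alpha: {config.alpha}",
            f"mojena_k: {config.mojena_k}",
            f"covariance_scale: {config.cov_scale}",
            f"cophenetic_correlation: {coph:.6f}",
            f"mojena_cutoff: {cutoff:.6f}",
            f"n_groups: {groups.n_groups}",
        ]
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
        written.append(out / "run.log")
        if config.make_plot:
            stage = "dendrogram plot"
            _plot_dendrogram(tree, cutoff, out / "dendrogram.png")
            _plot_contributions(contrib, out / "contributions.png")
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise PipelineStageError(f"pipeline failed at stage '{stage}': {exc}") from exc

    return PipelineResult(
        anova=anova_df, sk_groups=sk_df, genetic_params=gp_df, d2=d2,
        contributions=contrib, tree=tree, cophenetic=coph, cutoff=cutoff,
        groups=groups, out_dir=out,
    )


def _plot_dendrogram(tree: clustering.MergeTree, cutoff: float, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.cluster import hierarchy

    fig, ax = plt.subplots(figsize=(max(6, 0.12 * len(tree.leaves)), 4))
    hierarchy.dendrogram(
        tree.linkage, labels=list(tree.leaves), color_threshold=cutoff, ax=ax,
        leaf_font_size=6,
    )
    ax.axhline(cutoff, color="grey", linestyle="--", linewidth=0.8)
    ax.set_ylabel("fusion level (D$^2$)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _plot_contributions(contrib: divergence.ContributionTable, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = contrib.as_frame()
    fig, ax = plt.subplots(figsize=(max(5, 0.4 * len(df)), 3.5))
    ax.bar(df["trait"], df["percent"])
    ax.set_ylabel("relative contribution (%)")
    ax.tick_params(axis="x", rotation=90, labelsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def replay_mean_squares(ms: pd.DataFrame, k: int = 4) -> pd.DataFrame:
    """Recompute genetic parameters from published mean squares.

    ``ms`` must have columns ``trait, qmg, qmr, mean`` (one row per trait);
    ``k`` is the number of replicates of the original design.  Returns a
    frame with sigma_f2/sigma_e2/sigma_g2, h2 (%), CVg, CVe, CVg/CVe and
    CV% per trait — the desk-scale check against a published ANOVA table
    when the raw data are unavailable.
    """
    rows = []
    for rec in ms.itertuples(index=False):
        p = parameters_from_mean_squares(rec.trait, rec.qmg, rec.qmr, k, rec.mean)
        rows.append(
            {
                "trait": p.trait, "sigma_f2": p.sigma_f2, "sigma_e2": p.sigma_e2,
                "sigma_g2": p.sigma_g2, "h2_percent": p.h2_percent,
                "cvg_percent": p.cvg_percent, "cve_percent": p.cve_percent,
                "cvg_cve_ratio": p.cvg_cve_ratio, "cv_percent": p.cve_percent,
                "flags": ";".join(p.flags),
            }
        )
    return pd.DataFrame(rows)
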