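"""Bundled reference data.

``load_hymenaea_summary`` returns the published ANOVA summary for the
*Hymenaea martiana* germplasm survey: 160 mother plants, 18 fruit/seed/
seedling traits, 4 replicates in a completely randomized design.  Only
summary statistics were published (genotype and residual mean squares,
trait grand means, h2, CVg/CVe, CV%); the raw observations were not
deposited.  The mean squares and means are the inputs to the replay mode,
which recomputes the derived genetic parameters from them.

Two columns are flagged ``inconsistent=True`` (DMAP and ESI): their
printed h2 / CVg/CVe cannot be reconciled with their own printed mean
squares under the estimator definitions, so they are carried for
completeness but should not be used to validate computation.
"""

from __future__ import annotations

import io

import pandas as pd

__all__ = ["load_hymenaea_summary", "PRECISE_TRAITS", "PRECISE_CV_TRAITS"]

# trait, QMg, QMr, grand mean, published h2 (%), CVg/CVe, CV (%)
_SUMMARY_CSV = """\
trait,qmg,qmr,mean,h2_percent,cvg_cve_ratio,cv_percent,inconsistent
fruit_length_mm,837.33,25.52,91.12,96.95,2.82,5.54,False
fruit_width_mm,184.07,10.14,43.67,94.49,2.07,7.29,False
fruit_thickness_mm,99.76,4.65,28.61,95.34,2.26,7.53,False
fruit_weight_g,1487.68,93.24,61.84,93.73,1.93,15.61,False
seeds_per_fruit,5.55,0.33,3.40,94.06,1.99,17.08,False
seed_length_mm,41.07,0.62,24.76,98.47,4.01,3.23,False
seed_width_mm,8.89,0.62,19.01,92.95,1.81,4.15,False
seed_thickness_mm,10.84,3.07,13.93,71.66,0.79,12.51,False
seed_weight_g,6.33,0.11,4.89,98.29,3.80,6.57,False
seed_water_content_pct,15.07,2.27,11.13,84.91,1.19,13.49,False
first_emergence_count_pct,2579.24,125.08,42.00,95.15,2.21,26.61,False
emergence_pct,1775.88,144.89,59.00,91.84,1.67,20.48,False
emergence_speed_index,0.29,0.02,0.65,93.72,0.97,20.50,True
mean_emergence_time_days,32.55,1.00,23.00,96.92,2.80,4.28,False
shoot_length_cm,61.09,3.81,17.73,93.75,1.93,11.02,False
root_length_cm,39.28,5.82,14.96,85.17,1.19,16.12,False
shoot_dry_mass_g,7.84,0.05,1.01,87.24,1.31,26.28,True
root_dry_mass_g,0.08,0.009,0.32,87.99,1.35,29.81,False
"""

# Traits whose printed mean squares carry enough precision that h2 and
# CVg/CVe recompute to the printed two decimals.
PRECISE_TRAITS = (
    "fruit_length_mm",
    "fruit_width_mm",
    "fruit_thickness_mm",
    "fruit_weight_g",
    "first_emergence_count_pct",
    "emergence_pct",
)

# Subset whose printed grand mean additionally supports recomputing CV%
# to two decimals (the emergence percentages' means are printed too
# coarsely for that).
PRECISE_CV_TRAITS = (
    "fruit_length_mm",
    "fruit_width_mm",
    "fruit_thickness_mm",
    "fruit_weight_g",
)

REPLICATES = 4
N_MOTHER_PLANTS = 160


def load_hymenaea_summary() -> pd.DataFrame:
    """Published ANOVA summary, indexed by trait.

    Columns: ``qmg``, ``qmr`` (mean squares, k=4), ``mean`` (trait grand
    mean), published ``h2_percent``, ``cvg_cve_ratio``, ``cv_percent``,
    and an ``inconsistent`` flag for columns that do not reproduce from
    their own mean squares.
    """
    df = pd.read_csv(io.StringIO(_SUMMARY_CSV), index_col="trait")
    df["inconsistent"] = df["inconsistent"].astype(bool)
    return df
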