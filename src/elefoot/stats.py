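"""Descriptive gait and pressure statistics.

Covers the dimensionless speed (Froude number), step-weighted means,
grouped mean +- standard error summaries of regional peak pressures, the
fore/hind pressure contrast and cross-cohort pressure ratios.  Inferential
modelling (mixed models, ANOVA, post hoc tests) is out of scope: the
package's job is to emit the tidy long table those tools consume (random
effect of subject; fixed effects ROI, foot and placement position).
"""

from __future__ import annotations

from typing import Hashable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "froude",
    "weighted_mean",
    "summarize",
    "cohort_ratio",
    "percent_difference",
    "african_cohort",
    "COHORT_SUMMARY",
]

G_MS2 = 9.81


def froude(velocity_ms: float, height_m: float, g: float = G_MS2) -> float:
    """Dimensionless speed ``Fr = v^2 / (g * h)``.

    ``h`` is the characteristic limb height (hip height for quadrupedal
    gait comparisons).  A walk is typically Fr < 0.5; adult elephants
    self-select around Fr ~ 0.1.
    """
    if height_m <= 0:
        raise ValueError("height_m must be positive")
    if velocity_ms < 0:
        raise ValueError("velocity_ms must be non-negative")
    return velocity_ms**2 / (g * height_m)


def weighted_mean(values: Sequence[float], weights: Sequence[float]) -> float:
    """``sum(w * v) / sum(w)``; invariant to uniform rescaling of weights."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.shape != w.shape:
        raise ValueError("values and weights must have equal length")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    total = w.sum()
    if total == 0:
        raise ValueError("weights must not all be zero")
    return float((w * v).sum() / total)


def summarize(
    table: pd.DataFrame,
    group_by: Sequence[Hashable],
    value_col: str = "peak_pressure_kpa",
) -> pd.DataFrame:
    """Per-group mean, standard error (sample sd / sqrt(n)) and n.

    The standard error uses the n-1 (sample) standard deviation; groups of
    one report s.e. 0.
    """
    if table.empty:
        raise ValueError("empty table")
    g = table.groupby(list(group_by))[value_col]
    out = g.agg(mean="mean", n="count")
    sd = g.std(ddof=1).fillna(0.0)
    out["se"] = (sd / np.sqrt(out["n"])).fillna(0.0)
    return out.reset_index()[list(group_by) + ["mean", "se", "n"]]


def cohort_ratio(mean_a_kpa: float, mean_b_kpa: float) -> float:
    """Ratio of two cohort grand-mean pressures (a relative to b)."""
    if mean_b_kpa <= 0:
        raise ValueError("denominator mean must be positive")
    return mean_a_kpa / mean_b_kpa


def percent_difference(a: float, b: float) -> float:
    """Percent difference of ``a`` relative to ``b``: ``100 * (a - b) / b``."""
    if b == 0:
        raise ValueError("reference value must be non-zero")
    return 100.0 * (a - b) / b


def african_cohort() -> pd.DataFrame:
    """Published subject table for the five-adult African savanna elephant
    walking cohort (safari-park study; body masses are keeper estimates).

    Columns: subject, body_mass_kg, shoulder_height_m, froude, velocity_ms,
    n_steps, n_trials, plus per-foot mean maximum pressures (kPa).
    """
    return pd.DataFrame(
        {
            "subject": [1, 2, 3, 4, 5],
            "body_mass_kg": [2800.0, 3000.0, 1500.0, 1800.0, 2300.0],
            "shoulder_height_m": [2.43, 2.50, 2.22, 2.12, 2.30],
            "froude": [0.07, 0.05, 0.07, 0.08, 0.08],
            "velocity_ms": [1.24, 1.11, 1.24, 1.24, 1.34],
            "mean_max_pressure_fl_kpa": [317.0, 251.0, 256.0, 262.0, 315.0],
            "mean_max_pressure_fr_kpa": [296.0, 312.0, 236.0, 224.0, 318.0],
            "mean_max_pressure_hl_kpa": [237.0, 250.0, 243.0, 200.0, 297.0],
            "mean_max_pressure_hr_kpa": [244.0, 248.0, 251.0, 235.0, 284.0],
            "n_steps": [28, 29, 76, 48, 29],
            "n_trials": [13, 18, 30, 23, 10],
        }
    )


#: published cohort-level grand means: fore/hind mean peak pressures with
#: standard errors, ROI-level grand means for the African and (comparison)
#: Asian cohorts, all in kPa
COHORT_SUMMARY = {
    "fore_mean_kpa": 264.0,
    "fore_se_kpa": 5.31,
    "hind_mean_kpa": 246.0,
    "hind_se_kpa": 5.09,
    "african_grand_mean_kpa": 946.0,
    "asian_grand_mean_kpa": 567.0,
}
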