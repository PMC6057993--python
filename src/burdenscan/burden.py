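"""Per-gene variant-burden outlier detection.

The core procedure: count, for every gene, the distinct variants whose
alternate allele is present in at least one case (``n_case``) and at least
one control (``n_control``); regress control counts on case counts by
ordinary least squares; and call a gene an outlier when its raw residual
falls more than ``iqr_mult`` interquartile ranges below the first or above
the third quartile of all residuals.

Direction convention: with control counts on the y axis, a gene with an
excess burden in cases sits to the right of the regression line, i.e. its
residual is *below* the lower fence -> Group A ("more mutated in cases").
Residuals above the upper fence -> Group B ("more mutated in controls").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .vcfio import CohortGenotypes

DEFAULT_IQR_MULT = 6.0


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    residuals: np.ndarray
    q1: float
    q3: float
    iqr: float
    iqr_mult: float = DEFAULT_IQR_MULT

    @property
    def lower_fence(self) -> float:
        return self.q1 - self.iqr_mult * self.iqr

    @property
    def upper_fence(self) -> float:
        return self.q3 + self.iqr_mult * self.iqr


def count_burden(cohort: CohortGenotypes) -> pd.DataFrame:
    """Distinct-variant counts per gene for cases and controls.

    Requires gene-assigned variants (see :func:`burdenscan.vcfio.assign_genes`);
    a variant overlapping several genes contributes to each of them, and
    variants in no gene are skipped. Genes with zero variants in both groups
    are retained here and dropped at regression time.
    """
    if not any(v.genes for v in cohort.variants):
        raise ValueError("no variant carries a gene assignment; run assign_genes first")
    in_cases = cohort.present_in(cohort.case_mask)
    in_controls = cohort.present_in(cohort.control_mask)
    rows: dict[str, list[int]] = {}
    for j, v in enumerate(cohort.variants):
        for gene in v.genes:
            acc = rows.setdefault(gene, [0, 0])
            acc[0] += int(in_cases[j])
            acc[1] += int(in_controls[j])
    df = pd.DataFrame(
        [(g, c[0], c[1]) for g, c in rows.items()],
        columns=["gene", "n_case", "n_control"],
    )
    return df.sort_values("gene", ignore_index=True)


def fit_regression(
    table: pd.DataFrame, intercept: bool = True
) -> tuple[pd.DataFrame, RegressionFit]:
    """OLS of control counts on case counts; residual = observed - fitted.

    Genes with zero variants in both groups are excluded (uninformative and
    leverage-free). ``intercept=False`` forces the line through the origin.
    Returns the (filtered) table with a ``residual`` column and the fit.
    """
    used = table[(table["n_case"] > 0) | (table["n_control"] > 0)].copy()
    if len(used) < 3:
        raise ValueError("need at least 3 genes with non-zero counts")
    x = used["n_case"].to_numpy(dtype=float)
    y = used["n_control"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("case counts are constant; regression is degenerate")
    if intercept:
        res = stats.linregress(x, y)
        slope, icept = float(res.slope), float(res.intercept)
    else:
        slope = float(np.dot(x, y) / np.dot(x, x))
        icept = 0.0
    fitted = icept + slope * x
    residuals = y - fitted
    ss_res = float(np.sum(residuals**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    q1, q3 = np.percentile(residuals, [25.0, 75.0])  # linear interpolation
    used["residual"] = residuals
    fit = RegressionFit(slope, icept, r2, residuals, float(q1), float(q3),
                        float(q3 - q1))
    return used, fit


def detect_outliers(
    table: pd.DataFrame, fit: RegressionFit, iqr_mult: float = DEFAULT_IQR_MULT
) -> pd.DataFrame:
    """Assign Group A/B/none by the residual IQR fences.

    Residual below Q1 - m*IQR -> Group A (excess case burden); above
    Q3 + m*IQR -> Group B. A zero residual IQR means the fences collapse
    onto the quartiles and every gene would be an outlier; that degenerate
    input is rejected.
    """
    if iqr_mult <= 0:
        raise ValueError("iqr_mult must be positive")
    if fit.iqr <= 0:
        raise ValueError("residual IQR is zero; outlier fences are degenerate")
    fit.iqr_mult = iqr_mult
    out = table.copy()
    res = out["residual"].to_numpy()
    group = np.full(len(out), "none", dtype=object)
    group[res < fit.lower_fence] = "A"
    group[res > fit.upper_fence] = "B"
    out["group"] = group
    return out


def burden_outliers(
    table: pd.DataFrame,
    iqr_mult: float = DEFAULT_IQR_MULT,
    intercept: bool = True,
) -> tuple[pd.DataFrame, RegressionFit]:
    """Convenience: regression + fence detection in one call."""
    with_resid, fit = fit_regression(table, intercept=intercept)
    return detect_outliers(with_resid, fit, iqr_mult=iqr_mult), fit


def summarize_fit(table: pd.DataFrame, fit: RegressionFit) -> dict:
    groups = table["group"].value_counts()
    return {
        "slope": fit.slope,
        "intercept": fit.intercept,
        "r_squared": fit.r_squared,
        "q1": fit.q1,
        "q3": fit.q3,
        "iqr": fit.iqr,
        "iqr_mult": fit.iqr_mult,
        "n_genes": int(len(table)),
        "n_group_a": int(groups.get("A", 0)),
        "n_group_b": int(groups.get("B", 0)),
    }
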