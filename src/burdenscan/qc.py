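"""Case/control genetic-homogeneity checks.

Per-subject observed heterozygosity (He) and the inbreeding coefficient F
are computed over all variants, then compared between cases and controls
with a Mann-Whitney test. In a stratified or inbred subgroup these statistics
separate the groups; in a homogeneous cohort both tests should be null.

F follows the usual method-of-moments form

    F = (observed hom - expected hom) / (L - expected hom)

with the expected homozygote count taken under within-cohort allele
frequencies (monomorphic sites are excluded — they carry no information
about inbreeding and would only dilute the expectation).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .vcfio import CohortGenotypes

#: combined sample size at or below which the Mann-Whitney p-value is exact
EXACT_CROSSOVER = 12


def subject_qc(cohort: CohortGenotypes) -> pd.DataFrame:
    """Per-sample He and F over all variants.

    Subjects with no called genotype are excluded (there is nothing to
    estimate). Returns a frame with sample, group, he, f, n_called.
    """
    g = cohort.matrix
    called = g >= 0
    n_called = called.sum(axis=1)
    if (n_called == 0).any():
        keep = n_called > 0
    else:
        keep = np.ones(len(cohort.samples), dtype=bool)

    het = (g == 1) & called
    he = np.divide(
        het.sum(axis=1), n_called, out=np.zeros(len(n_called)), where=n_called > 0
    )

    # within-cohort alt-allele frequencies from called genotypes
    alt = np.where(called, g, 0).sum(axis=0)
    an = 2 * called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(an > 0, alt / an, 0.0)
    poly = (p > 0) & (p < 1)

    exp_hom_site = 1.0 - 2.0 * p * (1.0 - p)  # per-site P(homozygous) under HWE
    use = called[:, poly]
    obs_hom = ((g[:, poly] != 1) & use).sum(axis=1)
    exp_hom = use @ exp_hom_site[poly]
    L = use.sum(axis=1)
    denom = L - exp_hom
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(denom > 0, (obs_hom - exp_hom) / denom, np.nan)

    df = pd.DataFrame(
        {
            "sample": cohort.samples,
            "group": cohort.groups,
            "he": he,
            "f": f,
            "n_called": n_called,
        }
    )
    return df[keep].reset_index(drop=True)


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; (U of x, p).

    The p-value is exact (full enumeration of rank arrangements) when the
    combined sample size is at most ``EXACT_CROSSOVER`` and there are no
    ties; otherwise the normal approximation with tie and continuity
    correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (x.size + y.size <= EXACT_CROSSOVER and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def homogeneity_report(cohort: CohortGenotypes) -> dict:
    """He and F Mann-Whitney comparisons between cases and controls."""
    qc = subject_qc(cohort)
    out: dict = {"n_samples": int(len(qc))}
    for stat in ("he", "f"):
        a = qc.loc[qc["group"] == "case", stat].dropna()
        b = qc.loc[qc["group"] == "control", stat].dropna()
        u, p = mann_whitney(a, b)
        out[f"{stat}_U"] = u
        out[f"{stat}_p"] = p
    return out
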