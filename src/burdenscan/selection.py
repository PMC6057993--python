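"""PCA-based natural-selection scan along a chosen population axis.

Genotypes of a labelled reference panel are standardized per SNP and
decomposed by truncated SVD. The principal component that best separates two
focal populations (here Europe vs East Asia) is the "axis of variation"; each
SNP is then scored by the squared correlation of its standardized genotypes
with the axis scores, n*r^2, which is chi-square(1) under no differentiation.
Residual stratification inflates all statistics multiplicatively, so the
scores are rescaled by the genomic-inflation factor

    lambda_gc = median(stat) / median(chi-square_1)

before p-values are taken from the chi-square(1) upper tail. Significant
SNPs are selected by Benjamini-Hochberg at FDR q (default 0.1), polarized by
the ancestral allele into derived-allele frequencies per population, and
rolled up to genes: a gene is under selection iff at least one significant
SNP maps to it.

This is a deliberate single-axis restriction of the multi-PC communality
statistic used by pcadapt-style scans: only differentiation along the chosen
axis is tested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import ReferencePanel
from .vcfio import GeneCatalog, assign_genes

CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))  # 0.4549...

POP_DISPLAY = {"EUR": "Europe", "EAS": "East Asia", "AFR": "Africa"}


@dataclass
class PanelPCA:
    scores: np.ndarray        # (n_samples, k), U * S
    loadings: np.ndarray      # (k, m_kept)
    kept: np.ndarray          # indices of SNPs surviving the MAF filter
    standardized: np.ndarray  # (n_samples, m_kept)
    alt_freq: np.ndarray      # per kept SNP


def _standardize(genotypes: np.ndarray, maf_min: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """MAF-filter and scale genotype columns to mean 0, sd sqrt(p(1-p))."""
    g = np.asarray(genotypes, dtype=float)
    p = g.mean(axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    kept = np.flatnonzero(maf >= maf_min)
    if kept.size == 0:
        raise ValueError("no SNPs survive the MAF filter")
    pk = p[kept]
    x = (g[:, kept] - 2.0 * pk) / np.sqrt(pk * (1.0 - pk))
    return x, kept, pk


def pca_panel(
    genotypes: np.ndarray, n_components: int = 10, maf_min: float = 0.05
) -> PanelPCA:
    """Standardize genotypes and compute the leading principal components.

    Each SNP column is centered at its mean dosage and scaled by
    sqrt(p(1-p)); SNPs with minor-allele frequency below ``maf_min`` are
    dropped (near-fixed SNPs carry no structure and destabilize scaling).
    """
    g = np.asarray(genotypes, dtype=float)
    n, m = g.shape
    if n_components >= min(n, m):
        raise ValueError(
            f"n_components={n_components} must be < min(samples, SNPs)={min(n, m)}"
        )
    x, kept, pk = _standardize(g, maf_min)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    scores = u[:, :n_components] * s[:n_components]
    return PanelPCA(scores, vt[:n_components], kept, x, pk)


def select_axis(
    scores: np.ndarray,
    populations: np.ndarray,
    pop_a: str = "EUR",
    pop_b: str = "EAS",
) -> int:
    """1-based index of the PC best separating the two focal populations.

    Separation is |mean_a - mean_b| / pooled score SD; ties break to the
    lowest PC index.
    """
    populations = np.asarray(populations)
    mask_a = populations == pop_a
    mask_b = populations == pop_b
    for pop, mask in ((pop_a, mask_a), (pop_b, mask_b)):
        if not mask.any():
            raise ValueError(f"population label {pop!r} absent from panel")
    sd = scores.std(axis=0, ddof=1)
    sep = np.abs(scores[mask_a].mean(axis=0) - scores[mask_b].mean(axis=0)) / sd
    return int(np.argmax(sep)) + 1  # argmax returns the first maximum


def snp_axis_pvalues(
    standardized: np.ndarray,
    axis_scores: np.ndarray,
    axis_loadings: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-SNP (stat, p) against the axis, with lambda_gc rescaling.

    stat_j = n * corr(x_j, axis)^2 ~ chi-square(1) under the null;
    p_j = P(chi-square_1 > stat_j / lambda_gc).

    The axis score vector is itself a linear combination of the SNPs
    (s = sum_j v_j x_j), so each SNP's own loading inflates its correlation
    with the axis. At genome scale (millions of SNPs) the self-term is
    negligible, but at panel sizes of a few thousand SNPs it biases every
    statistic upward. When ``axis_loadings`` is supplied, SNP j is tested
    against the leave-one-out axis s - v_j x_j, which restores the
    chi-square(1) null while leaving signal shared with other SNPs intact.
    """
    n = standardized.shape[0]
    if n < 10:
        raise ValueError("need at least 10 samples for the axis statistic")
    s = axis_scores - axis_scores.mean()
    s_norm2 = float(s @ s)
    if s_norm2 == 0:
        raise ValueError("axis scores are constant")
    xc = standardized - standardized.mean(axis=0)
    col_norm2 = np.einsum("ij,ij->j", xc, xc)
    col_norm2[col_norm2 == 0] = np.inf  # constant SNP -> r = 0
    a = xc.T @ s  # per-SNP inner product with the axis
    if axis_loadings is not None:
        v = np.asarray(axis_loadings, dtype=float)
        if v.shape[0] != xc.shape[1]:
            raise ValueError("axis_loadings length must match the SNP count")
        num = a - v * col_norm2
        t_norm2 = s_norm2 - 2.0 * v * a + v**2 * col_norm2
        t_norm2[t_norm2 <= 0] = np.inf
        r2 = num**2 / (col_norm2 * t_norm2)
    else:
        r2 = a**2 / (col_norm2 * s_norm2)
    stat = n * r2
    lambda_gc = float(np.median(stat) / CHI2_1_MEDIAN)
    if lambda_gc <= 0:
        raise ValueError("degenerate statistics: non-positive lambda_gc")
    pvals = stats.chi2.sf(stat / lambda_gc, df=1)
    return stat, np.clip(pvals, np.finfo(float).tiny, 1.0), lambda_gc


def fdr_select(p_values: np.ndarray, q: float = 0.1) -> np.ndarray:
    """Benjamini-Hochberg step-up at level q; boolean significance flags."""
    if not (0.0 < q < 1.0):
        raise ValueError("q must lie in (0, 1)")
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p <= 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    thresholds = q * np.arange(1, m + 1) / m
    passing = np.flatnonzero(p[order] <= thresholds)
    flags = np.zeros(m, dtype=bool)
    if passing.size:
        flags[order[: passing[-1] + 1]] = True
    return flags


def derived_allele_freqs(
    panel: ReferencePanel,
    snp_indices: np.ndarray,
    pop_a: str = "EUR",
    pop_b: str = "EAS",
) -> pd.DataFrame:
    """Derived-allele frequencies per population for the given SNPs.

    The derived allele is the non-ancestral one; SNPs whose recorded
    ancestral allele matches neither ref nor alt are skipped with a warning.
    ``higher_daf_in`` names the focal population with the larger DAF
    ("tie" when equal).
    """
    pops = np.asarray(panel.populations)
    masks = {p: pops == p for p in dict.fromkeys(pops)}
    rows = []
    for j in np.asarray(snp_indices, dtype=int):
        v = panel.variants[j]
        aa = v.ancestral_allele
        if aa == v.ref:
            flip = False
        elif aa == v.alt:
            flip = True
        else:
            warnings.warn(
                f"{v.variant_id}: ancestral allele {aa!r} matches neither "
                "ref nor alt; SNP skipped",
                stacklevel=2,
            )
            continue
        row: dict = {"snp_index": int(j), "variant_id": v.variant_id}
        for pop, mask in masks.items():
            g = panel.genotypes[mask, j]
            alt_freq = float(g.mean() / 2.0)
            row[f"daf_{pop.lower()}"] = 1.0 - alt_freq if flip else alt_freq
        da, db = row[f"daf_{pop_a.lower()}"], row[f"daf_{pop_b.lower()}"]
        if da > db:
            row["higher_daf_in"] = POP_DISPLAY.get(pop_a, pop_a)
        elif db > da:
            row["higher_daf_in"] = POP_DISPLAY.get(pop_b, pop_b)
        else:
            row["higher_daf_in"] = "tie"
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class SelectionScanResult:
    table: pd.DataFrame  # per kept SNP: variant_id, stat, p_value, significant, ...
    axis: int            # 1-based PC index
    lambda_gc: float
    fdr_q: float

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    def genes_under_selection(self) -> pd.DataFrame:
        """Gene-level roll-up: a gene is under selection iff >=1 significant
        SNP maps to it; the population label joins those of its SNPs."""
        sig = self.significant
        sig = sig[sig["gene"] != ""]
        if sig.empty:
            return pd.DataFrame(columns=["gene", "higher_daf_in", "n_snps"])
        order = ["Europe", "East Asia", "tie"]
        rows = []
        for gene, sub in sig.groupby("gene"):
            labels = [l for l in order if l in set(sub["higher_daf_in"])]
            rows.append((gene, ", ".join(labels), len(sub)))
        return pd.DataFrame(rows, columns=["gene", "higher_daf_in", "n_snps"])


def scan_selection(
    panel: ReferencePanel,
    catalog: GeneCatalog | None = None,
    fdr_q: float = 0.1,
    n_components: int = 10,
    maf_min: float = 0.05,
    pop_a: str = "EUR",
    pop_b: str = "EAS",
) -> SelectionScanResult:
    """Full scan: PCA, axis choice, per-SNP tests, BH selection, DAF, genes.

    The per-SNP statistics use a split-half design: SNPs are alternately
    assigned to two folds, each fold's axis comes from a PCA of the *other*
    fold, and every SNP is tested against an axis it did not help build.
    Testing SNPs against a principal component of the very same matrix
    inflates all statistics by the top-eigenvalue excess of the noise
    (substantial at panel scale, where SNPs only outnumber samples by ~10x),
    which the split removes exactly; lambda_gc then mops up any residual
    shared stratification. The reported ``axis`` is the best-separating PC
    of the full-panel PCA, which is also what the DAF/gene roll-up uses.
    """
    n = panel.genotypes.shape[0]
    x, kept, _ = _standardize(panel.genotypes, maf_min)
    if n_components >= min(n, kept.size // 2):
        raise ValueError("n_components too large for the filtered panel")
    stat = np.empty(kept.size)
    folds = (np.arange(kept.size) % 2 == 0, np.arange(kept.size) % 2 == 1)
    for train, test in ((folds[0], folds[1]), (folds[1], folds[0])):
        u, s, _ = np.linalg.svd(x[:, train], full_matrices=False)
        scores = u[:, :n_components] * s[:n_components]
        ax = select_axis(scores, panel.populations, pop_a, pop_b)
        fold_stat, _, _ = snp_axis_pvalues(x[:, test], scores[:, ax - 1])
        stat[test] = fold_stat
    lam = float(np.median(stat) / CHI2_1_MEDIAN)
    pvals = np.clip(stats.chi2.sf(stat / lam, df=1), np.finfo(float).tiny, 1.0)
    flags = fdr_select(pvals, q=fdr_q)

    pca = pca_panel(panel.genotypes, n_components=n_components, maf_min=maf_min)
    axis = select_axis(pca.scores, panel.populations, pop_a, pop_b)
    table = pd.DataFrame(
        {
            "snp_index": kept,
            "variant_id": [panel.variants[j].variant_id for j in kept],
            "stat": stat,
            "p_value": pvals,
            "significant": flags,
        }
    )
    sig_idx = kept[flags]
    daf = derived_allele_freqs(panel, sig_idx, pop_a, pop_b)
    if not daf.empty:
        table = table.merge(daf.drop(columns=["variant_id"]), on="snp_index",
                            how="left")
    else:
        for pop in dict.fromkeys(panel.populations):
            table[f"daf_{pop.lower()}"] = np.nan
        table["higher_daf_in"] = None
    table["higher_daf_in"] = table.get("higher_daf_in", pd.Series(dtype=object)).fillna("")

    if catalog is not None:
        recs = [panel.variants[j] for j in kept]
        assign_genes(recs, catalog)
        table["gene"] = [";".join(r.genes) for r in recs]
    else:
        table["gene"] = ""
    return SelectionScanResult(table, axis, lam, fdr_q)
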