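"""Candidate-gene prioritization and reporting.

Joins the replicated outlier genes with the selection-scan positives, the
pLI (loss-of-function intolerance) table and a phenotype catalog, computes
cohort allele frequencies for exclusive variants, and emits the final
candidate table plus the headline summary percentages.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from ._util import percentage
from .replication import ReplicationResult

PLI_INTOLERANT = 0.9


def flag_lof_intolerance(pli: float) -> bool:
    """True iff pLI >= 0.9 (the extremely LoF-intolerant convention)."""
    if not (0.0 <= pli <= 1.0):
        raise ValueError(f"pLI must lie in [0, 1], got {pli}")
    return pli >= PLI_INTOLERANT


def allele_frequency(allele_count: int, n_diploid: int) -> float:
    """allele_count / (2 * n_diploid), half-up rounded to 4 decimals.

    The denominator is the cohort's diploid allele number; e.g. one allele
    among 78 diploid subjects -> 1/156 -> 0.0064.
    """
    if n_diploid <= 0:
        raise ValueError("n_diploid must be positive")
    if not (0 <= allele_count <= 2 * n_diploid):
        raise ValueError(
            f"allele_count {allele_count} outside [0, {2 * n_diploid}]"
        )
    q = (Decimal(allele_count) / (2 * Decimal(n_diploid))).quantize(
        Decimal("0.0001"), rounding=ROUND_HALF_UP
    )
    return float(q)


def build_candidate_table(
    replication: ReplicationResult,
    selection_genes: pd.DataFrame,
    pli_table: pd.DataFrame | None = None,
    trait_catalog: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict]:
    """One row per replicated gene under selection, plus a summary.

    ``selection_genes`` is the gene-level roll-up of the scan
    (:meth:`burdenscan.selection.SelectionScanResult.genes_under_selection`).
    Missing pLI or catalog entries are reported as unknown, never an error.
    """
    pli_map: Mapping[str, float] = (
        dict(zip(pli_table["gene"], pli_table["pli"])) if pli_table is not None else {}
    )
    trait_map: Mapping[str, str] = (
        dict(zip(trait_catalog["gene"], trait_catalog["traits"]))
        if trait_catalog is not None
        else {}
    )
    sel_map = dict(zip(selection_genes["gene"], selection_genes["higher_daf_in"]))

    rows = []
    for group, genes in (("A", replication.replicated_a), ("B", replication.replicated_b)):
        for gene in sorted(genes & set(sel_map)):
            pli = pli_map.get(gene)
            rows.append(
                {
                    "gene": gene,
                    "group": group,
                    "higher_daf_in": sel_map[gene],
                    "pli": pli if pli is not None else float("nan"),
                    "lof_intolerant": (
                        flag_lof_intolerance(pli) if pli is not None else None
                    ),
                    "catalog_traits": trait_map.get(gene, ""),
                }
            )
    table = pd.DataFrame(
        rows,
        columns=["gene", "group", "higher_daf_in", "pli", "lof_intolerant",
                 "catalog_traits"],
    )
    n_repl = len(replication.replicated)
    n_sel_a = int((table["group"] == "A").sum())
    n_sel_b = int((table["group"] == "B").sum())
    summary = {
        "n_replicated": n_repl,
        "n_under_selection": len(table),
        "n_under_selection_group_a": n_sel_a,
        "n_under_selection_group_b": n_sel_b,
        "percent_under_selection": (
            percentage(len(table), n_repl) if n_repl else 0
        ),
    }
    return table, summary


def exclusive_variant_report(
    variant_ids: Iterable[str],
    allele_counts: Mapping[str, int],
    n_diploid: int,
    followup_counts: Mapping[str, int] | None = None,
    followup_n_diploid: int | None = None,
) -> pd.DataFrame:
    """Allele counts and frequencies for candidate exclusive variants.

    Discovery-cohort frequency is AC / (2 * n_diploid). Follow-up values are
    reported as given (raw AC over the follow-up allele number) when a
    follow-up cohort is supplied, NA otherwise.
    """
    rows = []
    for vid in variant_ids:
        ac = allele_counts.get(vid, 0)
        row = {
            "variant_id": vid,
            "allele_count": ac,
            "frequency": allele_frequency(ac, n_diploid),
        }
        if followup_counts is not None and followup_n_diploid:
            fac = followup_counts.get(vid)
            row["followup_allele_count"] = fac
            row["followup_frequency"] = (
                allele_frequency(fac, followup_n_diploid) if fac is not None else None
            )
        else:
            row["followup_allele_count"] = None
            row["followup_frequency"] = None
        rows.append(row)
    return pd.DataFrame(rows)


def export_gene_lists(
    groups: Mapping[str, Iterable[str]], out_dir: str | Path
) -> dict[str, Path]:
    """One plain-text gene list per group (one symbol per line).

    These files feed external enrichment tools; the analysis itself stops
    at the gene lists.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, genes in groups.items():
        path = out / f"genes_{name}.txt"
        with open(path, "w") as fh:
            for g in sorted(genes):
                fh.write(f"{g}\n")
        paths[name] = path
    return paths
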