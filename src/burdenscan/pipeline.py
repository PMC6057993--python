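"""End-to-end orchestration, in memory or through files.

The stages mirror the study design: simulate (or load) cohorts -> QC
homogeneity -> per-gene burden + outlier fences in discovery and
replication -> direction-preserving replication -> exclusive-variant
spectrum -> PCA selection scan on the reference panel -> candidate table.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import burden, qc, replication, report, selection, spectrum
from .simulate import (
    CohortSim,
    ReferencePanel,
    SimConfig,
    simulate_study,
    write_cohort,
    write_panel,
)
from .vcfio import (
    CohortGenotypes,
    GeneCatalog,
    VariantRecord,
    assign_genes,
    attach_annotations,
    read_annotations,
    read_cohort,
)


def load_cohort(
    vcf_path: str | Path,
    group_map_path: str | Path,
    genes_path: str | Path,
    annotations_path: str | Path | None = None,
) -> tuple[CohortGenotypes, GeneCatalog]:
    """Read a cohort VCF with its gene catalog and optional annotations."""
    cohort = read_cohort(vcf_path, group_map_path)
    genes_path = Path(genes_path)
    if genes_path.suffix.lower() in (".gff", ".gff3"):
        catalog = GeneCatalog.from_gff3(genes_path)
    else:
        catalog = GeneCatalog.from_bed(genes_path)
    assign_genes(cohort.variants, catalog)
    if annotations_path is not None:
        attach_annotations(cohort, read_annotations(annotations_path))
    return cohort, catalog


def read_panel(
    vcf_path: str | Path,
    populations_path: str | Path,
    ancestral_path: str | Path,
) -> ReferencePanel:
    """Load a reference panel from VCF + population TSV + ancestral TSV."""
    from cyvcf2 import VCF

    pop_map = dict(
        pd.read_csv(populations_path, sep="\t", header=None, dtype=str).itertuples(
            index=False, name=None
        )
    )
    anc_map = dict(
        pd.read_csv(ancestral_path, sep="\t", header=None, dtype=str).itertuples(
            index=False, name=None
        )
    )
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    missing = [s for s in samples if s not in pop_map]
    if missing:
        raise ValueError(f"samples missing population labels: {missing}")
    variants: list[VariantRecord] = []
    cols = []
    for rec in vcf:
        for alt_index, alt in enumerate(rec.ALT, start=1):
            rec_obj = VariantRecord(rec.CHROM, rec.POS, rec.REF, alt)
            aa = anc_map.get(rec_obj.variant_id) or (rec.INFO.get("AA") or None)
            rec_obj.ancestral_allele = aa
            alleles = np.array([[g[0], g[1]] for g in rec.genotypes], dtype=np.int16)
            dosage = (alleles == alt_index).sum(axis=1).astype(np.int8)
            dosage[(alleles < 0).any(axis=1)] = -1
            variants.append(rec_obj)
            cols.append(dosage)
    vcf.close()
    genotypes = np.stack(cols, axis=1)
    populations = np.array([pop_map[s] for s in samples], dtype=object)
    return ReferencePanel(samples, populations, variants, genotypes,
                          truth=pd.DataFrame())


def analyze_cohort(
    cohort: CohortGenotypes, iqr_mult: float = burden.DEFAULT_IQR_MULT
) -> tuple[pd.DataFrame, burden.RegressionFit]:
    table = burden.count_burden(cohort)
    return burden.burden_outliers(table, iqr_mult=iqr_mult)


def _spectrum_block(
    cohort: CohortGenotypes, outlier_table: pd.DataFrame
) -> dict:
    parts = spectrum.partition_variants(cohort)
    out: dict = {}
    for group, exclusive in (("A", "case_only"), ("B", "control_only")):
        genes = list(outlier_table.loc[outlier_table["group"] == group, "gene"])
        for cls in ("exonic", "other"):
            key = f"group_{group.lower()}_{cls}"
            try:
                stat, p, n_a, n_b = spectrum.compare_class_proportions(
                    parts, genes, exclusive=exclusive, variant_class=cls
                )
                out[key] = {"statistic": stat, "p_value": p,
                            "n_exclusive": n_a, "n_shared": n_b}
            except ValueError as err:
                out[key] = {"error": str(err)}
    return out


def run_synthetic_study(
    config: SimConfig,
    out_dir: str | Path | None = None,
    iqr_mult: float = burden.DEFAULT_IQR_MULT,
    fdr_q: float = 0.1,
    n_components: int = 10,
) -> dict:
    """Simulate a full study and run every analysis stage on it.

    Returns a summary dict (JSON-serializable) with per-stage results plus
    recovery metrics against the planted truth; when ``out_dir`` is given,
    all inputs and result tables are also written there.
    """
    study = simulate_study(config)
    for sim in (study.discovery, study.replication):
        assign_genes(sim.cohort.variants, study.catalog)
        attach_annotations(sim.cohort, sim.annotations)

    qc_summary = qc.homogeneity_report(study.discovery.cohort)

    disc_table, disc_fit = analyze_cohort(study.discovery.cohort, iqr_mult)
    repl_table, repl_fit = analyze_cohort(study.replication.cohort, iqr_mult)
    repl_result = replication.replicate(disc_table, repl_table)

    spectrum_summary = _spectrum_block(study.discovery.cohort, disc_table)

    scan = selection.scan_selection(
        study.panel, catalog=study.catalog, fdr_q=fdr_q, n_components=n_components
    )
    sel_genes = scan.genes_under_selection()
    candidates, cand_summary = report.build_candidate_table(
        repl_result, sel_genes, study.pli, study.traits
    )

    truth = study.discovery.manifest.true_groups()
    planted_a = {g for g, grp in truth.items() if grp == "A"}
    planted_b = {g for g, grp in truth.items() if grp == "B"}
    found_a = set(disc_table.loc[disc_table["group"] == "A", "gene"])
    found_b = set(disc_table.loc[disc_table["group"] == "B", "gene"])
    planted = planted_a | planted_b
    found = found_a | found_b
    recovery = {
        "n_planted": len(planted),
        "n_detected": len(found),
        "true_positives": len((found_a & planted_a) | (found_b & planted_b)),
        "false_positives": len(found - planted),
        "sensitivity": (
            len((found_a & planted_a) | (found_b & planted_b)) / len(planted)
            if planted
            else None
        ),
    }
    summary = {
        "config": {"seed": config.seed, "n_genes": config.n_genes},
        "qc": qc_summary,
        "discovery": burden.summarize_fit(disc_table, disc_fit),
        "replication_cohort": burden.summarize_fit(repl_table, repl_fit),
        "replication": {
            "replicated_a": sorted(repl_result.replicated_a),
            "replicated_b": sorted(repl_result.replicated_b),
            "rate_percent": repl_result.rate_percent,
        },
        "spectrum": spectrum_summary,
        "selection": {
            "axis": scan.axis,
            "lambda_gc": scan.lambda_gc,
            "n_significant": int(scan.table["significant"].sum()),
            "genes_under_selection": sorted(sel_genes["gene"]),
        },
        "candidates": cand_summary,
        "recovery": recovery,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_cohort(study.discovery, out / "discovery")
        write_cohort(study.replication, out / "replication")
        write_panel(study.panel, out / "panel")
        study.pli.to_csv(out / "pli.tsv", sep="\t", index=False)
        study.traits.to_csv(out / "traits.tsv", sep="\t", index=False)
        disc_table.to_csv(out / "burden_discovery.tsv", sep="\t", index=False)
        repl_table.to_csv(out / "burden_replication.tsv", sep="\t", index=False)
        replication.replication_table(repl_result, disc_table, repl_table).to_csv(
            out / "replicated_genes.tsv", sep="\t", index=False
        )
        scan.table.to_csv(out / "selection_scan.tsv", sep="\t", index=False)
        candidates.to_csv(out / "candidates.tsv", sep="\t", index=False)
        report.export_gene_lists(
            {
                "A": repl_result.replicated_a,
                "B": repl_result.replicated_b,
                "candidates": set(candidates["gene"]),
            },
            out / "gene_lists",
        )
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
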