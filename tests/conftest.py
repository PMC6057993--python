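"""Shared fixtures: small synthetic studies and hand-built cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from burdenscan.simulate import SimConfig, simulate_study
from burdenscan.vcfio import (
    CohortGenotypes,
    VariantRecord,
    assign_genes,
    attach_annotations,
)

TINY_CONFIG = SimConfig(
    n_genes=40,
    planted_group_a=3,
    planted_group_b=3,
    burden_inflation=3.0,
    case_only_exonic_boost=3.0,
    n_panel_snps=1500,
    panel_size_afr=60,
    panel_size_eur=60,
    panel_size_eas=60,
    planted_selected_snps=15,
    seed=11,
)


@pytest.fixture(scope="session")
def tiny_study():
    """One fully simulated study (both cohorts, panel, tables), genes and
    annotations attached — the workhorse fixture for integration checks."""
    study = simulate_study(TINY_CONFIG)
    for sim in (study.discovery, study.replication):
        assign_genes(sim.cohort.variants, study.catalog)
        attach_annotations(sim.cohort, sim.annotations)
    return study


def build_cohort(
    genotype_rows: list[list[int]],
    groups: list[str],
    positions: list[int] | None = None,
    classes: list[str] | None = None,
    genes: list[tuple[str, ...]] | None = None,
) -> CohortGenotypes:
    """Hand-build a cohort from a genotype matrix (rows = samples)."""
    matrix = np.array(genotype_rows, dtype=np.int8)
    n_samples, n_variants = matrix.shape
    positions = positions or list(range(101, 101 + n_variants))
    variants = []
    for j in range(n_variants):
        v = VariantRecord("1", positions[j], "A", "C")
        if classes is not None:
            v.variant_class = classes[j]
        if genes is not None:
            v.genes = genes[j]
        variants.append(v)
    samples = [f"s{i}" for i in range(n_samples)]
    return CohortGenotypes(samples, np.array(groups, dtype=object), variants, matrix)
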