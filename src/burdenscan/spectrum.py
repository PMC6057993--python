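"""Exclusive-variant spectrum of outlier genes.

Each gene's variants split into three disjoint sets by who carries the
alternate allele: case-only, control-only, shared. For a set of genes (one
outlier group), the per-gene *proportion* of exonic variants in the
exclusive set is compared with the proportion in the shared set — the
proportion denominator is the gene's total distinct variant count, which
removes gene-size effects. An excess of exonic case-only variants in the
case-enriched genes is the signature of accumulated coding burden.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .qc import mann_whitney
from .vcfio import CohortGenotypes


@dataclass
class VariantPartition:
    """Disjoint case-only / control-only / shared variant-id sets of a gene."""

    gene: str
    case_only: frozenset[str]
    control_only: frozenset[str]
    shared: frozenset[str]
    exonic_ids: frozenset[str]

    @property
    def n_total(self) -> int:
        return len(self.case_only) + len(self.control_only) + len(self.shared)

    def count(self, which: str, variant_class: str = "exonic") -> int:
        ids = getattr(self, which)
        hits = ids & self.exonic_ids
        return len(hits) if variant_class == "exonic" else len(ids) - len(hits)

    def proportion(self, which: str, variant_class: str = "exonic") -> float:
        """Share of the gene's total variants that are in ``which`` and of
        the given class (the gene-size-free quantity that gets compared)."""
        return self.count(which, variant_class) / self.n_total if self.n_total else 0.0


def partition_variants(cohort: CohortGenotypes) -> dict[str, VariantPartition]:
    """Partition every gene's variants by carrier group.

    Variants with the alternate allele in no subject at all are ignored;
    variant classes must already be attached (``attach_annotations``).
    """
    in_cases = cohort.present_in(cohort.case_mask)
    in_controls = cohort.present_in(cohort.control_mask)
    buckets: dict[str, dict[str, set]] = {}
    for j, v in enumerate(cohort.variants):
        if not v.genes:
            continue
        if not (in_cases[j] or in_controls[j]):
            continue
        if in_cases[j] and in_controls[j]:
            key = "shared"
        elif in_cases[j]:
            key = "case_only"
        else:
            key = "control_only"
        for gene in v.genes:
            b = buckets.setdefault(
                gene,
                {"case_only": set(), "control_only": set(), "shared": set(),
                 "exonic": set()},
            )
            b[key].add(v.variant_id)
            if v.variant_class == "exonic":
                b["exonic"].add(v.variant_id)
    return {
        gene: VariantPartition(
            gene,
            frozenset(b["case_only"]),
            frozenset(b["control_only"]),
            frozenset(b["shared"]),
            frozenset(b["exonic"]),
        )
        for gene, b in buckets.items()
    }


def compare_class_proportions(
    partitions: dict[str, VariantPartition],
    genes: list[str],
    exclusive: str = "case_only",
    variant_class: str = "exonic",
    paired: bool = False,
    include_empty: bool = False,
) -> tuple[float, float, int, int]:
    """Rank test of exclusive-set vs shared-set class proportions over genes.

    Default is a two-sample Mann-Whitney/Wilcoxon rank-sum across genes (the
    two proportion distributions are compared as such); ``paired=True``
    switches to a Wilcoxon signed-rank on the per-gene differences. Genes
    whose relevant set is empty contribute no observation unless
    ``include_empty`` — an empty exclusive set is "no data", not "proportion
    zero". Returns (statistic, two-sided p, n_exclusive_obs, n_shared_obs).
    """
    if exclusive not in ("case_only", "control_only"):
        raise ValueError("exclusive must be case_only or control_only")
    a, b = [], []
    for g in genes:
        part = partitions.get(g)
        if part is None or part.n_total == 0:
            continue
        if include_empty or len(getattr(part, exclusive)) > 0:
            a.append(part.proportion(exclusive, variant_class))
        if include_empty or len(part.shared) > 0:
            b.append(part.proportion("shared", variant_class))
    if paired:
        pairs = [
            (
                part.proportion(exclusive, variant_class),
                part.proportion("shared", variant_class),
            )
            for g in genes
            if (part := partitions.get(g)) is not None and part.n_total
            and (include_empty or (getattr(part, exclusive) and part.shared))
        ]
        if len(pairs) < 2:
            raise ValueError("need at least 2 usable genes")
        d = np.array([x - y for x, y in pairs])
        if np.all(d == 0):
            return 0.0, 1.0, len(pairs), len(pairs)
        res = stats.wilcoxon(d, alternative="two-sided")
        return float(res.statistic), float(res.pvalue), len(pairs), len(pairs)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 usable genes per set")
    stat, p = mann_whitney(a, b)
    return stat, p, len(a), len(b)


def homozygous_exclusive_carriers(cohort: CohortGenotypes) -> list[dict]:
    """Subjects homozygous for an alt allele in their group's exclusive set.

    A plain listing (no statistics): genes carrying a homozygous case-only
    (or control-only) variant are candidates for near-Mendelian effects.
    """
    in_cases = cohort.present_in(cohort.case_mask)
    in_controls = cohort.present_in(cohort.control_mask)
    out = []
    for j, v in enumerate(cohort.variants):
        if in_cases[j] == in_controls[j]:  # shared or absent
            continue
        mask = cohort.case_mask if in_cases[j] else cohort.control_mask
        homs = np.flatnonzero((cohort.matrix[:, j] == 2) & mask)
        for i in homs:
            out.append(
                {
                    "variant_id": v.variant_id,
                    "genes": v.genes,
                    "sample": cohort.samples[i],
                    "group": "case" if in_cases[j] else "control",
                    "variant_class": v.variant_class,
                }
            )
    return out
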