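"""Cohort input/output: VCF, gene intervals, functional annotations.

The internal model is deliberately simple: a dense sample x variant matrix of
alternate-allele dosages (0/1/2, -1 for missing) plus ordered variant records.
Multiallelic VCF records are split so that every record/alt pair becomes one
biallelic variant keyed by ``chrom:pos:ref:alt`` — the key used to match
variants across cohorts for replication and exclusivity logic.

Coordinates: VCF positions are 1-based; gene intervals are stored 0-based
half-open (BED convention). The conversion lives in :mod:`burdenscan._util`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from ._util import vcf_pos_to_bed

#: Controlled vocabulary of functional annotation labels. ``exonic`` stands
#: alone; every other label collapses into the ``other`` class.
ANNOTATION_VOCABULARY = frozenset(
    {
        "exonic",
        "intronic",
        "upstream",
        "downstream",
        "UTR3",
        "UTR5",
        "ncRNA",
        "splicing",
        "intergenic",
    }
)

CASE = "case"
CONTROL = "control"


def classify_variant(annotation_label: str) -> str:
    """Collapse a functional annotation into the two-class scheme.

    ``exonic`` maps to ``"exonic"``; the remaining vocabulary (intronic,
    upstream, downstream, UTR3, UTR5, ncRNA, splicing, intergenic) maps to
    ``"other"``. Unknown labels raise — a silent default would corrupt the
    exonic-proportion comparisons downstream.
    """
    if annotation_label not in ANNOTATION_VOCABULARY:
        raise ValueError(
            f"unknown annotation label {annotation_label!r}; "
            f"expected one of {sorted(ANNOTATION_VOCABULARY)}"
        )
    return "exonic" if annotation_label == "exonic" else "other"


@dataclass
class VariantRecord:
    """One biallelic variant.

    ``gene`` holds every overlapping gene (a variant inside two overlapping
    genes is counted for both); empty until :func:`assign_genes` runs.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    variant_class: str | None = None  # "exonic" | "other"
    genes: tuple[str, ...] = ()
    ancestral_allele: str | None = None

    def __post_init__(self) -> None:
        if self.alt == self.ref:
            raise ValueError(f"alt equals ref at {self.chrom}:{self.pos}")

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass
class CohortGenotypes:
    """Samples x variants dosage matrix with case/control labels."""

    samples: list[str]
    groups: np.ndarray  # dtype=object, "case"/"control" per sample
    variants: list[VariantRecord]
    matrix: np.ndarray  # int8, shape (n_samples, n_variants); -1 = missing

    def __post_init__(self) -> None:
        n_samples, n_variants = self.matrix.shape
        if len(self.samples) != n_samples or len(self.groups) != n_samples:
            raise ValueError("sample list, group labels and matrix rows disagree")
        if len(self.variants) != n_variants:
            raise ValueError("variant list and matrix columns disagree")
        for grp in (CASE, CONTROL):
            if not np.any(self.groups == grp):
                raise ValueError(f"cohort has no {grp} samples")

    @property
    def case_mask(self) -> np.ndarray:
        return self.groups == CASE

    @property
    def control_mask(self) -> np.ndarray:
        return self.groups == CONTROL

    def carrier_counts(self, mask: np.ndarray) -> np.ndarray:
        """Number of subjects in ``mask`` carrying >=1 alt allele, per variant.

        Missing genotypes count as non-carriers (conservative for burden).
        """
        return (self.matrix[mask] > 0).sum(axis=0)

    def present_in(self, mask: np.ndarray) -> np.ndarray:
        """Boolean per variant: alt present in >=1 subject of the mask."""
        return self.carrier_counts(mask) > 0


@dataclass
class GeneCatalog:
    """Gene intervals, 0-based half-open, with an interval tree per contig."""

    intervals: pd.DataFrame  # columns: gene, chrom, start, end
    _trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        df = self.intervals
        required = {"gene", "chrom", "start", "end"}
        if not required.issubset(df.columns):
            raise ValueError(f"gene catalog needs columns {sorted(required)}")
        if (df["start"] >= df["end"]).any():
            bad = df[df["start"] >= df["end"]].iloc[0]
            raise ValueError(f"malformed interval for gene {bad['gene']}")
        if df["gene"].duplicated().any():
            # one gene may have several intervals; only (gene, interval)
            # duplicates are suspicious — allow multi-interval genes.
            pass
        for _, row in df.iterrows():
            tree = self._trees.setdefault(row["chrom"], IntervalTree())
            tree.addi(int(row["start"]), int(row["end"]), row["gene"])

    @classmethod
    def from_bed(cls, path: str | Path) -> "GeneCatalog":
        """BED3+name: chrom, start, end, gene (0-based half-open)."""
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            usecols=[0, 1, 2, 3],
            names=["chrom", "start", "end", "gene"],
            dtype={"chrom": str},
            comment="#",
        )
        return cls(df[["gene", "chrom", "start", "end"]])

    @classmethod
    def from_gff3(cls, path: str | Path, feature: str = "gene") -> "GeneCatalog":
        """Extract ``feature`` rows from a GFF3 file (1-based inclusive)."""
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 9 or parts[2] != feature:
                    continue
                attrs = dict(
                    kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
                )
                name = attrs.get("Name") or attrs.get("ID")
                if name is None:
                    raise ValueError(f"GFF3 {feature} row without Name/ID: {line!r}")
                # GFF3 is 1-based inclusive -> half-open 0-based
                rows.append((name, parts[0], int(parts[3]) - 1, int(parts[4])))
        if not rows:
            raise ValueError(f"no {feature} features found in {path}")
        return cls(pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"]))

    @property
    def genes(self) -> list[str]:
        return list(dict.fromkeys(self.intervals["gene"]))

    def overlapping_genes(self, chrom: str, pos: int) -> tuple[str, ...]:
        """Genes whose interval contains the 1-based position."""
        tree = self._trees.get(chrom)
        if tree is None:
            return ()
        hits = tree[vcf_pos_to_bed(pos)]
        return tuple(sorted(iv.data for iv in hits))


def read_group_map(path: str | Path) -> dict[str, str]:
    """TSV of (sample, group) with group in {case, control}."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "group"], dtype=str)
    if df.iloc[0]["sample"].lower() == "sample":  # tolerate a header row
        df = df.iloc[1:]
    bad = set(df["group"]) - {CASE, CONTROL}
    if bad:
        raise ValueError(f"group map contains labels outside case/control: {bad}")
    return dict(zip(df["sample"], df["group"]))


def read_cohort(vcf_path: str | Path, group_map_path: str | Path) -> CohortGenotypes:
    """Load a multi-sample VCF plus its sample->group map.

    Multiallelic records are split into one biallelic variant per alt allele.
    A genotype is missing (-1) when either allele call is missing.
    """
    from cyvcf2 import VCF  # deferred: import cost and htslib warnings

    group_map = read_group_map(group_map_path)
    vcf = VCF(str(vcf_path), gts012=False)
    samples = list(vcf.samples)
    missing = [s for s in samples if s not in group_map]
    if missing:
        raise ValueError(
            f"samples missing from group map: {', '.join(missing)}"
        )
    groups = np.array([group_map[s] for s in samples], dtype=object)

    variants: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    for rec in vcf:
        gts = rec.genotypes  # [[a0, a1, phased], ...]
        alleles = np.array([[g[0], g[1]] for g in gts], dtype=np.int16)
        any_missing = (alleles < 0).any(axis=1)
        for alt_index, alt in enumerate(rec.ALT, start=1):
            if alt in ("*", "<NON_REF>", "."):
                continue
            dosage = (alleles == alt_index).sum(axis=1).astype(np.int8)
            dosage[any_missing] = -1
            variants.append(VariantRecord(rec.CHROM, rec.POS, rec.REF, alt))
            columns.append(dosage)
    vcf.close()
    if not variants:
        raise ValueError(f"no usable variant records in {vcf_path}")
    matrix = np.stack(columns, axis=1)
    return CohortGenotypes(samples, groups, variants, matrix)


def read_annotations(path: str | Path) -> pd.DataFrame:
    """TSV of (variant_id, gene, class) with class in the controlled vocabulary."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"variant_id", "gene", "class"}
    if not required.issubset(df.columns):
        raise ValueError(f"annotation table needs columns {sorted(required)}")
    unknown = set(df["class"]) - ANNOTATION_VOCABULARY
    if unknown:
        raise ValueError(f"unknown annotation labels: {sorted(unknown)}")
    return df


def attach_annotations(cohort: CohortGenotypes, annotations: pd.DataFrame) -> None:
    """Set each variant's two-class label from an annotation table, in place."""
    class_by_id = {
        vid: classify_variant(label)
        for vid, label in zip(annotations["variant_id"], annotations["class"])
    }
    for v in cohort.variants:
        label = class_by_id.get(v.variant_id)
        if label is not None:
            v.variant_class = label


def assign_genes(
    variants: Iterable[VariantRecord], catalog: GeneCatalog
) -> list[VariantRecord]:
    """Attach every overlapping gene to each variant (in place).

    Variants overlapping no gene keep an empty tuple and are excluded from
    burden counting by the caller.
    """
    if catalog.intervals.empty:
        raise ValueError("gene catalog is empty")
    out = []
    for v in variants:
        v.genes = catalog.overlapping_genes(v.chrom, v.pos)
        out.append(v)
    return out


def write_vcf(
    path: str | Path,
    cohort: CohortGenotypes,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write the cohort as a plain-text VCF v4.2 (diploid GT only)."""
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    if contig_lengths is None:
        contig_lengths = {}
        for v in cohort.variants:
            contig_lengths[v.chrom] = max(
                contig_lengths.get(v.chrom, 0), v.pos + 1000
            )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=burdenscan\n")
        for chrom, length in contig_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(cohort.samples)
            + "\n"
        )
        for j, v in enumerate(cohort.variants):
            gts = "\t".join(gt_strings[int(g)] for g in cohort.matrix[:, j])
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.variant_id}\t{v.ref}\t{v.alt}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_group_map(path: str | Path, cohort: CohortGenotypes) -> None:
    with open(path, "w") as fh:
        for sample, group in zip(cohort.samples, cohort.groups):
            fh.write(f"{sample}\t{group}\n")


def write_bed(path: str | Path, catalog: GeneCatalog) -> None:
    catalog.intervals[["chrom", "start", "end", "gene"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def brute_force_gene_assignment(
    variants: Sequence[VariantRecord], catalog: GeneCatalog
) -> list[tuple[str, ...]]:
    """O(V x G) reference scan used to validate the interval-tree lookup."""
    out = []
    for v in variants:
        hits = []
        for _, row in catalog.intervals.iterrows():
            if row["chrom"] == v.chrom and row["start"] <= v.pos - 1 < row["end"]:
                hits.append(row["gene"])
        out.append(tuple(sorted(hits)))
    return out
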