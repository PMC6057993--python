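"""Synthetic case/control cohorts and reference panels with planted truth.

Everything downstream of sequencing is exercised on data from this module:
two case/control cohorts with heavy-tailed per-gene variant burdens, planted
burden-outlier genes, per-variant functional annotations, and a three-
population reference panel (AFR/EUR/EAS) with planted frequency-
differentiated SNPs and known ancestral alleles.

Calibration. Per-gene baseline burdens are lognormal with meanlog = ln 112
and sdlog = (ln 279 - ln 49) / (2 * 0.6745) ~ 1.289, matching the observed
cohort summaries (median 112, quartiles 49/279, mean far above the median —
a heavy right tail). Cohort sizes default to 78+78 (discovery) and 28+28
(replication).

Sharing model. Each variant is shared, case-only or control-only. The shared
fraction of a gene is binomial, but the *split* of the exclusive pool between
the two groups is balanced with bounded jitter (``sharing_jitter`` Bernoulli
trials, sd ~2.4 variants regardless of gene size). An independent per-variant
split would make the case-control count discrepancy grow as sqrt(gene
burden); with the heavy-tailed burden distribution above, the largest null
genes would then dominate any residual-fence outlier rule and planted effects
would be unrecoverable in principle. Keeping the null discrepancy
homoscedastic gives the generator a well-defined planted truth. See
docs/methods.md for the full argument.

Determinism: ``SimConfig.seed`` fully determines every output byte.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._util import check_probability
from .vcfio import (
    CASE,
    CONTROL,
    CohortGenotypes,
    GeneCatalog,
    VariantRecord,
    write_bed,
    write_group_map,
    write_vcf,
)

_Z75 = 0.6744897501960817  # 75th percentile of the standard normal

#: Lognormal parameters matched to the reported per-gene burden summaries.
DEFAULT_MEANLOG = math.log(112.0)
DEFAULT_SDLOG = (math.log(279.0) - math.log(49.0)) / (2.0 * _Z75)

# Non-exonic annotation mix (conditional on "not exonic"); WGS-flavoured:
# intronic dominates, the rest are peri-genic categories.
_OTHER_LABELS = ("intronic", "upstream", "downstream", "UTR3", "UTR5", "ncRNA", "splicing")
_OTHER_WEIGHTS = (0.66, 0.06, 0.06, 0.05, 0.03, 0.10, 0.04)

POPULATIONS = ("AFR", "EUR", "EAS")
_BASES = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic study, with study-design defaults."""

    n_genes: int = 200
    n_cases: int = 78
    n_controls: int = 78
    n_cases_replication: int = 28
    n_controls_replication: int = 28
    burden_meanlog: float = DEFAULT_MEANLOG
    burden_sdlog: float = DEFAULT_SDLOG
    planted_group_a: int = 0
    planted_group_b: int = 0
    burden_inflation: float = 3.0
    planted_min_count: int = 50
    planted_max_count: int = 500
    p_shared: float = 0.6
    sharing_jitter: int = 24
    exonic_fraction: float = 0.05
    case_only_exonic_boost: float = 1.0
    carrier_fraction: float = 0.03
    hom_fraction: float = 0.05
    missing_rate: float = 0.01
    # reference panel
    panel_size_afr: int = 100
    panel_size_eur: int = 100
    panel_size_eas: int = 100
    n_panel_snps: int = 5000
    planted_selected_snps: int = 0
    planted_afr_snps: int = 0
    daf_gap: float = 0.8
    drift_sd: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "n_cases_replication": self.n_cases_replication,
            "n_controls_replication": self.n_controls_replication,
            "planted_group_a": self.planted_group_a,
            "planted_group_b": self.planted_group_b,
            "n_panel_snps": self.n_panel_snps,
            "planted_selected_snps": self.planted_selected_snps,
            "planted_afr_snps": self.planted_afr_snps,
            "sharing_jitter": self.sharing_jitter,
        }
        for name, value in counts.items():
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value}")
        if self.n_genes == 0:
            raise ValueError("n_genes must be positive")
        if min(self.n_cases, self.n_controls) == 0:
            raise ValueError("both case and control groups must be non-empty")
        for name in ("p_shared", "exonic_fraction", "carrier_fraction",
                     "hom_fraction", "missing_rate"):
            check_probability(name, getattr(self, name))
        if self.burden_inflation < 1.0:
            raise ValueError("burden_inflation must be >= 1")
        if self.case_only_exonic_boost < 1.0:
            raise ValueError("case_only_exonic_boost must be >= 1")
        if not (0.0 < self.daf_gap < 1.0):
            raise ValueError("daf_gap must lie strictly inside (0, 1)")
        if self.drift_sd < 0:
            raise ValueError("drift_sd must be >= 0")

    @property
    def panel_sizes(self) -> dict[str, int]:
        return {
            "AFR": self.panel_size_afr,
            "EUR": self.panel_size_eur,
            "EAS": self.panel_size_eas,
        }


@dataclass
class TruthManifest:
    """Ground truth for one simulated cohort, JSON round-trippable."""

    cohort_id: str
    config: dict
    genes: list[dict]       # gene, interval, base_n, true_group, count truth
    samples: list[dict]     # sample, group, age, ptah
    variants: list[dict]    # variant_id, gene, status, label, class

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        with open(path) as fh:
            return cls(**json.load(fh))

    def true_groups(self) -> dict[str, str]:
        return {g["gene"]: g["true_group"] for g in self.genes}


@dataclass
class CohortSim:
    """In-memory result of one cohort simulation."""

    cohort: CohortGenotypes
    catalog: GeneCatalog
    annotations: pd.DataFrame
    manifest: TruthManifest


@dataclass
class ReferencePanel:
    """Diploid genotype panel with population labels and ancestral alleles."""

    samples: list[str]
    populations: np.ndarray          # dtype=object, per sample
    variants: list[VariantRecord]    # ancestral_allele set
    genotypes: np.ndarray            # int8, (n_samples, n_snps)
    truth: pd.DataFrame              # variant_id, selected, kind, daf_* per pop


@dataclass
class StudySim:
    """Full synthetic study: two cohorts + panel + gene-level lookup tables."""

    config: SimConfig
    plan: pd.DataFrame
    catalog: GeneCatalog
    discovery: CohortSim
    replication: CohortSim
    panel: ReferencePanel
    pli: pd.DataFrame
    traits: pd.DataFrame


# ---------------------------------------------------------------------------
# gene plan and burden counts
# ---------------------------------------------------------------------------

def gene_plan(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw per-gene baseline burdens, plant outlier genes, lay out intervals.

    Returns a frame with gene, chrom, start, end, base_n, true_group. Planted
    genes are sampled among genes whose baseline burden lies in
    [``planted_min_count``, ``planted_max_count``]: a multiplicative effect on
    a near-empty gene is not expressible, and planting on the extreme-size
    tail hands those genes enough regression leverage to bend the fitted line
    itself — either way the recovery metric would measure the size
    distribution, not the fence rule.
    """
    n = config.n_genes
    base_n = np.maximum(
        1, np.rint(rng.lognormal(config.burden_meanlog, config.burden_sdlog, n))
    ).astype(np.int64)
    width = len(str(n))
    genes = np.array([f"G{i + 1:0{width}d}" for i in range(n)])

    true_group = np.full(n, "none", dtype=object)
    n_plant = config.planted_group_a + config.planted_group_b
    if n_plant:
        eligible = np.flatnonzero(
            (base_n >= config.planted_min_count)
            & (base_n <= config.planted_max_count)
        )
        if len(eligible) < n_plant:
            raise ValueError(
                f"only {len(eligible)} genes have baseline burden in "
                f"[{config.planted_min_count}, {config.planted_max_count}]; "
                f"cannot plant {n_plant} outliers"
            )
        chosen = rng.choice(eligible, size=n_plant, replace=False)
        true_group[chosen[: config.planted_group_a]] = "A"
        true_group[chosen[config.planted_group_a:]] = "B"

    # lay genes end to end on one contig, leaving room for inflated counts
    spacing = 10
    capacity = np.ceil(base_n * config.burden_inflation).astype(np.int64) + 16
    lengths = capacity * spacing + 200
    starts = np.concatenate([[1000], 1000 + np.cumsum(lengths + 500)[:-1]])
    return pd.DataFrame(
        {
            "gene": genes,
            "chrom": "1",
            "start": starts,
            "end": starts + lengths,
            "base_n": base_n,
            "true_group": true_group,
        }
    )


def plan_catalog(plan: pd.DataFrame) -> GeneCatalog:
    return GeneCatalog(plan[["gene", "chrom", "start", "end"]].copy())


def simulate_burden_counts(
    config: SimConfig,
    rng: np.random.Generator | None = None,
    plan: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-gene true variant counts (shared / case-only / control-only).

    This is the count-level core of the generator: the cohort realization in
    :func:`simulate_cohort` draws variants and carriers on top of exactly
    these counts, so the frame doubles as the burden-counting oracle.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if plan is None:
        plan = gene_plan(config, rng)
    n = len(plan)
    base_n = plan["base_n"].to_numpy()
    group = plan["true_group"].to_numpy()

    shared = rng.binomial(base_n, config.p_shared)
    exclusive = base_n - shared
    # balanced split of the exclusive pool: bounded jitter keeps the null
    # case-control discrepancy homoscedastic across gene sizes
    k = np.minimum(exclusive, config.sharing_jitter)
    rem = exclusive - k
    odd = (rem % 2).astype(bool)
    case_only = rem // 2 + (odd & (rng.random(n) < 0.5)) + rng.binomial(k, 0.5)
    control_only = exclusive - case_only

    n_case = shared + case_only
    n_control = shared + control_only
    infl = config.burden_inflation
    extra_a = np.where(group == "A", np.rint((infl - 1.0) * n_case), 0).astype(np.int64)
    extra_b = np.where(group == "B", np.rint((infl - 1.0) * n_control), 0).astype(np.int64)
    case_only = case_only + extra_a
    control_only = control_only + extra_b

    return pd.DataFrame(
        {
            "gene": plan["gene"].to_numpy(),
            "true_group": group,
            "n_shared": shared,
            "n_case_only": case_only,
            "n_control_only": control_only,
            "n_case": shared + case_only,
            "n_control": shared + control_only,
            "n_total": shared + case_only + control_only,
        }
    )


# ---------------------------------------------------------------------------
# cohort realization
# ---------------------------------------------------------------------------

def _draw_carriers(
    rng: np.random.Generator,
    indices: np.ndarray,
    carrier_fraction: float,
    hom_fraction: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample >=1 carriers from a group and their dosages (1 het, 2 hom)."""
    n_carriers = 1 + rng.binomial(len(indices) - 1, carrier_fraction)
    chosen = rng.choice(indices, size=n_carriers, replace=False)
    dosages = np.where(rng.random(n_carriers) < hom_fraction, 2, 1).astype(np.int8)
    return chosen, dosages


def simulate_cohort(
    config: SimConfig,
    cohort_id: str = "discovery",
    rng: np.random.Generator | None = None,
    plan: pd.DataFrame | None = None,
    n_cases: int | None = None,
    n_controls: int | None = None,
) -> CohortSim:
    """Realize a full cohort: variants, genotypes, annotations, phenotypes."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if plan is None:
        plan = gene_plan(config, rng)
    counts = simulate_burden_counts(config, rng, plan)
    n_cases = config.n_cases if n_cases is None else n_cases
    n_controls = config.n_controls if n_controls is None else n_controls
    if min(n_cases, n_controls) < 1:
        raise ValueError("both groups must be non-empty")

    samples = [f"{cohort_id}_case{i + 1:03d}" for i in range(n_cases)] + [
        f"{cohort_id}_ctrl{i + 1:03d}" for i in range(n_controls)
    ]
    groups = np.array([CASE] * n_cases + [CONTROL] * n_controls, dtype=object)
    case_idx = np.arange(n_cases)
    ctrl_idx = np.arange(n_cases, n_cases + n_controls)

    variants: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    var_truth: list[dict] = []
    ann_rows: list[tuple[str, str, str]] = []
    n_samples = n_cases + n_controls

    boost_p = min(0.95, config.exonic_fraction * config.case_only_exonic_boost)
    other_weights = np.array(_OTHER_WEIGHTS)

    for row, crow in zip(plan.itertuples(index=False), counts.itertuples(index=False)):
        total = int(crow.n_total)
        statuses = np.array(
            ["shared"] * int(crow.n_shared)
            + ["case_only"] * int(crow.n_case_only)
            + ["control_only"] * int(crow.n_control_only),
            dtype=object,
        )
        rng.shuffle(statuses)
        positions = np.sort(
            rng.choice(np.arange(row.start + 1, row.end - 1), size=total, replace=False)
        )
        refs = _BASES[rng.integers(0, 4, size=total)]
        alts = np.array(
            [_BASES[(list(_BASES).index(r) + rng.integers(1, 4)) % 4] for r in refs]
        )
        for j in range(total):
            status = statuses[j]
            pos = int(positions[j]) + 1  # half-open 0-based -> 1-based inside
            pe = (
                boost_p
                if (row.true_group == "A" and status == "case_only")
                else config.exonic_fraction
            )
            if rng.random() < pe:
                label = "exonic"
            else:
                label = _OTHER_LABELS[rng.choice(len(_OTHER_LABELS), p=other_weights)]
            col = np.zeros(n_samples, dtype=np.int8)
            if status in ("shared", "case_only"):
                who, dose = _draw_carriers(
                    rng, case_idx, config.carrier_fraction, config.hom_fraction
                )
                col[who] = dose
            if status in ("shared", "control_only"):
                who, dose = _draw_carriers(
                    rng, ctrl_idx, config.carrier_fraction, config.hom_fraction
                )
                col[who] = dose
            if config.missing_rate > 0:
                noncarrier = np.flatnonzero(col == 0)
                drop = noncarrier[rng.random(len(noncarrier)) < config.missing_rate]
                col[drop] = -1
            rec = VariantRecord("1", pos, str(refs[j]), str(alts[j]))
            variants.append(rec)
            columns.append(col)
            var_truth.append(
                {
                    "variant_id": rec.variant_id,
                    "gene": row.gene,
                    "status": status,
                    "label": label,
                    "class": "exonic" if label == "exonic" else "other",
                }
            )
            ann_rows.append((rec.variant_id, row.gene, label))

    matrix = np.stack(columns, axis=1)
    cohort = CohortGenotypes(samples, groups, variants, matrix)

    ages = rng.integers(51, 91, size=n_samples)
    ptah = np.where(
        groups == CASE,
        np.round(rng.uniform(40.0, 110.0, n_samples), 1),
        np.round(rng.uniform(0.0, 25.0, n_samples), 1),
    )
    sample_truth = [
        {"sample": s, "group": g, "age": int(a), "ptah": float(p)}
        for s, g, a, p in zip(samples, groups, ages, ptah)
    ]
    gene_truth = [
        {
            "gene": row.gene,
            "chrom": row.chrom,
            "start": int(row.start),
            "end": int(row.end),
            "base_n": int(row.base_n),
            "true_group": row.true_group,
            "n_shared": int(crow.n_shared),
            "n_case_only": int(crow.n_case_only),
            "n_control_only": int(crow.n_control_only),
            "n_case": int(crow.n_case),
            "n_control": int(crow.n_control),
        }
        for row, crow in zip(plan.itertuples(index=False), counts.itertuples(index=False))
    ]
    manifest = TruthManifest(
        cohort_id=cohort_id,
        config=asdict(config),
        genes=gene_truth,
        samples=sample_truth,
        variants=var_truth,
    )
    annotations = pd.DataFrame(ann_rows, columns=["variant_id", "gene", "class"])
    return CohortSim(cohort, plan_catalog(plan), annotations, manifest)


# ---------------------------------------------------------------------------
# reference panel
# ---------------------------------------------------------------------------

def simulate_reference_panel(
    config: SimConfig,
    rng: np.random.Generator | None = None,
    catalog: GeneCatalog | None = None,
    target_genes: Sequence[str] | None = None,
) -> ReferencePanel:
    """Three-population diploid panel with planted differentiated SNPs.

    Null SNPs share one derived-allele frequency across populations, plus a
    small Gaussian drift (sd ``drift_sd``). Planted SNPs get an exact
    EUR-vs-EAS derived-frequency gap of ``daf_gap`` (AFR intermediate);
    ``planted_afr_snps`` are instead differentiated AFR vs (EUR=EAS), which
    lets African structure dominate the leading principal component. If a
    gene catalog is given, SNPs are placed inside genes (planted ones inside
    ``target_genes``) so significant SNPs can be rolled up to genes.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sizes = config.panel_sizes
    pops = [p for p, n in sizes.items() if n > 0]
    if len(pops) < 2:
        raise ValueError("reference panel needs at least two populations")
    for p in pops:
        if sizes[p] < 10:
            raise ValueError(f"population {p} needs >= 10 diploid samples")
    m = config.n_panel_snps
    n_eur_eas = config.planted_selected_snps
    n_afr = config.planted_afr_snps
    if n_eur_eas + n_afr > m:
        raise ValueError("more planted SNPs than panel SNPs")

    kind = np.full(m, "null", dtype=object)
    if n_eur_eas + n_afr:
        chosen = rng.choice(m, size=n_eur_eas + n_afr, replace=False)
        kind[chosen[:n_eur_eas]] = "eur_eas"
        kind[chosen[n_eur_eas:]] = "afr"

    daf = {p: np.empty(m) for p in POPULATIONS}
    p0 = rng.uniform(0.05, 0.95, size=m)
    for p in POPULATIONS:
        daf[p] = np.clip(p0 + rng.normal(0.0, config.drift_sd, size=m), 0.001, 0.999)
    gap = config.daf_gap
    for j in np.flatnonzero(kind == "eur_eas"):
        low = rng.uniform(0.02, 0.98 - gap)
        high = low + gap
        if rng.random() < 0.5:
            daf["EUR"][j], daf["EAS"][j] = high, low
        else:
            daf["EUR"][j], daf["EAS"][j] = low, high
        daf["AFR"][j] = (low + high) / 2.0
    for j in np.flatnonzero(kind == "afr"):
        low = rng.uniform(0.02, 0.98 - gap)
        daf["AFR"][j] = low + gap
        daf["EUR"][j] = daf["EAS"][j] = low

    # coordinates: inside genes when a catalog is supplied
    if catalog is not None:
        iv = catalog.intervals.reset_index(drop=True)
        weights = (iv["end"] - iv["start"]).to_numpy().astype(float)
        host = rng.choice(len(iv), size=m, p=weights / weights.sum())
        if target_genes:
            targets = [g for g in target_genes if g in set(iv["gene"])]
            planted_idx = np.flatnonzero(kind != "null")
            for i, j in enumerate(planted_idx):
                host[j] = iv.index[iv["gene"] == targets[i % len(targets)]][0]
        pos = np.array(
            [int(rng.integers(iv["start"][h] + 1, iv["end"][h])) + 1 for h in host]
        )
        chroms = iv["chrom"].to_numpy()[host]
    else:
        pos = 1000 + 50 * np.arange(m)
        chroms = np.full(m, "1", dtype=object)

    refs = _BASES[rng.integers(0, 4, size=m)]
    alts = np.array(
        [_BASES[(list(_BASES).index(r) + rng.integers(1, 4)) % 4] for r in refs]
    )
    anc_is_ref = rng.random(m) < 0.5

    samples: list[str] = []
    pop_labels: list[str] = []
    blocks: list[np.ndarray] = []
    for p in pops:
        n = sizes[p]
        samples += [f"{p}{i + 1:03d}" for i in range(n)]
        pop_labels += [p] * n
        alt_freq = np.where(anc_is_ref, daf[p], 1.0 - daf[p])
        blocks.append(rng.binomial(2, alt_freq, size=(n, m)).astype(np.int8))
    genotypes = np.concatenate(blocks, axis=0)

    variants = []
    order = np.argsort(pos, kind="stable")
    genotypes = genotypes[:, order]
    for j in order:
        variants.append(
            VariantRecord(
                str(chroms[j]),
                int(pos[j]),
                str(refs[j]),
                str(alts[j]),
                ancestral_allele=str(refs[j] if anc_is_ref[j] else alts[j]),
            )
        )
    truth = pd.DataFrame(
        {
            "variant_id": [v.variant_id for v in variants],
            "selected": (kind[order] == "eur_eas"),
            "kind": kind[order],
            **{f"daf_{p.lower()}": daf[p][order] for p in POPULATIONS},
        }
    )
    return ReferencePanel(samples, np.array(pop_labels, dtype=object), variants,
                          genotypes, truth)


# ---------------------------------------------------------------------------
# gene-level lookup tables
# ---------------------------------------------------------------------------

def simulate_pli_table(
    genes: Sequence[str],
    rng: np.random.Generator,
    lof_intolerant: Sequence[str] = (),
) -> pd.DataFrame:
    """Gene -> pLI in [0, 1]; designated genes get pLI >= 0.9."""
    intolerant = set(lof_intolerant)
    unknown = intolerant - set(genes)
    if unknown:
        raise ValueError(f"LoF-intolerant genes not in catalog: {sorted(unknown)}")
    pli = np.where(
        np.isin(genes, list(intolerant)),
        rng.uniform(0.9, 1.0, len(genes)),
        rng.uniform(0.0, 0.89, len(genes)),
    )
    return pd.DataFrame({"gene": list(genes), "pli": np.round(pli, 2)})


_TRAIT_POOL = (
    "height", "BMI", "QT interval", "schizophrenia", "asthma",
    "age at menarche", "refractive error", "pulmonary function",
    "motion sickness", "blood pressure",
)


def simulate_trait_catalog(
    genes: Sequence[str], rng: np.random.Generator, fraction: float = 0.6
) -> pd.DataFrame:
    """Gene -> previously-associated trait(s), for a random subset of genes."""
    check_probability("fraction", fraction)
    rows = []
    for g in genes:
        if rng.random() < fraction:
            traits = rng.choice(_TRAIT_POOL, size=rng.integers(1, 3), replace=False)
            rows.append((g, ", ".join(sorted(traits))))
    return pd.DataFrame(rows, columns=["gene", "traits"])


# ---------------------------------------------------------------------------
# whole study + file output
# ---------------------------------------------------------------------------

def simulate_study(config: SimConfig) -> StudySim:
    """Discovery + replication cohorts on one gene plan, panel and tables.

    Planted outlier genes are shared between the cohorts (same genes, same
    direction), emulating a real effect present in both populations; panel
    SNPs are placed across the gene catalog, with planted differentiated SNPs
    inside the planted outlier genes so the end-to-end prioritization has a
    non-empty truth.
    """
    rng = np.random.default_rng(config.seed)
    plan = gene_plan(config, rng)
    discovery = simulate_cohort(config, "discovery", rng, plan)
    replication = simulate_cohort(
        config,
        "replication",
        rng,
        plan,
        n_cases=config.n_cases_replication,
        n_controls=config.n_controls_replication,
    )
    catalog = plan_catalog(plan)
    planted = list(plan.loc[plan["true_group"] != "none", "gene"])
    panel = simulate_reference_panel(
        config, rng, catalog=catalog, target_genes=planted or None
    )
    pli = simulate_pli_table(list(plan["gene"]), rng, lof_intolerant=planted[:2])
    traits = simulate_trait_catalog(list(plan["gene"]), rng)
    return StudySim(config, plan, catalog, discovery, replication, panel, pli, traits)


def write_cohort(sim: CohortSim, out_dir: str | Path) -> dict[str, Path]:
    """Write VCF, group map, gene BED, annotation TSV and truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cid = sim.manifest.cohort_id
    paths = {
        "vcf": out / f"{cid}.vcf",
        "groups": out / f"{cid}.groups.tsv",
        "genes": out / f"{cid}.genes.bed",
        "annotations": out / f"{cid}.annotations.tsv",
        "manifest": out / f"{cid}.truth.json",
    }
    contig_len = {"1": int(sim.catalog.intervals["end"].max() + 1000)}
    write_vcf(paths["vcf"], sim.cohort, contig_len)
    write_group_map(paths["groups"], sim.cohort)
    write_bed(paths["genes"], sim.catalog)
    sim.annotations.to_csv(paths["annotations"], sep="\t", index=False)
    sim.manifest.to_json(paths["manifest"])
    return paths


def write_panel(panel: ReferencePanel, out_dir: str | Path) -> dict[str, Path]:
    """Write panel VCF, population labels TSV and ancestral-allele TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "panel.vcf",
        "populations": out / "panel.populations.tsv",
        "ancestral": out / "panel.ancestral.tsv",
        "truth": out / "panel.truth.tsv",
    }
    gt = {0: "0/0", 1: "0/1", 2: "1/1"}
    contigs: dict[str, int] = {}
    for v in panel.variants:
        contigs[v.chrom] = max(contigs.get(v.chrom, 0), v.pos + 1000)
    with open(paths["vcf"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##source=burdenscan\n")
        for chrom, length in contigs.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.samples) + "\n")
        for j, v in enumerate(panel.variants):
            gts = "\t".join(gt[int(g)] for g in panel.genotypes[:, j])
            fh.write(f"{v.chrom}\t{v.pos}\t{v.variant_id}\t{v.ref}\t{v.alt}"
                     f"\t.\tPASS\tAA={v.ancestral_allele}\tGT\t{gts}\n")
    with open(paths["populations"], "w") as fh:
        for s, p in zip(panel.samples, panel.populations):
            fh.write(f"{s}\t{p}\n")
    with open(paths["ancestral"], "w") as fh:
        for v in panel.variants:
            fh.write(f"{v.variant_id}\t{v.ancestral_allele}\n")
    panel.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
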