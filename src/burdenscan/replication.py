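"""Direction-preserving replication of outlier genes across cohorts.

A discovery-cohort outlier replicates iff the independent cohort assigns it
the *same* group (A stays A, B stays B); a direction-agnostic mode is
deliberately not offered, since an outlier that flips direction contradicts
rather than confirms the discovery signal. The replication rate is the
percentage of discovery outliers (both groups pooled) that replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from ._util import percentage


@dataclass
class ReplicationResult:
    replicated_a: frozenset[str]
    replicated_b: frozenset[str]
    discovery_a: frozenset[str]
    discovery_b: frozenset[str]
    rate_percent: int = field(init=False)

    def __post_init__(self) -> None:
        n_disc = len(self.discovery_a) + len(self.discovery_b)
        n_repl = len(self.replicated_a) + len(self.replicated_b)
        self.rate_percent = percentage(n_repl, n_disc) if n_disc else 0

    @property
    def replicated(self) -> frozenset[str]:
        return self.replicated_a | self.replicated_b

    @property
    def rate(self) -> float:
        """Unrounded replication rate in percent."""
        n_disc = len(self.discovery_a) + len(self.discovery_b)
        return 100.0 * len(self.replicated) / n_disc if n_disc else 0.0


def _groups(table: pd.DataFrame, which: str) -> frozenset[str]:
    return frozenset(table.loc[table["group"] == which, "gene"])


def replicate(discovery: pd.DataFrame, replication: pd.DataFrame) -> ReplicationResult:
    """Intersect outlier calls of two cohorts, direction preserved.

    Both tables come from :func:`burdenscan.burden.burden_outliers` on the
    same gene catalog; disjoint gene universes indicate mismatched inputs
    and raise.
    """
    if not set(discovery["gene"]) & set(replication["gene"]):
        raise ValueError("discovery and replication tables share no genes")
    disc_a, disc_b = _groups(discovery, "A"), _groups(discovery, "B")
    repl_a, repl_b = _groups(replication, "A"), _groups(replication, "B")
    return ReplicationResult(
        replicated_a=disc_a & repl_a,
        replicated_b=disc_b & repl_b,
        discovery_a=disc_a,
        discovery_b=disc_b,
    )


def replication_rate(n_replicated: int, n_discovery: int) -> int:
    """100 * replicated / discovery, half-up to the nearest integer percent."""
    if n_discovery <= 0:
        raise ValueError("n_discovery must be positive")
    if not (0 <= n_replicated <= n_discovery):
        raise ValueError("n_replicated must lie in [0, n_discovery]")
    return percentage(n_replicated, n_discovery)


def replication_table(
    result: ReplicationResult,
    discovery: pd.DataFrame,
    replication: pd.DataFrame,
) -> pd.DataFrame:
    """Replicated genes with both cohorts' counts, for reporting."""
    rows = []
    disc = discovery.set_index("gene")
    repl = replication.set_index("gene")
    for group, genes in (("A", result.replicated_a), ("B", result.replicated_b)):
        for g in sorted(genes):
            rows.append(
                {
                    "gene": g,
                    "group": group,
                    "discovery_n_case": int(disc.loc[g, "n_case"]),
                    "discovery_n_control": int(disc.loc[g, "n_control"]),
                    "replication_n_case": int(repl.loc[g, "n_case"]),
                    "replication_n_control": int(repl.loc[g, "n_control"]),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "group",
            "discovery_n_case", "discovery_n_control",
            "replication_n_case", "replication_n_control",
        ],
    )
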