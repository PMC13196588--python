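"""Per-gene enrichment of transposon-insertion mutants after phage challenge.

Phage infection of a saturated transposon library enriches insertions in
genes whose disruption confers resistance (receptor genes above all).
This module implements a transparent enrichment readout over per-gene
insertion counts: per-million library-size normalisation, a log2 fold
change of mean normalised abundance (infected vs uninfected control,
pseudocounted), a two-sided pooled two-proportion z-test per gene, and
Benjamini–Hochberg q-values across genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportions_ztest

DEFAULT_PSEUDOCOUNT = 1.0  # in per-million units


@dataclass(frozen=True)
class InsertionCountTable:
    """Gene x (condition, replicate) insertion counts.

    ``counts`` is indexed by gene with a (condition, replicate)
    MultiIndex on columns; ``library_sizes`` are the column sums.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.counts.columns, pd.MultiIndex):
            raise ValueError("counts needs (condition, replicate) column MultiIndex")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("insertion counts must be non-negative")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def conditions(self) -> list[str]:
        return list(self.counts.columns.get_level_values(0).unique())

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "InsertionCountTable":
        """Build from a long table with columns gene, condition, replicate, count."""
        wide = df.pivot_table(
            index="gene", columns=["condition", "replicate"], values="count",
            aggfunc="sum", fill_value=0,
        )
        return cls(counts=wide)


def normalize_insertion_counts(table: InsertionCountTable) -> pd.DataFrame:
    """Counts per million of the library, replicate structure preserved."""
    sizes = table.library_sizes
    if (sizes <= 0).any():
        bad = list(sizes[sizes <= 0].index)
        raise ValueError(f"zero library size for column(s) {bad}")
    return table.counts / sizes * 1e6


def _pooled_proportion_p(c1: float, n1: float, c2: float, n2: float) -> float:
    """Two-sided two-proportion z-test; degenerate cases map to p = 1."""
    if c1 + c2 == 0 or (c1 == n1 and c2 == n2):
        return 1.0
    if c1 / n1 == c2 / n2:
        return 1.0
    _, p = proportions_ztest([c1, c2], [n1, n2], alternative="two-sided")
    return float(p) if np.isfinite(p) else 1.0


def compute_enrichment(
    table: InsertionCountTable,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    infected: str = "infected",
    control: str = "control",
) -> pd.DataFrame:
    """Per-gene log2 fold change, p-value and BH q-value.

    log2FC = log2(mean CPM infected + pseudocount)
           − log2(mean CPM control + pseudocount); p-values come from a
    pooled two-proportion z-test (gene counts vs library sizes, replicates
    pooled per condition); q-values are Benjamini–Hochberg over all genes.
    Genes absent from one condition count as zero there.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    for cond in (infected, control):
        if cond not in table.conditions:
            raise ValueError(f"condition {cond!r} not in table {table.conditions}")

    cpm = normalize_insertion_counts(table)
    mean_inf = cpm[infected].mean(axis=1)
    mean_ctl = cpm[control].mean(axis=1)
    log2fc = np.log2(mean_inf + pseudocount) - np.log2(mean_ctl + pseudocount)

    pooled_inf = table.counts[infected].sum(axis=1)
    pooled_ctl = table.counts[control].sum(axis=1)
    n_inf = float(table.library_sizes[infected].sum())
    n_ctl = float(table.library_sizes[control].sum())
    pvals = np.array([
        _pooled_proportion_p(ci, n_inf, cc, n_ctl)
        for ci, cc in zip(pooled_inf, pooled_ctl)
    ])
    qvals = multipletests(pvals, method="fdr_bh")[1]

    return pd.DataFrame(
        {"gene": table.genes, "log2fc": log2fc.to_numpy(),
         "p": pvals, "q": qvals}
    ).sort_values("log2fc", ascending=False, kind="stable").reset_index(drop=True)


def read_count_table(path) -> InsertionCountTable:
    """Read a long-format per-gene count TSV (gene, condition, replicate, count)."""
    df = pd.read_csv(path, sep="\t" if str(path).endswith(".tsv") else ",")
    missing = {"gene", "condition", "replicate", "count"} - set(df.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    return InsertionCountTable.from_long(df)
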