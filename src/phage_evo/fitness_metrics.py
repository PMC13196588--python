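"""Fitness-cost metrics from count data.

Three standard readouts of the cost (or mechanism) of phage resistance:

* **Competition fitness W** — two strains co-cultured for 24 h; W is the
  ratio of their log fold-changes, ``W = ln(T_R24/T_R0) / ln(T_S24/T_S0)``,
  with the 24 h split of the total density inferred from phenotyping a
  sample of colonies (plaque-forming colonies are the phage-sensitive
  wild type).
* **Efficiency of plating (EOP)** — phage titer on a test strain divided
  by the titer on the wild-type host; 0 (no plaques) flags a receptor.
* **Adsorption rate** — fraction of input phage bound to cells after a
  fixed incubation, from the residual free-phage titer.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


class FitnessUndefinedError(ValueError):
    """The fitness ratio is undefined for this assay (log of a non-positive
    fold-change, or a zero proportion without continuity correction)."""


@dataclass(frozen=True)
class CompetitionAssay:
    """One replicate of a resistant-vs-wild-type competition.

    ``colonies_wt`` counts the plaque-forming (phage-sensitive) colonies
    among ``colonies_sampled`` picked at 24 h.
    """

    t0_resistant: float
    t0_wt: float
    t24_total: float
    colonies_sampled: int
    colonies_wt: int

    def __post_init__(self) -> None:
        if self.t0_resistant <= 0 or self.t0_wt <= 0:
            raise ValueError("initial densities must be positive")
        if not 0 <= self.colonies_wt <= self.colonies_sampled:
            raise ValueError("colonies_wt must be within [0, colonies_sampled]")


@dataclass(frozen=True)
class TiterPair:
    """Test and reference phage titers with the plating detection limit."""

    test_titer: float
    reference_titer: float
    detection_limit: float = 0.0


@dataclass(frozen=True)
class EOPResult:
    value: float
    below_detection: bool
    upper_bound: float | None = None


def competition_fitness(assay: CompetitionAssay, correction: bool = True) -> float:
    """Relative competitive fitness W of the resistant strain.

    The resistant proportion at 24 h is estimated from the colony sample;
    when the split is 0/n or n/n and ``correction`` is enabled, 0.5 is
    added to both phenotype cells (Haldane–Anscombe) so both log
    fold-changes stay finite.
    """
    if assay.colonies_sampled <= 0:
        raise ValueError("colonies_sampled must be positive")
    if assay.t24_total <= 0:
        raise ValueError("t24_total must be positive")

    n_res = assay.colonies_sampled - assay.colonies_wt
    n_wt = assay.colonies_wt
    if n_res == 0 or n_wt == 0:
        if not correction:
            raise FitnessUndefinedError(
                "one phenotype absent from the colony sample; enable the "
                "continuity correction or sample more colonies"
            )
        n_res += 0.5
        n_wt += 0.5
    p_res = n_res / (n_res + n_wt)

    t24_res = p_res * assay.t24_total
    t24_wt = (1.0 - p_res) * assay.t24_total
    denom = math.log(t24_wt / assay.t0_wt)
    if denom <= 0:
        raise FitnessUndefinedError(
            "wild-type fold-change <= 1; competition fitness undefined"
        )
    return math.log(t24_res / assay.t0_resistant) / denom


def efficiency_of_plating(tp: TiterPair) -> EOPResult:
    """EOP = test titer / reference titer.

    A zero test titer (no plaques) yields EOP 0 with the below-detection
    flag set and the upper bound ``detection_limit / reference_titer``
    recorded.
    """
    if tp.reference_titer <= 0:
        raise ValueError("reference titer must be positive")
    if tp.test_titer < 0:
        raise ValueError("test titer must be non-negative")
    if tp.test_titer == 0:
        return EOPResult(
            value=0.0,
            below_detection=True,
            upper_bound=tp.detection_limit / tp.reference_titer,
        )
    return EOPResult(value=tp.test_titer / tp.reference_titer, below_detection=False)


def adsorption_rate(initial_titer: float, free_titer: float) -> float:
    """Fraction of phage adsorbed: (initial - free) / initial, in [0, 1].

    Free titers exceeding the input (titration noise) clamp to 0 with a
    warning.
    """
    if initial_titer <= 0:
        raise ValueError("initial titer must be positive")
    if free_titer < 0:
        raise ValueError("free titer must be non-negative")
    rate = (initial_titer - free_titer) / initial_titer
    if rate < 0:
        warnings.warn(
            "free titer exceeds initial titer (measurement noise); rate clamped to 0",
            stacklevel=2,
        )
        return 0.0
    return min(rate, 1.0)


def read_competition_table(path) -> list[CompetitionAssay]:
    """Read competition assays from CSV (t0_r, t0_s, t24_total, n_sampled, n_wt)."""
    df = pd.read_csv(path, sep="\t" if str(path).endswith(".tsv") else ",")
    return [
        CompetitionAssay(
            t0_resistant=float(r.t0_r),
            t0_wt=float(r.t0_s),
            t24_total=float(r.t24_total),
            colonies_sampled=int(r.n_sampled),
            colonies_wt=int(r.n_wt),
        )
        for r in df.itertuples()
    ]


def summarize_competition(assays, correction: bool = True) -> pd.DataFrame:
    """Per-assay W values with a flag for undefined replicates."""
    rows = []
    for i, assay in enumerate(assays):
        try:
            rows.append({"replicate": i, "W": competition_fitness(assay, correction),
                         "undefined": False})
        except FitnessUndefinedError:
            rows.append({"replicate": i, "W": np.nan, "undefined": True})
    return pd.DataFrame(rows)
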