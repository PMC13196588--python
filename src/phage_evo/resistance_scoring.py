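"""Relative bacterial growth (RBG) scoring and resistance classification.

The RBG statistic quantifies the strength of phage resistance of a strain
from a paired endpoint absorbance assay: the OD600 gain over the assay
window with phage, divided by the gain of the no-phage control,

    RBG = [Abs600(t_end) - Abs600(t_0)]_phage / [Abs600(t_end) - Abs600(t_0)]_control

so 0 means complete sensitivity (no growth under phage) and 1 complete
resistance (growth equal to the control). Across many strain x phage
interactions the distribution of mean RBG is strongly bimodal; the module
calibrates class boundaries by kernel density estimation — locating the
two major density modes and the valley between them — and assesses the
stability of the valley by bootstrap, turning the 95% CI into sensitive /
intermediate / resistant class bounds. Cross-resistance between phages
grouped by their host receptor is then summarised from the classified
interaction matrix, and strain profiles are ordered by hierarchical
clustering.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats
from scipy.cluster import hierarchy

RESISTANT = "resistant"
INTERMEDIATE = "intermediate"
SENSITIVE = "sensitive"


class UndefinedRBGError(ValueError):
    """Control well did not grow; the RBG ratio is undefined."""


class UnimodalityError(ValueError):
    """Fewer than two density peaks; no threshold can be calibrated."""


@dataclass(frozen=True)
class InteractionMeasurement:
    """One replicate of a strain x phage endpoint absorbance assay."""

    strain_id: str
    selecting_phage: str
    focal_phage: str
    replicate: int
    abs_start_phage: float
    abs_end_phage: float
    abs_start_ctrl: float
    abs_end_ctrl: float
    endpoint_h: float = 8.0


@dataclass
class RBGMatrix:
    """Strain x phage grid of mean RBG with replicate backing.

    ``values`` holds per-cell replicate means (NaN marks a missing cell);
    ``replicate_values`` is the long-format per-replicate table.
    """

    strains: list[str]
    phages: list[str]
    values: pd.DataFrame
    replicate_values: pd.DataFrame
    receptor_of_phage: dict[str, str]
    selecting_phage_of_strain: dict[str, str]


@dataclass(frozen=True)
class ThresholdCalibration:
    """KDE peaks, valley, bootstrap CI and derived class boundaries."""

    peak_low: float
    peak_high: float
    valley: float
    ci_low: float
    ci_high: float
    class_bounds: tuple[float, float]
    n_boot: int
    bandwidth: float

    @property
    def sensitive_max(self) -> float:
        return self.class_bounds[0]

    @property
    def resistant_min(self) -> float:
        return self.class_bounds[1]


def compute_rbg(m: InteractionMeasurement) -> float:
    """RBG of one measurement: phage-well OD gain over control OD gain.

    A negative numerator (lysis below the inoculum density) is clamped to
    0 — semantically complete sensitivity — with a warning; values above
    1 are preserved.
    """
    ctrl_growth = m.abs_end_ctrl - m.abs_start_ctrl
    if ctrl_growth <= 0:
        raise UndefinedRBGError(
            f"control growth {ctrl_growth:.4f} <= 0 for strain {m.strain_id}, "
            f"phage {m.focal_phage}"
        )
    numerator = m.abs_end_phage - m.abs_start_phage
    if numerator < 0:
        warnings.warn(
            f"negative phage-well growth for {m.strain_id} x {m.focal_phage}; "
            "clamped to 0",
            stacklevel=2,
        )
        numerator = 0.0
    return numerator / ctrl_growth


def build_rbg_matrix(
    measurements: Iterable[InteractionMeasurement],
    receptor_map: Mapping[str, str],
) -> RBGMatrix:
    """Aggregate replicate measurements into a strain x phage mean-RBG grid.

    Missing cells stay NaN (absent, not zero). Duplicate
    (strain, phage, replicate) rows raise.
    """
    rows = []
    seen = set()
    selecting: dict[str, str] = {}
    for m in measurements:
        key = (m.strain_id, m.focal_phage, m.replicate)
        if key in seen:
            raise ValueError(f"duplicate measurement for {key}")
        seen.add(key)
        selecting[m.strain_id] = m.selecting_phage
        rows.append(
            {
                "strain": m.strain_id,
                "phage": m.focal_phage,
                "replicate": m.replicate,
                "rbg": compute_rbg(m),
            }
        )
    if not rows:
        raise ValueError("no measurements supplied")
    long = pd.DataFrame(rows)
    values = long.pivot_table(
        index="strain", columns="phage", values="rbg", aggfunc="mean"
    )
    # preserve first-appearance order rather than pivot's lexical order
    strain_order = list(dict.fromkeys(long["strain"]))
    phage_order = list(dict.fromkeys(long["phage"]))
    values = values.reindex(index=strain_order, columns=phage_order)
    return RBGMatrix(
        strains=strain_order,
        phages=phage_order,
        values=values,
        replicate_values=long,
        receptor_of_phage=dict(receptor_map),
        selecting_phage_of_strain=selecting,
    )


def _kde_peaks_valley(
    values: np.ndarray,
    bw_method,
    grid_size: int,
    prominence_frac: float,
):
    """Gaussian-KDE density, its two major modes and the valley between.

    Returns (peak_low, peak_high, valley, bandwidth). Raises
    :class:`UnimodalityError` when fewer than two peaks clear the
    prominence threshold. On a flat valley plateau the midpoint of the
    argmin set is taken.
    """
    kde = stats.gaussian_kde(values, bw_method=bw_method)
    bandwidth = float(kde.factor * values.std(ddof=1))
    # pad the evaluation window 3 bandwidths beyond the data range (as R's
    # density() does) so modes near the extremes keep their full prominence
    grid = np.linspace(values.min() - 3 * bandwidth,
                       values.max() + 3 * bandwidth, grid_size)
    density = kde(grid)
    peaks, _ = signal.find_peaks(density, prominence=prominence_frac * density.max())
    if len(peaks) < 2:
        raise UnimodalityError(
            f"found {len(peaks)} density peak(s); need two to place a threshold"
        )
    top_two = peaks[np.argsort(density[peaks])[-2:]]
    i_lo, i_hi = sorted(top_two)
    between = density[i_lo + 1 : i_hi]
    if len(between) == 0:
        raise UnimodalityError("no grid points between the two peaks")
    argmins = np.flatnonzero(between == between.min())
    valley_idx = i_lo + 1 + argmins[len(argmins) // 2]
    return float(grid[i_lo]), float(grid[i_hi]), float(grid[valley_idx]), bandwidth


def kde_valley(
    values: Sequence[float],
    bw_method: str | float = "silverman",
    grid_size: int = 512,
    prominence_frac: float = 0.01,
) -> float:
    """Valley of the RBG density between its two major modes (no bootstrap)."""
    values = np.asarray(values, dtype=float)
    return _kde_peaks_valley(values, bw_method, grid_size, prominence_frac)[2]


def calibrate_thresholds(
    rbg_values: Sequence[float],
    n_boot: int = 1000,
    seed: int = 0,
    bw_method: str | float = "silverman",
    grid_size: int = 512,
    prominence_frac: float = 0.01,
) -> ThresholdCalibration:
    """Calibrate sensitive/resistant class bounds from mean RBG values.

    Fits a Gaussian KDE (rule-of-thumb bandwidth) on a ``grid_size``-point
    grid over [min, max], keeps the two highest local maxima with
    prominence >= ``prominence_frac`` of the peak density, and takes the
    density argmin strictly between them as the threshold valley. The
    valley is bootstrapped (resampling with replacement, same procedure)
    for a percentile 95% CI; class bounds are the CI rounded outward to
    two decimals: (floor(ci_low, 2), ceil(ci_high, 2)).

    Requires at least 50 non-negative values. Bootstrap resamples whose
    density is unimodal are dropped from the percentile computation.
    """
    values = np.asarray(rbg_values, dtype=float)
    if len(values) < 50:
        raise ValueError(f"need >= 50 RBG values, got {len(values)}")
    if np.any(values < 0) or not np.all(np.isfinite(values)):
        raise ValueError("RBG values must be finite and non-negative")

    peak_low, peak_high, valley, bandwidth = _kde_peaks_valley(
        values, bw_method, grid_size, prominence_frac
    )

    rng = np.random.default_rng(seed)
    boot_valleys = []
    for _ in range(n_boot):
        sample = rng.choice(values, size=len(values), replace=True)
        try:
            boot_valleys.append(
                _kde_peaks_valley(sample, bw_method, grid_size, prominence_frac)[2]
            )
        except UnimodalityError:
            continue
    if boot_valleys:
        ci_low, ci_high = np.percentile(boot_valleys, [2.5, 97.5])
        ci_low = min(float(ci_low), valley)
        ci_high = max(float(ci_high), valley)
    else:
        ci_low = ci_high = valley

    class_bounds = (
        math.floor(ci_low * 100) / 100,
        math.ceil(ci_high * 100) / 100,
    )
    return ThresholdCalibration(
        peak_low=peak_low,
        peak_high=peak_high,
        valley=valley,
        ci_low=ci_low,
        ci_high=ci_high,
        class_bounds=class_bounds,
        n_boot=n_boot,
        bandwidth=bandwidth,
    )


def classify_resistance(rbg: float, cal: ThresholdCalibration) -> str:
    """Classify a mean RBG: sensitive (<= lower bound), resistant
    (>= upper bound), intermediate otherwise. Boundaries are inclusive on
    the outer classes."""
    if rbg <= cal.sensitive_max:
        return SENSITIVE
    if rbg >= cal.resistant_min:
        return RESISTANT
    return INTERMEDIATE


def cross_resistance_summary(
    matrix: RBGMatrix,
    cal: ThresholdCalibration,
    group_rule: Literal["all", "any"] = "all",
) -> pd.DataFrame:
    """Receptor-group level cross-resistance percentages.

    For each ordered pair of receptor groups (source != target): the
    denominator counts strains selected by a source-group phage that are
    resistant to their own focal (selecting) phage; the numerator counts
    those also resistant to the target group's phages — to every phage of
    the group under rule ``"all"``, to at least one under ``"any"``.
    Intermediate interactions do not count as resistant. Percentages are
    reported to one decimal; an empty denominator yields NaN with the
    ``undefined`` flag set, never 0.
    """
    if group_rule not in ("all", "any"):
        raise ValueError(f"unknown group_rule {group_rule!r}")
    receptor = matrix.receptor_of_phage
    missing = [p for p in matrix.phages if p not in receptor]
    if missing:
        raise ValueError(f"phages missing from receptor map: {missing}")

    def is_resistant(strain: str, phage: str) -> bool:
        value = matrix.values.at[strain, phage]
        return (not pd.isna(value)) and classify_resistance(value, cal) == RESISTANT

    groups = sorted(set(receptor[p] for p in matrix.phages))
    phages_of = {g: [p for p in matrix.phages if receptor[p] == g] for g in groups}

    rows = []
    for source in groups:
        focal_resistant = [
            s
            for s in matrix.strains
            if receptor.get(matrix.selecting_phage_of_strain.get(s, ""), None) == source
            and is_resistant(s, matrix.selecting_phage_of_strain[s])
        ]
        for target in groups:
            if target == source:
                continue
            combine = all if group_rule == "all" else any
            numerator = sum(
                combine(is_resistant(s, p) for p in phages_of[target])
                for s in focal_resistant
            )
            denominator = len(focal_resistant)
            percent = (
                round(100.0 * numerator / denominator, 1) if denominator else np.nan
            )
            rows.append(
                {
                    "source_group": source,
                    "target_group": target,
                    "percent": percent,
                    "numerator": numerator,
                    "denominator": denominator,
                    "undefined": denominator == 0,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ClusterResult:
    """Row ordering and linkage from hierarchical clustering of strains."""

    order: list[str]
    linkage: np.ndarray | None
    newick: str | None
    note: str | None = None
    imputed: bool = False


def _to_newick(node, labels) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _to_newick(node.get_left(), labels)
    right = _to_newick(node.get_right(), labels)
    return f"({left},{right}):{node.dist:.6g}"


def cluster_rbg_matrix(matrix: RBGMatrix) -> ClusterResult:
    """Order strain rows by agglomerative clustering (Euclidean, average
    linkage). Missing cells are imputed with the per-phage mean (flagged).
    Deterministic given input order; with < 2 rows the trivial ordering is
    returned with a note."""
    values = matrix.values.copy()
    imputed = False
    if values.isna().any().any():
        imputed = True
        warnings.warn("missing RBG cells imputed with per-phage means", stacklevel=2)
        values = values.fillna(values.mean(axis=0))
    if len(values) < 2:
        return ClusterResult(
            order=list(values.index),
            linkage=None,
            newick=None,
            note="fewer than 2 strains; trivial ordering",
            imputed=imputed,
        )
    linkage = hierarchy.linkage(values.to_numpy(), method="average", metric="euclidean")
    order_idx = hierarchy.leaves_list(linkage)
    labels = list(values.index)
    tree = hierarchy.to_tree(linkage)
    newick = _to_newick(tree, labels) + ";"
    return ClusterResult(
        order=[labels[i] for i in order_idx],
        linkage=linkage,
        newick=newick,
        imputed=imputed,
    )


def read_interaction_table(path) -> list[InteractionMeasurement]:
    """Read endpoint-absorbance measurements from CSV.

    Expected columns: strain, selecting_phage, focal_phage, replicate,
    a0_phage, a8_phage, a0_ctrl, a8_ctrl and optionally endpoint_h.
    """
    df = pd.read_csv(path, sep="\t" if str(path).endswith(".tsv") else ",")
    required = {
        "strain",
        "selecting_phage",
        "focal_phage",
        "replicate",
        "a0_phage",
        "a8_phage",
        "a0_ctrl",
        "a8_ctrl",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"interaction table missing columns: {sorted(missing)}")
    return [
        InteractionMeasurement(
            strain_id=str(r.strain),
            selecting_phage=str(r.selecting_phage),
            focal_phage=str(r.focal_phage),
            replicate=int(r.replicate),
            abs_start_phage=float(r.a0_phage),
            abs_end_phage=float(r.a8_phage),
            abs_start_ctrl=float(r.a0_ctrl),
            abs_end_ctrl=float(r.a8_ctrl),
            endpoint_h=float(getattr(r, "endpoint_h", 8.0)),
        )
        for r in df.itertuples()
    ]
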