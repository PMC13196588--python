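"""Plate-reader growth-curve kinetics.

Parses long-format OD600 time series and reduces each curve to the kinetic
summaries used downstream for fitness and phage-inhibition analyses: the
maximum specific growth rate (mu_max, per hour), the area under the curve
(AUC, OD·h), and the raw endpoint OD change over a configured assay window.

mu_max is estimated by sliding-window log-linear regression: the maximum,
over all contiguous windows of a fixed number of points, of the
least-squares slope of ln(OD − blank) against time. This is deliberately
the most transparent estimator — it can be checked exactly against a
brute-force fit of every window — rather than a parametric (logistic or
Baranyi) fit.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Floor applied to blank-corrected OD before taking logs.
OD_EPSILON = 1e-6

#: Default sliding-window length (points) for the mu_max regression.
DEFAULT_WINDOW_POINTS = 5

#: Default endpoint assay window in hours; slow growers may extend to 16 h.
DEFAULT_ENDPOINT_WINDOW = (0.0, 8.0)

#: Canonical column names for long-format growth tables.
GROWTH_COLUMNS = ("sample", "strain", "phage", "replicate", "time_h", "od600")


class SchemaError(ValueError):
    """A required column could not be resolved in an input table."""


class CurveLengthError(ValueError):
    """A growth curve is too short for the requested operation."""


@dataclass(frozen=True)
class GrowthCurve:
    """One well/condition worth of OD600 readings.

    Attributes
    ----------
    sample_id : str
        Well or sample identifier.
    strain_id : str
        Bacterial strain measured.
    phage_treatment : str or None
        Phage (or phage combination) added, ``None`` for the no-phage control.
    replicate : int
        Replicate index.
    times : ndarray
        Sampling times in hours, strictly increasing, length >= 3.
    od : ndarray
        OD600 readings, same length as ``times``.
    """

    sample_id: str
    strain_id: str
    phage_treatment: str | None
    replicate: int
    times: np.ndarray
    od: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        od = np.asarray(self.od, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "od", od)
        if times.ndim != 1 or od.ndim != 1 or len(times) != len(od):
            raise ValueError("times and od must be 1-D and equal length")
        if len(times) < 3:
            raise CurveLengthError("a growth curve needs at least 3 points")
        if not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        if not (np.all(np.isfinite(times)) and np.all(np.isfinite(od))):
            raise ValueError("times and od must be finite")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class KineticSummary:
    """Kinetic reduction of a single growth curve.

    ``no_growth`` is set when every OD reading is at or below the blank, in
    which case ``mu_max`` is reported as 0.
    """

    mu_max: float
    auc: float
    endpoint_delta: float
    window_used: tuple[float, float]
    no_growth: bool = False


def read_growth_table(
    path, schema: Mapping[str, str] | None = None
) -> list[GrowthCurve]:
    """Read a long-format growth table into :class:`GrowthCurve` objects.

    Parameters
    ----------
    path : path-like
        CSV or TSV file with one row per reading. Canonical columns are
        ``sample, strain, phage, replicate, time_h, od600``; ``strain``,
        ``phage`` and ``replicate`` are optional.
    schema : mapping, optional
        Aliases mapping canonical names to the actual column headers,
        e.g. ``{"od600": "OD"}``.

    Returns
    -------
    list of GrowthCurve
        One curve per (sample, phage treatment, replicate), time-sorted.
        Rows with missing OD are dropped (count logged).
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    schema = dict(schema or {})
    resolved: dict[str, str] = {}
    for canonical in GROWTH_COLUMNS:
        actual = schema.get(canonical, canonical)
        if actual in df.columns:
            resolved[canonical] = actual
    for required in ("sample", "time_h", "od600"):
        if required not in resolved:
            raise SchemaError(
                f"required column {required!r} not found in {path} "
                f"(available: {list(df.columns)})"
            )

    out = pd.DataFrame(
        {canon: df[actual] for canon, actual in resolved.items()}
    )
    for col in ("time_h", "od600"):
        coerced = pd.to_numeric(out[col], errors="coerce")
        bad = coerced.isna() & out[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"non-numeric {col!r} value {out[col].iloc[row]!r} at row {row}"
            )
        out[col] = coerced

    n_missing = int(out["od600"].isna().sum())
    if n_missing:
        logger.info("dropped %d rows with missing OD from %s", n_missing, path)
        out = out.dropna(subset=["od600"])

    if "strain" not in out:
        out["strain"] = out["sample"]
    if "phage" not in out:
        out["phage"] = None
    if "replicate" not in out:
        out["replicate"] = 1
    out["phage"] = out["phage"].where(pd.notna(out["phage"]), None)

    curves = []
    for (sample, phage, rep), grp in out.groupby(
        ["sample", "phage", "replicate"], dropna=False, sort=True
    ):
        grp = grp.sort_values("time_h")
        curves.append(
            GrowthCurve(
                sample_id=str(sample),
                strain_id=str(grp["strain"].iloc[0]),
                phage_treatment=None if pd.isna(phage) else str(phage),
                replicate=int(rep),
                times=grp["time_h"].to_numpy(float),
                od=grp["od600"].to_numpy(float),
            )
        )
    return curves


def _window_slopes(times: np.ndarray, log_od: np.ndarray, w: int) -> np.ndarray:
    """Least-squares slope of log_od vs times for every contiguous window."""
    n = len(times)
    slopes = np.empty(n - w + 1)
    for i in range(n - w + 1):
        t = times[i : i + w]
        y = log_od[i : i + w]
        tc = t - t.mean()
        slopes[i] = tc @ (y - y.mean()) / (tc @ tc)
    return slopes


def moving_average(values: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average with edge padding (width must be odd)."""
    if width % 2 != 1 or width < 3:
        raise ValueError("smoothing width must be an odd integer >= 3")
    padded = np.pad(np.asarray(values, dtype=float), (width // 2, width // 2),
                    mode="edge")
    return np.convolve(padded, np.ones(width) / width, mode="valid")


def summarize_kinetics(
    curve: GrowthCurve,
    blank: float = 0.0,
    window_points: int = DEFAULT_WINDOW_POINTS,
    endpoint_window: tuple[float, float] = DEFAULT_ENDPOINT_WINDOW,
    smooth_points: int = 0,
    min_od: float = 0.0,
) -> KineticSummary:
    """Compute mu_max, AUC and the endpoint OD change for one curve.

    mu_max is the maximum sliding-window log-linear slope of the
    blank-corrected series (floored at :data:`OD_EPSILON` before the log),
    clamped below at 0. AUC is the trapezoidal integral of blank-corrected
    OD with negative values clamped to 0. ``endpoint_delta`` is computed on
    the raw, uncorrected series over ``endpoint_window`` (clipped to the
    sampled range).

    ``smooth_points`` (odd width moving average applied before the log)
    and ``min_od`` (windows must keep the blank-corrected OD at or above
    this floor) are off by default; both tame the inflation of log-slopes
    by additive measurement noise at optical densities near the detection
    floor, at the cost of a small saturation bias, and are recommended for
    noisy data. When no window clears ``min_od`` the filter is ignored.
    """
    if blank < 0:
        raise ValueError("blank must be >= 0")
    if window_points < 3:
        raise ValueError("window_points must be >= 3")
    if window_points > len(curve):
        raise CurveLengthError(
            f"curve has {len(curve)} points, fewer than window_points={window_points}"
        )

    corrected = curve.od - blank
    no_growth = bool(np.all(corrected <= 0))
    if no_growth:
        warnings.warn(
            f"all OD <= blank for {curve.sample_id}; mu_max set to 0",
            stacklevel=2,
        )
        mu_max = 0.0
    else:
        series = moving_average(corrected, smooth_points) if smooth_points else corrected
        log_od = np.log(np.maximum(series, OD_EPSILON))
        slopes = _window_slopes(curve.times, log_od, window_points)
        if min_od > 0:
            w = window_points
            eligible = np.array([
                series[i : i + w].min() >= min_od for i in range(len(slopes))
            ])
            if eligible.any():
                slopes = slopes[eligible]
        mu_max = float(max(slopes.max(), 0.0))

    auc = float(np.trapezoid(np.maximum(corrected, 0.0), curve.times))

    lo, hi = endpoint_window
    inside = (curve.times >= lo) & (curve.times <= hi)
    if not inside.any():
        raise ValueError(f"endpoint window {endpoint_window} outside sampled times")
    idx = np.flatnonzero(inside)
    endpoint_delta = float(curve.od[idx[-1]] - curve.od[idx[0]])
    window_used = (float(curve.times[idx[0]]), float(curve.times[idx[-1]]))

    return KineticSummary(
        mu_max=mu_max,
        auc=auc,
        endpoint_delta=endpoint_delta,
        window_used=window_used,
        no_growth=no_growth,
    )


def relative_growth_rate(mutant: KineticSummary, wildtype: KineticSummary) -> float:
    """Relative fitness of a mutant: mutant mu_max over wild-type mu_max."""
    if wildtype.mu_max <= 0:
        raise ZeroDivisionError("wild-type mu_max is 0; relative rate undefined")
    return mutant.mu_max / wildtype.mu_max


def welch_test(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Welch t-test p-value, defined for degenerate groups.

    Zero-variance groups (where the Welch statistic is undefined) map to
    p = 1 for equal means and p = 0 otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def compare_groups_auc(
    groups: Mapping[str, Sequence[float]], bh_correct: bool = False
) -> pd.DataFrame:
    """Pairwise Welch comparison of AUC values between treatment groups.

    Returns one row per ordered pair of distinct groups with the mean
    difference (A − B) and the raw two-sided Welch p-value; a ``q``
    column (Benjamini–Hochberg over the unordered pairs) is added when
    ``bh_correct`` is set.
    """
    for name, values in groups.items():
        if len(values) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
    rows = []
    pair_p: dict[frozenset, float] = {}
    for a, b in itertools.permutations(groups, 2):
        key = frozenset((a, b))
        if key not in pair_p:
            pair_p[key] = welch_test(groups[a], groups[b])
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "mean_diff": float(np.mean(groups[a]) - np.mean(groups[b])),
                "p_value": pair_p[key],
            }
        )
    table = pd.DataFrame(rows)
    if bh_correct and len(table):
        from statsmodels.stats.multitest import multipletests

        table["q_value"] = multipletests(table["p_value"], method="fdr_bh")[1]
    return table


def write_kinetics_table(summaries: Mapping[str, KineticSummary], path) -> None:
    """Write per-sample kinetic summaries as TSV."""
    rows = [
        {
            "sample": sample,
            "mu_max": s.mu_max,
            "auc": s.auc,
            "endpoint_delta": s.endpoint_delta,
            "window_start_h": s.window_used[0],
            "window_end_h": s.window_used[1],
            "no_growth": s.no_growth,
        }
        for sample, s in summaries.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
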