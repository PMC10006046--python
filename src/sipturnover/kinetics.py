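"""Incorporation kinetics: exponential and Gompertz fits, group curves.

The exponential cumulative model

    LR(t) = a - exp(-k * t)

is fitted to every compound's labeling-ratio series by bounded
nonlinear least squares with multi-start initialization; ``k`` (1/d) is
the turnover rate and ``a`` the asymptote. Sigmoidal (delayed) series,
typical for proteins, are additionally described by the Gompertz curve

    LR(t) = a * exp(-exp(b - c * t))

whose rate equivalent is its maximum specific slope ratio ``c / e``.

Group-level trajectories aggregate many compounds per timepoint with
either the sample standard deviation or the 95% confidence interval of
the mean as dispersion band; two groups are compared by per-timepoint
interval overlap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .sbr import LRSeries
from . import io as _io

#: Optimizer box constraints: LR is a fraction, and rates far above the
#: fastest storage-polymer turnover observed here are unphysical.
A_BOUNDS = (1e-9, 1.2)
K_BOUNDS = (1e-9, 5.0)


@dataclass(frozen=True)
class FitResult:
    """Kinetic regression result for one compound.

    For the Gompertz model, ``k`` holds the rate equivalent ``c / e``
    and ``b``, ``c`` the shape parameters; for the exponential model
    ``b`` and ``c`` are ``None``.
    """

    model: str
    a: float
    k: float
    r_squared: float
    converged: bool
    n_points: int
    b: float | None = None
    c: float | None = None
    reason: str = ""

    def __post_init__(self) -> None:
        if self.converged:
            if self.k < 0:
                raise ValueError("converged fit must have k >= 0")
            if self.r_squared > 1 + 1e-12:
                raise ValueError("r_squared cannot exceed 1")


def _as_series(series: LRSeries | pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(series, LRSeries):
        return series.time_days, series.lr
    t = np.asarray(series["time_days"], dtype=float)
    y = np.asarray(series["lr"], dtype=float)
    return t, y


def _r_squared(y: np.ndarray, pred: np.ndarray) -> float:
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - ss_res / ss_tot


def eq1_curve(t: np.ndarray, a: float, k: float, form: str = "printed") -> np.ndarray:
    """Exponential incorporation model in either parameterization."""
    if form == "printed":
        return a - np.exp(-k * t)
    if form == "saturating":
        return a * (1.0 - np.exp(-k * t))
    raise ValueError(f"unknown form {form!r}")


def gompertz_curve(t: np.ndarray, a: float, b: float, c: float) -> np.ndarray:
    return a * np.exp(-np.exp(b - c * t))


def _multistart_lsq(residual, starts, bounds):
    best = None
    for x0 in starts:
        try:
            res = least_squares(
                residual, x0, bounds=bounds, method="trf",
                xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=2000,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    return best


def fit_eq1(
    series: LRSeries | pd.DataFrame,
    *,
    form: str = "printed",
    k_inits: tuple[float, ...] | None = None,
    srt_days: float = 7.55,
) -> FitResult:
    """Fit the exponential incorporation model to one LR series.

    Multi-start initialization at k0 in {1, 2, 4}/SRT and
    a0 = max(LR) + (1 - max(LR))/2; a degenerate (constant) series
    yields ``converged=False`` rather than an exception, since R^2 is
    undefined there.
    """
    t, y = _as_series(series)
    n = t.size
    if n < 3:
        return FitResult("eq1", math.nan, math.nan, math.nan, False, n, reason="fewer than 3 points")
    if not np.all(np.isfinite(y)):
        raise ValueError("LR values must be finite")
    if np.ptp(y) == 0.0:
        return FitResult("eq1", math.nan, math.nan, math.nan, False, n, reason="degenerate")

    if k_inits is None:
        k_inits = (1.0 / srt_days, 2.0 / srt_days, 4.0 / srt_days)
    ymax = float(y.max())
    a0 = min(max(ymax + (1.0 - ymax) / 2.0, A_BOUNDS[0] * 2), A_BOUNDS[1])

    def residual(x):
        return eq1_curve(t, x[0], x[1], form) - y

    best = _multistart_lsq(
        residual,
        [np.array([a0, max(min(k0, K_BOUNDS[1] * 0.99), K_BOUNDS[0] * 2)]) for k0 in k_inits],
        (np.array([A_BOUNDS[0], K_BOUNDS[0]]), np.array([A_BOUNDS[1], K_BOUNDS[1]])),
    )
    if best is None or not best.success:
        return FitResult("eq1", math.nan, math.nan, math.nan, False, n, reason="optimizer failure")
    a, k = best.x
    return FitResult("eq1", float(a), float(k), _r_squared(y, eq1_curve(t, a, k, form)), True, n)


def fit_gompertz(series: LRSeries | pd.DataFrame) -> FitResult:
    """Fit the Gompertz sigmoid to one LR series.

    Reports the rate equivalent ``k = c / e`` (the curve's maximum
    slope is ``a * c / e``, attained at ``t = b / c``) so sigmoidal and
    exponential fits can be compared on one axis.
    """
    t, y = _as_series(series)
    n = t.size
    if n < 4:
        return FitResult("gompertz", math.nan, math.nan, math.nan, False, n, reason="fewer than 4 points")
    if not np.all(np.isfinite(y)):
        raise ValueError("LR values must be finite")
    if np.ptp(y) == 0.0:
        return FitResult("gompertz", math.nan, math.nan, math.nan, False, n, reason="degenerate")

    ymax = float(y.max())
    a0 = min(max(ymax + (1.0 - ymax) / 2.0, 0.05), A_BOUNDS[1])
    starts = [
        np.array([a0, b0, c0])
        for b0 in (0.5, 1.0, 2.0)
        for c0 in (0.3, 0.9, 2.0)
    ]

    def residual(x):
        return gompertz_curve(t, x[0], x[1], x[2]) - y

    best = _multistart_lsq(
        residual,
        starts,
        (np.array([A_BOUNDS[0], -10.0, 1e-6]), np.array([A_BOUNDS[1], 20.0, 20.0])),
    )
    if best is None or not best.success:
        return FitResult("gompertz", math.nan, math.nan, math.nan, False, n, reason="optimizer failure")
    a, b, c = best.x
    return FitResult(
        "gompertz",
        float(a),
        float(c / math.e),
        _r_squared(y, gompertz_curve(t, a, b, c)),
        True,
        n,
        b=float(b),
        c=float(c),
    )


@dataclass(frozen=True)
class GroupTrajectory:
    """Mean labeling-ratio trajectory of a compound group with dispersion."""

    label: str
    time_days: np.ndarray
    mean: np.ndarray
    dispersion: np.ndarray
    n: np.ndarray
    dispersion_kind: str

    def __post_init__(self) -> None:
        if np.any(self.dispersion < 0):
            raise ValueError("dispersion must be >= 0")
        if np.any(self.n < 1):
            raise ValueError("every timepoint needs at least one member")


def group_trajectory(
    lr_table: pd.DataFrame,
    label: str = "",
    dispersion: str = "sd",
    value_column: str = "lr",
) -> GroupTrajectory:
    """Per-timepoint mean and dispersion of many compound LR series.

    ``dispersion`` is either ``"sd"`` (sample standard deviation, zero
    for a single member) or ``"ci95"`` (t-based 95% confidence
    half-width of the mean, requiring at least two members at every
    timepoint).
    """
    _io.require_columns(lr_table, ["time_days", value_column], "LR table")
    if dispersion not in ("sd", "ci95"):
        raise ValueError(f"dispersion must be 'sd' or 'ci95', got {dispersion!r}")
    grouped = lr_table.groupby("time_days")[value_column]
    times = np.array(sorted(lr_table["time_days"].unique()), dtype=float)
    means = grouped.mean().reindex(times).to_numpy()
    counts = grouped.count().reindex(times).to_numpy()
    sds = grouped.std(ddof=1).reindex(times).to_numpy()
    sds = np.where(counts > 1, sds, 0.0)
    if dispersion == "sd":
        band = sds
    else:
        bad = times[counts < 2]
        if bad.size:
            raise ValueError(
                f"ci95 requires >= 2 members per timepoint; offending timepoint(s): {bad.tolist()}"
            )
        tq = stats.t.ppf(0.975, counts - 1)
        band = tq * sds / np.sqrt(counts)
    return GroupTrajectory(label, times, means, band, counts.astype(int), dispersion)


@dataclass(frozen=True)
class OverlapReport:
    """Per-timepoint interval-overlap comparison of two group curves."""

    time_days: np.ndarray
    overlaps: np.ndarray
    overlap_fraction: float
    verdict: str


def compare_groups(
    g1: GroupTrajectory, g2: GroupTrajectory, *, no_difference_threshold: float = 0.9
) -> OverlapReport:
    """Do two group trajectories overlap within their dispersion bands?

    Intervals ``mean +- band`` intersect per timepoint; the summary is
    the overlapping fraction of timepoints and the verdict is "no
    difference detected" when that fraction reaches the threshold
    (default 0.9).
    """
    if g1.time_days.size != g2.time_days.size or np.any(g1.time_days != g2.time_days):
        raise ValueError("group trajectories must share the same time grid")
    lo1, hi1 = g1.mean - g1.dispersion, g1.mean + g1.dispersion
    lo2, hi2 = g2.mean - g2.dispersion, g2.mean + g2.dispersion
    overlaps = (lo1 <= hi2) & (lo2 <= hi1)
    fraction = float(overlaps.mean())
    verdict = (
        "no difference detected" if fraction >= no_difference_threshold else "difference detected"
    )
    return OverlapReport(g1.time_days, overlaps, fraction, verdict)


def fit_table(
    lr_table: pd.DataFrame,
    value_column: str = "lr",
    *,
    gompertz_for: tuple[str, ...] = ("protein",),
) -> pd.DataFrame:
    """Fit every compound in a tidy LR table.

    All compounds get the exponential fit; compounds whose class is in
    ``gompertz_for`` additionally get a Gompertz fit. Returns one row
    per (compound, model).
    """
    _io.require_columns(lr_table, ["compound_id", "time_days", value_column], "LR table")
    has_class = "compound_class" in lr_table.columns
    rows = []
    for cid, grp in lr_table.groupby("compound_id", sort=True):
        sub = grp.rename(columns={value_column: "lr"})[["time_days", "lr"]]
        cls = str(grp["compound_class"].iloc[0]) if has_class else ""
        fits = [fit_eq1(sub)]
        if cls in gompertz_for:
            fits.append(fit_gompertz(sub))
        for fr in fits:
            rows.append(
                {
                    "compound_id": cid,
                    "compound_class": cls,
                    "model": fr.model,
                    "a": fr.a,
                    "k": fr.k,
                    "b": fr.b,
                    "c": fr.c,
                    "r_squared": fr.r_squared,
                    "converged": fr.converged,
                    "n_points": fr.n_points,
                }
            )
    return pd.DataFrame(rows)
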