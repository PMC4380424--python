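"""Half-life estimation from substrate-depletion LC-MS peak areas.

A microsomal depletion experiment measures the parent compound's LC-MS peak
area (normalised by an internal standard) at a handful of incubation times.
Under first-order kinetics the log area ratio is linear in time,

    ln(A_t / IS_t) = ln r0 - k t,        t_1/2 = ln 2 / k,

so the elimination rate constant k is minus the OLS slope of the log-ratio
against time.  Depletion plots flatten late in the incubation (substrate
exhaustion, enzyme inactivation), so the fit uses only the initial linear
region: the longest window anchored at t = 0 whose OLS r-squared clears a
threshold (default 0.95).  Replicates are fitted independently and their
half-lives averaged ("fit" mode); a "pool" mode instead averages the
log-ratio curves across replicates and fits once.

Negative controls (no NADPH cofactor, hence no P450 turnover) are checked
separately: the analyte should not deplete appreciably without cofactor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "DepletionSeries",
    "FitWindow",
    "ReplicateFit",
    "HalfLifeResult",
    "ControlReport",
    "KineticsError",
    "NoDepletionError",
    "LN2",
    "log_ratio",
    "select_linear_window",
    "fit_elimination",
    "half_life",
    "estimate",
    "control_check",
]

#: ln 2 at full precision (reports round to 2 decimals, never internally).
LN2 = math.log(2.0)


class KineticsError(ValueError):
    pass


class NoDepletionError(KineticsError):
    """The log-ratio slope is non-negative: no measurable depletion."""


@dataclass
class DepletionSeries:
    """Timed analyte / internal-standard peak areas for one replicate.

    Times are minutes, strictly increasing and starting at 0; all areas
    must be positive (a vanished peak is a data error, not a measurement).
    """

    compound_id: str
    replicate: int
    times: np.ndarray
    analyte_areas: np.ndarray
    is_areas: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.analyte_areas = np.asarray(self.analyte_areas, dtype=float)
        self.is_areas = np.asarray(self.is_areas, dtype=float)
        n = len(self.times)
        if not (len(self.analyte_areas) == len(self.is_areas) == n):
            raise KineticsError("times and area vectors must have equal length")
        if n < 3:
            raise KineticsError("a depletion series needs at least 3 time points")
        if self.times[0] != 0:
            raise KineticsError("first time point must be t = 0")
        if np.any(np.diff(self.times) <= 0):
            raise KineticsError("times must be strictly increasing")


@dataclass(frozen=True)
class FitWindow:
    start: int
    end: int  # inclusive
    r2: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class ReplicateFit:
    replicate: int
    slope: float
    k: float
    r2: float
    window: FitWindow
    t_half: float
    warnings: list[str] = field(default_factory=list)


@dataclass
class HalfLifeResult:
    compound_id: str
    replicates: list[ReplicateFit]
    t_half_mean: float
    t_half_sd: float


@dataclass
class ControlReport:
    compound_id: str
    remaining_fraction: float
    depletion_fraction: float
    passed: bool


def log_ratio(series: DepletionSeries) -> tuple[np.ndarray, np.ndarray]:
    """Natural log of the analyte / internal-standard area ratio."""
    bad = np.flatnonzero(
        (series.analyte_areas <= 0) | (series.is_areas <= 0)
    )
    if bad.size:
        raise KineticsError(
            f"nonpositive peak area at t = {series.times[bad[0]]:g} min "
            f"(compound {series.compound_id}, replicate {series.replicate})"
        )
    return series.times.copy(), np.log(series.analyte_areas / series.is_areas)


def _ols(times: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(slope, r2) of an OLS fit; r2 defined as 1 for a zero-variance y."""
    if np.ptp(y) == 0:
        return 0.0, 1.0
    res = stats.linregress(times, y)
    return float(res.slope), float(res.rvalue**2)


def select_linear_window(
    times: np.ndarray,
    y: np.ndarray,
    min_points: int = 3,
    r2_min: float = 0.95,
) -> tuple[FitWindow, list[str]]:
    """Choose the initial linear region of a depletion plot.

    Candidates are contiguous windows anchored at index 0 with at least
    ``min_points`` points; the longest one with r-squared >= ``r2_min``
    wins.  If none qualifies, the minimal window is returned with a
    "nonlinear" warning so the caller can flag the fit.
    """
    n = len(times)
    if n < min_points:
        raise KineticsError(f"need at least {min_points} points, got {n}")
    best: FitWindow | None = None
    for end in range(min_points - 1, n):
        _, r2 = _ols(times[: end + 1], y[: end + 1])
        if r2 >= r2_min:
            cand = FitWindow(0, end, r2)
            if best is None or cand.length >= best.length:
                best = cand
    if best is not None:
        return best, []
    _, r2 = _ols(times[:min_points], y[:min_points])
    return (
        FitWindow(0, min_points - 1, r2),
        [f"nonlinear depletion plot: best window r2 = {r2:.4f} < {r2_min}"],
    )


def fit_elimination(
    times: np.ndarray, y: np.ndarray, window: FitWindow
) -> tuple[float, float, float]:
    """OLS fit inside the window: returns (slope, k = -slope, r2)."""
    if not (0 <= window.start < window.end < len(times)):
        raise KineticsError("fit window out of range")
    sl = slice(window.start, window.end + 1)
    slope, r2 = _ols(times[sl], y[sl])
    if slope >= 0:
        raise NoDepletionError(
            f"no measurable depletion (slope = {slope:+.4g} per min)"
        )
    return slope, -slope, r2


def half_life(k: float) -> float:
    """Half-life in minutes from the elimination rate constant (1/min)."""
    if k <= 0:
        raise KineticsError(f"elimination rate constant must be > 0, got {k:g}")
    return LN2 / k


def _fit_replicate(
    series: DepletionSeries, min_points: int, r2_min: float
) -> ReplicateFit:
    times, y = log_ratio(series)
    window, warnings = select_linear_window(times, y, min_points, r2_min)
    slope, k, r2 = fit_elimination(times, y, window)
    return ReplicateFit(series.replicate, slope, k, r2, window, half_life(k), warnings)


def estimate(
    series_list: list[DepletionSeries],
    min_points: int = 3,
    r2_min: float = 0.95,
    aggregate: str = "fit",
) -> HalfLifeResult:
    """Estimate a compound's half-life from its replicate depletion series.

    ``aggregate="fit"`` fits each replicate separately and averages the
    half-lives (sample sd across replicates; 0 for a single replicate).
    ``aggregate="pool"`` averages the log-ratio curves over replicates
    first and fits the mean curve once, mirroring plots of averaged data.
    """
    if not series_list:
        raise KineticsError("no depletion series given")
    if aggregate not in ("fit", "pool"):
        raise KineticsError(f"unknown aggregate mode {aggregate!r}")
    cid = series_list[0].compound_id
    if any(s.compound_id != cid for s in series_list):
        raise KineticsError("all series must belong to one compound")

    if aggregate == "pool" and len(series_list) > 1:
        times0, _ = log_ratio(series_list[0])
        ys = []
        for s in series_list:
            t, y = log_ratio(s)
            if not np.array_equal(t, times0):
                raise KineticsError("pool mode requires identical time grids")
            ys.append(y)
        mean_y = np.mean(ys, axis=0)
        window, warnings = select_linear_window(times0, mean_y, min_points, r2_min)
        slope, k, r2 = fit_elimination(times0, mean_y, window)
        fit = ReplicateFit(-1, slope, k, r2, window, half_life(k), warnings)
        return HalfLifeResult(cid, [fit], fit.t_half, 0.0)

    fits = []
    for s in series_list:
        try:
            fits.append(_fit_replicate(s, min_points, r2_min))
        except KineticsError as exc:
            raise KineticsError(
                f"compound {cid}, replicate {s.replicate}: {exc}"
            ) from exc
    t = np.array([f.t_half for f in fits])
    sd = float(np.std(t, ddof=1)) if len(t) > 1 else 0.0
    return HalfLifeResult(cid, fits, float(np.mean(t)), sd)


def control_check(
    series: DepletionSeries, max_depletion_fraction: float = 0.2
) -> ControlReport:
    """Validate a no-cofactor negative control.

    Without NADPH the microsomes are inactive, so the analyte/IS ratio at
    the final time point should stay close to its t = 0 value; depletion
    beyond ``max_depletion_fraction`` flags the control.
    """
    _, y = log_ratio(series)
    remaining = float(np.exp(y[-1] - y[0]))
    depletion = 1.0 - remaining
    return ControlReport(
        series.compound_id, remaining, depletion, depletion <= max_depletion_fraction
    )
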