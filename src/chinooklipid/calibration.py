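"""Fat-meter calibration: model II and segmented regression.

The handheld microwave fat meter reads tissue water content and reports a
lipid-like value for the spot under the sensor. To turn a position-1
reading into whole-body lipid content (% wet weight) the instrument is
calibrated against homogenized fish. Three regression families are
compared across the seven position combinations:

* model II regression (major-axis or standardized-major-axis) on raw
  readings — both variables carry measurement error;
* model II regression on log-transformed readings;
* continuous two-segment (segmented) least squares on raw readings — the
  meter saturates at low lipid, flattening the relationship above a
  breakpoint.

The published calibration is the position-1 segmented fit
``y = -1.973 + 6.758 x`` below the breakpoint ``psi = 1.059`` with slope
``6.758 - 6.202 = 0.556`` above it, and an instrument floor of 0.6 meter
units (the lowest reading ever recorded; it maps to roughly 2% lipid).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import reference
from .homogenate import CalibrationSample

__all__ = [
    "LinearFit",
    "PiecewiseCalibration",
    "TestResult",
    "fit_model2",
    "fit_segmented",
    "rank_calibrations",
    "predict_whole_body_lipid",
    "covariate_interaction_test",
    "sex_ancova",
]


@dataclass(frozen=True)
class LinearFit:
    """A straight-line reading→lipid fit (model II or OLS)."""

    slope: float            # % lipid per meter unit (or per log unit)
    intercept: float        # %
    method: str             # {"OLS", "MA", "SMA"}
    log_transformed_x: bool
    n: int
    r2_adj: float
    residual_se: float      # %

    def predict(self, x):
        x = np.log(np.asarray(x, dtype=float)) if self.log_transformed_x else np.asarray(x, dtype=float)
        return self.intercept + self.slope * x


@dataclass(frozen=True)
class PiecewiseCalibration:
    """Continuous two-segment reading→lipid calibration.

    Below the breakpoint ``breakpoint`` the curve is
    ``intercept + slope_below * x``; above it the slope changes by
    ``slope_change`` while staying continuous. ``floor`` is the lowest
    reading the instrument produces; readings below it are evaluated at
    the floor.
    """

    intercept: float        # %
    slope_below: float      # %/meter unit
    slope_change: float     # %/meter unit; slope above = slope_below + slope_change
    breakpoint: float       # meter units
    floor: float = 0.6      # meter units
    n: Optional[int] = None
    r2_adj: Optional[float] = None
    residual_se: Optional[float] = None
    degenerate: bool = False   # True when no admissible breakpoint was found

    def __post_init__(self) -> None:
        if not np.isfinite([self.intercept, self.slope_below, self.slope_change,
                            self.breakpoint, self.floor]).all():
            raise ValueError("calibration parameters must be finite")
        if self.floor > self.breakpoint and not self.degenerate:
            raise ValueError(
                f"floor {self.floor} exceeds breakpoint {self.breakpoint}"
            )

    @property
    def slope_above(self) -> float:
        return self.slope_below + self.slope_change

    @property
    def lipid_at_breakpoint(self) -> float:
        return self.intercept + self.slope_below * self.breakpoint

    def predict(self, reading):
        return predict_whole_body_lipid(reading, self)

    @classmethod
    def published(cls) -> "PiecewiseCalibration":
        """The published position-1 segmented calibration."""
        p = reference.PUBLISHED_CALIBRATION
        return cls(
            intercept=p["intercept"], slope_below=p["slope_below"],
            slope_change=p["slope_change"], breakpoint=p["breakpoint"],
            floor=p["floor"], n=p["n"], r2_adj=p["r2_adj"],
            residual_se=p["residual_se"],
        )


@dataclass(frozen=True)
class TestResult:
    """A hypothesis-test outcome (F, t, correlation ...)."""

    statistic: float
    df: Tuple[float, ...]
    p_value: float
    method: str
    extra: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p_value outside [0, 1]: {self.p_value}")


def predict_whole_body_lipid(reading, cal: PiecewiseCalibration):
    """Whole-body lipid (% wet weight) for a fat-meter reading.

    Readings below the instrument floor are evaluated at the floor (with a
    warning — field sheets occasionally contain them); predictions are
    clipped to [0, 100]%. Accepts scalars or arrays.
    """
    x = np.asarray(reading, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("readings must be finite")
    if np.any(x < 0):
        raise ValueError("readings must be >= 0")
    n_below = int(np.sum(x < cal.floor))
    if n_below:
        warnings.warn(
            f"{n_below} reading(s) below the instrument floor {cal.floor}; "
            "evaluated at the floor",
            stacklevel=2,
        )
    xf = np.maximum(x, cal.floor)
    below = cal.intercept + cal.slope_below * xf
    above = cal.lipid_at_breakpoint + cal.slope_above * (xf - cal.breakpoint)
    y = np.clip(np.where(xf < cal.breakpoint, below, above), 0.0, 100.0)
    return float(y) if np.isscalar(reading) or np.ndim(reading) == 0 else y


def _fit_stats(x: np.ndarray, y: np.ndarray, yhat: np.ndarray, n_params: int):
    n = len(y)
    rss = float(np.sum((y - yhat) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    df_resid = n - n_params
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / df_resid if df_resid > 0 else np.nan
    residual_se = np.sqrt(rss / df_resid) if df_resid > 0 else np.nan
    return r2_adj, residual_se


def fit_model2(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "SMA",
    log_x: bool = False,
) -> LinearFit:
    """Model II straight-line fit of lipid on fat-meter readings.

    Both axes are treated as measured with error. ``method`` selects the
    estimator:

    * ``"SMA"`` (standardized major axis): slope = sign(r) * sd(y)/sd(x).
      Appropriate when the variables are on different scales (the default).
    * ``"MA"`` (major axis): minimizes perpendicular squared distances.
    * ``"OLS"`` for comparison.

    With ``log_x`` the readings are natural-log transformed first.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d arrays")
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 points, got {n}")
    if log_x:
        if np.any(x <= 0):
            raise ValueError("log transform requires all readings > 0")
        x = np.log(x)
    sx = x.std(ddof=1)
    sy = y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in x or y")
    sxy = np.cov(x, y, ddof=1)[0, 1]
    r = sxy / (sx * sy)

    if method == "SMA":
        slope = np.sign(r if r != 0 else 1.0) * sy / sx
    elif method == "MA":
        vx, vy = sx**2, sy**2
        if sxy == 0:
            slope = 0.0 if vx > vy else np.inf
        else:
            slope = (vy - vx + np.sqrt((vy - vx) ** 2 + 4 * sxy**2)) / (2 * sxy)
    elif method == "OLS":
        slope = sxy / sx**2
    else:
        raise ValueError(f"unknown method {method!r}")
    intercept = y.mean() - slope * x.mean()
    yhat = intercept + slope * x
    r2 = r**2
    # report the squared correlation as the coefficient of determination
    # (the conventional model II summary), adjusted for 2 parameters
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    residual_se = float(np.sqrt(np.sum((y - yhat) ** 2) / (n - 2)))
    return LinearFit(
        slope=float(slope), intercept=float(intercept), method=method,
        log_transformed_x=log_x, n=n, r2_adj=float(r2_adj),
        residual_se=residual_se,
    )


def _hinge_rss(x: np.ndarray, y: np.ndarray, psi: float):
    """Profile RSS of the continuous two-segment model at breakpoint psi."""
    X = np.column_stack([np.ones_like(x), x, np.maximum(0.0, x - psi)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    return rss, beta


def fit_segmented(
    x: Sequence[float],
    y: Sequence[float],
    grid: Optional[Sequence[float]] = None,
    floor: Optional[float] = None,
    min_per_segment: int = 3,
) -> PiecewiseCalibration:
    """Continuous two-segment least-squares fit with estimated breakpoint.

    The model is the hinge parameterization
    ``y = b0 + b1*x + d*max(0, x - psi)``: both segments are estimated
    jointly and the fit is continuous at ``psi`` by construction. The
    breakpoint is found by profiling: an exhaustive search over candidate
    breakpoints (by default every midpoint between adjacent sorted unique
    readings with at least ``min_per_segment`` points on each side),
    refined by bounded scalar minimization between the neighbours of the
    best candidate.

    When no admissible breakpoint exists the single-line OLS fit is
    returned with ``slope_change = 0`` and ``degenerate=True``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d arrays")
    n = len(x)
    if n < 5:
        raise ValueError(f"need at least 5 points, got {n}")
    if floor is None:
        floor = float(np.min(x))

    xs = np.unique(x)
    if grid is None:
        mids = (xs[:-1] + xs[1:]) / 2.0
        grid = [
            psi for psi in mids
            if np.sum(x < psi) >= min_per_segment and np.sum(x > psi) >= min_per_segment
        ]
    else:
        grid = [
            psi for psi in grid
            if xs[0] < psi < xs[-1]
            and np.sum(x < psi) >= min_per_segment
            and np.sum(x > psi) >= min_per_segment
        ]

    if not grid:
        ols = fit_model2(x, y, method="OLS")
        return PiecewiseCalibration(
            intercept=ols.intercept, slope_below=ols.slope, slope_change=0.0,
            breakpoint=float(xs[-1]), floor=min(floor, float(xs[-1])), n=n,
            r2_adj=ols.r2_adj, residual_se=ols.residual_se, degenerate=True,
        )

    grid = np.sort(np.asarray(grid, dtype=float))
    rss_grid = np.array([_hinge_rss(x, y, psi)[0] for psi in grid])
    i_best = int(np.argmin(rss_grid))
    lo = grid[i_best - 1] if i_best > 0 else max(floor, xs[0])
    hi = grid[i_best + 1] if i_best < len(grid) - 1 else xs[-1]
    res = optimize.minimize_scalar(
        lambda p: _hinge_rss(x, y, p)[0],
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-10},
    )
    psi = float(res.x)
    if _hinge_rss(x, y, psi)[0] > rss_grid[i_best]:
        psi = float(grid[i_best])
    rss, beta = _hinge_rss(x, y, psi)
    yhat = beta[0] + beta[1] * x + beta[2] * np.maximum(0.0, x - psi)
    # 4 estimated quantities: intercept, two slopes, breakpoint
    r2_adj, residual_se = _fit_stats(x, y, yhat, 4)
    return PiecewiseCalibration(
        intercept=float(beta[0]), slope_below=float(beta[1]),
        slope_change=float(beta[2]), breakpoint=psi,
        floor=min(floor, psi), n=n, r2_adj=float(r2_adj),
        residual_se=float(residual_se),
    )


POSITION_COMBOS: Tuple[Tuple[int, ...], ...] = tuple(
    combo
    for k in (1, 2, 3)
    for combo in itertools.combinations((1, 2, 3), k)
)
FAMILIES = ("modelII", "modelII_log", "segmented")


def _combo_label(combo: Tuple[int, ...]) -> str:
    return "".join(str(p) for p in combo)


def rank_calibrations(
    samples: Iterable[CalibrationSample],
    model2_method: str = "SMA",
) -> pd.DataFrame:
    """Fit all 21 (position combo × family) calibrations and rank by adjusted R².

    Combos average the named positions' readings. Fish missing any reading
    of a combo are dropped listwise for that combo (``n`` reports the
    count used). Ties are broken in favour of fewer positions, then lower
    position indices.

    Returns a 21-row DataFrame with columns ``positions``, ``family``,
    ``n``, ``r2_adj``, ``residual_se``, ``rank``.
    """
    samples = list(samples)
    if len(samples) < 5:
        raise ValueError("need at least 5 calibration samples")
    readings = np.array([list(s.readings) for s in samples], dtype=float)
    lipid = np.array([s.whole_body_lipid_pct for s in samples], dtype=float)

    rows = []
    for combo in POSITION_COMBOS:
        cols = [p - 1 for p in combo]
        sub = readings[:, cols]
        ok = np.all(np.isfinite(sub), axis=1) & np.isfinite(lipid)
        xb = sub[ok].mean(axis=1)
        yb = lipid[ok]
        for family in FAMILIES:
            try:
                if family == "modelII":
                    fit = fit_model2(xb, yb, method=model2_method, log_x=False)
                    r2, rse = fit.r2_adj, fit.residual_se
                elif family == "modelII_log":
                    fit = fit_model2(xb, yb, method=model2_method, log_x=True)
                    r2, rse = fit.r2_adj, fit.residual_se
                else:
                    seg = fit_segmented(xb, yb)
                    r2, rse = seg.r2_adj, seg.residual_se
            except ValueError:
                r2, rse = np.nan, np.nan
            rows.append({
                "positions": _combo_label(combo),
                "family": family,
                "n": int(ok.sum()),
                "r2_adj": r2,
                "residual_se": rse,
                "n_positions": len(combo),
            })
    table = pd.DataFrame(rows)
    table = table.sort_values(
        by=["r2_adj", "n_positions", "positions"],
        ascending=[False, True, True],
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table.drop(columns="n_positions")


def _nested_f(y: np.ndarray, X_full: np.ndarray, X_reduced: np.ndarray, method: str) -> TestResult:
    """F-test of nested least-squares models."""
    n = len(y)
    for X in (X_full, X_reduced):
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("collinear design matrix")
    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return float(np.sum((y - X @ beta) ** 2))
    rss_f, rss_r = rss(X_full), rss(X_reduced)
    df1 = X_full.shape[1] - X_reduced.shape[1]
    df2 = n - X_full.shape[1]
    if df1 <= 0 or df2 <= 0:
        raise ValueError("invalid degrees of freedom for nested comparison")
    F = ((rss_r - rss_f) / df1) / (rss_f / df2)
    p = float(stats.f.sf(max(F, 0.0), df1, df2))
    return TestResult(statistic=float(F), df=(df1, df2), p_value=p, method=method)


def covariate_interaction_test(
    x: Sequence[float],
    y: Sequence[float],
    z: Sequence[float],
    label: str = "covariate",
) -> TestResult:
    """Does a covariate (GSI or body mass) modify the reading→lipid slope?

    Nested F-test of ``y ~ x + z + x:z`` against ``y ~ x + z``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if not (len(x) == len(y) == len(z)):
        raise ValueError("x, y, z must be equal length")
    if len(x) < 5:
        raise ValueError("need at least 5 complete cases")
    ones = np.ones_like(x)
    X_red = np.column_stack([ones, x, z])
    X_full = np.column_stack([ones, x, z, x * z])
    return _nested_f(y, X_full, X_red, method=f"interaction F-test (x:{label})")


def sex_ancova(
    groups: Dict[str, Tuple[Sequence[float], Sequence[float]]],
) -> Tuple[TestResult, TestResult]:
    """ANCOVA comparing reading→lipid regressions between groups (e.g. sexes).

    First tests homogeneity of slopes (group × reading interaction); then,
    under a common slope, equality of adjusted intercepts. Returns
    ``(slopes_test, intercepts_test)``; the intercept test is meaningful
    when the slope test does not reject.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    xs, ys, labels = [], [], []
    for g, (x, y) in groups.items():
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(x) != len(y) or len(x) < 3:
            raise ValueError(f"group {g!r}: need >= 3 paired points")
        if x.std() == 0:
            raise ValueError(f"group {g!r}: zero variance in x")
        xs.append(x)
        ys.append(y)
        labels.extend([g] * len(x))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    labels = np.asarray(labels)
    names = sorted(groups)
    dummies = np.column_stack([(labels == g).astype(float) for g in names[1:]])
    ones = np.ones_like(x)

    X_common = np.column_stack([ones, dummies, x])
    X_sep = np.column_stack([ones, dummies, x, dummies * x[:, None]])
    slopes = _nested_f(y, X_sep, X_common, method="ANCOVA slope homogeneity")

    X_nogrp = np.column_stack([ones, x])
    intercepts = _nested_f(y, X_common, X_nogrp, method="ANCOVA adjusted intercepts")
    return slopes, intercepts
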