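"""Field-survey analysis: lipid, energy density and run statistics per MU.

Survey records are carried as a pandas DataFrame with one row per fish
and columns

    fish_id, date, day_of_year, mu, stock, reading_pos1, fork_length,
    weight, sex, fin_clipped [, gsi, wbl_pct, ed_kcal_kg]

``mu`` is one of the five Fraser management units (Spring5_2, Spring4_2,
Summer5_2, Summer4_1, Fall4_1). ``wbl_pct`` (whole-body lipid, % wet
weight) is derived from the position-1 reading via a
:class:`~chinooklipid.calibration.PiecewiseCalibration`; ``ed_kcal_kg``
via an affine lipid→energy-density conversion fitted to MU mean pairs.

The statistics mirror a standard test-fishery workflow: per-MU summary
tables with run timing, one-way ANOVA with Tukey HSD letters for MU mean
lipid, within-MU seasonal (day-of-arrival) regressions and slope ANCOVA,
a Welch t-test for hatchery vs wild fish, and weekly CPUE aggregation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from . import reference
from .calibration import (
    LinearFit,
    PiecewiseCalibration,
    TestResult,
    _nested_f,
    predict_whole_body_lipid,
)

logger = logging.getLogger(__name__)

MU_LABELS = tuple(reference.MU_ORDER)

SURVEY_COLUMNS = [
    "fish_id", "date", "day_of_year", "mu", "stock", "reading_pos1",
    "fork_length", "weight", "sex", "fin_clipped",
]


@dataclass(frozen=True)
class EnergyConversion:
    """Affine lipid→energy-density map: ED [kcal/kg] = a + b · lipid [%]."""

    intercept: float                 # a, kcal/kg
    slope: float                     # b, kcal/kg per lipid percentage point
    kj_per_kcal: float = reference.KJ_PER_KCAL

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("energy density must increase with lipid (slope > 0)")

    @classmethod
    def from_mu_means(cls, exclude: Sequence[str] = ()) -> "EnergyConversion":
        """Fit to the packaged MU (mean lipid, mean ED) pairs."""
        mus = [mu for mu in reference.MU_ORDER if mu not in exclude]
        pairs = [(reference.MU_LIPID_MEANS[mu], reference.MU_ED_MEANS[mu]) for mu in mus]
        return fit_ed_conversion(pairs)


def fit_ed_conversion(pairs: Iterable[Tuple[float, float]]) -> EnergyConversion:
    """OLS line through (lipid %, energy density kcal/kg) pairs."""
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least 2 (lipid, ED) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("degenerate lipid values (no spread)")
    slope, intercept = np.polyfit(x, y, 1)
    return EnergyConversion(intercept=float(intercept), slope=float(slope))


def energy_density(lipid_pct, conv: EnergyConversion):
    """Energy density (kcal/kg) at whole-body lipid ``lipid_pct`` (%)."""
    L = np.asarray(lipid_pct, dtype=float)
    if np.any((L < 0) | (L > 100)):
        raise ValueError("lipid percent outside [0, 100]")
    out = conv.intercept + conv.slope * L
    return float(out) if np.ndim(lipid_pct) == 0 else out


def apply_calibration(records: pd.DataFrame, cal: PiecewiseCalibration) -> pd.DataFrame:
    """Attach ``wbl_pct`` derived from ``reading_pos1``; returns a copy.

    Rows with missing readings get ``wbl_pct = NaN`` and are excluded from
    downstream summaries. The count of readings at/below the instrument
    floor is logged.
    """
    out = records.copy()
    if len(out) == 0:
        out["wbl_pct"] = pd.Series(dtype=float)
        return out
    r = out["reading_pos1"].to_numpy(dtype=float)
    ok = np.isfinite(r)
    n_missing = int((~ok).sum())
    if n_missing:
        logger.warning("%d record(s) with missing readings flagged (wbl_pct=NaN)", n_missing)
    wbl = np.full(len(out), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # floor warnings counted below instead
        wbl[ok] = predict_whole_body_lipid(r[ok], cal)
    n_floor = int((r[ok] <= cal.floor).sum())
    if n_floor:
        logger.info("%d reading(s) at or below the instrument floor %.2f", n_floor, cal.floor)
    out["wbl_pct"] = wbl
    return out


def attach_energy_density(records: pd.DataFrame, conv: EnergyConversion) -> pd.DataFrame:
    """Attach ``ed_kcal_kg`` from ``wbl_pct``; returns a copy."""
    out = records.copy()
    wbl = out["wbl_pct"].to_numpy(dtype=float)
    ed = np.full(len(out), np.nan)
    ok = np.isfinite(wbl)
    if ok.any():
        ed[ok] = energy_density(wbl[ok], conv)
    out["ed_kcal_kg"] = ed
    return out


def _run_timing(dates: pd.Series) -> Tuple[pd.Timestamp, pd.Timestamp, pd.Timestamp]:
    """(first, 50%-cumulative, last) catch dates.

    The 50% date is the first date at which the cumulative catch count
    reaches at least half the MU total.
    """
    d = pd.to_datetime(dates).sort_values().reset_index(drop=True)
    n = len(d)
    i50 = int(np.ceil(0.5 * n)) - 1
    return d.iloc[0], d.iloc[i50], d.iloc[n - 1]


def mu_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Per-MU descriptive table: lipid/ED/length/weight stats and run timing.

    Empty MUs are omitted (logged). Rows follow the canonical MU order,
    then any other labels in order of appearance.
    """
    rows = []
    order = [m for m in MU_LABELS if m in set(records["mu"])]
    order += [m for m in records["mu"].unique() if m not in order]
    for mu in order:
        sub = records[records["mu"] == mu]
        sub = sub[np.isfinite(sub["wbl_pct"].astype(float))]
        if len(sub) == 0:
            logger.info("MU %s empty after filtering; omitted from summary", mu)
            continue
        row: Dict[str, object] = {"mu": mu, "n": len(sub)}
        for col, name in [("wbl_pct", "lipid"), ("ed_kcal_kg", "ed"),
                          ("fork_length", "fork_length"), ("weight", "weight")]:
            if col not in sub.columns:
                continue
            v = sub[col].astype(float).dropna()
            if len(v) == 0:
                continue
            row[f"{name}_mean"] = v.mean()
            row[f"{name}_sd"] = v.std(ddof=1) if len(v) > 1 else 0.0
            row[f"{name}_min"] = v.min()
            row[f"{name}_max"] = v.max()
        first, mid, last = _run_timing(sub["date"])
        row["run_first"], row["run_50pct"], row["run_last"] = first, mid, last
        rows.append(row)
    return pd.DataFrame(rows).set_index("mu")


# ---------------------------------------------------------------------------
# ANOVA + Tukey HSD with compact letter display


def _tukey_letters(names: List[str], means: np.ndarray, sig: np.ndarray) -> Dict[str, str]:
    """Compact letter display by insert-and-absorb.

    ``sig[i, j]`` is True when groups i and j differ significantly.
    Groups sharing a letter do not differ; groups with no common letter do.
    """
    k = len(names)
    order = np.argsort(-means)  # letters assigned from highest mean down
    cols: List[set] = [set(range(k))]
    for i in range(k):
        for j in range(i + 1, k):
            if not sig[i, j]:
                continue
            new_cols: List[set] = []
            for col in cols:
                if i in col and j in col:
                    new_cols.append(col - {i})
                    new_cols.append(col - {j})
                else:
                    new_cols.append(col)
            # absorb: drop columns that are subsets of another
            cols = []
            for c in new_cols:
                if c and not any(c < d or (c == d and d in cols) for d in new_cols if d is not c):
                    if c not in cols:
                        cols.append(c)
    # order columns by the highest-mean member so "A" is the top group
    cols.sort(key=lambda c: min(int(np.where(order == m)[0][0]) for m in c))
    letters = {i: "" for i in range(k)}
    for idx, col in enumerate(cols):
        letter = chr(ord("A") + idx)
        for m in col:
            letters[m] += letter
    return {names[i]: "".join(sorted(letters[i])) for i in range(k)}


def anova_tukey(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
) -> Tuple[TestResult, pd.DataFrame, Dict[str, str]]:
    """One-way ANOVA plus Tukey HSD letters for named lipid vectors.

    Groups with fewer than 2 observations are excluded (logged). Returns
    ``(anova, pairwise, letters)`` where ``pairwise`` has one row per
    group pair with the Tukey-adjusted p-value (studentized-range
    distribution) and ``letters`` is the compact letter display at
    ``alpha``.
    """
    clean: Dict[str, np.ndarray] = {}
    for name, v in groups.items():
        v = np.asarray(v, dtype=float)
        v = v[np.isfinite(v)]
        if len(v) < 2:
            logger.info("group %s has n < 2; excluded from ANOVA/Tukey", name)
            continue
        clean[name] = v
    if len(clean) < 2:
        raise ValueError("need at least 2 groups with n >= 2")
    names = list(clean)
    arrays = [clean[g] for g in names]
    F, p = stats.f_oneway(*arrays)
    k = len(names)
    n_tot = sum(len(a) for a in arrays)
    anova = TestResult(statistic=float(F), df=(k - 1, n_tot - k),
                       p_value=float(p), method="one-way ANOVA")

    res = stats.tukey_hsd(*arrays)
    means = np.array([a.mean() for a in arrays])
    sig = np.zeros((k, k), dtype=bool)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            pij = float(res.pvalue[i, j])
            sig[i, j] = sig[j, i] = pij < alpha
            rows.append({
                "group_a": names[i], "group_b": names[j],
                "mean_diff": means[i] - means[j], "p_value": pij,
                "significant": pij < alpha,
            })
    pairwise = pd.DataFrame(rows)
    letters = _tukey_letters(names, means, sig)
    return anova, pairwise, letters


# ---------------------------------------------------------------------------
# Seasonal trends


@dataclass(frozen=True)
class SeasonalTrend:
    """Within-MU lipid vs day-of-arrival regression."""

    mu: str
    slope_pp_per_day: float
    intercept: float
    p_value: float
    r2: float
    n: int
    span_days: float
    total_change_pp: float        # slope × observed run span (negative = decline)
    weekly_change_pp: Optional[float]  # last-week mean minus first-week mean

    @property
    def fit(self) -> LinearFit:
        return LinearFit(
            slope=self.slope_pp_per_day, intercept=self.intercept, method="OLS",
            log_transformed_x=False, n=self.n, r2_adj=self.r2,
            residual_se=float("nan"),
        )


def seasonal_trend(records: pd.DataFrame, mu: Optional[str] = None) -> SeasonalTrend:
    """OLS regression of ``wbl_pct`` on ``day_of_year`` for one MU.

    Reports the slope (pp/day), its p-value, the total change over the
    observed run span (slope × span), and a weekly-means version (mean of
    the last ISO week minus mean of the first) since the within-season
    decline can be read either way.
    """
    sub = records if mu is None else records[records["mu"] == mu]
    sub = sub[np.isfinite(sub["wbl_pct"].astype(float))]
    label = mu or (sub["mu"].iloc[0] if len(sub) else "all")
    if len(sub) < 3:
        raise ValueError(f"MU {label}: need >= 3 records with lipid values")
    day = sub["day_of_year"].to_numpy(dtype=float)
    y = sub["wbl_pct"].to_numpy(dtype=float)
    if np.ptp(day) == 0:
        raise ValueError(f"MU {label}: zero spread in capture dates")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant y triggers a harmless div-by-zero
        res = stats.linregress(day, y)
    p_value = 1.0 if np.isnan(res.pvalue) else float(res.pvalue)  # no spread = no trend
    span = float(np.ptp(day))
    weekly = None
    if "date" in sub.columns:
        iso = pd.to_datetime(sub["date"]).dt.isocalendar()
        wk = iso.year.astype(int) * 100 + iso.week.astype(int)
        by_week = pd.Series(y, index=wk.to_numpy()).groupby(level=0).mean()
        if len(by_week) >= 2:
            weekly = float(by_week.iloc[-1] - by_week.iloc[0])
    return SeasonalTrend(
        mu=label, slope_pp_per_day=float(res.slope), intercept=float(res.intercept),
        p_value=p_value, r2=float(res.rvalue**2), n=len(sub),
        span_days=span, total_change_pp=float(res.slope * span),
        weekly_change_pp=weekly,
    )


def compare_slopes(records_a: pd.DataFrame, records_b: pd.DataFrame) -> TestResult:
    """ANCOVA: do two MUs' seasonal lipid slopes differ?

    F-test on the group × day-of-year interaction in the pooled model.
    """
    frames = []
    for g, rec in (("a", records_a), ("b", records_b)):
        sub = rec[np.isfinite(rec["wbl_pct"].astype(float))]
        if len(sub) < 3 or np.ptp(sub["day_of_year"].to_numpy(dtype=float)) == 0:
            raise ValueError(f"group {g}: insufficient records or date spread")
        frames.append(pd.DataFrame({
            "day": sub["day_of_year"].astype(float),
            "y": sub["wbl_pct"].astype(float),
            "g": g,
        }))
    df = pd.concat(frames, ignore_index=True)
    d = (df["g"] == "b").to_numpy(dtype=float)
    day = df["day"].to_numpy()
    y = df["y"].to_numpy()
    ones = np.ones_like(day)
    X_full = np.column_stack([ones, d, day, d * day])
    X_red = np.column_stack([ones, d, day])
    return _nested_f(y, X_full, X_red, method="ANCOVA seasonal-slope contrast")


def hatchery_wild_test(records: pd.DataFrame) -> TestResult:
    """Welch t-test of lipid content, fin-clipped (hatchery) vs wild.

    Restrict ``records`` to a single population (e.g. the Harrison River
    stock) before calling, so hatchery origin is the only contrast.
    """
    sub = records[np.isfinite(records["wbl_pct"].astype(float))]
    clipped = sub[sub["fin_clipped"].astype(bool)]["wbl_pct"].to_numpy(dtype=float)
    wild = sub[~sub["fin_clipped"].astype(bool)]["wbl_pct"].to_numpy(dtype=float)
    if len(clipped) < 2 or len(wild) < 2:
        raise ValueError("need >= 2 fish in both the fin-clipped and wild classes")
    t, p = stats.ttest_ind(clipped, wild, equal_var=False)
    # Welch–Satterthwaite df
    v1, v2 = clipped.var(ddof=1) / len(clipped), wild.var(ddof=1) / len(wild)
    df = (v1 + v2) ** 2 / (v1**2 / (len(clipped) - 1) + v2**2 / (len(wild) - 1))
    return TestResult(
        statistic=float(t), df=(float(df),), p_value=float(p),
        method="Welch t-test hatchery vs wild",
        extra={
            "mean_clipped": float(clipped.mean()),
            "mean_wild": float(wild.mean()),
            "difference": float(clipped.mean() - wild.mean()),
            "n_clipped": len(clipped), "n_wild": len(wild),
        },
    )


def weekly_cpue(events: pd.DataFrame) -> pd.DataFrame:
    """Weekly catch-per-unit-effort per MU.

    ``events`` has columns ``date``, ``mu``, ``catch`` (fish) and
    ``effort`` (fathom-minutes per boat day). Rows with non-positive
    effort are rejected (logged). Weeks are ISO weeks of the capture
    date; CPUE is Σcatch / Σeffort within (MU, week).
    """
    ev = events.copy()
    bad = ~(ev["effort"].astype(float) > 0)
    if bad.any():
        logger.warning("%d CPUE row(s) with non-positive effort dropped", int(bad.sum()))
        ev = ev[~bad]
    if len(ev) == 0:
        return pd.DataFrame(columns=["mu", "iso_year", "iso_week", "catch", "effort", "cpue"])
    iso = pd.to_datetime(ev["date"]).dt.isocalendar()
    ev = ev.assign(iso_year=iso.year.astype(int).to_numpy(),
                   iso_week=iso.week.astype(int).to_numpy())
    out = (
        ev.groupby(["mu", "iso_year", "iso_week"], sort=True)[["catch", "effort"]]
        .sum()
        .reset_index()
    )
    out["cpue"] = out["catch"] / out["effort"]
    return out
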