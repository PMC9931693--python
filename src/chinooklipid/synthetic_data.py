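"""Seeded synthetic calibration and survey datasets.

The generators emulate the statistical structure of the 2020 Fraser River
study so every downstream stage is testable without the archived field
data:

* a 63-fish calibration cohort spanning readings 0.6–16.8 meter units and
  body masses 0.25–11.05 kg, whose tissue-level fields (masses, water
  fractions, dried-lipid replicates) are mutually consistent — the
  whole-body lipid recomputed from the tissues equals the value used to
  generate the fat-meter reading;
* a five-MU test-fishery survey with the printed sample sizes
  (289/9/72/966/473), run windows, season-pooled lipid means and SDs,
  linear within-season lipid declines, an increasing GSI for the two
  late-run MUs, and a hatchery (fin-clipped) lipid offset in the fall MU.

Fat-meter readings are produced by inverting the published piecewise
calibration, adding Gaussian meter noise, and clamping at the observed
instrument floor (0.6 by default). Dates are day-of-year integers
internally; calendar dates are rendered at the record level.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import reference
from .calibration import PiecewiseCalibration
from .homogenate import CalibrationSample

__all__ = [
    "CalibrationSimConfig",
    "MUBlock",
    "SurveySimConfig",
    "reading_from_lipid",
    "generate_calibration_set",
    "generate_survey",
    "default_calibration_config",
    "default_survey_config",
]


def reading_from_lipid(
    lipid_pct,
    cal: PiecewiseCalibration,
    noise_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
):
    """Fat-meter reading whose calibrated prediction is ``lipid_pct``.

    Exact inverse of the piecewise map, plus Gaussian meter noise, clamped
    below at the instrument floor (lipid values whose pre-image falls
    below the floor all read the floor, as observed in the field).
    Accepts scalars or arrays.
    """
    L = np.asarray(lipid_pct, dtype=float)
    if not np.all(np.isfinite(L)):
        raise ValueError("lipid values must be finite")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if cal.slope_below <= 0 or cal.slope_above <= 0:
        raise ValueError("calibration must be increasing to invert")
    below = (L - cal.intercept) / cal.slope_below
    above = cal.breakpoint + (L - cal.lipid_at_breakpoint) / cal.slope_above
    r = np.where(L <= cal.lipid_at_breakpoint, below, above)
    if noise_sd > 0:
        rng = np.random.default_rng() if rng is None else rng
        r = r + rng.normal(0.0, noise_sd, size=np.shape(r))
    r = np.maximum(r, cal.floor)
    return float(r) if np.ndim(lipid_pct) == 0 else r


@dataclass(frozen=True)
class CalibrationSimConfig:
    """Conditions for the homogenized calibration cohort."""

    n_fish: int = 63
    true_calibration: PiecewiseCalibration = field(
        default_factory=PiecewiseCalibration.published
    )
    reading_noise_sd: float = 0.15          # meter units, position 1
    position_extra_noise_sd: float = 0.8    # extra meter noise at positions 2-3
    lipid_range: Tuple[float, float] = (2.0, 13.9)   # % wet weight
    mass_range: Tuple[float, float] = (0.25, 11.05)  # kg
    sex_ratio: float = 0.5                  # fraction female
    gonad_lipid_female: Tuple[float, float] = reference.CALIBRATION_COHORT["gonad_lipid_female_pct"]
    gonad_lipid_male: Tuple[float, float] = reference.CALIBRATION_COHORT["gonad_lipid_male_pct"]
    gsi_range: Tuple[float, float] = (0.01, 0.17)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fish < 0:
            raise ValueError("n_fish must be >= 0")
        for name in ("lipid_range", "mass_range", "gsi_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be ordered (min <= max)")
        for name in ("reading_noise_sd", "position_extra_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("gonad_lipid_female", "gonad_lipid_male"):
            if getattr(self, name)[1] < 0:
                raise ValueError(f"{name} sd must be >= 0")
        if not (0.0 <= self.sex_ratio <= 1.0):
            raise ValueError("sex_ratio must be in [0, 1]")


def default_calibration_config(**overrides) -> CalibrationSimConfig:
    return CalibrationSimConfig(**overrides)


def _fork_length_cm(mass_kg: float, rng: np.random.Generator) -> float:
    # crude cube-root condition relation spanning ~25-77 cm over the mass range
    base = (mass_kg / 2.4e-5) ** (1.0 / 3.0)
    return float(max(15.0, base + rng.normal(0.0, 2.0)))


def generate_calibration_set(config: CalibrationSimConfig) -> List[CalibrationSample]:
    """Generate a mutually consistent homogenized-fish calibration set.

    Whole-body lipid is drawn uniformly over ``lipid_range`` and the
    tissue fields are solved so the mass-weighted recomputation returns
    exactly that value; the position-1 reading is the (noisy) inverse of
    the true calibration at that lipid. Positions 2 and 3 are position 1
    plus independent extra meter noise. Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    cal = config.true_calibration
    samples: List[CalibrationSample] = []
    season_2019 = (date(2019, 6, 15), date(2019, 9, 15))
    season_2020 = (date(2020, 4, 15), date(2020, 10, 15))
    n_troll = min(21, config.n_fish)
    for i in range(config.n_fish):
        L = float(rng.uniform(*config.lipid_range))
        total = float(rng.uniform(*config.mass_range))
        female = bool(rng.random() < config.sex_ratio)
        gsi = float(rng.uniform(*config.gsi_range))
        mu_g, sd_g = config.gonad_lipid_female if female else config.gonad_lipid_male
        gl = float(np.clip(rng.normal(mu_g, sd_g), 0.0, 60.0)) / 100.0
        gonad = total * gsi / (1.0 + gsi)
        somatic = total - gonad
        sl = (L / 100.0 * total - gonad * gl) / somatic
        if not (0.0 <= sl <= 0.6):
            # gonad draw incompatible with the target whole-body lipid:
            # fall back to a uniform-composition fish (both tissues at L)
            gl = sl = L / 100.0
        somatic_water = float(np.clip(0.78 - 0.006 * L + rng.normal(0.0, 0.01), 0.5, 0.92))
        gonad_water = float(np.clip(rng.normal(0.70, 0.02), 0.5, 0.9))
        somatic_dry = sl / (1.0 - somatic_water)
        gonad_dry = gl / (1.0 - gonad_water)
        e_s = min(0.01, somatic_dry / 2.0) * float(rng.random())
        e_g = min(0.01, gonad_dry / 2.0) * float(rng.random())
        somatic_reps = (somatic_dry - e_s, somatic_dry, somatic_dry + e_s)
        gonad_reps = (gonad_dry - e_g, gonad_dry + e_g)

        r1 = reading_from_lipid(L, cal, config.reading_noise_sd, rng)
        extra = rng.normal(0.0, config.position_extra_noise_sd, size=2)
        r2, r3 = (max(cal.floor, r1 + e) for e in extra)

        troll = i < n_troll
        lo, hi = season_2019 if troll else season_2020
        capture = lo + timedelta(days=int(rng.integers(0, (hi - lo).days + 1)))
        samples.append(
            CalibrationSample(
                fish_id=f"cal-{i + 1:03d}",
                source="troll" if troll else "test_fishery",
                capture_date=capture,
                sex="F" if female else "M",
                fork_length=_fork_length_cm(total, rng),
                total_mass=total,
                somatic_mass=somatic,
                gonad_mass=gonad,
                readings=(float(r1), float(r2), float(r3)),
                somatic_water_frac=somatic_water,
                somatic_lipid_dry_reps=somatic_reps,
                gonad_lipid_dry_reps=gonad_reps,
                gonad_water_frac=gonad_water,
            )
        )
    return samples


@dataclass(frozen=True)
class MUBlock:
    """Per-MU survey simulation block.

    ``lipid_start_mean``/``lipid_end_mean`` are the expected whole-body
    lipid (%) at the first and last day of the run window; the expectation
    declines linearly in day-of-year between them. ``lipid_sd`` is the
    residual SD around that trend. ``hatchery_lipid_offset`` (pp, hatchery
    minus wild) is applied symmetrically about the configured marginal
    mean so the MU mean is preserved.
    """

    n: int
    run_start: int                      # day of year
    run_end: int                        # day of year
    lipid_start_mean: float             # %
    lipid_end_mean: float               # %
    lipid_sd: float                     # %
    fork_length: Tuple[float, float]    # mean mm, sd
    weight: Tuple[float, float]         # mean kg, sd
    hatchery_fraction: float = 0.0
    hatchery_lipid_offset: float = 0.0  # pp, hatchery minus wild
    stock: str = ""
    gsi_start: float = 0.05
    gsi_end: float = 0.05

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("per-MU n must be >= 0")
        if self.run_start > self.run_end:
            raise ValueError("run_start must be <= run_end")
        if self.lipid_sd < 0:
            raise ValueError("lipid_sd must be >= 0")
        if not (0.0 <= self.hatchery_fraction <= 1.0):
            raise ValueError("hatchery_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SurveySimConfig:
    """Conditions for the five-MU test-fishery survey."""

    mus: Dict[str, MUBlock]
    seed: int = 0
    year: int = 2020
    calibration: PiecewiseCalibration = field(
        default_factory=PiecewiseCalibration.published
    )

    def with_seed(self, seed: int) -> "SurveySimConfig":
        return replace(self, seed=seed)


def _doy(iso_date: str) -> int:
    return date.fromisoformat(iso_date).timetuple().tm_yday


def default_survey_config(seed: int = 0) -> SurveySimConfig:
    """The packaged study conditions: printed sample sizes, run windows,
    season-pooled means/SDs, within-season declines, hatchery offset.

    The residual lipid SD is deconvolved from the printed season-pooled SD
    (variance of a uniform-date linear decline is decline²/12; the
    hatchery mixture adds f(1-f)·offset² in the fall MU) so the generated
    marginal SD matches the printed one.
    """
    mus: Dict[str, MUBlock] = {}
    stocks = {
        "Spring5_2": "UpperFraser", "Spring4_2": "MidFraser",
        "Summer5_2": "NorthThompson", "Summer4_1": "SouthThompson",
        "Fall4_1": "Harrison",
    }
    gsi = {
        "Spring5_2": (0.05, 0.05), "Spring4_2": (0.05, 0.05),
        "Summer5_2": (0.05, 0.05), "Summer4_1": (0.08, 0.15),
        "Fall4_1": (0.10, 0.20),
    }
    for mu in reference.MU_ORDER:
        t3 = reference.MU_SURVEY[mu]
        decline = reference.MU_SEASONAL_DECLINE_PP[mu]
        frac_h = 0.25 if mu == "Fall4_1" else 0.0
        offset = reference.HATCHERY_LIPID_OFFSET_PP if mu == "Fall4_1" else 0.0
        var_resid = (
            t3["lipid_sd"] ** 2
            - decline**2 / 12.0
            - frac_h * (1 - frac_h) * offset**2
        )
        mus[mu] = MUBlock(
            n=t3["n"],
            run_start=_doy(t3["run_first"]),
            run_end=_doy(t3["run_last"]),
            lipid_start_mean=t3["lipid_mean"] + decline / 2.0,
            lipid_end_mean=t3["lipid_mean"] - decline / 2.0,
            lipid_sd=float(np.sqrt(max(var_resid, 0.04))),
            fork_length=(t3["fork_length_mean"], t3["fork_length_sd"]),
            weight=(t3["weight_mean"], t3["weight_sd"]),
            hatchery_fraction=frac_h,
            hatchery_lipid_offset=offset,
            stock=stocks[mu],
            gsi_start=gsi[mu][0],
            gsi_end=gsi[mu][1],
        )
    return SurveySimConfig(mus=mus, seed=seed)


def generate_survey(config: SurveySimConfig) -> pd.DataFrame:
    """Generate the survey as a DataFrame (one row per fish).

    Columns: ``fish_id, date, day_of_year, mu, stock, reading_pos1,
    fork_length, weight, sex, fin_clipped, gsi``. The position-1 reading
    is the noiseless inverse of the configured calibration at the fish's
    simulated whole-body lipid, so applying that calibration recovers the
    configured lipid distribution (up to floor clamping at very low
    lipid). Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    cal = config.calibration
    jan1 = date(config.year, 1, 1)
    rows = []
    k = 0
    for mu, blk in config.mus.items():
        span = blk.run_end - blk.run_start
        for _ in range(blk.n):
            k += 1
            doy = int(rng.integers(blk.run_start, blk.run_end + 1))
            frac = (doy - blk.run_start) / span if span > 0 else 0.0
            mean_l = blk.lipid_start_mean + frac * (blk.lipid_end_mean - blk.lipid_start_mean)
            is_h = bool(rng.random() < blk.hatchery_fraction)
            lipid = mean_l + blk.hatchery_lipid_offset * (float(is_h) - blk.hatchery_fraction)
            lipid += float(rng.normal(0.0, blk.lipid_sd))
            lipid = float(np.clip(lipid, 0.5, 35.0))
            reading = reading_from_lipid(lipid, cal)
            gsi = max(0.0, blk.gsi_start + frac * (blk.gsi_end - blk.gsi_start)
                      + float(rng.normal(0.0, 0.01)))
            rows.append({
                "fish_id": f"alb-{k:04d}",
                "date": (jan1 + timedelta(days=doy - 1)).isoformat(),
                "day_of_year": doy,
                "mu": mu,
                "stock": blk.stock,
                "reading_pos1": float(reading),
                "fork_length": float(max(300.0, rng.normal(*blk.fork_length))),
                "weight": float(max(0.5, rng.normal(*blk.weight))),
                "sex": "F" if rng.random() < 0.5 else "M",
                "fin_clipped": is_h,
                "gsi": gsi,
            })
    columns = ["fish_id", "date", "day_of_year", "mu", "stock", "reading_pos1",
               "fork_length", "weight", "sex", "fin_clipped", "gsi"]
    return pd.DataFrame(rows, columns=columns)
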