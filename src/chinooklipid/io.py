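"""File formats, configuration and the replayable pipeline.

CSV (comma, UTF-8, "." decimal) is the single interchange format; dates
are ISO-8601 in files and day-of-year in statistics. Readers validate
rows and collect problems with line numbers instead of failing silently;
missing mandatory columns are a hard error. ``run_pipeline`` ties the
stages together — simulate → calibrate → survey → correlate → energetics
— and writes a run manifest that fully determines the outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__, bioenergetics, reference
from .calibration import PiecewiseCalibration, fit_segmented, rank_calibrations
from .homogenate import CalibrationSample
from .migration import (
    StockMigration,
    difficulty_correlation,
    mu_mean_indices,
    published_difficulty_correlations,
    published_mu_indices,
)
from .survey import (
    MU_LABELS,
    EnergyConversion,
    anova_tukey,
    apply_calibration,
    attach_energy_density,
    compare_slopes,
    hatchery_wild_test,
    mu_summary,
    seasonal_trend,
)
from .synthetic_data import (
    default_calibration_config,
    default_survey_config,
    generate_calibration_set,
    generate_survey,
)

logger = logging.getLogger(__name__)

CALIBRATION_COLUMNS = [
    "fish_id", "source", "capture_date", "sex", "fork_length_cm",
    "total_mass_kg", "somatic_mass_kg", "gonad_mass_kg",
    "reading_pos1", "reading_pos2", "reading_pos3",
    "somatic_water_frac", "gonad_water_frac",
    "somatic_lipid_dry_1", "somatic_lipid_dry_2", "somatic_lipid_dry_3",
    "gonad_lipid_dry_1", "gonad_lipid_dry_2",
    "whole_body_lipid_pct",
]

SURVEY_CSV_COLUMNS = [
    "fish_id", "date", "mu", "stock", "reading_pos1",
    "fork_length", "weight", "sex", "fin_clipped", "gsi",
]


# ---------------------------------------------------------------------------
# Calibration CSV

def write_calibration_csv(samples: Sequence[CalibrationSample], path) -> None:
    rows = []
    for s in samples:
        sreps = list(s.somatic_lipid_dry_reps) + [np.nan] * 3
        greps = list(s.gonad_lipid_dry_reps) + [np.nan] * 2
        rows.append({
            "fish_id": s.fish_id,
            "source": s.source,
            "capture_date": s.capture_date.isoformat() if s.capture_date else "",
            "sex": s.sex,
            "fork_length_cm": s.fork_length,
            "total_mass_kg": s.total_mass,
            "somatic_mass_kg": s.somatic_mass,
            "gonad_mass_kg": s.gonad_mass,
            "reading_pos1": s.readings[0],
            "reading_pos2": s.readings[1],
            "reading_pos3": s.readings[2],
            "somatic_water_frac": s.somatic_water_frac,
            "gonad_water_frac": s.gonad_water_frac,
            "somatic_lipid_dry_1": sreps[0],
            "somatic_lipid_dry_2": sreps[1],
            "somatic_lipid_dry_3": sreps[2],
            "gonad_lipid_dry_1": greps[0],
            "gonad_lipid_dry_2": greps[1],
            "whole_body_lipid_pct": s.whole_body_lipid_pct,
        })
    # %.17g guarantees bit-for-bit float round trips through the CSV
    pd.DataFrame(rows, columns=CALIBRATION_COLUMNS).to_csv(
        path, index=False, float_format="%.17g")


def read_calibration_csv(path) -> List[CalibrationSample]:
    """Read a calibration CSV into validated samples.

    Rows failing validation (e.g. somatic + gonad mass not matching total)
    are skipped with a warning carrying the file line number.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    df.columns = [c.lower() for c in df.columns]
    missing = [c for c in CALIBRATION_COLUMNS if c not in df.columns
               and not c.startswith(("gonad_lipid", "somatic_lipid"))
               and c not in ("whole_body_lipid_pct", "capture_date", "fork_length_cm")]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {missing}")
    samples: List[CalibrationSample] = []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            sreps = [row[c] for c in ("somatic_lipid_dry_1", "somatic_lipid_dry_2",
                                      "somatic_lipid_dry_3") if c in df.columns]
            greps = [row[c] for c in ("gonad_lipid_dry_1", "gonad_lipid_dry_2")
                     if c in df.columns]
            sreps = [float(v) for v in sreps if np.isfinite(float(v))]
            greps = [float(v) for v in greps if np.isfinite(float(v))]
            cd = row.get("capture_date")
            capture = date.fromisoformat(str(cd)) if isinstance(cd, str) and cd else None
            fl = row.get("fork_length_cm")
            samples.append(CalibrationSample(
                fish_id=str(row["fish_id"]),
                source=str(row.get("source", "test_fishery")),
                capture_date=capture,
                sex=str(row.get("sex", "unknown")),
                fork_length=float(fl) if fl is not None and np.isfinite(float(fl)) else None,
                total_mass=float(row["total_mass_kg"]),
                somatic_mass=float(row["somatic_mass_kg"]),
                gonad_mass=float(row["gonad_mass_kg"]),
                readings=(float(row["reading_pos1"]), float(row["reading_pos2"]),
                          float(row["reading_pos3"])),
                somatic_water_frac=float(row["somatic_water_frac"]),
                gonad_water_frac=float(row["gonad_water_frac"]),
                somatic_lipid_dry_reps=sreps,
                gonad_lipid_dry_reps=greps,
            ))
        except (ValueError, KeyError, TypeError) as exc:
            logger.warning("%s line %d: row skipped (%s)", path, line, exc)
    return samples


# ---------------------------------------------------------------------------
# Survey CSV

def write_survey_csv(records: pd.DataFrame, path) -> None:
    cols = [c for c in SURVEY_CSV_COLUMNS if c in records.columns]
    cols += [c for c in ("wbl_pct", "ed_kcal_kg") if c in records.columns]
    records[cols].to_csv(path, index=False, float_format="%.17g")


def read_survey_csv(path) -> pd.DataFrame:
    """Read survey records; derives ``day_of_year``; rejects unknown MUs.

    Dates must be ISO-8601. Rejected rows are logged with line numbers.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    df.columns = [c.lower() for c in df.columns]
    mandatory = ["fish_id", "date", "mu", "reading_pos1"]
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {missing}")
    dates = pd.to_datetime(df["date"], format="ISO8601", errors="coerce")
    bad_date = dates.isna()
    bad_mu = ~df["mu"].isin(MU_LABELS)
    for idx in df.index[bad_date]:
        logger.warning("%s line %d: unparsable date %r; row rejected",
                       path, idx + 2, df.loc[idx, "date"])
    for idx in df.index[bad_mu & ~bad_date]:
        logger.warning("%s line %d: unknown MU label %r; row rejected",
                       path, idx + 2, df.loc[idx, "mu"])
    keep = ~(bad_date | bad_mu)
    out = df[keep].copy()
    out["date"] = dates[keep].dt.date.astype(str)
    out["day_of_year"] = dates[keep].dt.dayofyear.astype(int)
    if "fin_clipped" in out.columns:
        out["fin_clipped"] = out["fin_clipped"].astype(bool)
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Stock migration CSV

def write_migration_csv(stocks: Sequence[StockMigration], path) -> None:
    pd.DataFrame(
        [{"stock": s.stock, "mu": s.mu, "distance_km": s.distance_km,
          "elevation_m": s.elevation_m} for s in stocks]
    ).to_csv(path, index=False, float_format="%.17g")


def read_migration_csv(path) -> List[StockMigration]:
    df = pd.read_csv(path, float_precision="round_trip")
    df.columns = [c.lower() for c in df.columns]
    missing = [c for c in ("stock", "mu", "distance_km", "elevation_m")
               if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {missing}")
    return [
        StockMigration(stock=str(r["stock"]), mu=str(r["mu"]),
                       distance_km=float(r["distance_km"]),
                       elevation_m=float(r["elevation_m"]))
        for _, r in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# Calibration (de)serialization

def write_calibration_yaml(cal: PiecewiseCalibration, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cal), fh, sort_keys=False)


def read_calibration_yaml(path) -> PiecewiseCalibration:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return PiecewiseCalibration(**d)


# ---------------------------------------------------------------------------
# Pipeline configuration

@dataclass
class PipelineConfig:
    """Configuration for a full pipeline run."""

    calibration_source: str = "published"   # {"fit", "published", "file"}
    calibration_file: Optional[str] = None
    conversion_source: str = "table3_fit"   # {"table3_fit", "coefficients"}
    conversion_coefficients: Optional[Tuple[float, float]] = None  # (a, b)
    alpha: float = 0.05
    stock_blocklist: Tuple[str, ...] = ()
    anova_exclude: Tuple[str, ...] = ("Spring4_2",)  # too few fish for the MU tests
    calibration_csv: Optional[str] = None
    survey_csv: Optional[str] = None
    migration_csv: Optional[str] = None
    simulate: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.calibration_source not in ("fit", "published", "file"):
            raise ValueError(f"unknown calibration_source {self.calibration_source!r}")
        if self.conversion_source not in ("table3_fit", "coefficients"):
            raise ValueError(f"unknown conversion_source {self.conversion_source!r}")


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    if "stock_blocklist" in d:
        d["stock_blocklist"] = tuple(d["stock_blocklist"])
    if "anova_exclude" in d:
        d["anova_exclude"] = tuple(d["anova_exclude"])
    if d.get("conversion_coefficients") is not None:
        d["conversion_coefficients"] = tuple(d["conversion_coefficients"])
    return PipelineConfig(**d)


# ---------------------------------------------------------------------------
# Pipeline

def run_pipeline(config: PipelineConfig, out_dir) -> Dict[str, object]:
    """Execute simulate → calibrate → survey → correlate → energetics.

    Writes all stage outputs plus ``manifest.json`` under ``out_dir`` and
    returns the in-memory results. Idempotent for a fixed seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: Dict[str, object] = {}

    # --- simulate / load
    if config.simulate:
        cal_samples = generate_calibration_set(
            default_calibration_config(seed=config.seed)
        )
        survey_df = generate_survey(default_survey_config(seed=config.seed + 1))
        write_calibration_csv(cal_samples, out / "calibration_fish.csv")
        write_survey_csv(survey_df, out / "survey_fish.csv")
        survey_df = read_survey_csv(out / "survey_fish.csv")
    else:
        if not config.calibration_csv or not config.survey_csv:
            raise ValueError("simulate=False requires calibration_csv and survey_csv")
        cal_samples = read_calibration_csv(config.calibration_csv)
        survey_df = read_survey_csv(config.survey_csv)
    if config.stock_blocklist:
        n0 = len(survey_df)
        survey_df = survey_df[~survey_df["stock"].isin(config.stock_blocklist)]
        logger.info("stock blocklist removed %d record(s)", n0 - len(survey_df))

    # --- calibrate
    ranking = rank_calibrations(cal_samples)
    ranking.to_csv(out / "calibration_ranking.csv", index=False)
    if config.calibration_source == "published":
        cal = PiecewiseCalibration.published()
    elif config.calibration_source == "file":
        cal = read_calibration_yaml(config.calibration_file)
    else:
        x = np.array([s.readings[0] for s in cal_samples])
        y = np.array([s.whole_body_lipid_pct for s in cal_samples])
        cal = fit_segmented(x, y)
    write_calibration_yaml(cal, out / "calibration.yaml")
    results["calibration"] = cal
    results["ranking"] = ranking

    # --- survey statistics
    if config.conversion_source == "coefficients":
        a, b = config.conversion_coefficients
        conv = EnergyConversion(intercept=a, slope=b)
    else:
        conv = EnergyConversion.from_mu_means()
    survey_df = apply_calibration(survey_df, cal)
    survey_df = attach_energy_density(survey_df, conv)
    summary = mu_summary(survey_df)
    summary.to_csv(out / "mu_summary.csv")
    results["conversion"] = conv
    results["mu_summary"] = summary
    results["survey"] = survey_df

    groups = {
        mu: survey_df.loc[survey_df["mu"] == mu, "wbl_pct"].to_numpy()
        for mu in MU_LABELS
        if mu in set(survey_df["mu"]) and mu not in config.anova_exclude
    }
    anova, pairwise, letters = anova_tukey(groups, alpha=config.alpha)
    pairwise.to_csv(out / "tukey_pairwise.csv", index=False)
    results["anova"] = anova
    results["tukey_letters"] = letters

    trends = {}
    for mu in summary.index:
        if (survey_df["mu"] == mu).sum() >= 3:
            trends[mu] = seasonal_trend(survey_df, mu)
    pd.DataFrame(
        [dataclasses.asdict(t) for t in trends.values()]
    ).to_csv(out / "seasonal_trends.csv", index=False)
    results["trends"] = trends

    test_rows = [{
        "test": "anova_mu_lipid", "statistic": anova.statistic,
        "df": str(anova.df), "p_value": anova.p_value,
    }]
    for pair in (("Summer5_2", "Fall4_1"), ("Summer4_1", "Fall4_1")):
        if all(m in trends for m in pair):
            tr = compare_slopes(survey_df[survey_df["mu"] == pair[0]],
                                survey_df[survey_df["mu"] == pair[1]])
            test_rows.append({"test": f"slope_{pair[0]}_vs_{pair[1]}",
                              "statistic": tr.statistic, "df": str(tr.df),
                              "p_value": tr.p_value})
    harrison = survey_df[(survey_df["mu"] == "Fall4_1")
                         & (survey_df["stock"] == "Harrison")]
    if harrison["fin_clipped"].nunique() == 2:
        hw = hatchery_wild_test(harrison)
        results["hatchery_wild"] = hw
        test_rows.append({"test": "hatchery_wild_harrison", "statistic": hw.statistic,
                          "df": str(hw.df), "p_value": hw.p_value})
    pd.DataFrame(test_rows).to_csv(out / "tests.csv", index=False)

    # --- migration correlations
    if config.migration_csv:
        stocks = read_migration_csv(config.migration_csv)
        indices = mu_mean_indices(stocks)
        lipid_means = summary["lipid_mean"].to_dict()
        corrs = difficulty_correlation(indices, lipid_means)
    else:
        # packaged MU-level indices against the packaged MU lipid means
        corrs = published_difficulty_correlations()
        indices = published_mu_indices()
    pd.DataFrame([dataclasses.asdict(c) for c in corrs]).to_csv(
        out / "difficulty_correlations.csv", index=False
    )
    results["correlations"] = corrs

    # --- energetics scenarios
    pop_energy = bioenergetics.reference_population_energy()
    scen_rows = []
    for mu in summary.index:
        ed = summary.loc[mu, "ed_mean"] if "ed_mean" in summary.columns else None
        if ed is None or not np.isfinite(ed):
            continue
        s = bioenergetics.EnergyScenario.build(mu, ed=float(ed),
                                               population_energy=pop_energy)
        scen_rows.append(dataclasses.asdict(s))
    scenarios = pd.DataFrame(scen_rows)
    scenarios.to_csv(out / "prey_scenarios.csv", index=False)
    results["scenarios"] = scenarios

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "calibration": dataclasses.asdict(cal),
        "conversion": {"intercept": conv.intercept, "slope": conv.slope,
                       "kj_per_kcal": conv.kj_per_kcal},
        "n_calibration_fish": len(cal_samples),
        "n_survey_records": int(len(survey_df)),
        "outputs": sorted(p.name for p in out.glob("*.csv")),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    results["manifest"] = manifest
    return results
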