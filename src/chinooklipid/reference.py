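"""Published reference values for the Fraser River Chinook lipid study.

These constants carry the study's printed summary tables so the
migration-difficulty correlation and energy-density conversion can be
replayed without the archived per-fish data: MU-level migration-difficulty
indices, MU-level lipid and energy-density summaries from the 2020 Albion
test-fishery season, and the published fat-meter calibration coefficients.

MU = management unit, the fishery-management grouping of Fraser Chinook
conservation units by run timing, age of return and juvenile life history.
"""

from __future__ import annotations

MU_ORDER = ["Spring5_2", "Spring4_2", "Summer5_2", "Summer4_1", "Fall4_1"]

# Published two-segment fat-meter calibration (position 1, raw readings).
PUBLISHED_CALIBRATION = {
    "intercept": -1.973,        # % wet weight
    "slope_below": 6.758,       # % per meter unit
    "slope_change": -6.202,     # slope above breakpoint = 0.556
    "breakpoint": 1.059,        # meter units
    "floor": 0.6,               # lowest reading ever recorded
    "n": 63,
    "r2_adj": 0.914,
    "residual_se": 1.03,
}

# MU-averaged migration-difficulty indices.
# work = (elevation_m * distance_km) / 1000 ; slope = 500 * elevation / distance,
# each computed per stock and then averaged within MU.
MU_MIGRATION = {
    "Spring5_2": {"elevation_m": 713.0, "distance_km": 994.0, "work": 712.9, "slope_index": 375.3},
    "Spring4_2": {"elevation_m": 570.0, "distance_km": 392.0, "work": 223.6, "slope_index": 726.2},
    "Summer5_2": {"elevation_m": 606.0, "distance_km": 705.0, "work": 464.9, "slope_index": 426.1},
    "Summer4_1": {"elevation_m": 350.0, "distance_km": 523.0, "work": 186.5, "slope_index": 341.9},
    "Fall4_1": {"elevation_m": 93.0, "distance_km": 112.0, "work": 11.3, "slope_index": 409.3},
}

# MU summaries from the 2020 test-fishery season: whole-body lipid
# (% wet weight), energy density (kcal/kg), fork length (mm), weight (kg),
# sample sizes and run-timing dates (first / 50%-cumulative / last catch).
MU_SURVEY = {
    "Spring5_2": {
        "n": 289,
        "lipid_mean": 12.8, "lipid_sd": 2.3, "lipid_min": 8.4, "lipid_max": 16.3,
        "ed_mean": 1900.0, "ed_sd": 194.0, "ed_min": 1539.0, "ed_max": 2200.0,
        "fork_length_mean": 660.9, "fork_length_sd": 67.4,
        "weight_mean": 7.0, "weight_sd": 2.4,
        "run_first": "2020-04-21", "run_50pct": "2020-07-13", "run_last": "2020-09-07",
    },
    "Spring4_2": {
        "n": 9,
        "lipid_mean": 12.2, "lipid_sd": 1.7, "lipid_min": 10.7, "lipid_max": 16.3,
        "ed_mean": 1849.0, "ed_sd": 147.0, "ed_min": 1720.0, "ed_max": 2205.0,
        "fork_length_mean": 584.7, "fork_length_sd": 70.9,
        "weight_mean": 4.8, "weight_sd": 2.1,
        "run_first": "2020-04-22", "run_50pct": "2020-07-15", "run_last": "2020-08-02",
    },
    "Summer5_2": {
        "n": 72,
        "lipid_mean": 12.7, "lipid_sd": 2.3, "lipid_min": 7.9, "lipid_max": 17.1,
        "ed_mean": 1890.0, "ed_sd": 196.0, "ed_min": 1487.0, "ed_max": 2271.0,
        "fork_length_mean": 658.3, "fork_length_sd": 55.0,
        "weight_mean": 7.1, "weight_sd": 1.9,
        "run_first": "2020-07-02", "run_50pct": "2020-08-13", "run_last": "2020-09-04",
    },
    "Summer4_1": {
        "n": 966,
        "lipid_mean": 10.8, "lipid_sd": 1.8, "lipid_min": 3.4, "lipid_max": 19.8,
        "ed_mean": 1728.0, "ed_sd": 151.0, "ed_min": 1101.0, "ed_max": 2229.0,
        "fork_length_mean": 638.2, "fork_length_sd": 49.8,
        "weight_mean": 6.4, "weight_sd": 1.6,
        "run_first": "2020-07-16", "run_50pct": "2020-08-28", "run_last": "2020-09-29",
    },
    "Fall4_1": {
        "n": 473,
        "lipid_mean": 7.3, "lipid_sd": 1.6, "lipid_min": 2.1, "lipid_max": 15.6,
        "ed_mean": 1436.0, "ed_sd": 138.0, "ed_min": 985.0, "ed_max": 2143.0,
        "fork_length_mean": 671.5, "fork_length_sd": 61.4,
        "weight_mean": 8.2, "weight_sd": 2.6,
        "run_first": "2020-08-24", "run_50pct": "2020-09-21", "run_last": "2020-10-27",
    },
}

# Calibration cohort descriptors.
CALIBRATION_COHORT = {
    "n_fish": 63,
    "reading_min": 0.6,
    "reading_max": 16.8,
    "mass_min_kg": 0.25,
    "mass_max_kg": 11.05,
    "gonad_lipid_female_pct": (10.03, 1.89),   # mean, sd, % wet weight
    "gonad_lipid_male_pct": (0.68, 0.36),
}

# Within-season whole-body lipid declines by MU (percentage points).
MU_SEASONAL_DECLINE_PP = {
    "Spring5_2": 5.0,
    "Spring4_2": 4.0,   # not printed; small-n MU, taken as the Fall-like low end
    "Summer5_2": 5.0,
    "Summer4_1": 6.0,
    "Fall4_1": 4.0,
}

# Hatchery (fin-clipped) minus wild lipid difference among Harrison River
# Chinook, percentage points.
HATCHERY_LIPID_OFFSET_PP = -0.82

# Prey-requirement scenario anchors: an average 8 kg Chinook prey and the
# whale population requiring 245,000 Spring5_2-quality fish per year.
PREY_MASS_KG = 8.0
SPRING5_2_PREY_COUNT = 245_000.0
KJ_PER_KCAL = 4.184

MU_LIPID_MEANS = {mu: MU_SURVEY[mu]["lipid_mean"] for mu in MU_ORDER}
MU_ED_MEANS = {mu: MU_SURVEY[mu]["ed_mean"] for mu in MU_ORDER}
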