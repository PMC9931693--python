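import itertools

import numpy as np
import pandas as pd
import pytest

from chinooklipid import reference
from chinooklipid.survey import (
    EnergyConversion,
    anova_tukey,
    apply_calibration,
    attach_energy_density,
    compare_slopes,
    energy_density,
    fit_ed_conversion,
    hatchery_wild_test,
    mu_summary,
    seasonal_trend,
    weekly_cpue,
)

TABLE3_PAIRS = [
    (reference.MU_LIPID_MEANS[mu], reference.MU_ED_MEANS[mu])
    for mu in reference.MU_ORDER
]


@pytest.fixture(scope="module")
def survey_with_lipid(survey_df, published_cal):
    df = apply_calibration(survey_df, published_cal)
    return attach_energy_density(df, EnergyConversion.from_mu_means())


class TestApplyCalibration:
    def test_floor_reading_maps_to_two_percent(self, published_cal):
        df = pd.DataFrame({"reading_pos1": [0.6], "mu": ["Fall4_1"],
                           "date": ["2020-09-01"], "day_of_year": [245]})
        out = apply_calibration(df, published_cal)
        assert out["wbl_pct"].iloc[0] == pytest.approx(2.0818)

    def test_empty_input_gives_empty_output(self, published_cal):
        out = apply_calibration(pd.DataFrame({"reading_pos1": []}), published_cal)
        assert len(out) == 0 and "wbl_pct" in out.columns

    def test_identical_readings_give_zero_variance(self, published_cal):
        df = pd.DataFrame({"reading_pos1": [4.0] * 10})
        assert apply_calibration(df, published_cal)["wbl_pct"].std() == pytest.approx(
            0.0, abs=1e-12)

    def test_missing_readings_flagged_not_fatal(self, published_cal):
        df = pd.DataFrame({"reading_pos1": [4.0, np.nan]})
        out = apply_calibration(df, published_cal)
        assert np.isfinite(out["wbl_pct"].iloc[0])
        assert np.isnan(out["wbl_pct"].iloc[1])


class TestEnergyConversion:
    def test_fit_to_printed_mu_means(self):
        conv = fit_ed_conversion(TABLE3_PAIRS)
        assert conv.slope == pytest.approx(84.287, abs=0.01)
        assert conv.intercept == pytest.approx(819.96, abs=0.05)

    def test_two_points_interpolated_exactly(self):
        conv = fit_ed_conversion([(5.0, 1200.0), (10.0, 1700.0)])
        assert energy_density(5.0, conv) == pytest.approx(1200.0)
        assert energy_density(10.0, conv) == pytest.approx(1700.0)

    def test_held_out_spring4_2_prediction(self):
        conv = EnergyConversion.from_mu_means(exclude=("Spring4_2",))
        assert energy_density(12.2, conv) == pytest.approx(1849.0, rel=0.005)

    def test_zero_lipid_returns_intercept(self):
        conv = EnergyConversion(intercept=820.0, slope=84.0)
        assert energy_density(0.0, conv) == 820.0

    def test_mean_lipid_maps_near_mean_ed(self):
        conv = fit_ed_conversion(TABLE3_PAIRS)
        assert energy_density(12.8, conv) == pytest.approx(1899, abs=2)

    def test_strictly_increasing(self):
        conv = fit_ed_conversion(TABLE3_PAIRS)
        L = np.linspace(0, 30, 50)
        assert np.all(np.diff(energy_density(L, conv)) > 0)

    def test_degenerate_pairs_rejected(self):
        with pytest.raises(ValueError):
            fit_ed_conversion([(5.0, 1200.0), (5.0, 1300.0)])
        with pytest.raises(ValueError):
            EnergyConversion(intercept=800, slope=-1.0)


class TestMuSummary:
    def test_single_record(self, published_cal):
        df = pd.DataFrame({
            "mu": ["Fall4_1"], "reading_pos1": [4.0], "date": ["2020-09-10"],
            "day_of_year": [254], "fork_length": [650.0], "weight": [8.0],
        })
        s = mu_summary(apply_calibration(df, published_cal))
        row = s.loc["Fall4_1"]
        assert row["n"] == 1 and row["lipid_sd"] == 0
        assert row["run_first"] == row["run_50pct"] == row["run_last"]

    def test_matches_brute_force_statistics(self, survey_with_lipid):
        s = mu_summary(survey_with_lipid)
        for mu in s.index:
            v = survey_with_lipid.loc[survey_with_lipid["mu"] == mu, "wbl_pct"]
            assert s.loc[mu, "n"] == len(v)
            assert s.loc[mu, "lipid_mean"] == pytest.approx(v.mean())
            assert s.loc[mu, "lipid_sd"] == pytest.approx(v.std(ddof=1))
            assert s.loc[mu, "lipid_min"] == v.min()
            assert s.loc[mu, "lipid_max"] == v.max()

    def test_mu_means_near_printed_values(self, survey_with_lipid):
        """Packaged default reproduces the printed MU lipid means (2 SE)."""
        s = mu_summary(survey_with_lipid)
        for mu in reference.MU_ORDER:
            t3 = reference.MU_SURVEY[mu]
            se = t3["lipid_sd"] / np.sqrt(t3["n"])
            assert abs(s.loc[mu, "lipid_mean"] - t3["lipid_mean"]) < 2.5 * se, mu

    def test_run_50pct_matches_cumulative_scan(self, survey_with_lipid):
        s = mu_summary(survey_with_lipid)
        for mu in s.index:
            dates = sorted(pd.to_datetime(
                survey_with_lipid.loc[survey_with_lipid["mu"] == mu, "date"]))
            n = len(dates)
            for i, d in enumerate(dates, start=1):
                if i >= 0.5 * n:
                    assert s.loc[mu, "run_50pct"] == d
                    break


class TestAnovaTukey:
    def test_identical_groups_share_a_letter(self):
        g = {"A1": [5.0, 6, 7, 8], "B1": [5.0, 6, 7, 8], "C1": [5.0, 6, 7, 8]}
        anova, pairwise, letters = anova_tukey(g)
        assert anova.statistic == pytest.approx(0.0)
        assert len(set(letters.values())) == 1

    def test_survey_default_letter_grouping(self, survey_with_lipid):
        """MU letters reproduce the printed grouping: springs/summers high,
        Summer4_1 intermediate, Fall4_1 low; Spring4_2 excluded (n = 9)."""
        groups = {
            mu: survey_with_lipid.loc[survey_with_lipid["mu"] == mu, "wbl_pct"]
            for mu in ("Spring5_2", "Summer5_2", "Summer4_1", "Fall4_1")
        }
        _, _, letters = anova_tukey(groups)
        assert letters == {"Spring5_2": "A", "Summer5_2": "A",
                           "Summer4_1": "B", "Fall4_1": "C"}

    def test_tukey_p_matches_permutation_oracle(self):
        """Studentized-range p agrees with a max-|mean diff| permutation null."""
        rng = np.random.default_rng(0)
        g = {
            "g1": np.array([4.9, 6.1, 5.3, 5.6, 5.1]),
            "g2": np.array([5.8, 6.4, 6.9, 6.1, 7.2]),
            "g3": np.array([5.2, 5.9, 5.5, 6.3, 5.0]),
        }
        _, pairwise, _ = anova_tukey(g)
        pooled = np.concatenate(list(g.values()))
        n = 5
        obs = {
            (r["group_a"], r["group_b"]): abs(r["mean_diff"])
            for _, r in pairwise.iterrows()
        }
        reps = 4000
        exceed = {k: 0 for k in obs}
        for _ in range(reps):
            perm = rng.permutation(pooled)
            means = [perm[i * n:(i + 1) * n].mean() for i in range(3)]
            mx = max(abs(a - b) for a, b in itertools.combinations(means, 2))
            for k, v in obs.items():
                exceed[k] += mx >= v
        # the max-statistic permutation null matches the studentized-range
        # p where it matters (small/moderate p); both calls agree on clearly
        # non-significant pairs
        for _, r in pairwise.iterrows():
            p_perm = exceed[(r["group_a"], r["group_b"])] / reps
            if r["p_value"] < 0.5:
                assert r["p_value"] == pytest.approx(p_perm, abs=0.07)
            else:
                assert p_perm > 0.5

    def test_small_groups_excluded(self):
        g = {"ok1": [1.0, 2, 3], "ok2": [2.0, 3, 4], "tiny": [1.0]}
        anova, pairwise, letters = anova_tukey(g)
        assert "tiny" not in letters
        assert anova.df == (1, 4)

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            anova_tukey({"only": [1.0, 2, 3]})


class TestSeasonalTrend:
    def _frame(self, day, y, mu="Summer4_1"):
        dates = pd.to_datetime("2020-01-01") + pd.to_timedelta(day - 1, unit="D")
        return pd.DataFrame({"mu": mu, "day_of_year": day,
                             "wbl_pct": y, "date": dates.astype(str)})

    def test_constant_lipid_gives_zero_slope(self):
        df = self._frame(np.arange(200, 240), np.full(40, 9.5))
        t = seasonal_trend(df)
        assert t.slope_pp_per_day == 0.0
        assert t.p_value == pytest.approx(1.0)

    def test_slope_equals_cov_over_var_on_toy(self):
        day = np.array([200, 210, 220, 230, 240], dtype=float)
        y = np.array([12.0, 11.1, 10.4, 9.2, 8.6])
        t = seasonal_trend(self._frame(day, y))
        expected = np.cov(day, y, ddof=1)[0, 1] / np.var(day, ddof=1)
        assert t.slope_pp_per_day == pytest.approx(expected)
        assert t.total_change_pp == pytest.approx(expected * 40)

    def test_weekly_and_regression_declines_both_emitted(self, survey_with_lipid):
        t = seasonal_trend(survey_with_lipid, "Summer4_1")
        assert t.total_change_pp == pytest.approx(-6.0, abs=0.8)
        assert t.weekly_change_pp == pytest.approx(-6.0, abs=1.5)
        assert t.p_value < 1e-3

    def test_zero_date_spread_rejected(self):
        df = self._frame(np.full(10, 220), np.random.default_rng(0).normal(10, 1, 10))
        with pytest.raises(ValueError):
            seasonal_trend(df)


class TestCompareSlopes:
    def _mu(self, slope, n, seed, mu):
        r = np.random.default_rng(seed)
        day = r.uniform(200, 280, n)
        y = 20 + slope * day + r.normal(0, 1.5, n)
        dates = pd.to_datetime("2020-01-01") + pd.to_timedelta(day.astype(int), unit="D")
        return pd.DataFrame({"mu": mu, "day_of_year": day, "wbl_pct": y,
                             "date": dates.astype(str)})

    def test_equal_slopes_not_rejected(self):
        hits = sum(
            compare_slopes(self._mu(-0.05, 100, 2 * s, "Summer4_1"),
                           self._mu(-0.05, 100, 2 * s + 1, "Fall4_1")).p_value < 0.05
            for s in range(60)
        )
        assert hits <= 9  # binomial(60, 0.05): mean 3

    def test_survey_scale_slope_difference_detected(self):
        a = self._mu(-0.08, 900, 1, "Summer4_1")
        b = self._mu(-0.04, 450, 2, "Fall4_1")
        assert compare_slopes(a, b).p_value < 1e-3

    def test_equals_nested_rss_f_on_toy(self):
        a = self._mu(-0.06, 8, 5, "a")
        b = self._mu(-0.02, 8, 6, "b")
        res = compare_slopes(a, b)
        day = np.concatenate([a["day_of_year"], b["day_of_year"]])
        y = np.concatenate([a["wbl_pct"], b["wbl_pct"]])
        d = np.repeat([0.0, 1.0], 8)
        ones = np.ones(16)

        def rss(X):
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            return np.sum((y - X @ beta) ** 2)

        F = ((rss(np.column_stack([ones, d, day]))
              - rss(np.column_stack([ones, d, day, d * day])))
             / (rss(np.column_stack([ones, d, day, d * day])) / 12))
        assert res.statistic == pytest.approx(F)


class TestHatcheryWildTest:
    def test_identical_groups(self):
        v = [6.0, 7, 8, 9]
        df = pd.DataFrame({"wbl_pct": v + v, "fin_clipped": [True] * 4 + [False] * 4})
        res = hatchery_wild_test(df)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_brute_force_welch_t(self):
        rng = np.random.default_rng(1)
        clipped = rng.normal(6.48, 1.6, 6)
        wild = rng.normal(7.30, 1.6, 20)
        df = pd.DataFrame({
            "wbl_pct": np.concatenate([clipped, wild]),
            "fin_clipped": [True] * 6 + [False] * 20,
        })
        res = hatchery_wild_test(df)
        se = np.sqrt(clipped.var(ddof=1) / 6 + wild.var(ddof=1) / 20)
        assert res.statistic == pytest.approx((clipped.mean() - wild.mean()) / se)
        assert res.extra["difference"] == pytest.approx(clipped.mean() - wild.mean())

    def test_harrison_offset_recovered_over_replicates(self, published_cal):
        """The configured −0.82 pp hatchery offset is recovered on average."""
        from chinooklipid.synthetic_data import default_survey_config, generate_survey
        diffs = []
        for seed in range(8):
            df = apply_calibration(
                generate_survey(default_survey_config(seed)), published_cal)
            harrison = df[df["stock"] == "Harrison"]
            diffs.append(hatchery_wild_test(harrison).extra["difference"])
        assert np.mean(diffs) == pytest.approx(-0.82, abs=0.15)

    def test_missing_class_rejected(self):
        df = pd.DataFrame({"wbl_pct": [1.0, 2, 3], "fin_clipped": [True] * 3})
        with pytest.raises(ValueError):
            hatchery_wild_test(df)


class TestWeeklyCpue:
    def test_simple_ratio(self):
        ev = pd.DataFrame({"date": ["2020-08-03"], "mu": ["Fall4_1"],
                           "catch": [10], "effort": [5.0]})
        out = weekly_cpue(ev)
        assert out["cpue"].iloc[0] == 2.0

    def test_splitting_week_across_days_preserves_value(self):
        one = pd.DataFrame({"date": ["2020-08-03"], "mu": ["Fall4_1"],
                            "catch": [10], "effort": [6.0]})
        split = pd.DataFrame({
            "date": ["2020-08-03", "2020-08-05"], "mu": ["Fall4_1"] * 2,
            "catch": [4, 6], "effort": [3.0, 3.0],
        })
        assert weekly_cpue(one)["cpue"].iloc[0] == weekly_cpue(split)["cpue"].iloc[0]

    def test_matches_brute_force_groupby_on_toy_table(self):
        rng = np.random.default_rng(2)
        ev = pd.DataFrame({
            "date": pd.to_datetime("2020-07-01")
            + pd.to_timedelta(rng.integers(0, 28, 20), unit="D"),
            "mu": rng.choice(["Summer4_1", "Fall4_1"], 20),
            "catch": rng.integers(0, 12, 20),
            "effort": rng.uniform(1, 10, 20),
        })
        out = weekly_cpue(ev)
        iso = ev["date"].dt.isocalendar()
        for _, row in out.iterrows():
            m = ((ev["mu"] == row["mu"]) & (iso.week == row["iso_week"])
                 & (iso.year == row["iso_year"]))
            assert row["cpue"] == pytest.approx(
                ev.loc[m, "catch"].sum() / ev.loc[m, "effort"].sum())

    def test_nonpositive_effort_rows_dropped(self):
        ev = pd.DataFrame({"date": ["2020-08-03", "2020-08-04"],
                           "mu": ["Fall4_1"] * 2, "catch": [5, 5],
                           "effort": [0.0, 5.0]})
        out = weekly_cpue(ev)
        assert out["effort"].sum() == 5.0
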