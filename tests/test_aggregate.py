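"""Camera deduplication and monthly numerators/denominators."""

from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from chitalseason import (
    at_risk_denominator,
    dedupe_camera_triggers,
    monthly_conceptions,
    monthly_hard_antler,
)


def obs_frame(minutes, camera="c1", source="camera", state="hard", base="2018-02-01"):
    t0 = pd.Timestamp(base)
    return pd.DataFrame(
        {
            "timestamp": [t0 + pd.Timedelta(minutes=m) for m in minutes],
            "source": source,
            "camera_id": camera,
            "antler_state": state,
        }
    )


class TestDedup:
    def test_greedy_thinning_against_last_kept(self):
        out = dedupe_camera_triggers(obs_frame([0, 30, 61, 200]))
        kept = [(t - pd.Timestamp("2018-02-01")).total_seconds() / 60
                for t in out["timestamp"]]
        assert kept == [0, 61, 200]  # 30 is <60 after 0; 61 is >=60 after 0

    def test_rule_is_per_camera(self):
        df = pd.concat(
            [obs_frame([0, 30], camera="c1"), obs_frame([0, 30], camera="c2")]
        )
        assert len(dedupe_camera_triggers(df)) == 2

    def test_exactly_window_gap_is_kept(self):
        assert len(dedupe_camera_triggers(obs_frame([0, 60]))) == 2

    def test_incidental_untouched(self):
        df = obs_frame([0, 1, 2], source="incidental")
        out = dedupe_camera_triggers(df)
        pd.testing.assert_frame_equal(
            out.sort_values("timestamp").reset_index(drop=True),
            df.sort_values("timestamp").reset_index(drop=True),
        )

    def test_empty_input(self):
        empty = obs_frame([]).iloc[:0]
        assert dedupe_camera_triggers(empty).empty

    @given(
        st.lists(st.integers(min_value=0, max_value=5000), min_size=0, max_size=40)
    )
    def test_idempotent(self, minutes):
        df = obs_frame(sorted(minutes))
        once = dedupe_camera_triggers(df)
        twice = dedupe_camera_triggers(once)
        pd.testing.assert_frame_equal(
            once.reset_index(drop=True), twice.reset_index(drop=True)
        )


class TestMonthlyAntler:
    def test_counts_and_proportion(self):
        df = obs_frame(range(10), source="incidental")
        df.loc[4:, "antler_state"] = "velvet"
        out = monthly_hard_antler(df)
        row = out.iloc[0]
        assert (row["n_sampled"], row["n_hard"]) == (10, 4)
        assert row["prop_hard"] == pytest.approx(0.4)

    def test_unknown_states_excluded_everywhere(self):
        df = obs_frame(range(6), source="incidental")
        df.loc[3:, "antler_state"] = "unknown"
        out = monthly_hard_antler(df)
        assert out.iloc[0]["n_sampled"] == 3

    def test_empty_months_flagged_missing_not_zero(self):
        jan = obs_frame([0], base="2018-01-15", source="incidental")
        mar = obs_frame([0], base="2018-03-15", source="incidental")
        out = monthly_hard_antler(pd.concat([jan, mar]))
        assert len(out) == 3
        assert np.isnan(out.loc[pd.Period("2018-02", "M"), "n_sampled"])

    def test_monthly_sums_match_totals(self, truth_small):
        from chitalseason import gen_antler_observations

        obs = gen_antler_observations(truth_small)
        deduped = dedupe_camera_triggers(obs)
        out = monthly_hard_antler(deduped)
        usable = deduped[deduped["antler_state"].isin(("hard", "velvet", "cast"))]
        assert out["n_sampled"].sum() == len(usable)
        assert out["n_hard"].sum() == (usable["antler_state"] == "hard").sum()
        with_data = out.dropna()
        assert (with_data["n_hard"] <= with_data["n_sampled"]).all()


class TestAtRisk:
    def test_gestation_window_months(self):
        counts = at_risk_denominator([date(2016, 11, 15)], 229)
        assert counts.index.min() == pd.Period("2016-04", "M")  # March excluded
        assert counts.index.max() == pd.Period("2016-11", "M")
        assert (counts == 1).all() and len(counts) == 8

    def test_same_day_cohort_denominator(self):
        counts = at_risk_denominator([date(2016, 11, 15)] * 10, 229)
        assert (counts == 10).all()

    def test_empty_culls_rejected(self):
        with pytest.raises(ValueError):
            at_risk_denominator([], 229)

    def test_conception_month_inside_own_window(self, truth_small):
        """Back-calculated conception months always lie in the at-risk span."""
        from chitalseason import back_calculate_table, gen_culls, gen_rainfall

        rain = gen_rainfall(truth_small)
        culls = gen_culls(truth_small, rain)
        conc = back_calculate_table(culls.rename(columns={}), truth_small.growth)
        at_risk = at_risk_denominator(
            culls["cull_date"], truth_small.growth.max_age
        )
        months = pd.PeriodIndex(conc["conception_date"], freq="M")
        assert all(at_risk.get(m, 0) > 0 for m in months)


class TestMonthlyConceptions:
    def test_percentage(self):
        at_risk = pd.Series(
            20, index=pd.period_range("2016-04", "2016-11", freq="M")
        )
        dates = [date(2016, 6, 1)] * 3
        out = monthly_conceptions(dates, at_risk)
        assert out.loc[pd.Period("2016-06", "M"), "pct_conceived"] == pytest.approx(
            15.0
        )

    def test_empty_conceptions_keep_denominators(self):
        at_risk = pd.Series(
            5, index=pd.period_range("2016-04", "2016-07", freq="M")
        )
        out = monthly_conceptions([], at_risk)
        assert (out["n_conceived"] == 0).all()
        assert (out["n_at_risk"] == 5).all()

    def test_conception_without_denominator_is_inconsistent(self):
        at_risk = pd.Series(
            [0, 4], index=pd.period_range("2016-04", "2016-05", freq="M")
        )
        with pytest.raises(ValueError, match="at-risk"):
            monthly_conceptions([date(2016, 4, 10)], at_risk)

    def test_numerator_never_exceeds_denominator(self, truth_small):
        from chitalseason import back_calculate_table, gen_culls, gen_rainfall

        rain = gen_rainfall(truth_small)
        culls = gen_culls(truth_small, rain)
        conc = back_calculate_table(culls, truth_small.growth)
        at_risk = at_risk_denominator(culls["cull_date"], 229)
        out = monthly_conceptions(conc["conception_date"], at_risk)
        ok = out["n_at_risk"] > 0
        assert (out.loc[ok, "n_conceived"] <= out.loc[ok, "n_at_risk"]).all()
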