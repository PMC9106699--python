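import numpy as np
import pandas as pd
import pytest

from helpers import dp_match_oracle, random_small_instance
from windmatch import (MatchedPairSet, MatchingConstraints, admissible, match_pairs,
                       matching_summary, pair_distance)
from windmatch.matching import admissibility_matrices


class TestConstraints:
    def test_defaults_mirror_study_design(self):
        c = MatchingConstraints()
        assert (c.min_date_gap, c.max_date_gap) == (4, 60)
        assert c.calipers == {"temperature": 5.0, "wind_speed": 0.5,
                              "humidity": 12.0, "pm10_lag1": 8.0}
        assert "rainfall_cat" in c.exact_vars and "w_lag1" in c.exact_vars

    def test_invalid_constraints_rejected(self):
        with pytest.raises(ValueError):
            MatchingConstraints(min_date_gap=10, max_date_gap=5)
        with pytest.raises(ValueError):
            MatchingConstraints(calipers={"temperature": 0.0})


class TestAdmissible:
    def test_within_all_calipers(self, day_pair):
        t, c = day_pair(c_temperature=18.0, c_wind_speed=3.3, c_humidity=55.0,
                        c_pm10_lag1=29.0)
        assert admissible(t, c) is True

    def test_temperature_caliper_binds_above_five(self, day_pair):
        t, c = day_pair(c_temperature=26.0)          # gap 6 > 5
        assert admissible(t, c) is False
        t, c = day_pair(c_temperature=25.0)          # gap exactly 5: closed caliper
        assert admissible(t, c) is True

    def test_sutva_minimum_date_gap(self, day_pair):
        t, c = day_pair(c_date=pd.Timestamp("2015-06-04"))   # 3 days apart
        assert admissible(t, c) is False
        t, c = day_pair(c_date=pd.Timestamp("2015-06-05"))   # 4 days: allowed
        assert admissible(t, c) is True
        t, c = day_pair(c_date=pd.Timestamp("2015-08-15"))   # 75 days: too far
        assert admissible(t, c) is False

    def test_exact_variables_must_match(self, day_pair):
        for field, value in (("rainfall_cat", 2), ("weekend", 1), ("w_lag1", 1.0)):
            t, c = day_pair(**{f"c_{field}": value})
            assert admissible(t, c) is False

    def test_missing_covariate_is_inadmissible_not_error(self, day_pair):
        t, c = day_pair(c_pm10_lag1=np.nan)
        assert admissible(t, c) is False

    def test_wrong_roles_rejected(self, day_pair):
        t, c = day_pair()
        with pytest.raises(ValueError):
            admissible(c, t)

    def test_both_zero_lag_option(self, day_pair):
        t, c = day_pair(t_w_lag1=1.0, c_w_lag1=1.0)
        assert admissible(t, c) is True
        strict = MatchingConstraints(lag_w_both_zero=True)
        assert admissible(t, c, strict) is False


class TestPairDistance:
    def test_coincident_days_have_zero_distance(self, day_pair):
        t, c = day_pair(c_date=pd.Timestamp("2015-06-01"))
        loose = MatchingConstraints(min_date_gap=0)
        assert pair_distance(t, c, loose) == 0.0

    def test_hand_computed_normalized_distance(self, day_pair):
        t, c = day_pair(c_temperature=18.0, c_wind_speed=2.8, c_humidity=54.0,
                        c_pm10_lag1=21.0, c_date=pd.Timestamp("2015-06-13"))
        # 2/5 + 0.2/0.5 + 6/12 + 4/8 + 12/60 = 2.0
        assert pair_distance(t, c) == pytest.approx(2.0)

    def test_distance_is_linear_in_gaps(self, day_pair):
        t, c1 = day_pair(c_temperature=19.0, c_wind_speed=2.9, c_humidity=57.0,
                         c_pm10_lag1=23.0, c_date=pd.Timestamp("2015-06-07"))
        t, c2 = day_pair(c_temperature=18.0, c_wind_speed=2.8, c_humidity=54.0,
                         c_pm10_lag1=21.0, c_date=pd.Timestamp("2015-06-13"))
        assert pair_distance(t, c2) == pytest.approx(2 * pair_distance(t, c1))

    def test_inadmissible_pair_rejected(self, day_pair):
        t, c = day_pair(c_temperature=30.0)
        with pytest.raises(ValueError):
            pair_distance(t, c)


def _mini_table(treated_days, control_days, **cols):
    rows = []
    for day in treated_days:
        rows.append({"date": pd.Timestamp("2016-05-01") + pd.Timedelta(days=day), "w": 1})
    for day in control_days:
        rows.append({"date": pd.Timestamp("2016-05-01") + pd.Timedelta(days=day), "w": 0})
    df = pd.DataFrame(rows)
    defaults = {"temperature": 15.0, "wind_speed": 3.0, "humidity": 60.0,
                "pm10_lag1": 20.0, "w_lag1": 0.0, "rainfall_cat": 1,
                "weekend": 0, "holiday": 0, "bank_day": 0}
    for col, val in (defaults | cols).items():
        df[col] = val
    return df.sort_values("date").reset_index(drop=True)


class TestMatchPairs:
    def test_picks_minimum_distance_perfect_matching(self):
        # treated at days 0, 10; controls at days 5, 15.  Date gaps:
        # (t0,c5)=5, (t0,c15)=15, (t10,c5)=5, (t10,c15)=5 -> optimal total
        # pairs t0-c5 and t10-c15 (10/60) beat t0-c15 + t10-c5 (20/60).
        df = _mini_table([0, 10], [5, 15])
        pairs = match_pairs(df)
        assert pairs.j == 2
        got = set(zip(pairs.pairs["treated_date"].dt.day, pairs.pairs["control_date"].dt.day))
        assert got == {(1, 6), (11, 16)}
        assert pairs.total_distance == pytest.approx(10 / 60)

    def test_no_admissible_edges_gives_empty_set(self):
        df = _mini_table([0], [1])   # gap 1 < SUTVA minimum of 4
        pairs = match_pairs(df)
        assert pairs.j == 0
        assert pairs.matched_fraction == 0.0

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(40):
            df, constraints = random_small_instance(rng)
            pairs = match_pairs(df, constraints)
            _, _, ok, dist = admissibility_matrices(df, constraints)
            card, total = dp_match_oracle(ok, dist)
            assert pairs.j == card
            assert pairs.total_distance == pytest.approx(total, abs=1e-8)

    def test_pairs_are_disjoint_and_admissible(self, medium_study):
        sds, pairs = medium_study
        assert pairs.j > 0
        pairs.validate(match_pairs_frame(sds.observed), MatchingConstraints())

    def test_relaxing_a_caliper_never_reduces_cardinality(self):
        rng = np.random.default_rng(77)
        df, constraints = random_small_instance(rng)
        relaxed_calipers = dict(constraints.calipers, temperature=999.0)
        relaxed = MatchingConstraints(min_date_gap=constraints.min_date_gap,
                                      max_date_gap=constraints.max_date_gap,
                                      calipers=relaxed_calipers)
        assert match_pairs(df, relaxed).j >= match_pairs(df, constraints).j

    def test_deterministic_across_runs(self, medium_study):
        sds, pairs = medium_study
        again = match_pairs(sds.observed, MatchingConstraints())
        pd.testing.assert_frame_equal(pairs.pairs, again.pairs)


def match_pairs_frame(df):
    """The table match_pairs actually matched on (with derived lag columns)."""
    from windmatch import add_lags_and_leads
    return add_lags_and_leads(df, ["w", "pm10"], [-1])


class TestMatchingSummary:
    def test_fraction_one_when_all_treated_matched(self):
        df = _mini_table([0, 10], [5, 15])
        pairs = match_pairs(df)
        assert matching_summary(df, pairs)["matched_fraction"] == 1.0

    def test_fraction_zero_when_nothing_matched(self):
        df = _mini_table([0], [1])
        pairs = match_pairs(df)
        assert matching_summary(df, pairs)["matched_fraction"] == 0.0

    def test_fraction_rounded_to_three_decimals(self):
        # 121 matched of 912 treated -> 0.133
        pairs = MatchedPairSet(
            pairs=pd.DataFrame({"treated_index": range(121),
                                "control_index": range(1000, 1121),
                                "treated_date": pd.NaT, "control_date": pd.NaT,
                                "distance": 0.0}),
            n_treated=912, n_control=3106)
        assert pairs.matched_fraction == pytest.approx(121 / 912)
        df = _mini_table([0], [5])
        assert matching_summary(df, pairs)["matched_fraction"] == 0.133
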