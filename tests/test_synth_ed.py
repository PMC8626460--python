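"""Synthetic attendance-stream generator: mechanism, drift events, determinism."""

import io

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from shapdrift import synth_ed
from shapdrift.synth_ed import (
    DEFAULT_INTERCEPT,
    make_scenario,
    simulate_cohort,
    true_risk,
    write_episodes_csv,
)


def zero_coef_scenario(intercept, **kw):
    sc = make_scenario("baseline", intercept=intercept, **kw)
    sc.numeric = {k: synth_ed.NumericSpec(v.mean, v.sd, v.missing_rate, 0.0, v.lo, v.hi) for k, v in sc.numeric.items()}
    sc.categorical = {
        k: synth_ed.CategoricalSpec(v.probs, {lv: 0.0 for lv in v.probs}) for k, v in sc.categorical.items()
    }
    sc.history = {k: synth_ed.HistorySpec(v.rate, 0.0) for k, v in sc.history.items()}
    return sc


class TestMakeScenario:
    def test_baseline_has_no_drift_events(self):
        sc = make_scenario("baseline")
        assert sc.drift_events == []
        assert sc.at_week(0).intercept == sc.at_week(sc.horizon_weeks - 1).intercept

    def test_prevalence_shift_is_step_in_intercept_only(self):
        sc = make_scenario("prevalence_shift", delta=1.0, onset_week=30)
        assert sc.at_week(29).intercept == pytest.approx(sc.intercept)
        assert sc.at_week(30).intercept == pytest.approx(sc.intercept + 1.0)
        assert sc.at_week(30).categorical["arrival_mode"].probs == sc.categorical["arrival_mode"].probs

    def test_unknown_kind_and_bad_onset_rejected(self):
        with pytest.raises(ValueError, match="unknown scenario kind"):
            make_scenario("apocalypse")
        with pytest.raises(ValueError):
            make_scenario("prevalence_shift", onset_week=99, horizon_weeks=48)

    def test_covid_like_combines_all_components(self):
        sc = make_scenario("covid_like")
        eff = sc.at_week(sc.horizon_weeks - 1)
        base = sc.at_week(0)
        assert eff.categorical["arrival_mode"].probs["walk_in"] < base.categorical["arrival_mode"].probs["walk_in"]
        assert eff.intercept > base.intercept
        assert eff.numeric["resp_rate"].missing_rate < base.numeric["resp_rate"].missing_rate
        assert "viral_illness" in eff.categorical["attendance_complaint"].probs
        assert "viral_illness" not in base.categorical["attendance_complaint"].probs
        assert eff.weekly_volume < base.weekly_volume

    def test_category_emergence_preserves_sum_to_one(self):
        sc = make_scenario("category_emergence", mass=0.25, onset_week=10)
        probs = sc.at_week(10).categorical["attendance_complaint"].probs
        assert sum(probs.values()) == pytest.approx(1.0)
        assert probs["viral_illness"] == pytest.approx(0.25)


class TestTrueRisk:
    def test_zero_coefficients_give_intercept_risk(self):
        sc = zero_coef_scenario(intercept=np.log(0.3 / 0.7))
        record = {"age": 99, "resp_rate": 40, "arrival_mode": "ambulance",
                  "attendance_complaint": "injury", "triage_complaint": "other",
                  "triage_discriminator": "other"}
        assert true_risk(record, sc, 0) == pytest.approx(0.3)

    def test_single_feature_closed_form(self):
        sc = zero_coef_scenario(intercept=0.0)
        sc.numeric["age"] = synth_ed.NumericSpec(0.0, 1.0, 0.0, 0.5)
        record = {"age": 2.0, "arrival_mode": "walk_in",
                  "attendance_complaint": "other", "triage_complaint": "other",
                  "triage_discriminator": "other"}
        assert true_risk(record, sc, 0) == pytest.approx(1 / (1 + np.exp(-1.0)), abs=1e-4)

    def test_monotone_in_positive_coefficient_feature(self):
        sc = make_scenario("baseline")
        base = {"age": 55, "resp_rate": 17, "pulse_rate": 85, "temperature": 36.9,
                "spo2": 96, "news2": 2, "arrival_mode": "walk_in",
                "attendance_complaint": "other", "triage_complaint": "other",
                "triage_discriminator": "other"}
        risks = [true_risk({**base, "resp_rate": v}, sc, 0) for v in (12, 17, 25, 35)]
        assert risks == sorted(risks)

    def test_unknown_level_outside_emergence_window_raises(self):
        sc = make_scenario("category_emergence", onset_week=10)
        record = {"age": 55, "arrival_mode": "walk_in",
                  "attendance_complaint": "viral_illness", "triage_complaint": "other",
                  "triage_discriminator": "other"}
        with pytest.raises(KeyError):
            true_risk(record, sc, 5)
        assert 0 < true_risk(record, sc, 10) < 1


class TestSimulateCohort:
    def test_null_mechanism_hits_binomial_rate(self):
        """All coefficients zero, intercept logit(0.3): empirical rate in the
        exact binomial 99% interval around 0.30."""
        sc = zero_coef_scenario(intercept=float(np.log(0.3 / 0.7)))
        table = simulate_cohort(sc, n=10_000, seed=42)
        lo, hi = stats.binom.interval(0.99, 10_000, 0.3)
        assert lo <= table["outcome"].sum() <= hi

    def test_empty_request_returns_valid_schema(self):
        sc = make_scenario("baseline")
        table = simulate_cohort(sc, n=0, seed=0)
        assert len(table) == 0
        assert list(table.columns) == synth_ed.csv_columns(sc)

    def test_same_seed_is_byte_identical(self):
        sc = make_scenario("covid_like")
        a = synth_ed.table_to_csv_bytes(simulate_cohort(sc, n=2000, seed=9))
        b = synth_ed.table_to_csv_bytes(simulate_cohort(sc, n=2000, seed=9))
        assert a == b

    def test_episode_ids_unique_and_timestamps_in_horizon(self):
        sc = make_scenario("baseline", horizon_weeks=10, split_weeks=(4, 8))
        table = simulate_cohort(sc, seed=1)
        assert table["episode_id"].is_unique
        end = sc.start_date + pd.Timedelta(weeks=10)
        assert (table["timestamp"] >= sc.start_date).all()
        assert (table["timestamp"] < end).all()

    def test_baseline_weekly_statistics_are_stationary(self):
        """No week's admission rate / walk-in fraction / missingness departs
        from the global value beyond exact binomial 99.9% bounds."""
        sc = make_scenario("baseline", weekly_volume=600, horizon_weeks=10, split_weeks=(4, 8))
        table = simulate_cohort(sc, seed=17)
        week = ((table["timestamp"] - sc.start_date).dt.days // 7).to_numpy()
        for series in (
            table["outcome"].to_numpy(),
            (table["arrival_mode"] == "walk_in").to_numpy(),
            table["resp_rate"].isna().to_numpy(),
        ):
            p = series.mean()
            for w in range(10):
                m = week == w
                lo, hi = stats.binom.interval(0.999, m.sum(), p)
                assert lo <= series[m].sum() <= hi

    def test_csv_round_trip(self, tmp_path):
        sc = make_scenario("baseline", horizon_weeks=4, split_weeks=(2, 3))
        table = simulate_cohort(sc, n=200, seed=3)
        path = tmp_path / "episodes.csv"
        write_episodes_csv(table, path)
        header = path.read_text().splitlines()[0]
        assert header.startswith("episode_id,timestamp,outcome,age,resp_rate,pulse_rate,")
        assert header.endswith("cohort")
        loaded = synth_ed.read_episodes_csv(path)
        assert len(loaded) == len(table)
        assert loaded["resp_rate"].isna().sum() == table["resp_rate"].isna().sum()


class TestDriftSemantics:
    def test_prevalence_shift_moves_rate_not_marginals(self):
        """Intercept step: outcome rate jumps while feature marginals are
        indistinguishable pre/post (two-sample KS over 20 seeds)."""
        pvals = []
        rate_gaps = []
        for seed in range(20):
            sc = make_scenario("prevalence_shift", delta=1.0, horizon_weeks=10,
                               onset_week=5, split_weeks=(4, 5), weekly_volume=500)
            table = simulate_cohort(sc, seed=seed)
            post = (table["timestamp"] >= sc.start_date + pd.Timedelta(weeks=5)).to_numpy()
            a = table.loc[~post, "age"].head(5000)
            b = table.loc[post, "age"].head(5000)
            pvals.append(stats.ks_2samp(a, b).pvalue)
            rate_gaps.append(table.loc[post, "outcome"].mean() - table.loc[~post, "outcome"].mean())
        # Bonferroni-style: no KS rejection at alpha/20
        assert min(pvals) > 0.01 / 20
        assert np.mean(rate_gaps) > 0.1

    def test_concept_shift_flips_association_not_marginal(self):
        """Sign-flipped resp_rate coefficient: the resp_rate marginal is
        unchanged while the conditional admission rate given high resp_rate
        drops below the low-resp_rate rate after onset."""
        sc = make_scenario("concept_shift", feature="resp_rate", horizon_weeks=10,
                           onset_week=5, split_weeks=(4, 5), weekly_volume=2000)
        table = simulate_cohort(sc, seed=5)
        post = (table["timestamp"] >= sc.start_date + pd.Timedelta(weeks=5)).to_numpy()
        rr = table["resp_rate"]
        high = rr > rr.median()
        pre_assoc = table.loc[~post & high, "outcome"].mean() - table.loc[~post & ~high, "outcome"].mean()
        post_assoc = table.loc[post & high, "outcome"].mean() - table.loc[post & ~high, "outcome"].mean()
        assert pre_assoc > 0.05
        assert post_assoc < -0.05
        ks = stats.ks_2samp(rr[~post].dropna().head(5000), rr[post].dropna().head(5000))
        assert ks.pvalue > 0.01
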