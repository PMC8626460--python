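"""Flagging rules, drift-type classification, end-to-end reproducibility."""

import json

import numpy as np
import pandas as pd
import pytest

from shapdrift import monitor
from shapdrift.driftstats import NormalisedShares
from shapdrift.monitor import (
    MonitorConfig,
    classify_drift,
    flag_importance_drift,
    flag_performance_drift,
    run_monitoring,
)

WEEK0 = pd.Timestamp("2019-04-01")


def shares_stream(shift_feature=None, shift_week=None, shift=0.0, n_weeks=12, per_week=80, seed=0):
    """Synthetic share rows: Dirichlet-ish stable shares with an optional step."""
    rng = np.random.default_rng(seed)
    d = 3
    rows, ts = [], []
    for w in range(n_weeks):
        raw = np.abs(rng.normal(1.0, 0.2, size=(per_week, d)))
        if shift_feature is not None and shift_week is not None and w >= shift_week:
            raw[:, shift_feature] *= 1.0 + shift
        rows.append(raw / raw.sum(axis=1, keepdims=True))
        ts.append(WEEK0 + pd.Timedelta(weeks=w) + pd.to_timedelta(rng.integers(0, 7, per_week), "D"))
    shares = np.vstack(rows)
    return NormalisedShares(shares, np.zeros(len(shares), bool), [f"f{i}" for i in range(d)]), pd.DatetimeIndex(np.concatenate([t.to_numpy() for t in ts]))


class TestFlagImportance:
    def test_step_shift_flagged_with_persistence(self):
        ns, ts = shares_stream(shift_feature=0, shift_week=8, shift=0.5, seed=1)
        flags = flag_importance_drift(ns, ts, (WEEK0, WEEK0 + pd.Timedelta(weeks=8)), k_consec=2, n_boot=300, seed=0)
        weeks = [w for w, _ in flags["f0"]]
        assert weeks and min(weeks) <= WEEK0 + pd.Timedelta(weeks=9)
        assert all(d == "up" for _, d in flags["f0"])

    def test_single_bin_excursion_not_flagged(self):
        ns, ts = shares_stream(seed=2)
        # inject a one-week excursion in the monitored period
        week_mask = (ts >= WEEK0 + pd.Timedelta(weeks=9)) & (ts < WEEK0 + pd.Timedelta(weeks=10))
        ns.shares[np.asarray(week_mask), 0] += 0.3
        ns.shares /= ns.shares.sum(axis=1, keepdims=True)
        flags = flag_importance_drift(ns, ts, (WEEK0, WEEK0 + pd.Timedelta(weeks=8)), k_consec=2, n_boot=300, seed=0)
        assert flags["f0"] == []

    def test_stable_stream_rarely_flags(self):
        total = 0
        for seed in range(5):
            ns, ts = shares_stream(seed=seed + 10)
            flags = flag_importance_drift(ns, ts, (WEEK0, WEEK0 + pd.Timedelta(weeks=8)), k_consec=2, n_boot=300, seed=seed)
            total += sum(len(v) for v in flags.values())
        # 5 streams x 3 features x 4 monitored weeks = 60 opportunities
        assert total <= 3

    def test_empty_baseline_rejected(self):
        ns, ts = shares_stream()
        with pytest.raises(ValueError):
            flag_importance_drift(ns, ts, (WEEK0 - pd.Timedelta(weeks=5), WEEK0), k_consec=2, n_boot=10)


class TestFlagPerformance:
    @staticmethod
    def series(ci_los, ci_his, defined=None):
        n = len(ci_los)
        return pd.DataFrame(
            {
                "week": [WEEK0 + pd.Timedelta(weeks=w) for w in range(n)],
                "auroc": np.add(ci_los, ci_his) / 2,
                "ci_lo": ci_los,
                "ci_hi": ci_his,
                "n": 100,
                "n_pos": 30,
                "defined": defined if defined is not None else [True] * n,
            }
        )

    def test_sustained_degradation_flagged(self):
        s = self.series([0.6] * 4 + [0.5] * 3, [0.82] * 4 + [0.7] * 3)
        flags = flag_performance_drift(s, reference_auroc=0.8, k_consec=2)
        assert flags == [WEEK0 + pd.Timedelta(weeks=5), WEEK0 + pd.Timedelta(weeks=6)]

    def test_overlapping_cis_never_flag(self):
        s = self.series([0.7] * 6, [0.85] * 6)
        assert flag_performance_drift(s, reference_auroc=0.8, k_consec=2) == []

    def test_single_low_week_not_flagged(self):
        s = self.series([0.6, 0.5, 0.6], [0.82, 0.7, 0.82])
        assert flag_performance_drift(s, reference_auroc=0.8, k_consec=2) == []

    def test_undefined_bins_skipped_not_fatal(self):
        s = self.series([0.5, np.nan, 0.5], [0.7, np.nan, 0.7], defined=[True, False, True])
        # the two defined bins are consecutive defined bins
        assert flag_performance_drift(s, reference_auroc=0.8, k_consec=2) == [WEEK0 + pd.Timedelta(weeks=2)]

    def test_all_undefined_rejected(self):
        s = self.series([np.nan], [np.nan], defined=[False])
        with pytest.raises(ValueError):
            flag_performance_drift(s, reference_auroc=0.8)


class TestClassify:
    WINDOW = (WEEK0, WEEK0 + pd.Timedelta(weeks=8))

    def test_rule_table(self):
        w = WEEK0 + pd.Timedelta(weeks=2)
        imp = {"f0": [(w, "up")]}
        no_imp = {"f0": []}
        perf = [w]
        assert classify_drift(no_imp, [], self.WINDOW) == "stable"
        assert classify_drift(imp, [], self.WINDOW) == "data_drift_no_degradation"
        assert classify_drift(no_imp, perf, self.WINDOW) == "concept_drift_suspected"
        assert classify_drift(imp, perf, self.WINDOW) == "data_drift_with_degradation"

    def test_flags_outside_window_ignored(self):
        w = WEEK0 + pd.Timedelta(weeks=20)
        assert classify_drift({"f0": [(w, "up")]}, [w], self.WINDOW) == "stable"

    def test_pure_function_of_flag_sets(self):
        w = WEEK0 + pd.Timedelta(weeks=1)
        imp = {"a": [(w, "up")], "b": [(w, "down")]}
        assert classify_drift(imp, [], self.WINDOW) == classify_drift(
            dict(reversed(list(imp.items()))), [], self.WINDOW
        )


@pytest.fixture(scope="module")
def quick_config():
    return dict(
        scenario_params={"weekly_volume": 60, "horizon_weeks": 30, "onset_week": 22, "split_weeks": (10, 22)},
        n_boot_shares=200,
        n_boot_auroc=100,
        background_size=16,
    )


class TestRunMonitoring:

    def test_report_is_reproducible(self, quick_config):
        a = run_monitoring(MonitorConfig(scenario="baseline", seed=5, **quick_config))
        b = run_monitoring(MonitorConfig(scenario="baseline", seed=5, **quick_config))
        assert a.to_json() == b.to_json()

    def test_report_structure_and_persistence(self, quick_config, tmp_path):
        rep = run_monitoring(MonitorConfig(scenario="covid_like", seed=5, **quick_config))
        assert rep.classification in monitor.CLASSIFICATIONS
        assert any(ev["level"] == "viral_illness" for ev in rep.new_category_events)
        assert not rep.importance_delta["delta"].isna().any()
        rep.to_json(tmp_path / "report.json")
        doc = json.loads((tmp_path / "report.json").read_text())
        assert doc["classification"] == rep.classification
        rep.write_tables(tmp_path)
        assert (tmp_path / "importance_series.csv").exists()
        assert (tmp_path / "prevalence_attendance_complaint.csv").exists()

    def test_stage_errors_are_tagged(self):
        with pytest.raises((RuntimeError, ValueError), match="scenario"):
            run_monitoring(MonitorConfig(scenario="nonsense", seed=0))
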