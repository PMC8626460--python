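"""Drift flagging, data-vs-concept drift typing, and the end-to-end pipeline.

The decision logic operationalises a simple surveillance principle: weekly
normalised-share series index how the model *uses* its inputs, weekly AUROC
indexes how well it ranks outcomes, and the combination types the drift —

======================  ====================  ================================
importance flags        performance flags     classification
======================  ====================  ================================
no                      no                    stable
yes                     no                    data_drift_no_degradation
no                      yes                   concept_drift_suspected
yes                     yes                   data_drift_with_degradation
======================  ====================  ================================

Performance degrading while the share series stay put means the model's
decision making has not changed, so the feature-outcome relationship must
have: concept drift. Moving shares are direct evidence of data drift,
retraining-relevant even before any performance loss appears.

Flagging rules (the quantitative thresholds are this package's own
operationalisation — share series in the source setting are read
qualitatively):

- importance: a feature is flagged at week b when its weekly mean share
  falls outside the baseline 95% interval, on the same side, for at least
  ``k_consec`` consecutive bins ending at b. The baseline interval for a bin
  of size n is the percentile interval of means of bootstrap samples of
  size n drawn from the pooled baseline-window episodes, i.e. the null
  distribution of a weekly mean at that bin's sample size.
- performance: a week is flagged when its AUROC bootstrap interval lies
  entirely below the pre-period reference for ``k_consec`` consecutive
  defined bins (one-sided: only degradation triggers retraining review).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import driftstats, features, perf, shapley, synth_ed, trees

__all__ = [
    "MonitorConfig",
    "DriftReport",
    "flag_importance_drift",
    "flag_performance_drift",
    "classify_drift",
    "run_monitoring",
    "CLASSIFICATIONS",
]

CLASSIFICATIONS = (
    "stable",
    "data_drift_no_degradation",
    "concept_drift_suspected",
    "data_drift_with_degradation",
)


def _consecutive_flags(weeks, outside, sides, k_consec: int):
    """Weeks with >= k_consec consecutive same-side excursions ending there."""
    flags = []
    run_side = 0
    run_len = 0
    for week, out, side in zip(weeks, outside, sides):
        if out and (run_len == 0 or side == run_side):
            run_len += 1
            run_side = side
        elif out:
            run_len, run_side = 1, side
        else:
            run_len, run_side = 0, 0
        if run_len >= k_consec:
            flags.append((week, "up" if run_side > 0 else "down"))
    return flags


def flag_importance_drift(
    shares: driftstats.NormalisedShares,
    timestamps,
    baseline_window: tuple,
    k_consec: int = 2,
    n_boot: int = driftstats.DEFAULT_N_BOOT,
    seed: int = 0,
) -> dict[str, list[tuple[pd.Timestamp, str]]]:
    """Flag features whose weekly mean share escapes its baseline interval.

    ``baseline_window`` is a half-open ``[start, end)`` timestamp pair; weeks
    starting at or after ``end`` are monitored against the pooled baseline
    episodes. Returns per-feature lists of (week, direction).
    """
    start, end = pd.Timestamp(baseline_window[0]), pd.Timestamp(baseline_window[1])
    if not start < end:
        raise ValueError("baseline window must be a non-empty [start, end) interval")
    ts = pd.to_datetime(pd.Series(np.asarray(timestamps)))
    weeks = perf.weekly_bins(ts)
    base_mask = ((ts >= start) & (ts < end)).to_numpy()
    if base_mask.sum() == 0:
        raise ValueError("baseline window contains no episodes")
    S = shares.shares
    base = S[base_mask]
    rng = np.random.default_rng(seed)

    monitored = sorted(w for w in weeks.unique() if w >= end)
    d = S.shape[1]
    outside = {f: [] for f in shares.feature_names}
    sides = {f: [] for f in shares.feature_names}
    mon_weeks = []
    for week in monitored:
        mask = (weeks == week).to_numpy()
        n = int(mask.sum())
        if n == 0:
            continue
        mon_weeks.append(week)
        means = S[mask].mean(axis=0)
        idx = rng.integers(0, len(base), size=(n_boot, n))
        null_means = base[idx].mean(axis=1)  # (n_boot, d)
        lo, hi = np.percentile(null_means, [2.5, 97.5], axis=0)
        for j, feat in enumerate(shares.feature_names):
            if means[j] > hi[j]:
                outside[feat].append(True)
                sides[feat].append(+1)
            elif means[j] < lo[j]:
                outside[feat].append(True)
                sides[feat].append(-1)
            else:
                outside[feat].append(False)
                sides[feat].append(0)
    return {
        feat: _consecutive_flags(mon_weeks, outside[feat], sides[feat], k_consec)
        for feat in shares.feature_names
    }


def flag_performance_drift(
    series: pd.DataFrame, reference_auroc: float, k_consec: int = 2
) -> list[pd.Timestamp]:
    """Weeks whose AUROC CI sits wholly below the reference for k consecutive bins."""
    defined = series[series["defined"]].reset_index(drop=True)
    if len(defined) == 0:
        raise ValueError("no defined weekly AUROC bins to monitor")
    below = (defined["ci_hi"] < reference_auroc).to_list()
    flags = _consecutive_flags(defined["week"], below, [-1] * len(below), k_consec)
    return [week for week, _ in flags]


def classify_drift(
    importance_flags: dict[str, list],
    performance_flags: list,
    window: tuple,
) -> str:
    """Apply the drift-typing rule table over a monitoring window.

    A pure function of the two flag sets restricted to ``[start, end)``.
    """
    start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])

    def _in_window(week) -> bool:
        return start <= pd.Timestamp(week) < end

    imp = any(
        _in_window(week) for flags in importance_flags.values() for week, _ in flags
    )
    perf_flag = any(_in_window(week) for week in performance_flags)
    if imp and perf_flag:
        return "data_drift_with_degradation"
    if imp:
        return "data_drift_no_degradation"
    if perf_flag:
        return "concept_drift_suspected"
    return "stable"


# ----------------------------------------------------------------------
# End-to-end pipeline
# ----------------------------------------------------------------------

@dataclass
class MonitorConfig:
    """Configuration of a full surveillance run.

    Either ``scenario``/``scenario_params`` (simulate) or ``episodes`` (a
    path to an episode CSV) selects the input stream. The desk-scale
    defaults trade statistical resolution for runtime and are documented in
    the methods note.
    """

    scenario: str | None = "baseline"
    scenario_params: dict = field(default_factory=dict)
    episodes: str | None = None
    seed: int = 0
    hyperparams: dict = field(
        default_factory=lambda: {"n_estimators": 150, "max_depth": 2}
    )
    smoothing_m: float = features.DEFAULT_SMOOTHING
    background_size: int = 32
    n_boot_shares: int = 1000
    n_boot_auroc: int = 200
    # Importance flags use a longer persistence run than performance flags:
    # with ~14 share series monitored on 95% intervals, two-week runs alone
    # produce false drift calls in a sizeable fraction of stable streams.
    k_consec_importance: int = 3
    k_consec_performance: int = 2
    classification_weeks: int = 8
    target_recall: float = 0.75

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "scenario_params": self.scenario_params,
            "episodes": self.episodes,
            "seed": self.seed,
            "hyperparams": self.hyperparams,
            "smoothing_m": self.smoothing_m,
            "background_size": self.background_size,
            "n_boot_shares": self.n_boot_shares,
            "n_boot_auroc": self.n_boot_auroc,
            "k_consec_importance": self.k_consec_importance,
            "k_consec_performance": self.k_consec_performance,
            "classification_weeks": self.classification_weeks,
            "target_recall": self.target_recall,
        }

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class DriftReport:
    """Everything a surveillance run produced, with provenance."""

    classification: str
    importance_flags: dict[str, list]
    performance_flags: list
    importance_series: pd.DataFrame
    performance_series: pd.DataFrame
    reference_auroc: float
    performance_pre: perf.PerformanceSummary
    performance_during: perf.PerformanceSummary | None
    importance_delta: pd.DataFrame
    prevalence_shifts: dict[str, pd.DataFrame]
    new_category_events: list[dict]
    classification_window: tuple
    config: MonitorConfig

    def summary(self) -> str:
        lines = [
            f"Drift classification: {self.classification}",
            f"  window: [{self.classification_window[0].date()}, {self.classification_window[1].date()})",
            f"  reference AUROC (pre period): {self.reference_auroc:.3f}",
        ]
        flagged = {f: v for f, v in self.importance_flags.items() if v}
        if flagged:
            lines.append("  importance flags:")
            for feat, flags in sorted(flagged.items(), key=lambda kv: -len(kv[1])):
                weeks = ", ".join(f"{w.date()}({d})" for w, d in flags)
                lines.append(f"    {feat}: {weeks}")
        else:
            lines.append("  importance flags: none")
        if self.performance_flags:
            lines.append(
                "  performance flags: "
                + ", ".join(str(pd.Timestamp(w).date()) for w in self.performance_flags)
            )
        else:
            lines.append("  performance flags: none")
        if self.new_category_events:
            lines.append("  new categories:")
            for ev in self.new_category_events:
                lines.append(f"    {ev['feature']}={ev['level']} (n={ev['count']})")
        top = self.importance_delta.head(3)
        lines.append("  largest share increases (during - pre):")
        for _, row in top.iterrows():
            lines.append(f"    {row.feature}: {row.delta:+.4f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "classification": self.classification,
            "classification_window": [str(w) for w in self.classification_window],
            "reference_auroc": self.reference_auroc,
            "importance_flags": {
                f: [[str(w), d] for w, d in flags]
                for f, flags in self.importance_flags.items()
            },
            "performance_flags": [str(w) for w in self.performance_flags],
            "performance_pre": self.performance_pre.to_dict(),
            "performance_during": (
                None if self.performance_during is None else self.performance_during.to_dict()
            ),
            "importance_delta": self.importance_delta.to_dict(orient="records"),
            "new_category_events": self.new_category_events,
            "prevalence_shifts": {
                feat: frame.replace([np.inf], "inf").to_dict(orient="records")
                for feat, frame in self.prevalence_shifts.items()
            },
            "provenance": {"config": self.config.to_dict(), "config_hash": self.config.hash()},
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True, default=str)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def write_tables(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.importance_series.to_csv(out / "importance_series.csv", index=False)
        self.performance_series.to_csv(out / "performance_series.csv", index=False)
        self.importance_delta.to_csv(out / "importance_delta.csv", index=False)
        for feat, frame in self.prevalence_shifts.items():
            frame.to_csv(out / f"prevalence_{feat}.csv", index=False)


def run_monitoring(config: MonitorConfig) -> DriftReport:
    """Simulate/load episodes, fit, explain, track and classify — end to end."""
    seeds = np.random.SeedSequence(config.seed).spawn(5)
    seed_ints = [int(s.generate_state(1)[0] % (2**31)) for s in seeds]

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # tag failures with their pipeline stage
            raise RuntimeError(f"monitoring stage '{name}' failed: {exc}") from exc

    # -- data ----------------------------------------------------------
    if config.episodes is not None:
        table = _stage("load", synth_ed.read_episodes_csv, config.episodes)
        scenario = None
        start = perf.weekly_bins(table["timestamp"]).min()
        # infer boundaries from cohort tags when present
        if "cohort" in table.columns and set(table["cohort"]) >= {"train", "test_pre"}:
            b1 = table.loc[table.cohort != "train", "timestamp"].min()
            during = table.loc[table.cohort == "test_during", "timestamp"]
            b2 = during.min() if len(during) else table["timestamp"].max()
        else:
            raise ValueError("episode CSV must carry cohort tags train/test_pre[/test_during]")
        b1, b2 = perf.weekly_bins(pd.Series([b1, b2]))
    else:
        scenario = _stage(
            "scenario",
            synth_ed.make_scenario,
            config.scenario,
            seed=config.seed,
            **config.scenario_params,
        )
        table = _stage("simulate", synth_ed.simulate_cohort, scenario, seed=seed_ints[0])
        start = scenario.start_date
        w1, w2 = scenario.split_weeks
        b1 = start + pd.Timedelta(weeks=w1)
        b2 = start + pd.Timedelta(weeks=w2)

    train, test_pre, test_during = _stage("split", features.temporal_split, table, b1, b2)
    if len(train) == 0 or len(test_pre) == 0:
        raise RuntimeError("monitoring stage 'split' failed: empty train or pre-period cohort")
    test = pd.concat([test_pre, test_during], ignore_index=True)

    # -- encode + fit --------------------------------------------------
    X_train = _stage("encode", features.encode_table, train, m=config.smoothing_m)
    ensemble = _stage(
        "fit",
        trees.fit_tree_ensemble,
        X_train,
        train["outcome"].to_numpy(),
        hyperparams=config.hyperparams,
        seed=seed_ints[1],
    )
    X_test = _stage(
        "encode", features.encode_table, test, maps=X_train.maps, history_vocab=X_train.history_vocab
    )

    # -- explain -------------------------------------------------------
    background = shapley.BackgroundSet.from_training(
        X_train, size=config.background_size, seed=seed_ints[2]
    )
    attr = _stage(
        "explain",
        shapley.explain_cohort,
        ensemble,
        X_test,
        background,
        episode_ids=test["episode_id"].to_numpy(),
    )
    shares = driftstats.normalise_attributions(attr)

    # -- track ---------------------------------------------------------
    ts_test = test["timestamp"]
    importance_series = _stage(
        "track",
        driftstats.bin_importance,
        shares,
        ts_test,
        n_boot=config.n_boot_shares,
        seed=seed_ints[3],
    )
    margins = ensemble.predict_margin(X_test)
    labels = test["outcome"].to_numpy()
    performance_series = _stage(
        "track",
        perf.binned_performance,
        margins,
        labels,
        ts_test,
        n_boot=config.n_boot_auroc,
        seed=seed_ints[4],
    )

    pre_mask = (ts_test < b2).to_numpy()
    during_mask = ~pre_mask
    reference_auroc = perf.auroc(margins[pre_mask], labels[pre_mask])
    performance_pre = _stage(
        "evaluate",
        perf.evaluate,
        margins[pre_mask],
        labels[pre_mask],
        target_recall=config.target_recall,
        n_boot=config.n_boot_auroc,
        seed=seed_ints[4],
    )
    performance_during = None
    if during_mask.sum() and 0 < labels[during_mask].sum() < during_mask.sum():
        performance_during = perf.evaluate(
            margins[during_mask],
            labels[during_mask],
            target_recall=config.target_recall,
            n_boot=config.n_boot_auroc,
            seed=seed_ints[4],
        )

    # -- flag + classify ----------------------------------------------
    importance_flags = _stage(
        "flag",
        flag_importance_drift,
        shares,
        ts_test,
        baseline_window=(b1, b2),
        k_consec=config.k_consec_importance,
        n_boot=config.n_boot_shares,
        seed=seed_ints[3],
    )
    performance_flags = _stage(
        "flag", flag_performance_drift, performance_series, reference_auroc,
        config.k_consec_performance,
    )
    # drop performance flags inside the reference period itself
    performance_flags = [w for w in performance_flags if pd.Timestamp(w) >= b2]

    end = perf.weekly_bins(ts_test).max() + pd.Timedelta(weeks=1)
    window = (end - pd.Timedelta(weeks=config.classification_weeks), end)
    classification = classify_drift(importance_flags, performance_flags, window)

    if during_mask.sum():
        delta = driftstats.importance_delta(
            shapley.AttributionMatrix(attr.phi[pre_mask], attr.phi0, attr.feature_names),
            shapley.AttributionMatrix(attr.phi[during_mask], attr.phi0, attr.feature_names),
            mode="share",
        )
        prevalence = {
            feat: driftstats.prevalence_shift(test[feat], pre_mask, during_mask)
            for feat in test.columns
            if feat in X_train.maps
        }
    else:
        delta = driftstats.importance_delta(attr, attr, mode="share")
        prevalence = {}

    return DriftReport(
        classification=classification,
        importance_flags=importance_flags,
        performance_flags=performance_flags,
        importance_series=importance_series,
        performance_series=performance_series,
        reference_auroc=reference_auroc,
        performance_pre=performance_pre,
        performance_during=performance_during,
        importance_delta=delta,
        prevalence_shifts=prevalence,
        new_category_events=X_test.new_category_events,
        classification_window=window,
        config=config,
    )
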