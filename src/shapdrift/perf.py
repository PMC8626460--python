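"""Discrimination metrics and bootstrap performance tracking.

AUROC is the probability that a random admitted episode outranks a random
discharged one, ties credited one half (the Mann-Whitney convention);
average precision is the step-sum under the precision-recall curve. Both are
rank statistics, so uncertainty is quantified with seeded percentile
bootstrap intervals (2.5/97.5), and weekly binning gives the time-resolved
performance series a deployed model would be monitored with. A confusion
matrix at a fixed operating recall (default 0.75) summarises the
threshold-level behaviour; with a prevalence shift between periods the
precision-based numbers are biased by the class mix, which is exactly why
the drift statistics elsewhere in this package work on normalised
attribution shares instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, NamedTuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = [
    "auroc",
    "average_precision",
    "bootstrap_ci",
    "BootstrapCI",
    "binned_performance",
    "confusion_at_recall",
    "ConfusionAtRecall",
    "PerformanceSummary",
    "evaluate",
    "weekly_bins",
]


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    return labels


def auroc(scores, labels) -> float:
    """Area under the ROC curve; undefined (raises) for single-class labels."""
    labels = _check_binary(labels)
    if labels.min() == labels.max():
        raise ValueError("AUROC undefined: only one class present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def average_precision(scores, labels) -> float:
    """Average precision (step-interpolated area under the PR curve)."""
    labels = _check_binary(labels)
    if labels.sum() == 0:
        raise ValueError("average precision undefined: no positives")
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


class BootstrapCI(NamedTuple):
    low: float
    high: float
    n_used: int
    n_skipped: int


def bootstrap_ci(
    stat_fn: Callable, data, n_boot: int = 1000, seed: int = 0
) -> BootstrapCI:
    """Seeded percentile bootstrap interval of ``stat_fn`` over row resamples.

    ``data`` is an array or a tuple of aligned arrays, resampled jointly by
    row. Resamples on which ``stat_fn`` raises ``ValueError`` (e.g. a
    single-class label draw for a rank statistic) are skipped and counted;
    if every resample degenerates, that is an error.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    arrays = data if isinstance(data, tuple) else (data,)
    arrays = tuple(np.asarray(a) for a in arrays)
    n = len(arrays[0])
    if n == 0:
        raise ValueError("cannot bootstrap empty data")
    rng = np.random.default_rng(seed)
    values = []
    skipped = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            values.append(stat_fn(*(a[idx] for a in arrays)))
        except ValueError:
            skipped += 1
    if not values:
        raise ValueError("all bootstrap resamples were degenerate")
    low, high = np.percentile(values, [2.5, 97.5])
    return BootstrapCI(float(low), float(high), len(values), skipped)


def _bootstrap_auroc(scores: np.ndarray, labels: np.ndarray, n_boot: int, rng) -> BootstrapCI:
    """Vectorised percentile bootstrap of AUROC (rank formulation)."""
    n = len(scores)
    idx = rng.integers(0, n, size=(n_boot, n))
    s = scores[idx]
    lab = labels[idx]
    n_pos = lab.sum(axis=1)
    ok = (n_pos > 0) & (n_pos < n)
    if not ok.any():
        raise ValueError("all bootstrap resamples were degenerate")
    ranks = rankdata(s[ok], axis=1)
    npos = n_pos[ok]
    auc = ((ranks * lab[ok]).sum(axis=1) - npos * (npos + 1) / 2) / (npos * (n - npos))
    low, high = np.percentile(auc, [2.5, 97.5])
    return BootstrapCI(float(low), float(high), int(ok.sum()), int(n_boot - ok.sum()))


def weekly_bins(timestamps) -> pd.Series:
    """Map timestamps to their Monday-anchored (ISO) week start dates."""
    ts = pd.to_datetime(pd.Series(np.asarray(timestamps)))
    return ts.dt.to_period("W-SUN").dt.start_time


def binned_performance(
    scores, labels, timestamps, n_boot: int = 1000, seed: int = 0
) -> pd.DataFrame:
    """Weekly AUROC series with bootstrap CIs.

    Returns one row per distinct ISO week spanned by the data, columns
    ``week, auroc, ci_lo, ci_hi, n, n_pos, defined``. Weeks with a single
    outcome class are flagged undefined (NaN estimates) rather than fatal.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    if not (len(scores) == len(labels) == len(timestamps)):
        raise ValueError("scores, labels and timestamps must align")
    weeks = weekly_bins(timestamps)
    rng = np.random.default_rng(seed)
    rows = []
    for week in sorted(weeks.unique()):
        mask = (weeks == week).to_numpy()
        s, lab = scores[mask], labels[mask]
        n, n_pos = len(s), int(lab.sum())
        if 0 < n_pos < n:
            point = auroc(s, lab)
            ci = _bootstrap_auroc(s, lab, n_boot, rng)
            rows.append((week, point, ci.low, ci.high, n, n_pos, True))
        else:
            rows.append((week, np.nan, np.nan, np.nan, n, n_pos, False))
    return pd.DataFrame(
        rows, columns=["week", "auroc", "ci_lo", "ci_hi", "n", "n_pos", "defined"]
    )


class ConfusionAtRecall(NamedTuple):
    threshold: float
    tp: int
    fp: int
    fn: int
    tn: int
    recall: float


def confusion_at_recall(scores, labels, target_recall: float = 0.75) -> ConfusionAtRecall:
    """Confusion matrix at the largest score threshold achieving the target recall."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("no positives: recall target unreachable")
    if not 0.0 <= target_recall <= 1.0:
        raise ValueError("target recall must lie in [0, 1]")
    n_neg = len(labels) - n_pos
    # cumulative TP/FP over descending unique thresholds (pred = score >= thr)
    uniq, inv = np.unique(-scores, return_inverse=True)
    thresholds = -uniq  # descending
    tp_at = np.bincount(inv, weights=labels, minlength=len(uniq)).cumsum()
    fp_at = np.bincount(inv, weights=1 - labels, minlength=len(uniq)).cumsum()
    k = int(np.searchsorted(tp_at, target_recall * n_pos - 1e-12))
    tp, fp = int(tp_at[k]), int(fp_at[k])
    return ConfusionAtRecall(
        float(thresholds[k]), tp, fp, n_pos - tp, n_neg - fp, tp / n_pos
    )


@dataclass
class PerformanceSummary:
    """Point estimates, bootstrap CIs and the fixed-recall confusion matrix."""

    auroc: float
    auroc_ci: BootstrapCI
    average_precision: float
    average_precision_ci: BootstrapCI
    confusion: ConfusionAtRecall
    n: int
    n_pos: int

    def summary(self) -> str:
        c = self.confusion
        return (
            f"n={self.n} (admitted {self.n_pos})\n"
            f"AUROC              {self.auroc:.3f} [{self.auroc_ci.low:.3f}, {self.auroc_ci.high:.3f}]\n"
            f"Average precision  {self.average_precision:.3f} "
            f"[{self.average_precision_ci.low:.3f}, {self.average_precision_ci.high:.3f}]\n"
            f"At recall {c.recall:.3f} (threshold {c.threshold:.4f}): "
            f"TP={c.tp} FP={c.fp} FN={c.fn} TN={c.tn}"
        )

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "n_pos": self.n_pos,
            "auroc": self.auroc,
            "auroc_ci": [self.auroc_ci.low, self.auroc_ci.high],
            "average_precision": self.average_precision,
            "average_precision_ci": [
                self.average_precision_ci.low,
                self.average_precision_ci.high,
            ],
            "confusion_at_recall": self.confusion._asdict(),
        }


def evaluate(
    scores,
    labels,
    target_recall: float = 0.75,
    n_boot: int = 1000,
    seed: int = 0,
) -> PerformanceSummary:
    """Full performance summary of one cohort."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    rng = np.random.default_rng(seed)
    return PerformanceSummary(
        auroc=auroc(scores, labels),
        auroc_ci=_bootstrap_auroc(scores, labels, n_boot, rng),
        average_precision=average_precision(scores, labels),
        average_precision_ci=bootstrap_ci(
            average_precision, (scores, labels), n_boot=n_boot, seed=seed + 1
        ),
        confusion=confusion_at_recall(scores, labels, target_recall),
        n=len(labels),
        n_pos=int(labels.sum()),
    )
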