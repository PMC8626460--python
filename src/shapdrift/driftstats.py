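"""Drift-monitoring statistics built on attribution matrices.

The central object is the per-attendance *normalised share*: the absolute
Shapley value of each feature divided by the row's total absolute Shapley
mass (the base value is not a feature and is excluded). Shares sum to one
per attendance, so they are invariant both to the overall magnitude of a
prediction and — because a prevalence change rescales a row's attributions
by a common factor — to changes in the outcome (target) distribution. That
invariance is what makes weekly share series a clean covariate-drift signal:
a moving share means the model is *using* its inputs differently, not merely
that admission rates moved.

Weekly bins are anchored to Mondays (ISO weeks) and summarised by the mean
share with a seeded percentile bootstrap 95% interval over the episodes in
the bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .perf import weekly_bins
from .shapley import AttributionMatrix

__all__ = [
    "NormalisedShares",
    "normalise_attributions",
    "bin_importance",
    "importance_delta",
    "prevalence_shift",
]

DEFAULT_N_BOOT = 1000


@dataclass
class NormalisedShares:
    """Per-attendance share vectors; each non-degenerate row sums to one."""

    shares: np.ndarray  # (n, d), s_ij >= 0
    degenerate: np.ndarray  # (n,) bool: source row was all-zero
    feature_names: list[str]

    def __len__(self) -> int:
        return len(self.shares)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.shares, columns=self.feature_names)
        frame["degenerate"] = self.degenerate
        return frame


def _phi_of(rows) -> tuple[np.ndarray, list[str]]:
    if isinstance(rows, AttributionMatrix):
        return rows.phi, list(rows.feature_names)
    if isinstance(rows, NormalisedShares):
        return rows.shares, list(rows.feature_names)
    arr = np.atleast_2d(np.asarray(rows, dtype=float))
    return arr, [f"f{i}" for i in range(arr.shape[1])]


def normalise_attributions(rows) -> NormalisedShares:
    """Convert attributions to per-row absolute shares.

    ``s_ij = |phi_ij| / Σ_k |phi_ik|``; an all-zero row has no defined
    shares and is assigned the uniform vector with its degenerate flag set
    (kept so row alignment with timestamps survives).
    """
    phi, names = _phi_of(rows)
    if len(phi) == 0:
        raise ValueError("no attribution rows to normalise")
    mass = np.abs(phi)
    totals = mass.sum(axis=1)
    degenerate = totals == 0.0
    d = phi.shape[1]
    shares = np.empty_like(mass)
    ok = ~degenerate
    shares[ok] = mass[ok] / totals[ok, None]
    shares[degenerate] = 1.0 / d
    return NormalisedShares(shares, degenerate, names)


def bin_importance(
    shares: NormalisedShares,
    timestamps,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> pd.DataFrame:
    """Weekly mean-share series with percentile bootstrap 95% intervals.

    Returns a tidy frame (feature, week, mean, ci_lo, ci_hi, n) covering
    every ISO week between the first and last timestamp; weeks with no
    episodes appear with ``n=0`` and no estimates.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    ts = pd.to_datetime(pd.Series(np.asarray(timestamps)))
    if len(ts) != len(shares):
        raise ValueError("timestamps do not align with share rows")
    weeks = weekly_bins(ts)
    all_weeks = pd.date_range(weeks.min(), weeks.max(), freq="7D")
    rng = np.random.default_rng(seed)
    rows = []
    S = shares.shares
    for week in all_weeks:
        mask = (weeks == week).to_numpy()
        n = int(mask.sum())
        if n == 0:
            for feat in shares.feature_names:
                rows.append((feat, week, np.nan, np.nan, np.nan, 0))
            continue
        block = S[mask]
        means = block.mean(axis=0)
        idx = rng.integers(0, n, size=(n_boot, n))
        boot_means = block[idx].mean(axis=1)  # (n_boot, d)
        lo, hi = np.percentile(boot_means, [2.5, 97.5], axis=0)
        for j, feat in enumerate(shares.feature_names):
            rows.append((feat, week, means[j], lo[j], hi[j], n))
    return pd.DataFrame(rows, columns=["feature", "week", "mean", "ci_lo", "ci_hi", "n"])


def importance_delta(rows_a, rows_b, mode: str = "share") -> pd.DataFrame:
    """Per-feature mean importance in two periods and their difference (B - A).

    ``mode="share"`` averages normalised shares (the cross-period comparison
    the normalisation argument calls for; signed deltas then sum to zero);
    ``mode="raw_abs"`` averages raw absolute attributions.
    """
    phi_a, names_a = _phi_of(rows_a)
    phi_b, names_b = _phi_of(rows_b)
    if names_a != names_b:
        raise ValueError("feature sets of the two periods differ")
    if mode == "share":
        a = normalise_attributions(rows_a).shares.mean(axis=0)
        b = normalise_attributions(rows_b).shares.mean(axis=0)
    elif mode == "raw_abs":
        a = np.abs(phi_a).mean(axis=0)
        b = np.abs(phi_b).mean(axis=0)
    else:
        raise ValueError("mode must be 'share' or 'raw_abs'")
    return pd.DataFrame(
        {"feature": names_a, "mean_a": a, "mean_b": b, "delta": b - a}
    ).sort_values("delta", ascending=False, ignore_index=True)


def prevalence_shift(column, mask_a, mask_b) -> pd.DataFrame:
    """Per-level prevalence in two periods and the B/A prevalence ratio.

    Levels present in B but absent in A are flagged ``new_category`` with an
    infinite ratio; levels absent from both periods are omitted.
    """
    column = pd.Series(np.asarray(column, dtype=object))
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if mask_a.sum() == 0 or mask_b.sum() == 0:
        raise ValueError("both periods must be non-empty")
    prev_a = column[mask_a].value_counts(normalize=True)
    prev_b = column[mask_b].value_counts(normalize=True)
    levels = sorted(set(prev_a.index) | set(prev_b.index))
    rows = []
    for level in levels:
        pa = float(prev_a.get(level, 0.0))
        pb = float(prev_b.get(level, 0.0))
        new = pa == 0.0 and pb > 0.0
        ratio = np.inf if new else (pb / pa if pa > 0 else np.nan)
        rows.append((level, pa, pb, ratio, new))
    return pd.DataFrame(
        rows, columns=["level", "prevalence_a", "prevalence_b", "ratio", "new_category"]
    ).sort_values("ratio", ascending=False, ignore_index=True)
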