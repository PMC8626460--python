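"""Episode-table encoding and temporal cohort splitting.

Numeric features pass straight through (missing values preserved as NaN, never
imputed); categorical descriptors are target encoded — each level replaced by
a smoothed mean of the binary admission outcome among training rows carrying
that level — and binary condition-history flags become one-hot {0,1} columns.
Encodings are fitted on the training cohort only and frozen, mirroring
deployment: applying a frozen map to later data both prevents outcome leakage
into drift statistics and makes the *emergence* of a previously unseen
category observable (unseen levels fall back to the global prior and are
logged as new-category events).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TargetEncodingMap",
    "ColumnMeta",
    "FeatureMatrix",
    "target_encode",
    "encode_table",
    "temporal_split",
    "save_encoding_maps",
    "load_encoding_maps",
]

RESERVED_COLUMNS = ("episode_id", "timestamp", "outcome", "cohort")

DEFAULT_SMOOTHING = 10.0


@dataclass
class TargetEncodingMap:
    """Frozen level -> encoded-value map for one categorical feature.

    The encoded value of a level seen ``count`` times with outcome mean
    ``level_mean`` is ``(count * level_mean + m * prior) / (count + m)``;
    levels unseen at fit time map to ``prior``.
    """

    feature: str
    mapping: dict[str, float]
    prior: float
    m: float

    def apply(self, column: pd.Series) -> tuple[np.ndarray, dict[str, int]]:
        """Encode ``column``; returns values and counts of unseen levels."""
        values = column.map(self.mapping)
        unseen_mask = values.isna()
        unseen: dict[str, int] = {}
        if unseen_mask.any():
            unseen = column[unseen_mask].value_counts().to_dict()
            values = values.fillna(self.prior)
        return values.to_numpy(dtype=float), unseen


def target_encode(
    column, outcome, m: float = DEFAULT_SMOOTHING, feature: str = ""
) -> tuple[np.ndarray, TargetEncodingMap]:
    """Fit a target encoding on one categorical column.

    Parameters
    ----------
    column, outcome:
        Level tokens and the aligned binary outcome vector.
    m:
        Smoothing weight (pseudo-count of the global prior); ``m=0`` gives
        plain per-level outcome means, ``m`` large shrinks every level to
        the prior.
    """
    column = pd.Series(column).reset_index(drop=True)
    outcome = np.asarray(outcome)
    if len(column) == 0:
        raise ValueError("cannot fit a target encoding on an empty column")
    if len(column) != len(outcome):
        raise ValueError("column and outcome lengths differ")
    if not np.isin(outcome, (0, 1)).all():
        raise ValueError("outcome must be binary 0/1")
    if m < 0:
        raise ValueError("smoothing weight m must be non-negative")
    prior = float(outcome.mean())
    grouped = pd.Series(outcome, dtype=float).groupby(column)
    counts = grouped.count()
    means = grouped.mean()
    encoded = (counts * means + m * prior) / (counts + m)
    mapping = {str(level): float(v) for level, v in encoded.items()}
    enc_map = TargetEncodingMap(feature or getattr(column, "name", "") or "", mapping, prior, float(m))
    values, _ = enc_map.apply(column)
    return values, enc_map


@dataclass(frozen=True)
class ColumnMeta:
    name: str
    origin: str  # numeric | target_encoded | history_onehot
    source: str


@dataclass
class FeatureMatrix:
    """Model-ready matrix with column provenance and new-category events."""

    frame: pd.DataFrame
    column_meta: list[ColumnMeta]
    maps: dict[str, TargetEncodingMap]
    history_vocab: list[str]
    new_category_events: list[dict] = field(default_factory=list)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    def __len__(self) -> int:
        return len(self.frame)


def _classify_columns(table: pd.DataFrame) -> tuple[list[str], list[str], list[str]]:
    numeric, categorical, history = [], [], []
    for col in table.columns:
        if col in RESERVED_COLUMNS:
            continue
        if col.startswith("hx_"):
            history.append(col)
        elif pd.api.types.is_numeric_dtype(table[col]):
            numeric.append(col)
        else:
            categorical.append(col)
    return numeric, categorical, history


def encode_table(
    table: pd.DataFrame,
    maps: dict[str, TargetEncodingMap] | str = "fit",
    history_vocab: list[str] | str = "fit",
    m: float = DEFAULT_SMOOTHING,
) -> FeatureMatrix:
    """Encode an episode table into a :class:`FeatureMatrix`.

    With ``maps="fit"`` the table must carry outcomes and the encodings are
    fitted on it; otherwise the frozen maps are applied and any level absent
    from a map is encoded as the prior *and* recorded in
    ``new_category_events`` — category emergence must be observable, not
    silently absorbed.
    """
    numeric_cols, categorical_cols, history_cols = _classify_columns(table)

    fit = isinstance(maps, str) and maps == "fit"
    if fit:
        if "outcome" not in table.columns or len(table) == 0:
            raise ValueError("fitting encodings requires a non-empty table with outcomes")
        fitted: dict[str, TargetEncodingMap] = {}
        for col in categorical_cols:
            _, fitted[col] = target_encode(table[col], table["outcome"].to_numpy(), m=m, feature=col)
        maps = fitted
    else:
        assert isinstance(maps, dict)
        missing = set(maps) - set(categorical_cols)
        extra = set(categorical_cols) - set(maps)
        if missing or extra:
            raise ValueError(
                f"categorical schema mismatch with fitted maps: missing={sorted(missing)} "
                f"unmapped={sorted(extra)}"
            )

    if isinstance(history_vocab, str) and history_vocab == "fit":
        history_vocab = list(history_cols)
    else:
        unknown = set(history_cols) - set(history_vocab)
        if unknown:
            raise ValueError(f"history flags outside fitted vocabulary: {sorted(unknown)}")

    data: dict[str, np.ndarray] = {}
    meta: list[ColumnMeta] = []
    events: list[dict] = []
    for col in numeric_cols:
        data[col] = table[col].to_numpy(dtype=float)
        meta.append(ColumnMeta(col, "numeric", col))
    for col in categorical_cols:
        values, unseen = maps[col].apply(table[col].astype(str))
        data[col] = values
        meta.append(ColumnMeta(col, "target_encoded", col))
        for level, count in unseen.items():
            events.append({"feature": col, "level": level, "count": int(count)})
    for col in history_vocab:
        if col in table.columns:
            data[col] = table[col].to_numpy(dtype=float)
        else:
            data[col] = np.zeros(len(table))
        meta.append(ColumnMeta(col, "history_onehot", col))

    frame = pd.DataFrame(data, index=table.index)
    return FeatureMatrix(frame, meta, dict(maps), list(history_vocab), events)


def temporal_split(
    table: pd.DataFrame, boundary_1, boundary_2
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Split episodes into three disjoint, exhaustive periods by timestamp.

    Intervals are half-open ``[start, boundary)``: a record timestamped
    exactly at a boundary belongs to the *later* period. Membership depends
    only on the timestamp, never on row order.
    """
    b1, b2 = pd.Timestamp(boundary_1), pd.Timestamp(boundary_2)
    if not b1 < b2:
        raise ValueError("boundary_1 must precede boundary_2")
    ts = pd.to_datetime(table["timestamp"])
    first = table[ts < b1]
    second = table[(ts >= b1) & (ts < b2)]
    third = table[ts >= b2]
    return first, second, third


# ----------------------------------------------------------------------
# Encoding-map (de)serialisation
# ----------------------------------------------------------------------

def save_encoding_maps(maps: dict[str, TargetEncodingMap], history_vocab: list[str], path) -> None:
    doc = {
        "history_vocab": list(history_vocab),
        "encodings": {
            name: {"mapping": em.mapping, "prior": em.prior, "m": em.m}
            for name, em in maps.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)


def load_encoding_maps(path) -> tuple[dict[str, TargetEncodingMap], list[str]]:
    with open(path) as fh:
        doc = json.load(fh)
    maps = {
        name: TargetEncodingMap(name, d["mapping"], d["prior"], d["m"])
        for name, d in doc["encodings"].items()
    }
    return maps, list(doc["history_vocab"])
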