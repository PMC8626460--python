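"""Synthetic emergency-department attendance streams with a known admission mechanism.

Real ED extracts of the kind used to train admission-risk models are private,
so this module generates attendance tables whose statistical structure mirrors
them: a logistic ground-truth admission mechanism over mixed numeric /
categorical / binary-history features, weekly attendance volumes, vital-sign
missingness, and injectable drift events (covariate shift, prevalence shift,
missingness shift, category emergence, concept shift) that switch on as step
functions at a chosen onset week.

The generated table doubles as the package's file interface: an episode CSV
with one row per attendance and a fixed column schema (see
:data:`CSV_COLUMNS`). Missing vitals are carried as NaN / empty CSV fields and
are never imputed here — downstream models are expected to handle missingness
natively.
"""

from __future__ import annotations

import copy
import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "NumericSpec",
    "CategoricalSpec",
    "HistorySpec",
    "DriftEvent",
    "ScenarioConfig",
    "make_scenario",
    "simulate_cohort",
    "true_risk",
    "write_episodes_csv",
    "read_episodes_csv",
    "SCENARIO_KINDS",
    "CSV_COLUMNS",
]

#: Monday anchoring the week grid; week w spans [START + 7w days, START + 7(w+1) days).
DEFAULT_START_DATE = pd.Timestamp("2019-04-01")  # a Monday

SECONDS_PER_WEEK = 7 * 24 * 3600


@dataclass(frozen=True)
class NumericSpec:
    """A numeric attendance feature (vital sign or demographic).

    ``coef`` is the log-odds weight applied to the standardised value
    ``(x - mean) / sd`` in the true admission mechanism; a missing value
    contributes zero (missingness is non-informative by construction).
    """

    mean: float
    sd: float
    missing_rate: float = 0.0
    coef: float = 0.0
    lo: float = -np.inf
    hi: float = np.inf


@dataclass(frozen=True)
class CategoricalSpec:
    """A categorical attendance descriptor.

    ``probs`` are level probabilities (must sum to one); ``effects`` are
    per-level log-odds offsets in the true admission mechanism.
    """

    probs: dict[str, float]
    effects: dict[str, float]


@dataclass(frozen=True)
class HistorySpec:
    """A binary condition-history flag with its prevalence and log-odds weight."""

    rate: float
    coef: float = 0.0


@dataclass(frozen=True)
class DriftEvent:
    """A step change applied to the generating mechanism from ``onset_week`` on."""

    kind: str
    onset_week: int
    params: dict = field(default_factory=dict)


EVENT_KINDS = {
    "covariate_shift",
    "prevalence_shift",
    "missingness_shift",
    "category_emergence",
    "concept_shift",
    "volume_shift",
}


@dataclass
class ScenarioConfig:
    """Full description of a synthetic attendance stream.

    The admission mechanism at week ``t`` is
    ``P(admit | x) = sigmoid(b0(t) + sum_j contrib_j(x, t))`` where numeric
    contributions use the *baseline* standardisation (so a covariate shift
    moves risk through the shifted values), categorical levels and history
    flags contribute their log-odds offsets, and drift events modify the
    effective parameters as step functions.
    """

    horizon_weeks: int
    weekly_volume: int
    numeric: dict[str, NumericSpec]
    categorical: dict[str, CategoricalSpec]
    history: dict[str, HistorySpec]
    intercept: float
    linkage_rate: float = 0.55
    split_weeks: tuple[int, int] = (16, 36)
    drift_events: list[DriftEvent] = field(default_factory=list)
    start_date: pd.Timestamp = DEFAULT_START_DATE
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.horizon_weeks <= 0:
            raise ValueError("horizon_weeks must be positive")
        if self.weekly_volume < 0:
            raise ValueError("weekly_volume must be non-negative")
        if not 0.0 <= self.linkage_rate <= 1.0:
            raise ValueError("linkage_rate must lie in [0, 1]")
        for name, spec in self.numeric.items():
            if not 0.0 <= spec.missing_rate <= 1.0:
                raise ValueError(f"missing_rate for {name!r} outside [0, 1]")
            if spec.sd <= 0:
                raise ValueError(f"sd for {name!r} must be positive")
        for name, spec in self.categorical.items():
            total = sum(spec.probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"level probabilities for {name!r} sum to {total}, not 1")
            if any(p < 0 for p in spec.probs.values()):
                raise ValueError(f"negative level probability in {name!r}")
            if set(spec.effects) - set(spec.probs):
                raise ValueError(f"effects for {name!r} reference unknown levels")
        for name, spec in self.history.items():
            if not 0.0 <= spec.rate <= 1.0:
                raise ValueError(f"history rate for {name!r} outside [0, 1]")
        for ev in self.drift_events:
            if ev.kind not in EVENT_KINDS:
                raise ValueError(f"unknown drift event kind {ev.kind!r}")
            if not 0 <= ev.onset_week < self.horizon_weeks:
                raise ValueError(
                    f"drift onset week {ev.onset_week} outside horizon "
                    f"[0, {self.horizon_weeks})"
                )
        b1, b2 = self.split_weeks
        if not 0 < b1 < b2 <= self.horizon_weeks:
            raise ValueError("split_weeks must satisfy 0 < b1 < b2 <= horizon")

    # ------------------------------------------------------------------
    # Effective (possibly drifted) parameters at a given week
    # ------------------------------------------------------------------
    def at_week(self, t: int) -> "ScenarioConfig":
        """Resolve drift events into the effective parameters for week ``t``."""
        if not 0 <= t < self.horizon_weeks:
            raise ValueError(f"week {t} outside horizon [0, {self.horizon_weeks})")
        numeric = dict(self.numeric)
        categorical = dict(self.categorical)
        history = dict(self.history)
        intercept = self.intercept
        volume = self.weekly_volume
        for ev in self.drift_events:
            if t < ev.onset_week:
                continue
            p = ev.params
            if ev.kind == "prevalence_shift":
                intercept += p["delta"]
            elif ev.kind == "volume_shift":
                volume = int(round(volume * p["factor"]))
            elif ev.kind == "missingness_shift":
                for name in p["features"]:
                    numeric[name] = replace(numeric[name], missing_rate=p["new_rate"])
            elif ev.kind == "covariate_shift":
                name = p["feature"]
                if name in numeric:
                    spec = numeric[name]
                    numeric[name] = replace(
                        spec,
                        mean=p.get("new_mean", spec.mean),
                        sd=p.get("new_sd", spec.sd),
                    )
                elif name in categorical:
                    spec = categorical[name]
                    new_probs = dict(p["new_probs"])
                    if set(new_probs) != set(spec.probs):
                        raise ValueError(
                            f"covariate_shift for {name!r} must re-specify the same levels"
                        )
                    categorical[name] = CategoricalSpec(new_probs, dict(spec.effects))
                else:
                    raise ValueError(f"covariate_shift references unknown feature {name!r}")
            elif ev.kind == "category_emergence":
                name, level, mass = p["feature"], p["level"], p["mass"]
                spec = categorical[name]
                if level in spec.probs:
                    raise ValueError(f"emergent level {level!r} already exists in {name!r}")
                scale = 1.0 - mass
                probs = {k: v * scale for k, v in spec.probs.items()}
                probs[level] = mass
                effects = dict(spec.effects)
                effects[level] = p.get("effect", 0.0)
                categorical[name] = CategoricalSpec(probs, effects)
            elif ev.kind == "concept_shift":
                name = p["feature"]
                if name in numeric:
                    numeric[name] = replace(numeric[name], coef=p["new_coef"])
                elif name in history:
                    history[name] = replace(history[name], coef=p["new_coef"])
                elif name in categorical:
                    spec = categorical[name]
                    categorical[name] = CategoricalSpec(
                        dict(spec.probs), {**spec.effects, **p["new_effects"]}
                    )
                else:
                    raise ValueError(f"concept_shift references unknown feature {name!r}")
        eff = copy.copy(self)
        eff.numeric, eff.categorical, eff.history = numeric, categorical, history
        eff.intercept, eff.weekly_volume = intercept, volume
        eff.drift_events = []
        return eff

    def weekly_volumes(self) -> np.ndarray:
        return np.array(
            [self.at_week(t).weekly_volume for t in range(self.horizon_weeks)], dtype=int
        )

    @property
    def history_flags(self) -> list[str]:
        return [f"hx_{name}" for name in self.history]


# ----------------------------------------------------------------------
# Default attendance mechanism (baseline study conditions)
# ----------------------------------------------------------------------

def _default_numeric() -> dict[str, NumericSpec]:
    vitals_missing = 0.30
    return {
        "age": NumericSpec(55.0, 20.0, 0.0, 0.6, lo=18.0, hi=100.0),
        "resp_rate": NumericSpec(17.0, 3.0, vitals_missing, 0.9, lo=8.0, hi=45.0),
        "pulse_rate": NumericSpec(85.0, 15.0, vitals_missing, 0.4, lo=35.0, hi=190.0),
        "temperature": NumericSpec(36.9, 0.6, vitals_missing, 0.3, lo=34.0, hi=41.5),
        "spo2": NumericSpec(96.5, 2.5, vitals_missing, -0.6, lo=70.0, hi=100.0),
        "news2": NumericSpec(2.0, 2.0, vitals_missing, 0.7, lo=0.0, hi=18.0),
    }


def _default_categorical() -> dict[str, CategoricalSpec]:
    return {
        # walk-ins are rarely admitted, ambulance arrivals often are — the
        # strong arrival-mode/acuity link that made the walk-in collapse so
        # visible in attribution tracking
        "arrival_mode": CategoricalSpec(
            probs={"walk_in": 0.6, "ambulance": 0.4},
            effects={"walk_in": -1.2, "ambulance": 1.2},
        ),
        "attendance_complaint": CategoricalSpec(
            probs={
                "injury": 0.25,
                "unwell_adult": 0.18,
                "chest_pain": 0.15,
                "abdominal_pain": 0.15,
                "breathing_difficulty": 0.12,
                "other": 0.15,
            },
            effects={
                "injury": -0.6,
                "unwell_adult": 0.2,
                "chest_pain": 0.5,
                "abdominal_pain": 0.1,
                "breathing_difficulty": 0.7,
                "other": 0.0,
            },
        ),
        "triage_complaint": CategoricalSpec(
            probs={
                "limb_problem": 0.22,
                "unwell_adult": 0.2,
                "chest_pain": 0.16,
                "abdominal_pain": 0.16,
                "shortness_of_breath": 0.12,
                "other": 0.14,
            },
            effects={
                "limb_problem": -0.5,
                "unwell_adult": 0.15,
                "chest_pain": 0.45,
                "abdominal_pain": 0.1,
                "shortness_of_breath": 0.65,
                "other": 0.0,
            },
        ),
        "triage_discriminator": CategoricalSpec(
            probs={
                "recent_mild_pain": 0.30,
                "minor_injury": 0.27,
                "acute_severe": 0.15,
                "low_spo2": 0.10,
                "pleuritic_pain": 0.08,
                "other": 0.10,
            },
            effects={
                "recent_mild_pain": -0.5,
                "minor_injury": -0.7,
                "acute_severe": 0.9,
                "low_spo2": 1.0,
                "pleuritic_pain": 0.6,
                "other": 0.0,
            },
        ),
    }


def _default_history() -> dict[str, HistorySpec]:
    return {
        "hypertension": HistorySpec(0.25, 0.4),
        "diabetes": HistorySpec(0.20, 0.3),
        "copd": HistorySpec(0.10, 0.5),
        "smoker": HistorySpec(0.30, 0.15),
    }


#: Baseline intercept, calibrated so the marginal admission rate is ~0.30
#: under the default mechanism (the latent log-odds spread pulls the mean
#: admission probability toward 0.5, so the intercept sits below logit(0.3)).
DEFAULT_INTERCEPT = -1.37

DEFAULT_HORIZON = 48
DEFAULT_WEEKLY_VOLUME = 150
DEFAULT_ONSET = 36

SCENARIO_KINDS = (
    "baseline",
    "covariate_shift",
    "prevalence_shift",
    "missingness_shift",
    "category_emergence",
    "concept_shift",
    "covid_like",
)

#: Default emergent complaint level used by category_emergence / covid_like.
EMERGENT_LEVEL = "viral_illness"


def make_scenario(kind: str = "baseline", **params) -> ScenarioConfig:
    """Build a :class:`ScenarioConfig` from a named scenario family.

    Parameters
    ----------
    kind:
        One of :data:`SCENARIO_KINDS`. ``covid_like`` combines a walk-in
        collapse, an admission-rate rise, a vitals-recording rise, an
        attendance-volume drop, and an emergent complaint level absent
        before onset — the pandemic-shock phenomenology.
    params:
        Overrides. Common ones: ``horizon_weeks``, ``weekly_volume``,
        ``onset_week`` (drift onset, default 36), ``seed``, ``split_weeks``,
        plus family-specific knobs (``delta`` for prevalence_shift,
        ``feature``/``new_coef`` for concept_shift, ``new_walk_in`` for the
        arrival-mode covariate shift, ``level``/``mass``/``effect`` for
        category emergence, ``new_rate`` for missingness).
    """
    if kind not in SCENARIO_KINDS:
        raise ValueError(f"unknown scenario kind {kind!r}; choose from {SCENARIO_KINDS}")
    horizon = int(params.pop("horizon_weeks", DEFAULT_HORIZON))
    volume = int(params.pop("weekly_volume", DEFAULT_WEEKLY_VOLUME))
    onset = int(params.pop("onset_week", DEFAULT_ONSET if DEFAULT_ONSET < horizon else horizon * 3 // 4))
    seed = int(params.pop("seed", 0))
    default_b2 = min(onset, horizon - 1)
    default_b1 = max(1, min(horizon // 3, default_b2 - 1))
    split_weeks = tuple(params.pop("split_weeks", (default_b1, default_b2)))
    intercept = float(params.pop("intercept", DEFAULT_INTERCEPT))
    linkage = float(params.pop("linkage_rate", 0.55))
    numeric = params.pop("numeric", _default_numeric())
    categorical = params.pop("categorical", _default_categorical())
    history = params.pop("history", _default_history())

    if onset >= horizon:
        raise ValueError(f"onset week {onset} beyond horizon {horizon}")

    events: list[DriftEvent] = []
    if kind == "covariate_shift":
        feature = params.pop("feature", "arrival_mode")
        if feature == "arrival_mode":
            new_walk_in = float(params.pop("new_walk_in", 0.2))
            new_probs = {"walk_in": new_walk_in, "ambulance": 1.0 - new_walk_in}
            events.append(DriftEvent("covariate_shift", onset, {"feature": feature, "new_probs": new_probs}))
        else:
            ev_params = {"feature": feature}
            for key in ("new_mean", "new_sd", "new_probs"):
                if key in params:
                    ev_params[key] = params.pop(key)
            events.append(DriftEvent("covariate_shift", onset, ev_params))
    elif kind == "prevalence_shift":
        events.append(DriftEvent("prevalence_shift", onset, {"delta": float(params.pop("delta", 1.0))}))
    elif kind == "missingness_shift":
        features = params.pop("features", ["resp_rate", "pulse_rate", "temperature", "spo2", "news2"])
        events.append(
            DriftEvent("missingness_shift", onset, {"features": features, "new_rate": float(params.pop("new_rate", 0.1))})
        )
    elif kind == "category_emergence":
        events.append(
            DriftEvent(
                "category_emergence",
                onset,
                {
                    "feature": params.pop("feature", "attendance_complaint"),
                    "level": params.pop("level", EMERGENT_LEVEL),
                    "mass": float(params.pop("mass", 0.25)),
                    "effect": float(params.pop("effect", 0.8)),
                },
            )
        )
    elif kind == "concept_shift":
        feature = params.pop("feature", "resp_rate")
        if "new_coef" in params:
            new_coef = float(params.pop("new_coef"))
        else:
            new_coef = -numeric[feature].coef if feature in numeric else -history[feature].coef
        events.append(DriftEvent("concept_shift", onset, {"feature": feature, "new_coef": new_coef}))
    elif kind == "covid_like":
        new_walk_in = float(params.pop("new_walk_in", 0.15))
        events += [
            DriftEvent("covariate_shift", onset, {"feature": "arrival_mode", "new_probs": {"walk_in": new_walk_in, "ambulance": 1.0 - new_walk_in}}),
            DriftEvent("prevalence_shift", onset, {"delta": float(params.pop("delta", 0.8))}),
            DriftEvent("missingness_shift", onset, {"features": ["resp_rate", "pulse_rate", "temperature", "spo2", "news2"], "new_rate": float(params.pop("new_rate", 0.08))}),
            DriftEvent("category_emergence", onset, {"feature": "attendance_complaint", "level": params.pop("level", EMERGENT_LEVEL), "mass": float(params.pop("mass", 0.50)), "effect": float(params.pop("effect", 3.0))}),
            DriftEvent("volume_shift", onset, {"factor": float(params.pop("volume_factor", 0.55))}),
        ]
    events += list(params.pop("extra_events", []))
    if params:
        raise TypeError(f"unrecognised scenario parameters: {sorted(params)}")

    return ScenarioConfig(
        horizon_weeks=horizon,
        weekly_volume=volume,
        numeric=numeric,
        categorical=categorical,
        history=history,
        intercept=intercept,
        linkage_rate=linkage,
        split_weeks=split_weeks,
        drift_events=events,
        seed=seed,
    )


# ----------------------------------------------------------------------
# Simulation
# ----------------------------------------------------------------------

def _standardised_contrib(values: np.ndarray, base: NumericSpec, coef: float) -> np.ndarray:
    z = (values - base.mean) / base.sd
    return np.where(np.isnan(values), 0.0, coef * z)


def _linear_predictor(
    scenario: ScenarioConfig,
    eff: ScenarioConfig,
    numeric_values: dict[str, np.ndarray],
    categorical_values: dict[str, np.ndarray],
    history_values: dict[str, np.ndarray],
) -> np.ndarray:
    """Log-odds of admission. Standardisation always uses the *baseline* spec."""
    n = len(next(iter(numeric_values.values())))
    eta = np.full(n, eff.intercept, dtype=float)
    for name, values in numeric_values.items():
        eta += _standardised_contrib(values, scenario.numeric[name], eff.numeric[name].coef)
    for name, levels in categorical_values.items():
        effects = eff.categorical[name].effects
        eta += np.array([effects[lv] for lv in levels])
    for name, flags in history_values.items():
        eta += eff.history[name].coef * flags
    return eta


def simulate_cohort(scenario: ScenarioConfig, n: int | None = None, seed: int | None = None) -> pd.DataFrame:
    """Simulate an episode table over the scenario horizon.

    ``n`` (if given) fixes the total episode count, allocated across weeks
    proportionally to the scenario's (possibly time-varying) weekly volumes;
    otherwise weekly volumes are used directly. All randomness descends from
    a single seed through ``numpy``'s SeedSequence spawning, so identical
    ``(scenario, n, seed)`` give byte-identical tables.
    """
    if seed is None:
        seed = scenario.seed
    if n is not None and n < 0:
        raise ValueError("n must be non-negative")

    volumes = scenario.weekly_volumes()
    if n is None:
        counts = volumes
    else:
        total = volumes.sum()
        if total == 0:
            counts = np.zeros_like(volumes)
            counts[: len(counts)] = n // max(len(counts), 1)
        else:
            exact = volumes * (n / total)
            counts = np.floor(exact).astype(int)
            remainder = n - counts.sum()
            # largest-remainder allocation keeps the split deterministic
            order = np.argsort(-(exact - counts), kind="stable")
            counts[order[:remainder]] += 1

    week_seeds = np.random.SeedSequence(seed).spawn(scenario.horizon_weeks)
    frames = []
    offset = 0
    b1, b2 = scenario.split_weeks
    for t in range(scenario.horizon_weeks):
        m = int(counts[t])
        if m == 0:
            continue
        rng = np.random.default_rng(week_seeds[t])
        eff = scenario.at_week(t)
        seconds = np.sort(rng.integers(0, SECONDS_PER_WEEK, size=m))
        timestamps = scenario.start_date + pd.to_timedelta(t * SECONDS_PER_WEEK + seconds, unit="s")

        numeric_values: dict[str, np.ndarray] = {}
        for name, spec in eff.numeric.items():
            vals = np.clip(rng.normal(spec.mean, spec.sd, size=m), spec.lo, spec.hi)
            missing = rng.random(m) < spec.missing_rate
            vals[missing] = np.nan
            numeric_values[name] = vals
        categorical_values: dict[str, np.ndarray] = {}
        for name, spec in eff.categorical.items():
            levels = np.array(list(spec.probs))
            probs = np.array([spec.probs[lv] for lv in levels])
            categorical_values[name] = rng.choice(levels, size=m, p=probs / probs.sum())
        linked = rng.random(m) < scenario.linkage_rate
        history_values: dict[str, np.ndarray] = {}
        for name, spec in eff.history.items():
            history_values[name] = ((rng.random(m) < spec.rate) & linked).astype(int)

        eta = _linear_predictor(scenario, eff, numeric_values, categorical_values, history_values)
        risk = 1.0 / (1.0 + np.exp(-eta))
        outcome = (rng.random(m) < risk).astype(int)

        cohort = "train" if t < b1 else ("test_pre" if t < b2 else "test_during")
        frame = pd.DataFrame({"episode_id": [f"E{offset + i:07d}" for i in range(m)], "timestamp": timestamps, "outcome": outcome})
        for name in scenario.numeric:
            frame[name] = numeric_values[name]
        for name in scenario.categorical:
            frame[name] = categorical_values[name]
        for name in scenario.history:
            frame[f"hx_{name}"] = history_values[name]
        frame["cohort"] = cohort
        frames.append(frame)
        offset += m

    if not frames:
        return _empty_table(scenario)
    return pd.concat(frames, ignore_index=True)


def _empty_table(scenario: ScenarioConfig) -> pd.DataFrame:
    cols: dict[str, pd.Series] = {
        "episode_id": pd.Series(dtype=str),
        "timestamp": pd.Series(dtype="datetime64[ns]"),
        "outcome": pd.Series(dtype=int),
    }
    for name in scenario.numeric:
        cols[name] = pd.Series(dtype=float)
    for name in scenario.categorical:
        cols[name] = pd.Series(dtype=str)
    for name in scenario.history:
        cols[f"hx_{name}"] = pd.Series(dtype=int)
    cols["cohort"] = pd.Series(dtype=str)
    return pd.DataFrame(cols)


def true_risk(record: dict, scenario: ScenarioConfig, t: int) -> float:
    """Ground-truth admission probability for one episode at week ``t``.

    ``record`` maps feature names to values (numeric features may be NaN /
    None; history flags are 0/1; categorical features are level tokens).
    Unknown categorical levels — e.g. an emergent level referenced before its
    onset week — raise ``KeyError``.
    """
    eff = scenario.at_week(t)
    eta = eff.intercept
    for name, base in scenario.numeric.items():
        v = record.get(name)
        v = np.nan if v is None else float(v)
        if not np.isnan(v):
            eta += eff.numeric[name].coef * (v - base.mean) / base.sd
    for name, spec in eff.categorical.items():
        level = record[name]
        if level not in spec.effects:
            raise KeyError(f"unknown level {level!r} for feature {name!r} at week {t}")
        eta += spec.effects[level]
    for name, spec in eff.history.items():
        eta += spec.coef * float(record.get(f"hx_{name}", record.get(name, 0)))
    return float(1.0 / (1.0 + np.exp(-eta)))


# ----------------------------------------------------------------------
# Episode CSV interface
# ----------------------------------------------------------------------

def csv_columns(scenario: ScenarioConfig) -> list[str]:
    return (
        ["episode_id", "timestamp", "outcome"]
        + list(scenario.numeric)
        + list(scenario.categorical)
        + [f"hx_{h}" for h in scenario.history]
        + ["cohort"]
    )


#: Column order of the default episode CSV schema.
CSV_COLUMNS = csv_columns(make_scenario("baseline"))


def write_episodes_csv(table: pd.DataFrame, path) -> None:
    """Write an episode table; missing numerics become empty fields."""
    out = table.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False, na_rep="")


def read_episodes_csv(path) -> pd.DataFrame:
    table = pd.read_csv(path, parse_dates=["timestamp"])
    table["outcome"] = table["outcome"].astype(int)
    return table


def table_to_csv_bytes(table: pd.DataFrame) -> bytes:
    buf = io.StringIO()
    write_episodes_csv(table, buf)
    return buf.getvalue().encode()
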