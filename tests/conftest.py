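import numpy as np
import pandas as pd
import pytest

from shapdrift import features, synth_ed, trees
from shapdrift.shapley import BackgroundSet


@pytest.fixture(scope="session")
def baseline_scenario():
    return synth_ed.make_scenario("baseline")


@pytest.fixture(scope="session")
def small_cohort(baseline_scenario):
    """~2.4k-episode baseline table (16 weeks at 150/week)."""
    sc = synth_ed.make_scenario("baseline", horizon_weeks=16, split_weeks=(8, 12))
    return synth_ed.simulate_cohort(sc, seed=101)


@pytest.fixture(scope="session")
def fitted_small(small_cohort):
    """Encoded matrix + fitted ensemble + background on the small cohort."""
    X = features.encode_table(small_cohort)
    ens = trees.fit_tree_ensemble(
        X,
        small_cohort["outcome"].to_numpy(),
        hyperparams={"n_estimators": 60, "max_depth": 3},
        seed=7,
    )
    bg = BackgroundSet.from_training(X, size=32, seed=3)
    return X, ens, bg


def random_ensemble(rng, d, n_trees=10, depth=3, n_fit=250):
    """A small fitted ensemble over d features with missingness."""
    X = rng.normal(size=(n_fit, d))
    X[rng.random((n_fit, d)) < 0.15] = np.nan
    beta = rng.normal(size=d)
    eta = np.where(np.isnan(X), 0.0, X * beta).sum(axis=1)
    y = (eta + rng.normal(size=n_fit) > 0).astype(int)
    return (
        trees.fit_tree_ensemble(
            X, y, hyperparams={"n_estimators": n_trees, "max_depth": depth}, seed=int(rng.integers(2**31))
        ),
        X,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_table(n=8, seed=0):
    """Tiny hand-controllable episode table."""
    rng = np.random.default_rng(seed)
    ts = pd.Timestamp("2019-04-01") + pd.to_timedelta(rng.integers(0, 14, n), unit="D")
    return pd.DataFrame(
        {
            "episode_id": [f"E{i}" for i in range(n)],
            "timestamp": ts,
            "outcome": rng.integers(0, 2, n),
            "age": rng.normal(55, 10, n),
            "resp_rate": rng.normal(17, 2, n),
            "arrival_mode": rng.choice(["walk_in", "ambulance"], n),
            "hx_hypertension": rng.integers(0, 2, n),
            "hx_diabetes": rng.integers(0, 2, n),
            "cohort": "train",
        }
    )
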