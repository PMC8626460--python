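"""Gradient-boosted tree fitting and a self-contained ensemble representation.

The classifier is fitted through XGBoost (binary logistic objective, native
missing-value handling), then extracted into a plain array-based tree
representation on which all downstream prediction and attribution runs. The
extraction is faithful by construction and verified at fit time: internal
margins must match backend margins to within float32 round-off. Keeping the
attribution engine on this internal representation means it never depends on
any training backend.

Traversal semantics (matching XGBoost): at an internal node with threshold
``t`` the left ("yes") branch is taken when ``x < t`` evaluated in float32;
a missing value follows the node's recorded default branch. Every row —
including an all-missing row — therefore reaches exactly one leaf per tree.
The ensemble margin is ``base_score + sum of leaf values``; admission risk is
the logistic transform of the margin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .features import FeatureMatrix

__all__ = [
    "Tree",
    "TreeEnsemble",
    "DEFAULT_HYPERPARAMS",
    "fit_tree_ensemble",
    "predict",
    "grid_search_hyperparams",
]

#: Fixed, documented hyperparameter set used in place of any automated search.
DEFAULT_HYPERPARAMS: dict = {
    "n_estimators": 200,
    "max_depth": 4,
    "learning_rate": 0.1,
    "subsample": 0.8,
    "min_child_weight": 1.0,
    "reg_lambda": 1.0,
}

LEAF = -1


@dataclass
class Tree:
    """One regression tree in flat-array form.

    ``feature[i] == LEAF`` marks leaves; for internal nodes the left child is
    taken when the feature value is < ``threshold[i]`` (float32 comparison),
    missing values go left iff ``default_left[i]``.
    """

    feature: np.ndarray  # int, LEAF for leaves
    threshold: np.ndarray  # float32
    left: np.ndarray  # int child index
    right: np.ndarray
    default_left: np.ndarray  # bool
    value: np.ndarray  # float64 leaf margins (0 for internal nodes)

    def __post_init__(self):
        self.feature = np.asarray(self.feature, dtype=np.int64)
        self.threshold = np.asarray(self.threshold, dtype=np.float32)
        self.left = np.asarray(self.left, dtype=np.int64)
        self.right = np.asarray(self.right, dtype=np.int64)
        self.default_left = np.asarray(self.default_left, dtype=bool)
        self.value = np.asarray(self.value, dtype=np.float64)
        self.validate()

    def validate(self) -> None:
        n = len(self.feature)
        internal = self.feature != LEAF
        for child in (self.left[internal], self.right[internal]):
            if child.size and (child.min() < 0 or child.max() >= n):
                raise ValueError("child index out of range")
        # every internal node must have two distinct children
        if internal.any() and np.any(self.left[internal] == self.right[internal]):
            raise ValueError("internal node with identical children")

    @property
    def n_leaves(self) -> int:
        return int((self.feature == LEAF).sum())

    def leaf_index(self, X32: np.ndarray) -> np.ndarray:
        """Vectorised traversal: leaf node index for every row of ``X32``."""
        node = np.zeros(len(X32), dtype=np.int64)
        while True:
            feat = self.feature[node]
            active = feat != LEAF
            if not active.any():
                return node
            rows = np.nonzero(active)[0]
            f = feat[rows]
            x = X32[rows, f]
            thr = self.threshold[node[rows]]
            nan = np.isnan(x)
            go_left = np.where(nan, self.default_left[node[rows]], x < thr)
            node[rows] = np.where(go_left, self.left[node[rows]], self.right[node[rows]])

    def predict_margin(self, X32: np.ndarray) -> np.ndarray:
        return self.value[self.leaf_index(X32)]


@dataclass
class TreeEnsemble:
    """An additive logistic tree ensemble: margin = base_score + Σ tree(x)."""

    trees: list[Tree]
    base_score: float  # margin-scale offset
    feature_names: list[str]
    hyperparams: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def _as_matrix(self, X) -> np.ndarray:
        if isinstance(X, FeatureMatrix):
            if list(X.columns) != self.feature_names:
                raise ValueError("feature columns do not match ensemble feature_names")
            X = X.values
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.n_features:
            raise ValueError(f"expected {self.n_features} columns, got {X.shape[1]}")
        return np.asarray(X, dtype=np.float32)

    def predict_margin(self, X) -> np.ndarray:
        X32 = self._as_matrix(X)
        margin = np.full(len(X32), self.base_score, dtype=np.float64)
        for tree in self.trees:
            margin += tree.predict_margin(X32)
        return margin

    def predict_risk(self, X) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.predict_margin(X)))

    # -- serialisation --------------------------------------------------
    def to_json(self, path=None) -> str:
        doc = {
            "base_score": self.base_score,
            "feature_names": self.feature_names,
            "hyperparams": self.hyperparams,
            "trees": [
                {
                    "feature": t.feature.tolist(),
                    "threshold": [float(v) for v in t.threshold],
                    "left": t.left.tolist(),
                    "right": t.right.tolist(),
                    "default_left": t.default_left.astype(int).tolist(),
                    "value": t.value.tolist(),
                }
                for t in self.trees
            ],
        }
        text = json.dumps(doc)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "TreeEnsemble":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        trees = [
            Tree(
                feature=d["feature"],
                threshold=d["threshold"],
                left=d["left"],
                right=d["right"],
                default_left=np.array(d["default_left"], dtype=bool),
                value=d["value"],
            )
            for d in doc["trees"]
        ]
        return cls(trees, float(doc["base_score"]), list(doc["feature_names"]), dict(doc.get("hyperparams", {})))


def predict(ensemble: TreeEnsemble, X, output: str = "risk") -> np.ndarray:
    """Predict margins (log-odds) or admission risks for ``X``."""
    if output == "margin":
        return ensemble.predict_margin(X)
    if output == "risk":
        return ensemble.predict_risk(X)
    raise ValueError("output must be 'margin' or 'risk'")


# ----------------------------------------------------------------------
# Fitting via XGBoost
# ----------------------------------------------------------------------

def _parse_dump_node(node: dict, feature_index: dict[str, int], nodes: dict[int, dict]) -> None:
    nodes[node["nodeid"]] = node
    for child in node.get("children", ()):
        _parse_dump_node(child, feature_index, nodes)


def _tree_from_dump(doc: dict, feature_index: dict[str, int]) -> Tree:
    nodes: dict[int, dict] = {}
    _parse_dump_node(doc, feature_index, nodes)
    order = sorted(nodes)  # nodeids are unique but not contiguous; remap
    remap = {nid: i for i, nid in enumerate(order)}
    n = len(order)
    feature = np.full(n, LEAF, dtype=np.int64)
    threshold = np.zeros(n, dtype=np.float32)
    left = np.zeros(n, dtype=np.int64)
    right = np.zeros(n, dtype=np.int64)
    default_left = np.zeros(n, dtype=bool)
    value = np.zeros(n, dtype=np.float64)
    for nid in order:
        i = remap[nid]
        node = nodes[nid]
        if "leaf" in node:
            value[i] = float(node["leaf"])
        else:
            feature[i] = feature_index[node["split"]]
            threshold[i] = np.float32(node["split_condition"])
            left[i] = remap[node["yes"]]
            right[i] = remap[node["no"]]
            default_left[i] = node["missing"] == node["yes"]
    return Tree(feature, threshold, left, right, default_left, value)


def fit_tree_ensemble(
    X, y, hyperparams: dict | None = None, seed: int = 0
) -> TreeEnsemble:
    """Fit a gradient-boosted logistic classifier and extract it.

    ``X`` may be a :class:`~shapdrift.features.FeatureMatrix` or a 2-D array;
    missing entries must be NaN. The returned ensemble is fully
    self-contained; extraction fidelity (internal vs backend margins) is
    asserted on the training rows before returning.
    """
    import xgboost as xgb

    if isinstance(X, FeatureMatrix):
        feature_names = list(X.columns)
        Xv = X.values
    else:
        Xv = np.asarray(X, dtype=float)
        feature_names = [f"f{i}" for i in range(Xv.shape[1])]
    y = np.asarray(y)
    if np.isnan(y.astype(float)).any():
        raise ValueError("labels contain missing values")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need both outcome classes to fit a classifier")

    hp = dict(DEFAULT_HYPERPARAMS)
    hp.update(hyperparams or {})
    n_rounds = int(hp.pop("n_estimators"))
    params = {
        "objective": "binary:logistic",
        "max_depth": int(hp.pop("max_depth")),
        "eta": float(hp.pop("learning_rate")),
        "subsample": float(hp.pop("subsample")),
        "min_child_weight": float(hp.pop("min_child_weight", 1.0)),
        "lambda": float(hp.pop("reg_lambda", 1.0)),
        "base_score": 0.5,  # margin offset 0; the intercept is learnt by the trees
        "tree_method": "hist",
        "nthread": 1,
        "seed": int(seed),
    }
    params.update(hp)  # any remaining extras pass straight to the backend

    dm = xgb.DMatrix(Xv, label=y, feature_names=feature_names, missing=np.nan)
    booster = xgb.train(params, dm, num_boost_round=n_rounds)

    feature_index = {name: i for i, name in enumerate(feature_names)}
    dumps = booster.get_dump(dump_format="json")
    trees = [_tree_from_dump(json.loads(d), feature_index) for d in dumps]

    ensemble = TreeEnsemble(
        trees,
        base_score=0.0,
        feature_names=feature_names,
        hyperparams={**DEFAULT_HYPERPARAMS, **(hyperparams or {})},
    )
    # Faithfulness check + empirical base offset (robust to backend versions
    # that store the global bias in their own parameterisation).
    probe = Xv[: min(len(Xv), 256)]
    backend = booster.predict(xgb.DMatrix(probe, feature_names=feature_names, missing=np.nan), output_margin=True)
    internal = ensemble.predict_margin(probe)
    offsets = backend.astype(np.float64) - internal
    if offsets.size and np.ptp(offsets) > 1e-4:
        raise RuntimeError("tree extraction unfaithful: non-constant margin offset")
    ensemble.base_score = float(np.mean(offsets)) if offsets.size else 0.0
    internal = ensemble.predict_margin(probe)
    if offsets.size and np.max(np.abs(internal - backend)) > 1e-4:
        raise RuntimeError("tree extraction unfaithful: margin mismatch")
    return ensemble


def grid_search_hyperparams(
    X, y, grid: dict[str, list], n_splits: int = 5, seed: int = 0
) -> tuple[dict, float]:
    """Plain cross-validated grid search over a small hyperparameter grid.

    Convenience helper only — the package's documented default set
    (:data:`DEFAULT_HYPERPARAMS`) is used everywhere unless overridden.
    Returns the best parameter dict and its mean validation AUROC.
    """
    from itertools import product

    from sklearn.model_selection import StratifiedKFold

    from .perf import auroc

    if isinstance(X, FeatureMatrix):
        Xv, names = X.values, list(X.columns)
    else:
        Xv, names = np.asarray(X, dtype=float), None
    y = np.asarray(y)
    keys = sorted(grid)
    best: tuple[float, dict] = (-np.inf, {})
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    for combo in product(*(grid[k] for k in keys)):
        hp = dict(zip(keys, combo))
        scores = []
        for train_idx, val_idx in skf.split(Xv, y):
            ens = fit_tree_ensemble(Xv[train_idx], y[train_idx], hyperparams=hp, seed=seed)
            scores.append(auroc(ens.predict_margin(Xv[val_idx]), y[val_idx]))
        mean_score = float(np.mean(scores))
        if mean_score > best[0]:
            best = (mean_score, hp)
    return best[1], best[0]
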