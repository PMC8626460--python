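"""Exact Shapley attributions for tree-ensemble margins.

Two independent routes are provided:

``brute_force_shapley``
    The definition itself — enumerate all 2^d feature coalitions, valuing a
    coalition S as the background-mean prediction with features in S taken
    from the explained instance and the rest from each background row
    (interventional conditioning). Exponential in d; it is the oracle.

``TreeExplainer`` / ``tree_shapley`` / ``explain_cohort``
    An exact polynomial algorithm exploiting tree structure. For a single
    tree, a single background row z and a leaf with value c, the coalition
    game restricted to that leaf is c * [IN ⊆ S] * [OUT ∩ S = ∅], where IN
    are path features the instance satisfies but z does not, and OUT the
    reverse (a leaf with a path feature satisfied by neither is unreachable
    and contributes nothing). The Shapley value of such a conjunction game
    has a closed form in |IN|, |OUT| and the total feature count, so each
    leaf's contribution is a table lookup; summing over leaves, trees and
    background rows reproduces the brute-force values exactly (up to float
    round-off). Attributions are additive across trees and across background
    rows by linearity of the Shapley operator.

Attributions live in margin (log-odds) space, where tree-path computation is
exact; ``probability_view`` provides a per-row linear rescaling onto the risk
scale. Because that rescaling multiplies a whole row by one scalar, the
normalised shares used downstream are identical in either space.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb, factorial

import numpy as np
import pandas as pd

from .features import FeatureMatrix
from .trees import LEAF, Tree, TreeEnsemble

__all__ = [
    "BackgroundSet",
    "AttributionMatrix",
    "brute_force_shapley",
    "tree_shapley",
    "explain_cohort",
    "TreeExplainer",
    "probability_view",
]

BRUTE_FORCE_MAX_FEATURES = 15


@dataclass
class BackgroundSet:
    """Equal-weight reference rows defining the expectation baseline."""

    X: np.ndarray  # (B, d) float, NaN for missing

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, dtype=np.float64))
        if len(self.X) < 1:
            raise ValueError("background must contain at least one row")

    @property
    def size(self) -> int:
        return len(self.X)

    @classmethod
    def from_training(cls, X, size: int = 256, seed: int = 0) -> "BackgroundSet":
        """Draw a composition-matched background from (encoded) training rows.

        Interventional expectations are only as good as the background's
        representativeness, and with small backgrounds the sampling error of
        *discrete* feature composition (e.g. the walk-in/ambulance mix)
        directly biases attribution magnitudes. Rows are therefore sorted
        lexicographically — low-cardinality (discrete) columns as the most
        significant keys, continuous columns last — and sampled
        systematically with a seeded random offset: level proportions of
        every discrete feature are then matched to within ~1/size, and
        continuous features are quantile-balanced.
        """
        Xv = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
        n = len(Xv)
        if n <= size:
            return cls(Xv)
        cardinality = [
            (len(np.unique(Xv[~np.isnan(Xv[:, j]), j])), j) for j in range(Xv.shape[1])
        ]
        # np.lexsort: the LAST key is the primary sort key
        ordered_cols = [j for _, j in sorted(cardinality, reverse=True)]
        order = np.lexsort(tuple(Xv[:, j] for j in ordered_cols))
        rng = np.random.default_rng(seed)
        step = n / size
        idx = (rng.uniform(0, step) + step * np.arange(size)).astype(int)
        return cls(Xv[order[idx]])


@dataclass
class AttributionMatrix:
    """Per-episode Shapley vectors plus the shared base value.

    ``phi0 + phi.sum(axis=1)`` reconstructs the margin of every row (local
    accuracy); ``margins`` carries the reconstructed predictions for
    verification and for the probability-space view.
    """

    phi: np.ndarray  # (n, d) margin-space attributions
    phi0: float  # expected margin over the background
    feature_names: list[str]
    episode_ids: np.ndarray | None = None
    margins: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.phi)

    def local_accuracy_error(self) -> np.ndarray:
        if self.margins is None:
            raise ValueError("margins not recorded")
        return np.abs(self.phi0 + self.phi.sum(axis=1) - self.margins)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.phi, columns=self.feature_names)
        frame.insert(0, "phi0", self.phi0)
        if self.episode_ids is not None:
            frame.insert(0, "episode_id", self.episode_ids)
        return frame

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ----------------------------------------------------------------------
# Brute-force coalition enumeration (the oracle)
# ----------------------------------------------------------------------

def brute_force_shapley(predict_fn, x, background: BackgroundSet) -> AttributionMatrix:
    """Shapley values by direct enumeration of all feature coalitions.

    ``predict_fn`` maps a (n, d) matrix to margins. ``v(S)`` is the mean of
    ``predict_fn`` over background rows with coordinates in S replaced by the
    instance's. Contract: d <= 15.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    d = len(x)
    if d > BRUTE_FORCE_MAX_FEATURES:
        raise ValueError(f"brute force limited to {BRUTE_FORCE_MAX_FEATURES} features, got {d}")
    B = background.size

    # v for all 2^d coalitions in one predict call
    n_sets = 1 << d
    masks = np.zeros((n_sets, d), dtype=bool)
    for i in range(d):
        masks[:, i] = (np.arange(n_sets) >> i) & 1
    hybrids = np.where(masks[:, None, :], x[None, None, :], background.X[None, :, :])
    preds = np.asarray(predict_fn(hybrids.reshape(n_sets * B, d)), dtype=np.float64)
    v = preds.reshape(n_sets, B).mean(axis=1)

    weights = np.array(
        [factorial(s) * factorial(d - s - 1) / factorial(d) for s in range(d)]
    )
    sizes = masks.sum(axis=1)
    phi = np.zeros(d)
    for i in range(d):
        without = np.nonzero(~masks[:, i])[0]
        with_i = without | (1 << i)
        phi[i] = np.sum(weights[sizes[without]] * (v[with_i] - v[without]))
    return AttributionMatrix(
        phi[None, :], float(v[0]), [f"f{i}" for i in range(d)], margins=np.array([v[-1]])
    )


# ----------------------------------------------------------------------
# Exact polynomial tree algorithm
# ----------------------------------------------------------------------

@dataclass
class _LeafPath:
    """Deduplicated per-feature conditions along one root-to-leaf path."""

    features: np.ndarray  # (p,) feature indices, unique
    value: float
    # per feature: list of (threshold, default_left, go_left) node conditions
    conditions: list[list[tuple[np.float32, bool, bool]]]

    def satisfied(self, X32: np.ndarray) -> np.ndarray:
        """(n, p) bool: does each row satisfy every condition of each path feature."""
        n = len(X32)
        ok = np.ones((n, len(self.features)), dtype=bool)
        for j, f in enumerate(self.features):
            col = X32[:, f]
            nan = np.isnan(col)
            for thr, default_left, go_left in self.conditions[j]:
                goes_left = np.where(nan, default_left, col < thr)
                ok[:, j] &= goes_left == go_left
        return ok


def _enumerate_leaf_paths(tree: Tree) -> list[_LeafPath]:
    paths: list[_LeafPath] = []

    def walk(node: int, conds: list[tuple[int, np.float32, bool, bool]]):
        if tree.feature[node] == LEAF:
            if tree.value[node] == 0.0 and not conds:
                return  # constant-zero root leaf contributes nothing
            by_feature: dict[int, list[tuple[np.float32, bool, bool]]] = {}
            for f, thr, dl, gl in conds:
                by_feature.setdefault(f, []).append((thr, dl, gl))
            feats = np.array(sorted(by_feature), dtype=np.int64)
            paths.append(
                _LeafPath(feats, float(tree.value[node]), [by_feature[f] for f in feats])
            )
            return
        f = int(tree.feature[node])
        thr = tree.threshold[node]
        dl = bool(tree.default_left[node])
        walk(int(tree.left[node]), conds + [(f, thr, dl, True)])
        walk(int(tree.right[node]), conds + [(f, thr, dl, False)])

    walk(0, [])
    return paths


def _shapley_weight_tables(d: int, max_path: int) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form Shapley weights for conjunction games with d players.

    For a game ``v(S) = [IN ⊆ S][OUT ∩ S = ∅]`` with |IN|=a, |OUT|=b and
    F = d - a - b free players:

    - each IN player gets  W+(a,b) = Σ_t C(F,t) (a-1+t)! (d-a-t)! / d!
    - each OUT player gets -W-(a,b), W-(a,b) = Σ_t C(F,t) (a+t)! (d-a-t-1)! / d!

    Computed in exact rational arithmetic, returned as float64 tables indexed
    [a, b] up to ``max_path``.
    """
    size = max_path + 1
    wpos = np.zeros((size + 1, size + 1))
    wneg = np.zeros((size + 1, size + 1))
    fact = [factorial(i) for i in range(d + 1)]
    d_fact = Fraction(fact[d])
    for a in range(size + 1):
        for b in range(size + 1):
            if a + b > d:
                continue
            F = d - a - b
            if a >= 1:
                total = sum(
                    Fraction(comb(F, t) * fact[a - 1 + t] * fact[d - a - t], 1)
                    for t in range(F + 1)
                )
                wpos[a, b] = float(total / d_fact)
            if b >= 1:
                total = sum(
                    Fraction(comb(F, t) * fact[a + t] * fact[d - a - t - 1], 1)
                    for t in range(F + 1)
                )
                wneg[a, b] = float(total / d_fact)
    return wpos, wneg


class TreeExplainer:
    """Exact interventional Shapley attribution for a :class:`TreeEnsemble`.

    Background-dependent quantities (per-leaf background reachability and the
    expected margin) are precomputed once, so explaining a cohort is a stream
    of small dense matrix operations.
    """

    def __init__(self, ensemble: TreeEnsemble, background: BackgroundSet):
        if background.X.shape[1] != ensemble.n_features:
            raise ValueError("background schema does not match ensemble features")
        self.ensemble = ensemble
        self.background = background
        d = ensemble.n_features
        Z32 = background.X.astype(np.float32)

        self._leaves: list[tuple[_LeafPath, np.ndarray]] = []
        max_path = 1
        for tree in ensemble.trees:
            for path in _enumerate_leaf_paths(tree):
                if len(path.features) == 0:
                    continue  # constant leaf: pure phi0 contribution
                z_ok = path.satisfied(Z32)  # (B, p)
                self._leaves.append((path, z_ok))
                max_path = max(max_path, len(path.features))
        self._wpos, self._wneg = _shapley_weight_tables(d, min(max_path, d))
        self.phi0 = float(np.mean(ensemble.predict_margin(background.X)))

    def shap_values(self, X, episode_ids=None) -> AttributionMatrix:
        ens = self.ensemble
        if isinstance(X, FeatureMatrix):
            if list(X.columns) != ens.feature_names:
                raise ValueError("feature columns do not match ensemble feature_names")
            Xv = X.values
        else:
            Xv = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if Xv.shape[1] != ens.n_features:
            raise ValueError("instance schema does not match ensemble features")
        X32 = Xv.astype(np.float32)
        n, d = Xv.shape
        B = self.background.size
        phi = np.zeros((n, d))
        for path, z_ok in self._leaves:
            x_ok = path.satisfied(X32).astype(np.float64)  # (n, p)
            not_x = 1.0 - x_ok
            z_okf = z_ok.astype(np.float64)
            not_z = 1.0 - z_okf
            a = x_ok @ not_z.T  # (n, B): |IN|
            b = not_x @ z_okf.T  # (n, B): |OUT|
            alive = (not_x @ not_z.T) == 0
            ai = a.astype(np.intp)
            bi = b.astype(np.intp)
            wp = np.where(alive, self._wpos[ai, bi], 0.0)
            wn = np.where(alive, self._wneg[ai, bi], 0.0)
            # phi contribution of path feature j:
            #   c/B * [x_ok_j * Σ_b ~z_ok_bj wp_nb  -  ~x_ok_j * Σ_b z_ok_bj wn_nb]
            contrib = x_ok * (wp @ not_z) - not_x * (wn @ z_okf)  # (n, p)
            phi[:, path.features] += (path.value / B) * contrib
        margins = ens.predict_margin(Xv)
        return AttributionMatrix(
            phi,
            self.phi0,
            list(ens.feature_names),
            episode_ids=None if episode_ids is None else np.asarray(episode_ids),
            margins=margins,
        )


def tree_shapley(ensemble: TreeEnsemble, x, background: BackgroundSet) -> AttributionMatrix:
    """Exact attribution of a single instance (see :class:`TreeExplainer`)."""
    return TreeExplainer(ensemble, background).shap_values(np.atleast_2d(x))


def explain_cohort(
    ensemble: TreeEnsemble,
    X,
    background: BackgroundSet,
    episode_ids=None,
    check_local_accuracy: bool = True,
    atol: float = 1e-6,
) -> AttributionMatrix:
    """Attribute every row of a cohort, preserving row order.

    Each row's attributions satisfy local accuracy; when
    ``check_local_accuracy`` is set, rows violating it beyond ``atol`` raise
    with their episode ids (this should never happen and indicates a
    schema/serialisation fault).
    """
    if isinstance(X, FeatureMatrix) and episode_ids is None and "episode_id" in getattr(X.frame, "attrs", {}):
        episode_ids = X.frame.attrs["episode_id"]
    n = len(X.frame) if isinstance(X, FeatureMatrix) else len(np.atleast_2d(X))
    if n == 0:
        raise ValueError("cannot explain an empty cohort")
    attr = TreeExplainer(ensemble, background).shap_values(X, episode_ids=episode_ids)
    if check_local_accuracy:
        err = attr.local_accuracy_error()
        bad = np.nonzero(err > atol)[0]
        if bad.size:
            ids = attr.episode_ids[bad[:5]] if attr.episode_ids is not None else bad[:5]
            raise RuntimeError(
                f"local accuracy violated on {bad.size} rows (first: {list(ids)}; "
                f"max error {err.max():.3g})"
            )
    return attr


def probability_view(attr: AttributionMatrix) -> AttributionMatrix:
    """Rescale margin-space attributions onto the risk (probability) scale.

    Each row is multiplied by the chord slope of the logistic link between
    the base margin and the row's margin, so local accuracy holds on the
    probability scale: sigmoid(phi0) + Σ phi_prob = sigmoid(margin). Being a
    per-row scalar rescaling, it leaves normalised shares unchanged.
    """
    if attr.margins is None:
        raise ValueError("margins required for the probability view")
    sig = lambda z: 1.0 / (1.0 + np.exp(-z))
    delta = attr.margins - attr.phi0
    p0 = sig(attr.phi0)
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = np.where(
            np.abs(delta) < 1e-12, p0 * (1 - p0), (sig(attr.margins) - p0) / delta
        )
    return AttributionMatrix(
        attr.phi * slope[:, None],
        float(p0),
        list(attr.feature_names),
        episode_ids=attr.episode_ids,
        margins=sig(attr.margins),
    )
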