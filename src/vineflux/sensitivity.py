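"""Forest-based global sensitivity analysis of the flux equations.

The predictors of the flux model (E_c, D_c, R_c, r_bh) are strongly
multicollinear, which defeats one-at-a-time and linear-regression
sensitivity screens.  Instead a random-forest regression is fitted and
predictor importance is read off the forest structure:

minimal depth
    for each tree, the depth of the shallowest node splitting on the
    predictor (root = 0); trees that never split on it contribute the
    tree's maximal depth + 1 (stated convention).  The forest value is the
    average over trees; lower is more important, with 0 the maximum
    possible importance.

second-order maximal subtrees
    for an ordered pair (v, w), the minimal depth of w is re-measured
    inside the maximal subtrees of v (subtrees rooted at v's shallowest
    splits) and normalized by the subtree depth to [0, 1]; 0 indicates
    strong pairwise association, 1 none.  The matrix is not symmetric.

The forest itself is a scikit-learn ``RandomForestRegressor``; the depth
statistics are computed here by walking the fitted tree structures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .exceptions import DegenerateFitError, InvalidInputError

DEFAULT_N_TREES = 1000
DEFAULT_MIN_NODE_SIZE = 5


@dataclass
class ForestModel:
    """A fitted regression forest plus the metadata needed for depth analysis."""

    model: RandomForestRegressor
    predictor_names: list[str]
    response_name: str
    oob_r2: float
    hyperparameters: dict


@dataclass
class SensitivityResult:
    """Per-predictor minimal depths and the pairwise interaction matrix."""

    response_name: str
    predictor_names: list[str]
    minimal_depth: pd.Series
    interaction_matrix: pd.DataFrame
    oob_r2: float
    hyperparameters: dict = field(default_factory=dict)

    def ranking(self) -> list[str]:
        """Predictors ordered from most to least important."""
        return list(self.minimal_depth.sort_values().index)


def fit_forest(table: pd.DataFrame, response: str,
               predictors: list[str] | None = None, *,
               n_trees: int = DEFAULT_N_TREES,
               mtry: int | None = None,
               min_node_size: int = DEFAULT_MIN_NODE_SIZE,
               seed: int = 0) -> ForestModel:
    """Fit a regression forest of ``response`` on ``predictors``.

    Defaults: ``n_trees`` = 1000, ``mtry`` = ceil(p / 3) candidate
    variables per split, minimum node size 5.  Requires at least two
    predictors and 50 rows; rows with missing values are dropped.
    """
    predictors = predictors or [c for c in table.columns if c != response]
    if len(predictors) < 2:
        raise InvalidInputError("need at least two predictors")
    if response not in table.columns:
        raise InvalidInputError(f"response column {response!r} not in table")
    data = table[predictors + [response]].dropna()
    if len(data) < 50:
        raise InvalidInputError(f"need at least 50 complete rows, got {len(data)}")
    y = data[response].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise DegenerateFitError("response is constant; forest fit is degenerate")
    mtry = mtry or math.ceil(len(predictors) / 3)
    hyper = {
        "n_trees": n_trees,
        "mtry": mtry,
        "min_node_size": min_node_size,
        "seed": seed,
    }
    model = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=mtry,
        min_samples_leaf=min_node_size,
        oob_score=True,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    model.fit(data[predictors].to_numpy(dtype=float), y)
    return ForestModel(model, list(predictors), response, float(model.oob_score_), hyper)


def _node_depths(tree) -> np.ndarray:
    depths = np.zeros(tree.node_count, dtype=np.int64)
    stack = [(0, 0)]
    while stack:
        node, depth = stack.pop()
        depths[node] = depth
        left, right = tree.children_left[node], tree.children_right[node]
        if left != -1:
            stack.append((left, depth + 1))
            stack.append((right, depth + 1))
    return depths


def _subtree_nodes(tree, root: int) -> np.ndarray:
    nodes = []
    stack = [root]
    while stack:
        node = stack.pop()
        nodes.append(node)
        left = tree.children_left[node]
        if left != -1:
            stack.append(left)
            stack.append(tree.children_right[node])
    return np.asarray(nodes)


def minimal_depth(forest: ForestModel) -> pd.Series:
    """Forest-averaged minimal depth of every predictor."""
    p = len(forest.predictor_names)
    totals = np.zeros(p)
    for est in forest.model.estimators_:
        tree = est.tree_
        depths = _node_depths(tree)
        internal = tree.children_left != -1
        max_depth = int(depths.max())
        for j in range(p):
            mask = internal & (tree.feature == j)
            totals[j] += depths[mask].min() if mask.any() else max_depth + 1
    return pd.Series(totals / len(forest.model.estimators_),
                     index=forest.predictor_names, name="minimal_depth")


def pairwise_interactions(forest: ForestModel) -> pd.DataFrame:
    """Normalized second-order maximal-subtree depths for all ordered pairs.

    For each tree and predictor v, the maximal subtrees are those rooted at
    nodes splitting on v with no ancestor splitting on v.  Within their
    union, the minimal depth of w relative to the shallowest subtree root,
    normalized by (deepest relative depth + 1), is the tree's (v, w) entry;
    1 when w never appears there (or v never splits).  Entries are averaged
    over trees; the diagonal is undefined and reported as NaN.
    """
    p = len(forest.predictor_names)
    totals = np.zeros((p, p))
    n_trees = len(forest.model.estimators_)
    for est in forest.model.estimators_:
        tree = est.tree_
        depths = _node_depths(tree)
        internal = tree.children_left != -1
        tree_vals = np.ones((p, p))
        for v in range(p):
            v_nodes = np.flatnonzero(internal & (tree.feature == v))
            if v_nodes.size == 0:
                continue
            # maximal subtrees: v-nodes with no v-split ancestor.  Visiting
            # candidates shallowest-first, a node already inside a chosen
            # subtree cannot be maximal.
            covered: set[int] = set()
            subtrees = []  # (node array, depth relative to subtree root)
            for node in sorted(v_nodes.tolist(), key=lambda n: depths[n]):
                if node in covered:
                    continue
                nodes = _subtree_nodes(tree, node)
                covered.update(nodes.tolist())
                subtrees.append((nodes, depths[nodes] - depths[node]))
            norm = max(rel.max() for _, rel in subtrees) + 1.0
            for w in range(p):
                if w == v:
                    continue
                best = None
                for nodes, rel in subtrees:
                    mask = internal[nodes] & (tree.feature[nodes] == w)
                    if mask.any():
                        d = rel[mask].min()
                        best = d if best is None else min(best, d)
                if best is not None:
                    tree_vals[v, w] = best / norm
        totals += tree_vals
    mat = totals / n_trees
    np.fill_diagonal(mat, np.nan)
    return pd.DataFrame(mat, index=forest.predictor_names,
                        columns=forest.predictor_names)


def tune_mtry(table: pd.DataFrame, response: str,
              predictors: list[str] | None = None, *,
              n_trees: int = 100, min_node_size: int = DEFAULT_MIN_NODE_SIZE,
              oob_tolerance: float = 5e-4, seed: int = 0) -> int:
    """Grid-search the candidate-variables-per-split count by OOB score.

    Fits small forests for every mtry from ceil(p / 3) to p and returns the
    largest value whose out-of-bag R^2 lies within ``oob_tolerance`` of the
    best.  Preferring the largest near-tied mtry matters for depth-based
    importance: with few candidates per split, shallow nodes are often
    forced onto random substitutes, which blurs minimal-depth orderings,
    so among statistically indistinguishable forests the least-randomized
    one gives the cleanest depth statistics.  This replaces an external
    hyperparameter optimization step with a reproducible in-package one.
    """
    predictors = predictors or [c for c in table.columns if c != response]
    candidates = range(math.ceil(len(predictors) / 3), len(predictors) + 1)
    scores = {}
    for mtry in candidates:
        forest = fit_forest(
            table, response, predictors,
            n_trees=n_trees, mtry=mtry, min_node_size=min_node_size, seed=seed,
        )
        scores[mtry] = forest.oob_r2
    best = max(scores.values())
    return max(m for m, s in scores.items() if s >= best - oob_tolerance)


def analyze(table: pd.DataFrame, response: str,
            predictors: list[str] | None = None, *,
            n_trees: int = DEFAULT_N_TREES, mtry: int | None = None,
            min_node_size: int = DEFAULT_MIN_NODE_SIZE,
            tune: bool = False, seed: int = 0) -> SensitivityResult:
    """Fit the forest and compute both sensitivity summaries in one call.

    With ``tune=True`` the per-split candidate count is first selected by
    the out-of-bag grid search of :func:`tune_mtry` (ignored when ``mtry``
    is given explicitly).
    """
    if tune and mtry is None:
        mtry = tune_mtry(table, response, predictors,
                         min_node_size=min_node_size, seed=seed)
    forest = fit_forest(
        table, response, predictors,
        n_trees=n_trees, mtry=mtry, min_node_size=min_node_size, seed=seed,
    )
    return SensitivityResult(
        response_name=response,
        predictor_names=forest.predictor_names,
        minimal_depth=minimal_depth(forest),
        interaction_matrix=pairwise_interactions(forest),
        oob_r2=forest.oob_r2,
        hyperparameters=forest.hyperparameters,
    )
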