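"""Model interpretation: variable contributions, partial dependence,
pairwise interaction sizes.

Relative influence of a predictor is its share of the total squared-error
improvement over all splits of all trees in the selected ensemble,
expressed as a percentage (contributions sum to 100).

Partial dependence is computed by weighted tree traversal: descending each
tree once per grid value, following the forced branch at splits on the
target predictor(s) and splitting the training occupancy (row weights,
tracked per conditional path) at splits on other predictors. Tracking
occupancy per path makes the traversal identical to averaging clamped
predictions over the training set.

The pairwise interaction size is the departure of the two-predictor
partial-dependence surface (logit scale, quantile lattice) from additivity
of its marginal effects: the surface is fit by least squares with row and
column main effects only, and the score is 1000 x the mean squared
residual — the convention of the standard BRT toolchain.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from tgbrt.brt_engine import BRTModel, RegressionTree, _sigmoid


def relative_influence(model: BRTModel) -> pd.DataFrame:
    """Percentage contribution of each predictor, descending.

    Split gains are summed over the first ``n_trees_used`` trees and
    normalized to 100. Ties are broken by predictor name.
    """
    if model.n_trees_used < 1 or not model.trees:
        raise ValueError("cannot compute contributions for an empty ensemble")
    gains = np.zeros(len(model.feature_names))
    for tree in model.trees[: model.n_trees_used]:
        internal = tree.feature >= 0
        np.add.at(gains, tree.feature[internal], tree.gain[internal])
    total = gains.sum()
    if total <= 0:
        raise ValueError("model contains no splits")
    df = pd.DataFrame({"predictor": model.feature_names,
                       "contribution": 100.0 * gains / total})
    return df.sort_values(["contribution", "predictor"],
                          ascending=[False, True], ignore_index=True)


def _tree_pd(tree: RegressionTree, X: np.ndarray, w: np.ndarray,
             target_cols: list[int], grid: np.ndarray) -> np.ndarray:
    """Weighted traversal PD of one tree over all grid points at once.

    ``grid`` is (G, len(target_cols)); returns the (G,) vector of
    occupancy-weighted terminal sums (unnormalized by total weight).
    """
    G = len(grid)

    def rec(node: int, rows: np.ndarray) -> np.ndarray:
        f = tree.feature[node]
        if f < 0:
            return np.full(G, tree.value[node] * w[rows].sum())
        thr = tree.threshold[node]
        if f in target_cols:
            gv = grid[:, target_cols.index(f)]
            left = rec(tree.left[node], rows)
            right = rec(tree.right[node], rows)
            return np.where(gv <= thr, left, right)
        mask = X[rows, f] <= thr
        return rec(tree.left[node], rows[mask]) + rec(tree.right[node], rows[~mask])

    return rec(0, np.arange(len(X)))


@dataclass
class PartialDependence:
    predictors: list[str]
    grid: np.ndarray  # (G, n_predictors)
    response: np.ndarray  # (G,)
    scale: str  # probability | logit

    def as_table(self) -> pd.DataFrame:
        df = pd.DataFrame(self.grid, columns=self.predictors)
        df["response"] = self.response
        return df

    def as_surface(self) -> pd.DataFrame:
        """2-D PD reshaped to a (levels_i x levels_j) matrix."""
        if len(self.predictors) != 2:
            raise ValueError("as_surface needs a 2-predictor PD")
        xi = np.unique(self.grid[:, 0])
        n_i = len(xi)
        return pd.DataFrame(self.response.reshape(n_i, -1), index=xi)


def partial_dependence(model: BRTModel, predictors, grid_points: int = 100,
                       grid_values=None, scale: str = "probability") -> PartialDependence:
    """Partial dependence on one or two predictors.

    The evaluation grid spans the observed range of each predictor
    (``grid_points`` equally spaced values), unless explicit
    ``grid_values`` (one array per predictor) are given. The response is
    the relative likelihood of occurrence by default; ``scale='logit'``
    returns the raw additive scale.
    """
    if isinstance(predictors, str):
        predictors = [predictors]
    if not 1 <= len(predictors) <= 2:
        raise ValueError("partial dependence supports 1 or 2 predictors")
    cols = []
    for p in predictors:
        if p not in model.feature_names:
            raise KeyError(f"unknown predictor {p!r}")
        cols.append(model.feature_names.index(p))
    X, w = model.X_train, model.w_train
    if grid_values is None:
        grid_values = [np.linspace(X[:, c].min(), X[:, c].max(), grid_points)
                       for c in cols]
    if len(predictors) == 1:
        grid = np.asarray(grid_values[0], float)[:, None]
    else:
        gi, gj = np.meshgrid(grid_values[0], grid_values[1], indexing="ij")
        grid = np.column_stack([gi.ravel(), gj.ravel()])
    eta = np.full(len(grid), model.intercept * w.sum())
    for tree in model.trees[: model.n_trees_used]:
        eta += model.params.learning_rate * _tree_pd(tree, X, w, cols, grid)
    eta /= w.sum()
    resp = _sigmoid(eta) if scale == "probability" else eta
    return PartialDependence(list(predictors), grid, resp, scale)


def _quantile_levels(x: np.ndarray, g: int) -> np.ndarray:
    return np.quantile(x, (np.arange(g) + 0.5) / g)


def interaction_size(model: BRTModel, predictor_i: str, predictor_j: str,
                     grid_points: int = 20) -> float:
    """Departure of the 2-D PD surface from additivity, x1000.

    The surface is evaluated on a quantile lattice (logit scale) and fit
    with row + column main effects by least squares; the score is 1000 x
    the mean squared residual. A predictor never used in splits gives a
    surface constant along its axis, hence score 0.
    """
    ci = model.feature_names.index(predictor_i)
    cj = model.feature_names.index(predictor_j)
    gv = [_quantile_levels(model.X_train[:, ci], grid_points),
          _quantile_levels(model.X_train[:, cj], grid_points)]
    pd2 = partial_dependence(model, [predictor_i, predictor_j],
                             grid_values=gv, scale="logit")
    M = pd2.response.reshape(grid_points, grid_points)
    row = M.mean(axis=1, keepdims=True)
    col = M.mean(axis=0, keepdims=True)
    resid = M - row - col + M.mean()
    return float(1000.0 * np.mean(resid ** 2))


@dataclass
class TopKReport:
    contributions: pd.DataFrame  # top-k rows
    interactions: pd.DataFrame  # pair_i, pair_j, score


def top_k_report(model: BRTModel, k: int = 3, grid_points: int = 20) -> TopKReport:
    """Top-k contributions and all pairwise interactions among them."""
    if k < 1:
        raise ValueError("k must be >= 1")
    contrib = relative_influence(model)
    if k > len(contrib):
        raise ValueError(f"k={k} exceeds the {len(contrib)} predictors")
    top = contrib.head(k).reset_index(drop=True)
    rows = [
        {"predictor_i": a, "predictor_j": b,
         "interaction": interaction_size(model, a, b, grid_points)}
        for a, b in combinations(top["predictor"], 2)
    ]
    inter = pd.DataFrame(rows, columns=["predictor_i", "predictor_j", "interaction"])
    if len(inter):
        inter = inter.sort_values("interaction", ascending=False, ignore_index=True)
    return TopKReport(top, inter)
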