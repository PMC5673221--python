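"""Independent brute-force oracles used to validate the package.

Everything here is written with naive loops and textbook formulas, on
purpose: these implementations share only the documented policies (split
rule, tie-breaking, Newton leaf values) with the package, never its code.
"""

from __future__ import annotations

import numpy as np

STABILIZER = 1e-6


def _sigmoid(eta):
    eta = np.asarray(eta, float)
    return np.where(eta >= 0, 1.0 / (1.0 + np.exp(-np.abs(eta))),
                    np.exp(-np.abs(eta)) / (1.0 + np.exp(-np.abs(eta))))


class OracleNode:
    def __init__(self, rows, depth):
        self.rows = rows
        self.depth = depth
        self.feature = None
        self.threshold = None
        self.left = None
        self.right = None
        self.value = 0.0


def _oracle_best_split(X, z, w, rows, min_obs):
    """Exhaustive split search with naive loops.

    Strictly-greater comparison while scanning features in ascending order
    and split positions in ascending threshold order reproduces the
    documented tie-break (lowest feature, then lowest threshold). Left
    sums are accumulated in ascending scan order and right sums taken as
    total minus left, so that numerically near-tied gains round the same
    way in both implementations and the tie-break comparison stays exact.
    """
    if len(rows) < 2 * min_obs:
        return None
    best = None
    m = len(rows)
    for f in range(X.shape[1]):
        xs = X[rows, f]
        order = np.argsort(xs, kind="stable")
        sr = rows[order]
        xv = xs[order]
        tot_w = 0.0
        tot_wz = 0.0
        for r in sr:
            tot_w += w[r]
            tot_wz += w[r] * z[r]
        lw = 0.0
        lwz = 0.0
        for k in range(m - 1):
            lw += w[sr[k]]
            lwz += w[sr[k]] * z[sr[k]]
            if xv[k] >= xv[k + 1]:
                continue
            if k + 1 < min_obs or m - k - 1 < min_obs:
                continue
            rw, rwz = tot_w - lw, tot_wz - lwz
            gain = lwz ** 2 / lw + rwz ** 2 / rw - tot_wz ** 2 / tot_w
            if gain > 0 and (best is None or gain > best[0]):
                thr = 0.5 * (xv[k] + xv[k + 1])
                if thr >= xv[k + 1]:
                    thr = xv[k]
                best = (gain, f, thr)
    return best


def oracle_fit_tree(X, z, w, h, max_depth, min_obs):
    """Best-first tree growth; highest gain first, earliest node on ties."""
    root = OracleNode(np.arange(len(z)), 0)
    nodes = [root]
    candidates = {}
    s = _oracle_best_split(X, z, w, root.rows, min_obs)
    if s is not None and max_depth >= 1:
        candidates[0] = s
    leaves, max_leaves = 1, 2 ** max_depth
    while candidates and leaves < max_leaves:
        nid = max(candidates, key=lambda n: (candidates[n][0], -n))
        gain, f, thr = candidates.pop(nid)
        node = nodes[nid]
        mask = X[node.rows, f] <= thr
        lnode = OracleNode(node.rows[mask], node.depth + 1)
        rnode = OracleNode(node.rows[~mask], node.depth + 1)
        node.feature, node.threshold = f, thr
        nodes.append(lnode)
        node.left = len(nodes) - 1
        nodes.append(rnode)
        node.right = len(nodes) - 1
        for cid in (node.left, node.right):
            child = nodes[cid]
            if child.depth < max_depth:
                s = _oracle_best_split(X, z, w, child.rows, min_obs)
                if s is not None:
                    candidates[cid] = s
        leaves += 1
    for node in nodes:
        if node.feature is None:
            node.value = (w[node.rows] * z[node.rows]).sum() / (
                h[node.rows].sum() + STABILIZER)
    return nodes


def oracle_tree_predict(nodes, X):
    out = np.empty(len(X))
    for i, x in enumerate(np.asarray(X, float)):
        nid = 0
        while nodes[nid].feature is not None:
            node = nodes[nid]
            nid = node.left if x[node.feature] <= node.threshold else node.right
        out[i] = nodes[nid].value
    return out


def oracle_gbm(X, y, w, learning_rate, max_depth, n_trees, min_obs=1):
    """Full-bag weighted Bernoulli gradient boosting, brute force.

    Returns (intercept, list_of_trees); prediction via
    ``oracle_gbm_predict``. Weights are normalized to mean one, as ratios
    are all that may matter.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    w = w / w.mean()
    p0 = (w * y).sum() / w.sum()
    intercept = float(np.log(p0 / (1 - p0)))
    F = np.full(len(y), intercept)
    trees = []
    for _ in range(n_trees):
        p = _sigmoid(F)
        z = y - p
        h = w * p * (1 - p)
        nodes = oracle_fit_tree(X, z, w, h, max_depth, min_obs)
        trees.append(nodes)
        F = F + learning_rate * oracle_tree_predict(nodes, X)
    return intercept, trees


def oracle_gbm_predict(intercept, trees, learning_rate, X):
    eta = np.full(len(X), intercept)
    for nodes in trees:
        eta = eta + learning_rate * oracle_tree_predict(nodes, X)
    return _sigmoid(eta)


def brute_force_pd(model, predictors, grid_values):
    """Clamped-average partial dependence on the logit scale.

    For every lattice point, clamp the target column(s) of the training
    matrix to the grid value, run the model's raw additive prediction on
    all training rows, and average with the training weights.
    """
    cols = [model.feature_names.index(p) for p in predictors]
    X, w = model.X_train, model.w_train
    if len(cols) == 1:
        grid = np.asarray(grid_values[0], float)[:, None]
    else:
        gi, gj = np.meshgrid(grid_values[0], grid_values[1], indexing="ij")
        grid = np.column_stack([gi.ravel(), gj.ravel()])
    lr = model.params.learning_rate
    out = np.empty(len(grid))
    for g, point in enumerate(grid):
        Xc = X.copy()
        for c, v in zip(cols, point):
            Xc[:, c] = v
        eta = np.full(len(Xc), model.intercept)
        for tree in model.trees[: model.n_trees_used]:
            eta = eta + lr * tree.predict(Xc)
        out[g] = float((w * eta).sum() / w.sum())
    return out


def trapezoid_auc(scores, labels):
    """ROC curve by threshold sweep over the observed scores, integrated
    with the trapezoidal rule."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, float)
    n_pos = (labels == 1).sum()
    n_neg = (labels == 0).sum()
    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    tpr = [np.sum((scores >= t) & (labels == 1)) / n_pos for t in thresholds]
    fpr = [np.sum((scores >= t) & (labels == 0)) / n_neg for t in thresholds]
    return float(np.trapezoid(tpr, fpr))


def permutation_moran_p(values, weight_scheme="queen", permutations=999, seed=0):
    """Two-sided permutation p-value for Moran's I with naive loops."""
    v = np.asarray(values, float)
    nrows, ncols = v.shape
    x = v.ravel()
    n = x.size
    offsets = {"rook": [(-1, 0), (1, 0), (0, -1), (0, 1)],
               "queen": [(-1, 0), (1, 0), (0, -1), (0, 1),
                         (-1, -1), (-1, 1), (1, -1), (1, 1)]}[weight_scheme]
    Wm = np.zeros((n, n))
    for r in range(nrows):
        for c in range(ncols):
            for dr, dc in offsets:
                rr, cc = r + dr, c + dc
                if 0 <= rr < nrows and 0 <= cc < ncols:
                    Wm[r * ncols + c, rr * ncols + cc] = 1.0

    def moran(xv):
        z = xv - xv.mean()
        return (n / Wm.sum()) * (z @ Wm @ z) / (z ** 2).sum()

    obs = moran(x)
    e_i = -1.0 / (n - 1)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(permutations):
        if abs(moran(rng.permutation(x)) - e_i) >= abs(obs - e_i):
            hits += 1
    return obs, (1 + hits) / (permutations + 1)
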