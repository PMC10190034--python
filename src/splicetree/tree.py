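"""A C4.5/C5.0-style decision tree with native missing-value handling.

The consensus model must score variants whose feature vectors are full of
holes (external predictors only operate in parts of the gene body), so the
learner is a single classification tree with the classic fractional
instance weighting scheme rather than imputation:

* splits are chosen by information gain ratio computed on the rows where
  the candidate feature is observed, with the gain scaled by the observed
  fraction;
* rows missing the chosen split feature are sent down *both* branches with
  their weight multiplied by the observed branch mass fractions;
* prediction mirrors training: a missing split feature yields the
  mass-weighted mixture of the branch predictions;
* leaves carry Laplace-smoothed positive-class probabilities
  (pos + 1) / (n + 2), so scores are continuous in (0, 1);
* optional pessimistic (upper-confidence-bound) error pruning.

Everything is deterministic given the data: gain-ratio ties break toward
the lowest feature index, then the lowest threshold; candidate thresholds
are midpoints of consecutive distinct observed values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import betaincinv

_EPS = 1e-12


@dataclass
class Node:
    """Internal node or leaf. ``feature`` is None for leaves."""

    n: float
    n_pos: float
    feature: int | None = None
    threshold: float | None = None
    mass_left: float = 0.0  # observed training-mass fractions; sum to 1
    mass_right: float = 0.0
    left: "Node | None" = None
    right: "Node | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def prob(self) -> float:
        """Laplace-smoothed positive-class probability of this node."""
        return (self.n_pos + 1.0) / (self.n + 2.0)

    def to_dict(self) -> dict:
        d = {"n": self.n, "n_pos": self.n_pos}
        if not self.is_leaf:
            d.update(
                feature=self.feature,
                threshold=self.threshold,
                mass_left=self.mass_left,
                mass_right=self.mass_right,
                left=self.left.to_dict(),
                right=self.right.to_dict(),
            )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Node":
        node = cls(n=d["n"], n_pos=d["n_pos"])
        if "feature" in d:
            node.feature = d["feature"]
            node.threshold = d["threshold"]
            node.mass_left = d["mass_left"]
            node.mass_right = d["mass_right"]
            node.left = cls.from_dict(d["left"])
            node.right = cls.from_dict(d["right"])
        return node


def _entropy(pos: float, total: float) -> float:
    if total <= _EPS or pos <= _EPS or total - pos <= _EPS:
        return 0.0
    p = pos / total
    return -(p * np.log2(p) + (1 - p) * np.log2(1 - p))


def _best_split_for_feature(
    col: np.ndarray, y: np.ndarray, w: np.ndarray, n_total: float, min_leaf: float
) -> tuple[float, float, float, float] | None:
    """Best (gain, gain_ratio, threshold, observed_fraction) for one feature.

    ``col`` may contain NaN. Gain is scaled by the observed fraction F and
    the split info includes the missing rows as their own branch, following
    the C4.5 treatment. Returns None when no feasible split exists.
    """
    known = ~np.isnan(col)
    nk = float(w[known].sum())
    if nk < 2 * min_leaf or nk <= _EPS:
        return None
    v = col[known]
    wk = w[known]
    pk = wk * y[known]
    order = np.argsort(v, kind="mergesort")
    v, wk, pk = v[order], wk[order], pk[order]

    cum_w = np.cumsum(wk)
    cum_p = np.cumsum(pk)
    # candidate boundaries: between consecutive distinct values
    boundary = np.nonzero(np.diff(v) > 0)[0]
    if boundary.size == 0:
        return None
    n_l = cum_w[boundary]
    p_l = cum_p[boundary]
    n_r = nk - n_l
    p_r = cum_p[-1] - p_l

    feasible = (n_l >= min_leaf - _EPS) & (n_r >= min_leaf - _EPS)
    if not feasible.any():
        return None
    n_l, p_l, n_r, p_r = n_l[feasible], p_l[feasible], n_r[feasible], p_r[feasible]
    bidx = boundary[feasible]

    h_known = _entropy(float(cum_p[-1]), nk)
    h_l = _vec_entropy(p_l, n_l)
    h_r = _vec_entropy(p_r, n_r)
    info = (n_l * h_l + n_r * h_r) / nk
    frac = nk / n_total
    gain = frac * (h_known - info)

    n_missing = n_total - nk
    shares = [n_l / n_total, n_r / n_total]
    split_info = -sum(s * np.log2(np.maximum(s, _EPS)) for s in shares)
    if n_missing > _EPS:
        sm = n_missing / n_total
        split_info = split_info - sm * np.log2(sm)
    ratio = np.where(split_info > _EPS, gain / np.maximum(split_info, _EPS), 0.0)

    good = gain > 1e-9
    if not good.any():
        return None
    ratio = np.where(good, ratio, -np.inf)
    best = int(np.argmax(ratio))  # argmax takes the first (lowest threshold) on ties
    thr = (v[bidx[best]] + v[bidx[best] + 1]) / 2.0
    return float(gain[best]), float(ratio[best]), float(thr), frac


def _vec_entropy(pos: np.ndarray, total: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.clip(pos / np.maximum(total, _EPS), _EPS, 1 - _EPS)
        h = -(p * np.log2(p) + (1 - p) * np.log2(1 - p))
    h[(pos <= _EPS) | (total - pos <= _EPS) | (total <= _EPS)] = 0.0
    return h


def grow_tree(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray | None = None,
    min_leaf: float = 2.0,
    max_depth: int = 30,
) -> Node:
    """Grow an unpruned tree on ``X`` (NaN = missing), labels ``y`` in {0,1}."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if w is None:
        w = np.ones(len(y), dtype=float)
    return _grow(X, y, np.asarray(w, dtype=float), min_leaf, max_depth, 0)


def _grow(X, y, w, min_leaf, max_depth, depth) -> Node:
    n = float(w.sum())
    n_pos = float((w * y).sum())
    node = Node(n=n, n_pos=n_pos)
    if (
        depth >= max_depth
        or n < 2 * min_leaf
        or n_pos <= _EPS
        or n - n_pos <= _EPS
    ):
        return node

    best: tuple[float, float, float, int] | None = None  # ratio, gain, thr, j
    for j in range(X.shape[1]):
        res = _best_split_for_feature(X[:, j], y, w, n, min_leaf)
        if res is None:
            continue
        gain, ratio, thr, _ = res
        if best is None or ratio > best[0] + _EPS:
            best = (ratio, gain, thr, j)
        # ties: keep the earlier (lower) feature index
    if best is None:
        return node

    _, _, thr, j = best
    col = X[:, j]
    known = ~np.isnan(col)
    go_left = known & (col <= thr)
    go_right = known & ~go_left
    nl = float(w[go_left].sum())
    nr = float(w[go_right].sum())
    f_l = nl / (nl + nr)
    f_r = nr / (nl + nr)

    miss = ~known
    idx_l = go_left | miss
    idx_r = go_right | miss
    w_l = np.where(go_left, w, w * f_l)[idx_l]
    w_r = np.where(go_right, w, w * f_r)[idx_r]

    node.feature = j
    node.threshold = thr
    node.mass_left = f_l
    node.mass_right = f_r
    node.left = _grow(X[idx_l], y[idx_l], w_l, min_leaf, max_depth, depth + 1)
    node.right = _grow(X[idx_r], y[idx_r], w_r, min_leaf, max_depth, depth + 1)
    return node


# ---------------------------------------------------------------------------
# pessimistic pruning


def _ucf(errors: float, n: float, cf: float) -> float:
    """Upper confidence bound on the binomial error rate (C4.5-style).

    Solves P(X <= errors | n, p) = cf for p via the regularized incomplete
    beta function; works for real-valued (weighted) counts.
    """
    if n <= _EPS:
        return 1.0
    if errors >= n - _EPS:
        return 1.0
    return float(1.0 - betaincinv(n - errors, errors + 1.0, cf))


def _subtree_error(node: Node, cf: float) -> float:
    if node.is_leaf:
        e = node.n - max(node.n_pos, node.n - node.n_pos)
        return node.n * _ucf(e, node.n, cf)
    return _subtree_error(node.left, cf) + _subtree_error(node.right, cf)


def prune_tree(node: Node, confidence: float = 0.25) -> Node:
    """Pessimistic error pruning, bottom-up, in place.

    A subtree is collapsed to a leaf when the upper-bound error estimate of
    the leaf does not exceed the summed estimate of its leaves.
    """
    if node.is_leaf:
        return node
    prune_tree(node.left, confidence)
    prune_tree(node.right, confidence)
    e_node = node.n - max(node.n_pos, node.n - node.n_pos)
    leaf_err = node.n * _ucf(e_node, node.n, confidence)
    if leaf_err <= _subtree_error(node, confidence) + 0.1:
        node.feature = None
        node.threshold = None
        node.left = node.right = None
    return node


# ---------------------------------------------------------------------------
# prediction


def predict_node(node: Node, x: np.ndarray) -> float:
    """Positive-class probability for one row (NaN = missing).

    Missing split features average the branch predictions weighted by the
    stored training-mass fractions; with nothing missing this reduces to a
    single root-to-leaf traversal.
    """
    if node.is_leaf:
        return node.prob
    v = x[node.feature]
    if np.isnan(v):
        return node.mass_left * predict_node(node.left, x) + node.mass_right * predict_node(
            node.right, x
        )
    child = node.left if v <= node.threshold else node.right
    return predict_node(child, x)


def iter_nodes(node: Node):
    yield node
    if not node.is_leaf:
        yield from iter_nodes(node.left)
        yield from iter_nodes(node.right)
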