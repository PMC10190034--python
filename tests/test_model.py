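"""Decision-tree learner: missing-value semantics, determinism, persistence."""

import json
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from splicetree.model import (
    SpliceImpactTree,
    cross_validate,
    feature_importance,
    load_model,
    predict_score,
    save_model,
    train_tree,
)
from splicetree.tree import Node, grow_tree, predict_node


def _frame(x, y, name="x"):
    return pd.DataFrame({name: x, "label": ["positive" if t else "negative" for t in y]})


def test_perfectly_separating_feature_single_split():
    frame = _frame([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
    model = train_tree(frame, prune_confidence=None)
    tree = model.trees_[0]
    assert not tree.is_leaf and tree.left.is_leaf and tree.right.is_leaf
    X = frame.drop(columns="label")
    assert (model.predict(X) == [0, 0, 0, 1, 1, 1]).all()  # training accuracy 1


def test_uninformative_features_single_leaf_smoothed_prior():
    # labels independent of the feature: pruning collapses to the root leaf
    frame = _frame([1, 2, 1, 2, 1, 2, 1, 2], [0, 1, 1, 0, 0, 1, 1, 0])
    model = train_tree(frame, prune_confidence=0.25)
    tree = model.trees_[0]
    assert tree.is_leaf
    assert tree.prob == pytest.approx((4 + 1) / (8 + 2))


def test_laplace_smoothing_at_pure_leaf():
    # 8 positives vs 4 negatives, cleanly separated: pure leaf of n=8
    frame = _frame([0] * 4 + [1] * 8, [0] * 4 + [1] * 8)
    model = train_tree(frame, prune_confidence=None)
    score = predict_score(model, {"x": 1.0})
    assert score == pytest.approx((8 + 1) / (8 + 2))  # = 0.9


# ---------------------------------------------------------------------------
# fractional-weighting oracle (single feature, exact rational arithmetic)


def _oracle_tree(rows, min_leaf=1):
    """Reference C4.5 fractional weighting on one feature, using Fractions.

    rows: list of (value_or_None, label, weight). Chooses the threshold by
    gain ratio exactly as defined: gain computed on observed rows scaled by
    the observed fraction, split info over {left, right, missing} shares.
    Returns a nested dict tree. Written independently of the implementation
    (plain loops, exact rational arithmetic, no vectorization).
    """
    import math

    def entropy(pos, total):
        if total == 0 or pos == 0 or pos == total:
            return 0.0
        p = float(pos / total)
        return -(p * math.log2(p) + (1 - p) * math.log2(1 - p))

    n = sum(w for _, _, w in rows)
    n_pos = sum(w for v, lab, w in rows if lab)
    node = {"n": n, "n_pos": n_pos}
    if n_pos == 0 or n_pos == n or float(n) < 2 * min_leaf:
        return node
    known = sorted([(v, lab, w) for v, lab, w in rows if v is not None])
    nk = sum(w for _, _, w in known)
    if float(nk) < 2 * min_leaf or not known:
        return node
    pk = sum(w for _, lab, w in known if lab)
    h_known = entropy(pk, nk)
    best = None
    values = sorted({v for v, _, _ in known})
    for lo, hi in zip(values, values[1:]):
        thr = (lo + hi) / 2
        nl = sum(w for v, _, w in known if v <= thr)
        pl = sum(w for v, lab, w in known if v <= thr and lab)
        nr, pr = nk - nl, pk - pl
        if float(nl) < min_leaf or float(nr) < min_leaf:
            continue
        info = (nl * entropy(pl, nl) + nr * entropy(pr, nr)) / nk
        gain = float(nk / n) * (h_known - info)
        if gain <= 1e-9:
            continue
        shares = [nl / n, nr / n]
        if n - nk > 0:
            shares.append((n - nk) / n)
        split_info = -sum(float(s) * math.log2(float(s)) for s in shares)
        ratio = gain / split_info
        if best is None or ratio > best[0] + 1e-12:
            best = (ratio, thr, nl, nr)
    if best is None:
        return node
    _, thr, nl, nr = best
    fl, fr = nl / (nl + nr), nr / (nl + nr)
    left_rows, right_rows = [], []
    for v, lab, w in rows:
        if v is None:
            left_rows.append((v, lab, w * fl))
            right_rows.append((v, lab, w * fr))
        elif v <= thr:
            left_rows.append((v, lab, w))
        else:
            right_rows.append((v, lab, w))
    node.update(
        thr=thr, fl=fl, fr=fr,
        left=_oracle_tree(left_rows, min_leaf),
        right=_oracle_tree(right_rows, min_leaf),
    )
    return node


def _oracle_predict(node, value):
    if "thr" not in node:
        return (node["n_pos"] + 1) / (node["n"] + 2)
    if value is None:
        return node["fl"] * _oracle_predict(node["left"], value) + node["fr"] * (
            _oracle_predict(node["right"], value)
        )
    child = node["left"] if value <= node["thr"] else node["right"]
    return _oracle_predict(child, value)


def _enumerate_toy_sets():
    """All <=5-row single-feature training sets with one missing cell."""
    for n_rows in (4, 5):
        values = [float(i) for i in range(n_rows)]
        for miss_idx in range(n_rows):
            vals = [None if i == miss_idx else values[i] for i in range(n_rows)]
            for labels in range(2**n_rows):
                y = [(labels >> i) & 1 for i in range(n_rows)]
                if len(set(y)) < 2:
                    continue
                yield vals, y


def test_fractional_weighting_matches_enumerated_oracle():
    """Exhaustive <=5-row sets, one missing cell: probabilities match the
    independent rational-arithmetic oracle; queries include missing."""
    checked = 0
    for vals, y in _enumerate_toy_sets():
        X = np.array([[np.nan if v is None else v] for v in vals])
        tree = grow_tree(X, np.array(y, dtype=float), min_leaf=1.0)
        rows = [
            (None if v is None else Fraction(v), bool(lab), Fraction(1))
            for v, lab in zip(vals, y)
        ]
        oracle = _oracle_tree(rows, min_leaf=1)
        queries = [None, -1.0, 0.5, 1.5, 2.5, 3.5, 10.0]
        for q in queries:
            got = predict_node(tree, np.array([np.nan if q is None else q]))
            want = float(_oracle_predict(oracle, None if q is None else Fraction(q)))
            assert got == pytest.approx(want, abs=1e-9), (vals, y, q)
        checked += 1
    assert checked > 200


def test_hand_computed_four_row_missing_case():
    """4 rows, feature [0,0,1,NaN], labels [0,0,1,1]: frozen hand-derived
    fractional-weighting probabilities."""
    X = np.array([[0.0], [0.0], [1.0], [np.nan]])
    y = np.array([0.0, 0.0, 1.0, 1.0])
    tree = grow_tree(X, y, min_leaf=1.0)
    # split at 0.5 over 3 observed rows: left mass 2, right 1 -> fl=2/3
    assert tree.threshold == pytest.approx(0.5)
    assert tree.mass_left == pytest.approx(2 / 3)
    # left leaf: n = 2 + 2/3, pos = 2/3 -> (2/3+1)/(8/3+2)
    p_left = (2 / 3 + 1) / (2 + 2 / 3 + 2)
    p_right = (1 + 1 / 3 + 1) / (1 + 1 / 3 + 2)
    assert predict_node(tree, np.array([0.0])) == pytest.approx(p_left)
    assert predict_node(tree, np.array([1.0])) == pytest.approx(p_right)
    mix = (8 / 3) / 4 * p_left + (4 / 3) / 4 * p_right
    assert predict_node(tree, np.array([np.nan])) == pytest.approx(mix)


def test_no_missing_reduces_to_single_path_traversal(rng):
    """Limit equivalence: with complete data the fractional prediction is
    exactly the plain root-to-leaf traversal."""
    X = rng.normal(size=(120, 4))
    y = (X[:, 0] + 0.4 * X[:, 2] > 0).astype(float)
    tree = grow_tree(X, y, min_leaf=2.0)

    def plain_traverse(node, x):
        while not node.is_leaf:
            node = node.left if x[node.feature] <= node.threshold else node.right
        return node.prob

    for row in X[:40]:
        assert predict_node(tree, row) == plain_traverse(tree, row)


def test_training_invariant_to_row_order_and_feature_rename(rng):
    X = pd.DataFrame(
        {"a": rng.integers(0, 5, 60).astype(float), "b": rng.integers(0, 3, 60).astype(float)}
    )
    y = ((X["a"] > 2) ^ (X["b"] > 1)).astype(int)
    frame = X.assign(label=y)
    m1 = train_tree(frame, prune_confidence=None)
    perm = rng.permutation(len(frame))
    m2 = train_tree(frame.iloc[perm].reset_index(drop=True), prune_confidence=None)
    grid = pd.DataFrame({"a": [0.0, 1, 2, 3, 4], "b": [0.0, 1, 2, 0, 1]})
    assert np.array_equal(m1.predict_proba(grid), m2.predict_proba(grid))
    # bijective rename preserves predictions
    m3 = train_tree(frame.rename(columns={"a": "alpha", "b": "beta"}),
                    prune_confidence=None)
    grid3 = grid.rename(columns={"a": "alpha", "b": "beta"})
    assert np.array_equal(m1.predict_proba(grid), m3.predict_proba(grid3))


def test_single_class_and_empty_registry_errors():
    with pytest.raises(ValueError, match="single class"):
        train_tree(_frame([1, 2], [1, 1]))
    with pytest.raises(ValueError, match="registry"):
        SpliceImpactTree().fit(pd.DataFrame(index=[0, 1]), [0, 1])


def test_scores_always_within_unit_interval(rng):
    X = rng.normal(size=(80, 3))
    X[rng.random(X.shape) < 0.3] = np.nan
    y = rng.integers(0, 2, 80)
    if len(np.unique(y)) < 2:
        y[0] = 1 - y[0]
    model = SpliceImpactTree().fit(pd.DataFrame(X, columns=list("abc")), y)
    Xq = rng.normal(size=(50, 3))
    Xq[rng.random(Xq.shape) < 0.5] = np.nan
    p = model.predict_proba(pd.DataFrame(Xq, columns=list("abc")))[:, 1]
    assert ((p >= 0) & (p <= 1)).all()


def test_all_features_missing_predicts_root_mixture():
    frame = _frame([0, 0, 1, 1, 0, 1], [0, 0, 1, 1, 0, 1])
    model = train_tree(frame, prune_confidence=None)
    s = predict_score(model, {"x": None})
    # root mixture over a clean split: (3/6)*leaf0 + (3/6)*leaf1
    assert s == pytest.approx(0.5 * ((0 + 1) / (3 + 2)) + 0.5 * ((3 + 1) / (3 + 2)))


def test_predict_score_rejects_unknown_feature():
    model = train_tree(_frame([0, 1, 0, 1], [0, 1, 0, 1]))
    with pytest.raises(ValueError, match="unknown feature"):
        predict_score(model, {"x": 0.0, "bogus": 1.0})


def test_cross_validate_deterministic_and_stratified():
    rng = np.random.default_rng(0)
    frame = pd.DataFrame(
        {"x": rng.normal(size=60), "label": ["positive", "negative"] * 30}
    )
    cv1 = cross_validate(frame, k=5, seed=42)
    cv2 = cross_validate(frame, k=5, seed=42)
    assert cv1 == cv2
    assert sorted(set(cv1["folds"])) == [0, 1, 2, 3, 4]
    assert cross_validate(frame, k=5, seed=7)["folds"] != cv1["folds"]
    with pytest.raises(ValueError):
        cross_validate(frame, k=1)


def test_feature_importance_usage_based():
    # nested two-feature tree: a splits at root, b splits one child
    frame = pd.DataFrame(
        {
            "a": [0, 0, 0, 0, 1, 1, 1, 1],
            "b": [0, 0, 1, 1, 0, 1, 0, 1],
            "label": ["negative"] * 4 + ["negative", "positive", "negative", "positive"],
        }
    )
    model = train_tree(frame, prune_confidence=None, min_leaf=1)
    imp = feature_importance(model)
    assert imp["a"] == 100.0
    # b splits a child holding half the training mass
    assert imp["b"] == pytest.approx(50.0)
    single = train_tree(_frame([0, 1, 0, 1], [0, 1, 0, 1]), prune_confidence=None)
    imp2 = feature_importance(single)
    assert imp2 == {"x": 100.0}


def test_save_load_round_trip_bit_exact(tmp_path, rng):
    X = pd.DataFrame(rng.normal(size=(100, 3)), columns=["u", "v", "w"])
    X[X > 1.2] = np.nan
    y = rng.integers(0, 2, 100)
    y[:2] = [0, 1]
    model = SpliceImpactTree(min_leaf=3).fit(X, y)
    path = save_model(model, tmp_path / "m.json")
    clone = load_model(path)
    assert np.array_equal(model.predict_proba(X), clone.predict_proba(X))
    payload = json.loads(path.read_text())
    assert payload["format_version"] == 1
    # registry tampering is detected
    payload["feature_names"][0] = "tampered"
    bad = tmp_path / "bad.json"
    bad.write_text(json.dumps(payload))
    with pytest.raises(ValueError, match="hash"):
        load_model(bad)


def test_parameter_recovery_close_to_bayes_optimal():
    """Training on data from a known tree recovers near-Bayes-optimal
    held-out ranking (fixed seed)."""
    rng = np.random.default_rng(2024)
    n = 6000
    X = pd.DataFrame(rng.uniform(0, 1, size=(n, 3)), columns=["a", "b", "c"])

    def true_p(row):  # generating tree: two nested splits
        if row["a"] <= 0.5:
            return 0.9 if row["b"] <= 0.4 else 0.2
        return 0.7 if row["c"] <= 0.6 else 0.1

    p = X.apply(true_p, axis=1).to_numpy()
    y = (rng.uniform(size=n) < p).astype(int)
    train_idx, test_idx = np.arange(0, 4000), np.arange(4000, n)
    model = SpliceImpactTree(min_leaf=20).fit(X.iloc[train_idx], y[train_idx])
    from sklearn.metrics import roc_auc_score

    scores = model.predict_proba(X.iloc[test_idx])[:, 1]
    auc_model = roc_auc_score(y[test_idx], scores)
    auc_bayes = roc_auc_score(y[test_idx], p[test_idx])
    assert auc_model >= auc_bayes - 0.02


def test_boosted_mode_is_deterministic_and_valid(rng):
    X = pd.DataFrame(rng.normal(size=(80, 2)), columns=["a", "b"])
    y = ((X["a"] + X["b"]) > 0).astype(int)
    m1 = SpliceImpactTree(n_trials=3).fit(X, y)
    m2 = SpliceImpactTree(n_trials=3).fit(X, y)
    p1, p2 = m1.predict_proba(X)[:, 1], m2.predict_proba(X)[:, 1]
    assert np.array_equal(p1, p2)
    assert ((p1 >= 0) & (p1 <= 1)).all()


def test_sklearn_clone_and_get_params():
    from sklearn.base import clone

    est = SpliceImpactTree(min_leaf=5, prune_confidence=None)
    cloned = clone(est)
    assert cloned.get_params() == est.get_params()
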