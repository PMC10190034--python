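"""The consensus splice-impact classifier as an sklearn-style estimator.

:class:`SpliceImpactTree` wraps the C4.5-style tree in the familiar
fit/predict_proba surface so it composes with sklearn pipelines and model
selection. Feature matrices are pandas DataFrames (or arrays) with NaN for
missing values; no imputation happens anywhere. Module-level functions
(:func:`train_tree`, :func:`predict_score`, :func:`cross_validate`, ...)
stay thin wrappers over the estimator.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .calibration import pr_curve
from .tree import Node, grow_tree, iter_nodes, predict_node, prune_tree

MODEL_FORMAT_VERSION = 1

_LABEL_MAP = {"negative": 0, "positive": 1, 0: 0, 1: 1, False: 0, True: 1}


class SpliceImpactTree(BaseEstimator, ClassifierMixin):
    """Single C4.5/C5.0-style decision tree with fractional missing-value
    weighting and Laplace-smoothed leaf probabilities.

    Parameters
    ----------
    min_leaf : float, default 2.0
        Minimum weighted training mass per branch (C5.0's minCases).
    prune_confidence : float or None, default 0.25
        Confidence level of pessimistic error pruning; None disables
        pruning.
    n_trials : int, default 1
        Boosting trials; 1 trains a single tree. Values > 1 run a
        deterministic AdaBoost.M1-style reweighting with probability
        averaging.
    max_depth : int, default 30
        Safety cap on tree depth.

    Attributes
    ----------
    trees_ : list of Node
        Trained tree(s), one per boosting trial.
    trial_weights_ : list of float
        Log-odds voting weights of the trials.
    feature_names_in_ : ndarray of str
    registry_hash_ : str
        SHA-256 of the ordered feature registry; checked when scoring a
        reloaded model.
    """

    def __init__(
        self,
        min_leaf: float = 2.0,
        prune_confidence: float | None = 0.25,
        n_trials: int = 1,
        max_depth: int = 30,
    ):
        self.min_leaf = min_leaf
        self.prune_confidence = prune_confidence
        self.n_trials = n_trials
        self.max_depth = max_depth

    # -- sklearn plumbing ---------------------------------------------------

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.input_tags.allow_nan = True
        return tags

    def _validate(self, X, *, fitting: bool):
        if isinstance(X, pd.DataFrame):
            names = np.asarray(X.columns, dtype=object)
            arr = X.to_numpy(dtype=float)
        else:
            arr = np.asarray(X, dtype=float)
            if arr.ndim != 2:
                raise ValueError("X must be 2-D")
            names = np.asarray([f"x{i}" for i in range(arr.shape[1])], dtype=object)
        if fitting:
            if arr.shape[1] == 0:
                raise ValueError("empty feature registry")
            self.feature_names_in_ = names
            self.n_features_in_ = arr.shape[1]
        else:
            if arr.shape[1] != self.n_features_in_:
                raise ValueError(
                    f"X has {arr.shape[1]} features, model expects {self.n_features_in_}"
                )
            if isinstance(X, pd.DataFrame) and list(names) != list(self.feature_names_in_):
                raise ValueError("feature names do not match the fitted registry")
        return arr

    # -- training -----------------------------------------------------------

    def fit(self, X, y):
        arr = self._validate(X, fitting=True)
        y = np.asarray([_LABEL_MAP.get(v, v) for v in np.asarray(y).ravel()])
        y = y.astype(float)
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError("labels must be binary (positive/negative or 0/1)")
        if len(np.unique(y)) < 2:
            raise ValueError("training data contains a single class")
        if len(y) != len(arr):
            raise ValueError("X and y length mismatch")

        self.classes_ = np.array([0, 1])
        self.registry_hash_ = registry_hash(self.feature_names_in_)
        self.n_samples_ = len(y)

        w = np.ones(len(y), dtype=float)
        self.trees_: list[Node] = []
        self.trial_weights_: list[float] = []
        for _ in range(max(1, int(self.n_trials))):
            tree = grow_tree(arr, y, w, min_leaf=self.min_leaf, max_depth=self.max_depth)
            if self.prune_confidence is not None:
                prune_tree(tree, self.prune_confidence)
            self.trees_.append(tree)
            if self.n_trials <= 1:
                self.trial_weights_.append(1.0)
                break
            proba = np.array([predict_node(tree, row) for row in arr])
            miss = (proba >= 0.5) != (y >= 0.5)
            err = float(w[miss].sum() / w.sum())
            if err <= 0.0 or err >= 0.5:
                self.trial_weights_.append(1.0 if not self.trial_weights_ else 0.0)
                break
            beta = err / (1.0 - err)
            self.trial_weights_.append(float(np.log(1.0 / beta)))
            w = np.where(miss, w, w * beta)
            w *= len(y) / w.sum()
        return self

    # -- prediction ---------------------------------------------------------

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        arr = self._validate(X, fitting=False)
        total = np.zeros(len(arr))
        wsum = sum(self.trial_weights_)
        for tree, tw in zip(self.trees_, self.trial_weights_):
            if tw == 0.0:
                continue
            total += tw * np.array([predict_node(tree, row) for row in arr])
        p1 = total / (wsum if wsum > 0 else 1.0)
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return self.classes_[(self.predict_proba(X)[:, 1] >= 0.5).astype(int)]

    def decision_function(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1]

    def _check_fitted(self) -> None:
        if not hasattr(self, "trees_"):
            raise RuntimeError("estimator is not fitted")


# ---------------------------------------------------------------------------
# functional wrappers


def registry_hash(feature_names: Sequence[str]) -> str:
    return hashlib.sha256("\x1f".join(map(str, feature_names)).encode()).hexdigest()


def _split_frame(frame: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    if "label" not in frame.columns:
        raise ValueError("training frame must carry a 'label' column")
    y = np.asarray([_LABEL_MAP.get(v, v) for v in frame["label"]])
    X = frame.drop(columns=["label"])
    X = X.select_dtypes(include=[np.number]).astype(float)
    return X, y


def train_tree(frame: pd.DataFrame, **params) -> SpliceImpactTree:
    """Fit a consensus tree on a frame with feature columns + 'label'."""
    X, y = _split_frame(frame)
    return SpliceImpactTree(**params).fit(X, y)


def predict_score(model: SpliceImpactTree, fv: Mapping[str, float] | pd.Series) -> float:
    """Score one feature vector (mapping or Series); NaN/None = missing.

    Unknown feature names raise; absent registry features count as missing.
    """
    model._check_fitted()
    if isinstance(fv, pd.Series):
        fv = fv.to_dict()
    known = set(map(str, model.feature_names_in_))
    extra = set(fv) - known - {"label", "region", "key"}
    if extra:
        raise ValueError(f"unknown feature name(s): {sorted(extra)}")
    row = np.array(
        [
            np.nan if fv.get(name) is None else float(fv.get(name, np.nan))
            for name in model.feature_names_in_
        ]
    )
    return float(model.predict_proba(row.reshape(1, -1))[0, 1])


def predict_frame(model: SpliceImpactTree, frame: pd.DataFrame) -> pd.Series:
    """Scores for a feature frame (columns aligned to the registry)."""
    X = frame.reindex(columns=list(model.feature_names_in_)).astype(float)
    return pd.Series(model.predict_proba(X)[:, 1], index=frame.index, name="score")


def cross_validate(
    frame: pd.DataFrame,
    k: int = 10,
    seed: int = 0,
    **params,
) -> dict:
    """Stratified k-fold cross-validation of the consensus tree.

    Returns per-fold auROC/auPRC, their means, and the fold assignment for
    audit. Deterministic given ``seed``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    X, y = _split_frame(frame)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.full(len(y), -1, dtype=int)
    per_fold = []
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        folds[te] = fold
        model = SpliceImpactTree(**params).fit(X.iloc[tr], y[tr])
        scores = model.predict_proba(X.iloc[te])[:, 1]
        y_te = y[te]
        if len(np.unique(y_te)) < 2:
            raise ValueError(f"fold {fold} contains a single class")
        per_fold.append(
            {
                "fold": fold,
                "n": int(len(te)),
                "auroc": float(roc_auc_score(y_te, scores)),
                "auprc": float(pr_curve(scores, y_te == 1).auprc),
            }
        )
    return {
        "k": k,
        "seed": seed,
        "folds": folds.tolist(),
        "per_fold": per_fold,
        "mean_auroc": float(np.mean([f["auroc"] for f in per_fold])),
        "mean_auprc": float(np.mean([f["auprc"] for f in per_fold])),
    }


def feature_importance(model: SpliceImpactTree) -> dict[str, float]:
    """Usage-based importance: training mass routed through each feature's
    splits, normalized so the top feature scores 100. Unused features: 0."""
    model._check_fitted()
    usage = {str(name): 0.0 for name in model.feature_names_in_}
    for tree, tw in zip(model.trees_, model.trial_weights_):
        root_n = tree.n or 1.0
        for node in iter_nodes(tree):
            if not node.is_leaf:
                name = str(model.feature_names_in_[node.feature])
                usage[name] += tw * node.n / root_n
    top = max(usage.values(), default=0.0)
    if top <= 0:
        return usage
    return {k: 100.0 * v / top for k, v in usage.items()}


def save_model(model: SpliceImpactTree, path: str | Path) -> Path:
    """Serialize to versioned JSON; round-trips predictions bit-exactly."""
    model._check_fitted()
    path = Path(path)
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "params": model.get_params(),
        "feature_names": [str(n) for n in model.feature_names_in_],
        "registry_hash": model.registry_hash_,
        "n_samples": model.n_samples_,
        "trial_weights": model.trial_weights_,
        "trees": [t.to_dict() for t in model.trees_],
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


def load_model(path: str | Path) -> SpliceImpactTree:
    payload = json.loads(Path(path).read_text())
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format: {payload.get('format_version')}")
    model = SpliceImpactTree(**payload["params"])
    model.feature_names_in_ = np.asarray(payload["feature_names"], dtype=object)
    model.n_features_in_ = len(model.feature_names_in_)
    model.classes_ = np.array([0, 1])
    model.n_samples_ = payload["n_samples"]
    model.trial_weights_ = payload["trial_weights"]
    model.trees_ = [Node.from_dict(d) for d in payload["trees"]]
    model.registry_hash_ = payload["registry_hash"]
    if registry_hash(model.feature_names_in_) != model.registry_hash_:
        raise ValueError("feature registry hash mismatch in model file")
    return model
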