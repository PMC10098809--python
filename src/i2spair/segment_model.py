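"""Feature ranking (MRMR), decision-tree segment classifier, and metrics.

The classifier maps one sensor's stride-scaled feature vector to one of
five body segments (foot, shank, thigh, sacrum, trunk) without ever
comparing sensors to each other, so it works for any sensor count.

Feature ranking is greedy minimum-redundancy-maximum-relevance: mutual
information with the class label (features discretized into equal-frequency
bins) minus the mean mutual information with already-selected features.
The tree is a CART-style gini tree fitted with scikit-learn and exported to
a plain nested-dict structure that this module walks at predict time; the
plain form serializes to JSON and keeps the shipped model free of any
pickled estimator.
"""

from __future__ import annotations

import dataclasses
import json
import os
from collections import Counter
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score, mutual_info_score, roc_auc_score
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureVector, ZScoreParams, apply_zscore

SEGMENTS = ("foot", "shank", "thigh", "sacrum", "trunk")
SIDES = ("left", "right")

MRMR_BINS = 10
MIN_SAMPLES_LEAF = 3
TREE_RANDOM_STATE = 0


class ModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# MRMR feature ranking
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RankedFeatures:
    """Descending-importance MRMR ordering: list of (name, score)."""

    ranking: list[tuple[str, float]]

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.ranking]


def _discretize(col: np.ndarray, bins: int = MRMR_BINS) -> np.ndarray:
    edges = np.unique(np.quantile(col, np.linspace(0, 1, bins + 1)[1:-1]))
    return np.searchsorted(edges, col, side="right")


def mrmr_rank(X: pd.DataFrame, y: Sequence, bins: int = MRMR_BINS) -> RankedFeatures:
    """Greedy difference-form MRMR ordering of all columns of ``X``.

    The first feature maximizes mutual information with the label; each
    subsequent feature maximizes relevance minus the mean MI with the
    features already selected.  Ties are broken by column order.
    """
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ModelError("labels are constant; ranking is undefined")
    names = [str(c) for c in X.columns]
    disc = {n: _discretize(X[n].to_numpy(dtype=float), bins) for n in names}
    relevance = {n: float(mutual_info_score(disc[n], y)) for n in names}

    remaining = list(names)
    selected: list[tuple[str, float]] = []
    red_cache: dict[tuple[str, str], float] = {}

    def redundancy(a: str, b: str) -> float:
        key = (a, b) if a < b else (b, a)
        if key not in red_cache:
            red_cache[key] = float(mutual_info_score(disc[a], disc[b]))
        return red_cache[key]

    while remaining:
        best_name, best_score = None, -np.inf
        for n in remaining:
            if selected:
                score = relevance[n] - float(
                    np.mean([redundancy(n, s) for s, _ in selected])
                )
            else:
                score = relevance[n]
            if score > best_score:  # strict > keeps column order on ties
                best_name, best_score = n, score
        selected.append((best_name, best_score))
        remaining.remove(best_name)
    return RankedFeatures(ranking=selected)


# ---------------------------------------------------------------------------
# Plain decision-tree model (JSON-serializable)
# ---------------------------------------------------------------------------

def _export_tree(clf: DecisionTreeClassifier, classes: Sequence[str]) -> dict:
    t = clf.tree_

    def node(i: int) -> dict:
        if t.children_left[i] == -1:
            counts = t.value[i][0] * t.weighted_n_node_samples[i]
            return {
                "counts": {str(c): float(v) for c, v in zip(classes, counts)},
            }
        return {
            "feature": int(t.feature[i]),
            "threshold": float(t.threshold[i]),
            "left": node(int(t.children_left[i])),
            "right": node(int(t.children_right[i])),
        }

    return node(0)


def _walk(tree: dict, x: np.ndarray) -> dict:
    node = tree
    while "counts" not in node:
        node = node["left"] if x[node["feature"]] <= node["threshold"] else node["right"]
    return node


@dataclasses.dataclass
class DecisionTreeModel:
    """A trained tree plus the preprocessing needed to apply it.

    ``zscore`` may be None for models on already-comparable inputs (the
    3-feature foot-side tree).  Prediction routes a named feature vector to
    a leaf; leaf class counts give a purity and a class distribution for
    tie-breaking and for demoting surplus labels in the pipeline.
    """

    features: list[str]
    classes: list[str]
    tree: dict
    zscore: Optional[ZScoreParams] = None

    def _vector(self, fv: Union[FeatureVector, Mapping[str, float]]) -> np.ndarray:
        if self.zscore is not None:
            fv = apply_zscore(fv, self.zscore)
        values = fv.values if isinstance(fv, FeatureVector) else fv
        try:
            return np.array([values[name] for name in self.features], dtype=float)
        except KeyError as exc:
            raise ModelError(f"feature {exc.args[0]!r} missing from vector at predict time")

    def predict(self, fv: Union[FeatureVector, Mapping[str, float]]) -> str:
        return self.predict_detail(fv)[0]

    def predict_detail(
        self, fv: Union[FeatureVector, Mapping[str, float]]
    ) -> tuple[str, float, dict[str, float]]:
        """Return (label, leaf purity, leaf class probabilities)."""
        leaf = _walk(self.tree, self._vector(fv))
        counts = leaf["counts"]
        total = sum(counts.values())
        probs = {c: counts.get(c, 0.0) / total for c in self.classes}
        label = max(self.classes, key=lambda c: probs[c])
        return label, probs[label], probs

    def to_json_dict(self) -> dict:
        doc = {
            "features": self.features,
            "classes": self.classes,
            "tree": self.tree,
        }
        if self.zscore is not None:
            doc["zscore"] = {"mean": self.zscore.mean, "std": self.zscore.std}
        return doc

    @classmethod
    def from_json_dict(cls, doc: dict) -> "DecisionTreeModel":
        zs = None
        if "zscore" in doc:
            zs = ZScoreParams(mean=dict(doc["zscore"]["mean"]), std=dict(doc["zscore"]["std"]))
        return cls(
            features=list(doc["features"]),
            classes=list(doc["classes"]),
            tree=doc["tree"],
            zscore=zs,
        )

    def save(self, path: Union[str, os.PathLike]) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh)

    @classmethod
    def load(cls, path: Union[str, os.PathLike]) -> "DecisionTreeModel":
        with open(path) as fh:
            return cls.from_json_dict(json.load(fh))


def train_tree(
    X: pd.DataFrame,
    y: Sequence,
    features: Sequence[str],
    zscore: Optional[ZScoreParams] = None,
    min_samples_leaf: int = MIN_SAMPLES_LEAF,
    random_state: int = TREE_RANDOM_STATE,
) -> DecisionTreeModel:
    """Fit a gini decision tree on ``X[features]`` (already standardized).

    ``zscore`` is embedded in the model so that raw feature vectors can be
    passed at predict time.
    """
    features = [str(f) for f in features]
    missing = [f for f in features if f not in X.columns]
    if missing:
        raise ModelError(f"features missing from training matrix: {missing}")
    clf = DecisionTreeClassifier(
        criterion="gini", min_samples_leaf=min_samples_leaf, random_state=random_state
    )
    clf.fit(X[features].to_numpy(dtype=float), np.asarray(y))
    classes = [str(c) for c in clf.classes_]
    return DecisionTreeModel(
        features=features, classes=classes, tree=_export_tree(clf, classes), zscore=zscore
    )


# ---------------------------------------------------------------------------
# Feature-count selection on a development set
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SelectionResult:
    k: int
    curves: pd.DataFrame  # columns: k, mce, f1, auc


def select_count(
    ranked: RankedFeatures,
    X_train: pd.DataFrame,
    y_train: Sequence,
    X_dev: pd.DataFrame,
    y_dev: Sequence,
    max_k: Optional[int] = None,
    tol: float = 0.005,
    min_samples_leaf: int = MIN_SAMPLES_LEAF,
    random_state: int = TREE_RANDOM_STATE,
) -> SelectionResult:
    """Sweep the number of top-ranked features and pick the elbow.

    For each k a tree is trained on the top-k features and scored on the
    development set (misclassification error, macro F1, macro one-vs-rest
    AUC).  The selected k is the smallest one whose MCE is within ``tol``
    of the minimum over the sweep.
    """
    y_train = np.asarray(y_train)
    y_dev = np.asarray(y_dev)
    names = ranked.names
    K = len(names) if max_k is None else min(max_k, len(names))
    rows = []
    for k in range(1, K + 1):
        feats = names[:k]
        clf = DecisionTreeClassifier(
            criterion="gini", min_samples_leaf=min_samples_leaf, random_state=random_state
        )
        clf.fit(X_train[feats].to_numpy(dtype=float), y_train)
        Xd = X_dev[feats].to_numpy(dtype=float)
        pred = clf.predict(Xd)
        mce = float(np.mean(pred != y_dev))
        f1 = float(f1_score(y_dev, pred, average="macro", zero_division=0))
        proba = clf.predict_proba(Xd)
        try:
            if proba.shape[1] == 2:
                auc = float(roc_auc_score(y_dev, proba[:, 1]))
            else:
                auc = float(
                    roc_auc_score(
                        y_dev, proba, multi_class="ovr", average="macro", labels=clf.classes_
                    )
                )
        except ValueError:  # a class missing from the dev split
            auc = float("nan")
        rows.append({"k": k, "mce": mce, "f1": f1, "auc": auc})
    curves = pd.DataFrame(rows)
    best = curves["mce"].min()
    k_sel = int(curves.loc[curves["mce"] <= best + tol, "k"].iloc[0])
    return SelectionResult(k=k_sel, curves=curves)


# ---------------------------------------------------------------------------
# Metrics and voting
# ---------------------------------------------------------------------------

def evaluate(
    pred: Sequence[str],
    truth: Sequence[str],
    classes: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """One-vs-rest metrics per class plus support-weighted overall row.

    Every multiclass label is scored as a binary task per class: accuracy
    (TP+TN)/N, precision, sensitivity (recall), specificity and F1.  The
    ``overall`` row weights per-class values by class support, matching the
    convention for imbalanced designs (sacrum/trunk have half the support
    of the paired segments).
    """
    pred = list(pred)
    truth = list(truth)
    if len(pred) != len(truth):
        raise ModelError("pred and truth must have equal lengths")
    if classes is None:
        classes = sorted(set(truth))
    classes = [str(c) for c in classes]
    for seqname, seq in (("pred", pred), ("truth", truth)):
        bad = sorted(set(map(str, seq)) - set(classes))
        if bad:
            raise ModelError(f"{seqname} contains labels outside the enumeration: {bad}")
    n = len(truth)
    pred_a = np.asarray(pred)
    truth_a = np.asarray(truth)
    rows = {}
    supports = {}
    for c in classes:
        tp = int(np.sum((pred_a == c) & (truth_a == c)))
        fp = int(np.sum((pred_a == c) & (truth_a != c)))
        fn = int(np.sum((pred_a != c) & (truth_a == c)))
        tn = n - tp - fp - fn
        precision = tp / (tp + fp) if tp + fp else 0.0
        sensitivity = tp / (tp + fn) if tp + fn else 0.0
        specificity = tn / (tn + fp) if tn + fp else 0.0
        f1 = (
            2 * precision * sensitivity / (precision + sensitivity)
            if precision + sensitivity
            else 0.0
        )
        rows[c] = {
            "accuracy": (tp + tn) / n,
            "precision": precision,
            "sensitivity": sensitivity,
            "specificity": specificity,
            "f1": f1,
            "support": tp + fn,
        }
        supports[c] = tp + fn
    total = sum(supports.values())
    overall = {}
    for metric in ("accuracy", "precision", "sensitivity", "specificity", "f1"):
        overall[metric] = (
            sum(rows[c][metric] * supports[c] for c in classes) / total if total else 0.0
        )
    overall["support"] = total
    df = pd.DataFrame(rows).T
    df.loc["overall"] = overall
    df["support"] = df["support"].astype(int)
    return df


def majority_vote(
    labels: Sequence[str], purities: Optional[Sequence[float]] = None
) -> str:
    """Modal label across repeated bouts of one sensor.

    Ties are broken by the highest mean leaf purity among the tied labels
    (alphabetical order as a last resort when purities are unavailable).
    """
    labels = list(labels)
    if not labels:
        raise ModelError("majority_vote needs at least one label")
    counts = Counter(labels)
    top = max(counts.values())
    tied = sorted(l for l, c in counts.items() if c == top)
    if len(tied) == 1 or purities is None:
        return tied[0]
    purities = list(purities)
    mean_purity = {
        l: float(np.mean([p for lab, p in zip(labels, purities) if lab == l])) for l in tied
    }
    return max(tied, key=lambda l: (mean_purity[l], l))
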