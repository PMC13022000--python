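"""Pocket-type classification benchmark over raw or latent features.

The benchmark predicts which of a finite set of ligand types (the reference
set: ADP, COA, FAD, HEM, NAD, NADP, SAM) a pocket binds, from either the
pooled language-model features (1280-d) or the contrastive latents (256-d).
Two classifier families are supported — a small feedforward network and an
RBF-kernel SVM — evaluated with per-class precision, recall and F1 from the
confusion matrix on a stratified 9:1 split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

LIGAND_TYPES = ("ADP", "COA", "FAD", "HEM", "NAD", "NADP", "SAM")


@dataclass
class LabeledPocketSet:
    """Feature matrix with one ligand-type label per pocket."""

    features: np.ndarray
    labels: np.ndarray
    split_tag: str = ""

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2 or len(self.labels) != self.features.shape[0]:
            raise ValueError("features must be n × d with one label per row")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features must be finite")

    def __len__(self) -> int:
        return self.features.shape[0]


@dataclass
class ClassMetrics:
    """Confusion matrix and the metrics derived from it."""

    classes: tuple
    confusion: np.ndarray  # rows: true class, columns: predicted class
    precision: dict = field(default_factory=dict)
    recall: dict = field(default_factory=dict)
    f1: dict = field(default_factory=dict)
    macro_precision: float = 0.0
    macro_recall: float = 0.0
    macro_f1: float = 0.0
    accuracy: float = 0.0


def split(dataset: LabeledPocketSet, ratio: float = 0.9, seed: int = 0
          ) -> tuple[LabeledPocketSet, LabeledPocketSet]:
    """Stratified train/test split (default 9:1), deterministic given seed."""
    if len(dataset) < 10:
        raise ValueError("need at least 10 samples to split")
    classes, counts = np.unique(dataset.labels, return_counts=True)
    small = classes[counts < 2]
    if small.size:
        raise ValueError(f"classes with fewer than 2 members: {small.tolist()}")
    idx = np.arange(len(dataset))
    train_idx, test_idx = train_test_split(
        idx, train_size=ratio, stratify=dataset.labels, random_state=seed)
    return (
        LabeledPocketSet(dataset.features[train_idx], dataset.labels[train_idx], "train"),
        LabeledPocketSet(dataset.features[test_idx], dataset.labels[test_idx], "test"),
    )


def fit_classifier(train_set: LabeledPocketSet, family: str = "feedforward",
                   seed: int = 0):
    """Fit one of the two classifier families on the training set.

    ``feedforward``: one hidden layer of 128 units, Adam at lr 0.001,
    up to 200 epochs.  ``svm_rbf``: RBF-kernel SVM with the scale bandwidth
    heuristic, one-vs-rest.  Both are deterministic given ``seed``.
    """
    if np.unique(train_set.labels).size < 2:
        raise ValueError("training set contains a single class")
    if family in ("feedforward", "nn"):
        clf = Pipeline([
            ("scale", StandardScaler()),
            ("mlp", MLPClassifier(hidden_layer_sizes=(128,), activation="relu",
                                  solver="adam", learning_rate_init=0.001,
                                  max_iter=200, random_state=seed)),
        ])
    elif family in ("svm_rbf", "svm"):
        clf = Pipeline([
            ("scale", StandardScaler()),
            ("svm", SVC(kernel="rbf", gamma="scale", decision_function_shape="ovr",
                        random_state=seed)),
        ])
    else:
        raise ValueError(f"unknown classifier family {family!r}")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MLP convergence warnings at max_iter
        clf.fit(train_set.features, train_set.labels)
    return clf


def confusion_matrix(y_true, y_pred, classes) -> np.ndarray:
    classes = list(classes)
    index = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[index[t], index[p]] += 1
    return cm


def metrics_from_confusion(cm: np.ndarray, classes) -> ClassMetrics:
    """Per-class precision/recall/F1 and macro averages from a confusion
    matrix (zero-denominator cases defined as 0)."""
    classes = tuple(classes)
    m = ClassMetrics(classes=classes, confusion=np.asarray(cm, dtype=int))
    for i, c in enumerate(classes):
        tp = cm[i, i]
        fp = cm[:, i].sum() - tp
        fn = cm[i, :].sum() - tp
        prec = tp / (tp + fp) if (tp + fp) > 0 else 0.0
        rec = tp / (tp + fn) if (tp + fn) > 0 else 0.0
        if (tp + fp) == 0 or (tp + fn) == 0:
            logger.debug("zero denominator for class %s", c)
        f1 = 2 * prec * rec / (prec + rec) if (prec + rec) > 0 else 0.0
        m.precision[c], m.recall[c], m.f1[c] = float(prec), float(rec), float(f1)
    m.macro_precision = float(np.mean([m.precision[c] for c in classes]))
    m.macro_recall = float(np.mean([m.recall[c] for c in classes]))
    m.macro_f1 = float(np.mean([m.f1[c] for c in classes]))
    total = cm.sum()
    m.accuracy = float(np.trace(cm) / total) if total else 0.0
    return m


def evaluate(classifier, test_set: LabeledPocketSet) -> ClassMetrics:
    """Evaluate a fitted classifier on the test set."""
    if len(test_set) == 0:
        raise ValueError("test set is empty")
    y_pred = classifier.predict(test_set.features)
    classes = sorted(set(np.unique(test_set.labels)) | set(np.unique(y_pred)))
    cm = confusion_matrix(test_set.labels, y_pred, classes)
    return metrics_from_confusion(cm, classes)


def compare_representations(raw_features, latent_features, labels, seed: int = 0
                            ) -> dict[str, ClassMetrics]:
    """Run the four benchmark variants on identical splits.

    Variants: raw/feedforward, raw/svm_rbf, latent/feedforward,
    latent/svm_rbf.  Returns metrics keyed by "<representation>-<family>".
    """
    results: dict[str, ClassMetrics] = {}
    for rep_name, features in (("raw", raw_features), ("latent", latent_features)):
        dataset = LabeledPocketSet(features, labels)
        train_set, test_set = split(dataset, ratio=0.9, seed=seed)
        for family in ("feedforward", "svm_rbf"):
            clf = fit_classifier(train_set, family=family, seed=seed)
            results[f"{rep_name}-{family}"] = evaluate(clf, test_set)
    return results
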