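"""Multi-family classifier panel, metrics, and resubstitution disagreement.

A signature's quality is judged by the *consensus* of many classifiers
drawn from different mathematical families rather than by any single
model.  The default panel has 25 members spanning Bayesian, linear,
instance-based, meta-ensemble, tree, rule and centroid families, all with
library default hyperparameters (no tuning, no cross-validation): each
member is fit once on the full training set and evaluated by straight
prediction on the training set itself (resubstitution) and on any held-out
sets.

The per-sample resubstitution *disagreement count* ``d_s`` — how many of
the N panel members predict a label different from the sample's recorded
clinical label — drives the data-pruning loop: a training sample
contradicted by a large fraction of diverse classifiers is suspected of
being mislabelled.

Nearest-centroid stands in for the shrunken-centroid classifier with its
shrinkage threshold at zero (shrinkage is itself a feature selector, which
is deliberately avoided since selection has already happened upstream).
Class-score ties predict the control class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import (
    LogisticRegression,
    Perceptron,
    RidgeClassifier,
    SGDClassifier,
)
from sklearn.naive_bayes import BernoulliNB, GaussianNB
from sklearn.neighbors import KNeighborsClassifier, NearestCentroid
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier, ExtraTreeClassifier

from .preprocessing import CLASS_CASE, CLASS_CONTROL, CLASS_OTHER, PanelMatrix

FAMILIES = (
    "bayesian",
    "linear",
    "instance-based",
    "ensemble",
    "rule-based",
    "tree-based",
    "centroid-based",
)


@dataclass(frozen=True)
class PanelMember:
    name: str
    family: str
    factory: Callable[[], object]


@dataclass
class ClassifierPanel:
    members: list[PanelMember]

    def __post_init__(self) -> None:
        families = {m.family for m in self.members}
        if len(families) < 5:
            raise ValueError(f"panel must span >=5 families, got {sorted(families)}")
        names = [m.name for m in self.members]
        if len(set(names)) != len(names):
            raise ValueError("duplicate classifier names in panel")

    @property
    def size(self) -> int:
        return len(self.members)


def default_panel(seed: int = 0) -> ClassifierPanel:
    """The default 25-member panel; every stochastic member is seeded."""
    s = int(seed)
    members = [
        PanelMember("gaussian_nb", "bayesian", GaussianNB),
        PanelMember("bernoulli_nb", "bayesian", lambda: BernoulliNB(binarize=0.0)),
        PanelMember("qda", "bayesian", lambda: QuadraticDiscriminantAnalysis(reg_param=0.1)),
        PanelMember("lda", "linear", LinearDiscriminantAnalysis),
        PanelMember("logistic", "linear", lambda: LogisticRegression(max_iter=2000)),
        PanelMember("ridge", "linear", RidgeClassifier),
        PanelMember("svm_linear", "linear", lambda: SVC(kernel="linear")),
        PanelMember("svm_rbf", "linear", lambda: SVC(kernel="rbf")),
        PanelMember(
            "mlp",
            "linear",
            lambda: MLPClassifier(hidden_layer_sizes=(16,), max_iter=2000, random_state=s + 9),
        ),
        PanelMember(
            "sgd_logistic",
            "linear",
            lambda: SGDClassifier(loss="log_loss", max_iter=2000, random_state=s + 10),
        ),
        PanelMember("perceptron", "linear", lambda: Perceptron(random_state=s + 11)),
        PanelMember("knn1", "instance-based", lambda: KNeighborsClassifier(n_neighbors=1)),
        PanelMember("knn2", "instance-based", lambda: KNeighborsClassifier(n_neighbors=2)),
        PanelMember("knn5", "instance-based", lambda: KNeighborsClassifier(n_neighbors=5)),
        PanelMember(
            "knn5_distance",
            "instance-based",
            lambda: KNeighborsClassifier(n_neighbors=5, weights="distance"),
        ),
        PanelMember("adaboost", "ensemble", lambda: AdaBoostClassifier(random_state=s + 15)),
        PanelMember("bagging", "ensemble", lambda: BaggingClassifier(random_state=s + 16)),
        PanelMember("random_forest", "ensemble", lambda: RandomForestClassifier(random_state=s + 17)),
        PanelMember("extra_trees", "ensemble", lambda: ExtraTreesClassifier(random_state=s + 18)),
        PanelMember(
            "gradient_boosting",
            "ensemble",
            lambda: GradientBoostingClassifier(random_state=s + 19),
        ),
        PanelMember("cart_gini", "tree-based", lambda: DecisionTreeClassifier(random_state=s + 20)),
        PanelMember(
            "cart_entropy",
            "tree-based",
            lambda: DecisionTreeClassifier(criterion="entropy", random_state=s + 21),
        ),
        PanelMember("extra_tree", "tree-based", lambda: ExtraTreeClassifier(random_state=s + 22)),
        PanelMember(
            "one_rule_stump",
            "rule-based",
            lambda: DecisionTreeClassifier(max_depth=1, random_state=s + 23),
        ),
        PanelMember("nearest_centroid", "centroid-based", NearestCentroid),
    ]
    return ClassifierPanel(members=members)


@dataclass
class EnsembleReport:
    """Predictions, per-classifier metrics, and disagreement counts.

    ``predictions[set_name]`` is a samples x classifiers frame of predicted
    labels; ``metrics`` has one row per (set, classifier) with accuracy,
    sensitivity and specificity (case = positive class, 'other' samples
    excluded); ``summary`` aggregates unweighted mean and sd over the panel.
    """

    panel_names: list[str]
    predictions: dict[str, pd.DataFrame]
    metrics: pd.DataFrame
    summary: pd.DataFrame
    disagreement: pd.Series  # training samples only

    @property
    def panel_size(self) -> int:
        return len(self.panel_names)


def _predict_binary(est, X: np.ndarray) -> np.ndarray:
    """Predict 0/1 with score ties resolved to the control class (0)."""
    if hasattr(est, "predict_proba"):
        p = est.predict_proba(X)
        pos = list(est.classes_).index(1)
        return (p[:, pos] > 0.5).astype(int)
    if hasattr(est, "decision_function"):
        score = est.decision_function(X)
        if score.ndim == 1:
            # decision_function > 0 corresponds to classes_[1]
            out = np.where(score > 0, est.classes_[1], est.classes_[0])
            return out.astype(int)
    return np.asarray(est.predict(X)).astype(int)


def _confusion_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    total = tp + tn + fp + fn
    return {
        "accuracy": (tp + tn) / total if total else np.nan,
        "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
        "specificity": tn / (tn + fp) if tn + fp else np.nan,
    }


def _encode(labels: pd.Series) -> np.ndarray:
    return (labels.to_numpy() == CLASS_CASE).astype(int)


def fit_predict(
    panel: ClassifierPanel,
    train: PanelMatrix,
    signature: list[str],
    eval_sets: dict[str, PanelMatrix] | None = None,
) -> EnsembleReport:
    """Fit every panel member once and evaluate on train + held-out sets.

    Training uses the continuous signature-column values of the case and
    control training samples.  Predictions are recorded for *all* samples
    of every set (including 'other' ones), but metric rows exclude 'other'.
    """
    eval_sets = dict(eval_sets or {})
    missing = [c for c in signature if c not in train.values.columns]
    if missing:
        raise KeyError(f"signature columns missing from training set: {missing}")
    train_cc = train.classified()
    y_train = _encode(train_cc.labels)
    if np.unique(y_train).size < 2:
        raise ValueError("training set must contain both case and control samples")
    X_train = train_cc.values[signature].to_numpy(dtype=float)

    sets: dict[str, PanelMatrix] = {"train": train}
    for name, pm in eval_sets.items():
        if name == "train":
            raise ValueError("eval set name 'train' is reserved")
        miss = [c for c in signature if c not in pm.values.columns]
        if miss:
            raise KeyError(f"signature columns missing from eval set {name!r}: {miss}")
        sets[name] = pm

    predictions: dict[str, pd.DataFrame] = {
        name: pd.DataFrame(index=pm.values.index, columns=[m.name for m in panel.members], dtype=object)
        for name, pm in sets.items()
    }
    rows = []
    for member in panel.members:
        est = member.factory()
        est.fit(X_train, y_train)
        for name, pm in sets.items():
            X = pm.values[signature].to_numpy(dtype=float)
            pred = _predict_binary(est, X)
            pred_labels = np.where(pred == 1, CLASS_CASE, CLASS_CONTROL)
            predictions[name][member.name] = pred_labels
            cc_mask = (pm.labels != CLASS_OTHER).to_numpy()
            m = _confusion_metrics(_encode(pm.labels[cc_mask]), pred[cc_mask])
            rows.append({"set": name, "classifier": member.name, "family": member.family, **m})

    metrics = pd.DataFrame(rows)
    summary = (
        metrics.groupby("set")[["accuracy", "sensitivity", "specificity"]]
        .agg(["mean", "std"])
        .sort_index()
    )

    train_pred = predictions["train"].loc[train_cc.values.index]
    obs = train_cc.labels
    disagreement = pd.Series(
        (train_pred.to_numpy() != obs.to_numpy()[:, None]).sum(axis=1),
        index=train_cc.values.index,
        name="disagreement",
    )
    return EnsembleReport(
        panel_names=[m.name for m in panel.members],
        predictions=predictions,
        metrics=metrics,
        summary=summary,
        disagreement=disagreement,
    )


def disagreement_histogram(report: EnsembleReport) -> pd.Series:
    """Counts of training samples per disagreement level, omitting d_s = 0."""
    d = report.disagreement
    return d[d > 0].value_counts().sort_index()
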