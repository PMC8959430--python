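"""Base learners, Behavioral Knowledge Space fusion, and boosted trees.

Three base learners are trained on the selected features: LDA, an RBF-kernel
SVM (soft margin C and kernel radius chosen by an internal stratified grid
search), and a single-hidden-layer MLP with 15 tanh units and a linear output
layer.  Their decisions are fused with the Behavioral Knowledge Space (BKS)
rule: every training row is filed under its joint decision tuple, and at
prediction time a tuple's cell votes with the majority of the true labels it
accumulated; unseen tuples and ties fall back to the class with the highest
mean posterior across learners.

Simultaneous (combined-movement) classification uses gradient-boosted
decision trees with 600 estimators, maximum depth 18 and learning rate 0.1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import softmax
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .features import FeatureTable
from .exceptions import StratificationError

logger = logging.getLogger(__name__)

__all__ = [
    "BaseLearnerOutput",
    "BksTable",
    "FittedLearner",
    "train_base_learners",
    "predict_output",
    "bks_fit",
    "bks_predict",
    "train_boosted_trees",
    "predict_boosted",
]


@dataclass
class BaseLearnerOutput:
    """Predicted labels and a row-stochastic posterior matrix."""

    labels: np.ndarray
    posteriors: np.ndarray  # (n_rows, n_classes), rows sum to 1
    classes: np.ndarray


@dataclass
class FittedLearner:
    """A fitted base learner plus how to obtain posteriors from it."""

    name: str
    model: object
    posterior_mode: str  # "predict_proba" | "softmax_decision"
    config: dict = field(default_factory=dict)


@dataclass
class BksTable:
    """BKS lookup: decision tuple -> per-class counts of the true label."""

    cells: dict[tuple, np.ndarray]
    classes: np.ndarray
    n_learners: int


# ---------------------------------------------------------------------------
# base learners
# ---------------------------------------------------------------------------

_SVM_GRID = {"svc__C": [0.1, 1.0, 10.0, 100.0], "svc__gamma": [0.01, 0.1, 1.0, 10.0]}


def train_base_learners(
    train: FeatureTable,
    feature_names: list[str] | None = None,
    seed: int = 0,
) -> list[FittedLearner]:
    """Fit LDA, RBF-SVM and MLP(15) on (a subset of) the feature columns."""
    feats = feature_names if feature_names is not None else train.feature_names
    X = train.data[feats].to_numpy(dtype=float)
    y = train.y
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise StratificationError("need at least 2 classes")
    if counts.min() < 2:
        raise StratificationError("every class needs at least 2 training rows")

    lda = LinearDiscriminantAnalysis()
    lda.fit(X, y)

    # SVM and MLP are scale-sensitive; both see z-scored features
    n_folds = min(3, int(counts.min()))
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    svm_pipe = Pipeline([("scale", StandardScaler()), ("svc", SVC(kernel="rbf"))])
    search = GridSearchCV(svm_pipe, _SVM_GRID, cv=cv, n_jobs=1)
    search.fit(X, y)
    svm = search.best_estimator_
    logger.info("SVM grid search chose %s", search.best_params_)

    # early stopping needs a validation split big enough to carry signal;
    # on small training sets it fires before the network has learned anything
    use_early_stop = y.size >= 200
    mlp = Pipeline([
        ("scale", StandardScaler()),
        ("mlp", MLPClassifier(
            hidden_layer_sizes=(15,),
            activation="tanh",
            solver="adam",
            early_stopping=use_early_stop,
            validation_fraction=0.1,
            n_iter_no_change=25,
            max_iter=2000,
            random_state=seed,
        )),
    ])
    mlp.fit(X, y)

    return [
        FittedLearner("lda", lda, "predict_proba", {"features": feats}),
        FittedLearner(
            "svm", svm, "softmax_decision",
            {"features": feats, **search.best_params_},
        ),
        FittedLearner(
            "mlp", mlp, "predict_proba",
            {
                "features": feats,
                "hidden_layer_sizes": mlp.named_steps["mlp"].hidden_layer_sizes,
            },
        ),
    ]


def predict_output(learner: FittedLearner, table: FeatureTable) -> BaseLearnerOutput:
    """Labels and posteriors for one learner; labels are argmax of posteriors."""
    X = table.data[learner.config["features"]].to_numpy(dtype=float)
    model = learner.model
    if learner.posterior_mode == "predict_proba":
        post = model.predict_proba(X)
    else:
        scores = model.decision_function(X)
        if scores.ndim == 1:  # binary: one margin column
            scores = np.column_stack([-scores, scores])
        post = softmax(scores, axis=1)
    post = post / post.sum(axis=1, keepdims=True)
    labels = model.classes_[np.argmax(post, axis=1)]
    return BaseLearnerOutput(labels=labels, posteriors=post, classes=model.classes_)


# ---------------------------------------------------------------------------
# BKS fusion
# ---------------------------------------------------------------------------

def bks_fit(outputs: list[BaseLearnerOutput], truth: np.ndarray) -> BksTable:
    """Index every training row by its joint decision tuple."""
    truth = np.asarray(truth)
    if truth.size == 0:
        raise ValueError("empty training set")
    classes = outputs[0].classes
    class_pos = {c: i for i, c in enumerate(classes)}
    decisions = np.column_stack([o.labels for o in outputs])
    cells: dict[tuple, np.ndarray] = {}
    for row, true_label in zip(decisions, truth):
        key = tuple(row.tolist())
        if key not in cells:
            cells[key] = np.zeros(classes.size)
        cells[key][class_pos[true_label]] += 1
    return BksTable(cells=cells, classes=classes, n_learners=len(outputs))


def bks_predict(outputs: list[BaseLearnerOutput], table: BksTable) -> np.ndarray:
    """Majority true class of each row's cell; ties/unseen tuples fall back to
    the class with the highest mean posterior across learners."""
    decisions = np.column_stack([o.labels for o in outputs])
    mean_post = np.mean([o.posteriors for o in outputs], axis=0)
    fallback = table.classes[np.argmax(mean_post, axis=1)]
    out = np.empty(decisions.shape[0], dtype=table.classes.dtype)
    for i, row in enumerate(decisions):
        counts = table.cells.get(tuple(row.tolist()))
        if counts is None:
            out[i] = fallback[i]
            continue
        top = counts.max()
        winners = np.flatnonzero(counts == top)
        out[i] = table.classes[winners[0]] if winners.size == 1 else fallback[i]
    return out


# ---------------------------------------------------------------------------
# boosted trees (simultaneous movements)
# ---------------------------------------------------------------------------

def train_boosted_trees(
    train: FeatureTable,
    n_estimators: int = 600,
    max_depth: int = 18,
    learning_rate: float = 0.1,
    seed: int = 0,
) -> XGBClassifier:
    """Gradient-boosted multiclass trees with the stated hyperparameters.

    Labels are mapped to a contiguous 0..c−1 range internally; the fitted
    model carries ``label_classes_`` for the inverse mapping.
    """
    y = train.y
    classes = np.unique(y)
    if classes.size < 2:
        raise StratificationError("boosted trees need at least 2 classes")
    y_enc = np.searchsorted(classes, y)
    model = XGBClassifier(
        n_estimators=n_estimators,
        max_depth=max_depth,
        learning_rate=learning_rate,
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
        objective="multi:softprob",
        num_class=classes.size,
    )
    model.fit(train.X, y_enc)
    model.label_classes_ = classes
    return model


def predict_boosted(model: XGBClassifier, table: FeatureTable) -> np.ndarray:
    """Predictions of a boosted-tree model on original label values."""
    return model.label_classes_[model.predict(table.X)]
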