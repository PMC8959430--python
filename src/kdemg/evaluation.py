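"""Confusion matrices, classification metrics, split schemes, agreement tests.

Per class i, with TP/TN/FP/FN read off the confusion matrix:

    PR_i  = TP_i / (TP_i + FP_i)          (precision)
    RL_i  = TP_i / (TP_i + FN_i)          (recall)
    Acc_i = (TP_i + TN_i) / N             (per-class accuracy)
    F_i   = 2·PR_i·RL_i / (PR_i + RL_i)

F_macro averages the F_i; when a class has TP_i = 0 and PR_i + RL_i = 0 its
F_i — and therefore F_macro — is NaN (reported as such, never zero-filled).
The micro-averaged F equals the pooled precision PR_u, the pooled recall
RL_u and the overall accuracy in single-label multiclass problems; that
identity is preserved exactly.

Split schemes: the three fixed repeated hold-out partitions of six movement
repetitions (test sets {1,4}, {2,5}, {3,6}) and seeded stratified k-fold.
Agreement statistics: Fleiss' kappa with a large-sample CI and McNemar's
test (exact binomial for few discordant pairs, continuity-corrected
chi-square otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .exceptions import StratificationError

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "SplitScheme",
    "confusion_from_labels",
    "metrics_report",
    "make_repeated_holdout",
    "make_kfold",
    "fleiss_kappa",
    "mcnemar_test",
    "misclassified_movements",
]


@dataclass
class ConfusionMatrix:
    """c x c count matrix, rows = truth, columns = predicted."""

    counts: np.ndarray
    class_names: list

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion_from_labels(
    y_true: np.ndarray, y_pred: np.ndarray, classes=None
) -> ConfusionMatrix:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    classes = np.asarray(classes)
    pos = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((classes.size, classes.size), dtype=int)
    for t, p in zip(y_true, y_pred):
        counts[pos[t], pos[p]] += 1
    return ConfusionMatrix(counts=counts, class_names=classes.tolist())


@dataclass
class MetricsReport:
    """Per-class and aggregate metrics for one confusion matrix."""

    class_names: list
    precision: np.ndarray
    recall: np.ndarray
    accuracy_per_class: np.ndarray
    f_score: np.ndarray
    f_macro: float
    f_micro: float
    precision_micro: float
    recall_micro: float
    overall_accuracy: float
    has_nan_class: bool
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "classes": [int(c) if np.isreal(c) else str(c) for c in self.class_names],
            "precision": self.precision.tolist(),
            "recall": self.recall.tolist(),
            "accuracy_per_class": self.accuracy_per_class.tolist(),
            "f_score": self.f_score.tolist(),
            "f_macro": float(self.f_macro),
            "f_micro": float(self.f_micro),
            "precision_micro": float(self.precision_micro),
            "recall_micro": float(self.recall_micro),
            "overall_accuracy": float(self.overall_accuracy),
            "has_nan_class": bool(self.has_nan_class),
        }


def metrics_report(cm: ConfusionMatrix) -> MetricsReport:
    counts = np.asarray(cm.counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(counts)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp
    tn = total - tp - fp - fn

    with np.errstate(invalid="ignore", divide="ignore"):
        pr = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        rl = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        acc_i = (tp + tn) / total
        denom = pr + rl
        f = np.where(denom > 0, 2.0 * pr * rl / np.where(denom > 0, denom, 1.0), np.nan)

    f_macro = float(np.mean(f))  # NaN propagates by design
    pr_u = float(tp.sum() / (tp.sum() + fp.sum()))
    rl_u = float(tp.sum() / (tp.sum() + fn.sum()))
    f_micro = 2.0 * pr_u * rl_u / (pr_u + rl_u) if pr_u + rl_u > 0 else 0.0
    overall = float(tp.sum() / total)
    return MetricsReport(
        class_names=list(cm.class_names),
        precision=pr,
        recall=rl,
        accuracy_per_class=acc_i,
        f_score=f,
        f_macro=f_macro,
        f_micro=float(f_micro),
        precision_micro=pr_u,
        recall_micro=rl_u,
        overall_accuracy=overall,
        has_nan_class=bool(np.isnan(f).any()),
    )


# ---------------------------------------------------------------------------
# split schemes
# ---------------------------------------------------------------------------

@dataclass
class SplitScheme:
    """Named list of (train, test) assignments.

    ``unit`` says what the assignments index: movement repetitions for the
    repeated hold-out, row indices for k-fold.
    """

    name: str
    splits: list[tuple[np.ndarray, np.ndarray]]
    unit: str  # "repetition" | "row"


def make_repeated_holdout(repetitions=range(1, 7)) -> SplitScheme:
    """The three fixed train/test partitions of six movement repetitions."""
    reps = sorted(int(r) for r in repetitions)
    if reps != [1, 2, 3, 4, 5, 6]:
        raise StratificationError("repeated hold-out is defined for repetitions 1..6")
    assignments = [
        (np.array([2, 3, 5, 6]), np.array([1, 4])),
        (np.array([1, 3, 4, 6]), np.array([2, 5])),
        (np.array([1, 2, 4, 5]), np.array([3, 6])),
    ]
    return SplitScheme(name="repeated_holdout_3", splits=assignments, unit="repetition")


def make_kfold(labels: np.ndarray, k: int = 4, seed: int = 0) -> SplitScheme:
    """Seeded stratified k-fold over rows."""
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise StratificationError(f"every class needs at least k={k} rows")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    splits = [
        (train.copy(), test.copy())
        for train, test in skf.split(np.zeros(labels.size), labels)
    ]
    return SplitScheme(name=f"kfold_{k}", splits=splits, unit="row")


# ---------------------------------------------------------------------------
# agreement statistics
# ---------------------------------------------------------------------------

def fleiss_kappa(table: np.ndarray) -> tuple[float, tuple[float, float]]:
    """Fleiss' kappa for an items x categories count table, with 95% CI.

    Each row holds the category counts assigned by the ``n`` raters to one
    item (row sums all equal ``n``).  The CI uses the large-sample standard
    error of kappa under the null-variance approximation.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[1] < 2:
        raise ValueError("need an items x categories table with >= 2 categories")
    n_items, _ = table.shape
    n_raters = table.sum(axis=1)
    if not np.all(n_raters == n_raters[0]):
        raise ValueError("all items must have the same number of ratings")
    n = float(n_raters[0])
    if n < 2:
        raise ValueError("need at least 2 raters")

    p_j = table.sum(axis=0) / (n_items * n)
    if np.count_nonzero(p_j) < 2:
        raise ValueError("kappa undefined: a single category was ever used")
    p_i = (np.sum(table**2, axis=1) - n) / (n * (n - 1))
    p_bar = float(np.mean(p_i))
    p_e = float(np.sum(p_j**2))
    kappa = (p_bar - p_e) / (1.0 - p_e)

    q_j = 1.0 - p_j
    s = float(np.sum(p_j * q_j))
    se = (np.sqrt(2.0 / (n_items * n * (n - 1)))
          * np.sqrt(s**2 - np.sum(p_j * q_j * (q_j - p_j))) / s)
    half = 1.959963984540054 * se
    return float(kappa), (float(kappa - half), float(kappa + half))


def mcnemar_test(
    correct_a: np.ndarray, correct_b: np.ndarray
) -> tuple[float, float]:
    """McNemar's test on per-row correctness of two classifiers.

    Exact two-sided binomial when the discordant count is below 25, otherwise
    the continuity-corrected chi-square statistic.  Zero discordant pairs give
    p = 1 by convention.  Returns ``(statistic, p)``: the statistic is the
    smaller discordant count in the exact branch and the chi-square value in
    the asymptotic branch.
    """
    a = np.asarray(correct_a, dtype=bool)
    b = np.asarray(correct_b, dtype=bool)
    if a.shape != b.shape or a.size == 0:
        raise ValueError("need two aligned non-empty boolean vectors")
    n01 = int(np.sum(a & ~b))
    n10 = int(np.sum(~a & b))
    n_disc = n01 + n10
    if n_disc == 0:
        return 0.0, 1.0
    if n_disc < 25:
        k = min(n01, n10)
        p = float(min(1.0, 2.0 * stats.binom.cdf(k, n_disc, 0.5)))
        return float(k), p
    chi2 = (abs(n01 - n10) - 1.0) ** 2 / n_disc
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def misclassified_movements(
    y_true: np.ndarray, y_pred: np.ndarray
) -> dict[int, int]:
    """Per movement class, 1 if any of its windows was wrongly labelled
    (either a false negative on the class or a false positive into it)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    out: dict[int, int] = {}
    for c in np.unique(y_true):
        fn = np.any((y_true == c) & (y_pred != c))
        fp = np.any((y_true != c) & (y_pred == c))
        out[int(c)] = int(fn or fp)
    return out
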