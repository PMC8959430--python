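"""Correlation-based feature selection (CFS) with best-first subset search.

The merit of a feature subset S with k features is

    Merit_S = k·r̄_cf / sqrt(k + k(k−1)·r̄_ff)

where r̄_cf is the mean feature-class correlation over S and r̄_ff the mean
feature-feature inter-correlation: good subsets are relevant to the class but
internally non-redundant.  The default correlation measure is symmetric
uncertainty, SU(X, Y) = 2·I(X;Y)/(H(X)+H(Y)), after equal-frequency
discretization of the features; |Pearson| is available as an alternative.

The subset space is explored with best-first search: start from the empty
set, expand by single-feature additions, always expand the best unexpanded
subset next, and stop after five consecutive fully expanded subsets that do
not improve on the best merit found.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field

import numpy as np

from .features import FeatureTable

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationMatrices",
    "SelectionResult",
    "compute_correlations",
    "cfs_merit",
    "best_first_search",
]


@dataclass
class CorrelationMatrices:
    """Feature-class and feature-feature correlations for CFS."""

    feature_names: list[str]
    feature_class: np.ndarray  # (p,)
    feature_feature: np.ndarray  # (p, p), symmetric, unit diagonal
    measure: str  # "symmetric_uncertainty" | "pearson_abs"

    def index(self, names: list[str]) -> np.ndarray:
        pos = {n: i for i, n in enumerate(self.feature_names)}
        return np.array([pos[n] for n in names], dtype=int)


@dataclass
class SelectionResult:
    """Outcome of a best-first CFS search."""

    selected: list[str]
    merit: float
    trace: list[tuple[tuple[str, ...], float]] = field(default_factory=list)
    stop_reason: str = ""
    n_expanded: int = 0


# ---------------------------------------------------------------------------
# correlation measures
# ---------------------------------------------------------------------------

def _discretize_equal_frequency(x: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Equal-frequency binning; collapses duplicate quantile edges."""
    qs = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    edges = np.unique(qs)
    return np.searchsorted(edges, x, side="right")


def _entropy(codes: np.ndarray) -> float:
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log2(p)))


def _mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    ja = np.unique(a, return_inverse=True)[1]
    jb = np.unique(b, return_inverse=True)[1]
    joint = np.zeros((ja.max() + 1, jb.max() + 1))
    np.add.at(joint, (ja, jb), 1.0)
    joint /= joint.sum()
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log2(joint[nz] / (pa @ pb)[nz])))


def _symmetric_uncertainty(a: np.ndarray, b: np.ndarray) -> float:
    ha, hb = _entropy(a), _entropy(b)
    if ha == 0 or hb == 0:
        return 0.0
    return 2.0 * _mutual_information(a, b) / (ha + hb)


def compute_correlations(
    table: FeatureTable,
    measure: str = "symmetric_uncertainty",
    n_bins: int | None = None,
) -> CorrelationMatrices:
    """Feature-class vector and feature-feature matrix for CFS.

    ``n_bins`` defaults to the square-root rule capped at 10: on small
    training splits a fixed fine binning makes the entropy estimates too
    noisy for the merit to rank subsets reliably.

    Constant features get zero correlations with a warning rather than an
    error, so a degenerate column cannot abort the search.
    """
    X = table.X
    y = table.y
    if n_bins is None:
        n_bins = int(min(10, max(2, np.floor(np.sqrt(X.shape[0])))))
    p = X.shape[1]
    if p < 2 or np.unique(y).size < 2:
        raise ValueError("need at least 2 features and 2 classes")
    r_cf = np.zeros(p)
    r_ff = np.eye(p)
    constant = X.std(axis=0) == 0
    if constant.any():
        logger.warning(
            "constant feature(s) %s: correlations set to 0",
            [table.feature_names[i] for i in np.flatnonzero(constant)],
        )

    if measure == "symmetric_uncertainty":
        codes = [
            _discretize_equal_frequency(X[:, j], n_bins) if not constant[j] else None
            for j in range(p)
        ]
        for j in range(p):
            if codes[j] is not None:
                r_cf[j] = _symmetric_uncertainty(codes[j], y)
        for j in range(p):
            for k in range(j + 1, p):
                if codes[j] is not None and codes[k] is not None:
                    r_ff[j, k] = r_ff[k, j] = _symmetric_uncertainty(codes[j], codes[k])
    elif measure == "pearson_abs":
        classes = np.unique(y)
        for j in range(p):
            if constant[j]:
                continue
            vals = [
                abs(np.corrcoef(X[:, j], (y == c).astype(float))[0, 1])
                for c in classes
                if 0 < (y == c).sum() < len(y)
            ]
            r_cf[j] = float(np.mean(vals)) if vals else 0.0
        cc = np.corrcoef(X, rowvar=False)
        cc = np.abs(np.nan_to_num(cc))
        mask = ~constant
        r_ff[np.ix_(mask, mask)] = cc[np.ix_(mask, mask)]
        np.fill_diagonal(r_ff, 1.0)
    else:
        raise ValueError(f"unknown correlation measure {measure!r}")

    return CorrelationMatrices(
        feature_names=list(table.feature_names),
        feature_class=r_cf,
        feature_feature=r_ff,
        measure=measure,
    )


# ---------------------------------------------------------------------------
# merit and search
# ---------------------------------------------------------------------------

def cfs_merit(subset: list[str], corr: CorrelationMatrices) -> float:
    """CFS merit of a feature subset (k = 1 reduces to the feature's r_cf)."""
    if not subset:
        return 0.0
    idx = corr.index(list(subset))
    k = idx.size
    r_cf = float(corr.feature_class[idx].mean())
    if k == 1:
        r_ff = 0.0
    else:
        sub = corr.feature_feature[np.ix_(idx, idx)]
        r_ff = float((sub.sum() - k) / (k * (k - 1)))
    denom = k + k * (k - 1) * r_ff
    if denom <= 0:
        return 0.0
    return k * r_cf / np.sqrt(denom)


def best_first_search(
    corr: CorrelationMatrices, max_stale: int = 5
) -> SelectionResult:
    """Best-first search over feature subsets using CFS merit.

    Deterministic: ties in the open list break on the lexicographically
    smallest subset.  Terminates after ``max_stale`` consecutive fully
    expanded subsets that produce no improvement, or when the space is
    exhausted.
    """
    names = sorted(corr.feature_names)
    if not names:
        raise ValueError("no features to search over")

    trace: list[tuple[tuple[str, ...], float]] = []
    evaluated: set[frozenset[str]] = set()
    expanded: set[frozenset[str]] = set()

    def evaluate(subset: tuple[str, ...]) -> float:
        merit = cfs_merit(list(subset), corr)
        trace.append((subset, merit))
        return merit

    best_subset: tuple[str, ...] = ()
    best_merit = 0.0
    # heap entries: (-merit, subset) so the best merit pops first with
    # lexicographic tie-breaking on the subset itself
    heap: list[tuple[float, tuple[str, ...]]] = [(0.0, ())]
    evaluated.add(frozenset())
    stale = 0
    stop_reason = "open list exhausted"

    while heap:
        neg_merit, subset = heapq.heappop(heap)
        key = frozenset(subset)
        if key in expanded:
            continue
        expanded.add(key)

        improved = False
        for name in names:
            if name in key:
                continue
            child = subset + (name,)
            child_key = frozenset(child)
            if child_key in evaluated:
                continue
            evaluated.add(child_key)
            merit = evaluate(child)
            if merit > best_merit:
                best_merit = merit
                best_subset = child
                improved = True
            heapq.heappush(heap, (-merit, child))

        if improved:
            stale = 0
        else:
            stale += 1
            if stale >= max_stale:
                stop_reason = f"{max_stale} consecutive non-improving expansions"
                break

    if not best_subset:
        # pathological all-zero merits: fall back to the best singleton
        order = np.argsort(-corr.feature_class, kind="stable")
        best_subset = (corr.feature_names[int(order[0])],)
        best_merit = cfs_merit(list(best_subset), corr)
        stop_reason = "degenerate merits; best singleton returned"

    return SelectionResult(
        selected=list(best_subset),
        merit=float(best_merit),
        trace=trace,
        stop_reason=stop_reason,
        n_expanded=len(expanded),
    )
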