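"""End-to-end experiment drivers.

Three experiment shapes:

* :func:`run_sequential_experiment` — middle-third density features per
  channel, CFS subset selection on each training split, LDA/SVM/MLP base
  learners fused with BKS, evaluated on the three fixed repetition hold-outs.
* :func:`run_online_simulation` — TMD-only features on short sliding epochs
  of several widths with an LDA classifier; reports accuracy and the measured
  per-epoch processing time for each width.
* :func:`run_simultaneous_experiment` — sliding-window density features on
  the nine-class simultaneous set, gradient-boosted trees vs LDA under
  stratified fourfold cross-validation, with a McNemar comparison.

Every driver is deterministic given its config and seed.  When an output
directory is configured, each run writes a config snapshot, a log file,
metrics as JSON and confusion matrices as CSV.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from . import ensemble as ens
from .evaluation import (
    MetricsReport,
    confusion_from_labels,
    make_kfold,
    make_repeated_holdout,
    mcnemar_test,
    metrics_report,
    misclassified_movements,
)
from .exceptions import ConfigError
from .features import ApEnParams, FeatureTable, TrimSpec, extract_feature_table
from .selection import best_first_search, compute_correlations
from .signal_io import SignalRecord, WindowSpec, bandpass_filter, standardize_dataset
from .synthetic import SyntheticConfig, generate_dataset, generate_simultaneous_dataset

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentConfig",
    "SequentialResult",
    "SimultaneousResult",
    "run_sequential_experiment",
    "run_online_simulation",
    "run_simultaneous_experiment",
]


@dataclass
class ExperimentConfig:
    """Settings shared by the experiment drivers."""

    synthetic: SyntheticConfig | None = None
    records: list[SignalRecord] | None = None
    feature_set: str = "kde"
    window: WindowSpec = field(default_factory=lambda: WindowSpec(mode="middle_third"))
    trim: TrimSpec = field(default_factory=TrimSpec)
    apen: ApEnParams = field(default_factory=ApEnParams)
    n_grid: int = 1024
    filter_band: tuple[float, float] = (20.0, 500.0)
    filter_order: int = 4
    feature_distribution: str = "shared"  # "shared" | "random_partition"
    edge_trim_frac: float = 0.1  # contraction fraction cut per end before sliding windows
    seed: int = 42
    output_dir: str | None = None

    def load_records(self) -> list[SignalRecord]:
        if self.records is not None:
            return self.records
        if self.synthetic is not None:
            return generate_dataset(self.synthetic)
        raise ConfigError("config needs either records or a synthetic config")


@dataclass
class SequentialResult:
    split_reports: list[dict[str, MetricsReport]]
    accuracies: pd.DataFrame  # rows = splits, columns = learners + ensemble
    mean_accuracy: dict[str, float]
    misclassification: pd.DataFrame
    selected_features: list[list[str]]
    seed: int


@dataclass
class SimultaneousResult:
    fold_reports: dict[str, list[MetricsReport]]
    accuracy: dict[str, float]  # mean CV accuracy per classifier
    per_class_f: pd.DataFrame
    mcnemar: tuple[float, float]
    n_windows: int
    seed: int


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------

def _preprocess(records: list[SignalRecord], config: ExperimentConfig) -> list[SignalRecord]:
    """Band-pass filter then standardize with per-subject pooled statistics."""
    low, high = config.filter_band
    filtered = [bandpass_filter(r, low, high, config.filter_order) for r in records]
    by_subject: dict[str, list[SignalRecord]] = {}
    for r in filtered:
        by_subject.setdefault(r.subject, []).append(r)
    out: list[SignalRecord] = []
    for recs in by_subject.values():
        out.extend(standardize_dataset(recs))
    return out


def _features(records: list[SignalRecord], config: ExperimentConfig,
              feature_set: str | None = None,
              window: WindowSpec | None = None) -> FeatureTable:
    return extract_feature_table(
        records,
        feature_set=feature_set or config.feature_set,
        window=window or config.window,
        trim=config.trim,
        apen=config.apen,
        n_grid=config.n_grid,
    )


def _trim_edges(records: list[SignalRecord], frac: float) -> list[SignalRecord]:
    """Cut the onset/offset ramps before sliding-window extraction, so no
    window straddles the rest/contraction transition."""
    if frac <= 0:
        return records
    out = []
    for r in records:
        n = r.n_samples
        k = int(frac * n)
        out.append(dataclasses.replace(r, samples=r.samples[:, k : n - k].copy()))
    return out


def _partition_features(names: list[str], n_parts: int, seed: int) -> list[list[str]]:
    rng = np.random.default_rng(seed)
    shuffled = list(names)
    rng.shuffle(shuffled)
    parts = [sorted(shuffled[i::n_parts]) for i in range(n_parts)]
    # a learner cannot train on an empty feature set
    return [p if p else list(names) for p in parts]


def _write_outputs(config: ExperimentConfig, tag: str, metrics: dict,
                   confusions: dict[str, np.ndarray]) -> None:
    if config.output_dir is None:
        return
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    snapshot = dataclasses.asdict(
        dataclasses.replace(config, records=None, output_dir=str(config.output_dir))
    )
    (out / "config.json").write_text(json.dumps(snapshot, indent=2, default=str))
    (out / f"{tag}_metrics.json").write_text(json.dumps(metrics, indent=2, default=str))
    for name, cm in confusions.items():
        np.savetxt(out / f"{tag}_confusion_{name}.csv", cm, fmt="%d", delimiter=",")
    with open(out / f"{tag}.log", "a") as fh:
        fh.write(f"{time.strftime('%Y-%m-%dT%H:%M:%S')} {tag} done; seed={config.seed}\n")


# ---------------------------------------------------------------------------
# sequential (conventional) control
# ---------------------------------------------------------------------------

def run_sequential_experiment(config: ExperimentConfig) -> SequentialResult:
    """Middle-third KDE features -> CFS -> LDA/SVM/MLP -> BKS, over the three
    fixed repetition hold-outs."""
    records = _preprocess(config.load_records(), config)
    table = _features(records, config)
    scheme = make_repeated_holdout()

    split_reports: list[dict[str, MetricsReport]] = []
    acc_rows = []
    selected_per_split: list[list[str]] = []
    miscls_rows = []
    confusions: dict[str, np.ndarray] = {}
    reps = table.repetitions

    for split_idx, (train_reps, test_reps) in enumerate(scheme.splits, start=1):
        train = table.subset_rows(np.isin(reps, train_reps))
        test = table.subset_rows(np.isin(reps, test_reps))

        corr = compute_correlations(train)
        selection = best_first_search(corr)
        selected = selection.selected
        selected_per_split.append(selected)
        logger.info("split %d: CFS selected %d features (merit %.3f)",
                    split_idx, len(selected), selection.merit)

        if config.feature_distribution == "random_partition":
            partitions = _partition_features(selected, 3, config.seed + split_idx)
            learners = []
            for part, name in zip(partitions, ("lda", "svm", "mlp")):
                fitted = ens.train_base_learners(train, feature_names=part,
                                                 seed=config.seed)
                learners.append(next(l for l in fitted if l.name == name))
        else:
            learners = ens.train_base_learners(train, feature_names=selected,
                                               seed=config.seed)

        train_outputs = [ens.predict_output(l, train) for l in learners]
        bks = ens.bks_fit(train_outputs, train.y)
        test_outputs = [ens.predict_output(l, test) for l in learners]
        fused = ens.bks_predict(test_outputs, bks)

        classes = np.unique(table.y)
        reports: dict[str, MetricsReport] = {}
        row = {"split": split_idx}
        for learner, out in zip(learners, test_outputs):
            cm = confusion_from_labels(test.y, out.labels, classes)
            reports[learner.name] = metrics_report(cm)
            row[learner.name] = reports[learner.name].overall_accuracy
        cm_ens = confusion_from_labels(test.y, fused, classes)
        reports["ensemble"] = metrics_report(cm_ens)
        row["ensemble"] = reports["ensemble"].overall_accuracy
        confusions[f"split{split_idx}_ensemble"] = cm_ens.counts
        split_reports.append(reports)
        acc_rows.append(row)
        miscls_rows.append(
            {"split": split_idx, **misclassified_movements(test.y, fused)}
        )

    accuracies = pd.DataFrame(acc_rows).set_index("split")
    mean_accuracy = accuracies.mean(axis=0).to_dict()
    miscls = pd.DataFrame(miscls_rows).set_index("split")
    result = SequentialResult(
        split_reports=split_reports,
        accuracies=accuracies,
        mean_accuracy=mean_accuracy,
        misclassification=miscls,
        selected_features=selected_per_split,
        seed=config.seed,
    )
    _write_outputs(
        config, "sequential",
        {
            "seed": config.seed,
            "mean_accuracy": mean_accuracy,
            "splits": [
                {k: r.to_dict() for k, r in rep.items()} for rep in split_reports
            ],
            "selected_features": selected_per_split,
        },
        confusions,
    )
    return result


# ---------------------------------------------------------------------------
# online epoch-width simulation
# ---------------------------------------------------------------------------

def run_online_simulation(
    config: ExperimentConfig,
    epoch_widths_ms: tuple[float, ...] = (300.0, 200.0, 100.0, 50.0),
) -> pd.DataFrame:
    """TMD features + LDA on sliding epochs of several widths.

    Epochs do not overlap (step = width).  Returns one row per width with the
    hold-out accuracy averaged over the three splits and the measured mean
    feature-extraction time per epoch (reported, never asserted).
    """
    records = _preprocess(config.load_records(), config)
    records = _trim_edges(records, config.edge_trim_frac)
    scheme = make_repeated_holdout()
    rows = []
    for width in epoch_widths_ms:
        if any(width / 1000.0 > r.duration_s for r in records):
            logger.warning("epoch width %.0f ms exceeds a record; skipped", width)
            continue
        spec = WindowSpec(width_ms=width, step_ms=width, mode="sliding")
        t0 = time.perf_counter()
        table = _features(records, config, feature_set="tmd", window=spec)
        latency = (time.perf_counter() - t0) / len(table.data)
        reps = table.repetitions
        accs = []
        for train_reps, test_reps in scheme.splits:
            train = table.subset_rows(np.isin(reps, train_reps))
            test = table.subset_rows(np.isin(reps, test_reps))
            lda = LinearDiscriminantAnalysis().fit(train.X, train.y)
            accs.append(float(np.mean(lda.predict(test.X) == test.y)))
        rows.append(
            {
                "width_ms": width,
                "accuracy": float(np.mean(accs)),
                "latency_s_per_epoch": latency,
                "n_epochs": len(table.data),
            }
        )
    out = pd.DataFrame(rows)
    _write_outputs(config, "online", {"seed": config.seed,
                                      "rows": out.to_dict("records")}, {})
    return out


# ---------------------------------------------------------------------------
# simultaneous control
# ---------------------------------------------------------------------------

def run_simultaneous_experiment(
    config: ExperimentConfig,
    window: WindowSpec | None = None,
) -> SimultaneousResult:
    """Sliding-window KDE features -> boosted trees vs LDA, fourfold CV.

    The dataset must carry the nine simultaneous classes (rest, four single
    movements, four combinations).
    """
    if config.records is not None:
        records = config.records
    else:
        synth = config.synthetic or SyntheticConfig(
            n_classes=4, n_channels=8, n_repetitions=4, fs=1200.0,
            contraction_s=3.0, band=(20.0, 450.0),
        )
        records = generate_simultaneous_dataset(synth)
    labels = {r.label for r in records}
    if len(labels) != 9:
        raise ConfigError(f"expected 9 simultaneous classes, got {sorted(labels)}")

    records = _preprocess(records, config)
    records = _trim_edges(records, config.edge_trim_frac)
    win = window or WindowSpec(width_ms=160.0, step_ms=40.0, mode="sliding")
    table = _features(records, config, feature_set="kde", window=win)
    scheme = make_kfold(table.y, k=4, seed=config.seed)

    classes = np.unique(table.y)
    fold_reports: dict[str, list[MetricsReport]] = {"xgb": [], "lda": []}
    xgb_correct, lda_correct = [], []
    confusions: dict[str, np.ndarray] = {}
    for fold_idx, (train_idx, test_idx) in enumerate(scheme.splits, start=1):
        mask_train = np.zeros(len(table.data), bool)
        mask_train[train_idx] = True
        train = table.subset_rows(mask_train)
        test = table.subset_rows(~mask_train)

        booster = ens.train_boosted_trees(train, seed=config.seed)
        pred_xgb = ens.predict_boosted(booster, test)
        lda = LinearDiscriminantAnalysis().fit(train.X, train.y)
        pred_lda = lda.predict(test.X)

        cm_x = confusion_from_labels(test.y, pred_xgb, classes)
        cm_l = confusion_from_labels(test.y, pred_lda, classes)
        fold_reports["xgb"].append(metrics_report(cm_x))
        fold_reports["lda"].append(metrics_report(cm_l))
        confusions[f"fold{fold_idx}_xgb"] = cm_x.counts
        xgb_correct.append(pred_xgb == test.y)
        lda_correct.append(pred_lda == test.y)

    accuracy = {
        name: float(np.mean([r.overall_accuracy for r in reps]))
        for name, reps in fold_reports.items()
    }
    per_class_f = pd.DataFrame(
        {
            name: np.nanmean([r.f_score for r in reps], axis=0)
            for name, reps in fold_reports.items()
        },
        index=classes,
    )
    mn = mcnemar_test(np.concatenate(xgb_correct), np.concatenate(lda_correct))
    result = SimultaneousResult(
        fold_reports=fold_reports,
        accuracy=accuracy,
        per_class_f=per_class_f,
        mcnemar=mn,
        n_windows=len(table.data),
        seed=config.seed,
    )
    _write_outputs(
        config, "simultaneous",
        {
            "seed": config.seed,
            "accuracy": accuracy,
            "mcnemar": {"statistic": mn[0], "p": mn[1]},
            "per_class_f": per_class_f.to_dict(),
        },
        confusions,
    )
    return result
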