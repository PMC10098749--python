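"""Cross-validation plans, classification metrics and classifier diversity.

Two fold-plan modes:

* ``plain`` k-fold: each test fold holds exactly ``floor(n/k)`` samples and
  any remainder stays in training for every fold (so a pool of 19,221
  signals at k=12 yields 1,601-signal test folds against 17,620 training
  signals);
* ``by-subject``: folds partition subjects, so no subject ever contributes
  to both the training and test side of a fold — the scientific default
  for multi-participant data.

Diversity between two classifiers is the 2x2 cross-tabulation of their
per-sample correctness (both hit / only A / only B / both miss); its cells
always sum to the number of evaluated samples.

:func:`evaluate_system` compares single-branch models (LSTM-only,
CNN-only) against the fused FFM on shared folds, for the Stage I task
problem and the Stage II sub-phase problems, reporting per-model metrics
and pairwise diversity tables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

from .fusion import (
    STAGE1_FFM,
    STAGE2_FFM,
    FcnClassifier,
    _condition_segment,
    _emotion_segments,
    compute_cnn_features,
    compute_spectral_features,
)
from .lstm import STAGE2_PRESET, LstmFeaturizer
from .mrmr import MrmrSelector
from .resnet import ResNet50Features
from .signals import SignalPool, extract_design_segments

__all__ = [
    "FoldPlan",
    "MetricsReport",
    "DiversityTable",
    "kfold_partition",
    "classification_metrics",
    "diversity_table",
    "evaluate_system",
]


@dataclass
class FoldPlan:
    """k disjoint test-index folds over n samples, plus the grouping mode."""

    k: int
    n: int
    test_indices: list[np.ndarray]
    mode: str = "plain"

    def __post_init__(self) -> None:
        seen = np.concatenate(self.test_indices) if self.test_indices else np.array([])
        if len(np.unique(seen)) != len(seen):
            raise ValueError("test folds overlap")

    def train_indices(self, fold: int) -> np.ndarray:
        mask = np.ones(self.n, dtype=bool)
        mask[self.test_indices[fold]] = False
        return np.flatnonzero(mask)


@dataclass
class MetricsReport:
    """Per-class precision/recall/F1 (percent), accuracy and confusion."""

    classes: list[str]
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    accuracy: float
    confusion: np.ndarray

    def as_dict(self) -> dict:
        per_class = {
            c: {
                "precision": round(float(p), 2),
                "recall": round(float(r), 2),
                "f1": round(float(f), 2),
                "support": int(s),
            }
            for c, p, r, f, s in zip(
                self.classes, self.precision, self.recall, self.f1, self.support
            )
        }
        return {
            "accuracy": round(float(self.accuracy), 2),
            "per_class": per_class,
            "confusion": self.confusion.tolist(),
        }


@dataclass
class DiversityTable:
    """2x2 correctness cross-tab of two classifiers on the same samples."""

    both_hit: int = 0
    a_only: int = 0  # A hit, B miss
    b_only: int = 0  # A miss, B hit
    both_miss: int = 0

    @property
    def total(self) -> int:
        return self.both_hit + self.a_only + self.b_only + self.both_miss

    def __add__(self, other: "DiversityTable") -> "DiversityTable":
        return DiversityTable(
            self.both_hit + other.both_hit,
            self.a_only + other.a_only,
            self.b_only + other.b_only,
            self.both_miss + other.both_miss,
        )

    def as_dict(self) -> dict:
        return {
            "both_hit": self.both_hit,
            "a_only": self.a_only,
            "b_only": self.b_only,
            "both_miss": self.both_miss,
        }


def kfold_partition(n: int, k: int, subjects=None, seed: int = 0,
                    mode: str | None = None) -> FoldPlan:
    """Build a k-fold plan over ``n`` samples.

    Plain mode shuffles indices and assigns exactly ``floor(n/k)`` to each
    test fold; the remainder is never tested and therefore always trains.
    By-subject mode (selected automatically when ``subjects`` is given)
    partitions the unique subject ids across folds instead.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    rng = np.random.default_rng(seed)
    if mode is None:
        mode = "by-subject" if subjects is not None else "plain"
    if mode == "plain":
        order = rng.permutation(n)
        size = n // k
        folds = [np.sort(order[i * size : (i + 1) * size]) for i in range(k)]
        return FoldPlan(k=k, n=n, test_indices=folds, mode="plain")
    if mode != "by-subject":
        raise ValueError("mode must be 'plain' or 'by-subject'")
    if subjects is None:
        raise ValueError("by-subject mode requires subject ids")
    subjects = np.asarray(subjects)
    if len(subjects) != n:
        raise ValueError("one subject id per sample required")
    uniq = np.unique(subjects)
    if k > len(uniq):
        raise ValueError(f"k={k} exceeds the number of subjects {len(uniq)}")
    order = rng.permutation(len(uniq))
    groups = np.array_split(uniq[order], k)
    folds = [np.flatnonzero(np.isin(subjects, g)) for g in groups]
    return FoldPlan(k=k, n=n, test_indices=folds, mode="by-subject")


def classification_metrics(predictions, labels, classes=None) -> MetricsReport:
    """Precision/recall/F1 per class and overall accuracy, in percent.

    A class never predicted gets precision 0 by convention.
    """
    y_pred = np.asarray(predictions)
    y_true = np.asarray(labels)
    if y_pred.shape != y_true.shape:
        raise ValueError("predictions and labels must have equal length")
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    classes = np.asarray(classes)
    p, r, f, s = precision_recall_fscore_support(
        y_true, y_pred, labels=classes, zero_division=0
    )
    cm = confusion_matrix(y_true, y_pred, labels=classes)
    acc = 100.0 * float((y_pred == y_true).mean())
    return MetricsReport(
        classes=[str(c) for c in classes],
        precision=100.0 * p,
        recall=100.0 * r,
        f1=100.0 * f,
        support=s,
        accuracy=acc,
        confusion=cm,
    )


def diversity_table(preds_a, preds_b, labels) -> DiversityTable:
    """Cross-tabulate per-sample correctness of two prediction vectors."""
    a = np.asarray(preds_a)
    b = np.asarray(preds_b)
    y = np.asarray(labels)
    if not (a.shape == b.shape == y.shape):
        raise ValueError("both prediction vectors and labels must share length")
    hit_a = a == y
    hit_b = b == y
    return DiversityTable(
        both_hit=int(np.sum(hit_a & hit_b)),
        a_only=int(np.sum(hit_a & ~hit_b)),
        b_only=int(np.sum(~hit_a & hit_b)),
        both_miss=int(np.sum(~hit_a & ~hit_b)),
    )


# ---------------------------------------------------------------------------
# system-level comparison
# ---------------------------------------------------------------------------


def _fit_predict_head(f_train, y_train, f_test, seed):
    head = FcnClassifier(random_state=seed).fit(f_train, y_train)
    return head.predict(f_test)


def _branch_predictions(features, y, train, test, seed, n_selected, mrmr_bins=8):
    """Predictions of LSTM-only, CNN-only and fused+MRMR models on one fold."""
    preds = {}
    for name in ("lstm", "cnn"):
        if features.get(name) is None:
            continue
        preds[name] = _fit_predict_head(
            features[name][train], y[train], features[name][test], seed
        )
    fused = np.concatenate(
        [features[b][:, :] for b in ("lstm", "cnn", "spectral") if features.get(b) is not None],
        axis=1,
    )
    selector = MrmrSelector(n_features_to_select=min(n_selected, fused.shape[1]),
                            bins=mrmr_bins).fit(fused[train], y[train])
    preds["ffm"] = _fit_predict_head(
        selector.transform(fused[train]), y[train], selector.transform(fused[test]), seed
    )
    return preds


def _evaluate_problem(features, y, plan, fold_indices, seed, n_selected):
    """Run the three models over the requested folds of one problem."""
    classes = np.unique(y)
    metrics: dict[str, list[MetricsReport]] = {}
    diversity = {"ffm_vs_lstm": DiversityTable(), "ffm_vs_cnn": DiversityTable()}
    for fold in fold_indices:
        test = plan.test_indices[fold]
        train = plan.train_indices(fold)
        preds = _branch_predictions(features, y, train, test, seed, n_selected)
        for name, pred in preds.items():
            metrics.setdefault(name, []).append(
                classification_metrics(pred, y[test], classes)
            )
        if "lstm" in preds:
            diversity["ffm_vs_lstm"] += diversity_table(preds["ffm"], preds["lstm"], y[test])
        if "cnn" in preds:
            diversity["ffm_vs_cnn"] += diversity_table(preds["ffm"], preds["cnn"], y[test])
    agg = {
        name: {
            "accuracy": float(np.mean([m.accuracy for m in reports])),
            "folds": reports,
        }
        for name, reports in metrics.items()
    }
    return {"metrics": agg, "diversity": diversity}


def _lstm_fold_features(X, y, train, hidden, dropout, epochs, seed):
    feat = LstmFeaturizer(
        hidden_sizes=hidden, dropout=dropout, epochs=epochs, random_state=seed
    ).fit(X[train], y[train])
    return feat.transform(X)


def evaluate_system(
    pool: SignalPool,
    plan: FoldPlan | None = None,
    k: int = 6,
    mode: str = "by-subject",
    fold_indices=None,
    stages=("stage1", "stage2_emotion", "stage2_memory"),
    lstm_epochs: int = 8,
    seed: int = 0,
    cnn_seed: int = 0,
    verbose: bool = False,
) -> dict:
    """Compare LSTM-only, CNN-only and fused FFM models on shared folds.

    Branch feature matrices that involve no training (scalogram-CNN,
    spectral) are computed once for the whole pool; the LSTM branch is
    re-trained on each fold's training side. Per-fold metrics are averaged
    (unweighted); diversity cells are summed across folds, so each table's
    cells total the number of evaluated signals.
    """
    conditioned = pool.conditioned()
    X = conditioned.to_matrix()
    y = conditioned.task_labels()
    subjects = conditioned.subject_ids()
    n = len(y)
    if plan is None:
        plan = kfold_partition(n, k, subjects=subjects if mode == "by-subject" else None,
                               seed=seed, mode=mode)
    if plan.n != n:
        raise ValueError("fold plan size inconsistent with pool")
    folds = list(range(plan.k)) if fold_indices is None else list(fold_indices)
    encoder = ResNet50Features(seed=cnn_seed)

    report: dict = {"n_signals": n, "mode": plan.mode, "k": plan.k, "folds_run": folds}

    if "stage1" in stages:
        if verbose:
            print("stage1: computing branch features ...")
        cnn_f = compute_cnn_features(X, encoder)
        spec_f = compute_spectral_features(X, levels=STAGE1_FFM["dwt_levels"])
        results = {}
        for fold in folds:
            train = plan.train_indices(fold)
            fL = _lstm_fold_features(
                X, y, train, (150, 100), (0.0, 0.0), lstm_epochs, seed
            )
            features = {"lstm": fL, "cnn": cnn_f, "spectral": spec_f}
            part = _evaluate_problem(
                features, y, plan, [fold], seed, STAGE1_FFM["n_selected"]
            )
            results = _merge_fold_results(results, part)
        report["stage1"] = results

    for stage, task, classes in (
        ("stage2_emotion", "emotion", ("high", "medium", "low")),
        ("stage2_memory", "memory", ("encode", "recall")),
    ):
        if stage not in stages:
            continue
        if verbose:
            print(f"{stage}: building segment problem ...")
        seg_X, seg_y, seg_owner = _segment_problem(conditioned, task)
        if len(seg_X) == 0:
            continue
        seg_cnn = compute_cnn_features(seg_X, encoder)
        seg_spec = compute_spectral_features(seg_X, levels=STAGE2_FFM["dwt_levels"])
        results = {}
        for fold in folds:
            train_sig = set(plan.train_indices(fold).tolist())
            test_sig = set(plan.test_indices[fold].tolist())
            seg_train = np.flatnonzero([o in train_sig for o in seg_owner])
            seg_test = np.flatnonzero([o in test_sig for o in seg_owner])
            if len(seg_train) == 0 or len(seg_test) == 0:
                continue
            fL = _lstm_fold_features(
                seg_X, seg_y, seg_train,
                STAGE2_PRESET["hidden_sizes"], STAGE2_PRESET["dropout"],
                lstm_epochs, seed,
            )
            features = {"lstm": fL, "cnn": seg_cnn, "spectral": seg_spec}
            seg_plan = FoldPlan(k=1, n=len(seg_y), test_indices=[seg_test], mode=plan.mode)
            part = _evaluate_problem(
                features, seg_y, seg_plan, [0], seed, STAGE2_FFM["n_selected"]
            )
            results = _merge_fold_results(results, part)
        report[stage] = results
    return report


def _segment_problem(conditioned: SignalPool, task: str):
    """Sub-phase segment matrix, labels, and owning-signal index per segment."""
    t2 = STAGE2_FFM["input_length"]
    seg_X, seg_y, owner = [], [], []
    for i, sig in enumerate(conditioned):
        if sig.task_label != task:
            continue
        if task == "emotion":
            labels = sig.subphase_labels
            segs = _emotion_segments(sig, len(labels) or 3, t2)
            if len(labels) != len(segs):
                continue
            pairs = zip(segs, labels)
        else:
            pairs = (
                (_condition_segment(seg, t2), label)
                for seg, label in extract_design_segments(sig)
            )
        for values, label in pairs:
            seg_X.append(values)
            seg_y.append(label)
            owner.append(i)
    return np.asarray(seg_X), np.asarray(seg_y), owner


def _merge_fold_results(acc: dict, part: dict) -> dict:
    if not acc:
        return part
    for name, entry in part["metrics"].items():
        if name in acc["metrics"]:
            acc["metrics"][name]["folds"].extend(entry["folds"])
            accs = [m.accuracy for m in acc["metrics"][name]["folds"]]
            acc["metrics"][name]["accuracy"] = float(np.mean(accs))
        else:
            acc["metrics"][name] = entry
    for key, table in part["diversity"].items():
        acc["diversity"][key] = acc["diversity"].get(key, DiversityTable()) + table
    return acc


def report_to_json(report: dict, path) -> None:
    """Serialise an :func:`evaluate_system` report to JSON."""

    def convert(obj):
        if isinstance(obj, MetricsReport):
            return obj.as_dict()
        if isinstance(obj, DiversityTable):
            return obj.as_dict()
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        raise TypeError(f"cannot serialise {type(obj)}")

    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, default=convert)
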