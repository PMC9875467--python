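"""Splitting, cross-validation, confusion-matrix metrics and ranking curves.

The anemic class is positive everywhere. Metrics are the standard
confusion-matrix ratios; two AUC-like quantities are reported side by
side: ``auc_paper_formula`` = (TPR - TNR)/2 — reproduced verbatim from the
source formulation even though it yields 0 for a perfect classifier (an
apparent typo) — and ``balanced_accuracy`` = (TPR + TNR)/2, its plausible
intended reading, plus a genuine trapezoidal ROC AUC from scores.

The 70/10/20 split supports two protocols: ``pooled`` randomly partitions
augmented views (augment-before-split, which lets views of one subject
straddle partitions and leaks identity into the test set) and ``grouped``
keeps all views of a subject in one partition. Comparing the two
quantifies the leakage inflation.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

PARTITIONS = ("train", "val", "test")


@dataclasses.dataclass
class SplitPlan:
    """70/10/20 assignment of pool entries to train/val/test.

    Val and test sizes are floor(frac * N); the remainder goes to train
    (with N = 2635 this yields 1845/263/527 exactly). ``grouped`` mode
    assigns whole patients atomically, so realized sizes can drift
    slightly from the targets (logged).
    """

    train_frac: float = 0.70
    val_frac: float = 0.10
    test_frac: float = 0.20
    mode: str = "pooled"  # pooled | grouped
    seed: int = 0
    assignment: np.ndarray | None = None  # filled by make_split

    def __post_init__(self):
        if not math.isclose(self.train_frac + self.val_frac + self.test_frac, 1.0):
            raise ValueError("split fractions must sum to 1")
        if self.mode not in ("pooled", "grouped"):
            raise ValueError(f"unknown split mode {self.mode!r}")

    def indices(self, partition: str) -> np.ndarray:
        if self.assignment is None:
            raise ValueError("split plan has no assignment yet; call make_split")
        return np.flatnonzero(self.assignment == partition)


def target_sizes(n: int, plan: SplitPlan) -> tuple[int, int, int]:
    """(n_train, n_val, n_test): floor for val/test, remainder to train."""
    n_val = int(np.floor(n * plan.val_frac))
    n_test = int(np.floor(n * plan.test_frac))
    return n - n_val - n_test, n_val, n_test


def make_split(groups, plan: SplitPlan) -> SplitPlan:
    """Assign each pool entry to train/val/test.

    ``groups`` is the per-entry patient id (any sequence; only its length
    matters in pooled mode). Deterministic given the plan's seed.
    """
    groups = np.asarray(groups)
    n = len(groups)
    if n == 0:
        raise ValueError("empty pool")
    n_train, n_val, n_test = target_sizes(n, plan)
    rng = np.random.default_rng(plan.seed)
    assignment = np.empty(n, dtype=object)
    if plan.mode == "pooled":
        order = rng.permutation(n)
        assignment[order[:n_test]] = "test"
        assignment[order[n_test : n_test + n_val]] = "val"
        assignment[order[n_test + n_val :]] = "train"
    else:
        uniq = np.unique(groups)
        rng.shuffle(uniq)
        counts = {pid: int(np.sum(groups == pid)) for pid in uniq}
        filled = {"test": 0, "val": 0}
        targets = {"test": n_test, "val": n_val}
        for pid in uniq:
            part = next(
                (p for p in ("test", "val") if filled[p] < targets[p]), "train"
            )
            assignment[groups == pid] = part
            if part in filled:
                filled[part] += counts[pid]
        for p in ("test", "val"):
            if filled[p] != targets[p]:
                logger.info(
                    "grouped split: %s partition has %d entries (target %d) "
                    "because patients are assigned atomically",
                    p, filled[p], targets[p],
                )
    plan.assignment = assignment
    return plan


@dataclasses.dataclass(frozen=True)
class ConfusionMatrix:
    """TP/TN/FP/FN counts; anemic is the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(labels, predictions) -> ConfusionMatrix:
    """Confusion counts from true and predicted labels (anemic positive).

    Accepts anemic/non_anemic strings or 0/1 integers (1 = anemic).
    """
    from .models import encode_labels

    y = encode_labels(labels)
    p = encode_labels(predictions)
    if len(y) != len(p):
        raise ValueError(f"length mismatch: {len(y)} labels vs {len(p)} predictions")
    return ConfusionMatrix(
        tp=int(np.sum((y == 1) & (p == 1))),
        tn=int(np.sum((y == 0) & (p == 0))),
        fp=int(np.sum((y == 0) & (p == 1))),
        fn=int(np.sum((y == 1) & (p == 0))),
    )


@dataclasses.dataclass(frozen=True)
class MetricReport:
    """Confusion-derived metrics, each in [0, 1].

    ``flags`` lists metrics whose denominator was zero (reported as 0 by
    convention, e.g. F1 = 0 when precision + recall = 0).
    """

    accuracy: float
    specificity: float
    recall: float
    precision: float
    f1: float
    balanced_accuracy: float
    auc_paper_formula: float
    auc_trapezoid: float | None
    flags: tuple = ()

    def as_percent_dict(self, ndigits: int = 2) -> dict:
        out = {}
        for f in dataclasses.fields(self):
            if f.name == "flags":
                continue
            v = getattr(self, f.name)
            out[f.name] = None if v is None else round(100.0 * v, ndigits)
        return out


def _ratio(num: float, den: float, name: str, flags: list) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def metrics(cm: ConfusionMatrix, scores=None, labels=None) -> MetricReport:
    """Evaluate the metric suite on a confusion matrix.

    specificity = TN/(TN+FP); recall = TP/(TP+FN); precision = TP/(TP+FP);
    F1 = 2PR/(P+R); accuracy = (TP+TN)/total; auc_paper_formula =
    (TPR - TNR)/2 (verbatim, degenerate by design); balanced_accuracy =
    (TPR + TNR)/2. If ``scores`` and ``labels`` are given, auc_trapezoid
    is the area under the ROC from a threshold sweep.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    flags: list = []
    specificity = _ratio(cm.tn, cm.tn + cm.fp, "specificity", flags)
    recall = _ratio(cm.tp, cm.tp + cm.fn, "recall", flags)
    precision = _ratio(cm.tp, cm.tp + cm.fp, "precision", flags)
    f1 = _ratio(2 * precision * recall, precision + recall, "f1", flags)
    auc_trap = None
    if scores is not None and labels is not None:
        from .models import encode_labels

        y = encode_labels(labels)
        if len(np.unique(y)) == 2:
            auc_trap = float(roc_auc_score(y, np.asarray(scores, dtype=np.float64)))
        else:
            flags.append("auc_trapezoid")
            auc_trap = 0.0
    return MetricReport(
        accuracy=(cm.tp + cm.tn) / cm.total,
        specificity=specificity,
        recall=recall,
        precision=precision,
        f1=f1,
        balanced_accuracy=(recall + specificity) / 2.0,
        auc_paper_formula=(recall - specificity) / 2.0,
        auc_trapezoid=auc_trap,
        flags=tuple(flags),
    )


def evaluate_predictions(labels, predictions, scores=None) -> MetricReport:
    """Convenience: confusion + metrics in one call."""
    return metrics(confusion(labels, predictions), scores=scores, labels=labels)


def kfold_cv(x, labels, trainer, k: int = 10, seed: int = 0) -> list[MetricReport]:
    """Stratified k-fold cross-validation of a trainer callable.

    ``trainer(x_train, labels_train)`` must return a TrainedModel. Folds
    whose training part lacks a class are skipped with a warning.
    """
    from .models import encode_labels

    x = np.asarray(x)
    y = encode_labels(labels)
    if len(x) < k:
        raise ValueError(f"partition of size {len(x)} cannot be split into {k} folds")
    reports = []
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for fold, (tr, te) in enumerate(skf.split(x, y)):
        if len(np.unique(y[tr])) < 2:
            logger.warning("kfold_cv: fold %d training part is single-class, skipped", fold)
            continue
        model = trainer(x[tr], y[tr])
        pred, score = model.predict(x[te])
        reports.append(metrics(confusion(y[te], pred), scores=score, labels=y[te]))
    return reports


def summarize_reports(reports: list[MetricReport]) -> dict:
    """Mean and sd of each metric across folds."""
    out = {}
    for f in dataclasses.fields(MetricReport):
        if f.name == "flags":
            continue
        vals = [getattr(r, f.name) for r in reports if getattr(r, f.name) is not None]
        if vals:
            out[f.name] = {"mean": float(np.mean(vals)), "sd": float(np.std(vals))}
    return out


def cumulative_gains(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative-gains curve: positives captured in the top-scored fraction.

    Items are sorted by descending score; tied scores share one rank block
    (a single curve point at the block end). Returns (fractions, gains)
    starting at (0, 0) and ending at (1, 1).
    """
    from .models import encode_labels

    s = np.asarray(scores, dtype=np.float64)
    y = encode_labels(labels)
    if len(s) == 0 or len(s) != len(y):
        raise ValueError("scores and labels must be non-empty and aligned")
    n_pos = int(y.sum())
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    # block ends: last index of each tied-score run
    block_end = np.flatnonzero(np.diff(s_sorted) != 0)
    ends = np.concatenate([block_end, [len(s) - 1]])
    cum_pos = np.cumsum(y_sorted)[ends]
    fractions = (ends + 1) / len(s)
    gains = cum_pos / n_pos if n_pos else np.zeros_like(cum_pos, dtype=float)
    return np.concatenate([[0.0], fractions]), np.concatenate([[0.0], gains])


def lift_curve(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    """Lift = gains(f) / f; the undefined f = 0 point is omitted."""
    fractions, gains = cumulative_gains(scores, labels)
    return fractions[1:], gains[1:] / fractions[1:]


def plot_gains_lift(scores, labels, path) -> None:
    """Write a two-panel cumulative-gains / lift SVG (matplotlib, Agg)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    f, g = cumulative_gains(scores, labels)
    fl, lift = lift_curve(scores, labels)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    ax1.plot(f, g, marker=".", label="model")
    ax1.plot([0, 1], [0, 1], "--", color="gray", label="chance")
    ax1.set(xlabel="fraction of items (by score)", ylabel="fraction of anemic captured",
            title="Cumulative gains")
    ax1.legend()
    ax2.plot(fl, lift, marker=".")
    ax2.axhline(1.0, ls="--", color="gray")
    ax2.set(xlabel="fraction of items (by score)", ylabel="lift", title="Lift")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
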