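"""Classifier evaluation: confusion metrics, ROC/PR, cross-validation,
staged embeddings and cohort-comparison statistics.

Conventions: the *Non-Reassuring* class is positive, *Reassuring* negative.
Threshold metrics derive from the 2x2 confusion matrix; rank metrics use the
midrank Mann-Whitney formulation (AUC) and step-wise interpolated precision
(average precision, whose random-ranking baseline equals the positive-class
prevalence).  k-fold results aggregate as mean +/- sample standard deviation
across folds plus an element-wise summed confusion matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import numpy as np
from scipy import stats
from sklearn.manifold import TSNE
from sklearn.model_selection import StratifiedKFold


@dataclass
class ConfusionMatrix:
    """2x2 counts; positive class = Non-Reassuring."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_predictions(cls, y_true: np.ndarray,
                         y_pred: np.ndarray) -> "ConfusionMatrix":
        y_true = np.asarray(y_true, dtype=bool)
        y_pred = np.asarray(y_pred, dtype=bool)
        return cls(tp=int((y_true & y_pred).sum()),
                   fp=int((~y_true & y_pred).sum()),
                   fn=int((y_true & ~y_pred).sum()),
                   tn=int((~y_true & ~y_pred).sum()))

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)


@dataclass
class MetricSet:
    accuracy: float = np.nan
    sensitivity: float = np.nan
    specificity: float = np.nan
    precision: float = np.nan
    f1_positive: float = np.nan
    f1_macro: float = np.nan
    auc: float = np.nan
    average_precision: float = np.nan

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); returning NaN",
                      RuntimeWarning, stacklevel=3)
        return np.nan
    return num / den


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricSet:
    """Threshold-dependent metrics from a 2x2 confusion matrix."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    sens = _ratio(cm.tp, cm.tp + cm.fn, "sensitivity")
    spec = _ratio(cm.tn, cm.tn + cm.fp, "specificity")
    prec = _ratio(cm.tp, cm.tp + cm.fp, "precision")
    f1_pos = _ratio(2 * cm.tp, 2 * cm.tp + cm.fp + cm.fn, "f1_positive")
    # negative-class F1 mirrors the positive one with classes swapped
    f1_neg = _ratio(2 * cm.tn, 2 * cm.tn + cm.fp + cm.fn, "f1_negative")
    return MetricSet(
        accuracy=(cm.tp + cm.tn) / cm.total,
        sensitivity=sens,
        specificity=spec,
        precision=prec,
        f1_positive=f1_pos,
        f1_macro=(f1_pos + f1_neg) / 2,
    )


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve by the midrank Mann-Whitney statistic."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)  # midranks for ties
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def pr_ap(scores: np.ndarray, labels: np.ndarray) -> float:
    """Average precision with step-wise (non-interpolated) precision:
    AP = sum_k (R_k - R_{k-1}) P_k over the score-ranked list."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("no positive samples")
    order = np.argsort(-scores, kind="stable")
    hits = labels[order].astype(float)
    tp = np.cumsum(hits)
    precision = tp / np.arange(1, len(hits) + 1)
    recall = tp / n_pos
    prev_recall = np.concatenate([[0.0], recall[:-1]])
    return float(np.sum((recall - prev_recall) * precision))


def random_baseline_ap(n_pos: int, n_neg: int) -> float:
    """Expected AP of a random ranking: the positive-class prevalence."""
    if n_pos <= 0 or n_neg < 0:
        raise ValueError("need n_pos > 0 and n_neg >= 0")
    return n_pos / (n_pos + n_neg)


def stratified_kfold(labels: np.ndarray, k: int = 5,
                     seed: int = 0) -> np.ndarray:
    """Stratified fold assignment (0..k-1 per sample), reproducible by seed.

    Per-fold class proportions stay within one sample of the global
    proportions.
    """
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"every class needs at least {k} samples")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(labels), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)),
                                                   labels)):
        assignment[test_idx] = fold
    return assignment


@dataclass
class FoldReport:
    per_fold: list
    mean: MetricSet
    sd: MetricSet
    aggregated_confusion: ConfusionMatrix

    def as_dict(self) -> dict:
        return {
            "per_fold": [m.as_dict() for m in self.per_fold],
            "mean": self.mean.as_dict(),
            "sd": self.sd.as_dict(),
            "aggregated_confusion": vars(self.aggregated_confusion),
        }


def aggregate_folds(per_fold: list) -> FoldReport:
    """Aggregate ``[(MetricSet, ConfusionMatrix), ...]`` across folds:
    per-metric mean and sample SD (n-1), plus summed confusion counts."""
    if len(per_fold) < 2:
        raise ValueError("need at least two folds")
    metric_sets = [m for m, _ in per_fold]
    agg_cm = per_fold[0][1]
    for _, cm in per_fold[1:]:
        agg_cm = agg_cm + cm
    mean, sd = MetricSet(), MetricSet()
    for f in fields(MetricSet):
        vals = np.array([getattr(m, f.name) for m in metric_sets], dtype=float)
        setattr(mean, f.name, float(np.mean(vals)))
        setattr(sd, f.name, float(np.std(vals, ddof=1)))
    return FoldReport(per_fold=metric_sets, mean=mean, sd=sd,
                      aggregated_confusion=agg_cm)


def evaluate_scores(scores: np.ndarray, labels: np.ndarray,
                    threshold: float = 0.5) -> tuple[MetricSet, ConfusionMatrix]:
    """Full metric set (threshold + rank based) for scored predictions."""
    labels = np.asarray(labels, dtype=bool)
    cm = ConfusionMatrix.from_predictions(labels,
                                          np.asarray(scores) >= threshold)
    ms = metrics_from_confusion(cm)
    ms.auc = roc_auc(scores, labels)
    ms.average_precision = pr_ap(scores, labels)
    return ms, cm


def staged_embeddings(net, inputs: np.ndarray, seed: int = 0,
                      perplexity: float = 30.0) -> dict:
    """t-SNE 2-D embeddings of features tapped at four network depths.

    Taps: the raw input, the stage-3 and stage-6 backbone outputs, and the
    post-CBAM pooled feature.  Each tap is flattened per sample and reduced
    to 2-D with a fixed seed; perplexity is capped at (n-1)/3.
    """
    from .model.autograd import Tensor

    n = len(inputs)
    if n < 5:
        raise ValueError("too few samples for a t-SNE embedding")
    perplexity = min(perplexity, (n - 1) / 3)
    net.eval()
    feats = {"input": [], "stage3": [], "stage6": [], "pooled": []}
    for start in range(0, n, 32):
        taps = net.forward_features(Tensor(inputs[start:start + 32]))
        for key in feats:
            feats[key].append(taps[key].data.reshape(taps[key].shape[0], -1))
    out = {}
    for key, chunks in feats.items():
        X = np.concatenate(chunks)
        out[key] = TSNE(n_components=2, perplexity=perplexity,
                        random_state=seed, init="pca",
                        max_iter=1000).fit_transform(X)
    return out


@dataclass
class ContinuousRow:
    """Group summaries for Welch's t-test from (n, mean, sd)."""

    name: str
    n1: int
    mean1: float
    sd1: float
    n2: int
    mean2: float
    sd2: float


@dataclass
class CategoricalRow:
    """2x2 counts: ``count`` of the attribute out of ``n`` per group."""

    name: str
    count1: int
    n1: int
    count2: int
    n2: int


@dataclass
class CohortTable:
    rows: list


def cohort_compare(table: CohortTable) -> dict:
    """Per-row p-values comparing two cohorts.

    Continuous rows use Welch's t-test computed from summary statistics;
    categorical 2x2 rows use the continuity-corrected chi-square test.
    """
    pvals = {}
    for row in table.rows:
        if isinstance(row, ContinuousRow):
            if row.sd1 == 0 and row.sd2 == 0:
                raise ValueError(f"zero variance in both groups: {row.name}")
            res = stats.ttest_ind_from_stats(
                row.mean1, row.sd1, row.n1, row.mean2, row.sd2, row.n2,
                equal_var=False)
            pvals[row.name] = float(res.pvalue)
        elif isinstance(row, CategoricalRow):
            contingency = [[row.count1, row.n1 - row.count1],
                           [row.count2, row.n2 - row.count2]]
            res = stats.chi2_contingency(contingency, correction=True)
            pvals[row.name] = float(res.pvalue)
        else:
            raise TypeError(f"unknown row type {type(row).__name__}")
    return pvals
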