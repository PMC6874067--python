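"""Chou-style accuracy metrics and the two evaluation protocols.

Metrics are expressed in the miss-count parameterisation common in PTM
predictor papers: with ``N⁺``/``N⁻`` the class totals, ``N₋⁺`` the
positives predicted negative and ``N₊⁻`` the negatives predicted
positive,

    Sn  = 1 − N₋⁺/N⁺
    Sp  = 1 − N₊⁻/N⁻
    Acc = 1 − (N₋⁺ + N₊⁻)/(N⁺ + N⁻)
    MCC = [1 − (N₋⁺/N⁺ + N₊⁻/N⁻)] /
          sqrt[(1 + (N₊⁻ − N₋⁺)/N⁺)(1 + (N₋⁺ − N₊⁻)/N⁻)]

which is algebraically the standard TP/TN/FP/FN form (checked
exhaustively in the test suite).  A metric whose denominator vanishes
(an empty class, or a degenerate MCC factor) is flagged undefined and
reported as 0/NaN rather than silently absorbed.

Two protocols are provided: *self-consistency* (train and test on the
same dataset — a resubstitution upper bound) and stratified *k-fold
cross-validation* with per-fold refitting of both scaler and model, so
no information leaks from test folds.  The headline CV number is the
unweighted mean of per-fold metrics; pooled-count metrics are reported
alongside.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from .features import featurize
from .model import CrotonylationClassifier
from .windows import BenchmarkDataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    """Class totals and miss counts of one binary evaluation."""

    n_pos: int  # N⁺: positive samples in total
    n_neg: int  # N⁻: negative samples in total
    n_pos_as_neg: int  # N₋⁺: positives predicted negative (misses)
    n_neg_as_pos: int  # N₊⁻: negatives predicted positive (false alarms)

    def __post_init__(self) -> None:
        if not (0 <= self.n_pos_as_neg <= self.n_pos):
            raise ValueError("need 0 <= n_pos_as_neg <= n_pos")
        if not (0 <= self.n_neg_as_pos <= self.n_neg):
            raise ValueError("need 0 <= n_neg_as_pos <= n_neg")

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=int).ravel()
        y_pred = np.asarray(y_pred, dtype=int).ravel()
        if y_true.size != y_pred.size:
            raise ValueError("y_true and y_pred differ in length")
        return cls(
            n_pos=int((y_true == 1).sum()),
            n_neg=int((y_true == 0).sum()),
            n_pos_as_neg=int(((y_true == 1) & (y_pred == 0)).sum()),
            n_neg_as_pos=int(((y_true == 0) & (y_pred == 1)).sum()),
        )

    # Standard confusion-matrix aliases.
    @property
    def tp(self) -> int:
        return self.n_pos - self.n_pos_as_neg

    @property
    def fn(self) -> int:
        return self.n_pos_as_neg

    @property
    def tn(self) -> int:
        return self.n_neg - self.n_neg_as_pos

    @property
    def fp(self) -> int:
        return self.n_neg_as_pos


@dataclass(frozen=True)
class MetricsReport:
    """Sensitivity / specificity / accuracy / MCC plus their counts.

    ``undefined`` lists metrics whose denominator vanished for this
    evaluation (they are reported as NaN, or 0 for MCC per the common
    convention).
    """

    sensitivity: float
    specificity: float
    accuracy: float
    mcc: float
    counts: ConfusionCounts
    protocol: str = ""
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "specificity": self.specificity,
            "sensitivity": self.sensitivity,
            "mcc": self.mcc,
            "counts": vars(self.counts),
            "protocol": self.protocol,
            "undefined": list(self.undefined),
        }


def compute_metrics(counts: ConfusionCounts, protocol: str = "") -> MetricsReport:
    """Evaluate Sn/Sp/Acc/MCC from confusion counts.

    Empty classes leave Sn or Sp (and MCC) undefined; a vanishing MCC
    denominator yields MCC = 0 with an ``undefined`` flag.
    """
    np_, nn = counts.n_pos, counts.n_neg
    miss, alarm = counts.n_pos_as_neg, counts.n_neg_as_pos
    undefined: list[str] = []

    sn = 1.0 - miss / np_ if np_ > 0 else math.nan
    sp = 1.0 - alarm / nn if nn > 0 else math.nan
    if np_ == 0:
        undefined.append("sensitivity")
    if nn == 0:
        undefined.append("specificity")
    if np_ + nn > 0:
        acc = 1.0 - (miss + alarm) / (np_ + nn)
    else:
        acc = math.nan
        undefined.append("accuracy")

    if np_ > 0 and nn > 0:
        numerator = 1.0 - (miss / np_ + alarm / nn)
        f1 = 1.0 + (alarm - miss) / np_
        f2 = 1.0 + (miss - alarm) / nn
        denom_sq = f1 * f2
        if denom_sq > 0:
            mcc = numerator / math.sqrt(denom_sq)
        else:
            mcc = 0.0
            undefined.append("mcc")
    else:
        mcc = 0.0
        undefined.append("mcc")

    return MetricsReport(
        sensitivity=sn,
        specificity=sp,
        accuracy=acc,
        mcc=mcc,
        counts=counts,
        protocol=protocol,
        undefined=tuple(undefined),
    )


def metrics_from_predictions(y_true, y_pred, protocol: str = "") -> MetricsReport:
    return compute_metrics(
        ConfusionCounts.from_predictions(y_true, y_pred), protocol
    )


# ---------------------------------------------------------------------------
# Fold planning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldPlan:
    """A reproducible partition of sample indices into k folds."""

    k: int
    assignments: np.ndarray  # sample index -> fold id
    seed: int
    stratified: bool

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments != fold)


def make_fold_plan(labels, k: int, seed: int) -> FoldPlan:
    """Stratified shuffled k-fold partition (random but reproducible).

    Stratification keeps each fold's class proportions within one
    sample of the global ratio.  When ``k`` exceeds the minority-class
    count (e.g. leave-one-out on a tiny set) the plan degrades to a
    plain shuffled partition, with a logged notice.
    """
    labels = np.asarray(labels, dtype=int).ravel()
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > labels.size:
        raise ValueError(f"k={k} exceeds the sample count {labels.size}")
    min_class = min(int((labels == c).sum()) for c in np.unique(labels))
    stratified = k <= min_class
    if stratified:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        logger.info(
            "k=%d exceeds the minority class size %d: plain partition",
            k, min_class,
        )
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    assignments = np.empty(labels.size, dtype=int)
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros_like(labels), labels)):
        assignments[test_idx] = fold
    return FoldPlan(k=k, assignments=assignments, seed=seed, stratified=stratified)


# ---------------------------------------------------------------------------
# Protocols
# ---------------------------------------------------------------------------

def _resolve_inputs(data, X=None) -> tuple[np.ndarray, np.ndarray]:
    """Accept a BenchmarkDataset or an (X, y) pair."""
    if isinstance(data, BenchmarkDataset):
        if X is not None:
            raise TypeError("pass either a dataset or an (X, y) pair")
        return featurize(data.windows), data.labels
    return np.asarray(data, dtype=float), np.asarray(X, dtype=int).ravel()


def self_consistency(
    data, y=None, classifier: CrotonylationClassifier | None = None,
    seed: int = 1,
) -> MetricsReport:
    """Resubstitution test: train on the full dataset, test on it.

    With the default capacity config this is an interpolation check —
    a sufficiently separable dataset should score 100% on all metrics.
    """
    X, labels = _resolve_inputs(data, y)
    clf = classifier if classifier is not None else CrotonylationClassifier(
        random_state=seed
    )
    clf.fit(X, labels)
    return metrics_from_predictions(
        labels, clf.predict(X), protocol="self-consistency"
    )


@dataclass
class CrossValidationReport:
    """Per-fold metrics plus their unweighted mean and the pooled view."""

    per_fold: list[MetricsReport]
    pooled: MetricsReport  # metrics of summed confusion counts
    plan: FoldPlan
    mean_metrics: dict = field(default_factory=dict)  # headline fold-means

    def as_dict(self) -> dict:
        return {
            "k": self.plan.k,
            "seed": self.plan.seed,
            "stratified": self.plan.stratified,
            "fold_mean": self.mean_metrics,
            "pooled": self.pooled.as_dict(),
            "per_fold": [r.as_dict() for r in self.per_fold],
        }


def kfold_cv(
    data, y=None, k: int = 10, seed: int = 1,
    classifier: CrotonylationClassifier | None = None,
) -> CrossValidationReport:
    """Stratified k-fold cross-validation with per-fold refitting.

    The scaler and network are re-fit from scratch inside every fold on
    the training rows only.  The headline metrics are the unweighted
    mean over folds (NaN-skipping, so leave-one-out folds with an empty
    class do not poison the average); pooled-count metrics are attached
    for comparison.
    """
    X, labels = _resolve_inputs(data, y)
    plan = make_fold_plan(labels, k=k, seed=seed)
    template = classifier if classifier is not None else CrotonylationClassifier()
    per_fold: list[MetricsReport] = []
    for fold in range(k):
        tr, te = plan.train_indices(fold), plan.test_indices(fold)
        clf = template.__class__(**template.get_params())
        if clf.random_state is None:
            clf.set_params(random_state=seed + fold)
        clf.fit(X[tr], labels[tr])
        per_fold.append(
            metrics_from_predictions(
                labels[te], clf.predict(X[te]), protocol=f"cv-fold-{fold}"
            )
        )

    mean_metrics = {
        name: float(
            np.nanmean([getattr(r, name) for r in per_fold])
        )
        for name in ("accuracy", "specificity", "sensitivity", "mcc")
    }
    total = ConfusionCounts(
        n_pos=sum(r.counts.n_pos for r in per_fold),
        n_neg=sum(r.counts.n_neg for r in per_fold),
        n_pos_as_neg=sum(r.counts.n_pos_as_neg for r in per_fold),
        n_neg_as_pos=sum(r.counts.n_neg_as_pos for r in per_fold),
    )
    pooled = compute_metrics(total, protocol=f"cv-pooled-k{k}")
    return CrossValidationReport(
        per_fold=per_fold,
        pooled=pooled,
        plan=plan,
        mean_metrics=mean_metrics,
    )
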