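"""Evaluation machinery for imbalanced multi-class grading experiments.

Covers the statistics layer of a stain-normalization study: the stratified
80/20 train–test split, stratified five-fold cross-validation assignment,
inverse-frequency class weighting ``w_c = N / (N_c · N_sc)``, weighted
categorical cross-entropy, balanced accuracy (macro-averaged recall),
mean ± sample-σ aggregation across models, and the two-sample t-test used
to compare score populations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "LabeledSet",
    "FoldAssignment",
    "EvalReport",
    "ComparisonResult",
    "stratified_split",
    "sffcv_folds",
    "class_weights",
    "wcce_loss",
    "balanced_accuracy",
    "aggregate_scores",
    "two_sample_ttest",
]


@dataclass
class LabeledSet:
    """Identifiers with one categorical label each (ids unique)."""

    ids: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.labels = np.asarray(self.labels)
        if self.ids.shape != self.labels.shape:
            raise ValueError("ids and labels must have equal length")
        if len(np.unique(self.ids)) != len(self.ids):
            raise ValueError("ids must be unique")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def class_counts(self) -> dict:
        values, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(values.tolist(), counts.tolist()))


@dataclass
class FoldAssignment:
    """Fold index (0 … n_folds−1) per id."""

    ids: np.ndarray
    folds: np.ndarray
    n_folds: int

    def fold_ids(self, k: int) -> np.ndarray:
        return self.ids[self.folds == k]


@dataclass
class EvalReport:
    per_class_recall: Mapping
    bac: float
    tp: Mapping
    fn: Mapping
    n: int


@dataclass
class ComparisonResult:
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t_statistic: float
    p_value: float
    test_variant: str
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def stratified_split(
    data: LabeledSet, test_fraction: float = 0.2, seed: int = 123
) -> tuple[LabeledSet, LabeledSet]:
    """Per-class split into train and test.

    The test count of each class is ``round-half-up(test_fraction · N_class)``
    — e.g. class sizes {588, 107, 102, 91} at fraction 0.2 give test counts
    {118, 21, 20, 18}. Membership is shuffled by ``seed``; train and test are
    an exact partition of the input.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in data.classes:
        idx = np.where(data.labels == cls)[0]
        n_test = math.floor(test_fraction * len(idx) + 0.5)
        if n_test == 0:
            warnings.warn(
                f"class {cls!r} too small for a test item at fraction {test_fraction}",
                stacklevel=2,
            )
        perm = rng.permutation(idx)
        test_idx.extend(perm[:n_test].tolist())
        train_idx.extend(perm[n_test:].tolist())
    train_idx.sort()
    test_idx.sort()
    return (
        LabeledSet(ids=data.ids[train_idx], labels=data.labels[train_idx]),
        LabeledSet(ids=data.ids[test_idx], labels=data.labels[test_idx]),
    )


def sffcv_folds(train: LabeledSet, n_folds: int = 5, seed: int = 123) -> FoldAssignment:
    """Stratified k-fold assignment: per class, fold sizes differ by ≤ 1."""
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    for cls, count in train.class_counts().items():
        if count < n_folds:
            warnings.warn(
                f"class {cls!r} has {count} items, fewer than {n_folds} folds",
                stacklevel=2,
            )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = np.empty(len(train), dtype=int)
    x_dummy = np.zeros((len(train), 1))
    for k, (_, val_idx) in enumerate(skf.split(x_dummy, train.labels)):
        folds[val_idx] = k
    return FoldAssignment(ids=train.ids.copy(), folds=folds, n_folds=n_folds)


def class_weights(train: LabeledSet) -> dict:
    """Inverse-frequency weights ``w_c = N / (N_c · N_sc)``.

    N is the set size, N_c the number of classes and N_sc the count of class
    c, so ``w_c · N_sc`` is the same for every class and a balanced set gets
    all-ones.
    """
    counts = train.class_counts()
    if any(v == 0 for v in counts.values()):
        raise ValueError("every class must be non-empty")
    n, n_c = len(train), len(counts)
    return {cls: n / (n_c * n_sc) for cls, n_sc in counts.items()}


def wcce_loss(
    scores: Sequence[float] | np.ndarray,
    true_class: int | Sequence[int],
    weights: Mapping | Sequence[float] | np.ndarray,
    classes: Sequence | None = None,
) -> float:
    """Weighted categorical cross-entropy ``−w_j · ln(softmax(s)_j)``.

    ``scores`` may be one sample's per-class score vector or a batch
    (n × n_classes); the batch loss is the mean over samples. ``weights``
    maps class → weight (or is an array in class order; ``classes`` gives
    the order for mapping inputs, defaulting to sorted keys).
    """
    s = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    single = s.ndim == 1
    if single:
        s = s[None, :]
        true = np.array([true_class])
    else:
        true = np.asarray(true_class)

    if isinstance(weights, Mapping):
        order = list(classes) if classes is not None else sorted(weights)
        w_arr = np.array([weights[c] for c in order], dtype=float)
        idx = np.array([order.index(t) for t in true])
    else:
        w_arr = np.asarray(weights, dtype=float)
        idx = true.astype(int)

    log_p = _log_softmax(s)
    losses = -w_arr[idx] * log_p[np.arange(len(idx)), idx]
    return float(losses.mean())


def _log_softmax(s: np.ndarray) -> np.ndarray:
    shifted = s - s.max(axis=1, keepdims=True)
    return shifted - np.log(np.exp(shifted).sum(axis=1, keepdims=True))


def balanced_accuracy(
    truth: Sequence, pred: Sequence, classes: Sequence | None = None
) -> EvalReport:
    """Balanced accuracy: the unweighted mean of per-class recalls
    ``TP_i / (TP_i + FN_i)`` over the classes present in the truth.

    A declared class absent from the truth is excluded from the mean with a
    warning (its recall is undefined).
    """
    t = np.asarray(truth)
    p = np.asarray(pred)
    if t.shape != p.shape:
        raise ValueError("truth and pred must have equal length")
    declared = np.unique(t) if classes is None else np.asarray(list(classes))
    recalls: dict = {}
    tp: dict = {}
    fn: dict = {}
    for cls in declared:
        mask = t == cls
        if not mask.any():
            warnings.warn(
                f"class {cls!r} absent from truth; excluded from balanced accuracy",
                stacklevel=2,
            )
            continue
        tp_i = int(np.sum(p[mask] == cls))
        fn_i = int(mask.sum()) - tp_i
        tp[cls.item() if hasattr(cls, "item") else cls] = tp_i
        fn[cls.item() if hasattr(cls, "item") else cls] = fn_i
        recalls[cls.item() if hasattr(cls, "item") else cls] = tp_i / (tp_i + fn_i)
    if not recalls:
        raise ValueError("no declared class present in truth")
    bac = float(np.mean(list(recalls.values())))
    return EvalReport(per_class_recall=recalls, bac=bac, tp=tp, fn=fn, n=len(t))


def aggregate_scores(scores: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and sample (n−1) standard deviation of a score set."""
    arr = np.asarray(scores, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 scores for a sample standard deviation")
    return float(arr.mean()), float(arr.std(ddof=1))


def two_sample_ttest(
    a: Sequence[float],
    b: Sequence[float],
    variant: str = "pooled_two_sample",
    alpha: float = 0.05,
) -> ComparisonResult:
    """Two-tailed t-test between two score populations.

    Variants: ``pooled_two_sample`` (classic Student, equal variances),
    ``welch`` (unequal variances), ``paired`` (matched samples, equal
    lengths required).
    """
    av = np.asarray(a, dtype=float)
    bv = np.asarray(b, dtype=float)
    if av.size < 2 or bv.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if variant == "pooled_two_sample":
        res = stats.ttest_ind(av, bv, equal_var=True)
    elif variant == "welch":
        res = stats.ttest_ind(av, bv, equal_var=False)
    elif variant == "paired":
        if av.size != bv.size:
            raise ValueError("paired t-test requires equal-length samples")
        res = stats.ttest_rel(av, bv)
    else:
        raise ValueError(f"unknown t-test variant {variant!r}")
    t_stat, p_val = float(res.statistic), float(res.pvalue)
    if not np.isfinite(t_stat) and np.isclose(av.mean(), bv.mean()):
        # degenerate zero-variance case with equal means: no difference
        t_stat, p_val = 0.0, 1.0
    return ComparisonResult(
        mean_a=float(av.mean()),
        sd_a=float(av.std(ddof=1)),
        mean_b=float(bv.mean()),
        sd_b=float(bv.std(ddof=1)),
        t_statistic=t_stat,
        p_value=p_val,
        test_variant=variant,
        alpha=alpha,
    )
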