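"""Fitness machinery: KNN identification under cross-validation and the
weighted-sum multiobjective score.

A candidate channel subset is scored by (i) how well a k-nearest-neighbour
classifier identifies subjects from the selected channels' AR features under
stratified 10-fold cross-validation, and (ii) how few channels it uses.  The
two objectives are scalarised as

    Fit = W1 * acc + W2 * (1 - n_selected / d),      W1 + W2 = 1,

with defaults W1=0.8, W2=0.2, so Fit lies in [0, 1] and fewer channels are
rewarded at fixed accuracy.

Identification metrics follow the biometric one-vs-rest convention: per
subject c, TA (true acceptance) = correct predictions of c, FA (false
acceptance) = others predicted as c, FR (false rejection) = c predicted as
someone else, TR = the rest; accuracy, recall (sensitivity), precision
(specificity in the biometric naming) and F-score derive from these counts,
macro-averaged over subjects.  The accuracy entering the fitness is the plain
multiclass fraction correct.

Cross-validation is the dominant cost of any wrapper search, so the evaluator
precomputes one squared-distance matrix per channel block; the distance for a
mask is the sum over selected blocks, fed to scikit-learn's KNN with
``metric='precomputed'``.  Reports are memoised by mask bit pattern because
metaheuristics revisit masks constantly.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.model_selection import StratifiedKFold, KFold
from sklearn.neighbors import KNeighborsClassifier

from .features import FeatureTable

__all__ = [
    "ChannelMask",
    "ConfusionCounts",
    "FitnessReport",
    "ObjectiveConfig",
    "confusion_counts",
    "metrics_from_counts",
    "weighted_fitness",
    "FitnessEvaluator",
    "knn_cv_evaluate",
    "exhaustive_best_mask",
]


@dataclass(frozen=True)
class ChannelMask:
    """Binary channel-selection vector; bit c set means channel c is used."""

    bits: tuple[int, ...]

    def __post_init__(self) -> None:
        bits = tuple(int(b) for b in self.bits)
        if not all(b in (0, 1) for b in bits):
            raise ValueError("mask bits must be 0 or 1")
        if sum(bits) == 0:
            raise ValueError("mask must select at least one channel")
        object.__setattr__(self, "bits", bits)

    @classmethod
    def from_indices(cls, indices, d: int) -> "ChannelMask":
        bits = [0] * d
        for i in indices:
            bits[int(i)] = 1
        return cls(tuple(bits))

    @property
    def n_selected(self) -> int:
        return sum(self.bits)

    @property
    def indices(self) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.bits))

    def __len__(self) -> int:
        return len(self.bits)

    def jaccard(self, other: "ChannelMask") -> float:
        a, b = set(self.indices.tolist()), set(other.indices.tolist())
        return len(a & b) / len(a | b)


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest confusion counts for a single class."""

    label: object
    ta: int
    tr: int
    fa: int
    fr: int

    def __post_init__(self) -> None:
        if min(self.ta, self.tr, self.fa, self.fr) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.ta + self.tr + self.fa + self.fr


@dataclass(frozen=True)
class ObjectiveConfig:
    """Weights, classifier and cross-validation settings for the fitness."""

    w1: float = 0.8
    w2: float = 0.2
    k_neighbors: int = 1
    n_folds: int = 10
    fold_seed: int = 0
    stratified: bool = True
    standardize: bool = False

    def __post_init__(self) -> None:
        if self.w1 <= 0 or self.w2 <= 0:
            raise ValueError("weights must be positive")
        if abs(self.w1 + self.w2 - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {self.w1 + self.w2}")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


@dataclass(frozen=True)
class FitnessReport:
    """Scores of one evaluated channel mask.

    ``acc`` is the multiclass fraction correct (displayed x100 as EEG_ACC);
    ``acc_ovr`` the macro-averaged one-vs-rest accuracy; precision, recall and
    F-score are macro one-vs-rest fractions; ``fit`` the weighted objective.
    """

    fit: float
    acc: float
    n_selected: int
    precision: float
    recall: float
    fscore: float
    acc_ovr: float = float("nan")
    counts: tuple[ConfusionCounts, ...] = field(default=(), repr=False)

    def to_record(self) -> str:
        """One-line delimited record: fit,acc,len,precision,recall,fscore."""
        return (
            f"{self.fit:.6f},{self.acc:.6f},{self.n_selected},"
            f"{self.precision:.6f},{self.recall:.6f},{self.fscore:.6f}"
        )

    RECORD_HEADER = "EEG_Fit,EEG_ACC,EEG_Len,EEG_Precision,EEG_Recall,EEG_Fscore"


def confusion_counts(y_true, y_pred, labels=None) -> list[ConfusionCounts]:
    """Per-class one-vs-rest TA/TR/FA/FR counts."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError(f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted")
    if labels is None:
        labels = np.unique(np.concatenate([y_true, y_pred]))
    n = len(y_true)
    out = []
    for c in labels:
        is_c = y_true == c
        pred_c = y_pred == c
        ta = int(np.sum(is_c & pred_c))
        fa = int(np.sum(~is_c & pred_c))
        fr = int(np.sum(is_c & ~pred_c))
        out.append(ConfusionCounts(label=c, ta=ta, fa=fa, fr=fr, tr=n - ta - fa - fr))
    return out


def _safe_ratio(num: float, den: float, what: str, label) -> float:
    if den == 0:
        warnings.warn(f"zero denominator for {what} of class {label!r}; contributing 0")
        return 0.0
    return num / den


def metrics_from_counts(counts: list[ConfusionCounts]) -> dict[str, float]:
    """Macro-averaged accuracy/recall/precision/F-score from one-vs-rest counts.

    Also reports ``acc`` = overall multiclass fraction correct (sum of TA over
    the total prediction count), the single number a biometric system quotes.
    """
    if not counts:
        raise ValueError("no confusion counts supplied")
    accs, recalls, precisions, fscores = [], [], [], []
    for cc in counts:
        accs.append((cc.ta + cc.tr) / cc.total)
        r = _safe_ratio(cc.ta, cc.ta + cc.fr, "recall", cc.label)
        p = _safe_ratio(cc.ta, cc.ta + cc.fa, "precision", cc.label)
        recalls.append(r)
        precisions.append(p)
        fscores.append(2 * r * p / (r + p) if (r + p) > 0 else 0.0)
    recall = float(np.mean(recalls))
    precision = float(np.mean(precisions))
    total = counts[0].total
    return {
        "acc": sum(cc.ta for cc in counts) / total,
        "acc_ovr": float(np.mean(accs)),
        "recall": recall,
        "precision": precision,
        "fscore": 2 * recall * precision / (recall + precision)
        if (recall + precision) > 0
        else 0.0,
        "fscore_per_class_macro": float(np.mean(fscores)),
    }


def weighted_fitness(
    acc: float, n_selected: int, d: int, w1: float = 0.8, w2: float = 0.2
) -> float:
    """Weighted-sum objective W1*acc + W2*(1 - n_selected/d), in [0, 1]."""
    if not 0.0 <= acc <= 1.0:
        raise ValueError(f"accuracy must be in [0, 1], got {acc}")
    if n_selected == 0:
        raise ValueError("n_selected must be >= 1 (repair empty masks upstream)")
    if not 1 <= n_selected <= d:
        raise ValueError(f"n_selected must be in [1, {d}], got {n_selected}")
    if abs(w1 + w2 - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    return w1 * acc + w2 * (1.0 - n_selected / d)


class FitnessEvaluator:
    """Memoising KNN-CV fitness evaluator over a channel-blocked table.

    Folds are fixed at construction (deterministic for a given ``fold_seed``),
    per-channel squared-distance matrices are precomputed once, and reports
    are cached by mask bit pattern.  ``n_evaluations`` counts uncached
    evaluations only.
    """

    def __init__(self, features: FeatureTable, config: ObjectiveConfig):
        self.features = features
        self.config = config
        self._cache: dict[tuple[int, ...], FitnessReport] = {}
        self.n_evaluations = 0

        X = features.matrix
        if config.standardize:
            sd = X.std(axis=0, ddof=0)
            sd[sd == 0] = 1.0
            X = (X - X.mean(axis=0)) / sd
        y = features.subjects
        self.y = y
        self.d = features.n_channels

        labels, counts = np.unique(y, return_counts=True)
        self.labels = labels
        if config.stratified:
            if counts.min() < config.n_folds:
                raise ValueError(
                    f"subject {labels[counts.argmin()]!r} has {counts.min()} rows, "
                    f"fewer than n_folds={config.n_folds}; extract features with "
                    "aggregate='per_recording' or reduce n_folds"
                )
            splitter = StratifiedKFold(
                n_splits=config.n_folds, shuffle=True, random_state=config.fold_seed
            )
        else:
            splitter = KFold(
                n_splits=config.n_folds, shuffle=True, random_state=config.fold_seed
            )
        self.folds = [
            (train, test) for train, test in splitter.split(np.zeros(len(y)), y)
        ]
        # squared Euclidean distance contribution of each channel block
        self._block_dist = np.empty((self.d, len(y), len(y)))
        for c, sl in features.channel_blocks.items():
            self._block_dist[c] = squareform(pdist(X[:, sl], "sqeuclidean"))

    def evaluate(self, mask: ChannelMask) -> FitnessReport:
        if len(mask) != self.d:
            raise ValueError(f"mask length {len(mask)} != {self.d} channels")
        key = mask.bits
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        self.n_evaluations += 1

        D = self._block_dist[mask.indices].sum(axis=0)
        y = self.y
        y_pred = np.empty(len(y), dtype=y.dtype)
        if self.config.k_neighbors == 1:
            # 1-NN fast path: argmin over train columns (ties -> first train
            # row, matching sklearn's behaviour for k=1)
            for train, test in self.folds:
                nearest = np.argmin(D[np.ix_(test, train)], axis=1)
                y_pred[test] = y[train[nearest]]
        else:
            knn = KNeighborsClassifier(
                n_neighbors=self.config.k_neighbors, metric="precomputed"
            )
            for train, test in self.folds:
                knn.fit(D[np.ix_(train, train)], y[train])
                y_pred[test] = knn.predict(D[np.ix_(test, train)])

        counts = confusion_counts(y, y_pred, labels=self.labels)
        m = metrics_from_counts(counts)
        fit = weighted_fitness(
            m["acc"], mask.n_selected, self.d, self.config.w1, self.config.w2
        )
        report = FitnessReport(
            fit=fit,
            acc=m["acc"],
            n_selected=mask.n_selected,
            precision=m["precision"],
            recall=m["recall"],
            fscore=m["fscore"],
            acc_ovr=m["acc_ovr"],
            counts=tuple(counts),
        )
        self._cache[key] = report
        return report


def knn_cv_evaluate(
    features: FeatureTable, mask: ChannelMask, config: ObjectiveConfig
) -> FitnessReport:
    """Score one channel mask by stratified KNN cross-validation."""
    return FitnessEvaluator(features, config).evaluate(mask)


def exhaustive_best_mask(
    features: FeatureTable,
    config: ObjectiveConfig,
    d_max: int = 12,
    evaluator: FitnessEvaluator | None = None,
) -> tuple[ChannelMask, FitnessReport]:
    """Brute-force optimum over all 2^d - 1 nonempty masks (d <= d_max guard).

    Ties are broken toward fewer selected channels, then toward the
    lexicographically smallest bit tuple (so (0,...,0,1) precedes (1,0,...,0)).
    """
    d = features.n_channels
    if d > d_max:
        raise ValueError(f"exhaustive enumeration refused for d={d} > d_max={d_max}")
    if evaluator is None:
        evaluator = FitnessEvaluator(features, config)
    best: tuple[float, int, tuple[int, ...]] | None = None
    best_pair: tuple[ChannelMask, FitnessReport] | None = None
    for bits in itertools.product((0, 1), repeat=d):
        if sum(bits) == 0:
            continue
        mask = ChannelMask(bits)
        report = evaluator.evaluate(mask)
        key = (-report.fit, mask.n_selected, bits)
        if best is None or key < best:
            best = key
            best_pair = (mask, report)
    assert best_pair is not None
    return best_pair
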