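"""Training and repeated-split evaluation of the diagnostic classifier.

The diagnostic model is a soft-margin SVM with an RBF kernel (decision by
the sign of the kernel expansion sum_i y_i alpha_i K(x, x_i) + b), fit by
scikit-learn's SVC. Because raw accuracy is misleading on an imbalanced
syndrome dataset, the evaluation protocol draws a *balanced* test set — by
default ten positive and ten negative patients — leaving the remaining
(still imbalanced) patients as the training set, and repeats this 100 times
with fresh random splits. Sensitivity, specificity, accuracy and G-mean

    g = sqrt(sensitivity * specificity)

are reported per repeat and in aggregate; the G-mean is the balanced metric
of record for the imbalanced setting. Pairwise undersampling, when enabled,
is applied to the majority class of the training split only — the test set
is never resampled.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .dataset_io import SymptomDataset
from .errors import ConfigError, ValidationError
from .undersampling import undersample

__all__ = [
    "ClassifierConfig",
    "EvalConfig",
    "EvaluationResult",
    "split_train_test",
    "train_classifier",
    "evaluate",
    "repeat_protocol",
]


@dataclass(frozen=True)
class ClassifierConfig:
    """RBF-SVM hyperparameters. ``gamma`` follows the 1/n_features
    convention ("auto"); a float fixes the kernel width explicitly."""

    cost: float = 1.0
    gamma: float | str = "auto"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cost <= 0:
            raise ConfigError("cost must be positive")
        if isinstance(self.gamma, (int, float)) and self.gamma <= 0:
            raise ConfigError("kernel width must be positive")


@dataclass(frozen=True)
class EvalConfig:
    """Repeated stratified-split protocol settings."""

    n_repeats: int = 100
    n_pos_test: int = 10
    n_neg_test: int = 10
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    metric: str = "squared_euclidean"
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise ConfigError("n_repeats must be >= 1")
        if self.n_pos_test < 1 or self.n_neg_test < 1:
            raise ConfigError("test composition counts must be >= 1")


@dataclass(frozen=True)
class EvaluationResult:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    g_mean: float

    def as_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "g_mean": self.g_mean,
        }


def split_train_test(
    dataset: SymptomDataset,
    n_pos_test: int = 10,
    n_neg_test: int = 10,
    seed: int = 0,
) -> tuple:
    """Random disjoint exhaustive split with a fixed test composition.

    The test set holds exactly ``n_pos_test`` positives and ``n_neg_test``
    negatives; everything else trains. Both classes must survive in the
    training set.
    """
    pos = np.flatnonzero(dataset.labels == 1)
    neg = np.flatnonzero(dataset.labels == 0)
    if len(pos) <= n_pos_test or len(neg) <= n_neg_test:
        raise ValidationError(
            f"cannot hold out {n_pos_test}+{n_neg_test} from "
            f"{len(pos)} positives / {len(neg)} negatives and still train"
        )
    rng = np.random.default_rng(seed)
    test_idx = np.concatenate(
        [
            rng.choice(pos, size=n_pos_test, replace=False),
            rng.choice(neg, size=n_neg_test, replace=False),
        ]
    )
    test_mask = np.zeros(dataset.n_samples, dtype=bool)
    test_mask[test_idx] = True
    return (
        dataset.subset(np.flatnonzero(~test_mask)),
        dataset.subset(np.flatnonzero(test_mask)),
    )


def train_classifier(X, y, config: ClassifierConfig | None = None) -> SVC:
    """Fit the RBF-kernel soft-margin SVM on (possibly fractional) features."""
    config = config or ClassifierConfig()
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValidationError("training set must contain both classes")
    model = SVC(
        kernel="rbf", C=config.cost, gamma=config.gamma, random_state=config.seed
    )
    model.fit(np.asarray(X, dtype=float), y)
    return model


def evaluate(model, X_test, y_test) -> EvaluationResult:
    """Confusion counts and the four metrics on a held-out test set.

    A rate whose denominator is zero (single-class test set) is reported as
    NaN with a warning, and the G-mean as 0.
    """
    y_test = np.asarray(y_test)
    if y_test.size == 0:
        raise ValidationError("empty test set")
    pred = np.asarray(model.predict(np.asarray(X_test, dtype=float)))
    tp = int(((pred == 1) & (y_test == 1)).sum())
    fp = int(((pred == 1) & (y_test == 0)).sum())
    tn = int(((pred == 0) & (y_test == 0)).sum())
    fn = int(((pred == 0) & (y_test == 1)).sum())
    if tp + fn == 0 or tn + fp == 0:
        warnings.warn("single-class test set: one rate undefined, g_mean set to 0")
    sen = tp / (tp + fn) if tp + fn else math.nan
    spe = tn / (tn + fp) if tn + fp else math.nan
    acc = (tp + tn) / y_test.size
    g = math.sqrt(sen * spe) if not (math.isnan(sen) or math.isnan(spe)) else 0.0
    return EvaluationResult(tp, fp, tn, fn, sen, spe, acc, g)


def _run_single(dataset, config: EvalConfig, seed: int, undersample_threshold):
    train, test = split_train_test(
        dataset, config.n_pos_test, config.n_neg_test, seed=seed
    )
    X, y = train.matrix, train.labels
    if undersample_threshold is not None:
        majority = 1 if train.n_positive >= train.n_negative else 0
        maj_mask = y == majority
        merged, _plan = undersample(
            X[maj_mask],
            undersample_threshold,
            metric=config.metric,
            seed=seed,
        )
        if merged.shape[0] < 2:
            return None
        X = np.vstack([merged, X[~maj_mask]])
        y = np.concatenate(
            [np.full(merged.shape[0], majority), y[~maj_mask]]
        )
    model = train_classifier(X, y, config.classifier)
    return evaluate(model, test.matrix, test.labels)


def repeat_protocol(
    dataset: SymptomDataset,
    config: EvalConfig | None = None,
    undersample_threshold: float | None = None,
    metric: str | None = None,
):
    """Run the split/train/evaluate protocol ``n_repeats`` times.

    Per-repeat seeds are spawned deterministically from ``master_seed``, so
    identical configs reproduce identical aggregates. Both the split and the
    undersampling tie-ranking are refreshed each repeat. Returns a dict with
    ``per_repeat`` (list of per-repeat metric dicts) and ``mean`` /
    ``median`` aggregates, or None if undersampling degenerated the
    training majority class in any repeat.
    """
    config = config or EvalConfig()
    if metric is not None and metric != config.metric:
        config = EvalConfig(
            n_repeats=config.n_repeats,
            n_pos_test=config.n_pos_test,
            n_neg_test=config.n_neg_test,
            classifier=config.classifier,
            metric=metric,
            master_seed=config.master_seed,
        )
    seeds = np.random.SeedSequence(config.master_seed).generate_state(
        config.n_repeats
    ) % (2**31)
    per_repeat = []
    for seed in seeds:
        result = _run_single(dataset, config, int(seed), undersample_threshold)
        if result is None:
            return None
        per_repeat.append(result.as_dict())
    metrics = ("sensitivity", "specificity", "accuracy", "g_mean")
    mean = {
        m: float(np.nanmean([r[m] for r in per_repeat])) for m in metrics
    }
    median = {
        m: float(np.nanmedian([r[m] for r in per_repeat])) for m in metrics
    }
    return {"per_repeat": per_repeat, "mean": mean, "median": median}
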