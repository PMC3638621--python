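"""Information-gain ranking and core-symptom selection.

A symptom X is scored against the syndrome label C by information gain

    IG(C|X) = H(C) - H(C|X)     (base-2 logarithms, bits)

with plug-in (empirical, unsmoothed) probabilities. Severely imbalanced
symptoms — those whose minority value occurs fewer than ``min_minority``
times — are dropped first: their high gains rest on a handful of instances
and do not generalise. Core symptoms are then the symptoms whose gain
strictly exceeds a threshold; the threshold is chosen by a sweep that
trains and evaluates the diagnostic classifier per candidate threshold and
keeps the accuracy-maximising one, breaking ties toward fewer symptoms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset_io import SymptomDataset
from .errors import ValidationError

__all__ = [
    "InformationGainTable",
    "CoreSymptomSet",
    "entropy",
    "conditional_entropy",
    "information_gain",
    "filter_imbalanced_symptoms",
    "rank_symptoms",
    "select_core_symptoms",
    "sweep_ig_thresholds",
]


@dataclass(frozen=True)
class InformationGainTable:
    """Per-symptom gains, sorted non-increasing (ties: lexicographic name)."""

    entries: tuple  # of (symptom_name, gain_bits)

    def __post_init__(self) -> None:
        gains = [g for _, g in self.entries]
        if any(b > a + 1e-12 for a, b in zip(gains, gains[1:])):
            raise ValidationError("entries must be sorted non-increasing by gain")

    def gains(self) -> dict:
        return {name: gain for name, gain in self.entries}

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class CoreSymptomSet:
    symptom_names: tuple
    threshold: float

    def __len__(self) -> int:
        return len(self.symptom_names)


def _entropy_from_counts(counts: np.ndarray) -> float:
    total = counts.sum()
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def entropy(labels) -> float:
    """Empirical Shannon entropy of a discrete vector, in bits (0·log0 = 0)."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValidationError("entropy of an empty vector is undefined")
    _, counts = np.unique(labels, return_counts=True)
    return _entropy_from_counts(counts)


def conditional_entropy(labels, feature) -> float:
    """H(C|X): P(x)-weighted average of within-stratum label entropies."""
    labels = np.asarray(labels)
    feature = np.asarray(feature)
    if labels.shape != feature.shape:
        raise ValidationError(
            f"length mismatch: {labels.shape} labels vs {feature.shape} feature"
        )
    if labels.size == 0:
        raise ValidationError("conditional entropy of empty vectors is undefined")
    n = labels.size
    total = 0.0
    for value in np.unique(feature):
        stratum = labels[feature == value]
        total += (stratum.size / n) * entropy(stratum)
    return total


def information_gain(labels, feature) -> float:
    """IG(C|X) = H(C) - H(C|X); non-negative up to floating error."""
    gain = entropy(labels) - conditional_entropy(labels, feature)
    return max(gain, 0.0)


def filter_imbalanced_symptoms(
    dataset: SymptomDataset, min_minority: int = 5
) -> list:
    """Retain symptoms whose minority value count is at least ``min_minority``.

    A symptom present in (say) all but three patients can reach a high gain
    from those three instances alone; with fewer than ``min_minority``
    minority instances the symptom is removed. Constant symptoms (minority
    count 0) always fail.
    """
    retained = []
    for j, name in enumerate(dataset.symptom_names):
        ones = int(dataset.matrix[:, j].sum())
        minority = min(ones, dataset.n_samples - ones)
        if minority >= min_minority:
            retained.append(name)
    return retained


def rank_symptoms(dataset: SymptomDataset, retained=None) -> InformationGainTable:
    """Information gain of each retained symptom vs the syndrome label.

    Sorted non-increasing by gain; ties broken lexicographically by symptom
    name for determinism.
    """
    if retained is None:
        retained = list(dataset.symptom_names)
    index = {name: j for j, name in enumerate(dataset.symptom_names)}
    unknown = [s for s in retained if s not in index]
    if unknown:
        raise ValidationError(f"unknown symptoms: {unknown}")
    scored = [
        (name, information_gain(dataset.labels, dataset.matrix[:, index[name]]))
        for name in retained
    ]
    scored.sort(key=lambda t: (-t[1], t[0]))
    return InformationGainTable(entries=tuple(scored))


def select_core_symptoms(
    table: InformationGainTable, threshold: float
) -> CoreSymptomSet:
    """Symptoms whose gain strictly exceeds ``threshold``, rank order kept."""
    if threshold < 0:
        raise ValidationError("threshold must be non-negative")
    names = tuple(name for name, gain in table.entries if gain > threshold)
    return CoreSymptomSet(symptom_names=names, threshold=threshold)


def sweep_ig_thresholds(dataset: SymptomDataset, thresholds, eval_config=None):
    """Mean test accuracy of the classifier per gain threshold.

    For each threshold the core-symptom subset is fixed from gains computed
    on the full dataset (as the reference analysis does), then the repeated
    stratified-split protocol of :mod:`zhengkit.diagnostic_eval` is run on
    that subset. Returns ``(results, selected_threshold)`` where results is
    a list of (threshold, n_symptoms, mean_accuracy) and the selection
    maximises accuracy with ties broken toward fewer symptoms. Thresholds
    that leave no symptom are skipped with a warning.
    """
    import warnings

    from .diagnostic_eval import EvalConfig, repeat_protocol

    if not len(list(thresholds)):
        raise ValidationError("thresholds must be non-empty")
    eval_config = eval_config or EvalConfig()
    retained = filter_imbalanced_symptoms(dataset)
    table = rank_symptoms(dataset, retained)
    results = []
    for threshold in thresholds:
        core = select_core_symptoms(table, threshold)
        if len(core) == 0:
            warnings.warn(f"threshold {threshold} leaves no symptoms; skipped")
            continue
        aggregate = repeat_protocol(
            dataset.restrict(core.symptom_names), eval_config
        )
        results.append((float(threshold), len(core), aggregate["mean"]["accuracy"]))
    if not results:
        raise ValidationError("every threshold left an empty symptom set")
    # max accuracy; ties toward fewer symptoms, then lower threshold index
    best = max(results, key=lambda t: (t[2], -t[1]))
    return results, best[0]
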