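"""Pairwise undersampling of the majority class by greedy sample mergence.

The imbalance-correction strategy: over the majority-class training samples
(restricted to the core symptoms), compute all pairwise distances, rank the
pairs ascending (ties permuted by a seeded RNG), then traverse the ranking
once and merge each pair whose distance is within the threshold, provided
neither member has been merged already — each sample is merged at most once
so information loss stays bounded. A merged pair is replaced by its
coordinate-wise mean, which is where fractional symptom values enter the
pipeline.

Distance metric
---------------
The published account describes a Euclidean-style distance but uses integer
thresholds of 8 and 10 on 24 binary core symptoms, where the plain Euclidean
distance cannot exceed sqrt(24) ~ 4.9. The squared Euclidean distance — on
binary vectors, exactly the number of differing coordinates (Hamming count)
— makes those thresholds meaningful and is therefore the default; plain
``euclidean`` is selectable. Every run report records the metric in use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = [
    "MergePlan",
    "pair_distance",
    "rank_pairs",
    "plan_merges",
    "apply_merges",
    "undersample",
    "sweep_distance_thresholds",
]

METRICS = ("squared_euclidean", "euclidean")


@dataclass(frozen=True)
class MergePlan:
    """Disjoint sample pairs selected for mergence.

    Indices refer to the sample array the plan was built from; no index
    appears twice across the plan, and every listed pair's distance is
    within the threshold.
    """

    pairs: tuple  # of (index_a, index_b)
    threshold: float
    metric: str
    seed: int

    def __post_init__(self) -> None:
        flat = [i for pair in self.pairs for i in pair]
        if len(flat) != len(set(flat)):
            raise ValidationError("a sample index appears twice in the merge plan")


def pair_distance(x, y, metric: str = "squared_euclidean") -> float:
    """Distance between two sample vectors under the chosen metric."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError(f"dimension mismatch: {x.shape} vs {y.shape}")
    if metric not in METRICS:
        raise ValidationError(f"unknown metric {metric!r}; expected one of {METRICS}")
    sq = float(((x - y) ** 2).sum())
    return sq if metric == "squared_euclidean" else float(np.sqrt(sq))


def rank_pairs(samples, seed: int = 0, metric: str = "squared_euclidean"):
    """All unordered sample pairs sorted ascending by distance.

    Equal distances are ranked randomly (seeded), as in the reference
    procedure; the output is deterministic given the seed.
    """
    samples = np.asarray(samples, dtype=float)
    n = samples.shape[0]
    if n < 2:
        raise ValidationError("need at least 2 samples to rank pairs")
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    dists = [pair_distance(samples[i], samples[j], metric) for i, j in pairs]
    rng = np.random.default_rng(seed)
    tiebreak = rng.permutation(len(pairs))
    order = sorted(range(len(pairs)), key=lambda k: (dists[k], tiebreak[k]))
    return [(pairs[k], dists[k]) for k in order]


def plan_merges(
    ranked,
    threshold: float,
    metric: str = "squared_euclidean",
    seed: int = 0,
    inclusive: bool = True,
) -> MergePlan:
    """One greedy pass over a ranked pair list.

    A pair enters the plan iff its distance is within the threshold
    (``<=`` by default; strict ``<`` when ``inclusive=False``) and neither
    member already appears in the plan.
    """
    used: set = set()
    chosen = []
    for (i, j), dist in ranked:
        ok = dist <= threshold if inclusive else dist < threshold
        if not ok:
            break  # ranked ascending: nothing further can qualify
        if i in used or j in used:
            continue
        chosen.append((i, j))
        used.update((i, j))
    return MergePlan(
        pairs=tuple(chosen), threshold=float(threshold), metric=metric, seed=seed
    )


def apply_merges(samples, plan: MergePlan) -> np.ndarray:
    """Replace each planned pair by its coordinate-wise mean.

    Unmerged samples pass through unchanged; output has
    ``len(samples) - len(plan.pairs)`` rows (merged means first, in plan
    order, then the untouched samples in original order).
    """
    samples = np.asarray(samples, dtype=float)
    n = samples.shape[0]
    merged_idx = {i for pair in plan.pairs for i in pair}
    if merged_idx and max(merged_idx) >= n:
        raise ValidationError("merge plan refers to samples outside the input")
    means = [samples[[i, j]].mean(axis=0) for i, j in plan.pairs]
    rest = [samples[i] for i in range(n) if i not in merged_idx]
    if not means and not rest:
        return samples[:0]
    return np.vstack(means + rest) if means or rest else samples[:0]


def undersample(
    samples,
    threshold: float,
    metric: str = "squared_euclidean",
    seed: int = 0,
) -> tuple:
    """Rank, plan and apply in one step; returns (merged_samples, plan)."""
    ranked = rank_pairs(samples, seed=seed, metric=metric)
    plan = plan_merges(ranked, threshold, metric=metric, seed=seed)
    return apply_merges(samples, plan), plan


def sweep_distance_thresholds(dataset, core, thresholds, eval_config=None):
    """Mean test accuracy per distance threshold under the repeat protocol.

    For every threshold and repeat: split, undersample the majority class of
    the *training* set only (distances on core symptoms), train, evaluate on
    the untouched test set. Returns ``(results, selected_threshold)`` with
    results a list of (threshold, mean_accuracy, mean_g_mean); the selection
    maximises accuracy. Thresholds that would shrink the majority class
    below 2 samples are skipped with a warning.
    """
    from .diagnostic_eval import EvalConfig, repeat_protocol

    thresholds = list(thresholds)
    if not thresholds:
        raise ValidationError("thresholds must be non-empty")
    eval_config = eval_config or EvalConfig()
    names = getattr(core, "symptom_names", core)
    restricted = dataset.restrict(list(names))
    results = []
    for threshold in thresholds:
        aggregate = repeat_protocol(
            restricted,
            eval_config,
            undersample_threshold=float(threshold),
            metric=eval_config.metric,
        )
        if aggregate is None:
            warnings.warn(
                f"distance threshold {threshold} left < 2 majority samples; skipped"
            )
            continue
        results.append(
            (
                float(threshold),
                aggregate["mean"]["accuracy"],
                aggregate["mean"]["g_mean"],
            )
        )
    if not results:
        raise ValidationError("no distance threshold produced a usable model")
    best = max(results, key=lambda t: t[1])
    return results, best[0]
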