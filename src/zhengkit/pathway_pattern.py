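"""Pathway Pattern mining: frequent pathway itemsets with bidirectional
confidence over gene -> pathway records.

Each relevant gene contributes one record: the set of pathways it belongs
to. The Pathway Pattern is the collection of pathway itemsets that (a) are
frequent — supported by at least ceil(min_support * n_records) records,
where a record supports an itemset iff it contains every pathway of it —
and (b), for itemsets of two or more pathways, admit a bipartition (A, B)
with confidence(A -> B) >= min_confidence in *both* directions, where
confidence(A -> B) = count(A u B) / count(A). Single-pathway itemsets are
support-only entries (confidence is undefined for them). A strict variant
requires every bipartition to pass.

The miner is a level-wise apriori: frequent k-itemsets are joined to
candidate (k+1)-itemsets, pruned by downward closure, and counted against
the records. Output is deterministically ordered by (size, -count,
lexicographic items).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

from .errors import PipelineError, ValidationError

__all__ = [
    "PathwayRecordSet",
    "PathwayPattern",
    "build_pathway_records",
    "read_gene_pathway_mapping",
    "min_support_count",
    "mine_frequent_itemsets",
    "apply_bidirectional_confidence",
    "mine_pathway_pattern",
    "assign_symbols",
]


@dataclass(frozen=True)
class PathwayRecordSet:
    """One non-empty pathway set per annotated gene."""

    records: dict  # gene id -> frozenset of pathway ids
    n_unannotated: int = 0

    def __post_init__(self) -> None:
        empty = [g for g, s in self.records.items() if not s]
        if empty:
            raise ValidationError(f"empty pathway records for genes: {empty}")

    @property
    def n_records(self) -> int:
        return len(self.records)

    def support_count(self, itemset: frozenset) -> int:
        return sum(1 for s in self.records.values() if itemset <= s)


@dataclass(frozen=True)
class PathwayPattern:
    """Retained itemsets with supporting counts and the thresholds used.

    ``itemsets`` is a tuple of (frozenset of pathway ids, count, support
    fraction), ordered by (size, -count, sorted items).
    """

    itemsets: tuple
    min_support: float
    min_confidence: float
    n_records: int

    def __len__(self) -> int:
        return len(self.itemsets)

    def by_size(self) -> dict:
        sizes: dict[int, list] = {}
        for itemset, count, support in self.itemsets:
            sizes.setdefault(len(itemset), []).append((itemset, count, support))
        return sizes

    def maximal_itemsets(self) -> list:
        sets = [s for s, _c, _f in self.itemsets]
        return [s for s in sets if not any(s < other for other in sets)]


def read_gene_pathway_mapping(path) -> dict:
    """Read gene -> pathway set from a two-column TSV or a GMT file.

    TSV: one (gene id, pathway id) pair per line, optional header. GMT
    (suffix ``.gmt``): one pathway per line — name, description, then member
    genes — transposed into per-gene pathway sets.
    """
    from pathlib import Path

    path = Path(path)
    mapping: dict[str, set] = {}
    if path.suffix.lower() == ".gmt":
        for line in path.read_text().splitlines():
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            pathway, _desc, *genes = fields
            for gene in genes:
                if gene:
                    mapping.setdefault(gene, set()).add(pathway)
    else:
        for i, line in enumerate(path.read_text().splitlines()):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                continue
            gene, pathway = fields[0], fields[1]
            if i == 0 and (gene.lower().startswith("gene") or pathway.lower().startswith("pathway")):
                continue
            mapping.setdefault(gene, set()).add(pathway)
    return {g: frozenset(s) for g, s in mapping.items()}


def build_pathway_records(genes, gene_to_pathways: dict) -> PathwayRecordSet:
    """One record per gene that has pathway annotation.

    Genes without any pathway are excluded and counted separately; an
    entirely unannotated gene list is a pipeline error.
    """
    records = {}
    unannotated = 0
    for gene in genes:
        pathways = gene_to_pathways.get(gene)
        if pathways:
            records[gene] = frozenset(pathways)
        else:
            unannotated += 1
    if not records:
        raise PipelineError("no gene in the list has pathway annotation")
    return PathwayRecordSet(records=records, n_unannotated=unannotated)


def min_support_count(n_records: int, min_support: float) -> int:
    """Smallest count c with c / n_records >= min_support."""
    if n_records < 1:
        raise ValidationError("n_records must be >= 1")
    if not 0 < min_support <= 1:
        raise ValidationError("min_support must lie in (0, 1]")
    return math.ceil(min_support * n_records - 1e-9)


def mine_frequent_itemsets(records: PathwayRecordSet, min_support: float) -> list:
    """All frequent itemsets (size >= 1) with their supporting counts.

    Level-wise apriori search; returns (itemset, count) sorted by
    (size, -count, lexicographic items). Downward closure holds on the
    output by construction.
    """
    threshold = min_support_count(records.n_records, min_support)
    item_counts: dict[frozenset, int] = {}
    for record in records.records.values():
        for item in record:
            key = frozenset((item,))
            item_counts[key] = item_counts.get(key, 0) + 1
    frequent = {k: c for k, c in item_counts.items() if c >= threshold}
    all_frequent = dict(frequent)
    level = frequent
    while level:
        items = sorted({i for s in level for i in s})
        candidates = set()
        level_keys = set(level)
        for a, b in combinations(sorted(level_keys, key=sorted), 2):
            union = a | b
            if len(union) != len(next(iter(level_keys))) + 1:
                continue
            # downward-closure prune: every k-subset must be frequent
            if all(
                frozenset(sub) in level_keys
                for sub in combinations(union, len(union) - 1)
            ):
                candidates.add(union)
        next_level = {}
        for cand in candidates:
            count = records.support_count(cand)
            if count >= threshold:
                next_level[cand] = count
        all_frequent.update(next_level)
        level = next_level
    return sorted(
        all_frequent.items(), key=lambda kv: (len(kv[0]), -kv[1], sorted(kv[0]))
    )


def apply_bidirectional_confidence(
    itemsets,
    records: PathwayRecordSet,
    min_confidence: float,
    min_support: float = 0.0,
    strategy: str = "any_bipartition",
) -> PathwayPattern:
    """Retain itemsets whose association rules hold in both directions.

    ``itemsets`` is the (itemset, count) output of the miner. A size-1
    itemset passes unconditionally. A larger itemset passes iff some
    bipartition (A, B) of it has confidence(A -> B) and confidence(B -> A)
    both >= min_confidence; with ``strategy="all_bipartitions"`` every
    bipartition must pass.
    """
    if strategy not in ("any_bipartition", "all_bipartitions"):
        raise ValidationError(f"unknown strategy {strategy!r}")
    counts = dict(itemsets)
    kept = []
    n = records.n_records
    for itemset, count in itemsets:
        if len(itemset) == 1:
            kept.append((itemset, count, count / n))
            continue
        verdicts = []
        for r in range(1, len(itemset)):
            for a in combinations(sorted(itemset), r):
                count_a = counts.get(frozenset(a), records.support_count(frozenset(a)))
                b = itemset - frozenset(a)
                count_b = counts.get(frozenset(b), records.support_count(frozenset(b)))
                ok = (
                    count / count_a >= min_confidence
                    and count / count_b >= min_confidence
                )
                verdicts.append(ok)
        passed = any(verdicts) if strategy == "any_bipartition" else all(verdicts)
        if passed:
            kept.append((itemset, count, count / n))
    kept.sort(key=lambda t: (len(t[0]), -t[1], sorted(t[0])))
    return PathwayPattern(
        itemsets=tuple(kept),
        min_support=min_support,
        min_confidence=min_confidence,
        n_records=n,
    )


def mine_pathway_pattern(
    records: PathwayRecordSet,
    min_support: float = 0.055,
    min_confidence: float = 0.800,
    strategy: str = "any_bipartition",
) -> PathwayPattern:
    """Full mining step at the reference thresholds (support 0.055,
    confidence 0.800)."""
    frequent = mine_frequent_itemsets(records, min_support)
    return apply_bidirectional_confidence(
        frequent, records, min_confidence, min_support=min_support, strategy=strategy
    )


def assign_symbols(pattern: PathwayPattern) -> dict:
    """Label itemsets 1a, 1b, ... 2a, ... by (size, -count, items) order,
    the labelling convention of the reference pattern table."""
    labels = {}
    by_size = pattern.by_size()
    for size in sorted(by_size):
        for i, (itemset, _count, _f) in enumerate(by_size[size]):
            suffix = ""
            k = i
            while True:
                suffix = chr(ord("a") + k % 26) + suffix
                k = k // 26 - 1
                if k < 0:
                    break
            labels[itemset] = f"{size}{suffix}"
    return labels
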