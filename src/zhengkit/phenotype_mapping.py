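"""Symptom-to-phenotype-term mapping and relevant-gene collection.

Core clinical symptoms are bridged to genes through a phenotype ontology
(e.g. the Human Phenotype Ontology): each symptom is matched, by
case-insensitive substring search of user-supplied keywords against term
names and synonyms, to a list of ontology terms; term-associated genes are
then collected and each gene scored by its *occurrence* — the number of
distinct mapped terms (de-duplicated across symptoms) whose association set
contains it. Genes occurring fewer than ``min_occurrence`` times (default 3)
are regarded as occasional and dropped; the survivors form the relevant-gene
set on which all downstream pathway analysis rests.

Some symptoms — classically the pulse- and fur-related observations of TCM
diagnosis — have no ontology counterpart; they are carried through reports
as unmapped rather than raised as errors.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import ValidationError

__all__ = [
    "OntologyIndex",
    "SymptomTermMap",
    "GeneOccurrenceTable",
    "RelevantGeneSet",
    "parse_ontology",
    "match_symptom_terms",
    "map_symptoms",
    "read_term_gene_associations",
    "collect_gene_occurrences",
    "filter_relevant_genes",
]

_TERM_ID = re.compile(r"^[A-Za-z]+:\d+$")


@dataclass(frozen=True)
class OntologyIndex:
    """Searchable id -> (name, synonyms) index over non-obsolete terms."""

    terms: dict  # id -> (name, tuple of synonyms)

    def __len__(self) -> int:
        return len(self.terms)

    def search(self, keyword: str) -> list:
        """Term ids whose name or any synonym contains ``keyword``
        (case-insensitive substring), sorted by id."""
        needle = keyword.lower()
        hits = [
            term_id
            for term_id, (name, synonyms) in self.terms.items()
            if needle in name.lower()
            or any(needle in s.lower() for s in synonyms)
        ]
        return sorted(hits)


@dataclass(frozen=True)
class SymptomTermMap:
    """symptom -> list of (term_id, term_name); empty list = unmapped."""

    mapping: dict

    def __post_init__(self) -> None:
        for symptom, terms in self.mapping.items():
            ids = [t[0] for t in terms]
            if len(ids) != len(set(ids)):
                raise ValidationError(f"duplicate term ids under {symptom!r}")
            bad = [i for i in ids if not _TERM_ID.match(i)]
            if bad:
                raise ValidationError(f"malformed term ids under {symptom!r}: {bad}")

    def distinct_term_ids(self) -> list:
        """All mapped term ids with duplicates across symptoms collapsed."""
        return sorted({t[0] for terms in self.mapping.values() for t in terms})

    def unmapped_symptoms(self) -> list:
        return sorted(s for s, terms in self.mapping.items() if not terms)


@dataclass(frozen=True)
class GeneOccurrenceTable:
    """gene id -> number of distinct mapped terms associating the gene."""

    counts: dict
    symbols: dict  # gene id -> display symbol

    def ranked(self) -> list:
        """(gene, count) sorted by descending count, then gene id."""
        return sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))


@dataclass(frozen=True)
class RelevantGeneSet:
    genes: tuple  # ordered by (-occurrence, gene id)
    min_occurrence: int

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)


def _synonym_text(raw: str) -> str:
    # OBO synonym lines quote the text: synonym: "Drowsiness" EXACT []
    m = re.search(r'"(.*)"', raw)
    return m.group(1) if m else raw


def parse_ontology(obo_path: str | Path) -> OntologyIndex:
    """Parse an OBO file into a searchable index (obsolete terms excluded)."""
    import obonet

    graph = obonet.read_obo(str(obo_path), ignore_obsolete=True)
    terms = {}
    for term_id, data in graph.nodes(data=True):
        name = data.get("name", "")
        synonyms = tuple(_synonym_text(s) for s in data.get("synonym", ()))
        terms[term_id] = (name, synonyms)
    return OntologyIndex(terms=terms)


def match_symptom_terms(symptom: str, keywords, index: OntologyIndex) -> list:
    """Ontology terms matching any keyword; de-duplicated, ordered by id.

    An empty result is legitimate (the symptom is recorded as unmapped).
    """
    if not keywords:
        raise ValidationError(f"no keywords supplied for symptom {symptom!r}")
    hits: set = set()
    for keyword in keywords:
        hits.update(index.search(keyword))
    return [(term_id, index.terms[term_id][0]) for term_id in sorted(hits)]


def map_symptoms(symptom_keywords: dict, index: OntologyIndex) -> SymptomTermMap:
    """Apply :func:`match_symptom_terms` to every symptom in the config."""
    mapping = {
        symptom: match_symptom_terms(symptom, keywords, index)
        for symptom, keywords in symptom_keywords.items()
    }
    unmapped = [s for s, t in mapping.items() if not t]
    if unmapped:
        warnings.warn(f"{len(unmapped)} symptoms left unmapped: {unmapped}")
    return SymptomTermMap(mapping=mapping)


def read_term_gene_associations(path: str | Path) -> dict:
    """Read a phenotype-to-genes TSV into term id -> {gene id -> symbol}.

    Expects at least the columns (term id, term name, gene id, gene symbol)
    in that order, tolerant of extra columns and of a comment/header line.
    """
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if frame.shape[1] < 4:
        raise ValidationError(
            "association table needs >= 4 columns: term id, term name, "
            "gene id, gene symbol"
        )
    assoc: dict[str, dict] = {}
    for term_id, _name, gene_id, symbol in frame.iloc[:, :4].itertuples(index=False):
        assoc.setdefault(str(term_id), {})[str(gene_id)] = str(symbol)
    return assoc


def collect_gene_occurrences(
    term_map: SymptomTermMap, assoc: dict
) -> GeneOccurrenceTable:
    """Count, per gene, the distinct mapped terms that associate it.

    Terms are de-duplicated across symptoms before counting, so a term
    shared by two symptoms contributes once. Terms absent from the
    association table are logged and skipped.
    """
    term_ids = term_map.distinct_term_ids()
    if not term_ids:
        raise ValidationError("term map contains no mapped terms")
    missing = [t for t in term_ids if t not in assoc]
    if missing:
        warnings.warn(f"{len(missing)} mapped terms lack gene associations")
    counts: dict[str, int] = {}
    symbols: dict[str, str] = {}
    for term_id in term_ids:
        for gene_id, symbol in assoc.get(term_id, {}).items():
            counts[gene_id] = counts.get(gene_id, 0) + 1
            symbols.setdefault(gene_id, symbol)
    return GeneOccurrenceTable(counts=counts, symbols=symbols)


def filter_relevant_genes(
    occ: GeneOccurrenceTable, min_occurrence: int = 3
) -> RelevantGeneSet:
    """Keep genes occurring at least ``min_occurrence`` times.

    Ordering is (-occurrence, gene id) for reproducibility. An empty result
    is returned with a warning rather than raised.
    """
    kept = [
        gene for gene, count in occ.ranked() if count >= min_occurrence
    ]
    if not kept:
        warnings.warn("no gene passed the occurrence filter")
    return RelevantGeneSet(genes=tuple(kept), min_occurrence=min_occurrence)
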