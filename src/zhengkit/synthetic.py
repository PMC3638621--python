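"""Synthetic symptom datasets and annotation fixtures.

The clinical dataset behind the reference study (166 acute ischemic stroke
patients, 120 positive for wind-phlegm collateral obstruction syndrome,
46 negative, 102 binary symptoms) is not publicly deposited. This module
generates datasets with the same statistical shape so every pipeline stage
is testable offline:

* class counts and the ~2.6:1 imbalance are configurable and default to the
  published counts;
* a minority of "informative" symptoms carry class signal (class-conditional
  Bernoulli rates), the rest are class-independent noise;
* optionally, a few "severely imbalanced" symptoms (minority value count
  below 5) exercise the minority-count filter.

Symptoms are class-conditionally independent: no attempt is made to emulate
real symptom co-occurrence structure.

For the molecular level, :func:`simulate_annotation_fixture` builds a small
ontology / term-gene / gene-pathway universe with a planted gene cluster
sharing a common pathway itemset, so pattern mining has a known recoverable
signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dataset_io import SymptomDataset
from .errors import ConfigError

__all__ = [
    "SimulationConfig",
    "AnnotationFixture",
    "simulate_dataset",
    "simulate_annotation_fixture",
    "write_annotation_fixture",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Generative settings for a binary symptom dataset.

    Defaults reproduce the published data shape: 120 positive / 46 negative
    patients, 102 symptoms of which 24 (the published core-symptom count)
    are informative. Informative symptoms are Bernoulli(p_informative_pos)
    in positives and Bernoulli(p_informative_neg) in negatives; noise
    symptoms are Bernoulli(p_noise) regardless of class. Effect sizes
    default to 0.8 vs 0.2 so planted gains dominate sampling noise at
    n = 166. ``n_severe`` appends class-independent symptoms whose minority
    count is forced below 5 to exercise the imbalanced-symptom filter.
    """

    n_positive: int = 120
    n_negative: int = 46
    n_symptoms: int = 102
    n_informative: int = 24
    p_informative_pos: float = 0.8
    p_informative_neg: float = 0.2
    p_noise: float = 0.5
    n_severe: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_informative_pos", "p_informative_neg", "p_noise"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name}={p} outside [0, 1]")
        for name in ("n_positive", "n_negative", "n_symptoms"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not 0 <= self.n_informative <= self.n_symptoms:
            raise ConfigError("n_informative must lie in [0, n_symptoms]")
        if self.n_severe < 0:
            raise ConfigError("n_severe must be non-negative")

    @property
    def informative_symptoms(self) -> tuple:
        return tuple(f"symptom_{j + 1:03d}" for j in range(self.n_informative))


def simulate_dataset(config: SimulationConfig) -> SymptomDataset:
    """Draw a symptom dataset under ``config``; deterministic given its seed.

    Columns 1..n_informative are informative (``config.informative_symptoms``
    names them), the remainder noise; ``n_severe`` extra severely imbalanced
    columns are appended after the noise block. Positive samples come first.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_positive + config.n_negative
    labels = np.concatenate(
        [np.ones(config.n_positive, int), np.zeros(config.n_negative, int)]
    )
    matrix = np.empty((n, config.n_symptoms + config.n_severe))
    k = config.n_informative
    pos = labels == 1
    matrix[pos, :k] = rng.random((config.n_positive, k)) < config.p_informative_pos
    matrix[~pos, :k] = rng.random((config.n_negative, k)) < config.p_informative_neg
    matrix[:, k : config.n_symptoms] = (
        rng.random((n, config.n_symptoms - k)) < config.p_noise
    )
    for j in range(config.n_severe):
        col = np.zeros(n)
        minority = rng.integers(0, 5)  # strictly below the default filter cutoff
        col[rng.choice(n, size=minority, replace=False)] = 1
        matrix[:, config.n_symptoms + j] = col
    names = [f"symptom_{j + 1:03d}" for j in range(config.n_symptoms)]
    names += [f"severe_{j + 1:03d}" for j in range(config.n_severe)]
    return SymptomDataset(
        sample_ids=tuple(f"P{i + 1:04d}" for i in range(n)),
        symptom_names=tuple(names),
        matrix=matrix,
        labels=labels,
    )


@dataclass(frozen=True)
class AnnotationFixture:
    """In-memory ontology + association universe with planted structure.

    ``ontology`` maps term id -> (name, synonyms tuple, parent ids tuple);
    ``term_to_genes`` maps term id -> frozenset of gene ids;
    ``gene_to_pathways`` maps gene id -> frozenset of pathway ids (genes
    without annotation are simply absent). ``planted_genes`` /
    ``planted_itemset`` expose the recoverable pattern-mining signal: every
    planted gene is annotated to every pathway of the planted itemset.
    """

    ontology: dict
    term_to_genes: dict
    gene_to_pathways: dict
    planted_genes: frozenset
    planted_itemset: frozenset
    symptom_keywords: dict = field(default_factory=dict)


def simulate_annotation_fixture(
    n_symptoms: int = 24,
    n_terms: int = 43,
    n_genes: int = 159,
    n_pathways: int = 30,
    n_planted_genes: int = 11,
    planted_itemset_size: int = 4,
    mean_pathways_per_gene: float = 3.0,
    mean_terms_per_symptom: float = 2.0,
    mean_genes_per_term: float = 25.0,
    seed: int = 0,
) -> AnnotationFixture:
    """Build a synthetic annotation universe; deterministic given seed.

    Defaults mirror the reference study's molecular layer: 24 core symptoms,
    43 ontology terms, 159 pathway-annotated genes, and a planted cluster of
    11 genes all sharing one 4-pathway itemset (so mining at support 0.055
    over 159 records must recover it with count 11).
    """
    for name, v in [
        ("n_symptoms", n_symptoms),
        ("n_terms", n_terms),
        ("n_genes", n_genes),
        ("n_pathways", n_pathways),
        ("n_planted_genes", n_planted_genes),
        ("planted_itemset_size", planted_itemset_size),
    ]:
        if v <= 0:
            raise ConfigError(f"{name} must be positive")
    if n_planted_genes > n_genes:
        raise ConfigError("planted cluster larger than gene universe")
    if planted_itemset_size > n_pathways:
        raise ConfigError("planted itemset larger than pathway universe")
    rng = np.random.default_rng(seed)

    pathways = [f"path:{i + 1:05d}" for i in range(n_pathways)]
    genes = [f"G{i + 1:04d}" for i in range(n_genes)]
    terms = [f"SY:{i + 1:07d}" for i in range(n_terms)]
    symptoms = [f"symptom_{i + 1:03d}" for i in range(n_symptoms)]

    planted_itemset = frozenset(pathways[:planted_itemset_size])
    planted_genes = frozenset(genes[:n_planted_genes])

    gene_to_pathways: dict[str, frozenset] = {}
    other_pathways = pathways[planted_itemset_size:]
    for i, gene in enumerate(genes):
        extra = min(rng.poisson(mean_pathways_per_gene), len(other_pathways))
        drawn = set(rng.choice(other_pathways, size=extra, replace=False))
        if gene in planted_genes:
            drawn |= planted_itemset
        elif not drawn:
            drawn = {other_pathways[int(rng.integers(len(other_pathways)))]}
        gene_to_pathways[gene] = frozenset(drawn)

    # ontology: a flat tree under a synthetic root, one synonym per term
    ontology = {"SY:0000000": ("clinical sign root", (), ())}
    for i, term in enumerate(terms):
        name = f"finding {i + 1:03d}"
        synonyms = (f"sign {i + 1:03d}",)
        ontology[term] = (name, synonyms, ("SY:0000000",))

    term_to_genes = {}
    for term in terms:
        size = max(1, min(rng.poisson(mean_genes_per_term), n_genes))
        term_to_genes[term] = frozenset(rng.choice(genes, size=size, replace=False))
    # guarantee the planted genes recur across enough terms to pass the
    # occurrence filter (count >= 3) regardless of the random draws
    for gene in sorted(planted_genes):
        for term in terms[:3]:
            term_to_genes[term] = term_to_genes[term] | {gene}

    # each symptom points at >= 1 term via the term's name as keyword
    symptom_keywords: dict[str, list] = {}
    for i, symptom in enumerate(symptoms):
        k = max(1, min(rng.poisson(mean_terms_per_symptom), n_terms))
        chosen = sorted(rng.choice(terms, size=k, replace=False))
        if i < 3:  # anchor symptoms to the occurrence-boosted terms
            chosen = sorted(set(chosen) | {terms[i]})
        symptom_keywords[symptom] = [ontology[t][0] for t in chosen]

    return AnnotationFixture(
        ontology=ontology,
        term_to_genes=term_to_genes,
        gene_to_pathways=gene_to_pathways,
        planted_genes=planted_genes,
        planted_itemset=planted_itemset,
        symptom_keywords=symptom_keywords,
    )


def write_annotation_fixture(fixture: AnnotationFixture, outdir: str | Path) -> dict:
    """Serialise a fixture to the pipeline's on-disk input formats.

    Writes ``ontology.obo`` (OBO 1.2), ``term_to_genes.tsv`` (term id, term
    name, gene id, gene symbol), ``gene_to_pathways.tsv`` (gene id, pathway
    id; one pair per line) and ``symptom_keywords.yaml``. Returns the paths.
    """
    import yaml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    obo = outdir / "ontology.obo"
    lines = ["format-version: 1.2", "ontology: synthetic-signs", ""]
    for term_id, (name, synonyms, parents) in fixture.ontology.items():
        lines += ["[Term]", f"id: {term_id}", f"name: {name}"]
        lines += [f'synonym: "{s}" EXACT []' for s in synonyms]
        lines += [f"is_a: {p}" for p in parents]
        lines.append("")
    obo.write_text("\n".join(lines))

    t2g = outdir / "term_to_genes.tsv"
    with t2g.open("w") as fh:
        fh.write("hpo_id\thpo_name\tgene_id\tgene_symbol\n")
        for term in sorted(fixture.term_to_genes):
            name = fixture.ontology[term][0]
            for gene in sorted(fixture.term_to_genes[term]):
                fh.write(f"{term}\t{name}\t{gene}\t{gene}\n")

    g2p = outdir / "gene_to_pathways.tsv"
    with g2p.open("w") as fh:
        fh.write("gene_id\tpathway_id\n")
        for gene in sorted(fixture.gene_to_pathways):
            for pathway in sorted(fixture.gene_to_pathways[gene]):
                fh.write(f"{gene}\t{pathway}\n")

    kw = outdir / "symptom_keywords.yaml"
    kw.write_text(
        yaml.safe_dump(
            {s: list(v) for s, v in fixture.symptom_keywords.items()},
            sort_keys=True,
        )
    )
    return {
        "ontology": obo,
        "term_to_genes": t2g,
        "gene_to_pathways": g2p,
        "symptom_keywords": kw,
    }
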