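"""End-to-end orchestration of the two-level analysis.

Level 1 (diagnostic): filter severely imbalanced symptoms, rank the rest by
information gain, sweep gain thresholds to pick the core symptoms, sweep
distance thresholds for pairwise undersampling, and report the repeated
split evaluation (sensitivity / specificity / accuracy / G-mean) with and
without undersampling.

Level 2 (molecular): map core symptoms to ontology terms via keyword
search, collect and filter term-associated genes by occurrence, mine the
Pathway Pattern from gene pathway records, build and prune the
symptom-gene-itemset multilayer network, and rank pathway
over-representation of the relevant genes.

Every random draw descends from one master seed; re-running an identical
config reproduces a byte-identical JSON report (no timestamps are stored).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .dataset_io import read_symptom_table, write_symptom_table
from .diagnostic_eval import ClassifierConfig, EvalConfig, repeat_protocol
from .enrichment import rank_enriched_pathways
from .errors import ConfigError
from .feature_selection import (
    filter_imbalanced_symptoms,
    rank_symptoms,
    select_core_symptoms,
    sweep_ig_thresholds,
)
from .network_builder import (
    build_multilayer_network,
    export_network,
    layer_nodes,
    prune_incomplete_paths,
)
from .pathway_pattern import (
    assign_symbols,
    build_pathway_records,
    mine_pathway_pattern,
    read_gene_pathway_mapping,
)
from .phenotype_mapping import (
    collect_gene_occurrences,
    filter_relevant_genes,
    map_symptoms,
    parse_ontology,
    read_term_gene_associations,
)
from .undersampling import sweep_distance_thresholds

__all__ = ["PipelineConfig", "run_all"]

log = logging.getLogger("zhengkit")

DEFAULT_IG_THRESHOLDS = (0.0, 0.002, 0.004, 0.008, 0.016)
DEFAULT_DISTANCE_THRESHOLDS = (2.0, 4.0, 6.0, 8.0, 10.0)


@dataclass(frozen=True)
class PipelineConfig:
    """All paths and thresholds of the two-level run.

    Defaults are the reference study's published settings: minority-count
    filter 5, 10+10 balanced test sets over 100 repeated splits, gene
    occurrence filter 3, itemset mining at support 0.055 / confidence 0.800.
    """

    dataset: str
    ontology: str
    associations: str
    gene_to_pathways: str
    symptom_keywords: str
    outdir: str = "zhengkit-run"
    label_column: str = "syndrome"
    # level 1
    min_minority: int = 5
    ig_thresholds: tuple = DEFAULT_IG_THRESHOLDS
    metric: str = "squared_euclidean"
    distance_thresholds: tuple = DEFAULT_DISTANCE_THRESHOLDS
    cost: float = 1.0
    gamma: float | str = "auto"
    n_repeats: int = 100
    n_pos_test: int = 10
    n_neg_test: int = 10
    master_seed: int = 0
    # level 2
    min_occurrence: int = 3
    min_support: float = 0.055
    min_confidence: float = 0.800
    rule_strategy: str = "any_bipartition"
    fdr: bool = False

    def eval_config(self) -> EvalConfig:
        return EvalConfig(
            n_repeats=self.n_repeats,
            n_pos_test=self.n_pos_test,
            n_neg_test=self.n_neg_test,
            classifier=ClassifierConfig(
                cost=self.cost, gamma=self.gamma, seed=self.master_seed
            ),
            metric=self.metric,
            master_seed=self.master_seed,
        )

    def validate_paths(self) -> None:
        for name in (
            "dataset",
            "ontology",
            "associations",
            "gene_to_pathways",
            "symptom_keywords",
        ):
            p = Path(getattr(self, name))
            if not p.exists():
                raise ConfigError(f"{name} path does not exist: {p}")


def _write_tsv(path: Path, header, rows) -> None:
    with path.open("w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def run_all(config: PipelineConfig) -> dict:
    """Execute both levels; return (and write) the run report.

    Artifacts land under ``config.outdir``; the report is also written
    there as ``report.json`` plus a ``manifest.json`` of artifact paths.
    Raises on stage failure, leaving earlier artifacts in place.
    """
    import yaml

    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    report: dict = {
        "version": __version__,
        "master_seed": config.master_seed,
        "distance_metric": config.metric,
    }

    def stage(name):
        log.info("stage: %s", name)
        return time.perf_counter()

    # ---- level 1: diagnostic -------------------------------------------
    t0 = stage("load-dataset")
    dataset = read_symptom_table(config.dataset, config.label_column)
    report["dataset"] = dataset.summary()

    stage("select-features")
    retained = filter_imbalanced_symptoms(dataset, config.min_minority)
    table = rank_symptoms(dataset, retained)
    gains_path = outdir / "information_gains.tsv"
    _write_tsv(gains_path, ("symptom", "information_gain"), table.entries)
    manifest["information_gains"] = str(gains_path)

    ig_results, ig_threshold = sweep_ig_thresholds(
        dataset, config.ig_thresholds, config.eval_config()
    )
    _write_tsv(
        outdir / "ig_threshold_sweep.tsv",
        ("threshold", "n_symptoms", "mean_accuracy"),
        ig_results,
    )
    manifest["ig_threshold_sweep"] = str(outdir / "ig_threshold_sweep.tsv")
    core = select_core_symptoms(table, ig_threshold)
    (outdir / "core_symptoms.json").write_text(
        json.dumps(
            {"threshold": ig_threshold, "symptoms": list(core.symptom_names)},
            indent=2,
        )
    )
    manifest["core_symptoms"] = str(outdir / "core_symptoms.json")
    report["feature_selection"] = {
        "n_retained": len(retained),
        "ig_threshold": ig_threshold,
        "n_core_symptoms": len(core),
    }

    stage("undersample-sweep")
    dist_results, dist_threshold = sweep_distance_thresholds(
        dataset, core, config.distance_thresholds, config.eval_config()
    )
    _write_tsv(
        outdir / "distance_threshold_sweep.tsv",
        ("threshold", "mean_accuracy", "mean_g_mean"),
        dist_results,
    )
    manifest["distance_threshold_sweep"] = str(
        outdir / "distance_threshold_sweep.tsv"
    )

    stage("evaluate")
    restricted = dataset.restrict(core.symptom_names)
    baseline = repeat_protocol(restricted, config.eval_config())
    undersampled = repeat_protocol(
        restricted, config.eval_config(), undersample_threshold=dist_threshold
    )
    metrics_path = outdir / "per_repeat_metrics.tsv"
    _write_tsv(
        metrics_path,
        ("pipeline", "repeat", "sensitivity", "specificity", "accuracy", "g_mean"),
        [
            (name, i, r["sensitivity"], r["specificity"], r["accuracy"], r["g_mean"])
            for name, agg in (("baseline", baseline), ("undersampled", undersampled))
            for i, r in enumerate(agg["per_repeat"])
        ],
    )
    manifest["per_repeat_metrics"] = str(metrics_path)
    report["diagnostic"] = {
        "distance_threshold": dist_threshold,
        "baseline_mean": baseline["mean"],
        "undersampled_mean": undersampled["mean"],
    }

    # ---- level 2: molecular --------------------------------------------
    stage("map-phenotypes")
    index = parse_ontology(config.ontology)
    keywords = yaml.safe_load(Path(config.symptom_keywords).read_text())
    core_keywords = {
        s: keywords.get(s, [s]) for s in core.symptom_names
    }
    term_map = map_symptoms(core_keywords, index)
    _write_tsv(
        outdir / "symptom_terms.tsv",
        ("symptom", "term_id", "term_name"),
        [
            (s, t_id, t_name)
            for s, terms in sorted(term_map.mapping.items())
            for t_id, t_name in terms
        ],
    )
    manifest["symptom_terms"] = str(outdir / "symptom_terms.tsv")

    assoc = read_term_gene_associations(config.associations)
    occurrences = collect_gene_occurrences(term_map, assoc)
    relevant = filter_relevant_genes(occurrences, config.min_occurrence)
    _write_tsv(
        outdir / "gene_occurrences.tsv",
        ("gene", "occurrence", "relevant"),
        [
            (g, c, int(g in set(relevant)))
            for g, c in occurrences.ranked()
        ],
    )
    manifest["gene_occurrences"] = str(outdir / "gene_occurrences.tsv")
    report["phenotype_mapping"] = {
        "n_mapped_symptoms": len(term_map.mapping)
        - len(term_map.unmapped_symptoms()),
        "n_unmapped_symptoms": len(term_map.unmapped_symptoms()),
        "n_distinct_terms": len(term_map.distinct_term_ids()),
        "n_genes_retrieved": len(occurrences.counts),
        "n_relevant_genes": len(relevant),
    }

    stage("mine-patterns")
    gene2path = read_gene_pathway_mapping(config.gene_to_pathways)
    records = build_pathway_records(relevant, gene2path)
    pattern = mine_pathway_pattern(
        records,
        config.min_support,
        config.min_confidence,
        strategy=config.rule_strategy,
    )
    symbols = assign_symbols(pattern)
    _write_tsv(
        outdir / "pathway_pattern.tsv",
        ("symbol", "pathway_entries", "count", "support"),
        [
            (symbols[s], ";".join(sorted(s)), c, f"{f:.6f}")
            for s, c, f in pattern.itemsets
        ],
    )
    manifest["pathway_pattern"] = str(outdir / "pathway_pattern.tsv")
    report["pathway_pattern"] = {
        "n_records": records.n_records,
        "n_unannotated_genes": records.n_unannotated,
        "n_itemsets": len(pattern),
        "itemsets_by_size": {
            str(size): len(items) for size, items in sorted(pattern.by_size().items())
        },
    }

    stage("build-network")
    network = build_multilayer_network(term_map, assoc, relevant, records, pattern)
    pruned = prune_incomplete_paths(network)
    export_network(pruned, "graphml", outdir / "network.graphml")
    export_network(pruned, "sif", outdir / "network.sif")
    manifest["network_graphml"] = str(outdir / "network.graphml")
    manifest["network_sif"] = str(outdir / "network.sif")
    report["network"] = {
        "n_symptom_nodes": len(layer_nodes(pruned, "symptom")),
        "n_gene_nodes": len(layer_nodes(pruned, "gene")),
        "n_itemset_nodes": len(layer_nodes(pruned, "itemset")),
        "n_edges": pruned.number_of_edges(),
    }

    stage("enrich")
    enrichment = rank_enriched_pathways(
        [g for g in relevant if g in gene2path],
        {p: {g for g, s in gene2path.items() if p in s} for p in
         sorted({p for s in gene2path.values() for p in s})},
        fdr=config.fdr,
    )
    enrichment.to_frame().to_csv(
        outdir / "enrichment.tsv", sep="\t", index=False
    )
    manifest["enrichment"] = str(outdir / "enrichment.tsv")
    report["enrichment"] = {
        "n_pathways_tested": len(enrichment),
        "top_pathways": [
            {"pathway": r["pathway"], "neg_log10_p": round(r["neg_log10_p"], 4)}
            for r in enrichment.rows[:5]
        ],
    }

    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    manifest["report"] = str(report_path)
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    log.info("run complete in %.1fs", time.perf_counter() - t0)
    return report
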