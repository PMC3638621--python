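"""Symptom-gene-pathway multilayer correlation network.

The network is tripartite and built "in the reverse direction" from the
mined pattern back to the symptoms:

* a gene connects to a pattern itemset iff the gene's pathway record
  contains every pathway of the itemset (superset rule);
* a symptom connects to a gene iff the gene appears among the genes
  associated with any of that symptom's mapped ontology terms.

Only complete symptom-gene-itemset paths carry meaning, so pruning
iteratively removes gene nodes lacking a symptom edge or an itemset edge
(dropping their edges) and then any isolated symptom or itemset node, to a
fixed point. Itemset nodes are the third layer — labelled with pattern
symbols (1a, 2b, ...) rather than individual pathways.

Exports: SIF (relations ``associates`` for symptom-gene, ``covers`` for
gene-itemset, plus a node-attribute TSV sidecar) and GraphML (lossless
round-trip of layers and counts). Both open directly in Cytoscape.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import networkx as nx

from .errors import PipelineError
from .pathway_pattern import PathwayPattern, PathwayRecordSet, assign_symbols
from .phenotype_mapping import RelevantGeneSet, SymptomTermMap

__all__ = [
    "build_multilayer_network",
    "prune_incomplete_paths",
    "export_network",
    "import_graphml",
    "layer_nodes",
]

LAYERS = ("symptom", "gene", "itemset")


def layer_nodes(network: nx.Graph, layer: str) -> list:
    return sorted(
        n for n, d in network.nodes(data=True) if d.get("layer") == layer
    )


def build_multilayer_network(
    term_map: SymptomTermMap,
    assoc: dict,
    relevant: RelevantGeneSet,
    records: PathwayRecordSet,
    pattern: PathwayPattern,
) -> nx.Graph:
    """Instantiate all candidate nodes and the two edge families.

    Nodes carry ``layer`` ("symptom" / "gene" / "itemset"); itemset nodes
    are keyed by their pattern symbol and carry the pathway ids and count;
    edges carry ``relation`` ("associates" / "covers").
    """
    if not pattern.itemsets:
        raise PipelineError("empty pathway pattern: no itemset layer to build")
    if not term_map.distinct_term_ids():
        raise PipelineError("empty term map: no symptom layer to build")
    network = nx.Graph()
    symbols = assign_symbols(pattern)
    relevant_set = set(relevant)
    for symptom in term_map.mapping:
        network.add_node(f"symptom::{symptom}", layer="symptom", label=symptom)
    for gene in sorted(relevant_set):
        network.add_node(f"gene::{gene}", layer="gene", label=gene)
    for itemset, count, _support in pattern.itemsets:
        symbol = symbols[itemset]
        network.add_node(
            f"itemset::{symbol}",
            layer="itemset",
            label=symbol,
            pathways=";".join(sorted(itemset)),
            count=count,
        )
    # symptom-gene: gene among the associated genes of the symptom's terms
    for symptom, terms in term_map.mapping.items():
        symptom_genes: set = set()
        for term_id, _name in terms:
            symptom_genes.update(assoc.get(term_id, {}))
        for gene in sorted(symptom_genes & relevant_set):
            network.add_edge(
                f"symptom::{symptom}", f"gene::{gene}", relation="associates"
            )
    # gene-itemset: record covers every pathway of the itemset
    for itemset, _count, _support in pattern.itemsets:
        symbol = symbols[itemset]
        for gene, record in records.records.items():
            if gene in relevant_set and itemset <= record:
                network.add_edge(
                    f"gene::{gene}", f"itemset::{symbol}", relation="covers"
                )
    return network


def prune_incomplete_paths(network: nx.Graph) -> nx.Graph:
    """Keep only nodes lying on complete symptom-gene-itemset paths.

    Iterates to a fixed point: a gene without both a symptom neighbour and
    an itemset neighbour is removed with its edges; symptom and itemset
    nodes left isolated are removed; repeat. (Symptom isolation cannot
    re-disqualify a surviving gene, but the fixed point is the conservative
    closure of the two removal rules.)
    """
    pruned = network.copy()
    changed = True
    while changed:
        changed = False
        for gene in layer_nodes(pruned, "gene"):
            neighbour_layers = {
                pruned.nodes[v]["layer"] for v in pruned.neighbors(gene)
            }
            if not {"symptom", "itemset"} <= neighbour_layers:
                pruned.remove_node(gene)
                changed = True
        isolated = [n for n in pruned.nodes if pruned.degree(n) == 0]
        if isolated:
            pruned.remove_nodes_from(isolated)
            changed = True
    if network.number_of_nodes() and not pruned.number_of_nodes():
        warnings.warn("pruning removed every node: no complete path exists")
    return pruned


def export_network(network: nx.Graph, fmt: str, path: str | Path) -> Path:
    """Write SIF (+ ``.nodes.tsv`` attribute sidecar) or GraphML."""
    path = Path(path)
    if network.number_of_nodes() == 0:
        warnings.warn("exporting an empty network")
    if fmt == "sif":
        with path.open("w") as fh:
            for u, v, data in sorted(network.edges(data=True)):
                fh.write(f"{u}\t{data.get('relation', 'links')}\t{v}\n")
        sidecar = path.with_suffix(path.suffix + ".nodes.tsv")
        with sidecar.open("w") as fh:
            fh.write("node\tlayer\tlabel\tpathways\tcount\n")
            for node, data in sorted(network.nodes(data=True)):
                fh.write(
                    "\t".join(
                        [
                            node,
                            data.get("layer", ""),
                            str(data.get("label", "")),
                            str(data.get("pathways", "")),
                            str(data.get("count", "")),
                        ]
                    )
                    + "\n"
                )
    elif fmt == "graphml":
        nx.write_graphml(network, path)
    else:
        raise ValueError(f"unknown export format {fmt!r}; use 'sif' or 'graphml'")
    return path


def import_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(str(path))
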