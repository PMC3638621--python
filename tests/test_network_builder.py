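import networkx as nx
import pytest

from zhengkit.errors import PipelineError
from zhengkit.network_builder import (
    build_multilayer_network,
    export_network,
    import_graphml,
    layer_nodes,
    prune_incomplete_paths,
)
from zhengkit.pathway_pattern import PathwayPattern, PathwayRecordSet
from zhengkit.phenotype_mapping import RelevantGeneSet, SymptomTermMap


def make_inputs(records, pattern_sets, term_genes):
    """Assemble consistent builder inputs from plain dicts.

    records: gene -> pathway set; pattern_sets: list of (itemset, count);
    term_genes: symptom -> gene list (one synthetic term per symptom).
    """
    term_map = SymptomTermMap(
        mapping={
            s: [(f"T:{i + 1:04d}", f"term for {s}")]
            for i, s in enumerate(term_genes)
        }
    )
    assoc = {
        f"T:{i + 1:04d}": {g: g for g in genes}
        for i, (s, genes) in enumerate(term_genes.items())
    }
    record_set = PathwayRecordSet(
        records={g: frozenset(s) for g, s in records.items()}
    )
    n = record_set.n_records
    pattern = PathwayPattern(
        itemsets=tuple(
            (frozenset(s), c, c / n) for s, c in pattern_sets
        ),
        min_support=0.1,
        min_confidence=0.8,
        n_records=n,
    )
    relevant = RelevantGeneSet(genes=tuple(sorted(records)), min_occurrence=0)
    return term_map, assoc, relevant, record_set, pattern


class TestBuild:
    def test_superset_rule_for_gene_itemset_edges(self):
        net = build_multilayer_network(
            *make_inputs(
                records={"g1": {"P", "Q", "R"}, "g2": {"P"}},
                pattern_sets=[({"P", "Q"}, 1)],
                term_genes={"s1": ["g1", "g2"]},
            )
        )
        assert net.has_edge("gene::g1", "itemset::2a")
        assert not net.has_edge("gene::g2", "itemset::2a")

    def test_symptom_gene_edges_via_term_associations(self):
        net = build_multilayer_network(
            *make_inputs(
                records={"g1": {"P"}, "g2": {"P"}},
                pattern_sets=[({"P"}, 2)],
                term_genes={"s1": ["g1"], "s2": []},
            )
        )
        assert net.has_edge("symptom::s1", "gene::g1")
        assert net.degree("symptom::s2") == 0

    def test_tripartite_no_intra_layer_edges(self, annotation_fixture):
        fx = annotation_fixture
        from zhengkit.pathway_pattern import build_pathway_records, mine_pathway_pattern
        from zhengkit.phenotype_mapping import (
            GeneOccurrenceTable,
            filter_relevant_genes,
        )

        term_map = SymptomTermMap(
            mapping={
                s: [(t, fx.ontology[t][0]) for t in sorted(fx.term_to_genes)[:5]]
                for s in list(fx.symptom_keywords)[:6]
            }
        )
        assoc = {t: {g: g for g in genes} for t, genes in fx.term_to_genes.items()}
        records = build_pathway_records(sorted(fx.gene_to_pathways), fx.gene_to_pathways)
        pattern = mine_pathway_pattern(records, 0.055, 0.8)
        relevant = RelevantGeneSet(
            genes=tuple(sorted(fx.gene_to_pathways)), min_occurrence=0
        )
        net = build_multilayer_network(term_map, assoc, relevant, records, pattern)
        for u, v in net.edges:
            layers = {net.nodes[u]["layer"], net.nodes[v]["layer"]}
            assert layers in ({"symptom", "gene"}, {"gene", "itemset"})

    def test_empty_pattern_rejected(self):
        term_map, assoc, relevant, records, pattern = make_inputs(
            records={"g1": {"P"}}, pattern_sets=[({"P"}, 1)], term_genes={"s": ["g1"]}
        )
        empty = PathwayPattern(
            itemsets=(), min_support=0.1, min_confidence=0.8, n_records=1
        )
        with pytest.raises(PipelineError):
            build_multilayer_network(term_map, assoc, relevant, records, empty)


class TestPrune:
    def chain_with_dangler(self):
        # complete path s1-g1-itemset; g2 has a symptom edge but no itemset
        return build_multilayer_network(
            *make_inputs(
                records={"g1": {"P"}, "g2": {"Z"}},
                pattern_sets=[({"P"}, 1)],
                term_genes={"s1": ["g1"], "s2": ["g2"]},
            )
        )

    def test_dangling_gene_and_cascaded_symptom_removed(self):
        pruned = prune_incomplete_paths(self.chain_with_dangler())
        assert layer_nodes(pruned, "symptom") == ["symptom::s1"]
        assert layer_nodes(pruned, "gene") == ["gene::g1"]
        assert layer_nodes(pruned, "itemset") == ["itemset::1a"]

    def test_fixed_point_when_all_paths_complete(self):
        net = build_multilayer_network(
            *make_inputs(
                records={"g1": {"P"}},
                pattern_sets=[({"P"}, 1)],
                term_genes={"s1": ["g1"]},
            )
        )
        pruned = prune_incomplete_paths(net)
        assert set(pruned.nodes) == set(net.nodes)
        assert set(pruned.edges) == set(net.edges)

    def test_idempotent(self):
        once = prune_incomplete_paths(self.chain_with_dangler())
        twice = prune_incomplete_paths(once)
        assert set(once.nodes) == set(twice.nodes)
        assert set(once.edges) == set(twice.edges)

    def test_never_adds_nodes_or_edges(self):
        net = self.chain_with_dangler()
        pruned = prune_incomplete_paths(net)
        assert set(pruned.nodes) <= set(net.nodes)
        assert set(pruned.edges) <= set(net.edges)

    def test_every_surviving_gene_on_complete_path(self):
        pruned = prune_incomplete_paths(self.chain_with_dangler())
        for gene in layer_nodes(pruned, "gene"):
            layers = {pruned.nodes[v]["layer"] for v in pruned.neighbors(gene)}
            assert {"symptom", "itemset"} <= layers

    def test_fully_pruned_network_warns_empty(self):
        net = build_multilayer_network(
            *make_inputs(
                records={"g1": {"Z"}},
                pattern_sets=[({"P"}, 1)],
                term_genes={"s1": ["g1"]},
            )
        )
        with pytest.warns(UserWarning, match="no complete path"):
            pruned = prune_incomplete_paths(net)
        assert pruned.number_of_nodes() == 0


class TestExport:
    def chain(self):
        return prune_incomplete_paths(
            build_multilayer_network(
                *make_inputs(
                    records={"g1": {"P"}},
                    pattern_sets=[({"P"}, 1)],
                    term_genes={"s1": ["g1"]},
                )
            )
        )

    def test_sif_chain_two_lines_with_relations(self, tmp_path):
        path = export_network(self.chain(), "sif", tmp_path / "n.sif")
        lines = path.read_text().splitlines()
        assert len(lines) == 2
        relations = {line.split("\t")[1] for line in lines}
        assert relations == {"associates", "covers"}
        assert (tmp_path / "n.sif.nodes.tsv").exists()

    def test_graphml_round_trip(self, tmp_path):
        net = self.chain()
        path = export_network(net, "graphml", tmp_path / "n.graphml")
        back = import_graphml(path)
        assert nx.is_isomorphic(net, back)
        assert {d["layer"] for _, d in back.nodes(data=True)} == {
            "symptom",
            "gene",
            "itemset",
        }

    def test_empty_network_export_warns(self, tmp_path):
        with pytest.warns(UserWarning, match="empty"):
            export_network(nx.Graph(), "sif", tmp_path / "e.sif")

    def test_unknown_format(self, tmp_path):
        with pytest.raises(ValueError):
            export_network(nx.Graph(), "dot", tmp_path / "e.dot")
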