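import itertools

import numpy as np
import pytest

from zhengkit.errors import PipelineError, ValidationError
from zhengkit.pathway_pattern import (
    PathwayRecordSet,
    apply_bidirectional_confidence,
    assign_symbols,
    build_pathway_records,
    min_support_count,
    mine_frequent_itemsets,
    mine_pathway_pattern,
    read_gene_pathway_mapping,
)


def brute_force_itemsets(records: PathwayRecordSet, min_support: float):
    """Enumerate every subset of the item universe and count directly."""
    threshold = min_support_count(records.n_records, min_support)
    universe = sorted({i for s in records.records.values() for i in s})
    out = []
    for size in range(1, len(universe) + 1):
        for combo in itertools.combinations(universe, size):
            itemset = frozenset(combo)
            count = sum(1 for s in records.records.values() if itemset <= s)
            if count >= threshold:
                out.append((itemset, count))
    out.sort(key=lambda kv: (len(kv[0]), -kv[1], sorted(kv[0])))
    return out


def random_records(rng, n_records, n_items):
    records = {}
    items = [f"p{i}" for i in range(n_items)]
    for g in range(n_records):
        size = rng.integers(1, n_items + 1)
        records[f"g{g}"] = frozenset(rng.choice(items, size=size, replace=False))
    return PathwayRecordSet(records=records)


class TestBuildRecords:
    def test_unannotated_genes_excluded_and_counted(self):
        mapping = {"g1": frozenset({"P1", "P2"}), "g2": frozenset()}
        records = build_pathway_records(["g1", "g2", "g3"], mapping)
        assert records.records == {"g1": frozenset({"P1", "P2"})}
        assert records.n_unannotated == 2

    def test_all_unannotated_is_pipeline_error(self):
        with pytest.raises(PipelineError):
            build_pathway_records(["g1"], {})

    def test_record_reduction_ratio(self):
        # 251 genes, 92 without annotation -> 159 records
        mapping = {f"g{i}": frozenset({"P1"}) for i in range(159)}
        genes = [f"g{i}" for i in range(251)]
        records = build_pathway_records(genes, mapping)
        assert records.n_records == 159
        assert records.n_unannotated == 92


class TestMinSupportCount:
    @pytest.mark.parametrize(
        "n,support,expected", [(159, 0.055, 9), (100, 0.05, 5), (10, 1.0, 10)]
    )
    def test_examples(self, n, support, expected):
        assert min_support_count(n, support) == expected

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            min_support_count(0, 0.1)
        with pytest.raises(ValidationError):
            min_support_count(10, 0.0)


class TestMiner:
    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(7)
        for trial in range(25):
            records = random_records(
                rng, n_records=int(rng.integers(2, 13)), n_items=int(rng.integers(2, 7))
            )
            for support in (0.1, 0.3, 0.6):
                assert mine_frequent_itemsets(records, support) == brute_force_itemsets(
                    records, support
                )

    def test_downward_closure_of_output(self):
        rng = np.random.default_rng(8)
        records = random_records(rng, 15, 6)
        mined = dict(mine_frequent_itemsets(records, 0.2))
        for itemset in mined:
            for size in range(1, len(itemset)):
                for sub in itertools.combinations(itemset, size):
                    assert frozenset(sub) in mined

    def test_single_record_every_subset_frequent(self):
        records = PathwayRecordSet(records={"g": frozenset({"a", "b", "c"})})
        mined = mine_frequent_itemsets(records, 1.0)
        assert len(mined) == 7  # all non-empty subsets

    def test_support_above_everything_gives_empty(self):
        records = PathwayRecordSet(
            records={"g1": frozenset({"a"}), "g2": frozenset({"b"})}
        )
        assert mine_frequent_itemsets(records, 0.9) == []

    def test_planted_itemset_recovered_with_construction_count(
        self, annotation_fixture
    ):
        fx = annotation_fixture
        records = build_pathway_records(
            sorted(fx.gene_to_pathways), fx.gene_to_pathways
        )
        assert records.n_records >= 159
        pattern = mine_pathway_pattern(records, 0.055, 0.800)
        counts = {s: c for s, c, _f in pattern.itemsets}
        assert counts.get(fx.planted_itemset) == len(fx.planted_genes) == 11
        assert fx.planted_itemset in pattern.maximal_itemsets()


class TestBidirectionalConfidence:
    def records_pq(self, n_p, n_q, n_pq, n_total):
        records = {}
        for i in range(n_pq):
            records[f"b{i}"] = frozenset({"P", "Q"})
        for i in range(n_p - n_pq):
            records[f"p{i}"] = frozenset({"P"})
        for i in range(n_q - n_pq):
            records[f"q{i}"] = frozenset({"Q"})
        for i in range(n_total - len(records)):
            records[f"x{i}"] = frozenset({"Z"})
        return PathwayRecordSet(records=records)

    def test_coequal_counts_pass_both_directions(self):
        records = self.records_pq(11, 11, 11, 40)
        mined = mine_frequent_itemsets(records, 0.05)
        pattern = apply_bidirectional_confidence(mined, records, 0.8)
        assert frozenset({"P", "Q"}) in {s for s, _c, _f in pattern.itemsets}

    def test_one_weak_direction_drops_itemset(self):
        # count(P)=100, count(PQ)=10 -> confidence(P->Q)=0.1
        records = self.records_pq(100, 10, 10, 110)
        mined = mine_frequent_itemsets(records, 0.05)
        pattern = apply_bidirectional_confidence(mined, records, 0.8)
        assert frozenset({"P", "Q"}) not in {s for s, _c, _f in pattern.itemsets}

    def test_single_item_entries_pass_unconditionally(self):
        records = self.records_pq(100, 10, 10, 110)
        mined = mine_frequent_itemsets(records, 0.05)
        pattern = apply_bidirectional_confidence(mined, records, 0.99)
        singles = {next(iter(s)) for s, _c, _f in pattern.itemsets if len(s) == 1}
        assert {"P", "Q"} <= singles

    def test_strict_strategy_is_subset_of_any(self):
        rng = np.random.default_rng(9)
        records = random_records(rng, 14, 5)
        mined = mine_frequent_itemsets(records, 0.2)
        any_sets = {
            s
            for s, _c, _f in apply_bidirectional_confidence(
                mined, records, 0.7, strategy="any_bipartition"
            ).itemsets
        }
        all_sets = {
            s
            for s, _c, _f in apply_bidirectional_confidence(
                mined, records, 0.7, strategy="all_bipartitions"
            ).itemsets
        }
        assert all_sets <= any_sets


class TestSymbolsAndIO:
    def test_symbol_labelling_follows_size_then_count(self):
        records = PathwayRecordSet(
            records={
                "g1": frozenset({"a", "b"}),
                "g2": frozenset({"a", "b"}),
                "g3": frozenset({"a"}),
            }
        )
        pattern = mine_pathway_pattern(records, 0.3, 0.5)
        symbols = assign_symbols(pattern)
        # 'a' (count 3) labels 1a, 'b' (count 2) labels 1b, {'a','b'} labels 2a
        assert symbols[frozenset({"a"})] == "1a"
        assert symbols[frozenset({"b"})] == "1b"
        assert symbols[frozenset({"a", "b"})] == "2a"

    def test_two_column_tsv_reader(self, tmp_path):
        p = tmp_path / "g2p.tsv"
        p.write_text("gene_id\tpathway_id\ng1\tP1\ng1\tP2\ng2\tP1\n")
        assert read_gene_pathway_mapping(p) == {
            "g1": frozenset({"P1", "P2"}),
            "g2": frozenset({"P1"}),
        }

    def test_gmt_reader_transposes(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("P1\tdesc\tg1\tg2\nP2\tdesc\tg1\n")
        assert read_gene_pathway_mapping(p) == {
            "g1": frozenset({"P1", "P2"}),
            "g2": frozenset({"P1"}),
        }
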