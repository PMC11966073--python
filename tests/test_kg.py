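import random

import pytest

from dskb.kg import (
    BulkParseError,
    Concept,
    ConceptType,
    GraphCounts,
    KnowledgeGraph,
    ROUTING,
    ReferentialError,
    RelationType,
    RoutingError,
    SchemaError,
    Triple,
    UnknownConceptError,
    export_bulk,
    import_bulk,
    make_id,
    route_relation,
    to_cypher,
)

from conftest import make_concept, random_graph


class TestRouting:
    @pytest.mark.parametrize(
        "head,tail,expected",
        [
            (ConceptType.DSI, ConceptType.DISEASE, RelationType.IS_EFFECTIVE_FOR),
            (ConceptType.DSI, ConceptType.DRUG, RelationType.INTERACTS_WITH),
            (ConceptType.DSP, ConceptType.DSI, RelationType.HAS_INGREDIENT),
            (ConceptType.DSI, ConceptType.TC, RelationType.HAS_THERAPEUTIC_CLASS),
            (ConceptType.DSI, ConceptType.SOC, RelationType.HAS_ADVERSE_EFFECT_ON),
            (ConceptType.DSI, ConceptType.SYMPTOM, RelationType.HAS_ADVERSE_REACTION),
        ],
    )
    def test_forward_pairs(self, head, tail, expected):
        relation, reversed_ = route_relation(head, tail)
        assert relation is expected and not reversed_

    def test_reverse_pair_same_relation_with_flag(self):
        relation, reversed_ = route_relation(ConceptType.DISEASE, ConceptType.DSI)
        assert relation is RelationType.IS_EFFECTIVE_FOR and reversed_

    @pytest.mark.parametrize(
        "head,tail",
        [
            (ConceptType.DISEASE, ConceptType.DRUG),
            (ConceptType.DSI, ConceptType.DSI),
            (ConceptType.DSP, ConceptType.DISEASE),
        ],
    )
    def test_unsupported_pair_names_both_types(self, head, tail):
        with pytest.raises(RoutingError) as exc:
            route_relation(head, tail)
        assert head.value in str(exc.value) and tail.value in str(exc.value)

    def test_routing_is_a_bijection(self):
        assert len(ROUTING) == len(RelationType) == 6
        assert set(ROUTING.values()) == set(RelationType)
        assert len(ConceptType) == 7

    def test_closed_enums(self):
        assert {t.value for t in ConceptType} == {
            "DSI", "DSP", "DISEASE", "DRUG", "SYMPTOM", "TC", "SOC",
        }


class TestGraph:
    def test_duplicate_triple_merges_provenance(self, small_graph):
        before = len(small_graph)
        changed = small_graph.add_triple(
            Triple("DI0000001", RelationType.IS_EFFECTIVE_FOR, "DZ0000001",
                   sources={"nmcd"})
        )
        assert not changed and len(small_graph) == before
        t = small_graph.neighbors("DZ0000001")[0]
        assert t.sources == {"mskcc", "nmcd"}
        assert any(e["event"] == "triple-merge" for e in small_graph.merge_log)

    def test_distinct_triples_both_count(self, small_graph):
        assert len(small_graph) == 3

    def test_dangling_endpoint_rejected(self, small_graph):
        with pytest.raises(ReferentialError):
            small_graph.add_triple(
                Triple("DI0000001", RelationType.IS_EFFECTIVE_FOR, "DZ9999999")
            )

    def test_type_inconsistent_relation_rejected(self, small_graph):
        with pytest.raises(SchemaError):
            small_graph.add_triple(
                Triple("DI0000001", RelationType.HAS_INGREDIENT, "DZ0000001")
            )

    def test_triple_set_semantics_random_insertions(self):
        rng = random.Random(5)
        g = KnowledgeGraph()
        g.add_concept(make_concept(ConceptType.DSI, 1, "a"))
        for i in range(1, 4):
            g.add_concept(make_concept(ConceptType.DISEASE, i, f"d{i}"))
        inserted = set()
        for _ in range(50):
            tail = make_id(ConceptType.DISEASE, rng.randint(1, 3))
            g.add_triple(Triple("DI0000001", RelationType.IS_EFFECTIVE_FOR, tail))
            inserted.add(("DI0000001", RelationType.IS_EFFECTIVE_FOR, tail))
        assert len(g) == len(inserted)

    def test_neighbors_filter_and_order(self, small_graph):
        all_triples = small_graph.neighbors("DI0000001")
        assert len(all_triples) == 3
        keys = [
            (t.relation.value, t.tail_id if t.head_id == "DI0000001" else t.head_id)
            for t in all_triples
        ]
        assert keys == sorted(keys)
        diseases = small_graph.neighbors("DI0000001", RelationType.IS_EFFECTIVE_FOR)
        assert [t.tail_id for t in diseases] == ["DZ0000001"]

    def test_neighbors_isolated_and_unknown(self, small_graph):
        assert small_graph.neighbors("SY0000001") == []
        with pytest.raises(UnknownConceptError):
            small_graph.neighbors("DI0009999")

    def test_duplicate_concept_id_rejected(self, small_graph):
        with pytest.raises(SchemaError):
            small_graph.add_concept(make_concept(ConceptType.DSI, 1, "again"))

    def test_empty_preferred_name_rejected(self):
        with pytest.raises(SchemaError):
            Concept(idisk_id="DI0000001", concept_type=ConceptType.DSI,
                    preferred_name="  ")

    def test_unknown_attribute_key_rejected(self):
        with pytest.raises(SchemaError):
            Concept(idisk_id="DI0000001", concept_type=ConceptType.DSI,
                    preferred_name="x", attributes={"color": "red"})

    def test_name_index_covers_synonyms(self):
        g = KnowledgeGraph()
        g.add_concept(
            make_concept(ConceptType.DSI, 1, "Acacia",
                         synonyms={"Fiber gum acacia", "Acacia gum extract"})
        )
        assert g.lookup_name(ConceptType.DSI, "fiber gum  ACACIA") == "DI0000001"


class TestBulk:
    def test_empty_graph_exports_thirteen_tables(self, tmp_path):
        paths = export_bulk(KnowledgeGraph(), str(tmp_path))
        assert len(paths) == 13
        assert import_bulk(str(tmp_path)) == KnowledgeGraph()

    def test_small_graph_round_trip(self, small_graph, tmp_path):
        export_bulk(small_graph, str(tmp_path))
        assert import_bulk(str(tmp_path)) == small_graph

    def test_random_round_trip_many(self, tmp_path):
        # export/import must be the identity on randomized graphs
        for i in range(100):
            g = random_graph(random.Random(i))
            d = tmp_path / f"g{i}"
            export_bulk(g, str(d))
            assert import_bulk(str(d)) == g

    def test_hand_written_pair_imports_two_triples(self, small_graph, tmp_path):
        export_bulk(small_graph, str(tmp_path))
        rel = tmp_path / "relationships_is_effective_for.csv"
        rel.write_text(
            "head_id,tail_id,interaction_rating,effectiveness_rating,sources\n"
            "DI0000001,DZ0000001,,effective,mskcc\n",
            encoding="utf-8",
        )
        (tmp_path / "relationships_interacts_with.csv").write_text(
            "head_id,tail_id,interaction_rating,effectiveness_rating,sources\n"
            "DI0000001,DR0000001,major,,nmcd\n",
            encoding="utf-8",
        )
        (tmp_path / "relationships_has_ingredient.csv").write_text(
            "head_id,tail_id,interaction_rating,effectiveness_rating,sources\n",
            encoding="utf-8",
        )
        g = import_bulk(str(tmp_path))
        assert len(g) == 2
        t = g.neighbors("DR0000001")[0]
        assert t.attributes == {"interaction_rating": "major"}

    def test_malformed_row_reports_file_and_line(self, small_graph, tmp_path):
        export_bulk(small_graph, str(tmp_path))
        bad = tmp_path / "concepts_DSI.csv"
        lines = bad.read_text().splitlines()
        lines.append("only,two")
        bad.write_text("\n".join(lines) + "\n", encoding="utf-8")
        with pytest.raises(BulkParseError) as exc:
            import_bulk(str(tmp_path))
        assert "concepts_DSI.csv" in str(exc.value)
        assert exc.value.line == len(lines)

    def test_cypher_emission_covers_graph(self, small_graph):
        text = to_cypher(small_graph)
        assert text.count("MERGE (n:") == 5
        assert text.count("-[:") == 3


class TestCounts:
    def test_empty_graph_totals_zero(self):
        counts = GraphCounts.from_graph(KnowledgeGraph())
        assert counts.concept_total == counts.relation_total == 0
        assert counts.attribute_total == 0

    def test_totals_are_sums_and_order_invariant(self):
        g1 = random_graph(random.Random(3))
        c1 = GraphCounts.from_graph(g1)
        assert c1.concept_total == len(g1.concepts)
        assert c1.relation_total == len(g1)
        # rebuild with shuffled insertion order
        g2 = KnowledgeGraph()
        rng = random.Random(9)
        concepts = list(g1.concepts.values())
        rng.shuffle(concepts)
        for c in concepts:
            g2.add_concept(c)
        triples = g1.triples
        rng.shuffle(triples)
        for t in triples:
            g2.add_triple(t)
        c2 = GraphCounts.from_graph(g2)
        assert (c1.concept_counts, c1.relation_counts, c1.attribute_counts) == (
            c2.concept_counts, c2.relation_counts, c2.attribute_counts,
        )
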