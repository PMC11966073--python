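import pytest

from dskb.ingest import AssertionRecord, ProductRecord
from dskb.integrate import (
    EntityRecord,
    build_triples,
    integrate_entities,
)
from dskb.kg import ConceptType, GraphCounts, RelationType


def _dsi(source, rid, name, cui=None, syns=()):
    return EntityRecord(
        source=source, record_id=rid, concept_type=ConceptType.DSI,
        name=name, synonyms=list(syns), cui=cui,
    )


def _dsp(source, rid, name, company):
    return EntityRecord(
        source=source, record_id=rid, concept_type=ConceptType.DSP,
        name=name, attributes={"company_name": company},
    )


SEED = ["lnhpd", "dsld", "mskcc"]


class TestIntegrateEntities:
    def test_same_product_and_company_merge(self):
        g, ledger, _ = integrate_entities(
            {ConceptType.DSP: [
                _dsp("lnhpd", "P1", "Fish Oil", "Acme"),
                _dsp("dsld", "P1", "fish  oil", "ACME"),
            ]},
            SEED,
        )
        assert len(g.concepts) == 1
        concept = next(iter(g.concepts.values()))
        assert concept.sources == {"lnhpd", "dsld"}
        reasons = {d.reason for d in ledger.decisions}
        assert reasons == {"new-entity", "product-name+company"}

    def test_same_cui_different_names_merge(self):
        g, ledger, _ = integrate_entities(
            {ConceptType.DSI: [
                _dsi("lnhpd", "I1", "Coenzyme Q10", cui="C0056077"),
                _dsi("mskcc", "I1", "Ubiquinone", cui="C0056077"),
            ]},
            SEED,
        )
        assert len(g.concepts) == 1
        concept = next(iter(g.concepts.values()))
        assert concept.preferred_name == "Coenzyme Q10"  # seed source wins
        assert "Ubiquinone" in concept.synonyms
        assert any(d.reason == "same-CUI" for d in ledger.decisions)

    def test_identical_name_merges_without_cui(self):
        g, _, _ = integrate_entities(
            {ConceptType.DSI: [
                _dsi("lnhpd", "I1", "Ginkgo"),
                _dsi("dsld", "I1", "GINKGO"),
            ]},
            SEED,
        )
        assert len(g.concepts) == 1

    def test_distinct_names_no_cui_stay_separate(self):
        g, _, _ = integrate_entities(
            {ConceptType.DSI: [
                _dsi("lnhpd", "I1", "Ginkgo"),
                _dsi("lnhpd", "I2", "Ginseng"),
            ]},
            SEED,
        )
        assert len(g.concepts) == 2

    def test_ledger_is_total_and_ids_deterministic(self):
        records = {
            ConceptType.DSI: [
                _dsi("dsld", "I1", "A"), _dsi("lnhpd", "I1", "B"),
                _dsi("mskcc", "I1", "a"),  # merges with "A" by name
            ]
        }
        g1, ledger1, _ = integrate_entities(records, SEED)
        g2, ledger2, _ = integrate_entities(records, SEED)
        assert set(ledger1.assignments) == {
            ("dsld", "I1"), ("lnhpd", "I1"), ("mskcc", "I1"),
        }
        assert ledger1.assignments == ledger2.assignments
        assert g1 == g2
        # seed source lnhpd folds first, so "B" gets the first identifier
        assert ledger1.assignments[("lnhpd", "I1")] == "DI0000001"
        assert ledger1.assignments[("dsld", "I1")] == "DI0000002"

    def test_concepts_never_exceed_records(self):
        records = [
            _dsi("lnhpd", f"I{i}", f"name {i % 4}", cui=f"C{i % 3:07d}")
            for i in range(12)
        ]
        g, _, _ = integrate_entities({ConceptType.DSI: records}, SEED)
        assert len(g.concepts) <= 12

    def test_attribute_conflicts_logged_first_source_wins(self):
        a = _dsi("lnhpd", "I1", "Zinc")
        a.attributes["safety"] = "safe"
        b = _dsi("dsld", "I1", "Zinc")
        b.attributes["safety"] = "unsafe"
        g, ledger, _ = integrate_entities({ConceptType.DSI: [a, b]}, SEED)
        concept = next(iter(g.concepts.values()))
        assert concept.attributes["safety"] == "safe"
        assert ledger.conflicts and ledger.conflicts[0]["field"] == "safety"


class TestBuildTriples:
    def _setup(self):
        records = {
            ConceptType.DSI: [_dsi("mskcc", "I1", "Vitamin C")],
            ConceptType.DISEASE: [
                EntityRecord(source="mskcc", record_id="A1:obj",
                             concept_type=ConceptType.DISEASE, name="Common cold")
            ],
        }
        return integrate_entities(records, SEED)

    def _assertion(self, source, rid, rating=None, subject="Vitamin C",
                   obj="Common cold", category="disease"):
        return AssertionRecord(
            source=source, record_id=rid, subject_name=subject,
            object_name=obj, object_category=category, rating_text=rating,
        )

    def test_duplicate_assertion_across_sources_one_triple(self):
        g, _, resolver = self._setup()
        skipped = build_triples(
            g, resolver,
            [self._assertion("mskcc", "A1"), self._assertion("nmcd", "A1")],
            [],
        )
        assert len(g) == 1 and skipped == []
        t = g.triples[0]
        assert t.sources == {"mskcc", "nmcd"}

    def test_ten_assertions_two_duplicates_give_eight_triples(self):
        records = {
            ConceptType.DSI: [_dsi("mskcc", f"I{i}", f"ing {i}") for i in range(8)],
            ConceptType.DISEASE: [
                EntityRecord(source="mskcc", record_id=f"D{i}",
                             concept_type=ConceptType.DISEASE, name=f"dis {i}")
                for i in range(8)
            ],
        }
        g, _, resolver = integrate_entities(records, SEED)
        assertions = [
            self._assertion("mskcc", f"A{i}", subject=f"ing {i}", obj=f"dis {i}")
            for i in range(8)
        ] + [
            self._assertion("nmcd", "A8", subject="ing 0", obj="dis 0"),
            self._assertion("nmcd", "A9", subject="ing 1", obj="dis 1"),
        ]
        build_triples(g, resolver, assertions, [])
        assert len(g) == 8

    def test_rating_stored_under_schema_attribute(self):
        g, _, resolver = self._setup()
        build_triples(g, resolver, [self._assertion("mskcc", "A1", rating="effective")], [])
        assert g.triples[0].attributes == {"effectiveness_rating": "effective"}
        assert g.triples[0].relation is RelationType.IS_EFFECTIVE_FOR

    def test_unmapped_subject_skipped_with_log(self):
        g, _, resolver = self._setup()
        skipped = build_triples(
            g, resolver, [self._assertion("mskcc", "A1", subject="Nonexistent")], []
        )
        assert len(g) == 0
        assert skipped[0]["reason"] == "unmapped subject"

    def test_product_with_three_ingredients_three_triples(self):
        records = {
            ConceptType.DSI: [_dsi("dsld", f"I{i}", f"ing {i}") for i in range(3)],
            ConceptType.DSP: [_dsp("dsld", "P1", "Multi", "Acme")],
        }
        g, _, resolver = integrate_entities(records, SEED)
        product = ProductRecord(
            source="dsld", record_id="P1", product_name="Multi",
            company_name="Acme", company_address="addr",
            ingredient_names=["ing 0", "ing 1", "ing 2"],
        )
        build_triples(g, resolver, [], [product])
        assert len(g) == 3
        counts = GraphCounts.from_graph(g)
        assert counts.relation_counts["has_ingredient"] == 3
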