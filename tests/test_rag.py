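import pytest

from dskb.kg import ConceptType, RelationType
from dskb.linker import EntityVectorIndex, HashingTrigramEmbedder
from dskb.rag import (
    ABSTAIN,
    DictionaryExtractor,
    KGAnswerer,
    NONE_OPTION,
    answer,
    answer_mcq,
    answer_tf,
    detect_intent,
    plan_query,
    retrieve,
)


@pytest.fixture
def embedder():
    return HashingTrigramEmbedder(dim=128, seed=0)


@pytest.fixture
def worked_index(worked_graph, embedder):
    return EntityVectorIndex.build(worked_graph, embedder)


class TestExtractor:
    def test_single_mention_with_offsets(self, worked_graph):
        ex = DictionaryExtractor(worked_graph)
        q = "Which disease is Omega-3 Fatty Acids effective for?"
        mentions = ex.extract(q)
        assert [m.text for m in mentions] == ["Omega-3 Fatty Acids"]
        m = mentions[0]
        assert q[m.start : m.end] == m.text

    def test_two_mentions_case_insensitive(self, worked_graph):
        ex = DictionaryExtractor(worked_graph)
        got = ex.extract("Is it true that Vitamin C is effective for the common cold?")
        assert [m.text for m in got] == ["Vitamin C", "common cold"]

    def test_no_graph_name_no_mentions(self, worked_graph):
        assert DictionaryExtractor(worked_graph).extract("hello") == []

    def test_mentions_do_not_overlap(self, worked_graph):
        mentions = DictionaryExtractor(worked_graph).extract(
            "Cardiovascular disease and Cancer and Cancer"
        )
        spans = [(m.start, m.end) for m in mentions]
        assert spans == sorted(spans)
        assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))


class TestIntent:
    @pytest.mark.parametrize(
        "question,expected",
        [
            ("Which disease is X effective for?", ConceptType.DISEASE),
            ("Does X interact with Y?", ConceptType.DRUG),
            ("What are the side effects of X?", ConceptType.SYMPTOM),
            ("Which therapeutic class does X belong to?", ConceptType.TC),
            ("What ingredients does P contain?", ConceptType.DSI),
            ("Tell me a story", None),
        ],
    )
    def test_keyword_lexicon(self, question, expected):
        assert detect_intent(question) is expected


class TestPlanAndRetrieve:
    def test_one_concept_neighborhood_plan(self, worked_graph):
        relation, cypher, query = plan_query(
            worked_graph, ["DI0000002"], ConceptType.DISEASE
        )
        assert relation is RelationType.IS_EFFECTIVE_FOR
        assert query["kind"] == "neighborhood"
        assert "is_effective_for" in cypher and "DI0000002" in cypher
        triples = retrieve(worked_graph, query)
        assert len(triples) == 6

    def test_two_concept_edge_plan_orients_by_routing(self, worked_graph):
        # reversed argument order still yields the canonical edge direction
        _, cypher, query = plan_query(worked_graph, ["DZ0000001", "DI0000001"], None)
        assert query == {
            "kind": "edge",
            "head": "DI0000001",
            "relation": "is_effective_for",
            "tail": "DZ0000001",
        }
        assert retrieve(worked_graph, query)

    def test_holdout_hides_single_source_triples(self, worked_graph):
        _, _, query = plan_query(worked_graph, ["DI0000001", "DZ0000001"], None)
        assert retrieve(worked_graph, query, frozenset({"mskcc"})) == []
        assert retrieve(worked_graph, query, frozenset({"other"})) != []


class TestAnswer:
    def test_neighborhood_answer_lists_exactly_the_retrieved_diseases(
        self, worked_graph, worked_index
    ):
        result = answer(
            "Which disease is Omega-3 Fatty Acids effective for?",
            worked_graph,
            worked_index,
        )
        listed = {
            line[2:] for line in result.text.splitlines() if line.startswith("- ")
        }
        assert listed == {
            "Cardiovascular disease", "Lupus", "Cancer", "Depression",
            "High cholesterol", "Atherosclerosis",
        }
        assert not result.plan.fallback_used

    def test_grounding_every_listed_entity_has_a_triple(self, worked_graph, worked_index):
        result = answer(
            "Which disease is Vitamin C effective for?", worked_graph, worked_index
        )
        endpoint_names = set()
        for t in result.plan.triples:
            endpoint_names.add(worked_graph.get(t.head_id).preferred_name)
            endpoint_names.add(worked_graph.get(t.tail_id).preferred_name)
        for line in result.text.splitlines():
            if line.startswith("- "):
                assert line[2:] in endpoint_names

    def test_unknown_entity_falls_back_flagged(self, worked_graph, worked_index):
        result = answer(
            "Is milk thistle good for liver disease?", worked_graph, worked_index
        )
        assert result.plan.fallback_used
        assert "not available" in result.text

    def test_answers_are_deterministic(self, worked_graph, worked_index):
        q = "Which disease is Omega-3 Fatty Acids effective for?"
        a1 = answer(q, worked_graph, worked_index)
        a2 = answer(q, worked_graph, worked_index)
        assert a1.text == a2.text
        assert a1.plan.cypher == a2.plan.cypher


class TestScoredAnswers:
    def test_tf_true_on_existing_edge(self, worked_graph, worked_index):
        assert answer_tf(
            "Is it true that Vitamin C is effective for the common cold?",
            worked_graph,
            worked_index,
        ) is True

    def test_tf_false_on_non_edge(self, worked_graph, worked_index):
        assert answer_tf(
            "Is it true that Vitamin C is effective for Stroke?",
            worked_graph,
            worked_index,
        ) is False

    def test_tf_abstains_without_two_links(self, worked_graph, worked_index):
        assert answer_tf(
            "Is it true that moonbeam extract cures everything?",
            worked_graph,
            worked_index,
        ) is None

    def test_mcq_picks_the_supported_option(self, worked_graph, worked_index):
        got = answer_mcq(
            "Out of the given list, which disease is Vitamin C effective for?",
            ["Bladder stones", "Common cold", "Stroke", "Bleeding hemorrhoids", NONE_OPTION],
            worked_graph,
            worked_index,
        )
        assert got == "Common cold"

    def test_mcq_none_of_the_above_when_unsupported(self, worked_graph, worked_index):
        got = answer_mcq(
            "Out of the given list, which disease is Vitamin C effective for?",
            ["Bladder stones", "Stroke", NONE_OPTION],
            worked_graph,
            worked_index,
        )
        assert got == NONE_OPTION

    def test_mcq_abstains_without_none_option(self, worked_graph, worked_index):
        got = answer_mcq(
            "Out of the given list, which disease is Glowberry effective for?",
            ["Bladder stones", "Stroke"],
            worked_graph,
            worked_index,
        )
        assert got == ABSTAIN

    def test_answerer_adapter_formats_verdicts(self, worked_graph, worked_index):
        from dskb.qa import QAItem

        system = KGAnswerer(worked_graph, worked_index)
        tf = QAItem(
            kind="TF", category="DS-disease",
            stem="Is it true that Vitamin C is effective for the common cold?",
            gold="True",
        )
        assert system(tf) == "True"
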