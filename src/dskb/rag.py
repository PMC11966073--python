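"""Graph-grounded question answering.

Pipeline: mention extraction -> embedding-based linking -> relation
routing -> graph query -> triple retrieval -> answer composition. When no
mention links to the graph, the pipeline falls back to the generative
component alone and flags the answer as outside the knowledge base.

Both the mention extractor and the answer generator are pluggable
contracts mirroring LLM-backed components; the defaults are deterministic
(longest-match dictionary scan, template renderer) so the full pipeline
runs offline and reproducibly. Relationships are never embedded: the
relation between two linked concepts is fixed by the type-pair routing
table, and answers composed by the template generator name only entities
that appear in retrieved triples — no hallucination by construction.

Retrieval honours a source-exclusion set ("holdout") at triple level: a
triple is invisible when all of its provenance labels are held out, so
benchmark questions derived from a held-out source cannot be answered
from memorized facts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Protocol, Sequence

from .kg import (
    ConceptType,
    KnowledgeGraph,
    RelationType,
    RoutingError,
    Triple,
    route_relation,
)
from .linker import DEFAULT_THRESHOLD, EntityVectorIndex, LinkResult

#: Abstain code returned when the subject of a scored question cannot be
#: linked; evaluation scores it as incorrect.
ABSTAIN = "ABSTAIN"

NONE_OPTION = "None of the above"

#: Keyword lexicon for intent detection: which concept type is asked about.
#: Checked in order; first hit wins.
_INTENT_KEYWORDS: list[tuple[str, ConceptType]] = [
    ("side effect", ConceptType.SYMPTOM),
    ("adverse", ConceptType.SYMPTOM),
    ("symptom", ConceptType.SYMPTOM),
    ("therapeutic class", ConceptType.TC),
    ("therapeutic", ConceptType.TC),
    ("organ", ConceptType.SOC),
    ("interact", ConceptType.DRUG),
    ("drug", ConceptType.DRUG),
    ("ingredient", ConceptType.DSI),
    ("contain", ConceptType.DSI),
    ("disease", ConceptType.DISEASE),
    ("effective", ConceptType.DISEASE),
    ("condition", ConceptType.DISEASE),
]

_VERB = {
    RelationType.IS_EFFECTIVE_FOR: "is effective for",
    RelationType.INTERACTS_WITH: "interacts with",
    RelationType.HAS_ADVERSE_REACTION: "may cause",
    RelationType.HAS_ADVERSE_EFFECT_ON: "has adverse effects on",
    RelationType.HAS_THERAPEUTIC_CLASS: "has therapeutic class",
    RelationType.HAS_INGREDIENT: "contains",
}


class PipelineError(RuntimeError):
    """A pipeline component failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class Mention:
    text: str
    start: int
    end: int


class MentionExtractor(Protocol):
    def extract(self, question: str) -> list[Mention]: ...


class DictionaryExtractor:
    """Longest-match dictionary scan over all knowledge-graph names.

    Deterministic stand-in for LLM-based entity extraction: finds
    non-overlapping, case-insensitive, word-bounded occurrences of any
    concept name, preferring the longest name at each position.
    """

    def __init__(self, graph: KnowledgeGraph):
        names: set[str] = set()
        for concept in graph.concepts.values():
            for name in concept.names():
                if len(name.strip()) >= 2:
                    names.add(name.strip())
        ordered = sorted(names, key=lambda n: (-len(n), n))
        if ordered:
            pattern = "|".join(re.escape(n) for n in ordered)
            self._regex = re.compile(rf"(?<!\w)(?:{pattern})(?!\w)", re.IGNORECASE)
        else:
            self._regex = None

    def extract(self, question: str) -> list[Mention]:
        if self._regex is None:
            return []
        return [
            Mention(m.group(0), m.start(), m.end())
            for m in self._regex.finditer(question)
        ]


class AnswerGenerator(Protocol):
    """Contract for the generative component (LLM-backed or template)."""

    def compose(self, question: str, rendered_facts: Sequence[str]) -> str: ...

    def fallback(self, question: str) -> str: ...


class TemplateGenerator:
    """Deterministic renderer grounded only in the retrieved triples."""

    def compose(self, question: str, rendered_facts: Sequence[str]) -> str:
        return "\n".join(rendered_facts)

    def fallback(self, question: str) -> str:
        return (
            "The requested information is not available within the "
            "knowledge base; no grounded answer can be given."
        )


@dataclass
class QueryPlan:
    """Trace of one question through the pipeline stages."""

    mentions: list[Mention] = field(default_factory=list)
    linked: list[tuple[str, Optional[LinkResult]]] = field(default_factory=list)
    relation: Optional[RelationType] = None
    cypher: str = ""
    query: dict = field(default_factory=dict)  # backend-neutral structured form
    triples: list[Triple] = field(default_factory=list)
    fallback_used: bool = False


def detect_intent(question: str) -> Optional[ConceptType]:
    """Which concept type the question asks about, by keyword lexicon."""
    q = question.casefold()
    for keyword, ctype in _INTENT_KEYWORDS:
        if keyword in q:
            return ctype
    return None


def _visible(triple: Triple, holdout: frozenset[str]) -> bool:
    return bool(triple.sources - holdout) or not triple.sources


def plan_query(
    graph: KnowledgeGraph,
    linked_ids: Sequence[str],
    intent: Optional[ConceptType],
) -> tuple[RelationType, str, dict]:
    """Build the graph query for the linked concepts.

    Two linked concepts yield an edge-existence query under the relation
    routed from their types; one concept yields a neighborhood query under
    the relation implied by the asked-about type. Returns the relation,
    openCypher text, and an equivalent backend-neutral structured form.
    """
    if not linked_ids:
        raise PipelineError("plan", "no linked concepts")
    a = graph.get(linked_ids[0])
    if len(linked_ids) >= 2:
        b = graph.get(linked_ids[1])
        relation, reversed_ = route_relation(a.concept_type, b.concept_type)
        head, tail = (b, a) if reversed_ else (a, b)
        cypher = (
            f"MATCH (h:{head.concept_type.value} {{idisk_id: '{head.idisk_id}'}})"
            f"-[r:{relation.value}]->"
            f"(t:{tail.concept_type.value} {{idisk_id: '{tail.idisk_id}'}}) RETURN r"
        )
        query = {
            "kind": "edge",
            "head": head.idisk_id,
            "relation": relation.value,
            "tail": tail.idisk_id,
        }
        return relation, cypher, query
    if intent is None:
        raise PipelineError("plan", "single-concept query requires an intent type")
    relation, reversed_ = route_relation(a.concept_type, intent)
    if reversed_:
        cypher = (
            f"MATCH (h:{intent.value})-[r:{relation.value}]->"
            f"(t:{a.concept_type.value} {{idisk_id: '{a.idisk_id}'}}) RETURN h"
        )
    else:
        cypher = (
            f"MATCH (h:{a.concept_type.value} {{idisk_id: '{a.idisk_id}'}})"
            f"-[r:{relation.value}]->(t:{intent.value}) RETURN t"
        )
    query = {
        "kind": "neighborhood",
        "concept": a.idisk_id,
        "relation": relation.value,
        "target_type": intent.value,
        "reversed": reversed_,
    }
    return relation, cypher, query


def retrieve(
    graph: KnowledgeGraph, query: dict, holdout: frozenset[str] = frozenset()
) -> list[Triple]:
    """Execute a structured query against the in-memory graph."""
    relation = RelationType(query["relation"])
    if query["kind"] == "edge":
        t = [
            t
            for t in graph.neighbors(query["head"], relation)
            if t.head_id == query["head"]
            and t.tail_id == query["tail"]
            and _visible(t, holdout)
        ]
        return t
    concept_id = query["concept"]
    out = []
    for t in graph.neighbors(concept_id, relation):
        other = t.tail_id if t.head_id == concept_id else t.head_id
        if graph.get(other).concept_type.value != query["target_type"]:
            continue
        if _visible(t, holdout):
            out.append(t)
    return out


def render_triple(graph: KnowledgeGraph, triple: Triple) -> str:
    head = graph.get(triple.head_id).preferred_name
    tail = graph.get(triple.tail_id).preferred_name
    return f"{head} {_VERB[triple.relation]} {tail}"


@dataclass
class Answer:
    text: str
    plan: QueryPlan


def _link_mentions(
    mentions: Sequence[Mention],
    index: EntityVectorIndex,
    threshold: float,
) -> list[tuple[str, Optional[LinkResult]]]:
    return [(m.text, index.link(m.text, threshold)) for m in mentions]


def answer(
    question: str,
    graph: KnowledgeGraph,
    index: EntityVectorIndex,
    extractor: Optional[MentionExtractor] = None,
    generator: Optional[AnswerGenerator] = None,
    threshold: float = DEFAULT_THRESHOLD,
    holdout: frozenset[str] = frozenset(),
) -> Answer:
    """Answer a free-text question over the knowledge graph.

    With retrieved triples, the generator composes an answer grounded in
    them; a neighborhood answer lists each retrieved fact. When no mention
    links, the answer is flagged as not available within the knowledge
    base and delegated to the generator's fallback (``fallback_used``).
    """
    extractor = extractor or DictionaryExtractor(graph)
    generator = generator or TemplateGenerator()
    plan = QueryPlan()
    try:
        plan.mentions = extractor.extract(question)
    except Exception as exc:  # contract: component failures carry the stage
        raise PipelineError("extract", str(exc)) from exc
    plan.linked = _link_mentions(plan.mentions, index, threshold) if len(index) else [
        (m.text, None) for m in plan.mentions
    ]
    linked_ids: list[str] = []
    for _, result in plan.linked:
        if result is not None and result.idisk_id not in linked_ids:
            linked_ids.append(result.idisk_id)
    if not linked_ids:
        plan.fallback_used = True
        return Answer(generator.fallback(question), plan)
    intent = detect_intent(question)
    try:
        relation, cypher, query = plan_query(graph, linked_ids, intent)
    except RoutingError as exc:
        raise PipelineError("plan", str(exc)) from exc
    plan.relation = relation
    plan.cypher = cypher
    plan.query = query
    plan.triples = retrieve(graph, query, holdout)
    if query["kind"] == "edge":
        subject = graph.get(query["head"]).preferred_name
        obj = graph.get(query["tail"]).preferred_name
        if plan.triples:
            text = f"True. {subject} {_VERB[relation]} {obj}."
        else:
            text = (
                f"False. No fact in the knowledge base states that "
                f"{subject} {_VERB[relation]} {obj}."
            )
        return Answer(text, plan)
    concept = graph.get(query["concept"])
    if not plan.triples:
        return Answer(
            f"No {query['target_type']} facts recorded for {concept.preferred_name}.",
            plan,
        )
    if isinstance(generator, TemplateGenerator):
        # deterministic list answer grounded only in the retrieved triples
        others = []
        for t in plan.triples:
            other = t.tail_id if t.head_id == concept.idisk_id else t.head_id
            others.append(graph.get(other).preferred_name)
        header = f"{concept.preferred_name} {_VERB[relation]}:"
        body = "\n".join(f"- {name}" for name in others)
        return Answer(f"{header}\n{body}", plan)
    facts = [render_triple(graph, t) for t in plan.triples]
    return Answer(generator.compose(question, facts), plan)


def answer_tf(
    question: str,
    graph: KnowledgeGraph,
    index: EntityVectorIndex,
    extractor: Optional[MentionExtractor] = None,
    threshold: float = DEFAULT_THRESHOLD,
    holdout: frozenset[str] = frozenset(),
) -> Optional[bool]:
    """Answer a true-or-false question; None means abstain (scored wrong).

    True iff the edge routed from the two linked concepts exists in the
    graph and is visible under the holdout set.
    """
    extractor = extractor or DictionaryExtractor(graph)
    mentions = extractor.extract(question)
    linked = _link_mentions(mentions, index, threshold) if len(index) else []
    ids: list[str] = []
    for _, result in linked:
        if result is not None and result.idisk_id not in ids:
            ids.append(result.idisk_id)
    if len(ids) < 2:
        return None
    try:
        _, _, query = plan_query(graph, ids[:2], None)
    except (PipelineError, RoutingError):
        return None
    return bool(retrieve(graph, query, holdout))


def answer_mcq(
    question: str,
    options: Sequence[str],
    graph: KnowledgeGraph,
    index: EntityVectorIndex,
    extractor: Optional[MentionExtractor] = None,
    threshold: float = DEFAULT_THRESHOLD,
    holdout: frozenset[str] = frozenset(),
) -> str:
    """Answer a multiple-choice question by checking each option's triple.

    Chooses the first option whose linked concept is retrieved as a
    neighbor of the question subject under the routed relation; otherwise
    the "None of the above" option when present, else the abstain code.
    """
    extractor = extractor or DictionaryExtractor(graph)
    mentions = extractor.extract(question)
    linked = _link_mentions(mentions, index, threshold) if len(index) else []
    subject_id: Optional[str] = None
    for _, result in linked:
        if result is not None:
            subject_id = result.idisk_id
            break
    if subject_id is None:
        return NONE_OPTION if NONE_OPTION in options else ABSTAIN
    intent = detect_intent(question)
    if intent is None:
        return ABSTAIN
    try:
        _, _, query = plan_query(graph, [subject_id], intent)
    except (PipelineError, RoutingError):
        return ABSTAIN
    triples = retrieve(graph, query, holdout)
    neighbor_ids = set()
    for t in triples:
        neighbor_ids.add(t.tail_id if t.head_id == subject_id else t.head_id)
    for option in options:
        if option == NONE_OPTION:
            continue
        result = index.link(option, threshold)
        if result is not None and result.idisk_id in neighbor_ids:
            return option
    return NONE_OPTION if NONE_OPTION in options else ABSTAIN


class KGAnswerer:
    """Adapter exposing the pipeline as a benchmark system callable.

    Maps a benchmark item to the string answer the scorer expects
    ("True"/"False", an option text, or the abstain code).
    """

    def __init__(
        self,
        graph: KnowledgeGraph,
        index: EntityVectorIndex,
        extractor: Optional[MentionExtractor] = None,
        threshold: float = DEFAULT_THRESHOLD,
        holdout: frozenset[str] = frozenset(),
    ):
        self.graph = graph
        self.index = index
        self.extractor = extractor or DictionaryExtractor(graph)
        self.threshold = threshold
        self.holdout = holdout

    def __call__(self, item) -> str:
        if item.kind == "TF":
            verdict = answer_tf(
                item.stem,
                self.graph,
                self.index,
                self.extractor,
                self.threshold,
                self.holdout,
            )
            if verdict is None:
                return ABSTAIN
            return "True" if verdict else "False"
        return answer_mcq(
            item.stem,
            item.options,
            self.graph,
            self.index,
            self.extractor,
            self.threshold,
            self.holdout,
        )
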