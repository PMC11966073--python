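import random

import pytest
from hypothesis import settings

from dskb.kg import (
    CONCEPT_ATTRIBUTE_KEYS,
    Concept,
    ConceptType,
    KnowledgeGraph,
    RelationType,
    Triple,
    make_id,
)

settings.register_profile("suite", derandomize=True, max_examples=100)
settings.load_profile("suite")


def make_concept(ctype: ConceptType, n: int, name: str, **kwargs) -> Concept:
    return Concept(
        idisk_id=make_id(ctype, n), concept_type=ctype, preferred_name=name, **kwargs
    )


@pytest.fixture
def small_graph() -> KnowledgeGraph:
    """Five concepts, three mixed-relation triples around one ingredient."""
    g = KnowledgeGraph()
    g.add_concept(make_concept(ConceptType.DSI, 1, "Ginkgo"))
    g.add_concept(make_concept(ConceptType.DISEASE, 1, "Tinnitus"))
    g.add_concept(make_concept(ConceptType.DRUG, 1, "Warfarin"))
    g.add_concept(make_concept(ConceptType.SYMPTOM, 1, "Headache"))
    g.add_concept(make_concept(ConceptType.DSP, 1, "Ginkgo Caps", attributes={"company_name": "Acme"}))
    g.add_triple(Triple("DI0000001", RelationType.IS_EFFECTIVE_FOR, "DZ0000001", sources={"mskcc"}))
    g.add_triple(Triple("DI0000001", RelationType.INTERACTS_WITH, "DR0000001", sources={"mskcc"}))
    g.add_triple(Triple("DP0000001", RelationType.HAS_INGREDIENT, "DI0000001", sources={"dsld"}))
    return g


@pytest.fixture
def worked_graph() -> KnowledgeGraph:
    """Graph holding the canonical worked examples.

    Vitamin C is effective for the common cold; Omega-3 Fatty Acids are
    effective for six diseases; three extra diseases serve as multiple-
    choice distractors.
    """
    g = KnowledgeGraph()
    g.add_concept(make_concept(ConceptType.DSI, 1, "Vitamin C"))
    g.add_concept(make_concept(ConceptType.DSI, 2, "Omega-3 Fatty Acids"))
    diseases = [
        "Common cold",
        "Cardiovascular disease",
        "Lupus",
        "Cancer",
        "Depression",
        "High cholesterol",
        "Atherosclerosis",
        "Bladder stones",
        "Stroke",
        "Bleeding hemorrhoids",
    ]
    for i, name in enumerate(diseases, start=1):
        g.add_concept(make_concept(ConceptType.DISEASE, i, name))
    g.add_triple(
        Triple("DI0000001", RelationType.IS_EFFECTIVE_FOR, "DZ0000001", sources={"mskcc"})
    )
    for i in range(2, 8):  # the six Omega-3 diseases
        g.add_triple(
            Triple(
                "DI0000002",
                RelationType.IS_EFFECTIVE_FOR,
                make_id(ConceptType.DISEASE, i),
                sources={"mskcc"},
            )
        )
    return g


def random_graph(rng: random.Random) -> KnowledgeGraph:
    """Small random graph with synonyms, attributes and provenance."""
    g = KnowledgeGraph()
    per_type = {t: rng.randint(0, 4) for t in ConceptType}
    per_type[ConceptType.DSI] = rng.randint(1, 5)
    for ctype, count in per_type.items():
        for i in range(1, count + 1):
            attrs = {}
            if rng.random() < 0.5:
                attrs[rng.choice(CONCEPT_ATTRIBUTE_KEYS)] = f"v{rng.randint(0, 9)}"
            g.add_concept(
                Concept(
                    idisk_id=make_id(ctype, i),
                    concept_type=ctype,
                    preferred_name=f"{ctype.value} {i}",
                    synonyms={f"alt {ctype.value} {i}"} if rng.random() < 0.4 else set(),
                    cui=f"C{rng.randint(1, 99):07d}" if rng.random() < 0.5 else None,
                    attributes=attrs,
                    sources={rng.choice("abc")},
                )
            )
    heads = {t: [c for c in g.concepts.values() if c.concept_type is t] for t in ConceptType}
    from dskb.kg import ROUTING

    for (htype, ttype), rel in ROUTING.items():
        for h in heads[htype]:
            for t in heads[ttype]:
                if rng.random() < 0.3:
                    attrs = {}
                    if rel is RelationType.IS_EFFECTIVE_FOR and rng.random() < 0.5:
                        attrs["effectiveness_rating"] = "effective"
                    if rel is RelationType.INTERACTS_WITH and rng.random() < 0.5:
                        attrs["interaction_rating"] = "major"
                    g.add_triple(
                        Triple(h.idisk_id, rel, t.idisk_id, attributes=attrs,
                               sources={rng.choice("abc")})
                    )
    return g
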