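"""Benchmark question generation and bootstrap accuracy evaluation.

True-or-false items are phrased from existing graph triples (gold True)
and from uniformly sampled same-type non-edges (gold False). Multiple-
choice items present the gold answer among three same-type distractors
plus a "None of the above" option (five options total); a configurable
fraction omits the true answer so "None of the above" is gold.

Scoring follows a bootstrap protocol: a fixed-size sample is drawn from
the question pool (with replacement by default), answered by the system
under test, and the per-repetition accuracies are aggregated — by
default 10 repetitions of 100 questions, i.e. 1000 answers per system
per question type.
"""

from __future__ import annotations

import json
import logging
import random
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

from .kg import ConceptType, KnowledgeGraph, RelationType
from .rag import NONE_OPTION

logger = logging.getLogger(__name__)

#: Question categories and the relation each one probes.
CATEGORY_RELATION = {
    "DS-disease": RelationType.IS_EFFECTIVE_FOR,
    "DS-drug": RelationType.INTERACTS_WITH,
}
_CATEGORY_TAIL = {
    "DS-disease": ConceptType.DISEASE,
    "DS-drug": ConceptType.DRUG,
}
_TF_STEM = {
    "DS-disease": "Is it true that {subject} is effective for {object}?",
    "DS-drug": "Is it true that {subject} interacts with {object}?",
}
_MCQ_STEM = {
    "DS-disease": "Out of the given list, which disease is {subject} effective for?",
    "DS-drug": "Out of the given list, which drug does {subject} interact with?",
}


@dataclass
class QAItem:
    kind: str  # "TF" | "MCQ"
    category: str  # "DS-disease" | "DS-drug"
    stem: str
    gold: str  # "True"/"False" or the gold option text
    options: list[str] = field(default_factory=list)  # MCQ only, 5 options
    provenance: Optional[tuple[str, str, str]] = None  # (head, relation, tail) ids

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": self.kind,
                "category": self.category,
                "stem": self.stem,
                "options": self.options,
                "gold": self.gold,
                "provenance": self.provenance,
            }
        )


def _category_triples(graph: KnowledgeGraph, category: str):
    relation = CATEGORY_RELATION[category]
    return sorted(
        (t for t in graph.triples if t.relation is relation),
        key=lambda t: (t.head_id, t.tail_id),
    )


def _subjects_and_tails(graph: KnowledgeGraph, category: str):
    tail_type = _CATEGORY_TAIL[category]
    subjects = sorted(
        c.idisk_id
        for c in graph.concepts.values()
        if c.concept_type is ConceptType.DSI
    )
    tails = sorted(
        c.idisk_id for c in graph.concepts.values() if c.concept_type is tail_type
    )
    return subjects, tails


def generate_tf(
    graph: KnowledgeGraph,
    category: str,
    n: int,
    rng: random.Random,
    positive_ratio: float = 0.5,
) -> list[QAItem]:
    """Generate true-or-false items for one category; seeded, reproducible.

    Positives restate an existing triple; negatives state a uniformly
    sampled non-edge between a supplement ingredient and a same-type tail.
    If the graph has too few non-edges, fewer negatives are emitted (logged).
    """
    triples = _category_triples(graph, category)
    if not triples:
        raise ValueError(f"graph has no {category} triples")
    relation = CATEGORY_RELATION[category]
    subjects, tails = _subjects_and_tails(graph, category)
    n_pos = round(n * positive_ratio)
    n_neg = n - n_pos
    items: list[QAItem] = []
    for t in (rng.choices(triples, k=n_pos) if triples else []):
        stem = _TF_STEM[category].format(
            subject=graph.get(t.head_id).preferred_name,
            object=graph.get(t.tail_id).preferred_name,
        )
        items.append(
            QAItem(
                kind="TF",
                category=category,
                stem=stem,
                gold="True",
                provenance=(t.head_id, relation.value, t.tail_id),
            )
        )
    edge_set = {(t.head_id, t.tail_id) for t in triples}
    n_non_edges = len(subjects) * len(tails) - len(edge_set)
    if n_non_edges < n_neg:
        logger.warning(
            "only %d non-edges available for %d negatives", n_non_edges, n_neg
        )
        n_neg = n_non_edges
    produced = 0
    while produced < n_neg:
        head = rng.choice(subjects)
        tail = rng.choice(tails)
        if (head, tail) in edge_set:
            continue
        stem = _TF_STEM[category].format(
            subject=graph.get(head).preferred_name,
            object=graph.get(tail).preferred_name,
        )
        items.append(
            QAItem(
                kind="TF",
                category=category,
                stem=stem,
                gold="False",
                provenance=(head, relation.value, tail),
            )
        )
        produced += 1
    return items


def generate_mcq(
    graph: KnowledgeGraph,
    category: str,
    n: int,
    rng: random.Random,
    none_gold_fraction: float = 0.2,
) -> list[QAItem]:
    """Generate five-option multiple-choice items for one category.

    Each item has one gold answer, three same-type distractors not linked
    to the subject, and a final "None of the above" option. With
    probability ``none_gold_fraction`` the true answer is omitted and
    "None of the above" is gold. Items whose subject lacks enough
    distractors are skipped with a log entry.
    """
    triples = _category_triples(graph, category)
    if not triples:
        raise ValueError(f"graph has no {category} triples")
    _, tails = _subjects_and_tails(graph, category)
    linked_by_subject: dict[str, set[str]] = {}
    for t in triples:
        linked_by_subject.setdefault(t.head_id, set()).add(t.tail_id)
    relation = CATEGORY_RELATION[category]
    items: list[QAItem] = []
    attempts = 0
    while len(items) < n and attempts < 20 * n:
        attempts += 1
        t = rng.choice(triples)
        candidates = [
            x for x in tails if x not in linked_by_subject[t.head_id]
        ]
        none_gold = rng.random() < none_gold_fraction
        need = 4 if none_gold else 3
        if len(candidates) < need:
            logger.warning("too few distractors for %s; item skipped", t.head_id)
            continue
        distractors = rng.sample(candidates, need)
        if none_gold:
            shown = list(distractors)
            gold = NONE_OPTION
        else:
            shown = [t.tail_id] + distractors
            gold = graph.get(t.tail_id).preferred_name
        names = [graph.get(x).preferred_name for x in shown]
        rng.shuffle(names)
        options = names + [NONE_OPTION]
        stem = _MCQ_STEM[category].format(
            subject=graph.get(t.head_id).preferred_name
        )
        items.append(
            QAItem(
                kind="MCQ",
                category=category,
                stem=stem,
                gold=gold,
                options=options,
                provenance=(t.head_id, relation.value, t.tail_id),
            )
        )
    if len(items) < n:
        logger.warning("generated %d of %d requested items", len(items), n)
    return items


@dataclass
class BootstrapReport:
    """Accuracy distribution over bootstrap repetitions."""

    accuracies: list[float]
    sample_size: int
    per_category: dict[str, float]

    @property
    def mean(self) -> float:
        return sum(self.accuracies) / len(self.accuracies)

    @property
    def total_answered(self) -> int:
        return len(self.accuracies) * self.sample_size


System = Callable[[QAItem], str]


def bootstrap_eval(
    system: System,
    pool: Sequence[QAItem],
    sample_size: int = 100,
    reps: int = 10,
    rng: Optional[random.Random] = None,
    with_replacement: bool = True,
) -> BootstrapReport:
    """Score a system on repeated random question samples.

    Each repetition draws ``sample_size`` questions from the pool (with
    replacement by default) and computes accuracy; the report aggregates
    the per-repetition accuracies and a per-category breakdown, answering
    ``reps * sample_size`` questions in total.
    """
    if not pool:
        raise ValueError("question pool is empty")
    if not with_replacement and sample_size > len(pool):
        raise ValueError("sample_size exceeds pool for sampling without replacement")
    rng = rng or random.Random(0)
    accuracies: list[float] = []
    cat_correct: dict[str, int] = {}
    cat_total: dict[str, int] = {}
    for _ in range(reps):
        sample = (
            rng.choices(pool, k=sample_size)
            if with_replacement
            else rng.sample(list(pool), sample_size)
        )
        correct = 0
        for item in sample:
            got = system(item)
            ok = got == item.gold
            correct += ok
            cat_correct[item.category] = cat_correct.get(item.category, 0) + ok
            cat_total[item.category] = cat_total.get(item.category, 0) + 1
        accuracies.append(correct / sample_size)
    per_category = {
        c: cat_correct[c] / cat_total[c] for c in sorted(cat_total)
    }
    return BootstrapReport(accuracies, sample_size, per_category)


def oracle_system(item: QAItem) -> str:
    """Reference system that reads the gold answer (upper bound = 1.0)."""
    return item.gold
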