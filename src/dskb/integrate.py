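"""Greedy cross-source entity integration and triple construction.

For each concept type the entity vocabulary is initialized from a seed
source, then records from later sources are folded in one at a time: a
record merges into an existing concept iff its merge key matches,
otherwise it founds a new concept. Merge keys follow the integration
rules of the upstream knowledge base:

* ingredients, diseases, symptoms, drugs — same CUI OR identical
  normalized term name;
* products — same (product name, company name) pair.

Every resulting concept receives a unique, deterministic, type-prefixed
identifier. A merge ledger maps every ingested record to its concept and
records the reason, so integration is fully auditable. Assertions and
product–ingredient pairs then become deduplicated triples whose relation
is fixed by the type-pair routing table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .ingest import (
    AssertionRecord,
    IngredientRecord,
    ProductRecord,
    clean_ingredient_name,
    group_synonyms,
    unify_field_variants,
)
from .kg import (
    Concept,
    ConceptType,
    KnowledgeGraph,
    RelationType,
    Triple,
    make_id,
    normalize_name,
    route_relation,
)
from .mapping import VocabularyEntry, Matcher, default_matcher, map_name

logger = logging.getLogger(__name__)

RecordKey = tuple[str, str]  # (source label, record id)

_CATEGORY_TO_TYPE = {
    "disease": ConceptType.DISEASE,
    "drug": ConceptType.DRUG,
    "symptom": ConceptType.SYMPTOM,
    "therapeutic class": ConceptType.TC,
    "organ system": ConceptType.SOC,
}

_MAPPED_TYPES = (
    ConceptType.DSI,
    ConceptType.DISEASE,
    ConceptType.DRUG,
    ConceptType.SYMPTOM,
)

_RATING_KEY = {
    RelationType.IS_EFFECTIVE_FOR: "effectiveness_rating",
    RelationType.INTERACTS_WITH: "interaction_rating",
}


@dataclass
class EntityRecord:
    """A normalized source entity ready for integration."""

    source: str
    record_id: str
    concept_type: ConceptType
    name: str
    synonyms: list[str] = field(default_factory=list)
    cui: Optional[str] = None
    attributes: dict[str, str] = field(default_factory=dict)
    #: all ingest-level record keys this entity record stands for
    member_keys: list[RecordKey] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.member_keys:
            self.member_keys = [(self.source, self.record_id)]

    def names(self) -> list[str]:
        return [self.name] + self.synonyms


@dataclass
class MergeDecision:
    key: RecordKey
    idisk_id: str
    reason: str  # same-CUI | identical-name | product-name+company | new-entity


@dataclass
class MergeLedger:
    """Total map from ingested record keys to concept ids, with reasons."""

    assignments: dict[RecordKey, str] = field(default_factory=dict)
    decisions: list[MergeDecision] = field(default_factory=list)
    conflicts: list[dict] = field(default_factory=list)

    def assign(self, key: RecordKey, idisk_id: str, reason: str) -> None:
        self.assignments[key] = idisk_id
        self.decisions.append(MergeDecision(key, idisk_id, reason))


class EntityResolver:
    """Name/CUI/product-key lookup into the integrated concept set."""

    def __init__(self) -> None:
        self.by_name: dict[tuple[ConceptType, str], str] = {}
        self.by_cui: dict[tuple[ConceptType, str], str] = {}
        self.by_product_key: dict[tuple[str, str], str] = {}

    def register(self, ctype: ConceptType, idisk_id: str, record: EntityRecord) -> None:
        for name in record.names():
            self.by_name.setdefault((ctype, normalize_name(name)), idisk_id)
        if record.cui:
            self.by_cui.setdefault((ctype, record.cui), idisk_id)

    def resolve(
        self,
        ctype: ConceptType,
        name: Optional[str] = None,
        cui: Optional[str] = None,
    ) -> Optional[str]:
        if cui is not None:
            hit = self.by_cui.get((ctype, cui))
            if hit is not None:
                return hit
        if name is not None:
            return self.by_name.get((ctype, normalize_name(name)))
        return None


def _source_rank(source: str, seed_order: Sequence[str]) -> tuple[int, str]:
    try:
        return (seed_order.index(source), source)
    except ValueError:
        return (len(seed_order), source)


def integrate_entities(
    records_by_type: dict[ConceptType, list[EntityRecord]],
    seed_order: Sequence[str],
) -> tuple[KnowledgeGraph, MergeLedger, EntityResolver]:
    """Greedy integration of per-type entity records into concepts.

    Records are folded in deterministic order (seed-source first, then by
    source label and record id), so re-running on identical input
    reproduces identical identifiers. Returns a graph holding only
    concepts (no triples yet), the merge ledger, and a resolver for
    subsequent triple construction.
    """
    graph = KnowledgeGraph()
    ledger = MergeLedger()
    resolver = EntityResolver()
    for ctype in ConceptType:
        records = sorted(
            records_by_type.get(ctype, []),
            key=lambda r: (_source_rank(r.source, seed_order), r.record_id),
        )
        counter = 0
        for rec in records:
            existing, reason = _find_merge_target(ctype, rec, resolver)
            if existing is None:
                counter += 1
                cid = make_id(ctype, counter)
                concept = Concept(
                    idisk_id=cid,
                    concept_type=ctype,
                    preferred_name=rec.name,
                    synonyms={s for s in rec.synonyms if normalize_name(s) != normalize_name(rec.name)},
                    cui=rec.cui,
                    attributes=dict(rec.attributes),
                    sources={rec.source},
                )
                graph.add_concept(concept)
                if ctype is ConceptType.DSP:
                    resolver.by_product_key.setdefault(_product_key(rec), cid)
                resolver.register(ctype, cid, rec)
                for key in rec.member_keys:
                    ledger.assign(key, cid, "new-entity")
            else:
                _merge_into(graph.concepts[existing], rec, ledger)
                resolver.register(ctype, existing, rec)
                if ctype is ConceptType.DSP:
                    resolver.by_product_key.setdefault(_product_key(rec), existing)
                for name in rec.names():
                    graph._index_name(graph.concepts[existing], name)
                for key in rec.member_keys:
                    ledger.assign(key, existing, reason)
    return graph, ledger, resolver


def _product_key(rec: EntityRecord) -> tuple[str, str]:
    return (
        normalize_name(rec.name),
        normalize_name(rec.attributes.get("company_name", "")),
    )


def _find_merge_target(
    ctype: ConceptType, rec: EntityRecord, resolver: EntityResolver
) -> tuple[Optional[str], str]:
    if ctype is ConceptType.DSP:
        hit = resolver.by_product_key.get(_product_key(rec))
        return hit, "product-name+company"
    if rec.cui is not None:
        hit = resolver.by_cui.get((ctype, rec.cui))
        if hit is not None:
            return hit, "same-CUI"
    for name in rec.names():
        hit = resolver.by_name.get((ctype, normalize_name(name)))
        if hit is not None:
            return hit, "identical-name"
    return None, "new-entity"


def _merge_into(concept: Concept, rec: EntityRecord, ledger: MergeLedger) -> None:
    pref_norm = normalize_name(concept.preferred_name)
    for name in rec.names():
        if normalize_name(name) != pref_norm:
            concept.synonyms.add(name)
    concept.sources.add(rec.source)
    if rec.cui is not None:
        if concept.cui is None:
            concept.cui = rec.cui
        elif concept.cui != rec.cui:
            ledger.conflicts.append(
                {
                    "field": "cui",
                    "idisk_id": concept.idisk_id,
                    "kept": concept.cui,
                    "dropped": rec.cui,
                    "source": rec.source,
                }
            )
    # attribute merge: earlier (higher-priority) source wins, conflicts logged
    for k, v in rec.attributes.items():
        if k not in concept.attributes:
            concept.attributes[k] = v
        elif concept.attributes[k] != v:
            ledger.conflicts.append(
                {
                    "field": k,
                    "idisk_id": concept.idisk_id,
                    "kept": concept.attributes[k],
                    "dropped": v,
                    "source": rec.source,
                }
            )


def build_triples(
    graph: KnowledgeGraph,
    resolver: EntityResolver,
    assertions: Sequence[AssertionRecord],
    products: Sequence[ProductRecord],
) -> list[dict]:
    """Construct deduplicated triples from assertions and product contents.

    Each assertion becomes one triple whose relation is routed from the
    endpoint types; each product–ingredient pair becomes a has_ingredient
    triple. Rating text is stored as a triple attribute where the schema
    defines one (effectiveness rating on ingredient–disease edges,
    interaction rating on ingredient–drug edges). Records naming an
    entity absent from the integrated concept set are skipped and
    returned in the skip log.
    """
    skipped: list[dict] = []
    for rec in sorted(assertions, key=lambda r: (r.source, r.record_id)):
        head = resolver.resolve(ConceptType.DSI, name=rec.subject_name)
        ttype = _CATEGORY_TO_TYPE[rec.object_category]
        tail = resolver.resolve(ttype, name=rec.object_name)
        if head is None or tail is None:
            which = "subject" if head is None else "object"
            skipped.append(
                {
                    "source": rec.source,
                    "record_id": rec.record_id,
                    "reason": f"unmapped {which}",
                    "subject": rec.subject_name,
                    "object": rec.object_name,
                }
            )
            logger.warning(
                "skipped assertion %s/%s: unmapped %s",
                rec.source,
                rec.record_id,
                which,
            )
            continue
        relation, _ = route_relation(ConceptType.DSI, ttype)
        attrs: dict[str, str] = {}
        if rec.rating_text:
            key = _RATING_KEY.get(relation)
            if key is not None:
                attrs[key] = rec.rating_text
            else:
                logger.debug(
                    "rating on %s edge has no schema attribute; dropped",
                    relation.value,
                )
        graph.add_triple(
            Triple(head, relation, tail, attributes=attrs, sources={rec.source})
        )
    for prod in sorted(products, key=lambda p: (p.source, p.record_id)):
        pid = resolver.by_product_key.get(
            (normalize_name(prod.product_name), normalize_name(prod.company_name))
        )
        if pid is None:
            skipped.append(
                {
                    "source": prod.source,
                    "record_id": prod.record_id,
                    "reason": "unmapped product",
                    "subject": prod.product_name,
                }
            )
            continue
        for ing in prod.ingredient_names:
            iid = resolver.resolve(ConceptType.DSI, name=ing)
            if iid is None:
                skipped.append(
                    {
                        "source": prod.source,
                        "record_id": prod.record_id,
                        "reason": "unmapped ingredient",
                        "object": ing,
                    }
                )
                continue
            graph.add_triple(
                Triple(
                    pid,
                    RelationType.HAS_INGREDIENT,
                    iid,
                    sources={prod.source},
                )
            )
    return skipped


# -- end-to-end pipeline -----------------------------------------------------


@dataclass
class SourceData:
    """All records ingested from one source database."""

    label: str
    products: list[ProductRecord] = field(default_factory=list)
    ingredients: list[IngredientRecord] = field(default_factory=list)
    assertions: list[AssertionRecord] = field(default_factory=list)


@dataclass
class BuildResult:
    graph: KnowledgeGraph
    ledger: MergeLedger
    resolver: EntityResolver
    skipped_triples: list[dict]
    dropped_names: list[tuple[str, str]]  # (source, dropped ingredient name)


def build_kg(
    sources: Sequence[SourceData],
    vocab: Sequence[VocabularyEntry],
    alias_table: Optional[dict[str, str]] = None,
    seed_order: Optional[Sequence[str]] = None,
    matcher: Matcher = default_matcher,
    min_similarity: float = 0.7,
) -> BuildResult:
    """Full construction pipeline: clean, normalize, integrate, triple-build.

    ``seed_order`` lists source labels in integration priority; the first
    source per type seeds the entity vocabulary (default: the order the
    sources are given).
    """
    alias_table = alias_table or {}
    if seed_order is None:
        seed_order = [s.label for s in sources]
    records_by_type: dict[ConceptType, list[EntityRecord]] = {
        t: [] for t in ConceptType
    }
    dropped: list[tuple[str, str]] = []
    all_assertions: list[AssertionRecord] = []
    all_products: list[ProductRecord] = []

    for src in sources:
        # nonsense-name filter on ingredient records
        kept_ingredients = []
        for rec in src.ingredients:
            if clean_ingredient_name(rec.name):
                kept_ingredients.append(rec)
            else:
                dropped.append((src.label, rec.name))
                logger.info("dropped nonsense ingredient %r from %s", rec.name, src.label)
        # synonym grouping, then one entity record per group
        for group in group_synonyms(kept_ingredients):
            canonical = group.canonical_name
            cui = None
            for name in group.names:
                cui = map_name(name, ConceptType.DSI, vocab, matcher, min_similarity)
                if cui is not None:
                    break
            attrs = {}
            for member in group.members:
                for key, val in (
                    ("background", member.background),
                    ("safety", member.safety),
                    ("mechanism_of_action", member.mechanism),
                    ("source_material", member.source_material),
                ):
                    if val and key not in attrs:
                        attrs[key] = val
            records_by_type[ConceptType.DSI].append(
                EntityRecord(
                    source=src.label,
                    record_id=group.members[0].record_id,
                    concept_type=ConceptType.DSI,
                    name=canonical,
                    synonyms=[n for n in group.names if n != canonical],
                    cui=cui,
                    attributes=attrs,
                    member_keys=[(src.label, m.record_id) for m in group.members],
                )
            )
        # products: unify address variants, clean ingredient lists
        for prod in src.products:
            address = unify_field_variants([prod.company_address], alias_table)[0]
            clean_list = [n for n in prod.ingredient_names if clean_ingredient_name(n)]
            for n in prod.ingredient_names:
                if not clean_ingredient_name(n):
                    dropped.append((src.label, n))
            prod = ProductRecord(
                source=prod.source,
                record_id=prod.record_id,
                product_name=prod.product_name,
                company_name=prod.company_name,
                company_address=address,
                purpose=prod.purpose,
                risk=prod.risk,
                ingredient_names=clean_list,
            )
            all_products.append(prod)
            attrs = {
                "company_name": prod.company_name,
                "company_address": address,
            }
            if prod.purpose:
                attrs["product_purpose"] = prod.purpose
            if prod.risk:
                attrs["product_risk"] = prod.risk
            records_by_type[ConceptType.DSP].append(
                EntityRecord(
                    source=src.label,
                    record_id=prod.record_id,
                    concept_type=ConceptType.DSP,
                    name=prod.product_name,
                    attributes=attrs,
                )
            )
        # assertion objects found new disease/drug/symptom/TC/SOC entities
        seen_objects: set[tuple[ConceptType, str]] = set()
        for rec in src.assertions:
            all_assertions.append(rec)
            ttype = _CATEGORY_TO_TYPE[rec.object_category]
            key = (ttype, normalize_name(rec.object_name))
            if key in seen_objects:
                continue
            seen_objects.add(key)
            cui = (
                map_name(rec.object_name, ttype, vocab, matcher, min_similarity)
                if ttype in _MAPPED_TYPES
                else None
            )
            records_by_type[ttype].append(
                EntityRecord(
                    source=src.label,
                    record_id=f"{rec.record_id}:obj",
                    concept_type=ttype,
                    name=rec.object_name,
                    cui=cui,
                )
            )

    graph, ledger, resolver = integrate_entities(records_by_type, seed_order)
    skipped = build_triples(graph, resolver, all_assertions, all_products)
    return BuildResult(graph, ledger, resolver, skipped, dropped)
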