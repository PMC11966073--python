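"""Typed property-graph model for the dietary-supplement knowledge base.

The graph has seven concept types (supplement ingredients and products,
diseases, drugs, symptoms, therapeutic classes, organ classes) connected by
six relation types. Which relation holds between two concepts is fully
determined by the ordered pair of their types ("relation routing"), so the
schema is closed: there is exactly one relation per supported type pair.

Concepts carry a preferred name, synonyms, an optional controlled-vocabulary
identifier (CUI), a small set of typed attributes, and source provenance.
Triples are <head, relation, tail> with optional rating attributes; the
triple set is deduplicated — re-inserting an existing triple merges
provenance instead of creating a duplicate edge.
"""

from __future__ import annotations

import csv
import io
import os
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional


class ConceptType(str, Enum):
    """The seven concept categories of the knowledge base."""

    DSI = "DSI"  # dietary supplement ingredient
    DSP = "DSP"  # dietary supplement product
    DISEASE = "DISEASE"
    DRUG = "DRUG"
    SYMPTOM = "SYMPTOM"
    TC = "TC"  # therapeutic class
    SOC = "SOC"  # system organ class


class RelationType(str, Enum):
    """The six relation categories of the knowledge base."""

    IS_EFFECTIVE_FOR = "is_effective_for"
    HAS_THERAPEUTIC_CLASS = "has_therapeutic_class"
    HAS_ADVERSE_EFFECT_ON = "has_adverse_effect_on"
    HAS_ADVERSE_REACTION = "has_adverse_reaction"
    HAS_INGREDIENT = "has_ingredient"
    INTERACTS_WITH = "interacts_with"


#: Allowed concept attribute keys (per-concept metadata columns).
CONCEPT_ATTRIBUTE_KEYS = (
    "company_name",
    "company_address",
    "product_purpose",
    "product_risk",
    "background",
    "safety",
    "mechanism_of_action",
    "source_material",
)

#: Allowed triple attribute keys (edge metadata).
TRIPLE_ATTRIBUTE_KEYS = ("interaction_rating", "effectiveness_rating")

#: Directed routing table: ordered (head type, tail type) -> relation.
#: This is a bijection between the six supported pairs and the six relations.
ROUTING: dict[tuple[ConceptType, ConceptType], RelationType] = {
    (ConceptType.DSP, ConceptType.DSI): RelationType.HAS_INGREDIENT,
    (ConceptType.DSI, ConceptType.DISEASE): RelationType.IS_EFFECTIVE_FOR,
    (ConceptType.DSI, ConceptType.SYMPTOM): RelationType.HAS_ADVERSE_REACTION,
    (ConceptType.DSI, ConceptType.DRUG): RelationType.INTERACTS_WITH,
    (ConceptType.DSI, ConceptType.TC): RelationType.HAS_THERAPEUTIC_CLASS,
    (ConceptType.DSI, ConceptType.SOC): RelationType.HAS_ADVERSE_EFFECT_ON,
}

_ID_PREFIX = {
    ConceptType.DSI: "DI",
    ConceptType.DSP: "DP",
    ConceptType.DISEASE: "DZ",
    ConceptType.DRUG: "DR",
    ConceptType.SYMPTOM: "SY",
    ConceptType.TC: "TC",
    ConceptType.SOC: "SC",
}


class RoutingError(ValueError):
    """No relation is defined for the given concept-type pair."""


class ReferentialError(KeyError):
    """A triple endpoint references a concept absent from the graph."""


class SchemaError(ValueError):
    """A value violates the graph schema (types, keys, uniqueness)."""


class UnknownConceptError(KeyError):
    """Lookup of a concept id that is not in the graph."""


class BulkParseError(ValueError):
    """A bulk-import file is malformed; carries file and line number."""

    def __init__(self, path: str, line: int, message: str):
        super().__init__(f"{path}:{line}: {message}")
        self.path = path
        self.line = line


def normalize_name(name: str) -> str:
    """Canonical form used for name equality: casefold + whitespace collapse."""
    return " ".join(name.split()).casefold()


def make_id(concept_type: ConceptType, n: int) -> str:
    """Type-prefixed zero-padded sequential identifier, e.g. DI0000001."""
    return f"{_ID_PREFIX[concept_type]}{n:07d}"


def route_relation(
    head_type: ConceptType, tail_type: ConceptType
) -> tuple[RelationType, bool]:
    """Return the unique relation for an ordered concept-type pair.

    Returns ``(relation, reversed)`` where ``reversed`` is True when the
    input pair is the reverse of the schema orientation (users name
    entities in either order; the stored edge direction is fixed).

    Raises :class:`RoutingError` for unsupported pairs, e.g. (DSI, DSI).
    """
    key = (head_type, tail_type)
    if key in ROUTING:
        return ROUTING[key], False
    rkey = (tail_type, head_type)
    if rkey in ROUTING:
        return ROUTING[rkey], True
    raise RoutingError(
        f"no relation defined between {head_type.value} and {tail_type.value}"
    )


@dataclass
class Concept:
    """A typed node: identifier, names, optional CUI, attributes, provenance."""

    idisk_id: str
    concept_type: ConceptType
    preferred_name: str
    synonyms: set[str] = field(default_factory=set)
    cui: Optional[str] = None
    attributes: dict[str, str] = field(default_factory=dict)
    sources: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.preferred_name or not self.preferred_name.strip():
            raise SchemaError("preferred_name must be nonempty")
        bad = set(self.attributes) - set(CONCEPT_ATTRIBUTE_KEYS)
        if bad:
            raise SchemaError(f"unknown concept attribute keys: {sorted(bad)}")

    def names(self) -> set[str]:
        return {self.preferred_name} | self.synonyms


@dataclass
class Triple:
    """A directed edge <head, relation, tail> with rating attributes."""

    head_id: str
    relation: RelationType
    tail_id: str
    attributes: dict[str, str] = field(default_factory=dict)
    sources: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        bad = set(self.attributes) - set(TRIPLE_ATTRIBUTE_KEYS)
        if bad:
            raise SchemaError(f"unknown triple attribute keys: {sorted(bad)}")

    @property
    def key(self) -> tuple[str, RelationType, str]:
        return (self.head_id, self.relation, self.tail_id)


class KnowledgeGraph:
    """In-memory property graph with a name index and deduplicated triples.

    Invariants maintained:

    * ``idisk_id`` is unique;
    * every triple endpoint exists and its relation matches the routing
      table for the endpoint types;
    * ``(head, relation, tail)`` is unique — duplicate inserts merge
      provenance and attributes, and each collapse is recorded in
      ``merge_log``;
    * the name index covers every preferred name and synonym.
    """

    def __init__(self) -> None:
        self.concepts: dict[str, Concept] = {}
        self._triples: dict[tuple[str, RelationType, str], Triple] = {}
        self.name_index: dict[tuple[ConceptType, str], str] = {}
        self.merge_log: list[dict] = []

    # -- concepts ---------------------------------------------------------

    def add_concept(self, concept: Concept) -> None:
        if concept.idisk_id in self.concepts:
            raise SchemaError(f"duplicate idisk_id {concept.idisk_id}")
        self.concepts[concept.idisk_id] = concept
        for name in concept.names():
            self._index_name(concept, name)

    def _index_name(self, concept: Concept, name: str) -> None:
        key = (concept.concept_type, normalize_name(name))
        # first writer wins: cross-concept name collisions are kept visible
        # in the merge log rather than silently re-pointed
        if key in self.name_index and self.name_index[key] != concept.idisk_id:
            self.merge_log.append(
                {
                    "event": "name-collision",
                    "name": name,
                    "kept": self.name_index[key],
                    "other": concept.idisk_id,
                }
            )
            return
        self.name_index[key] = concept.idisk_id

    def get(self, idisk_id: str) -> Concept:
        try:
            return self.concepts[idisk_id]
        except KeyError:
            raise UnknownConceptError(idisk_id) from None

    def lookup_name(
        self, concept_type: ConceptType, name: str
    ) -> Optional[str]:
        return self.name_index.get((concept_type, normalize_name(name)))

    # -- triples ----------------------------------------------------------

    @property
    def triples(self) -> list[Triple]:
        return list(self._triples.values())

    def __len__(self) -> int:
        return len(self._triples)

    def add_triple(self, triple: Triple) -> bool:
        """Insert a triple; returns True iff the graph changed.

        A duplicate ``(head, relation, tail)`` merges sources and
        attributes into the existing triple and returns False; the
        collapse is appended to ``merge_log``.
        """
        for endpoint in (triple.head_id, triple.tail_id):
            if endpoint not in self.concepts:
                raise ReferentialError(f"unknown triple endpoint {endpoint}")
        head = self.concepts[triple.head_id]
        tail = self.concepts[triple.tail_id]
        expected, reversed_ = route_relation(
            head.concept_type, tail.concept_type
        )
        if reversed_ or expected is not triple.relation:
            raise SchemaError(
                f"relation {triple.relation.value} inconsistent with types "
                f"({head.concept_type.value}, {tail.concept_type.value})"
            )
        existing = self._triples.get(triple.key)
        if existing is not None:
            existing.sources |= triple.sources
            for k, v in triple.attributes.items():
                existing.attributes.setdefault(k, v)
            self.merge_log.append(
                {
                    "event": "triple-merge",
                    "triple": (
                        triple.head_id,
                        triple.relation.value,
                        triple.tail_id,
                    ),
                    "sources": sorted(triple.sources),
                }
            )
            return False
        self._triples[triple.key] = triple
        return True

    def has_triple(
        self, head_id: str, relation: RelationType, tail_id: str
    ) -> bool:
        return (head_id, relation, tail_id) in self._triples

    def neighbors(
        self,
        concept_id: str,
        relation: Optional[RelationType] = None,
    ) -> list[Triple]:
        """All triples incident to a concept, optionally filtered by relation.

        Deterministic order: (relation code, neighbor id) so retrieved
        contexts — and hence generated answers — are stable across runs.
        """
        if concept_id not in self.concepts:
            raise UnknownConceptError(concept_id)
        out = [
            t
            for t in self._triples.values()
            if concept_id in (t.head_id, t.tail_id)
            and (relation is None or t.relation is relation)
        ]
        out.sort(
            key=lambda t: (
                t.relation.value,
                t.tail_id if t.head_id == concept_id else t.head_id,
            )
        )
        return out

    # -- equality (used by round-trip tests) -------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KnowledgeGraph):
            return NotImplemented
        if set(self.concepts) != set(other.concepts):
            return False
        for cid, c in self.concepts.items():
            o = other.concepts[cid]
            if (
                c.concept_type is not o.concept_type
                or c.preferred_name != o.preferred_name
                or c.synonyms != o.synonyms
                or c.cui != o.cui
                or c.attributes != o.attributes
                or c.sources != o.sources
            ):
                return False
        if set(self._triples) != set(other._triples):
            return False
        for key, t in self._triples.items():
            o = other._triples[key]
            if t.attributes != o.attributes or t.sources != o.sources:
                return False
        return True


# -- counts report ---------------------------------------------------------


@dataclass
class GraphCounts:
    """Per-type concept counts, per-relation and per-attribute counts.

    Totals are arithmetic sums of the per-row counts and are invariant
    under concept/triple reordering.
    """

    concept_counts: dict[str, int]
    relation_counts: dict[str, int]
    attribute_counts: dict[str, int]

    @property
    def concept_total(self) -> int:
        return sum(self.concept_counts.values())

    @property
    def relation_total(self) -> int:
        return sum(self.relation_counts.values())

    @property
    def attribute_total(self) -> int:
        return sum(self.attribute_counts.values())

    @classmethod
    def from_graph(cls, g: KnowledgeGraph) -> "GraphCounts":
        concept_counts = {t.value: 0 for t in ConceptType}
        for c in g.concepts.values():
            concept_counts[c.concept_type.value] += 1
        relation_counts = {r.value: 0 for r in RelationType}
        for t in g.triples:
            relation_counts[t.relation.value] += 1
        attribute_counts = {k: 0 for k in CONCEPT_ATTRIBUTE_KEYS}
        attribute_counts.update({k: 0 for k in TRIPLE_ATTRIBUTE_KEYS})
        for c in g.concepts.values():
            for k in c.attributes:
                attribute_counts[k] += 1
        for t in g.triples:
            for k in t.attributes:
                attribute_counts[k] += 1
        return cls(concept_counts, relation_counts, attribute_counts)


def table_totals(g: KnowledgeGraph) -> GraphCounts:
    """Counts report for a graph (concepts, relations, attributes + sums)."""
    return GraphCounts.from_graph(g)


# -- bulk export / import ---------------------------------------------------

_CONCEPT_HEADER = (
    ["idisk_id", "preferred_name", "synonyms", "cui"]
    + list(CONCEPT_ATTRIBUTE_KEYS)
    + ["sources"]
)
_REL_HEADER = ["head_id", "tail_id"] + list(TRIPLE_ATTRIBUTE_KEYS) + ["sources"]

_PIPE = "|"


def _join(values: Iterable[str]) -> str:
    return _PIPE.join(sorted(values))


def _split(value: str) -> set[str]:
    return set(v for v in value.split(_PIPE) if v) if value else set()


def export_bulk(g: KnowledgeGraph, outdir: str) -> dict[str, str]:
    """Write one CSV per concept type and one per relation type.

    The dialect is a plain UTF-8 header-row CSV compatible with
    property-graph bulk importers; multi-valued fields (synonyms, sources)
    are pipe-joined. Returns a mapping of table name -> file path.
    Thirteen files are always written, empty tables included.
    """
    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}
    for ctype in ConceptType:
        path = os.path.join(outdir, f"concepts_{ctype.value}.csv")
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(_CONCEPT_HEADER)
            rows = sorted(
                (c for c in g.concepts.values() if c.concept_type is ctype),
                key=lambda c: c.idisk_id,
            )
            for c in rows:
                w.writerow(
                    [c.idisk_id, c.preferred_name, _join(c.synonyms), c.cui or ""]
                    + [c.attributes.get(k, "") for k in CONCEPT_ATTRIBUTE_KEYS]
                    + [_join(c.sources)]
                )
        paths[f"concepts_{ctype.value}"] = path
    for rel in RelationType:
        path = os.path.join(outdir, f"relationships_{rel.value}.csv")
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(_REL_HEADER)
            rows = sorted(
                (t for t in g.triples if t.relation is rel),
                key=lambda t: (t.head_id, t.tail_id),
            )
            for t in rows:
                w.writerow(
                    [t.head_id, t.tail_id]
                    + [t.attributes.get(k, "") for k in TRIPLE_ATTRIBUTE_KEYS]
                    + [_join(t.sources)]
                )
        paths[f"relationships_{rel.value}"] = path
    return paths


def import_bulk(indir: str) -> KnowledgeGraph:
    """Rebuild a graph from :func:`export_bulk` output (round-trip identity).

    Raises :class:`BulkParseError` naming file and line on any malformed
    header or row.
    """
    g = KnowledgeGraph()
    for ctype in ConceptType:
        path = os.path.join(indir, f"concepts_{ctype.value}.csv")
        for lineno, row in _read_rows(path, _CONCEPT_HEADER):
            try:
                attrs = {
                    k: row[k]
                    for k in CONCEPT_ATTRIBUTE_KEYS
                    if row[k]
                }
                g.add_concept(
                    Concept(
                        idisk_id=row["idisk_id"],
                        concept_type=ctype,
                        preferred_name=row["preferred_name"],
                        synonyms=_split(row["synonyms"]),
                        cui=row["cui"] or None,
                        attributes=attrs,
                        sources=_split(row["sources"]),
                    )
                )
            except (SchemaError, KeyError) as exc:
                raise BulkParseError(path, lineno, str(exc)) from exc
    for rel in RelationType:
        path = os.path.join(indir, f"relationships_{rel.value}.csv")
        for lineno, row in _read_rows(path, _REL_HEADER):
            try:
                attrs = {k: row[k] for k in TRIPLE_ATTRIBUTE_KEYS if row[k]}
                g.add_triple(
                    Triple(
                        head_id=row["head_id"],
                        relation=rel,
                        tail_id=row["tail_id"],
                        attributes=attrs,
                        sources=_split(row["sources"]),
                    )
                )
            except (SchemaError, ReferentialError, KeyError) as exc:
                raise BulkParseError(path, lineno, str(exc)) from exc
    return g


def _read_rows(path: str, header: list[str]):
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            got = next(reader)
        except StopIteration:
            raise BulkParseError(path, 1, "missing header row") from None
        if got != header:
            raise BulkParseError(path, 1, f"bad header {got!r}")
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(header):
                raise BulkParseError(
                    path, lineno, f"expected {len(header)} fields, got {len(row)}"
                )
            yield lineno, dict(zip(header, row))


def to_cypher(g: KnowledgeGraph) -> str:
    """Emit openCypher MERGE statements for a live graph backend.

    Text-only adapter: nothing here requires a running server.
    """
    buf = io.StringIO()
    for cid in sorted(g.concepts):
        c = g.concepts[cid]
        name = c.preferred_name.replace("'", "\\'")
        buf.write(
            f"MERGE (n:{c.concept_type.value} {{idisk_id: '{cid}'}}) "
            f"SET n.preferred_name = '{name}';\n"
        )
    for t in sorted(g.triples, key=lambda t: (t.head_id, t.relation.value, t.tail_id)):
        buf.write(
            f"MATCH (h {{idisk_id: '{t.head_id}'}}), (t {{idisk_id: '{t.tail_id}'}}) "
            f"MERGE (h)-[:{t.relation.value}]->(t);\n"
        )
    return buf.getvalue()
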