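"""Synthetic multi-source fixtures with known ground truth.

Emulates the statistical structure of the upstream supplement databases —
cross-source entity overlap, ingredient synonymy, controlled-vocabulary
coverage, nonsense-name noise, and company-address spelling variants —
while recording exactly which true entity every emitted record denotes
and which triples the integrated graph should contain. The generator's
bookkeeping is the oracle for integration-recovery tests: on noiseless
settings the built graph must reproduce the ground-truth entity counts
and triple set exactly.

Entity names come from a pronounceable-syllable grammar, are globally
unique, and within each mapped category are kept mutually dissimilar
(string-similarity below the matcher's candidate floor) so that concept
mapping cannot cross-assign identifiers by near-miss. All randomness
flows from the single seed in the spec; identical specs produce
byte-identical fixture files.
"""

from __future__ import annotations

import difflib
import json
import os
import random
from dataclasses import asdict, dataclass, field
from typing import Optional

import yaml

from .ingest import AssertionRecord, IngredientRecord, ProductRecord, read_source
from .integrate import BuildResult, SourceData
from .kg import ConceptType, RelationType, normalize_name, route_relation
from .mapping import SEMANTIC_TYPE_FILTERS, VocabularyEntry

_CONSONANTS = "bdfglkmnprstvz"
_VOWELS = "aeiou"

#: Nonsense ingredient names the cleaning filter must drop.
_NOISE_NAMES = ["8", "%.", "42", "--", "7 7", "!", "9", "%%", "3.5", "_"]

#: Spelling variants per canonical country token, used for company
#: addresses; the matching alias table is emitted with the fixture.
_ADDRESS_VARIANTS = {
    "United States": ["U.S.A.", "United States of America", "USA"],
    "Canada": ["CAN", "Canada (CA)"],
    "Germany": ["Deutschland", "DE"],
}

_CATEGORY_OF_TYPE = {
    ConceptType.DISEASE: "disease",
    ConceptType.DRUG: "drug",
    ConceptType.SYMPTOM: "symptom",
    ConceptType.TC: "therapeutic class",
    ConceptType.SOC: "organ system",
}

PRODUCT_SOURCES = ("lnhpd", "dsld")
ASSERTION_SOURCES = ("mskcc", "nmcd")
ALL_SOURCES = ("lnhpd", "dsld", "mskcc", "nmcd")


@dataclass
class SynthSpec:
    """Study conditions for one synthetic corpus."""

    n_ingredients: int = 150
    n_products: int = 200
    n_diseases: int = 60
    n_drugs: int = 40
    n_symptoms: int = 30
    n_tcs: int = 12
    n_socs: int = 5
    n_assertions: int = 250
    synonym_rate: float = 0.2
    cross_source_overlap: float = 0.3
    cui_coverage: float = 0.9
    nonsense_noise_rate: float = 0.05
    address_variant_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "synonym_rate",
            "cross_source_overlap",
            "cui_coverage",
            "nonsense_noise_rate",
            "address_variant_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in (
            "n_ingredients",
            "n_products",
            "n_diseases",
            "n_drugs",
            "n_symptoms",
            "n_tcs",
            "n_socs",
            "n_assertions",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class TrueEntity:
    uid: str
    concept_type: ConceptType
    name: str
    synonyms: list[str] = field(default_factory=list)
    cui: Optional[str] = None
    group_id: Optional[str] = None

    def names(self) -> list[str]:
        return [self.name] + self.synonyms


@dataclass
class GroundTruth:
    """What integration should recover from the emitted records."""

    entity_counts: dict[str, int]  # concept-type code -> distinct entities emitted
    record_to_entity: dict[tuple[str, str], str]  # (source, record id) -> uid
    true_triples: set[tuple[str, str, str]]  # (head uid, relation code, tail uid)
    n_noise_records: int


@dataclass
class SynthResult:
    spec: SynthSpec
    sources: list[SourceData]
    vocabulary: list[VocabularyEntry]
    alias_table: dict[str, str]
    ground_truth: GroundTruth
    entities: dict[str, TrueEntity]


class _NameFactory:
    """Unique, pronounceable, per-category-dissimilar name generator."""

    def __init__(self, rng: random.Random, dissimilarity: float = 0.6):
        self.rng = rng
        self.used: set[str] = set()
        self.per_category: dict[str, list[str]] = {}
        self.dissimilarity = dissimilarity

    def _token(self) -> str:
        n = self.rng.randint(2, 3)
        return "".join(
            self.rng.choice(_CONSONANTS) + self.rng.choice(_VOWELS)
            for _ in range(n)
        ).capitalize()

    def make(self, category: str, n_tokens: int = 2) -> str:
        peers = self.per_category.setdefault(category, [])
        for _ in range(200):
            name = " ".join(self._token() for _ in range(n_tokens))
            key = normalize_name(name)
            if key in self.used:
                continue
            if any(
                difflib.SequenceMatcher(None, key, p).ratio() >= self.dissimilarity
                for p in peers
            ):
                continue
            self.used.add(key)
            peers.append(key)
            return name
        raise RuntimeError("name space exhausted; lower the entity counts")


def synthesize(spec: SynthSpec) -> SynthResult:
    """Generate per-source records, a vocabulary, and the ground truth."""
    rng = random.Random(spec.seed)
    names = _NameFactory(rng)
    entities: dict[str, TrueEntity] = {}

    def _new_entities(
        ctype: ConceptType, count: int, category: str, with_synonyms: bool
    ) -> list[TrueEntity]:
        out = []
        for i in range(count):
            uid = f"{ctype.value}:{i:04d}"
            syns = []
            if with_synonyms:
                k = 1 + (rng.random() < spec.synonym_rate)
                if rng.random() < spec.synonym_rate:
                    syns = [names.make(category) for _ in range(k)]
            cui = None
            if ctype in SEMANTIC_TYPE_FILTERS and rng.random() < spec.cui_coverage:
                cui = f"C{len(entities) + 1:07d}"
            e = TrueEntity(
                uid=uid,
                concept_type=ctype,
                name=names.make(category),
                synonyms=syns,
                cui=cui,
                group_id=f"GRP{i:04d}" if ctype is ConceptType.DSI else None,
            )
            entities[uid] = e
            out.append(e)
        return out

    ingredients = _new_entities(ConceptType.DSI, spec.n_ingredients, "DSI", True)
    diseases = _new_entities(ConceptType.DISEASE, spec.n_diseases, "DISEASE", False)
    drugs = _new_entities(ConceptType.DRUG, spec.n_drugs, "DRUG", False)
    symptoms = _new_entities(ConceptType.SYMPTOM, spec.n_symptoms, "SYMPTOM", False)
    tcs = _new_entities(ConceptType.TC, spec.n_tcs, "TC", False)
    socs = _new_entities(ConceptType.SOC, spec.n_socs, "SOC", False)

    # companies with canonical addresses
    countries = list(_ADDRESS_VARIANTS)
    companies = []
    for i in range(max(5, spec.n_products // 12)):
        companies.append(
            (
                names.make("COMPANY") + " Labs",
                f"{100 + i} {names.make('STREET')} Street, "
                f"{countries[i % len(countries)]}",
                countries[i % len(countries)],
            )
        )
    alias_table: dict[str, str] = {}
    for canonical, variants in _ADDRESS_VARIANTS.items():
        for v in variants:
            alias_table[v] = canonical

    products = []
    for i in range(spec.n_products):
        uid = f"DSP:{i:04d}"
        company, address, country = rng.choice(companies)
        e = TrueEntity(uid=uid, concept_type=ConceptType.DSP, name=names.make("DSP", 3))
        entities[uid] = e
        n_ing = rng.randint(1, 4)
        content = rng.sample(ingredients, min(n_ing, len(ingredients)))
        products.append((e, company, address, country, content))

    # assertions: distinct (ingredient, object) pairs per category
    object_pools = [diseases, drugs, symptoms, tcs, socs]
    weights = [len(p) for p in object_pools]
    assertion_pairs: list[tuple[TrueEntity, TrueEntity]] = []
    seen_pairs: set[tuple[str, str]] = set()
    guard = 0
    while len(assertion_pairs) < spec.n_assertions and guard < 50 * spec.n_assertions:
        guard += 1
        pool = rng.choices(object_pools, weights=weights)[0]
        subj = rng.choice(ingredients)
        obj = rng.choice(pool)
        if (subj.uid, obj.uid) in seen_pairs:
            continue
        seen_pairs.add((subj.uid, obj.uid))
        assertion_pairs.append((subj, obj))

    # -- emit per-source records -------------------------------------------
    record_to_entity: dict[tuple[str, str], str] = {}
    source_records: dict[str, SourceData] = {
        label: SourceData(label=label) for label in ALL_SOURCES
    }
    counters = {label: {"I": 0, "P": 0, "A": 0} for label in ALL_SOURCES}

    def _rid(label: str, kind: str) -> str:
        counters[label][kind] += 1
        return f"{kind}{counters[label][kind]:06d}"

    ingredient_sources = ("lnhpd", "dsld", "mskcc", "nmcd")

    def _emit_ingredient(e: TrueEntity, label: str, home: bool) -> None:
        rid = _rid(label, "I")
        record_to_entity[(label, rid)] = e.uid
        if not home and e.cui and rng.random() < spec.synonym_rate and e.synonyms:
            # synonym-only surface form: the merge must go through the CUI
            rec = IngredientRecord(
                source=label,
                record_id=rid,
                name=rng.choice(e.synonyms),
                synonyms=[],
                group_id=None,
            )
        else:
            rec = IngredientRecord(
                source=label,
                record_id=rid,
                name=e.name,
                synonyms=list(e.synonyms),
                group_id=e.group_id if label == "dsld" else None,
                background=f"Background of {e.name}." if label == "mskcc" else None,
                safety=f"Safety notes for {e.name}." if label == "lnhpd" else None,
                mechanism=f"Mechanism of {e.name}." if label == "mskcc" else None,
                source_material=f"Derived from {e.name}." if label == "lnhpd" else None,
            )
        source_records[label].ingredients.append(rec)

    for e in ingredients:
        home = rng.choice(ingredient_sources)
        _emit_ingredient(e, home, home=True)
        for label in ingredient_sources:
            if label != home and rng.random() < spec.cross_source_overlap:
                _emit_ingredient(e, label, home=False)

    true_triples: set[tuple[str, str, str]] = set()

    def _emit_product(e, company, address, country, content, label) -> None:
        rid = _rid(label, "P")
        record_to_entity[(label, rid)] = e.uid
        if rng.random() < spec.address_variant_rate:
            variant = rng.choice(_ADDRESS_VARIANTS[country])
            shown = address.replace(country, variant)
            alias_table.setdefault(shown, address)
        else:
            shown = address
        ingredient_names = [
            ing.name if not ing.synonyms or rng.random() >= spec.synonym_rate
            else rng.choice(ing.synonyms)
            for ing in content
        ]
        source_records[label].products.append(
            ProductRecord(
                source=label,
                record_id=rid,
                product_name=e.name,
                company_name=company,
                company_address=shown,
                purpose=f"Supports {rng.choice(ingredients).name}." if rng.random() < 0.5 else None,
                risk=f"Consult a clinician before use." if rng.random() < 0.5 else None,
                ingredient_names=ingredient_names,
            )
        )

    for e, company, address, country, content in products:
        home = rng.choice(PRODUCT_SOURCES)
        _emit_product(e, company, address, country, content, home)
        other = PRODUCT_SOURCES[1 - PRODUCT_SOURCES.index(home)]
        if rng.random() < spec.cross_source_overlap:
            _emit_product(e, company, address, country, content, other)
        for ing in content:
            true_triples.add((e.uid, RelationType.HAS_INGREDIENT.value, ing.uid))

    def _emit_assertion(subj: TrueEntity, obj: TrueEntity, label: str) -> None:
        rid = _rid(label, "A")
        record_to_entity[(label, f"{rid}:obj")] = obj.uid
        category = _CATEGORY_OF_TYPE[obj.concept_type]
        relation, _ = route_relation(ConceptType.DSI, obj.concept_type)
        rating = None
        if relation is RelationType.IS_EFFECTIVE_FOR:
            rating = rng.choice(["effective", "possibly effective", "insufficient evidence"])
        elif relation is RelationType.INTERACTS_WITH:
            rating = rng.choice(["major", "moderate", "minor"])
        source_records[label].assertions.append(
            AssertionRecord(
                source=label,
                record_id=rid,
                subject_name=subj.name,
                object_name=obj.name,
                object_category=category,
                rating_text=rating,
                sentence=f"{subj.name} is associated with {obj.name}.",
            )
        )

    # assertion subjects resolve through the global name index: every
    # ingredient has a home record somewhere, so no extra emission is needed
    for subj, obj in assertion_pairs:
        home = rng.choice(ASSERTION_SOURCES)
        _emit_assertion(subj, obj, home)
        other = ASSERTION_SOURCES[1 - ASSERTION_SOURCES.index(home)]
        if rng.random() < spec.cross_source_overlap:
            _emit_assertion(subj, obj, other)
        relation, _ = route_relation(ConceptType.DSI, obj.concept_type)
        true_triples.add((subj.uid, relation.value, obj.uid))

    # nonsense-name noise records (dropped by the cleaning filter)
    n_noise = 0
    if spec.nonsense_noise_rate > 0:
        for label in ingredient_sources:
            k = round(spec.nonsense_noise_rate * len(source_records[label].ingredients))
            for _ in range(k):
                rid = _rid(label, "I")
                source_records[label].ingredients.append(
                    IngredientRecord(
                        source=label,
                        record_id=rid,
                        name=rng.choice(_NOISE_NAMES),
                        synonyms=[],
                    )
                )
                n_noise += 1

    # renumber record ids to match file order (read_source assigns by row)
    for label in ALL_SOURCES:
        src = source_records[label]
        for kind, records in (
            ("I", src.ingredients),
            ("P", src.products),
            ("A", src.assertions),
        ):
            remap = {}
            for i, rec in enumerate(records, start=1):
                new_id = f"{kind}{i:06d}"
                remap[rec.record_id] = new_id
                rec.record_id = new_id
            for old, new in remap.items():
                for suffix in ("", ":obj"):
                    key = (label, f"{old}{suffix}")
                    if key in record_to_entity and old != new:
                        record_to_entity[(label, f"{new}{suffix}")] = record_to_entity.pop(key)

    # vocabulary: every name of every CUI'd entity + dissimilar decoys
    vocabulary: list[VocabularyEntry] = []
    for e in sorted(entities.values(), key=lambda e: e.uid):
        if e.cui is None or e.concept_type not in SEMANTIC_TYPE_FILTERS:
            continue
        stype = sorted(SEMANTIC_TYPE_FILTERS[e.concept_type])[0]
        vocabulary.append(
            VocabularyEntry(e.cui, e.name, frozenset({stype}), True)
        )
        for syn in e.synonyms:
            vocabulary.append(
                VocabularyEntry(e.cui, syn, frozenset({stype}), False)
            )
    for i in range(10):  # decoys: valid entries that match nothing emitted
        ctype = rng.choice(list(SEMANTIC_TYPE_FILTERS))
        stype = sorted(SEMANTIC_TYPE_FILTERS[ctype])[0]
        vocabulary.append(
            VocabularyEntry(
                f"C9{i:06d}", names.make(ctype.value), frozenset({stype}), True
            )
        )

    emitted_uids = set(record_to_entity.values())
    entity_counts = {t.value: 0 for t in ConceptType}
    for uid in emitted_uids:
        entity_counts[entities[uid].concept_type.value] += 1

    return SynthResult(
        spec=spec,
        sources=[source_records[label] for label in ALL_SOURCES],
        vocabulary=vocabulary,
        alias_table=alias_table,
        ground_truth=GroundTruth(
            entity_counts=entity_counts,
            record_to_entity=record_to_entity,
            true_triples=true_triples,
            n_noise_records=n_noise,
        ),
        entities=entities,
    )


# -- file emission / reload ---------------------------------------------------


def write_fixture(result: SynthResult, outdir: str) -> dict:
    """Write dialect files, vocabulary, alias table, config, ground truth."""
    os.makedirs(outdir, exist_ok=True)
    config: dict = {"seed_order": list(ALL_SOURCES), "sources": [], "alias_table": result.alias_table}
    for src in result.sources:
        entry = {"label": src.label, "files": {}}
        if src.products:
            path = os.path.join(outdir, f"{src.label}_products.tsv")
            _write_products(path, src.products)
            entry["files"]["product"] = os.path.basename(path)
        if src.ingredients:
            path = os.path.join(outdir, f"{src.label}_ingredients.tsv")
            _write_ingredients(path, src.ingredients)
            entry["files"]["ingredient"] = os.path.basename(path)
        if src.assertions:
            path = os.path.join(outdir, f"{src.label}_assertions.tsv")
            _write_assertions(path, src.assertions)
            entry["files"]["assertion"] = os.path.basename(path)
        config["sources"].append(entry)
    vocab_path = os.path.join(outdir, "vocabulary.tsv")
    with open(vocab_path, "w", encoding="utf-8") as fh:
        fh.write("cui\tterm\tsemantic_types\tpreferred\n")
        for e in result.vocabulary:
            fh.write(
                f"{e.cui}\t{e.term}\t{'|'.join(sorted(e.semantic_types))}\t"
                f"{'1' if e.preferred else '0'}\n"
            )
    config["vocabulary"] = "vocabulary.tsv"
    with open(os.path.join(outdir, "config.yaml"), "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    gt = result.ground_truth
    with open(os.path.join(outdir, "ground_truth.json"), "w", encoding="utf-8") as fh:
        json.dump(
            {
                "spec": asdict(result.spec),
                "entity_counts": gt.entity_counts,
                "record_to_entity": {
                    f"{s}/{r}": uid for (s, r), uid in sorted(gt.record_to_entity.items())
                },
                "true_triples": sorted(gt.true_triples),
                "n_noise_records": gt.n_noise_records,
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    return config


def _write_products(path: str, records: list[ProductRecord]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("product_name\tcompany_name\tcompany_address\tpurpose\trisk\tingredients\n")
        for r in records:
            fh.write(
                f"{r.product_name}\t{r.company_name}\t{r.company_address}\t"
                f"{r.purpose or ''}\t{r.risk or ''}\t{'|'.join(r.ingredient_names)}\n"
            )


def _write_ingredients(path: str, records: list[IngredientRecord]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("name\tsynonyms\tgroup_id\tbackground\tsafety\tmechanism\tsource_material\n")
        for r in records:
            fh.write(
                f"{r.name}\t{'|'.join(r.synonyms)}\t{r.group_id or ''}\t"
                f"{r.background or ''}\t{r.safety or ''}\t{r.mechanism or ''}\t"
                f"{r.source_material or ''}\n"
            )


def _write_assertions(path: str, records: list[AssertionRecord]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("subject_name\tobject_name\tobject_category\trating_text\tsentence\n")
        for r in records:
            fh.write(
                f"{r.subject_name}\t{r.object_name}\t{r.object_category}\t"
                f"{r.rating_text or ''}\t{r.sentence or ''}\n"
            )


def load_fixture(indir: str) -> tuple[list[SourceData], list[VocabularyEntry], dict, list[str]]:
    """Reload fixture files written by :func:`write_fixture`.

    Returns (sources, vocabulary, alias table, seed order).
    """
    from .mapping import load_vocabulary

    with open(os.path.join(indir, "config.yaml"), encoding="utf-8") as fh:
        config = yaml.safe_load(fh)
    sources = []
    for entry in config["sources"]:
        src = SourceData(label=entry["label"])
        for dialect, filename in entry["files"].items():
            report = read_source(
                os.path.join(indir, filename), dialect, entry["label"]
            )
            getattr(
                src,
                {"product": "products", "ingredient": "ingredients", "assertion": "assertions"}[dialect],
            ).extend(report.records)
        sources.append(src)
    vocab = load_vocabulary(os.path.join(indir, config["vocabulary"]))
    return sources, vocab, config.get("alias_table", {}), config["seed_order"]


# -- recovery oracles ---------------------------------------------------------


def recovered_triples(
    build: BuildResult, ground_truth: GroundTruth
) -> set[tuple[str, str, str]]:
    """Map the built graph's triples back to ground-truth entity ids."""
    to_uid: dict[str, str] = {}
    for key, cid in build.ledger.assignments.items():
        uid = ground_truth.record_to_entity.get(key)
        if uid is not None:
            to_uid.setdefault(cid, uid)
    out = set()
    for t in build.graph.triples:
        head = to_uid.get(t.head_id)
        tail = to_uid.get(t.tail_id)
        if head is not None and tail is not None:
            out.add((head, t.relation.value, tail))
    return out
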