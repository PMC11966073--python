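"""Source-record ingestion and cleaning.

Reads the three record dialects emitted by the upstream supplement
databases — product records, ingredient records, and assertion records —
from delimited text files, applies the cleaning filters (nonsense-name
removal, field-variant unification), and groups ingredient synonyms.

Malformed rows never abort a build: each is rejected with a logged reason
and the parse report always satisfies ``parsed + rejected == rows``.
"""

from __future__ import annotations

import logging
import unicodedata
from dataclasses import dataclass, field
from typing import Optional, Sequence

logger = logging.getLogger(__name__)

#: Object categories an assertion may name, mapped to concept-type codes.
ASSERTION_CATEGORIES = {
    "disease": "DISEASE",
    "drug": "DRUG",
    "symptom": "SYMPTOM",
    "therapeutic class": "TC",
    "organ system": "SOC",
}

_PIPE = "|"


@dataclass
class ProductRecord:
    source: str
    record_id: str
    product_name: str
    company_name: str
    company_address: str
    purpose: Optional[str] = None
    risk: Optional[str] = None
    ingredient_names: list[str] = field(default_factory=list)


@dataclass
class IngredientRecord:
    source: str
    record_id: str
    name: str
    synonyms: list[str] = field(default_factory=list)
    group_id: Optional[str] = None
    background: Optional[str] = None
    safety: Optional[str] = None
    mechanism: Optional[str] = None
    source_material: Optional[str] = None


@dataclass
class AssertionRecord:
    source: str
    record_id: str
    subject_name: str
    object_name: str
    object_category: str  # key of ASSERTION_CATEGORIES
    rating_text: Optional[str] = None
    sentence: Optional[str] = None


@dataclass
class ParseReport:
    """Outcome of reading one source file."""

    records: list
    rejections: list[tuple[int, str]]  # (line number, reason)
    n_rows: int

    @property
    def n_parsed(self) -> int:
        return len(self.records)

    @property
    def n_rejected(self) -> int:
        return len(self.rejections)


# column layouts per dialect (tab-delimited by default, lists pipe-joined)
_DIALECT_COLUMNS = {
    "product": [
        "product_name",
        "company_name",
        "company_address",
        "purpose",
        "risk",
        "ingredients",
    ],
    "ingredient": [
        "name",
        "synonyms",
        "group_id",
        "background",
        "safety",
        "mechanism",
        "source_material",
    ],
    "assertion": [
        "subject_name",
        "object_name",
        "object_category",
        "rating_text",
        "sentence",
    ],
}


def read_source(
    path: str, dialect: str, source: str, delimiter: str = "\t"
) -> ParseReport:
    """Parse one record file; rejects malformed rows instead of aborting.

    Parameters
    ----------
    path
        Delimited text file with a header row matching the dialect columns.
    dialect
        One of ``product``, ``ingredient``, ``assertion``.
    source
        Source-database label stamped onto every record (provenance).
    """
    if dialect not in _DIALECT_COLUMNS:
        raise ValueError(f"unknown dialect {dialect!r}")
    columns = _DIALECT_COLUMNS[dialect]
    records: list = []
    rejections: list[tuple[int, str]] = []
    n_rows = 0
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(delimiter)
        if header != columns:
            raise ValueError(f"{path}: bad header {header!r}, expected {columns!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            n_rows += 1
            fields = line.split(delimiter)
            if len(fields) != len(columns):
                rejections.append(
                    (lineno, f"expected {len(columns)} fields, got {len(fields)}")
                )
                continue
            row = dict(zip(columns, fields))
            rid = f"{dialect[0].upper()}{lineno - 1:06d}"
            try:
                records.append(_build_record(dialect, source, rid, row))
            except ValueError as exc:
                rejections.append((lineno, str(exc)))
    for lineno, reason in rejections:
        logger.warning("%s:%d rejected: %s", path, lineno, reason)
    logger.info(
        "%s: parsed %d, rejected %d of %d rows",
        path,
        len(records),
        len(rejections),
        n_rows,
    )
    return ParseReport(records, rejections, n_rows)


def _build_record(dialect: str, source: str, rid: str, row: dict):
    if dialect == "product":
        if not row["product_name"].strip():
            raise ValueError("missing product_name")
        return ProductRecord(
            source=source,
            record_id=rid,
            product_name=row["product_name"],
            company_name=row["company_name"],
            company_address=row["company_address"],
            purpose=row["purpose"] or None,
            risk=row["risk"] or None,
            ingredient_names=[
                s for s in row["ingredients"].split(_PIPE) if s.strip()
            ],
        )
    if dialect == "ingredient":
        if not row["name"].strip():
            raise ValueError("missing ingredient name")
        return IngredientRecord(
            source=source,
            record_id=rid,
            name=row["name"],
            synonyms=[s for s in row["synonyms"].split(_PIPE) if s.strip()],
            group_id=row["group_id"] or None,
            background=row["background"] or None,
            safety=row["safety"] or None,
            mechanism=row["mechanism"] or None,
            source_material=row["source_material"] or None,
        )
    # assertion
    if not row["subject_name"].strip():
        raise ValueError("missing subject_name")
    if not row["object_name"].strip():
        raise ValueError("missing object_name")
    category = row["object_category"].strip().lower()
    if category not in ASSERTION_CATEGORIES:
        raise ValueError(f"invalid object_category {row['object_category']!r}")
    return AssertionRecord(
        source=source,
        record_id=rid,
        subject_name=row["subject_name"],
        object_name=row["object_name"],
        object_category=category,
        rating_text=row["rating_text"] or None,
        sentence=row["sentence"] or None,
    )


def clean_ingredient_name(name: str) -> bool:
    """Keep/drop decision for an ingredient name; True means keep.

    Drops nonsense names: a stripped name shorter than two characters, or
    one consisting solely of digits, punctuation/symbols, and whitespace
    (so "8", "%." and "4 2" are dropped; "B6" is kept). Pure predicate —
    idempotent and order-independent over a record set.
    """
    s = name.strip()
    if len(s) < 2:
        return False
    for ch in s:
        if ch.isdigit() or ch.isspace():
            continue
        if unicodedata.category(ch)[0] in ("P", "S"):
            continue
        return True
    return False


def unify_field_variants(
    values: Sequence[str], alias_table: dict[str, str]
) -> list[str]:
    """Map each value to its canonical form via the alias table.

    The alias table is the deterministic stand-in for model-assisted
    unification of field spellings (e.g. several spellings of a country
    collapsing to one canonical form). Unknown values pass through
    unchanged and are logged.
    """
    out = []
    for v in values:
        canonical = alias_table.get(v)
        if canonical is None:
            if v:
                logger.debug("no alias for %r; passed through", v)
            out.append(v)
        else:
            out.append(canonical)
    return out


@dataclass
class SynonymGroup:
    """Ingredient records collapsed to one entity via shared group id."""

    group_id: Optional[str]
    names: list[str]  # union of member names, first-seen order
    members: list[IngredientRecord]

    @property
    def canonical_name(self) -> str:
        return self.names[0]


def group_synonyms(records: Sequence[IngredientRecord]) -> list[SynonymGroup]:
    """Collapse ingredient records that share a group id.

    Records sharing a ``group_id`` form one group whose name set is the
    union of member names (record name + listed synonyms); records without
    a group id form singleton groups. The output groups partition the
    input records. Conflicting group metadata: first-seen wins, logged.
    """
    groups: dict[str, SynonymGroup] = {}
    singletons: list[SynonymGroup] = []
    for rec in records:
        names = [rec.name] + list(rec.synonyms)
        if rec.group_id is None:
            singletons.append(SynonymGroup(None, _dedup(names), [rec]))
            continue
        g = groups.get(rec.group_id)
        if g is None:
            groups[rec.group_id] = SynonymGroup(rec.group_id, _dedup(names), [rec])
        else:
            g.members.append(rec)
            g.names = _dedup(g.names + names)
    return list(groups.values()) + singletons


def _dedup(names: list[str]) -> list[str]:
    seen: set[str] = set()
    out = []
    for n in names:
        key = " ".join(n.split()).casefold()
        if key not in seen:
            seen.add(key)
            out.append(n)
    return out
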