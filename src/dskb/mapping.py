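"""Concept normalization: map entity names to controlled-vocabulary CUIs.

Candidate generation is a pluggable matcher over a vocabulary table
(CUI, term, semantic types, preferred flag), restricted per entity
category by semantic-type allow-lists. When several candidates survive,
a three-tier prioritization picks the mapping:

1. similarity 1 and marked preferred;
2. similarity 1, even if not preferred;
3. preferred with the highest similarity.

If no tier applies, no CUI is assigned (``UNMAPPED``) — precision is
preferred over coverage.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

from .kg import ConceptType, normalize_name

#: Sentinel for "no CUI assigned".
UNMAPPED = None

#: Semantic-type allow-list per entity category. Standard groupings:
#: disorders for diseases, signs/symptoms for symptoms, pharmacologic and
#: clinical-drug types for drugs, chemical/food/organic types for
#: ingredients. Editable configuration, not a closed schema.
SEMANTIC_TYPE_FILTERS: dict[ConceptType, frozenset[str]] = {
    ConceptType.DSI: frozenset({"T109", "T127", "T168", "T196", "T002"}),
    ConceptType.DISEASE: frozenset({"T047", "T191", "T046", "T048"}),
    ConceptType.DRUG: frozenset({"T121", "T200", "T195"}),
    ConceptType.SYMPTOM: frozenset({"T184"}),
}

Matcher = Callable[[str, str], float]


@dataclass(frozen=True)
class VocabularyEntry:
    cui: str
    term: str
    semantic_types: frozenset[str]
    preferred: bool


@dataclass(frozen=True)
class MatchResult:
    """One candidate mapping: CUI, matched term, similarity, preferred flag."""

    cui: str
    term: str
    similarity: float
    preferred: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.similarity <= 1.0:
            raise ValueError(f"similarity {self.similarity} outside [0, 1]")


def load_vocabulary(path: str, delimiter: str = "\t") -> list[VocabularyEntry]:
    """Read a vocabulary table: cui, term, semantic_types (pipe-joined), preferred."""
    entries = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split(delimiter)
        expected = ["cui", "term", "semantic_types", "preferred"]
        if header != expected:
            raise ValueError(f"{path}: bad header {header!r}, expected {expected!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split(delimiter)
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 fields")
            cui, term, stypes, preferred = fields
            entries.append(
                VocabularyEntry(
                    cui=cui,
                    term=term,
                    semantic_types=frozenset(s for s in stypes.split("|") if s),
                    preferred=preferred.strip().lower() in ("1", "true", "yes"),
                )
            )
    return entries


def default_matcher(a: str, b: str) -> float:
    """Deterministic normalized string similarity in [0, 1].

    Exact match after casefold/whitespace normalization scores 1.0;
    otherwise a sequence-alignment ratio on the normalized strings.
    """
    na, nb = normalize_name(a), normalize_name(b)
    if na == nb:
        return 1.0
    return difflib.SequenceMatcher(None, na, nb).ratio()


def candidates(
    name: str,
    category: ConceptType,
    vocab: Sequence[VocabularyEntry],
    matcher: Matcher = default_matcher,
    min_similarity: float = 0.7,
    filters: Optional[dict[ConceptType, frozenset[str]]] = None,
) -> list[MatchResult]:
    """Vocabulary candidates for a name, restricted by semantic type.

    Only entries whose semantic types intersect the category's allow-list
    are considered; each surviving entry is scored by the matcher.
    Results are sorted by descending similarity, then CUI, then term.
    """
    allowed = (filters or SEMANTIC_TYPE_FILTERS).get(category)
    if allowed is None:
        raise ValueError(f"no semantic-type filter for category {category.value}")
    fast = matcher is default_matcher
    nname = normalize_name(name)
    out = []
    for entry in vocab:
        if not entry.semantic_types & allowed:
            continue
        if fast:
            nterm = normalize_name(entry.term)
            if nname == nterm:
                sim = 1.0
            else:
                sm = difflib.SequenceMatcher(None, nname, nterm)
                # cheap upper bounds before the quadratic ratio
                if (
                    sm.real_quick_ratio() < min_similarity
                    or sm.quick_ratio() < min_similarity
                ):
                    continue
                sim = sm.ratio()
        else:
            sim = matcher(name, entry.term)
        if sim >= min_similarity:
            out.append(
                MatchResult(
                    cui=entry.cui,
                    term=entry.term,
                    similarity=sim,
                    preferred=entry.preferred,
                )
            )
    out.sort(key=lambda m: (-m.similarity, m.cui, m.term))
    return out


def resolve(cands: Sequence[MatchResult]) -> Optional[str]:
    """Pick one CUI from candidates via the three-tier prioritization.

    Tier 1: similarity == 1 and preferred; tier 2: similarity == 1;
    tier 3: preferred with maximal similarity. No tier met -> ``UNMAPPED``.
    Permutation-invariant; ties within a tier break on lexicographic CUI.
    """
    tier1 = [m for m in cands if m.similarity == 1.0 and m.preferred]
    if tier1:
        return min(m.cui for m in tier1)
    tier2 = [m for m in cands if m.similarity == 1.0]
    if tier2:
        return min(m.cui for m in tier2)
    tier3 = [m for m in cands if m.preferred]
    if tier3:
        best = max(m.similarity for m in tier3)
        return min(m.cui for m in tier3 if m.similarity == best)
    return UNMAPPED


def map_name(
    name: str,
    category: ConceptType,
    vocab: Sequence[VocabularyEntry],
    matcher: Matcher = default_matcher,
    min_similarity: float = 0.7,
) -> Optional[str]:
    """Convenience: candidates + resolve for a single name."""
    return resolve(candidates(name, category, vocab, matcher, min_similarity))
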