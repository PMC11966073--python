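# Methods

## Graph model and identifier scheme

The knowledge base is a typed property graph with a closed schema: seven
concept types and six relation types in bijection with six ordered
type pairs. Because the relation is a function of the endpoint types,
relations are never embedded or inferred — `route_relation` also accepts
a reversed pair and reports the orientation, since users name entities in
either order.

Concept identifiers are type-prefixed, zero-padded sequential strings
(`DI0000001`, `DP0000001`, `DZ…`, `DR…`, `SY…`, `TC…`, `SC…`) assigned in
a deterministic fold order (seed source first, then source label, then
record id), so identical inputs always produce identical identifiers.
This scheme is a package design choice; any opaque unique string would
satisfy the data model.

Triples are a set keyed by `(head, relation, tail)`. Re-inserting an
existing triple merges source provenance and fills missing attributes;
every collapse is appended to a merge log rather than dropped silently.
Neighbor queries return triples sorted by (relation code, neighbor id) so
retrieved contexts — and the answers composed from them — are stable.

## Cleaning and normalization

*Nonsense-name filter*: an ingredient name is dropped when its stripped
form is shorter than two characters or consists solely of digits,
whitespace, and Unicode punctuation/symbol characters (category `P`/`S`,
which covers `%`). The predicate is pure, so it is idempotent and
order-independent; additional patterns belong in configuration, not code.

*Field-variant unification*: a variant→canonical alias table (the
deterministic stand-in for model-assisted unification of, e.g., country
spellings in company addresses). Unknown values pass through and are
logged — unification must never invent data.

*Synonym grouping*: ingredient records sharing a source-assigned group id
collapse to one entity whose name set is the union of member names;
groups partition the input, and conflicting metadata resolves first-seen.

## Concept mapping

Vocabulary candidates are restricted per entity category by semantic-type
allow-lists (shipping defaults cover standard disorder / sign-symptom /
pharmacologic / chemical-and-food groupings; the lists are editable
configuration). The matcher contract is any scorer into [0, 1]; the
default is deterministic normalized string similarity
(`difflib.SequenceMatcher` on casefolded, whitespace-collapsed text, with
quick-ratio upper bounds as a prefilter), with a candidate floor of 0.7.
The similarity measure is deliberately pluggable — different matchers
(character-gram Jaccard, cosine) are drop-in replacements.

Resolution uses three strict tiers: (1) similarity 1 and preferred,
(2) similarity 1, (3) preferred with maximal similarity; otherwise the
entity stays unmapped — precision over coverage. Ties inside a tier break
on lexicographic CUI; the choice is arbitrary but must be deterministic
for reproducible builds. A property test keeps `resolve` equal to a
literal brute-force scan of the three tiers.

## Integration

Greedy, seeded integration: the first source per type initializes the
vocabulary, later records merge iff a merge key matches. "Identical term
name" is evaluated case-insensitively after whitespace collapse — source
casing is noisy and byte equality would under-merge; this is logged per
record so merges can be audited. Attribute conflicts keep the
higher-priority (earlier-seeded) source's value and log the loser. The
merge ledger is total: every ingested record maps to a concept id with a
reason (`same-CUI`, `identical-name`, `product-name+company`,
`new-entity`). Triple ratings are stored only where the schema defines an
attribute (effectiveness rating on ingredient–disease edges, interaction
rating on ingredient–drug edges); ratings on other relations are dropped
with a log entry. The order in which non-seed sources fold in is
configuration; the merge rules make final counts order-independent, and
tests assert only that.

## Entity linking

The default embedding provider hashes padded character trigrams of the
normalized name into a fixed number of signed buckets (keyed blake2b,
salt = seed) and L2-normalizes — fully deterministic and offline, with
the provider fingerprint recorded in the index so mixed-provider indexes
are rejected. Real embedding APIs plug in behind the same
`embed(texts) -> unit vectors` contract.

Linking is an exhaustive scan (adequate at these graph scales; an ANN
engine would add a dependency without changing results): the argmax
similarity wins iff it is **≥ 0.75**, inclusive. Synonyms are embedded
separately and vote for their concept by max similarity; whether to embed
synonyms at all is a flag, defaulting to all names. Ties break on
lexicographic concept id, making results independent of insertion order.
Raising the threshold is monotone: it can only remove matches.

## Question answering

Mention extraction and answer generation are pluggable contracts whose
defaults are deterministic: a longest-match, word-bounded,
case-insensitive dictionary scan over all graph names, and a template
renderer that lists retrieved facts verbatim. With the template renderer,
every entity named in an answer is an endpoint of a retrieved triple —
grounding holds by construction. Intent (which type the question asks
about) comes from a small keyword lexicon checked in a fixed priority
order; this is the weakest component by design and the natural slot for
an LLM adapter.

Scored answering: true-or-false is edge existence under the routed
relation; multiple choice links each option and picks the first one
retrieved as a neighbor of the subject, else "None of the above", else an
abstain code that scores as incorrect. Holdout is honored at triple
level: a triple is invisible when *all* of its provenance labels are held
out (a fact still supported by another source remains visible, which is
the point of provenance merging).

## Benchmark generation and bootstrap scoring

Positive true-or-false items restate existing triples; negatives state
uniformly sampled same-type non-edges (the simplest null that gives the
task both answer classes). Multiple-choice items have five options —
gold, three distractors not linked to the subject, and "None of the
above" — with a configurable fraction (default 0.2) omitting the gold so
the final option is sometimes correct. All generation flows from a passed
`random.Random`.

Bootstrap evaluation samples `sample_size` questions per repetition
(default 100 × 10 repetitions = 1000 answers per question type), with
replacement by default; without-replacement sampling is supported because
the protocol's wording admits both readings.

## Synthetic data: what it emulates, and what it does not

The generator emulates the structural hazards of multi-source supplement
data: cross-source entity overlap, ingredient synonymy (including
synonym-only surface forms), partial vocabulary coverage, nonsense-name
noise, and address-spelling variants — with complete bookkeeping of which
true entity each record denotes and which triples should survive
integration. Defaults are ~500 entities (150 ingredients, 200 products,
60/40/30 diseases/drugs/symptoms, 12 therapeutic classes, 5 organ
classes), 250 assertions, synonym rate 0.2, cross-source overlap 0.3,
vocabulary coverage 0.9, nonsense-noise rate 0.05, address-variant rate
0.3, spread over four source dialects (two product-bearing, two
assertion-bearing).

Names come from a pronounceable-syllable grammar; they are globally
unique and, within each mapped category, kept below 0.6 string similarity
so the matcher cannot cross-assign CUIs by near-miss. Two deliberate
constraints keep ground-truth recovery well-defined: synonym-only surface
forms are emitted only for entities that carry a CUI (the merge rule —
same CUI or identical name — cannot merge CUI-less records appearing
under disjoint names, so emitting them would make exact recovery
unattainable by construction rather than by implementation defect), and
noise records never reuse real entity names.

Consequently, passing recovery tests show that the implementation applies
the stated merge rules exactly; they do not show robustness to hazards
the rules themselves cannot resolve — real typos in merge keys,
ambiguous vocabulary mappings, polysemous names across categories, or
incorrect CUIs in the vocabulary, all of which real source data contains.
Likewise the perfect closed-loop QA accuracy certifies the retrieval
machinery, not linguistic robustness: generated stems embed exact
concept names, which real user questions do not.

## Numerical choices and degenerate inputs

- Link threshold comparison is inclusive (`>= 0.75`), taken literally.
- Cosine similarity raises on zero vectors and dimension mismatch rather
  than returning a sentinel; results are clipped to [−1, 1] against
  rounding.
- Index persistence writes floats with `repr`, so reload is bit-exact.
- Empty graphs export all thirteen bulk tables (headers only) and import
  back to an empty graph; malformed bulk rows fail with file and line.
- Malformed source rows are rejected per-row with a reason, never
  aborting a build; parse reports satisfy `parsed + rejected = rows`.

## Problem sizes used by the tests and the acceptance script

Unit and property tests run on hand-built graphs of 5–12 concepts and
randomized graphs of ≤ ~25 concepts (100 instances for round-trip
identity). Recovery and closed-loop checks use the default ~500-entity
conditions; the bootstrap evaluation answers 1000 true-or-false and 1000
multiple-choice questions per run. These sizes exercise every code path
while keeping a full run in seconds.

## Known limitations

- No probabilistic record linkage: merging is exactly the stated rule
  set, so near-duplicate entities with different names and no shared CUI
  remain separate.
- The dictionary extractor cannot find paraphrased or misspelled
  mentions; the embedder tolerates small surface variation only.
- The live graph backend is an openCypher text emitter; no server
  integration is tested.
- Semantic-type allow-lists are pragmatic defaults, not a vetted
  ontology subset; deployments should replace them with curated lists.
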