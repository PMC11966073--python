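"""Embedding-based entity linking against the knowledge graph.

Every concept name (preferred name and synonyms) is embedded into a unit
vector by a pluggable provider and stored in an exhaustive-scan vector
index. A question mention links to the concept with the highest cosine
similarity, provided that similarity is at least the threshold
(default 0.75, inclusive); otherwise no match is reported and the
question-answering pipeline falls back to generation alone.

The default provider is a seeded character-trigram hashing embedder:
deterministic, offline, and reproducible bit-for-bit. Real embedding-API
providers plug in behind the same contract; the provider fingerprint is
recorded in the index so mixed-provider indexes are rejected.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Optional, Protocol, Sequence

import numpy as np

from .kg import KnowledgeGraph, normalize_name

#: Default acceptance threshold for a link (inclusive).
DEFAULT_THRESHOLD = 0.75


class EmbeddingProvider(Protocol):
    """Contract for text-embedding backends."""

    @property
    def fingerprint(self) -> str: ...

    def embed(self, texts: Sequence[str]) -> np.ndarray:
        """Return an array of shape (len(texts), dim), unit-normalized rows."""
        ...


class HashingTrigramEmbedder:
    """Deterministic character-trigram hashing embedder.

    Each padded character trigram of the normalized text is hashed (keyed
    by the seed) to a bucket and a sign; the bucket counts are then
    L2-normalized. Purely local and reproducible, so tests and offline
    builds need no embedding service.
    """

    def __init__(self, dim: int = 256, seed: int = 0):
        if dim < 2:
            raise ValueError("dim must be >= 2")
        self.dim = dim
        self.seed = seed

    @property
    def fingerprint(self) -> str:
        return f"hashing-trigram/dim={self.dim}/seed={self.seed}"

    def _trigrams(self, text: str):
        t = f"#{normalize_name(text)}#"
        if len(t) < 3:
            yield t
            return
        for i in range(len(t) - 2):
            yield t[i : i + 3]

    def embed(self, texts: Sequence[str]) -> np.ndarray:
        out = np.zeros((len(texts), self.dim), dtype=np.float64)
        salt = str(self.seed).encode()
        for row, text in enumerate(texts):
            for gram in self._trigrams(text):
                digest = hashlib.blake2b(
                    gram.encode("utf-8"), key=salt, digest_size=8
                ).digest()
                value = int.from_bytes(digest, "big")
                bucket = value % self.dim
                sign = 1.0 if (value >> 32) & 1 else -1.0
                out[row, bucket] += sign
            norm = np.linalg.norm(out[row])
            if norm > 0:
                out[row] /= norm
            else:  # degenerate text: deterministic unit fallback
                out[row, 0] = 1.0
        return out


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between two vectors, in [-1, 1]; symmetric.

    Raises on dimension mismatch or a zero vector (undefined similarity).
    """
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


@dataclass(frozen=True)
class LinkResult:
    idisk_id: str
    name: str  # the indexed surface form that matched best
    similarity: float


class EntityVectorIndex:
    """Exhaustive-scan vector index over every concept name in a graph.

    Synonyms are embedded separately and vote for their concept by max
    similarity. Link results are invariant to insertion order: ties at
    equal similarity break on lexicographic concept id, then name.
    """

    def __init__(self, provider: EmbeddingProvider):
        self.provider = provider
        self.ids: list[str] = []
        self.names: list[str] = []
        self.matrix: Optional[np.ndarray] = None

    @property
    def dim(self) -> int:
        return 0 if self.matrix is None else self.matrix.shape[1]

    def __len__(self) -> int:
        return len(self.ids)

    @classmethod
    def build(
        cls,
        graph: KnowledgeGraph,
        provider: EmbeddingProvider,
        include_synonyms: bool = True,
    ) -> "EntityVectorIndex":
        index = cls(provider)
        entries: list[tuple[str, str]] = []
        for cid in sorted(graph.concepts):
            concept = graph.concepts[cid]
            names = concept.names() if include_synonyms else {concept.preferred_name}
            for name in sorted(names):
                entries.append((cid, name))
        index.ids = [cid for cid, _ in entries]
        index.names = [name for _, name in entries]
        index.matrix = (
            provider.embed(index.names)
            if entries
            else np.zeros((0, 1), dtype=np.float64)
        )
        return index

    def link(
        self, mention: str, threshold: float = DEFAULT_THRESHOLD
    ) -> Optional[LinkResult]:
        """Link a mention to the best-matching concept, or None.

        The match is accepted iff the maximum cosine similarity over all
        indexed names is >= threshold (inclusive). Raising the threshold
        can only remove matches, never create them.
        """
        if not mention or not mention.strip():
            raise ValueError("mention must be nonempty")
        if self.matrix is None or len(self.ids) == 0:
            raise ValueError("index is empty")
        vec = self.provider.embed([mention])[0]
        return self.link_vector(vec, threshold)

    def link_vector(
        self, vec: np.ndarray, threshold: float = DEFAULT_THRESHOLD
    ) -> Optional[LinkResult]:
        """Link a precomputed query vector (same provider space)."""
        if self.matrix is None or len(self.ids) == 0:
            raise ValueError("index is empty")
        vec = np.asarray(vec, dtype=np.float64)
        if vec.shape != (self.matrix.shape[1],):
            raise ValueError(
                f"dimension mismatch: query {vec.shape} vs index dim {self.matrix.shape[1]}"
            )
        norm = np.linalg.norm(vec)
        if norm == 0.0:
            raise ValueError("cosine similarity undefined for a zero vector")
        sims = self.matrix @ (vec / norm)
        row_norms = np.linalg.norm(self.matrix, axis=1)
        sims = sims / np.where(row_norms == 0.0, 1.0, row_norms)
        best = None
        for i in np.flatnonzero(sims >= threshold):
            cand = (-sims[i], self.ids[i], self.names[i])
            if best is None or cand < best:
                best = cand
        if best is None:
            return None
        return LinkResult(idisk_id=best[1], name=best[2], similarity=float(-best[0]))

    # -- persistence -------------------------------------------------------

    def save(self, path: str) -> None:
        """Persist as a delimited vector table with a metadata header.

        Float values are written with ``repr`` so reload is bit-exact.
        """
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"#dim={self.dim}\n")
            fh.write(f"#provider={self.provider.fingerprint}\n")
            fh.write(f"#default_threshold={DEFAULT_THRESHOLD}\n")
            for cid, name, row in zip(self.ids, self.names, self.matrix):
                values = ",".join(repr(float(x)) for x in row)
                fh.write(f"{cid}\t{name}\t{values}\n")

    @classmethod
    def load(cls, path: str, provider: EmbeddingProvider) -> "EntityVectorIndex":
        """Reload an index; rejects a provider-fingerprint mismatch."""
        index = cls(provider)
        rows = []
        with open(path, encoding="utf-8") as fh:
            meta = {}
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                key, _, value = line[1:].rstrip("\n").partition("=")
                meta[key] = value
                pos = fh.tell()
                line = fh.readline()
            if meta.get("provider") != provider.fingerprint:
                raise ValueError(
                    f"provider fingerprint mismatch: index built with "
                    f"{meta.get('provider')!r}, given {provider.fingerprint!r}"
                )
            while line:
                cid, name, values = line.rstrip("\n").split("\t")
                index.ids.append(cid)
                index.names.append(name)
                rows.append([float(x) for x in values.split(",")])
                line = fh.readline()
        dim = int(meta["dim"])
        index.matrix = (
            np.array(rows, dtype=np.float64)
            if rows
            else np.zeros((0, dim), dtype=np.float64)
        )
        return index
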