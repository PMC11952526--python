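"""Embedder contract, the built-in hashed bag-of-words backend, and
per-document embedding assembly.

An *embedder* is any callable mapping clean text to a fixed-dimension
1-D float vector; :class:`EmbedderSpec` declares its name, dimension, and
the preprocessing policy it wants (stop-word removal, chunking).  External
model adapters (transformer back ends, static word vectors, remote APIs)
plug into the same one-function contract through the registry; the core
package never imports them, so the whole pipeline runs with no downloads.

The built-in backend is a signed feature-hashing bag of words: every token
is hashed (with a seeded keyed hash) to a coordinate and a sign, and the
vector accumulates signed token counts.  At large dimensions, unrelated
vocabularies land on nearly orthogonal coordinates, which is what the
retrieval and evaluation layers need from a deterministic, dependency-free
backend.
"""

from __future__ import annotations

import importlib
from dataclasses import dataclass
from hashlib import blake2b
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .preprocess import (
    DEFAULT_CHUNK_OVERLAP,
    DEFAULT_CHUNK_SIZE,
    DEFAULT_CHUNK_THRESHOLD,
    chunk_text,
)

__all__ = [
    "EmbedderSpec",
    "BackendContractError",
    "HashedBowEmbedder",
    "hashed_bow_embed",
    "embed_document",
    "embed_corpus",
    "average_embeddings",
    "write_embeddings",
    "read_embeddings",
    "get_embedder",
    "register_embedder",
]


class BackendContractError(RuntimeError):
    """An embedding backend returned a vector of the wrong shape."""


@dataclass(frozen=True)
class EmbedderSpec:
    """Declared properties of an embedding backend."""

    name: str
    dimension: int
    remove_stopwords: bool = False
    use_chunking: bool = False

    def __post_init__(self) -> None:
        if self.dimension < 1:
            raise ValueError("dimension must be >= 1")


def _token_slot(token: str, dimension: int, key: bytes) -> tuple[int, float]:
    digest = blake2b(token.encode("utf-8"), key=key, digest_size=8).digest()
    index = int.from_bytes(digest[:4], "little") % dimension
    sign = 1.0 if digest[4] & 1 else -1.0
    return index, sign


def hashed_bow_embed(text: str, dimension: int, seed: int) -> np.ndarray:
    """Signed feature-hashing bag-of-words vector of *text*.

    Deterministic in (text, dimension, seed); word order is irrelevant
    (bag semantics); empty text yields the zero vector.
    """
    if dimension < 1:
        raise ValueError("dimension must be >= 1")
    key = (int(seed) & 0xFFFFFFFFFFFFFFFF).to_bytes(8, "little")
    vec = np.zeros(dimension)
    for token in text.split():
        index, sign = _token_slot(token, dimension, key)
        vec[index] += sign
    return vec


class HashedBowEmbedder:
    """Callable hashed bag-of-words backend with a per-token slot cache.

    The cache makes corpus-scale embedding linear in the number of distinct
    tokens rather than token occurrences.
    """

    def __init__(
        self,
        dimension: int = 4096,
        seed: int = 0,
        remove_stopwords: bool = True,
        use_chunking: bool = False,
    ) -> None:
        self.spec = EmbedderSpec(
            name=f"hashed-bow-{dimension}",
            dimension=dimension,
            remove_stopwords=remove_stopwords,
            use_chunking=use_chunking,
        )
        self._key = (int(seed) & 0xFFFFFFFFFFFFFFFF).to_bytes(8, "little")
        self._slots: dict[str, tuple[int, float]] = {}

    def __call__(self, text: str) -> np.ndarray:
        vec = np.zeros(self.spec.dimension)
        slots = self._slots
        for token in text.split():
            slot = slots.get(token)
            if slot is None:
                slot = _token_slot(token, self.spec.dimension, self._key)
                slots[token] = slot
            vec[slot[0]] += slot[1]
        return vec


def embed_document(
    text: str,
    embedder: Callable[[str], np.ndarray],
    spec: EmbedderSpec,
    chunk_size: int = DEFAULT_CHUNK_SIZE,
    chunk_overlap: int = DEFAULT_CHUNK_OVERLAP,
    chunk_threshold: int = DEFAULT_CHUNK_THRESHOLD,
) -> np.ndarray:
    """Embed one clean document, chunk-averaging when the spec asks for it.

    When ``spec.use_chunking`` and the text exceeds the threshold, each
    overlapping window is embedded and the windows' vectors are averaged
    unweighted; otherwise the backend is applied to the whole text.
    """
    if spec.use_chunking and len(text) > chunk_threshold:
        windows = chunk_text(text, chunk_size, chunk_overlap, chunk_threshold)
        parts = [_checked(embedder(text[a:b]), spec) for a, b in windows]
        return np.mean(parts, axis=0)
    return _checked(embedder(text), spec)


def _checked(vec: np.ndarray, spec: EmbedderSpec) -> np.ndarray:
    vec = np.asarray(vec, dtype=float)
    if vec.shape != (spec.dimension,):
        raise BackendContractError(
            f"backend {spec.name!r} returned shape {vec.shape}, "
            f"declared dimension {spec.dimension}"
        )
    return vec


def embed_corpus(
    documents: Mapping[str, str],
    embedder: Callable[[str], np.ndarray],
    spec: EmbedderSpec,
    **chunk_params: int,
) -> dict[str, np.ndarray]:
    """Embed every accession -> clean-text document; returns accession -> vector."""
    return {
        acc: embed_document(text, embedder, spec, **chunk_params)
        for acc, text in documents.items()
    }


def average_embeddings(vectors: Sequence[np.ndarray] | Iterable[np.ndarray]) -> np.ndarray:
    """Component-wise arithmetic mean of same-dimension vectors."""
    vectors = [np.asarray(v, dtype=float) for v in vectors]
    if not vectors:
        raise ValueError("cannot average an empty list of embeddings")
    dims = {v.shape for v in vectors}
    if len(dims) > 1:
        raise ValueError(f"mixed embedding dimensions: {sorted(dims)}")
    return np.mean(vectors, axis=0)


# ---------------------------------------------------------------------------
# Text-based embedding store: accession + tab-separated floats, one per line.


def write_embeddings(path: str | Path, vectors: Mapping[str, np.ndarray]) -> None:
    lines = []
    for acc in sorted(vectors):
        values = "\t".join(repr(float(x)) for x in vectors[acc])
        lines.append(f"{acc}\t{values}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_embeddings(path: str | Path) -> dict[str, np.ndarray]:
    vectors: dict[str, np.ndarray] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        acc, _, rest = line.partition("\t")
        vectors[acc] = np.array([float(x) for x in rest.split("\t")])
    return vectors


# ---------------------------------------------------------------------------
# Registry: embedder name -> factory.  External adapters register themselves
# via "module:callable" entry strings; the built-in backend needs no plug-in.

_REGISTRY: dict[str, Callable[..., Callable[[str], np.ndarray]]] = {}


def register_embedder(name: str, factory: Callable[..., Callable[[str], np.ndarray]]) -> None:
    _REGISTRY[name] = factory


def get_embedder(
    name: str,
    dimension: int = 4096,
    seed: int = 0,
    remove_stopwords: bool = True,
    use_chunking: bool = False,
) -> tuple[Callable[[str], np.ndarray], EmbedderSpec]:
    """Construct a registered backend; returns (callable, spec).

    ``name`` may also be a ``module:callable`` entry string naming a factory
    with the same signature as :class:`HashedBowEmbedder`.
    """
    if name in _REGISTRY:
        factory = _REGISTRY[name]
    elif ":" in name:
        module, _, attr = name.partition(":")
        factory = getattr(importlib.import_module(module), attr)
    else:
        raise KeyError(f"unknown embedder {name!r}; registered: {sorted(_REGISTRY)}")
    backend = factory(
        dimension=dimension,
        seed=seed,
        remove_stopwords=remove_stopwords,
        use_chunking=use_chunking,
    )
    spec = getattr(backend, "spec", None) or EmbedderSpec(
        name=name, dimension=dimension, remove_stopwords=remove_stopwords,
        use_chunking=use_chunking,
    )
    return backend, spec


register_embedder("hashed-bow", HashedBowEmbedder)
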