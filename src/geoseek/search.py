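"""Similarity scoring and deterministic candidate ranking.

The retrieval step: average the embeddings of a set of known-relevant
series (the reference profile), score every candidate by cosine similarity
to that profile, and rank.  A word-overlap baseline (count of shared unique
words) is provided for comparison.  All rankings are deterministic: ties
are broken by ascending accession.
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Iterable, Mapping, TextIO

import numpy as np

from .embed import average_embeddings

__all__ = [
    "DegenerateEmbeddingError",
    "cosine_similarity",
    "word_overlap_similarity",
    "rank_candidates",
    "rank_by_word_overlap",
    "search_by_reference",
    "write_ranked_tsv",
    "read_accession_list",
]


class DegenerateEmbeddingError(ValueError):
    """A zero-norm embedding cannot be compared by cosine similarity."""

    def __init__(self, message: str, accession: str | None = None) -> None:
        super().__init__(message if accession is None else f"{message} ({accession})")
        self.accession = accession


def cosine_similarity(u: np.ndarray, v: np.ndarray, accession: str | None = None) -> float:
    """dot(u, v) / (|u| |v|); symmetric, scale-invariant, in [-1, 1]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise DegenerateEmbeddingError("zero-norm embedding", accession)
    return float(np.dot(u, v) / (nu * nv))


def word_overlap_similarity(a: str, b: str) -> int:
    """Number of unique words shared by two clean texts."""
    return len(set(a.split()) & set(b.split()))


def rank_candidates(
    reference: np.ndarray, candidates: Mapping[str, np.ndarray]
) -> list[tuple[str, float]]:
    """Score all candidates against the reference vector and sort.

    Scores are non-increasing; ties break by ascending accession, so the
    ranking is independent of mapping insertion order.
    """
    scored = [
        (acc, cosine_similarity(reference, vec, accession=acc))
        for acc, vec in candidates.items()
    ]
    scored.sort(key=lambda item: (-item[1], item[0]))
    return scored


def rank_by_word_overlap(
    reference_texts: Iterable[str],
    candidates: Mapping[str, str],
    mode: str = "union",
) -> list[tuple[str, float]]:
    """Word-overlap baseline ranking against a multi-document reference.

    ``union`` scores each candidate against the union of unique words across
    the reference texts (mirroring the averaged-embedding profile);
    ``pairwise-max`` scores against each reference text separately and keeps
    the best overlap.
    """
    ref_sets = [set(t.split()) for t in reference_texts]
    if mode == "union":
        profile = set().union(*ref_sets) if ref_sets else set()
        scored = [
            (acc, float(len(profile & set(text.split()))))
            for acc, text in candidates.items()
        ]
    elif mode == "pairwise-max":
        scored = []
        for acc, text in candidates.items():
            words = set(text.split())
            best = max((len(r & words) for r in ref_sets), default=0)
            scored.append((acc, float(best)))
    else:
        raise ValueError(f"unknown word-overlap mode: {mode!r}")
    scored.sort(key=lambda item: (-item[1], item[0]))
    return scored


def search_by_reference(
    reference_accessions: Iterable[str],
    corpus: Mapping[str, np.ndarray],
) -> list[tuple[str, float]]:
    """Rank all non-reference corpus members against the averaged references.

    This is the interactive workflow: a researcher supplies the accessions
    of series already known to be relevant; the corpus is every embedded
    series; the output ranks the rest by similarity to the averaged
    reference profile.
    """
    refs = sorted(set(reference_accessions))
    if not refs:
        raise ValueError("at least one reference accession is required")
    missing = [acc for acc in refs if acc not in corpus]
    if missing:
        raise KeyError(f"reference accessions not in corpus: {', '.join(missing)}")
    profile = average_embeddings([corpus[acc] for acc in refs])
    candidates = {acc: vec for acc, vec in corpus.items() if acc not in set(refs)}
    return rank_candidates(profile, candidates)


def write_ranked_tsv(
    path: str | Path,
    ranked: list[tuple[str, float]],
    embedder: str = "",
    chunking: bool = False,
    seed: int | None = None,
) -> None:
    """Write a ranked list with a provenance header comment."""
    buf = io.StringIO()
    buf.write(f"# embedder={embedder}\tchunking={str(chunking).lower()}\tseed={seed}\n")
    buf.write("rank\taccession\tscore\n")
    for i, (acc, score) in enumerate(ranked, start=1):
        buf.write(f"{i}\t{acc}\t{score!r}\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_accession_list(stream: TextIO | str) -> list[str]:
    """Read selected-series accessions: one per line or the first column of
    an exported table (extra columns and a header row are ignored)."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    accessions = []
    for line in stream:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        first = line.split("\t")[0].split(",")[0].strip().strip('"')
        if not first or first.lower() in {"accession", "id", "series"}:
            continue
        accessions.append(first)
    return accessions
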