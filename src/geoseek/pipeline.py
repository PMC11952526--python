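"""End-to-end convenience wrappers: records -> clean documents -> vectors ->
benchmark results.  Thin glue over the ingest/preprocess/embed/evaluate
modules, shared by the CLI, the test suite, and the reproduction script.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .embed import EmbedderSpec, HashedBowEmbedder, embed_corpus
from .evaluate import ConditionAnnotation, EvaluationResult, evaluate_vector_model
from .ingest import SeriesRecord
from .preprocess import clean_record, load_stopwords
from .synthetic import CorpusConfig, generate_corpus

__all__ = [
    "corpus_documents",
    "embed_records",
    "annotations_mapping",
    "benchmark_synthetic",
]


def corpus_documents(
    records: Sequence[SeriesRecord],
    remove_stopwords: bool = True,
    stopword_list: frozenset[str] | None = None,
) -> dict[str, str]:
    """Clean every record's document; returns accession -> clean text."""
    if remove_stopwords and stopword_list is None:
        stopword_list = load_stopwords()
    return {
        rec.accession: clean_record(rec, remove_stopwords, stopword_list or frozenset()).text
        for rec in records
    }


def embed_records(
    records: Sequence[SeriesRecord],
    dimension: int = 4096,
    seed: int = 0,
    remove_stopwords: bool = True,
    use_chunking: bool = False,
) -> tuple[dict[str, np.ndarray], EmbedderSpec]:
    """Clean and embed records with the built-in hashed bag-of-words backend."""
    embedder = HashedBowEmbedder(
        dimension=dimension,
        seed=seed,
        remove_stopwords=remove_stopwords,
        use_chunking=use_chunking,
    )
    documents = corpus_documents(records, remove_stopwords=remove_stopwords)
    return embed_corpus(documents, embedder, embedder.spec), embedder.spec


def annotations_mapping(
    annotations: Sequence[ConditionAnnotation],
) -> dict[str, frozenset[str]]:
    return {a.condition: a.accessions for a in annotations}


def benchmark_synthetic(
    config: CorpusConfig,
    dimension: int = 4096,
    seeds: Sequence[int] = (0,),
    ratios: Sequence[float | str] = ("all",),
    use_chunking: bool = False,
) -> list[EvaluationResult]:
    """Generate a synthetic corpus and run the full retrieval benchmark on it.

    The embedding hash seed is tied to the corpus seed so one config seed
    drives all randomness.
    """
    records, annotations = generate_corpus(config)
    vectors, spec = embed_records(
        records, dimension=dimension, seed=config.seed, use_chunking=use_chunking
    )
    return evaluate_vector_model(
        vectors,
        annotations_mapping(annotations),
        model=spec.name,
        seeds=seeds,
        ratios=ratios,
    )
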