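"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from fractions import Fraction
from math import comb

import pytest
from hypothesis import settings

from geoseek.ingest import SeriesRecord
from geoseek.synthetic import CorpusConfig, generate_corpus

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def ap_positive_position_oracle(labels) -> float:
    """Brute-force average precision: precision evaluated at each positive's
    rank position, averaged over positives.  Plain-loop reference kept
    independent of the vectorized implementation."""
    total = 0.0
    hits = 0
    positives = sum(labels)
    assert positives > 0
    for k, label in enumerate(labels, start=1):
        if label:
            hits += 1
            total += hits / k
    return total / positives


def expected_ap_random(n: int, p: int) -> float:
    """Exact expected average precision of a uniformly random ranking of
    *p* positives among *n* items, by enumeration over the order-statistic
    distribution of positive positions.

    The i-th positive (in rank order) sits at position k with probability
    C(k-1, i-1) C(n-k, p-i) / C(n, p) and contributes precision i/k.
    """
    total = Fraction(0)
    denom = comb(n, p)
    for i in range(1, p + 1):
        for k in range(i, n - p + i + 1):
            prob = Fraction(comb(k - 1, i - 1) * comb(n - k, p - i), denom)
            total += Fraction(i, k) * prob
    return float(total / p)


@pytest.fixture(scope="session")
def ap_oracle():
    return ap_positive_position_oracle


@pytest.fixture(scope="session")
def random_ap_expectation():
    return expected_ap_random


@pytest.fixture
def toy_records() -> list[SeriesRecord]:
    return [
        SeriesRecord(
            accession="GSE1",
            title="Transcriptome of juvenile idiopathic arthritis",
            summary="Expression profiling of blood from JIA patients.",
            overall_design="Case-control microarray design",
            organisms=frozenset({"Homo sapiens"}),
            experiment_types=frozenset({"expression profiling by array"}),
            platform_vendor="Affymetrix",
        ),
        SeriesRecord(
            accession="GSE2",
            title="Mouse brain atlas",
            summary="Single-cell profiling of mouse cortex.",
            overall_design=None,
            organisms=frozenset({"Mus musculus"}),
            experiment_types=frozenset({"expression profiling by array"}),
            platform_vendor="Affymetrix",
        ),
        SeriesRecord(
            accession="GSE3",
            title="Neuroblastoma cell lines",
            summary="RNA-seq of neuroblastoma lines.",
            overall_design=None,
            organisms=frozenset({"Homo sapiens"}),
            experiment_types=frozenset(
                {"expression profiling by high throughput sequencing"}
            ),
            platform_vendor="Illumina",
            is_subseries=True,
        ),
    ]


@pytest.fixture(scope="session")
def small_corpus():
    """A compact high-signal synthetic corpus shared across tests."""
    config = CorpusConfig(
        n_conditions=3,
        series_per_condition=(8, 8, 8),
        n_background_series=60,
        background_vocab_size=400,
        condition_vocab_size=40,
        signal=1.0,
        length_range=(10, 40),
        seed=7,
    )
    return generate_corpus(config)
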