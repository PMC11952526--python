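"""Synthetic condition-annotated metadata corpus with tunable lexical signal.

Emulates a curated corpus of study records: each *condition* owns a private
vocabulary, disjoint from every other condition's and from a shared
background vocabulary.  A condition-annotated series draws each token from
its condition's vocabulary with probability ``signal`` and from the
background otherwise; unannotated background series draw every token from
the background.  ``signal`` therefore controls how lexically distinctive a
condition's descriptions are: at 1.0 conditions are perfectly separable by
vocabulary, at 0.0 annotated and background series are distributionally
identical and retrieval can do no better than chance.

Token sampling is i.i.d. from the two urns — no grammar.  The retrieval
method under test is bag-like, so a lexical mixture suffices to emulate
varying distinctiveness of condition language.  Series lengths are drawn
uniformly from a token range whose default straddles the 256-character
chunking threshold, so both chunked and unchunked code paths are exercised.

An optional *near-miss* mode adds confuser conditions that share a fraction
of a target condition's vocabulary, emulating clinically overlapping
conditions that are easy to confuse in retrieval; it is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluate import ConditionAnnotation
from .ingest import SeriesRecord

__all__ = ["CorpusConfig", "generate_corpus"]


@dataclass(frozen=True)
class CorpusConfig:
    """Generator settings.

    signal
        Probability that a token of a condition-annotated series comes from
        the condition vocabulary rather than the background; in [0, 1].
    length_range
        Inclusive (min, max) token count per series; tokens are ~7-8
        characters, so the default 15-60 tokens spans roughly 120-480
        characters of clean text.
    near_miss_conditions / near_miss_share
        Number of confuser conditions to add and the fraction of the target
        condition's vocabulary each confuser reuses (0 disables).
    """

    n_conditions: int = 6
    series_per_condition: tuple[int, ...] = (12,) * 6
    n_background_series: int = 500
    background_vocab_size: int = 2000
    condition_vocab_size: int = 100
    signal: float = 0.75
    length_range: tuple[int, int] = (15, 60)
    seed: int = 0
    near_miss_conditions: int = 0
    near_miss_share: float = 0.5

    def __post_init__(self) -> None:
        object.__setattr__(self, "series_per_condition", tuple(self.series_per_condition))
        object.__setattr__(self, "length_range", tuple(self.length_range))
        if self.n_conditions < 1:
            raise ValueError("n_conditions must be positive")
        if len(self.series_per_condition) != self.n_conditions:
            raise ValueError("series_per_condition must have one entry per condition")
        if any(n < 1 for n in self.series_per_condition):
            raise ValueError("series_per_condition entries must be positive")
        if not 0.0 <= self.signal <= 1.0:
            raise ValueError("signal must lie in [0, 1]")
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ValueError("length_range must satisfy 1 <= min <= max")
        if self.near_miss_conditions and not 0.0 <= self.near_miss_share <= 1.0:
            raise ValueError("near_miss_share must lie in [0, 1]")


def _condition_vocab(index: int, size: int) -> list[str]:
    return [f"c{index:02d}t{i:04d}" for i in range(size)]


def generate_corpus(
    config: CorpusConfig,
) -> tuple[list[SeriesRecord], list[ConditionAnnotation]]:
    """Generate series records and their condition annotations.

    Deterministic: a fixed config (including seed) always produces the same
    records in the same order, so serialized output is byte-identical across
    runs.
    """
    rng = np.random.default_rng(config.seed)
    background = [f"bg{i:05d}" for i in range(config.background_vocab_size)]
    condition_vocabs = {
        f"cond{k:02d}": _condition_vocab(k, config.condition_vocab_size)
        for k in range(config.n_conditions)
    }
    counts = dict(zip(sorted(condition_vocabs), config.series_per_condition))

    if config.near_miss_conditions:
        targets = sorted(condition_vocabs)
        for j in range(config.near_miss_conditions):
            target = targets[j % len(targets)]
            shared_n = int(round(config.near_miss_share * config.condition_vocab_size))
            own = _condition_vocab(100 + j, config.condition_vocab_size - shared_n)
            vocab = list(condition_vocabs[target][:shared_n]) + own
            name = f"nearmiss{j:02d}_{target}"
            condition_vocabs[name] = vocab
            counts[name] = counts[target]

    vocab_sets = [set(background)] + [set(v) for v in condition_vocabs.values()]
    if not config.near_miss_conditions:
        total = sum(len(s) for s in vocab_sets)
        if len(set().union(*vocab_sets)) != total:
            raise RuntimeError("internal error: generated vocabularies overlap")

    records: list[SeriesRecord] = []
    annotations: dict[str, set[str]] = {cond: set() for cond in condition_vocabs}
    serial = 0

    def draw_series(condition: str | None) -> SeriesRecord:
        nonlocal serial
        serial += 1
        accession = f"GSE9{serial:06d}"
        lo, hi = config.length_range
        length = int(rng.integers(lo, hi + 1))
        bg_idx = rng.integers(0, len(background), size=length)
        if condition is None:
            tokens = [background[i] for i in bg_idx]
        else:
            vocab = condition_vocabs[condition]
            cond_idx = rng.integers(0, len(vocab), size=length)
            from_condition = rng.random(length) < config.signal
            tokens = [
                vocab[ci] if flag else background[bi]
                for ci, bi, flag in zip(cond_idx, bg_idx, from_condition)
            ]
        n_title = min(5, length)
        rest = tokens[n_title:]
        n_summary = (len(rest) * 7 + 9) // 10  # ~70% of the remainder
        has_design = bool(rng.random() < 0.75) and len(rest) > n_summary
        title = " ".join(tokens[:n_title])
        if has_design:
            summary = " ".join(rest[:n_summary])
            design = " ".join(rest[n_summary:])
        else:
            summary = " ".join(rest)
            design = None
        return SeriesRecord(
            accession=accession,
            title=title,
            summary=summary,
            overall_design=design,
            organisms=frozenset({"Homo sapiens"}),
            experiment_types=frozenset({"expression profiling by array"}),
            platform_vendor="Affymetrix",
            is_retired=False,
            is_subseries=False,
        )

    for condition in sorted(condition_vocabs):
        for _ in range(counts[condition]):
            rec = draw_series(condition)
            records.append(rec)
            annotations[condition].add(rec.accession)
    for _ in range(config.n_background_series):
        records.append(draw_series(None))

    annotation_list = [
        ConditionAnnotation(condition=cond, accessions=frozenset(accs))
        for cond, accs in sorted(annotations.items())
    ]
    return records, annotation_list
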