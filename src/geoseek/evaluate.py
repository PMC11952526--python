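"""Benchmark harness: condition splits, imbalance subsampling, and
retrieval metrics (average precision, recall@n, rank summaries).

The experimental design evaluates how well a ranking method finds the
held-out half of a condition's annotated series.  For each condition:

1. Randomly partition the condition's series into a *reference set* and
   *comparison set A* (the reference set gets the extra member when the
   count is odd).
2. All other annotated series form *comparison set B* — the non-relevant
   candidate pool, optionally subsampled to a fixed imbalance ratio
   (pool size as a multiple of |A|).
3. Rank A ∪ B against the averaged reference embedding and score the
   ranking: average precision (area under the precision-recall curve for a
   ranked binary list) and recall@n.

Randomness is explicit: every split and subsample takes a seed, and results
carry it.  Subsamples at different ratios under one seed are nested
(prefixes of one seeded permutation), so growing the ratio can only push
relevant series down — imbalance comparisons are paired, not re-randomized.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence, TextIO

import numpy as np
from scipy import stats

from .embed import average_embeddings
from .search import rank_by_word_overlap, rank_candidates

__all__ = [
    "ConditionAnnotation",
    "SplitAssignment",
    "EvaluationResult",
    "split_condition_sets",
    "build_comparison_pool",
    "subsample_imbalance",
    "average_precision",
    "recall_at_n",
    "recall_curve",
    "spearman_rho",
    "median_rank_table",
    "evaluate_condition",
    "evaluate_vector_model",
    "evaluate_word_overlap_model",
    "results_to_rows",
    "read_annotations",
    "annotations_to_tsv",
    "DEFAULT_RECALL_POINTS",
]

DEFAULT_RECALL_POINTS = (1, 2, 5, 10, 20, 50, 100, 200, 500, 1000)


@dataclass(frozen=True)
class ConditionAnnotation:
    """Curator-assigned condition label and its member series."""

    condition: str
    accessions: frozenset[str]

    def __post_init__(self) -> None:
        if not self.accessions:
            raise ValueError(f"{self.condition}: annotation has no accessions")
        object.__setattr__(self, "accessions", frozenset(self.accessions))


@dataclass(frozen=True)
class SplitAssignment:
    """Reference / comparison-A / comparison-B sets for one condition and seed."""

    condition: str
    reference: frozenset[str]
    comparison_a: frozenset[str]
    comparison_b: frozenset[str]
    seed: int


@dataclass(frozen=True)
class EvaluationResult:
    model: str
    condition: str
    seed: int
    imbalance_ratio: float | str
    auprc: float
    recall_curve: tuple[tuple[int, float], ...] = field(default_factory=tuple)


def split_condition_sets(
    accessions: Iterable[str], seed: int
) -> tuple[frozenset[str], frozenset[str]]:
    """Uniformly random half/half partition into (reference, comparison A).

    The reference set receives the extra member when the count is odd.
    Deterministic for a fixed seed.
    """
    pool = sorted(set(accessions))
    if len(pool) < 2:
        raise ValueError(
            f"need at least 2 accessions to split, got {len(pool)} (comparison set would be empty)"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pool))
    n_ref = (len(pool) + 1) // 2
    reference = frozenset(pool[i] for i in order[:n_ref])
    comparison_a = frozenset(pool[i] for i in order[n_ref:])
    return reference, comparison_a


def build_comparison_pool(
    all_annotated: Iterable[str], condition_accessions: Iterable[str]
) -> frozenset[str]:
    """Comparison set B: every annotated series not tagged with the condition."""
    universe = frozenset(all_annotated)
    condition = frozenset(condition_accessions)
    missing = condition - universe
    if missing:
        raise ValueError(
            f"condition accessions absent from the annotated universe: {', '.join(sorted(missing))}"
        )
    return universe - condition


def subsample_imbalance(
    comparison_b: Iterable[str],
    ratio: float | str,
    a_size: int,
    seed: int,
) -> frozenset[str]:
    """Uniform random subset of the non-relevant pool at a fixed imbalance.

    A ratio of 10 keeps ``round(10 * a_size)`` members (round half to even);
    the sentinel ``"all"`` returns the pool unchanged.  For one seed the
    subsets at increasing ratios are nested.
    """
    pool = sorted(set(comparison_b))
    if ratio == "all":
        return frozenset(pool)
    if a_size < 1:
        raise ValueError("a_size must be positive")
    k = round(float(ratio) * a_size)
    if k > len(pool):
        raise ValueError(
            f"ratio {ratio} needs {k} series but the pool has {len(pool)} "
            f"(maximum feasible ratio {len(pool) / a_size:g})"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pool))
    return frozenset(pool[i] for i in order[:k])


# ---------------------------------------------------------------------------
# Metrics


def average_precision(ranked_labels: Sequence[int] | Sequence[bool]) -> float:
    """Average precision of a ranked binary-label list.

    AP = (1/P) * sum over positive positions k of precision@k, the exact
    area under the precision-recall step curve of a ranking.
    """
    labels = np.asarray(ranked_labels, dtype=float)
    positives = labels.sum()
    if positives == 0:
        raise ValueError("average precision is undefined with zero positives")
    hits = np.cumsum(labels)
    ranks = np.arange(1, len(labels) + 1)
    return float(np.sum((hits / ranks) * labels) / positives)


def recall_at_n(ranked_labels: Sequence[int] | Sequence[bool], n: int) -> float:
    """Fraction of all positives found within the top *n* ranked items."""
    labels = np.asarray(ranked_labels, dtype=float)
    if n < 1 or n > len(labels):
        raise ValueError(f"n must be in [1, {len(labels)}], got {n}")
    positives = labels.sum()
    if positives == 0:
        raise ValueError("recall is undefined with zero positives")
    return float(labels[:n].sum() / positives)


def recall_curve(
    ranked_labels: Sequence[int] | Sequence[bool],
    points: Sequence[int] = DEFAULT_RECALL_POINTS,
) -> tuple[tuple[int, float], ...]:
    """(n, recall@n) at the requested cutoffs, clipped to the list length."""
    length = len(ranked_labels)
    ns = sorted({min(n, length) for n in points if n >= 1} | {length})
    return tuple((n, recall_at_n(ranked_labels, n)) for n in ns)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (midranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for a constant sequence")
    return float(stats.spearmanr(x, y).statistic)


def median_rank_table(
    auprc: Mapping[tuple[str, str], float]
) -> list[tuple[str, float]]:
    """Cross-condition model ranking summary.

    Within each condition, models are ranked by descending AUPRC (midranks
    for ties); each model's median rank across conditions is reported, best
    (lowest) first, ties broken by model name.
    """
    models = sorted({m for m, _ in auprc})
    conditions = sorted({c for _, c in auprc})
    missing = [(m, c) for m in models for c in conditions if (m, c) not in auprc]
    if missing:
        raise ValueError(f"missing (model, condition) cells: {missing}")
    ranks_by_model: dict[str, list[float]] = {m: [] for m in models}
    for cond in conditions:
        scores = np.array([auprc[(m, cond)] for m in models])
        ranks = stats.rankdata(-scores, method="average")
        for m, r in zip(models, ranks):
            ranks_by_model[m].append(float(r))
    medians = [(m, float(np.median(ranks_by_model[m]))) for m in models]
    medians.sort(key=lambda item: (item[1], item[0]))
    return medians


# ---------------------------------------------------------------------------
# Orchestration


def make_split(
    condition: str,
    annotations: Mapping[str, frozenset[str]],
    seed: int,
    universe: Iterable[str] | None = None,
) -> SplitAssignment:
    """Split one condition and assemble its full comparison pool.

    *universe* is the evaluated corpus (every candidate accession); it
    defaults to the union of all annotation sets.  Comparison set B is the
    universe minus the condition's own series, so it includes series
    annotated with other conditions as well as unannotated corpus members.
    """
    cond_accs = annotations[condition]
    if universe is None:
        universe = frozenset().union(*annotations.values())
    reference, comparison_a = split_condition_sets(cond_accs, seed)
    comparison_b = build_comparison_pool(universe, cond_accs)
    return SplitAssignment(
        condition=condition,
        reference=reference,
        comparison_a=comparison_a,
        comparison_b=comparison_b,
        seed=seed,
    )


def _labels_from_ranking(
    ranked: list[tuple[str, float]], relevant: frozenset[str]
) -> list[int]:
    return [1 if acc in relevant else 0 for acc, _ in ranked]


def evaluate_condition(
    split: SplitAssignment,
    rank: Callable[[frozenset[str], frozenset[str]], list[tuple[str, float]]],
    model: str,
    ratios: Sequence[float | str] = ("all",),
    recall_points: Sequence[int] = DEFAULT_RECALL_POINTS,
) -> list[EvaluationResult]:
    """Score one ranking callable on one condition split at each ratio.

    ``rank(reference, candidates)`` must return a ranked (accession, score)
    list over exactly the candidate accessions.
    """
    results = []
    a_size = len(split.comparison_a)
    for ratio in ratios:
        pool = subsample_imbalance(split.comparison_b, ratio, a_size, split.seed)
        candidates = split.comparison_a | pool
        ranked = rank(split.reference, candidates)
        labels = _labels_from_ranking(ranked, split.comparison_a)
        results.append(
            EvaluationResult(
                model=model,
                condition=split.condition,
                seed=split.seed,
                imbalance_ratio=ratio,
                auprc=average_precision(labels),
                recall_curve=recall_curve(labels, recall_points),
            )
        )
    return results


def evaluate_vector_model(
    vectors: Mapping[str, np.ndarray],
    annotations: Mapping[str, frozenset[str]],
    model: str,
    seeds: Sequence[int],
    ratios: Sequence[float | str] = ("all",),
    recall_points: Sequence[int] = DEFAULT_RECALL_POINTS,
) -> list[EvaluationResult]:
    """Run the full design for an embedding model over conditions and seeds."""

    def rank(reference: frozenset[str], candidates: frozenset[str]):
        profile = average_embeddings([vectors[a] for a in sorted(reference)])
        return rank_candidates(profile, {a: vectors[a] for a in candidates})

    results = []
    universe = frozenset(vectors)
    for condition in sorted(annotations):
        for seed in seeds:
            split = make_split(condition, annotations, seed, universe=universe)
            results.extend(
                evaluate_condition(split, rank, model, ratios, recall_points)
            )
    return results


def evaluate_word_overlap_model(
    documents: Mapping[str, str],
    annotations: Mapping[str, frozenset[str]],
    seeds: Sequence[int],
    ratios: Sequence[float | str] = ("all",),
    model: str = "word-overlap",
    mode: str = "union",
    recall_points: Sequence[int] = DEFAULT_RECALL_POINTS,
) -> list[EvaluationResult]:
    """Run the full design for the word-overlap baseline."""

    def rank(reference: frozenset[str], candidates: frozenset[str]):
        return rank_by_word_overlap(
            [documents[a] for a in sorted(reference)],
            {a: documents[a] for a in candidates},
            mode=mode,
        )

    results = []
    universe = frozenset(documents)
    for condition in sorted(annotations):
        for seed in seeds:
            split = make_split(condition, annotations, seed, universe=universe)
            results.extend(
                evaluate_condition(split, rank, model, ratios, recall_points)
            )
    return results


# ---------------------------------------------------------------------------
# Result and annotation I/O


def results_to_rows(
    results: Iterable[EvaluationResult],
) -> tuple[str, str]:
    """Serialize results to two TSV texts: summary rows and recall curves."""
    summary = io.StringIO()
    curves = io.StringIO()
    sw = csv.writer(summary, delimiter="\t", lineterminator="\n")
    cw = csv.writer(curves, delimiter="\t", lineterminator="\n")
    sw.writerow(["model", "condition", "seed", "imbalance_ratio", "auprc"])
    cw.writerow(["model", "condition", "seed", "imbalance_ratio", "n", "recall"])
    for r in results:
        sw.writerow([r.model, r.condition, r.seed, r.imbalance_ratio, repr(r.auprc)])
        for n, rec in r.recall_curve:
            cw.writerow([r.model, r.condition, r.seed, r.imbalance_ratio, n, repr(rec)])
    return summary.getvalue(), curves.getvalue()


def read_annotations(stream: TextIO | str) -> dict[str, frozenset[str]]:
    """Read a condition-annotation TSV (condition, accession; one pair per row)."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    pairs: dict[str, set[str]] = {}
    for i, row in enumerate(csv.reader(stream, delimiter="\t"), start=1):
        if not row or row[0].startswith("#"):
            continue
        if row[0].lower() == "condition":
            continue
        if len(row) < 2:
            raise ValueError(f"annotation line {i}: expected 'condition<TAB>accession'")
        pairs.setdefault(row[0], set()).add(row[1])
    return {cond: frozenset(accs) for cond, accs in pairs.items()}


def annotations_to_tsv(annotations: Mapping[str, Iterable[str]]) -> str:
    buf = io.StringIO()
    writer = csv.writer(buf, delimiter="\t", lineterminator="\n")
    writer.writerow(["condition", "accession"])
    for cond in sorted(annotations):
        for acc in sorted(annotations[cond]):
            writer.writerow([cond, acc])
    return buf.getvalue()
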