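"""Experimental-design splits, imbalance subsampling, and retrieval metrics."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from geoseek.evaluate import (
    average_precision,
    build_comparison_pool,
    make_split,
    median_rank_table,
    read_annotations,
    annotations_to_tsv,
    recall_at_n,
    recall_curve,
    spearman_rho,
    split_condition_sets,
    subsample_imbalance,
)


def accs(n, prefix="GSE"):
    return {f"{prefix}{i:04d}" for i in range(n)}


class TestSplit:
    def test_even_count_halves(self):
        ref, comp_a = split_condition_sets(accs(12), seed=0)
        assert len(ref) == 6 and len(comp_a) == 6
        assert ref | comp_a == accs(12) and not ref & comp_a

    def test_odd_count_reference_gets_extra(self):
        ref, comp_a = split_condition_sets(accs(13), seed=0)
        assert len(ref) == 7 and len(comp_a) == 6

    def test_deterministic_for_fixed_seed(self):
        assert split_condition_sets(accs(20), 5) == split_condition_sets(accs(20), 5)

    def test_seed_varies_partition(self):
        partitions = {split_condition_sets(accs(20), s)[0] for s in range(8)}
        assert len(partitions) > 1

    def test_uniformity_over_seeds(self):
        """Each accession should land in the reference set about half the time."""
        pool = sorted(accs(10))
        counts = {a: 0 for a in pool}
        n_seeds = 400
        for seed in range(n_seeds):
            ref, _ = split_condition_sets(pool, seed)
            for a in ref:
                counts[a] += 1
        for a, c in counts.items():
            assert abs(c / n_seeds - 0.5) < 0.1, (a, c)

    def test_too_few_accessions(self):
        with pytest.raises(ValueError, match="at least 2"):
            split_condition_sets({"GSE1"}, 0)


class TestComparisonPool:
    def test_annotated_corpus_scale_arithmetic(self):
        universe = accs(5997)
        condition = set(sorted(universe)[:12])
        pool = build_comparison_pool(universe, condition)
        assert len(pool) == 5985
        assert not pool & condition

    def test_condition_equals_universe_gives_empty_pool(self):
        u = accs(5)
        assert build_comparison_pool(u, u) == frozenset()

    def test_condition_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="GSEX"):
            build_comparison_pool(accs(3), {"GSEX"})


class TestSubsample:
    def test_ratio_10_size(self):
        pool = accs(200)
        sub = subsample_imbalance(pool, 10, a_size=6, seed=0)
        assert len(sub) == 60 and sub <= pool

    def test_ratio_1_size_matches_test_set(self):
        sub = subsample_imbalance(accs(50), 1, a_size=6, seed=0)
        assert len(sub) == 6

    def test_all_sentinel_returns_pool(self):
        pool = accs(37)
        for seed in (0, 1, 99):
            assert subsample_imbalance(pool, "all", 6, seed) == frozenset(pool)

    def test_round_half_to_even(self):
        assert len(subsample_imbalance(accs(50), 2.5, a_size=1, seed=0)) == 2
        assert len(subsample_imbalance(accs(50), 3.5, a_size=1, seed=0)) == 4

    def test_infeasible_ratio_reports_maximum(self):
        with pytest.raises(ValueError, match="maximum feasible ratio 5"):
            subsample_imbalance(accs(30), 10, a_size=6, seed=0)

    def test_nested_across_ratios_for_one_seed(self):
        pool = accs(120)
        subsets = [subsample_imbalance(pool, r, 6, seed=3) for r in (1, 5, 10, 20)]
        for small, large in zip(subsets, subsets[1:]):
            assert small <= large

    def test_deterministic(self):
        assert subsample_imbalance(accs(80), 5, 6, 2) == subsample_imbalance(
            accs(80), 5, 6, 2
        )


class TestAveragePrecision:
    @pytest.mark.parametrize(
        "labels, expected",
        [
            ([1, 1, 0], 1.0),
            ([1, 0, 1], 5 / 6),
            ([0, 0, 1], 1 / 3),
            ([1], 1.0),
        ],
    )
    def test_hand_computed(self, labels, expected):
        assert average_precision(labels) == pytest.approx(expected)

    def test_zero_positives_undefined(self):
        with pytest.raises(ValueError):
            average_precision([0, 0, 0])

    def test_matches_oracle_on_random_vectors(self, ap_oracle):
        rng = np.random.default_rng(0)
        for _ in range(50):
            labels = (rng.random(10) < 0.4).astype(int)
            if labels.sum() == 0:
                labels[rng.integers(10)] = 1
            assert average_precision(labels) == pytest.approx(ap_oracle(labels))

    def test_matches_sklearn_average_precision(self):
        from sklearn.metrics import average_precision_score

        rng = np.random.default_rng(1)
        for _ in range(20):
            labels = (rng.random(30) < 0.3).astype(int)
            if labels.sum() == 0:
                labels[0] = 1
            scores = -np.arange(30, dtype=float)  # ranked order as scores
            assert average_precision(labels) == pytest.approx(
                average_precision_score(labels, scores)
            )

    def test_perfect_ranking_is_one_and_reversal_is_minimum(self):
        for n, p in [(5, 2), (6, 3), (8, 1)]:
            perfect = [1] * p + [0] * (n - p)
            assert average_precision(perfect) == pytest.approx(1.0)
            worst = average_precision(perfect[::-1])
            values = [
                average_precision(list(perm))
                for perm in set(itertools.permutations(perfect))
            ]
            assert worst == pytest.approx(min(values))


class TestRecall:
    def test_half_of_positives_in_top_two(self):
        assert recall_at_n([1, 0, 1, 0], 2) == pytest.approx(0.5)

    def test_full_list_recall_is_one(self):
        assert recall_at_n([0, 1, 0, 1], 4) == 1.0

    def test_tail_positives_zero(self):
        assert recall_at_n([0, 0, 0, 1, 1], 3) == 0.0

    def test_n_beyond_length_rejected(self):
        with pytest.raises(ValueError):
            recall_at_n([1, 0], 3)

    @given(
        st.lists(st.integers(0, 1), min_size=2, max_size=30).filter(lambda l: sum(l) > 0)
    )
    def test_non_decreasing_in_n(self, labels):
        values = [recall_at_n(labels, n) for n in range(1, len(labels) + 1)]
        assert all(a <= b for a, b in zip(values, values[1:]))
        assert values[-1] == 1.0

    def test_curve_points_clipped_and_final_is_length(self):
        labels = [1, 0, 0, 1]
        curve = recall_curve(labels, points=(1, 2, 100))
        assert curve == ((1, 0.5), (2, 0.5), (4, 1.0))


class TestSpearman:
    def test_monotone_and_antitone(self):
        assert spearman_rho([1, 2, 3], [10, 20, 30]) == pytest.approx(1.0)
        assert spearman_rho([1, 2, 3], [30, 20, 10]) == pytest.approx(-1.0)

    def test_tied_case_matches_midrank_oracle(self):
        x = [1.0, 2.0, 2.0, 4.0, 5.0, 6.0]
        y = [3.0, 1.0, 4.0, 4.0, 5.0, 9.0]

        def midranks(v):
            order = sorted(range(len(v)), key=lambda i: v[i])
            ranks = [0.0] * len(v)
            i = 0
            while i < len(order):
                j = i
                while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                    j += 1
                avg = (i + j) / 2 + 1
                for k in range(i, j + 1):
                    ranks[order[k]] = avg
                i = j + 1
            return ranks

        rx, ry = midranks(x), midranks(y)
        mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
        cov = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
        sx = math.sqrt(sum((a - mx) ** 2 for a in rx))
        sy = math.sqrt(sum((b - my) ** 2 for b in ry))
        assert spearman_rho(x, y) == pytest.approx(cov / (sx * sy), abs=1e-12)

    def test_constant_sequence_undefined(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 1, 1], [1, 2, 3])

    def test_short_sequences_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 2], [3, 4])


class TestMedianRankTable:
    def test_two_model_hand_case(self):
        table = {
            ("A", "c1"): 0.9,
            ("A", "c2"): 0.8,
            ("B", "c1"): 0.5,
            ("B", "c2"): 0.7,
        }
        assert median_rank_table(table) == [("A", 1.0), ("B", 2.0)]

    def test_identical_models_name_ordered(self):
        table = {(m, c): 0.5 for m in "ZYX" for c in ("c1", "c2")}
        result = median_rank_table(table)
        assert [m for m, _ in result] == ["X", "Y", "Z"]
        assert len({r for _, r in result}) == 1

    def test_missing_cell_named(self):
        with pytest.raises(ValueError, match="B.*c2"):
            median_rank_table({("A", "c1"): 1, ("A", "c2"): 1, ("B", "c1"): 1})

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(9)
        models = [f"m{i}" for i in range(5)]
        conditions = [f"c{j}" for j in range(3)]
        table = {(m, c): float(rng.random()) for m in models for c in conditions}
        result = dict(median_rank_table(table))
        # oracle: per condition, rank by counting strictly-better models
        for m in models:
            ranks = []
            for c in conditions:
                better = sum(table[(o, c)] > table[(m, c)] for o in models)
                equal = sum(table[(o, c)] == table[(m, c)] for o in models)
                ranks.append(better + (equal + 1) / 2)
            assert result[m] == pytest.approx(sorted(ranks)[len(ranks) // 2])


class TestRandomRankingCalibration:
    def test_mean_ap_matches_enumerated_expectation(self, random_ap_expectation):
        """Over 200 seeded shuffles of 5 positives among 500 items the mean
        average precision sits within 3 standard errors of the exact
        expectation for a uniformly random ranking."""
        rng = np.random.default_rng(2024)
        base = np.array([1] * 5 + [0] * 495)
        values = []
        for _ in range(200):
            values.append(average_precision(rng.permutation(base)))
        values = np.array(values)
        se = values.std(ddof=1) / math.sqrt(len(values))
        expected = random_ap_expectation(500, 5)
        assert abs(values.mean() - expected) < 3 * se


class TestAnnotationIO:
    def test_round_trip(self):
        ann = {"jia": frozenset({"GSE2", "GSE1"}), "pd": frozenset({"GSE3"})}
        text = annotations_to_tsv(ann)
        assert read_annotations(text) == ann

    def test_header_and_comments_skipped(self):
        text = "# provenance\ncondition\taccession\njia\tGSE1\n"
        assert read_annotations(text) == {"jia": frozenset({"GSE1"})}

    def test_short_row_rejected(self):
        with pytest.raises(ValueError, match="line 1"):
            read_annotations("jia\n")


def test_make_split_sets_pairwise_disjoint():
    annotations = {
        "a": frozenset(accs(13, "A")),
        "b": frozenset(accs(20, "B")),
    }
    split = make_split("a", annotations, seed=1)
    assert len(split.reference) == 7 and len(split.comparison_a) == 6
    assert not split.reference & split.comparison_a
    assert not (split.reference | split.comparison_a) & split.comparison_b
    assert split.comparison_b == frozenset(accs(20, "B"))
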