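"""Sensitivity-to-first-FP statistic and embedding-based annotation transfer."""

import numpy as np
import pytest

from pro3di.homology import (
    BenchmarkResult,
    HitList,
    benchmark,
    eat_transfer,
    hitlists_from_scores,
    label_frequency_baseline,
    sensitivity_first_fp,
)
from pro3di.records import HierarchyLabel


def _label(fold, sup=0, fam=0):
    return HierarchyLabel((f"f{fold}", f"s{fold}-{sup}", f"m{fold}-{sup}-{fam}"))


def _random_universe(rng, n=30):
    labels = {
        f"t{i}": _label(rng.integers(0, 3), rng.integers(0, 2), rng.integers(0, 2))
        for i in range(n)
    }
    return labels


def _second_walk(hits, labels, level):
    """Independent re-implementation of the benchmark walk (different style)."""
    q = labels[hits.query_id]
    possible = [
        t for t in labels
        if t != hits.query_id and labels[t].levels[: level + 1] == q.levels[: level + 1]
    ]
    if not possible:
        return None
    found = 0
    for target, _ in hits.hits:
        t = labels[target]
        if t.levels[0] != q.levels[0]:
            break
        if t.levels[: level + 1] == q.levels[: level + 1]:
            found += 1
    return found / len(possible)


class TestSensitivity:
    LABELS = {
        "q": _label(0, 0, 0),
        **{f"fam{i}": _label(0, 0, 0) for i in range(4)},
        "neutral": _label(0, 1, 0),
        "fp": _label(1, 0, 0),
    }

    def test_all_tps_before_fp_gives_one(self):
        hits = HitList("q", [(f"fam{i}", 10.0 - i) for i in range(4)])
        assert sensitivity_first_fp(hits, self.LABELS, 2) == 1.0

    def test_first_hit_fp_gives_zero(self):
        hits = HitList("q", [("fp", 9.0), ("fam0", 8.0)])
        assert sensitivity_first_fp(hits, self.LABELS, 2) == 0.0

    def test_neutral_hits_neither_count_nor_terminate(self):
        # order: TP, neutral(same fold, other superfamily), TP, FP, TP -> 2/4
        hits = HitList(
            "q",
            [("fam0", 9), ("neutral", 8), ("fam1", 7), ("fp", 6), ("fam2", 5)],
        )
        assert sensitivity_first_fp(hits, self.LABELS, 2) == pytest.approx(0.5)

    def test_no_possible_tp_returns_none(self):
        labels = {"q": _label(0), "fp": _label(1)}
        assert sensitivity_first_fp(HitList("q", [("fp", 1.0)]), labels, 2) is None

    def test_unlabeled_target_rejected(self):
        with pytest.raises(ValueError, match="unlabeled"):
            sensitivity_first_fp(HitList("q", [("mystery", 1.0)]), self.LABELS, 0)

    def test_agrees_with_independent_walk_on_random_hitlists(self):
        rng = np.random.default_rng(0)
        labels = _random_universe(rng)
        ids = list(labels)
        for _ in range(200):
            q = ids[rng.integers(0, len(ids))]
            others = [t for t in ids if t != q]
            rng.shuffle(others)
            hits = HitList(q, [(t, float(len(others) - k)) for k, t in enumerate(others)])
            for level in range(3):
                assert sensitivity_first_fp(hits, labels, level) == _second_walk(
                    hits, labels, level
                )

    def test_permuting_neutral_hits_does_not_change_sensitivity(self):
        hits = [("fam0", 9), ("neutral", 8), ("fam1", 7), ("fp", 6)]
        base = sensitivity_first_fp(HitList("q", hits), self.LABELS, 2)
        # swap the neutral hit earlier; family-level sensitivity is unchanged
        swapped = [("neutral", 9.5)] + [h for h in hits if h[0] != "neutral"]
        assert sensitivity_first_fp(HitList("q", swapped), self.LABELS, 2) == base


class TestBenchmark:
    def test_mean_of_sensitivities(self):
        labels = {
            "q1": _label(0), "a": _label(0), "x": _label(1),
            "q2": _label(1), "b": _label(1),
        }
        hitlists = [
            HitList("q1", [("a", 2.0), ("x", 1.0)]),  # TP then FP -> 1.0
            HitList("q2", [("x", 2.0), ("b", 1.0)]),  # wait: x shares q2's fold
        ]
        # q2: first hit x is same fold (f1) at level 0 -> TP; b also TP -> 1.0
        res = benchmark(hitlists, labels, levels=[0])
        assert res.mean_sensitivity[0] == pytest.approx(1.0)

    def test_two_queries_mean_half(self):
        labels = {"q1": _label(0), "a": _label(0), "q2": _label(2), "z": _label(1)}
        labels["b"] = _label(2)
        hitlists = [
            HitList("q1", [("a", 2.0)]),            # 1.0
            HitList("q2", [("z", 2.0), ("b", 1.0)]),  # FP first -> 0.0
        ]
        res = benchmark(hitlists, labels, levels=[0])
        assert res.mean_sensitivity[0] == pytest.approx(0.5)

    def test_deterministic_on_identical_input(self):
        rng = np.random.default_rng(3)
        labels = _random_universe(rng)
        ids = list(labels)
        hitlists = []
        for q in ids[:10]:
            others = [t for t in ids if t != q]
            hitlists.append(HitList(q, [(t, float(i)) for i, t in enumerate(others)]))
        r1 = benchmark(hitlists, labels)
        r2 = benchmark(hitlists, labels)
        assert r1.mean_sensitivity == r2.mean_sensitivity

    def test_sorted_curve_area_equals_mean(self):
        rng = np.random.default_rng(4)
        labels = _random_universe(rng)
        ids = list(labels)
        hitlists = []
        for q in ids:
            others = [t for t in ids if t != q]
            rng.shuffle(others)
            hitlists.append(HitList(q, [(t, float(i)) for i, t in enumerate(others)]))
        res = benchmark(hitlists, labels, levels=[1])
        _x, y = res.sorted_curve(1)
        assert float(np.mean(y)) == pytest.approx(res.mean_sensitivity[1])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            benchmark([], {})

    def test_hitlist_validation(self):
        with pytest.raises(ValueError, match="self-hit"):
            HitList("q", [("q", 1.0)])
        with pytest.raises(ValueError, match="duplicate"):
            HitList("q", [("a", 1.0), ("a", 0.5)])

    def test_hitlists_from_scores_excludes_diagonal(self):
        ids = ["a", "b", "c"]
        S = np.array([[9, 2, 1], [2, 9, 3], [1, 3, 9]], dtype=float)
        hls = hitlists_from_scores(ids, S)
        assert hls[0].hits[0][0] == "b"
        assert all(h.query_id not in [t for t, _ in h.hits] for h in hls)


class TestEAT:
    def test_identical_vector_is_nearest_with_distance_zero(self):
        lookup = {"a": np.array([1.0, 0.0]), "b": np.array([0.0, 1.0])}
        labels = {"a": _label(0), "b": _label(1)}
        res = eat_transfer({"q": np.array([0.0, 1.0])}, lookup, labels)
        assert res.nearest["q"] == "b"
        assert res.predicted["q"] == _label(1)

    def test_hierarchical_rule_blocks_credit_below_first_error(self):
        lookup = {"n": np.zeros(2)}
        lookup_labels = {"n": HierarchyLabel(("C1", "A1", "T2", "H9"))}
        query_labels = {"q": HierarchyLabel(("C1", "A1", "T1", "H9"))}
        res = eat_transfer({"q": np.zeros(2)}, lookup, lookup_labels, query_labels)
        # correct at C and A; wrong at T; H matches textually but cannot count
        assert res.per_level_accuracy == [1.0, 1.0, 0.0, 0.0]

    def test_per_level_accuracy_non_increasing(self):
        rng = np.random.default_rng(0)
        lookup = {f"l{i}": rng.normal(0, 1, 8) for i in range(40)}
        lookup_labels = {
            f"l{i}": _label(rng.integers(0, 3), rng.integers(0, 2), rng.integers(0, 2))
            for i in range(40)
        }
        queries = {f"q{i}": rng.normal(0, 1, 8) for i in range(25)}
        query_labels = {
            f"q{i}": _label(rng.integers(0, 3), rng.integers(0, 2), rng.integers(0, 2))
            for i in range(25)
        }
        res = eat_transfer(queries, lookup, lookup_labels, query_labels)
        acc = res.per_level_accuracy
        assert all(a >= b - 1e-12 for a, b in zip(acc, acc[1:]))

    def test_width_mismatch_rejected(self):
        with pytest.raises(ValueError, match="width"):
            eat_transfer({"q": np.zeros(3)}, {"a": np.zeros(2)}, {"a": _label(0)})

    def test_query_in_lookup_rejected(self):
        with pytest.raises(ValueError, match="lookup"):
            eat_transfer({"a": np.zeros(2)}, {"a": np.zeros(2)}, {"a": _label(0)})

    def test_empty_lookup_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            eat_transfer({"q": np.zeros(2)}, {}, {})

    def test_label_frequency_baseline_prefix_rule(self):
        lookup_labels = {"a": _label(0, 0, 0), "b": _label(0, 0, 0), "c": _label(1, 0, 0)}
        query_labels = {"q1": _label(0, 0, 0), "q2": _label(1, 0, 0)}
        base = label_frequency_baseline(lookup_labels, query_labels)
        assert base == [0.5, 0.5, 0.5]
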