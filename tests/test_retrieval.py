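"""Similarity scoring: worked examples, oracles, and score-space properties."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pillid import retrieval as rt
from pillid._vocab import tokenize
from pillid.synthetic_data import COLORS, FORMS, SHAPES, PillRecord

SOURCE_FEATURES = ("square", "orange", "tablet")
SOURCE_IMPRINT = "M10_KI"
TARGETS = [
    PillRecord("T1", "square", "pink", "tablet", "M10_KI"),
    PillRecord("T2", "square", "pink", "tablet", "M10_Kb"),
    PillRecord("T3", "square", "orange", "tablet", "M10SPC_"),
]


def brute_edit_distance(a, b):
    """Exhaustive recursion: the independent Levenshtein oracle."""
    ta, tb = tuple(tokenize(a)), tuple(tokenize(b))

    def rec(i, j):
        if i == len(ta):
            return len(tb) - j
        if j == len(tb):
            return len(ta) - i
        cost = 0 if ta[i] == tb[j] else 1
        return min(rec(i + 1, j + 1) + cost, rec(i + 1, j) + 1, rec(i, j + 1) + 1)

    return rec(0, 0)


def random_imprint(rng, max_len=6, alphabet="AB01_mg"):
    # small alphabet makes edits/overlaps frequent
    n = rng.integers(0, max_len + 1)
    return "".join(rng.choice(list("AB01")) for _ in range(n))


class TestEditDistance:
    def test_worked_example(self):
        # 3 exchanges and 1 insertion
        assert rt.edit_distance("M10_KI", "M10SPC_") == 4

    def test_identity(self):
        for s in ("", "A", "M10_KI", "500mg"):
            assert rt.edit_distance(s, s) == 0

    def test_mg_is_single_token(self):
        # one substitution of the "mg" token, not two character edits
        assert rt.edit_distance("500mg", "500A") == 1
        assert rt.edit_distance("mg", "") == 1

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            a, b = random_imprint(rng), random_imprint(rng)
            assert rt.edit_distance(a, b) == brute_edit_distance(a, b)

    @given(st.text(alphabet="ABC01_", max_size=5),
           st.text(alphabet="ABC01_", max_size=5),
           st.text(alphabet="ABC01_", max_size=5))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_symmetry_and_triangle(self, a, b, c):
        assert rt.edit_distance(a, b) == rt.edit_distance(b, a)
        assert (rt.edit_distance(a, c)
                <= rt.edit_distance(a, b) + rt.edit_distance(b, c))


class TestNormalizedEditSimilarity:
    @pytest.mark.parametrize("a,b,expected", [
        ("M10_KI", "M10SPC_", Fraction(6, 13)),
        ("M10_KI", "M10_Kb", Fraction(10, 12)),
        ("M10_KI", "M10_KI", Fraction(1)),
    ])
    def test_worked_examples(self, a, b, expected):
        assert rt.normalized_edit_similarity(a, b) == expected

    def test_both_empty(self):
        assert rt.normalized_edit_similarity("", "") == 1

    def test_formula_consistency(self):
        # 2*matches/(|a|+|b|) == (|a|+|b|-d-x)/(|a|+|b|) with x substitutions:
        # matches + substitutions + deletions(=|a|-m-x) ... verified via the
        # distance decomposition on random pairs
        rng = np.random.default_rng(3)
        for _ in range(200):
            a, b = random_imprint(rng), random_imprint(rng)
            sim = rt.normalized_edit_similarity(a, b)
            la, lb = len(tokenize(a)), len(tokenize(b))
            if la + lb == 0:
                continue
            d = rt.edit_distance(a, b)
            m = sim * (la + lb) / 2
            x = la + lb - d - 2 * m  # substitutions implied by the identity
            assert x >= 0 and m >= 0
            assert m + x <= min(la, lb)


class TestOverlapSimilarity:
    @pytest.mark.parametrize("a,b,expected", [
        ("M10_KI", "M10SPC_", Fraction(8, 13)),
        ("M10_KI", "M10_Kb", Fraction(10, 12)),
        ("M10_KI", "M10_KI", Fraction(1)),
    ])
    def test_worked_examples(self, a, b, expected):
        assert rt.overlap_similarity(a, b) == expected

    def test_disjoint_alphabets(self):
        assert rt.overlap_similarity("ABC", "123") == 0

    def test_bounds_and_dominance_over_aligned_matches(self):
        # the multiset intersection is a superset of any alignment's matches
        rng = np.random.default_rng(5)
        for _ in range(300):
            a, b = random_imprint(rng), random_imprint(rng)
            ov = rt.overlap_similarity(a, b)
            ne = rt.normalized_edit_similarity(a, b)
            assert 0 <= ne <= 1 and 0 <= ov <= 1
            assert ov >= ne


class TestFeatureSimilarity:
    @pytest.mark.parametrize("target,expected", [
        (("square", "pink", "tablet"), Fraction(2, 3)),
        (("triangle", "orange", "capsule"), Fraction(1, 3)),
        (("round", "yellow", "capsule"), Fraction(0)),
    ])
    def test_worked_examples(self, target, expected):
        assert rt.feature_similarity(SOURCE_FEATURES, target) == expected

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            rt.feature_similarity(("blob", "orange", "tablet"),
                                  ("round", "orange", "tablet"))


class TestTotalScoreTable:
    def test_printed_totals_and_terms(self):
        totals = []
        for target in TARGETS:
            br = rt.total_score(SOURCE_FEATURES, SOURCE_IMPRINT, target)
            assert br.shape_term == Fraction(1, 3)
            assert br.form_term == Fraction(1, 3)
            totals.append(round(float(br.total), 2))
        assert totals == [2.67, 2.33, 2.08]
        br1 = rt.total_score(SOURCE_FEATURES, SOURCE_IMPRINT, TARGETS[0])
        assert (br1.edit_sim, br1.overlap_sim) == (Fraction(1), Fraction(1))
        br2 = rt.total_score(SOURCE_FEATURES, SOURCE_IMPRINT, TARGETS[1])
        assert (br2.edit_sim, br2.overlap_sim) == (Fraction(10, 12), Fraction(10, 12))
        br3 = rt.total_score(SOURCE_FEATURES, SOURCE_IMPRINT, TARGETS[2])
        assert (br3.edit_sim, br3.overlap_sim) == (Fraction(6, 13), Fraction(8, 13))

    def test_total_is_exact_sum(self):
        br = rt.total_score(SOURCE_FEATURES, SOURCE_IMPRINT, TARGETS[2])
        assert br.total == (br.shape_term + br.color_term + br.form_term
                            + br.edit_sim + br.overlap_sim)
        assert br.total == Fraction(27, 13)


class TestRanking:
    def test_table_order(self):
        ranked = rt.rank_database(SOURCE_FEATURES, SOURCE_IMPRINT, TARGETS, k=3)
        assert [c.pill_id for c in ranked] == ["T1", "T2", "T3"]
        assert [c.rank for c in ranked] == [1, 2, 3]

    def test_exact_match_scores_three(self):
        rec = TARGETS[0]
        ranked = rt.rank_database(rec.features, rec.imprint, TARGETS, k=1)
        assert ranked[0].pill_id == "T1"
        assert ranked[0].breakdown.total == 3

    def test_k_larger_than_database(self):
        ranked = rt.rank_database(SOURCE_FEATURES, SOURCE_IMPRINT, TARGETS, k=10)
        assert len(ranked) == 3

    def test_order_independent_of_database_permutation(self):
        rng = np.random.default_rng(11)
        db = [PillRecord(f"P{i}", SHAPES[rng.integers(0, 9)],
                         COLORS[rng.integers(0, 16)], FORMS[rng.integers(0, 2)],
                         random_imprint(rng) or "A")
              for i in range(50)]
        base = rt.rank_database(SOURCE_FEATURES, SOURCE_IMPRINT, db, k=10)
        for seed in range(3):
            perm = list(np.random.default_rng(seed).permutation(len(db)))
            shuffled = [db[i] for i in perm]
            again = rt.rank_database(SOURCE_FEATURES, SOURCE_IMPRINT, shuffled, k=10)
            assert [c.pill_id for c in again] == [c.pill_id for c in base]

    def test_ties_broken_by_pill_id(self):
        twins = [PillRecord("B", "round", "white", "tablet", "ZZ"),
                 PillRecord("A", "round", "white", "tablet", "ZZ")]
        ranked = rt.rank_database(("round", "white", "tablet"), "ZZ", twins, k=2)
        assert [c.pill_id for c in ranked] == ["A", "B"]


class TestEvaluateTopk:
    def _mk(self, ids):
        return [rt.RankedCandidate(pid, None, i + 1) for i, pid in enumerate(ids)]

    def test_all_exact(self):
        lists = [self._mk(["A", "B", "C"]), self._mk(["B", "A", "C"])]
        acc = rt.evaluate_topk(lists, ["A", "B"])
        assert acc == {1: 1.0, 3: 1.0}

    def test_truth_at_rank_two(self):
        lists = [self._mk(["X", "A", "C"])]
        acc = rt.evaluate_topk(lists, ["A"])
        assert acc == {1: 0.0, 3: 1.0}

    def test_matches_manual_count(self):
        rng = np.random.default_rng(2)
        ids = [f"P{i}" for i in range(10)]
        lists, truth = [], []
        for q in range(20):
            order = list(rng.permutation(ids))
            lists.append(self._mk(order[:3]))
            truth.append(ids[rng.integers(0, 10)])
        acc = rt.evaluate_topk(lists, truth)
        top1 = sum(l[0].pill_id == t for l, t in zip(lists, truth)) / 20
        top3 = sum(t in [c.pill_id for c in l] for l, t in zip(lists, truth)) / 20
        assert acc[1] == top1 and acc[3] == top3
        assert acc[3] >= acc[1]

    def test_absent_truth_counts_as_miss(self):
        acc = rt.evaluate_topk([self._mk(["A"])], ["ZZZ"])
        assert acc[1] == 0.0
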