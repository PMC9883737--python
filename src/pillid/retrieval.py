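"""Similarity scoring and ranking against the pill database.

The score between a predicted (shape, color, form, imprint) and a database
pill is the sum of five terms:

* one term of 1/3 per exactly matching feature (shape, color, form);
* normalized edit similarity between the imprints,
  ``2 * matches / (|a| + |b|)`` where ``matches`` is the number of aligned
  equal tokens in a minimum-cost edit script chosen, among all minimum-cost
  scripts, to maximize matches;
* overlap similarity, ``2 * |multiset intersection| / (|a| + |b|)`` over the
  imprint tokens (the "_" face separator counts as a token).

All terms are exact rationals (``fractions.Fraction``); the total lies in
[0, 3] and equals 3 exactly when every characteristic matches.  Imprints are
tokenized so that "mg" and "_" are single tokens.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

from ._vocab import tokenize
from .synthetic_data import COLORS, FORMS, SHAPES, PillRecord

# --------------------------------------------------------------------------
# Types
# --------------------------------------------------------------------------

_TERMS = ("shape", "color", "form", "edit", "overlap")


@dataclass(frozen=True)
class SimilarityBreakdown:
    """The five additive score terms and their exact total."""

    shape_term: Fraction
    color_term: Fraction
    form_term: Fraction
    edit_sim: Fraction
    overlap_sim: Fraction

    @property
    def total(self) -> Fraction:
        return (self.shape_term + self.color_term + self.form_term
                + self.edit_sim + self.overlap_sim)

    def as_dict(self) -> dict[str, float]:
        return {
            "shape": float(self.shape_term), "color": float(self.color_term),
            "form": float(self.form_term), "edit": float(self.edit_sim),
            "overlap": float(self.overlap_sim), "total": float(self.total),
        }


@dataclass(frozen=True)
class RankedCandidate:
    pill_id: str
    breakdown: SimilarityBreakdown
    rank: int


# --------------------------------------------------------------------------
# Imprint similarity
# --------------------------------------------------------------------------


def edit_distance(a: str, b: str) -> int:
    """Levenshtein distance over imprint tokens with unit costs."""
    ta, tb = tokenize(a), tokenize(b)
    la, lb = len(ta), len(tb)
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        for j in range(1, lb + 1):
            cost = 0 if ta[i - 1] == tb[j - 1] else 1
            cur[j] = min(prev[j - 1] + cost, prev[j] + 1, cur[j - 1] + 1)
        prev = cur
    return prev[lb]


def _max_matches(ta: Sequence[str], tb: Sequence[str]) -> tuple[int, int]:
    """(distance, matches): minimum edit cost, and the maximum number of
    aligned equal tokens among all minimum-cost scripts (lexicographic DP
    on (cost, -matches))."""
    la, lb = len(ta), len(tb)
    # dp[j] = (cost, -matches)
    prev = [(j, 0) for j in range(lb + 1)]
    for i in range(1, la + 1):
        cur = [(i, 0)] + [(0, 0)] * lb
        for j in range(1, lb + 1):
            if ta[i - 1] == tb[j - 1]:
                diag = (prev[j - 1][0], prev[j - 1][1] - 1)
            else:
                diag = (prev[j - 1][0] + 1, prev[j - 1][1])
            up = (prev[j][0] + 1, prev[j][1])
            left = (cur[j - 1][0] + 1, cur[j - 1][1])
            cur[j] = min(diag, up, left)
        prev = cur
    cost, neg = prev[lb]
    return cost, -neg


def normalized_edit_similarity(a: str, b: str) -> Fraction:
    """Edit-based imprint similarity in [0,1]: 2*matches/(|a|+|b|).

    Equivalently (|a|+|b|-d-x)/(|a|+|b|) with d the edit distance and x the
    substitution count of the match-maximizing minimum-cost script.  Two
    empty imprints have similarity 1.
    """
    ta, tb = tokenize(a), tokenize(b)
    if not ta and not tb:
        return Fraction(1)
    _, matches = _max_matches(ta, tb)
    return Fraction(2 * matches, len(ta) + len(tb))


def overlap_similarity(a: str, b: str) -> Fraction:
    """Order-free imprint similarity: 2*|multiset intersection|/(|a|+|b|)."""
    ta, tb = tokenize(a), tokenize(b)
    if not ta and not tb:
        return Fraction(1)
    inter = sum((Counter(ta) & Counter(tb)).values())
    return Fraction(2 * inter, len(ta) + len(tb))


# --------------------------------------------------------------------------
# Feature similarity
# --------------------------------------------------------------------------

_INVENTORY = {"shape": set(SHAPES), "color": set(COLORS), "form": set(FORMS)}


def feature_similarity(
    pred: tuple[str, str, str], target: tuple[str, str, str]
) -> Fraction:
    """1/3 per exactly matching feature label; in {0, 1/3, 2/3, 1}."""
    for (name, inv), p, t in zip(_INVENTORY.items(), pred, target):
        if p not in inv:
            raise ValueError(f"unknown {name} label {p!r}")
        if t not in inv:
            raise ValueError(f"unknown {name} label {t!r}")
    matches = sum(p == t for p, t in zip(pred, target))
    return Fraction(matches, 3)


# --------------------------------------------------------------------------
# Total score and ranking
# --------------------------------------------------------------------------


def total_score(
    pred_features: tuple[str, str, str],
    pred_imprint: str,
    target: PillRecord,
    ablate: Iterable[str] = (),
) -> SimilarityBreakdown:
    """Five-term similarity of a prediction against one database pill.

    ``ablate`` names score terms to zero out ("shape", "color", "form",
    "imprint" for both imprint terms) for ablation experiments.
    """
    ablate = set(ablate)
    unknown = ablate - {"shape", "color", "form", "imprint"}
    if unknown:
        raise ValueError(f"unknown ablation terms {sorted(unknown)}")
    third = Fraction(1, 3)
    terms = {
        "shape": third if pred_features[0] == target.shape else Fraction(0),
        "color": third if pred_features[1] == target.color else Fraction(0),
        "form": third if pred_features[2] == target.form else Fraction(0),
    }
    for name in ablate & {"shape", "color", "form"}:
        terms[name] = Fraction(0)
    if "imprint" in ablate:
        edit = overlap = Fraction(0)
    else:
        edit = normalized_edit_similarity(pred_imprint, target.imprint)
        overlap = overlap_similarity(pred_imprint, target.imprint)
    return SimilarityBreakdown(
        shape_term=terms["shape"], color_term=terms["color"],
        form_term=terms["form"], edit_sim=edit, overlap_sim=overlap)


def rank_database(
    pred_features: tuple[str, str, str],
    pred_imprint: str,
    database: Sequence[PillRecord],
    k: int = 3,
    ablate: Iterable[str] = (),
) -> list[RankedCandidate]:
    """Top-k candidates by total score, descending; ties by pill_id ascending."""
    if not database:
        raise ValueError("database is empty")
    if k < 1:
        raise ValueError("k must be >= 1")
    scored = [(total_score(pred_features, pred_imprint, rec, ablate), rec.pill_id)
              for rec in database]
    scored.sort(key=lambda s: (-s[0].total, s[1]))
    return [RankedCandidate(pill_id=pid, breakdown=br, rank=i + 1)
            for i, (br, pid) in enumerate(scored[:k])]


def evaluate_topk(
    ranked_lists: Sequence[Sequence[RankedCandidate]],
    truth_ids: Sequence[str],
    ks: Iterable[int] = (1, 3),
) -> dict[int, float]:
    """Fraction of queries whose true pill appears within rank <= k."""
    if len(ranked_lists) != len(truth_ids):
        raise ValueError("one truth id required per query")
    out: dict[int, float] = {}
    for k in ks:
        hits = sum(
            any(c.pill_id == truth and c.rank <= k for c in cands)
            for cands, truth in zip(ranked_lists, truth_ids))
        out[k] = hits / len(truth_ids) if truth_ids else 0.0
    return out
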