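"""Turn the final ordinal ranking into three discrete slice classes.

Once ranking is complete the session yields a total order of images
from most basal (rank 1) to most apical (rank N).  Discrete labels are
obtained by placing two cut points — the inflection where 'too basal'
becomes 'LV' and where 'LV' becomes 'too apical' — and labelling every
item by which segment its rank falls into.  Cut points are counted
items: ``cut_basal_lv`` is the number of too-basal items (ranks 1..c1),
``cut_lv_apical`` the number of too-basal plus LV items, so
``0 <= c1 <= c2 <= N``.

Cut points are calibrated from a small set of anchor items with known
one-at-a-time class labels: an exact search over candidate cut pairs
minimizes the number of anchors the contiguous labelling would
misclassify.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .rating import CLASS_LABELS

_CLASS_INDEX = {label: i for i, label in enumerate(CLASS_LABELS)}


@dataclass(frozen=True)
class CutPoints:
    """Rank cut points: counts of items at-or-above each boundary."""

    cut_basal_lv: int
    cut_lv_apical: int

    def __post_init__(self) -> None:
        if not (0 <= self.cut_basal_lv <= self.cut_lv_apical):
            raise ValueError("require 0 <= cut_basal_lv <= cut_lv_apical")


@dataclass(frozen=True)
class ClassAssignment:
    """One item's discrete label with the rank that produced it."""

    item_id: str
    class_label: str
    rank: int


def _class_of_rank(rank: int, cuts: CutPoints) -> str:
    if rank <= cuts.cut_basal_lv:
        return "too_basal"
    if rank <= cuts.cut_lv_apical:
        return "lv"
    return "too_apical"


def count_anchor_errors(ranking: Sequence[str],
                        anchors: Mapping[str, str],
                        cuts: CutPoints) -> int:
    """Number of anchors misclassified by the given cut points."""
    rank_of = {item_id: r for r, item_id in enumerate(ranking, start=1)}
    errors = 0
    for item_id, label in anchors.items():
        if _class_of_rank(rank_of[item_id], cuts) != label:
            errors += 1
    return errors


def _best_cut_midpoint(n: int, anchor_ranks: list[tuple[int, int]],
                       err_fn) -> int:
    """Minimize a piecewise-constant anchor-error function of one cut.

    The error only changes at anchor rank positions, so evaluating the
    breakpoints (each anchor rank and its predecessor, plus 0 and N) is
    an exact search.  The minimizing integer cuts form maximal
    intervals; the midpoint of the widest such interval is returned —
    the maximum-margin placement, which centres the boundary between
    the constraining anchors instead of hugging one of them.
    """
    breaks = sorted({0, n}
                    | {r for r, _ in anchor_ranks}
                    | {r - 1 for r, _ in anchor_ranks if r >= 1})
    breaks = [b for b in breaks if 0 <= b <= n]
    emin = min(err_fn(c) for c in breaks)
    intervals: list[tuple[int, int]] = []
    for k, c in enumerate(breaks):
        if err_fn(c) != emin:
            continue
        hi = c
        if k + 1 < len(breaks):
            nxt = breaks[k + 1]
            # error is constant on (c, nxt); extend across the plateau
            if nxt - 1 > c and err_fn(nxt - 1) == emin:
                hi = nxt - 1
        if intervals and intervals[-1][1] >= c - 1:
            intervals[-1] = (intervals[-1][0], max(intervals[-1][1], hi))
        else:
            intervals.append((c, hi))
    lo, hi = max(intervals, key=lambda iv: (iv[1] - iv[0], -iv[0]))
    return (lo + hi) // 2


def calibrate_cut_points(ranking: Sequence[str],
                         anchors: Mapping[str, str] | Iterable[tuple[str, str]],
                         ) -> CutPoints:
    """Find the cut pair minimizing anchor misclassifications (exact search).

    Under the contiguity rule the anchor error count is separable,
    ``errors(c1, c2) = F(c1) + G(c2)``: a too-basal anchor is wrong iff
    its rank exceeds c1, a too-apical anchor iff its rank is at most
    c2, and an LV anchor contributes one term to each.  Each cut is
    therefore optimized independently over the anchor-rank breakpoints
    (O(A^2) for A anchors) and placed at the midpoint of the widest
    error-minimizing interval — see :func:`_best_cut_midpoint`.  In the
    rare case of inconsistent anchors forcing c1 > c2, both cuts
    collapse to their common midpoint.
    """
    anchor_map = dict(anchors)
    if not anchor_map:
        raise ValueError("no anchors")
    rank_of = {item_id: r for r, item_id in enumerate(ranking, start=1)}
    unknown = [i for i in anchor_map if i not in rank_of]
    if unknown:
        raise ValueError(f"anchors reference unknown item(s): {unknown}")
    bad = [lbl for lbl in anchor_map.values() if lbl not in _CLASS_INDEX]
    if bad:
        raise ValueError(f"unknown anchor class label(s): {bad}")

    n = len(ranking)
    anchor_ranks = sorted(
        (rank_of[item_id], _CLASS_INDEX[label]) for item_id, label in anchor_map.items())

    def f(c1: int) -> int:  # basal|lv boundary errors
        return sum(1 for r, k in anchor_ranks
                   if (k == 0 and r > c1) or (k == 1 and r <= c1))

    def g(c2: int) -> int:  # lv|apical boundary errors
        return sum(1 for r, k in anchor_ranks
                   if (k == 2 and r <= c2) or (k == 1 and r > c2))

    c1 = _best_cut_midpoint(n, anchor_ranks, f)
    c2 = _best_cut_midpoint(n, anchor_ranks, g)
    if c1 > c2:
        # heavily inconsistent anchors can make the unconstrained optima
        # cross; fall back to a joint search over breakpoints under the
        # c1 <= c2 constraint (ties: widest LV band, then smallest c1)
        breaks = sorted({0, n}
                        | {r for r, _ in anchor_ranks}
                        | {r - 1 for r, _ in anchor_ranks if r >= 1})
        breaks = [b for b in breaks if 0 <= b <= n]
        best: tuple[int, int, int] | None = None
        for b1 in breaks:
            for b2 in breaks:
                if b2 < b1:
                    continue
                key = (f(b1) + g(b2), -(b2 - b1), b1)
                if best is None or key < best:
                    best = key
                    c1, c2 = b1, b2
    return CutPoints(c1, c2)


def assign_classes(ranking: Sequence[str], cuts: CutPoints) -> list[ClassAssignment]:
    """Label every ranked item by the segment its rank falls into."""
    n = len(ranking)
    if cuts.cut_lv_apical > n:
        raise ValueError(f"cut_lv_apical {cuts.cut_lv_apical} exceeds N = {n}")
    return [
        ClassAssignment(item_id=item_id, class_label=_class_of_rank(r, cuts), rank=r)
        for r, item_id in enumerate(ranking, start=1)
    ]
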