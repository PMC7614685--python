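"""Active batch composition and the stopping rule.

The scheduler decides which items an annotator sees next.  Two
prioritisation pressures apply, in strict order:

1. items that still need views (view_count below the session's
   ``min_views``) are taken first, lowest view-count tier first,
   sampled uniformly within a tier;
2. any remaining batch slots are filled from the already-covered items
   by weighted sampling without replacement with weight
   ``w_unseen / (1 + view_count) + w_volatile * volatility``, so
   disagreed-upon (volatile) items keep circulating until opinions
   settle.

The composed batch is returned in a fresh random display order so the
annotator's reordering work is not biased by the current ranking.
Labelling is complete once every item has been viewed at least
``min_views`` times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rating import ItemState, Session


@dataclass(frozen=True)
class BatchRequest:
    """A request for the next batch to present to one annotator."""

    requested_size: int
    annotator_id: str

    def __post_init__(self) -> None:
        if self.requested_size < 2:
            raise ValueError("requested_size must be >= 2")


def _weighted_sample_without_replacement(rng: np.random.Generator,
                                         pool: list[ItemState],
                                         weights: np.ndarray,
                                         k: int) -> list[ItemState]:
    # Efraimidis-Spirakis exponential-key sampling; zero-weight items are
    # only drawn (uniformly) when positive-weight items run out.
    positive = weights > 0
    n_pos = int(positive.sum())
    chosen: list[ItemState] = []
    if n_pos:
        idx_pos = np.flatnonzero(positive)
        keys = rng.exponential(size=n_pos) / weights[idx_pos]
        take = min(k, n_pos)
        order = np.argsort(keys)[:take]
        chosen.extend(pool[i] for i in idx_pos[order])
    if len(chosen) < k:
        idx_zero = np.flatnonzero(~positive)
        extra = rng.choice(idx_zero, size=k - len(chosen), replace=False)
        chosen.extend(pool[i] for i in extra)
    return chosen


def compose_next_batch(session: Session, request: BatchRequest) -> list[str]:
    """Select the next batch of item_ids, in randomized display order.

    Phase 1 draws under-viewed items (lowest view-count tier first) as a
    contiguous window of the tier in current-rank order, at a uniformly
    random starting position.  Ranking batches are most informative when
    their members are plausibly close on the ordinal axis, so windows
    make each submission resolve local order instead of re-confirming
    distant relations; at the start of a pass the current ranks carry
    no information yet and a window is equivalent to a uniform draw.
    While under-viewed items remain, a fraction ``revisit_fraction`` of
    the batch is reserved for phase 2.

    Phase 2 fills the remaining slots by weighted sampling without
    replacement with weight
    ``w_unseen/(1+view_count) + w_volatile*volatility``, multiplied by
    proximity to the phase-1 window when one exists — so disagreed-upon
    and rarely-seen items keep circulating next to the items they will
    actually be compared with.
    """
    size = request.requested_size
    items = list(session.items.values())
    if len(items) < 2:
        raise ValueError("session exhausted")
    if len(items) < size:
        raise ValueError(
            f"session has {len(items)} items, fewer than requested batch size {size}")
    cfg = session.config
    rng = session.rng

    chosen: list[ItemState] = []
    under = [s for s in items if s.view_count < cfg.min_views]
    phase1_cap = size
    if under:
        phase1_cap = max(1, int(np.ceil(size * (1.0 - cfg.revisit_fraction))))
    for tier_vc in sorted({s.view_count for s in under}):
        slots = min(phase1_cap, size) - len(chosen)
        if slots <= 0:
            break
        tier = sorted((s for s in under if s.view_count == tier_vc),
                      key=lambda s: s.rank)
        if len(tier) <= slots:
            chosen.extend(tier)
        else:
            start = int(rng.integers(len(tier) - slots + 1))
            chosen.extend(tier[start:start + slots])

    # phase 2: weighted revisits of the remaining items, kept rank-local.
    # With no under-viewed seeds (e.g. a completed session) a pivot is
    # drawn by the same weights first, so revisit batches still compare
    # neighbours rather than arbitrary distant items.
    slots = size - len(chosen)
    if slots:
        chosen_ids = {s.item_id for s in chosen}
        rest = [s for s in items if s.item_id not in chosen_ids]
        weights = np.array(
            [cfg.w_unseen / (1.0 + s.view_count) + cfg.w_volatile * s.volatility
             for s in rest])
        prox_power = 1.0
        if not chosen:
            # completed session: draw a pivot by the same weights, keep
            # its slot guaranteed, and gather the rest tightly around it
            # so every adjacent relation keeps receiving direct
            # comparisons
            pivot = _weighted_sample_without_replacement(rng, rest, weights, 1)[0]
            chosen.append(pivot)
            keep = [k for k, s in enumerate(rest) if s.item_id != pivot.item_id]
            rest = [rest[k] for k in keep]
            weights = weights[keep]
            slots -= 1
            prox_power = 3.0
        if slots:
            centre = float(np.mean([s.rank for s in chosen]))
            weights = weights * np.array(
                [1.0 / (1.0 + abs(s.rank - centre)) ** prox_power for s in rest])
            chosen.extend(_weighted_sample_without_replacement(rng, rest, weights, slots))

    order = rng.permutation(len(chosen))
    return [chosen[i].item_id for i in order]


def is_complete(session: Session, min_views: int | None = None) -> bool:
    """True iff every item has been viewed at least ``min_views`` times."""
    if not session.items:
        raise ValueError("empty session")
    if min_views is None:
        min_views = session.config.min_views
    if min_views < 1:
        raise ValueError("min_views must be >= 1")
    return all(s.view_count >= min_views for s in session.items.values())
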