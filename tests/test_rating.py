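"""Unit and property tests for the Elo-style batch rating engine."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from slicerank import (
    BatchRanking,
    SessionConfig,
    apply_pair_outcome,
    expected_score,
    initialize_session,
    ranked_items,
    recompute_ranking,
    refit_ratings,
    submit_batch,
    update_volatility,
)
from slicerank.rating import ItemState

from conftest import batch_of, make_session


class TestInitializeSession:
    def test_fresh_state(self):
        session = make_session(50)
        assert all(s.rating == 1500.0 for s in session.items.values())
        assert all(s.volatility == 0.0 for s in session.items.values())
        assert all(s.view_count == 0 for s in session.items.values())
        assert sorted(s.rank for s in session.items.values()) == list(range(1, 51))

    def test_single_item(self):
        session = initialize_session(["only"], SessionConfig(rng_seed=0))
        state = session.items["only"]
        assert state.rating == 1500.0 and state.rank == 1

    def test_seed_determinism(self):
        ranks_a = [s.rank for s in make_session(30, seed=9).items.values()]
        ranks_b = [s.rank for s in make_session(30, seed=9).items.values()]
        assert ranks_a == ranks_b

    def test_initial_ranks_randomized(self):
        ranks_a = [s.rank for s in make_session(30, seed=1).items.values()]
        ranks_b = [s.rank for s in make_session(30, seed=2).items.values()]
        assert ranks_a != ranks_b

    def test_empty_manifest_rejected(self):
        with pytest.raises(ValueError, match="no items"):
            initialize_session([], SessionConfig())

    def test_duplicate_id_named(self):
        with pytest.raises(ValueError, match="dup"):
            initialize_session(["a", "dup", "dup"], SessionConfig())


class TestExpectedScore:
    @pytest.mark.parametrize("ra,rb,scale,expected", [
        (1500.0, 1500.0, 400.0, 0.5),
        (1900.0, 1500.0, 400.0, 10.0 / 11.0),
        (1500.0, 1900.0, 400.0, 1.0 / 11.0),
    ])
    def test_analytic_values(self, ra, rb, scale, expected):
        assert expected_score(ra, rb, scale) == pytest.approx(expected, rel=1e-12)

    def test_complement_identity(self, rng):
        for _ in range(200):
            a, b = rng.uniform(0, 3000, size=2)
            total = expected_score(a, b, 400.0) + expected_score(b, a, 400.0)
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_monotone_in_first_rating(self):
        scores = [expected_score(r, 1500.0, 400.0) for r in (1000, 1400, 1500, 2000)]
        assert scores == sorted(scores)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            expected_score(float("nan"), 1500.0, 400.0)
        with pytest.raises(ValueError):
            expected_score(1500.0, 1500.0, 0.0)


class TestApplyPairOutcome:
    def test_symmetric_update(self):
        cfg = SessionConfig()
        w = ItemState("w", rating=1500.0, rank=1)
        l = ItemState("l", rating=1500.0, rank=2)
        nw, nl, surprise = apply_pair_outcome(w, l, cfg)
        assert nw.rating == pytest.approx(1516.0)
        assert nl.rating == pytest.approx(1484.0)
        assert surprise == pytest.approx(0.5)

    def test_expected_win_low_surprise(self):
        cfg = SessionConfig()
        w = ItemState("w", rating=1900.0, rank=1)
        l = ItemState("l", rating=1500.0, rank=2)
        _, _, surprise = apply_pair_outcome(w, l, cfg)
        assert surprise == pytest.approx(1.0 / 11.0, rel=1e-12)

    def test_zero_sum_away_from_bounds(self, rng):
        cfg = SessionConfig()
        for _ in range(1000):
            ra, rb = rng.uniform(500, 2500, size=2)
            w = ItemState("w", rating=ra, rank=1, view_count=int(rng.integers(0, 6)))
            l = ItemState("l", rating=rb, rank=2, view_count=int(rng.integers(0, 6)))
            nw, nl, _ = apply_pair_outcome(w, l, cfg)
            assert nw.rating + nl.rating == pytest.approx(ra + rb, abs=1e-9)

    def test_self_comparison_rejected(self):
        cfg = SessionConfig()
        s = ItemState("x", rating=1500.0, rank=1)
        with pytest.raises(ValueError, match="self-comparison"):
            apply_pair_outcome(s, s, cfg)

    def test_clipping_respects_bounds(self):
        cfg = SessionConfig()
        w = ItemState("w", rating=2999.9, rank=1)
        l = ItemState("l", rating=0.05, rank=2)
        nw, nl, _ = apply_pair_outcome(w, l, cfg)
        assert nw.rating <= cfg.rating_max and nl.rating >= cfg.rating_min


class TestUpdateVolatility:
    def test_zero_fixed_point(self):
        item = ItemState("x", rating=1500.0, rank=1, volatility=0.0)
        update_volatility(item, [0.0, 0.0], alpha=0.3)
        assert item.volatility == 0.0

    def test_one_step_closed_form(self):
        item = ItemState("x", rating=1500.0, rank=1, volatility=0.0)
        update_volatility(item, [1.0, 1.0, 1.0], alpha=0.3)
        assert item.volatility == pytest.approx(0.3)

    def test_bounded_and_converging(self):
        item = ItemState("x", rating=1500.0, rank=1, volatility=0.0)
        for _ in range(100):
            update_volatility(item, [1.0], alpha=0.3)
            assert 0.0 <= item.volatility <= 1.0
        assert item.volatility == pytest.approx(1.0, abs=1e-10)

    def test_out_of_range_surprise_rejected(self):
        item = ItemState("x", rating=1500.0, rank=1)
        with pytest.raises(ValueError, match="surprise"):
            update_volatility(item, [1.5], alpha=0.3)

    def test_unanimous_batches_decay_volatility(self):
        """Repeatedly agreeing annotators drive volatility monotonically down."""
        session = make_session(8)
        order = list(session.items)
        for t in range(6):
            submit_batch(session, batch_of(order, timestamp=t))
        vols = []
        for t in range(6, 16):
            submit_batch(session, batch_of(order, timestamp=t))
            vols.append(np.mean([s.volatility for s in session.items.values()]))
        assert all(b <= a + 1e-12 for a, b in zip(vols, vols[1:]))


class TestSubmitBatch:
    def test_pair_count_batch_of_8(self, small_session):
        submit_batch(small_session, batch_of(list(small_session.items)))
        assert small_session.pair_update_count == 28

    def test_pair_count_formula(self):
        for n in (2, 3, 5, 8):
            session = make_session(8)
            submit_batch(session, batch_of(list(session.items)[:n]))
            assert session.pair_update_count == n * (n - 1) // 2

    def test_view_counts_increment(self, small_session):
        ids = list(small_session.items)
        submit_batch(small_session, batch_of(ids[:2]))
        assert small_session.items[ids[0]].view_count == 1
        assert small_session.items[ids[1]].view_count == 1
        assert small_session.items[ids[2]].view_count == 0

    def test_batch_order_induces_rating_order(self, small_session):
        """A strict order over equal-rated items is reproduced transitively:
        items never directly compared still end up correctly ordered."""
        ids = list(small_session.items)
        submit_batch(small_session, batch_of(ids))
        ratings = [small_session.items[i].rating for i in ids]
        assert ratings == sorted(ratings, reverse=True)

    def test_repeat_submission_strictly_increases_top(self, small_session):
        ids = list(small_session.items)
        submit_batch(small_session, batch_of(ids, timestamp=0))
        first = small_session.items[ids[0]].rating
        submit_batch(small_session, batch_of(ids, timestamp=1))
        assert small_session.items[ids[0]].rating > first

    def test_unknown_item_rejected(self, small_session):
        with pytest.raises(ValueError, match="unknown"):
            submit_batch(small_session, batch_of(["i0", "ghost"]))

    def test_short_batch_rejected(self):
        with pytest.raises(ValueError):
            BatchRanking(ordered_items=("solo",), annotator_id="a", timestamp=0)

    def test_event_log_appended(self, small_session):
        submit_batch(small_session, batch_of(list(small_session.items)))
        assert len(small_session.event_log) == 1

    @settings(max_examples=20, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_bounds_invariant_random_batches(self, seed):
        """Ratings stay in [0, 3000] and volatility in [0, 1] under any
        sequence of random submissions."""
        rng = np.random.default_rng(seed)
        session = make_session(12, seed=seed)
        ids = list(session.items)
        for t in range(10):
            batch = list(rng.permutation(ids))[:8]
            submit_batch(session, batch_of(batch, timestamp=t))
        for s in session.items.values():
            assert 0.0 <= s.rating <= 3000.0
            assert 0.0 <= s.volatility <= 1.0

    def test_total_rating_mass_conserved(self, rng):
        """Zero-sum conservation across whole batches while away from bounds."""
        session = make_session(16)
        ids = list(session.items)
        before = sum(s.rating for s in session.items.values())
        for t in range(20):
            batch = list(rng.permutation(ids))[:8]
            submit_batch(session, batch_of(batch, timestamp=t))
        after = sum(s.rating for s in session.items.values())
        assert after == pytest.approx(before, abs=1e-6)


class TestRecomputeRanking:
    def test_strict_ordering(self):
        session = make_session(3)
        ids = list(session.items)
        for item_id, rating in zip(ids, (2000.0, 1500.0, 700.0)):
            session.items[item_id].rating = rating
        recompute_ranking(session)
        assert [session.items[i].rank for i in ids] == [1, 2, 3]

    def test_tie_break_by_item_id_stable(self):
        session = make_session(4)
        for s in session.items.values():
            s.rating = 1500.0
        recompute_ranking(session)
        first = [s.rank for s in session.items.values()]
        recompute_ranking(session)
        assert [s.rank for s in session.items.values()] == first
        ordered = ranked_items(session)
        assert [s.item_id for s in ordered] == sorted(s.item_id for s in ordered)

    def test_permutation_property(self, rng):
        for trial in range(50):
            n = int(rng.integers(2, 40))
            session = make_session(n, seed=trial)
            for s in session.items.values():
                s.rating = float(rng.uniform(0, 3000))
            recompute_ranking(session)
            assert sorted(s.rank for s in session.items.values()) == list(range(1, n + 1))


class TestRefitRatings:
    def test_refit_preserves_bookkeeping(self, rng):
        session = make_session(16)
        ids = list(session.items)
        for t in range(12):
            submit_batch(session, batch_of(list(rng.permutation(ids))[:8], timestamp=t))
        views = {i: s.view_count for i, s in session.items.items()}
        vols = {i: s.volatility for i, s in session.items.items()}
        refit_ratings(session)
        assert {i: s.view_count for i, s in session.items.items()} == views
        assert {i: s.volatility for i, s in session.items.items()} == vols
        assert len(session.event_log) == 12

    def test_refit_recovers_consistent_order(self, rng):
        """With abundant consistent batches the refit sorts all items exactly."""
        session = make_session(12)
        true_order = list(rng.permutation(list(session.items)))
        for t in range(30):
            members = sorted(rng.choice(12, size=8, replace=False))
            batch = [true_order[m] for m in members]
            submit_batch(session, batch_of(batch, timestamp=t))
        refit_ratings(session)
        recovered = [s.item_id for s in ranked_items(session)]
        assert recovered == true_order

    def test_ratings_within_bounds_unclipped_order(self, rng):
        session = make_session(20)
        ids = list(session.items)
        for t in range(40):
            batch = sorted(rng.choice(ids, size=8, replace=False))
            submit_batch(session, batch_of(batch, timestamp=t))
        refit_ratings(session)
        ratings = [s.rating for s in session.items.values()]
        assert min(ratings) > 0.0 and max(ratings) < 3000.0
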