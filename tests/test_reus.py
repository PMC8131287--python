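"""Exchange criterion, sweep bookkeeping and replica-exchange dynamics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from reusbind.restraints import UmbrellaWindow, build_window_ladder
from reusbind.reus import (
    REUSConfig,
    ReplicaEnsembleState,
    acceptance_rates,
    attempt_neighbor_exchanges,
    exchange_delta,
    metropolis_accept,
    predict_exchange_acceptance,
    replica_trace,
    run_reus,
)
from reusbind.toy_system import ToySystem, sample_biased_exact


class TestExchangeDelta:
    def test_identical_configurations_give_zero(self):
        w0 = UmbrellaWindow(0.0, 1.0)
        w1 = UmbrellaWindow(1.0, 1.0)
        assert exchange_delta(w0.energy, w1.energy, 0.3, 0.3, 1.0) == 0.0

    def test_hand_evaluated_example(self):
        # d=0 and d=1 (k=1, beta=1), zeta_i=0, zeta_j=1 -> (1 - 0 - 0 + 1) = 2
        w0 = UmbrellaWindow(0.0, 1.0)
        w1 = UmbrellaWindow(1.0, 1.0)
        assert exchange_delta(w0.energy, w1.energy, 0.0, 1.0, 1.0) == pytest.approx(2.0)

    @given(
        zi=st.floats(-5, 5),
        zj=st.floats(-5, 5),
        d0=st.floats(-3, 3),
        d1=st.floats(-3, 3),
        k=st.floats(0.1, 5),
        beta=st.floats(0.1, 3),
    )
    def test_antisymmetry_under_swap(self, zi, zj, d0, d1, k, beta):
        w0 = UmbrellaWindow(d0, k)
        w1 = UmbrellaWindow(d1, k)
        d_fwd = exchange_delta(w0.energy, w1.energy, zi, zj, beta)
        d_rev = exchange_delta(w0.energy, w1.energy, zj, zi, beta)
        assert d_fwd == pytest.approx(-d_rev, abs=1e-9)


class TestMetropolis:
    def test_nonpositive_delta_always_accepts(self):
        assert metropolis_accept(-1.0, 0.999999)
        assert metropolis_accept(0.0, 0.999999)

    def test_positive_delta_threshold(self):
        # e^-2 = 0.1353...: draw 0.10 accepts, 0.20 rejects
        assert metropolis_accept(2.0, 0.10)
        assert not metropolis_accept(2.0, 0.20)

    def test_nonfinite_delta_raises(self):
        with pytest.raises(ValueError):
            metropolis_accept(float("nan"), 0.5)


def _state(zetas, beta=1.0):
    n = len(zetas)
    pos = np.zeros((n, 3))
    pos[:, 2] = zetas
    s = ReplicaEnsembleState(
        window_of_replica=np.arange(n), positions=pos, velocities=np.zeros((n, 3))
    )
    s._beta = beta
    return s


class TestExchangeSweep:
    def test_identical_zetas_all_accepted(self, rng):
        ladder = build_window_ladder((-2.0, 2.0), 5, dense_region=None)
        state = _state(np.zeros(5))
        recs = attempt_neighbor_exchanges(state, ladder, parity=0, rng=rng)
        assert all(r.accepted for r in recs)
        assert all(r.delta == 0.0 for r in recs)
        assert state.check_bijection()

    def test_two_window_decision_matches_hand_calculation(self):
        # windows d=0, d=1, k=1, beta=1; zetas 0 and 1 -> Delta = 2
        ladder = [UmbrellaWindow(0.0, 1.0, 0), UmbrellaWindow(1.0, 1.0, 1)]
        accept_draw = np.random.default_rng(0)
        state = _state([0.0, 1.0])
        recs = attempt_neighbor_exchanges(
            state, ladder, parity=0, rng=accept_draw
        )
        assert len(recs) == 1
        assert recs[0].delta == pytest.approx(2.0)
        # default_rng(0).random() = 0.6369... > e^-2 -> reject
        assert not recs[0].accepted
        assert list(state.window_of_replica) == [0, 1]

    def test_parity_selects_pairs(self, rng):
        ladder = build_window_ladder((-2.0, 2.0), 6, dense_region=None)
        state = _state(np.zeros(6))
        even = attempt_neighbor_exchanges(state, ladder, parity=0, rng=rng)
        odd = attempt_neighbor_exchanges(state, ladder, parity=1, rng=rng)
        assert [(r.pair_lo, r.pair_hi) for r in even] == [(0, 1), (2, 3), (4, 5)]
        assert [(r.pair_lo, r.pair_hi) for r in odd] == [(1, 2), (3, 4)]

    def test_permutation_stays_bijective_under_random_sweeps(self, rng):
        ladder = build_window_ladder((-3.0, 3.0), 7, dense_region=None)
        state = _state(rng.normal(size=7))
        for parity in (0, 1) * 10:
            attempt_neighbor_exchanges(state, ladder, parity, rng)
            assert state.check_bijection()


def test_detailed_balance_two_windows(system):
    """With exact per-window resampling between attempts the accepted
    fraction matches the analytic <min(1, e^-Delta)> under the two biased
    densities, within 3 Monte-Carlo standard errors."""
    w0 = UmbrellaWindow(-1.0, 1.385, 0)
    w1 = UmbrellaWindow(-0.5, 1.385, 1)
    n = 4000
    zi = sample_biased_exact(system, w0.energy, n, seed=21)
    zj = sample_biased_exact(system, w1.energy, n, seed=22)
    rng = np.random.default_rng(23)
    accepted = [
        metropolis_accept(
            exchange_delta(w0.energy, w1.energy, a, b, system.beta), rng.random()
        )
        for a, b in zip(zi, zj)
    ]
    frac = np.mean(accepted)
    analytic = predict_exchange_acceptance(system, [w0, w1])[1]
    se = np.sqrt(analytic * (1 - analytic) / n)
    assert abs(frac - analytic) < 3 * se


class TestRunREUS:
    def test_zero_cycles_returns_initial_state(self, system):
        ladder = build_window_ladder((-2.0, 2.0), 4, dense_region=None)
        cfg = REUSConfig(n_cycles=0, seed=0)
        res = run_reus(system, ladder, None, cfg)
        assert res.zeta_by_window.shape == (4, 1)
        np.testing.assert_allclose(
            res.zeta_by_window[:, 0], [w.center for w in ladder]
        )
        assert res.records == []

    def test_reproducible_and_label_conserving(self, system):
        ladder = build_window_ladder((-3.0, 3.0), 6, dense_region=None)
        cfg = REUSConfig(n_cycles=50, steps_per_cycle=10, seed=99)
        r1 = run_reus(system, ladder, None, cfg)
        r2 = run_reus(system, ladder, None, cfg)
        assert np.array_equal(r1.zeta_by_window, r2.zeta_by_window)
        assert [(r.delta, r.accepted) for r in r1.records] == [
            (r.delta, r.accepted) for r in r2.records
        ]
        # multiset of labels invariant: every sweep leaves a permutation
        traces = np.array([replica_trace(r1, i) for i in range(6)])
        for t in traces.T:
            assert sorted(t) == list(range(6))

    def test_mismatched_initial_count_raises(self, system):
        ladder = build_window_ladder((-2.0, 2.0), 4, dense_region=None)
        with pytest.raises(ValueError):
            run_reus(system, ladder, None, REUSConfig(n_cycles=1), initial=[])


class TestAcceptanceBookkeeping:
    def test_empty_log(self):
        per_pair, overall = acceptance_rates([])
        assert per_pair == {}
        assert np.isnan(overall)

    def test_counting(self, system):
        from reusbind.reus import ExchangeRecord

        recs = [
            ExchangeRecord(10 * i, 0, 1, 0, 1, 0.0, accepted=i < 3)
            for i in range(10)
        ]
        per_pair, overall = acceptance_rates(recs)
        assert per_pair[(0, 1)] == pytest.approx(0.3)
        assert overall == pytest.approx(0.3)

    def test_all_accepted(self):
        from reusbind.reus import ExchangeRecord

        recs = [ExchangeRecord(1, m, m + 1, m, m + 1, -1.0, True) for m in range(3)]
        per_pair, overall = acceptance_rates(recs)
        assert all(v == 1.0 for v in per_pair.values())
        assert overall == 1.0


class TestReplicaTrace:
    def test_no_accepted_exchanges_constant(self, system):
        ladder = build_window_ladder((-12.0, 12.0), 4, dense_region=None)
        # far-apart stiff windows: nothing exchanges
        cfg = REUSConfig(n_cycles=20, steps_per_cycle=5, seed=0)
        res = run_reus(system, ladder, None, cfg)
        if not any(r.accepted for r in res.records):
            for i in range(4):
                assert np.all(replica_trace(res, i) == i)

    def test_neighbor_moves_only(self, bi_pipeline):
        res = bi_pipeline.reus_result
        for i in (0, 5, 20):
            trace = replica_trace(res, i)
            assert np.all(np.abs(np.diff(trace)) <= 1)

    def test_mixing_visits_multiple_windows(self, bi_pipeline):
        res = bi_pipeline.reus_result
        visited = [len(set(replica_trace(res, i))) for i in range(len(res.ladder))]
        assert np.median(visited) >= 3

    def test_unknown_replica_raises(self, bi_pipeline):
        with pytest.raises(ValueError):
            replica_trace(bi_pipeline.reus_result, 999)
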