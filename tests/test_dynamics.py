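"""Parallel spin dynamics, recall protocols, and attractor detection."""

import numpy as np
import pytest

from mixnet import (
    DynamicsConfig,
    NetworkState,
    corrupt,
    detect_attractor,
    generate_random_patterns,
    local_fields,
    mixed_matrix,
    overlap,
    run_am_protocol,
    run_spr_protocol,
    step,
    sweep_nu,
)


def _hopfield(n, p, seed=0):
    ps = generate_random_patterns(n, p, seed=seed)
    return ps, mixed_matrix(ps, 1.0)


class TestLocalFields:
    def test_zero_state_zero_field(self):
        _, J = _hopfield(20, 2)
        assert np.all(local_fields(J, np.zeros(20)) == 0.0)

    def test_matches_brute_force(self, small_patterns):
        J = mixed_matrix(small_patterns, 0.4)
        s = generate_random_patterns(6, 1, seed=8)[0].astype(float)
        theta = np.linspace(-0.2, 0.2, 6)
        expected = [sum(J.weights[i, j] * s[j] for j in range(6)) + theta[i]
                    for i in range(6)]
        assert np.allclose(local_fields(J, s, theta), expected)

    def test_field_aligned_with_single_stored_pattern(self):
        ps, J = _hopfield(100, 1)
        xi = ps[0]
        h = local_fields(J, xi)
        assert np.all(np.sign(h) == xi)


class TestStep:
    def test_zero_temperature_pattern_is_fixed_point(self):
        ps, J = _hopfield(100, 1)
        state = NetworkState(spins=ps[0].copy())
        new = step(state, J, DynamicsConfig(temperature=0.0))
        assert np.array_equal(new.spins, ps[0])
        assert new.time_index == 1

    def test_zero_temperature_positive_fields_give_all_plus(self):
        _, J = _hopfield(30, 1)
        state = NetworkState(spins=np.ones(30, dtype=np.int8))
        cfg = DynamicsConfig(temperature=0.0, external_field=np.full(30, 10.0))
        assert np.all(step(state, J, cfg).spins == 1)

    def test_infinite_temperature_is_a_fair_coin(self):
        # beta -> 0: each spin is +1 with probability 1/2 whatever the field
        ps, J = _hopfield(4000, 1, seed=2)
        state = NetworkState(spins=ps[0].copy())
        new = step(state, J, DynamicsConfig(temperature=1e12, seed=3))
        frac_up = np.mean(new.spins == 1)
        assert abs(frac_up - 0.5) < 5 * 0.5 / np.sqrt(4000)

    def test_synchronous_update_depends_only_on_previous_state(self):
        # recompute each new spin from the frozen previous state one by one
        ps = generate_random_patterns(30, 3, seed=5)
        J = mixed_matrix(ps, 0.3)
        state = NetworkState(spins=ps[1].copy())
        new = step(state, J, DynamicsConfig(temperature=0.0))
        for i in np.random.default_rng(0).permutation(30):
            h_i = float(J.weights[i] @ state.spins.astype(float))
            assert new.spins[i] == (1 if h_i >= 0 else -1)


class TestProtocols:
    def test_am_small_load_retrieves_exactly(self):
        ps, J = _hopfield(2000, 1, seed=4)
        m = run_am_protocol(J, ps, flip_fraction=0.1,
                            config=DynamicsConfig(temperature=0.0, seed=1))
        assert m == 1.0

    def test_am_zero_flip_is_trivial(self):
        ps, J = _hopfield(500, 2, seed=6)
        m = run_am_protocol(J, ps, flip_fraction=0.0, transient=0,
                            config=DynamicsConfig(temperature=0.0))
        assert m == 1.0

    def test_am_same_seed_reproduces(self):
        ps, J = _hopfield(300, 3, seed=7)
        cfg = DynamicsConfig(temperature=0.4, seed=21)
        a = run_am_protocol(J, ps, config=cfg)
        b = run_am_protocol(J, ps, config=DynamicsConfig(temperature=0.4, seed=21))
        assert a == b

    def test_spr_pure_sequence_retrieves_cycle(self):
        ps = generate_random_patterns(2000, 5, role="SPR", seed=8)
        J = mixed_matrix(ps, 0.0)
        m = run_spr_protocol(J, ps, config=DynamicsConfig(temperature=0.0, seed=2))
        assert m > 0.99

    def test_spr_fails_without_asymmetric_part(self):
        am = generate_random_patterns(2000, 5, seed=9)
        spr = generate_random_patterns(2000, 5, role="SPR", seed=10)
        J = mixed_matrix(am, 1.0, spr_set=spr)  # nu=1: no sequence couplings
        m = run_spr_protocol(J, spr, config=DynamicsConfig(temperature=0.0, seed=3))
        assert abs(m) < 0.2

    def test_spr_same_seed_reproduces(self):
        ps = generate_random_patterns(400, 4, role="SPR", seed=11)
        J = mixed_matrix(ps, 0.0)
        cfg = lambda: DynamicsConfig(temperature=0.3, seed=5)
        assert run_spr_protocol(J, ps, config=cfg()) == run_spr_protocol(J, ps, config=cfg())

    def test_empty_pattern_set_rejected(self):
        import mixnet.patterns as mp
        with pytest.raises(ValueError):
            mp.PatternSet(entries=np.empty((0, 20), dtype=np.int8))

    def test_am_overlap_does_not_increase_with_temperature(self):
        # smoke test: thermal noise cannot improve retrieval (within
        # simulation error over 10 seeds)
        means = []
        for T in [0.0, 0.2, 0.5, 2.0]:
            vals = []
            for s in range(10):
                ps, J = _hopfield(500, 3, seed=30 + s)
                vals.append(run_am_protocol(J, ps,
                                            config=DynamicsConfig(temperature=T, seed=s)))
            means.append(np.mean(vals))
        for lo, hi in zip(means[1:], means[:-1]):
            assert lo <= hi + 0.05


class TestAttractors:
    def test_stored_pattern_is_fixed_point(self):
        ps, J = _hopfield(400, 2, seed=12)
        rep = detect_attractor(J, NetworkState(spins=ps[0].copy()),
                               DynamicsConfig(temperature=0.0), horizon=50)
        assert rep.kind == "fixed_point" and rep.period == 1

    def test_sequence_gives_cycle_of_period_p(self):
        ps = generate_random_patterns(500, 5, role="SPR", seed=13)
        J = mixed_matrix(ps, 0.0)
        state = corrupt(ps[0], 0.05, seed=1)
        rep = detect_attractor(J, state, DynamicsConfig(temperature=0.0), horizon=100)
        assert rep.kind == "cycle" and rep.period == 5

    def test_zero_horizon_reports_none(self):
        ps, J = _hopfield(50, 1)
        rep = detect_attractor(J, NetworkState(spins=ps[0].copy()),
                               DynamicsConfig(temperature=0.0), horizon=0)
        assert rep.kind == "none"

    def test_nonzero_temperature_rejected(self):
        ps, J = _hopfield(50, 1)
        with pytest.raises(ValueError):
            detect_attractor(J, NetworkState(spins=ps[0].copy()),
                             DynamicsConfig(temperature=0.5))


class TestSweep:
    def test_coexistence_interval_only_with_independent_sets(self):
        # with independent sets there is a band of nu where both protocols
        # succeed almost perfectly; with one shared set no nu achieves both
        # P must not divide the AM transient, or a cycling one-set state
        # returns to its start pattern and masquerades as retrieval
        nus = [0.1, 0.35, 0.5, 0.65, 0.9]
        kwargs = dict(n_neurons=1000, p_am=10, p_spr=10, in_degree=250, seed=17)
        two = sweep_nu("two_set", nus, **kwargs)
        one = sweep_nu("one_set", nus, **kwargs)
        both_two = (two.overlap_am > 0.9) & (two.overlap_spr > 0.9)
        both_one = (one.overlap_am > 0.9) & (one.overlap_spr > 0.9)
        assert both_two.any()
        assert not both_one.any()

    def test_one_set_intermediate_nu_is_frustrated(self):
        # a shared pattern set cannot serve both dynamics: at nu ~ 0.5 the
        # state is a superposition with non-negligible overlap on several
        # patterns but high overlap on none
        df = sweep_nu("one_set", [0.5], n_neurons=1000, p_am=10, p_spr=10,
                      in_degree=250, seed=3)
        row = df.iloc[0]
        assert row.overlap_am < 0.9 and row.overlap_spr < 0.9

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            sweep_nu("three_set", [0.5])
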