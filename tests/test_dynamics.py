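import numpy as np
import pytest
from scipy.special import expit

from spikebright.dynamics import (
    Connectivity,
    NetworkConfig,
    NetworkState,
    SpikeRaster,
    StructuralError,
    Traces,
    check_refractory,
    excitatory_potential,
    excitatory_spike_probability,
    inhibitory_rate,
    init_weights,
    sample_connectivity,
    simulate,
)


def _clamped_state(u: float, K: int = 1, refrac: int = 5,
                   lateral_fanin_norm: bool = True) -> NetworkState:
    """Network with zero weights, no inhibition and b clamped to u."""
    cfg = NetworkConfig(N=1, K=K, J=0, refrac_E=refrac,
                        lateral_fanin_norm=lateral_fanin_norm)
    conn = Connectivity(
        m_ei=np.zeros((K, 0)), m_ie=np.zeros((0, K)), m_ii=np.zeros((0, 0)),
        b=np.full(K, float(u)),
    )
    W = np.full((K, 1), 1e-6)
    V = np.zeros((K, K))
    return NetworkState(cfg, conn, W, V)


class TestConfig:
    def test_defaults_match_stated_circuit(self):
        cfg = NetworkConfig()
        assert (cfg.p_EI, cfg.p_IE, cfg.p_II) == (0.6, 0.575, 0.55)
        assert (cfg.v_EI, cfg.v_IE, cfg.v_II) == (0.5, 0.5, 0.5)
        assert (cfg.refrac_E, cfg.refrac_I) == (5, 3)
        assert (cfg.N, cfg.K, cfg.J) == (900, 100, 50)

    def test_invalid_probability(self):
        with pytest.raises(StructuralError):
            NetworkConfig(p_EI=1.2)

    def test_negative_refractory(self):
        with pytest.raises(StructuralError):
            NetworkConfig(refrac_E=-1)


class TestConnectivity:
    def test_full_mask_at_probability_one(self):
        conn = sample_connectivity(NetworkConfig(K=10, J=5, p_EI=1.0), seed=0)
        assert np.all(conn.m_ei == 1)

    def test_empirical_density(self):
        cfg = NetworkConfig(K=100, J=50)
        conn = sample_connectivity(cfg, seed=1)
        n = 100 * 50
        se = np.sqrt(0.6 * 0.4 / n)
        assert abs(conn.m_ei.mean() - 0.6) < 3 * se

    def test_seed_determinism(self):
        a = sample_connectivity(NetworkConfig(K=20, J=10), seed=5)
        b = sample_connectivity(NetworkConfig(K=20, J=10), seed=5)
        assert np.array_equal(a.m_ei, b.m_ei)
        assert np.array_equal(a.b, b.b)

    def test_no_self_inhibition(self):
        conn = sample_connectivity(NetworkConfig(K=10, J=8, p_II=1.0), seed=2)
        assert np.all(np.diag(conn.m_ii) == 0)

    def test_masks_immutable(self):
        conn = sample_connectivity(NetworkConfig(K=5, J=3), seed=0)
        with pytest.raises(ValueError):
            conn.m_ei[0, 0] = 1.0
        with pytest.raises(ValueError):
            conn.b[0] = 2.0

    def test_excitabilities_uniform_unit_interval(self):
        conn = sample_connectivity(NetworkConfig(K=1000, J=1), seed=3)
        assert conn.b.min() >= 0 and conn.b.max() <= 1
        assert abs(conn.b.mean() - 0.5) < 3 * np.sqrt(1 / 12 / 1000)


class TestExcitatoryPotential:
    def test_zero_traces_gives_b(self):
        conn = sample_connectivity(NetworkConfig(K=3, J=2), seed=0)
        traces = Traces(np.zeros(4), np.zeros(3), np.zeros(2))
        W = np.full((3, 4), 0.5)
        V = np.zeros((3, 3))
        u = excitatory_potential(W, V, conn, traces, 0.5)
        np.testing.assert_allclose(u, conn.b)

    def test_single_active_input(self):
        conn = Connectivity(np.zeros((1, 1)), np.zeros((1, 1)), np.zeros((1, 1)),
                            b=np.array([0.1]))
        traces = Traces(np.array([0.6]), np.zeros(1), np.zeros(1))
        u = excitatory_potential(np.array([[0.5]]), np.zeros((1, 1)), conn, traces, 0.5)
        assert u[0] == pytest.approx(0.4)

    def test_inhibitory_trace_lowers_by_half(self):
        conn = Connectivity(np.ones((1, 1)), np.zeros((1, 1)), np.zeros((1, 1)),
                            b=np.array([0.1]))
        base = Traces(np.array([0.6]), np.zeros(1), np.zeros(1))
        inhibited = Traces(np.array([0.6]), np.zeros(1), np.ones(1))
        W = np.array([[0.5]])
        V = np.zeros((1, 1))
        u0 = excitatory_potential(W, V, conn, base, 0.5)
        u1 = excitatory_potential(W, V, conn, inhibited, 0.5)
        assert u0[0] - u1[0] == pytest.approx(0.5)


class TestSpikeProbability:
    def test_logistic_at_zero(self):
        assert excitatory_spike_probability(np.array([0.0]))[0] == pytest.approx(0.5)

    def test_vanishes_at_minus_infinity(self):
        assert excitatory_spike_probability(np.array([-800.0]))[0] == pytest.approx(0.0)

    def test_log_three_gives_three_quarters(self):
        p = excitatory_spike_probability(np.array([np.log(3.0)]))[0]
        assert p == pytest.approx(0.75)
        draws = np.random.default_rng(0).random(100_000) < p
        se = np.sqrt(0.75 * 0.25 / 100_000)
        assert abs(draws.mean() - 0.75) < 3 * se


class TestInhibitoryRate:
    def test_rectification(self):
        conn = Connectivity(np.zeros((1, 1)), np.zeros((1, 1)), np.ones((1, 1)) * 0,
                            b=np.zeros(1))
        # only inhibitory input -> negative potential -> rate 0
        conn2 = Connectivity(np.zeros((1, 1)), np.zeros((1, 1)), np.ones((1, 1)),
                             b=np.zeros(1))
        traces = Traces(np.zeros(1), np.zeros(1), np.ones(1))
        assert inhibitory_rate(conn2, traces, 0.5, 0.5)[0] == 0.0

    def test_two_unit_drive(self):
        conn = Connectivity(np.zeros((2, 1)), np.ones((1, 2)), np.zeros((1, 1)),
                            b=np.zeros(2))
        traces = Traces(np.zeros(1), np.array([1.0, 1.0]), np.zeros(1))
        assert inhibitory_rate(conn, traces, 0.5, 0.5)[0] == pytest.approx(1.0)

    def test_zero_traces(self):
        conn = sample_connectivity(NetworkConfig(K=4, J=3), seed=0)
        traces = Traces(np.zeros(900), np.zeros(4), np.zeros(3))
        assert np.all(inhibitory_rate(conn, traces, 0.5, 0.5) == 0)


class TestStep:
    def test_strongly_negative_bias_silences(self, rng):
        state = _clamped_state(-10.0, K=5)
        raster = simulate(state, np.zeros((1, 500), dtype=bool), rng)
        assert raster.z.sum() <= 2  # logistic(-10) ~ 4.5e-5

    def test_identical_seeds_identical_trajectories(self):
        cfg = NetworkConfig(N=4, K=6, J=3)
        conn = sample_connectivity(cfg, seed=0)
        W, V = init_weights(cfg, seed=1)
        x = np.random.default_rng(2).random((4, 80)) < 0.2
        outs = []
        for _ in range(2):
            state = NetworkState(cfg, conn, W.copy(), V.copy())
            raster = simulate(state, x, np.random.default_rng(77))
            outs.append(raster)
        assert np.array_equal(outs[0].z, outs[1].z)
        assert np.array_equal(outs[0].y, outs[1].y)

    def test_forced_inhibition_decreases_spiking(self):
        # paired comparison: same driving potential, with/without an
        # always-active inhibitory trace entering through v_EI
        cfg = NetworkConfig(N=1, K=1, J=1, refrac_E=0)
        W = np.full((1, 1), 1e-6)
        V = np.zeros((1, 1))
        spikes = {}
        for v_ei_traces, name in [(0.0, "free"), (8.0, "inhibited")]:
            conn = Connectivity(np.ones((1, 1)), np.zeros((1, 1)), np.zeros((1, 1)),
                                b=np.array([1.0]))
            state = NetworkState(cfg, conn, W.copy(), V.copy())
            rng = np.random.default_rng(5)
            count = 0
            for _ in range(3000):
                state._tr_y._state_f[:] = v_ei_traces  # force inhibitory trace
                state._tr_y._state_r[:] = 0.0
                z, _, _ = state.step(np.zeros(1), rng)
                count += int(z[0])
            spikes[name] = count
        assert spikes["inhibited"] < spikes["free"]

    def test_wrong_input_shape(self, rng):
        state = _clamped_state(0.0)
        with pytest.raises(StructuralError):
            state.step(np.zeros(3), rng)


class TestRefractoriness:
    def test_invariant_on_simulated_raster(self, rng):
        state = _clamped_state(2.0, K=8)
        raster = simulate(state, np.zeros((1, 2000), dtype=bool), rng)
        assert check_refractory(raster.z, 5)
        assert not check_refractory(np.array([[1, 1, 0, 0, 0, 0]]), 5)

    def test_clamped_rate_matches_renewal_formula(self):
        # acceptance criterion: rate = p / (1 + p * refrac) with p = logistic(u)
        u = 0.3
        T = 100_000
        state = _clamped_state(u, K=1, refrac=5)
        raster = simulate(state, np.zeros((1, T), dtype=bool),
                          np.random.default_rng(11))
        p = expit(u)
        expected = p / (1 + p * 5)
        se = np.sqrt(expected * (1 - expected) / T)
        assert abs(raster.z.mean() - expected) < 3 * se

    def test_traces_decay_during_refractoriness(self, rng):
        state = _clamped_state(50.0, K=1)
        zs, traces = [], []
        for _ in range(12):
            z, _, tr = state.step(np.zeros(1), rng)
            zs.append(bool(z[0]))
            traces.append(tr.z[0])
        first = zs.index(True)
        # trace rises then decays over the 5 silent steps after the spike
        segment = traces[first + 1: first + 6]
        assert segment[0] > 0
        assert segment[-1] < max(segment)


class TestImmutabilityAndRaster:
    def test_masks_and_b_unchanged_by_simulation(self, rng):
        cfg = NetworkConfig(N=4, K=6, J=3)
        conn = sample_connectivity(cfg, seed=0)
        before = (conn.m_ei.copy(), conn.m_ie.copy(), conn.m_ii.copy(), conn.b.copy())
        W, V = init_weights(cfg, seed=1)
        state = NetworkState(cfg, conn, W, V)
        simulate(state, np.random.default_rng(3).random((4, 100)) < 0.3, rng)
        after = (conn.m_ei, conn.m_ie, conn.m_ii, conn.b)
        for x, y in zip(before, after):
            assert np.array_equal(x, y)

    def test_raster_roundtrip(self, tmp_path, rng):
        state = _clamped_state(0.5, K=3)
        raster = simulate(state, np.zeros((1, 50), dtype=bool), rng)
        path = tmp_path / "raster.npz"
        raster.save(path, seed=7)
        loaded = SpikeRaster.load(path)
        assert np.array_equal(loaded.z, raster.z)
        assert np.array_equal(loaded.y, raster.y)

    def test_init_weights_range_and_zero_diagonal(self):
        cfg = NetworkConfig(N=10, K=6, J=3)
        W, V = init_weights(cfg, seed=0)
        assert W.min() >= 0.001 and W.max() < 1.0
        assert np.all(np.diag(V) == 0)
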