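"""NEF engine: tuning curves, decoders, synapses, dynamics compilation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from afterimage import nef_core as nef
from conftest import run_scalar_network


class TestGainBias:
    def test_rectified_linear_boundary_conditions(self):
        p = nef.NeuronParams("spiking_rectified_linear", 200.0, 0.0)
        g, b = nef.derive_gain_bias(p)
        assert nef.rectified_linear_rate(g * 1.0 + b) == pytest.approx(200.0)
        assert nef.rectified_linear_rate(g * 0.0 + b) == pytest.approx(0.0)

    def test_magnitude_mask_intercept(self):
        """With intercept 0.1 the neuron is silent at 10% of the radius."""
        p = nef.NeuronParams("spiking_rectified_linear", 200.0, 0.1)
        g, b = nef.derive_gain_bias(p)
        assert nef.rectified_linear_rate(g * 0.1 + b) == pytest.approx(0.0, abs=1e-9)
        assert nef.rectified_linear_rate(g * 0.09 + b) == 0.0

    def test_lif_matches_closed_form(self):
        """Derived gain/bias reproduce the closed-form LIF rate at the edge."""
        p = nef.NeuronParams("lif", 200.0, 0.0, tau_rc=0.02, tau_ref=0.002)
        g, b = nef.derive_gain_bias(p)
        J = g + b
        rate = 1.0 / (p.tau_ref + p.tau_rc * math.log1p(1.0 / (J - 1.0)))
        assert rate == pytest.approx(200.0, abs=1.0)

    def test_lif_impossible_rate_raises(self):
        with pytest.raises(ValueError):
            nef.derive_gain_bias(nef.NeuronParams("lif", 600.0, 0.0, tau_ref=0.002))

    @pytest.mark.parametrize("intercept", [-0.5, 0.0, 0.3, 0.9])
    def test_tuning_boundary_property(self, intercept):
        for kind in ("spiking_rectified_linear", "lif"):
            p = nef.NeuronParams(kind, 150.0, intercept)
            g, b = nef.derive_gain_bias(p)
            J_edge = g + b
            rate = (
                nef.lif_rate(np.array([J_edge]), p.tau_rc, p.tau_ref)[0]
                if kind == "lif"
                else nef.rectified_linear_rate(J_edge)
            )
            assert rate == pytest.approx(150.0, abs=1.0)


class TestDecoders:
    def _activities(self, n, rng, pts):
        ens = nef.Ensemble(1, nef.NeuronParams("lif"), polarity="hetero", neurons_per_dim=n)
        ens.build_tuning(rng)
        return ens.rates(np.array([0.0])), ens  # placeholder

    def test_identity_decode_accuracy(self, rng):
        """50-neuron scalar ensemble decodes identity with RMSE < 0.05."""
        ens = nef.Ensemble(1, nef.NeuronParams("lif"), polarity="hetero", neurons_per_dim=50)
        ens.build_tuning(rng)
        pts = np.linspace(-1, 1, 500)
        xi = pts[:, None] * ens.enc[0][None, :]
        J = ens.gain[0] * xi + ens.bias[0]
        A = nef.lif_rate(J, 0.02, 0.002)
        d = nef.solve_decoders(A, pts)
        rmse = np.sqrt(np.mean((A @ d - pts) ** 2))
        assert rmse < 0.05

    def test_zero_function_gives_zero_decoders(self, rng):
        ens = nef.Ensemble(1, nef.NeuronParams("lif"), polarity="hetero", neurons_per_dim=30)
        ens.build_tuning(rng)
        pts = np.linspace(-1, 1, 200)
        xi = pts[:, None] * ens.enc[0][None, :]
        A = nef.lif_rate(ens.gain[0] * xi + ens.bias[0], 0.02, 0.002)
        d = nef.solve_decoders(A, np.zeros_like(pts))
        assert np.max(np.abs(d)) <= 1e-6

    def test_symmetric_pair_decodes_odd(self):
        """A +1/-1 rectified-linear pair yields an odd-symmetric decode."""
        ens = nef.Ensemble(1, nef.NeuronParams("spiking_rectified_linear"), polarity="signed")
        ens.build_tuning(np.random.default_rng(0))
        pts = np.linspace(-1, 1, 101)
        xi = pts[:, None] * ens.enc[0][None, :]
        A = nef.rectified_linear_rate(ens.gain[0] * xi + ens.bias[0])
        d = nef.solve_decoders(A, pts)
        decoded = A @ d
        assert np.allclose(decoded, -decoded[::-1], atol=1e-9)


class TestSynapses:
    def test_lowpass_step_response(self):
        lp = nef.Lowpass(0.005)
        state = lp.make_state(())
        y = 0.0
        for _ in range(5):
            y = lp.step(state, 1.0, 0.001)
        assert y == pytest.approx(1 - math.exp(-1), rel=0.01)

    def test_highpass_step_decay(self):
        hp = nef.Highpass(1.0)
        state = hp.make_state(())
        dt = 0.001
        for i in range(1000):
            y = hp.step(state, 1.0, dt)
        assert y == pytest.approx(math.exp(-1.0), rel=0.01)

    @pytest.mark.parametrize("T", [0.25, 1.0, 2.0])
    def test_boxcar_rebound_magnitude(self, T):
        """Offset rebound equals -(1 - exp(-T/tau)) of the sustained level."""
        hp = nef.Highpass(1.0)
        state = hp.make_state(())
        dt = 0.001
        for _ in range(int(T / dt)):
            hp.step(state, 1.0, dt)
        rebound = hp.step(state, 0.0, dt)
        assert rebound == pytest.approx(-(1 - math.exp(-T)), rel=0.02)

    @given(st.lists(st.floats(-10, 10), min_size=1, max_size=200))
    @settings(max_examples=30, deadline=None)
    def test_complementarity(self, signal):
        """lowpass + highpass of the same signal reconstruct it exactly."""
        lp, hp = nef.Lowpass(0.05), nef.Highpass(0.05)
        sl, sh = lp.make_state(()), hp.make_state(())
        for u in signal:
            yl = lp.step(sl, u, 0.001)
            yh = hp.step(sh, u, 0.001)
            assert abs(yl + yh - u) < 1e-9


class TestTransformsAndDynamics:
    def test_conv_preserves_grid_size(self):
        t = nef.ConvTransform(np.ones((3, 3)), (6, 7), padding="zero")
        out = t.apply(np.ones(42))
        assert out.shape == (42,)

    def test_edge_vs_zero_padding(self):
        lap = np.array([[0, 1, 0], [1, -4, 1], [0, 1, 0]], dtype=float)
        uniform = np.ones(16)
        edge = nef.ConvTransform(lap, (4, 4), padding="edge").apply(uniform)
        zero = nef.ConvTransform(lap, (4, 4), padding="zero").apply(uniform)
        assert np.allclose(edge, 0.0)  # replicated border: no spurious edges
        assert zero.reshape(4, 4)[0, 0] != 0.0  # absorbing border leaks

    def test_compile_dynamics_closed_form(self):
        f_hat, g_hat = nef.compile_dynamics(lambda x: -2 * x, lambda u: 3 * u, 0.1)
        x = np.array([1.5])
        assert np.allclose(f_hat(x), 0.1 * (-2 * x) + x)
        assert np.allclose(g_hat(x), 0.1 * 3 * x)

    def test_rate_integrator(self):
        """f=0, g=u compiled through the synapse integrates its input."""
        rec, gin = nef.compile_linear_dynamics(0.0, 1.0, 0.1)
        net = nef.Network()
        u = net.add_node(np.array([1.0]), 1, "u")
        x = net.add_ensemble(1, nef.NeuronParams(), polarity="signed", label="int")
        net.connect(u, x, transform=gin, synapse=nef.Lowpass(0.1))
        net.connect(x, x, transform=rec, synapse=nef.Lowpass(0.1))
        probe = net.probe(x, synapse=None)
        trace = nef.Simulator(net, seed=0, mode="rate").run(0.5)[probe]
        assert trace.values[-1, 0] == pytest.approx(0.5, abs=0.02)

    def test_rate_leak_matches_ode(self):
        """f(x) = -x/tau_c gives a first-order response with constant tau_c."""
        tau_c = 0.15
        rec, gin = nef.compile_linear_dynamics(-1.0 / tau_c, 1.0 / tau_c, 0.05)
        net = nef.Network()
        u = net.add_node(np.array([1.0]), 1, "u")
        x = net.add_ensemble(1, nef.NeuronParams(), polarity="signed", label="leak")
        net.connect(u, x, transform=gin, synapse=nef.Lowpass(0.05))
        net.connect(x, x, transform=rec, synapse=nef.Lowpass(0.05))
        probe = net.probe(x, synapse=None)
        trace = nef.Simulator(net, seed=0, mode="rate").run(0.6)[probe]
        t = trace.times
        expected = 1 - np.exp(-t / tau_c)
        err = np.sqrt(np.mean((trace.values[:, 0] - expected) ** 2))
        assert err < 0.05


class TestSimulator:
    def test_empty_network_runs(self):
        sim = nef.Simulator(nef.Network(), seed=0)
        sim.run(0.1)
        assert sim._step_count == 100

    def test_rate_constant_encoding(self):
        trace = run_scalar_network(0.5, nef.NeuronParams(), "signed", 2, "rate")
        assert trace.values[-1, 0] == pytest.approx(0.5, abs=0.05)

    def test_spiking_constant_encoding(self):
        trace = run_scalar_network(
            0.5, nef.NeuronParams("lif"), "hetero", 100, "spiking", seed=3
        )
        assert np.mean(trace.values[-200:, 0]) == pytest.approx(0.5, abs=0.1)

    def test_spiking_decode_converges_with_population_size(self):
        """RMSE decreases as the population grows (3 sizes, 4x apart)."""
        rmses = []
        for npp in (25, 100, 400):
            trace = run_scalar_network(
                0.5, nef.NeuronParams("lif"), "hetero", npp, "spiking", seed=3, duration=0.7
            )
            vals = trace.values[-300:, 0]
            rmses.append(np.sqrt(np.mean((vals - 0.5) ** 2)))
        assert rmses[2] < rmses[1] < rmses[0]
        assert rmses[2] < 0.5 * rmses[0]

    def test_bit_reproducibility(self):
        a = run_scalar_network(0.3, nef.NeuronParams("lif"), "hetero", 40, "spiking", seed=7)
        b = run_scalar_network(0.3, nef.NeuronParams("lif"), "hetero", 40, "spiking", seed=7)
        assert np.array_equal(a.values, b.values)

    def test_different_seed_different_spikes(self):
        a = run_scalar_network(0.3, nef.NeuronParams("lif"), "hetero", 40, "spiking", seed=1)
        b = run_scalar_network(0.3, nef.NeuronParams("lif"), "hetero", 40, "spiking", seed=2)
        assert not np.array_equal(a.values, b.values)

    def test_nonfinite_state_aborts(self):
        net = nef.Network()
        x = net.add_ensemble(1, nef.NeuronParams(), polarity="signed", label="x")
        net.connect(x, x, transform=1e9, synapse=nef.Lowpass(0.001))
        inp = net.add_node(np.array([1.0]), 1)
        net.connect(inp, x, synapse=nef.Lowpass(0.001))
        sim = nef.Simulator(net, seed=0, mode="spiking")
        with pytest.raises(FloatingPointError):
            sim.run(1.0)
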