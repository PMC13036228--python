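"""Double-opponent edge detection and high-pass adaptation."""

import numpy as np
import pytest

from afterimage import adaptation_pathway as ap
from afterimage import nef_core as nef


def brute_force_laplacian(plane, k, padding="edge"):
    """Independent oracle: explicit loop convolution with k*L."""
    h, w = plane.shape
    pad = np.pad(plane, 1, mode="edge" if padding == "edge" else "constant")
    out = np.zeros_like(plane, dtype=float)
    for i in range(h):
        for j in range(w):
            ii, jj = i + 1, j + 1
            out[i, j] = k * (
                pad[ii - 1, jj] + pad[ii + 1, jj] + pad[ii, jj - 1] + pad[ii, jj + 1]
                - 4 * pad[ii, jj]
            )
    return out


class TestDoubleOpponent:
    def test_uniform_plane_gives_zero(self):
        assert np.allclose(ap.double_opponent(np.full((8, 8), 0.7), 5.0), 0.0)

    def test_single_pixel_kernel_shape(self):
        plane = np.zeros((7, 7))
        plane[3, 3] = 1.0
        out = ap.double_opponent(plane, 1.0)
        assert out[3, 3] == -4.0
        assert out[2, 3] == out[4, 3] == out[3, 2] == out[3, 4] == 1.0
        out[2:5, 3] = out[3, 2:5] = 0.0
        assert np.allclose(out, 0.0)

    def test_vertical_step_against_brute_force(self, rng):
        plane = np.zeros((10, 10))
        plane[:, 5:] = 0.3
        assert np.allclose(ap.double_opponent(plane, 5.0), brute_force_laplacian(plane, 5.0))

    def test_random_plane_against_brute_force(self, rng):
        plane = rng.normal(size=(12, 12))
        assert np.allclose(ap.double_opponent(plane, 2.0), brute_force_laplacian(plane, 2.0))

    def test_linearity(self, rng):
        a, b = rng.normal(size=(6, 6)), rng.normal(size=(6, 6))
        lhs = ap.double_opponent(2.0 * a + 3.0 * b, 5.0)
        rhs = 2.0 * ap.double_opponent(a, 5.0) + 3.0 * ap.double_opponent(b, 5.0)
        assert np.allclose(lhs, rhs, atol=1e-9)


class TestAdaptation:
    def test_sustained_input_decays_exponentially(self):
        dt = 0.001
        signal = np.ones((2000, 1)) * 0.5
        out = ap.adapt(signal, 1.0, dt)
        assert out[0, 0] == pytest.approx(0.5, rel=0.01)
        assert out[999, 0] == pytest.approx(0.5 * np.exp(-1.0), rel=0.01)

    @pytest.mark.parametrize("T,stronger", [(0.25, False), (2.0, True)])
    def test_longer_adaptation_larger_rebound(self, T, stronger):
        dt = 0.001
        ref_T = 1.0
        def rebound(duration):
            n = int(duration / dt)
            sig = np.concatenate([np.ones((n, 1)), np.zeros((10, 1))])
            return abs(ap.adapt(sig, 1.0, dt)[n, 0])
        r = rebound(T)
        r_ref = rebound(ref_T)
        assert (r > r_ref) == stronger

    def test_rebound_reverses_sign(self):
        dt = 0.001
        sig = np.concatenate([np.full((1000, 1), 0.4), np.zeros((100, 1))])
        out = ap.adapt(sig, 1.0, dt)
        assert out[500, 0] > 0
        assert out[1002, 0] == pytest.approx(-0.4 * (1 - np.exp(-1.0)), rel=0.02)


class TestNetworkStage:
    def _build(self, plane, mode, k=5.0, seed=0):
        h, w = plane.shape
        net = nef.Network()
        node = net.add_node(plane.ravel(), h * w, "so")
        ens = net.add_ensemble(
            h * w, nef.NeuronParams("spiking_rectified_linear"), polarity="signed",
            radius=1.0, label="do",
        )
        net.connect(
            node, ens,
            transform=nef.ConvTransform(k * ap.LAPLACIAN, (h, w), padding="edge"),
            synapse=nef.Lowpass(0.005),
        )
        probe = net.probe(ens, synapse=nef.Lowpass(0.02))
        sim = nef.Simulator(net, seed=seed, mode=mode)
        return sim.run(0.4)[probe]

    def test_rate_mode_matches_convolution(self, rng):
        plane = rng.uniform(-0.1, 0.1, size=(8, 8))
        trace = self._build(plane, "rate")
        expected = ap.double_opponent(plane, 5.0).ravel()
        assert np.allclose(trace.values[-1], expected, atol=1e-6)

    def test_spiking_matches_convolution_within_tolerance(self, rng):
        """Time-averaged spiking DO plane within 10% relative L2 of the oracle."""
        plane = rng.uniform(-0.12, 0.12, size=(12, 12))
        trace = self._build(plane, "spiking", seed=5)
        avg = trace.values[-200:].mean(axis=0)
        expected = ap.double_opponent(plane, 5.0).ravel()
        rel = np.linalg.norm(avg - expected) / np.linalg.norm(expected)
        assert rel < 0.10

    def test_adapted_synapse_rebound_polarity(self, rng):
        """After offset, every strong DO pixel reverses sign."""
        h = w = 8
        plane = rng.uniform(-0.1, 0.1, size=(h, w))
        frames = {0.0: plane.ravel(), 0.6: np.zeros(h * w)}

        def stim(t):
            return frames[0.0] if t <= 0.6 else frames[0.6]

        net = nef.Network()
        node = net.add_node(stim, h * w, "so")
        ens = net.add_ensemble(h * w, nef.NeuronParams(), polarity="signed", label="do")
        net.connect(node, ens, transform=nef.ConvTransform(5 * ap.LAPLACIAN, (h, w)),
                    synapse=nef.Lowpass(0.005))
        sink = net.add_node(lambda t, x: x, h * w, "ada")
        net.connect(ens, sink, synapse=ap.adapted_synapse(1.0, 0.005))
        probe = net.probe(sink, synapse=None)
        trace = nef.Simulator(net, seed=0, mode="rate").run(0.7)[probe]
        during = trace.values[550]
        after = trace.values[620]
        do = ap.double_opponent(plane, 5.0).ravel()
        strong = np.abs(do) > 0.5 * np.abs(do).max()
        assert np.all(np.sign(after[strong]) == -np.sign(during[strong]))
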