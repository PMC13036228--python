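"""Percept readout: anchored rescaling, composition, end-to-end veridicality."""

import numpy as np
import pytest

from afterimage import percept_readout as pr
from afterimage.color_space import M_OPP, TABLE1
from afterimage.runner import ExperimentConfig, NetworkConfig, run_experiment
from afterimage.stimuli import StimulusSpec


class TestRescale:
    def test_exact_affine_recovery(self, rng):
        """If raw is an exact affine image of the anchor, rescaling inverts it."""
        anchor = rng.normal(scale=0.05, size=(10, 10))
        raw = 0.3 - 4.0 * anchor
        out, coeffs = pr.rescale(raw, anchor, fit_intercept=True)
        assert coeffs.anchored
        assert np.allclose(out, anchor, atol=1e-9)

    def test_zero_intercept_recovery(self, rng):
        anchor = rng.normal(scale=0.05, size=(10, 10))
        raw = -7.0 * anchor
        out, coeffs = pr.rescale(raw, anchor, fit_intercept=False)
        assert coeffs.a == 0.0
        assert np.allclose(out, anchor, atol=1e-9)

    def test_affine_invariance(self, rng):
        """Pre-composing raw with any affine map leaves the output unchanged."""
        anchor = rng.normal(scale=0.05, size=(10, 10))
        raw = 0.1 + 2.0 * anchor
        out1, _ = pr.rescale(raw, anchor, fit_intercept=True)
        out2, _ = pr.rescale(5.0 - 3.0 * raw, anchor, fit_intercept=True)
        assert np.allclose(out1, out2, atol=1e-9)

    def test_noise_does_not_attenuate_slope(self):
        """Output noise must not shrink the recovered scale (inverse fit).

        A forward (anchor-on-raw) regression at this noise level would
        recover well under half the true slope; the inverse fit stays
        unbiased, so the seed-averaged estimate lands near the truth.
        """
        anchor = np.zeros((20, 20))
        anchor[5:15, 5:15] = -0.06
        slopes = []
        for seed in range(8):
            noise = np.random.default_rng(seed).normal(scale=0.02, size=anchor.shape)
            raw = 0.2 * anchor + noise
            _, coeffs = pr.rescale(raw, anchor, fit_intercept=False)
            slopes.append(coeffs.b)
        assert np.mean(slopes) == pytest.approx(1 / 0.2, rel=0.25)

    def test_missing_anchor_carries_previous(self, rng):
        prev = pr.RescaleCoeffs(0.0, -3.0, True)
        raw = rng.normal(size=(6, 6))
        out, coeffs = pr.rescale(raw, None, previous=prev)
        assert coeffs is prev
        assert np.allclose(out, -3.0 * raw)

    def test_missing_anchor_without_history_is_identity(self, rng):
        raw = rng.normal(size=(6, 6))
        out, coeffs = pr.rescale(raw, None, previous=None)
        assert not coeffs.anchored
        assert np.allclose(out, raw)

    def test_undetectable_anchor_displays_neutral(self, rng):
        """Pure-noise output with a real anchor yields zero, not noise."""
        anchor = np.zeros((20, 20))
        anchor[5:15, 5:15] = -0.06
        raw = rng.normal(scale=0.05, size=anchor.shape)  # no anchor content
        out, coeffs = pr.rescale(raw, anchor, fit_intercept=False)
        assert coeffs.b == 0.0
        assert np.allclose(out, 0.0)


class TestCompose:
    def test_gray_inverse(self):
        lum = np.full((4, 4), 223 / 255.0)
        frame = pr.compose(np.zeros((4, 4)), np.zeros((4, 4)), lum)
        assert np.all(frame == 223)

    def test_zero_planes_clip_to_black(self):
        frame = pr.compose(*(np.zeros((3, 3)),) * 3)
        assert np.all(frame == 0)

    def test_capped_composition_restores_channel_ratio(self):
        """Equal-magnitude overdriven channels saturate at their own caps."""
        caps = {"rg": 0.2, "by": 0.05}
        planes = np.stack([np.full((2, 2), 5.0), np.full((2, 2), 5.0), np.full((2, 2), 0.6)])
        capped = pr.compose_capped(planes, caps)
        uncapped_opp = M_OPP @ (capped[0, 0] / 255.0)
        assert uncapped_opp[0] == pytest.approx(0.2, abs=0.01)
        assert uncapped_opp[1] == pytest.approx(0.05, abs=0.01)


class TestEndToEnd:
    @pytest.fixture(scope="class")
    def rate_run(self):
        cfg = ExperimentConfig(
            StimulusSpec("contour", "I", "green", 24), NetworkConfig(mode="rate")
        )
        return run_experiment(cfg)

    def test_sampling_grid(self, rate_run):
        p = rate_run.percept
        assert len(p.times) == 40  # 2 s at 50 ms
        assert np.all(np.diff(p.times) > 0)

    def test_veridical_reconstruction(self, rate_run):
        """End of the chromatic stage reproduces the stimulus colors."""
        frame = rate_run.percept.frame_at(1.0).astype(float)
        stim = rate_run.sequence.frames[0].astype(float)
        err = np.abs(frame - stim)[1:-1, 1:-1].mean() / 255.0
        assert err < 10 / 255.0

    def test_percept_converges_toward_stimulus_within_stage(self, rate_run):
        """Veridical error shrinks as the chromatic stage progresses."""
        stim = rate_run.sequence.frames[0].astype(float)

        def err_at(t):
            return np.abs(rate_run.percept.frame_at(t).astype(float) - stim)[1:-1, 1:-1].mean()

        assert err_at(1.0) < err_at(0.15)

    def test_afterimage_magnitude_comparable_to_stimulus(self, rate_run):
        """Test-stage chromatic output lands within an order of magnitude
        of the chromatic-stage values (visible RGB rendering)."""
        p = rate_run.percept
        i1 = int(np.argmin(np.abs(p.times - 1.0)))
        mask = rate_run.sequence.masks["adapted_ring"]
        stage1 = np.abs(p.rescaled[i1, 0][mask]).mean()
        late = np.abs(p.rescaled[-1, 0][mask]).mean()
        assert late > 0.1 * stage1
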