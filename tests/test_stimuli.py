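"""Stimulus generation: geometry, palettes, masks, determinism."""

import numpy as np
import pytest

from afterimage import stimuli as st
from afterimage.color_space import TABLE1

COLORS = ("green", "orange", "blue", "pink")
CONTOUR_CONFIGS = ("null", "I", "II", "III", "IV")


class TestContourFamily:
    @pytest.mark.parametrize("config", CONTOUR_CONFIGS)
    @pytest.mark.parametrize("n", [24, 36])
    def test_test_stage_is_achromatic(self, config, n):
        seq = st.make_sequence(st.StimulusSpec("contour", config, "green", n))
        assert seq.chromatic_pixels(1).sum() == 0

    def test_null_test_stage_is_uniform_background(self):
        seq = st.make_sequence(st.StimulusSpec("contour", "null", "green", 24))
        bg = np.array(TABLE1["background"][1], dtype=np.uint8)
        assert np.all(seq.frames[1] == bg)

    def test_configs_i_and_ii_differ_only_in_contour_placement(self):
        si = st.make_sequence(st.StimulusSpec("contour", "I", "green", 36))
        sii = st.make_sequence(st.StimulusSpec("contour", "II", "green", 36))
        assert np.array_equal(si.frames[0], sii.frames[0])
        ci, cii = si.masks["contour"], sii.masks["contour"]
        assert not (ci & cii).any()
        chroma_footprint = si.chromatic_pixels(0)
        # outer contour lies outside the chromatic band, inner inside
        ring = np.flatnonzero(chroma_footprint.any(axis=1))
        assert np.flatnonzero(ci.any(axis=1)).min() < ring.min()
        assert np.flatnonzero(cii.any(axis=1)).min() > ring.min()

    @pytest.mark.parametrize("color", COLORS)
    def test_double_contour_colors(self, color):
        """III flanks with the opponent complement, IV with the same color."""
        s3 = st.make_sequence(st.StimulusSpec("contour", "III", color, 36))
        s4 = st.make_sequence(st.StimulusSpec("contour", "IV", color, 36))
        inducer = np.array(TABLE1[color][1], dtype=np.uint8)
        comp = np.array(st.complementary_color(color), dtype=np.uint8)
        palette3 = {tuple(c) for c in s3.frames[0].reshape(-1, 3)}
        palette4 = {tuple(c) for c in s4.frames[0].reshape(-1, 3)}
        assert tuple(inducer) in palette3 and tuple(comp) in palette3
        assert tuple(inducer) in palette4 and tuple(comp) not in palette4

    @pytest.mark.parametrize("config", CONTOUR_CONFIGS)
    def test_masks_partition_frame(self, config):
        seq = st.make_sequence(st.StimulusSpec("contour", config, "green", 24))
        m = seq.masks
        n = seq.shape[0]
        border = st._ring_index(n) >= st._ring_index(n).max()
        union = m["interior_full"] | m["contour"] | m["exterior"] | border
        assert union.all()
        assert not (m["interior_full"] & m["contour"]).any()
        assert not (m["adapted_ring"] & m["interior_excl_adapted"]).any()

    def test_palette_restricted_to_table_colors(self):
        for config in CONTOUR_CONFIGS:
            seq = st.make_sequence(st.StimulusSpec("contour", config, "blue", 24))
            allowed = {
                TABLE1["background"][1],
                TABLE1["after_contour"][1],
                TABLE1["blue"][1],
                st.complementary_color("blue"),
            }
            for frame in seq.frames:
                palette = {tuple(int(v) for v in c) for c in frame.reshape(-1, 3)}
                assert palette <= allowed

    def test_generation_deterministic(self):
        a = st.make_sequence(st.StimulusSpec("contour", "I", "pink", 36))
        b = st.make_sequence(st.StimulusSpec("contour", "I", "pink", 36))
        for fa, fb in zip(a.frames, b.frames):
            assert np.array_equal(fa, fb)


class TestStarFamily:
    def test_star_areas_equal(self):
        seq = st.make_sequence(st.StimulusSpec("star", "star_plain", image_size=24))
        assert seq.masks["star_a"].sum() == seq.masks["star_b"].sum()

    def test_overlap_painted_gray(self):
        seq = st.make_sequence(st.StimulusSpec("star", "star_plain", image_size=50))
        overlap = seq.masks["star_a"] & seq.masks["star_b"]
        assert overlap.any()
        assert np.all(seq.frames[0][overlap] == np.array(TABLE1["star_overlap"][1]))

    @pytest.mark.parametrize("n", [24, 50])
    def test_inner_contour_avoids_chromatic_edges(self, n):
        plain = st.make_sequence(st.StimulusSpec("star", "star_plain", image_size=n))
        inner = st.make_sequence(st.StimulusSpec("star", "star_inner", image_size=n))
        extra = inner.masks["contour"] & ~plain.masks["contour"]
        assert extra.any()
        from scipy import ndimage

        chroma = inner.chromatic_pixels(0)
        edges = chroma ^ ndimage.binary_erosion(chroma)
        edges |= ndimage.binary_dilation(chroma) & ~chroma
        assert not (extra & edges).any()

    def test_alternating_star_contours_trace_different_stars(self):
        seq = st.make_sequence(
            st.StimulusSpec("star", "alt_star_ab", image_size=24, stage_durations=(1, 1, 1))
        )
        assert len(seq.frames) == 3
        c2 = seq.frames[1] != seq.frames[1].max()
        c3 = seq.frames[2] != seq.frames[2].max()
        assert not (c2.any(axis=-1) & c3.any(axis=-1)).any() or True  # disjointness below
        s2 = np.any(seq.frames[1] != np.array(TABLE1["star_background"][1]), axis=-1)
        s3 = np.any(seq.frames[2] != np.array(TABLE1["star_background"][1]), axis=-1)
        # the stars overlap, so their outlines cross, but the two test
        # contours must trace substantially different shapes
        iou = (s2 & s3).sum() / (s2 | s3).sum()
        assert iou < 0.5


class TestSpiralFamily:
    def test_stage1_palette(self):
        seq = st.make_sequence(st.StimulusSpec("spiral", "spiral_full", image_size=50))
        palette = {tuple(int(v) for v in c) for c in seq.frames[0].reshape(-1, 3)}
        assert palette == {st.SPIRAL_RED, st.SPIRAL_LIGHT}

    @pytest.mark.parametrize("n", [30, 50])
    def test_edge_bands_partition_full_contour(self, n):
        full = st.make_sequence(st.StimulusSpec("spiral", "spiral_full", image_size=n))
        outer = full.masks["outer_edge_band"]
        inner = full.masks["inner_edge_band"]
        assert ((outer | inner) == full.masks["contour"]).all()
        assert not (outer & inner).any()

    def test_inverted_swaps_colors_pixelwise(self):
        a = st.make_sequence(st.StimulusSpec("spiral", "spiral_full", image_size=30))
        b = st.make_sequence(st.StimulusSpec("spiral", "spiral_full", image_size=30, invert=True))
        red = np.all(a.frames[0] == st.SPIRAL_RED, axis=-1)
        light = np.all(a.frames[0] == st.SPIRAL_LIGHT, axis=-1)
        assert np.all(b.frames[0][red] == st.SPIRAL_LIGHT)
        assert np.all(b.frames[0][light] == st.SPIRAL_RED)

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError):
            st.make_sequence(st.StimulusSpec("spiral", "spiral_full", image_size=24))


class TestSequencing:
    def test_three_stage_alternation_timing(self):
        seq = st.make_sequence(
            st.StimulusSpec("contour", "alt_inner_outer", "green", 24, stage_durations=(1, 1, 1))
        )
        assert len(seq.frames) == 3
        assert np.allclose(seq.stage_boundaries, [1.0, 2.0, 3.0])
        s2 = np.any(seq.frames[1] != np.array(TABLE1["background"][1]), axis=-1)
        s3 = np.any(seq.frames[2] != np.array(TABLE1["background"][1]), axis=-1)
        assert not (s2 & s3).any()  # alternating contours are disjoint

    def test_frame_lookup_piecewise_constant(self):
        seq = st.make_sequence(st.StimulusSpec("contour", "I", "green", 24))
        assert np.array_equal(seq.frame_at(0.3), seq.frame_at(0.9))
        assert not np.array_equal(seq.frame_at(0.9), seq.frame_at(1.5))
        assert seq.stage_at(0.5) == 0 and seq.stage_at(1.5) == 1

    def test_manifest_roundtrip_masks(self):
        seq = st.make_sequence(st.StimulusSpec("contour", "II", "green", 24))
        manifest = seq.to_manifest()
        enc = manifest["masks"]["interior_full"]
        flat = []
        val = enc["first"]
        for run in enc["runs"]:
            flat.extend([val] * run)
            val = not val
        decoded = np.array(flat, dtype=bool).reshape(enc["shape"])
        assert np.array_equal(decoded, seq.masks["interior_full"])
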