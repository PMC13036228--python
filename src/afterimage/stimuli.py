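"""Deterministic generation of all experimental stimulus sequences.

Every experiment is a timed sequence of static RGB frames: a chromatic
adaptation stage followed by one or two achromatic test-contour stages.
Families:

* ``contour`` — a thin closed chromatic square contour on a gray
  background (configurations ``null`` and ``I``–``IV``), followed by an
  achromatic test contour placed directly adjacent to the chromatic band
  (outside for the negative configuration, inside for the positive one;
  the double-contour configurations flank the test contour on both
  sides).
* ``star`` — two overlapping four-pointed stars in near-complementary
  colors with a gray central overlap; the test stage outlines one star.
* ``spiral`` — a light Archimedean spiral arm on a red background; the
  test contour traces the arm's outer edge, inner edge, or both.

All colors come from the published stimulus palette
(:data:`afterimage.color_space.TABLE1`) or, for the spiral family, from
the published RGB literals.  Generation is fully deterministic.

Geometry notes.  The square contours are concentric rings of Chebyshev
radius around the frame center; the chromatic band spans two rings with
outer ring index ``N // 3`` (side about two-thirds of the frame).  The
achromatic contours abut the chromatic band so that their luminance
edges spatially coincide with the adapted chromatic edges — the
coincidence that the inducer amplification mechanism requires, and the
arrangement shown in the source psychophysics displays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json

import numpy as np
from scipy import ndimage

from .color_space import TABLE1, rgb_to_opponent

__all__ = [
    "StimulusSpec",
    "StimulusSequence",
    "make_sequence",
    "make_contour_sequence",
    "make_star_sequence",
    "make_spiral_sequence",
    "make_alternating_sequence",
    "complementary_color",
    "SPIRAL_RED",
    "SPIRAL_LIGHT",
    "SPIRAL_CONTOUR",
]

#: RGB literals of the open-contour (spiral) experiment.
SPIRAL_RED = (250, 0, 0)
SPIRAL_LIGHT = (230, 230, 230)
SPIRAL_CONTOUR = (10, 10, 10)

#: Achromatic test-contour gray for the star family: the star background
#: (200) darkened by the same 8-bit step as the closed-contour family's
#: background/after-contour pair (223 -> 196).
STAR_AFTER = (173, 173, 173)

_CONTOUR_CONFIGS = ("null", "I", "II", "III", "IV")
_STAR_CONFIGS = ("star_plain", "star_inner")
_SPIRAL_CONFIGS = ("spiral_full", "spiral_outer", "spiral_inner")
_ALT_CONFIGS = ("alt_inner_outer", "alt_outer_inner", "alt_star_ab", "alt_star_ba")


@dataclass(frozen=True)
class StimulusSpec:
    """Declarative description of one stimulus sequence."""

    family: str  # contour | star | spiral
    configuration: str
    inducer_color: str = "green"  # TABLE1 key (contour family)
    image_size: int = 36
    contour_width: int = 2
    stage_durations: tuple[float, ...] = (1.0, 1.0)
    invert: bool = False  # spiral family: swap the two chromatic colors

    def __post_init__(self) -> None:
        valid = {
            "contour": _CONTOUR_CONFIGS + _ALT_CONFIGS[:2],
            "star": _STAR_CONFIGS + _ALT_CONFIGS[2:],
            "spiral": _SPIRAL_CONFIGS,
        }
        if self.family not in valid:
            raise ValueError(f"unknown family {self.family!r}")
        if self.configuration not in valid[self.family]:
            raise ValueError(
                f"configuration {self.configuration!r} invalid for family {self.family!r}"
            )
        if self.contour_width < 1:
            raise ValueError("contour_width must be >= 1")
        if len(self.stage_durations) < 2:
            raise ValueError("a sequence needs at least two stages")
        if self.family == "contour" and self.inducer_color not in (
            "green",
            "orange",
            "blue",
            "pink",
        ):
            raise ValueError(f"inducer_color {self.inducer_color!r} not a chromatic palette entry")


@dataclass
class StimulusSequence:
    """Timed stack of RGB frames plus named region masks."""

    spec: StimulusSpec
    frames: list[np.ndarray]  # one (H, W, 3) uint8 frame per stage
    stage_durations: list[float]
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._opponent = [rgb_to_opponent(f.astype(float) / 255.0) for f in self.frames]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].shape[:2]

    @property
    def stage_boundaries(self) -> np.ndarray:
        return np.cumsum(self.stage_durations)

    @property
    def duration(self) -> float:
        return float(sum(self.stage_durations))

    def stage_at(self, t: float) -> int:
        bounds = self.stage_boundaries
        return int(min(np.searchsorted(bounds, t, side="left"), len(self.frames) - 1))

    def frame_at(self, t: float) -> np.ndarray:
        return self.frames[self.stage_at(t)]

    def opponent_at(self, t: float) -> np.ndarray:
        """(3, H, W) opponent planes of the frame shown at time ``t``."""
        return self._opponent[self.stage_at(t)]

    def chromatic_pixels(self, stage: int) -> np.ndarray:
        """Mask of pixels with nonzero chromatic opponent content."""
        opp = self._opponent[stage]
        return (np.abs(opp[0]) > 1e-6) | (np.abs(opp[1]) > 1e-6)

    def to_manifest(self) -> dict:
        return {
            "family": self.spec.family,
            "configuration": self.spec.configuration,
            "inducer_color": self.spec.inducer_color,
            "image_size": self.spec.image_size,
            "stage_durations": list(self.stage_durations),
            "masks": {k: _rle_encode(v) for k, v in self.masks.items()},
        }

    def write_pngs(self, out_dir) -> list[str]:
        from pathlib import Path

        from PIL import Image

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        names = []
        for i, frame in enumerate(self.frames):
            name = f"stage{i}.png"
            Image.fromarray(frame, mode="RGB").save(out / name)
            names.append(name)
        (out / "manifest.json").write_text(json.dumps(self.to_manifest(), indent=2))
        return names


def _rle_encode(mask: np.ndarray) -> dict:
    flat = np.asarray(mask, dtype=bool).ravel()
    changes = np.flatnonzero(np.diff(flat.astype(np.int8)))
    runs = np.diff(np.concatenate([[0], changes + 1, [flat.size]]))
    return {"shape": list(mask.shape), "first": bool(flat[0]), "runs": runs.tolist()}


# ===========================================================================
# Shared geometry helpers
# ===========================================================================


def _ring_index(n: int) -> np.ndarray:
    """Chebyshev ring index of each pixel around the frame center."""
    c = (n - 1) / 2.0
    ii, jj = np.mgrid[0:n, 0:n]
    return np.floor(np.maximum(np.abs(ii - c), np.abs(jj - c))).astype(int)


def _paint(frame: np.ndarray, mask: np.ndarray, rgb: tuple[int, int, int]) -> None:
    frame[mask] = np.array(rgb, dtype=np.uint8)


def _uniform(n: int, rgb: tuple[int, int, int]) -> np.ndarray:
    frame = np.empty((n, n, 3), dtype=np.uint8)
    frame[...] = np.array(rgb, dtype=np.uint8)
    return frame


def complementary_color(name: str) -> tuple[int, int, int]:
    """Opponent-space complement of a palette color.

    The chromatic opponent components are negated while luminance is kept,
    then mapped back to sRGB.  This is the model-space notion of a
    complementary inducer used by the double-contour configurations.
    """
    from .color_space import M_OPP, M_OPP_INV

    rgb = np.array(TABLE1[name][1], dtype=float) / 255.0
    so = M_OPP @ rgb
    comp = M_OPP_INV @ np.array([-so[0], -so[1], so[2]])
    return tuple(int(v) for v in np.floor(np.clip(comp, 0.0, 1.0) * 255.0 + 0.5))


# ===========================================================================
# Closed square contours (configurations null, I-IV) and their alternation
# ===========================================================================


def _contour_geometry(n: int, width: int) -> dict[str, np.ndarray]:
    ring = _ring_index(n)
    rho = n // 3 - 1  # inner ring of the chromatic band
    bands = {
        "chromatic": (ring >= rho) & (ring <= rho + width - 1),
        "outer_test": (ring >= rho + width) & (ring <= rho + 2 * width - 1),
        "inner_test": (ring >= rho - width) & (ring <= rho - 1),
        "inner_chromatic": (ring >= rho - 2 * width) & (ring <= rho - width - 1),
    }
    bands["ring"] = ring
    bands["rho"] = rho
    return bands


def make_contour_sequence(spec: StimulusSpec) -> StimulusSequence:
    """Chromatic square contour followed by an achromatic test contour."""
    n, w = spec.image_size, spec.contour_width
    geo = _contour_geometry(n, w)
    ring, rho = geo["ring"], geo["rho"]
    if rho - 2 * w < 1:
        raise ValueError(f"image_size {n} too small for contour geometry (width {w})")
    bg = TABLE1["background"][1]
    after = TABLE1["after_contour"][1]
    inducer = TABLE1[spec.inducer_color][1]

    stage1 = _uniform(n, bg)
    config = spec.configuration
    if config in ("III", "IV"):
        # double-contour conditions: the inducer-colored contour sits inside
        # the (future) achromatic contour, the flanking outer contour is the
        # opponent complement (constructive) or the same color (destructive)
        outer_rgb = complementary_color(spec.inducer_color) if config == "III" else inducer
        _paint(stage1, geo["chromatic"], outer_rgb)
        _paint(stage1, geo["inner_chromatic"], inducer)
    else:
        _paint(stage1, geo["chromatic"], inducer)

    stage2 = _uniform(n, bg)
    if config == "I":
        test = geo["outer_test"]
    elif config in ("II", "III", "IV"):
        test = geo["inner_test"]
    else:  # null
        test = np.zeros((n, n), dtype=bool)
    _paint(stage2, test, after)

    masks = _contour_masks(ring, rho, w, config, test)
    return StimulusSequence(spec, [stage1, stage2], list(spec.stage_durations), masks)


def _contour_masks(ring, rho, w, config, test) -> dict[str, np.ndarray]:
    border = ring >= ring.max()
    if config in ("I", "null"):
        # interior of the outer test contour: includes the adapted band
        interior = ring <= rho + w - 1
        adapted = (ring >= rho - 1) & (ring <= rho + w - 1)
    elif config == "II":
        interior = ring <= rho - w - 1
        adapted = np.zeros_like(test)
    else:  # III / IV: interior of the achromatic contour, which encloses
        # the inner chromatic band; the adapted zone is that band plus its
        # inner neighbor ring (where the rebound fringe lives)
        interior = ring <= rho - w - 1
        adapted = (ring >= rho - 2 * w - 1) & (ring <= rho - w - 1)
    interior = interior & ~test
    masks = {
        "contour": test,
        "interior_full": interior & ~border,
        "adapted_ring": (adapted & interior) & ~border,
        "interior_excl_adapted": (interior & ~adapted) & ~border,
        "core": (ring <= rho - w - 2) & ~border,
        "exterior": (~interior & ~test) & ~border,
    }
    # never-stimulated surround: reference for neutralizing the slow
    # spatially-coherent noise drift of the recurrent populations
    masks["neutral_reference"] = (ring >= rho + w + 1) & ~test & ~border
    return masks


def _alternating_contour(spec: StimulusSpec) -> StimulusSequence:
    n, w = spec.image_size, spec.contour_width
    geo = _contour_geometry(n, w)
    ring, rho = geo["ring"], geo["rho"]
    bg = TABLE1["background"][1]
    after = TABLE1["after_contour"][1]
    stage1 = _uniform(n, bg)
    _paint(stage1, geo["chromatic"], TABLE1[spec.inducer_color][1])
    inner = _uniform(n, bg)
    _paint(inner, geo["inner_test"], after)
    outer = _uniform(n, bg)
    _paint(outer, geo["outer_test"], after)
    order = [inner, outer] if spec.configuration == "alt_inner_outer" else [outer, inner]
    masks = _contour_masks(ring, rho, w, "II", geo["inner_test"] | geo["outer_test"])
    durations = list(spec.stage_durations)
    if len(durations) != 3:
        durations = [durations[0], 1.0, 1.0]
    return StimulusSequence(spec, [stage1, *order], durations, masks)


# ===========================================================================
# Star stimuli
# ===========================================================================


def _polygon_mask(verts: np.ndarray, n: int) -> np.ndarray:
    """Even-odd rasterization of a polygon over pixel centers."""
    ii, jj = np.mgrid[0:n, 0:n]
    x, y = jj.astype(float), ii.astype(float)
    inside = np.zeros((n, n), dtype=bool)
    v = np.asarray(verts, dtype=float)
    for k in range(len(v)):
        x0, y0 = v[k]
        x1, y1 = v[(k + 1) % len(v)]
        if y0 == y1:
            continue
        crosses = (y0 > y) != (y1 > y)
        x_int = x0 + (y - y0) * (x1 - x0) / (y1 - y0)
        inside ^= crosses & (x < x_int)
    return inside


def _star_vertices(n: int, phase_deg: float) -> np.ndarray:
    c = (n - 1) / 2.0
    r_out = 0.46 * n
    r_in = 0.22 * n
    verts = []
    for k in range(4):
        for ang, r in ((k * 90.0 + phase_deg, r_out), (k * 90.0 + 45.0 + phase_deg, r_in)):
            a = np.radians(ang)
            verts.append((c + r * np.cos(a), c + r * np.sin(a)))
    return np.array(verts)


def _erode(mask: np.ndarray, it: int) -> np.ndarray:
    if it <= 0:
        return mask
    return ndimage.binary_erosion(mask, iterations=it)


def make_star_sequence(spec: StimulusSpec) -> StimulusSequence:
    """Two overlapping four-pointed stars, then an outline of star A."""
    n, w = spec.image_size, spec.contour_width
    star_a = _polygon_mask(_star_vertices(n, 0.0), n)
    star_b = _polygon_mask(_star_vertices(n, 45.0), n)
    overlap = star_a & star_b
    bg = TABLE1["star_background"][1]

    stage1 = _uniform(n, bg)
    _paint(stage1, star_a, TABLE1["red_star"][1])
    _paint(stage1, star_b, TABLE1["cyan_star"][1])
    _paint(stage1, overlap, TABLE1["star_overlap"][1])

    contour_a = star_a & ~_erode(star_a, w)
    contour_b = star_b & ~_erode(star_b, w)
    inner_core = _erode(overlap, w)
    inner_contour = inner_core & ~_erode(overlap, 2 * w)

    def contour_frame(contour: np.ndarray) -> np.ndarray:
        frame = _uniform(n, bg)
        _paint(frame, contour, STAR_AFTER)
        return frame

    config = spec.configuration
    if config in ("star_plain", "star_inner"):
        test = contour_a.copy()
        if config == "star_inner":
            test |= inner_contour
        frames = [stage1, contour_frame(test)]
        durations = list(spec.stage_durations)
    else:  # alternating star outlines
        first, second = (
            (contour_a, contour_b) if config == "alt_star_ab" else (contour_b, contour_a)
        )
        test = first | second
        frames = [stage1, contour_frame(first), contour_frame(second)]
        durations = list(spec.stage_durations)
        if len(durations) != 3:
            durations = [durations[0], 1.0, 1.0]

    border = _ring_index(n) >= _ring_index(n).max()
    interior_a = _erode(star_a, w) & ~test
    masks = {
        "contour": test,
        "interior_full": interior_a & ~border,
        "star_overlap": (_erode(overlap, 1) & ~test) & ~border,
        "star_a": star_a,
        "star_b": star_b,
        "exterior": (~interior_a & ~test) & ~border,
        "adapted_ring": np.zeros((n, n), dtype=bool),
        "interior_excl_adapted": interior_a & ~border,
        "neutral_reference": (~star_a & ~star_b & ~test) & ~border,
    }
    return StimulusSequence(spec, frames, durations, masks)


# ===========================================================================
# Spiral stimuli
# ===========================================================================


def _spiral_signed_distance(n: int, arm_width: float, pitch: float, r0: float, r_max: float):
    """Signed radial distance from each pixel to the spiral center line.

    Positive distances lie on the outward side of the arm.  Returns
    ``(dist, valid)`` where ``valid`` limits the arm to the wound range.
    """
    c = (n - 1) / 2.0
    ii, jj = np.mgrid[0:n, 0:n]
    x, y = jj - c, ii - c
    rho = np.hypot(x, y)
    theta = np.arctan2(y, x)
    b = pitch / (2 * np.pi)
    # nearest winding: solve r0 + b*(theta + 2 pi k) ~= rho
    k = np.round((rho - r0 - b * theta) / pitch)
    r_line = r0 + b * (theta + 2 * np.pi * k)
    dist = rho - r_line
    valid = (r_line >= r0 - 1e-9) & (r_line <= r_max)
    return dist, valid


def _spiral_enclosed(n: int, pitch: float, r0: float, r_max: float, half: float) -> np.ndarray:
    """Pixels radially inside the spiral's outermost winding."""
    c = (n - 1) / 2.0
    ii, jj = np.mgrid[0:n, 0:n]
    x, y = jj - c, ii - c
    rho = np.hypot(x, y)
    theta = np.arctan2(y, x)
    b = pitch / (2 * np.pi)
    k_max = np.floor((r_max - r0 - b * theta) / pitch)
    r_outer = r0 + b * (theta + 2 * np.pi * k_max) + half
    return rho < r_outer


def make_spiral_sequence(spec: StimulusSpec) -> StimulusSequence:
    """Light spiral on red background, then an achromatic arm outline.

    The full test contour is the union of the arm's outer and inner edge
    bands (each ``contour_width // 2`` or 1 px wide at small sizes); the
    two edge variants select one band only.
    """
    n = spec.image_size
    if n < 30:
        raise ValueError(
            "spiral stimuli need image_size >= 30: the arm must be wide "
            "enough that its two edge contours are farther apart than the "
            "1-px reach of the contour's luminance-edge support"
        )
    edge = spec.contour_width
    core = 1 if n < 40 else 2
    arm_w = 2 * edge + core
    pitch = arm_w + max(3, arm_w - 1)
    r0 = max(2.0, 0.09 * n)
    r_max = 0.46 * n
    dist, valid = _spiral_signed_distance(n, arm_w, pitch, r0, r_max)
    half = arm_w / 2.0
    arm = (np.abs(dist) <= half) & valid
    outer_band = arm & (dist > half - edge)
    inner_band = arm & (dist < -(half - edge))
    arm_core = arm & ~outer_band & ~inner_band
    enclosed = _spiral_enclosed(n, pitch, r0, r_max, half) & ~arm

    col_bg, col_arm = (SPIRAL_RED, SPIRAL_LIGHT) if not spec.invert else (SPIRAL_LIGHT, SPIRAL_RED)
    stage1 = _uniform(n, col_bg)
    _paint(stage1, arm, col_arm)

    contour = {
        "spiral_full": outer_band | inner_band,
        "spiral_outer": outer_band,
        "spiral_inner": inner_band,
    }[spec.configuration]
    stage2 = _uniform(n, SPIRAL_LIGHT)
    _paint(stage2, contour, SPIRAL_CONTOUR)

    border = _ring_index(n) >= _ring_index(n).max()
    near = ndimage.binary_dilation(arm, iterations=3)
    inside = (arm_core & ~contour) & ~border
    masks = {
        "contour": contour,
        "spiral_arm": arm,
        "outer_edge_band": outer_band,
        "inner_edge_band": inner_band,
        "inside_spiral": inside,
        "outside_spiral": (near & ~arm & ~enclosed) & ~border,
        "spiral_near": (near & ~contour) & ~border,
        "spiral_interior": enclosed & ~border,
        "interior_full": inside,
        "exterior": (~arm & ~contour) & ~border,
        "adapted_ring": np.zeros((n, n), dtype=bool),
        "interior_excl_adapted": inside,
    }
    return StimulusSequence(spec, [stage1, stage2], list(spec.stage_durations), masks)


# ===========================================================================
# Dispatch
# ===========================================================================


def make_alternating_sequence(spec: StimulusSpec) -> StimulusSequence:
    """Three-stage sequences: one chromatic stage, two alternating contours."""
    if spec.configuration in ("alt_inner_outer", "alt_outer_inner"):
        return _alternating_contour(spec)
    if spec.configuration in ("alt_star_ab", "alt_star_ba"):
        return make_star_sequence(spec)
    raise ValueError(f"{spec.configuration!r} is not an alternating configuration")


def make_sequence(spec: StimulusSpec) -> StimulusSequence:
    """Build the stimulus sequence for any configuration."""
    if spec.configuration.startswith("alt_"):
        return make_alternating_sequence(spec)
    if spec.family == "contour":
        return make_contour_sequence(spec)
    if spec.family == "star":
        return make_star_sequence(spec)
    return make_spiral_sequence(spec)
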