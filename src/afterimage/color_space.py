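"""Deterministic color conversions used throughout the model.

Three color representations are involved:

* **CIE xyY** — the colorimetric specification of the stimulus palette
  (chromaticity ``x, y`` and luminance ``Y`` on a 0-100 scale relative to
  the display white).
* **sRGB** — 8-bit display coordinates; the stimulus images and the
  predicted percepts live here at the package boundary.  Internally all
  images are sRGB floats in [0, 1].
* **Opponent space** — the model's internal representation: a red/green
  (L/M) plane, a blue/yellow (S/(L+M)) plane and a luminance plane,
  obtained per pixel by a fixed 3x3 linear map ``M_OPP``.

CIELAB (D65 white) is used only for analysis of predicted percepts; the
conversion is delegated to :mod:`skimage.color`.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
from skimage import color as _skcolor

log = logging.getLogger(__name__)

__all__ = [
    "XYYColor",
    "TABLE1",
    "M_OPP",
    "M_OPP_INV",
    "xyy_to_srgb",
    "srgb_to_linear",
    "linear_to_srgb",
    "rgb_to_opponent",
    "opponent_to_rgb",
    "srgb_to_cielab",
    "lab_hue_chroma",
]


@dataclass(frozen=True)
class XYYColor:
    """A color in CIE xyY; ``Y`` is on a 0-100 scale (white has Y=100)."""

    x: float
    y: float
    Y: float

    def __post_init__(self) -> None:
        if not (0.0 < self.y <= 1.0):
            raise ValueError(f"chromaticity y must be in (0, 1], got {self.y}")
        if not (0.0 <= self.Y <= 100.0):
            raise ValueError(f"luminance Y must be in [0, 100], got {self.Y}")


#: Stimulus palette: CIE xyY coordinates and the published 8-bit sRGB
#: triples actually used to render the stimuli.  Keeping the printed sRGB
#: values (rather than re-deriving them) makes stimulus generation immune
#: to rounding-mode ambiguity in the xyY->sRGB conversion.
TABLE1: dict[str, tuple[XYYColor, tuple[int, int, int]]] = {
    "green": (XYYColor(0.3514, 0.4417, 65.69), (193, 223, 129)),
    "orange": (XYYColor(0.3774, 0.3694, 58.65), (236, 193, 157)),
    "blue": (XYYColor(0.2600, 0.3058, 52.90), (142, 202, 219)),
    "pink": (XYYColor(0.3814, 0.2733, 29.87), (218, 115, 162)),
    "background": (XYYColor(0.3128, 0.3303, 73.87), (223, 223, 223)),
    "after_contour": (XYYColor(0.3128, 0.3303, 55.0), (196, 196, 196)),
    "red_star": (XYYColor(0.3768, 0.3285, 41.91), (221, 156, 157)),
    "cyan_star": (XYYColor(0.2597, 0.3330, 40.95), (109, 184, 181)),
    "star_overlap": (XYYColor(0.3127, 0.3290, 42.87), (175, 175, 175)),
    "star_background": (XYYColor(0.3127, 0.3290, 58.13), (200, 200, 200)),
}

# --------------------------------------------------------------------------
# sRGB <-> XYZ.  The XYZ->linear-sRGB matrix is derived exactly from the
# sRGB primaries and the D65 white point rather than taken from the usual
# 4-decimal tabulation; the chromatic palette entries then round-trip to
# the published 8-bit values exactly.
# --------------------------------------------------------------------------

_PRIMARIES = np.array([[0.64, 0.33], [0.30, 0.60], [0.15, 0.06]])
_WHITE_XY = (0.3127, 0.3290)


def _derive_rgb_xyz() -> tuple[np.ndarray, np.ndarray]:
    cols = np.array([[x / y, 1.0, (1.0 - x - y) / y] for x, y in _PRIMARIES]).T
    white = np.array(
        [
            _WHITE_XY[0] / _WHITE_XY[1],
            1.0,
            (1.0 - _WHITE_XY[0] - _WHITE_XY[1]) / _WHITE_XY[1],
        ]
    )
    scale = np.linalg.solve(cols, white)
    rgb2xyz = cols * scale
    return rgb2xyz, np.linalg.inv(rgb2xyz)


_RGB2XYZ, _XYZ2RGB = _derive_rgb_xyz()


def linear_to_srgb(linear: np.ndarray) -> np.ndarray:
    """Gamma-encode linear-light RGB into sRGB (both in [0, 1])."""
    linear = np.asarray(linear, dtype=float)
    return np.where(
        linear <= 0.0031308,
        12.92 * linear,
        1.055 * np.power(np.clip(linear, 0.0, None), 1.0 / 2.4) - 0.055,
    )


def srgb_to_linear(srgb: np.ndarray) -> np.ndarray:
    """Decode gamma-encoded sRGB into linear light (both in [0, 1])."""
    srgb = np.asarray(srgb, dtype=float)
    return np.where(
        srgb <= 0.04045,
        srgb / 12.92,
        np.power((srgb + 0.055) / 1.055, 2.4),
    )


def xyy_to_srgb(c: XYYColor) -> tuple[int, int, int]:
    """Convert CIE xyY (Y relative to white Y=100) to an 8-bit sRGB triple.

    The pipeline is xyY -> XYZ -> linear sRGB -> gamma encode -> scale to
    255 and round half-up.  Out-of-gamut components are clipped (and
    logged) rather than raised.
    """
    Yn = c.Y / 100.0
    xyz = np.array([c.x / c.y * Yn, Yn, (1.0 - c.x - c.y) / c.y * Yn])
    rgb_lin = _XYZ2RGB @ xyz
    if np.any(rgb_lin < -1e-9) or np.any(rgb_lin > 1.0 + 1e-9):
        log.info("xyY %s maps outside the sRGB gamut; clipping", c)
    srgb = linear_to_srgb(np.clip(rgb_lin, 0.0, 1.0))
    eight_bit = np.floor(np.clip(srgb, 0.0, 1.0) * 255.0 + 0.5).astype(int)
    return tuple(int(v) for v in eight_bit)


# --------------------------------------------------------------------------
# Opponent color space.
# --------------------------------------------------------------------------

#: RGB -> (SO_RG, SO_BY, Lum).  Row 1 is L/M (red-green) opponency, row 2
#: S/(L+M) (blue-yellow) opponency, row 3 luminance.  Rows 1-2 sum to zero
#: (grays are chromatically neutral); row 3 sums to one.
M_OPP = np.array(
    [
        [1.0 / 2.0, -1.0 / 2.0, 0.0],
        [-1.0 / 6.0, -1.0 / 6.0, 2.0 / 6.0],
        [1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0],
    ]
)

M_OPP_INV = np.linalg.inv(M_OPP)


def rgb_to_opponent(frame: np.ndarray) -> np.ndarray:
    """Map an ``(H, W, 3)`` RGB image in [0, 1] to opponent planes.

    Returns an ``(3, H, W)`` array ordered ``(SO_RG, SO_BY, Lum)``.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 3 or frame.shape[-1] != 3:
        raise ValueError(f"expected (H, W, 3) RGB image, got shape {frame.shape}")
    out = np.einsum("ck,hwk->chw", M_OPP, frame)
    return out


def opponent_to_rgb(planes: np.ndarray, clip: bool = True) -> np.ndarray:
    """Inverse of :func:`rgb_to_opponent`: ``(3, H, W)`` -> ``(H, W, 3)``.

    By default the result is clipped into the displayable [0, 1] range.
    """
    planes = np.asarray(planes, dtype=float)
    if planes.ndim != 3 or planes.shape[0] != 3:
        raise ValueError(f"expected (3, H, W) opponent planes, got {planes.shape}")
    rgb = np.einsum("kc,chw->hwk", M_OPP_INV, planes)
    return np.clip(rgb, 0.0, 1.0) if clip else rgb


# --------------------------------------------------------------------------
# CIELAB analysis helpers.
# --------------------------------------------------------------------------


def srgb_to_cielab(rgb: np.ndarray) -> np.ndarray:
    """Convert sRGB (8-bit ints or [0, 1] floats) to CIELAB, D65 white."""
    rgb = np.asarray(rgb, dtype=float)
    if rgb.max() > 1.0 + 1e-9:
        rgb = rgb / 255.0
    scalar = rgb.ndim == 1
    if scalar:
        rgb = rgb[None, None, :]
    lab = _skcolor.rgb2lab(np.clip(rgb, 0.0, 1.0))
    return lab[0, 0] if scalar else lab


def lab_hue_chroma(lab: np.ndarray) -> tuple[float, float]:
    """Return (hue_deg in [0, 360), chroma) of a CIELAB triple."""
    _, a, b = np.asarray(lab, dtype=float)
    chroma = float(np.hypot(a, b))
    hue = float(np.degrees(np.arctan2(b, a))) % 360.0
    return hue, chroma
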