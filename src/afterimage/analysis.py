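"""Quantification of predicted percepts in CIELAB space.

Percept frames are summarized per region of interest (interior of the
test contour, the adapted ring, star overlap, spiral surroundings, ...)
as the CIELAB coordinates of the region's mean color, with hue given by
the a*-b* angle and chroma by the radius.  Afterimage polarity is
classified by comparing the percept hue with the inducer hue: within 60
degrees counts as positive (same hue), within 60 degrees of the
opposite direction as negative (complementary), and anything of chroma
below threshold as neutral.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .color_space import lab_hue_chroma, linear_to_srgb, srgb_to_cielab, srgb_to_linear

__all__ = [
    "mean_color",
    "classify_polarity",
    "hue_projection",
    "trajectory",
    "segment_phases",
    "combination_test",
    "rotate_response_axes",
    "PolarityResult",
]


def mean_color(frame: np.ndarray, region: np.ndarray) -> np.ndarray:
    """CIELAB of a region's mean color.

    Averaging happens in linear light (physically meaningful mixing);
    the mean is then gamma-encoded and converted to CIELAB (D65).
    """
    region = np.asarray(region, dtype=bool)
    if not region.any():
        raise ValueError("empty region")
    rgb = np.asarray(frame, dtype=float)
    if rgb.max() > 1.0 + 1e-9:
        rgb = rgb / 255.0
    mean_lin = srgb_to_linear(rgb[region]).mean(axis=0)
    return srgb_to_cielab(linear_to_srgb(mean_lin))


@dataclass(frozen=True)
class PolarityResult:
    label: str  # positive | negative | neutral
    hue_deg: float
    chroma: float
    delta_hue_deg: float


def _circular_diff(a: float, b: float) -> float:
    return abs((a - b + 180.0) % 360.0 - 180.0)


def classify_polarity(
    lab: np.ndarray,
    inducer_hue_deg: float,
    hue_window: float = 60.0,
    chroma_threshold: float = 1.0,
) -> PolarityResult:
    """Classify a percept as positive, negative, or neutral."""
    hue, chroma = lab_hue_chroma(lab)
    dh = _circular_diff(hue, inducer_hue_deg)
    if chroma < chroma_threshold:
        label = "neutral"
    elif dh < hue_window:
        label = "positive"
    elif _circular_diff(hue, inducer_hue_deg + 180.0) < hue_window:
        label = "negative"
    else:
        label = "neutral"
    return PolarityResult(label, hue, chroma, dh)


def hue_projection(lab: np.ndarray, inducer_hue_deg: float) -> float:
    """Signed chroma along the inducer hue direction (positive = same hue)."""
    _, a, b = np.asarray(lab, dtype=float)
    ang = np.radians(inducer_hue_deg)
    return float(a * np.cos(ang) + b * np.sin(ang))


def trajectory(percept_frames: np.ndarray, times: np.ndarray, region: np.ndarray) -> pd.DataFrame:
    """Per-sample CIELAB metrics of a region over time."""
    rows = []
    for t, frame in zip(times, percept_frames):
        lab = mean_color(frame, region)
        hue, chroma = lab_hue_chroma(lab)
        rows.append({"time": float(t), "L": lab[0], "a": lab[1], "b": lab[2],
                     "hue_deg": hue, "chroma": chroma})
    return pd.DataFrame(rows)


def segment_phases(chroma: np.ndarray, smooth: int = 3, eps_frac: float = 0.1) -> list[str]:
    """Label each sample of a chroma time course as build-up/plateau/decay.

    The derivative of a lightly smoothed series is thresholded at
    ``eps_frac`` times its maximum magnitude.
    """
    c = np.asarray(chroma, dtype=float)
    if smooth > 1 and len(c) >= smooth:
        kernel = np.ones(smooth) / smooth
        c = np.convolve(c, kernel, mode="same")
    d = np.gradient(c)
    eps = eps_frac * np.max(np.abs(d)) if np.max(np.abs(d)) > 0 else 0.0
    labels = np.where(d > eps, "build-up", np.where(d < -eps, "decay", "plateau"))
    return labels.tolist()


def combination_test(
    metrics: dict[str, np.ndarray],
) -> dict:
    """Constructive/destructive interaction report.

    ``metrics`` maps configuration name (``I``, ``II``, ``III``, ``IV``)
    to the CIELAB triple of the end-of-test percept.  Checks that the
    constructive combination exceeds both single conditions in chroma,
    the destructive one falls below both, and reports the cosine
    similarity between the combined (a*, b*) vector and the vector sum
    of the two single conditions.
    """
    ab = {k: np.asarray(v, dtype=float)[1:3] for k, v in metrics.items()}
    chroma = {k: float(np.hypot(*v)) for k, v in ab.items()}
    vec_sum = ab["I"] + ab["II"]
    denom = np.linalg.norm(vec_sum) * np.linalg.norm(ab["III"])
    cosine = float(vec_sum @ ab["III"] / denom) if denom > 0 else np.nan
    return {
        "chroma": chroma,
        "constructive_exceeds_singles": chroma["III"] > max(chroma["I"], chroma["II"]),
        "destructive_below_singles": chroma["IV"] < min(chroma["I"], chroma["II"]),
        "vector_sum_cosine": cosine,
    }


def rotate_response_axes(points: np.ndarray, axis_hues_deg: np.ndarray) -> tuple[np.ndarray, float]:
    """Rigid rotation aligning response-diagram axes with CIELAB hues.

    ``points`` are 2-D coordinates whose axis directions (columns of the
    identity, or any current axis directions embedded as unit vectors in
    the first rows) should align with the CIELAB hue directions
    ``axis_hues_deg``.  The least-squares rotation angle is the circular
    mean of the per-axis angular offsets.  Returns the rotated points
    and the angle (degrees).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    hues = np.radians(np.asarray(axis_hues_deg, dtype=float))
    n_axes = len(hues)
    src = points[:n_axes]
    src_ang = np.arctan2(src[:, 1], src[:, 0])
    delta = hues - src_ang
    angle = float(np.arctan2(np.sin(delta).sum(), np.cos(delta).sum()))
    rot = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
    return points @ rot.T, float(np.degrees(angle))
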