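"""Conversion of probed channel outputs into predicted percept frames.

The diffusion outputs are sampled with a low-pass probe (default 50 ms),
rescaled per channel and per frame by an affine map anchored to the
single-opponent input when one is present, and recombined into RGB via
the inverse opponent transform.

The raw reconstruction produced by edge-driven diffusion is a
band-passed, contrast-inverted copy of the stimulus (the steady state of
``dI/dt = c_r Lap(I) + c_i Lap(I_in)`` is ``I = -(c_i/c_r) I_in`` up to
smoothing), so the anchored affine fit recovers both the scale and the
sign of the represented surface.  During afterimage stages no chromatic
anchor exists; the most recent anchored coefficients are carried
forward, which is what turns the sign-reversed adaptation rebound into a
complementary-hue percept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np

from . import nef_core as nef
from .color_space import opponent_to_rgb
from .stimuli import StimulusSequence

log = logging.getLogger(__name__)

__all__ = ["RescaleCoeffs", "PerceptTrace", "attach_percept_probes", "rescale", "compose", "build_percept_trace"]


@dataclass(frozen=True)
class RescaleCoeffs:
    a: float
    b: float
    anchored: bool

    def apply(self, plane: np.ndarray) -> np.ndarray:
        return self.a + self.b * plane


IDENTITY_COEFFS = RescaleCoeffs(0.0, 1.0, False)


def attach_percept_probes(
    net: nef.Network,
    channel_ensembles: dict[str, nef.Ensemble],
    probe_tau: float = 0.05,
    sample_every: float = 0.05,
) -> dict[str, nef.Probe]:
    """Low-pass probes on the filling-in outputs of all three channels."""
    return {
        ch: net.probe(ens, synapse=nef.Lowpass(probe_tau), sample_every=sample_every, label=f"percept_{ch}")
        for ch, ens in channel_ensembles.items()
    }


def rescale(
    raw: np.ndarray,
    anchor: np.ndarray | None,
    previous: RescaleCoeffs | None = None,
    border: int = 1,
    no_anchor: str = "carry",
    fit_intercept: bool = True,
    fit_state: dict | None = None,
) -> tuple[np.ndarray, RescaleCoeffs]:
    """Affine rescaling of a raw output plane.

    When ``anchor`` (the single-opponent input plane) carries signal, fit
    ``anchor ~ a + b * raw`` by least squares over non-border pixels and
    apply the map to the whole plane.  When the anchor is absent, reuse
    the last anchored coefficients (``no_anchor='carry'``) or pass the
    plane through unchanged (``'identity'``).

    Chromatic channels are fitted without the intercept
    (``fit_intercept=False``): opponent values are signed deviations
    from neutral, and a nonzero intercept would tint every neutral pixel
    of the percept.  The luminance channel keeps the full affine map.
    """
    raw = np.asarray(raw, dtype=float)
    sl = (slice(border, -border or None),) * 2
    have_anchor = anchor is not None and float(np.max(np.abs(anchor))) > 1e-3
    if have_anchor:
        x = raw[sl].ravel()
        y = np.asarray(anchor, dtype=float)[sl].ravel()
        if fit_intercept:
            xv, yv = x - x.mean(), y - y.mean()
        else:
            xv, yv = x, y
        sums = {"sy": float(yv @ yv), "sx": float(xv @ xv), "sxy": float(xv @ yv),
                "mx": float(x.mean()), "my": float(y.mean()), "n": 1.0}
        if fit_state is not None:
            # pool the regression over successive frames of the same
            # anchored stage; spike noise in single frames makes a
            # one-shot slope estimate jittery
            decay = 0.8
            for k, v in sums.items():
                fit_state[k] = decay * fit_state.get(k, 0.0) + v
            sums = fit_state
        if sums["sy"] < 1e-10 or float(np.ptp(y)) < 1e-6:
            log.debug("degenerate anchor plane; carrying previous coefficients")
        else:
            # regress raw on anchor and invert: spike noise lives in the
            # network output, so the forward (anchor-on-raw) slope would
            # be attenuated by the output's noise variance
            b_inv = sums["sxy"] / sums["sy"]
            r2 = b_inv**2 * sums["sy"] / sums["sx"] if sums["sx"] > 1e-12 else 0.0
            if abs(b_inv) < 1e-9 or r2 < 0.005:
                # the anchor pattern is not detectable in this output:
                # display neutral rather than amplified noise
                coeffs = RescaleCoeffs(0.0, 0.0, True)
            else:
                b = 1.0 / b_inv
                norm = sums["n"]
                a = (
                    -(sums["mx"] / norm - b_inv * sums["my"] / norm) * b
                    if fit_intercept
                    else 0.0
                )
                coeffs = RescaleCoeffs(a, b, True)
            return coeffs.apply(raw), coeffs
    if previous is not None and previous.anchored and no_anchor == "carry":
        return previous.apply(raw), previous
    if previous is None and no_anchor == "carry":
        log.warning("no anchored rescale coefficients available; using identity")
    return IDENTITY_COEFFS.apply(raw), IDENTITY_COEFFS


def compose(rg_out: np.ndarray, by_out: np.ndarray, lum_out: np.ndarray) -> np.ndarray:
    """Inverse opponent transform to an 8-bit RGB percept frame."""
    planes = np.stack([rg_out, by_out, lum_out])
    rgb = opponent_to_rgb(planes, clip=True)
    return np.floor(rgb * 255.0 + 0.5).astype(np.uint8)


def compose_capped(planes: np.ndarray, chroma_cap: dict) -> np.ndarray:
    """Compose a percept frame, saturating chromatic channels first.

    Each chromatic plane is clipped at the stimulus's own opponent
    range: clipping here, in opponent coordinates, keeps channel
    identity and sign, whereas clipping later at the RGB gamut lands on
    corner colors and corrupts hue.  The clip is symmetric, so zero-mean
    spike noise is not biased by it.
    """
    rg = np.clip(planes[0], -chroma_cap["rg"], chroma_cap["rg"])
    by = np.clip(planes[1], -chroma_cap["by"], chroma_cap["by"])
    return compose(rg, by, planes[2])


@dataclass
class PerceptTrace:
    """Time-sampled predicted percepts plus the raw channel outputs.

    ``rescaled`` holds the affine-rescaled opponent planes before display
    saturation; ``frames`` are the displayable 8-bit percepts.
    """

    times: np.ndarray
    raw: np.ndarray  # (T, 3, H, W): rg, by, lum before rescaling
    rescaled: np.ndarray  # (T, 3, H, W)
    frames: np.ndarray  # (T, H, W, 3) uint8
    coeffs: list[dict[str, RescaleCoeffs]] = field(default_factory=list)
    chroma_cap: dict | None = None

    def mean_frame(self, sel: np.ndarray, lum_override: float | None = None) -> np.ndarray:
        """Display frame of the time-averaged opponent percept.

        ``lum_override`` replaces the reconstructed luminance plane with
        a flat reference level.  Polarity analysis uses this: chroma in
        CIELAB collapses at very low lightness, so a dark reconstructed
        ring would mask the chromatic content it carries.
        """
        planes = self.rescaled[sel].mean(axis=0).copy()
        if lum_override is not None:
            planes[2] = lum_override
        return compose_capped(planes, self.chroma_cap)

    def frame_at(self, t: float) -> np.ndarray:
        idx = int(np.argmin(np.abs(self.times - t)))
        return self.frames[idx]

    def write_pngs(self, out_dir) -> list[str]:
        from pathlib import Path

        from PIL import Image

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        names = []
        for t, frame in zip(self.times, self.frames):
            name = f"percept_t{int(round(t * 1000)):04d}.png"
            Image.fromarray(frame, mode="RGB").save(out / name)
            names.append(name)
        return names


def build_percept_trace(
    channel_traces: dict[str, nef.ProbeTrace],
    sequence: StimulusSequence,
    no_anchor: str = "carry",
    drift_correct: bool = True,
) -> PerceptTrace:
    """Rescale and recombine probed channel outputs into percept frames."""
    h, w = sequence.shape
    times = channel_traces["rg"].times
    order = ("rg", "by", "lum")
    raw = np.stack([channel_traces[ch].values.reshape(len(times), h, w) for ch in order], axis=1)
    rescaled = np.empty_like(raw)
    frames = np.empty((len(times), h, w, 3), dtype=np.uint8)
    prev: dict[str, RescaleCoeffs | None] = {ch: None for ch in order}
    coeffs_log: list[dict[str, RescaleCoeffs]] = []
    interior = (slice(1, -1),) * 2
    # the surround re-referencing compensates the spiking populations'
    # slow coherent noise drift; the ideal rate mode has none, and the
    # reference ring sits close enough to the stimulus to carry a trace
    # of its afterimage, so the correction is applied only when needed
    neutral_ref = sequence.masks.get("neutral_reference") if drift_correct else None
    if neutral_ref is not None and neutral_ref.sum() < 24:
        neutral_ref = None
    fit_states: dict[str, dict] = {ch: {} for ch in order}
    current_stage = -1
    # largest opponent magnitude ever shown per chromatic channel: the
    # percept is displayed at most at stimulus strength (the affine carry
    # can otherwise drive the heavily amplified afterimage far outside
    # the display gamut, where clipping corrupts hue)
    chroma_cap = {
        ch: max(float(np.max(np.abs(opp[c]))) for opp in sequence._opponent)
        for c, ch in enumerate(order[:2])
    }
    for i, t in enumerate(times):
        stage = sequence.stage_at(t)
        if stage != current_stage:
            current_stage = stage
            fit_states = {ch: {} for ch in order}
        opp_in = sequence.opponent_at(t)
        entry = {}
        for c, ch in enumerate(order):
            anchor = opp_in[c]
            plane_raw = raw[i, c]
            if ch != "lum" and neutral_ref is not None:
                # re-reference to the never-stimulated surround: the
                # recurrent populations' slowest noise mode drifts
                # coherently across the plane on a much longer timescale
                # than the percept, and the neutral surround reads it out
                plane_raw = plane_raw - plane_raw[neutral_ref].mean()
            plane, coeffs = rescale(
                plane_raw,
                anchor,
                prev[ch],
                no_anchor=no_anchor,
                fit_intercept=(ch == "lum"),
                fit_state=fit_states[ch],
            )
            rescaled[i, c] = plane
            prev[ch] = coeffs
            entry[ch] = coeffs
        coeffs_log.append(entry)
        frames[i] = compose_capped(rescaled[i], chroma_cap)
    return PerceptTrace(times, raw, rescaled, frames, coeffs_log, chroma_cap)
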