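"""Single-opponent input, double-opponent edge detection, and adaptation.

The stimulus enters the network as three retinotopic single-opponent (SO)
planes — red/green, blue/yellow, luminance — mirroring the opponent
organization of retinal ganglion cells and the LGN.  The first cortical
stage convolves each plane with a scaled discrete Laplacian, modeling
double-opponent (DO) cells of V1 that respond to chromatic and luminance
edges:

    DO(ch) = SO(ch) * (k_ch L),    L = [[0, 1, 0], [1, -4, 1], [0, 1, 0]].

Chromatic DO signals then adapt: their outgoing connections carry a
high-pass synapse, so a sustained edge decays exponentially (time
constant ``tau_hp``) and, at stimulus offset, rebounds with reversed
sign.  These reversed chromatic edges are the seed of negative
afterimages.  The luminance DO channel is not adapted.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from . import nef_core as nef
from .stimuli import StimulusSequence

__all__ = [
    "LAPLACIAN",
    "double_opponent",
    "adapt",
    "build_single_opponent_input",
    "build_double_opponent",
    "adapted_synapse",
    "CHANNELS",
]

#: Discrete 4-neighbor Laplacian stencil.
LAPLACIAN = np.array([[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]])

#: Channel order used throughout: chromatic opponent planes then luminance.
CHANNELS = ("rg", "by", "lum")


def double_opponent(plane: np.ndarray, k: float, padding: str = "edge") -> np.ndarray:
    """Reference double-opponent response: convolution with ``k * L``.

    This closed form is what the network stage computes; it doubles as
    the oracle for the spiking implementation.
    """
    mode = "nearest" if padding == "edge" else "constant"
    return ndimage.convolve(np.asarray(plane, dtype=float), k * LAPLACIAN, mode=mode, cval=0.0)


def adapt(signal: np.ndarray, tau_hp: float, dt: float) -> np.ndarray:
    """Reference adaptation: high-pass filter a time series along axis 0.

    ``signal`` is ``(T, ...)``.  Returns the adapted series; a sustained
    input decays as ``exp(-t/tau_hp)`` and reverses sign at offset.
    """
    hp = nef.Highpass(tau_hp)
    state = hp.make_state(signal.shape[1:])
    out = np.empty_like(np.asarray(signal, dtype=float))
    for t in range(signal.shape[0]):
        out[t] = hp.step(state, signal[t], dt)
    return out


def build_single_opponent_input(
    net: nef.Network, sequence: StimulusSequence
) -> dict[str, nef.Node]:
    """Add one input node per opponent channel (piecewise-constant in time)."""
    planes = [
        {ch: np.ascontiguousarray(opp[i].ravel()) for i, ch in enumerate(CHANNELS)}
        for opp in (sequence.opponent_at(t) for t in _stage_times(sequence))
    ]
    bounds = sequence.stage_boundaries
    nodes = {}
    d = sequence.shape[0] * sequence.shape[1]

    def make_output(ch):
        def output(t):
            stage = int(min(np.searchsorted(bounds, t, side="left"), len(planes) - 1))
            return planes[stage][ch]

        return output

    for ch in CHANNELS:
        nodes[ch] = net.add_node(make_output(ch), d, label=f"so_{ch}")
    return nodes


def _stage_times(sequence: StimulusSequence):
    start = 0.0
    for dur in sequence.stage_durations:
        yield start + dur / 2.0
        start += dur


def build_double_opponent(
    net: nef.Network,
    so_nodes: dict[str, nef.Node],
    shape: tuple[int, int],
    k: dict[str, float],
    tau_syn: float = 0.005,
    max_rate: float = 200.0,
    radii: dict[str, float] | None = None,
) -> dict[str, nef.Ensemble]:
    """Add the three double-opponent ensembles (signed rectified-linear).

    Each pixel is represented by a +1/-1 encoder pair; the scale ``k_ch``
    is folded into the convolution kernel.  Edge padding keeps the output
    grid size equal to the input grid size.
    """
    d = shape[0] * shape[1]
    ens = {}
    for ch in CHANNELS:
        label = f"do_{ch}"
        e = net.add_ensemble(
            d,
            nef.NeuronParams("spiking_rectified_linear", max_rate, 0.0),
            polarity="signed",
            radius=(radii or {}).get(label, 1.0),
            label=label,
            grid_shape=shape,
        )
        net.connect(
            so_nodes[ch],
            e,
            transform=nef.ConvTransform(k[ch] * LAPLACIAN, shape, padding="edge"),
            synapse=nef.Lowpass(tau_syn),
            label=f"so_{ch}->do_{ch}",
        )
        ens[ch] = e
    return ens


def adapted_synapse(tau_hp: float, tau_syn: float = 0.005) -> nef.CascadeFilter:
    """Synapse for the outgoing connections of chromatic DO ensembles.

    Standard synaptic low-pass smoothing followed by the adaptation
    high-pass: a sustained DO edge decays with ``tau_hp`` and rebounds
    (sign-reversed) at stimulus offset.
    """
    return nef.CascadeFilter(nef.Lowpass(tau_syn), nef.Highpass(tau_hp))
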