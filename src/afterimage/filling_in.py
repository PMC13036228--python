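"""Diffusion-based perceptual filling-in as recurrent spiking networks.

Following the isomorphic theory of filling-in, the perceived surface
``I`` is reconstructed from edge signals by lateral spreading on the
retinotopic map:

    dI/dt = c_r Laplacian(I) + c_i E,

where ``E`` is the filling-in inducer (the adapted, contour-amplified
chromatic gradients; for the luminance channel, the raw luminance edge
signal).  The dynamics are compiled onto a recurrent NEF connection with
synaptic time constant ``tau_r``: the recurrent connection computes
``tau_r c_r L(I) + I`` (each pixel coupled to its four immediate
neighbors — horizontal connections), and the input connection computes
``tau_r c_i E``.  Zero padding makes the frame border an absorbing
boundary.

The populations are leaky integrate-and-fire neurons with randomized
tuning; ``neurons_per_pixel`` trades spike noise against runtime (the
reference configuration uses 200, the fast default 20).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nef_core as nef
from .adaptation_pathway import LAPLACIAN

__all__ = ["DiffusionParams", "build_diffusion", "build_luminance_filling", "forward_euler_reference"]


@dataclass(frozen=True)
class DiffusionParams:
    """Parameters of one diffusion (filling-in) stage."""

    c_r: float = 2.0  # recurrent diffusion coefficient (px^2/s)
    c_i: float = 0.25  # input (inducer) coefficient (1/s)
    tau_r: float = 0.01  # recurrent synapse time constant (s)
    neurons_per_pixel: int = 20
    tau_rc: float = 0.02
    tau_ref: float = 0.002

    def __post_init__(self) -> None:
        if min(self.c_r, self.c_i, self.tau_r) <= 0:
            raise ValueError("c_r, c_i and tau_r must be positive")
        if self.neurons_per_pixel < 1:
            raise ValueError("neurons_per_pixel must be >= 1")


def build_diffusion(
    net: nef.Network,
    inducer_source,
    shape: tuple[int, int],
    params: DiffusionParams,
    label: str,
    radius: float = 1.0,
    source_synapse: nef.Lowpass | None = None,
) -> nef.Ensemble:
    """Add a recurrent diffusion stage driven by ``inducer_source``.

    Returns the ensemble representing the reconstructed plane ``I``.
    """
    d = shape[0] * shape[1]
    ens = net.add_ensemble(
        d,
        nef.NeuronParams("lif", tau_rc=params.tau_rc, tau_ref=params.tau_ref),
        polarity="hetero",
        neurons_per_dim=params.neurons_per_pixel,
        radius=radius,
        label=label,
        grid_shape=shape,
    )
    recurrent, input_gain = nef.compile_linear_dynamics(
        nef.ConvTransform(params.c_r * LAPLACIAN, shape, padding="zero"),
        params.c_i,
        params.tau_r,
    )
    net.connect(
        inducer_source,
        ens,
        transform=input_gain,
        synapse=source_synapse or nef.Lowpass(params.tau_r),
        label=f"E->{label}",
    )
    net.connect(ens, ens, transform=recurrent, synapse=nef.Lowpass(params.tau_r), label=f"{label} recurrent")
    return ens


def build_luminance_filling(
    net: nef.Network,
    do_lum: nef.Ensemble,
    shape: tuple[int, int],
    params: DiffusionParams,
    radius: float = 1.0,
) -> nef.Ensemble:
    """Luminance filling-in: same dynamics, driven by unadapted edges."""
    return build_diffusion(net, do_lum, shape, params, label="fill_lum", radius=radius)


def forward_euler_reference(
    inducer: np.ndarray | callable,
    shape: tuple[int, int],
    params: DiffusionParams,
    duration: float,
    dt: float = 0.001,
    record_every: int | None = None,
) -> np.ndarray:
    """Forward-Euler integration of the diffusion equation.

    Independent reference dynamics for validating the recurrent network.
    ``inducer`` is either a constant plane or a function of time
    returning a plane.  Zero (absorbing) boundary padding, matching the
    network.  Returns the final plane, or the recorded stack if
    ``record_every`` is given.
    """
    from scipy import ndimage

    h, w = shape
    I = np.zeros((h, w))
    steps = int(round(duration / dt))
    out = []
    e_fn = inducer if callable(inducer) else (lambda t: inducer)
    for s in range(steps):
        t = s * dt
        lap = ndimage.convolve(I, LAPLACIAN, mode="constant", cval=0.0)
        I = I + dt * (params.c_r * lap + params.c_i * np.asarray(e_fn(t), dtype=float))
        if record_every and (s + 1) % record_every == 0:
            out.append(I.copy())
    return np.asarray(out) if record_every else I
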