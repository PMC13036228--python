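"""Chromatic-gradient modulation: the filling-in inducer.

The adapted chromatic gradients alone would only regenerate a faint
(classical) afterimage.  The achromatic test contour amplifies them
through a modulatory signal ``C`` that is excited by the luminance
double-opponent magnitude and gated off by the chromatic single-opponent
input:

    M_SO = |SO(RG)| + |SO(BY)|
    C    = max(|DO(Lum)| - beta * (M_SO * 1_{3x3}), 0)
    E    = sign(DO_ada) * (|DO_ada| + alpha * C)

While a chromatic stimulus is physically present its dilated
single-opponent magnitude (scaled by the large inhibition factor
``beta``) silences ``C``; once an achromatic contour replaces it, ``C``
lights up exactly on the contour's luminance edges and amplifies any
adapted chromatic gradient that spatially coincides with them.  Pixels
with no adapted gradient are left untouched (``sign(0) = 0``), so a
contour on virgin territory neither creates nor blocks color by itself.

Magnitudes are computed by pairs of one-polarity ensembles (intercept
0.1), whose thresholded tuning also denoises small spiking fluctuations.
The sign-gated recombination of ``E`` is evaluated on the decoded
population outputs.
"""

from __future__ import annotations

import numpy as np

from . import nef_core as nef
from .adaptation_pathway import adapted_synapse

__all__ = [
    "magnitude_pair",
    "so_inhibition",
    "modulatory_signal",
    "apply_modulation",
    "build_magnitude",
    "build_modulatory_signal",
    "build_inducer",
    "BOX3",
]

#: 3x3 box filter used to dilate the single-opponent magnitude so the
#: inhibition covers both sides of a chromatic boundary.
BOX3 = np.ones((3, 3))


# ---------------------------------------------------------------------------
# Closed-form references (used by the network builders' oracles and tests)
# ---------------------------------------------------------------------------


def magnitude_pair(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a signed plane into nonnegative (pos, neg) components."""
    x = np.asarray(x, dtype=float)
    return np.maximum(x, 0.0), np.maximum(-x, 0.0)


def so_inhibition(so_rg: np.ndarray, so_by: np.ndarray, beta: float, padding: str = "zero") -> np.ndarray:
    """``beta * (|SO_RG| + |SO_BY|)`` dilated with the 3x3 box filter."""
    from scipy import ndimage

    m_so = np.abs(np.asarray(so_rg, dtype=float)) + np.abs(np.asarray(so_by, dtype=float))
    mode = "nearest" if padding == "edge" else "constant"
    return beta * ndimage.convolve(m_so, BOX3, mode=mode, cval=0.0)


def modulatory_signal(lum_edge_magnitude: np.ndarray, inhibition: np.ndarray) -> np.ndarray:
    """Rectified difference ``max(|DO_Lum| - inhibition, 0)``."""
    return np.maximum(np.asarray(lum_edge_magnitude, dtype=float) - inhibition, 0.0)


def apply_modulation(do_ada: np.ndarray, c: np.ndarray, alpha: float) -> np.ndarray:
    """Sign-gated amplification ``sign(DO_ada) * (|DO_ada| + alpha C)``.

    Where the adapted gradient is exactly zero the inducer stays zero
    regardless of ``C``.
    """
    do_ada = np.asarray(do_ada, dtype=float)
    return np.sign(do_ada) * (np.abs(do_ada) + alpha * np.asarray(c, dtype=float))


# ---------------------------------------------------------------------------
# Network builders
# ---------------------------------------------------------------------------


def build_magnitude(
    net: nef.Network,
    source,
    dims: int,
    label: str,
    intercept: float = 0.1,
    max_rate: float = 200.0,
    synapse=None,
    radii: dict[str, float] | None = None,
    function=None,
) -> tuple[nef.Ensemble, nef.Ensemble]:
    """Positive/negative one-polarity ensemble pair projecting ``source``.

    The pair's decoded outputs satisfy ``pos_out >= 0`` and
    ``neg_out <= 0``; the magnitude is ``pos_out - neg_out``.
    """
    kwargs = dict(synapse=synapse) if synapse is not None else {}
    ens = []
    for pol in ("positive", "negative"):
        lbl = f"{label}_{pol[:3]}"
        e = net.add_ensemble(
            dims,
            nef.NeuronParams("spiking_rectified_linear", max_rate, intercept),
            polarity=pol,
            radius=(radii or {}).get(lbl, 1.0),
            label=lbl,
        )
        net.connect(source, e, function=function, **kwargs)
        ens.append(e)
    return tuple(ens)


def build_modulatory_signal(
    net: nef.Network,
    so_nodes: dict[str, nef.Node],
    do_lum: nef.Ensemble,
    shape: tuple[int, int],
    beta: float,
    intercept: float = 0.1,
    tau_syn: float = 0.005,
    radii: dict[str, float] | None = None,
) -> nef.Ensemble:
    """Assemble the gate ensemble ``C``.

    Excitation comes from the luminance DO magnitude pair; inhibition
    from the single-opponent magnitude pairs of both chromatic channels,
    each dilated by the box filter with ``-beta`` folded into the kernel.
    """
    d = shape[0] * shape[1]
    c_ens = net.add_ensemble(
        d,
        nef.NeuronParams("spiking_rectified_linear", 200.0, intercept),
        polarity="positive",
        radius=(radii or {}).get("c_gate", 1.0),
        label="c_gate",
    )
    lum_pos, lum_neg = build_magnitude(
        net, do_lum, d, "mag_lum", intercept=intercept, synapse=nef.Lowpass(tau_syn), radii=radii
    )
    net.connect(lum_pos, c_ens, transform=1.0, synapse=nef.Lowpass(tau_syn))
    net.connect(lum_neg, c_ens, transform=-1.0, synapse=nef.Lowpass(tau_syn))
    for ch in ("rg", "by"):
        pos, neg = build_magnitude(
            net, so_nodes[ch], d, f"mag_so_{ch}", intercept=intercept,
            synapse=nef.Lowpass(tau_syn), radii=radii,
        )
        for ens, sign in ((pos, -1.0), (neg, +1.0)):
            net.connect(
                ens,
                c_ens,
                transform=nef.ConvTransform(sign * beta * BOX3, shape, padding="zero"),
                synapse=nef.Lowpass(tau_syn),
            )
    return c_ens


def build_inducer(
    net: nef.Network,
    do_ch: nef.Ensemble,
    c_ens: nef.Ensemble,
    dims: int,
    channel: str,
    alpha: float,
    tau_hp: float,
    tau_syn: float = 0.005,
    intercept: float = 0.0,
    radii: dict[str, float] | None = None,
    gate_frac: float = 0.05,
    mode: str = "spiking",
) -> nef.Node:
    """Adapted-gradient decomposition and sign-gated amplification.

    The chromatic DO ensemble projects through the adapting (high-pass)
    synapse into a positive and a negative one-polarity ensemble; the
    gate ``C`` is added to each component with matching sign and the
    parts are recombined into the signed inducer ``E``.  Unlike the
    magnitude-mask ensembles these decomposition ensembles keep the
    default intercept 0 — they pass the adapted gradient through
    unchanged rather than thresholding it.

    Recruitment of the contour amplification requires the adapted
    gradient to exceed a small deadband (``gate_frac`` of the
    decomposition radius, i.e. a few percent of the channel's signal
    range).  A channel carrying only a trace of signal — below the level
    a single spike's synaptic tail reaches — must not recruit the
    (sign-only) amplification, or its percept would be inflated to the
    same strength as the channel carrying the stimulus.  Gradients above
    the deadband are amplified at full strength, which is what lets a
    partially recovered adaptation state drive the polarity reversal
    under alternating contours.
    """
    p_ens, n_ens = build_magnitude(
        net,
        do_ch,
        dims,
        f"ada_{channel}",
        intercept=intercept,
        synapse=adapted_synapse(tau_hp, tau_syn),
        radii=radii,
    )
    gate_eps = gate_frac * p_ens.radius

    def combine(t, x):
        pos = x[:dims]
        neg = x[dims : 2 * dims]
        c = x[2 * dims :]
        e = np.where(pos > gate_eps, pos + alpha * c, 0.0)
        e += np.where(neg < -gate_eps, neg - alpha * c, 0.0)
        return e

    e_node = net.add_node(combine, dims, label=f"inducer_{channel}", size_in=3 * dims)
    net.connect(p_ens, e_node, synapse=nef.Lowpass(tau_syn), post_slice=slice(0, dims))
    net.connect(n_ens, e_node, synapse=nef.Lowpass(tau_syn), post_slice=slice(dims, 2 * dims))
    net.connect(c_ens, e_node, synapse=nef.Lowpass(tau_syn), post_slice=slice(2 * dims, 3 * dims))
    return e_node
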