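"""Minimal Neural Engineering Framework (NEF) engine.

The NEF represents a vector ``x`` by the activity of a neural population,

    a_i = G_i[ alpha_i * (e_i . x) + J_i^bias ],

where ``G_i`` is the neuron model (rectified-linear or leaky
integrate-and-fire), ``e_i`` the preferred direction (encoder),
``alpha_i`` a gain and ``J_i^bias`` a background current.  The represented
value is recovered (or transformed) by linear decoding ``x_hat = sum_i
a_i d_i`` with decoders ``d_i`` solved by regularized least squares.
Dynamical systems ``dx/dt = f(x) + g(u)`` are compiled onto a recurrent
connection through the synaptic low-pass filter: the input connection
computes ``tau * g(u)`` and the recurrent connection ``tau * f(x) + x``.

This engine supports exactly what the afterimage model needs: retinotopic
"grid" ensembles (one small scalar population per pixel), signed and
single-polarity rectified-linear codes, heterogeneous LIF populations for
the diffusion stages, low-/high-pass synapses, and convolutional
transforms with edge or zero padding.

Two execution modes are provided.  ``spiking`` runs the spiking neuron
models and is the reference for all dynamical results.  ``rate`` is an
ideal rate-based mode: ensembles pass their represented value through the
tuning-implied nonlinearity exactly, with no spike noise and no decoding
error.  It is used for fast tests, for analytic oracles and for radius
calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable
import logging
import math

import numpy as np
from scipy import ndimage

log = logging.getLogger(__name__)

__all__ = [
    "NeuronParams",
    "derive_gain_bias",
    "rectified_linear_rate",
    "lif_rate",
    "solve_decoders",
    "Lowpass",
    "Highpass",
    "CascadeFilter",
    "ConvTransform",
    "DenseTransform",
    "compile_dynamics",
    "compile_linear_dynamics",
    "Node",
    "Ensemble",
    "Connection",
    "Probe",
    "Network",
    "Simulator",
]


# ===========================================================================
# Neuron models and tuning curves
# ===========================================================================


@dataclass(frozen=True)
class NeuronParams:
    """Tuning parameters of a single neuron (or a shared template).

    ``max_rate`` is the firing rate (Hz) at the edge of the representation
    range along the encoder; ``intercept`` is the normalized input below
    which the neuron is silent.  ``tau_rc``/``tau_ref`` apply to LIF only.
    """

    model_kind: str = "spiking_rectified_linear"  # or "lif"
    max_rate: float = 200.0
    intercept: float = 0.0
    tau_rc: float = 0.02
    tau_ref: float = 0.002

    def __post_init__(self) -> None:
        if self.max_rate <= 0:
            raise ValueError("max_rate must be positive")
        if not (-1.0 <= self.intercept < 1.0):
            raise ValueError("intercept must lie in [-1, 1)")
        if self.model_kind == "lif" and (self.tau_rc <= 0 or self.tau_ref < 0):
            raise ValueError("LIF requires tau_rc > 0 and tau_ref >= 0")


def rectified_linear_rate(J: np.ndarray) -> np.ndarray:
    """Rate of a rectified-linear neuron given input current ``J``."""
    return np.maximum(J, 0.0)


def lif_rate(J: np.ndarray, tau_rc: float, tau_ref: float) -> np.ndarray:
    """Steady-state LIF rate: ``1 / (tau_ref + tau_rc ln(1 + 1/(J-1)))``."""
    J = np.asarray(J, dtype=float)
    out = np.zeros_like(J)
    above = J > 1.0 + 1e-12
    Ja = J[above]
    out[above] = 1.0 / (tau_ref + tau_rc * np.log1p(1.0 / (Ja - 1.0)))
    return out


def derive_gain_bias(params: NeuronParams, radius: float = 1.0) -> tuple[float, float]:
    """Solve (gain, bias) so the tuning curve meets its boundary conditions.

    In normalized input units ``xi = (e . x) / radius``: the rate is zero
    at ``xi = intercept`` and equals ``max_rate`` at ``xi = 1``.  The
    returned gain is per unit of ``xi``; callers divide inputs by
    ``radius`` before applying it.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if params.model_kind == "lif":
        z = (1.0 / params.max_rate - params.tau_ref) / params.tau_rc
        if z <= 0:
            raise ValueError(
                "max_rate too high for this tau_ref/tau_rc (no finite LIF solution)"
            )
        j_max = 1.0 + 1.0 / math.expm1(z)
        gain = (j_max - 1.0) / (1.0 - params.intercept)
        bias = 1.0 - gain * params.intercept
    else:
        gain = params.max_rate / (1.0 - params.intercept)
        bias = -gain * params.intercept
    if not (np.isfinite(gain) and np.isfinite(bias)):
        raise ValueError(f"non-finite gain/bias for {params}")
    return float(gain), float(bias)


def _rates_from_current(J: np.ndarray, params_kind: str, tau_rc: float, tau_ref: float) -> np.ndarray:
    if params_kind == "lif":
        return lif_rate(J, tau_rc, tau_ref)
    return rectified_linear_rate(J)


# ===========================================================================
# Decoder solving
# ===========================================================================


def solve_decoders(
    activities: np.ndarray,
    targets: np.ndarray,
    reg: float = 0.1,
    max_rate: float = 200.0,
    debias_gain: bool = True,
) -> np.ndarray:
    """Ridge-regularized least-squares decoders.

    ``activities`` is ``(n_eval, n_neurons)``, ``targets`` ``(n_eval,)``.
    Regularization follows the usual NEF convention: the ridge term is
    ``(reg * max_rate)^2 * n_eval`` on the Gram matrix.  With very small
    populations the ridge shrinks the decode systematically, which would
    bias recurrent dynamics; ``debias_gain`` removes that global shrink by
    rescaling the solution to the least-squares gain of the fit (the
    direction of the ridge solution is kept, only its length corrected).
    """
    A = np.asarray(activities, dtype=float)
    t = np.asarray(targets, dtype=float)
    n_eval, n = A.shape
    sigma = reg * max_rate
    G = A.T @ A + n_eval * sigma**2 * np.eye(n)
    try:
        d = np.linalg.solve(G, A.T @ t)
    except np.linalg.LinAlgError:  # pragma: no cover - G is PD by construction
        log.warning("rank-deficient activity matrix; falling back to lstsq")
        d = np.linalg.lstsq(A, t, rcond=None)[0]
    if debias_gain:
        y = A @ d
        denom = float(y @ y)
        if denom > 1e-12 and float(t @ t) > 1e-12:
            d = d * (float(t @ y) / denom)
    return d


# ===========================================================================
# Synapse filters
# ===========================================================================


class Lowpass:
    """First-order low-pass filter, exact zero-order-hold discretization:
    ``y[t] = a y[t-1] + (1 - a) u[t]`` with ``a = exp(-dt / tau)``."""

    kind = "lowpass"

    def __init__(self, tau: float):
        if tau <= 0:
            raise ValueError("tau must be positive")
        self.tau = float(tau)

    def make_state(self, shape) -> dict:
        return {"y": np.zeros(shape)}

    def step(self, state: dict, u: np.ndarray, dt: float) -> np.ndarray:
        a = math.exp(-dt / self.tau)
        state["y"] = a * state["y"] + (1.0 - a) * u
        return state["y"]

    def __repr__(self) -> str:
        return f"Lowpass({self.tau})"


class Highpass:
    """Complement high-pass: ``y_hp = u - lowpass_tau(u)``.

    By construction ``lowpass(u) + highpass(u) = u`` sample by sample for
    equal tau.  A sustained input decays as ``exp(-t/tau)``; at input
    offset after duration ``T`` the output rebounds to
    ``-(1 - exp(-T/tau))`` times the sustained level.  This rebound is the
    adaptation aftereffect that seeds negative afterimages.
    """

    kind = "highpass"

    def __init__(self, tau: float):
        if tau <= 0:
            raise ValueError("tau must be positive")
        self.tau = float(tau)
        self._lp = Lowpass(tau)

    def make_state(self, shape) -> dict:
        return {"lp": self._lp.make_state(shape)}

    def step(self, state: dict, u: np.ndarray, dt: float) -> np.ndarray:
        return u - self._lp.step(state["lp"], u, dt)

    def __repr__(self) -> str:
        return f"Highpass({self.tau})"


class CascadeFilter:
    """Series composition of filters, applied left to right."""

    kind = "cascade"

    def __init__(self, *filters):
        self.filters = filters

    def make_state(self, shape) -> dict:
        return {"stages": [f.make_state(shape) for f in self.filters]}

    def step(self, state: dict, u: np.ndarray, dt: float) -> np.ndarray:
        y = u
        for f, s in zip(self.filters, state["stages"]):
            y = f.step(s, y, dt)
        return y

    def __repr__(self) -> str:
        return f"Cascade({', '.join(map(repr, self.filters))})"


# ===========================================================================
# Linear transforms
# ===========================================================================


class ConvTransform:
    """2-D stencil applied to a flattened ``(H, W)`` grid signal.

    Output grid size equals input grid size; the one-pixel margin is
    supplied by ``edge`` (replicate) or ``zero`` padding.  Constant scale
    factors are folded into the kernel.
    """

    def __init__(self, kernel: np.ndarray, shape: tuple[int, int], padding: str = "edge"):
        self.kernel = np.asarray(kernel, dtype=float)
        if padding not in ("edge", "zero"):
            raise ValueError("padding must be 'edge' or 'zero'")
        self.padding = padding
        self.shape = tuple(shape)

    @property
    def mode(self) -> str:
        return "nearest" if self.padding == "edge" else "constant"

    def apply(self, x: np.ndarray) -> np.ndarray:
        img = np.asarray(x, dtype=float).reshape(self.shape)
        out = ndimage.convolve(img, self.kernel, mode=self.mode, cval=0.0)
        return out.ravel()

    def scaled(self, factor: float) -> "ConvTransform":
        return ConvTransform(self.kernel * factor, self.shape, self.padding)

    def plus_identity(self) -> "ConvTransform":
        k = self.kernel.copy()
        c = tuple(s // 2 for s in k.shape)
        k[c] += 1.0
        return ConvTransform(k, self.shape, self.padding)


class DenseTransform:
    """Dense linear map ``y = W x`` for small (scalar-dimension) signals."""

    def __init__(self, matrix: np.ndarray):
        self.matrix = np.atleast_2d(np.asarray(matrix, dtype=float))

    def apply(self, x: np.ndarray) -> np.ndarray:
        return self.matrix @ np.atleast_1d(x)


def _apply_transform(transform, x: np.ndarray) -> np.ndarray:
    if transform is None:
        return x
    if np.isscalar(transform):
        return transform * x
    return transform.apply(x)


# ===========================================================================
# Dynamics compilation
# ===========================================================================


def compile_dynamics(
    f: Callable[[np.ndarray], np.ndarray],
    g: Callable[[np.ndarray], np.ndarray],
    tau: float,
) -> tuple[Callable, Callable]:
    """Compile ``dx/dt = f(x) + g(u)`` for a recurrent NEF connection.

    Returns ``(f_hat, g_hat)`` with ``f_hat(x) = tau f(x) + x`` (recurrent
    connection) and ``g_hat(u) = tau g(u)`` (input connection), where
    ``tau`` is the recurrent synapse's time constant.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")

    def f_hat(x):
        return tau * f(x) + x

    def g_hat(u):
        return tau * g(u)

    return f_hat, g_hat


def compile_linear_dynamics(
    f_transform: ConvTransform | float,
    g_gain: float,
    tau: float,
) -> tuple[ConvTransform | float, float]:
    """Transform-level version of :func:`compile_dynamics` for linear maps.

    ``f_transform`` is the linear operator in ``dx/dt = F x + g_gain * u``
    (a convolution stencil or a scalar).  Returns the recurrent transform
    ``tau F + I`` and the input gain ``tau * g_gain``.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if isinstance(f_transform, ConvTransform):
        recurrent = f_transform.scaled(tau).plus_identity()
    else:
        recurrent = tau * float(f_transform) + 1.0
    return recurrent, tau * g_gain


# ===========================================================================
# Network objects
# ===========================================================================


class Node:
    """A non-neural signal source/sink.

    ``output`` may be a constant vector, a function of time ``fn(t)``, or
    a function ``fn(t, x)`` of time and the node's summed filtered input
    (used for computed stages evaluated on decoded population outputs).
    """

    def __init__(self, output, size: int, label: str = "node", size_in: int | None = None):
        self.output_spec = output
        self.size = int(size)
        self.size_in = int(size_in) if size_in is not None else int(size)
        self.label = label
        self._takes_input = callable(output) and output.__code__.co_argcount >= 2

    def __repr__(self) -> str:
        return f"Node({self.label})"


class Ensemble:
    """A population of neurons representing a ``dims``-vector.

    Every dimension (pixel) gets its own scalar sub-population of
    ``neurons_per_dim`` neurons.  ``polarity`` selects the code:

    * ``signed`` — one +1 and one -1 encoder neuron per dimension
      (rectified-linear); represents signed scalars.
    * ``positive`` / ``negative`` — a single one-polarity neuron per
      dimension; the decoded output is rectified at the intercept, which
      is how magnitude masks and the modulatory gate acquire their
      thresholds.
    * ``hetero`` — ``neurons_per_dim`` neurons with randomized encoders,
      max rates and intercepts (used for the LIF diffusion populations
      and for generic scalar ensembles).
    """

    def __init__(
        self,
        dims: int,
        neuron_params: NeuronParams,
        polarity: str = "signed",
        neurons_per_dim: int | None = None,
        radius: float = 1.0,
        max_rate_range: tuple[float, float] = (200.0, 400.0),
        intercept_range: tuple[float, float] = (-0.95, 0.95),
        label: str = "ens",
        grid_shape: tuple[int, int] | None = None,
    ):
        if dims < 1:
            raise ValueError("dims must be >= 1")
        if polarity not in ("signed", "positive", "negative", "hetero"):
            raise ValueError(f"unknown polarity {polarity!r}")
        self.dims = int(dims)
        self.neuron_params = neuron_params
        self.polarity = polarity
        if neurons_per_dim is None:
            neurons_per_dim = {"signed": 2, "positive": 1, "negative": 1}.get(polarity, 50)
        self.npp = int(neurons_per_dim)
        if self.npp < 1:
            raise ValueError("neurons_per_dim must be >= 1")
        self.radius = float(radius)
        self.max_rate_range = max_rate_range
        self.intercept_range = intercept_range
        self.label = label
        self.grid_shape = grid_shape
        # filled in by Simulator.build
        self.gain: np.ndarray | None = None
        self.bias: np.ndarray | None = None
        self.enc: np.ndarray | None = None

    # -- tuning ------------------------------------------------------------

    def build_tuning(self, rng: np.random.Generator) -> None:
        p = self.neuron_params
        if self.polarity == "hetero":
            mr = rng.uniform(*self.max_rate_range, size=(self.dims, self.npp))
            ic = rng.uniform(*self.intercept_range, size=(self.dims, self.npp))
            enc = rng.choice([-1.0, 1.0], size=(self.dims, self.npp))
            gain = np.empty_like(mr)
            bias = np.empty_like(mr)
            for d in range(self.dims):
                for k in range(self.npp):
                    g, b = derive_gain_bias(
                        NeuronParams(p.model_kind, mr[d, k], ic[d, k], p.tau_rc, p.tau_ref)
                    )
                    gain[d, k] = g
                    bias[d, k] = b
            self.enc, self.gain, self.bias = enc, gain, bias
        else:
            if self.polarity == "signed":
                if self.npp % 2:
                    raise ValueError("signed ensembles need an even neurons_per_dim")
                enc_row = np.tile([1.0, -1.0], self.npp // 2)
            elif self.polarity == "positive":
                enc_row = np.ones(self.npp)
            else:
                enc_row = -np.ones(self.npp)
            g, b = derive_gain_bias(p)
            self.enc = np.broadcast_to(enc_row, (1, self.npp))
            self.gain = np.full((1, self.npp), g)
            self.bias = np.full((1, self.npp), b)

    def rates(self, x: np.ndarray) -> np.ndarray:
        """Analytic steady-state rates for represented values ``x`` (dims,)."""
        xi = self.enc * (np.atleast_1d(x)[:, None] / self.radius)
        J = self.gain * xi + self.bias
        p = self.neuron_params
        return _rates_from_current(J, p.model_kind, p.tau_rc, p.tau_ref)

    def eval_points(self, n: int | None = None) -> np.ndarray:
        n = n if n is not None else max(500, 2 * self.npp)
        return np.linspace(-self.radius, self.radius, n)

    def ideal_output(self, x: np.ndarray) -> np.ndarray:
        """The tuning-implied represented output (rate-mode semantics).

        Signed and heterogeneous codes pass the value through; one-polarity
        codes rectify at the intercept with slope normalized so the output
        equals the input at the radius edge.
        """
        x = np.asarray(x, dtype=float)
        if self.polarity in ("signed", "hetero"):
            return x
        theta = self.neuron_params.intercept
        sgn = 1.0 if self.polarity == "positive" else -1.0
        xi = sgn * x / self.radius
        return sgn * np.maximum(xi - theta, 0.0) / (1.0 - theta) * self.radius

    def __repr__(self) -> str:
        return f"Ensemble({self.label}, dims={self.dims}, npp={self.npp}, {self.polarity})"


class Connection:
    """A decoded, filtered, linearly transformed link between objects."""

    def __init__(
        self,
        pre,
        post,
        transform=None,
        synapse=Lowpass(0.005),
        function: Callable[[np.ndarray], np.ndarray] | None = None,
        post_slice: slice | None = None,
        label: str | None = None,
    ):
        self.pre = pre
        self.post = post
        self.transform = transform
        self.synapse = synapse
        self.function = function
        self.post_slice = post_slice
        self.label = label or f"{getattr(pre, 'label', pre)}->{getattr(post, 'label', post)}"
        self.decoders: np.ndarray | None = None

    def __repr__(self) -> str:
        return f"Connection({self.label})"


class Probe:
    """Records a (optionally filtered) signal every ``sample_every`` s."""

    def __init__(self, target, synapse=Lowpass(0.01), sample_every: float | None = None, label: str = "probe"):
        self.target = target
        self.synapse = synapse
        self.sample_every = sample_every
        self.label = label


class Network:
    """A container of nodes, ensembles, connections and probes."""

    def __init__(self, label: str = "net"):
        self.label = label
        self.nodes: list[Node] = []
        self.ensembles: list[Ensemble] = []
        self.connections: list[Connection] = []
        self.probes: list[Probe] = []

    def add_node(self, output, size: int, label: str = "node", size_in: int | None = None) -> Node:
        node = Node(output, size, label, size_in=size_in)
        self.nodes.append(node)
        return node

    def add_ensemble(self, *args, **kwargs) -> Ensemble:
        ens = Ensemble(*args, **kwargs)
        self.ensembles.append(ens)
        return ens

    def connect(self, pre, post, **kwargs) -> Connection:
        conn = Connection(pre, post, **kwargs)
        self.connections.append(conn)
        return conn

    def probe(self, target, **kwargs) -> Probe:
        probe = Probe(target, **kwargs)
        self.probes.append(probe)
        return probe


# ===========================================================================
# Simulator
# ===========================================================================


@dataclass
class ProbeTrace:
    times: np.ndarray
    values: np.ndarray

    def to_csv(self, path) -> None:
        import pandas as pd

        vals = np.atleast_2d(self.values.T).T
        cols = {"time": self.times}
        for i in range(vals.shape[1]):
            cols[f"value_{i}"] = vals[:, i]
        pd.DataFrame(cols).to_csv(path, index=False)


class Simulator:
    """Discrete-time simulator for a :class:`Network`.

    ``mode='spiking'`` runs the spiking neuron models; ``mode='rate'``
    runs the ideal rate-based semantics (no spikes, exact decoding).  The
    simulation is bit-reproducible given ``(seed, dt, mode)``.
    """

    def __init__(self, network: Network, dt: float = 0.001, seed: int = 0, mode: str = "spiking"):
        if dt <= 0:
            raise ValueError("dt must be positive")
        if mode not in ("spiking", "rate"):
            raise ValueError("mode must be 'spiking' or 'rate'")
        self.net = network
        self.dt = float(dt)
        self.seed = int(seed)
        self.mode = mode
        self._built = False

    # -- build -------------------------------------------------------------

    def build(self) -> None:
        seqs = np.random.SeedSequence(self.seed).spawn(len(self.net.ensembles))
        for ens, ss in zip(self.net.ensembles, seqs):
            ens.build_tuning(np.random.default_rng(ss))
        for conn in self.net.connections:
            if isinstance(conn.pre, Ensemble) and self.mode == "spiking":
                conn.decoders = self._solve_connection_decoders(conn)
        # runtime state
        self._ens_state: dict[Ensemble, dict] = {}
        self._ens_out: dict[Ensemble, np.ndarray] = {}
        self._node_out: dict[Node, np.ndarray] = {}
        self._node_in: dict[Node, np.ndarray] = {}
        self._ens_in: dict[Ensemble, np.ndarray] = {}
        for ens in self.net.ensembles:
            self._ens_state[ens] = self._init_neuron_state(ens)
            self._ens_out[ens] = np.zeros(ens.dims)
            self._ens_in[ens] = np.zeros(ens.dims)
        for node in self.net.nodes:
            self._node_out[node] = np.zeros(node.size)
            self._node_in[node] = np.zeros(node.size_in)
        self._conn_state = {c: (c.synapse.make_state(self._post_size(c)) if c.synapse else None)
                            for c in self.net.connections}
        self._probe_state = {}
        self._probe_data: dict[Probe, list] = {}
        self._probe_times: dict[Probe, list] = {}
        for p in self.net.probes:
            size = p.target.dims if isinstance(p.target, Ensemble) else p.target.size
            self._probe_state[p] = p.synapse.make_state(size) if p.synapse else None
            self._probe_data[p] = []
            self._probe_times[p] = []
        self._range_max = {ens: 0.0 for ens in self.net.ensembles}
        self._step_count = 0
        self._built = True

    def _post_size(self, conn: Connection) -> int:
        post = conn.post
        full = post.dims if isinstance(post, Ensemble) else post.size_in
        if conn.post_slice is not None:
            return len(range(*conn.post_slice.indices(full)))
        return full

    def _solve_connection_decoders(self, conn: Connection) -> np.ndarray:
        ens: Ensemble = conn.pre
        pts = ens.eval_points()
        target = ens.ideal_output(pts)
        if conn.function is not None:
            target = np.asarray(conn.function(target), dtype=float)
        if ens.polarity == "hetero":
            # independent tuning per dimension: batched ridge solve
            xi = pts[None, :, None] / ens.radius  # (1, E, 1)
            J = ens.gain[:, None, :] * (ens.enc[:, None, :] * xi) + ens.bias[:, None, :]
            p = ens.neuron_params
            A = _rates_from_current(J, p.model_kind, p.tau_rc, p.tau_ref)  # (D, E, npp)
            n_eval = len(pts)
            sigma = 0.1 * np.mean(ens.max_rate_range)
            G = np.einsum("dek,del->dkl", A, A) + n_eval * sigma**2 * np.eye(ens.npp)
            rhs = np.einsum("dek,e->dk", A, target)
            d = np.linalg.solve(G, rhs[..., None])[..., 0]
            y2 = np.einsum("dek,dk->de", A, d)
            denom = np.einsum("de,de->d", y2, y2)
            num = y2 @ target
            scale = np.where(denom > 1e-12, num / np.maximum(denom, 1e-12), 1.0)
            tt = float(target @ target)
            if tt <= 1e-12:
                scale = np.ones_like(scale)
            return d * scale[:, None]
        # shared tuning across dimensions: solve once
        A = _shared_rates(ens, pts)
        d = solve_decoders(A, target, reg=0.1, max_rate=ens.neuron_params.max_rate)
        return np.broadcast_to(d, (1, ens.npp))

    def _init_neuron_state(self, ens: Ensemble) -> dict:
        shape = (ens.dims, ens.npp)
        state = {"activity": np.zeros(shape)}
        if self.mode == "spiking":
            state["voltage"] = np.zeros(shape)
            if ens.neuron_params.model_kind == "lif":
                state["refractory"] = np.zeros(shape)
        return state

    # -- run ---------------------------------------------------------------

    def run(self, duration: float) -> dict[Probe, ProbeTrace]:
        if not self._built:
            self.build()
        n_steps = int(round(duration / self.dt))
        for _ in range(n_steps):
            self.step()
        return self.collect()

    def step(self) -> None:
        dt = self.dt
        t = (self._step_count + 1) * dt
        # 1. source outputs from current state
        for node in self.net.nodes:
            out = node.output_spec
            if callable(out):
                val = out(t, self._node_in[node]) if node._takes_input else out(t)
            else:
                val = out
            self._node_out[node] = np.broadcast_to(np.asarray(val, dtype=float), (node.size,))
        for ens in self.net.ensembles:
            self._ens_out[ens] = self._decode_identity(ens)
        # 2. zero accumulators
        for ens in self.net.ensembles:
            self._ens_in[ens] = np.zeros(ens.dims)
        for node in self.net.nodes:
            self._node_in[node] = np.zeros(node.size_in)
        # 3. propagate connections
        for conn in self.net.connections:
            y = self._conn_output(conn)
            y = _apply_transform(conn.transform, y)
            if conn.synapse is not None:
                y = conn.synapse.step(self._conn_state[conn], y, dt)
            sl = conn.post_slice if conn.post_slice is not None else slice(None)
            if isinstance(conn.post, Ensemble):
                self._ens_in[conn.post][sl] += y
            else:
                self._node_in[conn.post][sl] += y
        # 4. neuron updates
        for ens in self.net.ensembles:
            x = self._ens_in[ens]
            if ens.polarity == "positive":
                reach = float(np.max(x, initial=0.0))
            elif ens.polarity == "negative":
                reach = float(np.max(-x, initial=0.0))
            else:
                reach = float(np.max(np.abs(x), initial=0.0))
            if reach > self._range_max[ens]:
                self._range_max[ens] = reach
            self._update_neurons(ens, x)
        # 5. probes
        self._step_count += 1
        for p in self.net.probes:
            val = (self._decode_identity(p.target) if isinstance(p.target, Ensemble)
                   else self._node_out[p.target])
            if p.synapse is not None:
                val = p.synapse.step(self._probe_state[p], val, dt)
            every = max(1, int(round((p.sample_every or dt) / dt)))
            if self._step_count % every == 0:
                self._probe_data[p].append(np.array(val))
                self._probe_times[p].append(self._step_count * dt)

    def _conn_output(self, conn: Connection) -> np.ndarray:
        if isinstance(conn.pre, Node):
            return self._node_out[conn.pre]
        ens: Ensemble = conn.pre
        if self.mode == "rate":
            out = self._ens_out[ens]
            if conn.function is not None:
                out = np.asarray(conn.function(out), dtype=float)
            return out
        act = self._ens_state[ens]["activity"]
        return np.einsum("dk,dk->d", act, np.broadcast_to(conn.decoders, act.shape))

    def _decode_identity(self, ens: Ensemble) -> np.ndarray:
        if self.mode == "rate":
            return ens.ideal_output(self._repr_value(ens))
        act = self._ens_state[ens]["activity"]
        dec = getattr(ens, "_identity_decoders", None)
        if dec is None:
            dec = self._solve_connection_decoders(Connection(ens, ens, synapse=None))
            ens._identity_decoders = dec
        return np.einsum("dk,dk->d", act, np.broadcast_to(dec, act.shape))

    def _repr_value(self, ens: Ensemble) -> np.ndarray:
        return self._ens_in[ens]

    def _update_neurons(self, ens: Ensemble, x: np.ndarray) -> None:
        state = self._ens_state[ens]
        if self.mode == "rate":
            return  # rate mode carries the value in _ens_in directly
        xi = ens.enc * (x[:, None] / ens.radius)
        J = ens.gain * xi + ens.bias
        p = ens.neuron_params
        dt = self.dt
        if p.model_kind == "lif":
            # exact exponential integration with sub-step refractory and
            # spike-time (overshoot) correction; without it, rates at a
            # few hundred Hz are quantized to whole steps and biased low
            v = state["voltage"]
            ref = state["refractory"]
            delta_t = np.clip(dt - ref, 0.0, dt)
            v = J + (v - J) * np.exp(-delta_t / p.tau_rc)
            spiked = v > 1.0
            with np.errstate(divide="ignore", invalid="ignore"):
                overshoot = np.where(
                    spiked, p.tau_rc * np.log1p(-np.clip((v - 1.0) / np.where(J > 1, J - 1.0, np.inf), 0.0, 1.0 - 1e-12)), 0.0
                )
            t_spike = dt + overshoot  # time remaining in step after the spike
            state["activity"] = spiked / dt
            v = np.where(spiked, 0.0, np.maximum(v, 0.0))
            ref = np.maximum(ref - dt, 0.0)
            ref = np.where(spiked, p.tau_ref + t_spike - dt, ref)
            state["voltage"] = v
            state["refractory"] = ref
        else:
            rate = rectified_linear_rate(J)
            with np.errstate(invalid="ignore", over="ignore"):
                v = state["voltage"] + dt * rate
                spikes = np.floor(v)
                state["voltage"] = v - spikes
                state["activity"] = spikes / dt
        if not np.all(np.isfinite(state["activity"])):
            raise FloatingPointError(
                f"non-finite activity in {ens}; check radii and recurrent gains"
            )

    # -- results -----------------------------------------------------------

    def input_ranges(self) -> dict[str, float]:
        """Largest polarity-relevant input seen per ensemble label.

        Used to calibrate representational radii from a rate-mode run
        before building the spiking network.
        """
        return {ens.label: self._range_max[ens] for ens in self.net.ensembles}

    def collect(self) -> dict[Probe, ProbeTrace]:
        return {
            p: ProbeTrace(np.asarray(self._probe_times[p]), np.asarray(self._probe_data[p]))
            for p in self.net.probes
        }


def _shared_rates(ens: Ensemble, pts: np.ndarray) -> np.ndarray:
    """Activity matrix (n_eval, npp) for a shared-tuning ensemble."""
    xi = ens.enc[0][None, :] * (pts[:, None] / ens.radius)
    J = ens.gain[0][None, :] * xi + ens.bias[0][None, :]
    p = ens.neuron_params
    return _rates_from_current(J, p.model_kind, p.tau_rc, p.tau_ref)
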