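"""Two-hemisphere S-T/W-S localization network: construction and simulation.

The network mirrors the brainstem ILD circuit after the simplifications
that make it cheap on event-based hardware:

* per hemisphere, ``n_freq`` spatiotemporal-smoothing (S-T) units receive the
  ear's frequency channels through a single binomial smoothing kernel;
* per hemisphere and band, ``n_tunings`` weighted-summation (W-S) units — the
  LSO analogues — receive one excitatory one-to-one edge from the ipsilateral
  S-T unit and one inhibitory one-to-one edge from the contralateral S-T unit
  of the same band, with complementary weight ladders
  {1/(p+1), ..., p/(p+1)} (ipsi) and {p/(p+1), ..., 1/(p+1)} (contra);
* the MNTB relay that biologically converts contralateral excitation into
  ipsilateral inhibition is eliminated and absorbed into the direct
  inhibitory edge (see :func:`eliminate_relays`).

Kernel fan-ins are stored as explicit per-edge weights, never as a
convolution, because distributed event-based hardware has no convolution
primitive; the simulator compiles the edge list into sparse matrices purely
for speed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import scipy.sparse as sp

from .neurons import (
    ActivationSpec,
    RateNeuronParams,
    SpikingNeuronParams,
    activation,
)
from .stimuli import SpikeTrain

__all__ = [
    "NetworkSpec",
    "ConnectionKernel",
    "Unit",
    "Edge",
    "Network",
    "SimulationResult",
    "ws_weights",
    "binomial_kernel",
    "quantize_kernel",
    "build_network",
    "build_network_with_relays",
    "eliminate_relays",
    "validate_network",
    "simulate",
]

HEMISPHERES = ("L", "R")


@dataclass(frozen=True)
class NetworkSpec:
    """Declarative description of the two-hemisphere network."""

    n_freq: int = 64
    n_tunings: int = 7
    kernel_width: int = 3
    mode: str = "spiking"  # "rate" | "spiking"
    neuron_params: SpikingNeuronParams = field(default_factory=SpikingNeuronParams)
    activation: ActivationSpec = field(default_factory=ActivationSpec)

    def __post_init__(self) -> None:
        if self.n_freq < 1 or self.n_tunings < 1:
            raise ValueError("n_freq and n_tunings must be >= 1")
        if self.kernel_width < 1 or self.kernel_width % 2 == 0:
            raise ValueError("kernel_width must be odd and >= 1")
        if self.mode not in ("rate", "spiking"):
            raise ValueError(f"mode must be 'rate' or 'spiking', got {self.mode!r}")

    @property
    def rate_params(self) -> RateNeuronParams:
        return self.neuron_params.base


@dataclass(frozen=True)
class ConnectionKernel:
    """Weight vector over frequency-band offsets, tagged exc/inh."""

    weights: np.ndarray
    type: str = "exc"

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if np.any(w < 0):
            raise ValueError("kernel weights must be non-negative")
        if self.type not in ("exc", "inh"):
            raise ValueError("kernel type must be 'exc' or 'inh'")

    @property
    def width(self) -> int:
        return int(self.weights.size)


@dataclass(frozen=True)
class Unit:
    """A network node.  ``transfer`` is 'neuron' or 'linear' (pure relay)."""

    id: str
    hemisphere: str
    kind: str  # "st" | "ws" | "relay"
    band: int
    tuning: int | None = None
    transfer: str = "neuron"


@dataclass(frozen=True)
class Edge:
    """A typed, weighted connection; ``conn`` records the motif it came from."""

    src: str
    dst: str
    weight: float
    sign: str  # "exc" | "inh"
    conn: str  # "one_to_one" | "kernel"
    bundle: str | None = None


@dataclass
class Network:
    spec: NetworkSpec
    inputs: list[str]
    units: list[Unit]
    edges: list[Edge]

    @property
    def n_units(self) -> int:
        return len(self.units)

    def unit_ids(self) -> list[str]:
        return [u.id for u in self.units]

    def input_index(self, hemisphere: str, band: int) -> int:
        return self.inputs.index(f"{hemisphere}:in:{band}")

    def to_json(self) -> str:
        doc = {
            "spec": {
                "n_freq": self.spec.n_freq,
                "n_tunings": self.spec.n_tunings,
                "kernel_width": self.spec.kernel_width,
                "mode": self.spec.mode,
                "neuron_params": asdict(self.spec.neuron_params),
                "activation": asdict(self.spec.activation),
            },
            "inputs": self.inputs,
            "units": [asdict(u) for u in self.units],
            "edges": [asdict(e) for e in self.edges],
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "Network":
        doc = json.loads(text)
        sp_doc = doc["spec"]
        np_doc = sp_doc["neuron_params"]
        base = RateNeuronParams(**np_doc.pop("base"))
        spec = NetworkSpec(
            n_freq=sp_doc["n_freq"],
            n_tunings=sp_doc["n_tunings"],
            kernel_width=sp_doc["kernel_width"],
            mode=sp_doc["mode"],
            neuron_params=SpikingNeuronParams(base=base, **np_doc),
            activation=ActivationSpec(**sp_doc["activation"]),
        )
        return cls(
            spec=spec,
            inputs=list(doc["inputs"]),
            units=[Unit(**u) for u in doc["units"]],
            edges=[Edge(**e) for e in doc["edges"]],
        )


def ws_weights(n_tunings: int) -> tuple[np.ndarray, np.ndarray]:
    """Complementary ipsi/contra weight ladders for the W-S population.

    For p tunings, ipsi = (1/(p+1), ..., p/(p+1)) and contra is its
    reversal, so ipsi[j] + contra[j] = 1 for every tuning.
    """
    if n_tunings < 1:
        raise ValueError("n_tunings must be >= 1")
    p = n_tunings
    ipsi = np.arange(1, p + 1) / (p + 1)
    return ipsi, ipsi[::-1].copy()


def binomial_kernel(width: int, type: str = "exc") -> ConnectionKernel:
    """Normalized binomial smoothing kernel of odd ``width``."""
    if width < 1 or width % 2 == 0:
        raise ValueError(f"kernel width must be odd and >= 1, got {width}")
    row = np.array([math.comb(width - 1, k) for k in range(width)], dtype=float)
    return ConnectionKernel(weights=row / row.sum(), type=type)


def quantize_kernel(
    kernel: ConnectionKernel, max_level: int
) -> tuple[ConnectionKernel, float]:
    """Integer-quantize a kernel for fixed-resolution hardware weights.

    Each weight becomes round(w * max_level / max(w)); the returned scale
    factor minimizes the maximum absolute dequantization error over all
    scalar rescalings of that integer vector.
    """
    if max_level < 1:
        raise ValueError("max_level must be >= 1")
    w = kernel.weights
    if not np.any(w > 0):
        raise ValueError("cannot quantize an all-zero kernel")
    q = np.round(w * max_level / w.max())
    # minimax scale for |q*s - w|: the optimum is attained where two error
    # constraints meet, so scan the candidate crossings
    nz = q > 0
    candidates = list(w[nz] / q[nz])
    qi, wi = q[nz], w[nz]
    for i in range(qi.size):
        for j in range(i + 1, qi.size):
            candidates.append((wi[i] + wi[j]) / (qi[i] + qi[j]))
    scale = min(candidates, key=lambda s: np.max(np.abs(q * s - w)))
    return ConnectionKernel(weights=q, type=kernel.type), float(scale)


def _kernel_edges(
    kernel: ConnectionKernel,
    src_ids: list[str],
    dst_ids: list[str],
    sign: str,
    bundle: str,
) -> list[Edge]:
    """Explicit fan-in edge list for a kernel on a discrete band axis.

    Out-of-range offsets are dropped (zero padding at the boundaries).
    """
    half = kernel.width // 2
    edges = []
    n = len(dst_ids)
    for b in range(n):
        for k, wgt in enumerate(kernel.weights):
            src_band = b + k - half
            if 0 <= src_band < n and wgt > 0:
                edges.append(Edge(src=src_ids[src_band], dst=dst_ids[b],
                                  weight=float(wgt), sign=sign,
                                  conn="kernel", bundle=bundle))
    return edges


def build_network(spec: NetworkSpec) -> Network:
    """Assemble the simplified two-hemisphere network.

    Unit count is 2*n_freq*(1 + n_tunings): per hemisphere n_freq S-T units
    plus n_freq*n_tunings W-S units.  Input channels are virtual sources and
    are not counted as units.
    """
    kernel = binomial_kernel(spec.kernel_width)
    ipsi_w, contra_w = ws_weights(spec.n_tunings)
    inputs, units, edges = [], [], []
    for h in HEMISPHERES:
        inputs += [f"{h}:in:{b}" for b in range(spec.n_freq)]
    for h in HEMISPHERES:
        st_ids = [f"{h}:st:{b}" for b in range(spec.n_freq)]
        units += [Unit(id=i, hemisphere=h, kind="st", band=b)
                  for b, i in enumerate(st_ids)]
        edges += _kernel_edges(kernel,
                               [f"{h}:in:{b}" for b in range(spec.n_freq)],
                               st_ids, sign="exc", bundle=f"smooth:{h}")
    for h in HEMISPHERES:
        other = "R" if h == "L" else "L"
        for b in range(spec.n_freq):
            for j in range(spec.n_tunings):
                uid = f"{h}:ws:{b}:{j}"
                units.append(Unit(id=uid, hemisphere=h, kind="ws",
                                  band=b, tuning=j))
                edges.append(Edge(src=f"{h}:st:{b}", dst=uid,
                                  weight=float(ipsi_w[j]), sign="exc",
                                  conn="one_to_one"))
                edges.append(Edge(src=f"{other}:st:{b}", dst=uid,
                                  weight=float(contra_w[j]), sign="inh",
                                  conn="one_to_one"))
    return Network(spec=spec, inputs=inputs, units=units, edges=edges)


def build_network_with_relays(spec: NetworkSpec) -> Network:
    """Biologically faithful variant keeping the MNTB relay stage.

    Contralateral inhibition reaches each W-S unit through a dedicated
    linear relay (excited by the contralateral S-T unit, projecting an
    inhibitory edge), as in the brainstem circuit before simplification.
    :func:`eliminate_relays` reduces it to the direct form.
    """
    net = build_network(spec)
    edges = []
    for e in net.edges:
        if e.sign == "inh" and e.conn == "one_to_one":
            dst_unit = next(u for u in net.units if u.id == e.dst)
            rid = f"{dst_unit.hemisphere}:mntb:{dst_unit.band}:{dst_unit.tuning}"
            net.units.append(Unit(id=rid, hemisphere=dst_unit.hemisphere,
                                  kind="relay", band=dst_unit.band,
                                  tuning=dst_unit.tuning, transfer="linear"))
            edges.append(Edge(src=e.src, dst=rid, weight=1.0, sign="exc",
                              conn="one_to_one"))
            edges.append(Edge(src=rid, dst=e.dst, weight=e.weight, sign="inh",
                              conn="one_to_one"))
        else:
            edges.append(e)
    net.edges = edges
    return net


def eliminate_relays(network: Network) -> Network:
    """Absorb linear relay units into direct composed edges.

    A relay is a linear-transfer unit with exactly one incoming excitatory
    one-to-one edge and exactly one outgoing edge; it is replaced by a direct
    edge whose sign is the out-edge's and whose weight is the product of the
    two.  Chains of relays collapse completely.  Units that fail the pattern
    (e.g. multiple in-edges) are left untouched.
    """
    units = list(network.units)
    edges = list(network.edges)
    changed = True
    while changed:
        changed = False
        in_by_dst: dict[str, list[Edge]] = {}
        out_by_src: dict[str, list[Edge]] = {}
        for e in edges:
            in_by_dst.setdefault(e.dst, []).append(e)
            out_by_src.setdefault(e.src, []).append(e)
        for u in units:
            if u.transfer != "linear":
                continue
            ins = in_by_dst.get(u.id, [])
            outs = out_by_src.get(u.id, [])
            if (len(ins) == 1 and len(outs) == 1
                    and ins[0].sign == "exc" and ins[0].conn == "one_to_one"):
                e_in, e_out = ins[0], outs[0]
                edges = [e for e in edges if e is not e_in and e is not e_out]
                edges.append(Edge(src=e_in.src, dst=e_out.dst,
                                  weight=e_in.weight * e_out.weight,
                                  sign=e_out.sign, conn=e_out.conn,
                                  bundle=e_out.bundle))
                units = [x for x in units if x is not u]
                changed = True
                break
    return Network(spec=network.spec, inputs=network.inputs,
                   units=units, edges=edges)


def validate_network(network: Network) -> None:
    """Check the structural contract of a built network; raise on violation."""
    spec = network.spec
    expected = 2 * spec.n_freq * (1 + spec.n_tunings)
    if network.n_units != expected:
        raise ValueError(f"unit count {network.n_units} != {expected}")
    in_edges: dict[str, list[Edge]] = {u.id: [] for u in network.units}
    ids = set(in_edges)
    input_ids = set(network.inputs)
    for e in network.edges:
        if e.weight < 0:
            raise ValueError(f"negative weight on edge {e.src}->{e.dst}")
        if e.src not in ids and e.src not in input_ids:
            raise ValueError(f"dangling source {e.src}")
        in_edges[e.dst].append(e)
    for u in network.units:
        ins = in_edges[u.id]
        if u.kind == "st":
            bundles = {e.bundle for e in ins}
            if (len(bundles) != 1 or not all(e.conn == "kernel" for e in ins)
                    or bundles != {f"smooth:{u.hemisphere}"}):
                raise ValueError(f"S-T unit {u.id} lacks its single kernel bundle")
            if not all(e.src.startswith(f"{u.hemisphere}:in:") for e in ins):
                raise ValueError(f"S-T unit {u.id} fed from the wrong hemisphere")
        elif u.kind == "ws":
            exc = [e for e in ins if e.sign == "exc"]
            inh = [e for e in ins if e.sign == "inh"]
            other = "R" if u.hemisphere == "L" else "L"
            ok = (len(exc) == 1 and len(inh) == 1
                  and exc[0].conn == "one_to_one" and inh[0].conn == "one_to_one"
                  and exc[0].src == f"{u.hemisphere}:st:{u.band}"
                  and inh[0].src == f"{other}:st:{u.band}")
            if not ok:
                raise ValueError(f"W-S unit {u.id} violates the one-to-one pairing")


@dataclass
class SimulationResult:
    """Per-unit traces of one simulation run."""

    unit_ids: list[str]
    dt: float
    duration: float
    mode: str
    spikes: np.ndarray | None = None  # (n_units, n_steps) uint8, spiking mode
    rates: np.ndarray | None = None  # (n_units,) final output rates, rate mode

    def index(self, unit_id: str) -> int:
        return self.unit_ids.index(unit_id)

    def to_trains(self) -> list[SpikeTrain]:
        if self.spikes is None:
            raise ValueError("no spike data; run in spiking mode")
        times = np.arange(self.spikes.shape[1]) * self.dt
        return [
            SpikeTrain(unit_id=uid, times=times[self.spikes[i].astype(bool)],
                       duration=self.duration)
            for i, uid in enumerate(self.unit_ids)
        ]

    def spike_rate_hz(self, window_fraction: float = 0.5) -> np.ndarray:
        """Mean firing rate (Hz) per unit over the trailing window."""
        if self.spikes is None:
            raise ValueError("no spike data; run in spiking mode")
        n_steps = self.spikes.shape[1]
        start = n_steps - int(round(window_fraction * n_steps))
        window_ms = (n_steps - start) * self.dt
        return self.spikes[:, start:].sum(axis=1) * 1000.0 / window_ms


def _compile(network: Network) -> tuple[sp.csr_matrix, sp.csr_matrix, list[str]]:
    """Turn the edge list into exc/inh sparse matrices over [inputs, units]."""
    src_index = {s: i for i, s in enumerate(network.inputs)}
    n_in = len(network.inputs)
    for i, u in enumerate(network.units):
        src_index[u.id] = n_in + i
    unit_index = {u.id: i for i, u in enumerate(network.units)}
    n_src = n_in + len(network.units)
    mats = {}
    for sign in ("exc", "inh"):
        rows, cols, vals = [], [], []
        for e in network.edges:
            if e.sign == sign:
                rows.append(unit_index[e.dst])
                cols.append(src_index[e.src])
                vals.append(e.weight)
        mats[sign] = sp.csr_matrix(
            (vals, (rows, cols)), shape=(len(network.units), n_src)
        )
    return mats["exc"], mats["inh"], network.unit_ids()


def _poisson_spikes(rates_hz: np.ndarray, n_steps: int, dt: float,
                    rng: np.random.Generator) -> np.ndarray:
    """Bernoulli approximation to Poisson trains at fixed dt (rates in Hz)."""
    p = np.asarray(rates_hz, dtype=float) * dt / 1000.0
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("rate*dt must lie in [0, 1] per step")
    return (rng.random((n_steps, p.size)) < p[None, :]).astype(np.uint8)


def simulate(
    network: Network,
    inputs: np.ndarray,
    duration: float,
    dt: float = 0.1,
    seed: int | None = None,
) -> SimulationResult:
    """Time-step the network feed-forward (inputs -> S-T -> W-S).

    ``inputs`` covers both channels in the order ``network.inputs`` (left
    bands then right bands):

    * spiking mode — a float vector of Poisson rates in Hz (one per channel),
      a float array (n_channels, n_steps) of per-step rates, or a boolean
      array (n_channels, n_steps) of pre-generated spikes;
    * rate mode — a float vector (or per-step array) of input intensities.

    Every edge carries a one-step delay; given the same seed the result is
    bit-for-bit reproducible.
    """
    n_steps_f = duration / dt
    n_steps = int(round(n_steps_f))
    if abs(n_steps_f - n_steps) > 1e-9 or n_steps < 1:
        raise ValueError("duration must be a positive multiple of dt")
    inputs = np.asarray(inputs)
    n_in = len(network.inputs)
    if inputs.shape[0] != n_in:
        raise ValueError(
            f"inputs must cover all {n_in} channels, got shape {inputs.shape}"
        )
    if inputs.ndim == 2 and inputs.shape[1] != n_steps:
        raise ValueError("per-step inputs must span the full duration")
    W_exc, W_inh, unit_ids = _compile(network)
    if network.spec.mode == "spiking":
        return _simulate_spiking(network, inputs, n_steps, dt, seed,
                                 W_exc, W_inh, unit_ids, duration)
    return _simulate_rate(network, inputs, n_steps, dt,
                          W_exc, W_inh, unit_ids, duration)


def _simulate_spiking(network, inputs, n_steps, dt, seed,
                      W_exc, W_inh, unit_ids, duration) -> SimulationResult:
    rng = np.random.default_rng(seed)
    n_in = len(network.inputs)
    if inputs.dtype == bool or inputs.dtype == np.uint8:
        in_spikes = inputs.T.astype(np.uint8)  # (n_steps, n_in)
    elif inputs.ndim == 1:
        in_spikes = _poisson_spikes(inputs, n_steps, dt, rng)
    else:
        p = inputs.T * dt / 1000.0
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("rate*dt must lie in [0, 1] per step")
        in_spikes = (rng.random(p.shape) < p).astype(np.uint8)

    params = network.spec.neuron_params
    base = params.base
    n_units = len(unit_ids)
    v = np.zeros(n_units)
    w = np.zeros(n_units)
    g_exc = np.zeros(n_units)
    g_inh = np.zeros(n_units)
    decay_e = np.exp(-dt / params.syn_tau_exc)
    decay_i = np.exp(-dt / params.syn_tau_inh)
    spikes = np.zeros((n_units, n_steps), dtype=np.uint8)
    prev_unit_spk = np.zeros(n_units, dtype=np.uint8)
    for t in range(n_steps):
        src = np.concatenate([in_spikes[t], prev_unit_spk]).astype(float)
        g_exc = g_exc * decay_e + params.syn_increment * (W_exc @ src)
        g_inh = g_inh * decay_i + params.syn_increment * (W_inh @ src)
        b = base.alpha + g_exc + base.kappa * g_inh
        v_inf = (base.beta * g_exc - base.gamma * g_inh - w) / b
        v = v_inf + (v - v_inf) * np.exp(-b * (dt / base.tau))
        w = w + (params.adapt_coupling * v - w) * (dt / params.adapt_tau)
        fired = v >= params.threshold
        v[fired] = params.reset
        w[fired] += params.adapt_increment
        prev_unit_spk = fired.astype(np.uint8)
        spikes[:, t] = prev_unit_spk
    return SimulationResult(unit_ids=unit_ids, dt=dt, duration=duration,
                            mode="spiking", spikes=spikes)


def _simulate_rate(network, inputs, n_steps, dt,
                   W_exc, W_inh, unit_ids, duration) -> SimulationResult:
    base = network.spec.rate_params
    act = network.spec.activation
    n_units = len(unit_ids)
    linear = np.array([u.transfer == "linear" for u in network.units])
    v = np.zeros(n_units)
    out = np.zeros(n_units)
    static = inputs.ndim == 1
    for t in range(n_steps):
        in_t = inputs if static else inputs[:, t]
        src = np.concatenate([in_t.astype(float), out])
        exc = W_exc @ src
        inh = W_inh @ src
        b = base.alpha + exc + base.kappa * inh
        v_inf = (base.beta * exc - base.gamma * inh) / b
        v = v_inf + (v - v_inf) * np.exp(-b * (dt / base.tau))
        out = np.asarray(activation(v, act))
        if linear.any():
            out[linear] = exc[linear]  # relays pass their drive through
    return SimulationResult(unit_ids=unit_ids, dt=dt, duration=duration,
                            mode="rate", rates=out)
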