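"""Conductance-based rate neuron and its spiking (integrate-and-fire) mapping.

The canonical unit is a single-compartment, conductance-based rate neuron

    tau * dv/dt = -alpha*v + (beta - v)*E - (gamma + kappa*v)*I

where ``E`` and ``I`` are the summed, weighted excitatory and inhibitory
drives.  The leak pulls the state back to a resting value of 0, and the
reversal-potential structure bounds the state to (-gamma/kappa, beta) for
kappa > 0, which keeps network dynamics stable without any clipping.

The spike-based mapping keeps the same state equation, replaces the
non-linear output function by a fixed threshold with compare-and-reset,
adds a spike-triggered adaptation current, and low-pass filters incoming
spike trains into conductances with exponential synapses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "RateNeuronParams",
    "ActivationSpec",
    "SpikingNeuronParams",
    "NeuronState",
    "rate_step",
    "activation",
    "synapse_step",
    "spike_step",
    "rate_equilibrium",
]

#: default integration step (ms); the state is advanced by exponential Euler
#: (exact for conductances frozen within a step), which is unconditionally
#: stable and keeps the state inside its reversal-potential bounds even for
#: very large total conductance
DEFAULT_DT = 0.1


@dataclass(frozen=True)
class RateNeuronParams:
    """Coefficients of the conductance-based rate equation.

    Parameters
    ----------
    tau : float
        Membrane time constant in ms.
    alpha : float
        Leak conductance; drives the state back to rest at 0.
    beta : float
        Excitatory reversal bound; the state can never exceed it.
    gamma : float
        Inhibitory reversal coefficient (subtractive part of inhibition).
    kappa : float
        Divisive inhibition mix; kappa > 0 makes inhibition shunting and
        bounds the state below by -gamma/kappa.
    """

    tau: float = 10.0
    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 1.0
    kappa: float = 1.0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"tau must be positive, got {self.tau}")
        if self.alpha <= 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if self.beta <= 0:
            raise ValueError(f"beta must be positive, got {self.beta}")
        if self.gamma < 0 or self.kappa < 0:
            raise ValueError("gamma and kappa must be non-negative")


@dataclass(frozen=True)
class ActivationSpec:
    """Output non-linearity turning membrane state into a firing rate.

    ``kind`` is one of ``"relu"`` (rectification, linear above zero) or
    ``"sigmoid"`` (logistic, params ``gain`` and ``offset``).  Any member of
    the family is non-negative and non-decreasing.
    """

    kind: str = "relu"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("relu", "sigmoid"):
            raise ValueError(f"unknown activation kind {self.kind!r}")


@dataclass(frozen=True)
class SpikingNeuronParams:
    """Spiking extension: threshold/reset, adaptation and exponential synapses.

    ``adapt_coupling`` (a) and ``adapt_increment`` (b) follow the usual
    adaptive integrate-and-fire convention: between spikes the adaptation
    variable relaxes as dw/dt = (a*v - w)/adapt_tau and jumps by b at each
    emitted spike; w is subtracted from the state's drive.
    """

    base: RateNeuronParams = field(default_factory=RateNeuronParams)
    threshold: float = 0.5
    reset: float = 0.0
    adapt_increment: float = 0.05
    adapt_coupling: float = 0.0
    adapt_tau: float = 100.0
    syn_tau_exc: float = 10.0
    syn_tau_inh: float = 10.0
    syn_increment: float = 1.25

    def __post_init__(self) -> None:
        if self.threshold <= self.reset:
            raise ValueError("threshold must exceed reset")
        if min(self.adapt_tau, self.syn_tau_exc, self.syn_tau_inh) <= 0:
            raise ValueError("time constants must be positive")


@dataclass
class NeuronState:
    """Mutable per-unit state: membrane value, adaptation, conductances."""

    v: float = 0.0
    w_adapt: float = 0.0
    g_exc: float = 0.0
    g_inh: float = 0.0


def rate_step(
    state: NeuronState,
    exc: float,
    inh: float,
    params: RateNeuronParams,
    dt: float = DEFAULT_DT,
) -> NeuronState:
    """Advance the rate equation one exponential-Euler step.

    ``exc`` and ``inh`` are the already-weighted non-negative drives.  The
    equation is linear in v for fixed drives, tau*dv/dt = A - B*v with
    A = beta*exc - gamma*inh and B = alpha + exc + kappa*inh, so the step
    relaxes v exactly towards A/B with rate B/tau.  Returns a new state; no
    spiking side effects.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    if exc < 0 or inh < 0:
        raise ValueError("drives must be non-negative")
    p = params
    b = p.alpha + exc + p.kappa * inh
    v_inf = (p.beta * exc - p.gamma * inh) / b
    v = v_inf + (state.v - v_inf) * float(np.exp(-b * dt / p.tau))
    return replace(state, v=v)


def rate_equilibrium(exc: float, inh: float, params: RateNeuronParams) -> float:
    """Closed-form fixed point of the rate equation under constant drives.

    Setting dv/dt = 0 gives  v* = (beta*E - gamma*I) / (alpha + E + kappa*I).
    """
    p = params
    return (p.beta * exc - p.gamma * inh) / (p.alpha + exc + p.kappa * inh)


def activation(v, spec: ActivationSpec | None = None):
    """Map membrane state to a non-negative, non-decreasing output rate."""
    if spec is None:
        spec = ActivationSpec()
    v = np.asarray(v, dtype=float)
    if spec.kind == "relu":
        out = np.maximum(v, 0.0)
    else:  # sigmoid
        gain = spec.params.get("gain", 4.0)
        offset = spec.params.get("offset", 0.5)
        out = 1.0 / (1.0 + np.exp(-gain * (v - offset)))
    return out if out.ndim else float(out)


def synapse_step(
    g: float,
    n_spikes: int,
    weight: float,
    tau: float,
    dt: float = DEFAULT_DT,
    increment: float = 1.0,
) -> float:
    """Exponential moving average over an incoming spike stream.

    The conductance decays by exp(-dt/tau) and jumps by
    ``n_spikes * weight * increment``.  Excitatory and inhibitory streams are
    kept on separate conductances, so ``weight`` must be non-negative.
    """
    if dt <= 0 or dt > tau:
        raise ValueError("require 0 < dt <= tau")
    if n_spikes < 0:
        raise ValueError("spike count must be non-negative")
    if weight < 0:
        raise ValueError(
            "negative weight on a conductance channel; route inhibition "
            "through the inhibitory stream instead"
        )
    return g * float(np.exp(-dt / tau)) + n_spikes * weight * increment


def spike_step(
    state: NeuronState,
    params: SpikingNeuronParams,
    dt: float = DEFAULT_DT,
) -> tuple[NeuronState, bool]:
    """One step of the spiking neuron; conductances must be pre-updated.

    Integrates the rate dynamics minus the adaptation current, relaxes the
    adaptation variable, then applies compare-and-reset against the threshold.
    """
    p = params.base
    b = p.alpha + state.g_exc + p.kappa * state.g_inh
    v_inf = (p.beta * state.g_exc - p.gamma * state.g_inh
             - state.w_adapt) / b
    v = v_inf + (state.v - v_inf) * float(np.exp(-b * dt / p.tau))
    w = state.w_adapt + (
        params.adapt_coupling * state.v - state.w_adapt
    ) * (dt / params.adapt_tau)
    spiked = v >= params.threshold
    if spiked:
        v = params.reset
        w += params.adapt_increment
    return NeuronState(v=v, w_adapt=w, g_exc=state.g_exc, g_inh=state.g_inh), spiked
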