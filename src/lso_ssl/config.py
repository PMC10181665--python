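"""Experiment configuration: dataclasses mirrored one-to-one in YAML."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .neurons import ActivationSpec, RateNeuronParams, SpikingNeuronParams
from .network import NetworkSpec

__all__ = ["ExperimentConfig"]

_RATE_KEYS = ("tau", "alpha", "beta", "gamma", "kappa")


def _neuron_params_from_dict(doc: dict) -> SpikingNeuronParams:
    doc = dict(doc)
    base = RateNeuronParams(**{k: doc.pop(k) for k in _RATE_KEYS if k in doc})
    return SpikingNeuronParams(base=base, **doc)


def _neuron_params_to_dict(p: SpikingNeuronParams) -> dict:
    doc = asdict(p)
    doc.update(doc.pop("base"))
    return doc


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to rerun an experiment deterministically."""

    network: NetworkSpec = field(default_factory=NetworkSpec)
    # synthetic stimulus sweep
    base_rate: float = 2000.0  # Hz, total left+right Poisson rate
    rate_mode_drive: float = 2.0  # input intensity total in rate mode
    active_band: int = 32
    ild_grid: tuple = tuple(np.round(np.arange(-1.0, 1.01, 0.1), 10))
    duration: float = 4000.0  # ms per stimulus
    dt: float = 0.1  # ms
    seed: int = 0
    # audio front end
    f_lo: float = 100.0
    f_hi: float = 8000.0
    bin_ms: float = 1.0
    spike_prob: float = 0.5  # target peak Bernoulli probability per bin
    subsample_factor: int = 10
    # readout
    fit_band: int = 32
    fit_sound: str = "white_noise"
    penalty: float = 1.0
    threshold_zero: bool = True
    with_bias: bool = True
    rate_fraction: float = 0.5  # trailing window for rate estimates
    azimuth_grid: tuple = tuple(range(-90, 91, 10))

    def to_yaml(self, path=None) -> str:
        doc = asdict(self)
        net = doc.pop("network")
        net["neuron_params"] = _neuron_params_to_dict(self.network.neuron_params)
        net["activation"] = asdict(self.network.activation)
        doc["network"] = net
        doc["ild_grid"] = [float(x) for x in self.ild_grid]
        doc["azimuth_grid"] = [float(x) for x in self.azimuth_grid]
        text = yaml.safe_dump(doc, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "ExperimentConfig":
        if isinstance(source, (str, Path)) and Path(source).exists():
            doc = yaml.safe_load(Path(source).read_text())
        else:
            doc = yaml.safe_load(source)
        doc = dict(doc or {})
        net_doc = dict(doc.pop("network", {}))
        if "neuron_params" in net_doc:
            net_doc["neuron_params"] = _neuron_params_from_dict(
                net_doc["neuron_params"]
            )
        if "activation" in net_doc:
            net_doc["activation"] = ActivationSpec(**net_doc["activation"])
        doc["network"] = NetworkSpec(**net_doc)
        for key in ("ild_grid", "azimuth_grid"):
            if key in doc:
                doc[key] = tuple(doc[key])
        return cls(**doc)
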