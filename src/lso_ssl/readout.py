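"""Linear population readout and evidence-accumulation azimuth decoding.

Per frequency band, the readout forms a scalar estimate u = sum_p r_p * k_p
(+ bias) from the W-S rates of that band.  The weights k_p are fit once, by
least squares on a single band's responses across a training sweep, and
reused for every band.  Decoding compares each band's estimate u against the
discrete training targets u* through a clipped mismatch score
max(1 - c*|u - u*|, 0), sums the evidence across bands, and returns the
target with the largest total (ties go to the smallest target).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .stimuli import SpikeTrain

__all__ = [
    "ReadoutModel",
    "AzimuthEstimate",
    "rate_estimate",
    "readout_response",
    "fit_readout",
    "evidence",
    "estimate_azimuth",
    "decode_stimulus",
]


@dataclass(frozen=True)
class ReadoutModel:
    """Fitted readout: weights over tunings, targets, and decoder settings.

    ``penalty`` is the mismatch constant c; ``threshold_zero`` clips negative
    evidence at 0.  ``signed_mismatch`` selects the raw signed difference
    variant instead of the absolute one.  ``rank_deficient`` flags fits that
    needed a minimum-norm solution.
    """

    weights: np.ndarray
    targets: np.ndarray
    bias: float | None = None
    penalty: float = 1.0
    threshold_zero: bool = True
    signed_mismatch: bool = False
    rank_deficient: bool = False

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        t = np.asarray(self.targets, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "targets", t)
        if self.penalty < 0:
            raise ValueError("penalty must be non-negative")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("targets must be strictly increasing")

    def to_json(self) -> str:
        return json.dumps({
            "weights": self.weights.tolist(),
            "targets": self.targets.tolist(),
            "bias": self.bias,
            "penalty": self.penalty,
            "threshold_zero": self.threshold_zero,
            "signed_mismatch": self.signed_mismatch,
            "rank_deficient": self.rank_deficient,
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ReadoutModel":
        doc = json.loads(text)
        return cls(weights=np.array(doc["weights"]),
                   targets=np.array(doc["targets"]), bias=doc["bias"],
                   penalty=doc["penalty"], threshold_zero=doc["threshold_zero"],
                   signed_mismatch=doc["signed_mismatch"],
                   rank_deficient=doc["rank_deficient"])


@dataclass(frozen=True)
class AzimuthEstimate:
    """Decoded target value plus the per-band estimates it came from."""

    estimate: float
    target_index: int
    per_band: np.ndarray
    total_evidence: np.ndarray = field(default=None)  # type: ignore[assignment]


def rate_estimate(train: SpikeTrain, fraction: float = 0.5) -> float:
    """Firing rate (Hz) from the trailing ``fraction`` of a spike train.

    Using only the last part of the window excludes onset transients.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    if train.duration <= 0:
        raise ValueError("train duration must be positive")
    window_ms = fraction * train.duration
    count = int(np.count_nonzero(train.times >= train.duration - window_ms))
    return count * 1000.0 / window_ms


def readout_response(ws_rates: np.ndarray, model: ReadoutModel) -> float:
    """Per-band linear readout u = rates . weights (+ bias)."""
    rates = np.asarray(ws_rates, dtype=float)
    if rates.shape != model.weights.shape:
        raise ValueError(
            f"rate vector length {rates.size} != weights length "
            f"{model.weights.size}"
        )
    u = float(rates @ model.weights)
    if model.bias is not None:
        u += model.bias
    return u


def fit_readout(
    ws_rates_per_stimulus: np.ndarray,
    targets: np.ndarray,
    with_bias: bool = True,
    penalty: float = 1.0,
    threshold_zero: bool = True,
    signed_mismatch: bool = False,
) -> ReadoutModel:
    """Least-squares fit of the readout weights on one band's training sweep.

    Rows of ``ws_rates_per_stimulus`` are stimuli, columns tunings.  The
    decoder targets default to the sorted unique training values.  A
    rank-deficient design is solved minimum-norm and flagged.
    """
    X = np.asarray(ws_rates_per_stimulus, dtype=float)
    y = np.asarray(targets, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("need one rate vector per training target")
    design = np.hstack([X, np.ones((X.shape[0], 1))]) if with_bias else X
    if X.shape[0] < design.shape[1]:
        raise ValueError(
            f"need at least {design.shape[1]} stimuli, got {X.shape[0]}"
        )
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    deficient = rank < design.shape[1]
    bias = float(coef[-1]) if with_bias else None
    weights = coef[:-1] if with_bias else coef
    return ReadoutModel(weights=weights, targets=np.unique(y), bias=bias,
                        penalty=penalty, threshold_zero=threshold_zero,
                        signed_mismatch=signed_mismatch,
                        rank_deficient=bool(deficient))


def evidence(u: float, model: ReadoutModel) -> np.ndarray:
    """Clipped mismatch score of one band's estimate against every target.

    e_t = 1 - c*|u - u*_t| (or the signed difference if configured), clipped
    at 0 when ``threshold_zero`` is on; an exact match scores 1.
    """
    diff = u - model.targets
    if not model.signed_mismatch:
        diff = np.abs(diff)
    e = 1.0 - model.penalty * diff
    if model.threshold_zero:
        e = np.maximum(e, 0.0)
    return e


def estimate_azimuth(
    evidence_per_band: np.ndarray, model: ReadoutModel
) -> AzimuthEstimate:
    """Sum evidence across bands and pick the best-supported target.

    ``evidence_per_band`` has shape (n_bands, n_targets).  Ties break toward
    the smallest target index (np.argmax's first-maximum rule).
    """
    ev = np.atleast_2d(np.asarray(evidence_per_band, dtype=float))
    if ev.size == 0:
        raise ValueError("need evidence from at least one band")
    if ev.shape[1] != model.targets.size:
        raise ValueError("evidence columns must match the target grid")
    total = ev.sum(axis=0)
    idx = int(np.argmax(total))
    per_band = model.targets[np.argmax(ev, axis=1)]
    return AzimuthEstimate(estimate=float(model.targets[idx]),
                           target_index=idx, per_band=per_band,
                           total_evidence=total)


def decode_stimulus(
    u_per_band: np.ndarray, model: ReadoutModel
) -> AzimuthEstimate:
    """Convenience: per-band estimates -> evidence -> summed argmax."""
    u = np.atleast_1d(np.asarray(u_per_band, dtype=float))
    ev = np.stack([evidence(float(ui), model) for ui in u])
    base = estimate_azimuth(ev, model)
    return AzimuthEstimate(estimate=base.estimate,
                           target_index=base.target_index, per_band=u,
                           total_evidence=base.total_evidence)
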