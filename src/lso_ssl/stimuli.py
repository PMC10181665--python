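"""Model inputs: synthetic ILD stimuli and the cochlea-like audio front end.

Two input routes feed the localization network.  The synthetic route builds
controlled interaural-level-difference (ILD) stimuli in which a single
frequency band carries Poisson input whose left/right rates split a constant
total according to the ILD.  The audio route passes a stereo recording
through a gammatone filterbank (4th-order, ERB-spaced centre frequencies),
bins the per-channel envelope, and converts intensity to spikes with a
Bernoulli probability per time bin, optionally decimated to match the
network's operating range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.signal

__all__ = [
    "ILDStimulus",
    "SpikeTrain",
    "IntensityEnvelope",
    "synthetic_ild_stimulus",
    "ild_to_rates",
    "erb_space",
    "gammatone_filterbank",
    "intensity_to_spikes",
    "subsample_spikes",
    "trains_to_csv",
    "trains_from_csv",
    "trains_to_npz",
    "trains_from_npz",
]


@dataclass(frozen=True)
class SpikeTrain:
    """Timestamped events of one unit over a simulation window (times in ms)."""

    unit_id: str
    times: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.size and (t[0] < 0 or t[-1] >= self.duration):
            raise ValueError("spike times must lie in [0, duration)")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class ILDStimulus:
    """A single-band synthetic ILD stimulus, rates in Hz per frequency band."""

    ild: float
    left_rates: np.ndarray
    right_rates: np.ndarray
    active_band: int
    duration: float


@dataclass(frozen=True)
class IntensityEnvelope:
    """Per-band, per-bin non-negative intensity from the gammatone front end."""

    intensity: np.ndarray  # (n_bands, n_bins)
    center_frequencies: np.ndarray  # Hz
    bin_ms: float

    @property
    def n_bands(self) -> int:
        return self.intensity.shape[0]

    @property
    def duration(self) -> float:
        return self.intensity.shape[1] * self.bin_ms


def ild_to_rates(ild: float, base_rate: float) -> tuple[float, float]:
    """Complementary linear split of a constant total rate.

    left = base*(1+ild)/2, right = base*(1-ild)/2, so left+right = base for
    every ILD and ild = (left-right)/(left+right) is exactly recoverable.
    """
    if abs(ild) > 1:
        raise ValueError(f"ild must lie in [-1, 1], got {ild}")
    return base_rate * (1 + ild) / 2, base_rate * (1 - ild) / 2


def synthetic_ild_stimulus(
    ild: float,
    base_rate: float = 500.0,
    n_freq: int = 64,
    active_band: int = 32,
    duration: float = 1000.0,
) -> ILDStimulus:
    """Build a single-active-band ILD stimulus.

    Positive ILD means the left (ipsilateral) ear is louder.  All bands other
    than ``active_band`` are silent.
    """
    if base_rate <= 0:
        raise ValueError("base_rate must be positive")
    if not 0 <= active_band < n_freq:
        raise ValueError("active_band out of range")
    left, right = ild_to_rates(ild, base_rate)
    lr = np.zeros(n_freq)
    rr = np.zeros(n_freq)
    lr[active_band] = left
    rr[active_band] = right
    return ILDStimulus(ild=float(ild), left_rates=lr, right_rates=rr,
                       active_band=active_band, duration=duration)


def erb_space(f_lo: float, f_hi: float, n: int) -> np.ndarray:
    """Centre frequencies equally spaced on the ERB-rate scale (Glasberg & Moore)."""
    def hz_to_erb(f):
        return 21.4 * np.log10(1 + 0.00437 * f)

    def erb_to_hz(e):
        return (10 ** (e / 21.4) - 1) / 0.00437

    return erb_to_hz(np.linspace(hz_to_erb(f_lo), hz_to_erb(f_hi), n))


def gammatone_filterbank(
    waveform: np.ndarray,
    fs: float,
    n_channels: int = 64,
    f_lo: float = 100.0,
    f_hi: float = 8000.0,
    bin_ms: float = 1.0,
) -> IntensityEnvelope:
    """Decompose a mono waveform into per-band intensity envelopes.

    Each channel is a 4th-order IIR gammatone filter at an ERB-spaced centre
    frequency; the envelope is the RMS of the filter output within
    consecutive ``bin_ms`` windows.
    """
    if f_hi >= fs / 2:
        raise ValueError("f_hi must be below the Nyquist frequency fs/2")
    if n_channels < 1:
        raise ValueError("need at least one channel")
    waveform = np.asarray(waveform, dtype=float)
    if waveform.ndim != 1:
        raise ValueError("waveform must be mono (1-D); split stereo first")
    centers = erb_space(f_lo, f_hi, n_channels)
    samples_per_bin = max(int(round(bin_ms * fs / 1000.0)), 1)
    n_bins = waveform.size // samples_per_bin
    out = np.zeros((n_channels, n_bins))
    trimmed = waveform[: n_bins * samples_per_bin]
    for ch, fc in enumerate(centers):
        b, a = scipy.signal.gammatone(fc, "iir", fs=fs)
        y = scipy.signal.lfilter(b, a, trimmed)
        out[ch] = np.sqrt(
            np.mean(y.reshape(n_bins, samples_per_bin) ** 2, axis=1)
        )
    return IntensityEnvelope(intensity=out, center_frequencies=centers,
                             bin_ms=bin_ms)


def intensity_to_spikes(
    env: IntensityEnvelope,
    gain: float,
    seed: int | None = None,
    unit_prefix: str = "band",
) -> list[SpikeTrain]:
    """Bernoulli spike encoding: P(spike in bin) = gain * intensity.

    At most one spike per band per bin.  The caller must scale ``gain`` so
    that no probability exceeds 1.
    """
    p = gain * env.intensity
    if p.size and p.max() > 1.0:
        raise ValueError(
            f"gain * max(intensity) = {p.max():.3g} > 1; rescale the gain"
        )
    if np.any(p < 0):
        raise ValueError("intensities must be non-negative")
    rng = np.random.default_rng(seed)
    fires = rng.random(p.shape) < p
    n_bins = env.intensity.shape[1]
    bin_times = np.arange(n_bins) * env.bin_ms
    return [
        SpikeTrain(unit_id=f"{unit_prefix}{b}", times=bin_times[fires[b]],
                   duration=n_bins * env.bin_ms)
        for b in range(env.n_bands)
    ]


def subsample_spikes(train: SpikeTrain, factor: int) -> SpikeTrain:
    """Deterministic decimation: keep every ``factor``-th spike from the first."""
    if factor < 1:
        raise ValueError("factor must be a positive integer")
    return SpikeTrain(unit_id=train.unit_id, times=train.times[::factor],
                      duration=train.duration)


def trains_to_csv(trains: list[SpikeTrain], path) -> None:
    """Write spike trains as one event per row (columns unit_id, time_ms)."""
    rows = [(t.unit_id, time) for t in trains for time in t.times]
    pd.DataFrame(rows, columns=["unit_id", "time_ms"]).to_csv(path, index=False)


def trains_from_csv(path, duration: float) -> list[SpikeTrain]:
    """Read spike trains written by :func:`trains_to_csv`."""
    df = pd.read_csv(path)
    return [
        SpikeTrain(unit_id=str(uid), times=np.sort(grp["time_ms"].to_numpy()),
                   duration=duration)
        for uid, grp in df.groupby("unit_id", sort=True)
    ]


def trains_to_npz(trains: list[SpikeTrain], path) -> None:
    """Write spike trains to a compact compressed binary container."""
    arrays = {f"times/{t.unit_id}": t.times for t in trains}
    durations = np.array([t.duration for t in trains])
    np.savez_compressed(path, __durations__=durations, **arrays)


def trains_from_npz(path) -> list[SpikeTrain]:
    """Read spike trains written by :func:`trains_to_npz`."""
    with np.load(path) as doc:
        durations = doc["__durations__"]
        keys = [k for k in doc.files if k.startswith("times/")]
        return [
            SpikeTrain(unit_id=k.removeprefix("times/"), times=doc[k],
                       duration=float(d))
            for k, d in zip(keys, durations)
        ]
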