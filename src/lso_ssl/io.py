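"""File I/O: stereo WAV audio and serialized model objects."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import scipy.io.wavfile

__all__ = ["read_wav", "write_wav"]


def read_wav(path) -> tuple[np.ndarray, int]:
    """Read a WAV file to float samples in [-1, 1]; returns (data, fs).

    ``data`` has shape (n_samples,) for mono or (n_samples, n_channels).
    Integer PCM is rescaled by its dtype's full range.
    """
    fs, data = scipy.io.wavfile.read(Path(path))
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / np.iinfo(data.dtype).max
    else:
        data = data.astype(np.float64)
    return data, int(fs)


def write_wav(path, data: np.ndarray, fs: int) -> None:
    """Write float samples in [-1, 1] as 16-bit PCM WAV."""
    clipped = np.clip(np.asarray(data, dtype=np.float64), -1.0, 1.0)
    scipy.io.wavfile.write(Path(path), fs, (clipped * 32767).astype(np.int16))
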