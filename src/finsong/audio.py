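"""Audio container and RIFF WAV input/output.

Every pipeline stage consumes or produces an :class:`AudioClip`: a
single-channel pressure time series with a sampling rate and a start-time
offset.  Files are written as 16-bit PCM RIFF WAV, the format used by the
fixed autonomous recorders the pipeline emulates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile

__all__ = ["AudioClip", "read_wav", "write_wav"]

# Peak normalisation target when quantising to int16; leaves headroom so the
# dither-free quantisation never clips.
_PCM_PEAK = 0.9


@dataclass
class AudioClip:
    """A single-channel sampled pressure series.

    Parameters
    ----------
    data : ndarray
        Samples, float, arbitrary linear units.
    rate : float
        Sampling rate in samples per second.
    start_time : float
        Absolute time of the first sample in seconds (clip-local analyses
        use times referenced to this origin).
    """

    data: np.ndarray
    rate: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(np.float64)
        if self.data.ndim != 1:
            raise ValueError("AudioClip holds a single channel (1-D array)")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def duration(self) -> float:
        """Clip length in seconds."""
        return self.data.size / self.rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, referenced to ``start_time``."""
        return self.start_time + np.arange(self.data.size) / self.rate

    def scaled(self, factor: float) -> "AudioClip":
        return AudioClip(self.data * factor, self.rate, self.start_time)


def write_wav(path: str | Path, clip: AudioClip) -> None:
    """Write a clip as 16-bit PCM RIFF WAV, peak-normalised to 90% full scale.

    Normalisation preserves every ratio-based quantity downstream (SNR,
    detector thresholds are relative); the absolute scale of field
    recordings is uncalibrated anyway.
    """
    peak = np.max(np.abs(clip.data)) if clip.data.size else 0.0
    scale = (_PCM_PEAK / peak) if peak > 0 else 1.0
    pcm = np.round(clip.data * scale * 32767.0).astype(np.int16)
    wavfile.write(str(path), int(round(clip.rate)), pcm)


def read_wav(path: str | Path, start_time: float = 0.0) -> AudioClip:
    """Read a single-channel WAV into float samples in [-1, 1]."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"audio file not found: {path}")
    rate, data = wavfile.read(str(path))
    if data.ndim > 1:
        data = data[:, 0]
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    else:
        data = data.astype(np.float64)
    return AudioClip(data, float(rate), start_time)
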