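"""Short-time Fourier power spectrograms.

The measurement pipeline works on a fixed analysis grid: Hann window of
0.8 s (1.25 Hz frequency resolution) advanced in 0.4 s hops.  A coarser
0.5 s / 50%-overlap setting is kept as the plotting default only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .audio import AudioClip

__all__ = [
    "Spectrogram",
    "compute_spectrogram",
    "MEASUREMENT_WINDOW_S",
    "MEASUREMENT_HOP_S",
    "DISPLAY_WINDOW_S",
    "DISPLAY_HOP_S",
]

#: analysis grid for all measurements: 1/0.8 s = 1.25 Hz bins, 0.4 s frames
MEASUREMENT_WINDOW_S = 0.8
MEASUREMENT_HOP_S = 0.4
#: plotting default
DISPLAY_WINDOW_S = 0.5
DISPLAY_HOP_S = 0.25


@dataclass
class Spectrogram:
    """Per-frame, per-bin power on a regular time-frequency grid.

    ``power[i, j]`` is linear power (mean-square per frame, spectrum
    scaling) in frequency bin ``freqs[i]`` at frame centre ``times[j]``.
    """

    times: np.ndarray  # frame centres, seconds, referenced to clip start_time
    freqs: np.ndarray  # bin centres, Hz
    power: np.ndarray  # shape (n_freqs, n_times), linear units, >= 0
    window_length: float
    hop: float
    window: str = "hann"

    @property
    def freq_resolution(self) -> float:
        return 1.0 / self.window_length

    def band_slice(self, low: float, high: float) -> np.ndarray:
        """Boolean mask of bins whose centre lies in [low, high]."""
        return (self.freqs >= low) & (self.freqs <= high)

    def band_power_series(self, low: float, high: float) -> np.ndarray:
        """Summed in-band power per frame."""
        mask = self.band_slice(low, high)
        if not mask.any():
            raise ValueError(
                f"band [{low}, {high}] Hz contains no spectrogram bins "
                f"(range {self.freqs[0]}-{self.freqs[-1]} Hz)"
            )
        return self.power[mask].sum(axis=0)


def compute_spectrogram(
    clip: AudioClip,
    window_length: float = MEASUREMENT_WINDOW_S,
    hop: float = MEASUREMENT_HOP_S,
    window: str = "hann",
) -> Spectrogram:
    """Power spectrogram of a clip on a regular grid.

    Frame times are window centres referenced to the clip start.  Power uses
    'spectrum' scaling so that summing a frame over all bins recovers the
    mean-square of the windowed frame (Parseval, up to window gain); all
    downstream quantities are ratios or argmaxes, so the absolute scale
    convention only has to be consistent.

    Raises
    ------
    ValueError
        If the clip is shorter than one analysis window.
    """
    nperseg = int(round(window_length * clip.rate))
    nhop = int(round(hop * clip.rate))
    if nperseg < 2:
        raise ValueError("window shorter than 2 samples at this rate")
    if nhop < 1 or nhop > nperseg:
        raise ValueError("hop must be positive and no longer than the window")
    if clip.data.size < nperseg:
        raise ValueError(
            f"clip of {clip.duration:.2f} s is shorter than one "
            f"{window_length:.2f} s analysis window"
        )
    data = clip.data
    if data.dtype != np.float32:
        data = data.astype(np.float32)  # halves FFT cost; ample precision
    freqs, times, sxx = signal.spectrogram(
        data,
        fs=clip.rate,
        window=window,
        nperseg=nperseg,
        noverlap=nperseg - nhop,
        detrend=False,
        scaling="spectrum",
        mode="psd",
    )
    return Spectrogram(
        times=times + clip.start_time,
        freqs=freqs,
        power=sxx,
        window_length=nperseg / clip.rate,
        hop=nhop / clip.rate,
        window=window,
    )
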