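"""Per-note measurements and inter-note-interval (INI) series.

Implements the four selection measurements the analysis rests on —
Inband Power, SNR, Time 5% and Peak Frequency — plus the INI computation
(differences of consecutive 20 Hz-note Time-5% points within a sequence).

All measurements are computed on the measurement spectrogram (0.8 s Hann
window, 0.4 s hop), mirroring the time-frequency selection-box semantics
of interactive tools, not on raw samples.

SNR convention: the linear ratio r = (Signal Inband Power − Noise Inband
Power) / Noise Inband Power is reported in decibels as 10·log10(r)
(Inband Power is a power quantity).  A note whose selection holds no more
power than its noise companion (r ≤ 0) gets −inf, i.e. "absent".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .audio import AudioClip
from .detect import NoteSelection
from .spectrogram import Spectrogram, compute_spectrogram

__all__ = [
    "IniSeries",
    "inband_power",
    "snr",
    "noise_companion",
    "time5",
    "peak_frequency",
    "measure_selections",
    "ini_series",
    "DEFAULT_SEQUENCE_GAP_S",
    "DEFAULT_MAX_INI_S",
    "COMPANION_GUARD_S",
]

log = logging.getLogger(__name__)

#: a Time-5% difference larger than this starts a new sequence (silence)
DEFAULT_SEQUENCE_GAP_S = 60.0
#: differences above this are discarded as non-INIs even within a sequence
DEFAULT_MAX_INI_S = 35.0
#: clearance between a noise companion and its note, avoids edge leakage
COMPANION_GUARD_S = 1.0


@dataclass
class IniSeries:
    """INIs of one song: seconds between consecutive 20 Hz notes within a
    sequence, measured between their Time-5% points."""

    song_id: str
    values: list[float] = field(default_factory=list)
    note_pairs: list[tuple[int, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values)) if self.values else float("nan")

    @property
    def sd(self) -> float:
        # sample SD (n-1); undefined below 2 values
        return float(np.std(self.values, ddof=1)) if len(self.values) > 1 else float("nan")


def _selection_box(spec: Spectrogram, sel: NoteSelection):
    """Frame and bin masks of a selection's time-frequency box."""
    tmask = (spec.times >= sel.begin_time) & (spec.times <= sel.end_time)
    fmask = spec.band_slice(sel.low_freq, sel.high_freq)
    return tmask, fmask


def inband_power(spec: Spectrogram, sel: NoteSelection) -> float:
    """Summed spectrogram power over the selection's time-frequency box."""
    tmask, fmask = _selection_box(spec, sel)
    if not tmask.any() or not fmask.any():
        raise ValueError(
            f"selection [{sel.begin_time:.2f}, {sel.end_time:.2f}] s x "
            f"[{sel.low_freq}, {sel.high_freq}] Hz covers no spectrogram cells"
        )
    return float(spec.power[np.ix_(fmask, tmask)].sum())


def snr(signal_power: float, noise_power: float) -> float:
    """SNR in dB from signal and noise inband powers.

    r = (S − N)/N; returns 10·log10(r), or −inf when r ≤ 0 (the selection
    holds no excess power over its noise companion).
    """
    if noise_power <= 0:
        raise ValueError("noise inband power must be positive")
    r = (signal_power - noise_power) / noise_power
    if r <= 0:
        return float("-inf")
    return float(10.0 * np.log10(r))


def noise_companion(
    sel: NoteSelection,
    existing: list[NoteSelection],
    clip_start: float,
    clip_end: float,
    guard: float = COMPANION_GUARD_S,
) -> NoteSelection:
    """Place a noise selection of the same duration and band as ``sel``.

    The companion goes in the nearest interval before the note that does
    not overlap any existing detection; if no room exists before, it is
    placed after the note instead.

    Raises
    ------
    ValueError
        If no non-overlapping placement exists in the clip; the caller
        should flag and exclude the note.
    """
    d = sel.duration

    def clashes(begin: float, end: float) -> NoteSelection | None:
        for other in existing:
            if other is sel:
                continue
            if other.overlaps(begin - guard, end + guard):
                return other
        return None

    # walk backwards from the note
    end = sel.begin_time - guard
    while end - d >= clip_start:
        blocker = clashes(end - d, end)
        if blocker is None:
            return NoteSelection(end - d, end, sel.low_freq, sel.high_freq, kind=sel.kind)
        end = blocker.begin_time - guard
    # fall back: walk forwards after the note
    begin = sel.end_time + guard
    while begin + d <= clip_end:
        blocker = clashes(begin, begin + d)
        if blocker is None:
            return NoteSelection(begin, begin + d, sel.low_freq, sel.high_freq, kind=sel.kind)
        begin = blocker.end_time + guard
    raise ValueError("no non-overlapping noise-companion placement in clip")


def time5(spec: Spectrogram, sel: NoteSelection) -> float:
    """Time of 5% cumulative in-band energy within the selection.

    Each frame's in-band power is spread uniformly over its hop interval,
    giving a piecewise-linear cumulative energy curve; the returned instant
    divides the selection's energy 5% / 95%.  For a selection with uniform
    per-frame energy over [0, T] this is exactly 0.05·T.
    """
    tmask, fmask = _selection_box(spec, sel)
    if not tmask.any() or not fmask.any():
        raise ValueError("selection covers no spectrogram cells")
    frame_energy = spec.power[np.ix_(fmask, tmask)].sum(axis=0)
    total = frame_energy.sum()
    if total <= 0:
        raise ValueError("zero-energy selection has no Time 5%")
    centres = spec.times[tmask]
    half = spec.hop / 2.0
    # hop-interval edges, clipped to the selection box
    starts = np.clip(centres - half, sel.begin_time, sel.end_time)
    stops = np.clip(centres + half, sel.begin_time, sel.end_time)
    cum = np.concatenate([[0.0], np.cumsum(frame_energy)])
    target = 0.05 * total
    i = int(np.searchsorted(cum, target, side="right") - 1)
    i = min(i, frame_energy.size - 1)
    frac = (target - cum[i]) / frame_energy[i] if frame_energy[i] > 0 else 0.0
    t = starts[i] + frac * (stops[i] - starts[i])
    return float(np.clip(t, sel.begin_time, sel.end_time))


def peak_frequency(spec: Spectrogram, sel: NoteSelection) -> float:
    """Frequency of maximum energy within the selection.

    The bin (inside the selection band) maximising the time-summed power
    over the selection; reported at the bin centre; ties break toward the
    lower frequency.  Robust to the exact placement of the selection box.
    """
    tmask, fmask = _selection_box(spec, sel)
    if not tmask.any() or not fmask.any():
        raise ValueError("selection covers no spectrogram cells")
    profile = spec.power[np.ix_(fmask, tmask)].sum(axis=1)
    if profile.sum() <= 0:
        raise ValueError("zero-energy selection has no peak frequency")
    return float(spec.freqs[fmask][int(np.argmax(profile))])  # argmax takes first max


def measure_selections(
    clip: AudioClip,
    selections: list[NoteSelection],
    spec: Spectrogram | None = None,
) -> list[NoteSelection]:
    """Fill inband_power, snr_db, time5 and peak_freq for every selection.

    Selections whose noise companion cannot be placed are flagged
    ``no_noise_companion`` and keep snr_db=None (they are dropped later by
    the quality criteria).
    """
    if spec is None:
        spec = compute_spectrogram(clip)
    clip_start = clip.start_time
    clip_end = clip.start_time + clip.duration
    for sel in selections:
        sel.inband_power = inband_power(spec, sel)
        sel.time5 = time5(spec, sel)
        sel.peak_freq = peak_frequency(spec, sel)
        try:
            comp = noise_companion(sel, selections, clip_start, clip_end)
            noise_p = inband_power(spec, comp)
            sel.snr_db = snr(sel.inband_power, noise_p) if noise_p > 0 else float("-inf")
        except ValueError:
            sel.flags.append("no_noise_companion")
            sel.snr_db = None
    return selections


def ini_series(
    notes: list[NoteSelection],
    song_id: str = "",
    sequence_gap: float = DEFAULT_SEQUENCE_GAP_S,
    max_ini: float = DEFAULT_MAX_INI_S,
) -> IniSeries:
    """INIs between consecutive 20 Hz notes, from their Time-5% points.

    A difference larger than ``sequence_gap`` marks a silence between
    sequences and contributes no INI; differences above ``max_ini`` or
    non-positive are excluded (logged).  Fewer than two notes gives an
    empty series.
    """
    out = IniSeries(song_id=song_id)
    t5 = [n.time5 for n in notes]
    if any(t is None for t in t5):
        raise ValueError("all notes need time5 before INI computation")
    order = np.argsort(t5)
    for a, b in zip(order, order[1:]):
        diff = t5[b] - t5[a]
        if diff > sequence_gap:
            continue  # new sequence: silence, no INI
        if diff <= 0:
            log.warning("%s: non-positive INI %.3f s excluded", song_id, diff)
            continue
        if diff > max_ini:
            log.warning("%s: INI %.3f s above max_ini %.1f s excluded", song_id, diff, max_ini)
            continue
        out.values.append(float(diff))
        out.note_pairs.append((int(a), int(b)))
    return out
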