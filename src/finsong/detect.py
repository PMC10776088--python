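"""Band-limited energy detection of song notes.

The detector works on a spectrogram: the per-frame power summed over a
frequency band is compared with a running-median noise floor; runs of
frames exceeding the floor by a configurable margin become candidate note
selections.  This replaces the interactive band-limited energy detector
used in typical passive-acoustic workflows (e.g. Raven Pro) with a
deterministic, scriptable equivalent, and reads/writes the de-facto
tab-separated selection-table dialect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .spectrogram import Spectrogram

__all__ = [
    "NoteKind",
    "DetectorConfig",
    "NoteSelection",
    "detect_notes",
    "default_config",
    "selections_to_table",
    "read_selection_table",
    "write_selection_table",
]


class NoteKind:
    """Note categories: the stereotyped 20 Hz downsweep and the ~130 Hz
    upsweep (HF) component."""

    NOTE_20HZ = "NOTE_20HZ"
    NOTE_HF = "NOTE_HF"
    ALL = (NOTE_20HZ, NOTE_HF)


@dataclass
class DetectorConfig:
    """Parameters of the band-limited energy detector.

    The threshold is *relative*: frames are flagged when their in-band
    power exceeds ``threshold_db`` above a running-median noise floor, so
    detection is invariant to overall amplitude scaling of the recording.
    """

    band_low: float
    band_high: float
    threshold_db: float = 5.0
    min_duration: float = 0.3
    max_duration: float = 3.0
    merge_gap: float = 0.5
    noise_floor_window: float = 120.0
    kind: str = NoteKind.NOTE_20HZ

    def __post_init__(self) -> None:
        if not (0 < self.band_low < self.band_high):
            raise ValueError("require 0 < band_low < band_high")
        if not (0 < self.min_duration < self.max_duration):
            raise ValueError("require 0 < min_duration < max_duration")
        for name in ("merge_gap", "noise_floor_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


#: default detection bands per note kind
DEFAULT_BANDS = {
    NoteKind.NOTE_20HZ: (15.0, 30.0),
    NoteKind.NOTE_HF: (120.0, 140.0),
}


def default_config(kind: str) -> DetectorConfig:
    """Packaged defaults: 15-30 Hz for 20 Hz notes, 120-140 Hz for HF."""
    low, high = DEFAULT_BANDS[kind]
    return DetectorConfig(band_low=low, band_high=high, kind=kind)


@dataclass
class NoteSelection:
    """One detected (or annotated) note: a time-frequency box plus the
    measured quantities filled in by the measurement stage."""

    begin_time: float
    end_time: float
    low_freq: float
    high_freq: float
    kind: str = NoteKind.NOTE_20HZ
    inband_power: Optional[float] = None
    snr_db: Optional[float] = None
    time5: Optional[float] = None
    peak_freq: Optional[float] = None
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.begin_time < self.end_time:
            raise ValueError("begin_time must precede end_time")
        if not self.low_freq < self.high_freq:
            raise ValueError("low_freq must be below high_freq")

    @property
    def duration(self) -> float:
        return self.end_time - self.begin_time

    def overlaps(self, begin: float, end: float) -> bool:
        return self.begin_time < end and begin < self.end_time


def _running_median(x: np.ndarray, width: int) -> np.ndarray:
    width = max(3, min(width, x.size) | 1)  # odd, at least 3, at most n
    return ndimage.median_filter(x, size=width, mode="reflect")


def detect_notes(spec: Spectrogram, cfg: DetectorConfig) -> list[NoteSelection]:
    """Run the band-limited energy detector over one spectrogram.

    Frames whose in-band power exceeds the running-median noise floor by
    ``cfg.threshold_db`` are grouped into runs; runs separated by less than
    ``cfg.merge_gap`` are merged; runs outside the duration limits are
    dropped.  Each surviving run becomes a selection whose time bounds are
    the run bounds padded by one hop on each side (so the note's energy is
    fully inside the box) and whose frequency bounds are the config band.

    Returns selections sorted by begin time, non-overlapping.
    """
    if cfg.band_low < spec.freqs[0] or cfg.band_high > spec.freqs[-1] + 1e-9:
        raise ValueError(
            f"detector band [{cfg.band_low}, {cfg.band_high}] Hz outside "
            f"spectrogram range [{spec.freqs[0]}, {spec.freqs[-1]}] Hz"
        )
    series = spec.band_power_series(cfg.band_low, cfg.band_high)
    n = series.size
    if n == 0:
        return []
    floor_frames = int(round(cfg.noise_floor_window / spec.hop))
    floor = _running_median(series, floor_frames)
    # guard against an all-zero floor (silent clip): nothing detectable
    threshold = floor * 10.0 ** (cfg.threshold_db / 10.0)
    above = series > np.maximum(threshold, 0)
    above &= series > 0

    # frame runs -> (start_idx, stop_idx) inclusive
    runs: list[list[int]] = []
    idx = np.flatnonzero(above)
    for i in idx:
        if runs and i == runs[-1][1] + 1:
            runs[-1][1] = i
        else:
            runs.append([i, i])

    # merge runs with inter-run gap < merge_gap
    merged: list[list[int]] = []
    max_gap_frames = cfg.merge_gap / spec.hop
    for run in runs:
        if merged and (run[0] - merged[-1][1] - 1) < max_gap_frames:
            merged[-1][1] = run[1]
        else:
            merged.append(run)

    t0 = spec.times[0] - spec.window_length / 2.0  # clip start
    t_end = spec.times[-1] + spec.window_length / 2.0
    selections: list[NoteSelection] = []
    for start, stop in merged:
        # run duration = span of exceeding frame centres; an isolated
        # single-frame exceedance (span 0) never survives min_duration,
        # which suppresses almost all noise-only triggers
        begin = spec.times[start]
        end = spec.times[stop]
        if not (cfg.min_duration <= end - begin <= cfg.max_duration):
            continue
        begin = max(begin - spec.hop, t0)
        end = min(end + spec.hop, t_end)
        selections.append(
            NoteSelection(
                begin_time=begin,
                end_time=end,
                low_freq=cfg.band_low,
                high_freq=cfg.band_high,
                kind=cfg.kind,
            )
        )
    # padding can make adjacent selections touch; keep them disjoint
    for prev, cur in zip(selections, selections[1:]):
        if cur.begin_time < prev.end_time:
            mid = 0.5 * (cur.begin_time + prev.end_time)
            prev.end_time = mid
            cur.begin_time = mid
    return selections


# ---------------------------------------------------------------------------
# selection-table I/O (tab-separated, Raven-style header)

_TABLE_COLUMNS = {
    "Selection": "selection",
    "Begin Time (s)": "begin_time",
    "End Time (s)": "end_time",
    "Low Freq (Hz)": "low_freq",
    "High Freq (Hz)": "high_freq",
    "Kind": "kind",
    "Inband Power": "inband_power",
    "SNR (dB)": "snr_db",
    "Time 5% (s)": "time5",
    "Peak Freq (Hz)": "peak_freq",
}


def selections_to_table(selections: list[NoteSelection]) -> pd.DataFrame:
    """Selections as a DataFrame in selection-table column order."""
    rows = []
    for i, sel in enumerate(selections, start=1):
        rows.append(
            {
                "Selection": i,
                "Begin Time (s)": sel.begin_time,
                "End Time (s)": sel.end_time,
                "Low Freq (Hz)": sel.low_freq,
                "High Freq (Hz)": sel.high_freq,
                "Kind": sel.kind,
                "Inband Power": sel.inband_power,
                "SNR (dB)": sel.snr_db,
                "Time 5% (s)": sel.time5,
                "Peak Freq (Hz)": sel.peak_freq,
            }
        )
    return pd.DataFrame(rows, columns=list(_TABLE_COLUMNS))


def write_selection_table(path: str | Path, selections: list[NoteSelection]) -> None:
    selections_to_table(selections).to_csv(path, sep="\t", index=False)


def read_selection_table(path: str | Path) -> list[NoteSelection]:
    """Read a tab-separated selection table (package or Raven columns)."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        sel = NoteSelection(
            begin_time=float(row["Begin Time (s)"]),
            end_time=float(row["End Time (s)"]),
            low_freq=float(row["Low Freq (Hz)"]),
            high_freq=float(row["High Freq (Hz)"]),
            kind=str(row.get("Kind", NoteKind.NOTE_20HZ)),
        )
        for col, attr in [
            ("Inband Power", "inband_power"),
            ("SNR (dB)", "snr_db"),
            ("Time 5% (s)", "time5"),
            ("Peak Freq (Hz)", "peak_freq"),
        ]:
            if col in df.columns and pd.notna(row[col]):
                setattr(sel, attr, float(row[col]))
        out.append(sel)
    return out
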