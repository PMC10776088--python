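"""Song assembly: quality criteria, day-level sampling and summaries.

A "song" is the set of notes analysed from one (location, day): one note
chain (possibly spanning several sequences) kept per day, the one with the
highest mean SNR if several candidates exist.  Quality rules: notes need
SNR above 5 dB, and a chain needs at least 10 notes in series unless the
recording was heavily duty-cycled.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .detect import NoteKind, NoteSelection
from .measure import DEFAULT_MAX_INI_S, DEFAULT_SEQUENCE_GAP_S, IniSeries, ini_series

__all__ = ["Song", "QualityCriteria", "assemble_songs", "summarize_song", "songs_to_table"]

log = logging.getLogger(__name__)

#: note chains separated by more than this are distinct candidate songs of
#: a day; shorter silences (sequence gaps) stay within one candidate
SONG_SPLIT_GAP_S = 1800.0


@dataclass
class QualityCriteria:
    """Selection rules applied before a day's song is accepted."""

    min_snr_db: float = 5.0
    min_notes_in_series: int = 10
    require_single_singer: bool = False
    allow_short_series_for_duty_cycled: bool = False

    def __post_init__(self) -> None:
        if self.min_notes_in_series <= 0:
            raise ValueError("min_notes_in_series must be positive")


@dataclass
class Song:
    """One analysed song: the notes of one (location, day) plus summaries."""

    song_id: str
    location: str
    date: dt.date
    season_label: str
    notes: list[NoteSelection] = field(default_factory=list)
    ini: Optional[IniSeries] = None
    instrument: str = "AR"
    mean_ini: float = np.nan
    sd_ini: float = np.nan
    mean_f20: float = np.nan
    sd_f20: float = np.nan
    mean_fhf: float = np.nan
    sd_fhf: float = np.nan
    mean_snr_db: float = np.nan

    @property
    def n_notes(self) -> int:
        return len(self.notes)

    @property
    def n_inis(self) -> int:
        return len(self.ini) if self.ini is not None else 0


def season_of(date: dt.date) -> str:
    """The October–March singing season containing a date, labelled by its
    October year (e.g. 2003-01-15 -> '2002/2003')."""
    y = date.year if date.month >= 7 else date.year - 1
    return f"{y}/{y + 1}"


def _mean_sd(values: list[float]) -> tuple[float, float]:
    """Arithmetic mean and sample SD (n−1); SD is NaN for a single value."""
    if not values:
        return np.nan, np.nan
    arr = np.asarray(values, dtype=float)
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else np.nan
    return float(np.mean(arr)), sd


def summarize_song(
    song: Song,
    sequence_gap: float = DEFAULT_SEQUENCE_GAP_S,
    max_ini: float = DEFAULT_MAX_INI_S,
) -> Song:
    """Recompute all per-song summaries from the member notes.

    INIs pool across a day's sequences; summaries that have no supporting
    notes stay NaN (absent), never zero.
    """
    notes20 = [n for n in song.notes if n.kind == NoteKind.NOTE_20HZ]
    noteshf = [n for n in song.notes if n.kind == NoteKind.NOTE_HF]
    song.ini = ini_series(notes20, song.song_id, sequence_gap, max_ini)
    song.mean_ini, song.sd_ini = _mean_sd(song.ini.values)
    song.mean_f20, song.sd_f20 = _mean_sd(
        [n.peak_freq for n in notes20 if n.peak_freq is not None]
    )
    song.mean_fhf, song.sd_fhf = _mean_sd(
        [n.peak_freq for n in noteshf if n.peak_freq is not None]
    )
    snrs = [n.snr_db for n in song.notes if n.snr_db is not None and np.isfinite(n.snr_db)]
    song.mean_snr_db = float(np.mean(snrs)) if snrs else np.nan
    return song


def _split_candidates(notes: list[NoteSelection]) -> list[list[NoteSelection]]:
    """Split a day's notes into candidate songs at silences longer than
    SONG_SPLIT_GAP_S (sequence gaps stay within one candidate)."""
    notes = sorted(notes, key=lambda n: n.begin_time)
    chains: list[list[NoteSelection]] = []
    for note in notes:
        if chains and note.begin_time - chains[-1][-1].end_time <= SONG_SPLIT_GAP_S:
            chains[-1].append(note)
        else:
            chains.append([note])
    return chains


def _has_overlapping_chains(notes: list[NoteSelection], min_onset_gap: float = 2.0) -> bool:
    """Heuristic multi-singer flag: 20 Hz note onsets closer than
    ``min_onset_gap`` suggest two overlapping note chains."""
    t = sorted(n.begin_time for n in notes if n.kind == NoteKind.NOTE_20HZ)
    return bool(np.any(np.diff(t) < min_onset_gap)) if len(t) > 1 else False


def assemble_songs(
    selections_by_day: dict[tuple[str, dt.date], list[NoteSelection]],
    criteria: QualityCriteria | None = None,
    instruments: dict[str, str] | None = None,
) -> list[Song]:
    """Apply quality criteria and the one-song-per-day rule.

    Parameters
    ----------
    selections_by_day : mapping (location, date) -> measured selections
    criteria : quality thresholds; defaults per the packaged criteria
    instruments : optional mapping location -> instrument tag

    Notes failing ``min_snr_db`` (or without SNR) are dropped; candidate
    chains below ``min_notes_in_series`` 20 Hz notes are dropped unless
    short series are allowed (duty-cycled recordings); among surviving
    candidates of a day the one with the highest mean SNR is kept.
    """
    criteria = criteria or QualityCriteria()
    instruments = instruments or {}
    songs: list[Song] = []
    for (location, date), sels in sorted(selections_by_day.items()):
        good = [
            s
            for s in sels
            if s.snr_db is not None
            and np.isfinite(s.snr_db)
            and s.snr_db > criteria.min_snr_db
        ]
        if not good:
            continue
        candidates = []
        for chain in _split_candidates(good):
            n20 = sum(1 for n in chain if n.kind == NoteKind.NOTE_20HZ)
            if n20 < 2:
                continue
            if (
                n20 < criteria.min_notes_in_series
                and not criteria.allow_short_series_for_duty_cycled
            ):
                continue
            if criteria.require_single_singer and _has_overlapping_chains(chain):
                log.info("%s %s: candidate rejected, overlapping note chains", location, date)
                continue
            candidates.append(chain)
        if not candidates:
            continue
        best = max(
            candidates,
            key=lambda ch: np.mean([n.snr_db for n in ch if np.isfinite(n.snr_db)]),
        )
        song = Song(
            song_id=f"{location}_{date.isoformat()}",
            location=location,
            date=date,
            season_label=season_of(date),
            notes=best,
            instrument=instruments.get(location, "AR"),
        )
        songs.append(summarize_song(song))
    return songs


def songs_to_table(songs: list[Song]) -> pd.DataFrame:
    """Songs as a flat CSV-ready table."""
    rows = [
        dict(
            song_id=s.song_id,
            location=s.location,
            date=s.date.isoformat(),
            season=s.season_label,
            instrument=s.instrument,
            n_notes=s.n_notes,
            n_inis=s.n_inis,
            mean_ini=s.mean_ini,
            sd_ini=s.sd_ini,
            mean_f20=s.mean_f20,
            sd_f20=s.sd_f20,
            mean_fhf=s.mean_fhf,
            sd_fhf=s.sd_fhf,
            mean_snr_db=s.mean_snr_db,
        )
        for s in songs
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "song_id", "location", "date", "season", "instrument", "n_notes",
            "n_inis", "mean_ini", "sd_ini", "mean_f20", "sd_f20", "mean_fhf",
            "sd_fhf", "mean_snr_db",
        ],
    )
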