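"""End-to-end orchestration: synth → detect → measure → assemble →
classify → trend, reproducible from a single config and seed.

The pipeline streams song by song (audio for one song lives in memory at a
time), so full multi-season scenarios run on a small machine.  A run
directory receives the manifest, per-song selection tables, the songs CSV,
type percentages, trend JSON and a log with package version, config hash
and seed; re-running the same config and seed reproduces every CSV
bit-identically.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .audio import AudioClip, read_wav
from .classify import (
    IniTypeDef,
    SongTypeLabel,
    classify_song,
    default_ini_types,
    type_percentages,
)
from .detect import (
    DetectorConfig,
    NoteKind,
    NoteSelection,
    default_config,
    detect_notes,
    write_selection_table,
)
from .measure import measure_selections
from .songs import QualityCriteria, Song, assemble_songs, songs_to_table
from .spectrogram import compute_spectrogram
from .synth import (
    ScenarioTimeline,
    SongRecord,
    iter_scenario_songs,
    load_scenario,
)
from .trends import RESPONSES, TrendFilters, TrendFit, fit_trend, write_trend_json

__all__ = ["RunConfig", "PipelineError", "process_clip", "run_pipeline", "run_scenario"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and offending input."""

    def __init__(self, stage: str, source: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed on {source}: {cause}")
        self.stage = stage
        self.source = source


@dataclass
class RunConfig:
    """Everything a run needs; fully serialisable, hence reproducible."""

    seed: int = 0
    scenario: Optional[str] = None  # packaged name or YAML path
    input_dir: Optional[str] = None  # alternative: directory with manifest.csv + WAVs
    out_dir: str = "finsong_run"
    detector_20hz: dict = field(default_factory=dict)  # DetectorConfig overrides
    detector_hf: dict = field(default_factory=dict)
    quality: dict = field(default_factory=dict)  # QualityCriteria overrides
    ini_types: Optional[list[dict]] = None  # [{label, center, tolerance}]
    trend_filters: dict = field(default_factory=dict)  # per-response TrendFilters kwargs
    write_selection_tables: bool = True
    write_audio: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def detector(self, kind: str) -> DetectorConfig:
        cfg = default_config(kind)
        overrides = self.detector_20hz if kind == NoteKind.NOTE_20HZ else self.detector_hf
        return dataclasses.replace(cfg, **overrides)

    def criteria(self) -> QualityCriteria:
        return QualityCriteria(**self.quality)

    def types(self) -> list[IniTypeDef]:
        if self.ini_types is None:
            return default_ini_types()
        return [IniTypeDef(**t) for t in self.ini_types]


def process_clip(
    clip: AudioClip,
    cfg20: DetectorConfig | None = None,
    cfghf: DetectorConfig | None = None,
    detect_hf: bool = True,
) -> list[NoteSelection]:
    """Detect and measure all notes in one clip (both bands when the
    sampling rate reaches the HF band)."""
    spec = compute_spectrogram(clip)
    cfg20 = cfg20 or default_config(NoteKind.NOTE_20HZ)
    selections = detect_notes(spec, cfg20)
    if detect_hf:
        cfghf = cfghf or default_config(NoteKind.NOTE_HF)
        if spec.freqs[-1] >= cfghf.band_high:
            selections = sorted(
                selections + detect_notes(spec, cfghf), key=lambda s: s.begin_time
            )
    measure_selections(clip, selections, spec)
    return selections


def _iter_input_songs(input_dir: Path):
    """Yield SongRecord-like entries from a directory of WAVs + manifest."""
    manifest_path = input_dir / "manifest.csv"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.csv in {input_dir}")
    manifest = pd.read_csv(manifest_path)
    for _, row in manifest.iterrows():
        wav = Path(row["file"])
        if not wav.is_absolute():
            wav = input_dir / wav
        clip = read_wav(wav)  # raises FileNotFoundError naming the path
        yield SongRecord(
            song_id=str(row.get("song_id", wav.stem)),
            location=str(row["location"]),
            instrument=str(row.get("instrument", "AR")),
            season_label=str(row["season_label"]),
            date=dt.date.fromisoformat(str(row["date"])),
            pattern_label=str(row.get("pattern_label", "")),
            sample_rate=clip.rate,
            clip=clip,
            truth=pd.DataFrame(),
            true_ini_mean=float(row.get("true_ini_mean", np.nan)),
            true_f20=float(row.get("true_f20", np.nan)),
            true_fhf=float(row.get("true_fhf", np.nan)),
            wav_path=str(wav),
        )


@dataclass
class RunResult:
    out_dir: Path
    songs: list[Song]
    songs_table: pd.DataFrame
    labels: list[SongTypeLabel]
    percentages: pd.DataFrame
    trends: dict[str, TrendFit]
    manifest: pd.DataFrame


def run_pipeline(cfg: RunConfig) -> RunResult:
    """Execute all stages per the config and write the run directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sel_dir = out / "selections"
    if cfg.write_selection_tables:
        sel_dir.mkdir(exist_ok=True)

    if cfg.scenario is not None:
        timeline = load_scenario(cfg.scenario)
        song_iter = iter_scenario_songs(timeline, cfg.seed)
    elif cfg.input_dir is not None:
        song_iter = _iter_input_songs(Path(cfg.input_dir))
    else:
        raise PipelineError("config", "RunConfig", ValueError("need scenario or input_dir"))

    cfg20 = cfg.detector(NoteKind.NOTE_20HZ)
    cfghf = cfg.detector(NoteKind.NOTE_HF)

    selections_by_day: dict[tuple[str, dt.date], list[NoteSelection]] = {}
    instruments: dict[str, str] = {}
    manifest_rows = []
    for rec in song_iter:
        source = rec.wav_path or rec.song_id
        try:
            sels = process_clip(rec.clip, cfg20, cfghf)
        except Exception as exc:  # keep the stage and file in the message
            raise PipelineError("detect/measure", source, exc) from exc
        selections_by_day.setdefault((rec.location, rec.date), []).extend(sels)
        instruments[rec.location] = rec.instrument
        manifest_rows.append(
            dict(
                file=rec.wav_path or "", song_id=rec.song_id, location=rec.location,
                instrument=rec.instrument, season_label=rec.season_label,
                date=rec.date.isoformat(), pattern_label=rec.pattern_label,
                sample_rate=rec.sample_rate, true_ini_mean=rec.true_ini_mean,
                true_f20=rec.true_f20, true_fhf=rec.true_fhf, seed=cfg.seed,
            )
        )
        if cfg.write_selection_tables:
            write_selection_table(sel_dir / f"{rec.song_id}.txt", sels)
        rec.clip = None  # free audio before the next song

    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(out / "manifest.csv", index=False)

    try:
        songs = assemble_songs(selections_by_day, cfg.criteria(), instruments)
    except Exception as exc:
        raise PipelineError("assemble", "selections", exc) from exc
    table = songs_to_table(songs)
    table.to_csv(out / "songs.csv", index=False)

    labels = []
    for song in songs:
        if song.n_inis > 0:
            labels.append(classify_song(song, cfg.types()))
    pct = type_percentages(labels)
    pct.to_csv(out / "type_percentages.csv", index=False)

    trends: dict[str, TrendFit] = {}
    for response in RESPONSES:
        filt = TrendFilters(**cfg.trend_filters.get(response, {}))
        try:
            trends[response] = fit_trend(songs, response, filt)
        except ValueError as exc:
            log.info("trend %s not fitted: %s", response, exc)
    write_trend_json(out / "trends.json", trends)

    (out / "run.log").write_text(
        json.dumps(
            dict(
                package="finsong",
                version=__version__,
                seed=cfg.seed,
                config_hash=cfg.config_hash(),
                config=cfg.to_dict(),
                n_songs=len(songs),
            ),
            indent=2,
        )
    )
    return RunResult(
        out_dir=out, songs=songs, songs_table=table, labels=labels,
        percentages=pct, trends=trends, manifest=manifest,
    )


def songs_from_table(table: pd.DataFrame) -> list[Song]:
    """Rebuild lightweight Song objects (summaries only) from a songs CSV,
    enough for trend fitting and histograms."""
    out = []
    for _, row in table.iterrows():
        song = Song(
            song_id=str(row["song_id"]),
            location=str(row["location"]),
            date=dt.date.fromisoformat(str(row["date"])),
            season_label=str(row["season"]),
            instrument=str(row.get("instrument", "AR")),
        )
        for col in ("mean_ini", "sd_ini", "mean_f20", "sd_f20", "mean_fhf",
                    "sd_fhf", "mean_snr_db"):
            if col in table.columns:
                setattr(song, col, float(row[col]))
        out.append(song)
    return out


def assemble_from_run_dir(
    run_dir: str | Path, criteria: QualityCriteria | None = None
) -> list[Song]:
    """Re-assemble songs from a run directory's manifest and selection
    tables (the ``selections/<song_id>.txt`` files written by a run)."""
    from .detect import read_selection_table

    run_dir = Path(run_dir)
    manifest = pd.read_csv(run_dir / "manifest.csv")
    selections_by_day: dict[tuple[str, dt.date], list[NoteSelection]] = {}
    instruments: dict[str, str] = {}
    for _, row in manifest.iterrows():
        table_path = run_dir / "selections" / f"{row['song_id']}.txt"
        if not table_path.exists():
            raise FileNotFoundError(f"missing selection table {table_path}")
        sels = read_selection_table(table_path)
        key = (str(row["location"]), dt.date.fromisoformat(str(row["date"])))
        selections_by_day.setdefault(key, []).extend(sels)
        instruments[str(row["location"])] = str(row.get("instrument", "AR"))
    return assemble_songs(selections_by_day, criteria, instruments)


def run_scenario(
    scenario: str,
    seed: int,
    out_dir: str | Path,
    **config_overrides,
) -> RunResult:
    """Convenience wrapper: full pipeline on a packaged scenario."""
    cfg = RunConfig(seed=seed, scenario=scenario, out_dir=str(out_dir), **config_overrides)
    return run_pipeline(cfg)
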