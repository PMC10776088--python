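"""Seeded synthetic fin whale song generator.

Produces WAV audio and ground-truth note tables emulating fin whale songs:
stereotyped 20 Hz downswept notes (default 23→18 Hz over 1 s) and ~130 Hz
upsweep HF notes (default 0.4 s), organised in sequences with near-constant
inter-note interval (INI), embedded in red ocean-like background noise at a
calibrated per-note SNR.

Scenario timelines place songs across singing seasons (October–March) and
locations, either with per-season song-type mixtures (the rapid 19 s → 12 s
INI transition and its spatial gradient) or with linear year-drifts of INI
and note peak frequencies (the multi-year gradual changes).  Three scenario
configurations ship with the package: ``ona_transition``, ``spatial_2002``
and ``gradual_2006_2020``.

Everything is reproducible: identical (configuration, seed) gives
bit-identical audio.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterator, Optional

import numpy as np
import pandas as pd
import yaml

from .audio import AudioClip, write_wav
from .detect import DEFAULT_BANDS, NoteKind

__all__ = [
    "NoteModel",
    "IniComponent",
    "SongPattern",
    "NoiseModel",
    "SongSpec",
    "ScenarioTimeline",
    "SongRecord",
    "ScenarioDataset",
    "synth_note",
    "synth_song",
    "synth_scenario",
    "iter_scenario_songs",
    "load_scenario",
    "list_scenarios",
    "season_start_year",
    "decimal_year",
]

#: silent (noise-only) margin before the first and after the last note, so
#: noise companions and the running noise floor are well defined
LEAD_IN_S = 30.0
LEAD_OUT_S = 20.0

#: effective selection-box duration the detector produces for a note of
#: duration d is about d + 2 hops (one-hop padding each side of the run's
#: frame-centre span); the SNR calibration targets the in-box energy ratio
#: the measurement stage will actually compute
_BOX_EXTRA_S = 0.75


# ---------------------------------------------------------------------------
# models


@dataclass
class NoteModel:
    """A single note: linear chirp from f_start to f_end with raised-cosine
    taper over the first and last 10% of its duration."""

    kind: str
    f_start: float
    f_end: float
    duration: float
    source_level: float = 1.0
    freq_jitter_sd: float = 0.0  # per-note random shift of the whole sweep, Hz

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("note duration must be positive")
        if self.f_start <= 0 or self.f_end <= 0:
            raise ValueError("note frequencies must be positive")

    @property
    def center_freq(self) -> float:
        return 0.5 * (self.f_start + self.f_end)

    def shifted(self, delta_hz: float) -> "NoteModel":
        """The same sweep translated by ``delta_hz``."""
        return replace(self, f_start=self.f_start + delta_hz, f_end=self.f_end + delta_hz)


def default_note_20hz() -> NoteModel:
    return NoteModel(NoteKind.NOTE_20HZ, f_start=23.0, f_end=18.0, duration=1.0)


def default_note_hf() -> NoteModel:
    return NoteModel(NoteKind.NOTE_HF, f_start=125.0, f_end=135.0, duration=0.6)


@dataclass
class IniComponent:
    label: str
    ini_mean: float
    ini_sd: float
    weight: float

    def __post_init__(self) -> None:
        if self.ini_mean <= 0:
            raise ValueError("ini_mean must be positive")
        if self.ini_sd < 0 or self.weight < 0:
            raise ValueError("ini_sd and weight must be non-negative")


@dataclass
class SongPattern:
    """The INI structure of one song: a mixture of INI components (two
    components of nonzero weight make a hybrid pattern), arranged in
    ``n_sequences`` sequences of ``notes_per_sequence`` notes separated by
    silences of ``gap_between_sequences``."""

    ini_components: list[IniComponent]
    notes_per_sequence: int = 25
    gap_between_sequences: float = 90.0
    n_sequences: int = 4
    include_hf: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        if self.notes_per_sequence < 2:
            raise ValueError("a sequence needs at least 2 notes")
        if self.n_sequences < 1:
            raise ValueError("need at least one sequence")
        w = sum(c.weight for c in self.ini_components)
        if not self.ini_components or abs(w - 1.0) > 1e-9:
            raise ValueError("component weights must sum to 1")

    @property
    def is_hybrid(self) -> bool:
        return sum(1 for c in self.ini_components if c.weight > 0) >= 2

    @property
    def n_notes(self) -> int:
        return self.notes_per_sequence * self.n_sequences


@dataclass
class NoiseModel:
    """Red ocean-ambient background: Gaussian noise shaped to
    ``spectrum_slope`` dB/octave above ``corner_hz``, flat below.
    ``target_snr_db`` is the per-note SNR in the detection band of the
    note's kind, as the measurement stage will report it."""

    spectrum_slope: float = -3.0  # dB per octave, power
    level: float = 1.0
    target_snr_db: float = 10.0
    corner_hz: float = 5.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.target_snr_db):
            raise ValueError("target_snr_db must be finite")
        if self.level <= 0:
            raise ValueError("noise level must be positive")


# ---------------------------------------------------------------------------
# waveform synthesis


def synth_note(model: NoteModel, rate: float) -> AudioClip:
    """Synthesise one note as a tapered linear chirp.

    Raises
    ------
    ValueError
        If ``rate`` is below four times the highest sweep frequency
        (Nyquist with margin: the band must be well representable).
    """
    f_max = max(model.f_start, model.f_end)
    if rate < 4.0 * f_max:
        raise ValueError(
            f"sampling rate {rate} Hz too low for a note reaching {f_max} Hz: "
            f"need rate >= 4 x f_max = {4.0 * f_max} Hz (Nyquist margin)"
        )
    n = max(int(round(model.duration * rate)), 2)
    t = np.arange(n) / rate
    # linear instantaneous frequency f_start -> f_end; phase is its integral
    sweep = (model.f_end - model.f_start) / model.duration
    phase = 2.0 * np.pi * (model.f_start * t + 0.5 * sweep * t * t)
    x = np.sin(phase)
    # raised-cosine taper over the first/last 10% (no clicks)
    n_taper = max(int(round(0.1 * n)), 1)
    ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_taper) / n_taper))
    x[:n_taper] *= ramp
    x[-n_taper:] *= ramp[::-1]
    return AudioClip(x * model.source_level, rate)


def _shaped_noise(n: int, rate: float, noise: NoiseModel, rng: np.random.Generator):
    """Gaussian noise with the model's power spectrum.

    Returns (samples, band_msq) where band_msq maps each detection band to
    the noise mean-square power it contains (exact, from the realised
    spectrum) — the quantity the SNR calibration needs.
    """
    from scipy import fft as sfft

    nfft = sfft.next_fast_len(n)  # pad to a fast FFT size, slice back to n
    nf = nfft // 2 + 1
    freqs = np.fft.rfftfreq(nfft, d=1.0 / rate)
    # power ~ slope dB/octave above corner: P(f) = (f/corner)^(slope/10*log2(10)...)
    # slope in dB/octave: P(f)/P(corner) = 2^(slope/3.0103) per octave
    # exponent a with P ~ f^a: a = slope / (10*log10(2))
    a = noise.spectrum_slope / (10.0 * np.log10(2.0))
    shape = np.ones(nf)
    above = freqs > noise.corner_hz
    shape[above] = (freqs[above] / noise.corner_hz) ** (a / 2.0)  # amplitude
    # single precision: the dynamic range of ocean noise plus notes is far
    # below float32 limits, and the FFTs dominate generation cost
    spectrum = shape.astype(np.float32) * (
        rng.standard_normal(nf, dtype=np.float32)
        + 1j * rng.standard_normal(nf, dtype=np.float32)
    )
    spectrum[0] = 0.0
    if nfft % 2 == 0:
        spectrum[-1] = spectrum[-1].real
    x = sfft.irfft(spectrum, n=nfft)[:n]
    # normalise to the requested level (rms)
    rms = np.sqrt(np.mean(x * x))
    scale = noise.level / rms if rms > 0 else 1.0
    x *= scale
    # realised mean-square within each detection band (Parseval for irfft)
    band_msq = {}
    mag2 = np.abs(spectrum) ** 2 * scale**2
    for kind, (lo, hi) in DEFAULT_BANDS.items():
        mask = (freqs >= lo) & (freqs <= hi)
        band_msq[kind] = 2.0 * mag2[mask].sum() / (nfft * nfft)
    return x, band_msq


def _note_energy(unit_note: np.ndarray, rate: float) -> float:
    return float(np.sum(unit_note * unit_note) / rate)


def synth_song(
    pattern: SongPattern,
    notes: dict[str, NoteModel] | None,
    noise: NoiseModel,
    seed: int | np.random.Generator,
    rate: float = 250.0,
) -> tuple[AudioClip, pd.DataFrame]:
    """Synthesise one song and its ground truth.

    Note onsets advance by intervals drawn Normal(ini_mean_c, ini_sd_c),
    the component c drawn per interval with the pattern weights; sequences
    are separated by ``pattern.gap_between_sequences`` of silence.  When
    ``pattern.include_hf`` each 20 Hz note is accompanied by an HF note
    0.3 s after its onset.  Note amplitudes are calibrated so the in-band
    energy over the expected selection box exceeds the background by
    ``noise.target_snr_db``.

    Returns the clip and a ground-truth table with one row per note:
    columns note_idx, kind, sequence, onset, begin, end, component,
    true_peak_freq, ini_prev (NaN for the first 20 Hz note of a sequence
    and for HF notes).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if notes is None:
        notes = {}
    note20 = notes.get(NoteKind.NOTE_20HZ, default_note_20hz())
    notehf = notes.get(NoteKind.NOTE_HF, default_note_hf())

    weights = np.array([c.weight for c in pattern.ini_components])
    comp_idx_choices = np.arange(len(pattern.ini_components))

    # --- timeline of 20 Hz note onsets
    records = []
    onset = LEAD_IN_S
    for seq in range(pattern.n_sequences):
        if seq > 0:
            onset += pattern.gap_between_sequences
        for k in range(pattern.notes_per_sequence):
            ini_prev = np.nan
            comp_label = ""
            if k > 0:
                ci = int(rng.choice(comp_idx_choices, p=weights))
                comp = pattern.ini_components[ci]
                ini = comp.ini_mean + (rng.normal(0.0, comp.ini_sd) if comp.ini_sd > 0 else 0.0)
                ini = max(ini, note20.duration + 0.5)  # keep notes disjoint
                onset += ini
                ini_prev = ini
                comp_label = comp.label
            records.append(
                dict(kind=NoteKind.NOTE_20HZ, sequence=seq, onset=onset,
                     component=comp_label, ini_prev=ini_prev)
            )
            if pattern.include_hf:
                records.append(
                    dict(kind=NoteKind.NOTE_HF, sequence=seq, onset=onset + 0.3,
                         component=comp_label, ini_prev=np.nan)
                )

    total_dur = records[-1]["onset"] + max(note20.duration, notehf.duration) + LEAD_OUT_S
    n = int(round(total_dur * rate))
    samples, band_msq = _shaped_noise(n, rate, noise, rng)

    snr_ratio = 10.0 ** (noise.target_snr_db / 10.0)
    rows = []
    for i, rec in enumerate(records):
        model = note20 if rec["kind"] == NoteKind.NOTE_20HZ else notehf
        if model.freq_jitter_sd > 0:
            model_i = model.shifted(rng.normal(0.0, model.freq_jitter_sd))
        else:
            model_i = model
        unit = synth_note(replace(model_i, source_level=1.0), rate)
        e_unit = _note_energy(unit.data, rate)
        box_dur = model_i.duration + _BOX_EXTRA_S
        e_target = snr_ratio * band_msq[rec["kind"]] * box_dur
        amp = np.sqrt(e_target / e_unit) if e_unit > 0 else 0.0
        i0 = int(round(rec["onset"] * rate))
        i1 = min(i0 + unit.data.size, n)
        samples[i0:i1] += amp * unit.data[: i1 - i0]
        rows.append(
            dict(
                note_idx=i,
                kind=rec["kind"],
                sequence=rec["sequence"],
                onset=rec["onset"],
                begin=rec["onset"],
                end=rec["onset"] + model_i.duration,
                component=rec["component"],
                true_peak_freq=model_i.center_freq,
                ini_prev=rec["ini_prev"],
            )
        )
    truth = pd.DataFrame(rows)
    return AudioClip(samples, rate), truth


# ---------------------------------------------------------------------------
# scenarios


@dataclass
class SongSpec:
    """One location's contribution to one season."""

    location: str
    season_label: str
    n_songs: int
    instrument: str = "AR"
    include_hf: bool = False
    sample_rate: float = 250.0
    mixture: Optional[dict[str, float]] = None  # pattern label -> fraction
    f20_offset: float = 0.0  # instrument-response shift applied to audio, Hz


@dataclass
class ScenarioTimeline:
    """A full synthetic study: which song types (or drifting parameters)
    occur where and when."""

    name: str
    entries: list[SongSpec]
    patterns: dict[str, SongPattern] = field(default_factory=dict)
    note_20hz: NoteModel = field(default_factory=default_note_20hz)
    note_hf: NoteModel = field(default_factory=default_note_hf)
    noise: NoiseModel = field(default_factory=NoiseModel)
    # linear drifts (gradual scenarios); None disables a drift
    reference_year: float = 2006.75
    ini_baseline: Optional[float] = None
    ini_trend: float = 0.0
    ini_song_sd: float = 0.0
    ini_note_sd: float = 0.3
    f20_trend: float = 0.0
    f20_song_sd: float = 0.0
    fhf_trend: float = 0.0
    fhf_song_sd: float = 0.0
    song_shape: dict = field(default_factory=dict)  # notes_per_sequence etc.

    @property
    def uses_drift(self) -> bool:
        return self.ini_baseline is not None


@dataclass
class SongRecord:
    """One generated song: audio (possibly written to disk), ground truth
    and its true generating parameters."""

    song_id: str
    location: str
    instrument: str
    season_label: str
    date: dt.date
    pattern_label: str
    sample_rate: float
    clip: Optional[AudioClip]
    truth: pd.DataFrame
    true_ini_mean: float
    true_f20: float
    true_fhf: float
    wav_path: Optional[str] = None

    @property
    def decimal_year(self) -> float:
        return decimal_year(self.date)


@dataclass
class ScenarioDataset:
    name: str
    songs: list[SongRecord]
    manifest: pd.DataFrame


def season_start_year(label: str) -> int:
    """'2002/2003' -> 2002."""
    try:
        return int(label.split("/")[0])
    except (ValueError, IndexError) as exc:
        raise ValueError(f"season label {label!r} is not of the form 'YYYY/YYYY'") from exc


def decimal_year(date: dt.date) -> float:
    return date.year + (date.timetuple().tm_yday) / 365.25


def _season_dates(label: str, n: int, rng: np.random.Generator) -> list[dt.date]:
    """n distinct non-consecutive dates in Oct 1 – Mar 31 of the season."""
    start = dt.date(season_start_year(label), 10, 1)
    n_days = (dt.date(season_start_year(label) + 1, 3, 31) - start).days + 1
    even_days = np.arange(0, n_days, 2)  # every other day: never consecutive
    if n > even_days.size:
        raise ValueError(f"cannot place {n} non-consecutive songs in one season")
    chosen = np.sort(rng.choice(even_days, size=n, replace=False))
    return [start + dt.timedelta(days=int(d)) for d in chosen]


def _mixture_counts(mixture: dict[str, float], n: int) -> dict[str, int]:
    """Deterministic composition: largest-remainder apportionment of n songs
    to pattern labels."""
    labels = list(mixture)
    raw = np.array([mixture[l] for l in labels], dtype=float)
    if raw.sum() <= 0:
        raise ValueError("mixture fractions must sum to a positive value")
    raw = raw / raw.sum() * n
    counts = np.floor(raw).astype(int)
    rem = raw - counts
    for i in np.argsort(-rem)[: n - counts.sum()]:
        counts[i] += 1
    return dict(zip(labels, counts.tolist()))


def iter_scenario_songs(
    timeline: ScenarioTimeline, seed: int
) -> Iterator[SongRecord]:
    """Generate scenario songs one at a time (audio kept only per song).

    Deterministic: every song's random stream is spawned from (seed, song
    index) so the output is independent of consumption order.
    """
    shape = dict(notes_per_sequence=25, gap_between_sequences=90.0, n_sequences=4)
    shape.update(timeline.song_shape)
    root = np.random.SeedSequence(seed)
    song_counter = 0
    for entry_idx, entry in enumerate(timeline.entries):
        date_rng = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(1, entry_idx))
        )
        dates = _season_dates(entry.season_label, entry.n_songs, date_rng)
        if entry.mixture is not None:
            counts = _mixture_counts(entry.mixture, entry.n_songs)
            labels = [l for l, c in counts.items() for _ in range(c)]
            date_rng.shuffle(labels)
        else:
            labels = ["drift"] * entry.n_songs
        for j, (date, label) in enumerate(zip(dates, labels)):
            song_rng = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(2, entry_idx, j))
            )
            yield _make_song(timeline, entry, date, label, shape, song_rng)
            song_counter += 1


def _make_song(
    timeline: ScenarioTimeline,
    entry: SongSpec,
    date: dt.date,
    label: str,
    shape: dict,
    rng: np.random.Generator,
) -> SongRecord:
    year = decimal_year(date)
    note20 = timeline.note_20hz
    notehf = timeline.note_hf
    if timeline.uses_drift:
        dy = year - timeline.reference_year
        true_ini = (
            timeline.ini_baseline
            + timeline.ini_trend * dy
            + (rng.normal(0.0, timeline.ini_song_sd) if timeline.ini_song_sd > 0 else 0.0)
        )
        f20_shift = timeline.f20_trend * dy + (
            rng.normal(0.0, timeline.f20_song_sd) if timeline.f20_song_sd > 0 else 0.0
        )
        fhf_shift = timeline.fhf_trend * dy + (
            rng.normal(0.0, timeline.fhf_song_sd) if timeline.fhf_song_sd > 0 else 0.0
        )
        pattern = SongPattern(
            ini_components=[IniComponent("drift", true_ini, timeline.ini_note_sd, 1.0)],
            include_hf=entry.include_hf,
            label="drift",
            **shape,
        )
        true_f20 = note20.center_freq + f20_shift
        true_fhf = notehf.center_freq + fhf_shift
        note20 = note20.shifted(f20_shift + entry.f20_offset)
        notehf = notehf.shifted(fhf_shift)
    else:
        if label not in timeline.patterns:
            raise ValueError(f"scenario has no pattern named {label!r}")
        base = timeline.patterns[label]
        pattern = replace(base, include_hf=entry.include_hf, label=label, **shape)
        true_ini = float(
            np.sum([c.weight * c.ini_mean for c in pattern.ini_components])
        )
        true_f20 = note20.center_freq
        true_fhf = notehf.center_freq if entry.include_hf else np.nan
        note20 = note20.shifted(entry.f20_offset)

    clip, truth = synth_song(
        pattern,
        {NoteKind.NOTE_20HZ: note20, NoteKind.NOTE_HF: notehf},
        timeline.noise,
        rng,
        rate=entry.sample_rate,
    )
    song_id = f"{entry.location}_{date.isoformat()}"
    return SongRecord(
        song_id=song_id,
        location=entry.location,
        instrument=entry.instrument,
        season_label=entry.season_label,
        date=date,
        pattern_label=label,
        sample_rate=entry.sample_rate,
        clip=clip,
        truth=truth,
        true_ini_mean=true_ini,
        true_f20=true_f20,
        true_fhf=true_fhf if entry.include_hf else np.nan,
    )


def _manifest_row(rec: SongRecord, seed: int) -> dict:
    return dict(
        file=rec.wav_path or "",
        song_id=rec.song_id,
        location=rec.location,
        instrument=rec.instrument,
        season_label=rec.season_label,
        date=rec.date.isoformat(),
        pattern_label=rec.pattern_label,
        sample_rate=rec.sample_rate,
        true_ini_mean=rec.true_ini_mean,
        true_f20=rec.true_f20,
        true_fhf=rec.true_fhf,
        seed=seed,
    )


def synth_scenario(
    timeline: ScenarioTimeline,
    seed: int,
    out_dir: str | Path | None = None,
    keep_audio: bool | None = None,
) -> ScenarioDataset:
    """Materialise a scenario: every song, its ground truth, a manifest.

    With ``out_dir`` set, one WAV per (location, day) plus per-song
    ground-truth CSVs and a ``manifest.csv`` are written there; audio is
    then dropped from memory unless ``keep_audio=True``.  Without
    ``out_dir`` the clips stay in memory.

    An empty timeline yields an empty dataset and empty manifest.
    """
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    if keep_audio is None:
        keep_audio = out_path is None
    songs: list[SongRecord] = []
    rows = []
    for rec in iter_scenario_songs(timeline, seed):
        if out_path is not None:
            wav = out_path / f"{rec.song_id}.wav"
            write_wav(wav, rec.clip)
            rec.wav_path = str(wav)
            rec.truth.to_csv(out_path / f"{rec.song_id}_truth.csv", index=False)
            if not keep_audio:
                rec.clip = None
        songs.append(rec)
        rows.append(_manifest_row(rec, seed))
    manifest = pd.DataFrame(
        rows,
        columns=[
            "file", "song_id", "location", "instrument", "season_label", "date",
            "pattern_label", "sample_rate", "true_ini_mean", "true_f20",
            "true_fhf", "seed",
        ],
    )
    if out_path is not None:
        manifest.to_csv(out_path / "manifest.csv", index=False)
    return ScenarioDataset(name=timeline.name, songs=songs, manifest=manifest)


# ---------------------------------------------------------------------------
# packaged scenario configurations


def list_scenarios() -> list[str]:
    pkg = resources.files("finsong.scenarios")
    return sorted(p.name[:-5] for p in pkg.iterdir() if p.name.endswith(".yaml"))


def load_scenario(name_or_path: str | Path) -> ScenarioTimeline:
    """Load a packaged scenario by name, or any scenario YAML by path."""
    path = Path(name_or_path)
    if path.suffix in (".yaml", ".yml") and path.exists():
        text = path.read_text()
    else:
        pkg = resources.files("finsong.scenarios")
        candidate = pkg / f"{name_or_path}.yaml"
        if not candidate.is_file():
            raise ValueError(
                f"unknown scenario {name_or_path!r}; available: {', '.join(list_scenarios())}"
            )
        text = candidate.read_text()
    return timeline_from_config(yaml.safe_load(text))


def _note_from_config(cfg: dict, kind: str, fallback: NoteModel) -> NoteModel:
    if not cfg:
        return fallback
    return NoteModel(
        kind=kind,
        f_start=float(cfg.get("f_start", fallback.f_start)),
        f_end=float(cfg.get("f_end", fallback.f_end)),
        duration=float(cfg.get("duration", fallback.duration)),
        freq_jitter_sd=float(cfg.get("freq_jitter_sd", fallback.freq_jitter_sd)),
    )


def timeline_from_config(cfg: dict) -> ScenarioTimeline:
    """Build a timeline from a parsed configuration mapping (see the
    packaged YAML files for the schema)."""
    patterns = {}
    for label, pcfg in (cfg.get("patterns") or {}).items():
        comps = [
            IniComponent(
                label=str(c.get("label", label)),
                ini_mean=float(c["ini_mean"]),
                ini_sd=float(c.get("ini_sd", 0.3)),
                weight=float(c["weight"]),
            )
            for c in pcfg["components"]
        ]
        patterns[label] = SongPattern(ini_components=comps, label=label)

    entries: list[SongSpec] = []
    top_locations = cfg.get("locations") or []
    for scfg in cfg.get("seasons") or []:
        label = scfg["label"]
        loc_list = scfg.get("locations") or top_locations
        for loc in loc_list:
            entries.append(
                SongSpec(
                    location=loc["name"],
                    season_label=label,
                    n_songs=int(loc["n_songs"]),
                    instrument=str(loc.get("instrument", "AR")),
                    include_hf=bool(loc.get("include_hf", False)),
                    sample_rate=float(
                        loc.get("sample_rate", 2000.0 if loc.get("include_hf") else 250.0)
                    ),
                    mixture=loc.get("mixture", scfg.get("mixture")),
                    f20_offset=float(loc.get("f20_offset", 0.0)),
                )
            )

    drift = cfg.get("drift") or {}
    noise_cfg = cfg.get("noise") or {}
    timeline = ScenarioTimeline(
        name=str(cfg.get("name", "scenario")),
        entries=entries,
        patterns=patterns,
        note_20hz=_note_from_config(cfg.get("note_20hz"), NoteKind.NOTE_20HZ, default_note_20hz()),
        note_hf=_note_from_config(cfg.get("note_hf"), NoteKind.NOTE_HF, default_note_hf()),
        noise=NoiseModel(
            spectrum_slope=float(noise_cfg.get("spectrum_slope", -3.0)),
            level=float(noise_cfg.get("level", 1.0)),
            target_snr_db=float(noise_cfg.get("target_snr_db", 10.0)),
        ),
        song_shape=cfg.get("song") or {},
        reference_year=float(drift.get("reference_year", 2006.75)),
        ini_baseline=(float(drift["ini"]["baseline"]) if "ini" in drift else None),
        ini_trend=float(drift.get("ini", {}).get("rate", 0.0)),
        ini_song_sd=float(drift.get("ini", {}).get("song_sd", 0.0)),
        ini_note_sd=float(drift.get("ini", {}).get("note_sd", 0.3)),
        f20_trend=float(drift.get("f20", {}).get("rate", 0.0)),
        f20_song_sd=float(drift.get("f20", {}).get("song_sd", 0.0)),
        fhf_trend=float(drift.get("fhf", {}).get("rate", 0.0)),
        fhf_song_sd=float(drift.get("fhf", {}).get("song_sd", 0.0)),
    )
    return timeline
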