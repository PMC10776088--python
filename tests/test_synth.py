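"""Synthetic song generator: waveform contracts, ground truth, scenarios."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal

from finsong.audio import AudioClip, read_wav, write_wav
from finsong.detect import NoteKind
from finsong.synth import (
    IniComponent,
    NoiseModel,
    NoteModel,
    ScenarioTimeline,
    SongPattern,
    default_note_20hz,
    default_note_hf,
    list_scenarios,
    load_scenario,
    synth_note,
    synth_scenario,
    synth_song,
)


def periodogram_peak(clip: AudioClip) -> float:
    f, p = signal.periodogram(clip.data, clip.rate)
    return f[np.argmax(p)]


class TestSynthNote:
    def test_pure_tone_peak_frequency(self):
        model = NoteModel(NoteKind.NOTE_20HZ, f_start=20.0, f_end=20.0, duration=1.0)
        clip = synth_note(model, rate=250)
        assert abs(periodogram_peak(clip) - 20.0) <= 1.25

    def test_duration_within_one_sample(self):
        clip = synth_note(default_note_20hz(), rate=250)
        assert abs(clip.duration - 1.0) <= 1.0 / 250

    def test_hf_upsweep_energy_confined_to_band(self):
        model = NoteModel(NoteKind.NOTE_HF, f_start=127.0, f_end=133.0, duration=0.4)
        clip = synth_note(model, rate=2000)
        f, p = signal.periodogram(clip.data, clip.rate)
        inband = p[(f >= 120) & (f <= 140)].sum()
        assert inband / p.sum() > 0.95

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            NoteModel(NoteKind.NOTE_20HZ, f_start=20.0, f_end=20.0, duration=0.0)

    def test_rate_below_nyquist_margin_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            synth_note(default_note_20hz(), rate=80)

    def test_tapered_ends(self):
        clip = synth_note(default_note_20hz(), rate=250)
        assert abs(clip.data[0]) < 1e-6 and abs(clip.data[-1]) < 0.2


class TestSynthSong:
    def test_zero_variance_inis_exact(self):
        pattern = SongPattern(
            [IniComponent("12s", 12.0, 0.0, 1.0)], notes_per_sequence=10, n_sequences=1
        )
        _clip, truth = synth_song(pattern, None, NoiseModel(), seed=0, rate=250)
        inis = truth.ini_prev.dropna()
        assert len(inis) == 9
        assert np.allclose(inis, 12.0)

    def test_two_component_weights_recovered(self):
        pattern = SongPattern(
            [
                IniComponent("19s", 19.0, 0.1, 0.5),
                IniComponent("12s", 12.0, 0.1, 0.5),
            ],
            notes_per_sequence=201,
            n_sequences=1,
        )
        _clip, truth = synth_song(pattern, None, NoiseModel(), seed=5, rate=250)
        inis = truth.ini_prev.dropna().to_numpy()
        frac_19 = np.mean(np.abs(inis - 19.0) < 2.5)
        assert 0.4 <= frac_19 <= 0.6

    def test_include_hf_gives_both_kinds(self):
        pattern = SongPattern(
            [IniComponent("12s", 12.0, 0.0, 1.0)],
            notes_per_sequence=5,
            n_sequences=1,
            include_hf=True,
        )
        _clip, truth = synth_song(pattern, None, NoiseModel(), seed=0, rate=2000)
        assert set(truth.kind) == {NoteKind.NOTE_20HZ, NoteKind.NOTE_HF}

    def test_ini_count_per_sequence(self):
        pattern = SongPattern(
            [IniComponent("12s", 12.0, 0.2, 1.0)], notes_per_sequence=8, n_sequences=3
        )
        _clip, truth = synth_song(pattern, None, NoiseModel(), seed=2, rate=250)
        t20 = truth[truth.kind == NoteKind.NOTE_20HZ]
        for _, grp in t20.groupby("sequence"):
            assert grp.ini_prev.notna().sum() == 8 - 1

    def test_identical_seed_identical_samples(self):
        pattern = SongPattern(
            [IniComponent("12s", 12.0, 0.3, 1.0)], notes_per_sequence=5, n_sequences=1
        )
        a, _ = synth_song(pattern, None, NoiseModel(), seed=9, rate=250)
        b, _ = synth_song(pattern, None, NoiseModel(), seed=9, rate=250)
        c, _ = synth_song(pattern, None, NoiseModel(), seed=10, rate=250)
        assert np.array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SongPattern([IniComponent("x", 12.0, 0.0, 0.7)])


class TestNoiseModel:
    def test_red_spectrum_slope(self):
        from finsong.synth import _shaped_noise

        rng = np.random.default_rng(0)
        x, _ = _shaped_noise(250 * 600, 250.0, NoiseModel(spectrum_slope=-3.0), rng)
        f, p = signal.welch(x, 250.0, nperseg=4096)
        p10 = np.mean(p[(f > 9) & (f < 11)])
        p40 = np.mean(p[(f > 36) & (f < 44)])
        # two octaves above 10 Hz should be ~6 dB down
        assert 3.0 <= 10 * np.log10(p10 / p40) <= 9.0

    def test_infinite_target_snr_rejected(self):
        with pytest.raises(ValueError):
            NoiseModel(target_snr_db=float("inf"))


class TestWavRoundTrip:
    def test_write_read_preserves_rate_and_shape(self, tmp_path, small_song):
        clip, _ = small_song
        path = tmp_path / "song.wav"
        write_wav(path, clip)
        back = read_wav(path)
        assert back.rate == clip.rate
        assert back.data.size == clip.data.size
        # 16-bit quantisation: waveforms nearly proportional
        corr = np.corrcoef(back.data, clip.data)[0, 1]
        assert corr > 0.999

    def test_deterministic_wav_bytes(self, tmp_path):
        pattern = SongPattern(
            [IniComponent("12s", 12.0, 0.2, 1.0)], notes_per_sequence=4, n_sequences=1
        )
        paths = []
        for name in ("a.wav", "b.wav"):
            clip, _ = synth_song(pattern, None, NoiseModel(), seed=3, rate=250)
            p = tmp_path / name
            write_wav(p, clip)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_wav(tmp_path / "nope.wav")


class TestScenarios:
    def test_packaged_scenarios_present(self):
        names = list_scenarios()
        for expected in ("gradual_2006_2020", "ona_transition", "spatial_2002"):
            assert expected in names

    def test_unknown_scenario_lists_available(self):
        with pytest.raises(ValueError, match="gradual_2006_2020"):
            load_scenario("no_such_scenario")

    def test_empty_timeline_empty_dataset(self):
        ds = synth_scenario(ScenarioTimeline(name="empty", entries=[]), seed=0)
        assert ds.songs == []
        assert ds.manifest.empty

    def test_mixture_counts_largest_remainder(self):
        from finsong.synth import _mixture_counts

        counts = _mixture_counts({"19s": 0.91, "hybrid": 0.09}, 32)
        assert counts == {"19s": 29, "hybrid": 3}
        counts = _mixture_counts({"12s": 0.90, "hybrid": 0.10}, 32)
        assert sum(counts.values()) == 32

    def test_spatial_sw_has_no_pure_12s_songs(self):
        # southwesternmost location: hybrids present but no 12 s-type songs
        timeline = load_scenario("spatial_2002")
        sw = [e for e in timeline.entries if e.location == "SW"]
        assert sw and all("12s" not in (e.mixture or {}) for e in sw)
        from finsong.synth import _mixture_counts

        counts = _mixture_counts(sw[0].mixture, sw[0].n_songs)
        assert counts.get("12s", 0) == 0 and counts["hybrid"] > 0

    def test_scenario_songs_deterministic_and_dated(self, tmp_path):
        timeline = load_scenario("ona_transition")
        timeline.entries = [e for e in timeline.entries if e.season_label == "2004/2005"]
        timeline.entries[0].n_songs = 2
        timeline.song_shape = dict(notes_per_sequence=4, n_sequences=1)
        ds1 = synth_scenario(timeline, seed=5, out_dir=tmp_path / "a", keep_audio=False)
        ds2 = synth_scenario(timeline, seed=5, out_dir=tmp_path / "b", keep_audio=False)
        assert len(ds1.songs) == 2
        for rec in ds1.songs:
            assert rec.date.month in (10, 11, 12, 1, 2, 3)
        w1 = sorted((tmp_path / "a").glob("*.wav"))
        w2 = sorted((tmp_path / "b").glob("*.wav"))
        assert [p.read_bytes() for p in w1] == [p.read_bytes() for p in w2]
        assert (tmp_path / "a" / "manifest.csv").exists()

    def test_nonconsecutive_dates_within_location(self):
        from finsong.synth import _season_dates

        rng = np.random.default_rng(0)
        dates = _season_dates("2002/2003", 40, rng)
        diffs = np.diff([d.toordinal() for d in dates])
        assert (diffs >= 2).all()
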