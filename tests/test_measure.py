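"""Per-note measurements: inband power, SNR, Time 5%, peak frequency, INIs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from finsong.audio import AudioClip
from finsong.detect import NoteKind, NoteSelection
from finsong.measure import (
    inband_power,
    ini_series,
    noise_companion,
    peak_frequency,
    snr,
    time5,
)
from finsong.spectrogram import Spectrogram, compute_spectrogram
from finsong.synth import NoteModel, synth_note


def make_spec(power: np.ndarray, freqs=None, hop=0.4, window_length=0.8) -> Spectrogram:
    """Hand-built spectrogram: power shape (n_freqs, n_frames)."""
    n_frames = power.shape[1]
    times = window_length / 2 + hop * np.arange(n_frames)
    freqs = np.asarray(freqs if freqs is not None else [20.0], dtype=float)
    return Spectrogram(times=times, freqs=freqs, power=power.astype(float),
                       window_length=window_length, hop=hop)


def note_sel(begin, end, low=15.0, high=30.0):
    return NoteSelection(begin, end, low, high)


class TestSnr:
    def test_signal_twice_noise_is_zero_db(self):
        assert snr(2.0, 1.0) == pytest.approx(0.0)

    def test_signal_equal_noise_is_minus_inf(self):
        assert snr(1.0, 1.0) == float("-inf")

    def test_five_db_threshold_ratio(self):
        # r = 10^(5/10) = 3.1623 -> exactly 5 dB
        assert snr(4.1623, 1.0) == pytest.approx(5.0, abs=1e-3)

    def test_nonpositive_noise_rejected(self):
        with pytest.raises(ValueError):
            snr(1.0, 0.0)

    @given(st.floats(1.01, 1e6))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_monotone_in_signal(self, s):
        assert snr(s * 1.001, 1.0) > snr(s, 1.0)


class TestInbandPower:
    def test_all_zero_clip_zero_power(self):
        spec = make_spec(np.zeros((3, 10)), freqs=[15.0, 20.0, 25.0])
        assert inband_power(spec, note_sel(0.0, 4.0)) == 0.0

    def test_amplitude_doubling_quadruples_power(self):
        note = synth_note(NoteModel(NoteKind.NOTE_20HZ, 20, 20, 2.0), 250)
        clip1 = AudioClip(np.pad(note.data, 500), 250.0)
        clip2 = AudioClip(2 * np.pad(note.data, 500), 250.0)
        sel = note_sel(1.5, 4.5)
        p1 = inband_power(compute_spectrogram(clip1), sel)
        p2 = inband_power(compute_spectrogram(clip2), sel)
        assert p2 == pytest.approx(4 * p1, rel=1e-4)

    def test_tone_power_concentrated_in_its_band(self):
        t = np.arange(2000 * 10) / 2000
        clip = AudioClip(np.sin(2 * np.pi * 20 * t), 2000.0)
        spec = compute_spectrogram(clip)
        in_box = inband_power(spec, note_sel(1.0, 9.0, 15.0, 30.0))
        out_box = inband_power(spec, note_sel(1.0, 9.0, 100.0, 140.0))
        assert in_box / max(out_box, 1e-30) > 100

    def test_empty_box_rejected(self):
        spec = make_spec(np.ones((1, 10)))
        with pytest.raises(ValueError, match="no spectrogram cells"):
            inband_power(spec, note_sel(100.0, 104.0))


class TestTime5:
    def test_uniform_energy_exact_five_percent(self):
        hop = 0.4
        n = 50
        spec = make_spec(np.ones((1, n)), hop=hop)
        begin = spec.times[0] - hop / 2
        T = n * hop
        sel = note_sel(begin, begin + T)
        assert time5(spec, sel) == pytest.approx(begin + 0.05 * T, abs=1e-9)

    def test_all_energy_in_first_frame(self):
        power = np.zeros((1, 10))
        power[0, 0] = 5.0
        spec = make_spec(power)
        sel = note_sel(spec.times[0] - 0.2, spec.times[-1] + 0.2)
        t5 = time5(spec, sel)
        assert spec.times[0] - 0.2 <= t5 <= spec.times[0] + 0.2

    def test_translation_by_clip_delay(self):
        note = synth_note(NoteModel(NoteKind.NOTE_20HZ, 20, 20, 1.0), 250)
        rng = np.random.default_rng(0)
        base = 0.001 * rng.standard_normal(250 * 20)
        x = base.copy()
        x[250 * 5 : 250 * 6] += note.data
        delta = 4 * 0.4  # whole hops keep the frame grid aligned
        y = np.roll(x, int(delta * 250))
        sel_a = note_sel(4.5, 6.5)
        sel_b = note_sel(4.5 + delta, 6.5 + delta)
        t_a = time5(compute_spectrogram(AudioClip(x, 250.0)), sel_a)
        t_b = time5(compute_spectrogram(AudioClip(y, 250.0)), sel_b)
        assert t_b - t_a == pytest.approx(delta, abs=1e-6)

    def test_scaling_invariance(self, small_song, small_song_selections):
        clip, _ = small_song
        sel = small_song_selections[3]
        a = time5(compute_spectrogram(clip), sel)
        b = time5(compute_spectrogram(clip.scaled(13.7)), sel)
        assert a == pytest.approx(b, abs=1e-6)

    def test_zero_energy_selection_rejected(self):
        spec = make_spec(np.zeros((1, 10)))
        with pytest.raises(ValueError, match="[Zz]ero-energy"):
            time5(spec, note_sel(0.0, 4.0))


class TestPeakFrequency:
    def test_pure_tone_exact_bin(self):
        t = np.arange(250 * 10) / 250
        clip = AudioClip(np.sin(2 * np.pi * 20 * t), 250.0)
        spec = compute_spectrogram(clip)
        assert peak_frequency(spec, note_sel(1.0, 9.0)) == pytest.approx(20.0)

    def test_downsweep_within_sweep_range(self):
        note = synth_note(NoteModel(NoteKind.NOTE_20HZ, 23, 18, 1.0), 250)
        clip = AudioClip(np.pad(note.data, 500), 250.0)
        pf = peak_frequency(compute_spectrogram(clip), note_sel(1.5, 5.0))
        assert 18.0 - 1.25 <= pf <= 23.0 + 1.25

    def test_tie_breaks_toward_lower_frequency(self):
        power = np.zeros((3, 4))
        power[0] = 2.0  # 18.75 Hz
        power[2] = 2.0  # 21.25 Hz
        spec = make_spec(power, freqs=[18.75, 20.0, 21.25])
        sel = note_sel(0.0, 2.0)
        assert peak_frequency(spec, sel) == 18.75

    def test_scaling_invariance(self, small_song, small_song_selections):
        clip, _ = small_song
        sel = small_song_selections[2]
        a = peak_frequency(compute_spectrogram(clip), sel)
        b = peak_frequency(compute_spectrogram(clip.scaled(0.013)), sel)
        assert a == b


class TestNoiseCompanion:
    def test_isolated_note_companion_before(self):
        sel = note_sel(100.0, 101.0)
        comp = noise_companion(sel, [sel], clip_start=0.0, clip_end=200.0, guard=1.0)
        assert comp.end_time == pytest.approx(99.0)
        assert comp.duration == pytest.approx(sel.duration)
        assert (comp.low_freq, comp.high_freq) == (sel.low_freq, sel.high_freq)

    def test_blocked_before_falls_back_after(self):
        prev = note_sel(0.0, 99.5)
        sel = note_sel(100.0, 101.0)
        comp = noise_companion(sel, [prev, sel], clip_start=0.0, clip_end=200.0, guard=1.0)
        assert comp.begin_time >= sel.end_time

    def test_no_room_raises(self):
        sel = note_sel(1.0, 2.0)
        other = note_sel(2.1, 5.9)
        with pytest.raises(ValueError, match="companion"):
            noise_companion(sel, [sel, other], clip_start=0.9, clip_end=6.0, guard=0.1)

    def test_generator_snr_round_trip(self, medium_song_selections):
        snrs = [s.snr_db for s in medium_song_selections if s.snr_db is not None]
        assert abs(np.median(snrs) - 10.0) <= 1.5


class TestIniSeries:
    def test_simple_differences(self):
        notes = [note_sel(t, t + 1) for t in [10.0, 22.0, 34.0]]
        for n, t in zip(notes, [10.0, 22.0, 34.0]):
            n.time5 = t
        s = ini_series(notes)
        assert s.values == pytest.approx([12.0, 12.0])

    def test_sequence_gap_yields_no_ini(self):
        t5s = [10.0, 29.0, 41.0, 300.0, 312.0]
        notes = []
        for t in t5s:
            n = note_sel(t, t + 1)
            n.time5 = t
            notes.append(n)
        s = ini_series(notes, sequence_gap=60.0)
        assert s.values == pytest.approx([19.0, 12.0, 12.0])

    def test_single_note_empty(self):
        n = note_sel(5.0, 6.0)
        n.time5 = 5.5
        assert len(ini_series([n])) == 0

    def test_max_ini_excluded(self):
        notes = []
        for t in [0.0, 40.0, 52.0]:
            n = note_sel(t, t + 1)
            n.time5 = t
            notes.append(n)
        s = ini_series(notes, sequence_gap=60.0, max_ini=35.0)
        assert s.values == pytest.approx([12.0])

    @given(st.floats(-1e5, 1e5))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_translation_invariance(self, shift):
        t5s = [3.0, 15.5, 28.0, 40.0]
        base, moved = [], []
        for t in t5s:
            for target, offset in ((base, 0.0), (moved, shift)):
                n = note_sel(t + offset - 0.5, t + offset + 0.5)
                n.time5 = t + offset
                target.append(n)
        assert ini_series(base).values == pytest.approx(
            ini_series(moved).values, abs=1e-6
        )

    def test_round_trip_inis_within_one_hop(self, small_song, small_song_selections):
        _, truth = small_song
        sels = [s for s in small_song_selections if s.kind == NoteKind.NOTE_20HZ]
        measured = ini_series(sels).values
        true_inis = truth.ini_prev.dropna().to_numpy()
        assert len(measured) == len(true_inis)
        err = np.abs(np.array(measured) - true_inis)
        assert np.mean(err <= 0.4) >= 0.95
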