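"""Shared fixtures: small synthetic songs generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from finsong.measure import measure_selections
from finsong.pipeline import process_clip
from finsong.synth import IniComponent, NoiseModel, SongPattern, synth_song


@pytest.fixture(scope="session")
def small_song():
    """A 10-note 12 s-INI song at 250 Hz, target SNR 10 dB, fixed seed."""
    pattern = SongPattern(
        [IniComponent("12s", 12.0, 0.0, 1.0)], notes_per_sequence=10, n_sequences=1
    )
    clip, truth = synth_song(pattern, None, NoiseModel(target_snr_db=10.0), seed=7, rate=250)
    return clip, truth


@pytest.fixture(scope="session")
def small_song_selections(small_song):
    clip, _truth = small_song
    return process_clip(clip)


@pytest.fixture(scope="session")
def medium_song():
    """40 notes with INI jitter, one sequence, 250 Hz."""
    pattern = SongPattern(
        [IniComponent("12s", 12.0, 0.3, 1.0)], notes_per_sequence=40, n_sequences=1
    )
    clip, truth = synth_song(pattern, None, NoiseModel(target_snr_db=10.0), seed=11, rate=250)
    return clip, truth


@pytest.fixture(scope="session")
def medium_song_selections(medium_song):
    clip, _truth = medium_song
    return process_clip(clip)
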