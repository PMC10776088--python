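# Rapid INI transition at one location: songs with 19 s INIs replaced by
# 12 s INIs over six singing seasons, with hybrid songs (both INIs) during
# the transition peaking around 30% in 2002/2003.  Season mixtures define
# the song-type composition deterministically (largest-remainder counts).
name: ona_transition
noise:
  target_snr_db: 10.0
note_20hz: {f_start: 23.0, f_end: 18.0, duration: 1.0, freq_jitter_sd: 0.3}
song:
  notes_per_sequence: 25
  n_sequences: 4
  gap_between_sequences: 90.0
patterns:
  "19s":
    components:
      - {label: "19s", ini_mean: 19.0, ini_sd: 0.3, weight: 1.0}
  "12s":
    components:
      - {label: "12s", ini_mean: 12.0, ini_sd: 0.3, weight: 1.0}
  hybrid:
    components:
      - {label: "19s", ini_mean: 19.0, ini_sd: 0.3, weight: 0.5}
      - {label: "12s", ini_mean: 12.0, ini_sd: 0.3, weight: 0.5}
seasons:
  - label: "1999/2000"
    locations:
      - {name: SE, n_songs: 12, sample_rate: 250, mixture: {"19s": 1.0}}
  - label: "2000/2001"
    locations:
      - {name: SE, n_songs: 12, sample_rate: 250, mixture: {"19s": 0.9, hybrid: 0.1}}
  - label: "2001/2002"
    locations:
      - {name: SE, n_songs: 12, sample_rate: 250, mixture: {"19s": 0.55, hybrid: 0.2, "12s": 0.25}}
  - label: "2002/2003"
    locations:
      - {name: SE, n_songs: 40, sample_rate: 250, mixture: {"19s": 0.25, hybrid: 0.3, "12s": 0.45}}
  - label: "2003/2004"
    locations:
      - {name: SE, n_songs: 12, sample_rate: 250, mixture: {hybrid: 0.08, "12s": 0.92}}
  - label: "2004/2005"
    locations:
      - {name: SE, n_songs: 12, sample_rate: 250, mixture: {"12s": 1.0}}
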