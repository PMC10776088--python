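# Spatial gradient in the 2002/2003 singing season across six locations:
# 19 s songs dominate in the southwest (9% hybrids, no 12 s songs), 12 s
# songs dominate in the east (90% at CE, 83% at NE), hybrids most common
# (17-23%) at the central locations.
name: spatial_2002
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
  - label: "2002/2003"
    locations:
      - {name: SW, n_songs: 32, sample_rate: 250, mixture: {"19s": 0.91, hybrid: 0.09}}
      - {name: NW, n_songs: 16, sample_rate: 250, mixture: {"19s": 0.48, hybrid: 0.17, "12s": 0.35}}
      - {name: CW, n_songs: 16, sample_rate: 250, mixture: {"19s": 0.40, hybrid: 0.22, "12s": 0.38}}
      - {name: SE, n_songs: 16, sample_rate: 250, mixture: {"19s": 0.30, hybrid: 0.20, "12s": 0.50}}
      - {name: NE, n_songs: 24, sample_rate: 250, mixture: {"19s": 0.04, hybrid: 0.13, "12s": 0.83}}
      - {name: CE, n_songs: 32, sample_rate: 250, mixture: {hybrid: 0.10, "12s": 0.90}}
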