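# Gradual multi-year drift scenario: per-song true mean INI and note peak
# frequencies drift linearly with decimal year from the reference season.
# Drift rates are the scenario's configured truths; per-song and per-note
# jitter represents natural variability at reduced scale.
# The AR location carries a constant instrument-response shift of the 20 Hz
# band (+1.5 Hz), so the 20 Hz frequency trend is only clean on the
# EAR-tagged songs (instrument allow-list filter downstream).
name: gradual_2006_2020
noise:
  spectrum_slope: -3.0
  level: 1.0
  target_snr_db: 10.0
note_20hz: {f_start: 23.0, f_end: 18.0, duration: 1.0, freq_jitter_sd: 0.6}
note_hf: {f_start: 127.0, f_end: 137.0, duration: 0.6, freq_jitter_sd: 0.6}
song:
  notes_per_sequence: 25
  n_sequences: 4
  gap_between_sequences: 90.0
drift:
  reference_year: 2006.75
  ini: {baseline: 12.7, rate: 0.21, song_sd: 0.3, note_sd: 0.3}
  f20: {rate: -0.06, song_sd: 0.12}
  fhf: {rate: -0.35, song_sd: 0.3}
locations:
  - {name: Azores, instrument: EAR, include_hf: true, sample_rate: 2000, n_songs: 9}
  - {name: CelticSea, instrument: AR, include_hf: true, sample_rate: 2000, n_songs: 3, f20_offset: 1.5}
seasons:
  - {label: "2006/2007"}
  - {label: "2007/2008"}
  - {label: "2008/2009"}
  - {label: "2009/2010"}
  - {label: "2010/2011"}
  - {label: "2011/2012"}
  - {label: "2012/2013"}
  - {label: "2013/2014"}
  - {label: "2014/2015"}
  - {label: "2015/2016"}
  - {label: "2016/2017"}
  - {label: "2017/2018"}
  - {label: "2018/2019"}
  - {label: "2019/2020"}
  - {label: "2020/2021"}
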