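# Methods

This note documents the models and numerical choices behind `finsong`:
what the synthetic generator emulates, how the detector and measurements
are defined, and where genuinely open design decisions were resolved.

## Analysis grid

All measurements are computed on a short-time Fourier power spectrogram
with a 0.8 s Hann window advanced in 0.4 s hops, i.e. a 1.25 Hz × 0.4 s
time-frequency grid.  A coarser 0.5 s / 50%-overlap setting exists only as
a plotting default.  Selections are time-frequency boxes; every quantity
(Inband Power, SNR, Time 5%, Peak Frequency) is defined on the grid, not
on raw samples, mirroring the selection-box semantics of interactive
bioacoustics tools.  Frame times are window centres referenced to clip
start; 'spectrum' scaling is used, so all downstream ratios and argmaxes
are scale-convention free.

## Detector

Per-frame in-band power is compared against a running-median noise floor
(window 120 s, robust to the notes themselves) times 10^(5/10).  Runs of
exceeding frames become candidate notes; runs closer than 0.5 s merge;
a run's duration is the span of its exceeding frame centres, and runs
outside [0.3, 3] s are dropped.  The centre-span convention means an
isolated single-frame exceedance has zero duration and can never pass
`min_duration` — this is what keeps the false-alarm rate on note-free
recordings below a few percent per two-minute clip while leaving recall
at calibrated 10 dB SNR above 0.95.  Selection time bounds are the run's
centre span padded by one hop per side (the note's energy sits well inside
the box); frequency bounds are the detector band (15–30 Hz or 120–140 Hz).
Because the threshold is relative to the running floor, detection is
exactly invariant to amplitude scaling of the recording.

All detector parameters are configuration; the defaults above are package
choices (no reference values exist for them).

## Measurements

- **Inband Power** — sum of spectrogram power over the box.
- **SNR** — a noise companion selection with the note's duration and band
  is placed in the nearest clean interval before the note (1 s guard gap;
  fallback after the note; a note with no possible placement is flagged
  and excluded).  SNR = 10·log₁₀((S − N)/N) with S, N the signal and
  companion Inband Powers.  The ratio (S − N)/N is linear; the package
  applies the 5 dB quality threshold to its decibel transform
  (10·log₁₀, power quantities).  r ≤ 0 maps to −∞ ("note absent").
- **Time 5%** — each frame's in-band energy is spread uniformly over its
  hop interval, giving a piecewise-linear cumulative energy curve; Time 5%
  is where it crosses 5% of the box total.  On a uniform-energy selection
  of length T this is exactly 0.05·T.
- **Peak Frequency** — the in-band bin maximising time-summed power,
  reported at bin centre, ties broken toward the lower frequency.
- **INIs** — differences of consecutive 20 Hz-note Time-5% points.  A
  difference > 60 s (`sequence_gap`) is a silence between sequences and
  yields no INI; differences > 35 s (`max_ini`) or ≤ 0 are excluded with a
  logged reason.  Both bounds are package choices sized to the 9–19 s INI
  range the pipeline targets.

## Song assembly and typing

Notes below 5 dB SNR are dropped.  A day's notes split into candidate
songs at silences longer than 30 min; a candidate needs ≥ 10 notes in
series (waivable for heavily duty-cycled recordings, where shorter regular
series are still songs); the highest-mean-SNR candidate is the day's song.
One song per (location, day), INIs pooled across the day's sequences.
The "single singer" criterion of manual workflows cannot be verified from
one channel algorithmically; it is a generator guarantee plus an optional
flag that rejects days whose 20 Hz onsets come closer than 2 s
(overlapping chains).  Non-consecutive sampling days are a property of the
scenario designs, not a pipeline filter.

Song typing uses fixed type windows — 19 ± 2.5 s and 12 ± 2.5 s by
default, centres treated as known song types, not estimated — with a song
labelled a single type when that type holds ≥ 90% of its classified INIs,
hybrid when ≥ 2 types each hold ≥ 10% (and ≥ 5 INIs are classified),
unclassified otherwise.  The 10% / 5-INI evidence bar is the package's
operationalisation of a qualitative notion ("both INIs in variable
ratios"); both are configuration.  A histogram peak-picking helper
(0.5 s bins) suggests centres for datasets with unknown or bimodal INI
structure.  Percentages per (season, location) are over classified songs.

## Trends

The "Gaussian linear model with year as explanatory variable" is plain
OLS on (decimal year, per-song mean), one observation per song, no
weighting by per-song SD and no autocorrelation structure.  Decimal year =
year + day-of-year/365.25.  The fit reports slope, SE, adjusted R²,
two-sided slope p, and residual-vs-fitted / normal-quantile series for
assumption checks.  The 20 Hz-frequency trend is meaningful only on
recorders with a consistent low-frequency response, so `TrendFilters`
carries an instrument allow-list (plus year-range and region-exclude
filters) applied before fitting; filters only change the fitted set, never
upstream measurements.

## Synthetic songs: what is emulated, what is not

Notes are linear chirps (20 Hz note: 23→18 Hz over 1 s; HF note:
upsweep over 0.6 s, default centre 130–132 Hz) with a raised-cosine taper
over the first/last 10%.  No reference values exist for note durations or
sweep extents; these are explicit package choices that look right on a
spectrogram and are irrelevant to the pipeline's contracts.  Background
noise is Gaussian, shaped to −3 dB/octave above 5 Hz (generic red ocean
ambient).  Note amplitudes are calibrated per clip so that the SNR the
measurement stage computes — the in-box energy ratio against a
same-duration companion, box ≈ note duration + 0.75 s — matches the
configured target (default 10 dB) to within a fraction of a dB at the
median.

Scenario timelines assign songs to locations and October–March singing
seasons; dates are drawn uniformly from every other day of the season
(hence never consecutive).  Song-type mixtures are materialised as
deterministic counts (largest-remainder apportionment), so a configured
30% hybrid season contains exactly the closest realisable fraction;
only dates, INI jitter and frequency jitter are random.  Drift scenarios
move each song's true mean INI / peak frequencies linearly in decimal
year, plus per-song scatter (SD 0.3 s INI, 0.12 Hz for the 20 Hz note,
0.3 Hz HF) and per-note jitter (0.3 s INI; 0.6 Hz frequency).  The
per-note frequency jitter serves double duty as natural variability and as
dither: the peak-frequency readout is quantised to 1.25 Hz bins, and
without jitter comparable to half a bin the expected readout is a
staircase in the true frequency, which visibly attenuates a sub-bin/decade
drift such as −0.06 Hz/yr.  With 0.6 Hz jitter the residual staircase
ripple is below 0.01 Hz.

The generator does **not** emulate: propagation or multipath, instrument
response curves (beyond a constant per-instrument band offset used to
exercise the allow-list filter), seismometer channels, non-stationary
noise (shipping, storms), overlapping singers, or diel/seasonal behaviour.
Synthetic per-song scatter is smaller than field scatter, so fitted R²
runs far higher than on real data; slopes and percentages, not R², are the
calibrated quantities.  Passing round-trip tests therefore demonstrates
correctness of the measurement chain under clean, stationary conditions,
not robustness to every field contingency.

## Problem sizes and defaults

The packaged `gradual_2006_2020` scenario uses 15 seasons × 12 songs
(9 EAR + 3 AR per season) × ~100 notes per song at 2000 Hz;
`ona_transition` has 100 songs over six seasons and `spatial_2002` has
136 songs across six locations, both at 250 Hz (20 Hz notes only).  These
sizes keep a full desk reproduction to minutes while leaving slope
standard errors a small fraction of the encoded rates.

## Determinism

Every song's random stream is spawned from (scenario seed, entry index,
song index) via `numpy` seed sequences, so output is bit-identical for a
given (config, seed) and independent of consumption order.  WAV output is
16-bit PCM, peak-normalised; all pipeline quantities are ratios or
argmaxes and unaffected by normalisation.

## Known limitations

- The detector assumes the note band is mostly note-free between notes;
  continuous broadband interference inflates the running median and
  suppresses detections (by design: such periods fail manual quality
  criteria too).
- Time-5% timing inherits the 0.4 s frame grid; INI errors are well under
  one hop in clean conditions but the grid is a hard floor on timing
  resolution.
- SNR estimates use a single companion selection, as in the manual
  workflow, and carry its sampling variance (a few dB per note); per-song
  medians/means are the stable quantities.
- OLS treats songs as independent; repeated seasons per site violate this
  mildly, and no correction is applied.
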