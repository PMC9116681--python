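# Methods

## Calibration

Recordings are mono 16-bit PCM WAV.  Counts map to pressure through the
chain inverse

    p(t) [µPa] = counts(t) / 32768 · V_fs · 10^(−(M + G)/20)

with hydrophone sensitivity M (dBV/µPa), amplifier gain G (dB), and the
recorder full-scale voltage V_fs.  The symmetric full scale (32768, not
32767) is the standard PCM convention; the difference is under 0.001 dB.
V_fs is not derivable from the recording itself and is a required config
field.  An analog high-pass in a recording chain (e.g. 100 Hz ahead of a
boat-noise recorder) is recorded as metadata but not re-applied
digitally: the lowest analysis band edge (≈446 Hz) is far above any such
cutoff.  The 1-s analysis window is centred on the file midpoint; on odd
sample counts the start index is floor((N − W)/2), deterministic.

## Band levels

Third-octave bands use base-10 edges f_c·10^(±1/20); these differ from
base-2 edges by < 0.1 %.  Band intervals are half-open [lower, upper) so
tiling bands never double-count an FFT bin; DC and Nyquist are excluded.
The estimator is a rectangular-window FFT of the full window with power
summed over in-band bins.  At the default 1-s window this gives 1 Hz
resolution, making leakage negligible for noise-like signals, and is
bit-reproducible; a window function or an ANSI-style time-domain filter
bank would change individual estimates by fractions of a dB but none of
the downstream conclusions.  Per-window levels of stationary noise
fluctuate with the chi-square statistics of the band's time–bandwidth
product (≈ 4.34/√(BT) dB), which the suite checks.

## Soundscape statistics

Percentiles are computed in the dB domain (matching how third-octave
level distributions are reported) with linear interpolation between
order statistics.  Day is the local clock interval [07:00, 19:00);
season is membership of a configured campaign window (two contiguous
14-day periods, winter and summer).  Timestamps are naive local time.
Per-site summaries default to pooling both seasons and both diel
periods; any axis can instead be fixed through `StratumKey`.

## Detection gate

Detection of an approaching boat in a band is the earliest whole second
before CPA at which the boat's band level *strictly* exceeds
max(audiogram threshold, background level).  Equality does not trigger;
ties in the limiting-factor classification count as noise-limited,
since the background alone then enforces the gate.  The search runs
over t ∈ [−30, 0] s; a pass already above the gate at −30 s is reported
as censored (≥ 30 s of warning) rather than as 30, and a pass never
above it by t = 0 as not-detectable.  The earliest crossing is reported
even if the level later dips below the gate.  mph→m/s uses the exact
statute factor 0.44704; distances are rounded to the nearest metre.
This is a hard energy gate: no d′ or critical-ratio signal-excess model,
no localization, one boat at a time.

## Communication space

Practical spreading, TL = k·log10(r) with k = 15 and a 1 m reference —
intermediate between cylindrical and spherical spreading and a good fit
to transmission-loss measurements in shallow bays.  Detection distance
10^((SL−BG)/k) is clamped at the reference distance when SL ≤ BG
because source levels are referenced at 1 m and the model is undefined
inside it.  No absorption term.  Reported distances are rounded to one
decimal metre.  The shallow-water cutoff uses λ = depth with
c = 1500 m/s, i.e. f = c/d; this reproduces the standard field-scale
figures (4 m → 375 Hz, 1.5 m → 1 kHz) and is the model's documented
convention rather than a full waveguide mode calculation.

## Synthetic soundscapes

The generator emulates the monitoring study design: four sites, two
contiguous 14-day campaigns at 5-minute cadence (4,032 slots per
site-period), i.i.d. slot dropout with default probability 0.06 (field
deployments stored about 94 % of slots), and site/season/diel level
structure.  Per-sample variability is Gaussian jitter in the dB domain
(default sd 3 dB, a realistic 5-minute-scale spread for shallow coastal
sites); real soundscapes are heavier-tailed (boat passes, rain, snapping
shrimp), so passing recovery tests demonstrates the pipeline's
correctness, not that field distributions are Gaussian.  Audio synthesis
sums independent band-limited Gaussian noise components, each scaled so
its realized in-band rms equals the target exactly.  Boat passes follow
straight-line geometry r(t) = √((vt)² + d²) with received level
SL − k·log10 r, optional dB-domain jitter, and a default lateral miss
distance of 1.5 m (passes in the field were within 1–2 m).  All
generators are deterministic under a fixed seed.

The default scene's broadband medians are anchored so the
communication-space model reproduces the field-scale distance grid;
its third-octave targets follow the qualitative site ranking (quietest
to loudest) with +2 dB summer and +2 dB day offsets.

## Numerical choices and limitations

* Percentile convention: numpy linear interpolation; documented so
  summaries are reproducible.
* Band estimator tie-breaks: half-open bins, DC/Nyquist excluded.
* Degenerate inputs error loudly: empty strata (named in the message),
  multi-channel or zero-length WAVs, bands at or above Nyquist,
  overlapping campaign windows, negative warning times.
* The audiogram carries no default thresholds — they are study-specific
  laboratory measurements and must be supplied as config; all bundled
  audiograms in tests and examples are synthetic.
* Out of scope: surface-interference (Lloyd mirror) and range-dependent
  propagation modelling, psychophysical detection beyond the hard gate,
  vocalization detection/classification, and GIS mapping.

## Problem sizes

The test suite and acceptance script run entirely on synthetic data:
1-s clips at 44.1 kHz for band-level checks, 33-s pass tables, and
full-size campaign tables (32,256 slots) for bookkeeping, which keeps
the whole suite to a few seconds of CPU.
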