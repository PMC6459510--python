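# Methods

## Generative waveform model

An averaged suprathreshold ABR is modelled as four positive–negative wave
pairs. Wave *k* contributes a Gaussian bump of width σₖ (ms) centred at its
peak latency and an equal-magnitude negative bump (the trough) offset by
3σₖ. Peak amplitude and latency follow linear level laws in sensation
level SL = level − threshold:

* amplitude: aₖ(SL) = baseₖ + gainₖ·SL (µV)
* latency: ℓₖ(SL) = max(Lₖ − slopeₖ·SL, Lₖ/2) (ms)

Below threshold the trace is pure Gaussian recording noise. Defaults: base
latencies 1.4/2.2/3.1/4.1 ms (wave 1 reflecting auditory nerve, later
waves brainstem stations), widths 0.12–0.14 ms, base amplitudes
0.55/0.45/0.50/0.35 µV, gains 0.012–0.020 µV/dB, latency slope
0.005 ms/dB, noise sd 0.12 µV, 100 kHz sampling over an 8-ms epoch. The
published screens report only qualitative monotonicity (amplitudes grow,
latencies lengthen toward threshold); the linear laws and Gaussian shapes
were chosen so peak locations and amplitudes are analytic and every
detector can be tested against exact oracles. The latency slope is kept
small enough that wave windows never collide across the 60-dB SL range —
larger slopes make wave 2's search region at high level overlap wave 3's
rising edge, which real scorers disambiguate by eye but a windowed picker
cannot. Wave-2 splitting into a double bump at ≥ 40 dB SL is an option
(two equal sub-bumps at ±1.5σ), exercising the downstream policy of never
quantifying wave-2 amplitude.

## Threshold detector

Visual threshold scoring is replaced by an automated detector. Per level
the statistic combines (a) the maximum lag-limited (±0.5 ms) Pearson
cross-correlation between the trace and the trace one level above within
the signal window (0.4–5.5 ms), and (b) the ratio of signal-window RMS to
a noise floor taken as the median tail RMS (6–8 ms) across the ladder.
Detection requires correlation ≥ 0.35 and RMS ratio ≥ 1.15; the top level,
which has no level above, uses the RMS criterion alone. Threshold is the
lowest level that is detected with all higher levels also detected — the
consistency-with-higher-levels requirement of visual scoring. No detection
anywhere returns the maximum presented level with the ceiling flag, the
convention used throughout for "no response at 95 dB SPL". A quality gate
marks (never drops) levels whose tail RMS exceeds 3× the noise floor,
standing in for the visual masking check against myogenic/electrical
artefacts.

The two detector thresholds were calibrated once against the generator:
noise-free recovery is exact for every grid threshold 0–95 dB, and at
noise sd equal to a quarter of the near-threshold wave-1 amplitude the
estimate stays within one 5-dB step in ≥ 95% of replicates. Both
calibrations are re-verified by the test suite and the acceptance script.

## Reference ranges and calling conventions

* Percentiles use linear interpolation of order statistics (Hyndman–Fan
  type 7, the numpy default); Hazen (type 5) is a config switch. Ranges
  require n ≥ 20 control values.
* "Outside" the 95% range is strict; values exactly on a bound count
  inside, keeping control self-coverage at ≥ 95%.
* The 60% rule is evaluated stimulus-by-stimulus (the fraction of mice
  outside at that stimulus). The alternative reading — fraction of mice
  with any outside stimulus — is available as `rule60_denominator`.
* The 20-dB rule is inclusive (≥ 20 dB) on |line mean − control median|.
* Ceiling thresholds enter means and fractions at face value (95); a
  right-censoring sensitivity switch (`ceiling_mode="censored"`) excludes
  them from means instead.
* The Fisher table pools observations (one per mouse per stimulus) across
  the whole battery; per-stimulus testing is a switch. The two-sided p
  sums all tables with fixed margins whose hypergeometric probability does
  not exceed the observed table's (1e-7 relative tie tolerance); degenerate
  margins give p = 1. The implementation is built on scipy's hypergeometric
  pmf and is checked exhaustively against exact integer enumeration for
  all totals ≤ 60.
* The screen-wide Fisher significance level is α/m for m lines screened
  (for 1,211 lines, 4.1 × 10⁻⁵ at α = 0.05).

## Audiogram classification

Rules are applied in severity order on line means: Severe–Profound (every
mouse at ceiling for ≥ 2 adjacent tone frequencies), High-Frequency
(30-kHz elevation > 30 dB with some lower tone not elevated),
Low-Frequency (6 and 12 kHz elevated with some higher tone normal),
Moderate (≥ 4 of 6 stimuli elevated, each by > 15 dB), Mild (≤ 3 stimuli
elevated, none by > 30 dB), Normal (nothing altered). "Elevated" means the
line mean exceeds the stimulus's 97.5th control percentile; "elevation" is
the line mean minus the control median.

Two genuinely open points were resolved as follows. First, the
Low-Frequency criterion's "< 15 dB" bound is attached here to the
*normal higher-frequency* gate (a higher tone counts as normal when its
elevation is below 15 dB). The alternative parse — the smallest elevation
among *elevated* stimuli must be < 15 dB — is kept behind
`low_frequency_as_printed`, but it confines low-frequency lines to a
roughly 2σ-wide window between "elevated" (≈ +10 dB at control sd 5) and
15 dB, which no 4-mouse line can occupy reliably; the default reading is
the one a well-separated low-frequency line can actually satisfy. Second,
the five rules are not exhaustive (a single low-frequency stimulus
elevated by > 30 dB matches none), so unmatched patterns fall back to Mild
when ≤ 3 stimuli are elevated and Moderate otherwise, and a line called by
either rule that nevertheless classifies Normal is reported Mild so that
Normal remains equivalent to "no rule fired".

## Synthetic cohorts

Control thresholds per stimulus are drawn from a contaminated normal — 95%
N(median, 5), 5% N(median, 15) dB — because real control threshold
distributions test significantly non-normal; draws are rounded to the 5-dB
presentation grid and clipped at 95 with a ceiling flag when the latent
value exceeds the maximum. Default medians (click 20, 6 kHz 35, 12 kHz 20,
18 kHz 15, 24 kHz 25, 30 kHz 35 dB SPL) follow the typical 14-week
C57BL/6N-background audiogram, most sensitive in the mid frequencies. Sex
is generated but has no effect, matching large wild-type cohorts. Mutant
lines add a per-class threshold shift to control-like draws (same mixture,
so all-Normal lines are distributionally identical to controls and null
calibration is exact); canonical class templates are +100 dB everywhere
(Severe–Profound), +45 dB at 30 kHz (High-Frequency), +35 dB at 6 and
12 kHz (Low-Frequency), +30 dB everywhere (Moderate), +20 dB at click and
12 kHz (Mild). Every line spec is validated by classifying its noise-free
shifted audiogram against analytic control ranges — a spec whose shifts do
not produce its declared class is rejected. Optional artefacts (a
no-shift outlier mouse with configurable probability) exercise the
false-positive review stage. Per-stimulus level ladders default to the
screen's windows (click 0–85, 6 kHz 20–85, 12/18 kHz 0–70, 24 kHz 10–70,
30 kHz 20–85 dB SPL) and are extended to 95 for suspected impaired lines.

The association generator draws allele counts Binomial(2, MAF)
independently per marker, positions markers across the gene ± flank, and
builds raw traits as exp(intercept + β·count + sex and nuisance effects +
N(0, 0.35)) so the log-scale model is exactly linear; β defaults to 0
(null) and applies to the 4-kHz trait when set.

What the generator does *not* emulate — week-to-week drift in local
controls, cross-stimulus correlation within a mouse, genetic-background
strata, litter effects, real LD between markers, imputation error —
bounds what passing tests show: they validate the statistical machinery
under the stated sampling model, not robustness to those real-data
features.

## Numerical and scale choices

* Grid quantisation concentrates threshold mass on the percentile bounds,
  so strict-outside self-coverage of grid thresholds is ~1–3%, not the
  nominal 5%; coverage calibration is therefore computed on the continuous
  (pre-quantisation) control values the generator exposes, and the null
  60%-rule oracle uses the empirical grid-level outside probability per
  stimulus inside a binomial ≥ 3-of-4 calculation.
* IOF curves use SL ∈ {5, …, 60}: SL 0 is excluded (near-threshold
  responses are unstable) and quantification stops at the 60-dB
  suprathreshold range; the ≥ 40% flagging rule applies ceil(0.4·k) to
  however many SLs k are available.
* The flagging minimum on the full grid is ceil(0.4 × 12) = 5 of 12 SLs.
* Calibration problem sizes — 2,000-mouse control cohorts, 400-control
  reference for the waveform-level recovery run, 100 lines per class,
  2,000 null lines, 10,000-20,000 trend-test replicates — were chosen to give
  sampling error comfortably below each tolerance while keeping a full
  run in the minutes range on one CPU.
* Gene windows are 1-based inclusive on both bounds, clamped at position
  1; the per-allele test is the Wald slope test, numerically identical to
  the 1-df F-test (asymptotically equivalent to the score/trend form).
* Covariate adjustment is residualisation before testing rather than joint
  modelling (a switchless design choice made for modularity; for 1-df
  slope tests the two differ only through covariate degrees of freedom,
  negligible at the cohort sizes used).

## Known limitations

* The detector is calibrated to the generator's morphology; real ABRs with
  atypical waveforms (e.g. grossly abnormal responses where peaks cannot
  be matched) need the triage path, not the automatic picker.
* Classification operates on line means; with the minimum cohort of four
  mice a single extreme mouse can move a line across a rule boundary —
  that is intentional (it mirrors the screen's behaviour) and is what the
  review flags are for.
* The extrapolation of remaining genes is simple proportional scaling of
  the observed hit rate to the unscreened genome; it inherits every bias
  of the screened gene set.
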