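# Methods

This note documents the models, defaults, and design choices behind
`cardiosync`, and what the synthetic-data experiments do and do not
establish.

## Signal model of the synthetic generator

Each subject's IBI fluctuation around a resting mean (default 850 ms) is

    x_i(t) = AR1(φ, σ) + β·t + A·sin(2πt/T + φ_i) + g·σ·d(t − δ_i)

with defaults φ = 0.85, σ = 40 ms, trend β = 6 ms/min, seasonal amplitude
A = 15 ms at period T = 4 s (a respiratory-sinus-arrhythmia stand-in), and
a shared driver d: unit-variance Gaussian noise low-passed at 0.1 Hz
(second-order Butterworth, zero phase). The driver gain g is the
ground-truth coupling knob, expressed in units of the subject's own
fluctuation SD; subject 2's copy can be delayed by an integer number of
4 Hz samples to emulate leading/following. Values are clipped to the
physiological 300–2000 ms range. The 0.1 Hz driver bandwidth is a modelling
choice: cardiac co-fluctuation in this paradigm lives at multi-second
scales (the ±3 s lag window), and no spectral characterization of the
coupling exists to pin it down further.

Series are generated directly on the 4 Hz analysis grid by default. This
deliberately decouples testing of the prewhitening/CCF stages from peak
detection; the ECG path is exercised separately by
`generate_ecg_from_rpeaks`, which renders a stylized QRS template (sharp
Gaussian R wave, 12 ms sigma, small Q/S dips) at specified beat times plus
sub-0.6 Hz baseline wander and above-20 Hz broadband noise. The generator
makes no attempt at realistic ECG morphology beyond what threshold-based
peak detection needs (no P/T waves, no arrhythmia, no electrode artifacts),
so detection results on it bound performance only for morphologically clean
recordings.

What the generator does *not* emulate: non-stationary coupling within a
block, movement artifacts, ectopic beats, respiratory coupling between
partners, or floor/ceiling questionnaire effects. Passing tests therefore
demonstrate that the pipeline recovers planted effects under its own signal
model, not that any particular real dataset will behave this way.

## Preprocessing choices

- **Filters.** The band edges are 0.6 Hz (baseline wander) and 20 Hz
  (high-frequency noise). Realization: second-order Butterworth applied
  forward-backward, chosen so peak times are not biased by filter delay.
- **Peak detection.** Threshold = 0.5 × rolling 95th percentile over 2 s
  windows (floored at 30% of the global value so beat-free windows do not
  fire), minimum inter-peak distance 0.25 s, and a local-prominence floor
  (half the global 95th percentile within a 0.25 s window). The prominence
  floor exists because wander components just below the high-pass cutoff
  survive filtering with enough amplitude to cross the threshold; a QRS
  falls by its full height within tens of ms while a wander crest is almost
  flat on that scale. Peaks in the first/last 0.1 s are discarded
  (zero-phase edge transients). This replaces manual visual correction with
  a deterministic rule plus QC reporting (`io.qc_row`).
- **IBI cleaning.** Outliers are values outside 300–2000 ms or more than
  25% away from the 11-beat rolling median; they are replaced by a cubic
  spline over beat *time* (not beat index), preserving the temporal
  structure that feeds the 4 Hz grid. More than 25% flagged beats raises —
  the block is unusable. The spline order is an assumption; only "a spline"
  is specified by the procedure this implements.
- **Resampling.** Cubic spline of IBI versus beat time, evaluated on a
  4 Hz grid from the first to the last beat of the block; no extrapolation.
  Blocks are processed independently, and both subjects' grids are aligned
  to block start then trimmed to the overlapping span before
  cross-correlation.

## Prewhitening

The default engine is an exhaustive grid search over ARIMA(p,1,q) — and,
when a seasonal period m > 1 is supplied, (P,1,Q)_m — fit by maximum
likelihood (statsmodels SARIMAX with simple differencing). Choices that were
genuinely open and how they were resolved:

- **Selection criterion.** AICc alone selects; AIC and BIC are reported.
  (The procedure this follows lists three criteria with no combination
  rule; AICc is the small-sample-safe member.) Ties break toward fewer
  parameters, then lower q.
- **Seasonal period.** m is a *required* configuration value, defaulting to
  m = 1, which collapses the seasonal terms with a logged warning. The
  alternative — silently inventing a period — was rejected; the analysis
  series' sampling rate implies m = 16 for a 4 s respiratory period, and
  the tests use that.
- **Box–Cox.** Lambda minimizes the coefficient of variation of a
  Guerrero-style subseries dispersion measure, grid-searched over [−1, 2].
  Residuals stay on the transformed scale (only their correlations are
  used); the transformed series is standardized before fitting because
  extreme lambdas compress ~850 ms values into numerically degenerate
  magnitudes.
- **Failures.** Non-convergent candidates are skipped; an empty candidate
  set returns the differenced series flagged `converged=False`. A constant
  series takes the fallback path directly.

A fast path (`method="ar_diff"`) first-differences the series and fits an
autoregression by conditional least squares with AIC order selection (lags
up to 5, on a common sample so criteria are comparable). For the AR + trend
signal family of the generator it removes the same structure as the grid
search at roughly 1/1000 the cost; the large simulation studies
(calibration, power, study-scale recovery) use it so that thousands of
replicates fit in minutes. The two paths agree in the sense that both pass
the same whiteness checks on generator output; the exhaustive search is the
default for data analysis.

## Synchrony and surrogates

Lag values use full-series means and biased SDs (bounded, stable at the
maximum lag; configurable in principle but deliberately not windowed). The
lag-group partition is negative = −12..−5, zero = −4..+4, positive =
5..+12 — the unique non-overlapping 8+9+8 split consistent with a zero
group of −4..4. The synchrony index averages all 25 *signed* values (in-
versus anti-phase is meaningful), then Fisher-Z; the ×100 scale is
reporting convenience only, and all inference runs on unscaled Fisher-Z
values.

Pseudo-dyad enumeration pairs subject 1 of one dyad with subject 2 of
another (never subject 1 × subject 1 — the task roles are asymmetric)
within identical condition cells: block type, movement, leader role, and
the block's ordinal position within its condition. Per-subject ARIMA fits
are computed once and cached across pairings. Subsampling is seeded and
without replacement. Baseline blocks form their own cell and are compared
separately.

Note that surrogate synchrony values sharing a subject are not independent,
so Welch's t-test on REAL vs PSEUDO is an approximation; the calibration
simulation (500 uncoupled studies) shows the realized type-I error at the
desk-scale subsampling level stays within 3–7% at nominal 5%.

## HRV and behavior

rMSSD is computed on cleaned *beat-domain* IBIs — never on the 4 Hz
resample, which distorts successive differences — and HRV change is block
minus same-subject baseline. Behavioral trial differences are absolute
between-subject grasp-contact and start-release time differences; the
Tukey 1.5 × IQR fence is applied to the study-wide trial pool by default
(matching the use of single global retained ranges; per-block filtering is
available), then retained trials average to one value per block. The fence
is a single pass: iterating it is not in general idempotent (ties can
collapse the IQR), and no iteration is performed.

## Dyad-level models

Within-dyad predictors (social anxiety, perspective taking, HRV change)
enter as dyad SUM and ABSDIFF; continuous predictors are z-standardized
with scalers stored on the design. Factors are 0/1 indicators with "old",
"leader-follower", and "opposite" carrying the indicator, so a negative
novelty coefficient means higher synchrony in new blocks. Novelty itself is
coded by the transition rule: a task block is "new" iff its (block type,
movement, leader) combination differs from the immediately preceding task
block's (the first task block is "new"); an alternative
first-block-of-each-run rule can be had by reordering runs. The trim
decision uses α = 0.05 on the raw ABSDIFF p-values of the saturated fit.
Estimation is REML via statsmodels MixedLM with a by-dyad random intercept;
requested random slopes are dropped last-first on non-convergence down to
intercept-only, and the structure actually fit is recorded. Each model is
compared to an intercept-only null by an ML likelihood-ratio test and
reports Nakagawa marginal/conditional R². Wald p-values are FDR-adjusted
(Benjamini–Hochberg, implemented directly and oracle-checked) within each
model's coefficient family. Parametric-bootstrap intervals and
cumulative-link (ordinal) model internals are out of scope by design; the
design tables they would consume are produced here.

## Simulation scales

The heavy checks run at sizes chosen to make Monte-Carlo rates stable while
keeping the whole suite fast on one CPU: null calibration uses 500
uncoupled 8-dyad studies with 60 s blocks; the power study uses 200
replicates of 12 dyads × 8 two-minute blocks at driver gain 0.5 — the gain
at which the task-level averaged CCF lands in the reference 0.004–0.006
band (the measured mean is ≈ 0.0047); prewhitening adequacy uses 15
five-minute series (n = 1200, the study's own block length at 4 Hz); and
effect recovery uses 100 studies of 40 dyads with 45 s blocks, planted
gains 0.3 (task), +0.7 (novelty blocks), and −0.25 × standardized dyad
social-anxiety sum. Shorter blocks raise the per-block sampling noise of
the CCF, which these designs offset with more blocks or dyads; directions
and calibration rates, not absolute magnitudes, are the quantities under
test.

## Known limitations

- The ARIMA grid search is the computational bottleneck; seasonal fits at
  m = 16 cost seconds per series. The `ar_diff` path is the pragmatic
  alternative for simulation-scale work but cannot capture MA or seasonal
  structure.
- Welch REAL-vs-PSEUDO inference ignores surrogate-value dependence (see
  above); at study-scale exhaustive enumeration the effective sample size
  is smaller than the pair count.
- The detector targets clean single-lead ECG with dominant R waves;
  inverted leads or prominent T waves would need template or slope-based
  extensions.
- Time-varying synchrony, wavelet coherence, directionality measures, and
  phase-randomized or time-shifted surrogates are intentionally absent.
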