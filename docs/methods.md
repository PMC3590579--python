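# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `pulsemei`. It is the design record: everything here is
implemented and exercised by the test suite or `scripts/acceptance.py`;
no empirical claim is made that those do not themselves compute.

## Protocol and data model

A recording is a single-channel pressure-sensor series sampled at 500 Hz
over a 17-minute protocol: 5 min baseline (wrist cuff at 40 mmHg), 3 min
upper-arm occlusion at 200 mmHg, 9 min reactive hyperemia after release.
Phases are cut by protocol arithmetic (0-based, half-open sample ranges);
recordings within ±1 s of the nominal length are accepted and reconciled by
truncation only, never extrapolation — the handling of off-nominal lengths
is a package decision, since acquisition practice varies. Beat indices in
result documents are 1-based (X₁…X_N), matching clinical convention; the
conversion lives entirely in `signal_model`.

Device units are opaque. Nothing downstream depends on absolute scale:
DI is a ratio, and the entropy tolerance r is tied to the series SD
(`sample_entropy` is affine-invariant when r co-scales, a tested property).

## Beat detection

The literature behind wrist/PPG footpoint marking is heterogeneous, so the
detector is a deterministic, stated stand-in validated against the
generator's ground truth:

1. band-pass 0.5–10 Hz, zero-phase (2nd-order Butterworth, forward-backward);
2. candidate peaks by local-maximum search with refractory spacing
   60/max_hr (defaults 40–150 bpm) and prominence ≥ 0.3 × the rolling
   median prominence (31-beat window) — the relative threshold tracks the
   large amplitude swings across protocol phases;
3. peak refinement on the raw signal (±100 ms);
4. footpoint = raw-signal minimum between the previous peak and the current
   one (first beat: minimum over the preceding 0.5 s); beat amplitude =
   peak − footpoint, which cancels slow baseline drift.

Fewer than 3 beats (flat or non-pulsatile input) raises "no pulsatile
activity". Beats straddling a phase boundary belong to the phase containing
their peak. Validated performance on rendered recordings: median beat-time
error < 10 ms at 500 Hz, beat count within ±2 % at 60 dB SNR, amplitude
recovery within 2 %. No arrhythmia/ectopic-beat rejection is attempted.

## EMD detrending

Classical Huang-style EMD, fully deterministic: cubic-spline envelopes
through local maxima/minima with mirror extension of two extrema per
boundary; sifting stops on a Cauchy criterion SD < 0.2 *and* the
extrema/zero-crossing balance |#extrema − #crossings| ≤ 1, capped at 100
sifts per IMF; decomposition stops when the residue has < 4 extrema. The
residue is computed by subtraction, so IMFs + residue reconstruct the input
to float round-off (tested at 1e−9 of range over 100 fixtures). No
ensemble (noise-assisted) variant is used, keeping the pipeline
deterministic.

**Trend definition.** The removed trend is the residue **plus every IMF
whose mean period (2N / extrema count) exceeds one tenth of the series
length** (`trend_period_frac = 0.1`, i.e. slower than ~100 beats ≈ 1.7 min
at 71 bpm). Rationale: the hyperemic amplitude envelope is a rise-and-decay
bump spanning minutes; EMD systematically splits such a bump between the
residue and the slowest one or two IMFs, so a residue-only trend
under-removes it by an amount comparable to the physiological fluctuations
themselves (measured directly on generator output). The cutoff sits well
below the protocol timescale (minutes) and well above the fluctuation
scales that the τ ≤ 10 entropy analysis probes (≲ 30 beats). A residue-only
trend remains available (`trend_period_frac = None`) and is approximately
idempotent (< 5 % RMS change on re-detrending); the adaptive default trades
that idempotence for correct envelope removal. `trend_imfs = k` forces k
further slowest IMFs into the trend.

## Entropy analysis

Sample entropy follows the standard unordered-pair counting convention:
B counts pairs i < j ≤ N−m whose m-length templates lie within Chebyshev
distance r, A the same pairs at length m+1 (both template populations start
at the same indices; self-matches excluded); S_E = −ln(A/B). The −ln(A/B)
value is identical under ordered or unordered counting. The optimized
implementation builds the pairwise distance matrix incrementally (O(mN²)
time, O(N²) memory — trivial at N ≤ 1000) and is tested to 1e−12 against a
brute-force counter written independently of it.

Defaults follow the Costa convention: **m = 2, r = 0.15 × SD of the
scale-1 (detrended) series, r held fixed across scales**. All three are
configurable (`MSEConfig`), including per-scale r. Degenerate scales are
never silently zeroed: B = 0 gives NaN ("no_m_matches"), A = 0 gives +inf
("no_m1_matches"); flags propagate through the curve into the MEI (an
undefined scale makes its band undefined) and surface as CLI exit status 3.
Coarse-graining discards the trailing remainder (length ⌊N/τ⌋).

MEI_SS sums scales 1–5, MEI_LS scales 6–10. With ~1000 beats the τ = 10
series has ~100 points — short, which is why degeneracy handling matters.

## Dilatation index

DI = Amp_RH/Amp_Baseline × 100 %, each a mean beat amplitude over one 60-s
window (≥ 5 beats required). Window placement is a declared choice, since
"a representative one-minute period" under-determines it: the default
baseline window is the last 60 s of baseline (the settled state closest to
occlusion) and the hyperemic window is the mean-amplitude-maximizing 60-s
window among 10-s-stepped candidates in the first 180 s of hyperemia (the
window that captures the hyperemic peak). A fixed-offset policy and both
window positions are configurable, and the windows used are echoed in every
result document. "Mean amplitude" is read as mean *beat* amplitude, not
mean rectified signal.

## Synthetic cohort generator

The generator emulates four subject archetypes — healthy young, healthy
middle-aged/elderly, well-controlled diabetic, poorly controlled diabetic —
as beat-amplitude series plus optional rendered waveforms, with per-subject
seeds spawned deterministically from one master seed.

* **Beat times**: constant mean heart rate 71 bpm (≈ 1000 beats over the 14
  analyzed minutes; ≈ 355 baseline + ≈ 640 hyperemic), multiplicative
  Gaussian RR jitter with CV 0.04.
* **Envelope**: base amplitude in baseline; after release,
  base × (1 + (gain−1)·s(t)/s_max) with s(t) = (1−e^{−t/60 s})·e^{−t/180 s}.
  The 60-s rise reflects that vasodilation builds over tens of seconds (and
  keeps the spliced series continuous where the occlusion segment was
  deleted — a step there is both non-physiological and un-detrendable);
  the 180-s decay returns the envelope toward baseline within the hyperemic
  phase. Peak normalization makes the programmed gain the quantity DI
  estimates. Gains 2.0 / 1.65 / 1.6 / 1.33 anchor the four archetypes to
  clinical DI group means near 200/165/162/133 %.
* **Fluctuations**: additive, X_i = envelope(t_i) + base_amp·fluct_i, where
  fluct is unit-SD Gaussian noise with power spectrum ∝ 1/f^β synthesized
  spectrally, scaled by fluct_cv = 0.12 (beat-to-beat amplitude variability
  of ~10–15 % is typical of respiratory and autonomic modulation). The
  exponent β **is** the archetype's complexity parameter: β = 1 is fully
  1/f-correlated, β = 0 white. A two-component pink/white amplitude mixture
  was evaluated and rejected: its large-scale variance is dominated by the
  pink component even at small mix fractions, making MEI_LS non-monotone in
  the mixture weight, whereas MEI_LS increases monotonically in β over the
  range used. Additive (rather than amplitude-proportional) fluctuations
  keep the fluctuation variance constant across phases, so the entropy
  indices measure correlation structure rather than envelope
  heteroscedasticity.
* **Complexity defaults** β = 0.85 / 0.55 / 0.35 / 0.15 are free modeling
  parameters calibrated once — on generator output at two disjoint seed
  banks, before the validation suite was frozen — so that mean MEI_LS
  orders the archetypes strictly. They encode the hypothesis that ageing
  and glycemic burden whiten amplitude fluctuations; they are not measured
  clinical values.
* **Rendering**: each beat is an asymmetric template (two Gaussian lobes:
  fast systolic rise peaking at ~0.17 s, slower decay with a dicrotic bump
  at 0.40 s; onset and tail clamped to zero) scaled to its amplitude and
  placed at its onset; occlusion is near-flat; white sensor noise at
  snr_db = 40 dB relative to the pulsatile RMS. Beats closer than 0.35 s
  would overlap the template core and raise an error.
* **Cohort**: default group sizes 30/40/40/30 (140 subjects); group labels
  and coarse metadata (age, HbA1c medians per group) ride along for the
  report tables.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: arrhythmia and ectopy, motion artifacts, sensor
drift and saturation, respiration-locked periodic modulation (fluctuations
are broadband), inter-subject variability of heart rate and SNR within a
group, and any mechanistic hemodynamics (no Windkessel-style model). The
complexity-whitening mechanism is a plausible stand-in for the clinical
phenomenon, not a validated physiological model; the pipeline's clinical
claims rest on the original cohort, not on this simulator.

## Statistics

Group comparisons use the two-sample t-test, Welch (unequal-variance) by
default — group SDs of the entropy indices differ visibly — with a
pooled-variance mode for sensitivity analysis; p-values are two-sided and
no multiple-testing correction is applied (the report states this).
`summary_t` computes the same test from printed mean/SD/n summaries
(Welch–Satterthwaite df), enabling consistency checks of published tables:
the group-1-vs-2 and group-3-vs-4 large-scale-entropy comparisons reproduce
their printed significance (p ≈ 0.026 and 0.023 against printed 0.025 and
0.024), while the group-2-vs-3 entropy and group-1-vs-2 DI comparisons do
not reconcile under any standard two-sample t (Welch gives 0.074 and
0.0003 against printed 0.037 and 0.016) — these are reported as documented
discrepancies, suggesting an adjusted or nonparametric test was used for
them, and are not asserted. Pearson correlations use the t-transform
p-value with n−2 df.

## Numerical choices and degenerate inputs

* Monotonic input to EMD: zero IMFs, residue = input (not an error).
* Constant amplitude series: detrends to all zeros; fraction-of-SD
  tolerance then raises "degenerate tolerance" (SD = 0) rather than
  emitting meaningless entropy; with an absolute tolerance a constant
  series has S_E = 0 exactly.
* DI windows of different beat counts accumulate ~1 ulp of float round-off;
  DI on a constant series is 100 % to 1e−9.
* All simulation randomness flows through numpy Generators seeded from
  explicit integers; cohort subject seeds are SeedSequence children reduced
  mod 2³¹. Fixed seed ⇒ bit-identical recordings (tested).

## Problem sizes used in validation

The test suite and acceptance script use the sizes the method is designed
for: amplitude series of ~1000 beats, 50-seed Monte-Carlo bands for the
noise signatures, 100 random instances for the oracle-agreement and EMD
completeness sweeps, and 20 rendered subjects per group (80 full 17-min
recordings at 500 Hz) for the end-to-end archetype-recovery check. Beat-
detection unit tests run on a shortened 60/30/60-s protocol, which
exercises the same code paths per beat.

## Known limitations

* The entropy magnitudes depend on (m, r) and on the fluctuation model;
  published group means cannot be pinned without the original recordings,
  so validation targets orderings, identities and parameter recovery, not
  absolute MEI values.
* EMD boundary splines are extrapolative; trend-recovery guarantees hold on
  the interior ~90 % of a series.
* The adaptive trend rule removes genuine fluctuation power at periods
  longer than N/10 beats alongside the envelope; this slightly compresses
  the entropy separation between archetypes and is the price of removing
  the envelope reliably.
* The beat detector assumes a single-peaked systolic wave with a smaller
  dicrotic bump; exotic morphologies (severe damping, double systolic
  peaks) are out of scope.
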