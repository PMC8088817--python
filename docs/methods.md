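# Methods

This note records the models, estimators, numerical choices and known
limitations behind `ibp`, in the spirit of a statistical-software methods
appendix.  Everything quantitative stated here is computed by the test suite
or by `scripts/acceptance.py`; nothing is quoted from external data.

## Signal model and synthetic data

The background of one iEEG channel is zero-mean Gaussian noise with a
1/f^α power spectrum (α = 1 by default, configurable), scaled to a
standard deviation of 20 µV and sampled at 1000 Hz.  Five-minute epochs are
the canonical analysis unit; all rates are normalized to a 300 s denominator
regardless of the rendered epoch length.

Planted events:

- **Oscillation** — a Hann-tapered sinusoid of `n_cycles` (default 8) at a
  centre frequency in 80–300 Hz.  Eight cycles comfortably exceeds the STE
  peak-count minimum, so planted events are detectable by design; amplitudes
  are specified as multiples of the band-passed background SD (15 SD in the
  recovery fixtures).
- **Sharp transient** — a biphasic pulse `sign(t)·exp(−|t|/τ)` with a slope
  discontinuity at its apex.  The discontinuity is essential: band-pass
  filtering it produces a ripple-like deflection with no oscillatory content,
  which is exactly the false-ripple confound the verifier must reject.  A
  smooth (Gaussian-derivative) pulse does not ring and would make the
  verification fixture trivially easy.
- **Coupled carrier** — `A0·(1 + m·cos φ)·cos(2π·f_c·t)` added to a 3–4 Hz
  slow wave with phase φ.  The mean-vector-length modulation index of this
  family is analytically `A0·m/2`, giving a closed-form oracle.

Electrode layouts are random points on a hemispheric shell of radius 70 mm.
The epileptic territory is a contiguous cluster: the spiking zone is the
cluster, the seizure-onset zone its inner 30 %, the lesion (when the patient
has one on MRI) its inner 20 %; non-epileptic = outside all three.  The
resection is a contiguous cap around the SOZ centroid that either covers the
SOZ or deliberately spares its most peripheral channel, driven by the
patient's `soz_fully_resected` covariate.

Cohorts default to 135 patients with 64–152 channels each (≈108 on average).
Clinical covariates are drawn to match realistic marginals for a paediatric
epilepsy-surgery series (≈50 % male, ≈59 % MRI-lesional, 1–3 anti-epileptic
drugs, resection ≈16 % of the hemisphere); their joint structure is
independent draws, which is an acknowledged simplification.  Channel-level
generative oscillation rates are Gamma(2, ·) with non-epileptic mean
5 / 5 min, multiplied by `epileptic_rate_multiplier` (default 5) inside the
epileptic territory.  Detector-specific expected rates are the generative rate
times a fixed sensitivity (STE 0.18, SLL 1.00, HIL 1.15, MNI 0.14), which
reproduces the field's observed contrast between inclusive (SLL/HIL) and
conservative (STE/MNI) detectors at rate level.

Outcomes follow a logistic model on the 10 covariates plus the patient's true
Subtraction biomarker (computed exactly from the truth tables); the intercept
is solved so the cohort-mean success probability is 0.704.  The truth tables
are retained, so recovery tests can compare estimates against the exact
generating coefficients.

What the generator does **not** emulate: non-stationary sleep architecture,
volume conduction and montage effects, inter-channel correlation of the
background, realistic spike-wave morphology diversity, and any joint
covariate structure.  Passing tests therefore demonstrate correctness of the
*machinery* under controlled conditions, not clinical performance on real
iEEG.

## Detectors

All four detectors share a 4th-order Butterworth zero-phase band-pass
(forward–backward, ≥ 40 dB stop-band) and a common run machinery: windowed
statistics are left-aligned (index i summarizes samples [i, i+w)); supra-
threshold runs closer than 10 ms are merged *before* duration and peak
criteria; events must last ≥ 6 ms; supra-threshold samples within 50 ms of the
epoch boundary are discarded (filter and Hilbert transforms are unreliable
there).  All thresholds and windows are fields of `DetectorParams`.

- **STE**: 3 ms moving RMS; threshold mean + 5 SD of the epoch's RMS series;
  an event must contain more than 6 strict local maxima of the rectified
  band-passed trace exceeding mean + 3 SD (plateaus of equal samples count
  once).
- **SLL**: 12 ms line-length window (≈ one cycle at 80 Hz); threshold is the
  97.5th percentile of the epoch's line-length CDF, so ≈2.5 % of samples are
  supra-threshold by construction.
- **HIL**: analytic-signal envelope (reflect-padded Hilbert transform);
  threshold mean + 5 SD computed per 5 s analysis window.
- **MNI**: 10 ms windowed RMS energy.  Baseline windows are 125 ms stretches
  whose *within-band spectral flatness* is ≥ 0.45 — band-limited noise is flat
  across the passband while a sustained oscillation concentrates power.  If
  at least 5 % of the epoch is baseline, the threshold is the 99.9999th
  percentile of the baseline energy distribution; otherwise each 60 s segment
  is thresholded at the 95th percentile of its own energy CDF.  The
  re-detection iteration count is configurable and defaults to 1: each
  additional remove-and-recompute round lowers the threshold and inflates
  event coverage well beyond the nominal top-5 % rule (measured ≈48 % of
  samples after five rounds), so the plain CDF rule is the default.

A flatness criterion replaced the simpler "line length below the epoch
median" baseline proxy considered during design: a median split marks half of
every epoch as baseline, so the no-baseline branch could never engage and a
channel with continuous oscillatory activity would be thresholded against its
own oscillation.

Equivalence with literal brute-force implementations of each rule (explicit
loops, no vectorized shortcuts) is asserted event-for-event on 10 s fixtures.
Window sums use identical pairwise reduction in both paths, so agreement is
exact rather than approximate.

## Verification

Each event gets a Morlet CWT map (7 cycles, 30 log-spaced frequencies
10–300 Hz, 250 ms padding, reflect-padded at epoch edges) of the *unfiltered*
trace.  Two spectral profiles are averaged over the event window: a per-
frequency z-profile against the padded flanks ("does anything stand out
here?") and the raw-power profile ("what shape is the spectrum?").  The label
logic:

1. If no ≥ 80 Hz bin reaches z ≥ 3, the event is `Spike` when the sub-80 Hz
   z-anchor is strong, else `Others`.
2. Otherwise, candidate blobs are interior local maxima of the raw profile at
   ≥ 80 Hz that are themselves z-significant.  A candidate qualifies as vHFO
   when a valley below it drops under 50 % of its power, where the valley is
   searched (a) above the nearest lower frequency carrying at least the
   blob's own power and (b) within one octave below the peak.  Constraint (a)
   rejects wiggles on the flank of a broadband ridge; (b) encodes that a
   genuine oscillation is narrow-band — a transient whose overall spectral
   peak falls just above 80 Hz has its 50 %-point far down the slope, not
   within an octave.
3. Blobs that fail isolation fall through to `Spike` (strong low-frequency
   anchor) or `Artifact` (broadband, no anchor); ambiguous cases resolve to
   `Others`, deliberately conservative.

Sub-band assignment uses the blob's peak frequency with boundaries [80,150),
[150,250), [250,300].  vHFO rates nest exactly: the > 80 Hz rate is the sum of
the three sub-band rates.  Labels are invariant to amplitude scaling because
both profiles are used only through ratios and z-scores.  Equivalence with
any particular toolbox's unpublished auto-classification rules is *not*
claimed; performance is demonstrated on planted-truth fixtures
(sensitivity and specificity ≥ 0.9, typically 1.0, at 15 SD SNR).

## Modulation index

MI is the mean-vector length |⟨A·e^{iφ}⟩| over the whole epoch, with φ from
the 3–4 Hz band (2nd-order zero-phase filter — the band is only 1 Hz wide)
and A from the f–300 Hz band.  It carries the envelope's µV units, is
homogeneous of degree 1 in signal amplitude, bounded by the mean envelope,
and equals A0·m/2 on the synthetic coupled family (verified within 5 %; the
residual bias comes from filter transition bands).  A surrogate-normalized
variant (circular time shifts) is available but off by default: the raw
magnitude is the primary statistic and is what the downstream models consume.

## Normative atlas

The atlas stores non-epileptic site coordinates and biomarker values; a query
takes the k = 60 nearest sites by Euclidean distance in template millimetres
(ties broken by site index, so queries are deterministic).  Geodesic distance
on a cortical mesh would be an alternative; Euclidean was chosen because it
needs no mesh and the synthetic surface is convex.

Outlier exclusion is a single one-sided pass and is *jackknifed*: a value is
dropped when it exceeds mean + 10 SD of the **other** k−1 neighbours.  The
jackknife is forced by arithmetic: with the candidate included, the largest
achievable deviation among k values is (k−1)/√k SDs ≈ 7.6 for k = 60, so a
10-SD rule could never fire.  Exclusion never removes values at or below the
mean.  When the post-exclusion SD is zero (e.g. a detector that finds nothing
anywhere in non-epileptic cortex), the z-score is NA and remains NA through
Subtraction and modelling — affected patients drop out of that one model
listwise; nothing is imputed.

Sites that are themselves atlas members are z-scored leave-self-out (default
on), which makes the calibration property clean: on homogeneous synthetic
sites the z-scores have mean ≈ 0 and SD ≈ 1 (tolerance 0.15).  SDs use the
n−1 denominator.

## Subtraction biomarkers and outcome models

Subtraction-X = mean(X over resected) − mean(X over preserved), computed over
non-artifact channels only ("preserved" = analysed, non-resected).  The
statistic is antisymmetric under swapping the masks, invariant to adding a
constant, and equivariant under positive scaling — all asserted exhaustively
on small tables.

Models are maximum-likelihood logistic fits (Newton, BFGS fallback).
Reported: coefficients, Wald 95 % CIs, odds ratios (OR = e^β exactly),
Cox–Snell and Nagelkerke pseudo-R² (Nagelkerke is the headline figure, as in
common clinical-statistics software), the likelihood-ratio p, the ROC over
all unique fitted probabilities and its trapezoidal AUC (identical to the
Mann–Whitney U probability, asserted to 1e−12), and LOO probabilities
(each patient predicted by a model fitted on the remaining n−1; warm-started,
fully deterministic).  Complete or quasi-separation (any |β| > 15) is flagged
and the affected CIs reported unbounded rather than penalized; a Firth-type
penalty was considered out of scope.

The AUC comparison test is implemented literally as specified by its source
procedure: sensitivity×specificity products at the n−1 thresholds between
sorted scores, compared by paired t-test against a second model's products or
against the chance constant 0.25, with Bonferroni correction across the model
family of one run.  Its statistical validity is reproduced, not defended.

Calibration reports decile bins of predicted probability with observed
success frequency, the > 0.8 and < 0.2 summary cells, and Spearman's rho
between predicted probability and the ordinal ILAE class (class grows as
outcome worsens, so a concordant model yields negative rho).

## Pipeline and problem sizes

`run_pipeline` composes simulate → reference → detect → verify → MI → atlas
z-score → Subtraction → models into a pure function of (config, seed); the
JSON report is byte-identical across reruns (floats rounded to 10 decimals
before serialization to keep the payload stable).  The default demo config
uses 12 patients × 24–32 channels × 30 s epochs with k = 10 — sizes chosen so
a full run completes in seconds while exercising every stage; study-scale
values (135 patients, 300 s, k = 60) are plain config overrides.  The
acceptance script and test suite likewise use scaled cohorts (e.g. 10–20
five-minute single-channel epochs for detector recovery, 50–100 simulated
cohorts for coverage and optimism checks), stated in each test.

The k-sweep analysis runs at rate level (Poisson detector emulation via
`measure_rates`) rather than re-rendering signals per k: the z-scoring and
modelling stages under study are identical either way, and the sweep is about
atlas neighbourhood size, not detection.

## Known limitations

- Detector window lengths and the verification thresholds are taken from the
  original detector literature and exposed in config; exact numerical
  equivalence with any specific MATLAB toolbox implementation is not claimed.
- The MNI baseline detector uses spectral flatness rather than wavelet
  entropy; both identify oscillation-free background, but channel-level event
  sets may differ from the original implementation.
- The synthetic cohort's covariates are jointly independent; effects that
  depend on covariate correlation (confounding, collinearity-driven
  separation) are under-represented.
- EDF I/O targets the plain 16-bit EDF subset (uniform rate, integral-second
  records); EDF+ annotations are ignored on read.
- MI is estimated over the whole epoch; sliding-window MI and alternative
  phase-amplitude coupling estimators (KL-divergence MI, GLM-PAC) are out of
  scope.
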