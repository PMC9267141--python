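# Methods

## Overview

`hrbp` implements a lagged cross-correlation analysis of heart rate (HR)
and blood pressure (BP) reactivity: beat-series cleaning, 1-Hz resampling,
the ±30-lag sample cross-correlation function with a 2×SE significance
rule, a six-type classification of correlogram shapes, per-subject
central/peripheral/mixed meta-typing, and cohort-level statistics
(multivariate repeated-measures ANOVA, chi-square goodness of fit,
contingency crossing).  A synthetic generator of coupled HR–BP beat series
provides planted ground truth for validation.

## Preprocessing

**Flagging.**  Real analyses of this kind screen beat-detection errors
visually; `flag_artifacts` automates the screen.  Beat *i* is flagged when
|RRᵢ − m_RR| > 0.3·m_RR or |SBPᵢ − m_SBP| > 25 mmHg, where the *m*'s are
medians over the centered 11-beat window excluding beat *i* (truncated at
the edges).  The defaults (relative RR tolerance 0.3, absolute SBP
tolerance 25 mmHg, window 11) follow common heart-rate-variability artifact
heuristics; all are configurable.  A spuriously doubled peak halves the
apparent RR (deviation 50% ≫ 30%) and roughly halves the measured
pressures, so the canonical failure mode is caught with wide margin, while
clean synthetic records at default noise are never flagged (deviations of
4–5 σ from a local median would be required).

**Repair and rejection.**  An isolated flagged beat takes the arithmetic
mean of its two neighbours' RR and pressures (boundary beats copy the
single available neighbour — a choice that preserves series length with
minimal distortion).  Any run of ≥2 consecutive flagged beats rejects the
whole record: two adjacent corrupted beats leave no trustworthy local
reference, and interpolating across them would fabricate exactly the
dynamics the analysis measures.  Repair is idempotent and touches only
flagged beats.

**Derivation and resampling.**  HR = 60/RR bpm; MBP = DBP + PP/3 (the
standard one-third pulse-pressure approximation, used when the acquisition
device's own mean pressure is unavailable).  Resampling onto the grid
t = 1, 2, …, floor(last beat time) uses last-observation-carried-forward:
each output value is an actual beat measurement (no interpolation), which
keeps the uniform series faithful to what the detector produced and makes
the resampling exactly reproducible.  Grid points before the first beat
are dropped.  A fully covered 150-s record yields 148–149 samples.

## Cross-correlation and significance

The estimator is the standard sample CCF with full-series means and
standard deviations (divisor n):

    r(k) = C(k) / (s_HR · s_BP),
    C(k) = (1/n) Σ_{t} (HR_t − mean)(BP_{t+k} − mean),   k = −30 … +30.

Positive k means HR leads (BP at t+k pairs with HR at t).  Per-lag
standard errors use the white-noise bound SE(k) = 1/√(n − |k|), the
convention of the classic CCF output in mainstream statistics packages,
and a lag is significant when |r(k)| ≥ 2·SE(k) (two-sided, ≈95%).

**Caveat, load-bearing.**  The white-noise bound understates the variance
of r(k) for autocorrelated series by the factor 1 + 2·Σⱼ ρ_HR(j)ρ_BP(j).
For AR(1)-like series with lag-1 autocorrelation φ = 0.8 this factor is
≈4.6, i.e. the nominal 5% per-lag false-positive rate is really ~35%.  The
rule is kept because it is what this analysis tradition uses, but its
consequences for classification stability are measured and documented
below rather than hidden.

**Maximum CC.**  Among significant lags the CC of greatest absolute value
is selected, sign retained; ties break to the smaller |lag|, then to the
negative lag.  When no lag is significant the global absolute extremum is
returned flagged `from_significant=False`, so paired cohort analyses have
no missing cells.

## Profile classification

With S significant lags (P positive, N negative), in order: fewer than
s_min=5 significant lags → NONSIG; P/S ≥ 0.8 → POSITIVE; N/S ≥ 0.8 →
NEGATIVE; if each half-axis holds ≥2 significant lags and ≥80% of the
negative-half lags are positive while ≥80% of the positive-half lags are
negative → the split type (mirrored test → the mirrored split); otherwise
CYCLES.  Sign runs ignore interleaved non-significant lags, since curve
shapes are judged gap-tolerantly.  s_min=5 operationalises
"non-significant": under independence with 61 white-noise-calibrated tests
≈3 false significants are expected, so requiring 5 keeps truly uncoupled
records in NONSIG.  The 0.8 majority is deliberately strict to separate
the majority types from CYCLES; both parameters are exposed.

Meta-typing: a subject whose *rumination* profile is POSITIVE is CENTRAL
(co-activation persists under negative emotion); rumination in
{CYCLES, NEGATIVE, splits} with a non-POSITIVE math profile is PERIPHERAL;
everything else (including a positive-math/cyclic-rumination switcher) is
MIXED.  Alternative readings (e.g. CENTRAL requiring POSITIVE in both
tasks) can be built from the exposed labels.

## Cohort statistics

Repeated-measures ANOVAs use the multivariate approach: form the
p = c − 1 within-subject difference variables, compute Hotelling
T² = n·d̄ᵀS⁻¹d̄, then Λ = 1/(1 + T²/(n−1)), F = T²(n−p)/(p(n−1)) with
df (p, n−p), and partial η² = 1 − Λ — an exact identity in the one-way
case, which the implementation enforces and tests.  With two conditions
this reduces exactly to the squared paired t-test (verified against
`scipy.stats.ttest_rel` to 1e-10).  Incomplete subjects are dropped
listwise and counted.  Chi-square goodness of fit defaults to uniform
expected counts over the six profile types; the contingency table crosses
rumination types (rows) with math types (columns) over subjects valid in
both tasks.  The HR–SBP pair is the primary endpoint for classification
and contingency; HR–DBP and HR–MBP are computed throughout and agree in
shape on strongly coupled synthetic records (tested).

## Synthetic generator

Latent unit-variance AR(1) processes on a 1-s grid (coefficient 0.8 by
default) drive both channels:

* **central** — SBP_latent(t) = strength·HR_latent(t−d) + noise; positive
  CC peak at +d.
* **peripheral** — HR_latent(t) = −strength·SBP_latent(t−d) + noise;
  negative peak at −d (baroreflex-like).
* **cyclic** — shared sinusoid (period 20 s, quarter-period phase offset)
  plus noise; alternating-sign correlogram with 2–3 cycles inside ±30 lags.
* **independent** — two independent latents.
* **split_pos_neg / split_neg_pos** — two cross-coupled innovations
  u, v: HR(t) = u(t) ± s·v(t−d), BP(t) = v(t) ∓ s·u(t−d); positive CCs on
  one half-axis, negative on the other, with peak magnitude
  s(1−φ^{2d})/(1+s²) ≤ ½.  The private components u, v play the noise
  role; `noise_sd` is not a separate term here.

Beats are placed cumulatively with RR = (60/base_HR)·(1 − 0.05·z_HR) at
the beat's own time, pressures sample the latent BP process at the beat
time (SBP scale 6 mmHg; DBP = SBP − pulse pressure + 1.5 mmHg noise), so
HR series and beat clock are mutually consistent.  Defaults — HR 68 bpm,
SBP 130, DBP 70 mmHg, 150-s records — sit in the observed task-condition
ranges for seated adults.  Artifact injection multiplies RR and pressures
by 0.5 (a doubled-peak detection) at isolated beats (p = 0.02/beat) and,
rarely, runs of 2–3 beats (p = 0.0008/beat, giving a per-record rejection
probability near the 7–24% attrition typical of such studies).  Everything
is deterministic given the spec seeds or a cohort master seed.

What the generator does *not* emulate: respiratory sinus arrhythmia and
Mayer-wave band structure, non-stationary task-onset transients,
measurement drift of finger-cuff devices, and ectopic-beat morphology.
Passing tests therefore demonstrate correctness of the pipeline's
*mechanics* on AR-like coupled series, not that real recordings are this
well behaved.

## Validation conditions and their rationale

Planted-regime recovery is validated where the CC estimator is precise
enough for the shape rules to see the planted structure:

| regime        | ar_coef | strength | delay | duration |
|---------------|---------|----------|-------|----------|
| central       | 0.95    | 2.0      | 3 s   | 600 s    |
| peripheral    | 0.95    | 2.0      | 4 s   | 600 s    |
| cyclic        | 0.8     | 2.0      | —     | 600 s    |
| splits        | 0.95    | 1.0      | 10 s  | 4800 s   |

Measured recovery is 93–100% per regime across seeds, and independent
*white-noise* pairs (the condition under which the 2×SE rule is actually
calibrated) land in NONSIG in ≈95% of 150-s records.

The slow latents (φ = 0.95, time constants ~20 s, in the range of real
task-epoch autonomic components) produce the broad consistent-sign
significant bands the classification grammar expects; the long records
shrink the correlogram's sampling ripple relative to the planted
structure.  At the study-scale 150-s records with φ = 0.8 the same
experiment yields only ~35–70% recovery for the non-cyclic regimes: the
white-noise SE under-coverage and the compensating negative mass that
mean-centered cross-covariances must carry at far lags together produce
wrong-sign significant clusters in a large fraction of records, pushing
them into CYCLES.  This instability is a property of the 2×SE rule at
n ≈ 149, not of the implementation, and is worth knowing before trusting
single-record profile labels from 2.5-minute tasks.  The split regimes
need the longest records because their peak correlation is capped at ½.

## Numerical choices and degenerate inputs

Constant series, missing values, and series shorter than 2·max_lag + 1 are
rejected with explicit errors.  Zero difference variance with zero mean
difference yields T² = 0 (Λ = 1, F = 0, p = 1); a singular difference
covariance with non-zero mean raises.  Explicit chi-square expected
vectors are rescaled to the observed total.  Max-CC ties are broken
deterministically (smaller |lag|, then negative lag first).  Cohort
per-record seeds derive from a master seed via `numpy` SeedSequence and
stay below 2³¹.

## Known limitations

* The SE formula ignores autocorrelation; prewhitening or
  Bartlett-corrected bounds would change which lags are significant and
  are deliberately out of scope.
* Profile labels from single 150-s records are noisy (see above); the
  pipeline reports per-lag evidence (`ProfileLabel.evidence`) so users can
  judge stability.
* The meta-typing decision table is one consistent reading of the
  central/peripheral construct; it is exposed as data, not hard-wired into
  the statistics.
* No detrending or filtering is applied to the uniform series by design;
  slow drifts therefore dominate the correlogram exactly as they would in
  the traditional analysis.
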