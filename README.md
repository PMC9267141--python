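# hrbp — heart rate–blood pressure cross-correlation reactivity profiles

`hrbp` analyses how heart rate (HR) and blood pressure (BP) co-vary in time
during short psychophysiological task recordings, and classifies each
person's *hemodynamic reactivity profile*.  It is aimed at
psychophysiologists and biostatisticians working with beat-to-beat
laboratory recordings (ECG-derived RR intervals plus continuous
finger-cuff pressures) who want a reproducible, scriptable version of the
classic lagged cross-correlation analysis.

## The method

Each subject-task record is a beat series: beat times, RR intervals
(seconds), and per-beat systolic/diastolic pressures (mmHg).  The pipeline:

1. **Cleaning.**  Beats whose RR or SBP deviate grossly from a local median
   are flagged.  An isolated flagged beat is repaired with the mean of its
   neighbours; a run of two or more consecutive flagged beats makes the
   record unusable and it is rejected.
2. **Derivation and resampling.**  HR = 60/RR (bpm) and mean pressure
   MBP = DBP + (SBP − DBP)/3 are derived per beat, then each channel is
   resampled onto a 1-s grid by carrying the most recent beat forward, so a
   ~150-s task yields 148–149 samples.
3. **Lagged cross-correlation.**  For each BP channel, the sample CCF

   r(k) = (1/n) Σₜ (HRₜ − H̄R)(BPₜ₊ₖ − B̄P) / (s_HR · s_BP),  k = −30 … +30 s

   where a *positive* lag means HR leads and BP follows.  A lag is
   significant when |r(k)| ≥ 2·SE with SE = 1/√(n − |k|), and the maximum
   (positive or negative) significant CC is extracted per record.
4. **Profile classification.**  The signs and arrangement of the
   significant lags assign one of six shape types — majority-positive,
   majority-negative, non-significant, several sign cycles, or one of the
   two split patterns (positive CCs on one lag half-axis, negative on the
   other).  A subject's (math, rumination) pair of labels folds into a
   **central** (co-activation persists under rumination), **peripheral**
   (baroreflex-like balancing), or **mixed** meta-type.
5. **Cohort statistics.**  One-way repeated-measures ANOVAs in the
   multivariate form (Hotelling T² → Wilks' Λ, F, partial η² = 1 − Λ) on
   condition means and per-subject maximum CCs, chi-square goodness of fit
   over profile frequencies, and the 6×6 math×rumination contingency
   crossing.

Because beat-to-beat laboratory data of this kind are rarely shareable, the
package ships a first-class synthetic generator (`hrbp.simulate`) that
produces coupled HR–BP beat series with planted coupling regime, delay,
strength and beat-detection artifacts, so every stage is testable against
known ground truth.

## Worked example

```python
from hrbp import ReactivityStudy, generate_cohort
from hrbp.experiments import study_like_plan

beats, truth = generate_cohort(study_like_plan(1), master_seed=1)
results = ReactivityStudy(beats).fit()
print(results.summary())
```

prints (abridged):

```
Hemodynamic Reactivity Analysis
================================================================
        math:  31 records in,   4 rejected,  27 analyzed
  rumination:  31 records in,   4 rejected,  27 analyzed
  both tasks:  23 subjects valid

Maximum CC comparison between tasks (HR vs channel)
  HR-SBP: math=+0.459, rumination=-0.094; Lambda=0.751, F(1,22)=7.30, p=0.0130, eta^2=0.249 (n=23)

Profile frequencies (HR-SBP)
  math: positive=8, ..., cycles=14, negative=3, ...  chi2(5)=33.67, p=0.0000
  rumination: positive=2, ..., cycles=17, negative=5, ...  chi2(5)=44.78, p=0.0000

Meta-types: peripheral=14, mixed=7, central=2
```

Four records per task were rejected for consecutive beat-detection errors;
23 subjects have valid data in both tasks.  The mean maximum HR–SBP CC is
clearly positive under the cognitive task and near zero/negative under
rumination (Wilks' Λ = 0.751, partial η² = 0.249), and the rumination task
is dominated by cyclic (alternating-sign) profiles — the self-balancing,
'peripheral' pattern.

The same pipeline runs from the shell:

```bash
hrbp run-all --seed 1 --out-dir out/           # simulate -> ... -> stats
hrbp simulate --n-subjects 8 --regimes central,cyclic --seed 2 --out-dir out2/
hrbp preprocess out2/beats.csv --out-dir out2/
hrbp cc out2/uniform.csv --out-dir out2/
hrbp classify out2/cc.csv --out out2/labels.csv
hrbp stats out2/beats.csv --out out2/stats.json
```

All intermediate artifacts are plain CSV/JSON.

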