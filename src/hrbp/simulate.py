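"""Synthetic coupled heart rate / blood pressure beat-series generator.

Every record is driven by a pair of latent second-scale processes whose
cross-dependence is known by construction, so each downstream stage of the
pipeline (artifact repair, resampling, lagged cross-correlation, profile
classification) can be validated against planted ground truth.

Coupling regimes
----------------
``central``
    HR leads: the latent pressure process is a delayed, positively scaled
    copy of the latent HR process plus noise, so the cross-correlogram
    peaks positively at lag ``+delay_s``.
``peripheral``
    BP leads and HR compensates in the opposite direction, a
    baroreflex-like negative feedback: the correlogram peaks negatively
    at lag ``-delay_s``.
``cyclic``
    Both series share a sinusoid (default period 20 s) with a quarter-period
    phase offset, producing a correlogram that alternates sign across lags.
``independent``
    Two independent latent processes; no true coupling at any lag.
``split_pos_neg`` / ``split_neg_pos``
    Two cross-coupled innovations giving positive correlations on one
    half-axis of lags and negative on the other (and the mirror image).

The latent processes are AR(1) on a 1-s grid (coefficient 0.8 by default,
giving realistic short-range autocorrelation); beats are placed cumulatively
with RR intervals modulated by the latent HR process, and per-beat pressures
sample the latent BP process at the beat time, which is what a beat detector
applied to a continuous pressure trace would emit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .series import BeatSeries

REGIMES = (
    "central",
    "peripheral",
    "cyclic",
    "independent",
    "split_pos_neg",
    "split_neg_pos",
)

_MAX_DETECTABLE_DELAY = 30  # lags beyond the +/-30 s analysis window are invisible


@dataclass(frozen=True)
class CouplingSpec:
    """Ground-truth description of one synthetic subject-task record.

    ``strength`` and ``noise_sd`` weight the shared (coupled) and private
    latent components; with unit-variance latents the true peak correlation
    of the central/peripheral regimes is ``strength / sqrt(strength**2 +
    noise_sd**2)``.  ``hr_rel_sd`` and ``sbp_sd_mmhg`` scale the latent
    processes onto physiological units and do not affect correlations.
    """

    regime: str
    delay_s: int = 3
    strength: float = 2.0
    noise_sd: float = 0.5
    ar_coef: float = 0.8
    period_s: float = 20.0
    duration_s: float = 150.0
    base_hr_bpm: float = 68.0
    base_sbp_mmhg: float = 130.0
    base_dbp_mmhg: float = 70.0
    hr_rel_sd: float = 0.05
    sbp_sd_mmhg: float = 6.0
    dbp_noise_mmhg: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}; expected one of {REGIMES}")
        if not (1 <= int(self.delay_s) <= _MAX_DETECTABLE_DELAY):
            raise ValueError(
                f"delay_s must be in [1, {_MAX_DETECTABLE_DELAY}] s to be detectable"
            )
        if self.duration_s < 60:
            raise ValueError("duration_s must be >= 60 s")
        if self.base_sbp_mmhg <= self.base_dbp_mmhg:
            raise ValueError("base_sbp_mmhg must exceed base_dbp_mmhg")
        if self.strength <= 0:
            raise ValueError("strength must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (-1 < self.ar_coef < 1):
            raise ValueError("ar_coef must lie in (-1, 1)")
        if self.period_s <= 0:
            raise ValueError("period_s must be positive")


@dataclass(frozen=True)
class ArtifactSpec:
    """Beat-detection error model.

    ``p_single`` is the per-beat probability of an isolated corrupted beat;
    ``p_consecutive`` the per-beat probability of starting a run of two or
    more corrupted beats (the kind of error that forces record rejection).
    ``magnitude`` multiplies RR and both pressures at corrupted beats; the
    default 0.5 mimics a spuriously doubled peak detection, which halves the
    apparent RR interval.  ``single_beats`` and ``runs`` force corruptions at
    known positions for testing.
    """

    p_single: float = 0.02
    p_consecutive: float = 0.0008
    magnitude: float = 0.5
    seed: int = 0
    single_beats: tuple[int, ...] = ()
    runs: tuple[tuple[int, int], ...] = ()  # (start_beat, run_length)

    def validate(self) -> None:
        for name in ("p_single", "p_consecutive"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.magnitude == 1:
            raise ValueError("magnitude must differ from 1")
        for start, length in self.runs:
            if length < 2:
                raise ValueError("forced runs must have length >= 2")


def _ar1(rng: np.random.Generator, n: int, phi: float) -> np.ndarray:
    """Stationary unit-variance AR(1) path; phi=0 gives white noise."""
    if phi == 0.0:
        return rng.standard_normal(n)
    x = np.empty(n)
    x[0] = rng.standard_normal()
    innov_sd = np.sqrt(1.0 - phi * phi)
    e = rng.standard_normal(n - 1) * innov_sd
    for i in range(1, n):
        x[i] = phi * x[i - 1] + e[i - 1]
    return x


def _latent_pair(spec: CouplingSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Unit-scale latent HR and BP processes on the 1-s grid."""
    m = int(np.ceil(spec.duration_s)) + 2
    d = int(spec.delay_s)
    s, nsd, phi = spec.strength, spec.noise_sd, spec.ar_coef
    if spec.regime == "central":
        a = _ar1(rng, m + d, phi)
        b = _ar1(rng, m, phi)
        z_hr = a[d:]
        z_bp = (s * a[:m] + nsd * b) / np.hypot(s, nsd)
    elif spec.regime == "peripheral":
        b = _ar1(rng, m + d, phi)
        a = _ar1(rng, m, phi)
        z_bp = b[d:]
        z_hr = (-s * b[:m] + nsd * a) / np.hypot(s, nsd)
    elif spec.regime == "cyclic":
        t = np.arange(m, dtype=float)
        norm = np.sqrt(s * s / 2.0 + nsd * nsd)
        wave_hr = s * np.sin(2 * np.pi * t / spec.period_s)
        wave_bp = s * np.sin(2 * np.pi * (t - spec.period_s / 4.0) / spec.period_s)
        z_hr = (wave_hr + nsd * _ar1(rng, m, phi)) / norm
        z_bp = (wave_bp + nsd * _ar1(rng, m, phi)) / norm
    elif spec.regime == "independent":
        z_hr = _ar1(rng, m, phi)
        z_bp = _ar1(rng, m, phi)
    elif spec.regime in ("split_pos_neg", "split_neg_pos"):
        u = _ar1(rng, m + d, phi)  # HR-specific innovation
        v = _ar1(rng, m + d, phi)  # BP-specific innovation
        norm = np.hypot(1.0, s)
        if spec.regime == "split_pos_neg":
            z_hr = (u[d:] + s * v[:m]) / norm
            z_bp = (v[d:] - s * u[:m]) / norm
        else:
            z_hr = (u[d:] - s * v[:m]) / norm
            z_bp = (v[d:] + s * u[:m]) / norm
    else:  # pragma: no cover - guarded by validate()
        raise ValueError(spec.regime)
    return z_hr, z_bp


def generate_beat_pair(
    spec: CouplingSpec, subject_id: str = "sim", task: str = "task"
) -> BeatSeries:
    """Generate one beat-level record with the coupling described by *spec*.

    Beats are placed cumulatively from t = 0 with
    ``RR_i = (60 / base_hr_bpm) * (1 - hr_rel_sd * z_hr(t_i))``, so heart
    rate tracks the latent HR process; per-beat SBP samples the latent BP
    process at the beat time, and DBP is SBP minus the pulse pressure implied
    by the bases, plus small independent noise.  Deterministic given
    ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    z_hr, z_bp = _latent_pair(spec, rng)
    m = z_hr.size
    rr_base = 60.0 / spec.base_hr_bpm

    times: list[float] = []
    rrs: list[float] = []
    hr_idx: list[int] = []
    t = 0.0
    while True:
        # sample the latent HR process near the upcoming beat's own time so the
        # beat-level HR and BP channels stay aligned on the latent grid
        i = min(int(t + rr_base), m - 1)
        rr = rr_base * (1.0 - spec.hr_rel_sd * z_hr[i])
        rr = max(rr, 0.2)
        t_next = t + rr
        if t_next > spec.duration_s:
            break
        times.append(t_next)
        rrs.append(rr)
        hr_idx.append(i)
        t = t_next

    beat_t = np.asarray(times)
    idx = np.minimum(np.floor(beat_t).astype(int), m - 1)
    sbp = spec.base_sbp_mmhg + spec.sbp_sd_mmhg * z_bp[idx]
    pulse_pressure = spec.base_sbp_mmhg - spec.base_dbp_mmhg
    dbp = sbp - pulse_pressure + spec.dbp_noise_mmhg * rng.standard_normal(beat_t.size)

    return BeatSeries(
        subject_id=subject_id,
        task=task,
        beat_time_s=beat_t,
        rr_s=np.asarray(rrs),
        sbp_mmhg=sbp,
        dbp_mmhg=dbp,
        meta={
            "regime": spec.regime,
            "delay_s": int(spec.delay_s),
            "seed": int(spec.seed),
            "corrupted_beats": [],
        },
    )


def inject_artifacts(series: BeatSeries, spec: ArtifactSpec) -> BeatSeries:
    """Return a copy of *series* with corrupted beats.

    RR and both pressures at corrupted beats are multiplied by
    ``spec.magnitude``; the positions are recorded in
    ``meta['corrupted_beats']``.  Forced positions (``single_beats``,
    ``runs``) are applied first, then random corruptions drawn per beat.
    Deterministic given ``spec.seed``.
    """
    spec.validate()
    n = series.n_beats
    if n < 3:
        raise ValueError("series must have at least 3 beats")
    rng = np.random.default_rng(spec.seed)
    corrupt = np.zeros(n, dtype=bool)
    for b in spec.single_beats:
        corrupt[b] = True
    for start, length in spec.runs:
        corrupt[start : start + length] = True
    u = rng.random(n)
    run_len = 2 + rng.integers(0, 2, size=n)  # runs of 2 or 3 beats
    i = 0
    while i < n:
        if corrupt[i]:
            i += 1
            continue
        if u[i] < spec.p_consecutive:
            corrupt[i : i + int(run_len[i])] = True
            i += int(run_len[i])
        elif u[i] < spec.p_consecutive + spec.p_single:
            corrupt[i] = True
            i += 2  # keep random singles isolated
        else:
            i += 1
    out = series.copy()
    out.rr_s[corrupt] *= spec.magnitude
    out.sbp_mmhg[corrupt] *= spec.magnitude
    out.dbp_mmhg[corrupt] *= spec.magnitude
    out.meta["corrupted_beats"] = np.flatnonzero(corrupt).tolist()
    return out


@dataclass(frozen=True)
class CohortEntry:
    """One subject-task cell of a simulated cohort."""

    subject_id: str
    task: str
    coupling: CouplingSpec
    artifacts: ArtifactSpec | None = None


def _derive_seed(master_seed: int, index: int) -> int:
    ss = np.random.SeedSequence([int(master_seed), int(index)])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_cohort(
    plan: Sequence[CohortEntry], master_seed: int = 0
) -> tuple[list[BeatSeries], pd.DataFrame]:
    """Generate every record in *plan* plus a ground-truth table.

    Per-record seeds are derived deterministically from ``master_seed`` and
    the record's position, so the whole cohort is reproducible from the plan
    and one integer.  A coupling spec with a non-zero ``seed`` keeps it.
    """
    keys = [(e.subject_id, e.task) for e in plan]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate subject_id x task keys in cohort plan")
    records: list[BeatSeries] = []
    truth_rows = []
    for i, entry in enumerate(plan):
        cspec = entry.coupling
        if cspec.seed == 0:
            cspec = replace(cspec, seed=_derive_seed(master_seed, 2 * i))
        rec = generate_beat_pair(cspec, subject_id=entry.subject_id, task=entry.task)
        if entry.artifacts is not None:
            aspec = entry.artifacts
            if aspec.seed == 0:
                aspec = replace(aspec, seed=_derive_seed(master_seed, 2 * i + 1))
            rec = inject_artifacts(rec, aspec)
        records.append(rec)
        truth_rows.append(
            {
                "subject_id": entry.subject_id,
                "task": entry.task,
                "regime": cspec.regime,
                "delay_s": int(cspec.delay_s),
                "corrupted_beats": ";".join(
                    str(b) for b in rec.meta.get("corrupted_beats", [])
                ),
            }
        )
    return records, pd.DataFrame(
        truth_rows, columns=["subject_id", "task", "regime", "delay_s", "corrupted_beats"]
    )


def mixture_plan(
    regime_counts: dict[str, dict[str, int]],
    artifacts: ArtifactSpec | None = None,
    coupling_defaults: dict | None = None,
    per_regime_overrides: dict[str, dict] | None = None,
) -> list[CohortEntry]:
    """Build a cohort plan from per-task regime counts.

    ``regime_counts`` maps task -> {regime: n_subjects}.  Subjects are named
    s001, s002, ... in order; tasks must list the same total so every subject
    has one record per task.  ``per_regime_overrides`` adjusts coupling
    parameters for specific regimes (e.g. white-noise independents).
    """
    tasks = list(regime_counts)
    totals = {t: sum(regime_counts[t].values()) for t in tasks}
    if len(set(totals.values())) != 1:
        raise ValueError(f"tasks disagree on subject totals: {totals}")
    n_subjects = next(iter(totals.values()))
    subject_ids = [f"s{i + 1:03d}" for i in range(n_subjects)]
    defaults = coupling_defaults or {}
    overrides = per_regime_overrides or {}
    plan = []
    for task in tasks:
        regimes: list[str] = []
        for regime, count in regime_counts[task].items():
            regimes.extend([regime] * count)
        for sid, regime in zip(subject_ids, regimes):
            kwargs = dict(defaults)
            kwargs.update(overrides.get(regime, {}))
            plan.append(
                CohortEntry(
                    subject_id=sid,
                    task=task,
                    coupling=CouplingSpec(regime=regime, **kwargs),
                    artifacts=artifacts,
                )
            )
    return plan
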