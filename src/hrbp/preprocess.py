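"""Beat-level artifact handling and 1-Hz resampling.

The cleaning policy distinguishes two error classes, mirroring how
beat-detection failures are handled in practice:

* an *isolated* corrupted beat is repaired by replacing its RR interval and
  pressures with the mean of the neighbouring beats;
* a run of *two or more consecutive* corrupted beats cannot be repaired
  reliably, so the whole record is rejected.

Flagging is an automated surrogate for visual inspection: a beat is flagged
when its RR interval deviates from the local median by more than a relative
tolerance, or its SBP deviates by more than an absolute tolerance.  After
repair, heart rate (60/RR) and mean pressure (DBP + pulse pressure / 3) are
derived, and the record is resampled onto a 1-second grid by carrying the
most recent beat's values forward (sample-and-hold; no interpolation is
invented).  A fully covered 150-s record yields 148-149 samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import BeatSeries, UniformSeries

DEFAULT_RR_TOL = 0.3
DEFAULT_BP_TOL = 25.0
DEFAULT_WINDOW = 11


def flag_artifacts(
    series: BeatSeries,
    rr_tol: float = DEFAULT_RR_TOL,
    bp_tol: float = DEFAULT_BP_TOL,
    window: int = DEFAULT_WINDOW,
) -> BeatSeries:
    """Mark suspect beats against local medians.

    Beat *i* is flagged iff ``|rr_i - med_rr| > rr_tol * med_rr`` or
    ``|sbp_i - med_sbp| > bp_tol`` where the medians are taken over the
    centered window of ``window`` beats excluding beat *i* (truncated at the
    record edges).  Returns a flagged copy; deterministic.
    """
    n = series.n_beats
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > n:
        raise ValueError(f"window {window} larger than series ({n} beats)")
    h = window // 2
    rr, sbp = series.rr_s, series.sbp_mmhg

    def local_medians(x: np.ndarray) -> np.ndarray:
        med = np.empty(n)
        if n > window:
            # interior beats: full windows with the center column removed
            win = np.lib.stride_tricks.sliding_window_view(x, window)
            win = np.delete(win, h, axis=1)
            med[h : n - h] = np.median(win, axis=1)
        edge = list(range(h)) + list(range(max(h, n - h), n))
        for i in edge:
            lo, hi = max(0, i - h), min(n, i + h + 1)
            nb = np.r_[lo:i, i + 1 : hi]
            med[i] = np.median(x[nb])
        return med

    med_rr = local_medians(rr)
    med_sbp = local_medians(sbp)
    flags = (np.abs(rr - med_rr) > rr_tol * med_rr) | (np.abs(sbp - med_sbp) > bp_tol)
    out = series.copy()
    out.flags = flags
    return out


@dataclass(frozen=True)
class RejectionVerdict:
    """Keep/reject decision for one record."""

    kept: bool
    reason: str | None = None
    run_start: int | None = None
    run_length: int | None = None


def reject_record(series: BeatSeries) -> RejectionVerdict:
    """Reject iff the flags contain a run of >= 2 consecutive marked beats."""
    if series.flags is None:
        raise ValueError("flags not computed; run flag_artifacts first")
    flags = series.flags
    i = 0
    n = flags.size
    while i < n:
        if flags[i]:
            j = i
            while j + 1 < n and flags[j + 1]:
                j += 1
            if j > i:
                length = j - i + 1
                return RejectionVerdict(
                    kept=False,
                    reason=f"{length} consecutive flagged beats at index {i}",
                    run_start=i,
                    run_length=length,
                )
            i = j + 1
        else:
            i += 1
    return RejectionVerdict(kept=True)


def repair_single_flags(series: BeatSeries) -> BeatSeries:
    """Repair isolated flagged beats by neighbour averaging.

    A flagged beat whose adjacent beats are both unflagged takes the
    arithmetic mean of their RR and pressures and has its flag cleared.
    Flagged beats at the record boundary copy the single available
    neighbour.  Members of runs of >= 2 consecutive flags are left untouched
    (those records are rejected instead).  Identity on unflagged input;
    idempotent.
    """
    if series.flags is None:
        raise ValueError("flags not computed; run flag_artifacts first")
    out = series.copy()
    flags = series.flags
    n = flags.size
    for i in np.flatnonzero(flags):
        left = i - 1 if i > 0 else None
        right = i + 1 if i < n - 1 else None
        if (left is not None and flags[left]) or (right is not None and flags[right]):
            continue  # part of a run; not repairable
        for arr in (out.rr_s, out.sbp_mmhg, out.dbp_mmhg):
            if left is None:
                arr[i] = arr[right]
            elif right is None:
                arr[i] = arr[left]
            else:
                arr[i] = 0.5 * (arr[left] + arr[right])
        out.flags[i] = False
    return out


def derive_hemodynamics(series: BeatSeries) -> BeatSeries:
    """Attach per-beat heart rate and mean pressure.

    ``hr_bpm = 60 / rr_s`` and ``mbp_mmhg = dbp + (sbp - dbp) / 3``, the
    standard one-third pulse-pressure approximation to mean arterial
    pressure.
    """
    if np.any(series.rr_s <= 0):
        raise ValueError("rr_s must be positive to derive heart rate")
    out = series.copy()
    out.hr_bpm = 60.0 / out.rr_s
    out.mbp_mmhg = out.dbp_mmhg + (out.sbp_mmhg - out.dbp_mmhg) / 3.0
    return out


def resample_1hz(series: BeatSeries) -> UniformSeries:
    """Resample onto the grid t = 1, 2, ..., floor(last beat time) seconds.

    The value at grid second *t* is the most recent beat's value at or
    before *t* (last observation carried forward); grid points before the
    first beat are dropped.  Selecting rather than averaging keeps every
    output value an actual beat measurement.
    """
    if series.hr_bpm is None or series.mbp_mmhg is None:
        raise ValueError("derive_hemodynamics must run before resampling")
    if series.n_beats < 2 or np.floor(series.beat_time_s[-1]) < 2:
        raise ValueError("record shorter than 2 s cannot be resampled")
    t = np.arange(1, int(np.floor(series.beat_time_s[-1])) + 1, dtype=float)
    t = t[t >= series.beat_time_s[0]]
    idx = np.searchsorted(series.beat_time_s, t, side="right") - 1
    return UniformSeries(
        subject_id=series.subject_id,
        task=series.task,
        t_s=t,
        hr_bpm=series.hr_bpm[idx],
        sbp_mmhg=series.sbp_mmhg[idx],
        dbp_mmhg=series.dbp_mmhg[idx],
        mbp_mmhg=series.mbp_mmhg[idx],
    )


def preprocess_record(
    series: BeatSeries,
    rr_tol: float = DEFAULT_RR_TOL,
    bp_tol: float = DEFAULT_BP_TOL,
    window: int = DEFAULT_WINDOW,
) -> tuple[UniformSeries | None, RejectionVerdict]:
    """Run flag -> reject -> repair -> derive -> resample on one record.

    Returns ``(uniform, verdict)``; ``uniform`` is ``None`` when the record
    is rejected.
    """
    flagged = flag_artifacts(series, rr_tol=rr_tol, bp_tol=bp_tol, window=window)
    verdict = reject_record(flagged)
    if not verdict.kept:
        return None, verdict
    repaired = repair_single_flags(flagged)
    derived = derive_hemodynamics(repaired)
    return resample_1hz(derived), verdict
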