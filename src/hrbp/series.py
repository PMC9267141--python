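"""Data containers for beat-level and evenly resampled hemodynamic records.

A :class:`BeatSeries` holds one subject-task recording as parallel per-beat
arrays: beat times, RR intervals, and systolic/diastolic pressures, plus
artifact flags and the derived heart-rate / mean-pressure channels once
preprocessing has run.  A :class:`UniformSeries` is the same record after
resampling onto a 1-second grid, which puts heart rate and blood pressure
on a common time base for lagged cross-correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

BEAT_COLUMNS = ["subject_id", "task", "beat_time_s", "rr_s", "sbp_mmhg", "dbp_mmhg"]
UNIFORM_COLUMNS = [
    "subject_id",
    "task",
    "t_s",
    "hr_bpm",
    "sbp_mmhg",
    "dbp_mmhg",
    "mbp_mmhg",
]


def _as_float(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


@dataclass
class BeatSeries:
    """One subject-task recording of beat-to-beat hemodynamics.

    Parameters
    ----------
    subject_id, task
        Identifiers of the recording.
    beat_time_s
        Strictly increasing beat (pulse) times in seconds.
    rr_s
        Inter-beat (RR) intervals in seconds, one per beat.
    sbp_mmhg, dbp_mmhg
        Per-beat systolic and diastolic pressures in mmHg.
    flags
        Boolean artifact marks, set by the preprocessing stage.
    hr_bpm, mbp_mmhg
        Derived heart rate (60/RR) and mean pressure (DBP + PP/3); ``None``
        until :func:`hrbp.preprocess.derive_hemodynamics` has run.
    meta
        Free-form provenance, e.g. the generating regime and the ground-truth
        corrupted beat indices for synthetic records.
    """

    subject_id: str
    task: str
    beat_time_s: np.ndarray
    rr_s: np.ndarray
    sbp_mmhg: np.ndarray
    dbp_mmhg: np.ndarray
    flags: np.ndarray | None = None
    hr_bpm: np.ndarray | None = None
    mbp_mmhg: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.beat_time_s = _as_float(self.beat_time_s)
        self.rr_s = _as_float(self.rr_s)
        self.sbp_mmhg = _as_float(self.sbp_mmhg)
        self.dbp_mmhg = _as_float(self.dbp_mmhg)
        n = self.beat_time_s.size
        for name in ("rr_s", "sbp_mmhg", "dbp_mmhg"):
            if getattr(self, name).size != n:
                raise ValueError(f"{name} length {getattr(self, name).size} != {n}")
        if self.flags is not None:
            self.flags = np.asarray(self.flags, dtype=bool)
            if self.flags.size != n:
                raise ValueError("flags length mismatch")
        if n and np.any(np.diff(self.beat_time_s) <= 0):
            raise ValueError("beat_time_s must be strictly increasing")

    @property
    def n_beats(self) -> int:
        return self.beat_time_s.size

    @property
    def duration_s(self) -> float:
        return float(self.beat_time_s[-1]) if self.n_beats else 0.0

    def copy(self) -> "BeatSeries":
        return BeatSeries(
            subject_id=self.subject_id,
            task=self.task,
            beat_time_s=self.beat_time_s.copy(),
            rr_s=self.rr_s.copy(),
            sbp_mmhg=self.sbp_mmhg.copy(),
            dbp_mmhg=self.dbp_mmhg.copy(),
            flags=None if self.flags is None else self.flags.copy(),
            hr_bpm=None if self.hr_bpm is None else self.hr_bpm.copy(),
            mbp_mmhg=None if self.mbp_mmhg is None else self.mbp_mmhg.copy(),
            meta=dict(self.meta),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "task": self.task,
                "beat_time_s": self.beat_time_s,
                "rr_s": self.rr_s,
                "sbp_mmhg": self.sbp_mmhg,
                "dbp_mmhg": self.dbp_mmhg,
            }
        )

    @staticmethod
    def from_frame(df: pd.DataFrame) -> list["BeatSeries"]:
        """Split a tidy beat table (one row per beat) into records."""
        missing = [c for c in BEAT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"beat table missing columns: {missing}")
        out = []
        for (sid, task), g in df.groupby(["subject_id", "task"], sort=True):
            g = g.sort_values("beat_time_s")
            out.append(
                BeatSeries(
                    subject_id=str(sid),
                    task=str(task),
                    beat_time_s=g["beat_time_s"].to_numpy(),
                    rr_s=g["rr_s"].to_numpy(),
                    sbp_mmhg=g["sbp_mmhg"].to_numpy(),
                    dbp_mmhg=g["dbp_mmhg"].to_numpy(),
                )
            )
        return out


@dataclass
class UniformSeries:
    """A record resampled onto the 1-s grid t = 1, 2, ..., n seconds."""

    subject_id: str
    task: str
    t_s: np.ndarray
    hr_bpm: np.ndarray
    sbp_mmhg: np.ndarray
    dbp_mmhg: np.ndarray
    mbp_mmhg: np.ndarray

    def __post_init__(self) -> None:
        self.t_s = _as_float(self.t_s)
        for name in ("hr_bpm", "sbp_mmhg", "dbp_mmhg", "mbp_mmhg"):
            arr = _as_float(getattr(self, name))
            setattr(self, name, arr)
            if arr.size != self.t_s.size:
                raise ValueError(f"{name} length mismatch")

    @property
    def n(self) -> int:
        return self.t_s.size

    def channel(self, name: str) -> np.ndarray:
        """Return one channel by short name: hr, sbp, dbp or mbp."""
        key = {"hr": "hr_bpm", "sbp": "sbp_mmhg", "dbp": "dbp_mmhg", "mbp": "mbp_mmhg"}
        try:
            return getattr(self, key[name.lower()])
        except KeyError:
            raise KeyError(f"unknown channel {name!r}; expected hr/sbp/dbp/mbp")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "task": self.task,
                "t_s": self.t_s,
                "hr_bpm": self.hr_bpm,
                "sbp_mmhg": self.sbp_mmhg,
                "dbp_mmhg": self.dbp_mmhg,
                "mbp_mmhg": self.mbp_mmhg,
            }
        )


def concat_beats(records: Iterable[BeatSeries]) -> pd.DataFrame:
    frames = [r.to_frame() for r in records]
    if not frames:
        return pd.DataFrame(columns=BEAT_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def concat_uniform(records: Iterable[UniformSeries]) -> pd.DataFrame:
    frames = [r.to_frame() for r in records]
    if not frames:
        return pd.DataFrame(columns=UNIFORM_COLUMNS)
    return pd.concat(frames, ignore_index=True)
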