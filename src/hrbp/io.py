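"""Plain-text readers and writers for every pipeline artifact (CSV / JSON)."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .series import BeatSeries, UniformSeries, concat_beats, concat_uniform


def write_beats_csv(records: Iterable[BeatSeries], path: str | Path) -> None:
    concat_beats(records).to_csv(path, index=False)


def read_beats_csv(path: str | Path) -> list[BeatSeries]:
    return BeatSeries.from_frame(pd.read_csv(path))


def write_ground_truth_csv(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, index=False)


def write_uniform_csv(records: Iterable[UniformSeries], path: str | Path) -> None:
    concat_uniform(records).to_csv(path, index=False)


def read_uniform_csv(path: str | Path) -> list[UniformSeries]:
    df = pd.read_csv(path)
    out = []
    for (sid, task), g in df.groupby(["subject_id", "task"], sort=True):
        g = g.sort_values("t_s")
        out.append(
            UniformSeries(
                subject_id=str(sid),
                task=str(task),
                t_s=g["t_s"].to_numpy(),
                hr_bpm=g["hr_bpm"].to_numpy(),
                sbp_mmhg=g["sbp_mmhg"].to_numpy(),
                dbp_mmhg=g["dbp_mmhg"].to_numpy(),
                mbp_mmhg=g["mbp_mmhg"].to_numpy(),
            )
        )
    return out


def write_cc_csv(results, path: str | Path) -> None:
    """Per-record, per-pair, per-lag CC table from a ReactivityResults."""
    rows = []
    for a in results.analyses.values():
        for pair, ccf in a.ccfs.items():
            for lag, cc, se, sig in zip(ccf.lags, ccf.cc, ccf.se, ccf.significant):
                rows.append(
                    {
                        "subject_id": a.subject_id,
                        "task": a.task,
                        "pair": pair,
                        "lag_s": int(lag),
                        "cc": float(cc),
                        "se": float(se),
                        "significant": bool(sig),
                    }
                )
    pd.DataFrame(
        rows, columns=["subject_id", "task", "pair", "lag_s", "cc", "se", "significant"]
    ).to_csv(path, index=False)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_json(payload: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonable(payload), indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
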