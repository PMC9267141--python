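"""The `ReactivityStudy` model: one object that takes a cohort of beat-level
records and, on `fit()`, runs the full analysis - cleaning, 1-Hz resampling,
lagged HR-BP cross-correlation, profile classification and the cohort
statistics - returning a `ReactivityResults` object with the estimates and a
`summary()` table.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import pandas as pd

from .series import BeatSeries, UniformSeries
from .preprocess import preprocess_record
from .crosscorr import cross_correlation, max_significant_cc, CCFunction, MaxCC
from .classify import (
    classify_profile,
    meta_classify,
    ProfileLabel,
    ProfileType,
    MetaProfile,
)
from .cohort_stats import (
    rm_anova_wilks,
    compare_max_ccs,
    chi_square_gof,
    cross_tabulate,
    profile_frequencies,
    RMAnovaResult,
    ChiSquareResult,
    ContingencyTable,
)

#: Channels correlated against heart rate.
DEFAULT_PAIRS = ("sbp", "dbp", "mbp")
#: Hemodynamic variables entering the condition-mean comparison.
CONDITION_VARIABLES = ("hr", "sbp", "dbp", "mbp")


@dataclass(frozen=True)
class AnalysisConfig:
    """All tunable thresholds of the pipeline, with their defaults."""

    tasks: tuple[str, ...] = ("math", "rumination")
    pairs: tuple[str, ...] = DEFAULT_PAIRS
    primary_pair: str = "sbp"
    max_lag: int = 30
    rr_tol: float = 0.3
    bp_tol: float = 25.0
    window: int = 11
    s_min: int = 5
    majority: float = 0.8

    def validate(self) -> None:
        if len(self.tasks) < 1:
            raise ValueError("at least one task label required")
        if self.primary_pair not in self.pairs:
            raise ValueError("primary_pair must be among pairs")
        if self.max_lag < 1:
            raise ValueError("max_lag must be >= 1")
        if self.window % 2 == 0 or self.window < 3:
            raise ValueError("window must be an odd integer >= 3")
        if not (0.5 < self.majority <= 1.0):
            raise ValueError("majority must lie in (0.5, 1]")
        if self.s_min < 1:
            raise ValueError("s_min must be >= 1")


@dataclass
class RecordAnalysis:
    """Everything computed for one kept subject-task record."""

    subject_id: str
    task: str
    uniform: UniformSeries
    ccfs: dict[str, CCFunction]
    max_ccs: dict[str, MaxCC]
    labels: dict[str, ProfileLabel]
    condition_means: dict[str, float]


class ReactivityStudy:
    """Hemodynamic reactivity analysis of a cohort of beat-level records.

    Parameters
    ----------
    beats
        The cohort as a list of :class:`BeatSeries` (one per subject-task)
        or a tidy beat table with columns subject_id, task, beat_time_s,
        rr_s, sbp_mmhg, dbp_mmhg.
    config
        Pipeline thresholds; defaults are sensible for ~150 s task records.

    Examples
    --------
    >>> study = ReactivityStudy.from_dataframe(beat_table)
    >>> results = study.fit()
    >>> print(results.summary())
    """

    def __init__(
        self,
        beats: Sequence[BeatSeries] | pd.DataFrame,
        config: AnalysisConfig | None = None,
    ):
        if isinstance(beats, pd.DataFrame):
            beats = BeatSeries.from_frame(beats)
        self.beats: list[BeatSeries] = list(beats)
        self.config = config or AnalysisConfig()
        self.config.validate()
        keys = [(b.subject_id, b.task) for b in self.beats]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate subject_id x task records")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, config: AnalysisConfig | None = None):
        return cls(df, config=config)

    def fit(self) -> "ReactivityResults":
        cfg = self.config
        analyses: dict[tuple[str, str], RecordAnalysis] = {}
        rejections: list[dict] = []
        for rec in self.beats:
            uniform, verdict = preprocess_record(
                rec, rr_tol=cfg.rr_tol, bp_tol=cfg.bp_tol, window=cfg.window
            )
            if uniform is None:
                rejections.append(
                    {
                        "subject_id": rec.subject_id,
                        "task": rec.task,
                        "verdict": "rejected",
                        "reason": verdict.reason,
                    }
                )
                continue
            hr = uniform.channel("hr")
            ccfs, maxes, labels = {}, {}, {}
            for pair in cfg.pairs:
                ccf = cross_correlation(
                    hr, uniform.channel(pair), max_lag=cfg.max_lag, pair=pair
                )
                ccfs[pair] = ccf
                maxes[pair] = max_significant_cc(ccf)
                labels[pair] = classify_profile(ccf, s_min=cfg.s_min, majority=cfg.majority)
            cond_means = {
                var: float(uniform.channel(var).mean()) for var in CONDITION_VARIABLES
            }
            analyses[(rec.subject_id, rec.task)] = RecordAnalysis(
                subject_id=rec.subject_id,
                task=rec.task,
                uniform=uniform,
                ccfs=ccfs,
                max_ccs=maxes,
                labels=labels,
                condition_means=cond_means,
            )
        return ReactivityResults(self, analyses, rejections)


class ReactivityResults:
    """Fit results: per-record tables and the cohort statistics.

    Attributes of interest: ``max_cc_table`` and ``label_table``
    (per-record DataFrames), ``condition_anovas`` and ``maxcc_anovas``
    (Wilks' repeated-measures results keyed by variable / BP channel),
    ``profile_chisq`` (per-task goodness of fit over the six types),
    ``contingency`` (the 6x6 task crossing), ``meta_profiles`` and
    ``manifest`` (per-stage record accounting).
    """

    def __init__(
        self,
        model: ReactivityStudy,
        analyses: dict[tuple[str, str], RecordAnalysis],
        rejections: list[dict],
    ):
        self.model = model
        self.config = model.config
        self.analyses = analyses
        self.rejections = rejections
        self._compute()

    # -- assembly ---------------------------------------------------------
    def _compute(self) -> None:
        cfg = self.config
        tasks = list(cfg.tasks)
        self.max_cc_table = pd.DataFrame(
            [
                {
                    "subject_id": a.subject_id,
                    "task": a.task,
                    "pair": pair,
                    "max_cc": m.value,
                    "max_lag": m.lag,
                    "from_significant": m.from_significant,
                }
                for a in self.analyses.values()
                for pair, m in a.max_ccs.items()
            ],
            columns=["subject_id", "task", "pair", "max_cc", "max_lag", "from_significant"],
        )
        self.label_table = pd.DataFrame(
            [
                {
                    "subject_id": a.subject_id,
                    "task": a.task,
                    "pair": pair,
                    "profile": lab.type.value,
                }
                for a in self.analyses.values()
                for pair, lab in a.labels.items()
            ],
            columns=["subject_id", "task", "pair", "profile"],
        )
        self.condition_mean_table = pd.DataFrame(
            [
                {"subject_id": a.subject_id, "task": a.task, **a.condition_means}
                for a in self.analyses.values()
            ],
            columns=["subject_id", "task", *CONDITION_VARIABLES],
        )

        # condition-mean repeated-measures ANOVAs (subjects complete in all tasks)
        self.condition_anovas: dict[str, RMAnovaResult] = {}
        if len(tasks) >= 2 and not self.condition_mean_table.empty:
            for var in CONDITION_VARIABLES:
                wide = self.condition_mean_table.pivot(
                    index="subject_id", columns="task", values=var
                ).reindex(columns=tasks)
                if (~wide.isna().any(axis=1)).sum() >= len(tasks):
                    self.condition_anovas[var] = rm_anova_wilks(wide, conditions=tasks)

        # paired max-CC comparison per BP channel between the first two tasks
        self.maxcc_anovas: dict[str, RMAnovaResult] = {}
        if len(tasks) >= 2 and not self.max_cc_table.empty:
            for pair in cfg.pairs:
                sub = self.max_cc_table[self.max_cc_table["pair"] == pair]
                wide = sub.pivot(index="subject_id", columns="task", values="max_cc").reindex(
                    columns=tasks[:2]
                )
                both = wide.dropna()
                if len(both) >= 3:
                    self.maxcc_anovas[pair] = compare_max_ccs(
                        both[tasks[0]].to_numpy(),
                        both[tasks[1]].to_numpy(),
                        conditions=(tasks[0], tasks[1]),
                    )

        # per-task profile frequencies + chi-square over the six types
        primary = self.label_table[self.label_table["pair"] == cfg.primary_pair]
        self.profile_freq: dict[str, pd.Series] = {}
        self.profile_chisq: dict[str, ChiSquareResult] = {}
        for task in tasks:
            labs = primary.loc[primary["task"] == task, "profile"]
            freq = profile_frequencies(labs)
            self.profile_freq[task] = freq
            if freq.sum() > 0:
                self.profile_chisq[task] = chi_square_gof(freq.to_numpy(), "uniform")

        # contingency + meta-typing on subjects valid in the first two tasks
        self.contingency: ContingencyTable | None = None
        self.meta_profiles: dict[str, MetaProfile] = {}
        if len(tasks) >= 2:
            wide = primary.pivot(index="subject_id", columns="task", values="profile").reindex(
                columns=tasks[:2]
            )
            both = wide.dropna()
            self.contingency = cross_tabulate(
                [(row[tasks[0]], row[tasks[1]]) for _, row in both.iterrows()]
            )
            for sid, row in both.iterrows():
                self.meta_profiles[str(sid)] = meta_classify(
                    ProfileType(row[tasks[0]]), ProfileType(row[tasks[1]])
                )

        self.meta_table = pd.DataFrame(
            [
                {
                    "subject_id": sid,
                    f"{tasks[0]}_type": mp.math_label.value,
                    f"{tasks[1] if len(tasks) > 1 else 'other'}_type": mp.rumination_label.value,
                    "meta": mp.meta.value,
                }
                for sid, mp in self.meta_profiles.items()
            ]
        )

        # manifest: per-task accounting input = rejected + analyzed
        counts = {}
        for task in tasks:
            n_input = sum(1 for b in self.model.beats if b.task == task)
            n_rej = sum(1 for r in self.rejections if r["task"] == task)
            counts[task] = {
                "input": n_input,
                "rejected": n_rej,
                "analyzed": n_input - n_rej,
            }
        both_valid = len(self.meta_profiles) if len(tasks) >= 2 else None
        self.manifest = {
            "tasks": counts,
            "n_both_tasks_valid": both_valid,
            "config": asdict(self.config),
        }

    # -- convenience ------------------------------------------------------
    def mean_max_cc(self, task: str, pair: str | None = None) -> float:
        pair = pair or self.config.primary_pair
        sub = self.max_cc_table
        vals = sub.loc[(sub["task"] == task) & (sub["pair"] == pair), "max_cc"]
        return float(vals.mean())

    def summary(self) -> str:
        cfg = self.config
        lines = []
        lines.append("Hemodynamic Reactivity Analysis")
        lines.append("=" * 64)
        for task, c in self.manifest["tasks"].items():
            lines.append(
                f"{task:>12}: {c['input']:3d} records in, {c['rejected']:3d} rejected, "
                f"{c['analyzed']:3d} analyzed"
            )
        if self.manifest.get("n_both_tasks_valid") is not None:
            lines.append(f"{'both tasks':>12}: {self.manifest['n_both_tasks_valid']:3d} subjects valid")
        if self.condition_anovas:
            lines.append("")
            lines.append("Condition means (repeated measures, Wilks' lambda)")
            lines.append(
                f"{'var':>5} {'means':>28} {'Lambda':>7} {'F':>8} {'df':>8} {'p':>8} {'eta^2':>6}"
            )
            for var, r in self.condition_anovas.items():
                means = "/".join(f"{v:.1f}" for v in r.condition_means.values())
                lines.append(
                    f"{var:>5} {means:>28} {r.wilks_lambda:7.3f} {r.f_stat:8.2f} "
                    f"({r.df_hyp},{r.df_err:3d}) {r.p_value:8.4f} {r.partial_eta_sq:6.3f}"
                )
        if self.maxcc_anovas:
            lines.append("")
            lines.append("Maximum CC comparison between tasks (HR vs channel)")
            for pair, r in self.maxcc_anovas.items():
                means = ", ".join(f"{k}={v:+.3f}" for k, v in r.condition_means.items())
                lines.append(
                    f"  HR-{pair.upper()}: {means}; Lambda={r.wilks_lambda:.3f}, "
                    f"F({r.df_hyp},{r.df_err})={r.f_stat:.2f}, p={r.p_value:.4f}, "
                    f"eta^2={r.partial_eta_sq:.3f} (n={r.n})"
                )
        if self.profile_chisq:
            lines.append("")
            lines.append(f"Profile frequencies (HR-{cfg.primary_pair.upper()})")
            for task, freq in self.profile_freq.items():
                chis = self.profile_chisq.get(task)
                tail = (
                    f"  chi2({chis.df})={chis.statistic:.2f}, p={chis.p_value:.4f}"
                    if chis
                    else ""
                )
                lines.append(f"  {task}: " + ", ".join(f"{k}={v}" for k, v in freq.items()) + tail)
        if self.meta_profiles:
            meta_counts = pd.Series(
                [m.meta.value for m in self.meta_profiles.values()]
            ).value_counts()
            lines.append("")
            lines.append(
                "Meta-types: " + ", ".join(f"{k}={v}" for k, v in meta_counts.items())
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON-ready dictionary of the cohort statistics."""
        out = {
            "manifest": self.manifest,
            "condition_anovas": {k: r.to_dict() for k, r in self.condition_anovas.items()},
            "maxcc_anovas": {k: r.to_dict() for k, r in self.maxcc_anovas.items()},
            "profile_chisq": {k: r.to_dict() for k, r in self.profile_chisq.items()},
            "profile_frequencies": {
                k: {str(i): int(v) for i, v in f.items()} for k, f in self.profile_freq.items()
            },
        }
        if self.contingency is not None:
            out["contingency"] = {
                "rows_rumination": list(self.contingency.counts.index),
                "cols_math": list(self.contingency.counts.columns),
                "counts": self.contingency.counts.to_numpy().tolist(),
                "grand_total": self.contingency.grand_total,
            }
        return out
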