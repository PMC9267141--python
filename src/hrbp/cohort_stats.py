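"""Cohort-level statistics: repeated-measures ANOVA (multivariate, Wilks'
lambda), chi-square goodness of fit over profile-type frequencies, and the
task-by-task contingency crossing of profile types.

The repeated-measures ANOVA uses the multivariate (Hotelling T-squared)
approach: with c conditions, form the p = c - 1 within-subject difference
variables, then

    T2 = n * dbar' S^{-1} dbar
    Wilks' Lambda = 1 / (1 + T2 / (n - 1))
    F = T2 * (n - p) / (p * (n - 1))   with df (p, n - p)

and partial eta squared = 1 - Lambda, an exact identity in the one-way
case.  With two conditions this reduces to the squared paired t-test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .classify import PROFILE_ORDER, ProfileType


@dataclass
class RMAnovaResult:
    """One-way repeated-measures ANOVA (multivariate approach)."""

    wilks_lambda: float
    f_stat: float
    df_hyp: int
    df_err: int
    p_value: float
    partial_eta_sq: float
    n: int
    conditions: tuple[str, ...]
    n_dropped: int = 0
    condition_means: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "wilks_lambda": self.wilks_lambda,
            "f_stat": self.f_stat,
            "df_hyp": self.df_hyp,
            "df_err": self.df_err,
            "p_value": self.p_value,
            "partial_eta_sq": self.partial_eta_sq,
            "n": self.n,
            "n_dropped": self.n_dropped,
            "conditions": list(self.conditions),
            "condition_means": {k: float(v) for k, v in self.condition_means.items()},
        }


def rm_anova_wilks(
    values: np.ndarray | pd.DataFrame, conditions: Sequence[str] | None = None
) -> RMAnovaResult:
    """Fit the one-way repeated-measures ANOVA on a subjects x conditions matrix.

    Rows with any missing value are dropped (listwise deletion) and counted
    in ``n_dropped``.  Raises on a singular difference covariance with a
    non-zero mean difference, or when fewer complete subjects than
    conditions remain.
    """
    if isinstance(values, pd.DataFrame):
        if conditions is None:
            conditions = [str(c) for c in values.columns]
        X = values.to_numpy(dtype=float)
    else:
        X = np.asarray(values, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("values must be a subjects x conditions matrix with >= 2 conditions")
    c = X.shape[1]
    if conditions is None:
        conditions = [f"c{i}" for i in range(c)]
    complete = ~np.isnan(X).any(axis=1)
    n_dropped = int((~complete).sum())
    X = X[complete]
    n = X.shape[0]
    p = c - 1
    if n < c:
        raise ValueError(f"need at least {c} complete subjects, got {n}")
    D = X[:, 1:] - X[:, [0]]
    dbar = D.mean(axis=0)
    S = np.atleast_2d(np.cov(D, rowvar=False, ddof=1))
    if np.allclose(dbar, 0.0) and np.allclose(S, 0.0):
        t2 = 0.0
    else:
        try:
            t2 = float(n * dbar @ np.linalg.solve(S, dbar))
        except np.linalg.LinAlgError:
            if np.allclose(dbar, 0.0):
                t2 = 0.0
            else:
                raise ValueError("singular difference covariance matrix")
    lam = 1.0 / (1.0 + t2 / (n - 1))
    f_stat = t2 * (n - p) / (p * (n - 1))
    p_value = float(sps.f.sf(f_stat, p, n - p))
    return RMAnovaResult(
        wilks_lambda=lam,
        f_stat=f_stat,
        df_hyp=p,
        df_err=n - p,
        p_value=p_value,
        partial_eta_sq=1.0 - lam,
        n=n,
        conditions=tuple(conditions),
        n_dropped=n_dropped,
        condition_means={str(k): float(v) for k, v in zip(conditions, X.mean(axis=0))},
    )


def compare_max_ccs(
    max_cc_a: np.ndarray,
    max_cc_b: np.ndarray,
    conditions: tuple[str, str] = ("math", "rumination"),
) -> RMAnovaResult:
    """Paired two-condition comparison of per-subject maximum CCs.

    Inputs are aligned per subject; pairs with a missing value in either
    task are dropped.  Requires at least 3 complete pairs.
    """
    a = np.asarray(max_cc_a, dtype=float)
    b = np.asarray(max_cc_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("per-subject vectors must be aligned and equal length")
    X = np.column_stack([a, b])
    if (~np.isnan(X).any(axis=1)).sum() < 3:
        raise ValueError("fewer than 3 complete subject pairs")
    return rm_anova_wilks(X, conditions=list(conditions))


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    observed: np.ndarray
    expected: np.ndarray

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "observed": [int(o) for o in self.observed],
            "expected": [float(e) for e in self.expected],
        }


def chi_square_gof(
    observed: Sequence[int] | np.ndarray, expected: Sequence[float] | str = "uniform"
) -> ChiSquareResult:
    """Chi-square goodness of fit, df = k - 1.

    ``expected='uniform'`` spreads the observed total evenly across the
    categories; an explicit expected vector is rescaled to the observed
    total (the statistic compares shapes, not totals).
    """
    obs = np.asarray(observed, dtype=float)
    if obs.size < 2:
        raise ValueError("need at least 2 categories")
    if isinstance(expected, str):
        if expected != "uniform":
            raise ValueError("expected must be 'uniform' or a vector of counts")
        exp = np.full(obs.size, obs.sum() / obs.size)
    else:
        exp = np.asarray(expected, dtype=float)
        if exp.size != obs.size:
            raise ValueError("expected length mismatch")
        if np.any(exp <= 0):
            raise ValueError("expected counts must be positive")
        exp = exp * (obs.sum() / exp.sum())
    statistic, p_value = sps.chisquare(f_obs=obs, f_exp=exp)
    return ChiSquareResult(
        statistic=float(statistic),
        df=obs.size - 1,
        p_value=float(p_value),
        observed=obs.astype(int),
        expected=exp,
    )


@dataclass
class ContingencyTable:
    """Profile-type crossing between the two tasks, rumination in rows."""

    counts: pd.DataFrame  # rows: rumination types, columns: math types

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def row_margins(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def with_margins(self) -> pd.DataFrame:
        out = self.counts.copy()
        out["Total"] = self.row_margins
        total_row = out.sum(axis=0)
        total_row.name = "Total"
        return pd.concat([out, total_row.to_frame().T])

    def modal_cell(self) -> tuple[str, str, int]:
        """(rumination_type, math_type, count) of the largest cell."""
        arr = self.counts.to_numpy()
        r, c = np.unravel_index(np.argmax(arr), arr.shape)
        return (str(self.counts.index[r]), str(self.counts.columns[c]), int(arr[r, c]))


def cross_tabulate(
    labels: Iterable[tuple[ProfileType | str, ProfileType | str]]
) -> ContingencyTable:
    """Cross-tabulate per-subject (math_type, rumination_type) label pairs.

    Rows are rumination-task types and columns math-task types, both in the
    fixed presentation order; unknown labels raise.
    """
    order = [t.value for t in PROFILE_ORDER]
    counts = pd.DataFrame(0, index=order, columns=order, dtype=int)
    for math_t, rum_t in labels:
        m = math_t.value if isinstance(math_t, ProfileType) else str(math_t)
        r = rum_t.value if isinstance(rum_t, ProfileType) else str(rum_t)
        if m not in order or r not in order:
            raise ValueError(f"unknown profile label in pair ({m!r}, {r!r})")
        counts.loc[r, m] += 1
    counts.index.name = "rumination"
    counts.columns.name = "math"
    return ContingencyTable(counts=counts)


def profile_frequencies(labels: Iterable[ProfileType | str]) -> pd.Series:
    """Count labels per profile type in the fixed presentation order."""
    order = [t.value for t in PROFILE_ORDER]
    vals = [l.value if isinstance(l, ProfileType) else str(l) for l in labels]
    unknown = set(vals) - set(order)
    if unknown:
        raise ValueError(f"unknown profile labels: {sorted(unknown)}")
    return pd.Series(vals, dtype=object).value_counts().reindex(order, fill_value=0)
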