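"""Lagged cross-correlation of 1-Hz heart-rate and blood-pressure series.

The estimator is the standard sample cross-correlation function: full-series
means and standard deviations (divisor n), with

    cc(k) = (1/n) * sum_{t} (hr_t - hr_bar) * (bp_{t+k} - bp_bar) / (s_hr * s_bp)

so a *positive* lag k means heart rate leads and blood pressure follows k
seconds later; negative lags mean blood pressure leads.  Per-lag standard
errors use the white-noise bound 1 / sqrt(n - |k|), the convention of the
classic CCF output of mainstream statistics packages; a lag is significant
when |cc| >= 2 * SE (two-sided, approximately 95%).  Note that this bound
understates the true variance for autocorrelated series - see the methods
note - but it is the rule the profile classification is defined on.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

DEFAULT_MAX_LAG = 30


@dataclass
class CCFunction:
    """Cross-correlogram over lags -L..+L with significance mask."""

    lags: np.ndarray
    cc: np.ndarray
    se: np.ndarray
    significant: np.ndarray
    n: int
    pair: str = "sbp"

    def at_lag(self, k: int) -> float:
        """CC value at integer lag k."""
        idx = np.flatnonzero(self.lags == k)
        if idx.size == 0:
            raise KeyError(f"lag {k} outside computed range")
        return float(self.cc[idx[0]])

    @property
    def max_lag(self) -> int:
        return int(self.lags[-1])


@dataclass(frozen=True)
class MaxCC:
    """The selected per-record maximum cross-correlation."""

    value: float
    lag: int
    from_significant: bool


def cc_standard_error(n: int, k: int) -> float:
    """White-noise standard error of the CCF at lag k: 1/sqrt(n - |k|)."""
    overlap = n - abs(int(k))
    if overlap < 2:
        raise ValueError(f"lag {k} leaves fewer than 2 overlapping samples (n={n})")
    return 1.0 / np.sqrt(overlap)


def cross_correlation(
    hr: np.ndarray,
    bp: np.ndarray,
    max_lag: int = DEFAULT_MAX_LAG,
    pair: str = "sbp",
) -> CCFunction:
    """Sample CCF of two equal-length 1-Hz series over lags -max_lag..+max_lag.

    Positive lags pair ``hr_t`` with ``bp_{t+k}`` (HR leads).  Raises on
    missing values, constant series, or ``n <= 2 * max_lag``.
    """
    hr = np.asarray(hr, dtype=float)
    bp = np.asarray(bp, dtype=float)
    if hr.shape != bp.shape or hr.ndim != 1:
        raise ValueError("hr and bp must be equal-length 1-D vectors")
    n = hr.size
    if n <= 2 * max_lag:
        raise ValueError(f"series length {n} must exceed 2 * max_lag = {2 * max_lag}")
    if np.isnan(hr).any() or np.isnan(bp).any():
        raise ValueError("missing values are not allowed")
    hc = hr - hr.mean()
    bc = bp - bp.mean()
    s_hr = hr.std()  # divisor n
    s_bp = bp.std()
    if s_hr == 0.0 or s_bp == 0.0:
        raise ValueError("constant series has no defined correlation")
    lags = np.arange(-max_lag, max_lag + 1)
    cc = np.empty(lags.size)
    denom = n * s_hr * s_bp
    for j, k in enumerate(lags):
        if k >= 0:
            cc[j] = hc[: n - k] @ bc[k:] / denom
        else:
            cc[j] = hc[-k:] @ bc[: n + k] / denom
    se = 1.0 / np.sqrt(n - np.abs(lags))
    ccf = CCFunction(
        lags=lags,
        cc=cc,
        se=se,
        significant=np.zeros(lags.size, dtype=bool),
        n=n,
        pair=pair,
    )
    return significance_mask(ccf)


def significance_mask(ccf: CCFunction) -> CCFunction:
    """Set the two-sided 2xSE significance mask: |cc_k| >= 2 * se_k."""
    return replace(ccf, significant=np.abs(ccf.cc) >= 2.0 * ccf.se)


def max_significant_cc(ccf: CCFunction) -> MaxCC:
    """Select the maximum (positive or negative) significant CC.

    Among significant lags, the CC of greatest absolute value wins, sign
    retained; ties break to the smallest |lag|, then negative lag before
    positive.  If no lag is significant, the global absolute extremum is
    returned with ``from_significant=False`` so paired analyses have no
    missing cells.
    """
    any_sig = bool(ccf.significant.any())
    candidates = np.flatnonzero(ccf.significant) if any_sig else np.arange(ccf.lags.size)
    best = min(
        candidates,
        key=lambda i: (-abs(ccf.cc[i]), abs(int(ccf.lags[i])), int(ccf.lags[i]) >= 0),
    )
    return MaxCC(value=float(ccf.cc[best]), lag=int(ccf.lags[best]), from_significant=any_sig)


def cross_correlation_per_overlap(hr: np.ndarray, bp: np.ndarray, k: int) -> float:
    """Pearson correlation of the overlapping segments at lag k.

    Cross-check utility only: unlike :func:`cross_correlation`, means and
    standard deviations are recomputed per overlap, which is not the
    estimator the pipeline uses.
    """
    hr = np.asarray(hr, dtype=float)
    bp = np.asarray(bp, dtype=float)
    if k >= 0:
        x, y = hr[: hr.size - k], bp[k:]
    else:
        x, y = hr[-k:], bp[: bp.size + k]
    if x.size < 3:
        raise ValueError("fewer than 3 overlapping samples")
    return float(np.corrcoef(x, y)[0, 1])
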