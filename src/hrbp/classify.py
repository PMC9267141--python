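"""Deterministic classification of cross-correlogram shapes.

Each record's CC curve over lags -30..+30 is assigned one of six profile
types by the signs and arrangement of its significant lags:

* ``POSITIVE`` - a majority of significant CCs positive (HR and BP moving
  together, the 'central', cortically driven pattern when HR leads);
* ``NEGATIVE`` - a majority significant and negative (baroreflex-like
  counter-regulation);
* ``NONSIG`` - too few significant lags to call a shape;
* ``CYCLES`` - alternating sign runs across the lag axis (oscillatory,
  self-balancing coupling);
* ``POS_NEGLAG_NEG_POSLAG`` - positive CCs at negative lags and negative
  CCs at positive lags;
* ``NEG_NEGLAG_POS_POSLAG`` - the mirrored split.

A subject's pair of task labels (cognitive task, rumination task) is then
folded into a central / peripheral / mixed meta-type: retaining the positive
profile even under rumination marks a 'central' reactor; cyclic or negative
rumination profiles without a positive cognitive profile mark a 'peripheral'
reactor; everything else is 'mixed'.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .crosscorr import CCFunction

DEFAULT_S_MIN = 5
DEFAULT_MAJORITY = 0.8


class ProfileType(str, Enum):
    POSITIVE = "positive"
    POS_NEGLAG_NEG_POSLAG = "pos_neglag_neg_poslag"
    NONSIG = "nonsig"
    CYCLES = "cycles"
    NEGATIVE = "negative"
    NEG_NEGLAG_POS_POSLAG = "neg_neglag_pos_poslag"


#: Fixed presentation order for frequency and contingency tables.
PROFILE_ORDER = [
    ProfileType.POSITIVE,
    ProfileType.POS_NEGLAG_NEG_POSLAG,
    ProfileType.NONSIG,
    ProfileType.CYCLES,
    ProfileType.NEGATIVE,
    ProfileType.NEG_NEGLAG_POS_POSLAG,
]


class MetaType(str, Enum):
    CENTRAL = "central"
    PERIPHERAL = "peripheral"
    MIXED = "mixed"


@dataclass(frozen=True)
class SignRun:
    """Maximal block of consecutive significant lags sharing one sign."""

    sign: int  # +1 or -1
    lag_start: int
    lag_end: int
    n_lags: int


@dataclass
class RunSummary:
    runs: list[SignRun]
    n_pos_neghalf: int  # significant positive CCs at lags < 0
    n_neg_neghalf: int
    n_pos_poshalf: int  # significant positive CCs at lags > 0
    n_neg_poshalf: int
    n_pos: int  # totals including lag 0
    n_neg: int

    @property
    def n_significant(self) -> int:
        return self.n_pos + self.n_neg

    @property
    def n_runs(self) -> int:
        return len(self.runs)


@dataclass
class ProfileLabel:
    type: ProfileType
    evidence: dict = field(default_factory=dict)
    runs: list[SignRun] = field(default_factory=list)


def summarize_sign_runs(ccf: CCFunction) -> RunSummary:
    """Collapse significant lags into ordered sign runs.

    Runs are read left to right along the lag axis; interleaved
    non-significant lags do not break a run (raters judging curve shapes are
    gap-tolerant).  Also counts significant positive/negative lags on each
    half-axis (lag 0 contributes to the totals only).
    """
    sig = np.flatnonzero(ccf.significant)
    runs: list[SignRun] = []
    counts = dict(
        n_pos_neghalf=0, n_neg_neghalf=0, n_pos_poshalf=0, n_neg_poshalf=0, n_pos=0, n_neg=0
    )
    for i in sig:
        lag = int(ccf.lags[i])
        sign = 1 if ccf.cc[i] > 0 else -1
        counts["n_pos" if sign > 0 else "n_neg"] += 1
        if lag < 0:
            counts["n_pos_neghalf" if sign > 0 else "n_neg_neghalf"] += 1
        elif lag > 0:
            counts["n_pos_poshalf" if sign > 0 else "n_neg_poshalf"] += 1
        if runs and runs[-1].sign == sign:
            last = runs[-1]
            runs[-1] = SignRun(sign, last.lag_start, lag, last.n_lags + 1)
        else:
            runs.append(SignRun(sign, lag, lag, 1))
    return RunSummary(runs=runs, **counts)


def classify_profile(
    ccf: CCFunction,
    s_min: int = DEFAULT_S_MIN,
    majority: float = DEFAULT_MAJORITY,
) -> ProfileLabel:
    """Assign one of the six profile types to a cross-correlogram.

    Rule order, with S significant lags of which P positive and N negative:

    1. S < s_min                      -> NONSIG
    2. P/S >= majority                -> POSITIVE
    3. N/S >= majority                -> NEGATIVE
    4. each half-axis has >= 2 significant lags, >= majority of the
       negative-half lags positive and >= majority of the positive-half
       lags negative                  -> POS_NEGLAG_NEG_POSLAG
       (mirrored test                 -> NEG_NEGLAG_POS_POSLAG)
    5. otherwise                      -> CYCLES (alternating or
       heterogeneous sign pattern)

    ``s_min`` defaults to 5: with 61 lags tested at the two-sided ~95%
    criterion about 3 false significants are expected under independence,
    so requiring 5 keeps truly uncoupled records in NONSIG.
    """
    if s_min < 1:
        raise ValueError("s_min must be >= 1")
    if not (0.5 < majority <= 1.0):
        raise ValueError("majority must lie in (0.5, 1]")
    summary = summarize_sign_runs(ccf)
    S, P, N = summary.n_significant, summary.n_pos, summary.n_neg
    evidence = {
        "n_significant": S,
        "n_pos": P,
        "n_neg": N,
        "n_pos_neghalf": summary.n_pos_neghalf,
        "n_neg_neghalf": summary.n_neg_neghalf,
        "n_pos_poshalf": summary.n_pos_poshalf,
        "n_neg_poshalf": summary.n_neg_poshalf,
        "n_runs": summary.n_runs,
    }

    def label(t: ProfileType) -> ProfileLabel:
        return ProfileLabel(type=t, evidence=evidence, runs=summary.runs)

    if S < s_min:
        return label(ProfileType.NONSIG)
    if P / S >= majority:
        return label(ProfileType.POSITIVE)
    if N / S >= majority:
        return label(ProfileType.NEGATIVE)
    neg_half = summary.n_pos_neghalf + summary.n_neg_neghalf
    pos_half = summary.n_pos_poshalf + summary.n_neg_poshalf
    if neg_half >= 2 and pos_half >= 2:
        if (
            summary.n_pos_neghalf / neg_half >= majority
            and summary.n_neg_poshalf / pos_half >= majority
        ):
            return label(ProfileType.POS_NEGLAG_NEG_POSLAG)
        if (
            summary.n_neg_neghalf / neg_half >= majority
            and summary.n_pos_poshalf / pos_half >= majority
        ):
            return label(ProfileType.NEG_NEGLAG_POS_POSLAG)
    return label(ProfileType.CYCLES)


@dataclass(frozen=True)
class MetaProfile:
    meta: MetaType
    math_label: ProfileType
    rumination_label: ProfileType


def meta_classify(math: ProfileLabel | ProfileType, rumination: ProfileLabel | ProfileType) -> MetaProfile:
    """Fold a subject's task-pair of profile types into a meta-type.

    CENTRAL iff the rumination profile is POSITIVE (the co-activation
    pattern persists even under negative emotion); PERIPHERAL iff the
    rumination profile is cyclic/negative/split and the cognitive-task
    profile is not POSITIVE; MIXED otherwise.
    """
    m = math.type if isinstance(math, ProfileLabel) else math
    r = rumination.type if isinstance(rumination, ProfileLabel) else rumination
    peripheral_shapes = {
        ProfileType.CYCLES,
        ProfileType.NEGATIVE,
        ProfileType.POS_NEGLAG_NEG_POSLAG,
        ProfileType.NEG_NEGLAG_POS_POSLAG,
    }
    if r is ProfileType.POSITIVE:
        meta = MetaType.CENTRAL
    elif r in peripheral_shapes and m is not ProfileType.POSITIVE:
        meta = MetaType.PERIPHERAL
    else:
        meta = MetaType.MIXED
    return MetaProfile(meta=meta, math_label=m, rumination_label=r)
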