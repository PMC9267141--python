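"""Per-record visualisation: the four 1-Hz series and the CC-vs-lag curves
with their 2xSE significance bands."""

from __future__ import annotations

from .crosscorr import CCFunction
from .series import UniformSeries


def plot_record(uniform: UniformSeries, ccfs: dict[str, CCFunction] | None = None):
    """Two-panel figure: resampled series on top, cross-correlograms below.

    Returns the matplotlib figure; the caller decides whether to save or
    show it.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    nrows = 2 if ccfs else 1
    fig, axes = plt.subplots(nrows, 1, figsize=(8, 3.2 * nrows), squeeze=False)
    ax = axes[0, 0]
    ax.plot(uniform.t_s, uniform.hr_bpm, label="HR (bpm)", lw=1)
    ax.plot(uniform.t_s, uniform.sbp_mmhg, label="SBP (mmHg)", lw=1)
    ax.plot(uniform.t_s, uniform.dbp_mmhg, label="DBP (mmHg)", lw=1)
    ax.plot(uniform.t_s, uniform.mbp_mmhg, label="MBP (mmHg)", lw=1)
    ax.set_xlabel("time (s)")
    ax.set_title(f"{uniform.subject_id} / {uniform.task}")
    ax.legend(fontsize=8, ncol=4)

    if ccfs:
        ax = axes[1, 0]
        for pair, ccf in ccfs.items():
            ax.plot(ccf.lags, ccf.cc, marker=".", ms=3, lw=0.8, label=f"HR-{pair.upper()}")
        first = next(iter(ccfs.values()))
        ax.fill_between(
            first.lags, -2 * first.se, 2 * first.se, color="grey", alpha=0.25, label="±2 SE"
        )
        ax.axhline(0.0, color="k", lw=0.5)
        ax.set_xlabel("lag (s; positive = HR leads)")
        ax.set_ylabel("cross-correlation")
        ax.set_ylim(-1, 1)
        ax.legend(fontsize=8, ncol=2)
    fig.tight_layout()
    return fig
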