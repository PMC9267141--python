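import numpy as np
import pytest

from hrbp import BeatSeries


@pytest.fixture
def make_beats():
    """Factory for small hand-built beat records."""

    def _make(rr, sbp=None, dbp=None, flags=None, subject_id="s1", task="math", t0=None):
        rr = np.asarray(rr, dtype=float)
        start = rr[0] if t0 is None else t0
        t = start + np.concatenate([[0.0], np.cumsum(rr[1:])])
        if sbp is None:
            sbp = np.full(rr.size, 120.0)
        if dbp is None:
            dbp = np.asarray(sbp, dtype=float) - 50.0
        return BeatSeries(
            subject_id=subject_id,
            task=task,
            beat_time_s=t,
            rr_s=rr,
            sbp_mmhg=sbp,
            dbp_mmhg=dbp,
            flags=flags,
        )

    return _make
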