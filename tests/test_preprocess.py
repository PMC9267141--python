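"""Artifact flagging, repair/rejection rules, derivation and 1-Hz resampling."""

import numpy as np
import pytest

from hrbp import (
    CouplingSpec,
    derive_hemodynamics,
    flag_artifacts,
    generate_beat_pair,
    reject_record,
    repair_single_flags,
    resample_1hz,
)
from hrbp.preprocess import preprocess_record


class TestFlagArtifacts:
    def test_constant_series_unflagged(self, make_beats):
        out = flag_artifacts(make_beats([0.8] * 21))
        assert not out.flags.any()

    def test_single_short_rr_flagged(self, make_beats):
        rr = [0.8] * 10 + [0.4] + [0.8] * 10
        out = flag_artifacts(make_beats(rr), rr_tol=0.3)
        np.testing.assert_array_equal(np.flatnonzero(out.flags), [10])

    def test_two_consecutive_short_rr_both_flagged(self, make_beats):
        rr = [0.8] * 10 + [0.4, 0.4] + [0.8] * 10
        out = flag_artifacts(make_beats(rr), rr_tol=0.3)
        np.testing.assert_array_equal(np.flatnonzero(out.flags), [10, 11])

    def test_sbp_outlier_flagged(self, make_beats):
        sbp = np.full(21, 120.0)
        sbp[7] = 160.0
        out = flag_artifacts(make_beats([0.8] * 21, sbp=sbp), bp_tol=25.0)
        np.testing.assert_array_equal(np.flatnonzero(out.flags), [7])

    def test_even_window_rejected(self, make_beats):
        with pytest.raises(ValueError, match="odd"):
            flag_artifacts(make_beats([0.8] * 21), window=10)

    def test_window_larger_than_series_rejected(self, make_beats):
        with pytest.raises(ValueError, match="larger"):
            flag_artifacts(make_beats([0.8] * 5), window=11)


class TestRepairSingleFlags:
    def test_isolated_flag_takes_neighbor_mean(self, make_beats):
        flags = np.array([False, True, False])
        rec = make_beats([1.0, 1.0, 1.0], sbp=[120.0, 200.0, 124.0], flags=flags)
        out = repair_single_flags(rec)
        assert out.sbp_mmhg[1] == pytest.approx(122.0)
        assert not out.flags.any()

    def test_no_flags_identity(self, make_beats):
        rec = make_beats([0.8] * 5, sbp=[120, 121, 122, 123, 124.0], flags=np.zeros(5, bool))
        out = repair_single_flags(rec)
        np.testing.assert_array_equal(out.sbp_mmhg, rec.sbp_mmhg)
        np.testing.assert_array_equal(out.rr_s, rec.rr_s)

    def test_boundary_flag_copies_single_neighbor(self, make_beats):
        flags = np.array([True, False, False])
        rec = make_beats([1.0, 0.8, 0.8], sbp=[300.0, 120.0, 121.0], flags=flags)
        out = repair_single_flags(rec)
        assert out.sbp_mmhg[0] == 120.0
        assert out.rr_s[0] == 0.8

    def test_runs_left_untouched(self, make_beats):
        flags = np.array([False, True, True, False])
        rec = make_beats([0.8, 0.4, 0.4, 0.8], sbp=[120, 60, 60, 120.0], flags=flags)
        out = repair_single_flags(rec)
        np.testing.assert_array_equal(out.sbp_mmhg, rec.sbp_mmhg)
        np.testing.assert_array_equal(out.flags, flags)

    def test_idempotent(self, make_beats):
        flags = np.array([False, True, False, True, True, False])
        rec = make_beats(
            [0.8, 0.4, 0.8, 0.4, 0.4, 0.8],
            sbp=[120, 60, 121, 60, 60, 122.0],
            flags=flags,
        )
        once = repair_single_flags(rec)
        twice = repair_single_flags(once)
        np.testing.assert_array_equal(once.sbp_mmhg, twice.sbp_mmhg)
        np.testing.assert_array_equal(once.flags, twice.flags)

    def test_unflagged_beats_bit_identical(self, make_beats):
        rng = np.random.default_rng(0)
        sbp = 120 + rng.normal(0, 5, 30)
        flags = np.zeros(30, bool)
        flags[[4, 12, 20]] = True
        rec = make_beats(0.8 + rng.normal(0, 0.02, 30), sbp=sbp, flags=flags)
        out = repair_single_flags(rec)
        keep = ~flags
        np.testing.assert_array_equal(out.sbp_mmhg[keep], rec.sbp_mmhg[keep])
        np.testing.assert_array_equal(out.rr_s[keep], rec.rr_s[keep])


class TestRejectRecord:
    def test_consecutive_flags_rejected(self, make_beats):
        flags = np.zeros(10, bool)
        flags[[5, 6]] = True
        verdict = reject_record(make_beats([0.8] * 10, flags=flags))
        assert not verdict.kept
        assert verdict.run_start == 5
        assert verdict.run_length == 2

    def test_isolated_flags_kept(self, make_beats):
        flags = np.zeros(10, bool)
        flags[[5, 7]] = True
        assert reject_record(make_beats([0.8] * 10, flags=flags)).kept

    def test_no_flags_kept(self, make_beats):
        assert reject_record(make_beats([0.8] * 10, flags=np.zeros(10, bool))).kept

    def test_requires_flags(self, make_beats):
        with pytest.raises(ValueError, match="flags"):
            reject_record(make_beats([0.8] * 10))


class TestDeriveHemodynamics:
    def test_heart_rate_definition(self, make_beats):
        out = derive_hemodynamics(make_beats([1.0, 0.5, 0.75]))
        np.testing.assert_allclose(out.hr_bpm, [60.0, 120.0, 80.0])

    def test_mean_pressure_one_third_pulse_pressure(self, make_beats):
        rec = make_beats([0.8] * 3, sbp=[120.0] * 3, dbp=[60.0] * 3)
        out = derive_hemodynamics(rec)
        np.testing.assert_allclose(out.mbp_mmhg, 80.0)

    def test_nonpositive_rr_rejected(self, make_beats):
        rec = make_beats([0.8, 0.8, 0.8])
        rec.rr_s[1] = -0.1
        with pytest.raises(ValueError):
            derive_hemodynamics(rec)


class TestResample1Hz:
    def _derived(self, make_beats, times, values=None):
        n = len(times)
        rec = make_beats([0.8] * n, sbp=values if values is not None else np.full(n, 120.0))
        rec.beat_time_s = np.asarray(times, dtype=float)
        return derive_hemodynamics(rec)

    def test_length_149_when_last_beat_at_149_6(self, make_beats):
        times = np.linspace(0.4, 149.6, 188)
        out = resample_1hz(self._derived(make_beats, times))
        assert out.n == 149
        assert out.t_s[0] == 1.0 and out.t_s[-1] == 149.0

    def test_length_148_when_last_beat_at_148_9(self, make_beats):
        times = np.linspace(0.4, 148.9, 187)
        out = resample_1hz(self._derived(make_beats, times))
        assert out.n == 148

    def test_grid_points_before_first_beat_dropped(self, make_beats):
        times = np.linspace(2.5, 20.0, 23)
        out = resample_1hz(self._derived(make_beats, times))
        assert out.t_s[0] == 3.0

    def test_constant_beats_give_constant_series(self, make_beats):
        times = np.linspace(0.8, 60.0, 75)
        out = resample_1hz(self._derived(make_beats, times))
        assert np.all(out.sbp_mmhg == 120.0)
        assert np.all(out.hr_bpm == 75.0)

    def test_values_are_actual_beat_values(self, make_beats):
        # sample-and-hold must never invent values by interpolation
        rng = np.random.default_rng(1)
        rec = generate_beat_pair(CouplingSpec("independent", seed=9))
        out = resample_1hz(derive_hemodynamics(rec))
        beat_sbp = set(rec.sbp_mmhg.tolist())
        assert all(v in beat_sbp for v in out.sbp_mmhg.tolist())

    def test_locf_picks_most_recent_beat(self, make_beats):
        rec = make_beats([1.0], sbp=[100.0])
        rec.beat_time_s = np.array([0.5, 1.2, 2.7, 3.1])
        rec.rr_s = np.array([0.5, 0.7, 1.5, 0.4])
        rec.sbp_mmhg = np.array([100.0, 101.0, 102.0, 103.0])
        rec.dbp_mmhg = rec.sbp_mmhg - 50
        out = resample_1hz(derive_hemodynamics(rec))
        # t=1 -> beat at 0.5; t=2 -> beat at 1.2; t=3 -> beat at 2.7
        np.testing.assert_array_equal(out.sbp_mmhg, [100.0, 101.0, 102.0])

    def test_short_record_rejected(self, make_beats):
        rec = self._derived(make_beats, [0.5, 1.1])
        with pytest.raises(ValueError, match="shorter"):
            resample_1hz(rec)

    def test_requires_derivation(self, make_beats):
        with pytest.raises(ValueError, match="derive"):
            resample_1hz(make_beats([0.8] * 10))


class TestEndToEnd:
    def test_clean_record_kept_and_unchanged(self):
        # no injected artifacts: flag -> repair -> reject is a no-op keep
        for seed in (0, 1, 2):
            rec = generate_beat_pair(CouplingSpec("central", seed=seed))
            flagged = flag_artifacts(rec)
            assert not flagged.flags.any()
            assert reject_record(flagged).kept
            repaired = repair_single_flags(flagged)
            np.testing.assert_array_equal(repaired.sbp_mmhg, rec.sbp_mmhg)

    def test_150s_records_resample_to_148_or_149(self):
        for seed in range(10):
            uniform, verdict = preprocess_record(
                generate_beat_pair(CouplingSpec("independent", seed=seed))
            )
            assert verdict.kept
            assert uniform.n in (148, 149)
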