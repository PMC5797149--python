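"""Circadian and pharmacological HR read-outs."""

import numpy as np
import pytest

from telecg.epochs import HREpoch
from telecg.hranalysis import (
    DayNightSummary,
    activity_class,
    bin_hr_by_activity,
    daynight_summary,
    hr_epochs,
    iso_response,
    metoprolol_delta,
)
from telecg.sim.activity import ActivitySeries


def _segments(n, t0=0.0):
    return [(t0 + 300.0 * i, t0 + 300.0 * i + 60.0) for i in range(n)]


class TestHREpochs:
    def test_constant_100ms_rr_gives_600bpm(self):
        segs = _segments(1)
        beats = np.arange(0.0, 60.0, 0.1)
        (e,) = hr_epochs(beats, segs)
        assert e.valid and e.hr == pytest.approx(600.0)

    def test_empty_minute_invalid(self):
        (e,) = hr_epochs(np.array([]), _segments(1))
        assert not e.valid

    def test_against_bruteforce_beat_counting(self):
        rng = np.random.default_rng(0)
        segs = _segments(20)
        beats = np.cumsum(rng.uniform(0.09, 0.11, 14000))
        epochs = hr_epochs(beats, segs)
        for (a, b), e in zip(segs, epochs):
            n = np.sum((beats >= a) & (beats < b))
            if e.valid:
                # beats per minute approximates the RR-based epoch HR up to
                # edge quantisation (+/-1 beat) and RR jitter
                assert abs(e.hr - n) <= 2.0

    def test_artifact_overlap_invalidates(self):
        from telecg.detect import ArtifactIntervals

        segs = _segments(1)
        beats = np.arange(0.0, 60.0, 0.1)
        art = ArtifactIntervals(intervals=[(0.0, 20.0, "power")])
        (e,) = hr_epochs(beats, segs, art)
        assert not e.valid


class TestDayNight:
    @staticmethod
    def _epochs(day_hr, night_hr):
        out = []
        for h in range(24):
            hr = day_hr if 7 <= h < 19 else night_hr
            out.append(HREpoch(start=h * 3600.0, hr=hr, valid=True, n_beats=500))
        return out

    def test_uniform_500(self):
        s = daynight_summary(self._epochs(500.0, 500.0))
        assert (s.mean_day, s.mean_night, s.min_96h, s.max_96h) == (500, 500, 500, 500)

    def test_day_night_split(self):
        s = daynight_summary(self._epochs(500.0, 600.0))
        assert s.mean_day == 500 and s.mean_night == 600
        assert s.min_96h == 500 and s.max_96h == 600

    def test_no_valid_epochs_flagged_undefined(self):
        s = daynight_summary([HREpoch(start=0.0, hr=np.nan, valid=False)])
        assert not s.defined

    def test_generator_night_exceeds_day(self, balbc):
        from telecg.sim.study import longterm_epoch_hr

        _, _, epochs = longterm_epoch_hr(
            balbc, "baseline", rng=np.random.default_rng(5), duration_h=48.0)
        s = daynight_summary(epochs)
        assert s.mean_night > s.mean_day
        assert s.min_96h <= s.mean_day <= s.max_96h


class TestActivityBinning:
    @pytest.mark.parametrize("value,cls", [
        (0.0, 0), (3.0, 1), (5.0, 1), (5.1, 2), (12.0, 3), (20.0, 4),
        (25.0, 5), (30.0, 6), (31.0, 7), (250.0, 7), (300.0, 7),
    ])
    def test_class_boundaries(self, value, cls):
        assert activity_class(value)[0] == cls

    def test_above_300_clips_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            assert activity_class(400.0)[0] == 7

    def test_partition_every_epoch_in_exactly_one_class(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0, 300, 1000)
        cls = activity_class(vals)
        assert np.all((cls >= 0) & (cls <= 7))

    def test_null_coupling_means_equal_across_classes(self):
        """HR independent of activity -> per-class means agree."""
        rng = np.random.default_rng(2)
        n = 2000
        act = ActivitySeries(t0_clock=0.0, values=rng.uniform(0, 35, n))
        epochs = [HREpoch(start=300.0 * i, hr=550 + rng.normal(0, 5), valid=True,
                          n_beats=500) for i in range(n)]
        res = bin_hr_by_activity(epochs, act)["all"]
        present = res[~np.isnan(res)]
        assert np.ptp(present) < 3.0  # sampling error only


class TestMetoprololDelta:
    @staticmethod
    def _summary(day, night, phase):
        return DayNightSummary(mean_day=day, mean_night=night, min_96h=day,
                               max_96h=night, n_valid_day=10, n_valid_night=10,
                               defined=True, phase=phase)

    def test_simple_difference(self):
        d = metoprolol_delta(self._summary(600, 650, "baseline_96h"),
                             self._summary(550, 580, "metoprolol_96h"))
        assert d == (50.0, 70.0)

    def test_identical_summaries_zero(self):
        s = self._summary(600, 650, None)
        assert metoprolol_delta(s, s) == (0.0, 0.0)

    def test_antisymmetric_in_arguments(self):
        a = self._summary(600, 650, None)
        b = self._summary(550, 580, None)
        d1 = metoprolol_delta(a, b)
        d2 = metoprolol_delta(b, a)
        assert d1 == (-d2[0], -d2[1])

    def test_phase_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            metoprolol_delta(self._summary(600, 650, "metoprolol_96h"),
                             self._summary(550, 580, "baseline_96h"))

    def test_programmed_reduction_recovered_over_cohort(self, balbc):
        """Parameter recovery through the full epoch pipeline."""
        from telecg.sim.study import longterm_epoch_hr

        deltas = []
        for seed in range(6):
            _, _, eb = longterm_epoch_hr(balbc, "baseline", duration_h=48.0,
                                         rng=np.random.default_rng(1000 + seed))
            _, _, em = longterm_epoch_hr(balbc, "metoprolol", duration_h=48.0,
                                         rng=np.random.default_rng(2000 + seed))
            d, _ = metoprolol_delta(daynight_summary(eb), daynight_summary(em))
            deltas.append(d)
        assert np.mean(deltas) == pytest.approx(balbc.metoprolol_delta_day, abs=5.0)


class TestIsoResponse:
    def test_flat_hr_max_equals_mean(self):
        beats = np.arange(0.0, 18500.0, 60.0 / 700.0)  # 700 bpm
        r = iso_response(beats, t_inj=0.0)
        assert r.hr_max_5h == pytest.approx(700.0, abs=0.5)
        assert r.hr_mean_5h == pytest.approx(700.0, abs=0.5)
        assert not r.flagged

    def test_coverage_gap_flagged(self):
        beats = np.arange(0.0, 600.0, 0.1)  # only 10 min of 5 h covered
        r = iso_response(beats, t_inj=0.0)
        assert r.flagged

    def test_surge_peak_recovered_from_truth(self, balbc):
        """Arrhythmia-free agonist session: epoch max matches trace max."""
        import dataclasses

        from telecg.sim import apply_isoproterenol, simulate_beats, simulate_hr_profile
        from telecg.sim.hr import HRParams

        quiet = dataclasses.replace(balbc, event_rate_pvb=0, event_rate_coupled=0,
                                    event_rate_vt=0, event_rate_vf=0)
        rng = np.random.default_rng(3)
        tr = simulate_hr_profile(quiet, "baseline", None, 5.5 * 3600, rng=rng,
                                 dt=0.5, t0_clock=9 * 3600,
                                 params=HRParams(noise_sd=2.0))
        t_inj = 9 * 3600 + 600.0
        tr = apply_isoproterenol(tr, t_inj, quiet)
        truth = simulate_beats(tr, None)
        r = iso_response(truth, t_inj)
        assert r.hr_max_5h == pytest.approx(tr.hr.max(), abs=8.0)

    def test_vehicle_session_shows_no_surge(self, balbc):
        from telecg.sim import simulate_beats, simulate_hr_profile
        from telecg.sim.hr import HRParams

        rng = np.random.default_rng(4)
        tr = simulate_hr_profile(balbc, "baseline", None, 5.5 * 3600, rng=rng,
                                 dt=0.5, t0_clock=9 * 3600,
                                 params=HRParams(noise_sd=2.0))
        truth = simulate_beats(tr, None)
        r = iso_response(truth, 9 * 3600 + 600.0)
        assert r.hr_max_5h < balbc.hr_max  # no beta-adrenergic surge
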