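"""Arrhythmia grammar: criteria, run grouping, VF, counting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from telecg.rhythm import (
    ArrhythmiaEvent,
    ClassifierParams,
    EpisodeCounts,
    classify_beats,
    compute_rr,
    count_events,
    detect_vf,
    evaluate_pvb_criteria,
    expand_events,
    group_runs,
    group_summary,
    run_class,
)


class TestComputeRR:
    def test_simple_differences(self):
        rr = compute_rr([0.0, 0.1, 0.2])
        np.testing.assert_allclose(rr.rr_ms, [100.0, 100.0])

    def test_fewer_than_two_beats_empty(self):
        assert len(compute_rr([0.5])) == 0

    def test_matches_bruteforce_pairwise_differencing(self):
        rng = np.random.default_rng(0)
        t = np.sort(rng.uniform(0, 100, 500))
        t = t[np.concatenate([[True], np.diff(t) > 0])]
        rr = compute_rr(t)
        brute = [(t[i + 1] - t[i]) * 1000.0 for i in range(len(t) - 1)]
        np.testing.assert_allclose(rr.rr_ms, brute)

    def test_nonmonotone_rejected(self):
        with pytest.raises(ValueError):
            compute_rr([0.0, 0.2, 0.1])


class TestCriteria:
    REF = 100.0

    @pytest.mark.parametrize("c1,c2,c3", [
        (a, b, c) for a in (0, 1) for b in (0, 1) for c in (0, 1)
    ])
    def test_premature_beat_needs_at_least_two_criteria(self, c1, c2, c3):
        res = evaluate_pvb_criteria(
            rr_pre_ms=65.0,  # premature vs reference 100
            rr_post_ms=135.0 if c3 else 100.0,
            reference_ms=self.REF,
            morphology="atypical" if c1 else "normal",
            p_found=not c2,
        )
        assert res.premature
        assert res.n_met == c1 + c2 + c3
        assert res.is_pvb == (c1 + c2 + c3 >= 2)

    def test_non_premature_beat_never_pvb(self):
        res = evaluate_pvb_criteria(100.0, 135.0, self.REF, "atypical", False)
        assert not res.premature and not res.is_pvb

    def test_missing_reference_low_confidence(self):
        res = evaluate_pvb_criteria(65.0, 135.0, None, "atypical", False)
        assert res.low_confidence and not res.is_pvb

    def test_boundary_neighbours_treated_false(self):
        res = evaluate_pvb_criteria(None, None, self.REF, "atypical", True)
        assert not res.premature and not res.c3_compensatory_pause


class TestClassifyStream:
    def _stream_with_pvb(self, n=40, i_pvb=20):
        """Regular 100-ms sinus with one fully compensatory ectopic."""
        t = [0.0]
        for i in range(1, n):
            t.append(t[-1] + 0.1)
        t = np.array(t)
        t[i_pvb] = t[i_pvb - 1] + 0.065  # premature; next sinus beat unmoved
        morph = np.zeros(n, dtype=bool)
        morph[i_pvb] = True
        pf = np.ones(n, dtype=bool)
        pf[i_pvb] = False
        return t, morph, pf

    def test_injected_pvb_found_with_all_three_criteria(self):
        t, morph, pf = self._stream_with_pvb()
        labels, results = classify_beats(t, morph, pf)
        assert labels[20] == "PVB"
        r = results[20]
        assert r.premature and r.n_met == 3
        assert np.sum(labels == "PVB") == 1

    def test_single_criterion_insufficient(self):
        t, morph, pf = self._stream_with_pvb()
        morph[:] = False
        pf[:] = True  # only the compensatory pause remains
        labels, _ = classify_beats(t, morph, pf)
        assert np.sum(labels == "PVB") == 0

    def test_fast_path_equals_full_path(self):
        rng = np.random.default_rng(1)
        t = np.cumsum(rng.uniform(0.08, 0.12, 2000))
        morph = rng.random(2000) < 0.05
        pf = ~morph
        a, _ = classify_beats(t, morph, pf, collect_results=True)
        b, _ = classify_beats(t, morph, pf, collect_results=False)
        np.testing.assert_array_equal(a, b)


class TestGroupRuns:
    @pytest.mark.parametrize("labels,expected", [
        (["N", "PVB", "PVB", "N"], [("couplet", 2)]),
        (["PVB", "PVB", "PVB", "PVB"], [("VT", 4)]),
        (["N", "N", "N"], []),
        (["PVB", "N", "PVB", "PVB", "PVB", "N", "PVB"],
         [("PVB", 1), ("triplet", 3), ("PVB", 1)]),
    ])
    def test_grammar_examples(self, labels, expected):
        events = group_runs(labels)
        assert [(e.cls, e.n_beats) for e in events] == expected

    @pytest.mark.parametrize("k,cls", [(1, "PVB"), (2, "couplet"), (3, "triplet"),
                                       (4, "VT"), (7, "VT")])
    def test_run_class_mapping(self, k, cls):
        assert run_class(k) == cls

    @given(st.lists(st.sampled_from(["N", "PVB"]), max_size=60))
    @settings(max_examples=200, deadline=None)
    def test_matches_bruteforce_run_length_encoder(self, labels):
        events = group_runs(labels)
        # brute-force RLE oracle
        runs, i = [], 0
        while i < len(labels):
            if labels[i] == "PVB":
                j = i
                while j < len(labels) and labels[j] == "PVB":
                    j += 1
                runs.append(j - i)
                i = j
            else:
                i += 1
        expected = [{1: "PVB", 2: "couplet", 3: "triplet"}.get(r, "VT") for r in runs]
        assert [e.cls for e in events] == expected
        assert [e.n_beats for e in events] == runs

    @given(st.lists(st.sampled_from(["N", "PVB"]), max_size=60))
    @settings(max_examples=200, deadline=None)
    def test_expand_is_inverse_of_group(self, labels):
        events = group_runs(labels)
        np.testing.assert_array_equal(expand_events(events, len(labels)),
                                      np.asarray(labels))

    def test_adding_isolated_pvb_increments_counts_by_one(self):
        labels = ["N"] * 30
        labels[5:7] = ["PVB", "PVB"]
        before = count_events(group_runs(labels), (0, 100))
        labels[20] = "PVB"  # isolated, not adjacent to the couplet
        after = count_events(group_runs(labels), (0, 100))
        assert after.pvb == before.pvb + 1
        assert after.total == before.total + 1
        assert after.coupled == before.coupled


class TestDetectVF:
    def test_generator_vf_interval_recovered(self, vf_record):
        rec, truth, _ = vf_record
        assert truth.vf_intervals
        from telecg.detect import annotate_record

        beats, _, _ = annotate_record(rec)
        events = detect_vf(rec, beats)
        assert events
        for a, b in truth.vf_intervals:
            covered = sum(max(0.0, min(e.end, b) - max(e.start, a)) for e in events)
            assert covered >= 0.9 * (b - a)

    def test_clean_sinus_no_vf(self, clean_record):
        rec, _, _ = clean_record
        from telecg.detect import annotate_record

        beats, _, _ = annotate_record(rec)
        assert detect_vf(rec, beats) == []

    def test_flat_signal_fails_rms_gate(self):
        from telecg.sim.ecg import ECGRecord

        rec = ECGRecord(animal_id="z", strain="s", phase="b", session="s",
                        t0=0.0, fs=1000.0, signal=np.zeros(10_000))
        assert detect_vf(rec, []) == []


class TestCounting:
    def test_empty_event_list_all_zero(self):
        c = count_events([], (0, 100))
        assert (c.pvb, c.coupled, c.vt, c.vf, c.total) == (0, 0, 0, 0, 0)

    def test_conservation_total_is_class_sum(self):
        events = group_runs(["PVB", "N", "PVB", "PVB", "N"] + ["PVB"] * 5)
        c = count_events(events, (0, 100))
        assert c.total == c.pvb + c.coupled + c.vt + c.vf

    def test_window_additivity_over_disjoint_windows(self):
        rng = np.random.default_rng(2)
        times = np.sort(rng.uniform(0, 100, 50))
        events = [ArrhythmiaEvent(cls="PVB", start=t, end=t, n_beats=1)
                  for t in times]
        a = count_events(events, (0.0, 50.0))
        b = count_events(events, (50.0, 100.1))
        u = count_events(events, (0.0, 100.1))
        assert a.pvb + b.pvb == u.pvb

    def test_artifact_onsets_excluded(self):
        from telecg.detect import ArtifactIntervals

        events = [ArrhythmiaEvent(cls="PVB", start=5.0, end=5.0, n_beats=1),
                  ArrhythmiaEvent(cls="PVB", start=20.0, end=20.0, n_beats=1)]
        art = ArtifactIntervals(intervals=[(4.0, 6.0, "power")])
        assert count_events(events, (0, 100), art).pvb == 1

    def test_zero_vf_strains_report_zero_fraction(self):
        counts = {f"a{i}": EpisodeCounts(pvb=3, coupled=1, vt=0, vf=0)
                  for i in range(5)}
        df = group_summary(counts, {f"a{i}": "FVB" for i in range(5)})
        vf = df[(df["class"] == "vf")].iloc[0]
        assert vf["mean"] == 0.0 and vf["sem"] == 0.0 and vf["n_affected"] == 0
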