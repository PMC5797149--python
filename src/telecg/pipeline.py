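"""Stage orchestration: simulation -> classification -> analytics -> stats.

Two classification routes exist for simulated studies and must agree on
noiseless material:

``truth-bypass``
    Ground-truth beat labels go straight into the run-grouping grammar
    (plus ground-truth VF intervals).  This isolates the grammar and the
    counting stages.
``criteria``
    Ground-truth beat *features* (morphology flag, P-wave presence,
    times) go through the full RR-based 2-of-3 criteria evaluation, then
    run grouping.
``waveform``
    The synthesized ECG goes through QRS detection, template matching and
    P-wave search before criteria evaluation (handled by the caller via
    :func:`telecg.detect.annotate_record`).
"""

from __future__ import annotations

import numpy as np

from telecg.detect import ArtifactIntervals, BeatAnnotation
from telecg.hranalysis import DayNightSummary, daynight_summary, hr_epochs, iso_response
from telecg.rhythm import (
    ArrhythmiaEvent,
    ClassifierParams,
    EpisodeCounts,
    classify_beats,
    count_events,
    group_runs,
)
from telecg.sim.beats import BeatTruth
from telecg.sim.hr import HRTrace
from telecg.sim.study import Session, StudyData

POST_INJECTION_WINDOW_S = 5 * 3600.0


def events_from_truth(
    truth: BeatTruth,
    mode: str = "bypass",
    params: ClassifierParams | None = None,
) -> list[ArrhythmiaEvent]:
    """Classify a ground-truth beat stream into events.

    ``mode="bypass"`` groups the truth labels directly; ``"criteria"``
    re-derives beat labels through the 2-of-3 criteria from truth-level
    features.  VF intervals come from truth either way.
    """
    if mode == "bypass":
        labels = truth.labels
    elif mode == "criteria":
        params = params or ClassifierParams()
        labels, _ = classify_beats(
            truth.times, truth.labels == "PVB", truth.p_wave,
            params, vf_intervals=truth.vf_intervals, collect_results=False,
        )
    else:
        raise ValueError("mode must be 'bypass' or 'criteria'")
    events = group_runs(labels, truth.times)
    events += [ArrhythmiaEvent(cls="VF", start=a, end=b, n_beats=None)
               for a, b in truth.vf_intervals]
    return sorted(events, key=lambda e: e.start)


def events_from_annotations(
    beats: list[BeatAnnotation],
    params: ClassifierParams | None = None,
    vf_events: list[ArrhythmiaEvent] | None = None,
) -> list[ArrhythmiaEvent]:
    """Classify detector annotations (waveform route) into events."""
    params = params or ClassifierParams()
    times = np.array([b.time for b in beats])
    morph = [b.morphology for b in beats]
    p_found = [b.p_wave_found for b in beats]
    vf_iv = [(e.start, e.end) for e in (vf_events or [])]
    labels, _ = classify_beats(times, morph, p_found, params, vf_intervals=vf_iv)
    events = group_runs(labels, times)
    events += list(vf_events or [])
    return sorted(events, key=lambda e: e.start)


def acute_session_counts(
    session: Session,
    mode: str = "criteria",
    params: ClassifierParams | None = None,
    artifact: ArtifactIntervals | None = None,
) -> tuple[EpisodeCounts, list[ArrhythmiaEvent]]:
    """Event counts over the 5-h window after the first injection."""
    if session.truth is None:
        raise ValueError("session carries no beat-level truth (epoch fidelity?)")
    t_inj = session.injections[0][0]
    window = (t_inj, t_inj + POST_INJECTION_WINDOW_S)
    events = events_from_truth(session.truth, mode=mode, params=params)
    return count_events(events, window, artifact), events


def session_daynight(session: Session) -> DayNightSummary:
    """Day/night summary of a long-term session at its native fidelity."""
    if session.epochs is not None:
        epochs = session.epochs
    elif session.truth is not None:
        epochs = hr_epochs(session.truth, session.segments)
    else:
        raise ValueError("session has neither epochs nor beats")
    return daynight_summary(epochs, phase=session.phase)


def trace_iso_response(
    trace: HRTrace, t_inj: float, window_s: float = POST_INJECTION_WINDOW_S,
    epoch_s: float = 10.0,
) -> tuple[float, float]:
    """(max, mean) 10-s-epoch HR over the post-injection window, from the
    latent trace (epoch-fidelity route)."""
    t0, t1 = t_inj, min(t_inj + window_s, trace.times[-1])
    n = int((t1 - t0) // epoch_s)
    vals = []
    for i in range(n):
        a = t0 + i * epoch_s
        sel = (trace.times >= a) & (trace.times < a + epoch_s)
        if sel.any():
            vals.append(float(np.mean(trace.hr[sel])))
    return (max(vals), float(np.mean(vals))) if vals else (np.nan, np.nan)


def study_event_table(study: StudyData, mode: str = "criteria"):
    """Per-animal event counts in the isoproterenol session, plus strain map."""
    counts, strain_of = {}, {}
    for animal in study.animals:
        ses = animal.sessions.get("acute_iso")
        if ses is None:
            continue
        c, _ = acute_session_counts(ses, mode=mode)
        counts[animal.animal_id] = c
        strain_of[animal.animal_id] = animal.strain
    return counts, strain_of


def study_hr_table(study: StudyData):
    """Per-animal HR summaries across phases as a tidy list of dicts."""
    rows = []
    for animal in study.animals:
        row = {"animal": animal.animal_id, "strain": animal.strain}
        base = animal.sessions.get("baseline_96h")
        met = animal.sessions.get("metoprolol_96h")
        if base is not None:
            s = session_daynight(base)
            row.update(base_mean_day=s.mean_day, base_mean_night=s.mean_night,
                       base_min=s.min_96h, base_max=s.max_96h)
        if met is not None:
            s = session_daynight(met)
            row.update(met_mean_day=s.mean_day, met_mean_night=s.mean_night,
                       met_min=s.min_96h, met_max=s.max_96h)
        if base is not None and met is not None:
            row["delta_day"] = row["base_mean_day"] - row["met_mean_day"]
            row["delta_night"] = row["base_mean_night"] - row["met_mean_night"]
        iso = animal.sessions.get("acute_iso")
        if iso is not None:
            t_inj = iso.injections[0][0]
            if iso.truth is not None:
                r = iso_response(iso.truth, t_inj)
                row.update(iso_max_5h=r.hr_max_5h, iso_mean_5h=r.hr_mean_5h)
            elif iso.hr_trace is not None:
                mx, mn = trace_iso_response(iso.hr_trace, t_inj)
                row.update(iso_max_5h=mx, iso_mean_5h=mn)
        rows.append(row)
    return rows
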