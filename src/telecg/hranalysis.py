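"""Heart-rate read-outs of a telemetry study.

Long-term (96-h, duty-cycled) sessions yield per-minute epoch HRs, from
which day/night means, the naturally occurring minimal/maximal HR and
activity-normalised HR are computed.  Acute sessions yield the maximal
and mean HR over the 5 h following an injection on 10-s sliding epochs.
All HRs are bpm; an epoch HR is 60000 / (mean RR in ms) over the epoch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from telecg.epochs import HREpoch
from telecg.sim.activity import ActivitySeries
from telecg.sim.clock import DAY_WINDOW_H, is_day

#: Activity-class boundaries (A.U.).  Class 0 is exactly zero activity;
#: classes 1..7 are the half-open bins (0,5], (5,10], ... (25,30], (30,300].
ACTIVITY_CLASS_EDGES = (0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 300.0)
N_ACTIVITY_CLASSES = 8


def _beat_times(beats) -> np.ndarray:
    if hasattr(beats, "times"):
        return np.asarray(beats.times, dtype=float)
    arr = np.asarray(beats)
    if arr.dtype == object:  # list of annotations
        return np.array([b.time for b in beats], dtype=float)
    return arr.astype(float)


def hr_epochs(
    beats,
    segments: list[tuple[float, float]],
    artifact=None,
    *,
    min_beats: int = 20,
    max_artifact_overlap: float = 0.2,
) -> list[HREpoch]:
    """One HR epoch per recorded segment (minute) of a duty-cycled session.

    An epoch is invalid when it holds fewer than ``min_beats`` beats or
    when artifact intervals cover more than ``max_artifact_overlap`` of
    it.
    """
    t = _beat_times(beats)
    out: list[HREpoch] = []
    for a, b in segments:
        sel = t[(t >= a) & (t < b)]
        art_frac = artifact.overlap(a, b) / (b - a) if artifact is not None else 0.0
        if len(sel) < min_beats or art_frac > max_artifact_overlap:
            out.append(HREpoch(start=a, hr=np.nan, valid=False, n_beats=len(sel)))
            continue
        mean_rr_ms = float(np.mean(np.diff(sel))) * 1000.0
        out.append(HREpoch(start=a, hr=60000.0 / mean_rr_ms, valid=True, n_beats=len(sel)))
    return out


@dataclass(frozen=True)
class DayNightSummary:
    mean_day: float
    mean_night: float
    min_96h: float
    max_96h: float
    n_valid_day: int
    n_valid_night: int
    defined: bool
    phase: str | None = None


def daynight_summary(
    epochs: list[HREpoch],
    day_window: tuple[float, float] = DAY_WINDOW_H,
    phase: str | None = None,
) -> DayNightSummary:
    """Day/night mean and extreme epoch HRs over a long-term session."""
    valid = [e for e in epochs if e.valid]
    if not valid:
        return DayNightSummary(np.nan, np.nan, np.nan, np.nan, 0, 0, False, phase)
    hr = np.array([e.hr for e in valid])
    day = np.array([bool(is_day(e.start, day_window)) for e in valid])
    mean_day = float(hr[day].mean()) if day.any() else np.nan
    mean_night = float(hr[~day].mean()) if (~day).any() else np.nan
    return DayNightSummary(
        mean_day=mean_day, mean_night=mean_night,
        min_96h=float(hr.min()), max_96h=float(hr.max()),
        n_valid_day=int(day.sum()), n_valid_night=int((~day).sum()),
        defined=bool(day.any() and (~day).any()), phase=phase,
    )


def activity_class(values) -> np.ndarray:
    """Map activity values (A.U.) to classes 0-7.

    Class 0 is reserved for exactly zero activity; the remaining bins are
    half-open ``(lower, upper]``.  Values above 300 A.U. clip to class 7
    with a warning."""
    a = np.atleast_1d(np.asarray(values, dtype=float))
    if np.any(a < 0):
        raise ValueError("activity values must be non-negative")
    if np.any(a > ACTIVITY_CLASS_EDGES[-1]):
        warnings.warn("activity above 300 A.U. clipped to class 7")
        a = np.minimum(a, ACTIVITY_CLASS_EDGES[-1])
    cls = np.searchsorted(ACTIVITY_CLASS_EDGES, a, side="left")
    return cls.astype(int)


def bin_hr_by_activity(
    epochs: list[HREpoch],
    activity: ActivitySeries,
    day_window: tuple[float, float] | None = None,
) -> dict[str, np.ndarray]:
    """Average epoch HR per concurrent activity class.

    Returns arrays of length 8 (NaN where a class is empty) under keys
    ``"all"`` and, when ``day_window`` is given, ``"day"``/``"night"``.
    """
    valid = [e for e in epochs if e.valid]
    hr = np.array([e.hr for e in valid])
    act = activity.value_at(np.array([e.start for e in valid])) if valid else np.empty(0)
    cls = activity_class(act) if len(act) else np.empty(0, dtype=int)

    def per_class(mask):
        out = np.full(N_ACTIVITY_CLASSES, np.nan)
        for c in range(N_ACTIVITY_CLASSES):
            sel = mask & (cls == c)
            if sel.any():
                out[c] = hr[sel].mean()
        return out

    all_mask = np.ones(len(valid), dtype=bool)
    result = {"all": per_class(all_mask)}
    if day_window is not None:
        day = np.array([bool(is_day(e.start, day_window)) for e in valid])
        result["day"] = per_class(day)
        result["night"] = per_class(~day)
    return result


def metoprolol_delta(
    summary_baseline: DayNightSummary,
    summary_metoprolol: DayNightSummary,
) -> tuple[float, float]:
    """HR reduction under beta-blockade: baseline minus metoprolol means."""
    for s in (summary_baseline, summary_metoprolol):
        if not s.defined:
            raise ValueError("both summaries must be defined")
    pb, pm = summary_baseline.phase, summary_metoprolol.phase
    if pb is not None and pm is not None:
        if "metoprolol" in pb or "metoprolol" not in pm:
            raise ValueError(f"phase mismatch: got baseline={pb!r}, metoprolol={pm!r}")
    return (
        summary_baseline.mean_day - summary_metoprolol.mean_day,
        summary_baseline.mean_night - summary_metoprolol.mean_night,
    )


@dataclass(frozen=True)
class IsoResponse:
    hr_max_5h: float
    hr_mean_5h: float
    coverage: float
    flagged: bool  # True when the recording covered < 90% of the window


def iso_response(
    beats,
    t_inj: float,
    window_s: float = 5 * 3600.0,
    artifact=None,
    *,
    epoch_s: float = 10.0,
    hop_s: float = 5.0,
    min_beats: int = 5,
) -> IsoResponse:
    """Maximal and mean HR over the post-injection window.

    HR is evaluated on 10-s sliding epochs (5-s hop) so the surge peak is
    resolved; artifact-overlapping epochs are excluded.  A coverage gap
    above 10% flags the summary.
    """
    t = _beat_times(beats)
    t0, t1 = t_inj, t_inj + window_s
    vals = []
    covered = 0.0
    s = t0
    while s + epoch_s <= t1:
        sel = t[(t >= s) & (t < s + epoch_s)]
        art = artifact.overlap(s, s + epoch_s) if artifact is not None else 0.0
        if len(sel) >= min_beats and art == 0.0:
            vals.append(60.0 / float(np.mean(np.diff(sel))))
            covered += hop_s
        s += hop_s
    coverage = covered / window_s
    if not vals:
        return IsoResponse(np.nan, np.nan, 0.0, True)
    return IsoResponse(
        hr_max_5h=float(np.max(vals)), hr_mean_5h=float(np.mean(vals)),
        coverage=coverage, flagged=coverage < 0.9,
    )
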