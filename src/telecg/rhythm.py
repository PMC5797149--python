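"""Ventricular-arrhythmia grammar and event counting.

A premature beat is labelled a premature ventricular beat (PVB) when it
is premature (RR before it shorter than 0.8 of the rolling reference RR)
and at least 2 of 3 criteria hold:

1. atypical QRS configuration with alteration of the T wave
   (template-library morphology),
2. atrioventricular dissociation (no P wave before the QRS),
3. compensatory post-extrasystolic pause (RR after it longer than 1.15
   of the reference).

The rolling reference RR is the median of the last 5 intervals flanked
by normal-labelled beats.  Maximal runs of consecutive PVBs map to event
classes: 1 -> PVB, 2 -> couplet, 3 -> triplet, >= 4 -> ventricular
tachycardia (VT).  Ventricular fibrillation (VF) is detected separately
as intervals with no distinguishable QRS complexes and overrides
beat-level labels inside its extent.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from statistics import median

import numpy as np

__all__ = [
    "ClassifierParams",
    "RRSeries",
    "CriteriaResult",
    "ArrhythmiaEvent",
    "EpisodeCounts",
    "compute_rr",
    "evaluate_pvb_criteria",
    "classify_beats",
    "group_runs",
    "detect_vf",
    "count_events",
    "group_summary",
]


@dataclass(frozen=True)
class ClassifierParams:
    """Thresholds of the beat-level classifier.

    The qualitative criteria leave the ratios open; these defaults
    separate fully compensatory ectopy from sinus arrhythmia and are
    exposed in the pipeline configuration.
    """

    premature_ratio: float = 0.8
    pause_ratio: float = 1.15
    reference_k: int = 5


@dataclass
class RRSeries:
    """Successive RR intervals; ``rr_ms[i]`` spans beats ``i`` -> ``i+1``."""

    times: np.ndarray  # beat times, s
    rr_ms: np.ndarray

    def __len__(self) -> int:
        return len(self.rr_ms)


def compute_rr(beat_times) -> RRSeries:
    """Successive differences of a time-ordered beat stream, in ms."""
    t = np.asarray(beat_times, dtype=float)
    if len(t) < 2:
        return RRSeries(times=t, rr_ms=np.empty(0))
    rr = np.diff(t) * 1000.0
    if np.any(rr <= 0):
        raise ValueError("beat times must be strictly increasing")
    return RRSeries(times=t, rr_ms=rr)


@dataclass(frozen=True)
class CriteriaResult:
    premature: bool
    c1_atypical_qrs_t: bool
    c2_av_dissociation: bool
    c3_compensatory_pause: bool
    low_confidence: bool = False

    @property
    def n_met(self) -> int:
        return int(self.c1_atypical_qrs_t) + int(self.c2_av_dissociation) + int(self.c3_compensatory_pause)

    @property
    def is_pvb(self) -> bool:
        return self.premature and self.n_met >= 2


def evaluate_pvb_criteria(
    rr_pre_ms: float | None,
    rr_post_ms: float | None,
    reference_ms: float | None,
    morphology: str,
    p_found: bool,
    params: ClassifierParams = ClassifierParams(),
) -> CriteriaResult:
    """Evaluate the 2-of-3 PVB rule for a single beat.

    ``None`` neighbours (stream boundaries) and a missing rolling
    reference make the affected criteria false and mark the result
    low-confidence.
    """
    low = reference_ms is None or rr_pre_ms is None or rr_post_ms is None
    if reference_ms is None:
        return CriteriaResult(False, morphology == "atypical", not p_found, False, True)
    premature = rr_pre_ms is not None and rr_pre_ms < params.premature_ratio * reference_ms
    c3 = rr_post_ms is not None and rr_post_ms > params.pause_ratio * reference_ms
    return CriteriaResult(premature, morphology == "atypical", not p_found, c3, low)


def classify_beats(
    beat_times,
    morphology,
    p_found,
    params: ClassifierParams = ClassifierParams(),
    vf_intervals: list[tuple[float, float]] | None = None,
    collect_results: bool = True,
) -> tuple[np.ndarray, list[CriteriaResult]]:
    """Label every beat of a stream as ``"N"``, ``"PVB"`` or ``"VF"``.

    ``morphology`` is a per-beat sequence of ``normal|atypical|unmatched``
    labels (or booleans, True meaning atypical); ``p_found`` a per-beat
    boolean sequence.  Beats inside a VF interval are labelled ``"VF"``
    and excluded from the PVB grammar.  The rolling reference RR updates
    only from intervals whose flanking beats are both normal, exactly as
    a sequential reader would maintain it.
    """
    t = np.asarray(beat_times, dtype=float)
    n = len(t)
    morph = list(morphology)
    atyp = [m if isinstance(m, (bool, np.bool_)) else (m == "atypical") for m in morph]
    pf = np.asarray(p_found, dtype=bool)
    if not (len(atyp) == n and len(pf) == n):
        raise ValueError("morphology and p_found must match the beat count")

    in_vf = np.zeros(n, dtype=bool)
    for a, b in vf_intervals or []:
        in_vf |= (t >= a) & (t < b)

    labels = np.full(n, "N", dtype="<U3")
    labels[in_vf] = "VF"
    results: list[CriteriaResult] = []
    k = params.reference_k
    prem_ratio, pause_ratio = params.premature_ratio, params.pause_ratio
    window: deque[float] = deque(maxlen=k)
    rr = (np.diff(t) * 1000.0).tolist()
    any_vf = bool(in_vf.any())
    pf_list = pf.tolist()

    prev_is_pvb = False
    for i in range(n):
        if any_vf and in_vf[i]:
            if collect_results:
                results.append(CriteriaResult(False, False, False, False, True))
            prev_is_pvb = False
            continue
        rr_pre = rr[i - 1] if i >= 1 and not (any_vf and in_vf[i - 1]) else None
        rr_post = rr[i] if i + 1 < n and not (any_vf and in_vf[i + 1]) else None
        if len(window) == k:
            ref = sorted(window)[2] if k == 5 else median(window)
            premature = rr_pre is not None and rr_pre < prem_ratio * ref
            c3 = rr_post is not None and rr_post > pause_ratio * ref
            c1 = atyp[i]
            c2 = not pf_list[i]
            this_pvb = premature and (int(c1) + int(c2) + int(c3)) >= 2
            if collect_results:
                results.append(CriteriaResult(
                    premature, bool(c1), c2, c3,
                    rr_pre is None or rr_post is None))
        else:
            this_pvb = False
            if collect_results:
                results.append(CriteriaResult(False, bool(atyp[i]), not pf_list[i], False, True))
        if this_pvb:
            labels[i] = "PVB"
        elif i >= 1 and not prev_is_pvb and rr_pre is not None:
            window.append(rr_pre)
        prev_is_pvb = this_pvb
    return labels, results


@dataclass(frozen=True)
class ArrhythmiaEvent:
    """A classified event with its temporal extent and member beats."""

    cls: str  # PVB | couplet | triplet | VT | VF
    start: float
    end: float
    n_beats: int | None  # None for VF
    beat_indices: tuple[int, ...] = ()

    def validate(self) -> None:
        if self.cls == "VF":
            if self.end <= self.start:
                raise ValueError("VF events need positive duration")
        else:
            expected = {"PVB": 1, "couplet": 2, "triplet": 3}.get(self.cls)
            if expected is not None and self.n_beats != expected:
                raise ValueError(f"{self.cls} must span {expected} beats")
            if self.cls == "VT" and (self.n_beats or 0) < 4:
                raise ValueError("VT must span >= 4 beats")


_RUN_CLASS = {1: "PVB", 2: "couplet", 3: "triplet"}


def run_class(run_length: int) -> str:
    """Map a maximal run of consecutive PVBs to its event class."""
    if run_length < 1:
        raise ValueError("run length must be >= 1")
    return _RUN_CLASS.get(run_length, "VT")


def group_runs(labels, beat_times=None) -> list[ArrhythmiaEvent]:
    """Group maximal runs of PVB-labelled beats into events.

    Each run is counted once regardless of length: a 7-beat run is one
    VT, not seven PVBs.
    """
    lab = np.asarray(labels)
    n = len(lab)
    t = np.asarray(beat_times, dtype=float) if beat_times is not None else np.arange(n, dtype=float)
    if len(t) != n:
        raise ValueError("beat_times must match labels")
    is_p = lab == "PVB"
    events: list[ArrhythmiaEvent] = []
    i = 0
    while i < n:
        if not is_p[i]:
            i += 1
            continue
        j = i
        while j < n and is_p[j]:
            j += 1
        ev = ArrhythmiaEvent(
            cls=run_class(j - i), start=float(t[i]), end=float(t[j - 1]),
            n_beats=j - i, beat_indices=tuple(range(i, j)),
        )
        ev.validate()
        events.append(ev)
        i = j
    return events


def expand_events(events: list[ArrhythmiaEvent], n_beats: int) -> np.ndarray:
    """Inverse of :func:`group_runs` on the beat-index grammar."""
    lab = np.full(n_beats, "N", dtype="<U3")
    for ev in events:
        if ev.cls == "VF":
            continue
        for i in ev.beat_indices:
            lab[i] = "PVB"
    return lab


def detect_vf(
    record,
    beats,
    *,
    window_s: float = 1.0,
    hop_s: float = 0.5,
    min_duration_s: float = 1.0,
    rms_factor: float = 3.0,
    match_threshold: float = 0.8,
) -> list[ArrhythmiaEvent]:
    """Detect VF as intervals with no distinguishable QRS complexes.

    A sliding window is flagged when it contains no beat matching a
    template at or above ``match_threshold`` while the signal RMS stays
    above ``rms_factor`` times the record's noise floor (so flat signal
    never counts as VF).  Adjacent flagged windows merge; episodes below
    ``min_duration_s`` are dropped.
    """
    from telecg.detect import noise_floor  # local import, no cycle at module load

    floor = noise_floor(record)
    matched_times = np.array([
        b.time for b in beats
        if b.match_score is not None and b.match_score >= match_threshold
    ])
    events: list[ArrhythmiaEvent] = []
    for (a, b), sl in record.segment_slices():
        x = record.signal[sl]
        nwin = int(np.floor(((b - a) - window_s) / hop_s)) + 1
        flagged: list[tuple[float, float]] = []
        for w in range(max(nwin, 0)):
            w0 = a + w * hop_s
            w1 = w0 + window_s
            i0 = int((w0 - a) * record.fs)
            i1 = int((w1 - a) * record.fs)
            seg = x[i0:i1]
            rms = float(np.sqrt(np.mean(seg**2))) if len(seg) else 0.0
            has_beat = bool(np.any((matched_times >= w0) & (matched_times < w1)))
            if not has_beat and rms > rms_factor * floor:
                flagged.append((w0, w1))
        # a flagged window only certifies its interior; the episode extends
        # partway into the neighbouring windows, so pad by half a hop
        pad = hop_s / 2.0
        for s0, s1 in _merge_intervals(flagged):
            if s1 - s0 >= min_duration_s:
                events.append(ArrhythmiaEvent(
                    cls="VF", start=max(s0 - pad, a), end=min(s1 + pad, b),
                    n_beats=None))
    return events


def _merge_intervals(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    out: list[tuple[float, float]] = []
    for a, b in sorted(intervals):
        if out and a <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


@dataclass(frozen=True)
class EpisodeCounts:
    """Per-animal event counts over one analysis window."""

    pvb: int = 0
    coupled: int = 0
    vt: int = 0
    vf: int = 0

    @property
    def total(self) -> int:
        return self.pvb + self.coupled + self.vt + self.vf


def count_events(
    events: list[ArrhythmiaEvent],
    window: tuple[float, float],
    artifact=None,
) -> EpisodeCounts:
    """Count events whose onset falls in ``[start, end)``, skipping
    onsets inside artifact intervals.  Couplets and triplets pool as
    "coupled beats"."""
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window must have positive length")
    art = list(artifact.intervals) if artifact is not None else []
    c = {"PVB": 0, "coupled": 0, "VT": 0, "VF": 0}
    for ev in events:
        if not (t0 <= ev.start < t1):
            continue
        if any(a <= ev.start < b for a, b, *_ in art):
            continue
        if ev.cls in ("couplet", "triplet"):
            c["coupled"] += 1
        else:
            c[ev.cls] += 1
    return EpisodeCounts(pvb=c["PVB"], coupled=c["coupled"], vt=c["VT"], vf=c["VF"])


def group_summary(counts_by_animal: dict[str, EpisodeCounts], strain_by_animal: dict[str, str]):
    """Table-2-style group aggregation: mean +/- SEM per class and the
    fraction of animals showing >= 1 event of the class."""
    import pandas as pd

    rows = []
    strains = sorted(set(strain_by_animal.values()))
    for strain in strains:
        ids = [a for a, s in strain_by_animal.items() if s == strain]
        n = len(ids)
        for cls in ("pvb", "coupled", "vt", "vf", "total"):
            vals = np.array([getattr(counts_by_animal[a], cls) for a in ids], dtype=float)
            affected = int(np.sum(vals > 0))
            rows.append({
                "strain": strain, "class": cls, "n": n,
                "mean": float(vals.mean()) if n else np.nan,
                "sem": float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
                "n_affected": affected,
                "fraction": affected / n if n else np.nan,
            })
    return pd.DataFrame(rows)
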