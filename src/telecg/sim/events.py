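"""Ground-truth arrhythmia event scheduling.

Events of each class arrive as a homogeneous Poisson process over the
requested window at the strain's per-5-h rate.  A scheduled entry carries
the event class, its onset and either a run length in beats (ventricular
ectopy) or a duration in seconds (VF).  Entries never overlap and are
separated by at least ``min_gap_s`` of sinus rhythm so that every entry
maps onto exactly one maximal run of premature beats downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from telecg.profiles import StrainProfile

RATE_WINDOW_S = 5 * 3600.0  # rates are events per 5 h

#: run-length grammar for ventricular ectopy classes
RUN_LENGTHS = {"PVB": 1, "couplet": 2, "triplet": 3}

#: probability that a "coupled beats" event is a couplet (else triplet)
COUPLET_SHARE = 0.7


@dataclass(frozen=True)
class ScheduledEvent:
    cls: str  # PVB | couplet | triplet | VT | VF
    onset: float  # s
    run_length: int | None = None  # beats; None for VF
    duration: float | None = None  # s; VF only

    def footprint(self, nominal_rr_s: float = 0.1) -> float:
        """Approximate temporal extent used for overlap resolution."""
        if self.cls == "VF":
            return float(self.duration)
        return (self.run_length + 2) * nominal_rr_s

    def validate(self) -> None:
        if self.cls == "VF":
            if self.duration is None or self.duration <= 0:
                raise ValueError("VF events need a positive duration")
        elif self.cls == "VT":
            if self.run_length is None or self.run_length < 4:
                raise ValueError("VT run length must be >= 4 beats")
        elif self.cls in RUN_LENGTHS:
            if self.run_length != RUN_LENGTHS[self.cls]:
                raise ValueError(
                    f"{self.cls} must have run length {RUN_LENGTHS[self.cls]}"
                )
        else:
            raise ValueError(f"unknown event class {self.cls!r}")


@dataclass
class EventSchedule:
    entries: list[ScheduledEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.entries = sorted(self.entries, key=lambda e: e.onset)
        for e in self.entries:
            e.validate()

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def counts(self) -> dict[str, int]:
        out = {"PVB": 0, "couplet": 0, "triplet": 0, "VT": 0, "VF": 0}
        for e in self.entries:
            out[e.cls] += 1
        return out


def schedule_arrhythmias(
    profile: StrainProfile,
    window: tuple[float, float],
    *,
    rng: np.random.Generator,
    nominal_rr_s: float = 0.1,
    min_gap_s: float = 1.0,
    max_redraws: int = 10_000,
) -> EventSchedule:
    """Draw a non-overlapping event schedule for one session window.

    Per-class counts are Poisson with mean ``rate * window_len / 5 h``;
    onsets are uniform in the window.  Onsets whose footprint would
    overlap a neighbour (with ``min_gap_s`` separation) are re-drawn.
    """
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window length must be positive")
    scale = (t1 - t0) / RATE_WINDOW_S

    proposals: list[ScheduledEvent] = []

    def add(cls: str, n: int, run_length_fn, duration_fn=None) -> None:
        for _ in range(n):
            rl = run_length_fn() if run_length_fn else None
            du = duration_fn() if duration_fn else None
            proposals.append(
                ScheduledEvent(cls=cls, onset=float(rng.uniform(t0, t1)),
                               run_length=rl, duration=du)
            )

    add("PVB", rng.poisson(profile.event_rate_pvb * scale), lambda: 1)
    n_coupled = rng.poisson(profile.event_rate_coupled * scale)
    for _ in range(n_coupled):
        cls = "couplet" if rng.random() < COUPLET_SHARE else "triplet"
        proposals.append(
            ScheduledEvent(cls=cls, onset=float(rng.uniform(t0, t1)),
                           run_length=RUN_LENGTHS[cls])
        )
    add("VT", rng.poisson(profile.event_rate_vt * scale),
        lambda: int(profile.vt_runlength_law.sample(rng)))
    add("VF", rng.poisson(profile.event_rate_vf * scale), None,
        lambda: float(profile.vf_duration_law.sample(rng)))

    # resolve overlaps by re-drawing onsets until the packing is valid
    for _ in range(max_redraws):
        proposals.sort(key=lambda e: e.onset)
        bad = _first_overlap(proposals, nominal_rr_s, min_gap_s, t1)
        if bad is None:
            break
        e = proposals[bad]
        proposals[bad] = ScheduledEvent(
            cls=e.cls, onset=float(rng.uniform(t0, t1)),
            run_length=e.run_length, duration=e.duration,
        )
    else:
        raise RuntimeError(
            "could not place the drawn events without overlap; "
            "the window is too crowded for the requested rates"
        )
    return EventSchedule(entries=proposals)


def _first_overlap(
    entries: list[ScheduledEvent], nominal_rr_s: float, min_gap_s: float, t_end: float
) -> int | None:
    """Index of the first entry violating the packing, else None."""
    prev_end = -np.inf
    for i, e in enumerate(entries):
        if e.onset < prev_end + min_gap_s:
            return i
        end = e.onset + e.footprint(nominal_rr_s)
        if end > t_end:
            return i
        prev_end = end
    return None
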