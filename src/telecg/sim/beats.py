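"""Beat placement and ground-truth labels.

Sinus beats are placed by time-rescaling of the latent rate: beat k+1
occurs when the integrated rate since beat k reaches one, i.e.
``integral(HR(t)/60 dt) = 1``.  This is exact for a time-varying rate and
inherits its variability from the OU noise already present in the latent
HR, so sinus RR series are quasi-periodic rather than Poisson (a Poisson
RR stream would defeat any prematurity criterion).

Scheduled events then rewrite the beat stream:

* ectopic runs replace sinus beats with premature beats (coupling
  interval 0.65 of the local RR, intra-run RR 0.55) while the sinus
  clock keeps running underneath, so the beat after a single ectopic
  falls back on the undisturbed sinus grid - a fully compensatory pause
  (RR_pre + RR_post = 2 RR);
* VF intervals remove all discernible beats.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from telecg.sim.events import EventSchedule
from telecg.sim.hr import HRTrace

PVB_COUPLING = 0.65  # first premature beat, fraction of local RR
RUN_COUPLING = 0.55  # intra-run RR, fraction of local RR
RESUME_MARGIN = 0.5  # sinus beats closer than this (in RR) to the run end are absorbed


@dataclass
class BeatTruth:
    """Ground-truth beat stream for one recording session."""

    times: np.ndarray  # s, strictly increasing
    labels: np.ndarray  # "N" | "PVB"
    event_id: np.ndarray  # schedule entry index, -1 for sinus beats
    p_wave: np.ndarray  # bool, P wave present (omitted for ectopy)
    vf_intervals: list[tuple[float, float]] = field(default_factory=list)
    schedule: EventSchedule | None = None

    def __post_init__(self) -> None:
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("beat times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def n_pvb_beats(self) -> int:
        return int(np.sum(self.labels == "PVB"))


def sinus_times(hr: HRTrace, phase_frac: float = 0.5) -> np.ndarray:
    """Invert the integrated rate to quasi-periodic beat times."""
    rate = hr.hr / 60.0  # beats per second
    # each sample's rate applies over [t, t + dt): the integral covers the
    # full nominal duration n * dt
    cum = np.concatenate([[0.0], np.cumsum(rate * hr.dt)])
    grid = np.concatenate([hr.times, [hr.times[-1] + hr.dt]])
    n_beats = int(np.floor(cum[-1] - phase_frac))
    if n_beats <= 0:
        return np.empty(0)
    targets = phase_frac + np.arange(n_beats + 1)
    targets = targets[targets <= cum[-1]]
    return np.interp(targets, cum, grid)


def simulate_beats(
    hr: HRTrace,
    schedule: EventSchedule | None = None,
    *,
    rng: np.random.Generator | None = None,
) -> BeatTruth:
    """Generate the ground-truth beat stream for a latent HR trace."""
    phase = float(rng.uniform(0.2, 0.8)) if rng is not None else 0.5
    t = sinus_times(hr, phase)
    labels = np.full(len(t), "N", dtype="<U3")
    ev_id = np.full(len(t), -1, dtype=int)

    if schedule is None or len(schedule) == 0:
        return BeatTruth(times=t, labels=labels, event_id=ev_id,
                         p_wave=labels == "N", schedule=schedule)

    keep = np.ones(len(t), dtype=bool)
    ins_t: list[float] = []
    ins_id: list[int] = []
    vf_intervals: list[tuple[float, float]] = []
    last_end = -np.inf

    for k, ev in enumerate(schedule):
        if ev.onset <= t[0] or ev.onset >= t[-1]:
            raise ValueError(f"schedule entry {k} at {ev.onset:.3f}s lies outside the beat stream")
        if ev.cls == "VF":
            i0, i1 = np.searchsorted(t, [ev.onset, ev.onset + ev.duration])
            keep[i0:i1] = False
            vf_intervals.append((ev.onset, ev.onset + ev.duration))
            last_end = ev.onset + ev.duration
            continue
        i = int(np.searchsorted(t, ev.onset))
        L = ev.run_length
        if i < 1 or i + L + 2 >= len(t):
            raise ValueError(f"schedule entry {k} too close to the stream boundary")
        prev = t[i - 1]
        if prev < last_end:
            raise ValueError("scheduled events too dense for the local heart rate")
        rr = t[i] - t[i - 1]
        run = prev + rr * (PVB_COUPLING + RUN_COUPLING * np.arange(L))
        resume_after = run[-1] + RESUME_MARGIN * rr
        j = int(np.searchsorted(t, resume_after))
        keep[i:j] = False
        ins_t.extend(run.tolist())
        ins_id.extend([k] * L)
        last_end = resume_after

    all_t = np.concatenate([t[keep], np.asarray(ins_t)])
    all_lab = np.concatenate([labels[keep], np.full(len(ins_t), "PVB", dtype="<U3")])
    all_id = np.concatenate([ev_id[keep], np.asarray(ins_id, dtype=int)])
    order = np.argsort(all_t)
    truth = BeatTruth(
        times=all_t[order], labels=all_lab[order], event_id=all_id[order],
        p_wave=all_lab[order] == "N", vf_intervals=vf_intervals, schedule=schedule,
    )
    return truth
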