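"""Whole-study simulation following the telemetry protocol.

Per animal: a 96-h duty-cycled baseline recording, two continuous acute
cross-over sessions (vehicle and isoproterenol, order randomised, one
simulated week apart, two same-agent injections 30 min apart per
session), and a 96-h duty-cycled recording under chronic metoprolol.

Three fidelity levels trade realism for cost:

``"epoch"``
    Latent HR and activity only; per-minute epoch HRs are taken as the
    time-mean of the latent trace over each recorded minute.  Suited to
    circadian/pharmacological analyses over many animals.
``"beat"``
    Ground-truth beat streams (with scheduled arrhythmias in the
    isoproterenol session) but no waveform.  Suited to RR-based
    classification at scale.
``"waveform"``
    Full 1-kHz ECG synthesis.  Costly; intended for bounded durations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from telecg.epochs import HREpoch
from telecg.profiles import StrainProfile, StudyDesign
from telecg.sim.activity import ActivitySeries, generate_activity
from telecg.sim.beats import BeatTruth, simulate_beats, sinus_times
from telecg.sim.ecg import ECGRecord, NoiseParams, synthesize_ecg
from telecg.sim.events import EventSchedule, schedule_arrhythmias
from telecg.sim.hr import HRParams, HRTrace, apply_isoproterenol, simulate_hr_profile

FIDELITIES = ("epoch", "beat", "waveform")

#: events per 5 h injected in vehicle (NaCl) sessions: occasional single
#: ectopic beats in some animals, as seen under sham injection
VEHICLE_PVB_RATE = 0.3


@dataclass
class Session:
    phase: str  # baseline_96h | metoprolol_96h | acute_vehicle | acute_iso
    mode: str  # longterm | continuous
    fidelity: str
    t0: float  # clock s of session start
    duration: float  # s
    segments: list[tuple[float, float]]
    activity: ActivitySeries | None = None
    hr_trace: HRTrace | None = None
    epochs: list[HREpoch] | None = None
    truth: BeatTruth | None = None
    schedule: EventSchedule | None = None
    record: ECGRecord | None = None
    injections: list[tuple[float, str]] = field(default_factory=list)


@dataclass
class AnimalStudy:
    animal_id: str
    strain: str
    acute_order: tuple[str, str]
    sessions: dict[str, Session] = field(default_factory=dict)


@dataclass
class StudyData:
    design: StudyDesign
    animals: list[AnimalStudy] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.animals)


def _duty_segments(t0: float, duration: float, rec: float, block: float) -> list[tuple[float, float]]:
    out = []
    start = t0
    while start < t0 + duration:
        out.append((start, min(start + rec, t0 + duration)))
        start += block
    return out


def trace_epochs(trace: HRTrace, segments: list[tuple[float, float]]) -> list[HREpoch]:
    """Epoch HRs as time-means of the latent trace over recorded minutes."""
    out = []
    for a, b in segments:
        i0 = int(np.searchsorted(trace.times, a))
        i1 = int(np.searchsorted(trace.times, b))
        if i1 <= i0:
            out.append(HREpoch(start=a, hr=np.nan, valid=False))
            continue
        m = float(np.mean(trace.hr[i0:i1]))
        out.append(HREpoch(start=a, hr=m, valid=True, n_beats=int(m * (b - a) / 60)))
    return out


def segment_beats(trace: HRTrace, segments: list[tuple[float, float]]) -> BeatTruth:
    """Ground-truth sinus beats restricted to the recorded segments."""
    times = []
    for a, b in segments:
        i0 = int(np.searchsorted(trace.times, a))
        i1 = int(np.searchsorted(trace.times, b)) + 1
        sub = HRTrace(
            times=trace.times[i0:i1], dt=trace.dt, hr=trace.hr[i0:i1],
            components={k: v[i0:i1] for k, v in trace.components.items()},
            floor=trace.floor[i0:i1], profile_name=trace.profile_name, phase=trace.phase,
        )
        times.append(sinus_times(sub))
    t = np.concatenate(times) if times else np.empty(0)
    lab = np.full(len(t), "N", dtype="<U3")
    return BeatTruth(times=t, labels=lab, event_id=np.full(len(t), -1, dtype=int),
                     p_wave=np.ones(len(t), dtype=bool))


def longterm_epoch_hr(
    profile: StrainProfile,
    phase: str,
    *,
    rng: np.random.Generator,
    duration_h: float = 96.0,
    t0_clock: float = 0.0,
    hr_params: HRParams | None = None,
    duty: tuple[float, float] = (60.0, 300.0),
) -> tuple[ActivitySeries, HRTrace, list[HREpoch]]:
    """One long-term (duty-cycled) session at epoch fidelity."""
    duration = duration_h * 3600.0
    activity = generate_activity(profile, duration, rng=rng, t0_clock=t0_clock)
    trace = simulate_hr_profile(
        profile, phase, activity, duration, rng=rng, dt=1.0,
        t0_clock=t0_clock, params=hr_params,
    )
    segs = _duty_segments(t0_clock, duration, duty[0], duty[1])
    return activity, trace, trace_epochs(trace, segs)


def _longterm_session(
    profile: StrainProfile, phase_key: str, fidelity: str, t0: float,
    design: StudyDesign, rng: np.random.Generator, hr_params: HRParams | None,
    noise: NoiseParams,
) -> Session:
    phase = "metoprolol" if phase_key == "metoprolol_96h" else "baseline"
    duration = design.longterm_duration_h * 3600.0
    activity = generate_activity(profile, duration, rng=rng, t0_clock=t0)
    trace = simulate_hr_profile(profile, phase, activity, duration, rng=rng,
                                dt=1.0, t0_clock=t0, params=hr_params)
    segs = _duty_segments(t0, duration, *design.longterm_duty)
    ses = Session(phase=phase_key, mode="longterm", fidelity=fidelity, t0=t0,
                  duration=duration, segments=segs, activity=activity, hr_trace=trace)
    if fidelity == "epoch":
        ses.epochs = trace_epochs(trace, segs)
    else:
        ses.truth = segment_beats(trace, segs)
        ses.epochs = trace_epochs(trace, segs)
        if fidelity == "waveform":
            ses.record = _render_segments(trace, segs, design.sampling_rate, noise, rng, ses)
    return ses


def _render_segments(trace, segments, fs, noise, rng, ses) -> ECGRecord:
    chunks = []
    for a, b in segments:
        i0 = int(np.searchsorted(trace.times, a))
        i1 = int(np.searchsorted(trace.times, b)) + 1
        sub = HRTrace(
            times=trace.times[i0:i1], dt=trace.dt, hr=trace.hr[i0:i1],
            components={k: v[i0:i1] for k, v in trace.components.items()},
            floor=trace.floor[i0:i1], profile_name=trace.profile_name, phase=trace.phase,
        )
        rec, _ = synthesize_ecg(sub, None, fs=fs, noise=noise, rng=rng)
        n = int(round((b - a) * fs))
        chunks.append(rec.signal[:n])
    out = ECGRecord(
        animal_id="", strain=trace.profile_name, phase=ses.phase, session=ses.phase,
        t0=segments[0][0], fs=fs, signal=np.concatenate(chunks), segments=list(segments),
    )
    return out


def _acute_session(
    profile: StrainProfile, agent: str, fidelity: str, t0: float,
    design: StudyDesign, rng: np.random.Generator, hr_params: HRParams | None,
    noise: NoiseParams,
) -> Session:
    duration = design.acute_duration_min * 60.0
    activity = generate_activity(profile, duration, rng=rng, t0_clock=t0)
    dt = 0.5
    trace = simulate_hr_profile(profile, "baseline", activity, duration, rng=rng,
                                dt=dt, t0_clock=t0, params=hr_params)
    inj = [(t0 + 1800.0, agent), (t0 + 3600.0, agent)]
    if agent == "isoproterenol":
        for t_inj, _ in inj:
            trace = apply_isoproterenol(trace, t_inj, profile)
        rates = profile
    else:
        rates = profile.with_rates(pvb=VEHICLE_PVB_RATE, coupled=0.0, vt=0.0, vf=0.0)
    window = (inj[0][0] + 60.0, t0 + duration - 60.0)
    schedule = schedule_arrhythmias(rates, window, rng=rng, nominal_rr_s=0.15)
    ses = Session(
        phase=f"acute_{'iso' if agent == 'isoproterenol' else 'vehicle'}",
        mode="continuous", fidelity=fidelity, t0=t0, duration=duration,
        segments=[(t0, t0 + duration)], activity=activity, hr_trace=trace,
        schedule=schedule, injections=inj,
    )
    if fidelity == "epoch":
        return ses
    ses.truth = simulate_beats(trace, schedule, rng=rng)
    if fidelity == "waveform":
        rec, _ = synthesize_ecg(trace, schedule, fs=design.sampling_rate,
                                noise=noise, rng=rng, truth=ses.truth,
                                session=ses.phase)
        rec.phase = ses.phase
        ses.record = rec
    return ses


def simulate_study(
    design: StudyDesign,
    *,
    fidelity: str = "beat",
    hr_params: HRParams | None = None,
    noise: NoiseParams | None = None,
) -> StudyData:
    """Simulate the full study for every animal of the design.

    Deterministic given ``(design, design.seed)``: per-animal random
    streams are spawned from a single root ``SeedSequence``.
    """
    design.validate()
    if fidelity not in FIDELITIES:
        raise ValueError(f"fidelity must be one of {FIDELITIES}")
    noise = noise or NoiseParams()
    root = np.random.SeedSequence(design.seed)
    study = StudyData(design=design)

    strains = {p.name: p for p in design.strains}
    animal_seeds = root.spawn(design.n_animals)
    k = 0
    for name, n in design.n_per_strain.items():
        profile = strains[name]
        for j in range(n):
            rng = np.random.default_rng(animal_seeds[k])
            k += 1
            animal_id = f"{name.replace('/', '')}-{j + 1:02d}"
            order = ("vehicle", "isoproterenol") if rng.random() < 0.5 else ("isoproterenol", "vehicle")
            animal = AnimalStudy(animal_id=animal_id, strain=name, acute_order=order)
            sessions: dict[str, Session] = {}
            if "baseline_96h" in design.phases:
                sessions["baseline_96h"] = _longterm_session(
                    profile, "baseline_96h", fidelity, 0.0, design, rng, hr_params, noise)
            if "acute_crossover" in design.phases:
                day = 6 * 86400.0
                for agent in order:
                    key = "acute_iso" if agent == "isoproterenol" else "acute_vehicle"
                    sessions[key] = _acute_session(
                        profile, agent, fidelity, day + 9 * 3600.0, design, rng,
                        hr_params, noise)
                    day += 7 * 86400.0
            if "metoprolol_96h" in design.phases:
                sessions["metoprolol_96h"] = _longterm_session(
                    profile, "metoprolol_96h", fidelity, 28 * 86400.0, design, rng,
                    hr_params, noise)
            for ses in sessions.values():
                if ses.record is not None:
                    ses.record.animal_id = animal_id
            animal.sessions = sessions
            study.animals.append(animal)
    return study
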