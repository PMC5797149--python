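"""Strain profiles and study designs.

A :class:`StrainProfile` bundles everything the generator needs to emulate
one genetic background: circadian heart-rate plateaus, the naturally
occurring HR floor/ceiling, cage-activity levels, the pharmacodynamic
response to metoprolol and isoproterenol, and per-class ventricular
arrhythmia rates under beta-adrenergic stimulation.

The built-in table covers the four backgrounds commonly contrasted in
murine arrhythmia-susceptibility work (Balb/c, C57Bl/6, Black Swiss, FVB).
Rates are expressed per 5-hour observation window, the standard
post-injection analysis window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "RunLengthLaw",
    "DurationLaw",
    "StrainProfile",
    "StudyDesign",
    "BUILTIN_STRAINS",
    "default_design",
    "HR_CLIP",
    "PRECLIP_CEILING",
]

#: Hard output clip for any instantaneous-HR trace, bpm.
HR_CLIP = (150.0, 850.0)

#: Sanity ceiling for the *unclipped* sum of HR components, bpm.  Profile
#: validation requires ``hr_max + iso_peak_delta`` to stay below this.
PRECLIP_CEILING = 1100.0


@dataclass(frozen=True)
class RunLengthLaw:
    """Distribution of ventricular-tachycardia run lengths (beats).

    Shifted geometric: ``min_run + Geometric(p) - 1`` so the support is
    ``{min_run, min_run+1, ...}``.  ``min_run=4`` encodes the convention
    that a VT is a run of at least 4 consecutive premature beats.
    """

    min_run: int = 4
    p: float = 0.35

    def sample(self, rng: np.random.Generator, size: int | None = None):
        return self.min_run - 1 + rng.geometric(self.p, size=size)

    def validate(self) -> None:
        if self.min_run < 4:
            raise ValueError("VT run-length support must start at >= 4 beats")
        if not 0.0 < self.p <= 1.0:
            raise ValueError("geometric parameter p must lie in (0, 1]")


@dataclass(frozen=True)
class DurationLaw:
    """Log-normal law for ventricular-fibrillation episode durations (s)."""

    median_s: float = 3.0
    sigma: float = 0.5

    def sample(self, rng: np.random.Generator, size: int | None = None):
        return rng.lognormal(math.log(self.median_s), self.sigma, size=size)

    def validate(self) -> None:
        if self.median_s <= 0:
            raise ValueError("VF median duration must be positive")
        if self.sigma < 0:
            raise ValueError("VF duration sigma must be non-negative")


@dataclass(frozen=True)
class StrainProfile:
    """Generator parameters for one genetic background.

    HR values are bpm; activity in arbitrary units (A.U., telemetry
    transponder counts per 5-min epoch); taus in minutes; event rates in
    events per 5-hour window.
    """

    name: str
    hr_day_mean: float
    hr_night_mean: float
    hr_min: float
    hr_max: float
    activity_day_mean: float
    activity_night_mean: float
    metoprolol_delta_day: float = 50.0
    metoprolol_delta_night: float = 70.0
    iso_peak_delta: float = 250.0
    iso_rise_tau: float = 3.0
    iso_decay_tau: float = 45.0
    event_rate_pvb: float = 0.0
    event_rate_coupled: float = 0.0
    event_rate_vt: float = 0.0
    event_rate_vf: float = 0.0
    vt_runlength_law: RunLengthLaw = field(default_factory=RunLengthLaw)
    vf_duration_law: DurationLaw = field(default_factory=DurationLaw)

    def validate(self) -> None:
        if not (self.hr_min < self.hr_day_mean <= self.hr_night_mean < self.hr_max):
            raise ValueError(
                f"{self.name}: expected hr_min < hr_day_mean <= hr_night_mean "
                f"< hr_max, got {self.hr_min}, {self.hr_day_mean}, "
                f"{self.hr_night_mean}, {self.hr_max}"
            )
        rates = (
            self.event_rate_pvb,
            self.event_rate_coupled,
            self.event_rate_vt,
            self.event_rate_vf,
        )
        if any(r < 0 for r in rates):
            raise ValueError(f"{self.name}: event rates must be non-negative")
        if self.hr_max + self.iso_peak_delta > PRECLIP_CEILING:
            raise ValueError(
                f"{self.name}: hr_max + iso_peak_delta exceeds the "
                f"physiological pre-clip ceiling ({PRECLIP_CEILING} bpm)"
            )
        if self.iso_rise_tau <= 0 or self.iso_decay_tau <= 0:
            raise ValueError(f"{self.name}: isoproterenol taus must be positive")
        if self.iso_rise_tau >= self.iso_decay_tau:
            raise ValueError(f"{self.name}: rise tau must be below decay tau")
        self.vt_runlength_law.validate()
        self.vf_duration_law.validate()

    def with_rates(self, pvb=None, coupled=None, vt=None, vf=None) -> "StrainProfile":
        """Return a copy with some event rates replaced (kwargs in events/5 h)."""
        kw = {}
        if pvb is not None:
            kw["event_rate_pvb"] = pvb
        if coupled is not None:
            kw["event_rate_coupled"] = coupled
        if vt is not None:
            kw["event_rate_vt"] = vt
        if vf is not None:
            kw["event_rate_vf"] = vf
        return replace(self, **kw)

    @property
    def total_event_rate(self) -> float:
        return (
            self.event_rate_pvb
            + self.event_rate_coupled
            + self.event_rate_vt
            + self.event_rate_vf
        )


# Built-in backgrounds.  Floors/ceilings are the naturally occurring
# 96-h minimal/maximal epoch HRs per group; event rates are the group-mean
# event counts over the 5-h post-isoproterenol window.
BUILTIN_STRAINS: dict[str, StrainProfile] = {
    p.name: p
    for p in (
        StrainProfile(
            name="Balb/c",
            hr_day_mean=500.0, hr_night_mean=560.0,
            hr_min=317.0, hr_max=747.0,
            activity_day_mean=8.0, activity_night_mean=40.0,
            event_rate_pvb=158.2, event_rate_coupled=46.7,
            event_rate_vt=14.0, event_rate_vf=4.7,
        ),
        StrainProfile(
            name="C57Bl/6",
            hr_day_mean=510.0, hr_night_mean=575.0,
            hr_min=327.0, hr_max=768.0,
            activity_day_mean=9.0, activity_night_mean=45.0,
            event_rate_pvb=72.8, event_rate_coupled=18.2,
            event_rate_vt=1.2, event_rate_vf=0.0,
        ),
        StrainProfile(
            name="BS",
            hr_day_mean=545.0, hr_night_mean=620.0,
            hr_min=392.0, hr_max=763.0,
            activity_day_mean=12.0, activity_night_mean=60.0,
            event_rate_pvb=40.2, event_rate_coupled=11.2,
            event_rate_vt=0.5, event_rate_vf=0.0,
        ),
        StrainProfile(
            name="FVB",
            hr_day_mean=550.0, hr_night_mean=615.0,
            hr_min=372.0, hr_max=774.0,
            activity_day_mean=7.0, activity_night_mean=30.0,
            event_rate_pvb=89.8, event_rate_coupled=25.2,
            event_rate_vt=4.0, event_rate_vf=0.0,
        ),
    )
}


@dataclass(frozen=True)
class StudyDesign:
    """Design of a complete telemetry study.

    ``n_per_strain`` maps strain name to group size.  Phases are run in
    order: a 96-h baseline recording, the acute cross-over sessions
    (vehicle and isoproterenol, order randomised per animal), and a 96-h
    recording under chronic metoprolol.  Long-term recordings are
    duty-cycled (1 min stored per 5-min block); acute sessions are
    continuous.
    """

    strains: tuple[StrainProfile, ...] = tuple(BUILTIN_STRAINS.values())
    n_per_strain: dict[str, int] = field(
        default_factory=lambda: {"Balb/c": 6, "C57Bl/6": 6, "BS": 6, "FVB": 5}
    )
    phases: tuple[str, ...] = ("baseline_96h", "acute_crossover", "metoprolol_96h")
    day_window: tuple[float, float] = (7.0, 19.0)  # clock hours, lights on
    sampling_rate: float = 1000.0  # Hz
    longterm_duty: tuple[float, float] = (60.0, 300.0)  # s recorded per block
    longterm_duration_h: float = 96.0
    acute_duration_min: float = 330.0  # 30 min lead-in + 300 min observation
    seed: int = 0

    def validate(self) -> None:
        names = {p.name for p in self.strains}
        for label, n in self.n_per_strain.items():
            if label not in names:
                raise ValueError(f"unknown strain label: {label!r}")
            if n < 0:
                raise ValueError(f"group size for {label!r} must be >= 0, got {n}")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.acute_duration_min < 300:
            raise ValueError("acute sessions must cover >= 300 min")
        d0, d1 = self.day_window
        if not (0 <= d0 < d1 <= 24):
            raise ValueError("day_window must be an interval within [0, 24] h")
        rec, block = self.longterm_duty
        if not (0 < rec <= block):
            raise ValueError("duty cycle must record a positive fraction of a block")
        for p in self.strains:
            p.validate()

    @property
    def n_animals(self) -> int:
        return sum(self.n_per_strain.values())


def default_design(seed: int = 0) -> StudyDesign:
    """The standard 4-strain, 23-animal design."""
    return StudyDesign(seed=seed)
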