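"""Latent instantaneous heart-rate model.

Instantaneous HR is the sum of four additive components:

``circadian``
    Raised-cosine transitions between the day and night plateaus (1-h
    ramps at the 07:00 / 19:00 light switches) plus a mid-day quiescence
    trough during which the component relaxes below the strain's
    physiological floor ``hr_min``; the floor clip then pins deep-rest HR
    at exactly ``hr_min``, which is what makes the naturally occurring
    minimal epoch HR a calibrated quantity.

``activity``
    Saturating (Hill-type) gain on the concurrent 5-min activity value.

``drug``
    Metoprolol subtracts a day/night-specific delta (the floor shifts
    with it); isoproterenol adds a double-exponential surge
    (:func:`apply_isoproterenol`).

``noise``
    Mean-zero Ornstein-Uhlenbeck process (default sd 8 bpm, correlation
    time 30 s) giving realistic minute-scale HR dispersion.

The stored ``hr`` is the component sum clipped to
``[max(150, floor(t)), 850]`` bpm; the unclipped sum is always
recoverable as the exact sum of the stored components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from telecg.profiles import HR_CLIP, StrainProfile
from telecg.sim.activity import ActivitySeries
from telecg.sim.clock import fraction_night, is_day, rest_fraction

PHASES = ("baseline", "metoprolol")


@dataclass(frozen=True)
class HRParams:
    """Tunables of the latent HR process (bpm / seconds)."""

    noise_sd: float = 8.0
    noise_tau: float = 30.0
    activity_gain_max: float = 60.0
    activity_a50: float = 15.0
    trough_margin: float = 15.0  # circadian dip below hr_min inside the rest core
    ramp_s: float = 3600.0
    rest_window: tuple[float, float] = (12.0, 15.0)


@dataclass
class HRTrace:
    """Sampled latent HR with its additive decomposition."""

    times: np.ndarray  # s, clock-referenced, uniform grid
    dt: float
    hr: np.ndarray  # bpm, clipped
    components: dict[str, np.ndarray]
    floor: np.ndarray  # bpm, time-varying lower clip
    profile_name: str
    phase: str

    @property
    def unclipped(self) -> np.ndarray:
        """Exact component sum, before any clipping."""
        return sum(self.components.values())

    def hr_at(self, t: np.ndarray | float) -> np.ndarray:
        return np.interp(np.asarray(t, dtype=float), self.times, self.hr)


def _clip(unclipped: np.ndarray, floor: np.ndarray) -> np.ndarray:
    lo = np.maximum(floor, HR_CLIP[0])
    return np.clip(unclipped, lo, HR_CLIP[1])


def _ou(n: int, dt: float, sd: float, tau: float, rng: np.random.Generator) -> np.ndarray:
    """Exact discretisation of a stationary OU process."""
    if sd == 0.0 or n == 0:
        return np.zeros(n)
    from scipy.signal import lfilter

    a = np.exp(-dt / tau)
    innov_sd = sd * np.sqrt(1.0 - a * a)
    e = innov_sd * rng.standard_normal(n)
    e[0] = sd * rng.standard_normal()  # stationary start
    return lfilter([1.0], [1.0, -a], e)


def simulate_hr_profile(
    profile: StrainProfile,
    phase: str,
    activity: ActivitySeries | None,
    duration_s: float,
    *,
    rng: np.random.Generator,
    dt: float = 1.0,
    t0_clock: float = 0.0,
    params: HRParams | None = None,
) -> HRTrace:
    """Simulate the latent HR of one animal over ``duration_s`` seconds.

    ``phase`` is ``"baseline"`` or ``"metoprolol"``; isoproterenol surges
    are applied afterwards with :func:`apply_isoproterenol` so vehicle and
    agonist sessions share the same underlying trace machinery.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if phase not in PHASES:
        raise ValueError(f"unknown phase {phase!r}; expected one of {PHASES}")
    params = params or HRParams()
    n = int(round(duration_s / dt))
    t = t0_clock + dt * np.arange(n)

    s = fraction_night(t, ramp_s=params.ramp_s)
    rest = rest_fraction(t, rest_window=params.rest_window, ramp_s=params.ramp_s)
    base = profile.hr_day_mean + (profile.hr_night_mean - profile.hr_day_mean) * s
    trough_target = profile.hr_min - params.trough_margin
    circadian = base - (base - trough_target) * rest

    if activity is not None:
        a = activity.value_at(t)
        act = params.activity_gain_max * a / (a + params.activity_a50)
    else:
        act = np.zeros(n)

    if phase == "metoprolol":
        # the deltas are defined as reductions of the day- and night-window
        # means, so the drug term follows the hard light switch rather than
        # the circadian ramp
        day = is_day(t)
        drug = -np.where(day, profile.metoprolol_delta_day,
                         profile.metoprolol_delta_night)
    else:
        drug = np.zeros(n)

    noise = _ou(n, dt, params.noise_sd, params.noise_tau, rng)

    components = {
        "circadian": circadian,
        "activity": act,
        "drug": drug,
        "noise": noise,
    }
    floor = profile.hr_min + np.minimum(drug, 0.0)
    hr = _clip(sum(components.values()), floor)
    return HRTrace(
        times=t, dt=dt, hr=hr, components=components, floor=floor,
        profile_name=profile.name, phase=phase,
    )


def iso_peak_time(profile: StrainProfile) -> float:
    """Analytic time-to-peak of the isoproterenol surge, seconds after injection."""
    tr = profile.iso_rise_tau * 60.0
    td = profile.iso_decay_tau * 60.0
    return tr * td / (td - tr) * np.log(td / tr)


def iso_surge(
    t_after_inj: np.ndarray | float, profile: StrainProfile
) -> np.ndarray:
    """Double-exponential HR surge, bpm, peaking at ``iso_peak_delta``.

    Zero before the injection; by construction the residual at +300 min is
    below 1 bpm for any profile with ``iso_decay_tau`` <= ~52 min.
    """
    u = np.asarray(t_after_inj, dtype=float)
    tr = profile.iso_rise_tau * 60.0
    td = profile.iso_decay_tau * 60.0
    shape = np.where(u >= 0, np.exp(-np.maximum(u, 0.0) / td) - np.exp(-np.maximum(u, 0.0) / tr), 0.0)
    tpk = iso_peak_time(profile)
    peak = np.exp(-tpk / td) - np.exp(-tpk / tr)
    return profile.iso_peak_delta * shape / peak


def apply_isoproterenol(trace: HRTrace, t_inj: float, profile: StrainProfile) -> HRTrace:
    """Return a new trace with an isoproterenol surge injected at ``t_inj``.

    The surge joins the ``drug`` component; the clip floor is unchanged
    (the agonist raises HR) and the hard 850-bpm ceiling still applies.
    """
    if not (trace.times[0] <= t_inj <= trace.times[-1]):
        raise ValueError("injection time outside the trace")
    surge = iso_surge(trace.times - t_inj, profile)
    components = {k: v.copy() for k, v in trace.components.items()}
    components["drug"] = components["drug"] + surge
    hr = _clip(sum(components.values()), trace.floor)
    return HRTrace(
        times=trace.times, dt=trace.dt, hr=hr, components=components,
        floor=trace.floor, profile_name=trace.profile_name, phase=trace.phase,
    )
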