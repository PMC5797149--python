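"""Cage-activity generator.

The telemetry transponder logs one activity value (A.U.) per 5-min epoch.
Epoch values follow a zero-inflated gamma law whose mean tracks the
strain's day/night activity levels; the mid-day quiescence window forces
additional zeros so rest and activity are consistent with the HR model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from telecg.profiles import StrainProfile
from telecg.sim.clock import fraction_night, rest_fraction

EPOCH_LEN_S = 300.0
ACTIVITY_CAP = 300.0


@dataclass(frozen=True)
class ActivityParams:
    p_zero_day: float = 0.55
    p_zero_night: float = 0.15
    gamma_shape: float = 1.2
    cap: float = ACTIVITY_CAP


@dataclass
class ActivitySeries:
    """Contiguous, non-overlapping 5-min activity epochs."""

    t0_clock: float  # s since midnight of day 0, start of first epoch
    values: np.ndarray  # A.U., one per epoch
    epoch_len: float = EPOCH_LEN_S

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0) or np.any(self.values > ACTIVITY_CAP):
            raise ValueError(f"activity values must lie in [0, {ACTIVITY_CAP}] A.U.")

    @property
    def epoch_starts(self) -> np.ndarray:
        return self.t0_clock + self.epoch_len * np.arange(len(self.values))

    def value_at(self, t: np.ndarray | float) -> np.ndarray:
        """Activity value of the epoch containing each time (clipped to range)."""
        idx = np.floor((np.asarray(t, dtype=float) - self.t0_clock) / self.epoch_len)
        idx = np.clip(idx.astype(int), 0, len(self.values) - 1)
        return self.values[idx]


def generate_activity(
    profile: StrainProfile,
    duration_s: float,
    *,
    rng: np.random.Generator,
    t0_clock: float = 0.0,
    params: ActivityParams | None = None,
) -> ActivitySeries:
    """Generate a duty-cycle-aligned activity series of ``duration_s``.

    The epoch mean (zeros included) equals the strain's day/night activity
    level, smoothly blended across the light transitions.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    params = params or ActivityParams()
    n = int(np.ceil(duration_s / EPOCH_LEN_S))
    mid = t0_clock + EPOCH_LEN_S * (np.arange(n) + 0.5)
    s = fraction_night(mid)
    rest = rest_fraction(mid)

    mean = profile.activity_day_mean + (profile.activity_night_mean - profile.activity_day_mean) * s
    p0 = params.p_zero_day + (params.p_zero_night - params.p_zero_day) * s
    p_eff = 1.0 - (1.0 - p0) * (1.0 - rest)

    active = rng.random(n) >= p_eff
    values = np.zeros(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_active = np.where(p_eff < 1.0, mean / np.maximum(1.0 - p_eff, 1e-12), 0.0)
    scale = mean_active / params.gamma_shape
    draws = rng.gamma(params.gamma_shape, 1.0, size=n) * scale
    values[active] = draws[active]
    np.clip(values, 0.0, params.cap, out=values)
    return ActivitySeries(t0_clock=t0_clock, values=values)
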