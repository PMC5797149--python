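"""Clock-time helpers for the circadian machinery.

All session times are seconds; clock time is seconds since midnight of
study day 0 and wraps every 24 h.  Lights are on (day) 07:00-19:00.
"""

from __future__ import annotations

import numpy as np

#: Default lights-on window, clock hours.
DAY_WINDOW_H = (7.0, 19.0)

_DAY_S = 86400.0


def _ramp(x: np.ndarray) -> np.ndarray:
    """Raised-cosine 0 -> 1 over x in [0, 1], clipped outside."""
    x = np.clip(x, 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * x))


def fraction_night(
    t: np.ndarray | float,
    day_window: tuple[float, float] = DAY_WINDOW_H,
    ramp_s: float = 3600.0,
) -> np.ndarray:
    """Smooth night indicator: 1 deep in the night, 0 deep in the day.

    Transitions follow the lights with a raised-cosine ramp of ``ramp_s``
    seconds starting at each switch (07:00 night->day, 19:00 day->night).
    """
    t = np.asarray(t, dtype=float)
    tc = np.mod(t, _DAY_S)
    d0 = day_window[0] * 3600.0
    d1 = day_window[1] * 3600.0
    s = np.ones_like(tc)
    # descending ramp after lights-on
    s = np.where((tc >= d0) & (tc < d0 + ramp_s), 1.0 - _ramp((tc - d0) / ramp_s), s)
    s = np.where((tc >= d0 + ramp_s) & (tc < d1), 0.0, s)
    # ascending ramp after lights-off
    s = np.where((tc >= d1) & (tc < d1 + ramp_s), _ramp((tc - d1) / ramp_s), s)
    return s


def rest_fraction(
    t: np.ndarray | float,
    rest_window: tuple[float, float] = (12.0, 15.0),
    ramp_s: float = 3600.0,
) -> np.ndarray:
    """Mid-day quiescence bump in [0, 1].

    Mice consolidate rest during the light phase; the bump rises over the
    first ``ramp_s`` of the window, sits at 1 in the core and falls over
    the last ``ramp_s``.  During the core the circadian component relaxes
    to the strain's physiological HR floor.
    """
    t = np.asarray(t, dtype=float)
    tc = np.mod(t, _DAY_S)
    r0 = rest_window[0] * 3600.0
    r1 = rest_window[1] * 3600.0
    r = np.zeros_like(tc)
    r = np.where((tc >= r0) & (tc < r0 + ramp_s), _ramp((tc - r0) / ramp_s), r)
    r = np.where((tc >= r0 + ramp_s) & (tc < r1 - ramp_s), 1.0, r)
    r = np.where((tc >= r1 - ramp_s) & (tc < r1), 1.0 - _ramp((tc - (r1 - ramp_s)) / ramp_s), r)
    return r


def is_day(t: np.ndarray | float, day_window: tuple[float, float] = DAY_WINDOW_H) -> np.ndarray:
    """Hard day indicator by clock time (no ramps)."""
    tc = np.mod(np.asarray(t, dtype=float), _DAY_S) / 3600.0
    return (tc >= day_window[0]) & (tc < day_window[1])
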