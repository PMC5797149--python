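"""Per-minute HR epochs, the observable unit of duty-cycled telemetry."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class HREpoch:
    """Mean HR over one recorded minute of the 5-min duty cycle."""

    start: float  # clock s of the recorded minute
    hr: float  # bpm (undefined if not valid)
    valid: bool
    n_beats: int = 0


def epoch_frame(epochs: list[HREpoch]):
    """Convenience: epochs as (start, hr, valid, n_beats) numpy arrays."""
    start = np.array([e.start for e in epochs])
    hr = np.array([e.hr for e in epochs])
    valid = np.array([e.valid for e in epochs], dtype=bool)
    n = np.array([e.n_beats for e in epochs], dtype=int)
    return start, hr, valid, n
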