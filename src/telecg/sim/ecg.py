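"""ECG waveform synthesis and the telemetry duty cycle.

Each beat is rendered by stamping a parametric P-QRS-T template (sums of
Gaussians at murine scale: QRS ~ 10 ms, R ~ 1 mV) at its ground-truth
time.  Premature ventricular beats use a widened (x2.5) higher-amplitude
(x1.4) QRS with an inverted T wave and no P wave.  VF intervals are
rendered as a sum of three drifting 8-16 Hz sinusoids with no repeating
template.  Additive disturbances: slow baseline wander, white noise and
optional high-amplitude artifact bursts (movement artefact surrogate).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from telecg.sim.beats import BeatTruth, simulate_beats
from telecg.sim.events import EventSchedule
from telecg.sim.hr import HRTrace

R_AMP_MV = 1.0  # sinus R amplitude; SNR definitions reference this

# (amplitude mV, centre s, width s) of the sinus QRS-T complex
_QRS_T = (
    (-0.15, -0.007, 0.0015),  # Q
    (1.00, 0.000, 0.0025),    # R
    (-0.25, 0.006, 0.0020),   # S
    (0.18, 0.028, 0.0090),    # T
)
_P_WAVE = (0.10, -0.028, 0.0040)

PVB_WIDEN = 2.5
PVB_AMP = 1.4


@dataclass(frozen=True)
class NoiseParams:
    white_sd_mv: float = 0.03
    wander_mv: float = 0.05
    artifact_amp_mv: float = 1.2
    #: explicit artifact bursts as (start s, duration s), clock-referenced
    artifact_bursts: tuple[tuple[float, float], ...] = ()

    @property
    def snr_db(self) -> float:
        """Peak-R-to-white-noise ratio in dB (inf for a clean record)."""
        if self.white_sd_mv == 0:
            return np.inf
        return 20.0 * np.log10(R_AMP_MV / self.white_sd_mv)

    @staticmethod
    def clean() -> "NoiseParams":
        return NoiseParams(white_sd_mv=0.0, wander_mv=0.0)

    @staticmethod
    def from_snr_db(snr_db: float, wander_mv: float = 0.05) -> "NoiseParams":
        return NoiseParams(white_sd_mv=R_AMP_MV / 10 ** (snr_db / 20.0),
                           wander_mv=wander_mv)


@dataclass
class ECGRecord:
    """A sampled single-lead voltage trace with session metadata.

    ``t0`` is the clock time (s since midnight of study day 0) of the
    first sample.  ``segments`` lists the recorded intervals in clock
    time; the signal holds their concatenation, so a duty-cycled record
    stores only what the telemetry system kept.
    """

    animal_id: str
    strain: str
    phase: str
    session: str
    t0: float
    fs: float
    signal: np.ndarray
    segments: list[tuple[float, float]] = field(default_factory=list)
    artifact_truth: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("ECG signal must be finite")
        if not self.segments:
            self.segments = [(self.t0, self.t0 + len(self.signal) / self.fs)]

    @property
    def duration(self) -> float:
        return sum(b - a for a, b in self.segments)

    @property
    def is_continuous(self) -> bool:
        return len(self.segments) == 1

    def segment_slices(self) -> list[tuple[tuple[float, float], slice]]:
        """Pair each recorded interval with its slice into ``signal``."""
        out, i0 = [], 0
        for a, b in self.segments:
            n = int(round((b - a) * self.fs))
            out.append(((a, b), slice(i0, i0 + n)))
            i0 += n
        return out

    def time_axis(self) -> np.ndarray:
        """Clock time of every stored sample (concatenated segments)."""
        parts = [a + np.arange(sl.stop - sl.start) / self.fs
                 for (a, _), sl in self.segment_slices()]
        return np.concatenate(parts) if parts else np.empty(0)

    def sample_index(self, t: float) -> int:
        """Index into ``signal`` of clock time ``t`` (must be recorded)."""
        off = 0
        for (a, b), sl in self.segment_slices():
            if a <= t < b:
                return sl.start + int(round((t - a) * self.fs))
            off = sl.stop
        raise ValueError(f"time {t:.3f}s is not within a recorded segment")


def _stamp(signal: np.ndarray, fs: float, t_rel: float, parts, widen: float, amp: float) -> None:
    half = 0.08 * widen
    i0 = int(np.floor((t_rel - half) * fs))
    i1 = int(np.ceil((t_rel + half) * fs)) + 1
    i0c, i1c = max(i0, 0), min(i1, len(signal))
    if i0c >= i1c:
        return
    tt = np.arange(i0c, i1c) / fs - t_rel
    w = np.zeros_like(tt)
    for a, mu, sd in parts:
        w += a * amp * np.exp(-0.5 * ((tt - mu * widen) / (sd * widen)) ** 2)
    signal[i0c:i1c] += w


def _render_vf(signal: np.ndarray, fs: float, i0: int, i1: int, rng: np.random.Generator) -> None:
    n = i1 - i0
    if n <= 0:
        return
    t = np.arange(n) / fs
    x = np.zeros(n)
    for _ in range(3):
        f = 12.0 + 4.0 * np.sin(2 * np.pi * rng.uniform(0.05, 0.3) * t + rng.uniform(0, 2 * np.pi))
        f += np.cumsum(rng.standard_normal(n)) * 0.002  # slow frequency walk
        np.clip(f, 8.0, 16.0, out=f)
        phase = 2 * np.pi * np.cumsum(f) / fs + rng.uniform(0, 2 * np.pi)
        x += 0.45 * np.sin(phase)
    taper = np.minimum(1.0, np.minimum(t, t[::-1]) / 0.05) if n > 2 else np.ones(n)
    signal[i0:i1] += x * taper


def synthesize_ecg(
    hr: HRTrace,
    schedule: EventSchedule | None,
    fs: float = 1000.0,
    noise: NoiseParams | None = None,
    *,
    rng: np.random.Generator,
    truth: BeatTruth | None = None,
    animal_id: str = "A0",
    session: str = "session",
) -> tuple[ECGRecord, BeatTruth]:
    """Render a continuous ECG record (and its truth) from a latent HR trace.

    A pre-computed ``truth`` may be passed to reuse an existing beat
    stream; otherwise beats are generated here.
    """
    if fs < 500:
        raise ValueError("sampling rate must be >= 500 Hz for murine QRS")
    noise = noise or NoiseParams()
    if truth is None:
        truth = simulate_beats(hr, schedule, rng=rng)

    t0 = float(hr.times[0])
    n = int(round((hr.times[-1] + hr.dt - t0) * fs))
    signal = np.zeros(n)

    for bt, lab, has_p in zip(truth.times, truth.labels, truth.p_wave):
        t_rel = bt - t0
        if lab == "PVB":
            parts = [(-0.15, -0.007, 0.0015), (1.0, 0.0, 0.0025), (-0.25, 0.006, 0.002),
                     (-0.18 / PVB_AMP, 0.016, 0.009)]
            _stamp(signal, fs, t_rel, parts, widen=PVB_WIDEN, amp=PVB_AMP)
        else:
            _stamp(signal, fs, t_rel, _QRS_T, widen=1.0, amp=1.0)
            if has_p:
                _stamp(signal, fs, t_rel, (_P_WAVE,), widen=1.0, amp=1.0)

    for a, b in truth.vf_intervals:
        _render_vf(signal, fs, int((a - t0) * fs), int((b - t0) * fs), rng)

    if noise.wander_mv > 0:
        t = np.arange(n) / fs
        signal += noise.wander_mv * (
            np.sin(2 * np.pi * 0.25 * t + rng.uniform(0, 2 * np.pi))
            + 0.6 * np.sin(2 * np.pi * 0.09 * t + rng.uniform(0, 2 * np.pi))
        )
    if noise.white_sd_mv > 0:
        signal += noise.white_sd_mv * rng.standard_normal(n)

    artifact_truth = []
    for a, dur in noise.artifact_bursts:
        i0 = max(int((a - t0) * fs), 0)
        i1 = min(int((a + dur - t0) * fs), n)
        if i1 > i0:
            signal[i0:i1] += noise.artifact_amp_mv * rng.standard_normal(i1 - i0)
            artifact_truth.append((a, a + dur))

    rec = ECGRecord(
        animal_id=animal_id, strain=hr.profile_name, phase=hr.phase,
        session=session, t0=t0, fs=fs, signal=signal,
        segments=[(t0, t0 + n / fs)], artifact_truth=artifact_truth,
    )
    return rec, truth


def apply_sampling_scheme(record: ECGRecord, mode: str) -> ECGRecord:
    """Apply the telemetry storage scheme to a continuous record.

    ``"longterm"`` keeps the first minute of every 5-min block (the
    long-term duty cycle); ``"continuous"`` is the identity.
    """
    if mode == "continuous":
        return copy.deepcopy(record)
    if mode != "longterm":
        raise ValueError(f"unknown sampling mode {mode!r}")
    if not record.is_continuous:
        raise ValueError("duty cycling expects a continuous input record")
    rec_len, block = 60.0, 300.0
    a, b = record.segments[0]
    segments, chunks = [], []
    start = a
    while start < b:
        end = min(start + rec_len, b)
        i0 = int(round((start - a) * record.fs))
        i1 = int(round((end - a) * record.fs))
        segments.append((start, end))
        chunks.append(record.signal[i0:i1])
        start += block
    out = copy.copy(record)
    out.signal = np.concatenate(chunks) if chunks else np.empty(0)
    out.segments = segments
    out.artifact_truth = list(record.artifact_truth)
    return out
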