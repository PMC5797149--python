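import numpy as np
import pytest

from telecg import BUILTIN_STRAINS
from telecg.sim import (
    NoiseParams,
    schedule_arrhythmias,
    simulate_hr_profile,
    synthesize_ecg,
)


@pytest.fixture(scope="session")
def balbc():
    return BUILTIN_STRAINS["Balb/c"]


def make_waveform_fixture(
    profile,
    *,
    seed: int = 11,
    duration_s: float = 120.0,
    t0_clock: float = 22 * 3600.0,
    noise: NoiseParams | None = None,
    pvb_rate: float = 3000.0,
    coupled_rate: float = 500.0,
    vt_rate: float = 200.0,
    vf_rate: float = 0.0,
):
    """A short continuous waveform session with scheduled ectopy.

    Rates are per 5 h, scaled high so a 2-min record carries events.
    """
    rng = np.random.default_rng(seed)
    trace = simulate_hr_profile(profile, "baseline", None, duration_s, rng=rng,
                                dt=0.5, t0_clock=t0_clock)
    profile = profile.with_rates(pvb=pvb_rate, coupled=coupled_rate,
                                 vt=vt_rate, vf=vf_rate)
    schedule = schedule_arrhythmias(
        profile, (t0_clock + 5.0, t0_clock + duration_s - 5.0), rng=rng)
    rec, truth = synthesize_ecg(trace, schedule, fs=1000.0,
                                noise=noise or NoiseParams.clean(), rng=rng)
    return rec, truth, schedule


@pytest.fixture(scope="session")
def clean_record(balbc):
    return make_waveform_fixture(balbc)


@pytest.fixture(scope="session")
def noisy_record_10db(balbc):
    return make_waveform_fixture(balbc, noise=NoiseParams.from_snr_db(10.0))


@pytest.fixture(scope="session")
def vf_record(balbc):
    return make_waveform_fixture(balbc, seed=21, pvb_rate=0.0, coupled_rate=0.0,
                                 vt_rate=0.0, vf_rate=400.0)
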