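import numpy as np
import pytest

import ibp
from ibp.synthetic import SignalSpec, band_noise_sd

FS = 1000.0


@pytest.fixture(scope="session")
def fs() -> float:
    return FS


@pytest.fixture(scope="session")
def band_sd() -> float:
    """SD of the 80-300 Hz band-passed default background (SNR calibration)."""
    return band_noise_sd(SignalSpec(duration_s=30.0, seed=0))


@pytest.fixture()
def short_background() -> np.ndarray:
    """10 s of seeded pink-noise background."""
    return ibp.make_background(SignalSpec(duration_s=10.0, seed=42))


def plant_bursts(x: np.ndarray, amplitudes, t0s, f0s, n_cycles=8, fs=FS):
    """Inject several oscillation bursts; returns (signal, list of (t0, t1))."""
    spans = []
    for amp, t0, f0 in zip(amplitudes, t0s, f0s):
        ev = ibp.PlantedEvent("oscillation", t0=t0, f0=f0, n_cycles=n_cycles, amplitude=amp)
        x = ibp.inject_oscillation(x, ev, fs)
        spans.append((t0, t0 + ev.duration_s))
    return x, spans
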