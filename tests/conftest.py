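import numpy as np
import pytest

from qspike import RecordingMeta
from qspike.mea_io import ChannelTrace
from qspike.synth import BurstSpec, synthesize_mea_recording


@pytest.fixture(scope="session")
def small_bursting():
    """12-channel, 30 s bursting recording with ground truth (shared, read-only)."""
    meta = RecordingMeta(n_channels=12, sampling_rate_hz=20000.0, duration_s=30.0)
    rec, truth = synthesize_mea_recording(
        meta, rates_hz=0.4, burst_spec=BurstSpec(count=3, duration_s=0.5, rate_hz=25.0),
        snr=8.0, seed=11,
    )
    return meta, rec, truth


@pytest.fixture()
def noise_trace():
    """Unit-variance Gaussian noise clipped at 3 sigma: never crosses k=5."""
    rng = np.random.default_rng(42)
    x = np.clip(rng.normal(0.0, 1.0, 200_000), -3.0, 3.0)
    return ChannelTrace(0, "n0", x, 25000.0)
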