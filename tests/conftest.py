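import numpy as np
import pytest

from ncrkit import (FrequencyAxis, generate_rds, precise_encoder,
                    render_spectrogram, simulate_lnp)

#: fine Bernoulli step for the high-gain burst encoders (keeps rate*dt small)
FINE_SAMPLE_DT = 1.25e-4


@pytest.fixture(scope="session")
def axis():
    return FrequencyAxis.default()


@pytest.fixture(scope="session")
def sweeps60():
    """A 60 s random double sweep shared across decoder-level tests."""
    return generate_rds(duration=60.0, seed=11)


@pytest.fixture(scope="session")
def stim60(sweeps60, axis):
    """Analysis-resolution spectrogram (5 ms bins) of the 60 s sweep."""
    return render_spectrogram(sweeps60, axis)


@pytest.fixture(scope="session")
def stim60_fine(sweeps60, axis):
    """1 ms rendering of the same sweep, used to drive model neurons."""
    return render_spectrogram(sweeps60, axis, dt=1e-3)


@pytest.fixture(scope="session")
def burst_unit(stim60_fine):
    """A precisely tuned, strongly driven model unit on the 60 s sweep."""
    return simulate_lnp(precise_encoder(bf=16_000.0, seed=42), stim60_fine,
                        sample_dt=FINE_SAMPLE_DT, unit_id="burst42")


def on_grid_bf(axis, target_hz):
    """Nearest channel-center frequency, so ground-truth tuning sits on the
    analysis grid."""
    return float(axis.centers[np.argmin(np.abs(axis.centers - target_hz))])
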