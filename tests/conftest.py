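import numpy as np
import pytest

from beetaste.synth import DesignSpec, EphysSimConfig, ForagerParams, generate_grn_trace


@pytest.fixture(scope="session")
def snr3_sim():
    """One simulated trace at SNR 3 (spike amplitude = 3 x raw noise SD)."""
    cfg = EphysSimConfig(
        peak_rate=80, tonic_rate=25, spike_amplitude=1.0, noise_sd=1 / 3, seed=11
    )
    return generate_grn_trace(cfg)


@pytest.fixture()
def conditioning_spec():
    return DesignSpec(design="conditioning", group="control")


@pytest.fixture()
def preference_spec():
    return DesignSpec(design="preference", group="sucrose")
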