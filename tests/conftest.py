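import numpy as np
import pytest

import sparsescan as sp


@pytest.fixture(scope="session")
def stable_beam():
    """Constant beam: no decay within any realistic scan, no drift."""
    return sp.simulate_beam(duration=1e6, decay_time=1e12, topup_period=1e12, seed=0)


@pytest.fixture(scope="session")
def decaying_beam():
    """Strong pure-intensity decay (no top-up within a scan, no drift)."""
    return sp.simulate_beam(duration=1e6, decay_time=3600.0, topup_period=1e9, seed=0)


@pytest.fixture(scope="session")
def leaf32():
    return sp.make_phantom("leaf", 32, 32, 1.0, seed=3)


@pytest.fixture(scope="session")
def leaf64():
    return sp.make_phantom("leaf", 64, 64, 1.0, seed=3)


@pytest.fixture
def small_config():
    return sp.ScanConfig(rows=32, cols=32, t_stxm=0.005, t_xrf=1.0, elements=("C", "O"))


def absorption_reference(beam, config):
    """Flat-field open-beam signal at reference ring current."""
    return beam.nominal_flux * config.t_stxm


def offline_threshold_mask(sample, beam, config, threshold):
    """Independent oracle: threshold the noiseless absorption image."""
    signal = beam.nominal_flux * sample.transmission[: config.rows, : config.cols] * config.t_stxm
    absorption = absorption_reference(beam, config) - signal
    return absorption > threshold
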