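import numpy as np
import pytest

from retinachrome import synthetic_data as sd
from retinachrome.trace_processing import highpass_detrend


@pytest.fixture(scope="session")
def flicker10():
    """180 s balanced center-surround flicker at 10 Hz (inner-retina protocol)."""
    return sd.make_flicker_protocol(4, 10.0, 180.0, seed=5)


@pytest.fixture(scope="session")
def flash_protocol():
    """Interleaved UV/green center/surround/full-field flashes, 6 repeats."""
    return sd.make_flash_protocol(n_repeats=6)


@pytest.fixture(scope="session")
def simulate_trace():
    """Simulate a cell's detrended 500 Hz response at a given SNR."""

    def _sim(cell, protocol, snr=None, seed=0, nonlinearity="softplus"):
        noise = 0.0 if snr is None else sd.noise_sd_for_snr(cell, protocol, snr,
                                                            nonlinearity=nonlinearity)
        tr = sd.simulate_cell_response(cell, protocol, noise_sd=noise, seed=seed,
                                       nonlinearity=nonlinearity)
        return highpass_detrend(tr, 500.0)[0]

    return _sim


@pytest.fixture
def ventral_cone():
    return sd.GroundTruthCell(position_mm=-1.5, layer="OPL",
                              w_center_uv=-0.85, w_center_green=-0.15,
                              w_surround_uv=-0.06, w_surround_green=0.54,
                              polarity="Off", kinetics_tau_s=0.15)
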