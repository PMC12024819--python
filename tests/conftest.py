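import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ppgvo2.calibration import make_default_calibration, reference_intensity
from ppgvo2.features import PPGRecord, channel_name
from ppgvo2.spectra import compute_alpha, default_spectrum

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def spectrum():
    return default_spectrum()


@pytest.fixture(scope="session")
def scaled(spectrum):
    return compute_alpha(spectrum)


@pytest.fixture(scope="session")
def calib():
    return make_default_calibration(seed=7)


@pytest.fixture
def forward_record(spectrum, calib):
    """Factory: a quasi-DC record built directly from the Beer-Lambert model.

    Produces one 10-s window per requested saturation value, with constant
    hemoglobin concentration and pathlength, no noise — the exact signal the
    feature pipeline should invert.
    """

    def _make(saturations, c_tot=2.3e-3, path_cm=0.3, scale=1.0):
        s = np.asarray(saturations, dtype=float)
        cols = {}
        for wl in spectrum.wavelengths_nm:
            i = spectrum.index(wl)
            eps_mix = s * spectrum.eps_hbo2[i] + (1 - s) * spectrum.eps_hb[i]
            for group in ("pd1", "pd2"):
                i0 = reference_intensity(calib, wl, group)
                cols[channel_name(wl, group)] = scale * i0 * np.exp(-eps_mix * c_tot * path_cm)
        t = 5.0 + 10.0 * np.arange(s.size)
        return PPGRecord(t=t, signal=pd.DataFrame(cols), sampling_rate_hz=0.1,
                         subject_id="fwd", drive_ma=50.0)

    return _make
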