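import numpy as np
import pytest

from cannaqnmr import (ProcessingParams, Spectrum1D, build_signal_library,
                       compute_eretic_factor, default_acquisition, default_qr,
                       process, simulate_qr)

# reduced acquisition for fast unit tests: same spectral width, ~1 s AQ,
# 0.5 Hz digital resolution after zero filling.  At this acquisition time a
# 1.2 Hz line has not fully decayed and zero filling would leave truncation
# ripple, so quantitative small-size tests use 3 Hz lines (fully decayed).
SMALL_TD = 16384
TEST_FWHM_HZ = 3.0


@pytest.fixture(scope="session")
def small_acq():
    return default_acquisition(td=SMALL_TD, si=2 * SMALL_TD)


@pytest.fixture(scope="session")
def hemp_library():
    return build_signal_library("hemp")


@pytest.fixture(scope="session")
def proc_params(hemp_library):
    qr = default_qr()
    exclude = [s.window("hemp") for s in hemp_library]
    exclude += [c.signal_range_ppm for c in qr.components.values()]
    return ProcessingParams(baseline_exclude=exclude)


@pytest.fixture(scope="session")
def qr_standard():
    return default_qr()


@pytest.fixture(scope="session")
def eretic_small(small_acq, proc_params, qr_standard):
    """ERETIC factor from a noiseless simulated QR at the reduced size."""
    spec = process(simulate_qr(qr_standard, small_acq, seed=1,
                               fwhm_hz=TEST_FWHM_HZ), proc_params)
    return compute_eretic_factor(spec, qr_standard, small_acq)


def make_lorentzian_spectrum(centers, areas, fwhm_ppm, lo=-2.0, hi=12.0,
                             n=32768, sf=400.0, baseline=None):
    """Analytic absorption spectrum on a descending ppm axis (test helper)."""
    ppm = np.linspace(hi, lo, n)
    y = np.zeros_like(ppm)
    for c, a in zip(np.atleast_1d(centers), np.atleast_1d(areas)):
        hw = fwhm_ppm / 2.0
        y += a * (hw / np.pi) / ((ppm - c) ** 2 + hw ** 2)
    if baseline is not None:
        y = y + baseline(ppm)
    return Spectrum1D(real=y, imag=np.zeros_like(y), ppm=ppm, sf_mhz=sf,
                      acq=default_acquisition())
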