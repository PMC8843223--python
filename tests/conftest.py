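import numpy as np
import pytest

from ligamentnirs.io import Spectrum
from ligamentnirs.synthetic import (
    BandLibrary,
    NoiseSpec,
    generate_sample_spectra,
)

#: small per-detector grids used where full 2048/256-point spectra are overkill
SMALL_POINTS = {"d1": 256, "d2": 128}


@pytest.fixture
def water_band():
    return BandLibrary(bands={"water_content": [(1450.0, 40.0, 0.004)]})


@pytest.fixture
def small_record(water_band):
    """One noise-free sample with a single water band, small grids."""
    return generate_sample_spectra(
        {"water_content": 74.7},
        water_band,
        NoiseSpec.zero(),
        seed=0,
        n_points=SMALL_POINTS,
    )


def make_spectrum(values, lo=400.0, hi=900.0, detector="d1", kind="counts", mask=None):
    values = np.asarray(values, dtype=float)
    wl = np.linspace(lo, hi, values.size)
    return Spectrum(detector=detector, wavelengths=wl, values=values, kind=kind, mask=mask)
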