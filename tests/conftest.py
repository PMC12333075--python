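import numpy as np
import pandas as pd
import pytest

from peatspec.preprocess import harmonize
from peatspec.spectral_io import SpectralLibrary, Spectrum
from peatspec.synthetic_data import SimulationConfig, gen_study

FIXTURE_SEED = 7


@pytest.fixture(scope="session")
def small_study():
    """12-plot synthetic study (6 per trophic level) shared across tests."""
    return gen_study(SimulationConfig(seed=FIXTURE_SEED, n_plots=6))


@pytest.fixture(scope="session")
def default_study():
    """The generator's default study: 60 plots per trophic level."""
    return gen_study(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_harmonized(default_study):
    return (
        harmonize(default_study.plots),
        harmonize(default_study.endmembers),
    )


@pytest.fixture
def tiny_library():
    """Three-wavelength, two-sample library for I/O contract tests."""
    data = pd.DataFrame(
        {"s1": [0.1, 0.2, 0.3], "s2": [0.4, 0.5, 0.6]},
        index=pd.Index([400, 401, 402], name="wavelength_nm"),
    )
    meta = pd.DataFrame(
        {
            "sample_id": ["s1", "s2"],
            "role": ["plot", "plot"],
            "trophic_level": ["minerotrophic", "minerotrophic"],
            "quantity": ["HCRF", "HCRF"],
        }
    ).set_index("sample_id")
    return SpectralLibrary(data, meta)


def constant_spectrum(value=0.3, lo=350, hi=2500, sample_id="const"):
    w = np.arange(lo, hi + 1)
    return Spectrum(w, np.full(w.size, value), sample_id=sample_id)
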