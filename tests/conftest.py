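import numpy as np
import pandas as pd
import pytest

from smxdose.beam_model import (apply_circular_aperture, build_profile,
                                rescale_to_flux)
from smxdose.crystal_composition import load_reference_crystal
from smxdose.dose_engine import CrystalBlock


@pytest.fixture(scope="session")
def reference_contents():
    """Packaged synthetic nickel-dipeptide-heptahydrate reference cell."""
    return load_reference_crystal()


@pytest.fixture(scope="session")
def beamline_profile():
    """Gaussian 150x100 um FWHM beam trimmed by a 100 um aperture, with the
    calibrated 1%-transmission flux (8e9 ph/s) measured after the aperture."""
    beam = build_profile("gaussian", 8e9, 150.0, 100.0, aperture_um=100.0)
    return rescale_to_flux(beam, 8e9)


@pytest.fixture()
def small_crystal(reference_contents):
    return CrystalBlock((20.0, 6.0, 6.0), 1.0, reference_contents)


@pytest.fixture(scope="session")
def toy_reflections():
    """Two observations of one unique reflection plus singles, for hand checks."""
    return pd.DataFrame({
        "h": [1, 1, 2, 3],
        "k": [0, 0, 1, 1],
        "l": [0, 0, 1, 2],
        "d": [2.0, 2.0, 1.5, 1.1],
        "I": [90.0, 110.0, 50.0, 20.0],
        "sigI": [1.0, 1.0, 1.0, 1.0],
    })
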