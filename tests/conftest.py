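import numpy as np
import pytest

from camomatch import synthgen
from camomatch.rscolor import CalibrationMeta, RasterScene


@pytest.fixture
def simple_meta():
    """One-gain-per-DN calibration with no atmosphere (TOA settings)."""
    return CalibrationMeta(
        lmin=[0.0, 0.0, 0.0],
        lmax=[255.0, 255.0, 255.0],
        qcalmin=[0.0, 0.0, 0.0],
        qcalmax=[255.0, 255.0, 255.0],
        esun=[255.0 * np.pi, 255.0 * np.pi, 255.0 * np.pi],
        solar_zenith_deg=0.0,
    )


@pytest.fixture
def uniform_scene(simple_meta):
    """7x7 scene with DN 100 everywhere and unit pixels; with this
    calibration a DN of q calibrates to channel value q on the 0-255
    scale (rho = q/255, channel = 255*rho)."""
    dn = np.full((3, 7, 7), 100, dtype=np.uint8)
    return RasterScene(
        dn=dn, mask=np.zeros((7, 7), bool), pixel_size=1.0, meta=simple_meta
    )


@pytest.fixture
def small_landscape():
    return synthgen.LandscapeParams(
        grid_size=96, pixel_size=120.0, correlation_length=1200.0,
        masked_fraction=0.02,
    )


@pytest.fixture
def toy_alignment():
    """4 x 10 alignment used by the brute-force pairwise oracles."""
    from camomatch.popgen import HaplotypeAlignment

    return HaplotypeAlignment.from_strings(
        [
            "ACGTACGTAC",
            "ACGTACGTAA",
            "ACGTTCGTAA",
            "GCGTTCGTAC",
        ]
    )
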