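import warnings

import numpy as np
import pytest

from circalight.observers import CANONICAL_WAVELENGTHS, load_observer_tables
from circalight.pipeline import make_paired_table
from circalight.scenes import lab_protocol
from circalight.sensor import DistortionSpec
from circalight.spectral import SPD, CircadianParams

warnings.filterwarnings("ignore", message="SPD does not fully cover")


@pytest.fixture(scope="session")
def tables():
    return load_observer_tables()


@pytest.fixture(scope="session")
def params():
    return CircadianParams()


@pytest.fixture(scope="session")
def lab_pairs(tables):
    """The laboratory protocol at its stated size: 100 scenarios x 5."""
    return lab_protocol(100, 5, seed=11, tables=tables)


@pytest.fixture(scope="session")
def noisy_paired(lab_pairs, tables):
    """Paired ground-truth/sensor table under the default noise levels."""
    spec = DistortionSpec(lux_cv=0.05, cct_cv=0.02, channel_cv=0.05, seed=3)
    return make_paired_table(lab_pairs, spec, tables, seed=3)


@pytest.fixture(scope="session")
def clean_paired(lab_pairs, tables):
    """Paired table with the default distortion but zero noise."""
    spec = DistortionSpec(seed=3)
    return make_paired_table(lab_pairs, spec, tables, seed=3)


def random_spd(rng, kind="broad"):
    """Random nonnegative SPD on the canonical 5 nm grid.

    ``kind`` biases spectral placement so both branches of the
    circadian-light opponent channel get exercised: "red" spectra keep
    energy above 650 nm (b-y <= 0), "blue" spectra are short-wavelength
    heavy (b-y > 0).
    """
    lam = CANONICAL_WAVELENGTHS
    base = rng.gamma(2.0, 0.005, size=lam.size)
    if kind == "red":
        base = base * (lam >= 650)
    elif kind == "blue":
        base = base * np.exp(-0.5 * ((lam - 460) / 60.0) ** 2)
    return SPD(lam, base)
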