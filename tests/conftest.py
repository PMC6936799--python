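import numpy as np
import pytest

from cpch.theory import CpchModel, OpticalConfig, SpeciesParams


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def equal_optics():
    """Identical channels: r = 0.25 um, s = 5 (a typical confocal volume)."""
    return OpticalConfig.from_structure_factor(r=0.25, s=5.0)


@pytest.fixture
def unequal_optics():
    return OpticalConfig(r_A=0.25, z_A=1.0, r_B=0.35, z_B=1.6)


@pytest.fixture
def single_species_model(equal_optics):
    """N = 6, eps = 0.7 counts/bin at T = 10 us, tau_d = 50 us."""
    T = 10e-6
    sp = SpeciesParams.from_counts_per_bin(N=6.0, eps_A_bin=0.7, T=T, tau_d=50e-6)
    return CpchModel(equal_optics, (sp,))
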