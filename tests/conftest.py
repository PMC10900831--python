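import numpy as np
import pytest

from lignosim.kinetics import ParameterSet
from lignosim.substrate import StructureConfig


@pytest.fixture
def bare_chain_config():
    """Single cellulose chain, DP 10, nothing else."""
    return StructureConfig(cellulose_rings=(1,), cellulose_dp=10)


@pytest.fixture
def small_fibril_config():
    return StructureConfig(cellulose_rings=(4,), cellulose_dp=20)


@pytest.fixture
def layered_config():
    return StructureConfig(cellulose_rings=(2, 4), cellulose_dp=20,
                           hemicellulose_chains=6, hemicellulose_dp=20,
                           lignin_monomers=30)


@pytest.fixture
def amorphous_params():
    """Fully amorphous, uninhibited, no lignin adsorption."""
    return ParameterSet(
        K_EG=200.0, K_CBHA=200.0, K_CBHD=50.0, K_BGL=200.0, K_XYL=200.0,
        n_EG0=2.0, n_CBH0=2.0, n_BGL0=2.0, n_XYL0=2.0,
        X_cellulose=0.0, X_hemicellulose=0.0,
        r_cellulose=1.0, r_hemicellulose=1.0, L_adh=0.0,
        omega_EG_glc=0.0, omega_CBH_glc=0.0, omega_BGL_glc=0.0,
        omega_EG_cbs=0.0, omega_CBH_cbs=0.0)


@pytest.fixture
def fine_grid():
    return np.arange(0.0, 72.0 + 1e-9, 0.25)
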