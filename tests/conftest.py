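import numpy as np
import pytest

import rdcalign as ra
from rdcalign.fixtures import consecutive_pairs


def random_saupe(seed: int, scale: float = 1e-3) -> ra.SaupeTensor:
    rng = np.random.default_rng(seed)
    m = rng.standard_normal((3, 3))
    m = 0.5 * (m + m.T)
    m -= np.eye(3) * (np.trace(m) / 3.0)
    return ra.SaupeTensor(scale * m)


@pytest.fixture
def bent_molecule() -> ra.Molecule:
    """Asymmetric 14-atom solute with 13 bonded pairs, enough for SVD fits."""
    return ra.make_solute("bent", 14, "neutral", seed=2)


@pytest.fixture
def bent_pairs(bent_molecule):
    return consecutive_pairs(bent_molecule)


@pytest.fixture(scope="session")
def small_rod_medium() -> ra.MediumModel:
    """Uncharged rod particle on a coarse grid, cheap enough for many sweeps."""
    return ra.make_medium(
        ra.SyntheticMediumSpec(
            kind="helical_rod", length=24, radius=4, sphere_spacing=4,
            grid_spacing=1.5, grid_padding=5,
        )
    )


@pytest.fixture(scope="session")
def charged_rod_medium() -> ra.MediumModel:
    return ra.make_medium(
        ra.SyntheticMediumSpec(
            kind="helical_rod", length=24, radius=4, sphere_spacing=4,
            grid_spacing=1.5, grid_padding=5, surface_charge_density=0.02,
        )
    )


@pytest.fixture(scope="session")
def small_config() -> ra.SimulationConfig:
    return ra.SimulationConfig(
        grid_spacing=(1.5, 1.5, 1.5), grid_counts=(15, 15, 21),
        z_range=(6, 14), n_sphere=40, n_spin=6,
    )
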