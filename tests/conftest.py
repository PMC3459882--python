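import numpy as np
import pytest

from icnet.synthetic import (PlantedNetwork, generate_energy_trajectory,
                             generate_toy_complex)


@pytest.fixture(scope="session")
def toy_complex():
    """Small protein/guide/target complex shared across tests."""
    return generate_toy_complex(n_protein=8, n_guide=2, n_target=2, seed=11)


@pytest.fixture(scope="session")
def two_group_network():
    """Ten residues, two independent factor groups of two pairs each."""
    return PlantedNetwork(
        n_residues=10,
        groups=({(1, 3): 2.0, (3, 5): 2.0}, {(6, 8): 2.0, (8, 10): 2.0}),
    )


@pytest.fixture(scope="session")
def two_group_trajectory(two_group_network):
    return generate_energy_trajectory(two_group_network, n_frames=3000,
                                      seed=5)


def pearson_oracle(x, y):
    """Textbook two-pass Pearson correlation, independent of the package."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mx, my = x.mean(), y.mean()
    num = ((x - mx) * (y - my)).sum()
    den = np.sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum())
    return num / den
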