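import numpy as np
import pytest

from mlcmd.geometry import MolecularConfiguration


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_water_cluster(rng, n_molecules=8, spread=2.2, min_sep=2.3, max_radius=4.0):
    """Compact random cluster of rigid-ish 3-site water molecules."""
    centers = [np.zeros(3)]
    while len(centers) < n_molecules:
        c = rng.normal(0, spread, 3)
        if all(np.linalg.norm(c - o) > min_sep for o in centers) and np.linalg.norm(c) < max_radius:
            centers.append(c)
    pos = []
    theta0 = 1.910611932
    for c in centers:
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        v = rng.normal(size=3)
        v -= u * (u @ v)
        v /= np.linalg.norm(v)
        pos += [c, c + 0.98 * u, c + 0.98 * (np.cos(theta0) * u + np.sin(theta0) * v)]
    return MolecularConfiguration(["O", "H", "H"] * n_molecules, np.array(pos))


@pytest.fixture
def water_octamer(rng):
    return make_water_cluster(rng)
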