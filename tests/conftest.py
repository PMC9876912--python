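import numpy as np
import pytest

from elbench.landscape import EnergyLandscape, Well, default_landscape


@pytest.fixture(scope="session")
def landscape12():
    return default_landscape()


@pytest.fixture(scope="session")
def separable_landscape():
    """Same 3x4 grid, but with wells 12.5 widths apart and deep enough that
    essentially no occupancy remains in the inter-well background — the
    regime where nearest-center evaluation is exact."""
    base = default_landscape()
    wells = tuple(
        Well(id=w.id, center=w.center, depth=w.depth + 8.0, width=0.02) for w in base.wells
    )
    return EnergyLandscape(wells=wells)


@pytest.fixture(scope="session")
def small_phantom():
    from elbench.phantom import build_default_phantom

    return build_default_phantom(box_size=32, voxel_size=3.0)


@pytest.fixture(scope="session")
def phantom64():
    from elbench.phantom import build_default_phantom

    return build_default_phantom(box_size=64, voxel_size=3.0)


def make_clusters(rng, n_per=10, spread=1e-3, n_wells=12):
    """Twelve tight, widely separated clusters on a 3x4 grid in embedding
    space; returns (coords, labels)."""
    centers = np.array([(i % 4, i // 4) for i in range(n_wells)], dtype=float) * 10.0
    coords = np.vstack(
        [c + rng.normal(0.0, spread, size=(n_per, 2)) for c in centers]
    )
    labels = np.repeat(np.arange(1, n_wells + 1), n_per)
    return coords, labels


@pytest.fixture
def tight_clusters():
    rng = np.random.default_rng(42)
    return make_clusters(rng)


def count_strict_maxima(grid):
    """Brute-force count of lattice cells strictly greater than all of
    their (up to 8) neighbours."""
    n_max = 0
    rows, cols = grid.shape
    for i in range(rows):
        for j in range(cols):
            v = grid[i, j]
            neigh = [
                grid[a, b]
                for a in range(max(0, i - 1), min(rows, i + 2))
                for b in range(max(0, j - 1), min(cols, j + 2))
                if (a, b) != (i, j)
            ]
            if v > max(neigh):
                n_max += 1
    return n_max
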