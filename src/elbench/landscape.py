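"""Ground-truth conformational energy landscape.

The benchmark's ground truth is a two-coordinate energy landscape: a flat
background carrying a set of Gaussian wells of uneven depths.  At thermal
equilibrium the occupancy of a conformational state ``c`` follows the
Boltzmann factor ``exp(-E(c)/kT)``, so deep wells are strongly occupied and
the background is only weakly populated.  The default landscape places 12
wells on a 3 x 4 grid over the unit square, mirroring the characteristic
layout used for benchmarking conformational-heterogeneity methods.

Energies are expressed throughout in units of kT; coordinates (cc1, cc2)
are dimensionless in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "Well",
    "EnergyLandscape",
    "ConformationSample",
    "default_landscape",
    "energy_at",
    "occupancy_density",
    "sample_conformations",
    "label_conformation",
    "basin_masses",
]

#: depths (kT) of the 12 default wells, raster-ordered left-to-right,
#: bottom-to-top ("uneven depths"; fully configurable).
DEFAULT_DEPTHS = (2.0, 3.5, 2.5, 4.0, 3.0, 2.2, 4.5, 2.8, 3.8, 2.4, 3.2, 4.2)

#: default well width (standard deviation, conformational-coordinate units)
DEFAULT_WIDTH = 0.035

#: column positions along cc1 and row positions along cc2 of the 3 x 4 grid.
#: Offset from the exact {1/8,3/8,..} x {1/6,1/2,5/6} lattice so that no well
#: center coincides with a cell boundary of the midpoint occupancy lattice at
#: the resolutions in practical use (exact symmetric ties would otherwise
#: suppress strict density maxima at even resolutions).
DEFAULT_COLS = (0.1275, 0.3775, 0.6275, 0.8775)
DEFAULT_ROWS = (0.1675, 0.4975, 0.8275)


@dataclass(frozen=True)
class Well:
    """A single Gaussian energy well.

    Parameters
    ----------
    id : int
        Well label, 1-based; ids must be unique and contiguous within a
        landscape.
    center : tuple of float
        (cc1, cc2) position of the minimum, inside the domain.
    depth : float
        Depth below the background energy, in kT. Must be > 0.
    width : float
        Isotropic standard deviation in coordinate units. Must be > 0.
    """

    id: int
    center: tuple[float, float]
    depth: float
    width: float

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError(f"well {self.id}: depth must be > 0, got {self.depth}")
        if self.width <= 0:
            raise ValueError(f"well {self.id}: width must be > 0, got {self.width}")


@dataclass(frozen=True)
class EnergyLandscape:
    """A 2-D energy landscape built from Gaussian wells on a flat background.

    ``E(c) = background - sum_i depth_i * exp(-|c - center_i|^2 / (2 width_i^2))``
    """

    wells: tuple[Well, ...]
    kT: float = 1.0
    domain: tuple[tuple[float, float], tuple[float, float]] = ((0.0, 1.0), (0.0, 1.0))
    background_energy: float = 0.0

    def __post_init__(self) -> None:
        ids = [w.id for w in self.wells]
        if ids != list(range(1, len(ids) + 1)):
            raise ValueError(f"well ids must be contiguous 1..n, got {ids}")
        (x0, x1), (y0, y1) = self.domain
        for w in self.wells:
            cx, cy = w.center
            if not (x0 <= cx <= x1 and y0 <= cy <= y1):
                raise ValueError(f"well {w.id} center {w.center} outside domain")
        if self.kT <= 0:
            raise ValueError("kT must be positive")

    @property
    def n_wells(self) -> int:
        return len(self.wells)

    def centers(self) -> np.ndarray:
        """(n_wells, 2) array of well centers in id order."""
        return np.array([w.center for w in self.wells], dtype=float)

    def depths(self) -> np.ndarray:
        return np.array([w.depth for w in self.wells], dtype=float)

    def widths(self) -> np.ndarray:
        return np.array([w.width for w in self.wells], dtype=float)


@dataclass(frozen=True)
class ConformationSample:
    """One sampled conformation: continuous coordinates plus its basin label."""

    index: int
    cc: tuple[float, float]
    well_label: int


def default_landscape() -> EnergyLandscape:
    """The default 12-well landscape: 3 rows x 4 columns, uneven depths.

    Wells are raster-ordered (left to right along cc1, then bottom to top
    along cc2), ids 1..12.
    """
    wells = []
    k = 0
    for row in DEFAULT_ROWS:
        for col in DEFAULT_COLS:
            k += 1
            wells.append(
                Well(id=k, center=(col, row), depth=DEFAULT_DEPTHS[k - 1], width=DEFAULT_WIDTH)
            )
    return EnergyLandscape(wells=tuple(wells))


def _check_in_domain(landscape: EnergyLandscape, c: np.ndarray) -> None:
    (x0, x1), (y0, y1) = landscape.domain
    cx, cy = c[..., 0], c[..., 1]
    if np.any(cx < x0) or np.any(cx > x1) or np.any(cy < y0) or np.any(cy > y1):
        raise ValueError("conformational coordinate outside landscape domain")


def energy_at(landscape: EnergyLandscape, c) -> np.ndarray | float:
    """Energy E(c) in kT units at coordinate(s) ``c``.

    ``c`` may be a single (cc1, cc2) pair or an (n, 2) array; the return
    matches (scalar or (n,) array).  Raises ``ValueError`` for points
    outside the domain.
    """
    c_arr = np.asarray(c, dtype=float)
    scalar = c_arr.ndim == 1
    pts = np.atleast_2d(c_arr)
    _check_in_domain(landscape, pts)
    e = _energy_unchecked(landscape, pts)
    return float(e[0]) if scalar else e


def _energy_unchecked(landscape: EnergyLandscape, pts: np.ndarray) -> np.ndarray:
    """Vectorised Gaussian-well sum, no domain check. pts: (n, 2)."""
    e = np.full(pts.shape[0], landscape.background_energy, dtype=float)
    if landscape.n_wells == 0:
        return e
    centers = landscape.centers()  # (m, 2)
    d2 = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)  # (n, m)
    e -= (landscape.depths()[None, :] * np.exp(-d2 / (2.0 * landscape.widths()[None, :] ** 2))).sum(axis=1)
    return e


def _grid_centers(landscape: EnergyLandscape, grid_resolution: int):
    (x0, x1), (y0, y1) = landscape.domain
    ex = np.linspace(x0, x1, grid_resolution + 1)
    ey = np.linspace(y0, y1, grid_resolution + 1)
    cx = 0.5 * (ex[:-1] + ex[1:])
    cy = 0.5 * (ey[:-1] + ey[1:])
    return cx, cy


def occupancy_density(landscape: EnergyLandscape, grid_resolution: int) -> np.ndarray:
    """Normalised Boltzmann occupancy on a midpoint lattice.

    Returns a ``(grid_resolution, grid_resolution)`` array of cell masses
    (rows index cc2, columns cc1) proportional to ``exp(-E/kT)`` at each
    cell midpoint, normalised to sum to 1.
    """
    if grid_resolution < 8:
        raise ValueError("grid_resolution must be >= 8")
    cx, cy = _grid_centers(landscape, grid_resolution)
    gx, gy = np.meshgrid(cx, cy)  # (res, res), row-major over cc2
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    w = np.exp(-_energy_unchecked(landscape, pts) / landscape.kT)
    p = w / w.sum()
    return p.reshape(grid_resolution, grid_resolution)


def _max_boltzmann_weight(landscape: EnergyLandscape) -> float:
    """Least upper bound used as the rejection envelope: the global maximum
    of exp(-E/kT), found by multi-start local minimisation of E (each well
    center plus the best cell of a fine lattice), inflated by a tiny safety
    margin."""
    starts = [np.asarray(w.center, dtype=float) for w in landscape.wells]
    res = 256
    cx, cy = _grid_centers(landscape, res)
    gx, gy = np.meshgrid(cx, cy)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    e = _energy_unchecked(landscape, pts)
    starts.append(pts[int(np.argmin(e))])
    (x0, x1), (y0, y1) = landscape.domain
    best = float(np.min(e))
    for s in starts:
        r = optimize.minimize(
            lambda p: _energy_unchecked(landscape, p[None, :])[0],
            s,
            method="L-BFGS-B",
            bounds=[(x0, x1), (y0, y1)],
        )
        best = min(best, float(r.fun))
    return float(np.exp(-best / landscape.kT) * (1.0 + 1e-9))


def sample_conformations(
    landscape: EnergyLandscape, n: int, seed: int
) -> list[ConformationSample]:
    """Draw ``n`` Boltzmann-distributed conformations by rejection sampling.

    Proposals are uniform on the domain; the envelope is the global maximum
    of the Boltzmann weight.  Exact (no burn-in) and deterministic for a
    given ``seed``.  Each sample carries the ground-truth basin label from
    :func:`label_conformation`.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    (x0, x1), (y0, y1) = landscape.domain
    m = _max_boltzmann_weight(landscape)
    accepted = np.empty((0, 2))
    # acceptance rate = Z / (area * max weight); unknown a priori, so start
    # with a guess and re-batch from the observed rate
    batch = max(4 * n, 4096)
    proposed = 0
    while accepted.shape[0] < n:
        prop = np.column_stack(
            [rng.uniform(x0, x1, batch), rng.uniform(y0, y1, batch)]
        )
        w = np.exp(-_energy_unchecked(landscape, prop) / landscape.kT)
        keep = rng.uniform(0.0, m, batch) < w
        accepted = np.vstack([accepted, prop[keep]])
        proposed += batch
        rate = max(accepted.shape[0] / proposed, 1.0 / proposed)
        batch = min(int(1.3 * (n - accepted.shape[0]) / rate) + 64, 2_000_000)
    accepted = accepted[:n]
    labels = label_conformation(landscape, accepted)
    return [
        ConformationSample(index=i, cc=(float(accepted[i, 0]), float(accepted[i, 1])), well_label=int(labels[i]))
        for i in range(n)
    ]


def label_conformation(landscape: EnergyLandscape, c) -> np.ndarray | int:
    """Ground-truth basin label: id of the nearest well center (Euclidean).

    Ties are broken toward the lowest id.  Accepts a single pair or an
    (n, 2) array, returning an int or an (n,) int array respectively.
    """
    c_arr = np.asarray(c, dtype=float)
    scalar = c_arr.ndim == 1
    pts = np.atleast_2d(c_arr)
    _check_in_domain(landscape, pts)
    centers = landscape.centers()
    d2 = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    # argmin returns the first (= lowest-id) minimiser on ties
    labels = np.argmin(d2, axis=1) + 1
    return int(labels[0]) if scalar else labels


def basin_masses(landscape: EnergyLandscape, grid_resolution: int = 512) -> np.ndarray:
    """Numerically integrated occupancy mass of each well's Voronoi basin.

    Midpoint integration of the Boltzmann density over the nearest-center
    (Voronoi) partition of the domain; the independent oracle for sampling
    recovery checks.  Returns an (n_wells,) array summing to 1.
    """
    p = occupancy_density(landscape, grid_resolution)
    cx, cy = _grid_centers(landscape, grid_resolution)
    gx, gy = np.meshgrid(cx, cy)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    labels = label_conformation(landscape, pts)
    masses = np.bincount(labels - 1, weights=p.ravel(), minlength=landscape.n_wells)
    return masses
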