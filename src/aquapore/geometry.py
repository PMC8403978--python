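"""Cylindrical coordinates, pore-occupancy predicates and bin bookkeeping.

All analysis happens in the pore frame: the affine transform defined by the
geometry's axis origin/direction maps the pore axis onto z.  Axial positions
``z`` are reported relative to the membrane mid-plane.  Annular bin volumes
use the exact closed form pi*(r_out^2 - r_in^2)*dz so that count/volume
bookkeeping identities hold to machine precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple, Union

import numpy as np

from .core import Frame, PoreGeometry, WaterMolecule

#: default radial bin width for 1-D profiles (Å)
DEFAULT_DR = 0.1
#: default axial bin width for 2-D maps (Å)
DEFAULT_DZ = 0.2


@dataclass(frozen=True)
class CylindricalPosition:
    """Position in pore cylindrical coordinates (r, z, phi)."""

    r: float  # Å, distance from the pore axis, >= 0
    z: float  # Å, along the axis, origin at the membrane mid-plane
    phi: float  # radians in [0, 2*pi)

    def __post_init__(self) -> None:
        if self.r < 0:
            raise ValueError("r must be >= 0")
        if not (0.0 <= self.phi < 2.0 * math.pi):
            raise ValueError("phi must lie in [0, 2*pi)")


@dataclass
class BinGrid:
    """Radial (and optionally axial) bin edges with exact annular volumes.

    For a purely radial grid ``bin_volumes[i]`` is the full-slab annulus
    volume; for an (r, z) grid it is a (n_r, n_z) array of annular-sector
    volumes.
    """

    r_edges: np.ndarray
    z_edges: Optional[np.ndarray]
    bin_volumes: np.ndarray

    def __post_init__(self) -> None:
        self.r_edges = np.asarray(self.r_edges, dtype=float)
        if np.any(np.diff(self.r_edges) <= 0):
            raise ValueError("r_edges must be strictly increasing")
        if self.z_edges is not None:
            self.z_edges = np.asarray(self.z_edges, dtype=float)
            if np.any(np.diff(self.z_edges) <= 0):
                raise ValueError("z_edges must be strictly increasing")

    @property
    def n_r(self) -> int:
        return len(self.r_edges) - 1

    @property
    def n_z(self) -> int:
        return 0 if self.z_edges is None else len(self.z_edges) - 1

    @property
    def r_mid(self) -> np.ndarray:
        return 0.5 * (self.r_edges[:-1] + self.r_edges[1:])

    @property
    def z_mid(self) -> np.ndarray:
        if self.z_edges is None:
            raise ValueError("grid has no z edges")
        return 0.5 * (self.z_edges[:-1] + self.z_edges[1:])


def cylindrical_coords(
    points: np.ndarray, geom: PoreGeometry
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised (r, z, phi) for lab-frame points of shape (N, 3)."""
    p = geom.to_pore_frame(np.atleast_2d(points))
    r = np.hypot(p[:, 0], p[:, 1])
    z = p[:, 2] - geom.membrane_z_mid
    phi = np.mod(np.arctan2(p[:, 1], p[:, 0]), 2.0 * math.pi)
    return r, z, phi


def to_cylindrical(position: np.ndarray, geom: PoreGeometry) -> CylindricalPosition:
    """Cylindrical coordinates of one lab-frame point."""
    r, z, phi = cylindrical_coords(np.asarray(position, dtype=float).reshape(1, 3), geom)
    return CylindricalPosition(float(r[0]), float(z[0]), float(phi[0]))


def inside_pore_mask(
    oxygens: np.ndarray, geom: PoreGeometry, radial_margin: float = 0.0
) -> np.ndarray:
    """Boolean mask of oxygens inside the pore (closed boundaries).

    A molecule is in the pore iff its oxygen satisfies
    ``membrane_z_min <= z <= membrane_z_max`` (pore-frame z) and
    ``r <= radius_R + radial_margin``.
    """
    p = geom.to_pore_frame(np.atleast_2d(oxygens))
    r = np.hypot(p[:, 0], p[:, 1])
    z = p[:, 2]
    return (
        (z >= geom.membrane_z_min)
        & (z <= geom.membrane_z_max)
        & (r <= geom.radius_R + radial_margin)
    )


def inside_pore(
    molecule: Union[WaterMolecule, np.ndarray],
    geom: PoreGeometry,
    radial_margin: float = 0.0,
) -> bool:
    """Whether a molecule (judged by its oxygen alone) is inside the pore."""
    oxy = molecule.oxygen if isinstance(molecule, WaterMolecule) else np.asarray(molecule)
    return bool(inside_pore_mask(oxy.reshape(1, 3), geom, radial_margin)[0])


def _radial_edges(r_max: float, dr: float) -> np.ndarray:
    if dr <= 0:
        raise ValueError("dr must be > 0")
    if dr >= r_max:
        raise ValueError(f"dr={dr} must be smaller than the radial extent {r_max}")
    n = int(math.ceil(r_max / dr - 1e-9))
    edges = dr * np.arange(n + 1, dtype=float)
    edges[-1] = r_max  # exact outer edge so volumes sum to the cylinder volume
    return edges


def annular_volumes(r_edges: np.ndarray, dz: float) -> np.ndarray:
    """Exact annulus volumes pi*(r_out^2 - r_in^2)*dz per radial bin."""
    r2 = np.asarray(r_edges, dtype=float) ** 2
    return math.pi * np.diff(r2) * dz


def make_radial_grid(
    geom: PoreGeometry, dr: float = DEFAULT_DR, radial_margin: float = 0.0
) -> BinGrid:
    """Annular bins covering [0, R + radial_margin] over the full slab length."""
    r_max = geom.radius_R + radial_margin
    r_edges = _radial_edges(r_max, dr)
    return BinGrid(
        r_edges=r_edges,
        z_edges=None,
        bin_volumes=annular_volumes(r_edges, geom.length_L),
    )


def make_2d_grid(
    geom: PoreGeometry,
    dr: float = DEFAULT_DR,
    dz: float = DEFAULT_DZ,
    radial_margin: float = 0.0,
) -> BinGrid:
    """(r, z) bins covering the pore cross-section times the slab extent.

    z edges are relative to the membrane mid-plane, spanning [-L/2, L/2].
    """
    r_max = geom.radius_R + radial_margin
    r_edges = _radial_edges(r_max, dr)
    half = geom.length_L / 2.0
    n_z = int(math.ceil(geom.length_L / dz - 1e-9))
    z_edges = -half + dz * np.arange(n_z + 1, dtype=float)
    z_edges[-1] = half
    dz_eff = np.diff(z_edges)
    volumes = annular_volumes(r_edges, 1.0)[:, None] * dz_eff[None, :]
    return BinGrid(r_edges=r_edges, z_edges=z_edges, bin_volumes=volumes)
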