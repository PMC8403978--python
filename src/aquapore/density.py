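"""Density profiles, 2-D (r, z) maps and layer segmentation.

Confined water organises into concentric cylindrical layers about the pore
axis, roughly one molecular diameter (~2.5 Å) thick.  The radial number
density rho(r) exposes them as sharp peaks; the minima between successive
peaks define the layer boundaries (inner, optionally middle, and contact,
moving outward).  Densities are molecular number densities (oxygen count
per Å^3).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy.signal import find_peaks

from .core import CurveSeries, PoreGeometry, Trajectory
from .geometry import BinGrid, annular_volumes, cylindrical_coords, inside_pore_mask

logger = logging.getLogger("aquapore")

LAYER_LABELS = ("inner", "middle", "contact")

#: default smoothing window (bins) and prominence fraction for minima detection
DEFAULT_SMOOTHING_WINDOW = 5
DEFAULT_MIN_PROMINENCE = 0.05


@dataclass
class DensityProfile:
    """Radial number-density profile with exact counting bookkeeping.

    ``rho[b] = counts[b] / (volume_b * n_frames)`` so that
    ``sum_b rho[b] * volume_b * n_frames`` equals the total number of
    counted molecule-frames exactly.
    """

    grid: BinGrid
    rho: np.ndarray
    counts: np.ndarray
    n_frames: int

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(self.rho < 0):
            raise ValueError("rho must be non-negative")

    @property
    def total_molecule_frames(self) -> int:
        return int(self.counts.sum())


@dataclass
class LayerPartition:
    """Radial layer boundaries with outward-ordered labels.

    ``labels`` has one more entry than ``boundaries_r``; the outermost label
    is ``contact`` whenever more than one layer exists.
    """

    boundaries_r: np.ndarray
    labels: Sequence[str]

    def __post_init__(self) -> None:
        self.boundaries_r = np.asarray(self.boundaries_r, dtype=float)
        if len(self.labels) != len(self.boundaries_r) + 1:
            raise ValueError("need exactly one more label than boundary")
        if np.any(np.diff(self.boundaries_r) <= 0):
            raise ValueError("boundaries must be strictly increasing")
        unknown = set(self.labels) - set(LAYER_LABELS) - {"bulk_reference"}
        if unknown:
            raise ValueError(f"unknown layer labels: {unknown}")

    def layer_of(self, r: np.ndarray) -> np.ndarray:
        """Label index for each radius (outermost band is open-ended)."""
        return np.searchsorted(self.boundaries_r, np.asarray(r, dtype=float), side="right")

    def label_of(self, r: float) -> str:
        return self.labels[int(self.layer_of(np.array([r]))[0])]

    def band(self, label: str) -> tuple[float, float]:
        """(r_lo, r_hi) of a labelled band; outer bound inf for the last."""
        idx = list(self.labels).index(label)
        lo = 0.0 if idx == 0 else float(self.boundaries_r[idx - 1])
        hi = np.inf if idx == len(self.labels) - 1 else float(self.boundaries_r[idx])
        return lo, hi


def _in_pore_r(
    traj: Trajectory, geom: PoreGeometry, radial_margin: float
) -> List[np.ndarray]:
    """Per frame: radii of oxygens inside the pore slab."""
    out = []
    for frame in traj.frames:
        mask = inside_pore_mask(frame.oxygens, geom, radial_margin)
        r, _, _ = cylindrical_coords(frame.oxygens[mask], geom)
        out.append(r)
    return out


def radial_density(
    traj: Trajectory,
    geom: PoreGeometry,
    grid: BinGrid,
    radial_margin: float = 0.0,
) -> DensityProfile:
    """Cylindrically averaged number density rho(r) of in-pore water."""
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    counts = np.zeros(grid.n_r, dtype=int)
    for r in _in_pore_r(traj, geom, radial_margin):
        h, _ = np.histogram(r, bins=grid.r_edges)
        counts += h
    rho = counts / (grid.bin_volumes * traj.n_frames)
    return DensityProfile(grid=grid, rho=rho, counts=counts, n_frames=traj.n_frames)


def density_map_2d(
    traj: Trajectory,
    geom: PoreGeometry,
    grid: BinGrid,
    radial_margin: float = 0.0,
) -> DensityProfile:
    """Azimuthally averaged 2-D density over (r, z).

    Each cell is normalised by its exact annular-sector volume
    pi*(r_out^2 - r_in^2)*dz (equal to 2*pi*r_mid*dr*dz) and by the frame
    count, so that marginalising over z reproduces the radial profile.
    """
    if grid.z_edges is None:
        raise ValueError("2-D map needs a grid with z edges")
    counts = np.zeros((grid.n_r, grid.n_z), dtype=int)
    for frame in traj.frames:
        mask = inside_pore_mask(frame.oxygens, geom, radial_margin)
        r, z, _ = cylindrical_coords(frame.oxygens[mask], geom)
        h, _, _ = np.histogram2d(r, z, bins=(grid.r_edges, grid.z_edges))
        counts += h.astype(int)
    rho = counts / (grid.bin_volumes * traj.n_frames)
    return DensityProfile(grid=grid, rho=rho, counts=counts, n_frames=traj.n_frames)


def axial_contact_density(
    traj: Trajectory,
    geom: PoreGeometry,
    partition: LayerPartition,
    dz: float = 0.2,
    radial_margin: float = 0.0,
) -> CurveSeries:
    """Number density along z of water restricted to the contact layer."""
    if "contact" not in partition.labels:
        raise ValueError("partition has no contact layer")
    r_lo, r_hi = partition.band("contact")
    r_hi = min(r_hi, geom.radius_R + radial_margin)
    half = geom.length_L / 2.0
    n_z = int(np.ceil(geom.length_L / dz - 1e-9))
    z_edges = -half + dz * np.arange(n_z + 1)
    z_edges[-1] = half
    counts = np.zeros(n_z, dtype=int)
    for frame in traj.frames:
        mask = inside_pore_mask(frame.oxygens, geom, radial_margin)
        r, z, _ = cylindrical_coords(frame.oxygens[mask], geom)
        sel = (r >= r_lo) & (r <= r_hi)
        h, _ = np.histogram(z[sel], bins=z_edges)
        counts += h
    shell_area = np.pi * (r_hi**2 - r_lo**2)
    vol = shell_area * np.diff(z_edges)
    rho = counts / (vol * traj.n_frames)
    return CurveSeries(
        x=0.5 * (z_edges[:-1] + z_edges[1:]),
        y=rho,
        counts=counts,
        x_label="z_mid",
        y_label="rho",
    )


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with edge shrinkage; window must be odd."""
    if window < 1 or window % 2 == 0:
        raise ValueError("smoothing window must be a positive odd integer")
    if window == 1:
        return y.astype(float)
    half = window // 2
    padded = np.pad(y.astype(float), half, mode="edge")
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")


def segment_layers(
    profile: DensityProfile,
    smoothing_window: int = DEFAULT_SMOOTHING_WINDOW,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    max_layers: int = 3,
) -> LayerPartition:
    """Partition the pore radially at the minima of the smoothed rho(r).

    Boundaries are local minima of the moving-average-smoothed profile
    lying between density maxima; prominence is thresholded at
    ``min_prominence`` times the smoothed maximum and ties break toward the
    larger radius.  At most ``max_layers`` layers are kept (extra interior
    minima are dropped in increasing-prominence order).  With no interior
    minimum the whole pore becomes a single ``inner`` layer and a warning is
    emitted.
    """
    if profile.rho.ndim != 1:
        raise ValueError("segment_layers needs a radial (1-D) profile")
    rho_s = _smooth(profile.rho, smoothing_window)
    r_mid = profile.grid.r_mid
    peak_threshold = min_prominence * float(rho_s.max()) if rho_s.max() > 0 else 0.0
    # minima of rho are peaks of -rho; exclude the array ends (not interior)
    minima, props = find_peaks(-rho_s, prominence=peak_threshold)
    if len(minima) == 0:
        warnings.warn("no interior density minimum found; single-layer partition")
        return LayerPartition(boundaries_r=np.array([]), labels=["inner"])
    prom = props["prominences"]
    # keep at most max_layers-1 boundaries, by decreasing prominence;
    # ties toward larger radius (stable sort on (-prom, -r))
    order = np.lexsort((-minima, -prom))
    keep = np.sort(minima[order[: max_layers - 1]])
    boundaries = r_mid[keep]
    n_layers = len(boundaries) + 1
    if n_layers == 2:
        labels = ["inner", "contact"]
    else:
        labels = ["inner"] + ["middle"] * (n_layers - 2) + ["contact"]
    return LayerPartition(boundaries_r=boundaries, labels=labels)


def assign_layers(
    r: np.ndarray, partition: LayerPartition
) -> np.ndarray:
    """Layer label (string array) for each radius."""
    idx = partition.layer_of(r)
    labels = np.asarray(partition.labels, dtype=object)
    return labels[idx]
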