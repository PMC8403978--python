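"""Molecular-orientation analysis: the beta angle and its radial profiles.

For each water molecule, beta is the angle between (i) the projection of
the H-O-H bisector unit vector onto the base plane (the plane orthogonal to
the pore axis through the oxygen) and (ii) the outward radial direction at
the oxygen.  cos(beta) is signed: +1 means the bisector points straight at
the wall.  For uniformly random orientations <cos beta> = 0 and
<|cos beta|> = 2/pi ~ 0.6367, which serve as bulk anchors.

beta is undefined for molecules on the axis (no radial direction) or with
the bisector parallel to the axis (zero projection); such records are
excluded rather than zero-filled, to avoid biasing the innermost bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .core import CurveSeries, PoreGeometry, Trajectory, WaterMolecule
from .geometry import BinGrid, inside_pore_mask

#: radius below which the outward radial direction is considered undefined (Å)
EPS_AXIS = 1e-3
#: squared-projection threshold below which the bisector is considered axial
EPS_PROJ = 1e-6


@dataclass(frozen=True)
class OrientationRecord:
    molecule_id: int
    frame_time: float
    r: float
    cos_beta: float

    def __post_init__(self) -> None:
        if abs(self.cos_beta) > 1.0 + 1e-12:
            raise ValueError("|cos_beta| must be <= 1")


def cos_beta_from_sites(
    oxygens: np.ndarray,
    hydrogens1: np.ndarray,
    hydrogens2: np.ndarray,
    geom: PoreGeometry,
) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorised cos(beta) for (N, 3) site arrays.

    Returns ``(cos_beta, defined)``; entries with ``defined`` False are
    molecules whose beta is undefined (on-axis oxygen or axial bisector).
    Collinear O,H,H geometries raise.
    """
    o = geom.to_pore_frame(np.atleast_2d(oxygens))
    h1 = geom.to_pore_frame(np.atleast_2d(hydrogens1))
    h2 = geom.to_pore_frame(np.atleast_2d(hydrogens2))
    u1 = h1 - o
    u2 = h2 - o
    u1 /= np.linalg.norm(u1, axis=1, keepdims=True)
    u2 /= np.linalg.norm(u2, axis=1, keepdims=True)
    b = u1 + u2
    b_norm = np.linalg.norm(b, axis=1)
    if np.any(b_norm < 1e-9):
        raise ValueError("degenerate molecule: O-H vectors are anti-parallel")
    b /= b_norm[:, None]
    r = np.hypot(o[:, 0], o[:, 1])
    b_perp = b[:, :2]  # base-plane projection of the bisector
    proj = np.linalg.norm(b_perp, axis=1)
    defined = (r >= EPS_AXIS) & (proj >= np.sqrt(EPS_PROJ))
    cos_beta = np.zeros(len(o))
    if np.any(defined):
        rad = o[defined, :2] / r[defined, None]  # outward radial unit vector
        cos_beta[defined] = np.einsum("ij,ij->i", b_perp[defined], rad) / proj[defined]
    np.clip(cos_beta, -1.0, 1.0, out=cos_beta)
    return cos_beta, defined


def compute_cos_beta(molecule: WaterMolecule, geom: PoreGeometry) -> Optional[float]:
    """Signed cos(beta) of one molecule, or None where beta is undefined."""
    cb, ok = cos_beta_from_sites(
        molecule.oxygen.reshape(1, 3),
        molecule.hydrogen1.reshape(1, 3),
        molecule.hydrogen2.reshape(1, 3),
        geom,
    )
    return float(cb[0]) if ok[0] else None


def orientation_profiles(
    traj: Trajectory,
    geom: PoreGeometry,
    grid: BinGrid,
    radial_margin: float = 0.0,
) -> Tuple[CurveSeries, CurveSeries]:
    """Radial profiles of <cos beta> and <|cos beta|> over in-pore water.

    Bins without samples carry NaN values and zero counts (missing, not
    zero).
    """
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    n_bins = grid.n_r
    sum_cb = np.zeros(n_bins)
    sum_abs = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for frame in traj.frames:
        mask = inside_pore_mask(frame.oxygens, geom, radial_margin)
        if not np.any(mask):
            continue
        cb, ok = cos_beta_from_sites(
            frame.oxygens[mask], frame.hydrogens1[mask], frame.hydrogens2[mask], geom
        )
        o = geom.to_pore_frame(frame.oxygens[mask])
        r = np.hypot(o[:, 0], o[:, 1])[ok]
        cb = cb[ok]
        idx = np.searchsorted(grid.r_edges, r, side="right") - 1
        valid = (idx >= 0) & (idx < n_bins)
        np.add.at(sum_cb, idx[valid], cb[valid])
        np.add.at(sum_abs, idx[valid], np.abs(cb[valid]))
        np.add.at(counts, idx[valid], 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_cb = np.where(counts > 0, sum_cb / counts, np.nan)
        mean_abs = np.where(counts > 0, sum_abs / counts, np.nan)
    r_mid = grid.r_mid
    return (
        CurveSeries(r_mid, mean_cb, counts, "r_mid", "mean_cos_beta"),
        CurveSeries(r_mid, mean_abs, counts, "r_mid", "mean_abs_cos_beta"),
    )
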