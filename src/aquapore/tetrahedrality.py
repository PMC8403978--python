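"""Four-nearest-neighbour geometry: gamma angles and the tetrahedral order q.

Around each water oxygen the four nearest oxygen neighbours (minimum image,
over all molecules including reservoir water) subtend six pair angles gamma
at the centre.  A perfect tetrahedron gives gamma = 109.47 deg for all six
pairs.  The orientational order parameter

    q = 1 - (3/8) * sum_{i<j} (cos(gamma_ij) + 1/3)^2

equals 1 for the perfect tetrahedron (all cosines -1/3), averages 0 when
the four neighbour directions are independent and uniform (ideal gas), and
attains its minimum -3 when all four neighbours coincide in direction
(all six angles zero).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .core import CurveSeries, Frame, PoreGeometry, Trajectory, WaterMolecule, minimum_image
from .density import LayerPartition
from .geometry import cylindrical_coords, inside_pore_mask

#: the six unordered pairs among four neighbours
_PAIRS = list(itertools.combinations(range(4), 2))

DEFAULT_GAMMA_BIN_DEG = 2.0
DEFAULT_Q_BIN = 0.02


@dataclass(frozen=True)
class TetrahedralRecord:
    molecule_id: int
    frame_time: float
    layer: str
    gamma_angles: Tuple[float, ...]  # six, degrees
    q: float

    def __post_init__(self) -> None:
        if len(self.gamma_angles) != 6:
            raise ValueError("need exactly six gamma angles")
        if not (-3.0 - 1e-9 <= self.q <= 1.0 + 1e-9):
            raise ValueError("q out of range [-3, 1]")


def _wrap(points: np.ndarray, box: np.ndarray) -> np.ndarray:
    return np.mod(points, box)


def _neighbour_table(frame: Frame, k_query: int = 12) -> np.ndarray:
    """(N, 4) array of neighbour *indices* for every molecule in the frame.

    Uses a periodic k-d tree; exact distance ties break toward the lower
    molecule_id.
    """
    n = frame.n_molecules
    if n < 5:
        raise ValueError("need at least 5 molecules for four neighbours")
    pos = _wrap(frame.oxygens, frame.box)
    tree = cKDTree(pos, boxsize=frame.box)
    k = min(n, k_query)
    dist, idx = tree.query(pos, k=k)
    ids = frame.molecule_ids
    out = np.empty((n, 4), dtype=int)
    for i in range(n):
        cand = idx[i]
        d = dist[i]
        keep = cand != i
        cand, d = cand[keep], d[keep]
        order = np.lexsort((ids[cand], d))  # distance first, then molecule_id
        out[i] = cand[order[:4]]
    return out


def four_nearest_neighbours(
    center: WaterMolecule, frame: Frame, geom: Optional[PoreGeometry] = None
) -> List[int]:
    """molecule_ids of the four oxygens nearest to the centre (minimum image)."""
    pos_in_frame = np.nonzero(frame.molecule_ids == center.molecule_id)[0]
    if len(pos_in_frame) != 1:
        raise ValueError("center molecule not found in frame")
    table = _neighbour_table(frame)
    return [int(frame.molecule_ids[j]) for j in table[pos_in_frame[0]]]


def _brute_force_four_nearest(frame: Frame, center_index: int) -> List[int]:
    """All-periodic-images O(N) oracle for the neighbour search (tests)."""
    box = frame.box
    delta = frame.oxygens - frame.oxygens[center_index]
    best = np.full(len(delta), np.inf)
    for sx in (-1, 0, 1):
        for sy in (-1, 0, 1):
            for sz in (-1, 0, 1):
                shift = np.array([sx, sy, sz]) * box
                d = np.linalg.norm(delta + shift, axis=1)
                best = np.minimum(best, d)
    ids = frame.molecule_ids
    keep = np.arange(len(ids)) != center_index
    order = np.lexsort((ids[keep], best[keep]))
    return [int(i) for i in ids[keep][order[:4]]]


def gamma_angles(
    center: np.ndarray,
    neighbours: np.ndarray,
    box: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Six pair angles (degrees) at the central oxygen, each in [0, 180]."""
    neighbours = np.atleast_2d(np.asarray(neighbours, dtype=float))
    if neighbours.shape != (4, 3):
        raise ValueError("need exactly four neighbour positions")
    v = neighbours - np.asarray(center, dtype=float)
    if box is not None:
        v = minimum_image(v, np.asarray(box, dtype=float))
    norms = np.linalg.norm(v, axis=1)
    if np.any(norms < 1e-12):
        raise ValueError("zero-length center-neighbour vector")
    u = v / norms[:, None]
    cos = np.array([np.dot(u[i], u[j]) for i, j in _PAIRS])
    np.clip(cos, -1.0, 1.0, out=cos)
    return np.degrees(np.arccos(cos))


def q_parameter(gamma_angles_deg: Sequence[float]) -> float:
    """Tetrahedral order parameter q from the six gamma angles (degrees)."""
    g = np.asarray(gamma_angles_deg, dtype=float)
    if g.shape != (6,):
        raise ValueError("q needs exactly six angles")
    return float(q_from_cosines(np.cos(np.radians(g))[None, :])[0])


def q_from_cosines(cosines: np.ndarray) -> np.ndarray:
    """Vectorised q for an (M, 6) array of pair-angle cosines."""
    c = np.atleast_2d(np.asarray(cosines, dtype=float))
    if c.shape[1] != 6:
        raise ValueError("q needs six pair cosines")
    return 1.0 - (3.0 / 8.0) * np.sum((c + 1.0 / 3.0) ** 2, axis=1)


def tetrahedral_records(
    traj: Trajectory,
    geom: PoreGeometry,
    partition: LayerPartition,
    radial_margin: float = 0.0,
) -> List[TetrahedralRecord]:
    """gamma/q records for every in-pore central molecule of every frame.

    Central molecules are the in-pore waters; neighbour candidates are all
    molecules of the frame (reservoir water included), under minimum image.
    The layer is assigned from the central oxygen's instantaneous radius.
    """
    records: List[TetrahedralRecord] = []
    labels = np.asarray(partition.labels, dtype=object)
    for frame in traj.frames:
        in_pore = inside_pore_mask(frame.oxygens, geom, radial_margin)
        if not np.any(in_pore):
            continue
        table = _neighbour_table(frame)
        r, _, _ = cylindrical_coords(frame.oxygens, geom)
        layer_idx = partition.layer_of(r)
        for i in np.nonzero(in_pore)[0]:
            gam = gamma_angles(
                frame.oxygens[i], frame.oxygens[table[i]], box=frame.box
            )
            records.append(
                TetrahedralRecord(
                    molecule_id=int(frame.molecule_ids[i]),
                    frame_time=frame.time,
                    layer=str(labels[layer_idx[i]]),
                    gamma_angles=tuple(gam),
                    q=q_parameter(gam),
                )
            )
    return records


def layer_resolved_distributions(
    traj: Trajectory,
    geom: PoreGeometry,
    partition: LayerPartition,
    bin_width_gamma: float = DEFAULT_GAMMA_BIN_DEG,
    bin_width_q: float = DEFAULT_Q_BIN,
    radial_margin: float = 0.0,
) -> Dict[str, Dict[str, CurveSeries]]:
    """Normalised P(gamma) and P(q) per layer.

    gamma statistics aggregate all six pair angles of each central molecule
    (the same six entering q).  Histograms are probability densities
    (trapezoidal integral 1); an empty layer yields empty curves.
    """
    records = tetrahedral_records(traj, geom, partition, radial_margin)
    out: Dict[str, Dict[str, CurveSeries]] = {}
    g_edges = np.arange(0.0, 180.0 + bin_width_gamma, bin_width_gamma)
    n_q = int(math.ceil(4.0 / bin_width_q))
    q_edges = -3.0 + bin_width_q * np.arange(n_q + 1)
    q_edges[-1] = 1.0
    for label in partition.labels:
        recs = [rec for rec in records if rec.layer == label]
        gammas = np.concatenate([rec.gamma_angles for rec in recs]) if recs else np.array([])
        qs = np.array([rec.q for rec in recs])
        if len(recs):
            g_pdf, _ = np.histogram(gammas, bins=g_edges, density=True)
            q_pdf, _ = np.histogram(qs, bins=q_edges, density=True)
            g_counts, _ = np.histogram(gammas, bins=g_edges)
            q_counts, _ = np.histogram(qs, bins=q_edges)
        else:
            g_pdf = np.zeros(len(g_edges) - 1)
            q_pdf = np.zeros(len(q_edges) - 1)
            g_counts = np.zeros(len(g_edges) - 1, dtype=int)
            q_counts = np.zeros(len(q_edges) - 1, dtype=int)
        out[label] = {
            "gamma": CurveSeries(
                0.5 * (g_edges[:-1] + g_edges[1:]), g_pdf, g_counts, "gamma_mid", "pdf"
            ),
            "q": CurveSeries(
                0.5 * (q_edges[:-1] + q_edges[1:]), q_pdf, q_counts, "q_mid", "pdf"
            ),
        }
    return out


def regular_tetrahedron_vertices(bond_length: float = 2.8) -> np.ndarray:
    """Four unit-tetrahedron vertex directions scaled to ``bond_length``.

    Centred on the origin; every pair subtends arccos(-1/3) ~ 109.47 deg.
    """
    v = np.array(
        [
            [1.0, 1.0, 1.0],
            [1.0, -1.0, -1.0],
            [-1.0, 1.0, -1.0],
            [-1.0, -1.0, 1.0],
        ]
    ) / math.sqrt(3.0)
    return bond_length * v
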