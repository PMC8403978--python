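"""Geometric hydrogen-bond detection, counting and layer typing.

Two waters are hydrogen bonded when their O-O distance (minimum image) is
at most 3.5 Å and the angle between the donor O-H bond and the donor-to-
acceptor O-O vector is at most 30 deg; both boundaries are closed.  The
criterion is tested per O-H, so a molecule may in principle donate twice to
the same acceptor.  n_HB counts donated plus accepted bonds.

Bonds are typed by the instantaneous layer of the two oxygens
(contact_contact, contact_inner, inner_inner, middle_* for the large pore)
or "external" when either molecule sits outside the pore.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import Frame, PoreGeometry, Trajectory, minimum_image
from .density import LayerPartition
from .geometry import cylindrical_coords, inside_pore_mask

#: geometric criterion defaults
D_OO_MAX = 3.5  # Å
ANGLE_MAX_DEG = 30.0
#: closed-boundary float tolerance
_EPS = 1e-9


@dataclass(frozen=True)
class HBond:
    donor_id: int
    acceptor_id: int
    donor_hydrogen_index: int  # 1 or 2
    oo_distance: float  # Å
    angle_deg: float
    bond_type: str

    def __post_init__(self) -> None:
        if self.donor_id == self.acceptor_id:
            raise ValueError("self hydrogen bond")
        if self.donor_hydrogen_index not in (1, 2):
            raise ValueError("donor_hydrogen_index must be 1 or 2")


@dataclass
class HBondGraph:
    frame_time: float
    bonds: List[HBond]
    per_molecule_counts: Dict[int, int]

    def __post_init__(self) -> None:
        total = sum(self.per_molecule_counts.values())
        if total != 2 * len(self.bonds):
            raise ValueError("handshake identity violated: sum n_HB != 2 |bonds|")


def bond_type_label(layer_a: str, layer_b: str) -> str:
    """Canonical type label for a bond between two layers.

    Same-layer pairs give ``x_x``; any pair involving ``middle`` is
    ``middle_<other>``; the remaining mixed pair is ``contact_inner``.
    ``external`` wins whenever either side is outside the pore.
    """
    if layer_a == "external" or layer_b == "external":
        return "external"
    if layer_a == layer_b:
        return f"{layer_a}_{layer_b}"
    pair = {layer_a, layer_b}
    if "middle" in pair:
        other = (pair - {"middle"}).pop()
        return f"middle_{other}"
    return "contact_inner"


def _molecule_layers(
    frame: Frame,
    geom: PoreGeometry,
    partition: LayerPartition,
    radial_margin: float,
) -> np.ndarray:
    """Instantaneous layer label per molecule ('external' outside the pore)."""
    in_pore = inside_pore_mask(frame.oxygens, geom, radial_margin)
    r, _, _ = cylindrical_coords(frame.oxygens, geom)
    labels = np.asarray(partition.labels, dtype=object)[partition.layer_of(r)]
    labels = labels.astype(object)
    labels[~in_pore] = "external"
    return labels


def _evaluate_candidates(
    frame: Frame,
    donors: np.ndarray,
    acceptors: np.ndarray,
    d_oo_max: float,
    angle_max: float,
) -> List[Tuple[int, int, int, float, float]]:
    """Apply the distance+angle criterion to ordered (donor, acceptor) pairs.

    Returns tuples (donor_idx, acceptor_idx, hydrogen_index, d_oo, angle).
    """
    if len(donors) == 0:
        return []
    oo = minimum_image(frame.oxygens[acceptors] - frame.oxygens[donors], frame.box)
    d = np.linalg.norm(oo, axis=1)
    ok_d = d <= d_oo_max + _EPS
    out: List[Tuple[int, int, int, float, float]] = []
    for h_index, hyd in ((1, frame.hydrogens1), (2, frame.hydrogens2)):
        oh = hyd[donors] - frame.oxygens[donors]  # stored unwrapped: no image needed
        num = np.einsum("ij,ij->i", oh, oo)
        den = np.linalg.norm(oh, axis=1) * d
        with np.errstate(invalid="ignore", divide="ignore"):
            cosang = np.where(den > 0, num / den, -1.0)
        np.clip(cosang, -1.0, 1.0, out=cosang)
        ang = np.degrees(np.arccos(cosang))
        ok = ok_d & (ang <= angle_max + _EPS) & (d > _EPS)
        for di, ai, dd, aa in zip(donors[ok], acceptors[ok], d[ok], ang[ok]):
            out.append((int(di), int(ai), h_index, float(dd), float(aa)))
    return out


def detect_hbonds(
    frame: Frame,
    geom: PoreGeometry,
    partition: LayerPartition,
    d_oo_max: float = D_OO_MAX,
    angle_max: float = ANGLE_MAX_DEG,
    radial_margin: float = 0.0,
) -> HBondGraph:
    """All hydrogen bonds of one frame, typed by instantaneous layers."""
    pos = np.mod(frame.oxygens, frame.box)
    tree = cKDTree(pos, boxsize=frame.box)
    pairs = tree.query_pairs(r=d_oo_max + 1e-6, output_type="ndarray")
    if len(pairs):
        donors = np.concatenate([pairs[:, 0], pairs[:, 1]])
        acceptors = np.concatenate([pairs[:, 1], pairs[:, 0]])
    else:
        donors = acceptors = np.array([], dtype=int)
    found = _evaluate_candidates(frame, donors, acceptors, d_oo_max, angle_max)
    return _build_graph(frame, geom, partition, radial_margin, found)


def _build_graph(
    frame: Frame,
    geom: PoreGeometry,
    partition: LayerPartition,
    radial_margin: float,
    found: List[Tuple[int, int, int, float, float]],
) -> HBondGraph:
    layers = _molecule_layers(frame, geom, partition, radial_margin)
    counts: Dict[int, int] = {int(m): 0 for m in frame.molecule_ids}
    bonds: List[HBond] = []
    # deterministic order: by donor id, acceptor id, hydrogen index
    found = sorted(
        found,
        key=lambda t: (int(frame.molecule_ids[t[0]]), int(frame.molecule_ids[t[1]]), t[2]),
    )
    for di, ai, h_index, dd, aa in found:
        d_id = int(frame.molecule_ids[di])
        a_id = int(frame.molecule_ids[ai])
        bonds.append(
            HBond(
                donor_id=d_id,
                acceptor_id=a_id,
                donor_hydrogen_index=h_index,
                oo_distance=dd,
                angle_deg=aa,
                bond_type=bond_type_label(str(layers[di]), str(layers[ai])),
            )
        )
        counts[d_id] += 1
        counts[a_id] += 1
    return HBondGraph(frame_time=frame.time, bonds=bonds, per_molecule_counts=counts)


def _brute_force_hbonds(
    frame: Frame,
    geom: PoreGeometry,
    partition: LayerPartition,
    d_oo_max: float = D_OO_MAX,
    angle_max: float = ANGLE_MAX_DEG,
    radial_margin: float = 0.0,
) -> HBondGraph:
    """O(N^2) all-ordered-pairs oracle for the tree-based detection (tests)."""
    n = frame.n_molecules
    di, ai = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    mask = di != ai
    found = _evaluate_candidates(
        frame, di[mask].ravel(), ai[mask].ravel(), d_oo_max, angle_max
    )
    return _build_graph(frame, geom, partition, radial_margin, found)


def nhb_by_layer(
    traj: Trajectory,
    geom: PoreGeometry,
    partition: LayerPartition,
    d_oo_max: float = D_OO_MAX,
    angle_max: float = ANGLE_MAX_DEG,
    radial_margin: float = 0.0,
) -> pd.DataFrame:
    """Time- and molecule-averaged n_HB per layer.

    Each in-pore molecule contributes one sample per frame, to the layer it
    occupies in that frame.  Returns columns (layer, mean_nhb, se_nhb,
    n_samples); layers never occupied are absent.
    """
    samples: Dict[str, List[int]] = {}
    for frame in traj.frames:
        graph = detect_hbonds(frame, geom, partition, d_oo_max, angle_max, radial_margin)
        layers = _molecule_layers(frame, geom, partition, radial_margin)
        for i, mid in enumerate(frame.molecule_ids):
            lab = str(layers[i])
            if lab == "external":
                continue
            samples.setdefault(lab, []).append(graph.per_molecule_counts[int(mid)])
    rows = []
    for lab in partition.labels:
        if lab not in samples:
            continue
        arr = np.array(samples[lab], dtype=float)
        se = float(arr.std(ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else np.nan
        rows.append(
            {"layer": lab, "mean_nhb": float(arr.mean()), "se_nhb": se, "n_samples": len(arr)}
        )
    return pd.DataFrame(rows)


def hbond_type_fractions(
    traj: Trajectory,
    geom: PoreGeometry,
    partition: LayerPartition,
    source_layer: str,
    partner_layer: str,
    d_oo_max: float = D_OO_MAX,
    angle_max: float = ANGLE_MAX_DEG,
    radial_margin: float = 0.0,
    k_max: int = 4,
) -> Dict[int, float]:
    """Fraction of source-layer molecules engaging k bonds with the partner layer.

    k runs over 0..k_max (higher counts are folded into the top bin);
    fractions sum to 1 over all (frame, molecule) samples of the source
    layer.
    """
    occupation = np.zeros(k_max + 1)
    total = 0
    for frame in traj.frames:
        graph = detect_hbonds(frame, geom, partition, d_oo_max, angle_max, radial_margin)
        layers = _molecule_layers(frame, geom, partition, radial_margin)
        lab_by_id = {int(m): str(layers[i]) for i, m in enumerate(frame.molecule_ids)}
        k_by_id: Dict[int, int] = {
            int(m): 0 for m in frame.molecule_ids if lab_by_id[int(m)] == source_layer
        }
        for b in graph.bonds:
            for a, bb in ((b.donor_id, b.acceptor_id), (b.acceptor_id, b.donor_id)):
                if a in k_by_id and lab_by_id[bb] == partner_layer:
                    k_by_id[a] += 1
        for k in k_by_id.values():
            occupation[min(k, k_max)] += 1
            total += 1
    if total == 0:
        raise ValueError(f"no molecules found in source layer {source_layer!r}")
    return {k: float(occupation[k] / total) for k in range(k_max + 1)}


_NETWORK_HEADER = "# donor_id acceptor_id donor_hydrogen_index bond_type oo_distance angle_deg"


def export_network(graph: HBondGraph, path: str | Path) -> None:
    """Write the typed hydrogen-bond edge list as plain text."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# frame_time {graph.frame_time:.6f}\n")
        fh.write(_NETWORK_HEADER + "\n")
        for b in graph.bonds:
            fh.write(
                f"{b.donor_id} {b.acceptor_id} {b.donor_hydrogen_index} "
                f"{b.bond_type} {b.oo_distance:.6f} {b.angle_deg:.6f}\n"
            )


def read_network(path: str | Path) -> Tuple[float, List[HBond]]:
    """Re-parse an exported edge list (round-trips with export_network)."""
    path = Path(path)
    bonds: List[HBond] = []
    frame_time = 0.0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line.split()
                if len(parts) == 3 and parts[1] == "frame_time":
                    frame_time = float(parts[2])
                continue
            p = line.split()
            bonds.append(
                HBond(
                    donor_id=int(p[0]),
                    acceptor_id=int(p[1]),
                    donor_hydrogen_index=int(p[2]),
                    bond_type=p[3],
                    oo_distance=float(p[4]),
                    angle_deg=float(p[5]),
                )
            )
    return frame_time, bonds
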