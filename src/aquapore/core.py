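"""Domain types and trajectory I/O for confined-water analysis.

The package analyses rigid three-site water (one oxygen, two hydrogens per
molecule) confined in a finite cylindrical pore carved through a membrane
slab.  Everything downstream works in Å and ps; angles are reported in
degrees and handled in radians internally.

Two plain-text trajectory formats are supported:

* extended XYZ — per frame: an atom-count line, a comment line carrying
  ``Time=<ps>`` and ``Lattice="ax ay az bx by bz cx cy cz"``, then one
  ``species x y z`` line per atom.  Molecules are grouped by order: each
  oxygen is followed by its two hydrogens.
* column dump — per frame: a header ``FRAME <i> TIME <t> BOX <lx> <ly> <lz>``
  followed by one ``atom_id molecule_id species x y z`` line per atom.
  Molecules are grouped by their shared molecule id.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence

import numpy as np

logger = logging.getLogger("aquapore")

#: species labels accepted as water oxygen / hydrogen sites
OXYGEN_SPECIES = frozenset({"O", "OW"})
HYDROGEN_SPECIES = frozenset({"H", "HW", "H1", "H2"})

#: relative tolerance used for frame-spacing and slab-length consistency checks
TIME_RTOL = 1e-6
GEOMETRY_ATOL = 1e-6


class TrajectoryError(Exception):
    """Base class for trajectory loading/validation failures."""


class ParseError(TrajectoryError):
    """A frame header or atom line could not be parsed."""


class StructureError(TrajectoryError):
    """Frames are structurally inconsistent (atom counts, molecule sets)."""


class OrderingError(TrajectoryError):
    """Frame times are not strictly increasing with constant spacing."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WaterMolecule:
    """One rigid water: oxygen plus two hydrogens, positions in Å.

    Hydrogen positions are stored unwrapped relative to the oxygen, so a
    molecule is never broken across a periodic boundary.
    """

    molecule_id: int
    oxygen: np.ndarray
    hydrogen1: np.ndarray
    hydrogen2: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "oxygen", np.asarray(self.oxygen, dtype=float))
        object.__setattr__(self, "hydrogen1", np.asarray(self.hydrogen1, dtype=float))
        object.__setattr__(self, "hydrogen2", np.asarray(self.hydrogen2, dtype=float))
        d1 = float(np.linalg.norm(self.hydrogen1 - self.oxygen))
        d2 = float(np.linalg.norm(self.hydrogen2 - self.oxygen))
        if d1 <= 0.0 or d2 <= 0.0:
            raise ValueError(f"molecule {self.molecule_id}: O-H distance must be > 0")
        if np.allclose(self.hydrogen1, self.hydrogen2):
            raise ValueError(f"molecule {self.molecule_id}: hydrogens coincide")

    @property
    def oh_distances(self) -> tuple[float, float]:
        return (
            float(np.linalg.norm(self.hydrogen1 - self.oxygen)),
            float(np.linalg.norm(self.hydrogen2 - self.oxygen)),
        )

    @property
    def hoh_angle_deg(self) -> float:
        u = self.hydrogen1 - self.oxygen
        v = self.hydrogen2 - self.oxygen
        c = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
        return math.degrees(math.acos(max(-1.0, min(1.0, c))))


@dataclass
class Frame:
    """All water molecules of one stored time step.

    Site coordinates are held as (N, 3) arrays for vectorised analysis;
    :attr:`molecules` offers a per-molecule object view.
    """

    time: float
    box: np.ndarray  # 3 orthorhombic edge lengths, Å
    molecule_ids: np.ndarray  # (N,) int
    oxygens: np.ndarray  # (N, 3)
    hydrogens1: np.ndarray  # (N, 3)
    hydrogens2: np.ndarray  # (N, 3)

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float)
        self.molecule_ids = np.asarray(self.molecule_ids, dtype=int)
        self.oxygens = np.atleast_2d(np.asarray(self.oxygens, dtype=float))
        self.hydrogens1 = np.atleast_2d(np.asarray(self.hydrogens1, dtype=float))
        self.hydrogens2 = np.atleast_2d(np.asarray(self.hydrogens2, dtype=float))
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must hold 3 positive edge lengths")
        n = len(self.molecule_ids)
        if len(np.unique(self.molecule_ids)) != n:
            raise StructureError("molecule_ids not unique within frame")
        for arr in (self.oxygens, self.hydrogens1, self.hydrogens2):
            if arr.shape != (n, 3):
                raise ValueError("site array shape mismatch")

    @classmethod
    def from_molecules(
        cls, time: float, molecules: Sequence[WaterMolecule], box: Iterable[float]
    ) -> "Frame":
        if not molecules:
            raise ValueError("frame needs at least one molecule")
        return cls(
            time=time,
            box=np.asarray(list(box), dtype=float),
            molecule_ids=np.array([m.molecule_id for m in molecules]),
            oxygens=np.array([m.oxygen for m in molecules]),
            hydrogens1=np.array([m.hydrogen1 for m in molecules]),
            hydrogens2=np.array([m.hydrogen2 for m in molecules]),
        )

    @property
    def n_molecules(self) -> int:
        return len(self.molecule_ids)

    @property
    def molecules(self) -> List[WaterMolecule]:
        return [
            WaterMolecule(int(i), o, h1, h2)
            for i, o, h1, h2 in zip(
                self.molecule_ids, self.oxygens, self.hydrogens1, self.hydrogens2
            )
        ]

    def sorted_by_id(self) -> "Frame":
        order = np.argsort(self.molecule_ids, kind="stable")
        return Frame(
            time=self.time,
            box=self.box,
            molecule_ids=self.molecule_ids[order],
            oxygens=self.oxygens[order],
            hydrogens1=self.hydrogens1[order],
            hydrogens2=self.hydrogens2[order],
        )


@dataclass
class Trajectory:
    """Time-ordered sequence of frames with constant spacing (ps)."""

    frames: List[Frame]
    frame_spacing: float

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("trajectory has no frames")
        times = np.array([f.time for f in self.frames])
        if len(times) > 1:
            dt = np.diff(times)
            if np.any(dt <= 0):
                raise OrderingError("frame times not strictly increasing")
            ref = self.frame_spacing
            if not np.allclose(dt, ref, rtol=1e-4, atol=1e-9):
                raise OrderingError("frame spacing not constant")
        ids0 = frozenset(int(i) for i in self.frames[0].molecule_ids)
        for k, f in enumerate(self.frames[1:], start=1):
            if frozenset(int(i) for i in f.molecule_ids) != ids0:
                raise StructureError(f"frame {k}: molecule id set differs from frame 0")

    @classmethod
    def from_frames(cls, frames: Sequence[Frame]) -> "Trajectory":
        frames = list(frames)
        if not frames:
            raise ValueError("trajectory has no frames")
        spacing = frames[1].time - frames[0].time if len(frames) > 1 else 1.0
        return cls(frames=frames, frame_spacing=float(spacing))

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])


@dataclass
class CurveSeries:
    """Generic (abscissa, value, count) table for profiles and curves."""

    x: np.ndarray
    y: np.ndarray
    counts: np.ndarray
    x_label: str = "x"
    y_label: str = "y"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.counts = np.asarray(self.counts)
        if not (len(self.x) == len(self.y) == len(self.counts)):
            raise ValueError("x, y and counts must have equal length")


@dataclass
class PoreGeometry:
    """Cylindrical pore through a membrane slab, plus run metadata.

    The pore axis runs along ``axis_direction`` through ``axis_origin``;
    after the affine transform to the pore frame the axis is the z-axis and
    the membrane occupies ``membrane_z_min <= z <= membrane_z_max``.
    ``lattice_parameter_a`` (Å), ``hydrophobicity_c``, ``contact_angle_deg``
    and ``temperature_K`` are carried as metadata only.
    """

    radius_R: float
    length_L: float
    axis_origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axis_direction: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    membrane_z_min: Optional[float] = None
    membrane_z_max: Optional[float] = None
    lattice_parameter_a: float = 3.5
    hydrophobicity_c: float = 1.0
    contact_angle_deg: Optional[float] = None
    temperature_K: Optional[float] = None

    def __post_init__(self) -> None:
        self.axis_origin = np.asarray(self.axis_origin, dtype=float)
        self.axis_direction = np.asarray(self.axis_direction, dtype=float)
        if self.radius_R <= 0:
            raise ValueError("radius_R must be > 0")
        norm = float(np.linalg.norm(self.axis_direction))
        if not math.isclose(norm, 1.0, rel_tol=1e-6):
            raise ValueError("axis_direction must have unit norm")
        self.axis_direction = self.axis_direction / norm
        if self.membrane_z_min is None:
            self.membrane_z_min = -self.length_L / 2.0
        if self.membrane_z_max is None:
            self.membrane_z_max = self.length_L / 2.0
        if not math.isclose(
            self.membrane_z_max - self.membrane_z_min, self.length_L,
            rel_tol=1e-6, abs_tol=GEOMETRY_ATOL,
        ):
            raise ValueError("membrane slab extent must equal length_L")
        self._rotation = _rotation_to_z(self.axis_direction)

    @property
    def rotation(self) -> np.ndarray:
        """Lab-to-pore-frame rotation matrix (rows u, v, axis)."""
        return self._rotation

    @property
    def membrane_z_mid(self) -> float:
        return 0.5 * (self.membrane_z_min + self.membrane_z_max)

    def to_pore_frame(self, points: np.ndarray) -> np.ndarray:
        """Map lab-frame points (…, 3) into the pore frame (axis = z)."""
        p = np.asarray(points, dtype=float) - self.axis_origin
        return p @ self._rotation.T


def _rotation_to_z(direction: np.ndarray) -> np.ndarray:
    """Orthonormal matrix whose third row is ``direction``."""
    w = direction / np.linalg.norm(direction)
    seed = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(seed, w)) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    u = seed - np.dot(seed, w) * w
    u /= np.linalg.norm(u)
    v = np.cross(w, u)
    return np.vstack([u, v, w])


def minimum_image(displacement: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap a displacement vector (…, 3) into the nearest periodic image."""
    d = np.asarray(displacement, dtype=float)
    return d - box * np.round(d / box)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_LATTICE_RE = re.compile(r'Lattice\s*=\s*"([^"]+)"|Lattice\s*=\s*(\S+)')
_TIME_RE = re.compile(r"Time\s*=\s*([-+0-9.eE]+)")


def read_trajectory(
    path: str | Path,
    format: str = "extended_xyz",
    topology_rule: str = "auto",
) -> Trajectory:
    """Load a trajectory from an extended-XYZ file or a column dump.

    ``topology_rule`` selects how atoms are grouped into molecules:
    ``"order"`` (each O with the two H lines that follow it), ``"id"``
    (atoms sharing a molecule id), or ``"auto"`` (order for extended XYZ,
    id for the dump).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "extended_xyz":
        rule = "order" if topology_rule == "auto" else topology_rule
        frames = _read_xyz_frames(path, rule)
    elif format == "column_dump":
        rule = "id" if topology_rule == "auto" else topology_rule
        frames = _read_dump_frames(path, rule)
    else:
        raise ValueError(f"unknown format {format!r}")
    if not frames:
        raise ParseError(f"{path}: no frames found")
    counts = {f.n_molecules for f in frames}
    if len(counts) > 1:
        raise StructureError(f"{path}: molecule count varies across frames: {sorted(counts)}")
    return Trajectory.from_frames(frames)


def _unwrap_sites(oxy: np.ndarray, hyd: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Place hydrogen next to its oxygen through the nearest image."""
    return oxy + minimum_image(hyd - oxy, box)


def _group_by_order(
    species: List[str], coords: np.ndarray, box: np.ndarray, frame_index: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    n = len(species)
    if n % 3 != 0:
        raise StructureError(f"frame {frame_index}: {n} atoms not divisible by 3")
    ids, oxy, h1, h2 = [], [], [], []
    i = 0
    mol = 0
    while i < n:
        s0, s1, s2 = species[i], species[i + 1], species[i + 2]
        if s0 not in OXYGEN_SPECIES or s1 not in HYDROGEN_SPECIES or s2 not in HYDROGEN_SPECIES:
            raise StructureError(
                f"frame {frame_index}: atoms {i}..{i+2} not an O,H,H triple "
                f"({s0},{s1},{s2})"
            )
        o = coords[i]
        ids.append(mol)
        oxy.append(o)
        h1.append(_unwrap_sites(o, coords[i + 1], box))
        h2.append(_unwrap_sites(o, coords[i + 2], box))
        mol += 1
        i += 3
    return np.array(ids), np.array(oxy), np.array(h1), np.array(h2)


def _group_by_id(
    mol_ids: List[int], species: List[str], coords: np.ndarray, box: np.ndarray, frame_index: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    groups: dict[int, dict[str, list]] = {}
    for mid, sp, xyz in zip(mol_ids, species, coords):
        g = groups.setdefault(mid, {"O": [], "H": []})
        if sp in OXYGEN_SPECIES:
            g["O"].append(xyz)
        elif sp in HYDROGEN_SPECIES:
            g["H"].append(xyz)
        else:
            raise StructureError(f"frame {frame_index}: unknown species {sp!r}")
    ids, oxy, h1, h2 = [], [], [], []
    for mid in sorted(groups):
        g = groups[mid]
        if len(g["O"]) != 1 or len(g["H"]) != 2:
            raise StructureError(
                f"frame {frame_index}: molecule {mid} is not one O plus two H"
            )
        o = np.asarray(g["O"][0])
        ids.append(mid)
        oxy.append(o)
        h1.append(_unwrap_sites(o, np.asarray(g["H"][0]), box))
        h2.append(_unwrap_sites(o, np.asarray(g["H"][1]), box))
    return np.array(ids), np.array(oxy), np.array(h1), np.array(h2)


def _read_xyz_frames(path: Path, rule: str) -> List[Frame]:
    frames: List[Frame] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos = 0
    index = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n_atoms = int(lines[pos].strip())
        except ValueError as exc:
            raise ParseError(f"frame {index}: bad atom-count line {lines[pos]!r}") from exc
        if pos + 1 >= len(lines):
            raise ParseError(f"frame {index}: missing comment line")
        comment = lines[pos + 1]
        tm = _TIME_RE.search(comment)
        lm = _LATTICE_RE.search(comment)
        if tm is None or lm is None:
            raise ParseError(f"frame {index}: comment lacks Time=/Lattice=")
        time = float(tm.group(1))
        lat = np.array([float(x) for x in (lm.group(1) or lm.group(2)).split()])
        if lat.size != 9:
            raise ParseError(f"frame {index}: Lattice needs 9 reals")
        lat = lat.reshape(3, 3)
        if not np.allclose(lat, np.diag(np.diag(lat))):
            raise ParseError(f"frame {index}: only orthorhombic lattices supported")
        box = np.diag(lat).copy()
        body = lines[pos + 2 : pos + 2 + n_atoms]
        if len(body) < n_atoms:
            raise ParseError(f"frame {index}: truncated frame body")
        species: List[str] = []
        coords = np.empty((n_atoms, 3))
        for k, line in enumerate(body):
            parts = line.split()
            if len(parts) < 4:
                raise ParseError(f"frame {index}: bad atom line {line!r}")
            species.append(parts[0])
            coords[k] = [float(parts[1]), float(parts[2]), float(parts[3])]
        if rule == "order":
            ids, oxy, h1, h2 = _group_by_order(species, coords, box, index)
        else:
            ids, oxy, h1, h2 = _group_by_id(list(range(len(species))), species, coords, box, index)
        frames.append(Frame(time, box, ids, oxy, h1, h2))
        pos += 2 + n_atoms
        index += 1
    return frames


def _read_dump_frames(path: Path, rule: str) -> List[Frame]:
    frames: List[Frame] = []
    with open(path) as fh:
        lines = [ln for ln in fh.read().splitlines() if ln.strip()]
    pos = 0
    index = 0
    while pos < len(lines):
        parts = lines[pos].split()
        if len(parts) != 8 or parts[0] != "FRAME" or parts[2] != "TIME" or parts[4] != "BOX":
            raise ParseError(f"frame {index}: bad header {lines[pos]!r}")
        try:
            time = float(parts[3])
            box = np.array([float(parts[5]), float(parts[6]), float(parts[7])])
        except ValueError as exc:
            raise ParseError(f"frame {index}: bad header numbers") from exc
        pos += 1
        mol_ids: List[int] = []
        species: List[str] = []
        rows: List[List[float]] = []
        while pos < len(lines) and not lines[pos].startswith("FRAME"):
            aparts = lines[pos].split()
            if len(aparts) != 6:
                raise ParseError(f"frame {index}: bad atom line {lines[pos]!r}")
            mol_ids.append(int(aparts[1]))
            species.append(aparts[2])
            rows.append([float(aparts[3]), float(aparts[4]), float(aparts[5])])
            pos += 1
        coords = np.array(rows)
        if len(species) % 3 != 0:
            raise StructureError(f"frame {index}: {len(species)} atoms not divisible by 3")
        if rule == "id":
            ids, oxy, h1, h2 = _group_by_id(mol_ids, species, coords, box, index)
        else:
            ids, oxy, h1, h2 = _group_by_order(species, coords, box, index)
        frames.append(Frame(time, box, ids, oxy, h1, h2))
        index += 1
    return frames


def write_trajectory(
    traj: Trajectory,
    path: str | Path,
    format: str = "extended_xyz",
    precision: int = 6,
) -> None:
    """Write a trajectory; round-trips through :func:`read_trajectory`."""
    path = Path(path)
    fmt = f"{{:.{precision}f}}"

    def c3(v: np.ndarray) -> str:
        return " ".join(fmt.format(x) for x in v)

    with open(path, "w") as fh:
        for findex, frame in enumerate(traj.frames):
            f = frame.sorted_by_id()
            if format == "extended_xyz":
                lx, ly, lz = f.box
                fh.write(f"{3 * f.n_molecules}\n")
                fh.write(
                    f'Time={f.time:.6f} Lattice="{lx:.6f} 0 0 0 {ly:.6f} 0 0 0 {lz:.6f}"\n'
                )
                for o, h1, h2 in zip(f.oxygens, f.hydrogens1, f.hydrogens2):
                    fh.write(f"O {c3(o)}\nH {c3(h1)}\nH {c3(h2)}\n")
            elif format == "column_dump":
                fh.write(
                    f"FRAME {findex} TIME {f.time:.6f} "
                    f"BOX {f.box[0]:.6f} {f.box[1]:.6f} {f.box[2]:.6f}\n"
                )
                aid = 0
                for mid, o, h1, h2 in zip(f.molecule_ids, f.oxygens, f.hydrogens1, f.hydrogens2):
                    for sp, v in (("O", o), ("H", h1), ("H", h2)):
                        fh.write(f"{aid} {mid} {sp} {c3(v)}\n")
                        aid += 1
            else:
                raise ValueError(f"unknown format {format!r}")


def validate_geometry(geom: PoreGeometry, frame: Frame) -> List[str]:
    """Report-only consistency check of a pore geometry against one frame.

    Returns a (possibly empty) list of human-readable warnings: the membrane
    slab poking out of the box, or oxygens outside the box.
    """
    report: List[str] = []
    # slab bounds in pore frame; compare against box extent along the axis
    box_axis = float(np.dot(np.abs(geom.axis_direction), frame.box))
    if geom.membrane_z_max > box_axis / 2 or geom.membrane_z_min < -box_axis / 2:
        report.append("membrane slab extends beyond the simulation box")
    # oxygens are stored in lab coordinates; accept wrapped [0, box) or centred boxes
    oxy = frame.oxygens
    outside = np.any((oxy < -frame.box / 2 - 1e-9) | (oxy > frame.box + 1e-9), axis=1)
    for mid in frame.molecule_ids[outside]:
        report.append(f"molecule {int(mid)}: oxygen outside the box")
    return report


def validate_rigidity(traj: Trajectory, tol_distance: float = 1e-3, tol_angle_deg: float = 0.1) -> List[str]:
    """Check that O-H distances and the H-O-H angle are constant over time.

    Optional validation (not enforced on load); returns warnings for
    molecules whose internal geometry drifts beyond the tolerances.
    """
    report: List[str] = []
    ref = {}
    for m in traj.frames[0].molecules:
        ref[m.molecule_id] = (m.oh_distances, m.hoh_angle_deg)
    for k, frame in enumerate(traj.frames[1:], start=1):
        for m in frame.molecules:
            (d1, d2), ang = ref[m.molecule_id]
            e1, e2 = m.oh_distances
            if abs(e1 - d1) > tol_distance or abs(e2 - d2) > tol_distance:
                report.append(f"molecule {m.molecule_id}: O-H distance drift at frame {k}")
            elif abs(m.hoh_angle_deg - ang) > tol_angle_deg:
                report.append(f"molecule {m.molecule_id}: H-O-H angle drift at frame {k}")
    return report
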