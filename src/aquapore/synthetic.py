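"""Synthetic trajectory generators with known ground truth.

Every analysis stage in this package is validated against trajectories
whose statistical structure is known exactly.  The generators emulate the
phenomenology of water in a finite cylindrical pore — concentric density
layers ~2.5 Å thick, orientational bias at the wall, tetrahedral versus
random four-neighbour arrangements, diffusion with exchange into
reservoirs — without any claim of physical realism: molecules do not
interact except where a fixture prescribes exact geometry.

Molecules are emitted with a rigid internal geometry (O-H 1.0 Å, H-O-H
109.47 deg) so that orientation and hydrogen-bond operators receive
realistic three-site waters; these are generator constants, not force-field
parameters.

Generator kinds
---------------
uniform_gas      independent uniform positions/orientations per frame
layered_shells   Gaussian radial shells, optional axial modulation and
                 tangential wall orientation bias
brownian_pore    Euler-Maruyama diffusion with specular reflection and
                 optional memoryless escape into static reservoirs
tetra_fixture    exact regular-tetrahedron and collinear 5-molecule clusters
hbond_fixture    dimers/trimers straddling the hydrogen-bond criterion
lattice_fixture  proton-ordered diamond (ice-Ic-like) lattice, n_HB = 4
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Dict, List, Optional, Tuple

import numpy as np

from .core import Frame, PoreGeometry, Trajectory

GENERATOR_KINDS = (
    "uniform_gas",
    "layered_shells",
    "brownian_pore",
    "tetra_fixture",
    "hbond_fixture",
    "lattice_fixture",
)

#: rigid internal water geometry used by all generators (Å, degrees)
OH_LENGTH = 1.0
HOH_ANGLE_DEG = 109.47


@dataclass
class GeneratorSpec:
    """Recipe for one synthetic trajectory.

    ``params`` carries kind-specific knobs (shell radii/widths, diffusivity
    D, escape probability, axial modulation periods, orientation bias, wall
    reflection).  A fixed seed yields byte-identical output.
    """

    kind: str
    n_molecules: int = 500
    n_frames: int = 50
    frame_spacing: float = 1.0  # ps
    seed: int = 0
    geometry: Optional[PoreGeometry] = None
    params: Dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in GENERATOR_KINDS:
            raise ValueError(f"unknown generator kind {self.kind!r}")
        if self.n_molecules <= 0:
            raise ValueError("n_molecules must be > 0")
        if self.n_frames <= 0:
            raise ValueError("n_frames must be > 0")


def default_geometry(radius_R: float = 7.0, length_L: float = 26.0) -> PoreGeometry:
    """Small-pore study geometry: R = 7 Å, L = 26 Å, axis along z."""
    return PoreGeometry(radius_R=radius_R, length_L=length_L)


def _default_box(geom: PoreGeometry, reservoir_depth: float = 8.0) -> np.ndarray:
    lateral = 2.0 * (geom.radius_R + 3.0)
    return np.array([lateral, lateral, geom.length_L + 2.0 * reservoir_depth])


def _lab_origin(box: np.ndarray) -> np.ndarray:
    """Pore-frame origin placed at the box centre (lab coordinates)."""
    return box / 2.0


# ---------------------------------------------------------------------------
# rigid-water site construction
# ---------------------------------------------------------------------------


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def random_unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return _unit(v)


def _perpendicular_unit(b: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=b.shape)
    v -= np.einsum("ij,ij->i", v, b)[:, None] * b
    return _unit(v)


def water_sites(
    oxygens: np.ndarray, bisectors: np.ndarray, normals: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Hydrogen sites from oxygen positions, unit bisectors and unit normals.

    The bisector points from the oxygen toward the hydrogen side; the
    normal spans the molecular plane.
    """
    half = math.radians(HOH_ANGLE_DEG) / 2.0
    h1 = oxygens + OH_LENGTH * (math.cos(half) * bisectors + math.sin(half) * normals)
    h2 = oxygens + OH_LENGTH * (math.cos(half) * bisectors - math.sin(half) * normals)
    return h1, h2


def _random_waters(
    oxygens: np.ndarray, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    b = random_unit_vectors(rng, len(oxygens))
    n = _perpendicular_unit(b, rng)
    return water_sites(oxygens, b, n)


# ---------------------------------------------------------------------------
# kind-specific generators
# ---------------------------------------------------------------------------


def _uniform_cylinder(
    rng: np.random.Generator, n: int, radius: float, z_lo: float, z_hi: float
) -> np.ndarray:
    r = radius * np.sqrt(rng.uniform(size=n))
    phi = rng.uniform(0.0, 2.0 * math.pi, size=n)
    z = rng.uniform(z_lo, z_hi, size=n)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _gen_uniform_gas(spec: GeneratorSpec, geom: PoreGeometry, rng: np.random.Generator):
    """Ideal gas: independent uniform positions and orientations per frame.

    ``fill="pore"`` (default) places all molecules inside the pore volume,
    giving a flat radial profile at N/(pi R^2 L).  ``fill="box"`` spreads
    them over the whole box, so in-pore molecules see isotropic
    neighbourhoods even at the wall and the pore mouths (the ideal-gas
    anchors <q> = 0 and <|cos beta|> = 2/pi then hold without boundary
    bias).
    """
    fill = spec.params.get("fill", "pore")
    box = _default_box(geom, spec.params.get("reservoir_depth", 8.0))
    origin = _lab_origin(box)
    frames = []
    for k in range(spec.n_frames):
        if fill == "box":
            oxy = rng.uniform(0.0, 1.0, size=(spec.n_molecules, 3)) * box
        elif fill == "pore":
            pore_pos = _uniform_cylinder(
                rng, spec.n_molecules, geom.radius_R,
                geom.membrane_z_min, geom.membrane_z_max,
            )
            oxy = pore_pos + origin
        else:
            raise ValueError(f"unknown fill {fill!r}")
        h1, h2 = _random_waters(oxy, rng)
        frames.append(
            Frame(k * spec.frame_spacing, box, np.arange(spec.n_molecules), oxy, h1, h2)
        )
    volume = (
        float(np.prod(box))
        if fill == "box"
        else math.pi * geom.radius_R**2 * geom.length_L
    )
    truth = {
        "density": spec.n_molecules / volume,
        "mean_cos_beta": 0.0,
        "mean_abs_cos_beta": 2.0 / math.pi,
        "mean_q": 0.0,
        "fill": fill,
    }
    return frames, box, origin, truth


def _gen_layered_shells(spec: GeneratorSpec, geom: PoreGeometry, rng: np.random.Generator):
    p = spec.params
    shell_radii = np.asarray(p.get("shell_radii", [0.0, 4.0, 7.5]), dtype=float)
    if np.any(shell_radii > geom.radius_R + p.get("radial_margin", 1.0)):
        raise ValueError("shell radius exceeds the pore radius")
    widths = np.broadcast_to(
        np.asarray(p.get("shell_widths", 0.5), dtype=float), shell_radii.shape
    ).copy()
    weights = p.get("shell_weights")
    if weights is None:
        # populate shells in proportion to their circumference (area per length)
        weights = np.maximum(shell_radii, widths)
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    axial_periods = p.get("axial_periods")  # modulate the outermost shell only
    modulation_depth = p.get("modulation_depth", 0.8)
    bias = p.get("orientation_bias")  # None or {"sigma": ...} tangential bias
    counts = rng.multinomial(spec.n_molecules, weights)
    box = _default_box(geom, p.get("reservoir_depth", 8.0))
    origin = _lab_origin(box)
    L = geom.length_L
    frames = []
    for k in range(spec.n_frames):
        parts = []
        tangential_mask = []
        for s, (r0, w, m) in enumerate(zip(shell_radii, widths, counts)):
            if m == 0:
                continue
            if r0 < 1e-9:
                xy = rng.normal(scale=w, size=(m, 2))
            else:
                r = rng.normal(loc=r0, scale=w, size=m)
                r = np.abs(r)
                phi = rng.uniform(0.0, 2.0 * math.pi, size=m)
                xy = np.column_stack([r * np.cos(phi), r * np.sin(phi)])
            if s == len(shell_radii) - 1 and axial_periods:
                z = _sample_modulated_z(rng, m, L, int(axial_periods), modulation_depth)
            else:
                z = rng.uniform(-L / 2.0, L / 2.0, size=m)
            parts.append(np.column_stack([xy, z]))
            tangential_mask.append(
                np.full(m, bool(bias) and s == len(shell_radii) - 1)
            )
        pos = np.concatenate(parts)
        tangential = np.concatenate(tangential_mask)
        oxy = pos + origin
        b = random_unit_vectors(rng, len(oxy))
        if np.any(tangential):
            phi_hat = _unit(np.column_stack([-pos[:, 1], pos[:, 0], np.zeros(len(pos))]))
            sign = rng.choice([-1.0, 1.0], size=len(pos))[:, None]
            sigma = float(bias.get("sigma", 0.0)) if isinstance(bias, dict) else 0.0
            noisy = phi_hat * sign + sigma * rng.normal(size=pos.shape)
            b[tangential] = _unit(noisy)[tangential]
        n = _perpendicular_unit(b, rng)
        h1, h2 = water_sites(oxy, b, n)
        frames.append(
            Frame(k * spec.frame_spacing, box, np.arange(len(oxy)), oxy, h1, h2)
        )
    truth = {
        "shell_radii": shell_radii.tolist(),
        "shell_widths": widths.tolist(),
        "shell_fractions": (counts / counts.sum()).tolist(),
        "axial_periods": axial_periods,
        "tangential_bias": bool(bias),
    }
    return frames, box, origin, truth


def _sample_modulated_z(
    rng: np.random.Generator, n: int, L: float, periods: int, depth: float
) -> np.ndarray:
    """Rejection-sample z from density 1 + depth*cos(2*pi*k*z/L + pi).

    The pi phase puts the k density maxima at z = (m - 1/2) L / k, all
    interior to the slab, so exactly k peaks appear along the pore.
    """
    out = np.empty(0)
    while len(out) < n:
        z = rng.uniform(-L / 2.0, L / 2.0, size=2 * n)
        accept = rng.uniform(0.0, 1.0 + depth, size=2 * n) <= 1.0 - depth * np.cos(
            2.0 * math.pi * periods * z / L
        )
        out = np.concatenate([out, z[accept]])
    return out[:n]


def _gen_brownian_pore(spec: GeneratorSpec, geom: PoreGeometry, rng: np.random.Generator):
    p = spec.params
    D = float(p.get("D", 0.2))  # Å^2/ps
    escape_p = float(p.get("escape_probability", 0.0))
    reflecting = bool(p.get("reflecting_walls", True))
    reservoir_depth = float(p.get("reservoir_depth", 8.0))
    box = _default_box(geom, reservoir_depth)
    origin = _lab_origin(box)
    R, L = geom.radius_R, geom.length_L
    n = spec.n_molecules
    pos = _uniform_cylinder(rng, n, R, -L / 2.0, L / 2.0)
    in_pore = np.ones(n, dtype=bool)
    sigma = math.sqrt(2.0 * D * spec.frame_spacing)
    # frozen random orientation: molecules translate rigidly
    b = random_unit_vectors(rng, n)
    nrm = _perpendicular_unit(b, rng)
    frames = []
    for k in range(spec.n_frames):
        oxy = pos + origin
        h1, h2 = water_sites(oxy, b, nrm)
        frames.append(Frame(k * spec.frame_spacing, box, np.arange(n), oxy, h1, h2))
        # advance in-pore molecules; reservoir molecules are static
        step = sigma * rng.normal(size=(n, 3))
        new = pos.copy()
        new[in_pore] += step[in_pore]
        if reflecting:
            new[in_pore] = _confine_cylinder(pos[in_pore], new[in_pore], R, L)
        if escape_p > 0.0:
            esc = in_pore & (rng.uniform(size=n) < escape_p)
            ret = (~in_pore) & (rng.uniform(size=n) < escape_p)
            if np.any(esc):
                new[esc] = _reservoir_positions(rng, int(esc.sum()), box, L, origin)
            if np.any(ret):
                new[ret] = _uniform_cylinder(rng, int(ret.sum()), R, -L / 2.0, L / 2.0)
            in_pore = (in_pore & ~esc) | ret
        pos = new
    truth = {
        "D": D,
        "escape_probability": escape_p,
        "plateau_xy": R**2,
        "plateau_z": L**2 / 6.0,
    }
    return frames, box, origin, truth


def _confine_cylinder(old: np.ndarray, new: np.ndarray, R: float, L: float) -> np.ndarray:
    """Keep proposed positions inside the cylinder.

    Axial faces: exact mirror reflection (measure-preserving in 1D).
    Radial wall: Metropolis-style rejection — a move whose endpoint leaves
    r <= R is discarded and the molecule keeps its previous position.  With
    a symmetric Gaussian proposal this leaves the uniform distribution over
    the cylinder exactly stationary, so the long-time displacement plateaus
    attain their closed forms (R^2 planar, L^2/6 axial) without the
    curvature bias an endpoint-mirroring rule introduces at finite step
    size.
    """
    out = new.copy()
    for _ in range(8):  # repeated mirror for rare multi-length steps
        zlo = out[:, 2] < -L / 2.0
        zhi = out[:, 2] > L / 2.0
        if not (np.any(zlo) or np.any(zhi)):
            break
        out[zlo, 2] = -L - out[zlo, 2]
        out[zhi, 2] = L - out[zhi, 2]
    np.clip(out[:, 2], -L / 2.0, L / 2.0, out=out[:, 2])
    reject = np.hypot(out[:, 0], out[:, 1]) > R
    out[reject] = old[reject]
    return out


def _reservoir_positions(
    rng: np.random.Generator, n: int, box: np.ndarray, L: float, origin: np.ndarray
) -> np.ndarray:
    """Uniform positions in the two reservoir slabs (pore-frame coordinates)."""
    depth = (box[2] - L) / 2.0
    side = rng.choice([-1.0, 1.0], size=n)
    z = side * (L / 2.0 + rng.uniform(0.5, max(0.6, depth - 0.5), size=n))
    x = rng.uniform(-box[0] / 2.0 + 0.5, box[0] / 2.0 - 0.5, size=n)
    y = rng.uniform(-box[1] / 2.0 + 0.5, box[1] / 2.0 - 0.5, size=n)
    return np.column_stack([x, y, z])


def _gen_tetra_fixture(spec: GeneratorSpec, geom: PoreGeometry, rng: np.random.Generator):
    """Exact regular-tetrahedron clusters (q = 1) and collinear clusters (q = -3).

    Clusters of five molecules (centre + four neighbours) are placed far
    apart so each centre's four nearest neighbours are its own cluster.
    Tetrahedral clusters sit near the axis (inner layer), collinear ones in
    the contact band.
    """
    from .tetrahedrality import regular_tetrahedron_vertices

    p = spec.params
    bond = float(p.get("bond_length", 2.8))
    n_tetra = int(p.get("n_tetra", 2))
    n_collinear = int(p.get("n_collinear", 2))
    box = _default_box(geom, p.get("reservoir_depth", 8.0))
    origin = _lab_origin(box)
    L = geom.length_L
    n_clusters = n_tetra + n_collinear
    # interleaved axial slots keep clusters far enough apart that each
    # centre's four nearest neighbours are its own cluster members
    centres_z = np.linspace(-L / 2.0 + 4.0, L / 2.0 - 4.0, max(n_clusters, 1))
    oxy: List[np.ndarray] = []
    kinds: List[str] = []
    centre_ids: List[int] = []
    contact_r = min(geom.radius_R - 1.0, geom.radius_R * 0.8)
    for i in range(n_tetra):
        c = np.array([0.0, 0.0, centres_z[i]])
        cluster = np.vstack([c, c + regular_tetrahedron_vertices(bond)])
        centre_ids.append(len(oxy))
        kinds.append("tetrahedral")
        oxy.extend(cluster)
    for i in range(n_collinear):
        phi = 2.0 * math.pi * i / max(n_collinear, 1) + math.pi / max(n_collinear, 1)
        z = centres_z[n_tetra + i]
        c = np.array([contact_r * math.cos(phi), contact_r * math.sin(phi), z])
        direction = np.array([-math.sin(phi), math.cos(phi), 0.0])  # tangential
        cluster = np.vstack([c] + [c + d * direction for d in (2.0, 2.3, 2.6, 2.9)])
        centre_ids.append(len(oxy))
        kinds.append("collinear")
        oxy.extend(cluster)
    oxy_arr = np.asarray(oxy) + origin
    h1, h2 = _random_waters(oxy_arr, rng)
    frames = [
        Frame(k * spec.frame_spacing, box, np.arange(len(oxy_arr)), oxy_arr, h1, h2)
        for k in range(spec.n_frames)
    ]
    truth = {
        "centre_molecule_ids": centre_ids,
        "centre_kinds": kinds,
        "expected_q": {"tetrahedral": 1.0, "collinear": -3.0},
        "n_molecules": len(oxy_arr),
    }
    return frames, box, origin, truth


def _place_dimer(
    base: np.ndarray, d_oo: float, angle_deg: float
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Donor+acceptor waters with exact O-O distance and donor OH-OO angle.

    Returns (oxygens(2,3), h1(2,3), h2(2,3)); the acceptor's hydrogens point
    perpendicular to the O-O axis so it never donates back.
    """
    x, y, z = np.eye(3)
    o_d = base
    o_a = base + d_oo * x
    a = math.radians(angle_deg)
    h1_d = o_d + OH_LENGTH * (math.cos(a) * x + math.sin(a) * y)
    # second donor hydrogen at the rigid H-O-H angle from the first, tilted
    # out of plane so its angle to the O-O axis is far beyond the cutoff
    hoh = math.radians(HOH_ANGLE_DEG)
    d2 = math.cos(hoh) * (math.cos(a) * x + math.sin(a) * y) + math.sin(hoh) * z
    h2_d = o_d + OH_LENGTH * d2
    # acceptor hydrogens in the y-z plane: 90 deg from both O-O directions
    half = hoh / 2.0
    h1_a = o_a + OH_LENGTH * (math.cos(half) * y + math.sin(half) * z)
    h2_a = o_a + OH_LENGTH * (math.cos(half) * y - math.sin(half) * z)
    return np.vstack([o_d, o_a]), np.vstack([h1_d, h1_a]), np.vstack([h2_d, h2_a])


def _gen_hbond_fixture(spec: GeneratorSpec, geom: PoreGeometry, rng: np.random.Generator):
    """Dimers straddling each boundary of the geometric H-bond criterion."""
    del rng
    cases = spec.params.get(
        "cases",
        [
            {"d_oo": 2.8, "angle": 10.0, "bonded": True},
            {"d_oo": 3.6, "angle": 0.0, "bonded": False},
            {"d_oo": 3.0, "angle": 35.0, "bonded": False},
            {"d_oo": 3.0, "angle": 30.0, "bonded": True},
            {"d_oo": 3.5, "angle": 0.0, "bonded": True},
        ],
    )
    box = _default_box(geom, spec.params.get("reservoir_depth", 8.0))
    origin = _lab_origin(box)
    L = geom.length_L
    zs = np.linspace(-L / 2.0 + 2.0, L / 2.0 - 2.0, len(cases))
    oxy, h1s, h2s = [], [], []
    expected = 0
    pair_ids = []
    for case, z in zip(cases, zs):
        base = np.array([-2.0, 0.0, z])  # dimers lie inside the pore
        o, h1, h2 = _place_dimer(base, case["d_oo"], case["angle"])
        pair_ids.append((len(oxy), len(oxy) + 1, bool(case["bonded"])))
        if case["bonded"]:
            expected += 1
        oxy.extend(o)
        h1s.extend(h1)
        h2s.extend(h2)
    oxy_arr = np.asarray(oxy) + origin
    frames = [
        Frame(
            k * spec.frame_spacing,
            box,
            np.arange(len(oxy_arr)),
            oxy_arr,
            np.asarray(h1s) + origin,
            np.asarray(h2s) + origin,
        )
        for k in range(spec.n_frames)
    ]
    truth = {
        "cases": cases,
        "pairs": [[d, a, b] for d, a, b in pair_ids],
        "expected_bonds_per_frame": expected,
        "n_molecules": len(oxy_arr),
    }
    return frames, box, origin, truth


def _gen_lattice_fixture(spec: GeneratorSpec, geom: PoreGeometry, rng: np.random.Generator):
    """Proton-ordered diamond-cubic water lattice; every molecule has n_HB = 4.

    Oxygens occupy a diamond lattice with nearest-neighbour distance
    ``nn_distance``; each molecule donates along two of its four bonds and
    accepts along the other two (ice-rule-consistent ordered assignment),
    so under the 3.5 Å / 30 deg criterion every molecule engages exactly
    four hydrogen bonds, with full periodicity.
    """
    del rng
    p = spec.params
    nn = float(p.get("nn_distance", 2.75))
    cells = int(p.get("cells", 2))
    a = 4.0 * nn / math.sqrt(3.0)
    fcc = np.array([[0, 0, 0], [0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]])
    basis_a = fcc * a
    basis_b = basis_a + a / 4.0
    d_all = (a / 4.0) * np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
    )
    oxy, h1s, h2s = [], [], []
    for i in range(cells):
        for j in range(cells):
            for k in range(cells):
                shift = a * np.array([i, j, k], dtype=float)
                for site in basis_a:
                    o = site + shift
                    oxy.append(o)  # A sublattice donates along d1, d2
                    h1s.append(o + OH_LENGTH * _unit(d_all[0]))
                    h2s.append(o + OH_LENGTH * _unit(d_all[1]))
                for site in basis_b:
                    o = site + shift
                    oxy.append(o)  # B sublattice donates along -d3, -d4
                    h1s.append(o + OH_LENGTH * _unit(-d_all[2]))
                    h2s.append(o + OH_LENGTH * _unit(-d_all[3]))
    box = np.array([a * cells] * 3)
    oxy_arr = np.mod(np.asarray(oxy), box)
    h1_arr = oxy_arr + (np.asarray(h1s) - np.asarray(oxy))
    h2_arr = oxy_arr + (np.asarray(h2s) - np.asarray(oxy))
    frames = [
        Frame(k * spec.frame_spacing, box, np.arange(len(oxy_arr)), oxy_arr, h1_arr, h2_arr)
        for k in range(spec.n_frames)
    ]
    origin = box / 2.0
    truth = {"nn_distance": nn, "expected_nhb": 4, "n_molecules": len(oxy_arr)}
    return frames, box, origin, truth


_GENERATORS = {
    "uniform_gas": _gen_uniform_gas,
    "layered_shells": _gen_layered_shells,
    "brownian_pore": _gen_brownian_pore,
    "tetra_fixture": _gen_tetra_fixture,
    "hbond_fixture": _gen_hbond_fixture,
    "lattice_fixture": _gen_lattice_fixture,
}


def generate(
    spec: GeneratorSpec,
) -> Tuple[Trajectory, Dict[str, Any], PoreGeometry]:
    """Build a synthetic trajectory, its ground-truth record and geometry.

    The record always carries the effective box, the pore-frame origin and
    the geometry used, alongside kind-specific truth (density, shell
    parameters, diffusivity/escape law, expected q or bond counts).  For
    the fully periodic lattice fixture a covering slab geometry is
    attached, since the pore plays no role there.
    """
    geom = spec.geometry if spec.geometry is not None else default_geometry()
    rng = np.random.default_rng(spec.seed)
    frames, box, origin, truth = _GENERATORS[spec.kind](spec, geom, rng)
    if spec.kind == "lattice_fixture":
        geom = PoreGeometry(
            radius_R=float(np.linalg.norm(box[:2])),  # covers the whole box section
            length_L=float(box[2]),
            axis_origin=origin,
        )
    else:
        geom = PoreGeometry(
            radius_R=geom.radius_R,
            length_L=geom.length_L,
            axis_origin=origin,
            axis_direction=np.array([0.0, 0.0, 1.0]),
            lattice_parameter_a=geom.lattice_parameter_a,
            hydrophobicity_c=geom.hydrophobicity_c,
            contact_angle_deg=geom.contact_angle_deg,
            temperature_K=geom.temperature_K,
        )
    traj = Trajectory(frames=frames, frame_spacing=spec.frame_spacing)
    truth = dict(truth)
    truth.update(
        {
            "kind": spec.kind,
            "seed": spec.seed,
            "n_molecules": truth.get("n_molecules", spec.n_molecules),
            "n_frames": spec.n_frames,
            "frame_spacing": spec.frame_spacing,
            "box": box.tolist(),
            "pore_origin": origin.tolist(),
            "radius_R": geom.radius_R,
            "length_L": geom.length_L,
        }
    )
    return traj, truth, geom


def generate_with_geometry(spec: GeneratorSpec):
    """Alias of :func:`generate` (kept for readability at call sites)."""
    return generate(spec)
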