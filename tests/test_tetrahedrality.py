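"""Four-neighbour geometry, gamma angles and the order parameter q."""

import math

import numpy as np
import pytest
from scipy.stats import ks_2samp

from aquapore import (
    Frame,
    GeneratorSpec,
    LayerPartition,
    Trajectory,
    WaterMolecule,
    four_nearest_neighbours,
    gamma_angles,
    generate,
    layer_resolved_distributions,
    q_from_cosines,
    q_parameter,
    regular_tetrahedron_vertices,
    tetrahedral_records,
)
from aquapore.tetrahedrality import _brute_force_four_nearest, _neighbour_table


def _frame_from_oxygens(oxygens, box, ids=None):
    oxygens = np.asarray(oxygens, dtype=float)
    ids = np.arange(len(oxygens)) if ids is None else np.asarray(ids)
    h1 = oxygens + np.array([0.8, 0.4, 0.2])
    h2 = oxygens + np.array([-0.8, 0.4, 0.2])
    return Frame(0.0, np.asarray(box, dtype=float), ids, oxygens, h1, h2)


def test_constructed_five_molecule_neighbours():
    oxy = [[10, 10, 10], [12, 10, 10], [10, 13, 10], [10, 10, 14], [15, 15, 15], [10, 11, 10]]
    frame = _frame_from_oxygens(oxy, [30, 30, 30])
    centre = frame.molecules[0]
    ids = four_nearest_neighbours(centre, frame)
    assert sorted(ids) == [1, 2, 3, 5]


def test_periodic_image_closer_than_in_box_molecule():
    # neighbour at x=19.5 in a 20 Å box is 0.5 Å away from x=0 through the boundary
    oxy = [[0.5, 10, 10], [19.8, 10, 10], [4.0, 10, 10], [0.5, 13, 10], [0.5, 10, 13], [0.5, 6, 10]]
    frame = _frame_from_oxygens(oxy, [20, 20, 20])
    ids = four_nearest_neighbours(frame.molecules[0], frame)
    assert 1 in ids  # periodic image chosen over nothing: it is the closest
    assert _brute_force_four_nearest(frame, 0) == ids


def test_exact_tie_breaks_toward_lower_id():
    oxy = [[10, 10, 10], [12, 10, 10], [8, 10, 10], [10, 12, 10], [10, 8, 10], [10, 10, 13]]
    frame = _frame_from_oxygens(oxy, [30, 30, 30])
    # neighbours 1-4 are all exactly 2 Å away; molecule 5 is 3 Å away
    ids = four_nearest_neighbours(frame.molecules[0], frame)
    assert ids == [1, 2, 3, 4]


def test_tree_equals_brute_force_on_random_frames():
    rng = np.random.default_rng(33)
    for _ in range(10):
        n = 30
        box = [15.0, 15.0, 15.0]
        frame = _frame_from_oxygens(rng.uniform(0, 15, size=(n, 3)), box)
        table = _neighbour_table(frame)
        for i in range(n):
            expected = _brute_force_four_nearest(frame, i)
            assert [int(frame.molecule_ids[j]) for j in table[i]] == expected


def test_regular_tetrahedron_angles():
    g = gamma_angles(np.zeros(3), regular_tetrahedron_vertices(2.8))
    assert np.all(np.abs(g - math.degrees(math.acos(-1.0 / 3.0))) < 0.05)
    assert np.all(np.abs(g - 109.47) < 0.05)


def test_coincident_direction_pair_gives_zero_angle():
    neigh = np.array([[2, 0, 0], [3, 0, 0], [0, 2, 0], [0, 0, 2]], dtype=float)
    g = gamma_angles(np.zeros(3), neigh)
    assert g.min() == pytest.approx(0.0, abs=1e-9)


def test_square_planar_angles():
    neigh = np.array([[2, 0, 0], [0, 2, 0], [-2, 0, 0], [0, -2, 0]], dtype=float)
    g = np.sort(gamma_angles(np.zeros(3), neigh))
    np.testing.assert_allclose(g, [90, 90, 90, 90, 180, 180], atol=1e-9)


def test_q_perfect_tetrahedron_is_one():
    g = [math.degrees(math.acos(-1.0 / 3.0))] * 6
    assert q_parameter(g) == pytest.approx(1.0, abs=1e-10)


def test_q_collinear_is_minus_three():
    assert q_parameter([0.0] * 6) == pytest.approx(-3.0, abs=1e-10)


def test_q_random_directions_average_zero():
    rng = np.random.default_rng(17)
    n = 100000
    v = rng.normal(size=(n, 4, 3))
    v /= np.linalg.norm(v, axis=2, keepdims=True)
    pairs = [(i, j) for i in range(4) for j in range(i + 1, 4)]
    cos = np.stack([np.einsum("nk,nk->n", v[:, i], v[:, j]) for i, j in pairs], axis=1)
    q = q_from_cosines(cos)
    se = q.std() / math.sqrt(n)
    assert abs(q.mean()) <= 3.0 * se


def test_q_matches_brute_force_recomputation():
    rng = np.random.default_rng(8)
    for _ in range(20):
        centre = rng.uniform(0, 10, size=3)
        neigh = centre + rng.uniform(-3, 3, size=(4, 3))
        g = gamma_angles(centre, neigh)
        # independent recomputation straight from coordinates
        u = neigh - centre
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        s = 0.0
        for i in range(3):
            for j in range(i + 1, 4):
                s += (np.dot(u[i], u[j]) + 1.0 / 3.0) ** 2
        assert q_parameter(g) == pytest.approx(1.0 - 3.0 / 8.0 * s, abs=1e-12)


def test_records_bounds_and_fixture_layers():
    traj, truth, geom = generate(GeneratorSpec(kind="tetra_fixture", n_frames=1, seed=2))
    partition = LayerPartition(np.array([3.5]), ["inner", "contact"])
    recs = tetrahedral_records(traj, geom, partition)
    by_id = {r.molecule_id: r for r in recs}
    for cid, kind in zip(truth["centre_molecule_ids"], truth["centre_kinds"]):
        assert by_id[cid].q == pytest.approx(truth["expected_q"][kind], abs=1e-9)
        expected_layer = "inner" if kind == "tetrahedral" else "contact"
        assert by_id[cid].layer == expected_layer
    for r in recs:
        assert -3.0 - 1e-9 <= r.q <= 1.0 + 1e-9
        assert all(0.0 <= g <= 180.0 for g in r.gamma_angles)


def test_distributions_normalised_and_layer_contrast():
    traj, truth, geom = generate(
        GeneratorSpec(kind="tetra_fixture", n_frames=1, seed=2, params={"n_tetra": 3})
    )
    partition = LayerPartition(np.array([3.5]), ["inner", "contact"])
    dists = layer_resolved_distributions(traj, geom, partition)
    for label in ("inner", "contact"):
        for name, width in (("gamma", 2.0), ("q", 0.02)):
            c = dists[label][name]
            if c.counts.sum():
                dx = np.diff(np.concatenate([[c.x[0] - width / 2], c.x + width / 2]))
                assert np.sum(c.y * dx) == pytest.approx(1.0, abs=1e-9)
    # the inner layer holds the tetrahedral centres (mass at q = 1), the
    # contact layer the collinear ones (mass at q = -3); cluster-member
    # records add intermediate q values but do not reach the extremes
    q_in = dists["inner"]["q"]
    q_ct = dists["contact"]["q"]
    assert q_in.y[np.argmin(np.abs(q_in.x - 1.0))] > 0
    assert q_ct.y[np.argmin(np.abs(q_ct.x + 3.0))] > 0
    mean_in = np.sum(q_in.x * q_in.counts) / q_in.counts.sum()
    mean_ct = np.sum(q_ct.x * q_ct.counts) / q_ct.counts.sum()
    assert mean_in > mean_ct


def test_uniform_gas_q_matches_direct_sampling_oracle(uniform_gas_run):
    traj, _, geom = uniform_gas_run
    from aquapore import PoreGeometry

    # centres restricted away from the wall and the pore mouths, where the
    # ideal-gas neighbourhood is isotropic; neighbours stay unrestricted
    core = PoreGeometry(radius_R=7.0, length_L=18.0, axis_origin=geom.axis_origin)
    partition = LayerPartition(np.array([3.0]), ["inner", "contact"])
    recs = tetrahedral_records(traj, core, partition)
    # the four neighbour directions of an ideal gas are independent and
    # isotropic; compare with direct sampling
    q_obs = np.array([r.q for r in recs if r.layer == "inner"])
    rng = np.random.default_rng(5)
    v = rng.normal(size=(len(q_obs), 4, 3))
    v /= np.linalg.norm(v, axis=2, keepdims=True)
    pairs = [(i, j) for i in range(4) for j in range(i + 1, 4)]
    cos = np.stack([np.einsum("nk,nk->n", v[:, i], v[:, j]) for i, j in pairs], axis=1)
    q_ref = q_from_cosines(cos)
    stat, p = ks_2samp(q_obs, q_ref)
    assert p > 1e-3


def test_too_few_molecules_error():
    frame = _frame_from_oxygens([[1, 1, 1], [2, 2, 2], [3, 3, 3]], [10, 10, 10])
    with pytest.raises(ValueError):
        four_nearest_neighbours(frame.molecules[0], frame)
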