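"""Geometric hydrogen-bond criterion, counts, typing and network export."""

import math

import numpy as np
import pytest

from aquapore import (
    Frame,
    GeneratorSpec,
    LayerPartition,
    PoreGeometry,
    Trajectory,
    detect_hbonds,
    export_network,
    generate,
    hbond_type_fractions,
    nhb_by_layer,
    read_network,
)
from aquapore.hbond import _brute_force_hbonds, bond_type_label
from aquapore.synthetic import _place_dimer


@pytest.fixture
def single_layer():
    return LayerPartition(np.array([]), ["inner"])


def _dimer_frame(d_oo, angle_deg, base=(12.0, 15.0, 21.0), box=(30.0, 30.0, 42.0)):
    o, h1, h2 = _place_dimer(np.asarray(base, dtype=float), d_oo, angle_deg)
    return Frame(0.0, np.asarray(box), np.array([0, 1]), o, h1, h2)


@pytest.fixture
def covering_geom():
    return PoreGeometry(radius_R=25.0, length_L=42.0, axis_origin=np.array([15.0, 15.0, 21.0]))


@pytest.mark.parametrize(
    "d_oo,angle,expected",
    [
        (2.8, 10.0, 1),  # comfortably inside both cutoffs
        (3.6, 0.0, 0),  # distance fails
        (3.0, 35.0, 0),  # angle fails
        (3.0, 30.0, 1),  # closed angle boundary
        (3.5, 0.0, 1),  # closed distance boundary
    ],
)
def test_criterion_boundaries(covering_geom, single_layer, d_oo, angle, expected):
    frame = _dimer_frame(d_oo, angle)
    graph = detect_hbonds(frame, covering_geom, single_layer)
    assert len(graph.bonds) == expected
    if expected:
        b = graph.bonds[0]
        assert b.donor_id == 0 and b.acceptor_id == 1
        assert b.oo_distance == pytest.approx(d_oo, abs=1e-9)
        assert b.angle_deg == pytest.approx(angle, abs=1e-6)


def test_fixture_bond_count_matches_truth():
    traj, truth, geom = generate(GeneratorSpec(kind="hbond_fixture", n_frames=2, seed=1))
    part = LayerPartition(np.array([]), ["inner"])
    for frame in traj.frames:
        graph = detect_hbonds(frame, geom, part)
        assert len(graph.bonds) == truth["expected_bonds_per_frame"]
        bonded_pairs = {(b.donor_id, b.acceptor_id) for b in graph.bonds}
        for d, a, bonded in truth["pairs"]:
            assert ((d, a) in bonded_pairs) == bonded


def test_handshake_identity_on_random_frames(single_layer):
    for seed in (3, 4):
        traj, _, geom = generate(
            GeneratorSpec(kind="uniform_gas", n_molecules=120, n_frames=2, seed=seed)
        )
        for frame in traj.frames:
            g = detect_hbonds(frame, geom, single_layer)
            assert sum(g.per_molecule_counts.values()) == 2 * len(g.bonds)


def _bond_key_set(graph):
    return {
        (b.donor_id, b.acceptor_id, b.donor_hydrogen_index, round(b.oo_distance, 9))
        for b in graph.bonds
    }


def test_tree_detection_equals_brute_force(single_layer):
    traj, _, geom = generate(GeneratorSpec(kind="uniform_gas", n_molecules=80, n_frames=5, seed=6))
    for frame in traj.frames:
        fast = detect_hbonds(frame, geom, single_layer)
        slow = _brute_force_hbonds(frame, geom, single_layer)
        assert _bond_key_set(fast) == _bond_key_set(slow)


def test_lattice_every_molecule_has_four_bonds(single_layer):
    traj, truth, geom = generate(GeneratorSpec(kind="lattice_fixture", n_frames=1, seed=0))
    table = nhb_by_layer(traj, geom, single_layer)
    assert table.loc[0, "mean_nhb"] == pytest.approx(4.0)
    assert table.loc[0, "n_samples"] == truth["n_molecules"]
    graph = detect_hbonds(traj.frames[0], geom, single_layer)
    assert all(v == 4 for v in graph.per_molecule_counts.values())


def test_isolated_molecules_have_no_bonds(covering_geom, single_layer):
    oxy = np.array([[5.0, 5.0, 5.0], [15.0, 15.0, 15.0], [25.0, 25.0, 35.0]])
    frame = Frame(
        0.0,
        np.array([30.0, 30.0, 42.0]),
        np.arange(3),
        oxy,
        oxy + [0.8, 0.4, 0.2],
        oxy + [-0.8, 0.4, 0.2],
    )
    g = detect_hbonds(frame, covering_geom, single_layer)
    assert len(g.bonds) == 0


def test_bond_type_labels():
    assert bond_type_label("contact", "contact") == "contact_contact"
    assert bond_type_label("inner", "contact") == "contact_inner"
    assert bond_type_label("contact", "inner") == "contact_inner"
    assert bond_type_label("middle", "contact") == "middle_contact"
    assert bond_type_label("middle", "middle") == "middle_middle"
    assert bond_type_label("external", "inner") == "external"


def test_dimer_spanning_contact_inner_typed(covering_geom):
    # donor at r=2 (inner), acceptor at r=4.8 (contact) with boundary at 3.5
    part = LayerPartition(np.array([3.5]), ["inner", "contact"])
    centre = covering_geom.axis_origin
    o, h1, h2 = _place_dimer(centre + np.array([2.0, 0.0, 0.0]), 2.8, 5.0)
    frame = Frame(0.0, np.array([30.0, 30.0, 42.0]), np.array([0, 1]), o, h1, h2)
    g = detect_hbonds(frame, covering_geom, part)
    assert len(g.bonds) == 1
    assert g.bonds[0].bond_type == "contact_inner"


def test_type_fractions_trivial_cases(covering_geom):
    part = LayerPartition(np.array([3.5]), ["inner", "contact"])
    centre = covering_geom.axis_origin
    o, h1, h2 = _place_dimer(centre + np.array([2.0, 0.0, 0.0]), 2.8, 5.0)
    frame = Frame(0.0, np.array([30.0, 30.0, 42.0]), np.array([0, 1]), o, h1, h2)
    traj = Trajectory([frame], 1.0)
    # the single contact molecule engages exactly one bond with an inner one
    fr = hbond_type_fractions(traj, covering_geom, part, "contact", "inner")
    assert fr[1] == pytest.approx(1.0)
    assert sum(fr.values()) == pytest.approx(1.0)
    # no contact partner exists for the contact layer
    fr2 = hbond_type_fractions(traj, covering_geom, part, "contact", "contact")
    assert fr2[0] == pytest.approx(1.0)


def test_network_round_trip(tmp_path, covering_geom):
    part = LayerPartition(np.array([3.5]), ["inner", "contact"])
    traj, _, geom = generate(GeneratorSpec(kind="hbond_fixture", n_frames=1, seed=2))
    g = detect_hbonds(traj.frames[0], geom, part)
    path = tmp_path / "net.txt"
    export_network(g, path)
    t, bonds = read_network(path)
    assert t == pytest.approx(g.frame_time)
    assert len(bonds) == len(g.bonds)
    for a, b in zip(bonds, g.bonds):
        assert (a.donor_id, a.acceptor_id, a.bond_type) == (b.donor_id, b.acceptor_id, b.bond_type)
        assert a.oo_distance == pytest.approx(b.oo_distance, abs=1e-6)


def test_empty_graph_export(tmp_path, covering_geom, single_layer):
    oxy = np.array([[5.0, 5.0, 5.0], [20.0, 20.0, 30.0]])
    frame = Frame(
        0.0, np.array([30.0, 30.0, 42.0]), np.arange(2),
        oxy, oxy + [0.8, 0.4, 0.2], oxy + [-0.8, 0.4, 0.2],
    )
    g = detect_hbonds(frame, covering_geom, single_layer)
    path = tmp_path / "empty.txt"
    export_network(g, path)
    _, bonds = read_network(path)
    assert bonds == []


def test_detection_invariant_under_rotation_and_relabeling(single_layer):
    traj, _, geom = generate(GeneratorSpec(kind="hbond_fixture", n_frames=1, seed=5))
    frame = traj.frames[0]
    ref = detect_hbonds(frame, geom, single_layer)
    ang = 1.1
    c, s = math.cos(ang), math.sin(ang)
    rot = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
    centre = geom.axis_origin
    rotated = Frame(
        frame.time,
        frame.box,
        frame.molecule_ids[::-1].copy(),  # relabel molecules
        (frame.oxygens - centre) @ rot.T + centre,
        (frame.hydrogens1 - centre) @ rot.T + centre,
        (frame.hydrogens2 - centre) @ rot.T + centre,
    )
    alt = detect_hbonds(rotated, geom, single_layer)
    # bond multiset is isomorphic under the id relabeling old -> reversed
    relabel = dict(zip(frame.molecule_ids, frame.molecule_ids[::-1]))
    expected = {(relabel[b.donor_id], relabel[b.acceptor_id]) for b in ref.bonds}
    assert {(b.donor_id, b.acceptor_id) for b in alt.bonds} == expected
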