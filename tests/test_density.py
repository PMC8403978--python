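"""Density profiles, 2-D maps and layer segmentation against generator truth."""

import math

import numpy as np
import pytest

from aquapore import (
    Frame,
    GeneratorSpec,
    Trajectory,
    WaterMolecule,
    axial_contact_density,
    density_map_2d,
    generate,
    make_2d_grid,
    make_radial_grid,
    radial_density,
    segment_layers,
)
from aquapore.density import DensityProfile, LayerPartition


def test_uniform_gas_profile_is_flat(uniform_gas_run):
    traj, truth, geom = uniform_gas_run
    grid = make_radial_grid(geom, dr=0.5)
    prof = radial_density(traj, geom, grid)
    expected = truth["density"]
    # Poisson counting: 3 standard errors per bin
    lam = expected * grid.bin_volumes * traj.n_frames
    se = np.sqrt(lam) / (grid.bin_volumes * traj.n_frames)
    dev = np.abs(prof.rho - expected)
    assert np.all(dev <= 3.0 * se + 1e-12)


def test_counting_identity_exact(uniform_gas_run):
    traj, _, geom = uniform_gas_run
    grid = make_radial_grid(geom, dr=0.37)
    prof = radial_density(traj, geom, grid)
    recovered = np.sum(prof.rho * grid.bin_volumes * prof.n_frames)
    assert recovered == pytest.approx(prof.total_molecule_frames, abs=1e-8)


def test_single_molecule_on_axis(small_pore):
    mol = [WaterMolecule(0, [0, 0, 0], [0.8, 0.4, 0.2], [-0.8, 0.4, 0.2])]
    traj = Trajectory([Frame.from_molecules(0.0, mol, [30, 30, 60])], 1.0)
    grid = make_radial_grid(small_pore, dr=0.5)
    prof = radial_density(traj, small_pore, grid)
    assert prof.counts[0] == 1
    assert prof.counts[1:].sum() == 0
    assert np.sum(prof.rho * grid.bin_volumes) == pytest.approx(1.0)


def test_layered_shells_show_maxima_at_generator_radii():
    spec = GeneratorSpec(
        kind="layered_shells",
        n_molecules=4000,
        n_frames=5,
        seed=7,
        params={"shell_radii": [0.0, 5.0], "shell_widths": 0.5},
    )
    traj, truth, geom = generate(spec)
    grid = make_radial_grid(geom, dr=0.25)
    prof = radial_density(traj, geom, grid)
    # the two shells produce maxima within one bin width of 0 and 5 Å
    r_mid = grid.r_mid
    inner_peak = r_mid[np.argmax(np.where(r_mid < 2.5, prof.rho, -1))]
    outer_peak = r_mid[np.argmax(np.where(r_mid > 2.5, prof.rho, -1))]
    assert inner_peak <= 0.25 + 1e-9
    assert abs(outer_peak - 5.0) <= 0.25 + 1e-9


def test_2d_map_marginal_matches_radial_profile(uniform_gas_run):
    traj, _, geom = uniform_gas_run
    grid2 = make_2d_grid(geom, dr=0.5, dz=0.5)
    grid1 = make_radial_grid(geom, dr=0.5)
    map2d = density_map_2d(traj, geom, grid2)
    prof = radial_density(traj, geom, grid1)
    dz = np.diff(grid2.z_edges)
    marginal = np.sum(map2d.rho * dz[None, :], axis=1) / geom.length_L
    np.testing.assert_allclose(marginal, prof.rho, atol=1e-8)


def test_axial_contact_density_recovers_eight_peaks(small_pore):
    spec = GeneratorSpec(
        kind="layered_shells",
        n_molecules=6000,
        n_frames=10,
        seed=13,
        params={
            "shell_radii": [0.0, 5.8],
            "shell_widths": 0.4,
            "axial_periods": 8,
            "modulation_depth": 0.9,
        },
    )
    traj, truth, geom = generate(spec)
    partition = LayerPartition(np.array([3.0]), ["inner", "contact"])
    curve = axial_contact_density(traj, geom, partition, dz=26.0 / 64)
    # count maxima of the smoothed curve: the generator imprints 8 periods
    y = np.convolve(curve.y, np.ones(3) / 3, mode="same")
    peaks = [
        i
        for i in range(1, len(y) - 1)
        if y[i] >= y[i - 1] and y[i] > y[i + 1] and y[i] > y.mean()
    ]
    assert len(peaks) == truth["axial_periods"]


def test_axial_contact_density_empty_band(small_pore):
    # all molecules on the axis: the contact band holds nothing
    mols = [
        WaterMolecule(i, [0, 0, z], [0.8, 0.4, z + 0.2], [-0.8, 0.4, z + 0.2])
        for i, z in enumerate(np.linspace(-10, 10, 5))
    ]
    traj = Trajectory([Frame.from_molecules(0.0, mols, [30, 30, 60])], 1.0)
    partition = LayerPartition(np.array([3.0]), ["inner", "contact"])
    curve = axial_contact_density(traj, small_pore, partition, dz=1.0)
    assert curve.counts.sum() == 0
    assert np.all(curve.y == 0)


def _profile_from(rho, dr=0.25, L=26.0):
    edges = dr * np.arange(len(rho) + 1)
    vols = math.pi * np.diff(edges**2) * L
    counts = np.maximum(np.round(rho * vols), 0).astype(int)
    from aquapore.geometry import BinGrid

    grid = BinGrid(edges, None, vols)
    return DensityProfile(grid, rho, counts, 1)


def test_segment_layers_two_shell_minimum():
    r = 0.25 * np.arange(28) + 0.125
    rho = np.exp(-(r**2)) + np.exp(-((r - 5.0) ** 2))
    prof = _profile_from(rho)
    part = segment_layers(prof, smoothing_window=5, min_prominence=0.05)
    assert list(part.labels) == ["inner", "contact"]
    assert abs(part.boundaries_r[0] - 2.5) <= 0.5  # valley centre of the two shells


def test_segment_layers_three_shells_labelled_inner_middle_contact():
    r = 0.25 * np.arange(42) + 0.125
    rho = (
        np.exp(-(r**2) / 0.5)
        + np.exp(-((r - 4.0) ** 2) / 0.5)
        + np.exp(-((r - 7.5) ** 2) / 0.5)
    )
    part = segment_layers(_profile_from(rho), smoothing_window=5, min_prominence=0.05)
    assert list(part.labels) == ["inner", "middle", "contact"]
    assert 1.0 < part.boundaries_r[0] < 3.0
    assert 5.0 < part.boundaries_r[1] < 7.0


def test_segment_layers_monotone_profile_falls_back():
    rho = np.linspace(1.0, 0.2, 30)
    with pytest.warns(UserWarning):
        part = segment_layers(_profile_from(rho))
    assert list(part.labels) == ["inner"]
    assert len(part.boundaries_r) == 0
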