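"""Residence bookkeeping, survival function and restricted MSD."""

import math

import numpy as np
import pytest

from aquapore import (
    Frame,
    GeneratorSpec,
    PoreGeometry,
    Trajectory,
    WaterMolecule,
    generate,
    linear_distance,
    plateau_estimate,
    residence_ledger,
    restricted_msd,
    survival_function,
)


def _traj_with_z_pattern(z_by_frame, box=(30.0, 30.0, 60.0)):
    """One molecule whose axial position follows the given per-frame z."""
    frames = []
    for k, z in enumerate(z_by_frame):
        m = [WaterMolecule(0, [0, 0, z], [0.8, 0.4, z + 0.2], [-0.8, 0.4, z + 0.2])]
        frames.append(Frame.from_molecules(float(k), m, box))
    return Trajectory(frames, 1.0)


def test_ledger_always_inside(small_pore):
    traj = _traj_with_z_pattern([0.0] * 6)
    led = residence_ledger(traj, small_pore)
    assert led.intervals[0] == [(0, 5)]


def test_ledger_two_intervals(small_pore):
    # inside frames 0-4, outside 5-6 (reservoir z), inside 7-9
    zs = [0] * 5 + [20, 20] + [0] * 3
    led = residence_ledger(_traj_with_z_pattern(zs), small_pore)
    assert led.intervals[0] == [(0, 4), (7, 9)]


def test_ledger_never_inside(small_pore):
    led = residence_ledger(_traj_with_z_pattern([20.0] * 4), small_pore)
    assert led.intervals[0] == []


def test_sealed_pore_survival_is_one():
    traj, _, geom = generate(
        GeneratorSpec(kind="brownian_pore", n_molecules=100, n_frames=80, seed=1, params={"D": 1.0})
    )
    led = residence_ledger(traj, geom)
    s = survival_function(led, origin_stride=10)
    np.testing.assert_allclose(s.S, 1.0)


def test_memoryless_escape_gives_geometric_survival():
    p = 0.05
    traj, _, geom = generate(
        GeneratorSpec(
            kind="brownian_pore",
            n_molecules=400,
            n_frames=300,
            seed=2,
            params={"D": 0.5, "escape_probability": p},
        )
    )
    led = residence_ledger(traj, geom)
    # stride >= max_lag: non-overlapping windows, independent escape events
    s = survival_function(led, origin_stride=25, max_lag=25)
    expected = (1.0 - p) ** np.arange(26)
    se = np.sqrt(np.maximum(expected * (1.0 - expected), 1e-12) / s.n0)
    assert np.all(np.abs(s.S - expected) <= 3.0 * se + 1e-12)


def test_single_escape_drops_survival(small_pore):
    zs = [0] * 6 + [20] * 4
    led = residence_ledger(_traj_with_z_pattern(zs), small_pore)
    s = survival_function(led, origin_stride=1, max_lag=4)
    # origins 0 and 1 survive 4 lags; origin 5 fails already at lag 1
    assert s.S[0] == 1.0
    assert s.S[-1] < 1.0
    assert np.all(np.diff(s.S) <= 1e-12)


def test_static_configuration_msd_zero(small_pore):
    traj = _traj_with_z_pattern([0.0] * 8)
    led = residence_ledger(traj, small_pore)
    msd = restricted_msd(traj, led, small_pore, origin_stride=2)
    np.testing.assert_allclose(msd.msd_total, 0.0, atol=1e-12)


def test_decomposition_identity():
    traj, _, geom = generate(
        GeneratorSpec(kind="brownian_pore", n_molecules=60, n_frames=60, seed=3, params={"D": 1.0})
    )
    led = residence_ledger(traj, geom)
    msd = restricted_msd(traj, led, geom, origin_stride=10)
    ok = msd.n_pairs > 0
    np.testing.assert_allclose(
        msd.msd_total[ok], msd.msd_z[ok] + msd.msd_xy[ok], atol=1e-10
    )
    assert np.all(np.diff(msd.n_pairs) <= 0)


def test_reflecting_brownian_plateaus_match_closed_forms():
    R, L = 7.0, 26.0
    n_mol = 400
    traj, truth, geom = generate(
        GeneratorSpec(
            kind="brownian_pore", n_molecules=n_mol, n_frames=600, seed=4, params={"D": 2.0}
        )
    )
    led = residence_ledger(traj, geom)
    msd = restricted_msd(traj, led, geom, origin_stride=20)
    pl = plateau_estimate(msd)
    # molecules are independent: SE from the per-molecule spread of squared
    # displacements between the first and last frame
    p0 = traj.frames[0].oxygens - geom.axis_origin
    p1 = traj.frames[-1].oxygens - geom.axis_origin
    d = p1 - p0
    se_xy = np.std(d[:, 0] ** 2 + d[:, 1] ** 2, ddof=1) / math.sqrt(n_mol)
    se_z = np.std(d[:, 2] ** 2, ddof=1) / math.sqrt(n_mol)
    assert abs(pl["msd_xy_plateau"] - truth["plateau_xy"]) <= 3.0 * se_xy
    assert abs(pl["msd_z_plateau"] - truth["plateau_z"]) <= 3.0 * se_z


def test_free_axial_diffusion_einstein_relation():
    D = 0.5
    geom = PoreGeometry(radius_R=300.0, length_L=800.0)
    traj, _, g = generate(
        GeneratorSpec(
            kind="brownian_pore",
            n_molecules=300,
            n_frames=80,
            seed=5,
            geometry=geom,
            params={"D": D},
        )
    )
    led = residence_ledger(traj, g)
    msd = restricted_msd(traj, led, g, origin_stride=10, max_lag=40)
    for k in (10, 20, 40):
        expected = 2.0 * D * msd.lag_times[k]
        # Var(dz^2) = 2 (2 D t)^2 for Gaussian displacements
        se = math.sqrt(2.0) * expected / math.sqrt(300)
        assert abs(msd.msd_z[k] - expected) <= 3.0 * se


def test_origin_stride_invariance():
    traj, _, geom = generate(
        GeneratorSpec(
            kind="brownian_pore",
            n_molecules=300,
            n_frames=200,
            seed=6,
            params={"D": 0.5, "escape_probability": 0.03},
        )
    )
    led = residence_ledger(traj, geom)
    s1 = survival_function(led, origin_stride=20, max_lag=40)
    s2 = survival_function(led, origin_stride=10, max_lag=40)
    se = np.sqrt(np.maximum(s1.S * (1 - s1.S), 1e-12) / s1.n0)
    assert np.all(np.abs(s1.S - s2.S) <= np.maximum(3.0 * se, 0.02))


def test_linear_distance():
    assert linear_distance(64.0) == pytest.approx(8.0)
    assert linear_distance(0.0) == 0.0
    assert linear_distance(72.25) == pytest.approx(8.5)
    with pytest.raises(ValueError):
        linear_distance(-1.0)


def test_xy_plateau_scales_with_radius_squared():
    ratios = []
    for R, seed in ((5.0, 7), (7.0, 8), (10.2, 9)):
        geom = PoreGeometry(radius_R=R, length_L=26.0)
        traj, truth, g = generate(
            GeneratorSpec(
                kind="brownian_pore",
                n_molecules=400,
                n_frames=500,
                seed=seed,
                geometry=geom,
                params={"D": 2.0},
            )
        )
        led = residence_ledger(traj, g)
        msd = restricted_msd(traj, led, g, origin_stride=25)
        ratios.append(plateau_estimate(msd)["msd_xy_plateau"] / R**2)
    for r in ratios:
        assert abs(r - 1.0) <= 0.05
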