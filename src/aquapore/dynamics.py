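"""Residence bookkeeping, survival function and residence-restricted MSD.

The pore is finite, so molecules exchange with the reservoirs.  Dynamics is
therefore measured only over molecules *continuously* resident in the pore
across the lag window:

* ``S(t) = n(t)/n(0)`` — the fraction of molecules present at a time origin
  that are still continuously inside after a further lag t, averaged over
  strided time origins.
* restricted MSD — ``<(r_i(t)-r_i(0))^2>`` over (origin, molecule) pairs
  whose residence interval covers the window, split into the axial (z) and
  planar (xy) components in the pore frame.  In a sealed pore both
  components plateau at the uniform-equilibrium values: R^2 for xy and
  L^2/6 for z.

Continuity is assessed at the stored-frame resolution; excursions between
stored frames are invisible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .core import PoreGeometry, Trajectory, minimum_image
from .density import LayerPartition
from .geometry import cylindrical_coords, inside_pore_mask

DEFAULT_ORIGIN_STRIDE = 10


@dataclass
class ResidenceLedger:
    """Per-molecule maximal runs of consecutive in-pore frames.

    ``intervals[molecule_id]`` is an ordered list of disjoint (first_frame,
    last_frame) index pairs, both inclusive.
    """

    intervals: Dict[int, List[Tuple[int, int]]]
    n_frames: int
    frame_spacing: float

    def run_end_table(self, molecule_ids: np.ndarray) -> np.ndarray:
        """(n_frames, N) table: last frame of the current run, or -1 if outside."""
        n = len(molecule_ids)
        table = np.full((self.n_frames, n), -1, dtype=int)
        for col, mid in enumerate(molecule_ids):
            for s, e in self.intervals.get(int(mid), []):
                table[s : e + 1, col] = e
        return table


@dataclass
class SurvivalCurve:
    lag_times: np.ndarray  # ps
    S: np.ndarray
    n0: int  # total origin-molecule count at lag 0

    def __post_init__(self) -> None:
        self.lag_times = np.asarray(self.lag_times, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        if abs(self.S[0] - 1.0) > 1e-12:
            raise ValueError("S(0) must be 1")
        if np.any(np.diff(self.S) > 1e-12):
            raise ValueError("S must be non-increasing")


@dataclass
class MSDCurve:
    lag_times: np.ndarray  # ps
    msd_total: np.ndarray  # Å^2
    msd_z: np.ndarray
    msd_xy: np.ndarray
    n_pairs: np.ndarray

    def __post_init__(self) -> None:
        for name in ("lag_times", "msd_total", "msd_z", "msd_xy"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)
        ok = self.n_pairs > 0
        if np.any(self.msd_total[ok] < -1e-12):
            raise ValueError("msd must be non-negative")


def residence_ledger(
    traj: Trajectory, geom: PoreGeometry, radial_margin: float = 0.0
) -> ResidenceLedger:
    """Maximal intervals of continuous pore residence for every molecule."""
    frames = [f.sorted_by_id() for f in traj.frames]
    ids = frames[0].molecule_ids
    inside = np.stack(
        [inside_pore_mask(f.oxygens, geom, radial_margin) for f in frames]
    )  # (F, N)
    intervals: Dict[int, List[Tuple[int, int]]] = {int(m): [] for m in ids}
    for col, mid in enumerate(ids):
        col_mask = inside[:, col]
        # run-length encode the boolean column
        edges = np.flatnonzero(np.diff(np.concatenate(([0], col_mask.view(np.int8), [0]))))
        for s, e in zip(edges[::2], edges[1::2]):
            intervals[int(mid)].append((int(s), int(e) - 1))
    return ResidenceLedger(
        intervals=intervals, n_frames=traj.n_frames, frame_spacing=traj.frame_spacing
    )


def survival_function(
    ledger: ResidenceLedger,
    origin_stride: int = DEFAULT_ORIGIN_STRIDE,
    max_lag: Optional[int] = None,
) -> SurvivalCurve:
    """S(t) = n(t)/n(0) averaged over time origins spaced ``origin_stride``.

    A molecule "remains" at lag t from origin t0 iff a single residence
    interval covers [t0, t0+t] entirely.  Only origins whose full lag
    window fits inside the trajectory are used (default ``max_lag`` is half
    the trajectory), so the origin set is lag-independent and S is
    non-increasing by construction rather than distorted by end-of-
    trajectory truncation.
    """
    if origin_stride < 1:
        raise ValueError("origin_stride must be >= 1")
    if max_lag is None:
        max_lag = max(1, (ledger.n_frames - 1) // 2)
    max_lag = min(max_lag, ledger.n_frames - 1)
    t0_last = ledger.n_frames - 1 - max_lag
    # per (interval, eligible origin): contributes to all lags k <= e - t0
    reach_hist = np.zeros(max_lag + 2, dtype=np.int64)
    for runs in ledger.intervals.values():
        for s, e in runs:
            t0_first = ((s + origin_stride - 1) // origin_stride) * origin_stride
            for t0 in range(t0_first, min(e, t0_last) + 1, origin_stride):
                reach_hist[min(e - t0, max_lag)] += 1
    n_t = np.cumsum(reach_hist[::-1])[::-1][: max_lag + 1]  # n(k): reach >= k
    n0 = int(n_t[0])
    if n0 == 0:
        raise ValueError("no occupied time origins")
    return SurvivalCurve(
        lag_times=ledger.frame_spacing * np.arange(max_lag + 1),
        S=n_t / n0,
        n0=n0,
    )


def restricted_msd(
    traj: Trajectory,
    ledger: ResidenceLedger,
    geom: PoreGeometry,
    origin_stride: int = DEFAULT_ORIGIN_STRIDE,
    layer_filter: Optional[Tuple[LayerPartition, str]] = None,
    max_lag: Optional[int] = None,
) -> MSDCurve:
    """Residence-restricted MSD split into axial and planar components.

    For each lag, averages the squared oxygen displacement over all
    (origin, molecule) pairs whose residence interval covers the window;
    with ``layer_filter=(partition, label)`` the molecule must additionally
    occupy that layer at the origin frame.  Lags with no qualifying pair
    are reported as NaN with zero pair count.
    """
    frames = [f.sorted_by_id() for f in traj.frames]
    ids = frames[0].molecule_ids
    pos = np.stack([f.oxygens for f in frames])  # (F, N, 3), lab frame
    box = frames[0].box
    n_frames = len(frames)
    if max_lag is None:
        max_lag = n_frames - 1
    max_lag = min(max_lag, n_frames - 1)
    run_end = ledger.run_end_table(ids)  # (F, N)

    rot = geom.rotation  # displacement vectors rotate without the origin shift

    sum_z = np.zeros(max_lag + 1)
    sum_xy = np.zeros(max_lag + 1)
    n_pairs = np.zeros(max_lag + 1, dtype=np.int64)
    for t0 in range(0, n_frames, origin_stride):
        avail = run_end[t0] - t0  # lag reach per molecule; negative if outside
        eligible = avail >= 0
        if layer_filter is not None:
            partition, label = layer_filter
            r, _, _ = cylindrical_coords(pos[t0], geom)
            labels = np.asarray(partition.labels, dtype=object)[partition.layer_of(r)]
            eligible &= labels == label
        if not np.any(eligible):
            continue
        lmax = min(max_lag, n_frames - 1 - t0)
        # unwrap by accumulating per-frame minimum-image steps: a resident
        # molecule may travel farther than half the box over the window
        steps = minimum_image(
            pos[t0 + 1 : t0 + lmax + 1, eligible] - pos[t0 : t0 + lmax, eligible], box
        )
        disp = np.concatenate(
            [np.zeros((1, int(eligible.sum()), 3)), np.cumsum(steps, axis=0)]
        )
        disp = disp @ rot.T  # into the pore frame
        lag_ok = np.arange(lmax + 1)[:, None] <= avail[eligible][None, :]
        dz2 = disp[:, :, 2] ** 2
        dxy2 = disp[:, :, 0] ** 2 + disp[:, :, 1] ** 2
        sum_z[: lmax + 1] += np.sum(dz2 * lag_ok, axis=1)
        sum_xy[: lmax + 1] += np.sum(dxy2 * lag_ok, axis=1)
        n_pairs[: lmax + 1] += lag_ok.sum(axis=1)
    if n_pairs[0] == 0:
        raise ValueError("no qualifying (origin, molecule) pairs at lag 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        msd_z = np.where(n_pairs > 0, sum_z / n_pairs, np.nan)
        msd_xy = np.where(n_pairs > 0, sum_xy / n_pairs, np.nan)
    return MSDCurve(
        lag_times=traj.frame_spacing * np.arange(max_lag + 1),
        msd_total=msd_z + msd_xy,
        msd_z=msd_z,
        msd_xy=msd_xy,
        n_pairs=n_pairs,
    )


def linear_distance(msd_value: float) -> float:
    """Linear distance (Å) corresponding to a squared displacement (Å^2)."""
    if msd_value < 0:
        raise ValueError("msd must be >= 0")
    return math.sqrt(msd_value)


def plateau_estimate(curve: MSDCurve, tail_fraction: float = 0.2) -> Dict[str, float]:
    """Mean of the final ``tail_fraction`` of lags, per component.

    Reported with the corresponding linear distances; used by the pipeline
    summary.
    """
    n = len(curve.lag_times)
    start = max(1, int(math.floor(n * (1.0 - tail_fraction))))
    ok = curve.n_pairs[start:] > 0
    z = float(np.nanmean(curve.msd_z[start:][ok]))
    xy = float(np.nanmean(curve.msd_xy[start:][ok]))
    return {
        "msd_z_plateau": z,
        "msd_xy_plateau": xy,
        "linear_distance_z": linear_distance(z),
        "linear_distance_xy": linear_distance(xy),
    }
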