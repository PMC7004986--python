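"""Lagrangian post-processing of transport solutions.

The Eulerian solver returns per-interval velocities and interpolated
densities; this layer converts them into particle trajectories. The
conservation form of the advection/diffusion constraint moves mass with the
augmented velocity

    v_aug = v - sigma2 * grad(log mu),

so pathlines are integrated through the piecewise-in-time augmented field
(4th-order Runge-Kutta, trilinear spatial interpolation), recording speed at
every point ("speedlines"). Trajectories are then clustered by spatial
proximity with a single-pass QuickBundles sweep under the mean-direct-flip
(MDF) distance, small clusters are dropped as insignificant, and the
survivors are rasterized back onto the grid for volumetric and per-mask
summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import ImageGrid, ScalarField, VectorField, gradient

__all__ = [
    "Pathline",
    "PathlineSet",
    "augmented_velocity",
    "select_start_points",
    "VelocityTimeline",
    "timeline_from_solutions",
    "integrate_pathlines",
    "compute_streamlines",
    "mdf_distance",
    "resample_pathline",
    "cluster_and_filter",
    "rasterize_pathlines",
    "summarize_by_mask",
]

logger = logging.getLogger(__name__)

LOG_FLOOR_FRACTION = 1e-4  # mu floor (fraction of max) before grad(log mu)


@dataclass
class Pathline:
    """One particle trajectory in world coordinates with per-point speeds."""

    points: np.ndarray  # (K, 3) world coordinates
    speeds: np.ndarray  # (K,) >= 0
    start: tuple[int, int, int]
    cluster_id: int | None = None

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.speeds = np.asarray(self.speeds, dtype=float).ravel()
        if len(self.speeds) != len(self.points):
            raise ValueError("speeds must have one entry per point")
        if np.any(self.speeds < 0):
            raise ValueError("speeds must be nonnegative")

    @property
    def length(self) -> float:
        if len(self.points) < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclass
class PathlineSet:
    pathlines: list[Pathline]
    grid: ImageGrid
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pathlines)


def augmented_velocity(
    v: VectorField, mu: ScalarField, sigma2: float, floor_fraction: float = LOG_FLOOR_FRACTION
) -> VectorField:
    """Effective velocity of the conservation form: v - sigma2 * grad(log mu).

    ``mu`` is floored at ``floor_fraction * max(mu)`` before the logarithm so
    the correction stays finite in empty regions (where the density carries
    no particles anyway).
    """
    if sigma2 == 0.0:
        return VectorField(v.grid, v.components.copy())
    peak = float(mu.values.max())
    if peak <= 0:
        return VectorField(v.grid, v.components.copy())
    floored = np.maximum(mu.values, floor_fraction * peak)
    glog = gradient(ScalarField(mu.grid, np.log(floored)))
    return VectorField(v.grid, v.components - sigma2 * glog.components)


def select_start_points(series, threshold: float = 0.12, stride: int = 1) -> np.ndarray:
    """Seed voxels showing at least ``threshold`` fractional signal increase.

    ``series`` must be in percent-of-baseline units. A voxel qualifies when
    its maximum over the interval reaches ``100 * (1 + threshold)``; this
    max-over-frames reading keeps voxels that enhance during a rising phase.
    Returns an (S, 3) integer array, optionally decimated by ``stride``
    (every stride-th qualifying voxel in lexicographic order).
    """
    if getattr(series, "units", None) != "percent_baseline":
        raise ValueError("select_start_points expects a percent_baseline series")
    stack = series.as_array()
    peak = stack.max(axis=0)
    qualifying = peak >= 100.0 * (1.0 + threshold)
    idx = np.argwhere(qualifying)
    if stride > 1:
        idx = idx[::stride]
    if len(idx) == 0:
        logger.warning("select_start_points: no voxel exceeds %.0f%% increase", 100 * threshold)
    return idx


@dataclass
class VelocityTimeline:
    """Piecewise-constant-in-time velocity fields spanning consecutive intervals.

    ``fields[k]`` acts on the normalized-time interval
    ``[k*dt, (k+1)*dt)`` with ``dt = durations[k]``; pathlines integrate
    through the whole stack.
    """

    fields: list[VectorField]
    durations: np.ndarray

    def __post_init__(self) -> None:
        self.durations = np.asarray(self.durations, dtype=float).ravel()
        if len(self.durations) != len(self.fields):
            raise ValueError("one duration per field required")

    @property
    def total_time(self) -> float:
        return float(self.durations.sum())


def timeline_from_solutions(
    solutions, sigma2: float, use_augmented: bool = True
) -> VelocityTimeline:
    """Concatenate per-pair solutions into one augmented-velocity timeline.

    Each pair contributes its N sub-step velocities (augmented with the
    density at the sub-step start), each spanning dt = 1/N of the pair's
    normalized unit interval.
    """
    fields: list[VectorField] = []
    durations: list[float] = []
    for sol in solutions:
        N = len(sol.velocities)
        for n, v in enumerate(sol.velocities):
            if use_augmented:
                fields.append(augmented_velocity(v, sol.interpolants[n], sigma2))
            else:
                fields.append(VectorField(v.grid, v.components.copy()))
            durations.append(1.0 / N)
    return VelocityTimeline(fields, np.array(durations))


def _interp_velocity(v: VectorField, pos_idx: np.ndarray) -> np.ndarray:
    """Trilinear sample of the field at index-coordinate positions (P, 3)."""
    coords = pos_idx.T  # (3, P)
    return np.stack(
        [
            ndimage.map_coordinates(v.components[c], coords, order=1, mode="nearest")
            for c in range(3)
        ],
        axis=1,
    )  # (P, 3) world units / time


def _integrate(
    grid: ImageGrid,
    field_for_time,
    seeds_idx: np.ndarray,
    total_time: float,
    step_dt: float,
    speed_scale: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """RK4 integration of seeds through a (possibly time-varying) field.

    ``field_for_time(t)`` returns the VectorField active at normalized time
    t. Returns recorded index-coordinate positions (K+1, P, 3), speeds
    (K+1, P) and per-seed count of valid points (truncated at the domain
    boundary).
    """
    inv_lin = np.linalg.inv(grid.affine[:3, :3])  # world velocity -> index velocity

    def f(pos, t):
        vw = _interp_velocity(field_for_time(t), pos)
        return vw @ inv_lin.T, vw

    n_steps = max(1, int(np.ceil(total_time / step_dt - 1e-12)))
    h = total_time / n_steps
    P = len(seeds_idx)
    pos = seeds_idx.astype(float).copy()
    hi = np.array(grid.dims, dtype=float) - 1.0
    active = np.ones(P, dtype=bool)
    n_valid = np.full(P, 1, dtype=np.int64)

    positions = np.empty((n_steps + 1, P, 3))
    speeds = np.empty((n_steps + 1, P))
    positions[0] = pos
    k1v, vw0 = f(pos, 0.0)
    speeds[0] = np.linalg.norm(vw0, axis=1) * speed_scale

    t = 0.0
    for k in range(n_steps):
        k1, _ = f(pos, t)
        k2, _ = f(pos + 0.5 * h * k1, t + 0.5 * h)
        k3, _ = f(pos + 0.5 * h * k2, t + 0.5 * h)
        k4, _ = f(pos + h * k3, t + h)
        new = pos + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        out = np.any((new < 0.0) | (new > hi), axis=1)
        new = np.clip(new, 0.0, hi)
        pos = np.where(active[:, None], new, pos)
        t += h
        positions[k + 1] = pos
        _, vw = f(pos, min(t, total_time - 1e-12))
        speeds[k + 1] = np.linalg.norm(vw, axis=1) * speed_scale
        n_valid[active] += 1
        active &= ~out  # boundary point itself is kept, then truncated
    return positions, speeds, n_valid


def _build_set(grid, positions, speeds, n_valid, seeds_idx, provenance) -> PathlineSet:
    pathlines = []
    for p in range(len(seeds_idx)):
        k = int(n_valid[p])
        pts_idx = positions[:k, p]
        pathlines.append(
            Pathline(
                points=grid.voxel_to_world(pts_idx),
                speeds=speeds[:k, p],
                start=tuple(int(i) for i in seeds_idx[p]),
            )
        )
    return PathlineSet(pathlines, grid, provenance)


def integrate_pathlines(
    timeline: VelocityTimeline,
    seeds: np.ndarray,
    grid: ImageGrid,
    step_dt: float = 0.1,
    speed_scale: float = 1.0,
) -> PathlineSet:
    """Integrate seed voxels forward through the time-varying timeline.

    ``seeds`` is (S, 3) voxel indices; ``step_dt`` the RK4 step in
    normalized time; ``speed_scale`` converts recorded speeds to physical
    units (e.g. 1/frame-minutes). Trajectories leaving the domain are
    truncated at the boundary.
    """
    seeds = np.atleast_2d(np.asarray(seeds))
    if seeds.size == 0:
        return PathlineSet([], grid, {"empty": True})
    if np.any(seeds < 0) or np.any(seeds >= np.array(grid.dims)):
        raise ValueError("seeds must lie inside the grid")
    edges = np.concatenate([[0.0], np.cumsum(timeline.durations)])

    def field_for_time(t: float) -> VectorField:
        k = int(np.searchsorted(edges, t, side="right") - 1)
        return timeline.fields[min(max(k, 0), len(timeline.fields) - 1)]

    positions, speeds, n_valid = _integrate(
        grid, field_for_time, seeds, timeline.total_time, step_dt, speed_scale
    )
    return _build_set(
        grid, positions, speeds, n_valid, seeds,
        {"kind": "pathlines", "step_dt": step_dt, "n_seeds": len(seeds)},
    )


def compute_streamlines(
    v: VectorField,
    seeds: np.ndarray,
    step_dt: float = 0.1,
    total_time: float = 1.0,
    speed_scale: float = 1.0,
) -> PathlineSet:
    """Integrate a single frozen-time field (instantaneous streamlines)."""
    seeds = np.atleast_2d(np.asarray(seeds))
    if seeds.size == 0:
        return PathlineSet([], v.grid, {"empty": True})
    positions, speeds, n_valid = _integrate(
        v.grid, lambda t: v, seeds, total_time, step_dt, speed_scale
    )
    return _build_set(
        v.grid, positions, speeds, n_valid, seeds,
        {"kind": "streamlines", "step_dt": step_dt, "n_seeds": len(seeds)},
    )


def resample_pathline(points: np.ndarray, n_points: int = 12) -> np.ndarray:
    """Resample a polyline to ``n_points`` equally spaced along its arc length."""
    points = np.atleast_2d(points)
    if len(points) == 1:
        return np.repeat(points, n_points, axis=0)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] == 0.0:
        return np.repeat(points[:1], n_points, axis=0)
    targets = np.linspace(0.0, s[-1], n_points)
    out = np.empty((n_points, 3))
    for c in range(3):
        out[:, c] = np.interp(targets, s, points[:, c])
    return out


def mdf_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Mean direct-flip distance between two equally resampled polylines."""
    if a.shape != b.shape:
        raise ValueError("curves must be resampled to the same number of points")
    direct = float(np.linalg.norm(a - b, axis=1).mean())
    flipped = float(np.linalg.norm(a - b[::-1], axis=1).mean())
    return min(direct, flipped)


def cluster_and_filter(
    pset: PathlineSet,
    cluster_threshold: float | None = None,
    min_cluster_size: int = 5,
    n_points: int = 12,
) -> PathlineSet:
    """Single-pass QuickBundles clustering with small-cluster removal.

    Pathlines are resampled to ``n_points`` equispaced points; each is
    assigned to the nearest running-centroid cluster under the MDF metric if
    within ``cluster_threshold`` (default 2 voxel edge lengths, world
    units), otherwise it seeds a new cluster. Clusters with fewer than
    ``min_cluster_size`` members are deemed insignificant and removed.
    Deterministic: pathlines are swept in stored order.
    """
    if cluster_threshold is None:
        cluster_threshold = 2.0 * pset.grid.voxel_size
    resampled = [resample_pathline(pl.points, n_points) for pl in pset.pathlines]
    centroid_sums: list[np.ndarray] = []
    counts: list[int] = []
    labels = np.empty(len(pset.pathlines), dtype=np.int64)
    for i, curve in enumerate(resampled):
        best, best_d, best_flip = -1, np.inf, False
        for ci in range(len(centroid_sums)):
            centroid = centroid_sums[ci] / counts[ci]
            d_dir = float(np.linalg.norm(curve - centroid, axis=1).mean())
            d_flip = float(np.linalg.norm(curve[::-1] - centroid, axis=1).mean())
            d, flip = (d_dir, False) if d_dir <= d_flip else (d_flip, True)
            if d < best_d:
                best, best_d, best_flip = ci, d, flip
        if best >= 0 and best_d <= cluster_threshold:
            add = curve[::-1] if best_flip else curve
            centroid_sums[best] += add
            counts[best] += 1
            labels[i] = best
        else:
            centroid_sums.append(curve.copy())
            counts.append(1)
            labels[i] = len(centroid_sums) - 1

    sizes = np.bincount(labels, minlength=len(centroid_sums))
    keep_cluster = sizes >= min_cluster_size
    kept = []
    for i, pl in enumerate(pset.pathlines):
        if keep_cluster[labels[i]]:
            kept.append(
                Pathline(pl.points.copy(), pl.speeds.copy(), pl.start, int(labels[i]))
            )
    logger.info(
        "cluster_and_filter: %d clusters, %d significant, %d/%d pathlines kept",
        len(centroid_sums), int(keep_cluster.sum()), len(kept), len(pset.pathlines),
    )
    prov = dict(pset.provenance)
    prov.update({"cluster_threshold": cluster_threshold, "min_cluster_size": min_cluster_size})
    return PathlineSet(kept, pset.grid, prov)


def rasterize_pathlines(pset: PathlineSet, mode: str = "binary") -> ScalarField:
    """Deposit pathline samples back onto the cell-centered grid.

    Every recorded point is spread to its 8 neighboring cell centers with
    trilinear weights. ``mode="binary"`` returns the 0/1 footprint of the
    pathline network; ``mode="speed"`` the per-voxel weighted-average speed
    of the deposited samples.
    """
    if mode not in ("binary", "speed"):
        raise ValueError("mode must be 'binary' or 'speed'")
    grid = pset.grid
    wsum = np.zeros(grid.dims)
    ssum = np.zeros(grid.dims)
    for pl in pset.pathlines:
        idx = grid.world_to_voxel(pl.points)
        idx = np.clip(idx, 0.0, np.array(grid.dims, dtype=float) - 1.0)
        i0 = np.minimum(np.floor(idx).astype(np.int64), np.maximum(np.array(grid.dims) - 2, 0))
        f = idx - i0
        for off in np.ndindex(2, 2, 2):
            off_a = np.array(off)
            corner = np.minimum(i0 + off_a, np.array(grid.dims) - 1)
            w = np.prod(np.where(off_a == 1, f, 1.0 - f), axis=1)
            np.add.at(wsum, tuple(corner.T), w)
            np.add.at(ssum, tuple(corner.T), w * pl.speeds)
    hit = wsum > 1e-12
    if mode == "binary":
        return ScalarField(grid, hit.astype(float))
    speed = np.zeros(grid.dims)
    speed[hit] = ssum[hit] / wsum[hit]
    return ScalarField(grid, speed)


def summarize_by_mask(
    binary_map: ScalarField, speed_map: ScalarField, masks: dict[str, np.ndarray]
) -> pd.DataFrame:
    """Per-mask pathline volume (voxel count) and mean speed.

    Mean speed averages the speed map over the nonzero binary voxels inside
    the mask; empty intersections report volume 0 and NaN speed.
    """
    net = binary_map.values > 0
    rows = []
    for name, mask in masks.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != binary_map.grid.dims:
            raise ValueError(f"mask {name!r} not on the map grid")
        inside = net & mask
        volume = int(inside.sum())
        mean_speed = float(speed_map.values[inside].mean()) if volume else float("nan")
        rows.append({"mask": name, "pathline_volume_voxels": volume, "mean_speed": mean_speed})
    return pd.DataFrame(rows)
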