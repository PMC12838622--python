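"""Movement-quality outcomes from the bimanual object-hit task.

Four outcome measures per hand: number of target hits (primary), mean hand
speed, mean absolute acceleration, and space covered — the workspace area the
hand traversed over the task, measured on an occupancy grid.  Trajectory
segments between consecutive samples are rasterised onto the grid so that
fast sweeps are not undercounted.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .io import N_BINS, TaskLog, TimeSeries

__all__ = [
    "KinematicSummary",
    "OccupancyMap",
    "WORKSPACE_CM",
    "count_hits",
    "hand_speed_accel",
    "space_covered",
    "summarize_hand",
]

#: shared workspace extent (width x height) in centimetres
WORKSPACE_CM = (76.0, 44.0)


@dataclass
class OccupancyMap:
    """Per-hand 2D visit-count grid over the workspace.

    ``grid[iy, ix]`` counts trajectory segments that intersected the cell;
    cell ``(ix, iy)`` spans ``origin + [ix, ix+1) * cell_size`` in x (same in
    y).  Area covered is the number of visited cells times ``cell_size**2``.
    """

    grid: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    @property
    def area(self) -> float:
        return float(np.count_nonzero(self.grid)) * self.cell_size**2


@dataclass
class KinematicSummary:
    hand: str
    hits_total: int
    hits_per_bin: np.ndarray
    mean_speed: float
    mean_abs_accel: float
    space_covered: float

    def __post_init__(self) -> None:
        if self.hits_total != int(np.sum(self.hits_per_bin)):
            raise ValueError("hits_total must equal the sum of hits_per_bin")


def count_hits(log: TaskLog) -> dict[str, np.ndarray]:
    """Exact hit counts per hand, keyed by the release bin of the struck ball."""
    counts = {"left": np.zeros(N_BINS, dtype=int), "right": np.zeros(N_BINS, dtype=int)}
    for hit in log.hits:
        counts[hit.hand][hit.bin] += 1
    return counts


def _lowpass(values: np.ndarray, rate: float, cutoff: float) -> np.ndarray:
    sos = signal.butter(2, cutoff, btype="lowpass", fs=rate, output="sos")
    return signal.sosfiltfilt(sos, values)


def hand_speed_accel(
    traj_x: TimeSeries, traj_y: TimeSeries, smooth_hz: float | None = 10.0
) -> tuple[TimeSeries, TimeSeries]:
    """Speed and absolute acceleration magnitude of one hand.

    Positions are optionally low-passed (default 10 Hz, 2nd-order Butterworth,
    zero-phase) to suppress sensor noise before differentiation by central
    differences (one-sided at the endpoints).  Output lengths match the input.
    """
    if traj_x.rate != traj_y.rate or traj_x.n != traj_y.n:
        raise ValueError("x and y trajectories must share rate and length")
    x, y = traj_x.values, traj_y.values
    if smooth_hz is not None and traj_x.n > 9:
        x = _lowpass(x, traj_x.rate, smooth_hz)
        y = _lowpass(y, traj_y.rate, smooth_hz)
    dt = 1.0 / traj_x.rate
    vx = np.gradient(x, dt)
    vy = np.gradient(y, dt)
    ax = np.gradient(vx, dt)
    ay = np.gradient(vy, dt)
    speed = np.hypot(vx, vy)
    accel = np.hypot(ax, ay)
    mk = lambda v, ch, units: TimeSeries(
        t0=traj_x.t0, rate=traj_x.rate, values=v, units=units, channel=ch
    )
    return mk(speed, "speed", "cm/s"), mk(accel, "abs-accel", "cm/s^2")


def _segment_cells(
    x0: float, y0: float, x1: float, y1: float, cell: float, nx: int, ny: int
) -> set[tuple[int, int]]:
    """Grid cells intersected by one segment (Amanatides-Woo traversal)."""

    def _idx(v: float, n: int) -> int:
        return min(max(int(math.floor(v / cell)), 0), n - 1)

    ix, iy = _idx(x0, nx), _idx(y0, ny)
    jx, jy = _idx(x1, nx), _idx(y1, ny)
    cells = {(ix, iy), (jx, jy)}
    dx, dy = x1 - x0, y1 - y0
    sx = 1 if dx > 0 else -1
    sy = 1 if dy > 0 else -1
    if dx != 0:
        t_max_x = ((ix + (sx > 0)) * cell - x0) / dx
        t_dx = cell / abs(dx)
    else:
        t_max_x, t_dx = math.inf, math.inf
    if dy != 0:
        t_max_y = ((iy + (sy > 0)) * cell - y0) / dy
        t_dy = cell / abs(dy)
    else:
        t_max_y, t_dy = math.inf, math.inf
    # bounded by the taxicab cell distance, so the walk always terminates
    for _ in range(abs(jx - ix) + abs(jy - iy) + 2):
        if min(t_max_x, t_max_y) > 1.0:
            break
        if t_max_x <= t_max_y:
            ix += sx
            t_max_x += t_dx
        else:
            iy += sy
            t_max_y += t_dy
        if not (0 <= ix < nx and 0 <= iy < ny):
            break
        cells.add((ix, iy))
    return cells


def space_covered(
    traj_x: TimeSeries,
    traj_y: TimeSeries,
    cell_size: float = 1.0,
    workspace: tuple[float, float] = WORKSPACE_CM,
    origin: tuple[float, float] = (0.0, 0.0),
) -> tuple[OccupancyMap, float]:
    """Occupancy map and covered area (cm^2) of one hand's trajectory.

    Every grid cell intersected by any sampled path segment is marked.
    Samples outside the workspace are clipped to its bounds with a warning.
    """
    if traj_x.n != traj_y.n:
        raise ValueError("x and y trajectories must have equal length")
    nx = int(math.ceil(workspace[0] / cell_size))
    ny = int(math.ceil(workspace[1] / cell_size))
    x = traj_x.values - origin[0]
    y = traj_y.values - origin[1]
    if np.any(x < 0) or np.any(x > workspace[0]) or np.any(y < 0) or np.any(y > workspace[1]):
        warnings.warn("trajectory exceeds workspace bounds; clipping", stacklevel=2)
        x = np.clip(x, 0.0, workspace[0])
        y = np.clip(y, 0.0, workspace[1])
    grid = np.zeros((ny, nx), dtype=int)
    if x.size == 1:
        ix = min(max(int(x[0] // cell_size), 0), nx - 1)
        iy = min(max(int(y[0] // cell_size), 0), ny - 1)
        grid[iy, ix] = 1
    else:
        for k in range(x.size - 1):
            for ix, iy in _segment_cells(x[k], y[k], x[k + 1], y[k + 1], cell_size, nx, ny):
                grid[iy, ix] += 1
    omap = OccupancyMap(grid=grid, cell_size=cell_size, origin=origin)
    return omap, omap.area


def summarize_hand(
    log: TaskLog,
    hand: str,
    cell_size: float = 1.0,
    smooth_hz: float | None = 10.0,
    workspace: tuple[float, float] = WORKSPACE_CM,
) -> KinematicSummary:
    """All four outcome measures for one hand of a task log."""
    if hand not in log.trajectories:
        raise KeyError(f"no trajectory for hand {hand!r}")
    per_bin = count_hits(log)[hand]
    tx, ty = log.trajectories[hand]
    speed, accel = hand_speed_accel(tx, ty, smooth_hz=smooth_hz)
    _, area = space_covered(tx, ty, cell_size=cell_size, workspace=workspace)
    return KinematicSummary(
        hand=hand,
        hits_total=int(per_bin.sum()),
        hits_per_bin=per_bin,
        mean_speed=float(np.mean(speed.values)),
        mean_abs_accel=float(np.mean(accel.values)),
        space_covered=area,
    )
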