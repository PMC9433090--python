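"""Behavioral endpoints: chemotaxis and food-choice indices, exploration
grid coverage, and centroid speed.

The chemotaxis index is (animals at odor - animals at control) / all scored
animals, in [-1, 1]; the food-choice index is the fraction of in-patch
animals found in the experimental patch, in [0, 1]. Exploration coverage
counts 3.5 mm grid squares touched by the track on a 60 mm plate, using
exact segment-grid rasterization so fast segments cannot skip squares.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def chemotaxis_index(n_odor: int, n_control: int, n_other: int = 0) -> float:
    """(n_odor - n_control) / (n_odor + n_control + n_other)."""
    total = n_odor + n_control + n_other
    if min(n_odor, n_control, n_other) < 0:
        raise ValueError("counts must be non-negative")
    if total <= 0:
        raise ValueError("no scored animals on the plate")
    return (n_odor - n_control) / total


def food_choice_index(n_exp: int, n_control: int) -> float:
    """n_exp / (n_exp + n_control); animals outside both patches are excluded."""
    if min(n_exp, n_control) < 0:
        raise ValueError("counts must be non-negative")
    if n_exp + n_control <= 0:
        raise ValueError("both patches empty")
    return n_exp / (n_exp + n_control)


def plate_indices(counts: pd.DataFrame, assay: str = "chemotaxis") -> pd.DataFrame:
    """Per-plate index plus a mean +/- SEM summary row attribute.

    ``counts`` columns: plate_id and n_odor/n_control/n_other (chemotaxis) or
    n_exp/n_control (food_choice). The returned frame has plate_id and index;
    its ``.attrs`` carry ``mean`` and ``sem`` over plates.
    """
    if assay == "chemotaxis":
        vals = [chemotaxis_index(r.n_odor, r.n_control, getattr(r, "n_other", 0))
                for r in counts.itertuples()]
    elif assay == "food_choice":
        vals = [food_choice_index(r.n_exp, r.n_control) for r in counts.itertuples()]
    else:
        raise ValueError(f"unknown assay {assay!r}")
    out = pd.DataFrame({"plate_id": counts["plate_id"], "index": vals})
    arr = np.asarray(vals, dtype=float)
    out.attrs["mean"] = float(arr.mean())
    out.attrs["sem"] = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else float("nan")
    return out


def _segment_cells(p0, p1, origin, size):
    """Grid cells intersected by segment p0->p1 (Amanatides-Woo traversal)."""
    x0 = (p0[0] - origin[0]) / size
    y0 = (p0[1] - origin[1]) / size
    x1 = (p1[0] - origin[0]) / size
    y1 = (p1[1] - origin[1]) / size
    ix, iy = int(np.floor(x0)), int(np.floor(y0))
    ix1, iy1 = int(np.floor(x1)), int(np.floor(y1))
    cells = {(ix, iy)}
    dx, dy = x1 - x0, y1 - y0
    step_x = 1 if dx > 0 else -1
    step_y = 1 if dy > 0 else -1
    t_max_x = ((ix + (step_x > 0)) - x0) / dx if dx != 0 else np.inf
    t_max_y = ((iy + (step_y > 0)) - y0) / dy if dy != 0 else np.inf
    t_delta_x = abs(1.0 / dx) if dx != 0 else np.inf
    t_delta_y = abs(1.0 / dy) if dy != 0 else np.inf
    # bounded walk: at most the manhattan cell distance
    for _ in range(abs(ix1 - ix) + abs(iy1 - iy)):
        if t_max_x < t_max_y:
            ix += step_x
            t_max_x += t_delta_x
        else:
            iy += step_y
            t_max_y += t_delta_y
        cells.add((ix, iy))
    cells.add((ix1, iy1))
    return cells


def exploration_coverage(
    track: pd.DataFrame | np.ndarray,
    square_mm: float = 3.5,
    plate_diameter: float = 60.0,
    grid_offset: tuple[float, float] = (0.0, 0.0),
    average_phases: bool = False,
) -> float:
    """Number of grid squares intersected by the track polyline.

    The grid is anchored at the corner of the plate's bounding square (plus
    an optional ``grid_offset``). Because the real assay's manual grid
    placement is unregistered, ``average_phases`` averages the count over
    four quarter-square phase offsets.
    """
    pos = track[["x_mm", "y_mm"]].to_numpy() if isinstance(track, pd.DataFrame) \
        else np.asarray(track, dtype=float)
    if pos.ndim != 2 or pos.shape[0] < 1:
        raise ValueError("track must contain at least one position")
    if np.any(pos < -1e-9) or np.any(pos > plate_diameter + 1e-9):
        raise ValueError("track leaves the plate bounding square")
    if average_phases:
        phases = [(0.0, 0.0), (square_mm / 4, 0.0), (0.0, square_mm / 4),
                  (square_mm / 4, square_mm / 4)]
        return float(np.mean([
            exploration_coverage(pos, square_mm, plate_diameter,
                                 grid_offset=(grid_offset[0] + px, grid_offset[1] + py))
            for px, py in phases
        ]))
    origin = (grid_offset[0], grid_offset[1])
    cells: set[tuple[int, int]] = set()
    if pos.shape[0] == 1:
        cells.add((int(np.floor((pos[0, 0] - origin[0]) / square_mm)),
                   int(np.floor((pos[0, 1] - origin[1]) / square_mm))))
    for p0, p1 in zip(pos[:-1], pos[1:]):
        cells |= _segment_cells(p0, p1, origin, square_mm)
    return float(len(cells))


def centroid_speed(time, position) -> tuple[np.ndarray, float]:
    """Per-interval speed (mm/s) from a centroid track, and its mean.

    Speed i is the displacement between frames i and i+1 divided by the frame
    interval; the series has length n-1.
    """
    t = np.asarray(time, dtype=float)
    pos = np.asarray(position, dtype=float)
    if t.size < 2:
        raise ValueError("need at least two frames")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("duplicate or decreasing timestamps")
    disp = np.hypot(np.diff(pos[:, 0]), np.diff(pos[:, 1]))
    speed = disp / dt
    return speed, float(speed.mean())
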