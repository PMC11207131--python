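"""Tissue- and single-cell-level readouts from fused cell-cycle tracks.

* Voronoi tessellation of nucleus centers, clipped to the field of view,
  approximating each cell's footprint (valid in confluent, dense tissue).
* Per-track tangential velocities (forward differences) and their Eulerian
  aggregation: mean nuclear velocity in square bins of side 1/10 of the FOV
  length centered on 181 points of a triangular lattice with 1/20-FOV row
  spacing. Bins are wider than the point spacing on purpose — the overlap
  smooths the field.
* Phase-count time series (absolute and fractional) and mean Voronoi area by
  phase with a 95% normal-approximation confidence interval.

Exact FOV clipping is obtained by reflecting every seed across the four FOV
edges before the tessellation: the bisector between a seed and its mirror is
the edge itself, so interior regions are finite and the per-frame areas sum
to the FOV area to float precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import Voronoi
from shapely.geometry import Polygon, box

from .config import KinematicsParams
from .core import FusedCellTrack, Phase


@dataclass
class VoronoiCell:
    """One nucleus-seeded, FOV-clipped convex polygon."""

    cell_id: int
    frame: int
    polygon: Polygon
    area: float
    perimeter: float
    is_border: bool


@dataclass
class VelocityField:
    """Mean-velocity vectors (px/frame) sampled on the triangular lattice."""

    frame_window: tuple[int, int]
    sample_points: np.ndarray  # (P, 2)
    vectors: np.ndarray        # (P, 2), NaN where undefined
    counts: np.ndarray         # (P,) nuclei contributing per bin
    defined: np.ndarray        # (P,) bool


def voronoi_frame(centers: np.ndarray, fov: float, frame: int = 0,
                  cell_ids: list[int] | None = None) -> list[VoronoiCell]:
    """Tessellate one frame's nucleus centers, clipped to [0, fov]^2.

    ``centers`` pools every nucleus present in the frame (both channels'
    fused tracks). Duplicate centers (closer than 1e-9 px) raise an error
    naming the frame.
    """
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    n = len(centers)
    if n < 1:
        raise ValueError("voronoi_frame needs at least one center")
    if n > 1:
        from scipy.spatial.distance import pdist
        if pdist(centers).min() < 1e-9:
            raise ValueError(f"duplicate nucleus centers in frame {frame}")
    if cell_ids is None:
        cell_ids = list(range(n))

    L = float(fov)
    mirrored = np.vstack([
        centers,
        centers * [-1, 1],                    # across x = 0
        centers * [1, -1],                    # across y = 0
        np.column_stack([2 * L - centers[:, 0], centers[:, 1]]),  # x = L
        np.column_stack([centers[:, 0], 2 * L - centers[:, 1]]),  # y = L
    ])
    vor = Voronoi(mirrored)
    fov_box = box(0.0, 0.0, L, L)

    cells = []
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        verts = vor.vertices[region]
        # regions of interior seeds are finite convex polygons; order by angle
        c = verts.mean(axis=0)
        order = np.argsort(np.arctan2(verts[:, 1] - c[1], verts[:, 0] - c[0]))
        poly = Polygon(verts[order]).intersection(fov_box)
        is_border = poly.exterior.distance(fov_box.exterior) < 1e-7
        cells.append(VoronoiCell(cell_id=cell_ids[i], frame=frame, polygon=poly,
                                 area=float(poly.area),
                                 perimeter=float(poly.exterior.length),
                                 is_border=bool(is_border)))
    return cells


def voronoi_all(cells: list[FusedCellTrack], fov: float) -> pd.DataFrame:
    """Tessellate every frame of a fused-track set.

    Returns one row per (cell_id, frame) with area, perimeter, is_border and
    the polygon as WKT.
    """
    rows = []
    by_frame: dict[int, list[tuple[int, float, float]]] = {}
    for c in cells:
        for r in c.records:
            by_frame.setdefault(r.frame, []).append((c.cell_id, r.x, r.y))
    for frame in sorted(by_frame):
        entries = by_frame[frame]
        centers = np.array([(x, y) for _, x, y in entries])
        ids = [cid for cid, _, _ in entries]
        for vc in voronoi_frame(centers, fov, frame=frame, cell_ids=ids):
            rows.append((vc.cell_id, vc.frame, vc.area, vc.perimeter,
                         vc.is_border, vc.polygon.wkt))
    return pd.DataFrame(rows, columns=["cell_id", "frame", "area", "perimeter",
                                       "is_border", "polygon_wkt"])


def tangential_velocity(cell: FusedCellTrack) -> pd.DataFrame:
    """Forward-difference velocity per frame (px/frame); the last frame
    carries the previous frame's vector."""
    if len(cell.records) < 2:
        raise ValueError("tangential velocity needs a track with >= 2 frames")
    pos = cell.positions().sort_values("frame").to_numpy(dtype=float)
    frames, xy = pos[:, 0], pos[:, 1:]
    dt = np.diff(frames)
    v = np.diff(xy, axis=0) / dt[:, None]
    v = np.vstack([v, v[-1]])
    return pd.DataFrame({"frame": frames.astype(int),
                         "vx": v[:, 0], "vy": v[:, 1]})


def velocity_grid(fov: float, params: KinematicsParams | None = None) -> np.ndarray:
    """Sample points of the Eulerian field: a triangular lattice centered in
    the FOV.

    Full rows of ``n`` points with in-row spacing ``bin_side_fraction`` x FOV
    alternate with offset rows of ``n - 1`` points shifted by half that
    spacing; rows are ``grid_row_spacing_fraction`` x FOV apart. With the
    default fractions (1/10 and 1/20) this yields 10x10 + 9x9 = 181 points.
    """
    params = params or KinematicsParams()
    L = float(fov)
    s = params.bin_side_fraction * L          # in-row spacing of full rows
    h = params.grid_row_spacing_fraction * L  # row spacing and row offset
    n = int(round(1.0 / params.bin_side_fraction))
    n_rows = 2 * n - 1
    width, height = (n - 1) * s, (n_rows - 1) * h
    if width >= L or height >= L:
        raise ValueError("lattice does not fit inside the FOV for these params")
    x0, y0 = (L - width) / 2.0, (L - height) / 2.0
    pts = []
    for r in range(n_rows):
        y = y0 + r * h
        if r % 2 == 0:  # full row
            pts.extend((x0 + i * s, y) for i in range(n))
        else:           # offset row
            pts.extend((x0 + h + i * s, y) for i in range(n - 1))
    return np.array(pts)


def velocity_field(cells: list[FusedCellTrack], frame_window: tuple[int, int],
                   fov: float, params: KinematicsParams | None = None
                   ) -> VelocityField:
    """Average nuclear velocities in square bins of side
    ``bin_side_fraction`` x FOV centered at each lattice point.

    Every (position, velocity) sample of every track within the inclusive
    frame window contributes to every bin that contains its position; empty
    bins are flagged undefined.
    """
    params = params or KinematicsParams()
    points = velocity_grid(fov, params)
    f0, f1 = frame_window
    samples_pos, samples_v = [], []
    for c in cells:
        if len(c.records) < 2:
            continue
        vel = tangential_velocity(c)
        sel = (vel["frame"] >= f0) & (vel["frame"] <= f1)
        if not sel.any():
            continue
        pos = c.positions().set_index("frame")
        for row in vel[sel].itertuples(index=False):
            p = pos.loc[int(row.frame)]
            samples_pos.append((float(p["x"]), float(p["y"])))
            samples_v.append((row.vx, row.vy))

    vectors = np.full((len(points), 2), np.nan)
    counts = np.zeros(len(points), dtype=int)
    if samples_pos:
        P = np.asarray(samples_pos)
        V = np.asarray(samples_v)
        half = 0.5 * params.bin_side_fraction * float(fov)
        for k, (cx, cy) in enumerate(points):
            inside = (np.abs(P[:, 0] - cx) <= half) & (np.abs(P[:, 1] - cy) <= half)
            counts[k] = int(inside.sum())
            if counts[k]:
                vectors[k] = V[inside].mean(axis=0)
    return VelocityField(frame_window=(f0, f1), sample_points=points,
                         vectors=vectors, counts=counts, defined=counts > 0)


def velocity_field_frame(field: VelocityField,
                         params: KinematicsParams | None = None) -> pd.DataFrame:
    """Flatten a VelocityField to a table, adding um/min columns."""
    params = params or KinematicsParams()
    scale = 1.0 / (params.px_per_um * params.min_per_frame)  # px/frame -> um/min
    return pd.DataFrame({
        "x": field.sample_points[:, 0], "y": field.sample_points[:, 1],
        "vx_px_frame": field.vectors[:, 0], "vy_px_frame": field.vectors[:, 1],
        "vx_um_min": field.vectors[:, 0] * scale,
        "vy_um_min": field.vectors[:, 1] * scale,
        "n": field.counts, "defined": field.defined,
        "window_start": field.frame_window[0],
        "window_end": field.frame_window[1]})


def phase_counts(cells: list[FusedCellTrack],
                 frames: list[int] | None = None) -> pd.DataFrame:
    """Absolute and fractional counts of RED / YELLOW / GREEN cells per frame."""
    tally: dict[int, dict[str, int]] = {}
    for c in cells:
        for r in c.records:
            t = tally.setdefault(r.frame, {"red": 0, "yellow": 0, "green": 0})
            t[r.phase.value] += 1
    if frames is None:
        frames = sorted(tally)
    rows = []
    for f in frames:
        t = tally.get(f, {"red": 0, "yellow": 0, "green": 0})
        total = t["red"] + t["yellow"] + t["green"]
        fr = (lambda k: t[k] / total if total else 0.0)
        rows.append((f, t["red"], t["yellow"], t["green"], total,
                     fr("red"), fr("yellow"), fr("green")))
    return pd.DataFrame(rows, columns=["frame", "red", "yellow", "green",
                                       "total", "frac_red", "frac_yellow",
                                       "frac_green"])


def area_by_phase(voronoi_df: pd.DataFrame, cells: list[FusedCellTrack],
                  exclude_border: bool = True) -> pd.DataFrame:
    """Mean Voronoi area per frame and phase with 95% CI.

    CI = mean +/- 1.96 * sd / sqrt(n) (normal approximation); NaN when n < 2.
    Border cells are excluded by default because their clipped areas are
    biased low.
    """
    phase_rows = [(c.cell_id, r.frame, r.phase.value)
                  for c in cells for r in c.records]
    phases = pd.DataFrame(phase_rows, columns=["cell_id", "frame", "phase"])
    joined = voronoi_df.merge(phases, on=["cell_id", "frame"], how="inner")
    if exclude_border:
        joined = joined[~joined["is_border"]]
    rows = []
    for (frame, phase), grp in joined.groupby(["frame", "phase"], sort=True):
        n = len(grp)
        mean = float(grp["area"].mean())
        if n >= 2:
            half = 1.96 * float(grp["area"].std(ddof=1)) / np.sqrt(n)
            lo, hi = mean - half, mean + half
        else:
            lo = hi = float("nan")
        rows.append((frame, phase, n, mean, lo, hi))
    return pd.DataFrame(rows, columns=["frame", "phase", "n", "mean_area",
                                       "ci_low", "ci_high"])


def plot_velocity_field(field: VelocityField, path: str, fov: float) -> None:
    """Quick-look quiver plot of a velocity field (PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    ok = field.defined
    ax.quiver(field.sample_points[ok, 0], field.sample_points[ok, 1],
              field.vectors[ok, 0], field.vectors[ok, 1], angles="xy")
    ax.set_xlim(0, fov)
    ax.set_ylim(fov, 0)  # image convention: y down
    ax.set_aspect("equal")
    ax.set_xlabel("x (px)")
    ax.set_ylabel("y (px)")
    ax.set_title(f"velocity field, frames {field.frame_window[0]}"
                 f"-{field.frame_window[1]}")
    fig.savefig(path, dpi=120)
    plt.close(fig)
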