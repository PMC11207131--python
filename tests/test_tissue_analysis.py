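"""Voronoi morphology, tangential velocities, the triangular sampling
lattice, Eulerian velocity fields, and tissue-level summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial import cKDTree

from fucciflow import Channel, FusionParams, KinematicsParams, Phase
from fucciflow.core import ChannelTrack, Detection
from fucciflow.fucci_sim import simulate_monolayer, tracks_from_ground_truth
from fucciflow.tissue_analysis import (area_by_phase, phase_counts,
                                       tangential_velocity, velocity_field,
                                       velocity_grid, voronoi_all,
                                       voronoi_frame)
from fucciflow.track_fusion import fuse, fuse_all

from conftest import small_config


def fused_from_points(cell_id, channel, points):
    dets = [Detection(frame=f, channel=channel, label_id=cell_id, x=x, y=y,
                      area=float("nan"), perimeter=float("nan"),
                      mean_intensity=float("nan")) for f, x, y in points]
    t = ChannelTrack(track_id=cell_id, channel=channel, detections=dets)
    cell = fuse(t, None) if channel is Channel.RED else fuse(None, t)
    cell.cell_id = cell_id
    return cell


# --- Voronoi ----------------------------------------------------------------

def test_single_center_claims_whole_fov():
    [cell] = voronoi_frame(np.array([[40.0, 60.0]]), fov=100.0)
    assert cell.area == pytest.approx(100.0 ** 2)
    assert cell.is_border


def test_mirror_symmetric_pair_halves_the_fov():
    cells = voronoi_frame(np.array([[30.0, 50.0], [70.0, 50.0]]), fov=100.0)
    assert [c.area for c in cells] == pytest.approx([5000.0, 5000.0])


def test_four_point_square_fixture_gives_2500_each():
    centers = np.array([[25.0, 25.0], [75.0, 25.0], [25.0, 75.0], [75.0, 75.0]])
    cells = voronoi_frame(centers, fov=100.0)
    assert [c.area for c in cells] == pytest.approx([2500.0] * 4)
    assert all(c.perimeter == pytest.approx(200.0) for c in cells)
    assert all(c.is_border for c in cells)


def test_duplicate_centers_rejected_with_frame_name():
    pts = np.array([[10.0, 10.0], [10.0, 10.0], [50.0, 50.0]])
    with pytest.raises(ValueError, match="frame 3"):
        voronoi_frame(pts, fov=100.0, frame=3)


@settings(deadline=None, derandomize=True, max_examples=20)
@given(seed=st.integers(0, 1000), n=st.integers(1, 40))
def test_voronoi_areas_tile_the_fov(seed, n):
    rng = np.random.default_rng(seed)
    pts = rng.uniform(1.0, 99.0, size=(n, 2))
    # drop near-duplicates the error contract rejects
    keep = []
    for p in pts:
        if all(np.linalg.norm(p - q) > 1e-6 for q in keep):
            keep.append(p)
    cells = voronoi_frame(np.array(keep), fov=100.0)
    total = sum(c.area for c in cells)
    assert total == pytest.approx(100.0 ** 2, rel=1e-9)
    for c, p in zip(cells, keep):
        assert c.polygon.buffer(1e-9).contains(
            __import__("shapely.geometry", fromlist=["Point"]).Point(p))


# --- tangential velocity ----------------------------------------------------

def test_velocity_of_stationary_and_uniform_tracks():
    still = fused_from_points(0, Channel.RED,
                              [(f, 20.0, 30.0) for f in range(5)])
    v = tangential_velocity(still)
    assert np.allclose(v[["vx", "vy"]], 0.0)
    mover = fused_from_points(1, Channel.RED,
                              [(f, 10.0 + 2.0 * f, 40.0) for f in range(5)])
    v = tangential_velocity(mover)
    assert np.allclose(v["vx"], 2.0) and np.allclose(v["vy"], 0.0)


def test_velocity_three_point_polyline_hand_example():
    cell = fused_from_points(0, Channel.RED,
                             [(0, 0.0, 0.0), (1, 3.0, 4.0), (2, 3.0, 10.0)])
    v = tangential_velocity(cell)
    assert v.loc[0, ["vx", "vy"]].tolist() == [3.0, 4.0]
    assert v.loc[1, ["vx", "vy"]].tolist() == [0.0, 6.0]
    # last frame carries the previous vector
    assert v.loc[2, ["vx", "vy"]].tolist() == [0.0, 6.0]


# --- sampling lattice -------------------------------------------------------

@pytest.mark.parametrize("fov", [64.0, 100.0, 512.0, 2048.0])
def test_default_lattice_has_181_points(fov):
    pts = velocity_grid(fov)
    assert len(pts) == 181
    assert np.all(pts > 0) and np.all(pts < fov)


def test_lattice_nearest_neighbour_offsets():
    fov = 200.0
    pts = velocity_grid(fov)
    d, idx = cKDTree(pts).query(pts, k=7)
    diag = np.hypot(fov / 20, fov / 20)
    for k in range(len(pts)):
        for dist, j in zip(d[k, 1:], idx[k, 1:]):
            off = np.abs(pts[j] - pts[k])
            if dist <= diag + 1e-9:
                assert (np.allclose(off, [fov / 20, fov / 20])
                        or np.allclose(off, [fov / 10, 0.0])
                        or np.allclose(off, [0.0, fov / 10]))


def test_lattice_scale_equivariance():
    assert np.allclose(velocity_grid(512.0), 2.0 * velocity_grid(256.0))


def test_lattice_must_fit_inside_fov():
    with pytest.raises(ValueError, match="does not fit"):
        velocity_grid(100.0, KinematicsParams(grid_row_spacing_fraction=0.6))


# --- Eulerian velocity field ------------------------------------------------

def test_uniform_flow_reproduced_at_every_defined_sample():
    cells = [fused_from_points(i, Channel.RED,
                               [(f, 10.0 + 20.0 * i + 1.5 * f, 50.0 + 7.0 * i)
                                for f in range(6)])
             for i in range(8)]
    field = velocity_field(cells, (0, 5), fov=200.0)
    assert field.defined.any()
    assert np.allclose(field.vectors[field.defined],
                       [1.5, 0.0], atol=1e-9)


def test_empty_window_leaves_all_samples_undefined():
    cells = [fused_from_points(0, Channel.RED,
                               [(f, 50.0, 50.0) for f in range(3)])]
    field = velocity_field(cells, (10, 12), fov=100.0)
    assert not field.defined.any()
    assert np.isnan(field.vectors).all()
    assert len(field.sample_points) == 181


def test_bin_average_matches_bruteforce_scan():
    cells = [fused_from_points(0, Channel.RED,
                               [(0, 100.0, 100.0), (1, 101.0, 100.0)]),
             fused_from_points(1, Channel.RED,
                               [(0, 103.0, 102.0), (1, 106.0, 102.0)])]
    fov, params = 200.0, KinematicsParams()
    field = velocity_field(cells, (0, 1), fov, params)
    # brute-force oracle: rebuild every bin average from the raw samples
    samples = []
    for c in cells:
        v = tangential_velocity(c)
        pos = c.positions().set_index("frame")
        for row in v.itertuples(index=False):
            p = pos.loc[int(row.frame)]
            samples.append((p["x"], p["y"], row.vx, row.vy))
    half = 0.5 * params.bin_side_fraction * fov
    for k, (cx, cy) in enumerate(field.sample_points):
        sel = [(vx, vy) for x, y, vx, vy in samples
               if abs(x - cx) <= half and abs(y - cy) <= half]
        if sel:
            assert field.counts[k] == len(sel)
            assert np.allclose(field.vectors[k], np.mean(sel, axis=0))
        else:
            assert not field.defined[k]
    # the two nuclei share bins: those averages mix (1,0) and (3,0)
    both = [k for k in range(181) if field.counts[k] == 4]
    assert both and np.allclose(field.vectors[both], [2.0, 0.0])


# --- tissue summaries -------------------------------------------------------

def test_phase_counts_single_red_cell():
    cells = [fused_from_points(0, Channel.RED,
                               [(f, 10.0, 10.0) for f in range(5)])]
    ts = phase_counts(cells)
    assert (ts["red"] == 1).all() and (ts["frac_red"] == 1.0).all()
    assert (ts[["yellow", "green"]] == 0).all().all()


def test_phase_counts_conserved_and_hand_fixture():
    r = fused_from_points(0, Channel.RED, [(f, 10.0, 10.0) for f in range(4)])
    g = fused_from_points(1, Channel.GREEN, [(f, 40.0, 40.0) for f in range(2, 6)])
    # a third cell with all three phases
    red_t = ChannelTrack(track_id=2, channel=Channel.RED, detections=[
        Detection(frame=f, channel=Channel.RED, label_id=2, x=70.0, y=70.0,
                  area=1.0, perimeter=1.0, mean_intensity=1.0)
        for f in range(0, 3)])
    green_t = ChannelTrack(track_id=2, channel=Channel.GREEN, detections=[
        Detection(frame=f, channel=Channel.GREEN, label_id=2, x=70.0, y=70.0,
                  area=1.0, perimeter=1.0, mean_intensity=1.0)
        for f in range(2, 5)])
    tri = fuse(red_t, green_t)
    tri.cell_id = 2
    ts = phase_counts([r, g, tri]).set_index("frame")
    # hand count: frame 0 -> 2 red; frame 2 -> 1 red, 1 green, 1 yellow
    assert ts.loc[0, ["red", "yellow", "green"]].tolist() == [2, 0, 0]
    assert ts.loc[2, ["red", "yellow", "green"]].tolist() == [1, 1, 1]
    assert (ts[["red", "yellow", "green"]].sum(axis=1) == ts["total"]).all()
    fr = ts[["frac_red", "frac_yellow", "frac_green"]].sum(axis=1)
    assert np.allclose(fr, 1.0)


def test_area_by_phase_hand_statistics():
    # three red cells and one green, areas known from the 4-point fixture
    cells = [fused_from_points(i, Channel.RED, [(0, x, y)])
             for i, (x, y) in enumerate([(25.0, 25.0), (75.0, 25.0),
                                         (25.0, 75.0)])]
    cells.append(fused_from_points(3, Channel.GREEN, [(0, 75.0, 75.0)]))
    vor = voronoi_all(cells, fov=100.0)
    stats = area_by_phase(vor, cells, exclude_border=False)
    row = stats[(stats.phase == "red")].iloc[0]
    areas = [2500.0, 2500.0, 2500.0]
    assert row["n"] == 3 and row["mean_area"] == pytest.approx(2500.0)
    half = 1.96 * np.std(areas, ddof=1) / np.sqrt(3)
    assert row["ci_high"] - row["mean_area"] == pytest.approx(half)  # zero here
    g = stats[(stats.phase == "green")].iloc[0]
    assert g["n"] == 1 and np.isnan(g["ci_low"])  # CI undefined at n=1


def test_yellow_cells_in_sparse_region_have_larger_areas():
    """Qualitative ordering: cells placed at locally lower density get
    larger Voronoi areas than cells packed densely."""
    rng = np.random.default_rng(0)
    cells = []
    cid = 0
    for x in np.linspace(5, 45, 6):          # dense red block
        for y in np.linspace(5, 95, 10):
            cells.append(fused_from_points(
                cid, Channel.RED, [(0, float(x), float(y + rng.uniform(-1, 1)))]))
            cid += 1
    for x in np.linspace(60, 95, 3):         # sparse co-expressing block
        for y in np.linspace(10, 90, 4):
            red_t = ChannelTrack(track_id=cid, channel=Channel.RED, detections=[
                Detection(frame=0, channel=Channel.RED, label_id=cid,
                          x=float(x), y=float(y), area=1.0, perimeter=1.0,
                          mean_intensity=1.0)])
            green_t = ChannelTrack(track_id=cid, channel=Channel.GREEN,
                                   detections=[
                Detection(frame=0, channel=Channel.GREEN, label_id=cid,
                          x=float(x), y=float(y), area=1.0, perimeter=1.0,
                          mean_intensity=1.0)])
            try:
                c = fuse(red_t, green_t)
            except ValueError:
                continue
            c.cell_id = cid
            cells.append(c)
            cid += 1
    vor = voronoi_all(cells, fov=100.0)
    stats = area_by_phase(vor, cells, exclude_border=False).set_index("phase")
    assert stats.loc["yellow", "mean_area"] > stats.loc["red", "mean_area"]


def test_voronoi_all_on_simulation_conserves_area(sim_records):
    cfg, rec = sim_records
    cells = fuse_all(tracks_from_ground_truth(rec, Channel.RED),
                     tracks_from_ground_truth(rec, Channel.GREEN),
                     FusionParams(), fov=cfg.fov_size_px)
    vor = voronoi_all(cells, cfg.fov_size_px)
    sums = vor.groupby("frame")["area"].sum()
    assert np.allclose(sums, cfg.fov_size_px ** 2, rtol=1e-9)
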