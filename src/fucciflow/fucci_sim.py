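"""Synthetic confluent-monolayer FUCCI movie generator with ground truth.

Cells move by a persistent random walk with soft pairwise repulsion and an
optional uniform drift, reflecting at the field-of-view walls. Each cell
carries a phase clock COLORLESS -> RED -> YELLOW -> GREEN whose per-phase
durations are drawn once per cell from a truncated normal; when the GREEN
phase expires and division is enabled the cell is replaced by two COLORLESS
daughters. Fluorophore intensities follow a piecewise-linear profile: the red
reporter ramps 0 -> peak across RED and decays to 0 across YELLOW while the
green reporter ramps 0 -> peak across YELLOW and holds through GREEN — a
qualitative stand-in for cdt1/geminin kinetics, not calibrated to any cell
line.

All stochastic draws come from one generator seeded by ``rng_seed`` and occur
in a fixed order (initial placement, then per-cell clock draws, then per-frame
headings in cell-id order, then division axes as divisions happen), so runs
are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .config import SimConfig
from .core import Channel, ChannelTrack, Detection, Phase

GT_COLUMNS = ["cell_id", "frame", "x", "y", "phase",
              "red_intensity", "green_intensity", "parent_id"]

_PHASES = [Phase.COLORLESS, Phase.RED, Phase.YELLOW, Phase.GREEN]


@dataclass
class _CellState:
    cell_id: int
    pos: np.ndarray
    heading: np.ndarray
    durations: dict[str, int]
    phase_idx: int
    frames_left: int
    parent_id: int


def _draw_durations(cfg: SimConfig, rng: np.random.Generator) -> dict[str, int]:
    out = {}
    for name in ("colorless", "red", "yellow", "green"):
        mean = cfg.phase_durations[name]
        if cfg.phase_duration_cv <= 0:
            d = float(mean)
        else:
            d = rng.normal(mean, cfg.phase_duration_cv * mean)
        out[name] = max(1, int(round(d)))
    return out


def _unit(rng: np.random.Generator) -> np.ndarray:
    theta = rng.uniform(0.0, 2.0 * np.pi)
    return np.array([np.cos(theta), np.sin(theta)])


def _intensities(phase: Phase, i_in_phase: int, durations: dict[str, int],
                 peaks: dict[str, float]) -> tuple[float, float]:
    """Piecewise-linear reporter levels at frame ``i_in_phase`` of ``phase``."""
    if phase is Phase.RED:
        d = durations["red"]
        return peaks["red"] * (i_in_phase + 1) / d, 0.0
    if phase is Phase.YELLOW:
        d = durations["yellow"]
        red = peaks["red"] * (d - i_in_phase) / d
        green = peaks["green"] * (i_in_phase + 1) / d
        return red, green
    if phase is Phase.GREEN:
        return 0.0, peaks["green"]
    return 0.0, 0.0


def _initial_positions(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample positions at least ``repulsion_radius`` apart."""
    lo, hi = 2.0, cfg.fov_size_px - 3.0
    positions: list[np.ndarray] = []
    max_tries = 200 * cfg.n_cells_init
    tries = 0
    while len(positions) < cfg.n_cells_init and tries < max_tries:
        tries += 1
        p = rng.uniform(lo, hi, size=2)
        if not positions:
            positions.append(p)
            continue
        d = np.min(np.linalg.norm(np.asarray(positions) - p, axis=1))
        if d >= cfg.repulsion_radius:
            positions.append(p)
    while len(positions) < cfg.n_cells_init:  # dense fallback: accept overlaps
        positions.append(rng.uniform(lo, hi, size=2))
    return np.asarray(positions)


def _init_clock(cfg: SimConfig, durations: dict[str, int],
                rng: np.random.Generator) -> tuple[int, int]:
    """Return (phase index, frames left) for a cell entering the movie."""
    if cfg.init_phase != "random":
        idx = [p.value for p in _PHASES].index(cfg.init_phase)
        return idx, durations[_PHASES[idx].value]
    total = sum(durations.values())
    elapsed = int(rng.integers(0, total))
    for idx, ph in enumerate(_PHASES):
        d = durations[ph.value]
        if elapsed < d:
            return idx, d - elapsed
        elapsed -= d
    return 3, 1  # unreachable


def simulate_monolayer(config: SimConfig) -> pd.DataFrame:
    """Simulate the monolayer and return one row per (cell, frame).

    Columns: cell_id, frame, x, y, phase, red_intensity, green_intensity,
    parent_id (-1 for founder cells). Deterministic for a fixed
    ``config.rng_seed``.
    """
    rng = np.random.default_rng(config.rng_seed)
    L = float(config.fov_size_px)
    positions = _initial_positions(config, rng)

    cells: list[_CellState] = []
    for i in range(config.n_cells_init):
        durations = _draw_durations(config, rng)
        phase_idx, frames_left = _init_clock(config, durations, rng)
        cells.append(_CellState(cell_id=i, pos=positions[i].copy(),
                                heading=_unit(rng), durations=durations,
                                phase_idx=phase_idx, frames_left=frames_left,
                                parent_id=-1))
    next_id = config.n_cells_init
    drift = np.asarray(config.drift, dtype=float)

    rows: list[tuple] = []
    for frame in range(config.n_frames):
        for c in cells:
            ph = _PHASES[c.phase_idx]
            i_in = c.durations[ph.value] - c.frames_left
            red, green = _intensities(ph, i_in, c.durations,
                                      config.peak_intensity)
            rows.append((c.cell_id, frame, c.pos[0], c.pos[1], ph.value,
                         red, green, c.parent_id))

        if frame == config.n_frames - 1:
            break

        # --- motion update -------------------------------------------------
        disp = np.zeros((len(cells), 2))
        for k, c in enumerate(cells):
            if config.motility_speed > 0:
                c.heading = (config.persistence * c.heading
                             + (1.0 - config.persistence) * _unit(rng))
                n = np.linalg.norm(c.heading)
                if n > 0:
                    c.heading /= n
                disp[k] += config.motility_speed * c.heading
            disp[k] += drift
        if len(cells) > 1 and config.repulsion_radius > 0:
            pos = np.asarray([c.pos for c in cells])
            tree = cKDTree(pos)
            for i, j in tree.query_pairs(config.repulsion_radius):
                delta = pos[i] - pos[j]
                d = np.linalg.norm(delta)
                if d < 1e-12:
                    continue
                push = 0.5 * (config.repulsion_radius - d) * (delta / d)
                disp[i] += push
                disp[j] -= push
        for k, c in enumerate(cells):
            p = c.pos + disp[k]
            for ax in (0, 1):  # reflect at walls
                if p[ax] < 0:
                    p[ax] = -p[ax]
                if p[ax] > L - 1:
                    p[ax] = 2 * (L - 1) - p[ax]
                p[ax] = min(max(p[ax], 0.0), L - 1)
            c.pos = p

        # --- phase clock ---------------------------------------------------
        survivors: list[_CellState] = []
        for c in cells:
            c.frames_left -= 1
            if c.frames_left > 0:
                survivors.append(c)
                continue
            if c.phase_idx < 3:
                c.phase_idx += 1
                c.frames_left = c.durations[_PHASES[c.phase_idx].value]
                survivors.append(c)
            elif not config.division_enabled:
                c.frames_left = c.durations["green"]  # linger in GREEN
                survivors.append(c)
            else:
                axis = _unit(rng)
                off = 0.5 * config.repulsion_radius
                for sign in (+1.0, -1.0):
                    p = np.clip(c.pos + sign * off * axis, 0.0, L - 1)
                    durations = _draw_durations(config, rng)
                    survivors.append(_CellState(
                        cell_id=next_id, pos=p, heading=_unit(rng),
                        durations=durations, phase_idx=0,
                        frames_left=durations["colorless"],
                        parent_id=c.cell_id))
                    next_id += 1
        cells = survivors

    df = pd.DataFrame(rows, columns=GT_COLUMNS)
    return df.astype({"cell_id": int, "frame": int, "parent_id": int})


def render_channels(records: pd.DataFrame,
                    config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Render the red and green stacks (float32, T x H x W).

    Each nucleus is an isotropic Gaussian spot of scale ``nucleus_sigma_px``
    and amplitude equal to its reporter intensity; background and Gaussian
    camera noise are added and the result clipped at zero.
    """
    L = config.fov_size_px
    T = int(records["frame"].max()) + 1 if len(records) else config.n_frames
    red = np.zeros((T, L, L), dtype=np.float64)
    green = np.zeros((T, L, L), dtype=np.float64)
    sigma = config.nucleus_sigma_px
    half = max(1, int(np.ceil(4 * sigma)))

    for row in records.itertuples(index=False):
        for stack, amp in ((red, row.red_intensity), (green, row.green_intensity)):
            if amp <= 0:
                continue
            cx, cy = row.x, row.y
            x0, x1 = max(0, int(cx) - half), min(L, int(cx) + half + 1)
            y0, y1 = max(0, int(cy) - half), min(L, int(cy) + half + 1)
            xs = np.arange(x0, x1) - cx
            ys = np.arange(y0, y1) - cy
            g = np.exp(-(ys[:, None] ** 2 + xs[None, :] ** 2) / (2 * sigma ** 2))
            stack[row.frame, y0:y1, x0:x1] += amp * g

    rng = np.random.default_rng((config.rng_seed, 0xF1)) if config.noise_sd > 0 else None
    out = []
    for stack in (red, green):
        stack += config.background
        if rng is not None:
            stack += rng.normal(0.0, config.noise_sd, size=stack.shape)
        out.append(np.clip(stack, 0.0, None).astype(np.float32))
    return out[0], out[1]


def export_ground_truth(records: pd.DataFrame, path: str | Path) -> Path:
    """Write the ground-truth table as CSV (stable schema, float positions)."""
    path = Path(path)
    records.reindex(columns=GT_COLUMNS).to_csv(path, index=False)
    return path


def load_ground_truth(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if list(df.columns) != GT_COLUMNS:
        raise ValueError(f"unexpected ground-truth schema: {list(df.columns)}")
    return df.astype({"cell_id": int, "frame": int, "parent_id": int})


# ---------------------------------------------------------------------------
# Ground-truth views used to test downstream stages in isolation
# ---------------------------------------------------------------------------

def tracks_from_ground_truth(records: pd.DataFrame,
                             channel: Channel) -> list[ChannelTrack]:
    """Ideal per-channel tracks: a cell is present in the red channel during
    RED and YELLOW, and in the green channel during YELLOW and GREEN.
    Track ids equal ground-truth cell ids."""
    if channel is Channel.RED:
        visible = records["phase"].isin([Phase.RED.value, Phase.YELLOW.value])
    else:
        visible = records["phase"].isin([Phase.YELLOW.value, Phase.GREEN.value])
    sub = records[visible]
    tracks = []
    for cid, grp in sub.groupby("cell_id", sort=True):
        grp = grp.sort_values("frame")
        dets = [Detection(frame=int(r.frame), channel=channel, label_id=int(cid),
                          x=float(r.x), y=float(r.y), area=float("nan"),
                          perimeter=float("nan"),
                          mean_intensity=float(r.red_intensity if channel is Channel.RED
                                               else r.green_intensity))
                for r in grp.itertuples(index=False)]
        if dets:
            tracks.append(ChannelTrack(track_id=int(cid), channel=channel,
                                       detections=dets))
    return tracks


def yellow_intervals(records: pd.DataFrame) -> dict[int, tuple[int, int]]:
    """Ground-truth YELLOW window per cell: (first, last) frame, inclusive."""
    ylw = records[records["phase"] == Phase.YELLOW.value]
    return {int(cid): (int(g["frame"].min()), int(g["frame"].max()))
            for cid, g in ylw.groupby("cell_id")}
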