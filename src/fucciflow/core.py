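"""Core data model shared by every pipeline stage.

Coordinate convention (used everywhere in this package): images are indexed
``[row, col]``; positions are reported as ``(x, y)`` with ``x = column`` and
``y = row``, 0-based, pixel centers at integer coordinates. Time is measured in
frames (0-based); physical units are applied only at export.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class Channel(str, enum.Enum):
    """Fluorescence channel of the FUCCI reporter pair."""

    RED = "red"      # cdt1-MKO2, high in G0/G1
    GREEN = "green"  # geminin-mAG1, high in S/G2/M


class Phase(str, enum.Enum):
    """Observable color state of a nucleus.

    COLORLESS marks newborn cells in which neither fluorophore has
    accumulated; YELLOW is the co-expression window around the G1->S
    transition.
    """

    COLORLESS = "colorless"
    RED = "red"
    YELLOW = "yellow"
    GREEN = "green"


#: canonical cycle order, used by monotonicity checks
PHASE_ORDER = (Phase.COLORLESS, Phase.RED, Phase.YELLOW, Phase.GREEN)


@dataclass
class Detection:
    """One segmented nucleus in one frame of one channel."""

    frame: int
    channel: Channel
    label_id: int
    x: float
    y: float
    area: float
    perimeter: float
    mean_intensity: float
    contour: np.ndarray | None = None  # (N, 2) array of (x, y) vertices

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass
class ChannelTrack:
    """A time-ordered chain of detections in a single channel.

    Frames are strictly increasing; gaps (missed detections reconnected by
    gap closing) are allowed. ``position_at`` interpolates linearly across
    gaps so a position is defined for every frame in [start, end].
    """

    track_id: int
    channel: Channel
    detections: list[Detection] = field(default_factory=list)

    def __post_init__(self) -> None:
        frames = [d.frame for d in self.detections]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise ValueError("detections must have strictly increasing frames")

    @property
    def start_frame(self) -> int:
        return self.detections[0].frame

    @property
    def end_frame(self) -> int:
        return self.detections[-1].frame

    @property
    def frames(self) -> np.ndarray:
        """Frames with an actual detection (gap frames excluded)."""
        return np.array([d.frame for d in self.detections], dtype=int)

    def covered_frames(self) -> np.ndarray:
        """Every frame in [start, end], including gap-closed frames."""
        return np.arange(self.start_frame, self.end_frame + 1)

    def covers(self, frame: int) -> bool:
        return self.start_frame <= frame <= self.end_frame

    def position_at(self, frame: int | float) -> np.ndarray:
        """Centroid at ``frame``; gap frames are linearly interpolated."""
        if not self.covers(int(np.floor(frame))) and not self.covers(int(np.ceil(frame))):
            raise ValueError(f"frame {frame} outside track span "
                             f"[{self.start_frame}, {self.end_frame}]")
        f = self.frames
        x = np.interp(frame, f, [d.x for d in self.detections])
        y = np.interp(frame, f, [d.y for d in self.detections])
        return np.array([x, y])

    def detection_at(self, frame: int) -> Detection | None:
        for d in self.detections:
            if d.frame == frame:
                return d
        return None

    def __len__(self) -> int:
        return len(self.detections)


@dataclass
class FusedRecord:
    """One frame of a fused cell-cycle track."""

    frame: int
    x: float
    y: float
    phase: Phase
    source: str  # "red_only" | "green_only" | "both"
    area_red: float = float("nan")
    perimeter_red: float = float("nan")
    area_green: float = float("nan")
    perimeter_green: float = float("nan")


@dataclass
class FusedCellTrack:
    """One cell's merged red+green trajectory with per-frame phase labels.

    ``phase_intervals`` maps each observed phase to its inclusive
    ``(first_frame, last_frame)`` window; ``g1s_frame`` is the called G1->S
    transition (None when the co-expression window was not observed).
    """

    cell_id: int
    records: list[FusedRecord]
    phase_intervals: dict[Phase, tuple[int, int]]
    g1s_frame: int | None
    red_track_id: int | None
    green_track_id: int | None

    @property
    def start_frame(self) -> int:
        return self.records[0].frame

    @property
    def end_frame(self) -> int:
        return self.records[-1].frame

    def phase_at(self, frame: int) -> Phase | None:
        for r in self.records:
            if r.frame == frame:
                return r.phase
        return None

    def positions(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"frame": [r.frame for r in self.records],
             "x": [r.x for r in self.records],
             "y": [r.y for r in self.records]}
        )


# ---------------------------------------------------------------------------
# DataFrame conversions (the CSV-facing flat form of the objects above)
# ---------------------------------------------------------------------------

DETECTION_COLUMNS = ["frame", "channel", "label_id", "x", "y", "area",
                     "perimeter", "mean_intensity", "contour_wkt"]


def _contour_wkt(contour: np.ndarray | None) -> str:
    if contour is None or len(contour) < 3:
        return ""
    pts = ", ".join(f"{x:.3f} {y:.3f}" for x, y in contour)
    first = f"{contour[0, 0]:.3f} {contour[0, 1]:.3f}"
    return f"POLYGON (({pts}, {first}))"


def detections_to_frame(detections: list[Detection]) -> pd.DataFrame:
    rows = [
        (d.frame, d.channel.value, d.label_id, d.x, d.y, d.area,
         d.perimeter, d.mean_intensity, _contour_wkt(d.contour))
        for d in detections
    ]
    return pd.DataFrame(rows, columns=DETECTION_COLUMNS)


def detections_from_frame(df: pd.DataFrame) -> list[Detection]:
    dets = []
    for row in df.itertuples(index=False):
        dets.append(Detection(
            frame=int(row.frame), channel=Channel(row.channel),
            label_id=int(row.label_id), x=float(row.x), y=float(row.y),
            area=float(row.area), perimeter=float(row.perimeter),
            mean_intensity=float(row.mean_intensity)))
    return dets


TRACK_COLUMNS = ["track_id", "channel", "frame", "x", "y", "area",
                 "perimeter", "mean_intensity"]


def tracks_to_frame(tracks: list[ChannelTrack]) -> pd.DataFrame:
    rows = []
    for t in tracks:
        for d in t.detections:
            rows.append((t.track_id, t.channel.value, d.frame, d.x, d.y,
                         d.area, d.perimeter, d.mean_intensity))
    return pd.DataFrame(rows, columns=TRACK_COLUMNS)


def tracks_from_frame(df: pd.DataFrame) -> list[ChannelTrack]:
    tracks = []
    for (tid, chan), grp in df.groupby(["track_id", "channel"], sort=True):
        grp = grp.sort_values("frame")
        dets = [Detection(frame=int(r.frame), channel=Channel(chan),
                          label_id=int(tid), x=float(r.x), y=float(r.y),
                          area=float(getattr(r, "area", float("nan"))),
                          perimeter=float(getattr(r, "perimeter", float("nan"))),
                          mean_intensity=float(getattr(r, "mean_intensity", float("nan"))))
                for r in grp.itertuples(index=False)]
        tracks.append(ChannelTrack(track_id=int(tid), channel=Channel(chan),
                                   detections=dets))
    return tracks


FUSED_COLUMNS = ["cell_id", "frame", "x", "y", "phase", "source",
                 "area_red", "perimeter_red", "area_green", "perimeter_green"]


def fused_to_frame(cells: list[FusedCellTrack]) -> pd.DataFrame:
    rows = []
    for c in cells:
        for r in c.records:
            rows.append((c.cell_id, r.frame, r.x, r.y, r.phase.value, r.source,
                         r.area_red, r.perimeter_red, r.area_green,
                         r.perimeter_green))
    return pd.DataFrame(rows, columns=FUSED_COLUMNS)


def fused_summary_frame(cells: list[FusedCellTrack]) -> pd.DataFrame:
    """Per-cell summary: phase intervals, G1->S frame, source track ids."""
    rows = []
    for c in cells:
        row: dict = {"cell_id": c.cell_id,
                     "start_frame": c.start_frame, "end_frame": c.end_frame,
                     "red_track_id": c.red_track_id,
                     "green_track_id": c.green_track_id,
                     "g1s_frame": c.g1s_frame}
        for ph in (Phase.RED, Phase.YELLOW, Phase.GREEN):
            iv = c.phase_intervals.get(ph)
            row[f"{ph.value}_start"] = None if iv is None else iv[0]
            row[f"{ph.value}_end"] = None if iv is None else iv[1]
        rows.append(row)
    df = pd.DataFrame(rows)
    for col in df.columns:  # ids and frames are integers or missing
        df[col] = df[col].astype("Int64")
    return df
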