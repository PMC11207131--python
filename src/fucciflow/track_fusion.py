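"""Red/green track pairing and fusion into continuous cell-cycle tracks.

A cell expressing the FUCCI reporters is seen twice: as a red-channel track
(G0/G1 through the co-expression window) and as a green-channel track (the
co-expression window through mitosis). The two tracks coexist only around the
G1->S transition, where the nucleus appears yellow. This module decides which
red and green tracks belong to the same cell and merges them:

1. a coarse spatial pre-filter keeps only red/green pairs whose trajectories
   ever visited the same square of an n x n grid over the field of view
   (n = 10 by default);
2. each surviving pair is scored by the similarity metric ``s_ij``, the
   average Euclidean distance between the two nuclei's centers over their
   temporally overlapping frames;
3. pairs with ``s_ij`` strictly below the threshold (2 px at 10x) are
   accepted greedily in ascending ``s_ij``, enforcing a one-to-one matching;
4. matched pairs are fused into a single track labelled RED / YELLOW / GREEN
   per frame, the YELLOW window being exactly the frames covered by both
   source tracks; unmatched tracks survive as single-phase cells so
   tissue-level counts still see every nucleus.

The G1->S transition frame is then called from the YELLOW window alone —
its start, midpoint, or end — with no user-chosen intensity threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import FusionParams
from .core import ChannelTrack, FusedCellTrack, FusedRecord, Phase


@dataclass
class CandidatePair:
    """A red/green track pair that survived the grid pre-filter, with its
    similarity score (average per-overlapping-frame center distance)."""

    red_track_id: int
    green_track_id: int
    overlap_frames: list[int]
    s_ij: float


def _grid_occupancy(track: ChannelTrack, grid_n: int, fov: float) -> set[tuple[int, int]]:
    """Half-open grid squares visited by a track's detections; the far FOV
    edges close onto the last square."""
    side = fov / grid_n
    squares = set()
    for d in track.detections:
        gx = min(int(d.x // side), grid_n - 1)
        gy = min(int(d.y // side), grid_n - 1)
        squares.add((gx, gy))
    return squares


def grid_prefilter(red_tracks: list[ChannelTrack], green_tracks: list[ChannelTrack],
                   grid_n: int, fov: float) -> list[tuple[int, int]]:
    """Candidate (red_id, green_id) pairs: tracks that passed through the
    same grid square at any time in their trajectories."""
    occ_green: dict[tuple[int, int], set[int]] = {}
    for g in green_tracks:
        for sq in _grid_occupancy(g, grid_n, fov):
            occ_green.setdefault(sq, set()).add(g.track_id)
    candidates = set()
    for r in red_tracks:
        for sq in _grid_occupancy(r, grid_n, fov):
            for gid in occ_green.get(sq, ()):
                candidates.add((r.track_id, gid))
    return sorted(candidates)


def similarity(red_track: ChannelTrack, green_track: ChannelTrack,
               min_overlap_frames: int = 2) -> CandidatePair | None:
    """Score a pair by the mean center distance over overlapping frames.

    A frame overlaps when both tracks cover it (a detection, or a gap-closed
    frame whose position is linearly interpolated). Returns None when fewer
    than ``min_overlap_frames`` frames overlap.
    """
    f0 = max(red_track.start_frame, green_track.start_frame)
    f1 = min(red_track.end_frame, green_track.end_frame)
    frames = list(range(f0, f1 + 1))
    if len(frames) < min_overlap_frames:
        return None
    dists = [float(np.linalg.norm(red_track.position_at(f) - green_track.position_at(f)))
             for f in frames]
    return CandidatePair(red_track_id=red_track.track_id,
                         green_track_id=green_track.track_id,
                         overlap_frames=frames, s_ij=float(np.mean(dists)))


def match_pairs(candidates: list[CandidatePair], similarity_threshold: float
                ) -> list[CandidatePair]:
    """One-to-one matching: drop pairs with ``s_ij`` >= threshold (strict
    acceptance), then accept survivors in ascending ``s_ij`` (ties by lower
    red id, then green id), skipping pairs whose red or green track is
    already taken."""
    survivors = [c for c in candidates if c.s_ij < similarity_threshold]
    survivors.sort(key=lambda c: (c.s_ij, c.red_track_id, c.green_track_id))
    taken_red: set[int] = set()
    taken_green: set[int] = set()
    accepted = []
    for c in survivors:
        if c.red_track_id in taken_red or c.green_track_id in taken_green:
            continue
        accepted.append(c)
        taken_red.add(c.red_track_id)
        taken_green.add(c.green_track_id)
    return accepted


def _morphology(det) -> tuple[float, float]:
    if det is None:
        return float("nan"), float("nan")
    return det.area, det.perimeter


def fuse(red_track: ChannelTrack | None, green_track: ChannelTrack | None,
         cell_id: int = 0,
         transition_criterion: str = "window_mid") -> FusedCellTrack:
    """Merge a matched red/green pair (or a lone track) into one cell track.

    Per frame: RED where only the red track covers it, YELLOW where both do,
    GREEN where only the green track does. The fused position is the red
    centroid on RED frames, the green centroid on GREEN frames, and the mean
    of both centroids on YELLOW frames. Morphology is carried from whichever
    channel observed the frame.
    """
    if red_track is None and green_track is None:
        raise ValueError("at least one source track is required")
    if red_track is not None and green_track is not None:
        f0 = min(red_track.start_frame, green_track.start_frame)
        f1 = max(red_track.end_frame, green_track.end_frame)
        if (min(red_track.end_frame, green_track.end_frame)
                < max(red_track.start_frame, green_track.start_frame)):
            raise ValueError("matched pair has zero overlapping frames")
    elif red_track is not None:
        f0, f1 = red_track.start_frame, red_track.end_frame
    else:
        f0, f1 = green_track.start_frame, green_track.end_frame

    records = []
    for f in range(f0, f1 + 1):
        in_red = red_track is not None and red_track.covers(f)
        in_green = green_track is not None and green_track.covers(f)
        if in_red and in_green:
            pr, pg = red_track.position_at(f), green_track.position_at(f)
            pos = 0.5 * (pr + pg)
            phase, source = Phase.YELLOW, "both"
        elif in_red:
            pos = red_track.position_at(f)
            phase, source = Phase.RED, "red_only"
        elif in_green:
            pos = green_track.position_at(f)
            phase, source = Phase.GREEN, "green_only"
        else:
            continue  # outside both spans (cannot happen for matched pairs)
        ar, pr_ = _morphology(red_track.detection_at(f) if in_red else None)
        ag, pg_ = _morphology(green_track.detection_at(f) if in_green else None)
        records.append(FusedRecord(frame=f, x=float(pos[0]), y=float(pos[1]),
                                   phase=phase, source=source,
                                   area_red=ar, perimeter_red=pr_,
                                   area_green=ag, perimeter_green=pg_))

    intervals: dict[Phase, tuple[int, int]] = {}
    for r in records:
        if r.phase not in intervals:
            intervals[r.phase] = (r.frame, r.frame)
        else:
            a, _ = intervals[r.phase]
            intervals[r.phase] = (a, r.frame)

    fused = FusedCellTrack(
        cell_id=cell_id, records=records, phase_intervals=intervals,
        g1s_frame=None,
        red_track_id=None if red_track is None else red_track.track_id,
        green_track_id=None if green_track is None else green_track.track_id)
    fused.g1s_frame = g1s_transition(fused, transition_criterion)
    return fused


def g1s_transition(fused: FusedCellTrack,
                   criterion: str = "window_mid") -> int | None:
    """Call the G1->S transition frame from the YELLOW (co-expression)
    window: its first frame, its floor midpoint, or its last frame. None
    when the window was never observed."""
    iv = fused.phase_intervals.get(Phase.YELLOW)
    if iv is None:
        return None
    first, last = iv
    if criterion == "window_start":
        return first
    if criterion == "window_end":
        return last
    if criterion == "window_mid":
        return math.floor((first + last) / 2)
    raise ValueError(f"unknown criterion {criterion!r}")


def fuse_all(red_tracks: list[ChannelTrack], green_tracks: list[ChannelTrack],
             params: FusionParams, fov: float,
             use_prefilter: bool = True) -> list[FusedCellTrack]:
    """Full fusion stage: pre-filter, score, match, fuse, call G1->S.

    Unmatched tracks become single-phase cells. Output cell ids are ordered
    by start frame, then y, then x of the first record. ``use_prefilter``
    exists so the grid pre-filter can be checked against the brute-force
    all-pairs computation.
    """
    red_by_id = {t.track_id: t for t in red_tracks}
    green_by_id = {t.track_id: t for t in green_tracks}
    if use_prefilter:
        cand_ids = grid_prefilter(red_tracks, green_tracks, params.grid_n, fov)
    else:
        cand_ids = [(r.track_id, g.track_id)
                    for r in red_tracks for g in green_tracks]
    scored = []
    for rid, gid in cand_ids:
        c = similarity(red_by_id[rid], green_by_id[gid],
                       params.min_overlap_frames)
        if c is not None:
            scored.append(c)
    accepted = match_pairs(scored, params.similarity_threshold)

    fused = []
    matched_red = {c.red_track_id for c in accepted}
    matched_green = {c.green_track_id for c in accepted}
    for c in accepted:
        fused.append(fuse(red_by_id[c.red_track_id], green_by_id[c.green_track_id],
                          transition_criterion=params.transition_criterion))
    for t in red_tracks:
        if t.track_id not in matched_red:
            fused.append(fuse(t, None,
                              transition_criterion=params.transition_criterion))
    for t in green_tracks:
        if t.track_id not in matched_green:
            fused.append(fuse(None, t,
                              transition_criterion=params.transition_criterion))

    fused.sort(key=lambda c: (c.start_frame, c.records[0].y, c.records[0].x))
    for i, c in enumerate(fused):
        c.cell_id = i
    return fused


def fused_from_frame(df, transition_criterion: str = "window_mid"
                     ) -> list[FusedCellTrack]:
    """Rebuild fused cell tracks from a fused-tracks table (the inverse of
    :func:`fucciflow.core.fused_to_frame`); G1->S frames are re-called with
    the given criterion."""
    cells = []
    for cid, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("frame")
        records = [FusedRecord(frame=int(r.frame), x=float(r.x), y=float(r.y),
                               phase=Phase(r.phase), source=str(r.source),
                               area_red=float(getattr(r, "area_red", float("nan"))),
                               perimeter_red=float(getattr(r, "perimeter_red", float("nan"))),
                               area_green=float(getattr(r, "area_green", float("nan"))),
                               perimeter_green=float(getattr(r, "perimeter_green", float("nan"))))
                   for r in grp.itertuples(index=False)]
        intervals: dict[Phase, tuple[int, int]] = {}
        for r in records:
            if r.phase not in intervals:
                intervals[r.phase] = (r.frame, r.frame)
            else:
                intervals[r.phase] = (intervals[r.phase][0], r.frame)
        cell = FusedCellTrack(cell_id=int(cid), records=records,
                              phase_intervals=intervals, g1s_frame=None,
                              red_track_id=None, green_track_id=None)
        cell.g1s_frame = g1s_transition(cell, transition_criterion)
        cells.append(cell)
    return cells
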