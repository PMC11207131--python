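"""LAP-style per-channel tracking: frame-to-frame linking plus gap closing.

Frame-to-frame links are the minimum-total-cost one-to-one assignment on
Euclidean centroid distance (Hungarian algorithm), with links beyond
``max_link_distance_px`` forbidden. Track fragments are then reconnected
across detection gaps of up to ``max_gap_frames`` frames by a second
assignment over fragment ends and starts. A TrackMate-XML subset can be
imported (and exported) for interoperability with FIJI-produced tracks.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
from scipy.optimize import linear_sum_assignment

from .config import TrackingParams
from .core import Channel, ChannelTrack, Detection

_FORBIDDEN = 1e12


def _solve_lap(cost: np.ndarray, allowed: np.ndarray) -> list[tuple[int, int]]:
    """Min-cost one-to-one assignment; pairs where ``allowed`` is False are
    never returned."""
    if cost.size == 0:
        return []
    padded = np.where(allowed, cost, _FORBIDDEN)
    rows, cols = linear_sum_assignment(padded)
    return [(int(i), int(j)) for i, j in zip(rows, cols) if allowed[i, j]]


def link_frames(dets_a: list[Detection], dets_b: list[Detection],
                max_dist: float) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Assign detections of frame *a* to frame *b*.

    Returns ``(pairs, unmatched_a, unmatched_b)`` where pairs are index pairs
    into the two input lists. Any link longer than ``max_dist`` is forbidden;
    leftover detections are track ends (a) or starts (b).
    """
    if not dets_a or not dets_b:
        return [], list(range(len(dets_a))), list(range(len(dets_b)))
    pa = np.array([[d.x, d.y] for d in dets_a])
    pb = np.array([[d.x, d.y] for d in dets_b])
    cost = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
    pairs = _solve_lap(cost, cost <= max_dist)
    ia = {i for i, _ in pairs}
    ib = {j for _, j in pairs}
    return (pairs,
            [i for i in range(len(dets_a)) if i not in ia],
            [j for j in range(len(dets_b)) if j not in ib])


def build_tracks(detections: list[Detection],
                 params: TrackingParams) -> list[ChannelTrack]:
    """Link detections (one channel) into tracks with gap closing.

    Track ids are assigned deterministically by (start frame, then y, then x
    of the first detection); tracks with fewer than ``min_track_length``
    detections are discarded.
    """
    if not detections:
        return []
    channels = {d.channel for d in detections}
    if len(channels) > 1:
        raise ValueError("build_tracks expects detections from one channel")
    channel = channels.pop()

    by_frame: dict[int, list[Detection]] = {}
    for d in detections:
        by_frame.setdefault(d.frame, []).append(d)
    for dets in by_frame.values():  # deterministic intra-frame order
        dets.sort(key=lambda d: (d.y, d.x, d.label_id))

    # --- pass 1: frame-to-frame linking ------------------------------------
    fragments: list[list[Detection]] = []
    active: list[list[Detection]] = []
    for frame in range(min(by_frame), max(by_frame) + 1):
        dets = by_frame.get(frame, [])
        carried = [t for t in active if t[-1].frame == frame - 1]
        stalled = [t for t in active if t[-1].frame != frame - 1]
        fragments.extend(stalled)
        ends = [t[-1] for t in carried]
        pairs, unmatched_end, unmatched_new = link_frames(
            ends, dets, params.max_link_distance_px)
        new_active = []
        for i, j in pairs:
            carried[i].append(dets[j])
            new_active.append(carried[i])
        fragments.extend(carried[i] for i in unmatched_end)
        new_active.extend([dets[j]] for j in unmatched_new)
        active = new_active
    fragments.extend(active)

    # --- pass 2: gap closing ------------------------------------------------
    if params.max_gap_frames > 0 and len(fragments) > 1:
        n = len(fragments)
        cost = np.zeros((n, n))
        allowed = np.zeros((n, n), dtype=bool)
        for i, fi in enumerate(fragments):
            for j, fj in enumerate(fragments):
                if i == j:
                    continue
                # dt-1 missed frames; a gap of g frames means dt = g + 1
                dt = fj[0].frame - fi[-1].frame
                if not 2 <= dt <= params.max_gap_frames + 1:
                    continue
                d = float(np.hypot(fj[0].x - fi[-1].x, fj[0].y - fi[-1].y))
                if d <= params.max_gap_distance_px:
                    cost[i, j] = d
                    allowed[i, j] = True
        successor = dict(_solve_lap(cost, allowed))
        has_pred = set(successor.values())
        merged: list[list[Detection]] = []
        for i, frag in enumerate(fragments):
            if i in has_pred:
                continue
            chain = list(frag)
            k = i
            while k in successor:
                k = successor[k]
                chain.extend(fragments[k])
            merged.append(chain)
        fragments = merged

    fragments = [f for f in fragments if len(f) >= params.min_track_length]
    fragments.sort(key=lambda f: (f[0].frame, f[0].y, f[0].x))
    return [ChannelTrack(track_id=i, channel=channel, detections=f)
            for i, f in enumerate(fragments)]


# ---------------------------------------------------------------------------
# TrackMate-XML subset interoperability
# ---------------------------------------------------------------------------

def import_trackmate_xml(path: str | Path,
                         channel: Channel = Channel.RED) -> list[ChannelTrack]:
    """Rebuild tracks from a TrackMate-style XML file.

    Reads ``Spot`` elements (ID, FRAME, POSITION_X, POSITION_Y, pixel units)
    and ``Edge`` elements (SPOT_SOURCE_ID, SPOT_TARGET_ID); every other
    element is ignored. Tracks are the connected components of the edge
    graph, ordered by frame.
    """
    root = ET.parse(str(path)).getroot()
    spots: dict[int, Detection] = {}
    for el in root.iter("Spot"):
        sid = int(el.attrib["ID"])
        spots[sid] = Detection(
            frame=int(round(float(el.attrib["FRAME"]))), channel=channel,
            label_id=sid, x=float(el.attrib["POSITION_X"]),
            y=float(el.attrib["POSITION_Y"]),
            area=float(el.attrib.get("AREA", "nan")),
            perimeter=float("nan"),
            mean_intensity=float(el.attrib.get("MEAN_INTENSITY", "nan")))

    parent: dict[int, int] = {sid: sid for sid in spots}

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for el in root.iter("Edge"):
        s, t = int(el.attrib["SPOT_SOURCE_ID"]), int(el.attrib["SPOT_TARGET_ID"])
        if s not in spots or t not in spots:
            raise ValueError(f"edge references unknown spot: {s} -> {t}")
        parent[find(s)] = find(t)

    components: dict[int, list[Detection]] = {}
    linked = {int(e.attrib[k]) for e in root.iter("Edge")
              for k in ("SPOT_SOURCE_ID", "SPOT_TARGET_ID")}
    for sid in spots:
        if sid in linked:
            components.setdefault(find(sid), []).append(spots[sid])

    tracks = []
    frags = sorted(components.values(),
                   key=lambda dets: (min(d.frame for d in dets),
                                     dets[0].y, dets[0].x))
    for i, dets in enumerate(frags):
        dets.sort(key=lambda d: d.frame)
        tracks.append(ChannelTrack(track_id=i, channel=channel, detections=dets))
    return tracks


def export_trackmate_xml(tracks: list[ChannelTrack], path: str | Path) -> Path:
    """Write tracks in the same minimal TrackMate-XML subset the importer
    reads (spot ids are regenerated)."""
    root = ET.Element("TrackMate")
    model = ET.SubElement(root, "Model", spatialunits="pixel", timeunits="frame")
    all_spots = ET.SubElement(model, "AllSpots")
    all_tracks = ET.SubElement(model, "AllTracks")
    sid = 0
    frames: dict[int, ET.Element] = {}
    for t in tracks:
        ids = []
        for d in t.detections:
            if d.frame not in frames:
                frames[d.frame] = ET.SubElement(all_spots, "SpotsInFrame",
                                                frame=str(d.frame))
            ET.SubElement(frames[d.frame], "Spot", ID=str(sid),
                          FRAME=str(d.frame),
                          POSITION_X=f"{d.x:.6f}", POSITION_Y=f"{d.y:.6f}")
            ids.append(sid)
            sid += 1
        track_el = ET.SubElement(all_tracks, "Track", TRACK_ID=str(t.track_id))
        for a, b in zip(ids, ids[1:]):
            ET.SubElement(track_el, "Edge", SPOT_SOURCE_ID=str(a),
                          SPOT_TARGET_ID=str(b))
    path = Path(path)
    ET.ElementTree(root).write(str(path), xml_declaration=True, encoding="utf-8")
    return path
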