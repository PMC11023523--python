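"""Linking of per-frame defects into tracks, and topology event calling.

Defects are linked between consecutive frames by greedy mutual-nearest-
neighbour matching within a link radius, respecting charge. Annihilation
events are (+1, −1) track pairs whose deaths coincide in time and space;
proliferation events are the symmetric condition on births. Around an
annihilation, the velocity direction in the corridor between the two
defects reverses by ~180°, which :func:`reversal_angle` measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synth import VelocityFieldFrame
from .topology import DefectSet


@dataclass
class DefectTrack:
    track_id: int
    charge: int
    frames: list[int] = field(default_factory=list)
    positions: list[np.ndarray] = field(default_factory=list)

    @property
    def birth(self) -> int:
        return self.frames[0]

    @property
    def death(self) -> int:
        """Last frame in which the defect was detected."""
        return self.frames[-1]

    @property
    def n_points(self) -> int:
        return len(self.frames)

    def position_at(self, which: str) -> np.ndarray:
        return self.positions[0] if which == "birth" else self.positions[-1]


@dataclass
class TopologyEvent:
    type: str                 # "annihilation" | "proliferation"
    frame: int
    midpoint: np.ndarray
    plus_track: int
    minus_track: int


def link_tracks(sets: list[DefectSet], link_radius: float,
                max_gap: int = 0) -> list[DefectTrack]:
    """Greedy mutual-nearest-neighbour linking of same-charge defects.

    Candidate links between consecutive frames are sorted by distance and
    accepted while both endpoints are unclaimed and the distance is below
    ``link_radius``. Unmatched records start or end tracks. Gap closing
    is disabled by default (the persistence filter already smooths
    single-frame dropouts).
    """
    if max_gap != 0:
        raise NotImplementedError("gap closing not supported")
    tracks: list[DefectTrack] = []
    open_tracks: dict[int, DefectTrack] = {}   # record index -> track

    def _new_track(rec, frame):
        t = DefectTrack(track_id=len(tracks), charge=rec.charge)
        t.frames.append(frame)
        t.positions.append(np.asarray(rec.position, dtype=float))
        tracks.append(t)
        return t

    prev = None
    for s in sets:
        cur: dict[int, DefectTrack] = {}
        if prev is None or not len(prev):
            for k, rec in enumerate(s.records):
                cur[k] = _new_track(rec, s.frame)
        else:
            cands = []
            for a, ra in enumerate(prev.records):
                for b, rb in enumerate(s.records):
                    if ra.charge != rb.charge:
                        continue
                    dist = float(np.hypot(*(np.asarray(rb.position)
                                            - np.asarray(ra.position))))
                    if dist <= link_radius:
                        cands.append((dist, a, b))
            cands.sort()
            used_a: set[int] = set()
            used_b: set[int] = set()
            for dist, a, b in cands:
                if a in used_a or b in used_b:
                    continue
                used_a.add(a)
                used_b.add(b)
                tr = open_tracks[a]
                tr.frames.append(s.frame)
                tr.positions.append(np.asarray(s.records[b].position,
                                               dtype=float))
                cur[b] = tr
            for b, rec in enumerate(s.records):
                if b not in used_b:
                    cur[b] = _new_track(rec, s.frame)
        open_tracks = cur
        prev = s
    return tracks


def track_velocity(track: DefectTrack, frame_interval_h: float) -> float | None:
    """Mean defect speed in μm/h: path length / number of time points.

    Returns None (excluded) for tracks shorter than 25 consecutive time
    points, matching the stability requirement for defect-velocity
    estimates.
    """
    if track.n_points < 25:
        return None
    pos = np.asarray(track.positions)
    path = float(np.hypot(*(np.diff(pos, axis=0)).T.reshape(2, -1)).sum())
    per_point = path / track.n_points           # μm per time point
    return per_point / frame_interval_h


def mean_defect_velocity(tracks: list[DefectTrack], frame_interval_h: float,
                         charge: int | None = None) -> float | None:
    """Per-track mean of eligible track velocities (a 'per-well' average)."""
    vels = [track_velocity(t, frame_interval_h) for t in tracks
            if charge is None or t.charge == charge]
    vels = [v for v in vels if v is not None]
    return float(np.mean(vels)) if vels else None


def call_events(tracks: list[DefectTrack], event_radius: float = 165.0,
                event_frame_window: int = 1,
                frame_range: tuple[int, int] | None = None,
                bounds: tuple[float, float, float, float] | None = None,
                border_margin: float = 165.0) -> list[TopologyEvent]:
    """Annihilation and proliferation events from linked tracks.

    Annihilation: a (+1, −1) track pair whose deaths are within
    ``event_frame_window`` frames of each other and whose final positions
    are within ``event_radius``; proliferation is the symmetric condition
    on births. Tracks dying at the last observed frame (or born at the
    first) are not event candidates, and endpoints within
    ``border_margin`` of the field bounds are excluded — a defect leaving
    the field of view is not an annihilation.
    """
    if frame_range is None:
        lo = min((t.birth for t in tracks), default=0)
        hi = max((t.death for t in tracks), default=0)
    else:
        lo, hi = frame_range

    def _interior(pos) -> bool:
        if bounds is None:
            return True
        xmin, xmax, ymin, ymax = bounds
        return (xmin + border_margin <= pos[0] <= xmax - border_margin
                and ymin + border_margin <= pos[1] <= ymax - border_margin)

    events: list[TopologyEvent] = []
    for kind, which, edge_frame in (("annihilation", "death", hi),
                                    ("proliferation", "birth", lo)):
        plus = [t for t in tracks if t.charge == +1
                and getattr(t, which) != edge_frame
                and _interior(t.position_at(which))]
        minus = [t for t in tracks if t.charge == -1
                 and getattr(t, which) != edge_frame
                 and _interior(t.position_at(which))]
        cands = []
        for tp in plus:
            for tm in minus:
                if abs(getattr(tp, which) - getattr(tm, which)) \
                        > event_frame_window:
                    continue
                dist = float(np.hypot(*(tp.position_at(which)
                                        - tm.position_at(which))))
                if dist <= event_radius:
                    cands.append((dist, tp, tm))
        cands.sort(key=lambda c: c[0])
        used: set[int] = set()
        for dist, tp, tm in cands:
            if tp.track_id in used or tm.track_id in used:
                continue
            used.update((tp.track_id, tm.track_id))
            mid = 0.5 * (tp.position_at(which) + tm.position_at(which))
            frame = max(getattr(tp, which), getattr(tm, which)) \
                if kind == "annihilation" \
                else min(getattr(tp, which), getattr(tm, which))
            events.append(TopologyEvent(type=kind, frame=frame, midpoint=mid,
                                        plus_track=tp.track_id,
                                        minus_track=tm.track_id))
    return events


def partner_exchanges(events: list[TopologyEvent]) -> list[tuple]:
    """Proliferation → annihilation chains sharing a track.

    A defect born in a proliferation event that later annihilates with a
    defect from a *different* pair has switched partners — the signature
    of collective reorientation through transient defect pairs. Reported
    descriptively as (proliferation, annihilation) pairs; no summary
    statistic is defined.
    """
    prolifs = [e for e in events if e.type == "proliferation"]
    annis = [e for e in events if e.type == "annihilation"]
    chains = []
    for p in prolifs:
        born = {p.plus_track, p.minus_track}
        for a in annis:
            if a.frame <= p.frame:
                continue
            dying = {a.plus_track, a.minus_track}
            if len(born & dying) == 1:       # one partner kept, one switched
                chains.append((p, a))
    return chains


def is_clean_annihilation(event: TopologyEvent, sets: list[DefectSet],
                          clearance_radius: float = 330.0,
                          clearance_frames: int = 6) -> bool:
    """True if the event really removed the pair from its neighbourhood.

    A genuine annihilation leaves the region defect-free; if any defect
    is detected within ``clearance_radius`` of the event midpoint during
    the following ``clearance_frames`` frames, the 'deaths' were more
    likely detection dropouts or a partner exchange, and the corridor
    reversal is not a clean before/after comparison.
    """
    if event.type != "annihilation":
        raise ValueError("expected an annihilation event")
    for fr in range(event.frame + 1,
                    min(event.frame + 1 + clearance_frames, len(sets))):
        for rec in sets[fr].records:
            if np.hypot(*(np.asarray(rec.position) - event.midpoint)) \
                    < clearance_radius:
                return False
    return True


def _corridor_mask(frame: VelocityFieldFrame, p0: np.ndarray, p1: np.ndarray,
                   half_width: float) -> np.ndarray:
    X, Y = np.meshgrid(frame.x, frame.y)
    seg = p1 - p0
    L = float(np.hypot(*seg))
    if L == 0:
        return (np.hypot(X - p0[0], Y - p0[1]) <= half_width) & frame.valid()
    t = ((X - p0[0]) * seg[0] + (Y - p0[1]) * seg[1]) / L**2
    perp = np.abs((X - p0[0]) * seg[1] - (Y - p0[1]) * seg[0]) / L
    return (t >= 0) & (t <= 1) & (perp <= half_width) & frame.valid()


def reversal_angle(event: TopologyEvent, tracks: list[DefectTrack],
                   frames: list[VelocityFieldFrame],
                   event_frame_window: int = 1,
                   half_width: float | None = None,
                   end_margin: float = 0.25,
                   min_points: int = 2) -> float | None:
    """Absolute change (degrees) of corridor migration direction across
    an annihilation.

    The corridor is the rectangle between the pair's final positions
    (half-width one grid spacing by default), shortened by ``end_margin``
    of the segment at each end so the swirling flow right at the defect
    cores does not dilute the corridor direction. The circular-mean
    velocity direction there is compared between the last frame both
    defects were present and ``event_frame_window`` frames after the
    event. Returns a value in [0°, 180°], or None if the required frames
    are unavailable or the corridor covers fewer than ``min_points``
    grid points (the direction change of an unresolved corridor is not
    measurable).
    """
    if event.type != "annihilation":
        raise ValueError("reversal_angle requires an annihilation event")
    by_id = {t.track_id: t for t in tracks}
    tp, tm = by_id[event.plus_track], by_id[event.minus_track]
    before_f = min(tp.death, tm.death)
    after_f = event.frame + event_frame_window
    if before_f < 0 or after_f >= len(frames):
        return None
    p0, p1 = tp.positions[-1], tm.positions[-1]
    seg = p1 - p0
    p0 = p0 + end_margin * seg
    p1 = p1 - end_margin * seg
    hw = half_width if half_width is not None else frames[0].spacing
    mask = _corridor_mask(frames[before_f], p0, p1, hw)
    if mask.sum() < max(min_points, 1):
        return None

    def _mean_dir(fr: VelocityFieldFrame) -> float:
        theta = fr.direction()[mask & fr.valid()]
        return float(np.arctan2(np.sin(theta).mean(), np.cos(theta).mean()))

    a0 = _mean_dir(frames[before_f])
    a1 = _mean_dir(frames[after_f])
    dpsi = np.abs(np.arctan2(np.sin(a1 - a0), np.cos(a1 - a0)))
    return float(np.degrees(dpsi))
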