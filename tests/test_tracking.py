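import numpy as np
import pytest

import polarweave as pw
from polarweave.topology import DefectRecord, DefectSet
from polarweave.tracking import call_events, link_tracks, track_velocity


def _sets_from_paths(paths, charges, n_frames, present=None):
    """Build per-frame DefectSets from path callables x(t), y(t)."""
    sets = []
    for f in range(n_frames):
        recs = []
        for k, path in enumerate(paths):
            if present is not None and not present[k](f):
                continue
            x, y = path(f)
            recs.append(DefectRecord(f, np.array([x, y], float), charges[k]))
        sets.append(DefectSet(frame=f, time=f * 0.25, records=recs))
    return sets


class TestLinkTracks:
    def test_static_defect_single_track(self):
        sets = _sets_from_paths([lambda f: (0.0, 0.0)], [+1], 30)
        tracks = link_tracks(sets, link_radius=165.0)
        assert len(tracks) == 1
        assert tracks[0].n_points == 30

    def test_crossing_defects_stay_separate(self):
        # same charge, crossing in x but separated in y by > link radius
        a = lambda f: (-500.0 + 50.0 * f, 200.0)
        b = lambda f: (500.0 - 50.0 * f, -200.0)
        sets = _sets_from_paths([a, b], [+1, +1], 21)
        tracks = link_tracks(sets, link_radius=165.0)
        assert len(tracks) == 2
        assert all(t.n_points == 21 for t in tracks)

    def test_charge_respected(self):
        # a +1 and a -1 at the same position never link
        sets = _sets_from_paths([lambda f: (0.0, 0.0)], [+1], 5)
        sets2 = _sets_from_paths([lambda f: (0.0, 0.0)], [-1], 5)
        mixed = [DefectSet(frame=f, time=f * 0.25,
                           records=(sets[f].records if f < 2
                                    else sets2[f].records))
                 for f in range(5)]
        tracks = link_tracks(mixed, link_radius=165.0)
        assert sorted((t.charge, t.n_points) for t in tracks) \
            == [(-1, 3), (1, 2)]

    def test_jittered_tracks_correctly_linked(self):
        rng = np.random.default_rng(0)
        n, n_frames = 6, 25
        starts = rng.uniform(-1500, 1500, size=(n, 2))
        while True:  # keep starts well separated
            d = np.hypot(*(starts[:, None] - starts[None]).T)
            np.fill_diagonal(d, np.inf)
            if d.min() > 600:
                break
            starts = rng.uniform(-1500, 1500, size=(n, 2))
        jit = rng.uniform(-40, 40, size=(n_frames, n, 2))
        paths = [(lambda f, k=k: tuple(starts[k] + jit[f, k]))
                 for k in range(n)]
        sets = _sets_from_paths(paths, [+1] * 3 + [-1] * 3, n_frames)
        tracks = link_tracks(sets, link_radius=165.0)
        assert len(tracks) == n
        assert all(t.n_points == n_frames for t in tracks)


class TestTrackVelocity:
    def test_static_track_zero(self):
        sets = _sets_from_paths([lambda f: (0.0, 0.0)], [+1], 25)
        t = link_tracks(sets, 165.0)[0]
        assert track_velocity(t, frame_interval_h=0.25) == 0.0

    def test_straight_track_formula(self):
        # 30 points, 10 um per frame: (29*10)/30 um per point
        sets = _sets_from_paths([lambda f: (10.0 * f, 0.0)], [+1], 30)
        t = link_tracks(sets, 165.0)[0]
        v = track_velocity(t, frame_interval_h=0.25)
        assert v == pytest.approx((29 * 10 / 30) / 0.25)

    def test_short_track_excluded(self):
        sets = _sets_from_paths([lambda f: (10.0 * f, 0.0)], [+1], 24)
        t = link_tracks(sets, 165.0)[0]
        assert track_velocity(t, frame_interval_h=0.25) is None

    def test_per_well_mean(self):
        sets = _sets_from_paths(
            [lambda f: (10.0 * f, 0.0), lambda f: (1000.0, 20.0 * f)],
            [+1, -1], 30)
        tracks = link_tracks(sets, link_radius=700.0)
        v = pw.mean_defect_velocity(tracks, frame_interval_h=0.25)
        v1 = (29 * 10 / 30) / 0.25
        v2 = (29 * 20 / 30) / 0.25
        assert v == pytest.approx((v1 + v2) / 2)


class TestCallEvents:
    def test_converging_pair_annihilation(self):
        # pair approaches, disappears at frame 10 of 20
        a = lambda f: (-300.0 + 25.0 * f, 0.0)
        b = lambda f: (300.0 - 25.0 * f, 0.0)
        present = [lambda f: f <= 10, lambda f: f <= 10]
        sets = _sets_from_paths([a, b], [+1, -1], 20, present)
        tracks = link_tracks(sets, 165.0)
        events = call_events(tracks, event_radius=165.0, frame_range=(0, 19))
        assert len(events) == 1
        assert events[0].type == "annihilation"
        assert events[0].midpoint == pytest.approx([0.0, 0.0], abs=30)

    def test_diverging_pair_proliferation(self):
        a = lambda f: (-25.0 * (f - 5), 0.0)
        b = lambda f: (25.0 * (f - 5), 0.0)
        present = [lambda f: f >= 5, lambda f: f >= 5]
        sets = _sets_from_paths([a, b], [+1, -1], 20, present)
        tracks = link_tracks(sets, 165.0)
        events = call_events(tracks, event_radius=165.0, frame_range=(0, 19))
        assert [e.type for e in events] == ["proliferation"]
        assert events[0].frame == 5

    def test_border_death_not_an_event(self):
        # both tracks end near the field border: exiting, not annihilating
        a = lambda f: (900.0 + 25.0 * f, 0.0)
        b = lambda f: (900.0 + 25.0 * f, 100.0)
        present = [lambda f: f <= 10, lambda f: f <= 10]
        sets = _sets_from_paths([a, b], [+1, -1], 20, present)
        tracks = link_tracks(sets, 165.0)
        events = call_events(tracks, event_radius=165.0, frame_range=(0, 19),
                             bounds=(-1320, 1320, -1320, 1320),
                             border_margin=300.0)
        assert events == []

    def test_track_ending_at_last_frame_not_death(self):
        a = lambda f: (-100.0, 0.0)
        b = lambda f: (100.0, 0.0)
        sets = _sets_from_paths([a, b], [+1, -1], 10)
        tracks = link_tracks(sets, 165.0)
        events = call_events(tracks, event_radius=300.0, frame_range=(0, 9))
        assert events == []


class TestReversalAngle:
    def _annihilation_sequence(self):
        x, y = pw.make_grid(30 * 66.0, 31)
        # cores at generic positions (off grid lines) so winding detections
        # surround each core symmetrically
        cx, cy = x[15] + 13.0, y[15] + 21.0
        frames = []
        for k, s in enumerate([600.0, 450.0, 300.0, 200.0]):
            frames.append(pw.compose_defect_field(
                [pw.DefectSpec((cx - s / 2, cy), +1, np.pi / 2),
                 pw.DefectSpec((cx + s / 2, cy), -1, 0.0)],
                x, y, time=k * 0.25))
        # after annihilation the field is uniform along the far-field
        # direction psi_total = pi/2
        from polarweave.synth import VelocityFieldFrame
        ones = np.ones((31, 31))
        for k in range(2):
            frames.append(VelocityFieldFrame(
                x=x, y=y, u=0 * ones, v=35 * ones, time=(4 + k) * 0.25))
        return frames

    def test_synthetic_annihilation_reverses_180(self):
        frames = self._annihilation_sequence()
        params = pw.DetectionParams()
        sets = pw.filter_persistent(pw.detect_series(frames, params), params)
        tracks = link_tracks(sets, link_radius=params.merge_radius)
        events = call_events(tracks, event_radius=300.0,
                             frame_range=(0, len(frames) - 1))
        ann = [e for e in events if e.type == "annihilation"]
        assert len(ann) == 1
        angle = pw.reversal_angle(ann[0], tracks, frames)
        assert angle == pytest.approx(180.0, abs=15.0)

    def test_non_annihilation_rejected(self):
        frames = self._annihilation_sequence()
        ev = pw.TopologyEvent(type="proliferation", frame=2,
                              midpoint=np.zeros(2), plus_track=0,
                              minus_track=1)
        with pytest.raises(ValueError):
            pw.reversal_angle(ev, [], frames)


def test_partner_exchange_chain_detected():
    """A defect born in a proliferation that annihilates with a defect
    from another pair is reported as a partner exchange."""
    p = pw.TopologyEvent(type="proliferation", frame=3,
                         midpoint=np.zeros(2), plus_track=4, minus_track=5)
    a_switch = pw.TopologyEvent(type="annihilation", frame=9,
                                midpoint=np.zeros(2), plus_track=4,
                                minus_track=7)
    a_same = pw.TopologyEvent(type="annihilation", frame=9,
                              midpoint=np.zeros(2), plus_track=4,
                              minus_track=5)
    assert pw.partner_exchanges([p, a_switch]) == [(p, a_switch)]
    assert pw.partner_exchanges([p, a_same]) == []


def test_charge_bookkeeping_between_frames():
    """Away from borders, N+ - N- changes only via paired events."""
    a = lambda f: (-300.0 + 25.0 * f, 0.0)
    b = lambda f: (300.0 - 25.0 * f, 0.0)
    c = lambda f: (-800.0, 800.0)
    present = [lambda f: f <= 10, lambda f: f <= 10, lambda f: True]
    sets = _sets_from_paths([a, b, c], [+1, -1, +1], 20, present)
    diffs = [s.count(+1) - s.count(-1) for s in sets]
    assert len(set(diffs)) == 1    # +1 throughout: pair loss cancels
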