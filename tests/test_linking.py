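"""Gated optimal assignment and track building."""

import itertools

import numpy as np
import pytest

import casatrack as ct


def det(x, y, frame=0):
    return ct.Detection(frame, (y, x), (float(x), float(y)), 10.0, 100.0)


def brute_force_assignment(current, nxt, gate):
    """Exhaustive oracle: maximise within-gate matches, then minimise cost."""
    n, m = len(current), len(nxt)
    best = ([], 0, 0.0)  # pairs, n_matched, -cost
    a = np.array([[d.x_um, d.y_um] for d in current]) if current else np.empty((0, 2))
    b = np.array([[d.x_um, d.y_um] for d in nxt]) if nxt else np.empty((0, 2))
    for k in range(min(n, m), -1, -1):
        candidates = []
        for rows in itertools.combinations(range(n), k):
            for cols in itertools.permutations(range(m), k):
                dists = [np.linalg.norm(a[i] - b[j]) for i, j in zip(rows, cols)]
                if all(d <= gate for d in dists):
                    candidates.append((sorted(zip(rows, cols)), sum(dists)))
        if candidates:
            best_pairs, best_cost = min(candidates, key=lambda t: t[1])
            return best_pairs, best_cost
    return [], 0.0


class TestLinkFrames:
    def test_well_separated_pair(self):
        cur = [det(0, 0), det(50, 0)]
        nxt = [det(1, 0), det(51, 0)]
        cfg = ct.LinkingConfig(max_link_distance=10.0)
        assert ct.link_frames(cur, nxt, cfg) == [(0, 0), (1, 1)]

    def test_gate_exclusion_ends_track(self):
        cur = [det(0, 0)]
        nxt = [det(30, 0)]
        cfg = ct.LinkingConfig(max_link_distance=10.0)
        assert ct.link_frames(cur, nxt, cfg) == []

    def test_empty_lists(self):
        cfg = ct.LinkingConfig()
        assert ct.link_frames([], [det(0, 0)], cfg) == []
        assert ct.link_frames([det(0, 0)], [], cfg) == []

    def test_crossing_pair_beats_greedy(self):
        # Greedy nearest-neighbour would give nxt[0] to cur[0] (distance 4)
        # and leave cur[1] unmatched (its only alternative is out of gate);
        # the cost-minimal same-cardinality assignment links cur[1]->nxt[0]
        # (distance 1) instead.
        cur = [det(0, 0), det(5, 0)]
        nxt = [det(4, 0), det(100, 0)]
        cfg = ct.LinkingConfig(max_link_distance=20.0)
        pairs = ct.link_frames(cur, nxt, cfg)
        assert pairs == [(1, 0)]
        expected, _ = brute_force_assignment(cur, nxt, 20.0)
        assert pairs == expected

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_minimum_small_scenes(self, seed):
        rng = np.random.default_rng(seed)
        n, m = rng.integers(1, 5, 2)
        cur = [det(*p) for p in rng.uniform(0, 30, (n, 2))]
        nxt = [det(*p) for p in rng.uniform(0, 30, (m, 2))]
        gate = 15.0
        cfg = ct.LinkingConfig(max_link_distance=gate)
        pairs = ct.link_frames(cur, nxt, cfg)
        expected_pairs, expected_cost = brute_force_assignment(cur, nxt, gate)
        got_cost = sum(
            np.hypot(cur[i].x_um - nxt[j].x_um, cur[i].y_um - nxt[j].y_um)
            for i, j in pairs
        )
        assert len(pairs) == len(expected_pairs)
        assert got_cost == pytest.approx(expected_cost)


class TestBuildTracks:
    def _straight_scene(self, n_frames=10, n_sperm=3, spacing=100.0, step=2.0):
        frames = []
        for f in range(n_frames):
            frames.append(
                [det(i * spacing + f * step, 0.0, frame=f) for i in range(n_sperm)]
            )
        return frames

    def test_single_sperm_full_clip(self):
        frames = self._straight_scene(n_sperm=1)
        tracks = ct.build_tracks(frames, ct.LinkingConfig(max_link_distance=5.0), fps=30.0)
        assert len(tracks) == 1
        assert tracks[0].n_frames == 10

    def test_track_ends_on_exit_no_resurrection(self):
        frames = self._straight_scene(n_sperm=1)
        frames = frames[:5] + [[] for _ in range(5)]
        cfg = ct.LinkingConfig(max_link_distance=5.0, max_frame_gap=0)
        tracks = ct.build_tracks(frames, cfg, fps=30.0)
        assert len(tracks) == 1
        assert tracks[0].n_frames == 5

    def test_well_separated_identities_preserved(self, wobbly_params):
        tracks_gt = ct.simulate_tracks(
            wobbly_params, 10, 1.0, 30, field_of_view=(1000.0, 1000.0),
            seed=17, min_separation=80.0, spawn_margin=40.0,
        )
        # Feed exact ground-truth coordinates as detections.
        n_frames = max(t.n_frames for t in tracks_gt)
        by_frame = [
            [
                det(t.x[f], t.y[f], frame=f)
                for t in tracks_gt
                if t.n_frames > f
            ]
            for f in range(n_frames)
        ]
        cfg = ct.LinkingConfig(max_link_distance=ct.default_gate(30.0))
        rec = ct.build_tracks(by_frame, cfg, fps=30.0)
        assert len(rec) == len(tracks_gt)
        match = ct.match_to_ground_truth(rec, tracks_gt, tol_um=1e-6)
        assert all(v is not None for v in match.values())

    def test_conservation_of_detections(self, wobbly_params):
        tracks_gt = ct.simulate_tracks(
            wobbly_params, 8, 0.5, 30, field_of_view=(400.0, 400.0), seed=23
        )
        n_frames = max(t.n_frames for t in tracks_gt)
        by_frame = [
            [det(t.x[f], t.y[f], frame=f) for t in tracks_gt if t.n_frames > f]
            for f in range(n_frames)
        ]
        cfg = ct.LinkingConfig(max_link_distance=ct.default_gate(30.0), min_track_length=2)
        tracks = ct.build_tracks(by_frame, cfg, fps=30.0)
        total = sum(len(d) for d in by_frame)
        in_tracks = sum(t.n_frames for t in tracks)
        assert in_tracks <= total
        # Every track detection is one of the inputs (no duplication).
        seen = set()
        for t in tracks:
            for d in t.detections:
                key = (d.frame_index, d.x_um, d.y_um)
                assert key not in seen
                seen.add(key)

    def test_order_independence(self, wobbly_params):
        tracks_gt = ct.simulate_tracks(
            wobbly_params, 6, 0.3, 30, field_of_view=(500.0, 500.0),
            seed=29, min_separation=60.0, spawn_margin=30.0,
        )
        n_frames = max(t.n_frames for t in tracks_gt)
        by_frame = [
            [det(t.x[f], t.y[f], frame=f) for t in tracks_gt if t.n_frames > f]
            for f in range(n_frames)
        ]
        rng = np.random.default_rng(0)
        shuffled = [list(rng.permutation(len(fr))) for fr in by_frame]
        by_frame_shuffled = [
            [fr[i] for i in order] for fr, order in zip(by_frame, shuffled)
        ]
        cfg = ct.LinkingConfig(max_link_distance=ct.default_gate(30.0))
        t1 = ct.build_tracks(by_frame, cfg, fps=30.0)
        t2 = ct.build_tracks(by_frame_shuffled, cfg, fps=30.0)
        coords1 = sorted(tuple(zip(t.x_um, t.y_um)) for t in t1)
        coords2 = sorted(tuple(zip(t.x_um, t.y_um)) for t in t2)
        assert coords1 == coords2

    def test_min_track_length_filter_and_dense_ids(self):
        frames = [
            [det(0, 0, 0), det(100, 0, 0)],
            [det(1, 0, 1), det(101, 0, 1)],
            [det(2, 0, 2)],  # second sperm vanishes after 2 frames
            [det(3, 0, 3)],
        ]
        cfg = ct.LinkingConfig(max_link_distance=5.0, min_track_length=3)
        tracks = ct.build_tracks(frames, cfg, fps=30.0)
        assert len(tracks) == 1
        assert tracks[0].track_id == 0
        assert tracks[0].n_frames == 4


def test_default_gate_scales_with_fps():
    assert ct.default_gate(100.0) == pytest.approx(2.0)
    assert ct.default_gate(30.0) == pytest.approx(200.0 / 30.0)


def test_config_validation():
    with pytest.raises(ct.ConfigError):
        ct.LinkingConfig(max_link_distance=0.0)
    with pytest.raises(ct.ConfigError):
        ct.LinkingConfig(min_track_length=1)
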