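import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from filotrack.core import Track
from filotrack.tracking import (
    LinkCandidate,
    TrackingConfig,
    direction_measure,
    find_candidates,
    length_measure,
    link_frame,
    track_movie,
)

from conftest import make_instance


class TestLengthMeasure:
    @pytest.mark.parametrize("lc, lp, expected", [
        (4.0, 4.0, 0.0),
        (2.0, 4.0, 0.5),
        (1.0, 100.0, 0.99),
    ])
    def test_printed_formula(self, lc, lp, expected):
        assert length_measure(lc, lp) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.floats(0.01, 1e3), st.floats(0.01, 1e3))
    def test_symmetric_and_bounded(self, a, b):
        m = length_measure(a, b)
        assert 0.0 <= m <= 1.0
        assert m == length_measure(b, a)

    def test_rejects_non_positive(self):
        with pytest.raises(ValueError):
            length_measure(0.0, 1.0)


class TestDirectionMeasure:
    def test_parallel_zero(self):
        assert direction_measure([0, 1, 2], [0, 2, 4]) == pytest.approx(0.0)

    def test_antiparallel_one(self):
        assert direction_measure([0, 1, 0], [0, -3, 0]) == pytest.approx(1.0)

    def test_orthogonal_half(self):
        assert direction_measure([0, 1, 0], [0, 0, 1]) == pytest.approx(0.5)

    def test_zero_vector_uninformative(self):
        with pytest.warns(UserWarning, match="zero direction"):
            assert direction_measure([0, 0, 0], [0, 1, 0]) == 0.5

    def test_magnitudes_cancel(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=3), rng.normal(size=3)
        assert direction_measure(a, b) == pytest.approx(direction_measure(5 * a, 0.1 * b))


def _track_with(instance, track_id=0):
    tr = Track(track_id=track_id)
    tr.add(instance)
    return tr


class TestFindCandidates:
    def test_beyond_cutoff_no_candidates(self, calibration):
        prev = _track_with(make_instance(0, 0, origin=(2, 10, 10)))
        cur = [make_instance(1, 1, origin=(2, 60, 10))]  # 30+ px away, > 25 cutoff
        assert find_candidates(cur, [prev], 1, TrackingConfig(), calibration) == []

    def test_identical_paths_score_zero(self, calibration):
        prev = _track_with(make_instance(0, 0, origin=(2, 10, 10)))
        cur = [make_instance(5, 1, origin=(2, 10, 10))]
        (cand,) = find_candidates(cur, [prev], 1, TrackingConfig(), calibration)
        assert cand.m_length == 0.0
        assert cand.m_direction == 0.0
        assert cand.score == 0.0

    def test_score_is_exact_weighted_sum(self, calibration):
        rng = np.random.default_rng(1)
        cfg = TrackingConfig()
        tracks = [
            _track_with(make_instance(i, 0, origin=(2, int(rng.integers(5, 50)), 10),
                                      length_vox=int(rng.integers(5, 30)),
                                      direction=(0, 0, 1)), track_id=i)
            for i in range(4)
        ]
        cur = [make_instance(10 + i, 1, origin=(2, int(rng.integers(5, 50)), 12),
                             length_vox=int(rng.integers(5, 30)), direction=(0, 1, 0))
               for i in range(4)]
        for c in find_candidates(cur, tracks, 1, cfg, None):
            assert c.score == cfg.weight_length * c.m_length + cfg.weight_direction * c.m_direction

    def test_matches_brute_force_on_random_scenes(self, calibration):
        cfg = TrackingConfig()
        for seed in range(10):
            rng = np.random.default_rng(seed)
            tracks = [
                _track_with(
                    make_instance(i, 0, origin=(2, int(rng.integers(0, 90)), int(rng.integers(0, 90))),
                                  length_vox=int(rng.integers(3, 15))),
                    track_id=i,
                )
                for i in range(rng.integers(1, 5))
            ]
            cur = [
                make_instance(100 + i, 1, origin=(2, int(rng.integers(0, 90)), int(rng.integers(0, 90))),
                              length_vox=int(rng.integers(3, 15)))
                for i in range(rng.integers(1, 5))
            ]
            got = {(c.instance_id, c.track_id) for c in find_candidates(cur, tracks, 1, cfg, None)}
            # oracle: exhaustive pairwise min voxel distance
            expected = set()
            for inst in cur:
                for tr in tracks:
                    prev = tr.instances[0]
                    d = min(
                        np.linalg.norm((a - b).astype(float))
                        for a in inst.path for b in prev.path
                    )
                    if d <= cfg.cutoff_radius_px:
                        expected.add((inst.instance_id, tr.track_id))
            assert got == expected

    def test_lookback_window_excludes_stale_tracks(self, calibration):
        cfg = TrackingConfig(lookback_frames=5)
        prev = _track_with(make_instance(0, 0, origin=(2, 10, 10)))
        cur = [make_instance(1, 6, origin=(2, 10, 10))]
        assert find_candidates(cur, [prev], 6, cfg, calibration) == []
        assert len(find_candidates(cur, [prev], 5, cfg, calibration)) == 1


def _brute_force_greedy(candidates):
    """Independent re-implementation: sort by score, link greedily."""
    pairs = sorted(
        [(c.score, c.m_length, c.instance_id, c.track_id) for c in candidates]
    )
    used_i, used_t, links = set(), set(), {}
    for s, ml, iid, tid in pairs:
        if iid in used_i or tid in used_t:
            continue
        links[iid] = tid
        used_i.add(iid)
        used_t.add(tid)
    return links


class TestLinkFrame:
    def test_crossed_scores_hand_example(self):
        cands = [
            LinkCandidate("a", 1, 0, 0, 0.1),
            LinkCandidate("a", 2, 0, 0, 0.2),
            LinkCandidate("b", 1, 0, 0, 0.15),
            LinkCandidate("b", 2, 0, 0, 0.4),
        ]
        assert link_frame(cands) == {"a": 1, "b": 2}

    def test_no_candidates(self):
        assert link_frame([]) == {}

    def test_matches_brute_force_oracle(self):
        for seed in range(50):
            rng = np.random.default_rng(seed)
            cands = [
                LinkCandidate(int(i), int(t), float(rng.random()), float(rng.random()),
                              float(np.round(rng.random(), 2)))
                for i in range(rng.integers(1, 7))
                for t in range(rng.integers(1, 7))
                if rng.random() < 0.6
            ]
            assert link_frame(cands) == _brute_force_greedy(cands)


class TestTrackMovie:
    def test_persistent_instance_with_drift_single_track(self, calibration):
        frames = {
            t: [make_instance(0, t, origin=(2, 10 + 2 * t, 10))] for t in range(10)
        }
        tracks = track_movie(frames, TrackingConfig(), calibration)
        assert len(tracks) == 1
        assert tracks[0].lifetime_frames == 10

    def test_gap_equal_to_lookback_starts_new_track(self, calibration):
        cfg = TrackingConfig(lookback_frames=5)
        frames = {0: [make_instance(0, 0)], 6: [make_instance(1, 6)]}
        tracks = track_movie(frames, cfg, calibration)
        assert len(tracks) == 2

    def test_gap_within_lookback_continues_track(self, calibration):
        cfg = TrackingConfig(lookback_frames=5)
        frames = {0: [make_instance(0, 0)], 4: [make_instance(1, 4)]}
        tracks = track_movie(frames, cfg, calibration)
        assert len(tracks) == 1
        assert tracks[0].frames == [0, 4]

    def test_injective_matching_within_frame(self, calibration):
        frames = {
            0: [make_instance(0, 0, origin=(2, 10, 10)),
                make_instance(1, 0, origin=(2, 20, 10))],
            1: [make_instance(0, 1, origin=(2, 11, 10)),
                make_instance(1, 1, origin=(2, 21, 10))],
        }
        tracks = track_movie(frames, TrackingConfig(), calibration)
        assert len(tracks) == 2
        for t in tracks:
            assert t.lifetime_frames == 2

    def test_translation_invariant_track_count(self, calibration):
        rng = np.random.default_rng(9)
        base = {
            t: [
                make_instance(i, t, origin=(2, int(rng.integers(10, 80)), int(rng.integers(10, 80))),
                              length_vox=int(rng.integers(3, 12)))
                for i in range(3)
            ]
            for t in range(4)
        }
        shifted = {
            t: [
                make_instance(i.instance_id, t, origin=tuple(i.path[0] + np.array([0, 7, 7])),
                              length_vox=len(i.path))
                for i in insts
            ]
            for t, insts in base.items()
        }
        n0 = len(track_movie(base, TrackingConfig(), calibration))
        n1 = len(track_movie(shifted, TrackingConfig(), calibration))
        assert n0 == n1

    def test_max_length_over_lifetime(self, calibration):
        frames = {
            0: [make_instance(0, 0, length_vox=10)],
            1: [make_instance(0, 1, length_vox=30)],
            2: [make_instance(0, 2, length_vox=20)],
        }
        (track,) = track_movie(frames, TrackingConfig(), calibration)
        assert track.max_length_um == pytest.approx(2.9, abs=0.05)


class TestTrackingConfig:
    def test_paper_defaults(self):
        cfg = TrackingConfig()
        assert cfg.lookback_frames == 5
        assert cfg.cutoff_radius_px == 25.0
        assert cfg.weight_length == 0.46
        assert cfg.weight_direction == 0.6

    @pytest.mark.parametrize("bad", [
        dict(lookback_frames=0), dict(cutoff_radius_px=0), dict(weight_length=-1),
    ])
    def test_invalid_rejected(self, bad):
        with pytest.raises(ValueError):
            TrackingConfig(**bad)
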