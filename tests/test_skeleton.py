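import numpy as np
import pytest
from scipy import ndimage as ndi

from filotrack.core import LineSegment, path_length_vox
from filotrack.skeleton import (
    EditCommand,
    EditScript,
    apply_edits,
    auto_accept,
    extend_skeleton_tips,
    load_edits,
    mask_skeleton,
    save_edits,
    skeletonize_frame,
    split_segments,
)

from conftest import solid_tube_mask


class TestSkeletonize:
    def test_straight_tube_thins_to_single_path(self):
        mask = solid_tube_mask()
        sk = extend_skeleton_tips(skeletonize_frame(mask), mask)
        segs = split_segments(sk)
        assert len(segs) == 1
        assert path_length_vox(segs[0].path) == pytest.approx(40, abs=3)

    def test_skeleton_subset_of_mask(self):
        mask = solid_tube_mask()
        sk = skeletonize_frame(mask)
        assert not (sk & ~mask).any()

    def test_empty_mask(self):
        assert not skeletonize_frame(np.zeros((4, 8, 8), bool)).any()

    def test_ball_shrinks_to_tiny_core(self):
        zz, yy, xx = np.meshgrid(*(np.arange(s) for s in (24, 24, 24)), indexing="ij")
        ball = (zz - 12) ** 2 + (yy - 12) ** 2 + (xx - 12) ** 2 <= 8**2
        sk = skeletonize_frame(ball)
        assert sk.sum() <= 0.05 * ball.sum()

    def test_component_count_preserved(self):
        mask = np.zeros((5, 40, 40), bool)
        mask[2, 10:13, 5:35] = True
        mask[2, 30:33, 5:35] = True
        sk = skeletonize_frame(mask)
        s = np.ones((3, 3, 3))
        assert ndi.label(sk, s)[1] == ndi.label(mask, s)[1]


class TestMaskSkeleton:
    def test_is_set_difference(self):
        rng = np.random.default_rng(0)
        sk = rng.random((4, 10, 10)) < 0.2
        body = rng.random((4, 10, 10)) < 0.3
        out = mask_skeleton(sk, body)
        assert np.array_equal(out, sk & ~body)

    def test_disjoint_unchanged(self):
        sk = np.zeros((3, 8, 8), bool)
        sk[0, 0, :4] = True
        body = np.zeros_like(sk)
        body[2, 6, :] = True
        assert np.array_equal(mask_skeleton(sk, body), sk)

    def test_fully_inside_empty(self):
        sk = np.zeros((3, 8, 8), bool)
        sk[1, 4, 2:6] = True
        assert not mask_skeleton(sk, np.ones_like(sk)).any()

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            mask_skeleton(np.zeros((3, 8, 8), bool), np.zeros((3, 8, 9), bool))


class TestExtendTips:
    def test_recovers_thinning_retraction(self):
        mask = solid_tube_mask()
        sk = skeletonize_frame(mask)
        ext = extend_skeleton_tips(sk, mask)
        assert ext.sum() >= sk.sum()
        assert not (ext & ~mask).any()  # never leaves the support

    def test_no_op_without_support(self):
        sk = np.zeros((3, 10, 10), bool)
        sk[1, 5, 2:8] = True
        assert np.array_equal(extend_skeleton_tips(sk, sk), sk)


def _segments_cover(segments, skeleton):
    covered = np.zeros_like(skeleton)
    for s in segments:
        covered[s.path[:, 0], s.path[:, 1], s.path[:, 2]] = True
    # voxels not covered may only be isolated single-voxel components
    lab, n = ndi.label(skeleton & ~covered, np.ones((3, 3, 3)))
    sizes = np.bincount(lab.ravel())[1:]
    return all(sz == 1 for sz in sizes)


class TestSplitSegments:
    def test_y_shape_splits_into_three(self):
        sk = np.zeros((3, 20, 20), bool)
        sk[1, 10, 2:11] = True          # stem
        for i in range(1, 8):           # two diagonal arms from (10, 10)
            sk[1, 10 - i, 10 + i] = True
            sk[1, 10 + i, 10 + i] = True
        segs = split_segments(sk)
        assert len(segs) == 3
        shared = {}
        for s in segs:
            for v in map(tuple, s.path):
                shared[v] = shared.get(v, 0) + 1
        assert sum(1 for c in shared.values() if c > 1) == 1  # one branch voxel

    def test_open_curve_single_segment_endpoints_preserved(self):
        sk = np.zeros((3, 20, 20), bool)
        pts = [(1, 5 + i, 2 + i) for i in range(10)]
        for p in pts:
            sk[p] = True
        segs = split_segments(sk)
        assert len(segs) == 1
        ends = {tuple(segs[0].path[0]), tuple(segs[0].path[-1])}
        assert ends == {pts[0], pts[-1]}

    def test_cycle_decomposed_without_repeats(self):
        sk = np.zeros((3, 10, 10), bool)
        for x in range(3, 7):
            sk[1, 3, x] = sk[1, 6, x] = True
        for y in range(3, 7):
            sk[1, y, 3] = sk[1, y, 6] = True
        segs = split_segments(sk)
        assert _segments_cover(segs, sk)

    def test_random_thin_components_match_graph_oracle(self):
        rng = np.random.default_rng(6)
        sk = np.zeros((4, 30, 30), bool)
        # random walks produce thin branched structures
        for _ in range(6):
            p = np.array([rng.integers(1, 3), rng.integers(5, 25), rng.integers(5, 25)])
            for _ in range(25):
                sk[tuple(p)] = True
                p = np.clip(p + rng.integers(-1, 2, 3), 0, [3, 29, 29])
        segs = split_segments(sk)
        assert _segments_cover(segs, sk)
        # shared voxels are branch voxels (>= 3 neighbors in the skeleton)
        counts = {}
        for s in segs:
            for v in map(tuple, s.path):
                counts[v] = counts.get(v, 0) + 1
        for v, c in counts.items():
            if c > 1:
                z, y, x = v
                nb = sk[max(z-1, 0):z+2, max(y-1, 0):y+2, max(x-1, 0):x+2].sum() - 1
                assert nb >= 3

    def test_deterministic(self):
        rng = np.random.default_rng(7)
        sk = rng.random((4, 20, 20)) < 0.1
        a = split_segments(sk)
        b = split_segments(sk)
        assert len(a) == len(b)
        for s1, s2 in zip(a, b):
            assert np.array_equal(s1.path, s2.path)


class TestEditScript:
    def test_auto_accept_covers_all_segments(self):
        path = np.array([[0, 0, 0], [0, 0, 1], [0, 0, 2]])
        segs = [LineSegment(i, 0, path + np.array([0, 3 * i, 0])) for i in range(3)]
        script = auto_accept(segs)
        assert len(script.commands) == 3
        assert all(c.op == "accept" for c in script.commands)
        script.validate(segs)

    def test_empty_input_empty_script(self):
        assert auto_accept([]).commands == []

    def test_validation_rejects_unknown_and_double_use(self):
        path = np.array([[0, 0, 0], [0, 0, 1]])
        segs = [LineSegment(0, 0, path)]
        with pytest.raises(ValueError, match="unknown"):
            EditScript([EditCommand("remove", (9,))]).validate(segs)
        with pytest.raises(ValueError, match="more than one"):
            EditScript([
                EditCommand("remove", (0,)),
                EditCommand("accept", (0,), instance_id=1),
            ]).validate(segs)

    def test_merge_across_frames_rejected(self):
        path = np.array([[0, 0, 0], [0, 0, 1]])
        segs = [LineSegment(0, 0, path), LineSegment(1, 1, path.copy())]
        with pytest.raises(ValueError, match="frames"):
            EditScript([EditCommand("merge", (0, 1), instance_id=5)]).validate(segs)

    def test_json_round_trip(self, tmp_path):
        script = EditScript([
            EditCommand("remove", (3,)),
            EditCommand("merge", (0, 1), instance_id=7),
            EditCommand("accept", (2,), instance_id=8),
        ])
        p = tmp_path / "edits.json"
        save_edits(script, p)
        back = load_edits(p)
        assert back == script


class TestApplyEdits:
    def test_merge_collinear_segments_length_sums_plus_gap(self, calibration):
        a = np.column_stack([np.ones(5, int), np.full(5, 5), np.arange(0, 5)])
        b = np.column_stack([np.ones(6, int), np.full(6, 5), np.arange(7, 13)])
        segs = [LineSegment(0, 0, a), LineSegment(1, 0, b)]
        script = EditScript([EditCommand("merge", (0, 1), instance_id=0)])
        out = apply_edits(segs, script, calibration)
        assert len(out) == 1
        # 4 steps + 5 steps + the 3-pixel gap jump = 12 pixels
        assert out[0].path_length_vox == pytest.approx(12.0)

    def test_merge_too_far_apart_names_ids(self, calibration):
        a = np.array([[0, 0, 0], [0, 0, 1]])
        b = np.array([[0, 30, 0], [0, 30, 1]])
        segs = [LineSegment(4, 0, a), LineSegment(9, 0, b)]
        script = EditScript([EditCommand("merge", (4, 9), instance_id=0)])
        with pytest.raises(ValueError, match=r"4, 9"):
            apply_edits(segs, script, calibration)

    def test_remove_all_gives_empty(self, calibration):
        path = np.array([[0, 0, 0], [0, 0, 1]])
        segs = [LineSegment(i, 0, path + np.array([0, 3 * i, 0])) for i in range(3)]
        script = EditScript([EditCommand("remove", (i,)) for i in range(3)])
        assert apply_edits(segs, script, calibration) == []

    def test_straight_segment_direction(self, calibration):
        path = np.column_stack([np.zeros(6, int), np.arange(6), np.zeros(6, int)])
        body = np.zeros((2, 10, 10), bool)
        body[0, 0, 0] = True  # base anchor at origin
        out = apply_edits([LineSegment(0, 0, path)], auto_accept([LineSegment(0, 0, path)]),
                          calibration, cell_body=body)
        d = out[0].mean_direction
        assert np.allclose(d / np.linalg.norm(d), [0, 1, 0])

    def test_base_is_endpoint_nearer_body(self, calibration):
        path = np.column_stack([np.ones(8, int), np.arange(8, 0, -1), np.full(8, 3)])
        body = np.zeros((3, 12, 12), bool)
        body[1, 0, 3] = True
        out = apply_edits([LineSegment(0, 0, path)], EditScript([]), calibration,
                          cell_body=body)
        assert tuple(out[0].base) == (1, 1, 3)  # the end closest to the body

    def test_voxel_conservation(self, calibration):
        rng = np.random.default_rng(8)
        segs = []
        for i in range(4):
            n = rng.integers(3, 8)
            path = np.column_stack(
                [np.full(n, 1), np.full(n, 4 * i), np.arange(n)]
            )
            segs.append(LineSegment(i, 0, path))
        script = EditScript([
            EditCommand("remove", (1,)),
        ])
        out = apply_edits(segs, script, calibration)
        in_vox = sorted(tuple(v) for s in segs if s.segment_id != 1 for v in s.path)
        out_vox = sorted(tuple(v) for inst in out for v in inst.path)
        assert in_vox == out_vox

    def test_unreferenced_segments_kept_as_singletons(self, calibration):
        path = np.array([[0, 0, 0], [0, 0, 1]])
        segs = [LineSegment(5, 2, path)]
        out = apply_edits(segs, EditScript([]), calibration)
        assert len(out) == 1
        assert out[0].instance_id == 5
        assert out[0].frame == 2
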