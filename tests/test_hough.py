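import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

import ghtrack as gt
from ghtrack import hough
from ghtrack._geometry import wrap_angle

from conftest import synthetic_model, transformed_matches

EXTENT = (160, 200)  # (H, W)


def brute_force_accumulator(matches, model, extent, weight_threshold=0.5,
                            thickness_ratio=(0.95, 1.05), prev_scale=1.0):
    """Independent accumulator: test every cell against every ring directly."""
    H, W = extent
    uu, vv = np.meshgrid(np.arange(W), np.arange(H))
    grid = np.zeros((H, W))
    for i, kp, w in matches.pairs:
        if w <= weight_threshold:
            continue
        d = model.keypoints[i].center_distance * prev_scale
        r_min, r_max = thickness_ratio[0] * d, thickness_ratio[1] * d
        if r_max < 0.5:
            grid[int(round(kp.position[1])), int(round(kp.position[0]))] += w
            continue
        # thin rings widen to a half-cell band about the midline
        mid = 0.5 * (r_min + r_max)
        r_min = min(r_min, max(mid - 0.5, 0.0))
        r_max = max(r_max, mid + 0.5)
        # total ring cell count on an unbounded grid, for the per-cell share
        pad = int(np.ceil(r_max)) + 2
        gu, gv = np.meshgrid(
            np.arange(int(np.floor(kp.position[0])) - pad, int(np.ceil(kp.position[0])) + pad + 1),
            np.arange(int(np.floor(kp.position[1])) - pad, int(np.ceil(kp.position[1])) + pad + 1),
        )
        gdist = np.hypot(gu - kp.position[0], gv - kp.position[1])
        n_cells = int(np.count_nonzero((gdist >= r_min) & (gdist <= r_max)))
        dist = np.hypot(uu - kp.position[0], vv - kp.position[1])
        grid += (w / n_cells) * ((dist >= r_min) & (dist <= r_max))
    return grid


def brute_force_center(grid, sigma=2.0):
    """Exhaustive lexicographic argmax scan over the smoothed grid."""
    sm = gaussian_filter(grid, sigma)
    best, best_cell = -np.inf, None
    for v in range(sm.shape[0]):
        for u in range(sm.shape[1]):
            if sm[v, u] > best:
                best, best_cell = sm[v, u], (u, v)
    return np.array(best_cell, dtype=float)


def vector_voting_center(matches, model, extent, sigma=2.0):
    """Classic GHT oracle: each keypoint casts one displaced point vote."""
    H, W = extent
    grid = np.zeros((H, W))
    for i, kp, w in matches.pairs:
        mk = model.keypoints[i]
        target = kp.position + mk.center_distance * np.array(
            [np.cos(mk.absolute_center_angle), np.sin(mk.absolute_center_angle)]
        )
        u, v = int(round(target[0])), int(round(target[1]))
        if 0 <= u < W and 0 <= v < H:
            grid[v, u] += w
    sm = gaussian_filter(grid, sigma)
    v, u = np.unravel_index(np.argmax(sm), sm.shape)
    return np.array([u, v], dtype=float)


class TestVoteRadius:
    @pytest.mark.parametrize(
        "d,s,expected",
        [
            (100.0, 1.0, (95.0, 105.0)),
            (0.0, 1.0, (0.0, 0.0)),
            (50.0, 2.0, (95.0, 105.0)),
        ],
    )
    def test_examples(self, d, s, expected):
        assert hough.vote_radius(d, s) == pytest.approx(expected)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            hough.vote_radius(-1.0, 1.0)
        with pytest.raises(ValueError):
            hough.vote_radius(10.0, 0.0)


class TestCastVotes:
    def test_zero_distance_keypoint_makes_point_vote(self):
        model = synthetic_model(n=3)
        mk = model.keypoints[0]
        mk.center_distance = 0.0
        kp = gt.Keypoint(np.array([50.0, 60.0]), mk.keypoint.descriptor, 0.0, 1.0)
        matches = gt.MatchSet(pairs=[(0, kp, 0.8)])
        acc = hough.cast_votes(matches, model, accumulator_extent=EXTENT)
        assert acc.grid[60, 50] == pytest.approx(0.8)
        assert acc.total_mass == pytest.approx(0.8)

    def test_all_weights_at_threshold_give_zero_accumulator(self):
        model = synthetic_model()
        matches = transformed_matches(model, (100, 80), weights=[0.5] * len(model))
        acc = hough.cast_votes(matches, model, accumulator_extent=EXTENT)
        assert acc.total_mass == 0.0

    def test_mass_bounded_by_total_weight(self):
        model = synthetic_model()
        # center near the border: parts of the rings fall off-image
        matches = transformed_matches(model, (10, 10))
        acc = hough.cast_votes(matches, model, accumulator_extent=EXTENT)
        assert acc.total_mass <= sum(w for _i, _kp, w in matches.pairs) + 1e-9
        assert np.all(acc.grid >= 0)

    def test_matches_brute_force_oracle(self):
        model = synthetic_model(n=3, radius=30.0, seed=5)
        matches = transformed_matches(model, (90.0, 70.0))
        acc = hough.cast_votes(matches, model, accumulator_extent=EXTENT)
        oracle = brute_force_accumulator(matches, model, EXTENT)
        assert np.allclose(acc.grid, oracle, atol=1e-12)
        center = hough.find_center(acc)
        # true center within one ring half-thickness (5% of 30 px) of the max
        assert np.hypot(*(center - [90, 70])) <= 0.05 * 30.0 + 1.0

    def test_removing_keypoints_never_raises_mass(self):
        model = synthetic_model(n=10, seed=2)
        matches = transformed_matches(model, (100, 80))
        full = hough.cast_votes(matches, model, accumulator_extent=EXTENT)
        reduced = gt.MatchSet(pairs=matches.pairs[:5])
        part = hough.cast_votes(reduced, model, accumulator_extent=EXTENT)
        assert np.all(part.grid <= full.grid + 1e-12)


class TestFindCenter:
    def test_single_cell(self):
        grid = np.zeros(EXTENT)
        grid[33, 44] = 1.0
        assert np.array_equal(hough.find_center(hough.Accumulator(grid)), [44, 33])

    def test_tie_breaks_lexicographically(self):
        grid = np.zeros(EXTENT)
        grid[40, 60] = 1.0
        grid[80, 120] = 1.0  # identical isolated peaks after smoothing
        assert np.array_equal(hough.find_center(hough.Accumulator(grid)), [60, 40])

    def test_zero_accumulator_signals_no_detection(self):
        assert hough.find_center(hough.Accumulator(np.zeros(EXTENT))) is None

    def test_agrees_with_exhaustive_scan(self):
        model = synthetic_model(n=5, radius=25.0, seed=7)
        matches = transformed_matches(model, (110.0, 90.0))
        acc = hough.cast_votes(matches, model, accumulator_extent=EXTENT)
        assert np.array_equal(hough.find_center(acc), brute_force_center(acc.grid))


class TestClassifyVotes:
    def test_midpoint_distance_is_positive(self):
        model = synthetic_model(n=4, radius=40.0)
        matches = transformed_matches(model, (100.0, 80.0))
        states, positive = hough.classify_votes(matches, model, (100.0, 80.0))
        assert states.sum() == len(model)
        assert len(positive) == len(model)
        assert all(mk.negative_streak == 0 for mk in model.keypoints)

    def test_below_weight_threshold_is_negative(self):
        model = synthetic_model(n=4, radius=40.0)
        weights = [0.4, 1.0, 1.0, 1.0]
        matches = transformed_matches(model, (100.0, 80.0), weights=weights)
        states, _ = hough.classify_votes(matches, model, (100.0, 80.0))
        assert states[0] == 0 and states[1:].all()
        assert model.keypoints[0].negative_streak == 1

    def test_displaced_keypoint_is_negative(self):
        model = synthetic_model(n=4, radius=40.0)
        matches = transformed_matches(model, (100.0, 80.0))
        i, kp, w = matches.pairs[0]
        far = gt.Keypoint(kp.position + [80.0, 0.0], kp.descriptor, kp.orientation, 1.0)
        matches.pairs[0] = (i, far, w)
        states, _ = hough.classify_votes(matches, model, (100.0, 80.0))
        assert states[0] == 0


class TestEstimateScaleRotation:
    def test_identity(self):
        model = synthetic_model(n=8)
        matches = transformed_matches(model, (100.0, 80.0))
        s, th, carried = hough.estimate_scale_rotation(matches.pairs, (100.0, 80.0), model)
        assert not carried
        assert s == pytest.approx(1.0, abs=1e-9)
        assert th == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("angle_deg", [30.0, -45.0, 120.0, 179.0])
    def test_rigid_rotation(self, angle_deg):
        model = synthetic_model(n=8)
        theta = np.deg2rad(angle_deg)
        matches = transformed_matches(model, (100.0, 80.0), rotation=theta)
        _s, th, _c = hough.estimate_scale_rotation(matches.pairs, (100.0, 80.0), model)
        assert wrap_angle(th - theta) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_scaling(self):
        model = synthetic_model(n=8)
        matches = transformed_matches(model, (100.0, 80.0), scale=1.2)
        s, _th, _c = hough.estimate_scale_rotation(matches.pairs, (100.0, 80.0), model)
        assert s == pytest.approx(1.2, abs=1e-9)

    def test_too_few_positives_carries_previous_pose(self):
        model = synthetic_model(n=8)
        matches = transformed_matches(model, (100.0, 80.0))
        s, th, carried = hough.estimate_scale_rotation(
            matches.pairs[:1], (100.0, 80.0), model, prev=(1.3, 0.7)
        )
        assert carried and s == 1.3 and th == 0.7


class TestRotationInvariance:
    @pytest.mark.parametrize("angle_deg", list(range(0, 360, 10)))
    def test_center_found_at_any_rotation(self, angle_deg):
        model = synthetic_model(n=10, radius=35.0, seed=1)
        true_center = np.array([105.0, 85.0])
        matches = transformed_matches(model, true_center, rotation=np.deg2rad(angle_deg))
        acc = hough.cast_votes(matches, model, accumulator_extent=EXTENT)
        center = hough.find_center(acc)
        half_thickness = 0.05 * 35.0
        assert np.hypot(*(center - true_center)) <= half_thickness + 1.0

    def test_classic_ght_equivalence_without_rotation(self):
        # with a degenerate ring (r_d = [1, 1]) and zero rotation, ring voting
        # reduces to the classic single-vector voting scheme
        for seed in range(5):
            model = synthetic_model(n=8, radius=30.0, seed=seed)
            true_center = np.array([95.0, 75.0])
            matches = transformed_matches(model, true_center)
            acc = hough.cast_votes(
                matches, model, accumulator_extent=EXTENT, thickness_ratio=(1.0, 1.0)
            )
            ours = hough.find_center(acc)
            oracle = vector_voting_center(matches, model, EXTENT)
            assert np.abs(ours - oracle).max() <= 1.0

    def test_scale_coverage_within_thickness(self):
        # per-frame scale change inside r_d: the true center still receives
        # every inlier's vote
        model = synthetic_model(n=8, radius=40.0, seed=3)
        true_center = np.array([100.0, 80.0])
        cu, cv = int(true_center[0]), int(true_center[1])
        for s in [0.96, 1.0, 1.04]:
            matches = transformed_matches(model, true_center, scale=s)
            for pair in matches.pairs:
                per_kp = brute_force_accumulator(
                    gt.MatchSet(pairs=[pair]), model, EXTENT
                )
                # each single ring covers the true-center neighbourhood
                assert per_kp[cv - 1 : cv + 2, cu - 1 : cu + 2].max() > 0


def test_outlier_robustness():
    """<= 40% wild matches leave the detected center within 1 bin of inlier-only."""
    rng = np.random.default_rng(0)
    model = synthetic_model(n=10, radius=35.0, seed=4)
    true_center = np.array([100.0, 80.0])
    matches = transformed_matches(model, true_center)
    inlier_center = hough.find_center(
        hough.cast_votes(matches, model, accumulator_extent=EXTENT)
    )
    corrupted = list(matches.pairs)
    for k in range(4):  # 40% of 10
        i, kp, w = corrupted[k]
        wild = gt.Keypoint(
            rng.uniform([0, 0], [EXTENT[1], EXTENT[0]]), kp.descriptor, kp.orientation, 1.0
        )
        corrupted[k] = (i, wild, w)
    center = hough.find_center(
        hough.cast_votes(gt.MatchSet(pairs=corrupted), model, accumulator_extent=EXTENT)
    )
    inlier_err = np.hypot(*(inlier_center - true_center))
    err = np.hypot(*(center - true_center))
    assert err <= inlier_err + 1.0
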