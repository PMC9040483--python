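"""Map fusion, peak detection, point matching, MCC, and tuning."""

import itertools

import numpy as np
import pytest

from stomakit.fusion import (
    ConfusionCounts,
    DetectionSet,
    FusionParams,
    combine_maps,
    find_peaks,
    flag_close_pairs,
    match_points,
    mcc,
    smooth_map,
    tune_fusion,
)
from conftest import make_annotation


def gaussian_bump(shape, cx, cy, height, sigma=3.0):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    return height * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2))


class TestCombine:
    def test_single_weight_identity(self):
        rng = np.random.default_rng(0)
        maps = [rng.random((16, 16)) for _ in range(3)]
        w = np.array([0.0, 1.0, 0.0])
        assert np.allclose(combine_maps(maps, w), maps[1])

    def test_mean_of_zeros_and_ones(self):
        out = combine_maps([np.zeros((8, 8)), np.ones((8, 8))])
        assert np.allclose(out, 0.5)

    def test_renormalizes_weights(self, caplog):
        maps = [np.full((4, 4), 0.2), np.full((4, 4), 0.8)]
        out = combine_maps(maps, np.array([0.2, 0.2]))
        assert np.allclose(out, 0.5)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            combine_maps([np.zeros((4, 4)), np.zeros((5, 5))])

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            combine_maps([np.zeros((4, 4))], np.array([-1.0]))


class TestSmooth:
    def test_sigma_zero_identity(self):
        m = np.random.default_rng(1).random((10, 10))
        assert np.array_equal(smooth_map(m, 0.0), m)

    def test_constant_preserved(self):
        m = np.full((12, 12), 0.4)
        assert np.allclose(smooth_map(m, 2.5), 0.4)

    def test_impulse_matches_direct_convolution_oracle(self):
        m = np.zeros((41, 41))
        m[20, 20] = 1.0
        out = smooth_map(m, 1.5)
        r = int(4 * 1.5 + 0.5)
        x = np.arange(-r, r + 1)
        k1 = np.exp(-0.5 * (x / 1.5) ** 2)
        k1 /= k1.sum()
        oracle = np.outer(k1, k1)
        assert np.allclose(out[20 - r : 20 + r + 1, 20 - r : 20 + r + 1], oracle, atol=1e-8)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            smooth_map(np.zeros((4, 4)), -1.0)


def brute_force_peaks(prob_map, threshold, min_sep):
    """Oracle: exhaustive local-maximum scan + greedy suppression."""
    h, w = prob_map.shape
    cands = []
    for i in range(h):
        for j in range(w):
            v = prob_map[i, j]
            if v <= 0:
                continue
            neigh = [
                prob_map[a, b]
                for a in range(max(0, i - 1), min(h, i + 2))
                for b in range(max(0, j - 1), min(w, j + 2))
                if (a, b) != (i, j)
            ]
            if all(v >= x for x in neigh) and any(v > x for x in neigh):
                cands.append((v, i, j))
    cands.sort(key=lambda t: (-t[0], t[1], t[2]))
    accepted = []
    for v, i, j in cands:
        if v < threshold:
            continue
        if all((i - a) ** 2 + (j - b) ** 2 >= min_sep**2 for _, a, b in accepted):
            accepted.append((v, i, j))
    return {(j, i) for _, i, j in accepted}


class TestFindPeaks:
    def test_single_bump(self):
        m = gaussian_bump((64, 64), 30, 20, 0.9)
        det = find_peaks(m, 0.5, 5.0)
        assert len(det) == 1
        assert tuple(det.points[0]) == (30, 20)

    def test_threshold_dominates(self):
        m = gaussian_bump((64, 64), 30, 20, 0.9)
        det = find_peaks(m, 0.95, 5.0)
        assert len(det) == 0
        assert len(det.rejected) >= 1

    def test_two_close_bumps_keep_higher(self):
        m = np.maximum(
            gaussian_bump((64, 64), 30, 30, 0.9), gaussian_bump((64, 64), 34, 30, 0.8)
        )
        det = find_peaks(m, 0.5, 10.0)
        assert len(det) == 1
        assert det.heights[0] == pytest.approx(0.9, abs=0.05)
        assert brute_force_peaks(m, 0.5, 10.0) == {tuple(p) for p in det.points}

    def test_matches_brute_force_on_random_fields(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            m = smooth_map(rng.random((64, 64)), 2.0)
            det = find_peaks(m, 0.45, 6.0)
            assert brute_force_peaks(m, 0.45, 6.0) == {tuple(p) for p in det.points}

    def test_translation_invariant_count(self):
        rng = np.random.default_rng(3)
        base = smooth_map(rng.random((80, 80)), 2.5)
        shifted = np.roll(base, (7, 5), axis=(0, 1))
        # compare interior peaks only (wrap band excluded)
        d0 = find_peaks(base, 0.45, 6.0)
        d1 = find_peaks(shifted, 0.45, 6.0)
        inner0 = {
            (x + 5, y + 7)
            for x, y in map(tuple, d0.points)
            if 10 <= x < 65 and 10 <= y < 63
        }
        inner1 = {(x, y) for x, y in map(tuple, d1.points) if 15 <= x < 70 and 17 <= y < 70}
        assert inner0 == inner1


class TestMatchPoints:
    def test_perfect_agreement(self):
        pts = np.array([[5.0, 5.0], [20.0, 9.0], [40.0, 30.0]])
        det = DetectionSet(points=pts, heights=np.ones(3))
        counts = match_points(det, make_annotation(pts), 4.0)
        assert (counts.TP, counts.FP, counts.FN) == (3, 0, 0)

    def test_disjoint_sets(self):
        det = DetectionSet(points=np.array([[0.0, 0], [1, 0], [2, 0]]), heights=np.ones(3))
        truth = make_annotation([[100, 100], [110, 100], [120, 100], [130, 100]])
        counts = match_points(det, truth, 5.0)
        assert (counts.TP, counts.FP, counts.FN) == (0, 3, 4)

    def test_greedy_matches_exhaustive_assignment_oracle(self):
        # one detection equidistant-nearest to two truths: it pairs with the
        # lower-index truth, the other truth is a miss
        det = DetectionSet(points=np.array([[10.0, 10.0]]), heights=np.ones(1))
        truth = make_annotation([[12.0, 10.0], [8.0, 10.0]])
        counts = match_points(det, truth, 3.0)
        # oracle: enumerate all one-to-one assignments within the radius
        best = 0
        pairs_ok = [
            (0, j)
            for j in range(2)
            if np.hypot(*(det.points[0] - truth.points[j])) <= 3.0
        ]
        for r in range(len(pairs_ok) + 1):
            for combo in itertools.combinations(pairs_ok, r):
                if len({i for i, _ in combo}) == len(combo) == len({j for _, j in combo}):
                    best = max(best, len(combo))
        assert counts.TP == best == 1
        assert counts.FN == 1

    def test_tn_counts_far_rejected_candidates(self):
        det = DetectionSet(
            points=np.empty((0, 2)),
            heights=np.empty(0),
            rejected=np.array([[50.0, 50.0], [5.0, 5.0]]),
        )
        truth = make_annotation([[4.0, 5.0]])
        counts = match_points(det, truth, 5.0)
        assert counts.TN == 1  # (50,50) far; (5,5) near truth


class TestMCC:
    def test_perfect(self):
        assert mcc(ConfusionCounts(10, 0, 0, 10, 5.0)) == pytest.approx(1.0)

    def test_symmetric_zero(self):
        assert mcc(ConfusionCounts(1, 1, 1, 1, 5.0)) == pytest.approx(0.0)

    def test_derived_example(self):
        assert mcc(ConfusionCounts(TP=2, FP=1, FN=1, TN=3, match_radius_px=5.0)) == pytest.approx(
            5.0 / 12.0
        )

    def test_exhaustive_against_direct_formula(self):
        for tp, fp, fn, tn in itertools.product(range(6), repeat=4):
            if tp == fp == fn == tn == 0:
                with pytest.raises(ValueError):
                    mcc(ConfusionCounts(tp, fp, fn, tn, 1.0))
                continue
            denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
            expected = 0.0 if denom == 0 else (tp * tn - fp * fn) / np.sqrt(denom)
            assert mcc(ConfusionCounts(tp, fp, fn, tn, 1.0)) == pytest.approx(expected, abs=1e-12)


class TestFlagClosePairs:
    def test_mutual_proximity(self):
        det = DetectionSet(points=np.array([[0.0, 0], [3.0, 0]]), heights=np.ones(2))
        out = flag_close_pairs(det, 5.0)
        assert out.close_flags.tolist() == [True, True]

    def test_no_flags_when_far(self):
        det = DetectionSet(points=np.array([[0.0, 0], [30.0, 0]]), heights=np.ones(2))
        assert not flag_close_pairs(det, 5.0).close_flags.any()

    def test_chain_matches_all_pairs_oracle(self):
        pts = np.array([[0.0, 0], [4.0, 0], [8.0, 0]])
        det = DetectionSet(points=pts, heights=np.ones(3))
        out = flag_close_pairs(det, 5.0)
        oracle = [
            any(
                i != j and np.hypot(*(pts[i] - pts[j])) <= 5.0
                for j in range(len(pts))
            )
            for i in range(len(pts))
        ]
        assert out.close_flags.tolist() == oracle == [True, True, True]


class TestTuneFusion:
    def _planted(self, seed=0, n_img=2):
        """Fused maps where only thresholds in (0.58, 0.62) reproduce truth.

        Truth bumps sit above 0.62; decoy bumps are spread over (0.1,
        0.58) so the MCC rises in a staircase as the threshold climbs
        toward the separating band around 0.6.
        """
        rng = np.random.default_rng(seed)
        maps_per_image, truths = [], []
        for _ in range(n_img):
            m = np.zeros((128, 128))
            truth_pts, decoys = [], []
            for _ in range(30):
                x, y = rng.integers(10, 118, 2)
                if all(np.hypot(x - a, y - b) > 12 for a, b in truth_pts + decoys):
                    (truth_pts if len(truth_pts) < 8 else decoys).append((x, y))
            for x, y in truth_pts:
                m = np.maximum(m, gaussian_bump(m.shape, x, y, rng.uniform(0.62, 0.88), 2.0))
            for x, y in decoys:
                m = np.maximum(m, gaussian_bump(m.shape, x, y, rng.uniform(0.10, 0.58), 2.0))
            maps_per_image.append([m] * 9)
            truths.append(make_annotation(truth_pts))
        return maps_per_image, truths

    def test_recovers_planted_threshold(self):
        maps_per_image, truths = self._planted()
        init = FusionParams(smooth_sigma_px=1e-6, height_threshold=0.45, min_separation_px=6.0)
        tuned, score = tune_fusion(maps_per_image, truths, init, max_iter=200, match_radius_px=4.0)
        assert abs(tuned.height_threshold - 0.6) <= 0.05
        assert score == pytest.approx(1.0, abs=1e-6)

    def test_ascent_guarantee(self):
        maps_per_image, truths = self._planted(seed=1)
        init = FusionParams(smooth_sigma_px=2.0, height_threshold=0.3, min_separation_px=6.0)
        from stomakit.fusion import mean_mcc

        fused = [m[0] for m in maps_per_image]
        base = mean_mcc(fused, truths, 2.0, 0.3, 6.0, 4.0)
        _, score = tune_fusion(maps_per_image, truths, init, max_iter=60, match_radius_px=4.0)
        assert score >= base - 1e-12

    def test_zero_budget_returns_init(self):
        maps_per_image, truths = self._planted(seed=2)
        init = FusionParams(smooth_sigma_px=1.0, height_threshold=0.33, min_separation_px=6.0)
        tuned, _ = tune_fusion(maps_per_image, truths, init, max_iter=0, match_radius_px=4.0)
        assert tuned.height_threshold == init.height_threshold
        assert tuned.smooth_sigma_px == init.smooth_sigma_px

    def test_no_annotations_rejected(self):
        with pytest.raises(ValueError):
            tune_fusion([[np.zeros((8, 8))]], [make_annotation(np.empty((0, 2)))])

    def test_weight_optimization_upweights_informative_map(self):
        """One map carries the signal, the rest carry decoys; tuning the
        weights should beat uniform fusion and favor the signal map."""
        rng = np.random.default_rng(3)
        good = np.zeros((96, 96))
        truth_pts = [(20, 20), (60, 30), (40, 70), (75, 75)]
        for x, y in truth_pts:
            good = np.maximum(good, gaussian_bump(good.shape, x, y, 0.9, 2.5))
        junk = np.zeros((96, 96))
        for _ in range(6):
            x, y = rng.integers(8, 88, 2)
            junk = np.maximum(junk, gaussian_bump(junk.shape, x, y, 0.9, 2.5))
        maps = [good, junk, junk]
        truths = [make_annotation(truth_pts)]
        init = FusionParams(
            weights=np.full(3, 1 / 3), smooth_sigma_px=1e-6,
            height_threshold=0.45, min_separation_px=6.0,
        )
        _, base = tune_fusion([maps], truths, init, max_iter=0, match_radius_px=4.0)
        tuned, score = tune_fusion(
            [maps], truths, init, max_iter=300, match_radius_px=4.0, optimize_weights=True
        )
        assert score >= base
        assert tuned.weights[0] > 1 / 3
        assert score == pytest.approx(1.0, abs=1e-9)


def test_probability_map_float_tiff_roundtrip(tmp_path):
    from stomakit.fusion import read_probability_map, write_probability_map

    m = np.random.default_rng(12).random((24, 24)).astype(np.float32)
    write_probability_map(tmp_path / "m.tif", m)
    assert np.array_equal(read_probability_map(tmp_path / "m.tif"), m)
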