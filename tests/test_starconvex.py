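"""Star-convex geometry: targets, IoU, NMS, rasterization."""

import numpy as np
import pytest

from sishdetect.errors import ParameterError
from sishdetect.starconvex import (
    PolygonCandidate,
    candidate_polygons,
    compute_object_probability,
    compute_radial_distances,
    greedy_nms,
    polygon_iou,
    radial_ground_truth,
    rasterize_detections,
    rasterize_polygon,
)
from sishdetect.synthetic import SceneConfig, generate_scene, make_star_convex_blob

from .conftest import make_disk
from .oracles import nms_oracle, polygon_iou_oracle, ray_distance_oracle


def random_candidates(rng, n, span=30.0):
    out = []
    for _ in range(n):
        radii = rng.uniform(2, 8, 16)
        out.append(
            PolygonCandidate(
                center=(rng.uniform(5, span), rng.uniform(5, span)),
                radii=radii,
                score=float(rng.uniform(0.2, 1.0)),
            )
        )
    return out


class TestRadialDistances:
    def test_disk_center_radii(self):
        mask = make_disk(10)
        c = mask.shape[0] // 2
        radii = compute_radial_distances(mask, 32)[c, c]
        assert np.all(np.abs(radii - 10) <= 1.0)
        assert np.abs(radii.mean() - 10) <= 0.5

    def test_background_is_zero(self, default_scene):
        dist = compute_radial_distances(default_scene.mask, 8)
        assert not dist[default_scene.mask == 0].any()

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_scalar_marching_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mask = np.zeros((40, 40), dtype=np.int32)
        for lab in (1, 2, 3):
            blob = make_star_convex_blob(
                (rng.uniform(8, 32), rng.uniform(8, 32)), 6, 0.2,
                seed=seed * 3 + lab, shape=(40, 40),
            )
            mask[blob] = lab
        dist = compute_radial_distances(mask, 16)
        fg = np.argwhere(mask > 0)
        for row, col in fg[rng.permutation(len(fg))[:40]]:
            assert np.array_equal(
                dist[row, col], ray_distance_oracle(mask, row, col, 16)
            )

    def test_min_rays_enforced(self):
        with pytest.raises(ParameterError):
            compute_radial_distances(make_disk(5), 4)

    def test_translation_equivariance(self):
        mask = np.zeros((40, 40), dtype=np.int32)
        mask[8:20, 8:22] = make_disk(5)[2:14, 1:15]
        shifted = np.roll(mask, (7, 5), axis=(0, 1))
        d1 = compute_radial_distances(mask, 16)
        d2 = compute_radial_distances(shifted, 16)
        assert np.array_equal(np.roll(d1, (7, 5), axis=(0, 1)), d2)


class TestObjectProbability:
    def test_background_zero_instance_max_one(self, default_scene):
        prob = compute_object_probability(default_scene.mask)
        assert not prob[default_scene.mask == 0].any()
        for lab in np.unique(default_scene.mask[default_scene.mask > 0]):
            assert prob[default_scene.mask == lab].max() == pytest.approx(1.0)

    def test_disk_probability_decreases_outward(self):
        mask = make_disk(9)
        prob = compute_object_probability(mask)
        c = mask.shape[0] // 2
        row = prob[c, c:]
        inside = row[row > 0]
        assert np.all(np.diff(inside) <= 1e-9)
        assert prob[c, c] == pytest.approx(1.0)


class TestPolygonIoU:
    def test_self_iou_is_one(self):
        cand = PolygonCandidate((10.0, 10.0), np.full(16, 5.0), 0.9)
        assert polygon_iou(cand, cand) == 1.0

    def test_disjoint_supports_zero(self):
        a = PolygonCandidate((5.0, 5.0), np.full(16, 3.0), 0.9)
        b = PolygonCandidate((50.0, 50.0), np.full(16, 3.0), 0.8)
        assert polygon_iou(a, b) == 0.0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_independent_rasterizer(self, seed):
        rng = np.random.default_rng(seed)
        a, b = random_candidates(rng, 2, span=22.0)
        assert polygon_iou(a, b) == pytest.approx(
            polygon_iou_oracle(a, b), abs=1e-12
        )


class TestCandidatePolygons:
    def test_all_subthreshold_empty(self):
        prob = np.full((8, 8), 0.2)
        dist = np.ones((8, 8, 16))
        assert candidate_polygons(prob, dist, 0.5) == []

    def test_single_candidate_carries_its_radii(self):
        prob = np.zeros((8, 8))
        prob[3, 4] = 0.9
        dist = np.arange(8 * 8 * 16, dtype=float).reshape(8, 8, 16)
        cands = candidate_polygons(prob, dist, 0.5)
        assert len(cands) == 1
        assert cands[0].center == (3.0, 4.0)
        assert np.array_equal(cands[0].radii, dist[3, 4])
        assert cands[0].score == 0.9

    def test_count_equals_superthreshold_pixels(self):
        rng = np.random.default_rng(2)
        prob = rng.uniform(size=(16, 16))
        dist = rng.uniform(1, 5, (16, 16, 16))
        cands = candidate_polygons(prob, dist, 0.6)
        assert len(cands) == int((prob > 0.6).sum())


class TestGreedyNMS:
    def test_single_candidate_kept(self):
        c = PolygonCandidate((5.0, 5.0), np.full(16, 3.0), 0.7)
        assert greedy_nms([c], 0.4) == [c]

    def test_identical_polygons_keep_higher_score(self):
        radii = np.full(16, 4.0)
        hi = PolygonCandidate((10.0, 10.0), radii, 0.9)
        lo = PolygonCandidate((10.0, 10.0), radii, 0.8)
        kept = greedy_nms([lo, hi], 0.4)
        assert kept == [hi]

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_sequential_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        cands = random_candidates(rng, 8)
        kept = greedy_nms(cands, 0.4)
        expected = [cands[i] for i in nms_oracle(cands, 0.4, polygon_iou)]
        assert kept == expected

    def test_kept_set_pairwise_subthreshold(self):
        rng = np.random.default_rng(7)
        kept = greedy_nms(random_candidates(rng, 30), 0.4)
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                assert polygon_iou(kept[i], kept[j]) < 0.4

    def test_invariant_to_input_permutation(self):
        rng = np.random.default_rng(11)
        cands = random_candidates(rng, 12)
        kept1 = greedy_nms(cands, 0.4)
        shuffled = [cands[i] for i in rng.permutation(len(cands))]
        kept2 = greedy_nms(shuffled, 0.4)
        assert kept1 == kept2

    def test_threshold_validation(self):
        with pytest.raises(ParameterError):
            greedy_nms([], 1.0)


class TestRasterizeDetections:
    def test_nonoverlapping_polygons_keep_solo_areas(self):
        a = PolygonCandidate((10.0, 10.0), np.full(16, 4.0), 0.9)
        b = PolygonCandidate((30.0, 30.0), np.full(16, 5.0), 0.8)
        ds = rasterize_detections([a, b], (45, 45))
        for label, cand in ((1, a), (2, b)):
            solo = rasterize_polygon(cand, (45, 45))
            assert (ds.instance_mask == label).sum() == solo.sum()

    def test_contested_pixels_go_to_higher_score(self):
        a = PolygonCandidate((10.0, 10.0), np.full(16, 5.0), 0.9)
        b = PolygonCandidate((13.0, 10.0), np.full(16, 5.0), 0.5)
        ds = rasterize_detections([a, b], (30, 30))
        overlap = rasterize_polygon(a, (30, 30)) & rasterize_polygon(b, (30, 30))
        assert np.all(ds.instance_mask[overlap] == 1)

    def test_empty_list(self):
        ds = rasterize_detections([], (10, 10))
        assert ds.instance_mask.max() == 0
        assert ds.centroids == []

    def test_centroids_match_painted_pixels(self):
        rng = np.random.default_rng(5)
        kept = greedy_nms(random_candidates(rng, 10), 0.4)
        ds = rasterize_detections(kept, (40, 40))
        for label, (r, c) in enumerate(ds.centroids, start=1):
            sel = np.argwhere(ds.instance_mask == label)
            assert r == pytest.approx(sel[:, 0].mean())
            assert c == pytest.approx(sel[:, 1].mean())


class TestReconstruction:
    @pytest.mark.parametrize("radius", [5, 6.5, 8, 9.5, 11, 12.5, 14])
    def test_disk_reconstruction_quality(self, radius):
        """Center-pixel polygons reconstruct disks well at 32 rays; the
        integer-stepping quantization caps the worst radii near 0.93."""
        mask = make_disk(radius)
        c = mask.shape[0] // 2
        radii = compute_radial_distances(mask, 32)[c, c]
        poly = rasterize_polygon(
            PolygonCandidate((float(c), float(c)), radii, 1.0), mask.shape
        )
        disk = mask > 0
        iou = (poly & disk).sum() / (poly | disk).sum()
        assert iou >= 0.93

    def test_ground_truth_chain_recovers_separated_scene(self):
        """GT prob/dist maps through candidates+NMS+rasterization detect
        every nucleus of a well-separated scene exactly."""
        sc = generate_scene(
            SceneConfig(seed=21, n_nuclei=6, overlap_fraction=0, border_fraction=0)
        )
        gt = radial_ground_truth(sc.mask, 32)
        kept = greedy_nms(candidate_polygons(gt.prob, gt.dist, 0.5), 0.4)
        assert len(kept) == 6
        ds = rasterize_detections(kept, sc.mask.shape)
        from sishdetect.evaluation import match_instances

        res = match_instances(ds.instance_mask, sc.mask, 0.5)
        assert (res.tp, res.fp, res.fn) == (6, 0, 0)
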