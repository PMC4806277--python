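"""Fibonacci erosion schedule, Case I/II decision, seeds and GVF snakes."""

import numpy as np
import pytest
from scipy import ndimage

from pollensep import overlap
from pollensep.overlap import RegionCase

from conftest import random_blob


def brute_erode(mask, R):
    """Independent oracle: explicit Minkowski erosion with the Euclidean
    offset set {‖o‖ ≤ R}, out-of-frame treated as background."""
    H, W = mask.shape
    offs = [
        (dy, dx)
        for dy in range(-R, R + 1)
        for dx in range(-R, R + 1)
        if dy * dy + dx * dx <= R * R
    ]
    out = np.zeros_like(mask)
    for y in range(H):
        for x in range(W):
            if mask[y, x] and all(
                0 <= y + dy < H and 0 <= x + dx < W and mask[y + dy, x + dx]
                for dy, dx in offs
            ):
                out[y, x] = True
    return out


def brute_count(mask, min_area):
    labeled, n = ndimage.label(mask, structure=np.ones((3, 3)))
    return sum(
        1 for i in range(1, n + 1) if (labeled == i).sum() >= min_area
    )


class TestSchedule:
    def test_first_terms(self):
        assert overlap.fibonacci_schedule(6).tolist() == [0, 1, 1, 2, 3, 5]

    def test_full_schedule_ends_at_6765(self):
        sched = overlap.fibonacci_schedule(21)
        assert len(sched) == 21
        assert sched[-1] == 6765
        assert (np.diff(sched) >= 0).all()

    def test_minimal(self):
        assert overlap.fibonacci_schedule(2).tolist() == [0, 1]

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            overlap.fibonacci_schedule(1)


class TestErosionProfile:
    def test_single_disk_never_splits(self):
        yy, xx = np.mgrid[0:50, 0:50]
        disk = (yy - 25) ** 2 + (xx - 25) ** 2 <= 400
        prof = overlap.erosion_profile(disk)
        counts = [c for _, c in prof.steps]
        nonzero = [c for c in counts if c > 0]
        assert set(nonzero) == {1}
        assert prof.initial_count == 1 and prof.final_count == 1

    def test_two_disjoint_disks(self):
        yy, xx = np.mgrid[0:100, 0:100]
        m = ((yy - 30) ** 2 + (xx - 25) ** 2 <= 225) | (
            (yy - 70) ** 2 + (xx - 75) ** 2 <= 225
        )
        prof = overlap.erosion_profile(m)
        assert prof.initial_count == 2 and prof.final_count == 2

    def test_two_overlapping_disks_split(self, two_disk_region):
        region, _, _ = two_disk_region
        prof = overlap.erosion_profile(region)
        counts = [c for _, c in prof.steps]
        assert prof.initial_count == 1
        assert 2 in counts
        assert prof.final_count == 2

    def test_matches_brute_force_oracle(self, rng):
        schedule = np.array([0, 1, 2, 3, 5, 8])
        for _ in range(5):
            mask = random_blob(rng, size=48)
            if not mask.any():
                continue
            prof = overlap.erosion_profile(mask, schedule, min_object_area=4)
            for (radius, count) in prof.steps:
                expect = brute_count(brute_erode(mask, radius), 4)
                assert count == expect

    def test_zeros_stay_zero_after_vanish(self, rng):
        mask = random_blob(rng, size=32, n_seeds=1)
        prof = overlap.erosion_profile(mask)
        counts = [c for _, c in prof.steps]
        if 0 in counts:
            assert all(c == 0 for c in counts[counts.index(0):])

    def test_empty_region_errors(self):
        with pytest.raises(ValueError):
            overlap.erosion_profile(np.zeros((10, 10), bool))


class TestClassifyCase:
    @pytest.mark.parametrize(
        "initial,final,expected",
        [(1, 1, RegionCase.CASE_I), (1, 2, RegionCase.CASE_II),
         (3, 3, RegionCase.CASE_I), (2, 3, RegionCase.CASE_II)],
    )
    def test_rule(self, initial, final, expected):
        prof = overlap.ErosionProfile(steps=[(0, initial)], initial_count=initial,
                                      final_count=final)
        assert overlap.classify_case(prof) is expected

    @pytest.mark.parametrize("seed", range(4))
    def test_convex_grain_always_case_i(self, seed):
        """Erosion of a convex region stays connected, so single ellipses
        are Case I at any size/orientation."""
        r = np.random.default_rng(seed)
        yy, xx = np.mgrid[0:120, 0:120]
        a, b = r.uniform(15, 40), r.uniform(10, 25)
        th = r.uniform(0, np.pi)
        u = (xx - 60) * np.cos(th) + (yy - 60) * np.sin(th)
        v = -(xx - 60) * np.sin(th) + (yy - 60) * np.cos(th)
        ellipse = (u / max(a, b)) ** 2 + (v / min(a, b)) ** 2 <= 1
        prof = overlap.erosion_profile(ellipse)
        assert overlap.classify_case(prof) is RegionCase.CASE_I


class TestExtractSeeds:
    def test_two_disk_seeds(self, two_disk_region):
        region, gt, (c1, c2) = two_disk_region
        prof = overlap.erosion_profile(region)
        seeds = overlap.extract_seeds(region, prof)
        assert len(seeds) == 2
        # disjoint and inside the region
        assert not (seeds[0] & seeds[1]).any()
        for s in seeds:
            assert (s <= region).all()
        # each seed contains exactly one ground-truth center
        centers = [c1, c2]
        containment = [[s[cy, cx] for (cy, cx) in centers] for s in seeds]
        assert sorted(map(sum, containment)) == [1, 1]

    def test_case_i_rejected(self):
        yy, xx = np.mgrid[0:40, 0:40]
        disk = (yy - 20) ** 2 + (xx - 20) ** 2 <= 100
        prof = overlap.erosion_profile(disk)
        with pytest.raises(ValueError):
            overlap.extract_seeds(disk, prof)

    def test_fragments_near_touch_returned_unchanged(self):
        """A dumbbell whose eroded halves sit 2 px apart admits no
        dilation step, so the seeds equal the eroded fragments."""
        region = np.zeros((20, 32), bool)
        region[4:16, 2:15] = True
        region[4:16, 17:30] = True
        region[9:11, 15:17] = True  # 1-px-wide bridge
        prof = overlap.erosion_profile(region, np.array([0, 1, 1, 2, 3, 5, 8]))
        assert overlap.classify_case(prof) is RegionCase.CASE_II
        seeds = overlap.extract_seeds(region, prof)
        assert len(seeds) == 2
        union, n = ndimage.label(
            np.logical_or.reduce(seeds), structure=np.ones((3, 3))
        )
        assert n == 2

    def test_three_grain_chain(self):
        yy, xx = np.mgrid[0:80, 0:160]
        m = np.zeros((80, 160), bool)
        for cx in (35, 70, 105):
            m |= (yy - 40) ** 2 + (xx - cx) ** 2 <= 400
        prof = overlap.erosion_profile(m)
        assert overlap.classify_case(prof) is RegionCase.CASE_II
        seeds = overlap.extract_seeds(m, prof)
        assert len(seeds) == 3
        for i in range(3):
            for j in range(i + 1, 3):
                assert not (seeds[i] & seeds[j]).any()


class TestGVF:
    def test_mu_zero_fixed_point(self):
        """Without diffusion the field equals the edge-map gradient
        wherever the gradient is nonzero."""
        mask = np.zeros((40, 40), bool)
        mask[:, :20] = True
        field = overlap.gvf_field(mask, mu=0.0, n_iter=150, sigma=1.5)
        smooth = ndimage.gaussian_filter(mask.astype(float), 1.5)
        gy, gx = np.gradient(smooth)
        f = gx**2 + gy**2
        f /= f.max()
        fy, fx = np.gradient(f)
        strong = fx**2 + fy**2 > 1e-6
        assert np.abs(field.u - fx)[strong].max() < 1e-8
        assert np.abs(field.v - fy)[strong].max() < 1e-8

    def test_constant_mask_zero_field(self):
        field = overlap.gvf_field(np.ones((20, 20), bool))
        assert np.allclose(field.u, 0) and np.allclose(field.v, 0)

    def test_disk_field_points_inward(self):
        yy, xx = np.mgrid[0:80, 0:80]
        disk = (yy - 40) ** 2 + (xx - 40) ** 2 <= 20**2
        field = overlap.gvf_field(disk)
        rr = np.hypot(yy - 40.0, xx - 40.0)
        ring = (rr > 24) & (rr < 26)
        # inward radial direction at each ring pixel
        safe = np.where(rr == 0, 1.0, rr)
        ux = -(xx - 40.0) / safe
        uy = -(yy - 40.0) / safe
        dot = field.u * ux + field.v * uy
        mag = np.hypot(field.u, field.v)
        inward = dot[ring] > 0
        assert mag[ring].min() > 0
        assert inward.mean() >= 0.95

    def test_bad_params(self):
        with pytest.raises(ValueError):
            overlap.gvf_field(np.ones((5, 5), bool), mu=np.nan)
        with pytest.raises(ValueError):
            overlap.gvf_field(np.ones((5, 5), bool), sigma=0)


class TestSnake:
    def test_expands_to_region_boundary(self):
        """A seed deep inside a disk-shaped region inflates to the region
        boundary; the 15 px gap needs a GVF diffused long enough for the
        boundary force to reach the seed (capture range ~ √(μ·n_iter))."""
        yy, xx = np.mgrid[0:80, 0:80]
        region = (yy - 40) ** 2 + (xx - 40) ** 2 <= 25**2
        seed = (yy - 40) ** 2 + (xx - 40) ** 2 <= 10**2
        field = overlap.gvf_field(region, n_iter=500)
        contour = overlap.evolve_snake(seed, field, n_iter=300)
        x, y = contour[:, 0], contour[:, 1]
        area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
        assert abs(area - region.sum()) / region.sum() < 0.10

    def test_pure_tension_contracts(self):
        yy, xx = np.mgrid[0:60, 0:60]
        seed = (yy - 30) ** 2 + (xx - 30) ** 2 <= 15**2
        field = overlap.GVFField(
            u=np.zeros((60, 60)), v=np.zeros((60, 60)), mu=0.2, iterations=0
        )

        def perim(c):
            closed = np.vstack([c, c[:1]])
            return np.hypot(*np.diff(closed, axis=0).T).sum()

        perims = [
            perim(overlap.evolve_snake(seed, field, alpha=0.2, beta=0.0,
                                       kappa=0.0, n_iter=n))
            for n in (10, 30, 50)
        ]
        assert perims[0] > perims[1] > perims[2]

    def test_collapse_raises(self):
        yy, xx = np.mgrid[0:60, 0:60]
        seed = (yy - 30) ** 2 + (xx - 30) ** 2 <= 12**2
        field = overlap.GVFField(
            u=np.zeros((60, 60)), v=np.zeros((60, 60)), mu=0.2, iterations=0
        )
        with pytest.raises(overlap.SnakeCollapseError):
            overlap.evolve_snake(seed, field, alpha=0.5, beta=0.0, kappa=0.0,
                                 n_iter=2000)

    def test_two_seed_separation_quality(self, two_disk_region):
        region, gt, _ = two_disk_region
        prof = overlap.erosion_profile(region)
        seeds = overlap.extract_seeds(region, prof)
        field = overlap.gvf_field(region, n_iter=300)
        contours = [overlap.evolve_snake(s, field, n_iter=150) for s in seeds]
        from pollensep.overlap import _contour_interior

        interiors = [_contour_interior(c, region.shape) for c in contours]
        inter = (interiors[0] & interiors[1]).sum()
        assert inter / min(i.sum() for i in interiors) < 0.20
        # each contour covers >= 80% of its own disk
        cover = np.zeros((2, 2))
        for i, interior in enumerate(interiors):
            for j, g in enumerate(gt):
                cover[i, j] = (interior & g).sum() / g.sum()
        best = cover.max(axis=0)
        assert (best >= 0.80).all()


class TestSeparateRegion:
    def test_partition_contract(self, two_disk_region):
        region, gt, _ = two_disk_region
        case, masks, _ = overlap.split_region(region)
        assert case is RegionCase.CASE_II
        assert len(masks) == 2
        union = np.logical_or.reduce(masks)
        assert (union == region).all()
        assert not (masks[0] & masks[1]).any()

    def test_two_disk_iou(self, two_disk_region):
        region, gt, _ = two_disk_region
        _, masks, _ = overlap.split_region(region)
        from pollensep.pipeline import match_masks

        matches = match_masks(masks, gt)
        assert len(matches) == 2
        assert all(iou >= 0.8 for _, _, iou in matches)

    def test_requires_two_contours(self):
        with pytest.raises(ValueError):
            overlap.separate_region(np.ones((10, 10), bool), [np.zeros((4, 2))])

    def test_disjoint_contours_get_their_interiors(self):
        region = np.ones((30, 50), bool)
        sq1 = np.array([[2.0, 2.0], [20.0, 2.0], [20.0, 25.0], [2.0, 25.0]])
        sq2 = np.array([[28.0, 2.0], [47.0, 2.0], [47.0, 25.0], [28.0, 25.0]])
        masks = overlap.separate_region(region, [sq1, sq2])
        assert masks[0][10, 10] and not masks[0][10, 40]
        assert masks[1][10, 40] and not masks[1][10, 10]
        assert (np.logical_or.reduce(masks) == region).all()
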