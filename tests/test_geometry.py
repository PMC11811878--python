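import math

import numpy as np
import pytest

from mtcortex.geometry import (
    CylinderDomain,
    SegmentSet,
    collision_angle,
    first_intersection,
    first_intersection_brute,
    heading_unit,
    polyline_length,
    unit_to_heading,
    wrap_x,
)


class TestWrapX:
    @pytest.mark.parametrize(
        "x, expected_frac",
        [(lambda W: W + 1.0, 1.0), (lambda W: -0.5, lambda W: W - 0.5), (lambda W: 0.0, 0.0)],
    )
    def test_examples(self, domain, x, expected_frac):
        W = domain.circumference
        xv = x(W)
        expected = expected_frac(W) if callable(expected_frac) else expected_frac
        assert wrap_x(xv, domain) == pytest.approx(expected, abs=1e-12)

    def test_idempotent(self, domain):
        rng = np.random.default_rng(0)
        xs = rng.uniform(-100, 100, 200)
        once = wrap_x(xs, domain)
        assert np.allclose(wrap_x(once, domain), once)
        assert np.all((once >= 0) & (once < domain.circumference))


class TestCollisionAngle:
    def test_direct_difference(self):
        a = collision_angle(math.radians(10), math.radians(50))
        assert math.degrees(a.angle) == pytest.approx(40.0)

    def test_undirected_folding_and_sense(self):
        # incoming along the axis vs an obstructing line at 170 deg: the
        # minimal angle folds to 10 deg and the co-aligned sense is the
        # antiparallel branch of the obstructing trajectory
        a = collision_angle(0.0, math.radians(170))
        assert math.degrees(a.angle) == pytest.approx(10.0)
        assert math.degrees(a.coaligned_psi) == pytest.approx(350.0)

    def test_parallel(self):
        a = collision_angle(math.pi / 2, math.pi / 2)
        assert a.angle == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            psi = rng.uniform(0, 2 * math.pi)
            phi = rng.uniform(0, math.pi)
            a1 = collision_angle(psi, phi)
            a2 = collision_angle(psi, (phi + math.pi) % (2 * math.pi) % math.pi)
            assert a1.angle == pytest.approx(a2.angle, abs=1e-12)
            assert 0.0 <= a1.angle <= math.pi / 2 + 1e-12


class TestFirstIntersection:
    def test_perpendicular_cross(self, domain):
        # transverse path from (0, 5); axial obstacle at x = 2
        segs = SegmentSet.from_static(
            np.array([[2.0, 3.0]]), np.array([[2.0, 8.0]]), np.array([7])
        )
        hit = first_intersection((0.0, 5.0), math.pi / 2, segs, domain, 10.0)
        assert hit is not None
        assert hit.mt_id == 7
        assert hit.distance == pytest.approx(2.0, abs=1e-12)

    def test_hit_across_seam(self, domain):
        W = domain.circumference
        # obstacle just left of the seam; a path heading in -x from x = 0.5
        segs = SegmentSet.from_static(
            np.array([[W - 1.0, 3.0]]), np.array([[W - 1.0, 8.0]]), np.array([0])
        )
        hit = first_intersection((0.5, 5.0), 3 * math.pi / 2, segs, domain, 10.0)
        assert hit is not None
        assert hit.distance == pytest.approx(1.5, abs=1e-9)
        brute = first_intersection_brute((0.5, 5.0), 3 * math.pi / 2, segs, domain, 10.0)
        assert brute.distance == pytest.approx(hit.distance, abs=1e-12)

    def test_empty(self, domain):
        assert first_intersection((0, 0), 0.3, SegmentSet.empty(), domain, 5.0) is None

    def test_matches_brute_force_on_random_configs(self, domain):
        """The vectorized periodic-image search equals the exhaustive
        all-pairs oracle on seeded random configurations."""
        rng = np.random.default_rng(42)
        W = domain.circumference
        for _ in range(100):
            n = int(rng.integers(1, 51))
            a = np.column_stack([rng.uniform(-W, 2 * W, n), rng.uniform(0, 24, n)])
            ang = rng.uniform(0, 2 * math.pi, n)
            L = rng.exponential(3.0, n)
            b = a + np.column_stack([np.sin(ang) * L, np.cos(ang) * L])
            segs = SegmentSet.from_static(a, b, np.arange(n))
            p0 = [rng.uniform(0, W), rng.uniform(0, 24)]
            psi = rng.uniform(0, 2 * math.pi)
            h1 = first_intersection(p0, psi, segs, domain, 6.0)
            h2 = first_intersection_brute(p0, psi, segs, domain, 6.0)
            assert (h1 is None) == (h2 is None)
            if h1 is not None:
                assert h1.mt_id == h2.mt_id
                assert h1.distance == pytest.approx(h2.distance, abs=1e-9)

    def test_moving_extent_agreement(self, domain):
        """Moving-endpoint coverage (growing/shrinking tips, treadmilling
        minus ends) is handled identically by both implementations."""
        rng = np.random.default_rng(7)
        W = domain.circumference
        for _ in range(100):
            n = int(rng.integers(1, 30))
            a = np.column_stack([rng.uniform(-W, 2 * W, n), rng.uniform(0, 24, n)])
            ang = rng.uniform(0, 2 * math.pi, n)
            L = rng.exponential(2.0, n)
            b = a + np.column_stack([np.sin(ang) * L, np.cos(ang) * L])
            sa = rng.choice([0.0, 0.01], n)
            sb = rng.choice([0.06, -0.09, 0.0], n)
            segs = SegmentSet(a, b, np.arange(n), np.zeros(n, dtype=int), sa, sb, t0=5.0)
            p0 = [rng.uniform(0, W), rng.uniform(0, 24)]
            psi = rng.uniform(0, 2 * math.pi)
            h1 = first_intersection(p0, psi, segs, domain, 6.0, speed=0.06, t_start=5.0)
            h2 = first_intersection_brute(p0, psi, segs, domain, 6.0, speed=0.06, t_start=5.0)
            assert (h1 is None) == (h2 is None)
            if h1 is not None:
                assert (h1.mt_id, h1.seg_idx) == (h2.mt_id, h2.seg_idx)
                assert h1.time == pytest.approx(h2.time, abs=1e-9)

    def test_degenerate_segments_skipped(self, domain):
        segs = SegmentSet.from_static(
            np.array([[1.0, 5.0]]), np.array([[1.0, 5.0]]), np.array([0])
        )
        assert first_intersection((0.0, 5.0), math.pi / 2, segs, domain, 10.0) is None


def test_heading_roundtrip():
    for psi in np.linspace(0, 2 * math.pi, 17, endpoint=False):
        assert unit_to_heading(heading_unit(psi)) == pytest.approx(psi % (2 * math.pi), abs=1e-12)


def test_polyline_length():
    assert polyline_length(np.array([[0, 0], [3, 4]])) == pytest.approx(5.0)
    assert polyline_length(np.array([[1, 1]])) == 0.0
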