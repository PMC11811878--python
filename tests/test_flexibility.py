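import math

import numpy as np
import pytest

from mtcortex.flexibility import (
    FlexibilityParams,
    accept_bundle_deflection,
    calibrate_max_deflection,
    follow_bend,
    generate_growth_path,
    next_deflection_distance,
    sample_deflection_angle,
)
from mtcortex.metrics import estimate_persistence_length


class TestCalibration:
    def test_reference_values(self):
        # m = sqrt(3 * delta_d / L_p)
        assert calibrate_max_deflection(300.0, 0.3) == pytest.approx(math.sqrt(0.003))
        assert calibrate_max_deflection(26.0, 0.3) == pytest.approx(0.18605, abs=1e-4)

    def test_rigid_limit(self):
        assert calibrate_max_deflection(math.inf, 0.3) == 0.0

    def test_small_angle_warning(self):
        with pytest.warns(UserWarning):
            calibrate_max_deflection(2.0, 0.3)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            calibrate_max_deflection(-1.0, 0.3)


class TestSampling:
    def test_deflection_distance_mean_and_scaling(self, rng):
        n = 100_000
        d1 = np.array([next_deflection_distance(rng, 0.3) for _ in range(n)])
        assert np.all(d1 > 0)
        se = 0.3 / math.sqrt(n)
        assert abs(d1.mean() - 0.3) < 3 * se
        d2 = np.array([next_deflection_distance(rng, 0.15) for _ in range(n)])
        assert d2.mean() == pytest.approx(d1.mean() / 2, rel=0.05)

    def test_angle_variance_and_support(self, rng):
        m = 0.1
        a = np.array([sample_deflection_angle(rng, m) for _ in range(100_000)])
        assert np.all(np.abs(a) <= m)
        var_target = m * m / 3
        se = var_target * math.sqrt(2.0 / len(a))  # approximate SE of the variance
        assert abs(a.var() - var_target) < 3 * se

    def test_zero_m_and_min_threshold(self, rng):
        assert sample_deflection_angle(rng, 0.0) == 0.0
        a = np.array([sample_deflection_angle(rng, 0.1, m_min=0.05) for _ in range(2000)])
        assert np.all((a == 0.0) | (np.abs(a) >= 0.05))
        assert np.any(a == 0.0)


class TestBundleDeflection:
    def test_solo_always_accepts(self, rng):
        assert all(accept_bundle_deflection(0, rng) for _ in range(100))

    def test_one_other_accepts_half(self, rng):
        acc = sum(accept_bundle_deflection(1, rng) for _ in range(10_000)) / 10_000
        assert abs(acc - 0.5) < 3 * math.sqrt(0.25 / 10_000)

    def test_large_bundle_rarely_accepts(self, rng):
        acc = sum(accept_bundle_deflection(99, rng) for _ in range(10_000)) / 10_000
        assert acc < 0.02


class TestFollowBend:
    def test_small_bend_followed(self, rng):
        assert follow_bend([math.radians(5)], [1], math.radians(10), rng) == 0

    def test_large_bend_exits(self, rng):
        assert follow_bend([math.radians(15)], [1], math.radians(10), rng) is None

    def test_split_proportional_to_occupancy(self, rng):
        counts = [0, 0]
        for _ in range(10_000):
            c = follow_bend([0.01, 0.02], [3, 1], math.radians(10), rng)
            counts[c] += 1
        f = counts[0] / 10_000
        assert abs(f - 0.75) < 3 * math.sqrt(0.75 * 0.25 / 10_000)


class TestPaths:
    def test_rigid_paths_are_straight(self, rng):
        p = generate_growth_path(rng, FlexibilityParams(), 20.0, psi0=0.7)
        assert len(p) == 2
        assert np.hypot(*(p[-1] - p[0])) == pytest.approx(20.0)

    @pytest.mark.parametrize("Lp", [50.0, 300.0])
    def test_persistence_recovery(self, Lp):
        params = FlexibilityParams(persistence_length=Lp, deflection_step=0.3)
        rng = np.random.default_rng(int(Lp) + 1)
        paths = [generate_growth_path(rng, params, 50.0) for _ in range(250)]
        est = estimate_persistence_length(paths)
        assert abs(est - Lp) / Lp < 0.10

    def test_discretization_invariance(self):
        # halving the step (and recalibrating m) leaves the recovered L_p
        # within the estimator's scatter
        ests = []
        for step, seed in ((0.3, 11), (0.15, 12)):
            params = FlexibilityParams(persistence_length=300.0, deflection_step=step)
            rng = np.random.default_rng(seed)
            paths = [generate_growth_path(rng, params, 50.0) for _ in range(250)]
            ests.append(estimate_persistence_length(paths))
        assert abs(ests[0] - ests[1]) / 300.0 < 0.10
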