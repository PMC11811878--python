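import math

import numpy as np
import pytest

from mtcortex.fixtures import _add_straight, parallel_lines, random_array, single
from mtcortex.metrics import (
    angle_histogram,
    band_gap_density,
    density_profile,
    estimate_persistence_length,
    fraction_in_bands,
    mean_orientation,
    metrics_row,
    populated_band_count,
)
from mtcortex.prepattern import Prepattern
from mtcortex.state import ArrayState, total_length


@pytest.fixture
def pattern():
    # 4 bands of 1 um with 5 um gaps on H = 24
    return Prepattern.regular(4, 1.0, 5.0)


class TestDensityProfile:
    def test_single_ring_in_one_bin(self, domain):
        st = single(domain, start=(0.0, 10.3), psi=math.pi / 2, length=domain.circumference)
        prof = density_profile(st, bin_width=0.5)
        i = int(10.3 / 0.5)
        assert prof.length[i] == pytest.approx(domain.circumference)
        assert prof.length.sum() == pytest.approx(domain.circumference)

    def test_axial_segment_split_between_bins(self, domain):
        st = single(domain, start=(1.0, 9.75), psi=0.0, length=0.5)
        prof = density_profile(st, bin_width=0.5)
        i = int(9.75 / 0.5)
        assert prof.length[i] == pytest.approx(0.25)
        assert prof.length[i + 1] == pytest.approx(0.25)

    def test_inclined_segment_apportioned_geometrically(self, domain):
        # 30 deg from the axis, crossing one bin boundary
        st = single(domain, start=(0.0, 9.8), psi=math.radians(30), length=0.6)
        prof = density_profile(st, bin_width=0.5)
        dz = 0.6 * math.cos(math.radians(30))
        frac_below = (10.0 - 9.8) / dz
        i = int(9.8 / 0.5)
        assert prof.length[i] == pytest.approx(0.6 * frac_below)
        assert prof.length[i + 1] == pytest.approx(0.6 * (1 - frac_below))

    def test_mass_conservation_random_array(self, domain):
        st = random_array(domain, n=25, seed=9)
        prof = density_profile(st, bin_width=0.5)
        assert prof.length.sum() == pytest.approx(total_length(st), rel=1e-9)
        assert np.sum(prof.density * np.diff(prof.edges) * domain.circumference) == (
            pytest.approx(total_length(st), rel=1e-6)
        )


class TestBandMetrics:
    def test_uniform_rings_equal_densities(self, domain, pattern):
        # one ring per 0.5 um everywhere: uniform coverage
        st = ArrayState(domain=domain)
        for z in np.arange(0.25, 24.0, 0.5):
            _add_straight(st, np.array([0.0, z]), math.pi / 2, domain.circumference)
        band_d, gap_d = band_gap_density(st, pattern)
        assert band_d == pytest.approx(gap_d, rel=1e-9)
        assert fraction_in_bands(st, pattern) == pytest.approx(100.0 * 4.0 / 24.0, rel=1e-9)

    def test_all_mass_in_bands(self, domain, pattern):
        st = ArrayState(domain=domain)
        for z0 in (0.5, 6.5, 12.5, 18.5):
            _add_straight(st, np.array([0.0, z0]), math.pi / 2, domain.circumference)
        band_d, gap_d = band_gap_density(st, pattern)
        assert gap_d == 0.0
        assert fraction_in_bands(st, pattern) == pytest.approx(100.0)

    def test_mixed_toy_matches_manual(self, domain, pattern):
        st = ArrayState(domain=domain)
        _add_straight(st, np.array([0.0, 0.5]), math.pi / 2, 4.0)  # in band 0
        _add_straight(st, np.array([0.0, 3.0]), math.pi / 2, 6.0)  # in a gap
        W = domain.circumference
        band_d, gap_d = band_gap_density(st, pattern)
        assert band_d == pytest.approx(4.0 / (4 * 1.0 * W))
        assert gap_d == pytest.approx(6.0 / (20.0 * W))
        assert fraction_in_bands(st, pattern) == pytest.approx(100.0 * 4.0 / 10.0)

    def test_axial_spanning_microtubule(self, domain, pattern):
        st = single(domain, start=(1.0, 0.0), psi=0.0, length=24.0)
        assert fraction_in_bands(st, pattern) == pytest.approx(100.0 * 4.0 / 24.0)

    def test_empty_array_fraction_is_nan(self, domain, pattern):
        assert math.isnan(fraction_in_bands(ArrayState(domain=domain), pattern))


class TestPopulatedBands:
    def test_threshold_is_three_times_gap(self, domain, pattern):
        st = ArrayState(domain=domain)
        W = domain.circumference
        # two dense bands, some gap mass
        for z0 in (0.5, 6.5):
            for _ in range(10):
                _add_straight(st, np.array([0.0, z0]), math.pi / 2, W)
        _add_straight(st, np.array([0.0, 3.0]), math.pi / 2, W)
        assert populated_band_count(st, pattern) == 2

    def test_empty_array(self, domain, pattern):
        assert populated_band_count(ArrayState(domain=domain), pattern) == 0

    def test_zero_gap_convention(self, domain, pattern):
        st = single(domain, start=(0.0, 0.5), psi=math.pi / 2, length=5.0)
        assert populated_band_count(st, pattern) == 1


class TestOrientation:
    def test_single_segment_histogram(self, domain):
        st = single(domain, start=(0, 5), psi=math.radians(92), length=5.0)
        hist, edges = angle_histogram(st, bins=36)
        assert hist.sum() == pytest.approx(5.0)
        assert hist[int(92 // 5)] == pytest.approx(5.0)

    def test_symmetric_pair_mean_is_transverse(self, domain):
        st = ArrayState(domain=domain)
        _add_straight(st, np.array([0.0, 5.0]), math.radians(80), 3.0)
        _add_straight(st, np.array([0.0, 15.0]), math.radians(100), 3.0)
        ori, S = mean_orientation(st)
        assert ori == pytest.approx(90.0, abs=1e-9)

    def test_perfect_alignment_order_one(self, domain):
        st = parallel_lines(domain, 3, orientation=math.radians(92))
        ori, S = mean_orientation(st)
        assert ori == pytest.approx(92.0, abs=1e-6)
        assert S == pytest.approx(1.0)

    def test_isotropic_order_near_zero(self, domain):
        rng = np.random.default_rng(0)
        st = ArrayState(domain=domain)
        for _ in range(10_000):
            _add_straight(st, np.array([rng.uniform(0, 12), rng.uniform(0, 20)]),
                          rng.uniform(0, 2 * math.pi), 1.0)
        _, S = mean_orientation(st)
        assert S < 0.05

    def test_empty_is_nan(self, domain):
        ori, S = mean_orientation(ArrayState(domain=domain))
        assert math.isnan(ori) and math.isnan(S)


class TestPersistenceEstimator:
    def test_straight_paths_give_infinity(self):
        paths = [np.array([[0.0, 0.0], [0.0, 10.0], [0.0, 20.0]])] * 5
        assert estimate_persistence_length(paths) == math.inf

    def test_longer_paths_reduce_scatter(self):
        from mtcortex.flexibility import FlexibilityParams, generate_growth_path
        params = FlexibilityParams(persistence_length=100.0)
        ests = {}
        for L, seed in ((25.0, 1), (100.0, 1)):
            rng = np.random.default_rng(seed)
            reps = [estimate_persistence_length(
                [generate_growth_path(rng, params, L) for _ in range(30)])
                for _ in range(12)]
            ests[L] = np.std(reps)
        assert ests[100.0] < ests[25.0]


def test_metrics_row_contents(domain):
    st = parallel_lines(domain, 2)
    row = metrics_row(st, Prepattern.regular(4, 1.0, 5.0))
    for key in ("total_length_um", "n_mt", "band_density", "gap_density",
                "populated_bands", "frac_in_bands_pct", "mean_orientation_deg",
                "order_param_S", "n_crossovers"):
        assert key in row
    assert row["n_mt"] == 2
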