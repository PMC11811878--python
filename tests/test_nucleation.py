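import math

import numpy as np
import pytest
from scipy import stats

from mtcortex.fixtures import parallel_lines, single
from mtcortex.nucleation import (
    ComplexPool,
    NucleationParams,
    handle_appearance,
    isotropic_nucleate,
    metatrajectory_weight,
    outcome_probabilities,
    ray_hits,
    release_complexes,
    sample_bound_geometry,
)
from mtcortex.state import ArrayState


@pytest.fixture
def params():
    return NucleationParams(n_dir=24, D=0.013, r_u=0.013, d_max=10.0)


class TestWeights:
    def test_zero_distance_weight(self, params):
        assert metatrajectory_weight(0.0, params) == pytest.approx(1.0 / params.n_dir)

    def test_strictly_decreasing(self, params):
        d = np.linspace(0, params.d_max, 50)
        w = np.array([metatrajectory_weight(x, params) for x in d])
        assert np.all(np.diff(w) < 0)

    def test_probabilities_sum_to_one(self, domain, params):
        st = parallel_lines(domain, 3, spacing=1.0, z0=10.0)
        hits = ray_hits(st, np.array([3.0, 10.5]), 0.3, params)
        P, P_iso = outcome_probabilities(hits, params)
        assert P.sum() + P_iso == pytest.approx(1.0, abs=1e-12)
        assert np.all(P >= 0) and 0 <= P_iso <= 1

    def test_empty_array_all_unbound(self, domain, params):
        st = ArrayState(domain=domain)
        hits = ray_hits(st, np.array([1.0, 5.0]), 0.0, params)
        P, P_iso = outcome_probabilities(hits, params)
        assert P_iso == 1.0

    def test_added_microtubule_increases_bound_probability(self, domain, params):
        point = np.array([3.0, 10.5])
        st1 = parallel_lines(domain, 1, z0=10.0)
        _, iso1 = outcome_probabilities(ray_hits(st1, point, 0.3, params), params)
        st2 = parallel_lines(domain, 2, spacing=1.0, z0=10.0)
        _, iso2 = outcome_probabilities(ray_hits(st2, point, 0.3, params), params)
        assert iso2 < iso1

    def test_bound_hits_lie_on_first_intersected(self, domain, params):
        # a ray pointing up from z=10.5 must hit the ring at z=11, not z=12
        st = parallel_lines(domain, 3, spacing=1.0, z0=10.0)
        hits = ray_hits(st, np.array([3.0, 10.5]), 0.0, params)
        up = hits[0]  # offset 0: first ray along +z
        assert up is not None
        assert up.point[1] == pytest.approx(11.0, abs=1e-9)


class TestAppearance:
    def test_full_pool_always_rejected(self, domain, params, rng):
        st = ArrayState(domain=domain)
        pool = ComplexPool(size=5, occupied=5, releases=[math.inf] * 5)
        for _ in range(100):
            out = handle_appearance(st, params, pool, rng)
            assert out.mode == "rejected" and out.reason == "occupancy"

    def test_outcome_frequencies_match_analytics(self, domain, rng):
        """Empirical bound/unbound frequencies on a fixed 3-ring toy
        configuration match the per-ray analytic probabilities."""
        st = parallel_lines(domain, 3, spacing=1.0, z0=10.0)
        params = NucleationParams(n_dir=24, p_acc_mt=1.0, p_acc_free=1.0)
        point, offset = np.array([3.0, 10.5]), 0.3
        hits = ray_hits(st, point, offset, params)
        P, P_iso = outcome_probabilities(hits, params)
        exp_parent = {}
        for h, p in zip(hits, P):
            if h is not None:
                exp_parent[h.mt_id] = exp_parent.get(h.mt_id, 0.0) + p
        n = 20_000
        counts = {k: 0 for k in exp_parent}
        unbound = 0
        for _ in range(n):
            out = handle_appearance(st, params, None, rng, fixed_point=point, fixed_offset=offset)
            if out.mode == "bound":
                counts[out.parent] += 1
            else:
                unbound += 1
        obs = [counts[k] for k in sorted(exp_parent)] + [unbound]
        exp = [exp_parent[k] * n for k in sorted(exp_parent)] + [P_iso * n]
        assert stats.chisquare(obs, exp).pvalue > 0.01

    def test_bound_positions_on_parent(self, domain, params, rng):
        st = parallel_lines(domain, 3, spacing=1.0, z0=10.0)
        seen = 0
        for _ in range(300):
            out = handle_appearance(st, params, None, rng)
            if out.mode == "bound":
                seen += 1
                assert out.position[1] == pytest.approx(round(out.position[1]), abs=1e-9)
        assert seen > 0


class TestPool:
    def test_release_exactly_after_t_occ(self):
        pool = ComplexPool(size=3)
        pool.occupy(10.0, 90.0)
        assert pool.occupied == 1
        release_complexes(pool, 99.999)
        assert pool.occupied == 1
        release_complexes(pool, 100.0)
        assert pool.occupied == 0

    def test_staggered_releases_in_order(self):
        pool = ComplexPool(size=3)
        pool.occupy(0.0, 50.0)
        pool.occupy(10.0, 50.0)
        release_complexes(pool, 55.0)
        assert pool.occupied == 1
        release_complexes(pool, 60.0)
        assert pool.occupied == 0

    def test_stationary_rejection_matches_mean_occupancy(self, domain):
        """At stationarity the occupancy-rejection frequency equals the
        time-averaged occupied fraction (queueing balance)."""
        st = ArrayState(domain=domain)
        params = NucleationParams(r_app=1.0, pool_size=40, t_occ=30.0,
                                  p_acc_free=1.0, p_acc_mt=1.0)
        pool = ComplexPool(size=params.pool_size)
        rng = np.random.default_rng(3)
        t, burn, last = 0.0, 400.0, 400.0
        occ_time = rejected = attempts = 0
        while t < 3500.0:
            t += rng.exponential(1.0 / params.r_app)
            pool.release_until(t)
            if t < burn:
                handle_appearance(st, params, pool, rng, t)
                continue
            occ_time += pool.occupied * (t - last)
            last = t
            attempts += 1
            out = handle_appearance(st, params, pool, rng, t)
            rejected += out.mode == "rejected" and out.reason == "occupancy"
        freq = rejected / attempts
        mean_occ = occ_time / (t - burn) / params.pool_size
        se = math.sqrt(freq * (1 - freq) / attempts)
        assert abs(freq - mean_occ) < 3 * se + 0.02


class TestBranchGeometry:
    def test_pure_parallel_and_antiparallel(self, rng):
        par = NucleationParams(branch_mix=(1.0, 0.0, 0.0))
        anti = NucleationParams(branch_mix=(0.0, 1.0, 0.0))
        for _ in range(50):
            assert sample_bound_geometry(0.7, par, rng) == pytest.approx(0.7)
            assert sample_bound_geometry(0.7, anti, rng) == pytest.approx(0.7 + math.pi)

    def test_branched_mode_and_side_symmetry(self, rng):
        params = NucleationParams(branch_mix=(0.0, 0.0, 1.0))
        rel = []
        for _ in range(20_000):
            psi = sample_bound_geometry(0.0, params, rng)
            r = math.remainder(psi, 2 * math.pi)
            rel.append(r)
        rel = np.array(rel)
        left = np.sum(rel < 0) / len(rel)
        assert abs(left - 0.5) < 3 * math.sqrt(0.25 / len(rel))
        # empirical mode near the configured 35 degrees
        hist, edges = np.histogram(np.abs(rel), bins=36, range=(0, math.pi))
        mode = math.degrees(0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1]))
        assert abs(mode - 35.0) < 7.5


class TestIsotropic:
    def test_uniform_position_and_heading(self, domain, rng):
        st = ArrayState(domain=domain)
        xs, zs, psis = [], [], []
        for _ in range(5000):
            out = isotropic_nucleate(st, rng)
            xs.append(out.position[0])
            zs.append(out.position[1])
            psis.append(out.heading)
        W, H = domain.circumference, domain.height
        assert stats.kstest(np.array(xs) / W, "uniform").pvalue > 0.01
        assert stats.kstest(np.array(zs) / H, "uniform").pvalue > 0.01
        assert stats.kstest(np.array(psis) / (2 * math.pi), "uniform").pvalue > 0.01
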