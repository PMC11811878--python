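import math

import numpy as np
import pytest

from mtcortex.engine import DynamicsParams, Simulation
from mtcortex.fixtures import _add_straight, random_array, single
from mtcortex.flexibility import FlexibilityParams
from mtcortex.geometry import CylinderDomain
from mtcortex.state import ArrayState, Microtubule, total_length


def make_sim(domain, dyn, state, **kw):
    kw.setdefault("record_events", True)
    return Simulation(domain, dyn, initial_state=state, **kw)


class TestBallistics:
    def test_free_growth_minus_treadmilling(self, domain):
        dyn = DynamicsParams(v_plus=0.05, v_minus=0.08, v_tm=0.01,
                             r_cat=0.0, r_res=0.0, r_sever=0.0)
        st = single(domain, start=(1.0, 12.0), psi=math.pi / 2, length=1.0)
        res = make_sim(domain, dyn, st).run(100.0)
        assert total_length(res.state) == pytest.approx(1.0 + (0.05 - 0.01) * 100.0)

    def test_t_end_zero_returns_initial_state(self, domain, quiet_dyn):
        st = single(domain, start=(1.0, 12.0), psi=math.pi / 2, length=1.0)
        res = make_sim(domain, quiet_dyn, st).run(0.0)
        assert total_length(res.state) == pytest.approx(1.0)
        assert res.state.time == 0.0

    def test_shrinking_death_time(self, domain):
        # shrinking tip with no rescue dies at length/(v_minus + v_tm)
        dyn = DynamicsParams(v_plus=0.05, v_minus=0.08, v_tm=0.01,
                             r_cat=0.0, r_res=0.0, r_sever=0.0)
        st = single(domain, start=(1.0, 12.0), psi=math.pi / 2, length=4.5, growing=False)
        res = make_sim(domain, dyn, st).run(100.0)
        deaths = [e for e in res.events if e["kind"] == "death"]
        assert len(deaths) == 1
        assert deaths[0]["time"] == pytest.approx(4.5 / 0.09)


class TestEdge:
    def test_edge_catastrophe_and_clamp(self, domain, quiet_dyn):
        st = single(domain, start=(0.0, 20.0), psi=0.0, length=0.5)  # heading +z
        sim = make_sim(domain, quiet_dyn, st)
        res = sim.run(80.0)
        ev = [e for e in res.events if e["kind"] == "edge_catastrophe"]
        assert len(ev) == 1
        assert ev[0]["time"] == pytest.approx((24.0 - 20.5) / 0.05)

    def test_shrinking_tip_at_edge_no_event(self, domain, quiet_dyn):
        st = single(domain, start=(0.0, 23.0), psi=0.0, length=1.0, growing=False)
        res = make_sim(domain, quiet_dyn, st).run(5.0)
        assert not [e for e in res.events if e["kind"] == "edge_catastrophe"]


class TestCollisions:
    def _crossing_pair(self, domain, growing_obstacle=False):
        st = ArrayState(domain=domain)
        _add_straight(st, np.array([3.0, 8.0]), 0.0, 4.0, growing=growing_obstacle)
        _add_straight(st, np.array([0.5, 10.0]), math.pi / 2, 0.0)
        return st

    def test_induced_catastrophe_at_predicted_time(self, domain):
        dyn = DynamicsParams(v_plus=0.05, v_minus=0.0, v_tm=0.0,
                             r_cat=0.0, r_res=0.0, r_sever=0.0, p_cat=1.0)
        res = make_sim(domain, dyn, self._crossing_pair(domain)).run(100.0)
        ev = [e for e in res.events if e["kind"] == "induced_catastrophe"]
        assert len(ev) == 1
        assert ev[0]["time"] == pytest.approx(2.5 / 0.05)  # hits x=3 from x=0.5

    def test_crossover_complement_of_catastrophe(self, domain):
        dyn = DynamicsParams(v_plus=0.05, v_minus=0.0, v_tm=0.0,
                             r_cat=0.0, r_res=0.0, r_sever=0.0, p_cat=0.0)
        res = make_sim(domain, dyn, self._crossing_pair(domain)).run(100.0)
        assert [e for e in res.events if e["kind"] == "crossover"]
        assert len(res.state.crossovers) == 1

    def test_bundling_below_threshold(self, domain):
        dyn = DynamicsParams(v_plus=0.05, v_minus=0.0, v_tm=0.0,
                             r_cat=0.0, r_res=0.0, r_sever=0.0)
        st = ArrayState(domain=domain)
        _add_straight(st, np.array([2.0, 9.0]), math.radians(60), 4.0, growing=False)
        _add_straight(st, np.array([0.5, 10.0]), math.radians(90), 0.0)
        res = make_sim(domain, dyn, st).run(120.0)
        ev = [e for e in res.events if e["kind"] == "bundle"]
        assert len(ev) == 1
        mt = res.state.mts[1]
        assert "bundling-entry" in mt.vkinds
        # entrained exactly along the obstructing direction (30 deg < 40 deg)
        assert math.degrees(mt.tip_psi) == pytest.approx(60.0)

    def test_severing_mean_delay(self, domain):
        """One crossover with rate r carries an exponential clock: the mean
        severing delay over many seeds is 1/r."""
        r_sever = 0.05
        dyn = DynamicsParams(v_plus=0.05, v_minus=0.0, v_tm=0.0,
                             r_cat=0.0, r_res=0.0, r_sever=r_sever, p_cat=0.0)
        delays = []
        for seed in range(400):
            st = self._crossing_pair(domain)
            res = make_sim(domain, dyn, st, seed=seed).run(400.0)
            made = next(e for e in res.events if e["kind"] == "crossover")
            cut = [e for e in res.events if e["kind"] == "sever"]
            if cut:
                delays.append(cut[0]["time"] - made["time"])
        # censored tail is negligible: P(delay > 350) ~ 2.5e-8
        d = np.array(delays)
        se = (1 / r_sever) / math.sqrt(len(d))
        assert abs(d.mean() - 1 / r_sever) < 3 * se

    def test_crossover_removed_when_tip_retracts_past_it(self, domain):
        # a long shrinking obstacle crosses the incoming path; its tip later
        # retracts past the crossing point, which erases the crossover and
        # invalidates the pending severing event
        dyn = DynamicsParams(v_plus=0.05, v_minus=0.08, v_tm=0.0,
                             r_cat=0.0, r_res=0.0, r_sever=1e-6, p_cat=0.0)
        st = ArrayState(domain=domain)
        _add_straight(st, np.array([3.0, 2.0]), 0.0, 20.0, growing=False)
        _add_straight(st, np.array([0.5, 10.0]), math.pi / 2, 0.0)
        res = make_sim(domain, dyn, st, seed=5).run(400.0)
        made = [e for e in res.events if e["kind"] == "crossover"]
        gone = [e for e in res.events if e["kind"] == "crossover_gone"]
        assert len(made) == 1 and made[0]["time"] == pytest.approx(50.0)
        # obstacle tip passes z=10 at t = (22-10)/0.08 = 150
        assert len(gone) == 1 and gone[0]["time"] == pytest.approx(150.0)
        assert len(res.state.crossovers) == 0
        assert not [e for e in res.events if e["kind"] == "sever"]

    def test_self_collision_after_wrapping(self, domain):
        # an inclined microtubule whose tip path wraps the cylinder and
        # re-crosses the periodic image of its own first segment
        dyn = DynamicsParams(v_plus=0.05, v_minus=0.0, v_tm=0.0,
                             r_cat=0.0, r_res=0.0, r_sever=0.0, p_cat=0.0,
                             theta_bundle=math.radians(1.0))
        st = ArrayState(domain=domain)
        mt = Microtubule(
            id=st.new_mt_id(),
            verts=[np.array([0.0, 10.0]), np.array([3.0, 11.5]), np.array([3.0, 11.5])],
            vert_t=[0.0, 0.0, 0.0], vkinds=["", "", ""],
            tip_psi=math.radians(95.0),
        )
        st.add_mt(mt)
        res = make_sim(domain, dyn, st).run(400.0)
        made = [e for e in res.events if e["kind"] == "crossover"]
        assert made, "expected a self-crossover after wrapping"
        x = list(res.state.crossovers.values())[0]
        assert x.over_mt == x.under_mt == 0


class TestConservation:
    def test_inter_event_length_balance(self, domain, dyn):
        """Between consecutive events d(total length)/dt equals
        #growing*v+ - #shrinking*v- - #mt*v_tm."""
        st = random_array(domain, n=15, seed=8, mean_length=4.0)
        sim = make_sim(domain, dyn, st, seed=2, audit_conservation=True)
        res = sim.run(400.0)
        assert len(res.audit) > 50
        for (t0, L0, g0, s0, n0), (t1, L1, *_ ) in zip(res.audit, res.audit[1:]):
            pred = L0 + (g0 * dyn.v_plus - s0 * dyn.v_minus - n0 * dyn.v_tm) * (t1 - t0)
            assert abs(pred - L1) < 1e-6


class TestDeterminism:
    def test_identical_seed_identical_event_log(self, domain, dyn):
        def run_once():
            st = random_array(domain, n=12, seed=4, mean_length=4.0)
            flex = FlexibilityParams(persistence_length=300.0)
            sim = make_sim(domain, dyn, st, seed=99, flex=flex)
            return sim.run(300.0).events

        assert run_once() == run_once()

    def test_different_seed_differs(self, domain, dyn):
        def run_once(seed):
            st = random_array(domain, n=12, seed=4, mean_length=4.0)
            sim = make_sim(domain, dyn, st, seed=seed)
            return sim.run(300.0).events

        assert run_once(1) != run_once(2)


class TestRescueRetrace:
    def test_rescued_tip_resumes_along_polyline(self, big_domain):
        dyn = DynamicsParams(v_plus=0.05, v_minus=0.08, v_tm=0.0,
                             r_cat=0.002, r_res=0.02, r_sever=0.0)
        st = ArrayState(domain=big_domain)
        _add_straight(st, np.array([0.0, 1e5]), math.radians(50), 10.0)
        res = make_sim(big_domain, dyn, st, seed=11).run(5000.0)
        mt = list(res.state.mts.values())[0]
        # free growth with no deflections: the polyline stays on one line
        pts = np.array(mt.verts)
        d = np.diff(pts, axis=0)
        angles = np.arctan2(d[:, 0], d[:, 1])
        assert np.allclose(angles, angles[0], atol=1e-9)
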