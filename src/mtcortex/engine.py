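"""Event-driven stochastic core of the cortical array simulator.

The simulation advances from event to event: between events every quantity
evolves deterministically (tips grow or shrink at constant speed, minus ends
treadmill), so the next state change can always be computed exactly.
Stochastic events (spontaneous catastrophe, rescue, katanin severing,
nucleation-complex appearance) carry exponential waiting times; geometric
events (collision, edge arrival, deflection point, band/gap boundary
crossing, vertex passage, death, bundle-vertex arrival) are computed in
closed form. Events are executed in non-decreasing time order, with
deterministic events ordered before stochastic ones at equal times and ties
broken by subject id, so a run is exactly reproducible from its seed.

Collisions are scheduled against *moving* segment extents: every segment
lies on a fixed carrier line and only its two terminal arc coordinates move,
so the crossing time of a growing tip with any segment is the solution of a
linear equation. Scheduled events are lazily invalidated: each carries
per-subject sequence numbers (and, for collisions and bundle tracking, the
obstacle's geometry version) and is recomputed on mismatch at pop time.
Whenever a tip starts covering new ground (nucleation, rescue, deflection,
bundling), all other growing tips are probed against the new moving segment
so no earlier collision can be missed.

All randomness flows from one seed through three named substreams
(dynamics, nucleation, flexibility), so adding events in one subsystem does
not perturb another's stream.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Any, Callable, Dict, List, Optional, Tuple

import numpy as np

from .flexibility import (
    FlexibilityParams,
    accept_bundle_deflection,
    follow_bend,
    next_deflection_distance,
    sample_deflection_angle,
)
from .geometry import (
    PARALLEL_TOL,
    PATH_TOL,
    CylinderDomain,
    Hit,
    SegmentSet,
    collision_angle,
    first_intersection,
    first_intersection_brute,
    heading_unit,
    orientation_of,
    unit_to_heading,
)
from .nucleation import (
    ComplexPool,
    NucleationParams,
    handle_appearance,
    isotropic_nucleate,
)
from .prepattern import PhaseSchedule, Prepattern, biased_nucleation_angle, local_catastrophe_rate
from .state import (
    GROWING,
    ON_TOL,
    SHRINKING,
    ArrayState,
    BundleRef,
    Crossover,
    Microtubule,
    arc_from_plus,
    locate_on_mt,
    occupancy_at,
    sever,
    total_length,
)

DETERMINISTIC = 0
STOCHASTIC = 1

INF = math.inf


@dataclass(frozen=True)
class DynamicsParams:
    """Dynamic-instability and interaction parameters.

    Speeds in um/s, rates in 1/s. There are deliberately no defaults for the
    measured quantities; a configuration must state them.
    """

    v_plus: float  # plus-end growth speed
    v_minus: float  # plus-end shrinkage speed
    v_tm: float  # minus-end treadmilling (retraction) speed
    r_cat: float  # spontaneous catastrophe rate
    r_res: float  # rescue rate
    r_sever: float  # katanin severing rate per crossover
    p_cat: float = 0.09  # induced-catastrophe probability at steep collisions
    theta_bundle: float = math.radians(40.0)  # bundling threshold angle (rad)
    edge_catastrophe: bool = True  # catastrophe at the cylinder edges

    def __post_init__(self) -> None:
        for name in ("v_plus", "v_minus", "v_tm", "r_cat", "r_res", "r_sever"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.p_cat <= 1.0:
            raise ValueError("p_cat must be in [0, 1]")
        if not 0.0 < self.theta_bundle < math.pi / 2:
            raise ValueError("theta_bundle must be in (0, pi/2)")


class _SegmentStore:
    """Incrementally maintained segment table with moving terminal endpoints.

    Each row stores a segment's base endpoints at an anchor time together
    with scalar arc speeds of the two endpoints along the segment's own
    carrier direction, so the whole table can be materialized at any query
    time with a few vectorized operations.
    """

    def __init__(self) -> None:
        self._cap = 64
        self._n = 0
        self.A = np.zeros((self._cap, 2))
        self.B = np.zeros((self._cap, 2))
        self.Wdir = np.zeros((self._cap, 2))
        self.sa = np.zeros(self._cap)
        self.sb = np.zeros(self._cap)
        self.T0 = np.zeros(self._cap)
        self.mt_id = np.full(self._cap, -1, dtype=int)
        self.seg_idx = np.zeros(self._cap, dtype=int)
        self.active = np.zeros(self._cap, dtype=bool)
        self._rows: Dict[int, List[int]] = {}
        self._free: List[int] = []
        self.version = 0  # bumped on any topology change, for snapshot caching

    def _alloc(self) -> int:
        if self._free:
            return self._free.pop()
        if self._n >= self._cap:
            new_cap = self._cap * 2
            for name in ("A", "B", "Wdir"):
                arr = getattr(self, name)
                grown = np.zeros((new_cap, 2))
                grown[: self._cap] = arr
                setattr(self, name, grown)
            for name, dtype in (("sa", float), ("sb", float), ("T0", float)):
                arr = getattr(self, name)
                grown = np.zeros(new_cap, dtype=dtype)
                grown[: self._cap] = arr
                setattr(self, name, grown)
            for name in ("mt_id", "seg_idx"):
                arr = getattr(self, name)
                grown = np.full(new_cap, -1 if name == "mt_id" else 0, dtype=int)
                grown[: self._cap] = arr
                setattr(self, name, grown)
            grown_active = np.zeros(new_cap, dtype=bool)
            grown_active[: self._cap] = self.active
            self.active = grown_active
            self._cap = new_cap
        r = self._n
        self._n += 1
        return r

    def remove_mt(self, mt_id: int) -> None:
        self.version += 1
        for r in self._rows.pop(mt_id, ()):
            self.active[r] = False
            self.mt_id[r] = -1
            self._free.append(r)

    def refresh_mt(self, mt: Microtubule, t: float, dyn: DynamicsParams) -> None:
        """Replace all rows of one microtubule with its current geometry."""
        self.remove_mt(mt.id)
        self.version += 1
        pts = mt.points_at(t, dyn.v_plus, dyn.v_minus, dyn.v_tm)
        k = len(pts)
        rows: List[int] = []
        for i in range(k - 1):
            a, b = pts[i], pts[i + 1]
            d = b - a
            L = math.hypot(d[0], d[1])
            if L <= PATH_TOL:
                if i == k - 2:
                    w = heading_unit(mt.tip_psi)
                    b = a + w * 1e-12
                    L = 1e-12
                else:
                    continue
            else:
                w = d / L
            sa = dyn.v_tm if (i == 0 and dyn.v_tm != 0) else 0.0
            sb = 0.0
            if i == k - 2:
                sb = dyn.v_plus if mt.plus_state == GROWING else -dyn.v_minus
            r = self._alloc()
            self.A[r] = a
            self.B[r] = b
            self.Wdir[r] = w
            self.sa[r] = sa
            self.sb[r] = sb
            self.T0[r] = t
            self.mt_id[r] = mt.id
            self.seg_idx[r] = i
            self.active[r] = True
            rows.append(r)
        self._rows[mt.id] = rows

    def snapshot(self, t: float) -> SegmentSet:
        idx = np.nonzero(self.active[: self._n])[0]
        dt = (t - self.T0[idx])[:, None]
        a = self.A[idx] + self.Wdir[idx] * (self.sa[idx][:, None] * dt)
        b = self.B[idx] + self.Wdir[idx] * (self.sb[idx][:, None] * dt)
        return SegmentSet(
            a, b, self.mt_id[idx].copy(), self.seg_idx[idx].copy(),
            self.sa[idx].copy(), self.sb[idx].copy(), t,
        )


@dataclass
class SimResult:
    state: ArrayState
    events: List[Dict[str, Any]]
    audit: List[Tuple[float, float, int, int, int]]  # (t, total_length, n_grow, n_shrink, n_mt)
    metrics: List[Dict[str, Any]]


class Simulation:
    """One seeded, configured simulation run."""

    def __init__(
        self,
        domain: CylinderDomain,
        dyn: DynamicsParams,
        flex: Optional[FlexibilityParams] = None,
        nuc: Optional[NucleationParams] = None,
        prepattern: Optional[Prepattern] = None,
        schedule: Optional[PhaseSchedule] = None,
        seed: int = 0,
        initial_state: Optional[ArrayState] = None,
        sample_interval: Optional[float] = None,
        sampler: Optional[Callable[["Simulation", ArrayState], Dict[str, Any]]] = None,
        record_events: bool = False,
        audit_conservation: bool = False,
        collision_audit: Optional["CollisionAudit"] = None,
    ) -> None:
        self.domain = domain
        self.dyn = dyn
        self.flex = flex if flex is not None else FlexibilityParams()
        self.nuc = nuc
        self.prepattern = prepattern
        self.schedule = schedule
        self.sample_interval = sample_interval
        self.sampler = sampler
        self.record_events = record_events
        self.audit_conservation = audit_conservation
        self.collision_audit = collision_audit

        ss = np.random.SeedSequence(seed)
        dyn_ss, nuc_ss, flex_ss = ss.spawn(3)
        self.rng_dyn = np.random.default_rng(dyn_ss)
        self.rng_nuc = np.random.default_rng(nuc_ss)
        self.rng_flex = np.random.default_rng(flex_ss)

        self.state = initial_state if initial_state is not None else ArrayState(domain=domain)
        self.state.domain = domain
        self.state.v_plus = dyn.v_plus
        self.state.v_minus = dyn.v_minus
        self.state.v_tm = dyn.v_tm

        self.pool = (
            ComplexPool(size=nuc.pool_size) if (nuc is not None and nuc.mode == "local_density") else None
        )
        self.seg_cap = domain.circumference / 2.0  # max straight segment length

        self.heap: List[Tuple[float, int, int, int, str, Any]] = []
        self._seq = 0
        self.events: List[Dict[str, Any]] = []
        self.audit: List[Tuple[float, float, int, int, int]] = []
        self.metrics: List[Dict[str, Any]] = []
        self.segstore = _SegmentStore()
        self._snap_cache: Optional[Tuple[float, int, SegmentSet]] = None
        self._next_det: Dict[int, float] = {}  # per-mt time of the queued tip event
        self._started = False

    # ------------------------------------------------------------------
    # queue plumbing
    # ------------------------------------------------------------------
    def _push(self, t: float, prio: int, subj: int, kind: str, payload: Any) -> None:
        if not math.isfinite(t):
            return
        heapq.heappush(self.heap, (t, prio, subj, self._seq, kind, payload))
        self._seq += 1

    def _log(self, kind: str, t: float, **data: Any) -> None:
        if self.record_events:
            rec = {"time": t, "kind": kind}
            rec.update(data)
            self.events.append(rec)

    def _snapshot(self, t: float) -> SegmentSet:
        c = self._snap_cache
        if c is not None and c[0] == t and c[1] == self.segstore.version:
            return c[2]
        snap = self.segstore.snapshot(t)
        self._snap_cache = (t, self.segstore.version, snap)
        return snap

    # ------------------------------------------------------------------
    # per-microtubule bookkeeping
    # ------------------------------------------------------------------
    def _sync(self, mt: Microtubule) -> None:
        """Advance a microtubule's moving endpoints to the current time."""
        t = self.state.time
        if mt.plus_state == GROWING and math.isfinite(mt.next_deflection_s):
            mt.next_deflection_s -= self.dyn.v_plus * (t - mt.t_plus)
            if mt.next_deflection_s < 0:
                mt.next_deflection_s = 0.0
        mt.materialize(t, self.dyn.v_plus, self.dyn.v_minus, self.dyn.v_tm)

    def _bump(self, mt: Microtubule, cascade: bool = True) -> None:
        """Geometry/motion of ``mt`` changed: refresh rows and reschedule."""
        mt.geom_version += 1
        self.segstore.refresh_mt(mt, self.state.time, self.dyn)
        self._sched_tip(mt)
        self._sched_minus(mt)
        for xid in list(self.state.mt_crossovers.get(mt.id, ())):
            x = self.state.crossovers.get(xid)
            if x is not None:
                self._sched_xdeath(x)
        if cascade:
            for fid in list(mt.followers):
                f = self.state.mts.get(fid)
                if f is not None and f.id != mt.id:
                    self._sched_tip(f)

    def _remove_mt(self, mt: Microtubule) -> None:
        followers = [f for f in mt.followers if f != mt.id]
        self.segstore.remove_mt(mt.id)
        self.state.remove_mt(mt.id)
        self._next_det.pop(mt.id, None)
        for fid in followers:
            f = self.state.mts.get(fid)
            if f is not None:
                self._sched_tip(f)

    def _spawn_mt(
        self, pos: np.ndarray, psi: float, bundle: Optional[BundleRef] = None
    ) -> Microtubule:
        t = self.state.time
        mt = Microtubule(
            id=self.state.new_mt_id(),
            verts=[np.array(pos, dtype=float), np.array(pos, dtype=float)],
            vert_t=[t, t],
            vkinds=["", ""],
            plus_state=GROWING,
            tip_psi=psi % (2.0 * math.pi),
            birth_time=t,
            t_plus=t,
            t_minus=t,
        )
        if not self.flex.rigid:
            mt.next_deflection_s = next_deflection_distance(self.rng_flex, self.flex.deflection_step)
        if bundle is not None:
            mt.bundle = bundle
            host = self.state.mts.get(bundle.host_id)
            if host is not None:
                host.followers.add(mt.id)
        mt.scan_origin = (mt.verts[-1].copy(), t)
        self.state.add_mt(mt)
        self.segstore.refresh_mt(mt, t, self.dyn)
        self._sched_tip(mt)
        self._sched_minus(mt)
        self._sched_dyn(mt)
        self._cross_test(mt)
        return mt

    # ------------------------------------------------------------------
    # scheduling
    # ------------------------------------------------------------------
    def _local_rate(self, z: float, dirz: float) -> float:
        t = self.state.time
        z_eval = min(max(z + dirz * 1e-9, 0.0), self.domain.height)
        return local_catastrophe_rate(z_eval, t, self.prepattern, self.dyn.r_cat)

    def _sched_dyn(self, mt: Microtubule) -> None:
        """(Re)draw the stochastic plus-end switching clock."""
        mt.dyn_seq += 1
        t = self.state.time
        if mt.plus_state == GROWING:
            u = heading_unit(mt.tip_psi)
            z = mt.plus_pos(t, self.dyn.v_plus, self.dyn.v_minus)[1]
            rate = self._local_rate(z, u[1])
            kind = "catastrophe"
        else:
            rate = self.dyn.r_res
            kind = "rescue"
        if rate <= 0:
            return
        wait = self.rng_dyn.exponential(1.0 / rate)
        self._push(t + wait, STOCHASTIC, mt.id, kind, (mt.dyn_seq,))

    def _bundle_vertex_tau(
        self, mt: Microtubule, tip: np.ndarray
    ) -> Tuple[float, Optional[Tuple[int, int]]]:
        """Time until a bundled tip reaches the end of its current host segment.

        Returns (tau, (host_id, host_geom_version)); clears the bundle
        reference and returns (inf, None) if the host no longer covers the
        follower's position.
        """
        ref = mt.bundle
        if ref is None:
            return INF, None
        host = self.state.mts.get(ref.host_id)
        if host is None:
            self._clear_bundle(mt)
            return INF, None
        t = self.state.time
        ph = tip - np.array([ref.x_offset, 0.0])
        loc = locate_on_mt(self.state, host, ph, t)
        if loc is None:
            self._clear_bundle(mt)
            return INF, None
        i, s = loc
        pts = host.points_at(t, self.dyn.v_plus, self.dyn.v_minus, self.dyn.v_tm)
        seg_len = lambda j: float(np.hypot(*(pts[j + 1] - pts[j])))
        L = seg_len(i)
        v = self.dyn.v_plus
        if v <= 0:
            return INF, None
        # a tip sitting exactly on a shared vertex belongs to the segment in
        # its direction of travel; otherwise the gap would be zero forever
        eps = 1e-9
        if ref.sense > 0:
            while i + 1 < len(pts) - 1 and L - s <= eps:
                i += 1
                s = 0.0
                L = seg_len(i)
        else:
            while i > 0 and s <= eps:
                i -= 1
                L = seg_len(i)
                s = L
        if ref.sense > 0:
            gap = L - s
            if i + 1 == len(pts) - 1:  # target is the host's moving plus end
                if host.plus_state == GROWING:
                    rel = v - self.dyn.v_plus  # same speed: never caught
                else:
                    rel = v + self.dyn.v_minus
            else:
                rel = v
        else:
            gap = s
            if i == 0 and self.dyn.v_tm != 0:  # target is the treadmilling minus end
                rel = v + self.dyn.v_tm
            else:
                rel = v
        if rel <= 0:
            return INF, (host.id, host.geom_version)
        return max(gap, 0.0) / rel, (host.id, host.geom_version)

    def _sched_tip(self, mt: Microtubule) -> None:
        """Compute and queue the next deterministic event of a plus end."""
        self._sync(mt)
        mt.tip_seq += 1
        t = self.state.time
        dyn = self.dyn
        cands: List[Tuple[float, int, str, Any]] = []  # (tau, rank, kind, data)
        tip = mt.verts[-1]
        if mt.plus_state == GROWING:
            v = dyn.v_plus
            if v <= 0:
                self._next_det[mt.id] = INF
                return
            u = heading_unit(mt.tip_psi)
            # edge arrival
            if u[1] > PARALLEL_TOL:
                cands.append((max(self.domain.height - tip[1], 0.0) / (u[1] * v), 0, "edge", None))
            elif u[1] < -PARALLEL_TOL:
                cands.append((max(tip[1], 0.0) / (-u[1] * v), 0, "edge", None))
            # death by treadmilling outrunning growth
            if len(mt.verts) == 2 and dyn.v_tm > v:
                L = float(np.hypot(*(mt.verts[1] - mt.verts[0])))
                cands.append((L / (dyn.v_tm - v), 0, "death", None))
            # deflection
            if not self.flex.rigid:
                cands.append((mt.next_deflection_s / v, 2, "deflect", None))
            # band/gap boundary crossing (rate re-draw point)
            if self.prepattern is not None and t >= self.prepattern.t_band and abs(u[1]) > PARALLEL_TOL:
                bounds = self.prepattern.boundaries()
                z = tip[1]
                if u[1] > 0:
                    ahead = bounds[bounds > z + 1e-9]
                    if len(ahead):
                        cands.append(((ahead[0] - z) / (u[1] * v), 3, "boundary", None))
                else:
                    behind = bounds[bounds < z - 1e-9]
                    if len(behind):
                        cands.append(((z - behind[-1]) / (-u[1] * v), 3, "boundary", None))
            # bundle tracking: arrival at the end of the host segment
            tau_bv, host_ref = self._bundle_vertex_tau(mt, tip)
            if host_ref is not None and math.isfinite(tau_bv):
                cands.append((tau_bv, 1, "bundle_vertex", host_ref))
            # straight-segment cap (inserts a 'wrap' vertex)
            L_last = float(np.hypot(*(mt.verts[-1] - mt.verts[-2])))
            cands.append((max(self.seg_cap - L_last, 0.0) / v, 4, "rescan", None))
            # collision: search up to the earliest other candidate
            tau_min = min(c[0] for c in cands)
            max_dist = v * tau_min
            if max_dist > PATH_TOL:
                segs = self._snapshot(t)
                exclude = ((mt.id, len(mt.verts) - 2),)
                hit = first_intersection(
                    tip, mt.tip_psi, segs, self.domain, max_dist,
                    speed=v, t_start=t, exclude=exclude,
                )
                if self.collision_audit is not None:
                    brute = first_intersection_brute(
                        tip, mt.tip_psi, segs, self.domain, max_dist,
                        speed=v, t_start=t, exclude=exclude,
                    )
                    self.collision_audit.compare(t, mt.id, hit, brute, v)
                if hit is not None:
                    obstacle = self.state.mts.get(hit.mt_id)
                    if obstacle is not None:
                        cands.append(
                            (hit.distance / v, -1, "collision", (hit.mt_id, obstacle.geom_version, hit))
                        )
        else:
            v = dyn.v_minus
            if v <= 0 and dyn.v_tm <= 0:
                self._next_det[mt.id] = INF
                return
            if len(mt.verts) > 2:
                L_last = float(np.hypot(*(mt.verts[-1] - mt.verts[-2])))
                if v > 0:
                    cands.append((L_last / v, 0, "tip_vertex", None))
            else:
                L = float(np.hypot(*(mt.verts[1] - mt.verts[0])))
                rel = v + dyn.v_tm
                if rel > 0:
                    cands.append((L / rel, 0, "death", None))
        if not cands:
            self._next_det[mt.id] = INF
            return
        tau, _, kind, data = min(cands, key=lambda c: (c[0], c[1]))
        self._next_det[mt.id] = t + tau
        self._push(t + tau, DETERMINISTIC, mt.id, "tip", (mt.tip_seq, kind, data))

    def _sched_minus(self, mt: Microtubule) -> None:
        mt.minus_seq += 1
        if self.dyn.v_tm <= 0 or len(mt.verts) < 3:
            return
        t = self.state.time
        L0 = float(np.hypot(*(mt.verts[1] - mt.minus_pos(t, self.dyn.v_tm))))
        self._push(t + L0 / self.dyn.v_tm, DETERMINISTIC, mt.id, "minus_vertex", (mt.minus_seq,))

    def _sched_xdeath(self, x: Crossover) -> None:
        """Queue the moment a retracting end erases a crossover."""
        x.seq += 1
        if not x.alive:
            return
        t = self.state.time
        best = INF
        versions = []
        for mt_id, pt in ((x.over_mt, x.point_over), (x.under_mt, x.point_under)):
            mt = self.state.mts.get(mt_id)
            if mt is None:
                self.state.remove_crossover(x.id)
                return
            versions.append(mt.geom_version)
            arc_p = arc_from_plus(self.state, mt, pt, t)
            if arc_p is None:
                self.state.remove_crossover(x.id)
                return
            if mt.plus_state == SHRINKING and self.dyn.v_minus > 0:
                best = min(best, arc_p / self.dyn.v_minus)
            if self.dyn.v_tm > 0:
                total = mt.length(t, self.dyn.v_plus, self.dyn.v_minus, self.dyn.v_tm)
                arc_m = max(total - arc_p, 0.0)
                # the minus end reaches the point only if the plus end does not move it away;
                # conservatively schedule and re-verify at pop
                best = min(best, arc_m / self.dyn.v_tm)
        self._push(t + best, DETERMINISTIC, min(x.over_mt, x.under_mt), "x_death",
                   (x.id, x.seq, tuple(versions)))

    def _cross_test(self, mt: Microtubule) -> None:
        """A tip started covering new ground: probe every other growing tip
        against its moving segment and reschedule any that would hit it
        before their currently queued deterministic event."""
        t = self.state.time
        v = self.dyn.v_plus
        if v <= 0:
            return
        a = mt.verts[-1]
        u0 = heading_unit(mt.tip_psi)
        n0x, n0z = -u0[1], u0[0]
        others = [
            o for o in self.state.mts.values()
            if o.id != mt.id and o.plus_state == GROWING
        ]
        if not others:
            return
        P = np.array([o.plus_pos(t, v, self.dyn.v_minus) for o in others])
        psis = np.array([o.tip_psi for o in others])
        U = np.column_stack([np.sin(psis), np.cos(psis)])
        fallback = t + self.seg_cap / v
        horizon = np.array([
            min(self._next_det.get(o.id, INF), fallback) for o in others
        ])
        max_dist = v * (horizon - t)
        denom = n0x * U[:, 0] + n0z * U[:, 1]
        W = self.domain.circumference
        k0 = np.round((P[:, 0] - a[0]) / W)
        need = np.zeros(len(others), dtype=bool)
        with np.errstate(divide="ignore", invalid="ignore"):
            for dk in (-1.0, 0.0, 1.0):
                shift = (k0 + dk) * W
                rhs = n0x * (a[0] + shift - P[:, 0]) + n0z * (a[1] - P[:, 1])
                d = rhs / denom
                ok = (np.abs(denom) > PARALLEL_TOL) & (d > PATH_TOL) & (d <= max_dist)
                if not np.any(ok):
                    continue
                # arc position of the crossing on the probe's carrier; the
                # probe covers [0, v * (t_hit - t)] as the tip advances
                qx = P[:, 0] + U[:, 0] * d - (a[0] + shift)
                qz = P[:, 1] + U[:, 1] * d - a[1]
                s = u0[0] * qx + u0[1] * qz
                ok &= (s >= -PATH_TOL) & (s <= d + PATH_TOL)
                need |= ok
        for flag, o in zip(need, others):
            if flag:
                self._sched_tip(o)

    # ------------------------------------------------------------------
    # event execution
    # ------------------------------------------------------------------
    def _exec_tip(self, mt: Microtubule, kind: str, data: Any) -> None:
        t = self.state.time
        if kind == "collision":
            obstacle_id, obstacle_ver, hit = data
            obstacle = self.state.mts.get(obstacle_id)
            if obstacle is None or obstacle.geom_version != obstacle_ver:
                self._sched_tip(mt)
                return
            self._exec_collision(mt, obstacle, hit)
            return
        if kind == "bundle_vertex":
            self._exec_bundle_vertex(mt, data)
            return
        self._sync(mt)
        if kind == "edge":
            tip = mt.verts[-1]
            tip[1] = 0.0 if tip[1] < self.domain.height / 2 else self.domain.height
            mt.plus_state = SHRINKING
            self._log("edge_catastrophe", t, mt=mt.id)
            self._sched_dyn(mt)
            self._bump(mt)
        elif kind == "death":
            self._log("death", t, mt=mt.id)
            self._remove_mt(mt)
        elif kind == "deflect":
            self._exec_deflection(mt)
        elif kind == "boundary":
            self._log("boundary_cross", t, mt=mt.id, z=float(mt.verts[-1][1]))
            self._sched_dyn(mt)
            self._sched_tip(mt)
        elif kind == "rescan":
            # subdivide a long straight stretch so no segment exceeds W/2
            q = mt.verts[-1].copy()
            mt.vkinds[-1] = "wrap"
            mt.verts.append(q)
            mt.vert_t.append(t)
            mt.vkinds.append("")
            self._bump(mt)
        elif kind == "tip_vertex":
            # shrinking plus end retracts past an interior vertex
            mt.verts.pop()
            mt.vert_t.pop()
            mt.vkinds.pop()
            mt.vkinds[-1] = ""
            mt.vert_t[-1] = t
            mt.t_plus = t
            mt.tip_psi = unit_to_heading(mt.last_dir())
            self._bump(mt)
        else:  # pragma: no cover - defensive
            raise RuntimeError(f"unknown tip event {kind}")

    def _frame_offset(self, point: np.ndarray, mt: Microtubule) -> Optional[float]:
        """x-shift k*W mapping ``point`` into ``mt``'s unwrapped frame.

        Unwrapped frames of different microtubules can differ by many turns,
        so the candidate image is centred on the frame separation.
        """
        W = self.domain.circumference
        t = self.state.time
        kc = round((point[0] - float(mt.verts[-1][0])) / W)
        for dk in (0, -1, 1, -2, 2, -3, 3):
            shifted = point - np.array([(kc + dk) * W, 0.0])
            if locate_on_mt(self.state, mt, shifted, t, tol=1e-6) is not None:
                return (kc + dk) * W
        return None

    def _exec_collision(self, mt: Microtubule, obstacle: Microtubule, hit: Hit) -> None:
        t = self.state.time
        self._sync(mt)
        mt.verts[-1] = hit.point.copy()  # land exactly on the crossing point
        mt.t_plus = t
        if self.collision_audit is not None:
            self.collision_audit.executed += 1
        ca = collision_angle(mt.tip_psi, orientation_of(unit_to_heading(hit.obstruct_dir)))
        if ca.angle < self.dyn.theta_bundle:
            # bundling: entrain along the co-aligned sense of the obstructing trajectory
            offset = self._frame_offset(hit.point, obstacle)
            mt.vkinds[-1] = "bundling-entry"
            mt.verts.append(hit.point.copy())
            mt.vert_t.append(t)
            mt.vkinds.append("")
            mt.tip_psi = ca.coaligned_psi
            if mt.bundle is not None:
                self._clear_bundle(mt)
            if offset is not None:
                w = heading_unit(ca.coaligned_psi)
                sense = 1 if float(np.dot(w, hit.obstruct_dir)) >= 0 else -1
                mt.bundle = BundleRef(host_id=obstacle.id, x_offset=offset, sense=sense)
                obstacle.followers.add(mt.id)
            self._log("bundle", t, mt=mt.id, host=obstacle.id, angle=math.degrees(ca.angle))
            self._bump(mt)
            self._cross_test(mt)
        elif self.rng_dyn.random() < self.dyn.p_cat:
            mt.plus_state = SHRINKING
            self._log("induced_catastrophe", t, mt=mt.id, against=obstacle.id,
                      angle=math.degrees(ca.angle))
            self._sched_dyn(mt)
            self._bump(mt)
        else:
            offset = self._frame_offset(hit.point, obstacle)
            if offset is not None:
                x = Crossover(
                    id=self.state.next_x_id,
                    over_mt=mt.id,
                    under_mt=obstacle.id,
                    point_over=hit.point.copy(),
                    point_under=hit.point - np.array([offset, 0.0]),
                    created=t,
                )
                self.state.next_x_id += 1
                self.state.add_crossover(x)
                if self.dyn.r_sever > 0:
                    self._push(
                        t + self.rng_dyn.exponential(1.0 / self.dyn.r_sever),
                        STOCHASTIC, x.id, "sever", (x.id,),
                    )
                self._sched_xdeath(x)
                self._log("crossover", t, mt=mt.id, under=obstacle.id, xid=x.id,
                          angle=math.degrees(ca.angle))
            self._sched_tip(mt)

    def _clear_bundle(self, mt: Microtubule) -> None:
        if mt.bundle is not None:
            host = self.state.mts.get(mt.bundle.host_id)
            if host is not None:
                host.followers.discard(mt.id)
            mt.bundle = None

    def _exec_deflection(self, mt: Microtubule) -> None:
        t = self.state.time
        tip = mt.verts[-1]
        u = heading_unit(mt.tip_psi)
        n_other = max(occupancy_at(self.state, tip, u, t) - 1, 0)
        accepted = accept_bundle_deflection(n_other, self.rng_flex)
        mt.next_deflection_s = next_deflection_distance(self.rng_flex, self.flex.deflection_step)
        if not accepted:
            self._log("deflection_rejected", t, mt=mt.id, n_other=n_other)
            self._sched_tip(mt)
            return
        angle = sample_deflection_angle(
            self.rng_flex, self.flex.max_deflection, self.flex.min_deflection
        )
        self._clear_bundle(mt)
        if angle != 0.0:
            mt.vkinds[-1] = "deflection"
            mt.verts.append(tip.copy())
            mt.vert_t.append(t)
            mt.vkinds.append("")
            mt.tip_psi = (mt.tip_psi + angle) % (2.0 * math.pi)
            self._log("deflection", t, mt=mt.id, angle=angle)
            self._bump(mt)
            self._cross_test(mt)
        else:
            self._log("deflection", t, mt=mt.id, angle=0.0)
            self._sched_tip(mt)

    def _exec_bundle_vertex(self, mt: Microtubule, host_ref: Tuple[int, int]) -> None:
        host_id, host_ver = host_ref
        host = self.state.mts.get(host_id)
        if host is None or host.geom_version != host_ver:
            self._sched_tip(mt)
            return
        t = self.state.time
        self._sync(mt)
        tip = mt.verts[-1]
        u = heading_unit(mt.tip_psi)
        cands = self._continuations_at(tip, u, exclude_mt=mt.id)
        choice = follow_bend(
            [c[0] for c in cands], [c[3] for c in cands],
            self.flex.bundle_tracking_angle, self.rng_flex,
        )
        if choice is None:
            self._clear_bundle(mt)
            self._log("bundle_exit", t, mt=mt.id)
            self._sched_tip(mt)
            return
        angle, direction, (ref_mt, offset, sense), occ = cands[choice]
        if angle > 1e-12:
            mt.vkinds[-1] = "bundle-bend"
            mt.verts.append(tip.copy())
            mt.vert_t.append(t)
            mt.vkinds.append("")
            mt.tip_psi = unit_to_heading(direction)
        self._clear_bundle(mt)
        mt.bundle = BundleRef(host_id=ref_mt, x_offset=offset, sense=sense)
        host2 = self.state.mts.get(ref_mt)
        if host2 is not None:
            host2.followers.add(mt.id)
        self._log("bundle_bend", t, mt=mt.id, host=ref_mt, angle=math.degrees(angle))
        self._bump(mt)
        if angle > 1e-12:
            self._cross_test(mt)

    def _continuations_at(
        self, point: np.ndarray, incoming: np.ndarray, exclude_mt: int
    ) -> List[Tuple[float, np.ndarray, Tuple[int, float, int], int]]:
        """Candidate bundle continuations at a shared polyline vertex.

        Returns (bend_angle, unit direction, (host id, x offset, sense),
        occupancy) per distinct outgoing direction, where occupancy counts
        the microtubules offering that direction.
        """
        W = self.domain.circumference
        t = self.state.time
        groups: List[List[Any]] = []  # [dir, [(mt, offset, sense)], angle]
        for mt2 in self.state.mts.values():
            if mt2.id == exclude_mt:
                continue
            pts = mt2.points_at(t, self.dyn.v_plus, self.dyn.v_minus, self.dyn.v_tm)
            kv = np.round((point[0] - pts[:, 0]) / W)
            dx = point[0] - pts[:, 0] - kv * W
            dz = point[1] - pts[:, 1]
            matches = np.nonzero((np.abs(dx) <= 1e-6) & (np.abs(dz) <= 1e-6))[0]
            for j in matches:
                for k in (int(kv[j]),):
                    outs = []
                    if j + 1 < len(pts):
                        seg = pts[j + 1] - pts[j]
                        L = math.hypot(seg[0], seg[1])
                        if L > PATH_TOL:
                            outs.append((seg / L, 1))
                    if j > 0:
                        seg = pts[j - 1] - pts[j]
                        L = math.hypot(seg[0], seg[1])
                        if L > PATH_TOL:
                            outs.append((seg / L, -1))
                    for w, sense in outs:
                        dot = float(np.clip(np.dot(incoming, w), -1.0, 1.0))
                        ang = math.acos(dot)
                        if ang >= math.pi / 2:
                            continue  # backward or sideways, not a continuation
                        placed = False
                        for g in groups:
                            if float(np.dot(g[0], w)) > 1.0 - 1e-9:
                                g[1].append((mt2.id, k * W, sense))
                                placed = True
                                break
                        if not placed:
                            groups.append([w.copy(), [(mt2.id, k * W, sense)], ang])
        out = []
        for g in groups:
            members = sorted(set(g[1]))
            mt_ids = {m[0] for m in members}
            ref = members[0]
            out.append((g[2], g[0], ref, len(mt_ids)))
        return out

    # ------------------------------------------------------------------
    # stochastic / global events
    # ------------------------------------------------------------------
    def _exec_sever(self, xid: int) -> None:
        x = self.state.crossovers.get(xid)
        if x is None or not x.alive:
            return
        t = self.state.time
        over = self.state.mts.get(x.over_mt)
        if over is None:
            self.state.remove_crossover(xid)
            return
        frag = sever(self.state, x)
        self._log("sever", t, mt=x.over_mt, xid=xid, fragment=(frag.id if frag else None))
        self._sched_dyn(over)  # the plus-side tip state is unchanged but its
        # clock is redrawn (memoryless) to keep bookkeeping simple
        self._bump(over)
        self._mark_origin(over.id)
        if frag is not None:
            frag.scan_origin = (frag.verts[-1].copy(), t)
            self.segstore.refresh_mt(frag, t, self.dyn)
            self._sched_tip(frag)
            self._sched_minus(frag)
            self._sched_dyn(frag)
            for xid2 in list(self.state.mt_crossovers.get(frag.id, ())):
                x2 = self.state.crossovers.get(xid2)
                if x2 is not None:
                    self._sched_xdeath(x2)

    def _exec_xdeath(self, xid: int, seq: int, versions: Tuple[int, ...]) -> None:
        x = self.state.crossovers.get(xid)
        if x is None or not x.alive or x.seq != seq:
            return
        over = self.state.mts.get(x.over_mt)
        under = self.state.mts.get(x.under_mt)
        cur = tuple(m.geom_version for m in (over, under) if m is not None)
        if over is None or under is None or cur != versions:
            self._sched_xdeath(x)
            return
        t = self.state.time
        # verify: one of the ends has indeed reached the crossing point
        still = (
            locate_on_mt(self.state, over, x.point_over, t, tol=1e-6) is not None
            and locate_on_mt(self.state, under, x.point_under, t, tol=1e-6) is not None
        )
        self.state.remove_crossover(xid)
        self._log("crossover_gone", t, xid=xid, verified=not still)

    def _exec_appearance(self) -> None:
        t = self.state.time
        nuc = self.nuc
        assert nuc is not None
        # schedule the next appearance
        rate = nuc.r_iso if nuc.mode == "isotropic" else nuc.r_app
        if rate > 0:
            self._push(t + self.rng_nuc.exponential(1.0 / rate), STOCHASTIC, -1, "appearance", None)
        in_bias = self.schedule is not None and t < self.schedule.t_bias_end
        if in_bias:
            if self.pool is not None and self.rng_nuc.random() < self.pool.occupied_fraction:
                self._log("nucleation_rejected", t, reason="occupancy")
                return
            pos = np.array([
                self.rng_nuc.uniform(0.0, self.domain.circumference),
                self.rng_nuc.uniform(0.0, self.domain.height),
            ])
            psi = biased_nucleation_angle(
                self.rng_nuc, self.schedule.theta_bias, self.schedule.sigma_bias
            )
            if self.pool is not None:
                t_rel = self.pool.occupy(t, nuc.t_occ)
                self._push(t_rel, DETERMINISTIC, -1, "release", None)
            mt = self._spawn_mt(pos, psi)
            self._log("nucleation", t, mt=mt.id, mode="biased")
            return
        if nuc.mode == "isotropic":
            out = isotropic_nucleate(self.state, self.rng_nuc)
            mt = self._spawn_mt(out.position, out.heading)
            self._log("nucleation", t, mt=mt.id, mode="isotropic")
            return
        out = handle_appearance(self.state, nuc, self.pool, self.rng_nuc, t)
        if out.mode == "rejected":
            self._log("nucleation_rejected", t, reason=out.reason)
            return
        if self.pool is not None and self.pool.releases:
            self._push(self.pool.releases[-1], DETERMINISTIC, -1, "release", None)
        bundle = None
        if out.mode == "bound":
            # parallel and antiparallel daughters share the parent trajectory:
            # entrain them as bundle members from birth
            parent = self.state.mts.get(out.parent)
            if parent is not None:
                loc = locate_on_mt(self.state, parent, out.parent_point, t, tol=1e-6)
                if loc is not None:
                    pts = parent.points_at(t, self.dyn.v_plus, self.dyn.v_minus, self.dyn.v_tm)
                    seg = pts[loc[0] + 1] - pts[loc[0]]
                    L = math.hypot(seg[0], seg[1])
                    if L > PATH_TOL:
                        dot = float(np.dot(heading_unit(out.heading), seg / L))
                        if abs(abs(dot) - 1.0) < 1e-9:
                            bundle = BundleRef(
                                host_id=parent.id,
                                x_offset=out.position[0] - out.parent_point[0],
                                sense=1 if dot > 0 else -1,
                            )
        mt = self._spawn_mt(out.position, out.heading, bundle=bundle)
        self._log("nucleation", t, mt=mt.id, mode=out.mode, parent=out.parent)

    def _exec_activation(self) -> None:
        t = self.state.time
        self._log("band_activation", t)
        for mt in list(self.state.mts.values()):
            if mt.plus_state == GROWING:
                self._sched_dyn(mt)
                self._sched_tip(mt)

    def _exec_sample(self) -> None:
        t = self.state.time
        if self.sampler is not None:
            row = self.sampler(self, self.state)
            if row is not None:
                row.setdefault("time_s", t)
                self.metrics.append(row)
        if self.sample_interval:
            nxt = t + self.sample_interval
            if nxt <= self._t_end + 1e-9:
                self._push(nxt, DETERMINISTIC, -2, "sample", None)

    # ------------------------------------------------------------------
    # main loop
    # ------------------------------------------------------------------
    def _start(self, t_end: float) -> None:
        self._t_end = t_end
        for mt in self.state.mts.values():
            self.segstore.refresh_mt(mt, self.state.time, self.dyn)
        for mt in list(self.state.mts.values()):
            mt.scan_origin = (mt.verts[-1].copy(), self.state.time)
            self._sched_tip(mt)
            self._sched_minus(mt)
            self._sched_dyn(mt)
        if self.nuc is not None:
            rate = self.nuc.r_iso if self.nuc.mode == "isotropic" else self.nuc.r_app
            if rate > 0:
                self._push(
                    self.state.time + self.rng_nuc.exponential(1.0 / rate),
                    STOCHASTIC, -1, "appearance", None,
                )
        if self.prepattern is not None and self.prepattern.t_band <= t_end:
            self._push(self.prepattern.t_band, DETERMINISTIC, -3, "activate", None)
        if self.sample_interval:
            self._push(self.state.time, DETERMINISTIC, -2, "sample", None)
        self._started = True

    def run(self, t_end: float) -> SimResult:
        """Advance the simulation to ``t_end`` and return the result."""
        if not self._started:
            self._start(t_end)
        state = self.state
        while self.heap:
            t, prio, subj, _seq, kind, payload = heapq.heappop(self.heap)
            if t > t_end:
                heapq.heappush(self.heap, (t, prio, subj, _seq, kind, payload))
                break
            state.time = t
            if not self._validate(subj, kind, payload):
                continue
            self._dispatch(subj, kind, payload)
            if self.audit_conservation:
                # events conserve total length instantaneously, so the length
                # and the post-event counts together describe the interval
                # that starts here
                n_grow = sum(1 for m in state.mts.values() if m.plus_state == GROWING)
                n_shrink = len(state.mts) - n_grow
                self.audit.append((t, total_length(state, t), n_grow, n_shrink, len(state.mts)))
        state.time = t_end
        for mt in state.mts.values():
            mt.materialize(t_end, self.dyn.v_plus, self.dyn.v_minus, self.dyn.v_tm)
        return SimResult(state=state, events=self.events, audit=self.audit, metrics=self.metrics)

    def _validate(self, subj: int, kind: str, payload: Any) -> bool:
        if kind == "tip":
            mt = self.state.mts.get(subj)
            return mt is not None and payload[0] == mt.tip_seq
        if kind == "minus_vertex":
            mt = self.state.mts.get(subj)
            return mt is not None and payload[0] == mt.minus_seq
        if kind in ("catastrophe", "rescue"):
            mt = self.state.mts.get(subj)
            if mt is None or payload[0] != mt.dyn_seq:
                return False
            return mt.plus_state == (GROWING if kind == "catastrophe" else SHRINKING)
        if kind == "x_death":
            x = self.state.crossovers.get(payload[0])
            return x is not None and x.alive and x.seq == payload[1]
        if kind == "sever":
            x = self.state.crossovers.get(payload[0])
            return x is not None and x.alive
        return True

    def _mark_origin(self, mt_id: int) -> None:
        mt = self.state.mts.get(mt_id)
        if mt is not None:
            mt.scan_origin = (mt.verts[-1].copy(), self.state.time)

    def _dispatch(self, subj: int, kind: str, payload: Any) -> None:
        t = self.state.time
        if kind == "tip":
            mt = self.state.mts[subj]
            self._exec_tip(mt, payload[1], payload[2])
            self._mark_origin(subj)
        elif kind == "minus_vertex":
            mt = self.state.mts[subj]
            self._sync(mt)
            mt.verts.pop(0)
            mt.vert_t.pop(0)
            mt.vkinds.pop(0)
            mt.vkinds[0] = ""
            mt.vert_t[0] = t
            mt.t_minus = t
            self._bump(mt)
        elif kind == "catastrophe":
            mt = self.state.mts[subj]
            self._sync(mt)
            mt.plus_state = SHRINKING
            self._log("catastrophe", t, mt=mt.id)
            self._sched_dyn(mt)
            self._bump(mt)
            self._mark_origin(subj)
        elif kind == "rescue":
            mt = self.state.mts[subj]
            self._sync(mt)
            mt.plus_state = GROWING
            mt.tip_psi = unit_to_heading(mt.last_dir())
            if not self.flex.rigid:
                mt.next_deflection_s = next_deflection_distance(
                    self.rng_flex, self.flex.deflection_step
                )
            self._log("rescue", t, mt=mt.id)
            self._sched_dyn(mt)
            self._bump(mt)
            self._cross_test(mt)
            self._mark_origin(subj)
        elif kind == "x_death":
            self._exec_xdeath(*payload)
        elif kind == "sever":
            self._exec_sever(payload[0])
        elif kind == "appearance":
            self._exec_appearance()
        elif kind == "release":
            if self.pool is not None:
                self.pool.release_until(t)
        elif kind == "activate":
            self._exec_activation()
        elif kind == "sample":
            self._exec_sample()
        else:  # pragma: no cover - defensive
            raise RuntimeError(f"unknown event kind {kind}")
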