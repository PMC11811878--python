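"""Data model for microtubules, crossovers, and whole-array state.

A microtubule is a polyline from its minus end to its plus end on the
unrolled cylinder (unwrapped ``x``). Interior vertices are static and record
where the growth direction changed (deflections, bundling entries, bundle
bends) or where a long straight stretch was subdivided (``wrap`` vertices,
inserted so no single segment exceeds half the circumference). The two end
vertices move: the plus end grows at ``v_plus`` or shrinks at ``v_minus``
along the last segment, and the minus end treadmills toward the plus end at
``v_tm`` along the first segment. End positions are stored as anchors
(position at an anchor time); the engine materializes them at query time.

Each vertex carries the time it was laid down, which lets validation code
ask whether a point on the polyline was already covered at a given time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Optional, Set, Tuple

import numpy as np
import pandas as pd

from .geometry import (
    PATH_TOL,
    CylinderDomain,
    SegmentSet,
    heading_unit,
    polyline_length,
    unit_to_heading,
    wrap_x,
)

GROWING = "growing"
SHRINKING = "shrinking"

#: positional tolerance for "lies on the trajectory" queries (um); bundled
#: geometry is exactly collinear by construction so this can be tight.
ON_TOL = 1e-7


@dataclass
class BundleRef:
    """Reference from an entrained (following) microtubule to its host trajectory."""

    host_id: int
    x_offset: float  #: follower-frame x minus host-frame x of the same physical point
    sense: int  #: +1 follows the host minus->plus, -1 follows it plus->minus


@dataclass
class Microtubule:
    id: int
    verts: List[np.ndarray]  # unwrapped (x, z); verts[0] = minus end, verts[-1] = plus end
    vert_t: List[float]  # lay-down time per vertex
    vkinds: List[str]  # per-vertex tag: "", deflection, bundling-entry, bundle-bend, wrap
    plus_state: str = GROWING
    tip_psi: float = 0.0  # growth heading of the plus end (rad from the long axis)
    birth_time: float = 0.0
    t_plus: float = 0.0  # anchor time of verts[-1]
    t_minus: float = 0.0  # anchor time of verts[0]
    bundle: Optional[BundleRef] = None
    followers: Set[int] = field(default_factory=set)
    # --- event bookkeeping (engine-owned) ---
    geom_version: int = 0
    tip_seq: int = 0
    minus_seq: int = 0
    dyn_seq: int = 0
    next_deflection_s: float = math.inf  # remaining straight growth until next deflection (um)
    # position/time of the last executed tip event: the free path since then
    # contains no executed crossings (used by collision validation)
    scan_origin: Optional[Tuple[np.ndarray, float]] = None

    # ------------------------------------------------------------------
    def last_dir(self) -> np.ndarray:
        """Unit direction of the last segment (falls back to the tip heading)."""
        if len(self.verts) >= 2:
            d = self.verts[-1] - self.verts[-2]
            L = math.hypot(d[0], d[1])
            if L > 0:
                return d / L
        return heading_unit(self.tip_psi)

    def first_dir(self) -> np.ndarray:
        """Unit direction of the first segment (minus end travel direction)."""
        if len(self.verts) >= 2:
            d = self.verts[1] - self.verts[0]
            L = math.hypot(d[0], d[1])
            if L > 0:
                return d / L
        return heading_unit(self.tip_psi)

    def plus_velocity(self, v_plus: float, v_minus: float) -> np.ndarray:
        u = self.last_dir()
        if self.plus_state == GROWING:
            return heading_unit(self.tip_psi) * v_plus
        return -u * v_minus

    def plus_pos(self, t: float, v_plus: float, v_minus: float) -> np.ndarray:
        return self.verts[-1] + self.plus_velocity(v_plus, v_minus) * (t - self.t_plus)

    def minus_pos(self, t: float, v_tm: float) -> np.ndarray:
        if v_tm == 0:
            return self.verts[0]
        return self.verts[0] + self.first_dir() * v_tm * (t - self.t_minus)

    def materialize(self, t: float, v_plus: float, v_minus: float, v_tm: float) -> None:
        """Advance the two moving end vertices to time ``t`` in place."""
        self.verts[-1] = self.plus_pos(t, v_plus, v_minus)
        self.vert_t[-1] = t
        self.t_plus = t
        if v_tm != 0:
            self.verts[0] = self.minus_pos(t, v_tm)
        self.t_minus = t

    def length(self, t: float, v_plus: float, v_minus: float, v_tm: float) -> float:
        pts = [self.minus_pos(t, v_tm)] + self.verts[1:-1] + [self.plus_pos(t, v_plus, v_minus)]
        return polyline_length(np.array(pts))

    def points_at(self, t: float, v_plus: float, v_minus: float, v_tm: float) -> np.ndarray:
        return np.array(
            [self.minus_pos(t, v_tm)] + self.verts[1:-1] + [self.plus_pos(t, v_plus, v_minus)]
        )


@dataclass
class Crossover:
    """A crossing of two microtubules; the later-arriving one is severable.

    The same physical point has different unwrapped coordinates in the two
    microtubules' frames, so it is stored once per frame.
    """

    id: int
    over_mt: int  # later-arriving, cytoplasmic-side microtubule (severed by katanin)
    under_mt: int
    point_over: np.ndarray  # crossing point in the over microtubule's unwrapped frame
    point_under: np.ndarray
    created: float = 0.0
    alive: bool = True
    seq: int = 0  # invalidation counter for the crossover-death event


@dataclass
class ArrayState:
    """Full simulation state: microtubules, crossovers, clock."""

    domain: CylinderDomain
    mts: Dict[int, Microtubule] = field(default_factory=dict)
    crossovers: Dict[int, Crossover] = field(default_factory=dict)
    mt_crossovers: Dict[int, Set[int]] = field(default_factory=dict)
    time: float = 0.0
    next_mt_id: int = 0
    next_x_id: int = 0

    # speeds needed to materialize moving endpoints; set by the engine
    v_plus: float = 0.0
    v_minus: float = 0.0
    v_tm: float = 0.0

    def new_mt_id(self) -> int:
        i = self.next_mt_id
        self.next_mt_id += 1
        return i

    def add_mt(self, mt: Microtubule) -> None:
        self.mts[mt.id] = mt
        self.mt_crossovers.setdefault(mt.id, set())

    def remove_mt(self, mt_id: int) -> None:
        for xid in list(self.mt_crossovers.get(mt_id, ())):
            self.remove_crossover(xid)
        self.mt_crossovers.pop(mt_id, None)
        mt = self.mts.pop(mt_id)
        if mt.bundle is not None:
            host = self.mts.get(mt.bundle.host_id)
            if host is not None:
                host.followers.discard(mt_id)
        for fid in list(mt.followers):
            f = self.mts.get(fid)
            if f is not None and f.bundle is not None and f.bundle.host_id == mt_id:
                f.bundle = None

    def add_crossover(self, x: Crossover) -> None:
        self.crossovers[x.id] = x
        self.mt_crossovers.setdefault(x.over_mt, set()).add(x.id)
        self.mt_crossovers.setdefault(x.under_mt, set()).add(x.id)

    def remove_crossover(self, xid: int) -> None:
        x = self.crossovers.pop(xid, None)
        if x is None:
            return
        x.alive = False
        self.mt_crossovers.get(x.over_mt, set()).discard(xid)
        self.mt_crossovers.get(x.under_mt, set()).discard(xid)


# ---------------------------------------------------------------------------
# Whole-array queries
# ---------------------------------------------------------------------------


def total_length(state: ArrayState, t: Optional[float] = None) -> float:
    """Sum of polyline arc lengths over all microtubules (um)."""
    if t is None:
        t = state.time
    return sum(
        mt.length(t, state.v_plus, state.v_minus, state.v_tm) for mt in state.mts.values()
    )


def collect_segments(
    state: ArrayState, t: Optional[float] = None, exclude_mt: Iterable[int] = ()
) -> SegmentSet:
    """Snapshot of all segments with moving terminal endpoints, materialized at ``t``.

    Zero-length growing tip segments are given a tiny extension along the tip
    heading so their carrier direction is defined; their true extent at any
    later time comes from the endpoint arc speeds.
    """
    if t is None:
        t = state.time
    excl = set(exclude_mt)
    A: List[np.ndarray] = []
    B: List[np.ndarray] = []
    mid: List[int] = []
    sid: List[int] = []
    sad: List[float] = []
    sbd: List[float] = []
    for mt in state.mts.values():
        if mt.id in excl:
            continue
        pts = mt.points_at(t, state.v_plus, state.v_minus, state.v_tm)
        k = len(pts)
        for i in range(k - 1):
            a, b = pts[i], pts[i + 1]
            sa = sb = 0.0
            if i == 0 and state.v_tm != 0:
                sa = state.v_tm  # minus end advances toward verts[1]
            if i == k - 2:
                if mt.plus_state == GROWING:
                    sb = state.v_plus
                else:
                    sb = -state.v_minus
                if math.hypot(b[0] - a[0], b[1] - a[1]) <= PATH_TOL:
                    b = a + heading_unit(mt.tip_psi) * 1e-12
            A.append(a)
            B.append(b)
            mid.append(mt.id)
            sid.append(i)
            sad.append(sa)
            sbd.append(sb)
    if not mid:
        return SegmentSet.empty()
    return SegmentSet(
        np.array(A), np.array(B), np.array(mid, dtype=int), np.array(sid, dtype=int),
        np.array(sad), np.array(sbd), t,
    )


def locate_on_mt(
    state: ArrayState, mt: Microtubule, point: np.ndarray, t: Optional[float] = None,
    tol: float = ON_TOL,
) -> Optional[Tuple[int, float]]:
    """Segment index and arc offset of a point on a microtubule's polyline.

    ``point`` must be expressed in the microtubule's own unwrapped frame.
    Returns ``None`` if the polyline does not currently cover the point.
    """
    if t is None:
        t = state.time
    pts = mt.points_at(t, state.v_plus, state.v_minus, state.v_tm)
    for i in range(len(pts) - 1):
        a, b = pts[i], pts[i + 1]
        d = b - a
        L = math.hypot(d[0], d[1])
        if L <= PATH_TOL:
            continue
        w = d / L
        r = point - a
        s = r[0] * w[0] + r[1] * w[1]
        perp = abs(r[0] * w[1] - r[1] * w[0])
        if perp <= tol and -tol <= s <= L + tol:
            return i, float(min(max(s, 0.0), L))
    return None


def arc_from_plus(
    state: ArrayState, mt: Microtubule, point: np.ndarray, t: Optional[float] = None
) -> Optional[float]:
    """Arc distance from the plus end back to a point on the polyline."""
    if t is None:
        t = state.time
    loc = locate_on_mt(state, mt, point, t)
    if loc is None:
        return None
    i, s = loc
    pts = mt.points_at(t, state.v_plus, state.v_minus, state.v_tm)
    arc = 0.0
    for j in range(i + 1, len(pts) - 1):
        arc += float(np.hypot(*(pts[j + 1] - pts[j])))
    seg_len = float(np.hypot(*(pts[i + 1] - pts[i])))
    return arc + (seg_len - s)


def occupancy_at(
    state: ArrayState,
    point: np.ndarray,
    direction: np.ndarray,
    t: Optional[float] = None,
    tol: float = ON_TOL,
    ang_tol: float = 1e-6,
) -> int:
    """Number of microtubules whose trajectory covers ``point`` parallel to ``direction``.

    This is the geometric recount behind bundle occupancy: bundled
    microtubules share identical trajectories, so membership at a point is
    simply collinear coverage. ``point`` is interpreted on the cylinder
    (periodic images are checked).
    """
    if t is None:
        t = state.time
    W = state.domain.circumference
    n = 0
    for mt in state.mts.values():
        pts = mt.points_at(t, state.v_plus, state.v_minus, state.v_tm)
        hit = False
        for i in range(len(pts) - 1):
            a, b = pts[i], pts[i + 1]
            d = b - a
            L = math.hypot(d[0], d[1])
            if L <= PATH_TOL:
                continue
            w = d / L
            cross = abs(w[0] * direction[1] - w[1] * direction[0])
            if cross > ang_tol:
                continue
            k0 = round((point[0] - 0.5 * (a[0] + b[0])) / W)
            for k in (k0 - 1, k0, k0 + 1):
                r = point - a - np.array([k * W, 0.0])
                s = r[0] * w[0] + r[1] * w[1]
                perp = abs(r[0] * w[1] - r[1] * w[0])
                if perp <= tol and -tol <= s <= L + tol:
                    hit = True
                    break
            if hit:
                break
        if hit:
            n += 1
    return n


# ---------------------------------------------------------------------------
# Severing
# ---------------------------------------------------------------------------


def sever(state: ArrayState, x: Crossover) -> Optional[Microtubule]:
    """Katanin severing of the over microtubule at a crossover.

    The over microtubule is split at the crossing point into a minus-side
    fragment whose new plus end starts shrinking, and a plus-side fragment
    (which keeps the original identity, plus-end state and heading) with a
    new treadmilling minus end. Total length is conserved at the severing
    instant and the count increases by one, unless the cut falls exactly on
    an endpoint, in which case the zero-length fragment is discarded.

    Returns the new minus-side fragment (or ``None`` if it was degenerate).
    The crossover record itself is removed; other crossovers on the over
    microtubule are reassigned to whichever fragment covers them. The caller
    (engine) is responsible for rescheduling events.
    """
    t = state.time
    mt = state.mts.get(x.over_mt)
    if mt is None:
        return None
    mt.materialize(t, state.v_plus, state.v_minus, state.v_tm)
    loc = locate_on_mt(state, mt, x.point_over, t)
    state.remove_crossover(x.id)
    if loc is None:  # stale crossover: microtubule no longer passes through
        return None
    i, s = loc
    pts = mt.verts
    q = x.point_over.copy()
    seg_len = math.hypot(*(pts[i + 1] - pts[i]))

    # minus-side fragment: verts[0..i] + q, new shrinking plus end
    minus_verts = [p.copy() for p in pts[: i + 1]] + [q.copy()]
    minus_t = list(mt.vert_t[: i + 1]) + [t]
    minus_kinds = list(mt.vkinds[: i + 1]) + [""]
    minus_len = polyline_length(np.array(minus_verts))

    # plus-side keeps the original microtubule object: verts = q + rest
    plus_verts = [q.copy()] + [p.copy() for p in pts[i + 1 :]]
    plus_t = [t] + list(mt.vert_t[i + 1 :])
    plus_kinds = [""] + list(mt.vkinds[i + 1 :])
    plus_len = polyline_length(np.array(plus_verts))

    frag: Optional[Microtubule] = None
    if plus_len <= PATH_TOL:
        # cut at the plus end: the original becomes the minus-side fragment
        mt.verts = minus_verts
        mt.vert_t = minus_t
        mt.vkinds = minus_kinds
        mt.plus_state = SHRINKING
        mt.tip_psi = unit_to_heading(mt.last_dir())
        mt.t_plus = t
        mt.t_minus = t
    elif minus_len <= PATH_TOL:
        mt.verts = plus_verts
        mt.vert_t = plus_t
        mt.vkinds = plus_kinds
        mt.t_plus = t
        mt.t_minus = t
    else:
        mt.verts = plus_verts
        mt.vert_t = plus_t
        mt.vkinds = plus_kinds
        mt.t_plus = t
        mt.t_minus = t
        frag = Microtubule(
            id=state.new_mt_id(),
            verts=minus_verts,
            vert_t=minus_t,
            vkinds=minus_kinds,
            plus_state=SHRINKING,
            tip_psi=unit_to_heading(
                (minus_verts[-1] - minus_verts[-2])
                / max(math.hypot(*(minus_verts[-1] - minus_verts[-2])), PATH_TOL)
            ),
            birth_time=mt.birth_time,
            t_plus=t,
            t_minus=t,
        )
        state.add_mt(frag)
    # reassign remaining crossovers on the over microtubule to the covering fragment
    for xid in list(state.mt_crossovers.get(mt.id, ())):
        xo = state.crossovers[xid]
        pt = xo.point_over if xo.over_mt == mt.id else xo.point_under
        if locate_on_mt(state, mt, pt, t) is not None:
            continue
        state.mt_crossovers[mt.id].discard(xid)
        if frag is not None and locate_on_mt(state, frag, pt, t) is not None:
            if xo.over_mt == mt.id:
                xo.over_mt = frag.id
            else:
                xo.under_mt = frag.id
            state.mt_crossovers.setdefault(frag.id, set()).add(xid)
        else:
            state.remove_crossover(xid)
    return frag


# ---------------------------------------------------------------------------
# Snapshot export / import
# ---------------------------------------------------------------------------


def snapshot_frame(state: ArrayState, t: Optional[float] = None) -> pd.DataFrame:
    """One row per polyline vertex, with canonical (wrapped) x coordinates."""
    if t is None:
        t = state.time
    rows = []
    for mt in sorted(state.mts.values(), key=lambda m: m.id):
        pts = mt.points_at(t, state.v_plus, state.v_minus, state.v_tm)
        for j, p in enumerate(pts):
            rows.append(
                {
                    "mt_id": mt.id,
                    "vertex_index": j,
                    "x_um": float(wrap_x(p[0], state.domain)),
                    "z_um": float(p[1]),
                    "vertex_kind": mt.vkinds[j] if j < len(mt.vkinds) else "",
                    "plus_state": mt.plus_state,
                }
            )
    return pd.DataFrame(
        rows, columns=["mt_id", "vertex_index", "x_um", "z_um", "vertex_kind", "plus_state"]
    )


def state_from_snapshot(df: pd.DataFrame, domain: CylinderDomain) -> ArrayState:
    """Rebuild an ArrayState from a snapshot frame (geometry only).

    Canonical x coordinates are unwrapped by minimal-image continuation, so a
    polyline that crossed the seam is reconstructed continuously.
    """
    state = ArrayState(domain=domain)
    W = domain.circumference
    for mt_id, g in df.groupby("mt_id"):
        g = g.sort_values("vertex_index")
        xs = g["x_um"].to_numpy(dtype=float)
        zs = g["z_um"].to_numpy(dtype=float)
        ux = [xs[0]]
        for x in xs[1:]:
            dx = x - (ux[-1] % W)
            if dx > W / 2:
                dx -= W
            elif dx < -W / 2:
                dx += W
            ux.append(ux[-1] + dx)
        verts = [np.array([x, z]) for x, z in zip(ux, zs)]
        kinds = [str(k) for k in g["vertex_kind"].fillna("")]
        mt = Microtubule(
            id=int(mt_id),
            verts=verts,
            vert_t=[0.0] * len(verts),
            vkinds=kinds,
            plus_state=str(g["plus_state"].iloc[0]),
        )
        if len(verts) >= 2:
            mt.tip_psi = unit_to_heading(mt.last_dir())
        state.add_mt(mt)
        state.next_mt_id = max(state.next_mt_id, int(mt_id) + 1)
    return state
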