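"""Geometry on the unrolled cylindrical cell surface.

The cortical array lives on a cylinder of radius ``R`` and height ``H``,
simulated on the unrolled rectangle ``[0, W) x [0, H]`` with ``W = 2*pi*R``.
The circumferential coordinate ``x`` is periodic; the axial coordinate ``z``
is bounded by catastrophe-inducing edges. Internally, ``x`` is kept
*unwrapped* (a real number) so that polylines stay continuous; periodicity is
applied when testing for intersections (periodic images) and when exporting
canonical coordinates.

Angle convention: a directed growth heading ``psi`` is measured in radians
from the cylinder long axis (the ``z`` axis), so that transverse growth --
around the circumference -- is ``psi = pi/2``. The undirected orientation is
``phi = psi mod pi``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np

#: intersections closer than this along a path are treated as coincident with
#: the collision just resolved and skipped (um).
PATH_TOL = 1e-9

#: angular tolerance below which two directions are treated as parallel
#: (no transversal intersection exists).
PARALLEL_TOL = 1e-12


@dataclass(frozen=True)
class CylinderDomain:
    """Cylindrical simulation domain (unrolled to a periodic rectangle)."""

    radius: float  # R, um
    height: float  # H, um

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.height <= 0:
            raise ValueError("radius and height must be positive")

    @property
    def circumference(self) -> float:
        """W = 2*pi*R (um)."""
        return 2.0 * math.pi * self.radius

    @property
    def area(self) -> float:
        return self.circumference * self.height


def wrap_x(x: float | np.ndarray, domain: CylinderDomain) -> float | np.ndarray:
    """Canonicalize a circumferential coordinate into ``[0, W)``.

    For tiny negative inputs ``x mod W`` can round to exactly ``W``; those
    are mapped back to 0 so the half-open contract holds.
    """
    W = domain.circumference
    w = np.mod(x, W)
    return np.where(w >= W, 0.0, w) if isinstance(w, np.ndarray) else (0.0 if w >= W else w)


def heading_unit(psi: float) -> np.ndarray:
    """Unit vector (dx, dz) of a directed heading psi (from the long axis)."""
    return np.array([math.sin(psi), math.cos(psi)])


def unit_to_heading(u: Sequence[float]) -> float:
    """Directed heading psi in [0, 2*pi) of a unit (dx, dz) vector."""
    return math.atan2(u[0], u[1]) % (2.0 * math.pi)


def orientation_of(psi: float) -> float:
    """Undirected orientation phi = psi mod pi."""
    return psi % math.pi


class CollisionAngle(NamedTuple):
    angle: float  #: minimal angle between incoming heading and obstructing line, [0, pi/2]
    coaligned_psi: float  #: directed sense of the obstructing trajectory co-aligned with incoming


def collision_angle(psi_in: float, phi_obstruct: float) -> CollisionAngle:
    """Collision angle between a directed incoming heading and an undirected segment.

    Returns the minimal angle (in ``[0, pi/2]``) between the incoming
    direction and the two senses of the obstructing trajectory, together with
    the co-aligned sense (used to entrain a bundling microtubule).
    """
    u = heading_unit(psi_in)
    w = heading_unit(phi_obstruct)
    dot = float(u[0] * w[0] + u[1] * w[1])
    cross = float(u[0] * w[1] - u[1] * w[0])
    # atan2 keeps full precision near parallel, unlike acos near |dot| = 1
    ang = math.atan2(abs(cross), abs(dot))
    coaligned = phi_obstruct if dot >= 0 else (phi_obstruct + math.pi) % (2.0 * math.pi)
    return CollisionAngle(ang, coaligned)


# ---------------------------------------------------------------------------
# Segment sets and first-intersection queries
# ---------------------------------------------------------------------------


@dataclass
class SegmentSet:
    """A snapshot of obstructing segments, with optional endpoint motion.

    Endpoints of terminal segments of live microtubules move along the
    segment's own carrier line (the plus end grows/shrinks, the minus end
    treadmills), so each endpoint carries a signed arc speed along the
    direction from ``a`` to ``b``. Positions are materialized at ``t0``.
    """

    a: np.ndarray  # (n, 2) start points at t0 (unwrapped x)
    b: np.ndarray  # (n, 2) end points at t0
    mt_id: np.ndarray  # (n,) int
    seg_idx: np.ndarray  # (n,) int, index into the owning polyline
    sa_dot: np.ndarray  # (n,) arc speed of the 'a' endpoint (um/s, + toward b)
    sb_dot: np.ndarray  # (n,) arc speed of the 'b' endpoint
    t0: float = 0.0

    def __len__(self) -> int:
        return len(self.mt_id)

    @staticmethod
    def empty() -> "SegmentSet":
        z = np.zeros((0, 2))
        zi = np.zeros(0, dtype=int)
        zf = np.zeros(0)
        return SegmentSet(z, z.copy(), zi, zi.copy(), zf, zf.copy(), 0.0)

    @staticmethod
    def from_static(
        a: np.ndarray, b: np.ndarray, mt_id: np.ndarray, seg_idx: Optional[np.ndarray] = None
    ) -> "SegmentSet":
        a = np.asarray(a, dtype=float).reshape(-1, 2)
        b = np.asarray(b, dtype=float).reshape(-1, 2)
        mt_id = np.asarray(mt_id, dtype=int)
        if seg_idx is None:
            seg_idx = np.zeros(len(mt_id), dtype=int)
        zf = np.zeros(len(mt_id))
        return SegmentSet(a, b, mt_id, np.asarray(seg_idx, dtype=int), zf, zf.copy(), 0.0)


class Hit(NamedTuple):
    mt_id: int
    seg_idx: int
    distance: float  #: arc distance along the tip path (um)
    time: float  #: absolute time of the crossing (s); equals t_start + distance/speed
    point: np.ndarray  #: (2,) unwrapped coordinates of the crossing
    obstruct_dir: np.ndarray  #: (2,) unit direction of the obstructing segment


def first_intersection(
    p0: Sequence[float],
    psi: float,
    segments: SegmentSet,
    domain: CylinderDomain,
    max_dist: float,
    *,
    speed: float = 1.0,
    t_start: Optional[float] = None,
    exclude: Iterable[tuple[int, int]] = (),
    min_dist: float = PATH_TOL,
) -> Optional[Hit]:
    """Nearest crossing of a directed tip path with a set of segments.

    The tip starts at ``p0`` (unwrapped coordinates) at time ``t_start``
    (default: ``segments.t0``) and advances along heading ``psi`` at
    ``speed``; crossings are searched up to arc distance ``max_dist``.
    Periodic circumferential images are tested exactly. Segments whose
    endpoints move (``sa_dot``/``sb_dot``) are treated as covering the
    crossing point only if their extent covers it at the crossing *time*.

    Ties are broken by smallest distance, then lowest ``mt_id``, then lowest
    ``seg_idx``. Degenerate (zero-length, non-moving) segments and segments
    parallel to the path are skipped. Returns ``None`` if nothing is hit.
    """
    n = len(segments)
    if n == 0 or max_dist <= 0:
        return None
    if t_start is None:
        t_start = segments.t0
    W = domain.circumference
    p0 = np.asarray(p0, dtype=float)
    u = heading_unit(psi)

    a, b = segments.a, segments.b
    ab = b - a
    L = np.hypot(ab[:, 0], ab[:, 1])
    moving = (np.abs(segments.sa_dot) > 0) | (np.abs(segments.sb_dot) > 0)
    ok = (L > 0) | moving
    # unit direction of each carrier line; zero-length moving segments need a
    # direction too -- caller encodes it by a tiny but exact ab? They cannot;
    # such rows are handled by the engine passing an epsilon-extended b.
    w = np.zeros_like(ab)
    nz = L > 0
    w[nz] = ab[nz] / L[nz, None]
    ok &= nz

    # normal component of the carrier line is time-invariant
    nx, nzc = -w[:, 1], w[:, 0]  # normal = perp(w)
    denom = nx * u[0] + nzc * u[1]  # n . u
    ok &= np.abs(denom) > PARALLEL_TOL

    # time horizon for extent growth when choosing periodic images
    dt_max = max_dist / speed

    # x-extent of the path and of each segment (inflated by motion)
    px_lo = min(p0[0], p0[0] + u[0] * max_dist)
    px_hi = max(p0[0], p0[0] + u[0] * max_dist)
    grow = (np.maximum(np.abs(segments.sa_dot), np.abs(segments.sb_dot)) * dt_max) + PATH_TOL
    sx_lo = np.minimum(a[:, 0], b[:, 0]) - grow
    sx_hi = np.maximum(a[:, 0], b[:, 0]) + grow

    if not np.any(ok):
        return None
    k_lo = int(np.floor((px_lo - np.max(sx_hi[ok])) / W)) if np.any(ok) else 0
    k_hi = int(np.ceil((px_hi - np.min(sx_lo[ok])) / W))

    best: Optional[tuple[float, int, int, float, np.ndarray, np.ndarray]] = None
    exclude_set = set(exclude)

    for k in range(k_lo, k_hi + 1):
        shift = k * W
        # crossing time of the moving tip with each carrier line
        # n . (p0 + u*speed*tau - (a + [shift,0])) = 0
        rhs = nx * (a[:, 0] + shift - p0[0]) + nzc * (a[:, 1] - p0[1])
        with np.errstate(divide="ignore", invalid="ignore"):
            tau = rhs / denom  # arc distance along the path (speed folded below)
        d = tau  # distance along path
        cand = ok & (d > min_dist) & (d <= max_dist)
        if not np.any(cand):
            continue
        with np.errstate(invalid="ignore"):
            t_hit = t_start + d / speed
            # crossing point and its arc coordinate along the segment
            qx = p0[0] + u[0] * d
            qz = p0[1] + u[1] * d
            s_q = w[:, 0] * (qx - (a[:, 0] + shift)) + w[:, 1] * (qz - a[:, 1])
            dt = t_hit - segments.t0
            s_lo = segments.sa_dot * dt
            s_hi = L + segments.sb_dot * dt
            cand &= (s_q >= s_lo - PATH_TOL) & (s_q <= s_hi + PATH_TOL)
        if not np.any(cand):
            continue
        idx = np.nonzero(cand)[0]
        for i in idx:
            if (int(segments.mt_id[i]), int(segments.seg_idx[i])) in exclude_set:
                continue
            key = (float(d[i]), int(segments.mt_id[i]), int(segments.seg_idx[i]))
            if best is None or key < (best[0], best[1], best[2]):
                best = (
                    float(d[i]),
                    int(segments.mt_id[i]),
                    int(segments.seg_idx[i]),
                    float(t_hit[i]),
                    np.array([qx[i], qz[i]]),
                    w[i].copy(),
                )
    if best is None:
        return None
    d0, mid, sid, th, q, wdir = best
    return Hit(mid, sid, d0, th, q, wdir)


def first_intersection_brute(
    p0: Sequence[float],
    psi: float,
    segments: SegmentSet,
    domain: CylinderDomain,
    max_dist: float,
    *,
    speed: float = 1.0,
    t_start: Optional[float] = None,
    exclude: Iterable[tuple[int, int]] = (),
    min_dist: float = PATH_TOL,
) -> Optional[Hit]:
    """Scalar all-pairs reference for :func:`first_intersection`.

    Loops explicitly over every segment and every periodic image, solving the
    2x2 linear crossing system per pair. Slow; used as an independent cross
    check in validation runs and tests.
    """
    if t_start is None:
        t_start = segments.t0
    W = domain.circumference
    p0x, p0z = float(p0[0]), float(p0[1])
    ux, uz = math.sin(psi), math.cos(psi)
    exclude_set = set(exclude)
    best: Optional[tuple[float, int, int]] = None
    best_hit: Optional[Hit] = None
    for i in range(len(segments)):
        key_id = (int(segments.mt_id[i]), int(segments.seg_idx[i]))
        if key_id in exclude_set:
            continue
        ax, az = segments.a[i]
        bx, bz = segments.b[i]
        L = math.hypot(bx - ax, bz - az)
        if L <= 0:
            continue
        wx, wz = (bx - ax) / L, (bz - az) / L
        cross = ux * wz - uz * wx
        if abs(cross) <= PARALLEL_TOL:
            continue
        dt_max = max_dist / speed
        pad = max(abs(segments.sa_dot[i]), abs(segments.sb_dot[i])) * dt_max + 1.0
        lo = min(p0x, p0x + ux * max_dist) - max(ax, bx) - pad
        hi = max(p0x, p0x + ux * max_dist) - min(ax, bx) + pad
        for k in range(int(math.floor(lo / W)), int(math.ceil(hi / W)) + 1):
            sx = ax + k * W
            # solve p0 + d*u = a_k + s*w  (2x2)
            rx, rz = sx - p0x, az - p0z
            d = (rx * wz - rz * wx) / cross
            s = (rx * uz - rz * ux) / cross
            if d <= min_dist or d > max_dist:
                continue
            t_hit = t_start + d / speed
            dts = t_hit - segments.t0
            s_lo = segments.sa_dot[i] * dts
            s_hi = L + segments.sb_dot[i] * dts
            if s < s_lo - PATH_TOL or s > s_hi + PATH_TOL:
                continue
            key = (d, key_id[0], key_id[1])
            if best is None or key < best:
                best = key
                q = np.array([p0x + ux * d, p0z + uz * d])
                best_hit = Hit(key_id[0], key_id[1], d, t_hit, q, np.array([wx, wz]))
    return best_hit


def polyline_length(verts: np.ndarray) -> float:
    """Arc length of a polyline given as an (k, 2) vertex array."""
    v = np.asarray(verts, dtype=float)
    if len(v) < 2:
        return 0.0
    d = np.diff(v, axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())
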