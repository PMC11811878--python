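"""Microtubule nucleation: isotropic mode and local density-dependent mode.

The local density-dependent algorithm approximates the membrane diffusion of
gamma-tubulin nucleation complexes without simulating particles. Complexes
appear at Poisson rate ``r_app`` at uniform points; from the appearance
point, ``n_dir`` straight "metatrajectories" in equally spaced directions
(with one shared random offset) stand in for the directions the complex
could diffuse. A ray that first crosses a microtubule at distance ``d``
contributes a microtubule-bound nucleation weight

    P_j = (1 / n_dir) * exp(-d_j * sqrt(r_u / D)),

the splitting probability that a complex diffusing with coefficient ``D``
and nucleating freely at rate ``r_u`` reaches distance ``d`` before
nucleating; the remaining probability mass is an unbound nucleation at the
appearance point. A successful candidate is then accepted with probability
``p_acc_mt`` (bound) or ``p_acc_free`` (unbound), the complement of the
empirical dissociation frequencies. Accepted nucleations occupy one complex
from a fixed pool of ``N_c`` for a duration ``t_occ``; appearance events are
rejected outright with probability ``occupied / N_c``, which throttles the
global nucleation rate when many complexes are busy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .geometry import CylinderDomain, Hit, first_intersection, heading_unit, unit_to_heading
from .state import ArrayState, collect_segments


@dataclass(frozen=True)
class NucleationParams:
    """Parameters of the nucleation machinery (rates in 1/s, lengths in um)."""

    mode: str = "local_density"  # or "isotropic"
    r_app: float = 1.0  # appearance-event rate over the whole domain
    n_dir: int = 24  # metatrajectories per appearance
    D: float = 0.013  # complex diffusion coefficient (um^2/s)
    r_u: float = 0.013  # unbound nucleation rate while diffusing (1/s)
    d_max: float = 10.0  # intersection search cutoff (um)
    p_acc_mt: float = 0.62  # acceptance of a microtubule-bound candidate
    p_acc_free: float = 0.02  # acceptance of an unbound candidate
    pool_size: int = 200  # N_c, total nucleation complexes
    t_occ: float = 90.0  # occupancy duration after a successful nucleation (s)
    branch_mix: Tuple[float, float, float] = (0.31, 0.07, 0.62)  # forward, anti, branched
    theta_branch_mode: float = math.radians(35.0)  # mode of the branching angle
    branch_spread: float = math.radians(15.0)  # dispersion of the branching angle
    r_iso: float = 0.02  # isotropic-mode nucleation rate (legacy mode)

    def __post_init__(self) -> None:
        if self.mode not in ("local_density", "isotropic"):
            raise ValueError(f"unknown nucleation mode {self.mode!r}")
        if abs(sum(self.branch_mix) - 1.0) > 1e-9:
            raise ValueError("branch_mix must sum to 1")
        for p in (self.p_acc_mt, self.p_acc_free, *self.branch_mix):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_dir < 1 or self.d_max <= 0:
            raise ValueError("n_dir >= 1 and d_max > 0 required")

    @property
    def decay_length(self) -> float:
        """Length scale sqrt(D / r_u) of the bound-nucleation weight (um)."""
        return math.sqrt(self.D / self.r_u)


@dataclass
class ComplexPool:
    """Fixed pool of nucleation complexes, free or occupied."""

    size: int
    occupied: int = 0
    releases: List[float] = field(default_factory=list)  # pending release times (sorted)

    def occupy(self, t: float, t_occ: float) -> float:
        """Occupy one complex; returns the scheduled release time."""
        if self.occupied >= self.size:
            raise RuntimeError("pool exhausted")
        self.occupied += 1
        t_rel = t + t_occ
        self.releases.append(t_rel)
        self.releases.sort()
        return t_rel

    def release_until(self, t: float) -> int:
        """Apply all releases scheduled at or before ``t``; returns how many."""
        n = 0
        while self.releases and self.releases[0] <= t:
            self.releases.pop(0)
            self.occupied -= 1
            n += 1
        return n

    @property
    def occupied_fraction(self) -> float:
        return self.occupied / self.size if self.size else 0.0


def release_complexes(pool: ComplexPool, t: float) -> int:
    return pool.release_until(t)


def metatrajectory_weight(d: float, params: NucleationParams) -> float:
    """Bound-nucleation weight of one ray hitting a microtubule at distance ``d``.

    The survival factor exp(-d * sqrt(r_u / D)) is the 1D
    diffusion-with-killing splitting probability; the 1/n_dir prefactor
    shares the appearance event equally over the rays. Isolated here so the
    functional form is swappable.
    """
    return math.exp(-d * math.sqrt(params.r_u / params.D)) / params.n_dir


@dataclass
class NucleationOutcome:
    mode: str  # "unbound", "bound", or "rejected"
    position: Optional[np.ndarray] = None  # unwrapped (x, z)
    heading: Optional[float] = None  # psi of the new plus end
    parent: Optional[int] = None  # microtubule id for bound outcomes
    parent_point: Optional[np.ndarray] = None  # crossing point in the parent's frame
    reason: str = ""  # for rejected outcomes: occupancy / dissociation


def ray_hits(
    state: ArrayState,
    point: np.ndarray,
    offset: float,
    params: NucleationParams,
    t: Optional[float] = None,
) -> List[Optional[Hit]]:
    """First microtubule crossing of each metatrajectory within ``d_max``."""
    if t is None:
        t = state.time
    segs = collect_segments(state, t)
    # the rays are an instantaneous probe: freeze all endpoint motion at t
    segs.sa_dot[:] = 0.0
    segs.sb_dot[:] = 0.0
    return static_ray_hits(np.asarray(point, dtype=float), offset, params.n_dir,
                           params.d_max, segs, state.domain)


def static_ray_hits(
    point: np.ndarray,
    offset: float,
    n_dir: int,
    d_max: float,
    segs,
    domain: CylinderDomain,
) -> List[Optional[Hit]]:
    """Nearest static crossing of each of ``n_dir`` equally spaced rays.

    Vectorized over rays x segments x periodic images; semantics match
    :func:`mtcortex.geometry.first_intersection` on a frozen segment set
    (nearest hit, ties by lowest microtubule then segment id).
    """
    hits: List[Optional[Hit]] = [None] * n_dir
    n_seg = len(segs)
    if n_seg == 0:
        return hits
    W = domain.circumference
    psis = (offset + 2.0 * math.pi * np.arange(n_dir) / n_dir) % (2.0 * math.pi)
    U = np.column_stack([np.sin(psis), np.cos(psis)])  # (n_dir, 2)
    ab = segs.b - segs.a
    L = np.hypot(ab[:, 0], ab[:, 1])
    ok_seg = L > 0
    w = np.zeros_like(ab)
    w[ok_seg] = ab[ok_seg] / L[ok_seg, None]
    nx, nz = -w[:, 1], w[:, 0]
    denom = U[:, 0][:, None] * nx[None, :] + U[:, 1][:, None] * nz[None, :]
    px, pz = float(point[0]), float(point[1])
    sx_hi = np.maximum(segs.a[:, 0], segs.b[:, 0])
    sx_lo = np.minimum(segs.a[:, 0], segs.b[:, 0])
    k_lo = int(math.floor((px - d_max - float(sx_hi.max())) / W))
    k_hi = int(math.ceil((px + d_max - float(sx_lo.min())) / W))
    best_d = np.full(n_dir, np.inf)
    best_j = np.full(n_dir, -1, dtype=int)
    for k in range(k_lo, k_hi + 1):
        shift = k * W
        rhs = nx * (segs.a[:, 0] + shift - px) + nz * (segs.a[:, 1] - pz)
        with np.errstate(divide="ignore", invalid="ignore"):
            d = rhs[None, :] / denom
            qx = px + U[:, 0][:, None] * d
            qz = pz + U[:, 1][:, None] * d
            s = w[:, 0][None, :] * (qx - (segs.a[:, 0] + shift)[None, :]) + \
                w[:, 1][None, :] * (qz - segs.a[:, 1][None, :])
            valid = (
                ok_seg[None, :]
                & (np.abs(denom) > 1e-12)
                & (d > 0.0)
                & (d <= d_max)
                & (s >= -1e-9)
                & (s <= (L + 1e-9)[None, :])
            )
        dm = np.where(valid, d, np.inf)
        # rows are stored in ascending (mt, seg) order and argmin returns the
        # first minimum, which implements the distance-then-id tie-break
        jmin = np.argmin(dm, axis=1)
        rows = np.arange(n_dir)
        dmin = dm[rows, jmin]
        better = dmin < best_d
        best_d = np.where(better, dmin, best_d)
        best_j = np.where(better, jmin, best_j)
    for i in range(n_dir):
        j = best_j[i]
        if j < 0 or not math.isfinite(best_d[i]):
            continue
        d = float(best_d[i])
        q = np.array([px + U[i, 0] * d, pz + U[i, 1] * d])
        hits[i] = Hit(
            int(segs.mt_id[j]), int(segs.seg_idx[j]), d, segs.t0, q, w[j].copy()
        )
    return hits


def outcome_probabilities(
    hits: Sequence[Optional[Hit]], params: NucleationParams
) -> Tuple[np.ndarray, float]:
    """Per-ray bound probabilities P_j and the unbound probability P_iso.

    Rays without an intersection contribute their whole weight to the
    unbound outcome; the probabilities sum to exactly 1.
    """
    P = np.array(
        [metatrajectory_weight(h.distance, params) if h is not None else 0.0 for h in hits]
    )
    P_iso = 1.0 - float(P.sum())
    return P, P_iso


def handle_appearance(
    state: ArrayState,
    params: NucleationParams,
    pool: Optional[ComplexPool],
    rng: np.random.Generator,
    t: Optional[float] = None,
    *,
    fixed_point: Optional[Sequence[float]] = None,
    fixed_offset: Optional[float] = None,
) -> NucleationOutcome:
    """Resolve one nucleation-complex appearance event.

    Order of operations: (1) rejection with probability equal to the
    occupied fraction of the pool; (2) uniform appearance point; (3) rays
    with one shared random angular offset; (4) per-ray nearest intersection
    within ``d_max``; (5) bound weights and unbound remainder; (6) draw one
    outcome; (7) post-hoc acceptance; (8) occupy a complex on success. The
    ``fixed_point`` / ``fixed_offset`` hooks pin steps 2-3 for statistical
    validation against the analytic probabilities.

    Note: a successful outcome is *not* placed into the array here; the
    caller decides the new microtubule's branch geometry and identity.
    """
    if t is None:
        t = state.time
    if pool is not None and rng.random() < pool.occupied_fraction:
        return NucleationOutcome(mode="rejected", reason="occupancy")
    if fixed_point is not None:
        point = np.asarray(fixed_point, dtype=float)
    else:
        point = np.array(
            [rng.uniform(0.0, state.domain.circumference), rng.uniform(0.0, state.domain.height)]
        )
    offset = float(rng.uniform(0.0, 2.0 * math.pi)) if fixed_offset is None else float(fixed_offset)
    hits = ray_hits(state, point, offset, params, t)
    P, P_iso = outcome_probabilities(hits, params)
    u = rng.random()
    acc = rng.random()
    cum = 0.0
    chosen: Optional[Hit] = None
    for j, pj in enumerate(P):
        cum += pj
        if u < cum:
            chosen = hits[j]
            break
    if chosen is None:
        # unbound outcome at the appearance point
        if acc >= params.p_acc_free:
            return NucleationOutcome(mode="rejected", reason="dissociation")
        if pool is not None:
            pool.occupy(t, params.t_occ)
        psi = float(rng.uniform(0.0, 2.0 * math.pi))
        return NucleationOutcome(mode="unbound", position=point, heading=psi)
    if acc >= params.p_acc_mt:
        return NucleationOutcome(mode="rejected", reason="dissociation")
    if pool is not None:
        pool.occupy(t, params.t_occ)
    parent = state.mts[chosen.mt_id]
    parent_psi = unit_to_heading(chosen.obstruct_dir)
    psi = sample_bound_geometry(parent_psi, params, rng)
    # express the crossing point in the parent's unwrapped frame
    pts = parent.points_at(t, state.v_plus, state.v_minus, state.v_tm)
    a = pts[chosen.seg_idx]
    W = state.domain.circumference
    k = round((chosen.point[0] - a[0]) / W)
    parent_point = chosen.point - np.array([k * W, 0.0])
    return NucleationOutcome(
        mode="bound",
        position=chosen.point.copy(),
        heading=psi,
        parent=chosen.mt_id,
        parent_point=parent_point,
    )


def sample_bound_geometry(
    parent_psi: float, params: NucleationParams, rng: np.random.Generator
) -> float:
    """Heading of a microtubule-bound nucleation relative to its parent.

    Forward-parallel and antiparallel daughters copy the parent trajectory;
    branched daughters pick a side equiprobably and draw the relative angle
    from a normal distribution with mode ``theta_branch_mode`` truncated to
    (0, pi).
    """
    f_par, f_anti, f_branch = params.branch_mix
    u = rng.random()
    if u < f_par:
        return parent_psi % (2.0 * math.pi)
    if u < f_par + f_anti:
        return (parent_psi + math.pi) % (2.0 * math.pi)
    side = 1.0 if rng.random() < 0.5 else -1.0
    while True:
        a = rng.normal(params.theta_branch_mode, params.branch_spread)
        if 0.0 < a < math.pi:
            break
    return (parent_psi + side * a) % (2.0 * math.pi)


def isotropic_nucleate(
    state: ArrayState, rng: np.random.Generator
) -> NucleationOutcome:
    """Legacy isotropic nucleation: uniform position and direction."""
    point = np.array(
        [rng.uniform(0.0, state.domain.circumference), rng.uniform(0.0, state.domain.height)]
    )
    psi = float(rng.uniform(0.0, 2.0 * math.pi))
    return NucleationOutcome(mode="unbound", position=point, heading=psi)
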