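"""Deterministic toy arrays for tests, examples and oracle checks."""

from __future__ import annotations

import math
from typing import Optional

import numpy as np

from .geometry import CylinderDomain, heading_unit, unit_to_heading
from .state import GROWING, ArrayState, Microtubule


def _add_straight(
    state: ArrayState, start: np.ndarray, psi: float, length: float, growing: bool = True
) -> Microtubule:
    # subdivide like the engine does, so no segment exceeds half the
    # circumference (required for exact periodic-image handling and for the
    # minimal-image snapshot round trip)
    u = heading_unit(psi)
    cap = state.domain.circumference / 2.0
    n_seg = max(int(math.ceil(length / cap)), 1)
    step = length / n_seg
    start = np.asarray(start, dtype=float)
    verts = [start + u * (step * i) for i in range(n_seg + 1)]
    kinds = [""] + ["wrap"] * (n_seg - 1) + [""]
    mt = Microtubule(
        id=state.new_mt_id(),
        verts=verts,
        vert_t=[0.0] * len(verts),
        vkinds=kinds,
        plus_state=GROWING if growing else "shrinking",
        tip_psi=psi % (2 * math.pi),
    )
    state.add_mt(mt)
    return mt


def parallel_lines(
    domain: CylinderDomain, n: int = 3, spacing: float = 1.0, z0: float = 1.0,
    orientation: float = math.pi / 2, length: Optional[float] = None,
) -> ArrayState:
    """n parallel straight microtubules; transverse by default (full rings)."""
    state = ArrayState(domain=domain)
    L = length if length is not None else domain.circumference
    for i in range(n):
        _add_straight(state, np.array([0.0, z0 + i * spacing]), orientation, L)
    return state


def grid(domain: CylinderDomain, n_transverse: int = 2, n_axial: int = 2) -> ArrayState:
    """Crossing transverse and axial lines (n_t * n_a crossing candidates)."""
    state = ArrayState(domain=domain)
    H, W = domain.height, domain.circumference
    for i in range(n_transverse):
        z = H * (i + 1) / (n_transverse + 1)
        _add_straight(state, np.array([0.0, z]), math.pi / 2, W)
    for j in range(n_axial):
        x = W * (j + 1) / (n_axial + 1)
        _add_straight(state, np.array([x, 0.0]), 0.0, H)
    return state


def single(
    domain: CylinderDomain, start=(0.0, 0.0), psi: float = math.pi / 2, length: float = 5.0,
    growing: bool = True,
) -> ArrayState:
    state = ArrayState(domain=domain)
    _add_straight(state, np.asarray(start, dtype=float), psi, length, growing)
    return state


def random_array(
    domain: CylinderDomain, n: int = 20, seed: int = 0,
    mean_length: float = 4.0,
) -> ArrayState:
    """Seeded random straight microtubules (uniform positions/directions)."""
    rng = np.random.default_rng(seed)
    state = ArrayState(domain=domain)
    for _ in range(n):
        start = np.array([
            rng.uniform(0, domain.circumference), rng.uniform(0, domain.height)
        ])
        psi = rng.uniform(0, 2 * math.pi)
        L = rng.exponential(mean_length)
        # clip so the polyline stays inside [0, H] axially
        u = heading_unit(psi)
        if abs(u[1]) > 1e-12:
            if u[1] > 0:
                L = min(L, (domain.height - start[1]) / u[1])
            else:
                L = min(L, -start[1] / u[1])
        L = max(L, 1e-3)
        _add_straight(state, start, psi, L)
    return state


def generate_fixture(kind: str, domain: CylinderDomain, seed: int = 0, **params) -> ArrayState:
    """Dispatch by name: parallel_lines, grid, single, random."""
    if kind == "parallel_lines":
        return parallel_lines(domain, **params)
    if kind == "grid":
        return grid(domain, **params)
    if kind == "single":
        return single(domain, **params)
    if kind == "random":
        return random_array(domain, seed=seed, **params)
    raise ValueError(f"unknown fixture kind {kind!r}")
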