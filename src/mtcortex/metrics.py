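"""Observables of the simulated array.

Axial density profiles, band/gap densities, populated-band counts, fraction
of polymer length residing in bands, length-weighted orientation statistics
(nematic convention), and a worm-like-chain persistence-length estimator.

Density is reported as microtubule length per unit membrane area
(um of polymer / um^2, i.e. um^-1); per-bin raw length is also emitted since
experimental work often quotes length per axial bin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .geometry import CylinderDomain
from .prepattern import Prepattern
from .state import ArrayState


def _all_segments(state: ArrayState, t: Optional[float] = None) -> Tuple[np.ndarray, np.ndarray]:
    """(n, 2) start and end points of every polyline segment (unwrapped)."""
    if t is None:
        t = state.time
    A: List[np.ndarray] = []
    B: List[np.ndarray] = []
    for mt in state.mts.values():
        pts = mt.points_at(t, state.v_plus, state.v_minus, state.v_tm)
        A.extend(pts[:-1])
        B.extend(pts[1:])
    if not A:
        return np.zeros((0, 2)), np.zeros((0, 2))
    return np.array(A), np.array(B)


def _overlap_lengths(a: np.ndarray, b: np.ndarray, z_lo: float, z_hi: float) -> np.ndarray:
    """Arc length of each segment falling inside the axial slab [z_lo, z_hi).

    A segment's length is apportioned by its exact axial overlap with the
    slab; segments at constant z (transverse rings) count fully iff their z
    lies inside.
    """
    dz = b[:, 1] - a[:, 1]
    L = np.hypot(b[:, 0] - a[:, 0], dz)
    out = np.zeros(len(L))
    flat = np.abs(dz) <= 1e-12
    inside = flat & (a[:, 1] >= z_lo) & (a[:, 1] < z_hi)
    out[inside] = L[inside]
    sl = ~flat
    if np.any(sl):
        z0 = np.minimum(a[sl, 1], b[sl, 1])
        z1 = np.maximum(a[sl, 1], b[sl, 1])
        ov = np.clip(np.minimum(z1, z_hi) - np.maximum(z0, z_lo), 0.0, None)
        out[sl] = L[sl] * ov / (z1 - z0)
    return out


@dataclass
class DensityProfile:
    edges: np.ndarray  # bin edges along z (um)
    length: np.ndarray  # raw polymer length per bin (um)
    density: np.ndarray  # length per unit area (um^-1)


def density_profile(state: ArrayState, bin_width: float = 0.5) -> DensityProfile:
    """Axial profile of local microtubule density."""
    H = state.domain.height
    W = state.domain.circumference
    n = max(int(math.ceil(H / bin_width - 1e-9)), 1)
    edges = np.minimum(np.arange(n + 1) * bin_width, H)
    a, b = _all_segments(state)
    length = np.zeros(n)
    for i in range(n):
        hi = edges[i + 1] if i < n - 1 else H + 1e-9  # last bin closed at H
        length[i] = _overlap_lengths(a, b, edges[i], hi).sum() if len(a) else 0.0
    areas = np.diff(edges) * W
    with np.errstate(divide="ignore", invalid="ignore"):
        dens = np.where(areas > 0, length / areas, 0.0)
    return DensityProfile(edges=edges, length=length, density=dens)


def band_gap_density(state: ArrayState, prepattern: Prepattern) -> Tuple[float, float]:
    """Mean microtubule density (um^-1) in band and in gap regions."""
    W = state.domain.circumference
    H = state.domain.height
    a, b = _all_segments(state)
    band_len = 0.0
    for z0, z1 in prepattern.band_intervals():
        if len(a):
            band_len += float(_overlap_lengths(a, b, z0, z1).sum())
    total = float(np.hypot(b[:, 0] - a[:, 0], b[:, 1] - a[:, 1]).sum()) if len(a) else 0.0
    band_area = prepattern.n_bands * prepattern.band_width * W
    gap_area = max(H * W - band_area, 0.0)
    band_d = band_len / band_area if band_area > 0 else 0.0
    gap_d = max(total - band_len, 0.0) / gap_area if gap_area > 0 else 0.0
    return band_d, gap_d


def populated_band_count(state: ArrayState, prepattern: Prepattern) -> int:
    """Bands whose density strictly exceeds 3x the mean gap density.

    If the mean gap density is exactly zero, a band counts as populated iff
    its own density is positive.
    """
    W = state.domain.circumference
    a, b = _all_segments(state)
    _, gap_d = band_gap_density(state, prepattern)
    n = 0
    for z0, z1 in prepattern.band_intervals():
        if not len(a):
            continue
        d = float(_overlap_lengths(a, b, z0, z1).sum()) / ((z1 - z0) * W)
        if (gap_d == 0.0 and d > 0.0) or (gap_d > 0.0 and d > 3.0 * gap_d):
            n += 1
    return n


def fraction_in_bands(state: ArrayState, prepattern: Prepattern) -> float:
    """Percentage of total microtubule length residing in the band regions.

    Returns NaN for an empty array.
    """
    a, b = _all_segments(state)
    if not len(a):
        return math.nan
    total = float(np.hypot(b[:, 0] - a[:, 0], b[:, 1] - a[:, 1]).sum())
    if total <= 0:
        return math.nan
    band_len = sum(
        float(_overlap_lengths(a, b, z0, z1).sum()) for z0, z1 in prepattern.band_intervals()
    )
    return 100.0 * band_len / total


def angle_histogram(
    state: ArrayState, bins: int = 36
) -> Tuple[np.ndarray, np.ndarray]:
    """Length-weighted histogram of segment orientations over [0, 180) deg."""
    a, b = _all_segments(state)
    edges = np.linspace(0.0, 180.0, bins + 1)
    if not len(a):
        return np.zeros(bins), edges
    d = b - a
    L = np.hypot(d[:, 0], d[:, 1])
    keep = L > 0
    phi = np.degrees(np.mod(np.arctan2(d[keep, 0], d[keep, 1]), math.pi))
    hist, _ = np.histogram(phi, bins=edges, weights=L[keep])
    return hist, edges


def mean_orientation(state: ArrayState) -> Tuple[float, float]:
    """Length-weighted mean orientation (deg from the long axis) and nematic
    order parameter S.

    Orientations are averaged on the doubled-angle circle (180-degree
    period); S is the resultant magnitude, 1 for perfect alignment and ~0
    for an isotropic array. Returns (nan, nan) for an empty array.
    """
    a, b = _all_segments(state)
    if not len(a):
        return math.nan, math.nan
    d = b - a
    L = np.hypot(d[:, 0], d[:, 1])
    keep = L > 0
    if not np.any(keep):
        return math.nan, math.nan
    phi = np.mod(np.arctan2(d[keep, 0], d[keep, 1]), math.pi)
    w = L[keep]
    c = float(np.sum(w * np.cos(2 * phi)))
    s = float(np.sum(w * np.sin(2 * phi)))
    S = math.hypot(c, s) / float(np.sum(w))
    mean = 0.5 * math.atan2(s, c) % math.pi
    return math.degrees(mean), S


# ---------------------------------------------------------------------------
# Persistence length estimation
# ---------------------------------------------------------------------------


def _tangent_angles(path: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Cumulative (unwrapped) tangent angle along a polyline.

    The tangent is exactly piecewise constant between vertices; returns the
    arc position of each segment start and the segment's angle relative to
    the first tangent. Individual turns are assumed below pi in magnitude.
    """
    d = np.diff(path, axis=0)
    L = np.hypot(d[:, 0], d[:, 1])
    keep = L > 0
    d, L = d[keep], L[keep]
    psi = np.arctan2(d[:, 0], d[:, 1])
    turns = np.diff(psi)
    turns = (turns + math.pi) % (2 * math.pi) - math.pi
    theta = np.concatenate([[0.0], np.cumsum(turns)])
    s_start = np.concatenate([[0.0], np.cumsum(L)[:-1]])
    return s_start, theta


def _theta_at(s_start: np.ndarray, theta: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Step-function lookup of the tangent angle at arc positions."""
    idx = np.clip(np.searchsorted(s_start, grid, side="right") - 1, 0, len(theta) - 1)
    return theta[idx]


def mean_square_angle_curve(
    paths: Sequence[np.ndarray], n_grid: int = 50, fit_fraction: float = 1.0
) -> Tuple[np.ndarray, np.ndarray]:
    """<theta^2(s)>: mean squared tangent angle (relative to the initial
    tangent) on a common arc-length grid across paths."""
    smax = min(
        (float(np.hypot(*np.diff(p, axis=0).T.reshape(2, -1)).sum()) for p in paths),
        default=0.0,
    )
    smax *= fit_fraction
    if smax <= 0:
        return np.zeros(0), np.zeros(0)
    grid = np.linspace(smax / n_grid, smax, n_grid)
    acc = np.zeros(n_grid)
    count = 0
    for p in paths:
        s_start, theta = _tangent_angles(np.asarray(p, dtype=float))
        if len(s_start) < 1:
            continue
        th = _theta_at(s_start, theta, grid)
        acc += (th - theta[0]) ** 2
        count += 1
    if count == 0:
        return np.zeros(0), np.zeros(0)
    return grid, acc / count


def estimate_persistence_length(
    paths: Sequence[np.ndarray],
    n_grid: int = 50,
    fit_fraction: float = 1.0,
) -> float:
    """Persistence length from the tangent-variance law <theta^2(s)> = s / L_p.

    Because the squared tangent angle grows linearly in s with independent
    increments, the efficient straight-line fit of <theta^2(s)> through the
    origin pools the angle increments over the arc-length grid: the slope is
    the mean of (delta theta)^2 / (delta s) over all windows and paths, and
    L_p is its reciprocal. Perfectly straight paths return ``inf``.
    """
    smax = min(
        (float(np.hypot(*np.diff(p, axis=0).T.reshape(2, -1)).sum()) for p in paths),
        default=0.0,
    )
    smax *= fit_fraction
    if smax <= 0:
        return math.inf
    grid = np.linspace(0.0, smax, n_grid + 1)
    ds = grid[1] - grid[0]
    num = 0.0
    count = 0
    for p in paths:
        s_start, theta = _tangent_angles(np.asarray(p, dtype=float))
        if len(s_start) < 1:
            continue
        th = _theta_at(s_start, theta, grid)
        num += float(np.sum(np.diff(th) ** 2))
        count += n_grid
    if count == 0:
        return math.inf
    slope = num / (count * ds)
    if slope <= 1e-12:
        return math.inf
    return 1.0 / slope


def metrics_row(
    state: ArrayState, prepattern: Optional[Prepattern] = None
) -> dict:
    """Standard metrics record for one sampled time point."""
    from .state import total_length  # local import to avoid cycle at module load

    L = total_length(state)
    ori, S = mean_orientation(state)
    row = {
        "time_s": state.time,
        "total_length_um": L,
        "n_mt": len(state.mts),
        "n_crossovers": len(state.crossovers),
        "mean_orientation_deg": ori,
        "order_param_S": S,
    }
    if prepattern is not None:
        band_d, gap_d = band_gap_density(state, prepattern)
        row.update(
            band_density=band_d,
            gap_density=gap_d,
            populated_bands=populated_band_count(state, prepattern),
            frac_in_bands_pct=fraction_in_bands(state, prepattern),
        )
    return row
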