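"""Semiflexible microtubule growth via discrete stochastic deflections.

Instead of bending continuously, a growing plus end travels straight for an
exponentially distributed distance (mean ``delta_d``) and then abruptly
turns by an angle drawn uniformly from ``[-m, m]``. On the 2D cell surface
this random walk of the tangent angle has variance ``(m^2/3) * s / delta_d``
after arc length ``s``, so choosing ``m = sqrt(3 * delta_d / L_p)`` gives
the worm-like-chain tangent-variance law ``<theta^2(s)> = s / L_p`` and
hence persistence length ``L_p`` (tangent correlation ``exp(-s / (2 L_p))``
in two dimensions).

Deflections interact with bundles in two ways: a microtubule inside a
bundle of ``n`` other members only executes a deflection with probability
``1/(n+1)`` (leaving the bundle when it does), and microtubules follow
their bundle around polyline bends smaller than a maximum tracking angle,
choosing among diverging branches proportionally to branch occupancy.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

#: above this maximum deflection angle (rad) the small-angle calibration
#: behind m = sqrt(3 delta_d / L_p) starts to break down.
SMALL_ANGLE_LIMIT = 0.35


@dataclass(frozen=True)
class FlexibilityParams:
    """Parameters of the deflection process.

    persistence_length : target L_p in um; ``inf`` gives rigid microtubules.
    deflection_step : mean straight distance between deflection attempts (um).
    min_deflection : angles below this magnitude are snapped to zero (rad),
        avoiding numerically meaningless micro-bends.
    bundle_tracking_angle : maximum bend angle (rad) a bundled microtubule
        follows; must stay below the bundling threshold angle.
    """

    persistence_length: float = math.inf
    deflection_step: float = 0.3
    min_deflection: float = 1e-3
    bundle_tracking_angle: float = math.radians(10.0)

    def __post_init__(self) -> None:
        if self.deflection_step <= 0:
            raise ValueError("deflection_step must be positive")
        if self.persistence_length <= 0:
            raise ValueError("persistence_length must be positive (use inf for rigid)")
        if self.min_deflection < 0:
            raise ValueError("min_deflection must be non-negative")

    @property
    def max_deflection(self) -> float:
        """Maximum deflection angle m (rad) calibrated to the persistence length."""
        return calibrate_max_deflection(self.persistence_length, self.deflection_step)

    @property
    def rigid(self) -> bool:
        return not math.isfinite(self.persistence_length)


def calibrate_max_deflection(L_p: float, delta_d: float) -> float:
    """Maximum deflection angle m such that uniform[-m, m] turns every
    ``delta_d`` give tangent-angle variance ``s / L_p``.

    Equates the per-step variance ``m^2 / 3`` to ``delta_d / L_p``, i.e.
    ``m = sqrt(3 delta_d / L_p)``; ``L_p = inf`` returns the rigid limit 0.
    """
    if delta_d <= 0 or L_p <= 0:
        raise ValueError("persistence length and deflection step must be positive")
    if not math.isfinite(L_p):
        return 0.0
    m = math.sqrt(3.0 * delta_d / L_p)
    if m > SMALL_ANGLE_LIMIT:
        warnings.warn(
            f"max deflection angle {m:.3f} rad exceeds the small-angle regime "
            f"({SMALL_ANGLE_LIMIT} rad); decrease deflection_step or increase L_p",
            stacklevel=2,
        )
    return m


def next_deflection_distance(rng: np.random.Generator, delta_d: float) -> float:
    """Straight growth distance until the next deflection attempt (exponential)."""
    if delta_d <= 0:
        raise ValueError("delta_d must be positive")
    return float(rng.exponential(delta_d))


def sample_deflection_angle(
    rng: np.random.Generator, m: float, m_min: float = 0.0
) -> float:
    """Deflection angle: uniform on [-m, m], snapped to 0 below ``m_min``."""
    if m == 0:
        return 0.0
    a = float(rng.uniform(-m, m))
    return 0.0 if abs(a) < m_min else a


def accept_bundle_deflection(n_other: int, rng: np.random.Generator) -> bool:
    """Whether a deflection inside a bundle is executed.

    With ``n`` other microtubules sharing the trajectory, a fraction
    ``n/(n+1)`` of deflection attempts is rejected, approximating that only
    the outermost member has room to bend away. An accepted deflection makes
    the microtubule leave the bundle at that point.
    """
    if n_other < 0:
        raise ValueError("n_other must be non-negative")
    if n_other == 0:
        return True
    return bool(rng.random() < 1.0 / (n_other + 1))


def follow_bend(
    bend_angles: Sequence[float],
    occupancies: Sequence[int],
    theta_track: float,
    rng: np.random.Generator,
) -> Optional[int]:
    """Continuation choice of a bundled tip at a bend or split point.

    ``bend_angles`` are the absolute angles (rad) between the incoming
    heading and each candidate continuation; ``occupancies`` the number of
    bundle members along each. Candidates at or above ``theta_track`` are
    not followable. Returns the index of the branch to follow, chosen with
    probability proportional to occupancy among followable branches, or
    ``None`` if there is none (the tip leaves the bundle and grows straight).
    """
    ok = [i for i, a in enumerate(bend_angles) if abs(a) < theta_track]
    if not ok:
        return None
    if len(ok) == 1:
        return ok[0]
    w = np.array([max(occupancies[i], 0) for i in ok], dtype=float)
    if w.sum() <= 0:
        w[:] = 1.0
    p = w / w.sum()
    return int(ok[int(rng.choice(len(ok), p=p))])


def generate_growth_path(
    rng: np.random.Generator,
    params: FlexibilityParams,
    total_length: float,
    psi0: float = 0.0,
    origin: Sequence[float] = (0.0, 0.0),
) -> np.ndarray:
    """A free (interaction-less) growth path of given arc length.

    Mirrors what the event engine does for an isolated growing tip: straight
    exponential-length runs punctuated by uniform deflections. Used for
    persistence-length calibration checks and as a light-weight fixture.
    Returns an (k, 2) polyline.
    """
    m = params.max_deflection
    pts = [np.asarray(origin, dtype=float)]
    psi = psi0
    s = 0.0
    while s < total_length:
        if params.rigid:
            step = total_length - s
        else:
            step = min(next_deflection_distance(rng, params.deflection_step), total_length - s)
        pts.append(pts[-1] + np.array([math.sin(psi), math.cos(psi)]) * step)
        s += step
        if s < total_length and not params.rigid:
            psi += sample_deflection_angle(rng, m, params.min_deflection)
    return np.array(pts)
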