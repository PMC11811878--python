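"""Band/gap prepattern and the protoxylem phase schedule.

The pattern of secondary cell wall bands in developing protoxylem is
prefigured by a banded ROP/MIDD1 pattern. This module represents that
pattern as fixed, alternating axial band and gap intervals: bands keep the
normal catastrophe rate, gaps get it multiplied by ``f_cat`` once the
banding phase activates at ``t_band``. Before that, a two-part initiation
phase establishes a transverse array: a biased-nucleation phase (nucleation
angles drawn from a normal distribution around the bias angle) followed by
the configured nucleation mode under uniform dynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np

BAND = "band"
GAP = "gap"


@dataclass(frozen=True)
class Prepattern:
    """Axial band intervals, stored half-open [start, start + width)."""

    band_starts: Tuple[float, ...]  # z of each band start (um), sorted
    band_width: float  # w_b (um)
    f_cat: float = 3.0  # catastrophe multiplier in gaps after activation
    t_band: float = 7200.0  # activation time of the gap catastrophe factor (s)

    def __post_init__(self) -> None:
        starts = tuple(sorted(self.band_starts))
        object.__setattr__(self, "band_starts", starts)
        if self.band_width <= 0:
            raise ValueError("band_width must be positive")
        for s0, s1 in zip(starts, starts[1:]):
            if s1 < s0 + self.band_width:
                raise ValueError("bands must not overlap")

    @staticmethod
    def regular(
        n_bands: int, band_width: float = 1.0, gap_width: float = 5.0,
        f_cat: float = 3.0, t_band: float = 7200.0,
    ) -> "Prepattern":
        """Evenly spaced layout with the first band starting at z = 0."""
        pitch = band_width + gap_width
        return Prepattern(
            band_starts=tuple(i * pitch for i in range(n_bands)),
            band_width=band_width, f_cat=f_cat, t_band=t_band,
        )

    @property
    def n_bands(self) -> int:
        return len(self.band_starts)

    @property
    def height(self) -> float:
        """Domain height implied by a regular layout (end of the last pitch)."""
        if self.n_bands < 2:
            return self.band_starts[-1] + self.band_width if self.band_starts else 0.0
        pitch = self.band_starts[1] - self.band_starts[0]
        return self.band_starts[0] + self.n_bands * pitch

    def band_intervals(self) -> List[Tuple[float, float]]:
        return [(s, s + self.band_width) for s in self.band_starts]

    def region_of(self, z: float) -> str:
        """'band' iff z lies inside a band interval (half-open convention)."""
        for s in self.band_starts:
            if s <= z < s + self.band_width:
                return BAND
        return GAP

    def boundaries(self) -> np.ndarray:
        """Sorted z positions where the region changes."""
        b = []
        for s in self.band_starts:
            b.extend((s, s + self.band_width))
        return np.array(sorted(set(b)))

    def catastrophe_factor(self, z: float, t: float) -> float:
        """Multiplier on the spontaneous catastrophe rate at (z, t)."""
        if t < self.t_band or self.region_of(z) == BAND:
            return 1.0
        return self.f_cat


def local_catastrophe_rate(
    z: float, t: float, prepattern: Prepattern | None, r_cat: float
) -> float:
    """Position- and time-dependent spontaneous catastrophe rate."""
    if prepattern is None:
        return r_cat
    return r_cat * prepattern.catastrophe_factor(z, t)


@dataclass(frozen=True)
class PhaseSchedule:
    """Timing and bias of the protoxylem initiation protocol (seconds)."""

    t_bias_end: float = 1800.0  # end of the biased-nucleation phase
    t_band: float = 7200.0  # activation of the gap catastrophe factor
    t_end: float = 25200.0  # simulation end (default 7 h)
    theta_bias: float = math.pi / 2  # bias angle (rad; pi/2 = transverse)
    sigma_bias: float = 0.018  # bias standard deviation (rad)

    def __post_init__(self) -> None:
        if not (0 < self.t_bias_end <= self.t_band <= self.t_end):
            raise ValueError("need 0 < t_bias_end <= t_band <= t_end")
        if self.sigma_bias < 0:
            raise ValueError("sigma_bias must be non-negative")


def biased_nucleation_angle(
    rng: np.random.Generator, theta_bias: float, sigma_bias: float
) -> float:
    """Directed heading for a biased-phase nucleation.

    The orientation is normal around the bias angle; the direction along it
    (psi or psi + pi) is chosen equiprobably.
    """
    psi = float(rng.normal(theta_bias, sigma_bias))
    if rng.random() < 0.5:
        psi += math.pi
    return psi % (2.0 * math.pi)
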