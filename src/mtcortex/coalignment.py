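"""Analytic geometry of array-ROP co-alignment on a cylinder.

A banded ROP pattern must close smoothly around the cell while keeping its
intrinsic band spacing ``b``: it can form rings (spiral number n = 0) or an
n-start spiral. Going once around the circumference ``W``, an n-start spiral
advances axially by n band spacings, so the admissible pattern orientations,
measured from transverse, are the discrete set

    theta_n = arctan(n * b / W),   n = 0, 1, 2, ...

A microtubule array can take any orientation; assuming the ROP pattern
adopts the admissible orientation closest to the array's, the array-pattern
mismatch is the distance to the nearest theta_n, and its worst case is the
largest half-gap between successive admissible orientations. Two further
straight-line limits quantify when a microtubule can still live inside a
band of width ``w_b`` despite a mismatch: the largest mismatch at which it
spans the full circumference within the band, arctan(w_b / W), and the
largest in-band length at mismatch alpha, w_b / sin(alpha).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np


@dataclass(frozen=True)
class CoalignmentGeometry:
    """Cylinder and band-layout parameters for the mismatch analytics."""

    height: float  # H, domain length (um)
    circumference: float  # W (um)
    n_bands: int  # number of bands in the equivalently spaced banded array
    band_width: float = 1.0  # w_b (um)

    def __post_init__(self) -> None:
        if self.height <= 0 or self.circumference <= 0 or self.n_bands < 1:
            raise ValueError("height, circumference > 0 and n_bands >= 1 required")

    @staticmethod
    def from_radius(
        radius: float, n_bands: int = 10, band_spacing: float = 6.0, band_width: float = 1.0
    ) -> "CoalignmentGeometry":
        return CoalignmentGeometry(
            height=n_bands * band_spacing,
            circumference=2.0 * math.pi * radius,
            n_bands=n_bands,
            band_width=band_width,
        )

    @property
    def band_spacing(self) -> float:
        """b = H / n_b, the axial centre-to-centre band spacing (um)."""
        return self.height / self.n_bands


def admissible_orientations(geom: CoalignmentGeometry, n_max: int) -> np.ndarray:
    """Admissible ring/spiral orientations theta_n in degrees from transverse.

    n = 0 is the ring solution (0 deg); angles increase with the spiral
    number while the gaps between successive angles shrink.
    """
    if n_max < 0:
        raise ValueError("n_max must be >= 0")
    n = np.arange(n_max + 1)
    return np.degrees(np.arctan(n * geom.band_spacing / geom.circumference))


def minimal_mismatch(
    array_orientation: float | np.ndarray, geom: CoalignmentGeometry, n_max: int = 32
) -> float | np.ndarray:
    """Mismatch (deg) between an array orientation (deg from transverse) and
    the nearest admissible ring/spiral orientation."""
    adm = admissible_orientations(geom, n_max)
    o = np.atleast_1d(np.asarray(array_orientation, dtype=float))
    d = np.min(np.abs(o[:, None] - adm[None, :]), axis=1)
    return float(d[0]) if np.isscalar(array_orientation) else d


def max_minimal_mismatch(geom: CoalignmentGeometry, n_max: int = 32) -> float:
    """Worst-case minimal mismatch (deg): the largest half-gap between
    successive admissible orientations."""
    adm = admissible_orientations(geom, n_max)
    return float(np.max(np.diff(adm)) / 2.0)


def spanning_mismatch_limit(band_width: float, circumference: float) -> float:
    """Largest mismatch (deg) at which a straight microtubule still spans the
    whole circumference inside one band (drift of one band width per turn)."""
    if band_width <= 0 or circumference <= 0:
        raise ValueError("band_width and circumference must be positive")
    return math.degrees(math.atan(band_width / circumference))


def max_inband_length(band_width: float, mismatch_deg: float) -> float:
    """Largest straight length (um) fitting inside a band at a given mismatch.

    ``inf`` at zero mismatch; equals the band width at 90 degrees.
    """
    if mismatch_deg == 0:
        return math.inf
    return band_width / math.sin(math.radians(mismatch_deg))


def mismatch_curve(
    geom: CoalignmentGeometry, n_max: int = 32, n_points: int = 721,
    max_orientation: Optional[float] = None,
) -> np.ndarray:
    """(orientation, minimal mismatch) table in degrees, for plotting/export."""
    if max_orientation is None:
        max_orientation = float(admissible_orientations(geom, n_max)[-1])
    o = np.linspace(0.0, max_orientation, n_points)
    return np.column_stack([o, minimal_mismatch(o, geom, n_max)])
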