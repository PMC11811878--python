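"""Worst-case mismatch between a microtubule array and a banded ROP pattern.

A banded/spiral ROP pattern on a cylinder can only take discrete
orientations theta_n = arctan(n*b/W) (n = spiral number, b = band spacing,
W = circumference). A microtubule array can take any orientation, so if the
ROP pattern co-aligns with the nearest admissible orientation, some
residual mismatch is unavoidable. This script prints the admissible
orientations and the worst-case mismatch for the default protoxylem
geometry, plus the straight-line limits on how long a microtubule can stay
inside a band at a given mismatch.
"""

from mtcortex.coalignment import (
    CoalignmentGeometry,
    admissible_orientations,
    max_inband_length,
    max_minimal_mismatch,
    spanning_mismatch_limit,
)

geom = CoalignmentGeometry.from_radius(radius=7.5, n_bands=10, band_spacing=6.0, band_width=1.0)

print(f"cylinder: W = {geom.circumference:.2f} um, band spacing b = {geom.band_spacing:.1f} um")
angles = admissible_orientations(geom, n_max=5)
print("admissible pattern orientations (deg from transverse):",
      ", ".join(f"{a:.2f}" for a in angles))
print(f"worst-case minimal mismatch: {max_minimal_mismatch(geom):.2f} deg "
      "(half the gap between rings and the single spiral)")
lim = spanning_mismatch_limit(geom.band_width, geom.circumference)
print(f"largest mismatch at which a straight microtubule spans the "
      f"circumference inside one band: {lim:.2f} deg")
for a in (1.0, 2.0, 3.6):
    print(f"  at {a:.1f} deg mismatch a straight microtubule fits "
          f"{max_inband_length(geom.band_width, a):.1f} um inside a band")
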