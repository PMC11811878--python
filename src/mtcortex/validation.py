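"""Independent cross-checks of the event engine.

Collision audit: whenever the engine schedules a growing tip's next
deterministic event, it has searched for the first crossing of the tip's
free path (up to the event horizon) with every segment, including moving
extents. With auditing enabled, the same search is re-derived by the scalar
all-pairs brute force (:func:`mtcortex.geometry.first_intersection_brute`)
and the two must agree exactly: same hit identity and crossing time within
tolerance when a collision is scheduled, and no brute-force hit inside the
horizon when none is. Executed collisions are counted as checked because
each one ran through this comparison at its final (re)scheduling.

Bundled microtubules share exactly coincident trajectories, so a crossing
can be attributed to any member at the same point and time; coincident-point
equal-time hits therefore count as agreement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .geometry import Hit


@dataclass
class CollisionAudit:
    """Collector for collision cross-check results."""

    time_tol: float = 1e-9
    executed: int = 0  # collisions actually executed
    scans: int = 0  # scheduling-time comparisons performed
    mismatches: List[dict] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.mismatches

    def compare(
        self, t: float, mt_id: int, engine_hit: Optional[Hit], brute_hit: Optional[Hit],
        speed: float,
    ) -> None:
        self.scans += 1
        if engine_hit is None and brute_hit is None:
            return
        if engine_hit is not None and brute_hit is not None:
            same_id = engine_hit.mt_id == brute_hit.mt_id and engine_hit.seg_idx == brute_hit.seg_idx
            dt = abs(engine_hit.time - brute_hit.time)
            same_point = (
                float(np.hypot(*(engine_hit.point - brute_hit.point))) <= 1e-6
            )
            if dt <= max(self.time_tol, 1e-9 * max(abs(t), 1.0)) and (same_id or same_point):
                return
        self.mismatches.append(
            {
                "time": t,
                "mt": mt_id,
                "engine": None if engine_hit is None else (engine_hit.mt_id, engine_hit.seg_idx, engine_hit.time),
                "brute": None if brute_hit is None else (brute_hit.mt_id, brute_hit.seg_idx, brute_hit.time),
            }
        )
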