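"""Protoxylem band-formation protocol and run-level orchestration.

The protocol has three phases. Phase 1 (biased initiation, first 30 min by
default): nucleations occur at uniform positions with directions drawn from
a normal distribution around the bias angle, establishing a transverse
array. Phase 2: the configured nucleation mode takes over while dynamics
stay uniform, generating a realistic array microstructure. Phase 3 (band
formation, from ``t_band``): the catastrophe rate in the gap regions is
multiplied by ``f_cat``, draining microtubules from the gaps and
concentrating the array into the prepatterned bands.
"""

from __future__ import annotations

from typing import Any, Dict, Optional

import pandas as pd

from .config import SimulationConfig
from .engine import SimResult, Simulation
from .metrics import metrics_row
from .state import ArrayState, snapshot_frame


def build_simulation(
    config: SimulationConfig,
    seed: Optional[int] = None,
    initial_state: Optional[ArrayState] = None,
    **kwargs: Any,
) -> Simulation:
    """A Simulation wired from a validated config, sampling the standard
    metrics columns at the configured interval."""
    prepattern = config.prepattern

    def sampler(sim: Simulation, state: ArrayState) -> Dict[str, Any]:
        return metrics_row(state, prepattern)

    return Simulation(
        domain=config.domain,
        dyn=config.dynamics,
        flex=config.flexibility,
        nuc=config.nucleation,
        prepattern=config.prepattern,
        schedule=config.schedule,
        seed=config.seed if seed is None else seed,
        initial_state=initial_state,
        sample_interval=config.sample_interval,
        sampler=sampler if config.sample_interval else None,
        **kwargs,
    )


def simulate(
    config: SimulationConfig,
    seed: Optional[int] = None,
    t_end: Optional[float] = None,
    **kwargs: Any,
) -> SimResult:
    """Run a configured simulation to ``t_end`` (default from the config)."""
    sim = build_simulation(config, seed=seed, **kwargs)
    return sim.run(config.t_end if t_end is None else t_end)


def run_protoxylem(
    config: SimulationConfig,
    seed: Optional[int] = None,
    record_events: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, SimResult]:
    """Full protoxylem band-formation run.

    Returns (metrics time series, final snapshot frame, raw result). The
    config must define a scenario (prepattern + phase schedule).
    """
    if config.prepattern is None or config.schedule is None:
        raise ValueError("run_protoxylem requires a scenario (prepattern and schedule)")
    res = simulate(config, seed=seed, record_events=record_events)
    metrics = pd.DataFrame(res.metrics)
    snap = snapshot_frame(res.state)
    return metrics, snap, res
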