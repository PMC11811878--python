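"""Configuration loading, validation and round-tripping.

Configs are JSON (YAML accepted) with units embedded in key names (``_um``,
``_per_s``, ``_deg``) to prevent unit bugs. Time fields accept plain seconds
or strings with ``s``/``min``/``h`` suffixes. Measured dynamics quantities
(speeds and rates) are required fields: there are no silent defaults for
them.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Optional, Tuple, Union

import yaml

from .engine import DynamicsParams
from .flexibility import FlexibilityParams
from .geometry import CylinderDomain
from .nucleation import NucleationParams
from .prepattern import PhaseSchedule, Prepattern


class ConfigError(ValueError):
    """Raised with the full list of validation problems."""

    def __init__(self, problems: List[str]):
        self.problems = problems
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(problems))


_TIME_UNITS = {"s": 1.0, "sec": 1.0, "min": 60.0, "m": 60.0, "h": 3600.0, "hr": 3600.0}


def parse_time(value: Union[int, float, str], field_name: str = "") -> float:
    """Seconds from a number or a string like '90min' / '2h' / '30 s'."""
    if isinstance(value, (int, float)):
        return float(value)
    s = str(value).strip().lower()
    for suffix in sorted(_TIME_UNITS, key=len, reverse=True):
        if s.endswith(suffix):
            num = s[: -len(suffix)].strip()
            try:
                return float(num) * _TIME_UNITS[suffix]
            except ValueError:
                break
    try:
        return float(s)
    except ValueError:
        raise ValueError(f"cannot parse time value {value!r} for {field_name}") from None


@dataclass
class SimulationConfig:
    seed: int
    domain: CylinderDomain
    dynamics: DynamicsParams
    flexibility: FlexibilityParams
    nucleation: Optional[NucleationParams]
    prepattern: Optional[Prepattern]
    schedule: Optional[PhaseSchedule]
    sample_interval: Optional[float] = None
    t_end: float = 0.0

    def to_dict(self) -> Dict[str, Any]:
        d: Dict[str, Any] = {
            "seed": self.seed,
            "geometry": {
                "radius_um": self.domain.radius,
                "height_um": self.domain.height,
            },
            "dynamics": {
                "v_plus_um_s": self.dynamics.v_plus,
                "v_minus_um_s": self.dynamics.v_minus,
                "v_tm_um_s": self.dynamics.v_tm,
                "r_cat_per_s": self.dynamics.r_cat,
                "r_res_per_s": self.dynamics.r_res,
                "r_sever_per_s": self.dynamics.r_sever,
                "p_cat": self.dynamics.p_cat,
                "theta_bundle_deg": math.degrees(self.dynamics.theta_bundle),
                "edge_catastrophe": self.dynamics.edge_catastrophe,
            },
            "flexibility": {
                "persistence_length_um": (
                    "inf" if self.flexibility.rigid else self.flexibility.persistence_length
                ),
                "deflection_step_um": self.flexibility.deflection_step,
                "min_deflection_rad": self.flexibility.min_deflection,
                "bundle_tracking_deg": math.degrees(self.flexibility.bundle_tracking_angle),
            },
            "outputs": {"sample_interval_s": self.sample_interval, "t_end_s": self.t_end},
        }
        if self.nucleation is not None:
            n = self.nucleation
            d["nucleation"] = {
                "mode": n.mode,
                "r_app_per_s": n.r_app,
                "n_dir": n.n_dir,
                "D_um2_s": n.D,
                "r_u_per_s": n.r_u,
                "d_max_um": n.d_max,
                "p_acc_mt": n.p_acc_mt,
                "p_acc_free": n.p_acc_free,
                "pool_size": n.pool_size,
                "t_occ_s": n.t_occ,
                "branch_mix": list(n.branch_mix),
                "branch_mode_deg": math.degrees(n.theta_branch_mode),
                "branch_spread_deg": math.degrees(n.branch_spread),
                "r_iso_per_s": n.r_iso,
            }
        if self.prepattern is not None or self.schedule is not None:
            sc: Dict[str, Any] = {}
            if self.prepattern is not None:
                p = self.prepattern
                pitch = (
                    p.band_starts[1] - p.band_starts[0] if p.n_bands >= 2 else p.band_width
                )
                sc.update(
                    n_bands=p.n_bands,
                    band_width_um=p.band_width,
                    gap_width_um=pitch - p.band_width,
                    f_cat=p.f_cat,
                    t_band_s=p.t_band,
                )
            if self.schedule is not None:
                s = self.schedule
                sc.update(
                    t_bias_end_s=s.t_bias_end,
                    t_band_s=s.t_band,
                    t_end_s=s.t_end,
                    theta_bias_deg=math.degrees(s.theta_bias),
                    sigma_bias_deg=math.degrees(s.sigma_bias),
                )
            d["scenario"] = sc
        return d


_KNOWN_SECTIONS = {"seed", "geometry", "dynamics", "flexibility", "nucleation", "scenario", "outputs"}

_REQUIRED_DYNAMICS = [
    "v_plus_um_s", "v_minus_um_s", "v_tm_um_s", "r_cat_per_s", "r_res_per_s", "r_sever_per_s",
]


def config_from_dict(raw: Dict[str, Any]) -> SimulationConfig:
    """Build and validate a SimulationConfig; raises ConfigError listing all
    violations at once. Unknown keys produce warnings in the problem list
    prefixed with 'warning:' but do not fail validation."""
    problems: List[str] = []
    warnings_: List[str] = []
    for k in raw:
        if k not in _KNOWN_SECTIONS:
            warnings_.append(f"warning: unknown section {k!r} ignored")

    seed = int(raw.get("seed", 0))

    geo = raw.get("geometry", {})
    sc = raw.get("scenario", {})
    radius = geo.get("radius_um")
    if radius is None:
        problems.append("geometry.radius_um is required")
        radius = 1.0
    height = geo.get("height_um")

    prepattern = None
    schedule = None
    if sc:
        n_bands = int(sc.get("n_bands", 10))
        band_w = float(sc.get("band_width_um", 1.0))
        gap_w = float(sc.get("gap_width_um", 5.0))
        f_cat = float(sc.get("f_cat", 3.0))
        t_band = parse_time(sc.get("t_band_s", 7200.0), "scenario.t_band_s")
        try:
            prepattern = Prepattern.regular(n_bands, band_w, gap_w, f_cat, t_band)
        except ValueError as e:
            problems.append(f"scenario: {e}")
        t_end_default = parse_time(sc.get("t_end_s", 25200.0), "scenario.t_end_s")
        try:
            schedule = PhaseSchedule(
                t_bias_end=parse_time(sc.get("t_bias_end_s", 1800.0), "scenario.t_bias_end_s"),
                t_band=t_band,
                t_end=t_end_default,
                theta_bias=math.radians(float(sc.get("theta_bias_deg", 90.0))),
                sigma_bias=math.radians(float(sc.get("sigma_bias_deg", math.degrees(0.018)))),
            )
        except ValueError as e:
            problems.append(f"scenario: {e}")
        if height is None:
            height = n_bands * (band_w + gap_w)
    if height is None:
        problems.append("geometry.height_um is required (or derivable from scenario bands)")
        height = 1.0

    try:
        domain = CylinderDomain(radius=float(radius), height=float(height))
    except ValueError as e:
        problems.append(f"geometry: {e}")
        domain = CylinderDomain(1.0, 1.0)

    dyn_raw = raw.get("dynamics", {})
    missing = [k for k in _REQUIRED_DYNAMICS if k not in dyn_raw]
    for k in missing:
        problems.append(f"dynamics.{k} is required")
    dynamics = None
    if not missing:
        try:
            dynamics = DynamicsParams(
                v_plus=float(dyn_raw["v_plus_um_s"]),
                v_minus=float(dyn_raw["v_minus_um_s"]),
                v_tm=float(dyn_raw["v_tm_um_s"]),
                r_cat=float(dyn_raw["r_cat_per_s"]),
                r_res=float(dyn_raw["r_res_per_s"]),
                r_sever=float(dyn_raw["r_sever_per_s"]),
                p_cat=float(dyn_raw.get("p_cat", 0.09)),
                theta_bundle=math.radians(float(dyn_raw.get("theta_bundle_deg", 40.0))),
                edge_catastrophe=bool(dyn_raw.get("edge_catastrophe", True)),
            )
        except ValueError as e:
            problems.append(f"dynamics: {e}")

    flex_raw = raw.get("flexibility", {})
    lp = flex_raw.get("persistence_length_um", "inf")
    lp_val = math.inf if (isinstance(lp, str) and lp.lower() in ("inf", "infinity")) else float(lp)
    flexibility = None
    try:
        flexibility = FlexibilityParams(
            persistence_length=lp_val,
            deflection_step=float(flex_raw.get("deflection_step_um", 0.3)),
            min_deflection=float(flex_raw.get("min_deflection_rad", 1e-3)),
            bundle_tracking_angle=math.radians(float(flex_raw.get("bundle_tracking_deg", 10.0))),
        )
    except ValueError as e:
        problems.append(f"flexibility: {e}")

    nucleation = None
    nuc_raw = raw.get("nucleation")
    if nuc_raw is not None:
        try:
            nucleation = NucleationParams(
                mode=nuc_raw.get("mode", "local_density"),
                r_app=float(nuc_raw.get("r_app_per_s", 1.0)),
                n_dir=int(nuc_raw.get("n_dir", 24)),
                D=float(nuc_raw.get("D_um2_s", 0.013)),
                r_u=float(nuc_raw.get("r_u_per_s", 0.013)),
                d_max=float(nuc_raw.get("d_max_um", 10.0)),
                p_acc_mt=float(nuc_raw.get("p_acc_mt", 0.62)),
                p_acc_free=float(nuc_raw.get("p_acc_free", 0.02)),
                pool_size=int(nuc_raw.get("pool_size", 200)),
                t_occ=parse_time(nuc_raw.get("t_occ_s", 90.0), "nucleation.t_occ_s"),
                branch_mix=tuple(nuc_raw.get("branch_mix", (0.31, 0.07, 0.62))),
                theta_branch_mode=math.radians(float(nuc_raw.get("branch_mode_deg", 35.0))),
                branch_spread=math.radians(float(nuc_raw.get("branch_spread_deg", 15.0))),
                r_iso=float(nuc_raw.get("r_iso_per_s", 0.02)),
            )
        except ValueError as e:
            problems.append(f"nucleation: {e}")

    out_raw = raw.get("outputs", {})
    sample_interval = out_raw.get("sample_interval_s")
    if sample_interval is not None:
        sample_interval = parse_time(sample_interval, "outputs.sample_interval_s")
    t_end = out_raw.get("t_end_s")
    if t_end is None:
        t_end = schedule.t_end if schedule is not None else 0.0
    else:
        t_end = parse_time(t_end, "outputs.t_end_s")

    if problems:
        raise ConfigError(problems + warnings_)
    return SimulationConfig(
        seed=seed,
        domain=domain,
        dynamics=dynamics,
        flexibility=flexibility,
        nucleation=nucleation,
        prepattern=prepattern,
        schedule=schedule,
        sample_interval=sample_interval,
        t_end=float(t_end),
    )


def load_config(path: Union[str, Path]) -> SimulationConfig:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    if not isinstance(raw, dict):
        raise ConfigError(["top-level config must be a mapping"])
    return config_from_dict(raw)


def write_config(config: SimulationConfig, path: Union[str, Path]) -> None:
    path = Path(path)
    d = config.to_dict()
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(d, sort_keys=False))
    else:
        path.write_text(json.dumps(d, indent=2))
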