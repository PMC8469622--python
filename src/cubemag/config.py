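"""Run configuration and the reproducible pipeline driver.

A :class:`RunConfig` (YAML-serializable, strictly validated — unknown keys
are rejected) fully determines a run together with its seed; ``run_pipeline``
executes the requested stages and writes a manifest recording versions,
seeds, the numerical defaults actually used, and SHA-256 checksums of every
output file.
"""

from __future__ import annotations

import hashlib
import json
import platform
import time
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .geometry import AssemblySpec, NanocubeShape, build_assembly, \
    build_truncated_cube, ds_for_size
from .hysteresis import FieldSweepProtocol, run_loop
from .io import properties_json, write_ovf
from .materials import magnetite
from .thermal import AmbientLaw, HeatSources, ThermalScene, fit_slp, \
    q_mnps, solve_heat

__all__ = ["RunConfig", "run_pipeline"]

_DIRECTIONS = {"100": (1, 0, 0), "110": (1, 1, 0), "111": (1, 1, 1)}


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryConfig(_Strict):
    l_nm: float = 20.0
    ds_nm: float | None = None
    assembly: str = "single"  # single | cluster | chain
    n: int | None = None
    d_gap_nm: float = 6.0


class MaterialConfig(_Strict):
    Ms_kA_per_m: float = 410.0
    k_ex_pJ_per_m: float = 12.0
    K1_kJ_per_m3: float = -13.5
    K2_kJ_per_m3: float = -4.4
    alpha: float = 0.1


class ProtocolConfig(_Strict):
    direction: str = "100"  # "100" | "110" | "111" or "x,y,z"
    H_max_kA_per_m: float = 200.0
    coarse_step_kA_per_m: float = 4.0
    fine_step_kA_per_m: float = 0.5
    tilt_deg: float = 1.0
    method: str = "minimize"
    torque_tol: float = 1e-4
    half_loop: bool = False

    def direction_vector(self):
        if self.direction in _DIRECTIONS:
            return _DIRECTIONS[self.direction]
        return tuple(float(x) for x in self.direction.split(","))


class ThermalConfig(_Strict):
    slp_W_per_g: float = 120.0
    m_mnps_mg: float = 5.43
    v_water_ml: float | None = None  # default: the scene's suspension volume
    Q_ext_kW_per_m3: float = 45.0
    t_heat_min: float = 65.0
    t_cool_min: float = 60.0
    dt_s: float = 5.0
    h_conv: float = 25.0
    suspension: str = "sample3"
    ambient_T0_C: float = 25.0
    ambient_rise_C: float = 9.0


class RunConfig(_Strict):
    """Full description of a reproducible run."""

    stages: list[str] = Field(default_factory=lambda: ["geometry", "loop"])
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    material: MaterialConfig = Field(default_factory=MaterialConfig)
    protocol: ProtocolConfig = Field(default_factory=ProtocolConfig)
    thermal: ThermalConfig = Field(default_factory=ThermalConfig)
    seed: int = 0
    outdir: str = "cubemag_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh) or {})

    def to_yaml(self, path=None) -> str:
        s = yaml.safe_dump(self.model_dump(), sort_keys=False)
        if path is not None:
            Path(path).write_text(s)
        return s


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _material(cfg: MaterialConfig):
    return magnetite(Ms=cfg.Ms_kA_per_m * 1e3, k_ex=cfg.k_ex_pJ_per_m * 1e-12,
                     K1=cfg.K1_kJ_per_m3 * 1e3, K2=cfg.K2_kJ_per_m3 * 1e3,
                     alpha=cfg.alpha)


def _geometry(cfg: GeometryConfig):
    ds = cfg.ds_nm if cfg.ds_nm is not None else ds_for_size(cfg.l_nm)
    if cfg.assembly == "single":
        return build_truncated_cube(cfg.l_nm, ds)
    spec = AssemblySpec(kind=cfg.assembly, n=cfg.n, d_gap=cfg.d_gap_nm)
    return build_assembly(NanocubeShape(cfg.l_nm), spec, ds)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; return (and write) the run manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "cubemag_version": __version__,
        "numpy_version": np.__version__,
        "python_version": platform.python_version(),
        "seed": config.seed,
        "config": config.model_dump(),
        "stages": {},
        "outputs": {},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    geom = None
    try:
        for stage in config.stages:
            if stage == "geometry":
                geom = _geometry(config.geometry)
                p = out / "geometry.json"
                p.write_text(geom.to_json())
                manifest["stages"]["geometry"] = geom.meta()
                manifest["outputs"]["geometry.json"] = None
            elif stage == "loop":
                if geom is None:
                    geom = _geometry(config.geometry)
                proto = FieldSweepProtocol(
                    direction=config.protocol.direction_vector(),
                    H_max=config.protocol.H_max_kA_per_m * 1e3,
                    coarse_step=config.protocol.coarse_step_kA_per_m * 1e3,
                    fine_step=config.protocol.fine_step_kA_per_m * 1e3,
                    tilt_deg=config.protocol.tilt_deg,
                    method=config.protocol.method,
                    torque_tol=config.protocol.torque_tol,
                    half_loop=config.protocol.half_loop,
                )
                mat = _material(config.material)
                loop = run_loop(geom, mat, proto)
                loop.to_csv(out / "loop.csv")
                props = loop.properties
                properties_json(props, meta=loop.meta, path=out / "properties.json")
                for name, m in loop.snapshots.items():
                    write_ovf(out / f"snapshot_{name}.ovf", m, geom,
                              title=f"{name} state")
                    manifest["outputs"][f"snapshot_{name}.ovf"] = None
                if loop.energy_trace is not None:
                    loop.energy_trace.to_csv(out / "energy_trace.csv", index=False)
                    manifest["outputs"]["energy_trace.csv"] = None
                manifest["stages"]["loop"] = {
                    **props.as_dict_pretty(),
                    "defaults_used": {
                        "coarse_step_A_per_m": proto.coarse_step,
                        "fine_step_A_per_m": proto.fine_step,
                        "torque_tol": proto.torque_tol,
                        "tilt_deg": proto.tilt_deg,
                        "ds_nm": geom.ds,
                        "method": proto.method,
                    },
                }
                manifest["outputs"]["loop.csv"] = None
                manifest["outputs"]["properties.json"] = None
            elif stage == "thermal":
                tc = config.thermal
                scene = ThermalScene(suspension=tc.suspension, h_conv=tc.h_conv)
                v_ml = (tc.v_water_ml if tc.v_water_ml is not None
                        else scene.suspension_volume_ml)
                Q = q_mnps(tc.slp_W_per_g, tc.m_mnps_mg, v_ml) * 1e3
                src = HeatSources(Q_mnps=Q, Q_ext=tc.Q_ext_kW_per_m3 * 1e3,
                                  t_off=tc.t_heat_min * 60.0)
                amb = AmbientLaw(T0=tc.ambient_T0_C, A_rise=tc.ambient_rise_C,
                                 t_switch=tc.t_heat_min * 60.0)
                t = np.arange(0.0, (tc.t_heat_min + tc.t_cool_min) * 60.0 + 1,
                              tc.dt_s)
                traces = solve_heat(scene, src, t, T_ext=amb)
                traces["P4"].to_csv(out / "trace.csv")
                manifest["outputs"]["trace.csv"] = None
                from .thermal import effective_capacity

                res = fit_slp(traces["P4"], effective_capacity(scene),
                              tc.m_mnps_mg, v_ml,
                              Q_ext=tc.Q_ext_kW_per_m3 * 1e3, T_env=amb)
                (out / "slp.json").write_text(json.dumps({
                    "SLP_W_per_g": res.slp,
                    "CI": list(res.conf_int()),
                    "Q_MNPs_kW_per_m3": Q / 1e3,
                }, indent=2))
                manifest["outputs"]["slp.json"] = None
                manifest["stages"]["thermal"] = {"SLP_W_per_g": res.slp,
                                                 "Q_MNPs_kW_per_m3": Q / 1e3}
            else:
                raise ValueError(f"unknown stage {stage!r}")
    except Exception as exc:
        manifest["error"] = {"stage": stage, "message": str(exc)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    for name in list(manifest["outputs"]):
        manifest["outputs"][name] = _sha256(out / name)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
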