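"""Run configuration: unit-suffixed YAML in, validated SI objects out.

Every quantity in the config file carries an explicit unit suffix
(`length_mm`, `diameter_um`, `oxygen_mmHg`, `glucose_low_mM`, ...) and is
converted to SI on load; unknown keys are rejected with the offending key
name.  An empty config file yields the full default setup: the 12 x 4 mm
chamber with two free islets of 100 and 150 um diameter, atmospheric-
equilibrated inflow (140 mmHg), and the calibrated kinetics.

Named fixtures provide ready-made configurations for the standard in-silico
experiments (glucose staircase, single step, oxygen sweep, encapsulation
comparison, single-islet radial model).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .flow import FlowParams, solve_steady_flow
from .geometry import ChamberSpec, IsletSpec, build_chamber, mesh_geometry, radial_grid
from .kinetics import HillParams, KineticsConfig, po2_to_conc
from .transport import DiffusionSet, Protocol, SimulationResult, TransportSystem

__all__ = [
    "SolverOptions", "RadialSpec", "RunConfig", "ConfigError",
    "load_config", "make_fixture", "FIXTURE_NAMES", "write_timeseries",
    "default_two_islet_chamber",
]

TIMESERIES_COLUMNS = ["time_s", "gluc_in_mM", "pO2_in_mmHg",
                      "insulin_outflux_mol_per_s", "insulin_out_conc_mM"]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SolverOptions:
    resolution: float = 150e-6     # target lumen element size [m]
    dt_max: float = 0.5            # maximum transient step [s]
    seed: int = 0                  # mesh-jitter / multistart seed
    navier_stokes: bool = False    # default steady Stokes (Re << 1)
    steady_tol: float = 1e-10


@dataclass(frozen=True)
class RadialSpec:
    """Reduced 1D spherically-symmetric model of a single islet."""

    islet_diameter: float = 150e-6
    medium_shell: float = 300e-6
    capsule: float | None = None
    n_nodes: int = 120


@dataclass(frozen=True)
class RunConfig:
    kinetics: KineticsConfig = field(default_factory=KineticsConfig)
    diffusion: DiffusionSet = field(default_factory=DiffusionSet)
    chamber: ChamberSpec = field(default_factory=lambda: default_two_islet_chamber())
    flow: FlowParams = field(default_factory=FlowParams)
    protocol: Protocol = field(default_factory=Protocol)
    solver: SolverOptions = field(default_factory=SolverOptions)
    radial: RadialSpec | None = None
    sweep_po2_mmHg: tuple[float, ...] = ()
    compare_po2_mmHg: tuple[float, ...] = ()
    snapshot_times: tuple[float, ...] = ()

    def build(self):
        """Mesh the chamber, solve the flow once, and assemble the transport system."""
        geom = build_chamber(self.chamber)
        mesh = mesh_geometry(geom, resolution=self.solver.resolution, seed=self.solver.seed)
        vel = solve_steady_flow(mesh, self.flow, navier_stokes=self.solver.navier_stokes)
        return TransportSystem(mesh, vel, self.kinetics, self.diffusion)

    def build_radial(self):
        if self.radial is None:
            raise ConfigError("config has no radial section")
        r = self.radial
        return radial_grid(r.islet_diameter, r.medium_shell, r.capsule, r.n_nodes)


def default_two_islet_chamber(encapsulated: bool = False,
                              length: float = 12e-3, height: float = 4e-3) -> ChamberSpec:
    """Two representative islets (d = 100 and 150 um), 1 mm apart along the flow.

    The islets are staggered across the channel (±0.4 mm off the midline) so
    the downstream islet does not sit in the upstream islet's oxygen-depletion
    wake: the two are meant to represent independent size classes, and a
    coaxial placement would make the oxygen response depend on an arbitrary
    alignment accident.
    """
    x0 = length / 2.0 - 0.5e-3
    return ChamberSpec(length=length, height=height, islets=(
        IsletSpec(center=(x0, height / 2.0 - 0.4e-3), diameter=100e-6,
                  encapsulated=encapsulated),
        IsletSpec(center=(x0 + 1e-3, height / 2.0 + 0.4e-3), diameter=150e-6,
                  encapsulated=encapsulated),
    ))


# ---------------------------------------------------------------------------
# YAML loading with unit suffixes

_UNIT_FACTORS = {
    "m": 1.0, "mm": 1e-3, "um": 1e-6,
    "s": 1.0, "min": 60.0,
    "mM": 1.0, "uM": 1e-3, "mol_m3": 1.0,
    "m_s": 1.0, "um_s": 1e-6, "mm_min": 1e-3 / 60.0,
    "per_s": 1.0, "mM_s": 1.0,
    "Pa_s": 1.0, "mPa_s": 1e-3, "kg_m3": 1.0,
    "m2_s": 1.0,
}


def _take(d: dict, section: str, key_unit: str, default):
    """Pop `name_unit` from d and convert; name is key_unit minus its unit suffix."""
    for suffix, factor in sorted(_UNIT_FACTORS.items(), key=lambda kv: -len(kv[0])):
        key = f"{key_unit}_{suffix}"
        if key in d:
            v = d.pop(key)
            if not isinstance(v, (int, float)):
                raise ConfigError(f"{section}.{key}: expected a number, got {v!r}")
            return float(v) * factor
    return default


def _reject_unknown(d: dict, section: str):
    if d:
        key = next(iter(d))
        raise ConfigError(f"unknown key '{key}' in section '{section}'")


def _parse_islet(d: dict, i: int) -> IsletSpec:
    d = dict(d)
    x = _take(d, f"chamber.islets[{i}]", "x", None)
    y = _take(d, f"chamber.islets[{i}]", "y", None)
    dia = _take(d, f"chamber.islets[{i}]", "diameter", None)
    if x is None or y is None or dia is None:
        raise ConfigError(f"chamber.islets[{i}]: x, y and diameter (with unit suffix, "
                          "e.g. diameter_um) are required")
    if dia <= 0:
        raise ConfigError(f"chamber.islets[{i}].diameter must be > 0")
    enc = bool(d.pop("encapsulated", False))
    thick = _take(d, f"chamber.islets[{i}]", "capsule_thickness", 150e-6)
    _reject_unknown(d, f"chamber.islets[{i}]")
    return IsletSpec(center=(x, y), diameter=dia, encapsulated=enc, capsule_thickness=thick)


def _parse_chamber(d: dict) -> ChamberSpec:
    d = dict(d)
    length = _take(d, "chamber", "length", 12e-3)
    height = _take(d, "chamber", "height", 4e-3)
    islets_raw = d.pop("islets", None)
    _reject_unknown(d, "chamber")
    if islets_raw is None:
        base = default_two_islet_chamber(length=length, height=height)
        return base
    islets = tuple(_parse_islet(it, i) for i, it in enumerate(islets_raw))
    return ChamberSpec(length=length, height=height, islets=islets)


def _parse_protocol(d: dict, kin: KineticsConfig) -> Protocol:
    d = dict(d)
    c_low = _take(d, "protocol", "glucose_low", 1.0)
    tau = _take(d, "protocol", "tau", 30.0)
    duration = _take(d, "protocol", "duration", 3600.0)
    po2 = d.pop("oxygen_mmHg", 140.0)
    steps_raw = d.pop("steps", [])
    _reject_unknown(d, "protocol")
    steps = []
    for i, s in enumerate(list(steps_raw)):
        s = dict(s)
        t = _take(s, f"protocol.steps[{i}]", "t", None)
        dc = _take(s, f"protocol.steps[{i}]", "delta", None)
        if t is None or dc is None:
            raise ConfigError(f"protocol.steps[{i}]: t and delta (with unit suffix) required")
        _reject_unknown(s, f"protocol.steps[{i}]")
        steps.append((t, dc))
    return Protocol(c_low=c_low, steps=tuple(steps), tau=tau,
                    c_oxy_in=float(po2_to_conc(po2, kin)), duration=duration)


def _parse_flow(d: dict) -> FlowParams:
    d = dict(d)
    rho = _take(d, "flow", "density", 993.0)
    eta = _take(d, "flow", "viscosity", 0.7e-3)
    vin = _take(d, "flow", "inflow_speed", 1e-4)
    _reject_unknown(d, "flow")
    return FlowParams(density=rho, viscosity=eta, v_in=vin)


def _parse_solver(d: dict) -> SolverOptions:
    d = dict(d)
    res = _take(d, "solver", "resolution", 150e-6)
    dtm = _take(d, "solver", "dt_max", 0.5)
    seed = int(d.pop("seed", 0))
    ns = bool(d.pop("navier_stokes", False))
    _reject_unknown(d, "solver")
    return SolverOptions(resolution=res, dt_max=dtm, seed=seed, navier_stokes=ns)


def _parse_hill(d: dict, section: str, base: HillParams) -> HillParams:
    d = dict(d)
    r = _take(d, section, "r_max", base.r_max)
    ch = _take(d, section, "c_half", base.c_half)
    n = float(d.pop("n", base.n))
    _reject_unknown(d, section)
    return HillParams(r_max=r, c_half=ch, n=n)


def _parse_kinetics(d: dict) -> KineticsConfig:
    d = dict(d)
    base = KineticsConfig()
    kw = {}
    for name in ("oxy_consumption", "gluc_consumption", "ins_phase2",
                 "ins_phase1", "ins_oxy_mod"):
        if name in d:
            kw[name] = _parse_hill(d.pop(name), f"kinetics.{name}", getattr(base, name))
    for plain in ("phi_base", "phi_metab", "phi_scale"):
        if plain in d:
            kw[plain] = float(d.pop(plain))
    kw["c_crit_oxy"] = _take(d, "kinetics", "c_crit_oxy", base.c_crit_oxy)
    kw["step_scale"] = _take(d, "kinetics", "step_scale", base.step_scale)
    kw["k_insL"] = _take(d, "kinetics", "k_insL", base.k_insL)
    kw["c_mid_sigma"] = _take(d, "kinetics", "c_mid_sigma", base.c_mid_sigma)
    kw["sigma_slope"] = float(d.pop("sigma_slope", base.sigma_slope))
    _reject_unknown(d, "kinetics")
    return replace(base, **kw)


def _parse_diffusion(d: dict) -> DiffusionSet:
    d = dict(d)
    base = DiffusionSet()
    kw = {}
    for sp in ("oxy", "gluc", "ins"):
        if sp in d:
            s = dict(d.pop(sp))
            w, t, c = getattr(base, sp)
            w = _take(s, f"diffusion.{sp}", "water", w)
            t = _take(s, f"diffusion.{sp}", "tissue", t)
            c = _take(s, f"diffusion.{sp}", "capsule", c)
            _reject_unknown(s, f"diffusion.{sp}")
            kw[sp] = (w, t, c)
    if "insL_m2_s" in d:
        kw["insL"] = float(d.pop("insL_m2_s"))
    _reject_unknown(d, "diffusion")
    return replace(base, **kw)


def _parse_radial(d: dict) -> RadialSpec:
    d = dict(d)
    dia = _take(d, "radial", "islet_diameter", 150e-6)
    shell = _take(d, "radial", "medium_shell", 300e-6)
    cap = _take(d, "radial", "capsule", None)
    n = int(d.pop("n_nodes", 120))
    _reject_unknown(d, "radial")
    return RadialSpec(islet_diameter=dia, medium_shell=shell, capsule=cap, n_nodes=n)


def _parse_output(d: dict) -> tuple[float, ...]:
    d = dict(d)
    if "snapshot_times_s" in d:
        times = tuple(float(t) for t in d.pop("snapshot_times_s"))
    elif "snapshot_times_min" in d:
        times = tuple(60.0 * float(t) for t in d.pop("snapshot_times_min"))
    else:
        times = ()
    _reject_unknown(d, "output")
    return times


def config_from_dict(raw: dict | None) -> RunConfig:
    raw = dict(raw or {})
    kin = _parse_kinetics(raw.pop("kinetics", {}))
    cfg = RunConfig(
        kinetics=kin,
        diffusion=_parse_diffusion(raw.pop("diffusion", {})),
        chamber=_parse_chamber(raw.pop("chamber", {})),
        flow=_parse_flow(raw.pop("flow", {})),
        protocol=_parse_protocol(raw.pop("protocol", {}), kin),
        solver=_parse_solver(raw.pop("solver", {})),
        radial=_parse_radial(raw.pop("radial")) if "radial" in raw else None,
        sweep_po2_mmHg=tuple(float(p) for p in raw.pop("sweep_po2_mmHg", ())),
        compare_po2_mmHg=tuple(float(p) for p in raw.pop("compare_po2_mmHg", ())),
        snapshot_times=_parse_output(raw.pop("output", {})),
    )
    _reject_unknown(raw, "<top level>")
    cfg.chamber.validate()
    return cfg


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration; empty file -> full defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is not None and not isinstance(raw, dict):
        raise ConfigError("config file must contain a YAML mapping")
    return config_from_dict(raw)


# ---------------------------------------------------------------------------
# fixtures

def _staircase_protocol(kin: KineticsConfig, po2: float = 140.0,
                        plateau: float = 1800.0) -> Protocol:
    """G1 -> G3 -> G5 -> G7 -> G10 -> G15 -> G30 staircase with fixed plateaus."""
    levels = [1.0, 3.0, 5.0, 7.0, 10.0, 15.0, 30.0]
    steps = tuple((plateau * (i + 1), levels[i + 1] - levels[i])
                  for i in range(len(levels) - 1))
    return Protocol(c_low=levels[0], steps=steps, tau=30.0,
                    c_oxy_in=float(po2_to_conc(po2, kin)),
                    duration=plateau * len(levels))


def make_fixture(name: str) -> RunConfig:
    """Named preset configurations for the standard in-silico experiments."""
    kin = KineticsConfig()
    if name == "fig4_staircase":
        return RunConfig(protocol=_staircase_protocol(kin))
    if name == "fig5_step":
        return RunConfig(protocol=Protocol(
            c_low=1.0, steps=((1200.0, 14.0), (3600.0, -14.0)), tau=30.0,
            c_oxy_in=0.200, duration=5400.0))
    if name == "fig6_sweep":
        return RunConfig(
            protocol=Protocol(c_low=15.0, steps=(), c_oxy_in=0.200, duration=600.0),
            sweep_po2_mmHg=(140.0, 100.0, 80.0, 60.0, 50.0, 40.0, 30.0, 25.0,
                            20.0, 15.0, 10.0, 5.0))
    if name == "fig11_encapsulation":
        return RunConfig(chamber=default_two_islet_chamber(encapsulated=True),
                         protocol=_staircase_protocol(kin),
                         compare_po2_mmHg=(140.0, 45.0))
    if name == "single_islet_radial":
        return RunConfig(radial=RadialSpec(islet_diameter=150e-6))
    raise ConfigError(f"unknown fixture '{name}'; available: {', '.join(FIXTURE_NAMES)}")


FIXTURE_NAMES = ("fig4_staircase", "fig5_step", "fig6_sweep",
                 "fig11_encapsulation", "single_islet_radial")


# ---------------------------------------------------------------------------
# time-series output

def write_timeseries(result: SimulationResult, path) -> None:
    """Write the outflow trace CSV with the fixed column schema (bit-stable)."""
    q = result.outflow_rate
    conc = result.outflow_flux / q if q > 0 else np.zeros_like(result.outflow_flux)
    df = pd.DataFrame({
        "time_s": result.t,
        "gluc_in_mM": result.gluc_in,
        "pO2_in_mmHg": np.full_like(result.t, result.oxy_in_mmHg),
        "insulin_outflux_mol_per_s": result.outflow_flux,
        "insulin_out_conc_mM": conc,
    })
    df.to_csv(path, index=False, float_format="%.12e")


def read_timeseries(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if list(df.columns) != TIMESERIES_COLUMNS:
        raise ConfigError(f"unexpected time-series columns in {path}")
    return df
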