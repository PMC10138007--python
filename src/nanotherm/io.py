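"""Configuration files, result tables, VTK export and run manifests.

The configuration dialect is TOML with sections ``[domain]``, ``[[tumors]]``,
``[tissue.healthy]``/``[tissue.tumor]``, ``[treatment]`` and the optional
``[solver]`` and ``[optimizer]``; all quantities are SI (metres, seconds,
W/m³, °C). Omitted tissue/treatment keys fall back to the standard values;
unknown keys are rejected by name.

Temperature fields are exported as legacy ASCII VTK ``STRUCTURED_POINTS``
files (point scalars ``temperature_C`` and ``tissue_mask``), loadable in
ParaView and diffable in tests. Optimization tables are CSV with per-column
``Mean``/``SD`` footer rows.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .damage import DamageReport
from .optimizer import DESettings, OptimizationResult
from .scenario import (
    ConfigError,
    Domain,
    ScenarioConfig,
    TissueParameters,
    TreatmentSettings,
    TumorSphere,
    HEALTHY_TISSUE,
    TUMOR_TISSUE,
)
from .solver import SolverSettings, TemperatureField
from .scenario import Scenario

__all__ = [
    "read_config",
    "write_config",
    "config_to_dict",
    "write_vtk",
    "read_vtk",
    "write_results_csv",
    "write_damage_json",
    "RunManifest",
    "write_manifest",
]

_TISSUE_KEYS = ("k", "omega_b", "rho", "rho_b", "Q_m", "c", "c_b")
_TREATMENT_KEYS = ("A", "r0", "Np", "t_end", "ht", "T_a", "T_init", "T_damage")
_SOLVER_KEYS = ("ht", "t_end", "snapshot_stride", "engine", "check_monotone", "force")
_OPTIMIZER_KEYS = (
    "pop_multiplier",
    "F",
    "C",
    "atol",
    "tol",
    "max_generations",
    "seed",
    "force_crossover",
)


def _check_keys(section: dict, allowed: Sequence[str], where: str) -> None:
    unknown = set(section) - set(allowed)
    if unknown:
        raise ConfigError(f"unknown key(s) in [{where}]: {', '.join(sorted(unknown))}")


def _tissue_from(section: dict, base: TissueParameters, where: str) -> TissueParameters:
    _check_keys(section, _TISSUE_KEYS, where)
    kwargs = {k: float(section.get(k, getattr(base, k))) for k in _TISSUE_KEYS}
    return TissueParameters(**kwargs)


def read_config(path) -> tuple[ScenarioConfig, SolverSettings, DESettings]:
    """Parse and validate a TOML scenario file.

    Returns the scenario configuration plus solver and optimizer settings
    (populated with documented defaults for any omitted optional key).
    """
    raw = tomllib.loads(Path(path).read_text())
    _check_keys(raw, ("domain", "tumors", "tissue", "treatment", "solver", "optimizer"), "top level")

    if "domain" not in raw:
        raise ConfigError("missing required section [domain]")
    dom = raw["domain"]
    _check_keys(dom, ("L", "N"), "domain")
    for key in ("L", "N"):
        if key not in dom:
            raise ConfigError(f"missing required key domain.{key}")
    domain = Domain(side_length=float(dom["L"]), intervals=int(dom["N"]))

    tumors = []
    for i, t in enumerate(raw.get("tumors", [])):
        _check_keys(t, ("center", "radius"), f"tumors[{i}]")
        if "center" not in t or "radius" not in t:
            raise ConfigError(f"tumors[{i}] requires both center and radius")
        tumors.append(TumorSphere(center=tuple(t["center"]), radius=float(t["radius"])))

    tissue = raw.get("tissue", {})
    _check_keys(tissue, ("healthy", "tumor"), "tissue")
    healthy = _tissue_from(tissue.get("healthy", {}), HEALTHY_TISSUE, "tissue.healthy")
    tumor = _tissue_from(tissue.get("tumor", {}), TUMOR_TISSUE, "tissue.tumor")

    treat = raw.get("treatment", {})
    _check_keys(treat, _TREATMENT_KEYS, "treatment")
    defaults = TreatmentSettings(Np=max(len(tumors), 1))
    tkw = {}
    for key in _TREATMENT_KEYS:
        val = treat.get(key, getattr(defaults, key))
        tkw[key] = int(val) if key == "Np" else float(val)
    treatment = TreatmentSettings(**tkw)

    config = ScenarioConfig(
        domain=domain, tumors=tuple(tumors), healthy=healthy, tumor=tumor, treatment=treatment
    )

    sol = raw.get("solver", {})
    _check_keys(sol, _SOLVER_KEYS, "solver")
    solver = SolverSettings(
        ht=float(sol["ht"]) if "ht" in sol else None,
        t_end=float(sol["t_end"]) if "t_end" in sol else None,
        snapshot_stride=int(sol["snapshot_stride"]) if "snapshot_stride" in sol else None,
        engine=str(sol.get("engine", "auto")),
        check_monotone=bool(sol.get("check_monotone", False)),
        force=bool(sol.get("force", False)),
    )

    opt = raw.get("optimizer", {})
    _check_keys(opt, _OPTIMIZER_KEYS, "optimizer")
    f_val = opt.get("F", (0.5, 1.0))
    de = DESettings(
        pop_multiplier=int(opt.get("pop_multiplier", 35)),
        F=tuple(f_val) if isinstance(f_val, (list, tuple)) else float(f_val),
        C=float(opt.get("C", 0.7)),
        atol=float(opt.get("atol", 0.0)),
        tol=float(opt.get("tol", 0.01)),
        max_generations=int(opt.get("max_generations", 10_000)),
        seed=int(opt["seed"]) if "seed" in opt else None,
        force_crossover=bool(opt.get("force_crossover", True)),
    )
    return config, solver, de


def _fmt(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if isinstance(v, float):
        return repr(float(v))
    if isinstance(v, (list, tuple, np.ndarray)):
        return "[" + ", ".join(_fmt(x) for x in v) + "]"
    return f'"{v}"'


def write_config(
    config: ScenarioConfig,
    path,
    solver: SolverSettings | None = None,
    de: DESettings | None = None,
) -> None:
    """Serialize a scenario configuration (and optional settings) to TOML."""
    lines = ["[domain]", f"L = {_fmt(config.domain.side_length)}", f"N = {config.domain.intervals}", ""]
    for s in config.tumors:
        lines += ["[[tumors]]", f"center = {_fmt(list(s.center))}", f"radius = {_fmt(s.radius)}", ""]
    for name, tp in (("healthy", config.healthy), ("tumor", config.tumor)):
        lines.append(f"[tissue.{name}]")
        lines += [f"{k} = {_fmt(getattr(tp, k))}" for k in _TISSUE_KEYS]
        lines.append("")
    lines.append("[treatment]")
    lines += [f"{k} = {_fmt(getattr(config.treatment, k))}" for k in _TREATMENT_KEYS]
    lines.append("")
    if solver is not None:
        lines.append("[solver]")
        for k in _SOLVER_KEYS:
            v = getattr(solver, k)
            if v is not None:
                lines.append(f"{k} = {_fmt(v)}")
        lines.append("")
    if de is not None:
        lines.append("[optimizer]")
        for k in _OPTIMIZER_KEYS:
            v = getattr(de, k)
            if v is not None:
                lines.append(f"{k} = {_fmt(v)}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def config_to_dict(config: ScenarioConfig) -> dict:
    """JSON-friendly snapshot of a scenario configuration."""
    return dataclasses.asdict(config)


def write_vtk(T: TemperatureField, scenario: Scenario, path) -> None:
    """Write a temperature field as legacy ASCII VTK STRUCTURED_POINTS.

    Point data: ``temperature_C`` (double) and ``tissue_mask`` (int,
    0 healthy / 1 tumor); origin (0,0,0), spacing (h,h,h).
    """
    if T.values.shape != scenario.domain.shape:
        raise ValueError("temperature field shape does not match scenario grid")
    n = scenario.domain.n_nodes
    h = scenario.domain.spacing
    # VTK point order: x fastest, z slowest
    temp = np.transpose(T.values, (2, 1, 0)).ravel()
    mask = np.transpose(scenario.tumor_mask.astype(np.int8), (2, 1, 0)).ravel()
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"nanotherm temperature field at t={T.time:g} s\n")
        fh.write("ASCII\nDATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {n} {n} {n}\n")
        fh.write("ORIGIN 0 0 0\n")
        fh.write(f"SPACING {h:.17g} {h:.17g} {h:.17g}\n")
        fh.write(f"POINT_DATA {n ** 3}\n")
        fh.write("SCALARS temperature_C double\nLOOKUP_TABLE default\n")
        fh.write("\n".join(f"{v:.17g}" for v in temp))
        fh.write("\nSCALARS tissue_mask int\nLOOKUP_TABLE default\n")
        fh.write("\n".join(str(int(v)) for v in mask))
        fh.write("\n")


def read_vtk(path) -> dict:
    """Read back a STRUCTURED_POINTS file written by :func:`write_vtk`.

    Returns a dict with ``dimensions``, ``origin``, ``spacing`` and one
    (nx, ny, nz)-shaped array per scalar field.
    """
    lines = Path(path).read_text().splitlines()
    if not lines[0].startswith("# vtk DataFile"):
        raise ValueError(f"{path} is not a legacy VTK file")
    dims = origin = spacing = None
    out: dict = {}
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if not parts:
            i += 1
            continue
        kw = parts[0]
        if kw == "DIMENSIONS":
            dims = tuple(int(p) for p in parts[1:4])
        elif kw == "ORIGIN":
            origin = tuple(float(p) for p in parts[1:4])
        elif kw == "SPACING":
            spacing = tuple(float(p) for p in parts[1:4])
        elif kw == "SCALARS":
            name, dtype = parts[1], parts[2]
            i += 2  # skip LOOKUP_TABLE line
            n_vals = dims[0] * dims[1] * dims[2]
            vals: list[float] = []
            while len(vals) < n_vals:
                vals.extend(float(v) for v in lines[i].split())
                i += 1
            arr = np.array(vals[:n_vals])
            if dtype in ("int", "long", "short", "char"):
                arr = arr.astype(np.int64)
            # undo the x-fastest flattening
            out[name] = arr.reshape(dims[::-1]).transpose(2, 1, 0)
            continue
        i += 1
    out["dimensions"] = dims
    out["origin"] = origin
    out["spacing"] = spacing
    return out


def write_results_csv(results: Sequence, path) -> pd.DataFrame:
    """Write an optimization (or damage) table with Mean/SD footer rows.

    For :class:`OptimizationResult` lists the columns are
    X1,Y1,Z1[,X2,Y2,Z2,...],O(p) — one row per run — mirroring the layout of
    the benchmark result tables; a mixed-Np list is an error. For
    :class:`DamageReport` lists the columns are the damage metrics.
    Returns the full DataFrame including the footer.
    """
    if len(results) == 0:
        raise ValueError("results list is empty")
    if isinstance(results[0], OptimizationResult):
        if not all(isinstance(r, OptimizationResult) for r in results):
            raise ValueError("results list mixes types")
        nparams = {r.best_vector.size for r in results}
        if len(nparams) > 1:
            raise ValueError(f"results list mixes Np (vector sizes {sorted(nparams)})")
        nparam = nparams.pop()
        cols = [f"{ax}{i + 1}" for i in range(nparam // 3) for ax in ("X", "Y", "Z")]
        if nparam % 3:
            cols = [f"x{i}" for i in range(nparam)]
        rows = [list(r.best_vector) + [r.best_objective] for r in results]
        cols = cols + ["O(p)"]
    elif isinstance(results[0], DamageReport):
        if not all(isinstance(r, DamageReport) for r in results):
            raise ValueError("results list mixes types")
        cols = ["Nt", "Nh", "beta", "O(p)"]
        rows = [
            [r.tumor_damage_pct, r.healthy_damage_pct, int(r.full_ablation), r.objective]
            for r in results
        ]
    else:
        raise TypeError(f"unsupported result type {type(results[0]).__name__}")

    df = pd.DataFrame(rows, columns=cols, index=pd.RangeIndex(1, len(rows) + 1))
    footer = pd.DataFrame(
        [df.mean(axis=0), df.std(axis=0, ddof=0)], index=["Mean", "SD"], columns=cols
    )
    full = pd.concat([df, footer])
    full.to_csv(path, index_label="Run")
    return full


def write_damage_json(report: DamageReport, path, extra: dict | None = None) -> None:
    payload = report.to_dict()
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


@dataclass
class RunManifest:
    """Provenance record: enough to re-run a result exactly."""

    command: str
    config: dict
    seeds: list[int] = field(default_factory=list)
    software_version: str = ""
    created: str = field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc).isoformat()
    )
    outputs: list[str] = field(default_factory=list)
    parameters: dict = field(default_factory=dict)


def write_manifest(manifest: RunManifest, path) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(manifest), indent=2) + "\n")
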