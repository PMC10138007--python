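"""Explicit finite-difference solver for the modified Pennes bioheat equation.

The tissue temperature T(x, t) obeys

    ρc ∂T/∂t = ∇·(k ∇T) + ω_b ρ_b c_b (T_a − T) + Q_m + Q_r

on the cubic domain with zero-flux (insulated) boundaries and uniform
initial temperature. Space is discretized with a node-centred 7-point
stencil whose face conductivities are harmonic means of the two adjacent
node values (flux-continuous across material interfaces), and time with the
explicit forward-Euler / central-space (FTCS) scheme, first order in time
and second order in space. Being explicit, the scheme carries a time-step
stability bound which ``simulate`` enforces by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import _kernels
from .sar import InjectionSet, sar_field
from .scenario import Scenario

__all__ = [
    "SolverError",
    "StabilityError",
    "TemperatureField",
    "SolverSettings",
    "face_conductivity",
    "stability_limit",
    "step",
    "simulate",
]


class SolverError(RuntimeError):
    """The time integration failed (non-finite values or broken invariant)."""


class StabilityError(ValueError):
    """Requested time step exceeds the explicit stability bound."""


@dataclass
class TemperatureField:
    """Node-centred temperature snapshot: (N+1)³ array in °C at a given time."""

    values: np.ndarray
    time: float = 0.0

    @classmethod
    def uniform(cls, scenario: Scenario, temperature: float | None = None) -> "TemperatureField":
        t0 = scenario.treatment.T_init if temperature is None else temperature
        return cls(np.full(scenario.domain.shape, float(t0)), time=0.0)


@dataclass
class SolverSettings:
    """Time-integration settings; ``None`` fields fall back to the scenario's
    treatment settings (ht, t_end)."""

    ht: float | None = None
    t_end: float | None = None
    snapshot_stride: int | None = None
    engine: str = "auto"
    check_monotone: bool = False
    force: bool = False


def face_conductivity(k1, k2):
    """Harmonic-mean conductivity at the midpoint between two nodes.

    Returns 2·k1·k2/(k1+k2); symmetric, bounded by min and max of its
    arguments, and flux-continuous across a material interface.
    Accepts scalars or arrays.
    """
    k1 = np.asarray(k1, dtype=float)
    k2 = np.asarray(k2, dtype=float)
    if np.any(k1 <= 0) or np.any(k2 <= 0):
        raise ValueError("conductivities must be strictly positive")
    out = 2.0 * k1 * k2 / (k1 + k2)
    return float(out) if out.ndim == 0 else out


def stability_limit(scenario: Scenario) -> float:
    """Largest stable explicit time step, seconds.

    Standard diffusion-plus-decay bound for the 3D 7-point stencil:
    ht_max = h²·ρc_min / (6·k_max + h²·(ω_b ρ_b c_b)_max).
    """
    h2 = scenario.domain.spacing ** 2
    k_max = float(scenario.k.max())
    perf_max = max(
        scenario.config.healthy.perfusion_coefficient,
        scenario.config.tumor.perfusion_coefficient,
    )
    rc_min = float(scenario.rho_c.min())
    return h2 * rc_min / (6.0 * k_max + h2 * perf_max)


def _pad_reflect(arr: np.ndarray) -> np.ndarray:
    # ghost layer = first interior layer (zero-flux mirror)
    return np.pad(arr, 1, mode="reflect")


def _tumor_boxes(mask: np.ndarray) -> np.ndarray:
    """Half-open padded-index boxes covering every node whose update differs
    from the homogeneous healthy stencil: the bounding boxes of the connected
    tumor regions, inflated by one node."""
    labels, n_lab = ndimage.label(mask)
    boxes = []
    n = mask.shape[0]
    for sl in ndimage.find_objects(labels):
        lo = [max(s.start - 1, 0) for s in sl]
        hi = [min(s.stop + 1, n) for s in sl]
        # +1 converts real-node indices to padded-array indices
        boxes.append([lo[0] + 1, hi[0] + 1, lo[1] + 1, hi[1] + 1, lo[2] + 1, hi[2] + 1])
    return np.array(boxes, dtype=np.int64).reshape(len(boxes), 6)


class _FastEngine:
    """Precomputed two-material stepper (healthy-bulk stencil + tumor boxes)."""

    def __init__(self, scenario: Scenario, qr: np.ndarray, ht: float):
        cfg = scenario.config
        healthy, tumor = cfg.healthy, cfg.tumor
        if not np.all(scenario.rho_c == scenario.rho_c.flat[0]):
            raise ValueError("fast engine requires spatially uniform ρc")
        rc = float(scenario.rho_c.flat[0])
        h2 = scenario.domain.spacing ** 2
        self.ht = ht
        self.Ta = cfg.treatment.T_a
        self.c1 = ht / (rc * h2)
        kH = healthy.k
        pcH = ht * healthy.perfusion_coefficient / rc
        self.a0 = 1.0 - 6.0 * self.c1 * kH - pcH
        self.ak = self.c1 * kH
        self.const = pcH * self.Ta + ht * healthy.Q_m / rc
        kh = np.empty((2, 2))
        kh[0, 0] = healthy.k
        kh[1, 1] = tumor.k
        kh[0, 1] = kh[1, 0] = face_conductivity(healthy.k, tumor.k)
        self.kh = kh
        self.pc = np.array(
            [pcH, ht * tumor.perfusion_coefficient / rc]
        )
        self.qm = np.array([ht * healthy.Q_m / rc, ht * tumor.Q_m / rc])
        self.mask_p = _pad_reflect(scenario.tumor_mask.astype(np.uint8))
        self.src_p = np.pad(ht * qr / rc, 1)
        self.boxes = _tumor_boxes(scenario.tumor_mask)

    def __call__(self, T_p: np.ndarray, Tn_p: np.ndarray) -> None:
        _kernels.mirror_ghosts(T_p)
        _kernels.step_uniform(T_p, Tn_p, self.src_p, self.a0, self.ak, self.const)
        if self.boxes.shape[0]:
            _kernels.step_boxes(
                T_p, Tn_p, self.mask_p, self.kh, self.pc, self.qm,
                self.src_p, self.c1, self.Ta, self.boxes,
            )


class _GeneralEngine:
    """Literal per-node-field stepper (reference path, arbitrary media)."""

    def __init__(self, scenario: Scenario, qr: np.ndarray, ht: float):
        self.ht = ht
        self.Ta = scenario.treatment.T_a
        self.h2 = scenario.domain.spacing ** 2
        self.k_p = _pad_reflect(scenario.k)
        self.rc_p = _pad_reflect(scenario.rho_c)
        self.perf_p = _pad_reflect(scenario.perfusion_field)
        self.q_p = _pad_reflect(scenario.Q_m + qr)

    def __call__(self, T_p: np.ndarray, Tn_p: np.ndarray) -> None:
        _kernels.mirror_ghosts(T_p)
        _kernels.step_general(
            T_p, Tn_p, self.k_p, self.rc_p, self.perf_p, self.q_p,
            self.ht, self.h2, self.Ta,
        )


def _make_engine(scenario: Scenario, qr: np.ndarray, ht: float, engine: str):
    if engine == "auto":
        rc_uniform = np.all(scenario.rho_c == scenario.rho_c.flat[0])
        engine = "fast" if (rc_uniform and scenario.two_material) else "general"
    if engine == "fast":
        return _FastEngine(scenario, qr, ht)
    if engine == "general":
        return _GeneralEngine(scenario, qr, ht)
    raise ValueError(f"unknown engine {engine!r}")


def step(
    T: TemperatureField,
    scenario: Scenario,
    qr: np.ndarray | None = None,
    ht: float | None = None,
    engine: str = "general",
) -> TemperatureField:
    """Advance one explicit time step and return the new field.

    Interior nodes follow the FTCS update with harmonic-mean face
    conductivities; boundary nodes use zero-flux mirroring in each missing
    direction. ``qr`` is the precomputed SAR field (zero if omitted).
    Intended for unit-level use; ``simulate`` runs full sessions.
    """
    if T.values.shape != scenario.domain.shape:
        raise ValueError("temperature field shape does not match scenario grid")
    ht = scenario.treatment.ht if ht is None else ht
    if ht < 0:
        raise ValueError("ht must be >= 0")
    if ht == 0.0:
        return TemperatureField(T.values.copy(), T.time)
    if qr is None:
        qr = np.zeros(scenario.domain.shape)
    eng = _make_engine(scenario, qr, ht, engine)
    T_p = _pad_reflect(T.values)
    Tn_p = T_p.copy()
    eng(T_p, Tn_p)
    out = Tn_p[1:-1, 1:-1, 1:-1].copy()
    if not np.isfinite(out).all():
        raise SolverError("non-finite temperature after step (unstable time step?)")
    return TemperatureField(out, T.time + ht)


def simulate(
    scenario: Scenario,
    injections: "InjectionSet | np.ndarray | None" = None,
    settings: SolverSettings | None = None,
    *,
    ht: float | None = None,
    t_end: float | None = None,
    snapshot_stride: int | None = None,
    engine: str = "auto",
    check_monotone: bool = False,
    force: bool = False,
):
    """Run a full treatment session and return the final temperature field.

    ``injections`` may be an :class:`InjectionSet`, an (Np, 3) array of
    points in metres, or ``None`` for a source-free baseline run. ``ht`` and
    ``t_end`` default to the scenario's treatment settings; the number of
    steps is ``round(t_end/ht)``. The explicit stability bound is enforced
    unless ``force=True``. With ``snapshot_stride`` set, returns
    ``(final, snapshots)`` where snapshots are taken every so many steps.

    ``check_monotone=True`` additionally verifies, at coarse intervals, that
    nodal temperatures never decrease — the expected behaviour when heating
    starts from a uniform temperature at or below every local equilibrium.
    """
    if settings is not None:
        ht = settings.ht if ht is None else ht
        t_end = settings.t_end if t_end is None else t_end
        snapshot_stride = settings.snapshot_stride if snapshot_stride is None else snapshot_stride
        engine = settings.engine if engine == "auto" else engine
        check_monotone = check_monotone or settings.check_monotone
        force = force or settings.force

    tr = scenario.treatment
    ht = tr.ht if ht is None else float(ht)
    t_end = tr.t_end if t_end is None else float(t_end)
    if ht <= 0 or t_end <= 0:
        raise ValueError("ht and t_end must be > 0")
    limit = stability_limit(scenario)
    if ht > limit and not force:
        raise StabilityError(
            f"ht={ht} s exceeds the explicit stability limit {limit:.6g} s; "
            "reduce ht or pass force=True"
        )
    n_steps = int(round(t_end / ht))

    if injections is None:
        qr = np.zeros(scenario.domain.shape)
    else:
        if not isinstance(injections, InjectionSet):
            injections = InjectionSet(np.asarray(injections, dtype=float))
        qr = sar_field(scenario.domain, injections, tr.A, tr.r0)

    eng = _make_engine(scenario, qr, ht, engine)

    T_p = np.full(tuple(s + 2 for s in scenario.domain.shape), float(tr.T_init))
    Tn_p = T_p.copy()
    snapshots: list[TemperatureField] = []
    monitor_stride = 500
    prev_monitor = T_p[1:-1, 1:-1, 1:-1].copy() if check_monotone else None

    for n in range(n_steps):
        eng(T_p, Tn_p)
        T_p, Tn_p = Tn_p, T_p
        done = n + 1
        if done % monitor_stride == 0 or done == n_steps:
            cur = T_p[1:-1, 1:-1, 1:-1]
            if not np.isfinite(cur).all() or np.abs(cur).max() > 1e6:
                raise SolverError(
                    f"diverging temperature at step {done} (t={done * ht:.3f} s); "
                    "the explicit scheme likely went unstable"
                )
            if prev_monitor is not None:
                if np.any(cur < prev_monitor - 1e-9):
                    raise SolverError(
                        f"nodal temperature decreased by step {done}; "
                        "monotone-heating invariant violated"
                    )
                prev_monitor = cur.copy()
        if snapshot_stride and (done % snapshot_stride == 0) and done != n_steps:
            snapshots.append(
                TemperatureField(T_p[1:-1, 1:-1, 1:-1].copy(), done * ht)
            )

    final = TemperatureField(T_p[1:-1, 1:-1, 1:-1].copy(), n_steps * ht)
    if snapshot_stride:
        snapshots.append(final)
        return final, snapshots
    return final
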