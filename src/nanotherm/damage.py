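"""Thermal-damage metrics and the treatment-planning objective.

A node counts as damaged when its final temperature reaches the ablation
threshold (43 °C by default, inclusive). Damage is quantified at the end of
the session only — no thermal-dose time integration — as the percentage of
tumor nodes damaged (Nt), the percentage of healthy nodes damaged (Nh), and
a full-ablation indicator β (1 iff every tumor node is damaged). The
objective to minimize is

    O(p) = 300 − Nt − (100 − Nh) − 100·β

which rewards tumor coverage, penalizes healthy damage, grants a bonus of
100 for complete ablation, and reduces exactly to the healthy-damage
percentage Nh whenever the tumor is fully ablated.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .scenario import Scenario
from .solver import TemperatureField, simulate

__all__ = ["DamageReport", "damage_fractions", "objective", "evaluate_injections"]


@dataclass(frozen=True)
class DamageReport:
    """Damage summary of one simulated treatment."""

    tumor_damage_pct: float  # Nt, % of tumor nodes at or above threshold
    healthy_damage_pct: float  # Nh, % of healthy nodes at or above threshold
    full_ablation: bool  # β = 1 iff the whole tumor reached the threshold
    objective: float  # O(p)

    def to_dict(self) -> dict:
        return asdict(self)


def damage_fractions(
    T: TemperatureField,
    scenario: Scenario,
    T_damage: float | None = None,
    allow_empty_tumor: bool = False,
) -> tuple[float, float, int]:
    """(Nt, Nh, β) damage percentages of a temperature field.

    Percentages are node counts within each mask; the threshold is
    inclusive (T ≥ T_damage counts as damaged).
    """
    thr = scenario.treatment.T_damage if T_damage is None else float(T_damage)
    if T.values.shape != scenario.tumor_mask.shape:
        raise ValueError("temperature field shape does not match scenario grid")
    hot = T.values >= thr
    tumor = scenario.tumor_mask
    n_tumor = int(tumor.sum())
    if n_tumor == 0:
        if not allow_empty_tumor:
            raise ValueError(
                "scenario has no tumor nodes; tumor damage is undefined "
                "(pass allow_empty_tumor=True for baseline fixtures)"
            )
        nt, beta = 0.0, 0
    else:
        hot_tumor = int((hot & tumor).sum())
        nt = 100.0 * hot_tumor / n_tumor
        beta = 1 if hot_tumor == n_tumor else 0
    n_healthy = hot.size - n_tumor
    nh = 100.0 * int((hot & ~tumor).sum()) / n_healthy
    return nt, nh, beta


def objective(nt: float, nh: float, beta: int) -> float:
    """Planning objective O = 300 − Nt − (100 − Nh) − 100·β (lower is better).

    Equals Nh exactly when Nt = 100 and β = 1; equals 200 + Nh when the
    tumor is untouched.
    """
    return 300.0 - nt - (100.0 - nh) - 100.0 * beta


def evaluate_injections(
    scenario: Scenario,
    points,
    T_damage: float | None = None,
    **simulate_kwargs,
) -> DamageReport:
    """Simulate a treatment with the given injection points and score it.

    ``points`` is an (Np, 3) array of injection coordinates in metres (or an
    :class:`~nanotherm.sar.InjectionSet`). Keyword arguments are forwarded
    to :func:`~nanotherm.solver.simulate` (e.g. ``ht``, ``t_end``,
    ``engine``). Deterministic for fixed inputs.
    """
    final = simulate(scenario, points, **simulate_kwargs)
    nt, nh, beta = damage_fractions(final, scenario, T_damage)
    return DamageReport(
        tumor_damage_pct=nt,
        healthy_damage_pct=nh,
        full_ablation=bool(beta),
        objective=objective(nt, nh, beta),
    )
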