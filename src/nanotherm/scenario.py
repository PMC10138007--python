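"""Simulation scenarios: cubic tissue domain, spherical tumors, tissue properties.

A scenario discretizes a cubic block of tissue of side ``L`` into a
node-centred grid of ``(N+1)**3`` points at coordinates ``i*h`` with
``h = L/N``, classifies each node as tumor or healthy by spherical
inclusion, and assembles per-node fields of the thermal/perfusion
parameters used by the bioheat solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ConfigError",
    "Domain",
    "TumorSphere",
    "TissueParameters",
    "TreatmentSettings",
    "ScenarioConfig",
    "Scenario",
    "HEALTHY_TISSUE",
    "TUMOR_TISSUE",
    "DEFAULT_TREATMENT",
    "build_scenario",
    "builtin_scenario",
    "naive_injection_points",
    "random_scenario",
]


class ConfigError(ValueError):
    """A scenario configuration failed validation. Message names the offending key."""


@dataclass(frozen=True)
class Domain:
    """Cubic domain [0, L]^3 discretized into N intervals per axis.

    Nodes sit at coordinates ``i*h`` for ``i = 0..N`` with ``h = L/N``,
    giving ``(N+1)**3`` grid points.
    """

    side_length: float  # L, metres
    intervals: int  # N, intervals per axis

    def __post_init__(self) -> None:
        if not self.side_length > 0:
            raise ConfigError(f"domain.L must be > 0, got {self.side_length}")
        if int(self.intervals) != self.intervals or self.intervals < 2:
            raise ConfigError(f"domain.N must be an integer >= 2, got {self.intervals}")
        object.__setattr__(self, "intervals", int(self.intervals))

    @property
    def spacing(self) -> float:
        """Grid spacing h = L/N in metres."""
        return self.side_length / self.intervals

    @property
    def n_nodes(self) -> int:
        """Nodes per axis, N+1."""
        return self.intervals + 1

    @property
    def shape(self) -> tuple[int, int, int]:
        n = self.n_nodes
        return (n, n, n)

    def node_coordinates(self) -> np.ndarray:
        """1-D array of the N+1 node coordinates along one axis, metres."""
        return np.arange(self.n_nodes) * self.spacing

    def contains(self, point: Sequence[float]) -> bool:
        p = np.asarray(point, dtype=float)
        return bool(np.all(p >= 0.0) and np.all(p <= self.side_length))


@dataclass(frozen=True)
class TumorSphere:
    """Spherical tumor region: centre (metres) and radius (metres)."""

    center: tuple[float, float, float]
    radius: float

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ConfigError(f"tumors.radius must be > 0, got {self.radius}")
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))
        if len(self.center) != 3:
            raise ConfigError("tumors.center must have 3 coordinates")

    def inside_domain(self, domain: Domain) -> bool:
        c = np.asarray(self.center)
        return bool(
            np.all(c - self.radius >= 0.0)
            and np.all(c + self.radius <= domain.side_length)
        )


@dataclass(frozen=True)
class TissueParameters:
    """Thermal and perfusion properties of one tissue type.

    k       thermal conductivity, W/(m °C)
    omega_b blood perfusion rate, 1/s
    rho     tissue density, kg/m³
    rho_b   blood density, kg/m³
    Q_m     metabolic heat generation, W/m³
    c       tissue specific heat, J/(kg °C)
    c_b     blood specific heat, J/(kg °C)
    """

    k: float
    omega_b: float
    rho: float
    rho_b: float
    Q_m: float
    c: float
    c_b: float

    def __post_init__(self) -> None:
        for name in ("k", "omega_b", "rho", "rho_b", "Q_m", "c", "c_b"):
            if not getattr(self, name) > 0:
                raise ConfigError(
                    f"tissue.{name} must be > 0, got {getattr(self, name)}"
                )

    @property
    def rho_c(self) -> float:
        """Volumetric heat capacity ρ·c, J/(m³ °C)."""
        return self.rho * self.c

    @property
    def perfusion_coefficient(self) -> float:
        """ω_b·ρ_b·c_b, the perfusion heat-sink coefficient, W/(m³ °C)."""
        return self.omega_b * self.rho_b * self.c_b

    @property
    def equilibrium_offset(self) -> float:
        """Steady uniform temperature excess over arterial blood, Q_m/(ω_b ρ_b c_b), °C."""
        return self.Q_m / self.perfusion_coefficient


@dataclass(frozen=True)
class TreatmentSettings:
    """Hyperthermia session settings.

    A         peak volumetric heating of one injection, W/m³
    r0        Gaussian radius of coverage of one injection, metres
    Np        number of injection points
    t_end     session duration, seconds
    ht        solver time step, seconds
    T_a       arterial blood temperature, °C
    T_init    initial tissue temperature, °C
    T_damage  ablation threshold temperature, °C
    """

    A: float = 0.08e6
    r0: float = 1.9e-2
    Np: int = 1
    t_end: float = 3000.0
    ht: float = 0.1
    T_a: float = 37.0
    T_init: float = 37.0
    T_damage: float = 43.0

    def __post_init__(self) -> None:
        if not self.A > 0:
            raise ConfigError(f"treatment.A must be > 0, got {self.A}")
        if not self.r0 > 0:
            raise ConfigError(f"treatment.r0 must be > 0, got {self.r0}")
        if self.Np < 1:
            raise ConfigError(f"treatment.Np must be >= 1, got {self.Np}")
        if not self.t_end > 0:
            raise ConfigError(f"treatment.t_end must be > 0, got {self.t_end}")
        if not self.ht > 0:
            raise ConfigError(f"treatment.ht must be > 0, got {self.ht}")
        if not self.T_damage > self.T_init:
            raise ConfigError(
                f"treatment.T_damage ({self.T_damage}) must exceed T_init ({self.T_init})"
            )


#: Healthy-tissue properties used in all built-in scenarios.
HEALTHY_TISSUE = TissueParameters(
    k=0.51, omega_b=5.0e-4, rho=1000.0, rho_b=1000.0, Q_m=420.0, c=4200.0, c_b=4200.0
)

#: Tumor-tissue properties used in all built-in scenarios.
TUMOR_TISSUE = TissueParameters(
    k=0.64, omega_b=1.25e-3, rho=1000.0, rho_b=1000.0, Q_m=4200.0, c=4200.0, c_b=4200.0
)

#: Default 50-minute session with ht = 0.1 s and a single injection.
DEFAULT_TREATMENT = TreatmentSettings()


@dataclass(frozen=True)
class ScenarioConfig:
    """Declarative description of a simulation scenario."""

    domain: Domain
    tumors: tuple[TumorSphere, ...]
    healthy: TissueParameters = HEALTHY_TISSUE
    tumor: TissueParameters = TUMOR_TISSUE
    treatment: TreatmentSettings = DEFAULT_TREATMENT

    def __post_init__(self) -> None:
        object.__setattr__(self, "tumors", tuple(self.tumors))
        for i, sphere in enumerate(self.tumors):
            if not sphere.inside_domain(self.domain):
                raise ConfigError(
                    f"tumors[{i}]: sphere centre {sphere.center} radius "
                    f"{sphere.radius} extends outside the domain [0, "
                    f"{self.domain.side_length}]^3"
                )

    def with_intervals(self, N: int) -> "ScenarioConfig":
        """Same scenario on a grid with N intervals per axis."""
        return replace(self, domain=Domain(self.domain.side_length, N))


@dataclass
class Scenario:
    """Discretized scenario: per-node property fields and tissue masks.

    Fields ``k``, ``omega_b``, ``Q_m`` and ``rho_c`` are ``(N+1)**3`` arrays
    holding the healthy or tumor value of the corresponding parameter at each
    node; ``tumor_mask`` is the boolean sphere-inclusion mask.
    """

    config: ScenarioConfig
    k: np.ndarray
    omega_b: np.ndarray
    Q_m: np.ndarray
    rho_c: np.ndarray
    tumor_mask: np.ndarray

    @property
    def domain(self) -> Domain:
        return self.config.domain

    @property
    def treatment(self) -> TreatmentSettings:
        return self.config.treatment

    @property
    def healthy_mask(self) -> np.ndarray:
        return ~self.tumor_mask

    @property
    def n_tumor_nodes(self) -> int:
        return int(self.tumor_mask.sum())

    @property
    def perfusion_field(self) -> np.ndarray:
        """ω_b·ρ_b·c_b per node, W/(m³ °C), from the per-node ω_b field."""
        h, t = self.config.healthy, self.config.tumor
        rbcb = np.where(self.tumor_mask, t.rho_b * t.c_b, h.rho_b * h.c_b)
        return self.omega_b * rbcb

    @property
    def two_material(self) -> bool:
        """True when every field is exactly the healthy/tumor pair on the mask."""
        h, t = self.config.healthy, self.config.tumor
        m = self.tumor_mask
        for arr, hv, tv in (
            (self.k, h.k, t.k),
            (self.omega_b, h.omega_b, t.omega_b),
            (self.Q_m, h.Q_m, t.Q_m),
            (self.rho_c, h.rho_c, t.rho_c),
        ):
            if not (np.all(arr[m] == tv) if m.any() else True):
                return False
            if not np.all(arr[~m] == hv):
                return False
        return True


def _sphere_mask(domain: Domain, spheres: Sequence[TumorSphere]) -> np.ndarray:
    """Boolean mask of nodes lying inside any sphere (inclusive boundary)."""
    coords = domain.node_coordinates()
    mask = np.zeros(domain.shape, dtype=bool)
    x = coords[:, None, None]
    y = coords[None, :, None]
    z = coords[None, None, :]
    for s in spheres:
        cx, cy, cz = s.center
        d2 = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2
        # tiny relative slack keeps exact surface ties inclusive under
        # floating-point rounding of the node coordinates
        mask |= d2 <= s.radius**2 * (1.0 + 1e-12)
    return mask


def build_scenario(config: ScenarioConfig) -> Scenario:
    """Discretize a configuration into per-node property fields and masks.

    A node belongs to the tumor iff it lies within (or exactly on the surface
    of) any tumor sphere; surface ties count as tumor, erring toward full
    tumor coverage.
    """
    domain = config.domain
    mask = _sphere_mask(domain, config.tumors)
    h, t = config.healthy, config.tumor

    def _field(hv: float, tv: float) -> np.ndarray:
        arr = np.full(domain.shape, hv, dtype=np.float64)
        arr[mask] = tv
        return arr

    return Scenario(
        config=config,
        k=_field(h.k, t.k),
        omega_b=_field(h.omega_b, t.omega_b),
        Q_m=_field(h.Q_m, t.Q_m),
        rho_c=_field(h.rho_c, t.rho_c),
        tumor_mask=mask,
    )


# Tumor centres of the three benchmark scenarios (metres).
_BUILTIN_CENTERS = {
    1: ((0.050, 0.050, 0.050),),
    2: ((0.040, 0.040, 0.040), (0.060, 0.060, 0.060)),
    3: ((0.045, 0.035, 0.040), (0.045, 0.055, 0.045), (0.065, 0.055, 0.060)),
}


def builtin_scenario(scenario_id: int, N: int = 128) -> ScenarioConfig:
    """One of the three benchmark scenarios.

    All three use a 0.1 m cube, tumor radius 0.01 m, a 50-minute session at
    ht = 0.1 s, and the standard tissue parameters. Scenario 1 has a single
    central tumor, scenario 2 two diagonal tumors, scenario 3 three tumors.
    ``Np`` defaults to one injection per tumor (the naive plan's count).
    """
    if scenario_id not in _BUILTIN_CENTERS:
        raise ConfigError(f"scenario id must be 1, 2 or 3, got {scenario_id}")
    centers = _BUILTIN_CENTERS[scenario_id]
    return ScenarioConfig(
        domain=Domain(side_length=0.1, intervals=N),
        tumors=tuple(TumorSphere(center=c, radius=0.01) for c in centers),
        healthy=HEALTHY_TISSUE,
        tumor=TUMOR_TISSUE,
        treatment=replace(DEFAULT_TREATMENT, Np=len(centers)),
    )


def naive_injection_points(config: ScenarioConfig) -> np.ndarray:
    """The naive plan: one injection at each tumor centre, shape (n_tumors, 3)."""
    return np.array([s.center for s in config.tumors], dtype=float)


def random_scenario(
    seed: int,
    n_tumors: int = 1,
    radius_range: tuple[float, float] = (0.005, 0.015),
    margin: float = 0.005,
    N: int = 32,
    L: float = 0.1,
    max_tries: int = 1000,
) -> ScenarioConfig:
    """Reproducible randomized scenario for testing.

    Draws ``n_tumors`` pairwise non-overlapping spheres with radii uniform in
    ``radius_range``, each kept at least ``margin`` away from the domain
    faces. Tissue and treatment parameters are the standard ones with
    ``Np = max(n_tumors, 1)``.
    """
    if n_tumors < 0:
        raise ConfigError(f"n_tumors must be >= 0, got {n_tumors}")
    lo_r, hi_r = radius_range
    if not 0 < lo_r <= hi_r:
        raise ConfigError(f"radius_range must satisfy 0 < lo <= hi, got {radius_range}")
    if hi_r + margin >= L / 2:
        raise ConfigError("radius_range and margin leave no room inside the domain")

    rng = np.random.default_rng(seed)
    spheres: list[TumorSphere] = []
    tries = 0
    while len(spheres) < n_tumors:
        if tries >= max_tries:
            raise ConfigError(
                f"could not place {n_tumors} disjoint spheres in {max_tries} tries"
            )
        tries += 1
        r = rng.uniform(lo_r, hi_r)
        lo, hi = r + margin, L - r - margin
        c = rng.uniform(lo, hi, size=3)
        if all(
            np.linalg.norm(c - np.asarray(s.center)) > r + s.radius for s in spheres
        ):
            spheres.append(TumorSphere(center=tuple(c), radius=r))

    return ScenarioConfig(
        domain=Domain(side_length=L, intervals=N),
        tumors=tuple(spheres),
        healthy=HEALTHY_TISSUE,
        tumor=TUMOR_TISSUE,
        treatment=replace(DEFAULT_TREATMENT, Np=max(n_tumors, 1)),
    )
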