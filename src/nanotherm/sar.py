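"""Specific absorption rate (SAR) of magnetic-nanoparticle injections.

Each injection deposits heat as an isotropic Gaussian of peak ``A`` (W/m³)
and radius of coverage ``r0`` (m) centred at the injection point; multiple
injections superpose:

    Q_r(x) = sum_i A * exp(-||x - x0_i||^2 / r0^2)

The field is time-independent: it is evaluated once per injection set and
held fixed for the whole session.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .scenario import Domain

__all__ = ["InjectionSet", "sar_field"]


@dataclass(frozen=True)
class InjectionSet:
    """Np nanoparticle injection points, metres, shape (Np, 3)."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=np.float64))
        if pts.size == 0:
            pts = pts.reshape(0, 3)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"injection points must have shape (Np, 3), got {pts.shape}")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return self.points.shape[0]

    def validate_inside(self, domain: Domain) -> None:
        for i, p in enumerate(self.points):
            if not domain.contains(p):
                raise ValueError(
                    f"injection point {i} at {tuple(p)} lies outside the domain "
                    f"[0, {domain.side_length}]^3"
                )


def sar_field(
    domain: Domain,
    injections: "InjectionSet | Sequence[Sequence[float]] | np.ndarray",
    A: float,
    r0: float,
) -> np.ndarray:
    """Per-node SAR field, W/m³, on the (N+1)³ node grid.

    An empty injection set yields the zero field (a pure-baseline run);
    a point outside the domain is an error.
    """
    if not isinstance(injections, InjectionSet):
        injections = InjectionSet(np.asarray(injections, dtype=float))
    if not A > 0:
        raise ValueError(f"A must be > 0, got {A}")
    if not r0 > 0:
        raise ValueError(f"r0 must be > 0, got {r0}")
    injections.validate_inside(domain)

    field = np.zeros(domain.shape, dtype=np.float64)
    if len(injections) == 0:
        return field

    coords = domain.node_coordinates()
    x = coords[:, None, None]
    y = coords[None, :, None]
    z = coords[None, None, :]
    inv_r02 = 1.0 / (r0 * r0)
    for cx, cy, cz in injections.points:
        d2 = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2
        field += A * np.exp(-d2 * inv_r02)
    return field
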