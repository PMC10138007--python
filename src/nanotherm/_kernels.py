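"""Numba kernels for the explicit bioheat stepper.

All kernels operate on arrays padded with one ghost layer per face; ghost
values are mirror copies of the first interior layer, which realises the
zero-flux boundary (the missing neighbour of a face node is replaced by its
interior mirror, and the mirrored conductivity makes both face fluxes equal).

Two update paths exist and agree to round-off:

``step_general``
    Literal heterogeneous-medium update: per-node conductivity, perfusion,
    metabolic and capacity fields, harmonic-mean face conductivities
    computed on the fly. Reference path; used for arbitrary fields and in
    oracle tests.

``step_uniform`` + ``step_boxes``
    Production path for the (common) piecewise-two-material case with
    uniform ρc: a constant-coefficient stencil with the healthy-tissue
    coefficients sweeps the whole grid, then the nodes inside the inflated
    bounding boxes of the tumor regions — the only places where any face
    conductivity, perfusion or metabolic term differs from the healthy
    constants — are recomputed with the two-material update. Box updates
    read only from the old field, so overlapping boxes are harmless.
"""

from __future__ import annotations

import numba
import numpy as np


@numba.njit(cache=True)
def mirror_ghosts(a: np.ndarray) -> None:
    """Copy the first interior layer into the ghost layer on all six faces."""
    n = a.shape[0]
    a[0, :, :] = a[2, :, :]
    a[n - 1, :, :] = a[n - 3, :, :]
    a[:, 0, :] = a[:, 2, :]
    a[:, n - 1, :] = a[:, n - 3, :]
    a[:, :, 0] = a[:, :, 2]
    a[:, :, n - 1] = a[:, :, n - 3]


@numba.njit(cache=True, fastmath=True)
def step_uniform(T, Tn, src, a0, ak, const):
    """Constant-coefficient 7-point stencil over every real node.

    Tn = a0*T + ak*(sum of 6 neighbours) + const + src, where a0, ak, const
    fold the diffusion, perfusion and metabolic terms of the homogeneous
    healthy medium and src holds ht/ρc times the SAR field.
    """
    n = T.shape[0]
    for i in range(1, n - 1):
        for j in range(1, n - 1):
            for k in range(1, n - 1):
                Tn[i, j, k] = (
                    a0 * T[i, j, k]
                    + ak
                    * (
                        T[i - 1, j, k]
                        + T[i + 1, j, k]
                        + T[i, j - 1, k]
                        + T[i, j + 1, k]
                        + T[i, j, k - 1]
                        + T[i, j, k + 1]
                    )
                    + const
                    + src[i, j, k]
                )


@numba.njit(cache=True, fastmath=True)
def step_boxes(T, Tn, mask, kh, pc, qm, src, c1, Ta, boxes):
    """Two-material update over the listed index boxes (overwrites Tn there).

    mask is the uint8 tumor indicator (ghosts mirrored); kh is the 2x2 table
    of harmonic-mean face conductivities between materials; pc[m] and qm[m]
    are ht/ρc times the perfusion coefficient and metabolic rate of material
    m; c1 = ht/(ρc h²). boxes is an (nb, 6) int array of half-open padded
    index ranges [i0,i1) x [j0,j1) x [k0,k1).
    """
    for b in range(boxes.shape[0]):
        i0, i1, j0, j1, k0, k1 = boxes[b]
        for i in range(i0, i1):
            for j in range(j0, j1):
                for k in range(k0, k1):
                    t = T[i, j, k]
                    m = mask[i, j, k]
                    d = (
                        kh[m, mask[i - 1, j, k]] * (T[i - 1, j, k] - t)
                        + kh[m, mask[i + 1, j, k]] * (T[i + 1, j, k] - t)
                        + kh[m, mask[i, j - 1, k]] * (T[i, j - 1, k] - t)
                        + kh[m, mask[i, j + 1, k]] * (T[i, j + 1, k] - t)
                        + kh[m, mask[i, j, k - 1]] * (T[i, j, k - 1] - t)
                        + kh[m, mask[i, j, k + 1]] * (T[i, j, k + 1] - t)
                    )
                    Tn[i, j, k] = t + c1 * d + pc[m] * (Ta - t) + qm[m] + src[i, j, k]


@numba.njit(cache=True)
def step_general(T, Tn, k, rho_c, perf, q, ht, h2, Ta):
    """Literal heterogeneous update with on-the-fly harmonic-mean faces.

    k, rho_c, perf (= ω_b ρ_b c_b) and q (= Q_m + Q_r) are per-node padded
    fields (ghosts mirrored where read).
    """
    n = T.shape[0]
    for i in range(1, n - 1):
        for j in range(1, n - 1):
            for kk in range(1, n - 1):
                t = T[i, j, kk]
                kc = k[i, j, kk]
                flux = 0.0
                ko = k[i - 1, j, kk]
                flux += 2.0 * kc * ko / (kc + ko) * (T[i - 1, j, kk] - t)
                ko = k[i + 1, j, kk]
                flux += 2.0 * kc * ko / (kc + ko) * (T[i + 1, j, kk] - t)
                ko = k[i, j - 1, kk]
                flux += 2.0 * kc * ko / (kc + ko) * (T[i, j - 1, kk] - t)
                ko = k[i, j + 1, kk]
                flux += 2.0 * kc * ko / (kc + ko) * (T[i, j + 1, kk] - t)
                ko = k[i, j, kk - 1]
                flux += 2.0 * kc * ko / (kc + ko) * (T[i, j, kk - 1] - t)
                ko = k[i, j, kk + 1]
                flux += 2.0 * kc * ko / (kc + ko) * (T[i, j, kk + 1] - t)
                Tn[i, j, kk] = t + ht / rho_c[i, j, kk] * (
                    flux / h2 + perf[i, j, kk] * (Ta - t) + q[i, j, kk]
                )
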