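"""Solvent-accessible surface area: LCPO analytic estimate and a
Monte-Carlo sphere-sampling reference.

LCPO approximates each atom's SASA as a linear combination of pairwise
sphere-overlap areas:

    A_i = P1 * S_i + P2 * sum_j A_ij + P3 * sum_{j,k} A_jk
          + P4 * sum_j [ A_ij * sum_k A_jk ]

where S_i = 4 pi R_i^2 (R = atomic radius + probe), A_ij is the area of
sphere i buried by neighbour j, the (j, k) sum runs over ordered neighbour
pairs of i that are also neighbours of each other, and the coefficients are
per-atom-type parameters. Per-atom areas are clamped at zero; hydrogens are
assigned zero area. The nonpolar solvation term is G_SA = gamma * SASA.
"""

from __future__ import annotations

import numpy as np

from ..errors import ParameterizationError
from .topology import ParameterizedSystem


def _buried_area(Ri: float, Rj: float, d: float) -> float:
    """Area of sphere i's surface buried inside sphere j (both solvent-
    inflated), zero when the spheres do not intersect."""
    if d >= Ri + Rj:
        return 0.0
    if d + Ri <= Rj:
        return 4.0 * np.pi * Ri**2  # i fully inside j
    if d + Rj <= Ri:
        return 0.0  # j fully inside i: no cap on i's surface
    return 2.0 * np.pi * Ri * (Ri - d / 2.0 - (Ri**2 - Rj**2) / (2.0 * d))


def sasa_lcpo(
    sys: ParameterizedSystem, coords: np.ndarray, probe: float | None = None
):
    """LCPO per-atom SASA, total SASA (A^2) and G_SA (kcal/mol)."""
    coords = np.asarray(coords, dtype=float).reshape(sys.n_atoms, 3)
    probe = sys.globals["probe_radius"] if probe is None else probe
    heavy = sys.structure.heavy_mask()
    if (sys.lcpo_radius[heavy] <= 0).any():
        raise ParameterizationError("missing LCPO radius for a heavy atom")
    R = sys.lcpo_radius + probe
    n = sys.n_atoms
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    per_atom = np.zeros(n)
    # neighbour lists over heavy atoms only
    idx = np.flatnonzero(heavy)
    neigh = {
        int(i): [int(j) for j in idx if j != i and d[i, j] < R[i] + R[j]] for i in idx
    }
    A = {}  # cached buried areas

    def buried(i, j):
        if (i, j) not in A:
            A[(i, j)] = _buried_area(R[i], R[j], d[i, j])
        return A[(i, j)]

    for i in idx:
        p1, p2, p3, p4 = sys.lcpo_p[i]
        s1 = 4.0 * np.pi * R[i] ** 2
        nb = neigh[i]
        t2 = sum(buried(i, j) for j in nb)
        t3 = 0.0
        t4 = 0.0
        for j in nb:
            inner = sum(buried(j, k) for k in nb if k != j and d[j, k] < R[j] + R[k])
            t3 += inner
            t4 += buried(i, j) * inner
        per_atom[i] = max(0.0, p1 * s1 + p2 * t2 + p3 * t3 + p4 * t4)
    total = float(per_atom.sum())
    return per_atom, total, sys.globals["gamma"] * total


def mc_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = 1.4,
    n_points: int = 100_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo sphere-sampling SASA (A^2), the numerical reference the
    analytic LCPO estimate is validated against.

    For each atom, uniform points on its solvent-inflated sphere are kept if
    they fall outside every other inflated sphere; the accessible fraction
    scales the full sphere area.
    """
    coords = np.asarray(coords, dtype=float)
    R = np.asarray(radii, dtype=float) + probe
    rng = np.random.default_rng(seed)
    n = coords.shape[0]
    total = 0.0
    for i in range(n):
        pts = rng.normal(size=(n_points, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        pts = coords[i] + R[i] * pts
        others = [j for j in range(n) if j != i
                  and np.linalg.norm(coords[i] - coords[j]) < R[i] + R[j]]
        accessible = np.ones(n_points, dtype=bool)
        for j in others:
            accessible &= (
                ((pts - coords[j]) ** 2).sum(axis=1) > R[j] ** 2
            )
        total += 4.0 * np.pi * R[i] ** 2 * accessible.mean()
    return float(total)
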