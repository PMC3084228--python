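"""Gas-phase molecular-mechanics energy and analytic gradient.

Terms follow the AMBER-style functional form: E_bond = k (r - r0)^2,
E_angle = k (theta - theta0)^2, E_torsion = sum_n Vn/2 (1 + cos(n phi -
phase)), LJ 12-6 in rmin/epsilon form and Coulomb with the interior
dielectric, over all non-excluded pairs with no distance cutoff.
"""

from __future__ import annotations

import numpy as np

from .topology import ParameterizedSystem


def _torsion_arrays(sys: ParameterizedSystem):
    """Flattened per-Fourier-term index/parameter arrays, cached on the
    system (one row per (torsion, term) pair)."""
    cached = getattr(sys, "_torsion_cache", None)
    if cached is not None:
        return cached
    rows_ijkl, tor_of_term, vn, per, phase = [], [], [], [], []
    for t, (i, j, k, l, terms) in enumerate(sys.torsions):
        rows_ijkl.append((i, j, k, l))
        for v, n, ph in terms:
            tor_of_term.append(t)
            vn.append(v)
            per.append(n)
            phase.append(ph)
    cache = (
        np.array(rows_ijkl, int).reshape(-1, 4),
        np.array(tor_of_term, int),
        np.array(vn),
        np.array(per, float),
        np.array(phase),
    )
    object.__setattr__(sys, "_torsion_cache", cache)
    return cache


def _all_dihedrals(coords, ijkl):
    """Signed dihedral angles plus the intermediate vectors needed by the
    analytic gradient."""
    b1 = coords[ijkl[:, 1]] - coords[ijkl[:, 0]]
    b2 = coords[ijkl[:, 2]] - coords[ijkl[:, 1]]
    b3 = coords[ijkl[:, 3]] - coords[ijkl[:, 2]]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2, axis=1)
    y = (np.cross(n1, n2) * b2).sum(axis=1) / np.where(nb2 > 0, nb2, 1.0)
    x = (n1 * n2).sum(axis=1)
    phi = np.arctan2(y, x)
    return phi, b1, b2, b3, n1, n2, nb2


def _pair_terms(sys: ParameterizedSystem, coords: np.ndarray):
    n = sys.n_atoms
    diff = coords[:, None, :] - coords[None, :, :]
    r = np.sqrt((diff**2).sum(axis=2))
    np.fill_diagonal(r, np.inf)
    eps_ij = np.sqrt(sys.epsilon[:, None] * sys.epsilon[None, :])
    rmin_ij = sys.rmin_half[:, None] + sys.rmin_half[None, :]
    q_ij = sys.charge[:, None] * sys.charge[None, :]
    return diff, r, eps_ij, rmin_ij, q_ij


def mm_energy(sys: ParameterizedSystem, coords: np.ndarray) -> dict[str, float]:
    """Return the gas-phase term dictionary: E_bond, E_angle, E_torsion,
    E_vdw, E_elec and their sum E_MM (kcal/mol)."""
    coords = np.asarray(coords, dtype=float).reshape(sys.n_atoms, 3)
    out = {"E_bond": 0.0, "E_angle": 0.0, "E_torsion": 0.0}

    if len(sys.bonds):
        d = coords[sys.bonds[:, 0]] - coords[sys.bonds[:, 1]]
        r = np.linalg.norm(d, axis=1)
        out["E_bond"] = float((sys.bond_k * (r - sys.bond_r0) ** 2).sum())

    if len(sys.angles):
        i, j, k = sys.angles.T
        v1 = coords[i] - coords[j]
        v2 = coords[k] - coords[j]
        cos_t = (v1 * v2).sum(axis=1) / (
            np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
        )
        theta = np.arccos(np.clip(cos_t, -1.0, 1.0))
        out["E_angle"] = float((sys.angle_k * (theta - sys.angle_t0) ** 2).sum())

    if sys.torsions:
        ijkl, tot, vn, per, phase = _torsion_arrays(sys)
        phi = _all_dihedrals(coords, ijkl)[0]
        out["E_torsion"] = float(
            (0.5 * vn * (1.0 + np.cos(per * phi[tot] - phase))).sum()
        )

    _, r, eps_ij, rmin_ij, q_ij = _pair_terms(sys, coords)
    x6 = (rmin_ij / r) ** 6
    lj = eps_ij * (x6 * x6 - 2.0 * x6)
    out["E_vdw"] = float(0.5 * (sys.pair_scale_vdw * lj).sum())
    kc = sys.globals["k_coulomb"] / sys.globals["eps_in"]
    out["E_elec"] = float(0.5 * (sys.pair_scale_ee * kc * q_ij / r).sum())
    out["E_MM"] = sum(out[k] for k in ("E_bond", "E_angle", "E_torsion", "E_vdw", "E_elec"))
    return out


def _dihedral(p0, p1, p2, p3) -> float:
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    # sign convention chosen to match the analytic derivative decomposition
    return float(np.arctan2(np.cross(n1, n2) @ (b2 / np.linalg.norm(b2)), n1 @ n2))


def mm_gradient(sys: ParameterizedSystem, coords: np.ndarray) -> np.ndarray:
    """Analytic gradient of the gas-phase energy, shape (n_atoms, 3)."""
    coords = np.asarray(coords, dtype=float).reshape(sys.n_atoms, 3)
    grad = np.zeros_like(coords)

    if len(sys.bonds):
        i, j = sys.bonds.T
        d = coords[i] - coords[j]
        r = np.linalg.norm(d, axis=1)
        f = (2.0 * sys.bond_k * (r - sys.bond_r0) / r)[:, None] * d
        np.add.at(grad, i, f)
        np.add.at(grad, j, -f)

    if len(sys.angles):
        ii, jj, kk = sys.angles.T
        v1 = coords[ii] - coords[jj]
        v2 = coords[kk] - coords[jj]
        r1 = np.linalg.norm(v1, axis=1)
        r2 = np.linalg.norm(v2, axis=1)
        cos_t = np.clip((v1 * v2).sum(axis=1) / (r1 * r2), -1.0, 1.0)
        theta = np.arccos(cos_t)
        sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 1e-12, None))
        dE = 2.0 * sys.angle_k * (theta - sys.angle_t0)
        # dtheta/dx via standard angle derivatives
        di = (cos_t[:, None] * v1 / r1[:, None] ** 2 - v2 / (r1 * r2)[:, None]) / sin_t[:, None]
        dk = (cos_t[:, None] * v2 / r2[:, None] ** 2 - v1 / (r1 * r2)[:, None]) / sin_t[:, None]
        np.add.at(grad, ii, dE[:, None] * di)
        np.add.at(grad, kk, dE[:, None] * dk)
        np.add.at(grad, jj, -dE[:, None] * (di + dk))

    if sys.torsions:
        ijkl, tot, vn, per, phase = _torsion_arrays(sys)
        phi, b1, b2, b3, n1, n2, nb2 = _all_dihedrals(coords, ijkl)
        n1sq = (n1**2).sum(axis=1)
        n2sq = (n2**2).sum(axis=1)
        ok = (n1sq > 1e-12) & (n2sq > 1e-12)
        dE = np.zeros(len(sys.torsions))
        np.add.at(dE, tot, -0.5 * vn * per * np.sin(per * phi[tot] - phase))
        dE = np.where(ok, dE, 0.0)
        safe1 = np.where(ok, n1sq, 1.0)
        safe2 = np.where(ok, n2sq, 1.0)
        dphi_di = (-nb2 / safe1)[:, None] * n1
        dphi_dl = (nb2 / safe2)[:, None] * n2
        s = (b1 * b2).sum(axis=1) / nb2**2
        t = (b3 * b2).sum(axis=1) / nb2**2
        dphi_dj = -(1.0 + s)[:, None] * dphi_di + t[:, None] * dphi_dl
        dphi_dk = s[:, None] * dphi_di - (1.0 + t)[:, None] * dphi_dl
        np.add.at(grad, ijkl[:, 0], dE[:, None] * dphi_di)
        np.add.at(grad, ijkl[:, 1], dE[:, None] * dphi_dj)
        np.add.at(grad, ijkl[:, 2], dE[:, None] * dphi_dk)
        np.add.at(grad, ijkl[:, 3], dE[:, None] * dphi_dl)

    diff, r, eps_ij, rmin_ij, q_ij = _pair_terms(sys, coords)
    x6 = (rmin_ij / r) ** 6
    # dE/dr for LJ and Coulomb, combined into a radial force factor
    dlj = eps_ij * (-12.0 / r) * (x6 * x6 - x6)
    kc = sys.globals["k_coulomb"] / sys.globals["eps_in"]
    dee = -kc * q_ij / r**2
    fac = (sys.pair_scale_vdw * dlj + sys.pair_scale_ee * dee) / r
    grad += (fac[:, :, None] * diff).sum(axis=1)
    return grad
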