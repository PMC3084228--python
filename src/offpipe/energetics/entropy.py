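"""Normal-mode entropy: translational, rotational and vibrational terms.

The mass-weighted Hessian is built by central finite differences of the
analytic gas-phase gradient (step 1e-4 A). Up to six near-zero external
modes (rigid translation/rotation of an unrestrained molecule) are removed;
any further negative eigenvalue is dropped with a warning. Vibrational
entropy uses the quantum harmonic-oscillator formula per mode, translational
entropy is Sackur-Tetrode at 1 atm, and rotational entropy is the classical
rigid rotor from the inertia tensor (zero for a single atom). All terms are
returned as T*S in kcal/mol.

An optional harmonic position restraint (same E = k d^2 convention as the
minimizer) can be included, which also permits restrained-NMA checks such as
a single particle in an isotropic well.
"""

from __future__ import annotations

import warnings

import numpy as np

from ..errors import NotMinimizedError
from .mm import mm_gradient
from .topology import ParameterizedSystem

H_PLANCK = 6.62607015e-34  # J s
K_BOLTZ = 1.380649e-23  # J/K
N_AVOGADRO = 6.02214076e23
R_GAS = 8.314462618  # J/mol/K
AMU = 1.66053906660e-27  # kg
ATM = 101325.0  # Pa
J_PER_KCAL = 4184.0
# kcal/mol/A^2/amu -> s^-2
_LAMBDA_TO_OMEGA2 = J_PER_KCAL / (1e-3 * 1e-20)


def _gradient(sys, coords, restraint):
    g = mm_gradient(sys, coords)
    if restraint is not None:
        k, ref = restraint
        g = g + 2.0 * k * (coords - ref)
    return g


def _hessian(sys, coords, restraint, step=1e-4):
    n3 = sys.n_atoms * 3
    H = np.empty((n3, n3))
    flat = coords.ravel()
    for a in range(n3):
        xp = flat.copy()
        xp[a] += step
        xm = flat.copy()
        xm[a] -= step
        gp = _gradient(sys, xp.reshape(-1, 3), restraint).ravel()
        gm = _gradient(sys, xm.reshape(-1, 3), restraint).ravel()
        H[:, a] = (gp - gm) / (2.0 * step)
    return 0.5 * (H + H.T)


def _vibrational_ts(eigvals: np.ndarray, T: float) -> float:
    """T * S_vib (kcal/mol) from mass-weighted Hessian eigenvalues."""
    ts = 0.0
    for lam in eigvals:
        omega = np.sqrt(lam * _LAMBDA_TO_OMEGA2)
        x = H_PLANCK * omega / (2.0 * np.pi * K_BOLTZ * T)
        s = R_GAS * (x / np.expm1(x) - np.log1p(-np.exp(-x)))
        ts += T * s / J_PER_KCAL
    return ts


def _translational_ts(total_mass_amu: float, T: float) -> float:
    m = total_mass_amu * AMU
    q = (2.0 * np.pi * m * K_BOLTZ * T / H_PLANCK**2) ** 1.5 * K_BOLTZ * T / ATM
    s = R_GAS * (np.log(q) + 2.5)
    return T * s / J_PER_KCAL


def _rotational_ts(sys, coords, T: float) -> float:
    if sys.n_atoms == 1:
        return 0.0
    m = sys.mass * AMU  # per-molecule moments (kg m^2)
    xyz = coords * 1e-10
    com = (m[:, None] * xyz).sum(axis=0) / m.sum()
    d = xyz - com
    I = np.zeros((3, 3))
    for mi, di in zip(m, d):
        I += mi * ((di @ di) * np.eye(3) - np.outer(di, di))
    moments = np.sort(np.linalg.eigvalsh(I))
    rot_const = 8.0 * np.pi**2 * K_BOLTZ * T / H_PLANCK**2
    if moments[0] < 1e-6 * moments[2]:  # linear molecule: q = 8 pi^2 I k T / h^2
        s = R_GAS * (np.log(rot_const * moments[2]) + 1.0)
    else:
        # nonlinear rigid rotor, sigma = 1: q = sqrt(pi (8 pi^2 kT/h^2)^3 Ia Ib Ic)
        q = np.sqrt(np.pi) * rot_const**1.5 * np.sqrt(np.prod(moments))
        s = R_GAS * (np.log(q) + 1.5)
    return T * s / J_PER_KCAL


def normal_mode_entropy(
    sys: ParameterizedSystem,
    coords: np.ndarray,
    T: float | None = None,
    grad_tol: float = 0.1,
    restraint: tuple[float, np.ndarray] | None = None,
) -> tuple[float, float, float]:
    """Return (TS_trans, TS_rot, TS_vib) in kcal/mol at temperature T.

    ``coords`` must be at a local minimum: the inf-norm of the gradient must
    not exceed ``grad_tol`` (kcal/mol/A). ``restraint`` is an optional
    ``(k, reference_coords)`` harmonic well added to the potential.
    """
    coords = np.asarray(coords, dtype=float).reshape(sys.n_atoms, 3)
    T = sys.globals["temperature"] if T is None else T
    g = _gradient(sys, coords, restraint)
    gnorm = np.abs(g).max()
    if gnorm > grad_tol:
        raise NotMinimizedError(
            f"gradient inf-norm {gnorm:.4f} exceeds tolerance {grad_tol}"
        )
    H = _hessian(sys, coords, restraint)
    inv_sqrt_m = 1.0 / np.sqrt(np.repeat(sys.mass, 3))
    Hmw = H * inv_sqrt_m[:, None] * inv_sqrt_m[None, :]
    eig = np.linalg.eigvalsh(Hmw)

    # remove up to six near-zero external modes (translation/rotation of an
    # unrestrained molecule); a trapped system keeps all of its modes
    scale = max(np.abs(eig).max(), 1.0)
    order = np.argsort(np.abs(eig))
    external = [k for k in order[:6] if abs(eig[k]) < 1e-6 * scale]
    keep = np.ones(len(eig), dtype=bool)
    keep[external] = False
    vib = eig[keep]
    if (vib < 0).any():
        warnings.warn(
            f"dropping {(vib < 0).sum()} negative eigenvalue(s) beyond the "
            "external modes (imperfect minimum)",
            stacklevel=2,
        )
        vib = vib[vib >= 0]
    ts_vib = _vibrational_ts(vib, T)
    ts_trans = _translational_ts(float(sys.mass.sum()), T)
    ts_rot = _rotational_ts(sys, coords, T)
    return ts_trans, ts_rot, ts_vib
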