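"""Rigid-body geometry: Kabsch superposition and RMSD."""

from __future__ import annotations

import numpy as np

from .errors import DegenerateFitError


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of Q onto P.

    Returns ``(R, t, rmsd)`` such that ``Q @ R.T + t`` minimizes the RMSD to
    ``P`` over proper rotations (det(R) = +1) and translations.

    Parameters
    ----------
    P, Q : (n, 3) arrays
        Paired coordinates, ``n >= 3`` and not all collinear.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise DegenerateFitError("paired coordinate arrays must both be (n, 3)")
    n = P.shape[0]
    if n < 3:
        raise DegenerateFitError(f"need >=3 point pairs for a rigid fit, got {n}")
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    # collinearity check: rank of the centered cloud
    if min(np.linalg.matrix_rank(Pc, tol=1e-8), np.linalg.matrix_rank(Qc, tol=1e-8)) < 2:
        raise DegenerateFitError("collinear point set: rotation underdetermined")
    H = Qc.T @ Pc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = P.mean(axis=0) - Q.mean(axis=0) @ R.T
    diff = (Q @ R.T + t) - P
    rmsd = float(np.sqrt((diff**2).sum() / n))
    return R, t, rmsd


def apply_transform(coords: np.ndarray, R: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Apply a rotation/translation pair produced by :func:`kabsch`."""
    return np.asarray(coords, dtype=float) @ np.asarray(R).T + np.asarray(t)


def rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    """Plain (no refitting) root-mean-square deviation between paired coords."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    return float(np.sqrt(((P - Q) ** 2).sum() / P.shape[0]))
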