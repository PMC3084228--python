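"""Pose transfer, steric filtering, rescoring and contact analysis.

A ligand pose is carried from its source complex into a screened receptor
through the rigid transform of the binding-site alignment, locally optimized
as a rigid body, and scored with a simple physics-based interaction score
(Lennard-Jones + Coulomb with distance-dependent dielectric eps(r) = 4r +
a hydrogen-bond bonus). Raw scores are only meaningful relative to a decoy
background: the normalized docking score (NDS) is the z-score of the pose
against decoy placements on the same receptor, so systematic bias in the
scoring function cancels. Poses with severe steric clashes or NDS above the
cutoff (worse than random, like the published EPHA2 case at NDS = 1.328)
are removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize as _scipy_minimize
from scipy.spatial.transform import Rotation

from .errors import NormalizationError, OptimizationError, ParameterizationError
from .geometry import apply_transform
from .structio import Structure

_HBOND_ELEMENTS = {"N", "O"}


@dataclass
class Pose:
    """Ligand coordinates expressed in a receptor frame."""

    atoms: list  # ligand atom roster (same order as source ligand)
    coords: np.ndarray
    source_id: str = "pose"
    transform_id: str = "identity"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(len(self.atoms), 3)
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite pose coordinates")


@dataclass
class ScorePanel:
    raw_score: float
    clash_count: int
    nds: float | None = None
    severe_clash: bool = False
    retained: bool | None = None


@dataclass
class ContactReport:
    hbonds: list  # (donor atom name, acceptor atom name, distance)
    hydrophobic: list  # (receptor C name, ligand C name, distance)


def transfer_pose(ligand: Structure, rotation, translation, transform_id="aligned") -> Pose:
    """Map a ligand into a target receptor frame via a site-alignment
    transform (proper rotation + translation)."""
    R = np.asarray(rotation, dtype=float)
    if R.shape != (3, 3) or abs(np.linalg.det(R) - 1.0) > 1e-6:
        raise ValueError("transform must be a proper rotation matrix")
    return Pose(
        atoms=list(ligand.atoms),
        coords=apply_transform(ligand.coords, R, np.asarray(translation, float)),
        source_id=ligand.structure_id,
        transform_id=transform_id,
    )


def clash_report(receptor: Structure, pose: Pose, d_clash: float = 1.5) -> int:
    """Count receptor-ligand heavy-atom pairs closer than ``d_clash``."""
    rec = receptor.coords[receptor.heavy_mask()]
    lig = pose.coords[[a.is_heavy for a in pose.atoms]]
    d = np.linalg.norm(rec[:, None, :] - lig[None, :, :], axis=2)
    return int((d < d_clash).sum())


def _resolve_nonbonded(atoms, ff):
    """Charge / LJ parameter arrays for a pose or receptor atom list."""
    q, eps, rmh = [], [], []
    for a in atoms:
        t = ff.assign_type(a.residue_name, a.name, a.element)
        if t not in ff.atom_types:
            raise ParameterizationError(f"atom type {t!r} has no parameters")
        at = ff.atom_types[t]
        q.append(at.charge)
        eps.append(at.epsilon)
        rmh.append(at.rmin_half)
    return np.array(q), np.array(eps), np.array(rmh)


def raw_interaction_score(receptor: Structure, pose: Pose, ff) -> float:
    """Intermolecular interaction score (kcal/mol-like, lower is better).

    LJ 12-6 plus Coulomb with the distance-dependent dielectric eps(r) = 4r,
    and a -1.0 bonus per donor/acceptor N/O pair within 3.5 A (distance-only
    criterion; poses may lack hydrogens).
    """
    q_r, eps_r, rmh_r = _resolve_nonbonded(receptor.atoms, ff)
    q_l, eps_l, rmh_l = _resolve_nonbonded(pose.atoms, ff)
    d = np.linalg.norm(receptor.coords[:, None, :] - pose.coords[None, :, :], axis=2)
    d = np.clip(d, 0.3, None)  # guard against overlapping centres
    eps_ij = np.sqrt(eps_r[:, None] * eps_l[None, :])
    rmin_ij = rmh_r[:, None] + rmh_l[None, :]
    x6 = (rmin_ij / d) ** 6
    e_lj = float((eps_ij * (x6 * x6 - 2.0 * x6)).sum())
    kc = ff.globals["k_coulomb"]
    e_el = float((kc * q_r[:, None] * q_l[None, :] / (4.0 * d * d)).sum())
    hb_r = np.array([a.element in _HBOND_ELEMENTS for a in receptor.atoms])
    hb_l = np.array([a.element in _HBOND_ELEMENTS for a in pose.atoms])
    n_hb = int((d[np.ix_(hb_r, hb_l)] <= 3.5).sum())
    return e_lj + e_el - 1.0 * n_hb


def local_optimize_pose(
    receptor: Structure,
    pose: Pose,
    ff,
    max_displacement: float = 5.0,
    tol: float = 1e-4,
) -> tuple[Pose, float]:
    """Rigid-body (3 translation + 3 rotation) local refinement of a pose.

    Coordinate-descent over the six rigid degrees of freedom, bounded to
    ``max_displacement`` of the starting centroid: a pose is refined in
    place, never re-docked. The returned score never exceeds the input
    score.
    """
    start = raw_interaction_score(receptor, pose, ff)
    if not np.isfinite(start):
        raise OptimizationError("non-finite starting interaction score")
    centroid0 = pose.coords.mean(axis=0)
    local = pose.coords - centroid0

    def build(x):
        rot = Rotation.from_rotvec(x[3:]).as_matrix()
        return local @ rot.T + centroid0 + x[:3]

    def fun(x):
        if np.linalg.norm(x[:3]) > max_displacement:
            return start + 1e3 * (np.linalg.norm(x[:3]) - max_displacement)
        p = Pose(pose.atoms, build(x), pose.source_id, pose.transform_id)
        return raw_interaction_score(receptor, p, ff)

    res = _scipy_minimize(
        fun,
        np.zeros(6),
        method="Powell",
        options={"xtol": tol, "ftol": tol, "maxiter": 40},
    )
    if res.fun <= start:
        out = Pose(pose.atoms, build(res.x), pose.source_id, pose.transform_id + "+opt")
        return out, float(res.fun)
    return pose, start


def normalized_docking_score(score: float, background) -> float:
    """z-score of a raw docking score against a decoy background.

    Negative means better than random placements; invariant under any
    affine recalibration applied jointly to score and background.
    """
    bg = np.asarray(background, dtype=float)
    if bg.size < 20:
        raise NormalizationError(f"need >= 20 background scores, got {bg.size}")
    sd = bg.std(ddof=1)
    if sd < 1e-12:
        raise NormalizationError("constant decoy background")
    return float((score - bg.mean()) / sd)


def decoy_background_scores(
    receptor: Structure,
    pose: Pose,
    ff,
    n_decoys: int = 50,
    seed: int = 0,
    max_shift: float = 8.0,
) -> list[float]:
    """Scores of random rigid placements of the same ligand near the pocket,
    the background the NDS normalizes against."""
    rng = np.random.default_rng(seed)
    centroid = pose.coords.mean(axis=0)
    local = pose.coords - centroid
    out = []
    for _ in range(n_decoys):
        rot = Rotation.from_rotvec(rng.normal(size=3) * np.pi).as_matrix()
        shift = rng.uniform(-max_shift, max_shift, size=3)
        decoy = Pose(pose.atoms, local @ rot.T + centroid + shift, pose.source_id, "decoy")
        out.append(raw_interaction_score(receptor, decoy, ff))
    return out


def nds_filter(panels: dict[str, ScorePanel], nds_max: float = 0.0) -> list[str]:
    """Retain hits that beat the decoy background (nds < nds_max) and show
    no severe clash; returns retained target ids, and marks each panel."""
    retained = []
    for tid, p in panels.items():
        if p.nds is None:
            raise NormalizationError(f"hit {tid!r} has no NDS")
        p.retained = (p.nds < nds_max) and not p.severe_clash
        if p.retained:
            retained.append(tid)
    return retained


def analyze_contacts(
    receptor: Structure,
    pose: Pose,
    hbond_max: float = 3.5,
    hydrophobic_max: float = 4.5,
) -> ContactReport:
    """Distance-based protein-ligand contact report.

    Hydrogen bonds: N/O donor-acceptor heavy-atom pairs within
    ``hbond_max`` (assumed protonation; no angle term). Hydrophobic:
    carbon-carbon pairs within ``hydrophobic_max``.
    """
    hb, phob = [], []
    d = np.linalg.norm(receptor.coords[:, None, :] - pose.coords[None, :, :], axis=2)
    for i, ra in enumerate(receptor.atoms):
        for j, la in enumerate(pose.atoms):
            dist = float(d[i, j])
            pair_r = f"{ra.chain}:{ra.residue_number}:{ra.name}"
            pair_l = la.name
            if ra.element in _HBOND_ELEMENTS and la.element in _HBOND_ELEMENTS and dist <= hbond_max:
                hb.append((pair_r, pair_l, round(dist, 3)))
            elif ra.element == "C" and la.element == "C" and dist <= hydrophobic_max:
                phob.append((pair_r, pair_l, round(dist, 3)))
    return ContactReport(hbonds=sorted(set(hb)), hydrophobic=sorted(set(phob)))
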