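"""Snapshot and ensemble MM/GBSA assembly, plus trajectory diagnostics.

Single-trajectory convention: receptor and ligand terms are evaluated on
coordinates sliced from the complex snapshot, so intramolecular gas-phase
terms cancel exactly in the binding differences and the enthalpy is carried
by the intermolecular and solvation terms.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..errors import DegenerateFitError, SelectionError
from ..structio import BACKBONE_NAMES, TrajectoryEnsemble, rmsd_series
from .entropy import normal_mode_entropy
from .gb import gb_polar_energy
from .minimize import gas_phase_minimize
from .mm import mm_energy
from .sasa import sasa_lcpo
from .topology import ParameterizedSystem


@dataclass
class EnergyBreakdown:
    """One subsystem's free-energy terms (kcal/mol)."""

    E_bond: float
    E_angle: float
    E_torsion: float
    E_vdw: float
    E_elec: float
    G_GB: float
    G_SA: float
    TS_trans: float = 0.0
    TS_rot: float = 0.0
    TS_vib: float = 0.0
    entropy_included: bool = False

    @property
    def E_MM(self) -> float:
        return self.E_bond + self.E_angle + self.E_torsion + self.E_vdw + self.E_elec

    @property
    def TS(self) -> float:
        return self.TS_trans + self.TS_rot + self.TS_vib

    @property
    def G_total(self) -> float:
        return self.E_MM + self.G_GB + self.G_SA - self.TS


@dataclass
class BindingFreeEnergy:
    """Ensemble-averaged binding free energy, dG = dH - dTS."""

    per_snapshot_dH: np.ndarray
    per_snapshot_dTS: np.ndarray  # at the entropy stride; empty if skipped
    dH: float
    dTS: float
    dG: float
    se_dH: float
    se_dTS: float
    se_dG: float
    n_snapshots: int
    entropy_included: bool


def assemble_delta_g(dH: float, dTS: float) -> float:
    """Free-energy bookkeeping dG = dH - dTS (kcal/mol)."""
    if not (np.isfinite(dH) and np.isfinite(dTS)):
        raise ValueError("non-finite enthalpy/entropy input")
    return dH - dTS


def snapshot_mmgbsa(
    sys: ParameterizedSystem,
    coords: np.ndarray,
    include_entropy: bool = False,
    entropy_grad_tol: float = 0.1,
) -> dict[str, EnergyBreakdown]:
    """Evaluate complex, receptor and ligand breakdowns on one snapshot.

    With ``include_entropy`` each subsystem is gas-phase minimized first and
    its normal-mode entropy computed; otherwise TS terms are zero and flagged
    via ``entropy_included=False``.
    """
    if sys.receptor_mask is None or sys.ligand_mask is None:
        raise SelectionError("system has no receptor/ligand masks")
    if not sys.ligand_mask.any():
        raise SelectionError("empty ligand mask")
    coords = np.asarray(coords, dtype=float).reshape(sys.n_atoms, 3)
    out = {}
    for name, sub, mask in (
        ("complex", sys, np.ones(sys.n_atoms, bool)),
        ("receptor", sys.subsystem(sys.receptor_mask), sys.receptor_mask),
        ("ligand", sys.subsystem(sys.ligand_mask), sys.ligand_mask),
    ):
        sub_coords = coords[mask]
        terms = mm_energy(sub, sub_coords)
        g_gb = gb_polar_energy(sub, sub_coords)
        _, _, g_sa = sasa_lcpo(sub, sub_coords)
        ts = (0.0, 0.0, 0.0)
        if include_entropy:
            mini = gas_phase_minimize(sub, sub_coords, gtol=1e-3)
            ts = normal_mode_entropy(sub, mini, grad_tol=entropy_grad_tol)
        out[name] = EnergyBreakdown(
            E_bond=terms["E_bond"],
            E_angle=terms["E_angle"],
            E_torsion=terms["E_torsion"],
            E_vdw=terms["E_vdw"],
            E_elec=terms["E_elec"],
            G_GB=g_gb,
            G_SA=g_sa,
            TS_trans=ts[0],
            TS_rot=ts[1],
            TS_vib=ts[2],
            entropy_included=include_entropy,
        )
    return out


def _se(x: np.ndarray) -> float:
    x = np.asarray(x, float)
    if x.size < 2:
        return 0.0
    return float(x.std(ddof=1) / np.sqrt(x.size))


def ensemble_binding_free_energy(
    sys: ParameterizedSystem,
    traj: TrajectoryEnsemble,
    include_entropy: bool = True,
    entropy_stride: int = 1,
    entropy_grad_tol: float = 0.1,
) -> BindingFreeEnergy:
    """Average per-snapshot binding terms over a trajectory ensemble.

    dH is the mean over all snapshots of dE_MM + dG_GB + dG_SA; dTS is the
    mean of the entropy differences computed on every ``entropy_stride``-th
    snapshot (each subsystem minimized before its normal-mode analysis).
    """
    if traj.n_snapshots == 0:
        raise SelectionError("empty trajectory")
    if traj.template.n_atoms != sys.n_atoms:
        raise SelectionError("trajectory roster does not match the system")
    dH_list, dTS_list = [], []
    for k in range(traj.n_snapshots):
        do_entropy = include_entropy and (k % entropy_stride == 0)
        br = snapshot_mmgbsa(
            sys, traj.coords[k], include_entropy=do_entropy,
            entropy_grad_tol=entropy_grad_tol,
        )
        dH = (
            br["complex"].E_MM + br["complex"].G_GB + br["complex"].G_SA
            - br["receptor"].E_MM - br["receptor"].G_GB - br["receptor"].G_SA
            - br["ligand"].E_MM - br["ligand"].G_GB - br["ligand"].G_SA
        )
        dH_list.append(dH)
        if do_entropy:
            dTS_list.append(
                br["complex"].TS - br["receptor"].TS - br["ligand"].TS
            )
    dH = float(np.mean(dH_list))
    dTS = float(np.mean(dTS_list)) if dTS_list else 0.0
    return BindingFreeEnergy(
        per_snapshot_dH=np.array(dH_list),
        per_snapshot_dTS=np.array(dTS_list),
        dH=dH,
        dTS=dTS,
        dG=assemble_delta_g(dH, dTS),
        se_dH=_se(dH_list),
        se_dTS=_se(dTS_list),
        se_dG=float(np.hypot(_se(dH_list), _se(dTS_list))),
        n_snapshots=traj.n_snapshots,
        entropy_included=bool(dTS_list),
    )


# ---------------------------------------------------------------------------
# trajectory stability diagnostics
# ---------------------------------------------------------------------------

@dataclass
class StabilityReport:
    receptor_flag: str  # "PASS" | "FAIL"
    ligand_flag: str  # "OK" | "POCKET_EXIT"
    max_backbone_rmsd: float
    mean_ligand_rmsd: float
    fraction_outside_site: float


def stability_check(
    traj: TrajectoryEnsemble,
    backbone_selection=BACKBONE_NAMES,
    ligand_mask: np.ndarray | None = None,
    rmsd_pass: float = 3.0,
    exit_threshold: float = 4.0,
    site_cutoff: float = 5.0,
) -> StabilityReport:
    """Flag unstable receptors and pocket-exiting ligands.

    The receptor passes when the maximum backbone RMSD over the window stays
    below ``rmsd_pass`` (default 3.0 A). The ligand is flagged POCKET_EXIT
    when its mean heavy-atom RMSD exceeds ``exit_threshold`` or its centroid
    strays farther than ``site_cutoff`` from its first-frame position in
    more than half of the snapshots. The trajectory must already be fitted
    to its first frame on the backbone selection.
    """
    bb_mask = traj.template.name_mask(backbone_selection)
    if bb_mask.sum() < 3:
        raise SelectionError("backbone selection matched fewer than 3 atoms")
    if ligand_mask is None:
        ligand_mask = np.array(
            [a.record_kind == "hetero" and a.is_heavy for a in traj.template.atoms]
        )
    ligand_mask = np.asarray(ligand_mask, dtype=bool)
    if not ligand_mask.any():
        raise SelectionError("empty ligand selection")
    # superposition precondition: refitting any snapshot onto frame 1 must
    # not improve the backbone RMSD (it cannot, if the caller already fitted)
    from ..geometry import kabsch

    ref = traj.coords[0][bb_mask]
    for k in range(1, traj.n_snapshots):
        raw = float(np.sqrt(((traj.coords[k][bb_mask] - ref) ** 2).sum() / bb_mask.sum()))
        fitted = kabsch(ref, traj.coords[k][bb_mask])[2]
        if fitted < raw - 1e-6:
            raise DegenerateFitError(
                f"trajectory not superposed to its first frame (snapshot {k + 1} "
                f"backbone RMSD {raw:.3f} A improves to {fitted:.3f} A on refit)"
            )
    bb = np.array([r for _, r in rmsd_series(traj, bb_mask)])
    lig = np.array([r for _, r in rmsd_series(traj, ligand_mask)])
    centroid0 = traj.coords[0][ligand_mask].mean(axis=0)
    dist = np.array(
        [np.linalg.norm(traj.coords[k][ligand_mask].mean(axis=0) - centroid0)
         for k in range(traj.n_snapshots)]
    )
    frac_out = float((dist > site_cutoff).mean())
    exited = lig.mean() > exit_threshold or frac_out > 0.5
    return StabilityReport(
        receptor_flag="PASS" if bb.max() < rmsd_pass else "FAIL",
        ligand_flag="POCKET_EXIT" if exited else "OK",
        max_backbone_rmsd=float(bb.max()),
        mean_ligand_rmsd=float(lig.mean()),
        fraction_outside_site=frac_out,
    )


# ---------------------------------------------------------------------------
# published free-energy table bookkeeping
# ---------------------------------------------------------------------------

def load_reference_free_energy_table() -> pd.DataFrame:
    """Published ensemble-average MM/GBSA table for Nelfinavir (ligand 1UN)
    and co-crystallized kinase inhibitors; columns target, ligand, dH, dTS,
    dG (kcal/mol)."""
    ref = importlib.resources.files("offpipe.data") / "kinase_mmgbsa_table.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def check_free_energy_table(
    table: pd.DataFrame | None = None, tol: float = 0.01
) -> pd.DataFrame:
    """Verify dG = dH - dTS row by row on a read-in free-energy table.

    Rows whose printed dG deviates from the assembled value by more than
    ``tol`` (default 0.01 kcal/mol, i.e. beyond printed-rounding drift) are
    flagged ``consistent = False``.
    """
    if table is None:
        table = load_reference_free_energy_table()
    out = table.copy()
    out["dG_assembled"] = [
        assemble_delta_g(h, ts) for h, ts in zip(out["dH"], out["dTS"])
    ]
    out["deviation"] = (out["dG"] - out["dG_assembled"]).round(6)
    out["consistent"] = out["deviation"].abs() <= tol + 1e-12
    return out
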