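"""Structures, snapshot ensembles, PDB I/O and synthetic test complexes.

Coordinates are always in Angstrom, times always in picoseconds. The PDB
dialect is fixed-width v3.3: only ATOM/HETATM/MODEL/ENDMDL records are
interpreted, altLoc other than blank/'A' is skipped, and insertion codes are
rejected (the synthetic fixtures never produce them).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (
    DegenerateFitError,
    GenerationError,
    PDBParseError,
    RosterError,
    SelectionError,
)
from .geometry import apply_transform, kabsch

_WATER_NAMES = {"HOH", "WAT", "TIP3", "SOL"}
_ION_NAMES = {"NA", "CL", "K", "MG", "CA2", "ZN", "NA+", "CL-"}

#: default backbone atom-name set used for trajectory fitting
BACKBONE_NAMES = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class Atom:
    serial: int
    name: str
    element: str
    chain: str
    residue_number: int
    residue_name: str
    record_kind: str  # "protein" | "hetero"

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"


@dataclass
class Structure:
    """An atom roster plus one coordinate set (Angstrom)."""

    atoms: list[Atom]
    coords: np.ndarray  # (n_atoms, 3)
    structure_id: str = "struct"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(len(self.atoms), 3)
        if not self.atoms:
            raise ValueError("a Structure needs at least one atom")
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite coordinates")
        keys = [(a.chain, a.residue_number, a.name) for a in self.atoms]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chain, residue_number, atom name) in model")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def heavy_mask(self) -> np.ndarray:
        return np.array([a.is_heavy for a in self.atoms], dtype=bool)

    def name_mask(self, names) -> np.ndarray:
        names = set(names)
        return np.array([a.name in names for a in self.atoms], dtype=bool)

    def subset(self, mask: np.ndarray, structure_id: str | None = None) -> "Structure":
        mask = np.asarray(mask, dtype=bool)
        atoms = [a for a, m in zip(self.atoms, mask) if m]
        return Structure(atoms, self.coords[mask], structure_id or self.structure_id)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        return Structure(list(self.atoms), np.asarray(coords, dtype=float), self.structure_id)

    def residue_ids(self) -> list[tuple[str, int]]:
        seen: list[tuple[str, int]] = []
        prev = None
        for a in self.atoms:
            rid = (a.chain, a.residue_number)
            if rid != prev:
                if rid not in seen:
                    seen.append(rid)
                prev = rid
        return seen


@dataclass
class ComplexModel:
    """Receptor/ligand partition of a protein-ligand complex."""

    receptor: Structure
    ligand: Structure
    complex_id: str = "complex"

    def __post_init__(self) -> None:
        if self.ligand.n_atoms < 1:
            raise ValueError("ligand must have at least one atom")

    def merged(self) -> Structure:
        atoms = list(self.receptor.atoms) + list(self.ligand.atoms)
        coords = np.vstack([self.receptor.coords, self.ligand.coords])
        return Structure(atoms, coords, self.complex_id)

    @property
    def ligand_mask(self) -> np.ndarray:
        n_r, n_l = self.receptor.n_atoms, self.ligand.n_atoms
        m = np.zeros(n_r + n_l, dtype=bool)
        m[n_r:] = True
        return m


@dataclass
class TrajectoryEnsemble:
    """Ordered snapshots over a fixed atom roster."""

    template: Structure
    coords: np.ndarray  # (n_snapshots, n_atoms, 3)
    times: np.ndarray  # ps, strictly increasing

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1] != self.template.n_atoms:
            raise RosterError("snapshot coordinate block does not match the atom roster")
        if self.coords.shape[0] != self.times.shape[0]:
            raise ValueError("times/snapshots length mismatch")
        if len(self.times) > 1 and not (np.diff(self.times) > 0).all():
            raise ValueError("snapshot times must be strictly increasing")

    @property
    def n_snapshots(self) -> int:
        return self.coords.shape[0]

    def snapshot(self, k: int) -> Structure:
        return self.template.with_coords(self.coords[k])


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def _infer_element(name: str, res_name: str) -> str:
    stripped = name.strip()
    for ch in stripped:
        if ch.isalpha():
            # two-letter ions written flush left ("NA", "CL", "MG")
            if res_name.strip().upper() in _ION_NAMES and len(stripped) >= 2:
                return stripped[:2].capitalize()
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {name!r}")


def _parse_atom_line(line: str, lineno: int) -> tuple[Atom, np.ndarray] | None:
    if len(line) < 54:
        raise PDBParseError(f"line {lineno}: ATOM/HETATM record shorter than 54 columns")
    altloc = line[16]
    if altloc not in (" ", "A"):
        return None
    icode = line[26]
    if icode != " ":
        raise PDBParseError(f"line {lineno}: insertion codes are not supported")
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        res_name = line[17:20].strip()
        chain = line[21]
        res_num = int(line[22:26])
        xyz = np.array([float(line[30:38]), float(line[38:46]), float(line[46:54])])
    except ValueError as exc:
        raise PDBParseError(f"line {lineno}: malformed fixed-width field ({exc})") from exc
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = _infer_element(name, res_name)
    element = element.capitalize()
    kind = "protein" if line.startswith("ATOM") else "hetero"
    return Atom(serial, name, element, chain, res_num, res_name, kind), xyz


def read_pdb(
    text: str,
    structure_id: str = "struct",
    interval_ps: float = 10.0,
    t0_ps: float | None = None,
):
    """Parse PDB text into a :class:`Structure` or, for multi-MODEL input,
    a :class:`TrajectoryEnsemble`.

    Snapshot times are synthesized from ``interval_ps`` (the PDB format
    carries none): frame *k* gets ``t0_ps + k * interval_ps`` with ``t0_ps``
    defaulting to ``interval_ps`` so that a run of *n* frames spans
    ``(0, n * interval_ps]``.
    """
    models: list[tuple[list[Atom], list[np.ndarray]]] = []
    cur_atoms: list[Atom] = []
    cur_xyz: list[np.ndarray] = []
    in_model = False
    saw_model_record = False

    def flush():
        nonlocal cur_atoms, cur_xyz
        if cur_atoms:
            models.append((cur_atoms, cur_xyz))
        cur_atoms, cur_xyz = [], []

    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec == "MODEL":
            saw_model_record = True
            flush()
            in_model = True
        elif rec == "ENDMDL":
            flush()
            in_model = False
        elif rec in ("ATOM", "HETATM"):
            parsed = _parse_atom_line(line, lineno)
            if parsed is not None:
                atom, xyz = parsed
                cur_atoms.append(atom)
                cur_xyz.append(xyz)
    flush()

    if not models:
        raise PDBParseError("no ATOM/HETATM records found")

    structures = [
        Structure(atoms, np.array(xyz), structure_id) for atoms, xyz in models
    ]
    if len(structures) == 1 and not saw_model_record:
        return structures[0]
    if len(structures) == 1:
        return structures[0]

    roster0 = [(a.chain, a.residue_number, a.name) for a in structures[0].atoms]
    for k, s in enumerate(structures[1:], start=2):
        roster = [(a.chain, a.residue_number, a.name) for a in s.atoms]
        if roster != roster0:
            raise RosterError(f"MODEL {k} atom roster differs from MODEL 1")
    t0 = interval_ps if t0_ps is None else t0_ps
    times = t0 + interval_ps * np.arange(len(structures))
    coords = np.stack([s.coords for s in structures])
    return TrajectoryEnsemble(structures[0], coords, times)


def _format_atom_line(a: Atom, xyz: np.ndarray) -> str:
    rec = "ATOM  " if a.record_kind == "protein" else "HETATM"
    name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
    return (
        f"{rec}{a.serial:5d} {name}{'':1s}{a.residue_name:>3s} {a.chain}"
        f"{a.residue_number:4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}"
    )


def write_pdb(obj) -> str:
    """Serialize a Structure, ComplexModel or TrajectoryEnsemble to PDB text."""
    if isinstance(obj, ComplexModel):
        obj = obj.merged()
    lines: list[str] = []
    if isinstance(obj, TrajectoryEnsemble):
        for k in range(obj.n_snapshots):
            lines.append(f"MODEL {k + 1:8d}")
            for a, xyz in zip(obj.template.atoms, obj.coords[k]):
                lines.append(_format_atom_line(a, xyz))
            lines.append("ENDMDL")
    elif isinstance(obj, Structure):
        for a, xyz in zip(obj.atoms, obj.coords):
            lines.append(_format_atom_line(a, xyz))
    else:
        raise TypeError(f"cannot write {type(obj).__name__} as PDB")
    lines.append("END")
    return "\n".join(lines) + "\n"


def split_complex(s: Structure, ligand_selector: str) -> ComplexModel:
    """Partition a structure into receptor and ligand.

    ``ligand_selector`` is a hetero residue name, or ``"NAME/chain"`` to
    disambiguate multiple copies. Waters and common ions are dropped from
    both sides.
    """
    sel = ligand_selector.strip()
    chain = None
    if "/" in sel:
        sel, chain = sel.split("/", 1)
    matches = [
        i
        for i, a in enumerate(s.atoms)
        if a.record_kind == "hetero"
        and a.residue_name == sel
        and (chain is None or a.chain == chain)
    ]
    if not matches:
        raise SelectionError(f"ligand selector {ligand_selector!r} matched nothing")
    lig_residues = {(s.atoms[i].chain, s.atoms[i].residue_number) for i in matches}
    if len(lig_residues) > 1:
        raise SelectionError(
            f"ligand selector {ligand_selector!r} matches {len(lig_residues)} residues; "
            "disambiguate with 'NAME/chain'"
        )
    lig_mask = np.zeros(s.n_atoms, dtype=bool)
    lig_mask[matches] = True
    rec_mask = np.array(
        [
            a.record_kind == "protein" and a.residue_name not in _WATER_NAMES
            for a in s.atoms
        ],
        dtype=bool,
    )
    rec_mask &= ~lig_mask
    return ComplexModel(
        s.subset(rec_mask), s.subset(lig_mask), complex_id=s.structure_id
    )


# ---------------------------------------------------------------------------
# Synthetic fixtures
# ---------------------------------------------------------------------------

_AA20 = (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO "
    "SER THR TRP TYR VAL"
).split()


def _spherical_cap_points(n: int, radius: float, cap_fraction: float) -> np.ndarray:
    """n roughly even points on a spherical cap (Fibonacci spiral), leaving an
    opening around +z of angular size (1 - cap_fraction) of the sphere."""
    ga = np.pi * (3.0 - np.sqrt(5.0))
    k = np.arange(n)
    # z from -1 up to (1 - 2*cap_fraction) keeps a polar opening at +z
    z = -1.0 + 2.0 * cap_fraction * (k + 0.5) / n
    r_xy = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    theta = ga * k
    pts = np.stack([r_xy * np.cos(theta), r_xy * np.sin(theta), z], axis=1)
    return radius * pts


def make_synthetic_complex(
    seed: int,
    n_residues: int = 30,
    n_ligand_atoms: int = 10,
    pocket_depth: float = 4.0,
) -> ComplexModel:
    """Generate a deterministic coarse-grained receptor-ligand complex.

    The receptor is a self-avoiding chain of CA atoms (plus one inward-facing
    CB dummy per residue) laid out on a spherical cap around a concave pocket;
    the ligand is a compact cluster of carbons seated in the pocket with every
    receptor-ligand heavy-atom distance >= 2.5 Angstrom. Output is
    bit-reproducible for a fixed seed.
    """
    if n_residues < 4:
        raise ValueError("n_residues must be >= 4")
    if n_ligand_atoms < 1:
        raise ValueError("n_ligand_atoms must be >= 1")
    rng = np.random.default_rng(seed)
    shell = pocket_depth + 3.2
    ca = _spherical_cap_points(n_residues, shell, cap_fraction=0.85)
    ca += rng.normal(0.0, 0.15, size=ca.shape)  # break exact symmetry
    # CB dummies point toward the pocket centre
    norms = np.linalg.norm(ca, axis=1, keepdims=True)
    cb = ca * (1.0 - 1.5 / norms)

    rec_pts = np.vstack([ca, cb])
    for attempt in range(256):
        # self-avoiding 1.5-A-step walk, recentred into the pocket mouth
        pts = [np.zeros(3)]
        for _ in range(n_ligand_atoms - 1):
            for _ in range(32):
                step = rng.normal(size=3)
                cand = pts[-1] + 1.5 * step / np.linalg.norm(step)
                if all(np.linalg.norm(cand - p) >= 1.2 for p in pts[:-1]):
                    break
            pts.append(cand if n_ligand_atoms > 1 else pts[-1])
        lig = np.array(pts[:n_ligand_atoms])
        lig -= lig.mean(axis=0)
        lig += np.array([0.0, 0.0, 0.30 * pocket_depth])
        dmin_rl = np.min(
            np.linalg.norm(rec_pts[:, None, :] - lig[None, :, :], axis=2)
        )
        if dmin_rl >= 2.5:
            break
    else:
        raise GenerationError("could not place ligand clash-free after 256 retries")

    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    serial = 1
    for i in range(n_residues):
        res_name = _AA20[int(rng.integers(0, 20))]
        for name, xyz in (("CA", ca[i]), ("CB", cb[i])):
            atoms.append(Atom(serial, name, "C", "A", i + 1, res_name, "protein"))
            coords.append(xyz)
            serial += 1
    receptor = Structure(atoms, np.array(coords), structure_id=f"synth{seed}")
    lig_atoms = [
        Atom(serial + j, f"C{j + 1}", "C", "L", 1, "LIG", "hetero")
        for j in range(n_ligand_atoms)
    ]
    ligand = Structure(lig_atoms, lig, structure_id=f"synth{seed}")
    return ComplexModel(receptor, ligand, complex_id=f"synth{seed}")


def perturb_ensemble(
    c: ComplexModel,
    n: int,
    sigma: float,
    drift: float = 0.0,
    seed: int = 0,
    interval_ps: float = 10.0,
) -> TrajectoryEnsemble:
    """Emulate MD snapshots: i.i.d. Gaussian coordinate noise per snapshot plus
    an optional rigid-body drift of the ligand (``k * drift`` Angstrom along a
    fixed random unit vector at snapshot k, zero-based)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if sigma < 0 or drift < 0:
        raise ValueError("sigma and drift must be >= 0")
    rng = np.random.default_rng(seed)
    merged = c.merged()
    base = merged.coords
    lig_mask = c.ligand_mask
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    snaps = np.empty((n, merged.n_atoms, 3))
    for k in range(n):
        snap = base + rng.normal(0.0, sigma, size=base.shape)
        snap[lig_mask] += k * drift * direction
        snaps[k] = snap
    times = interval_ps * np.arange(1, n + 1)
    return TrajectoryEnsemble(merged, snaps, times)


def select_snapshots(
    t: TrajectoryEnsemble, window_ps: tuple[float, float], interval_ps: float
) -> TrajectoryEnsemble:
    """Pick snapshots with time in ``(start, end]`` at the given spacing.

    The window is half-open on the left so that e.g. the last 2 ns of an 8 ns
    run sampled every 10 ps yields exactly 200 frames.
    """
    start, end = window_ps
    if interval_ps <= 0:
        raise ValueError("interval must be > 0")
    if start >= end:
        raise SelectionError("empty window")
    if end > t.times[-1] + 1e-9:
        raise SelectionError(
            f"window end {end} ps beyond trajectory end {t.times[-1]} ps"
        )
    wanted = start + interval_ps * np.arange(1, int(round((end - start) / interval_ps)) + 1)
    wanted = wanted[wanted <= end + 1e-9]
    idx = []
    for w in wanted:
        j = np.argmin(np.abs(t.times - w))
        if abs(t.times[j] - w) < 1e-6 * max(1.0, interval_ps):
            idx.append(int(j))
    if not idx:
        raise SelectionError("no snapshots fall in the requested window/spacing")
    idx = sorted(set(idx))
    return TrajectoryEnsemble(t.template, t.coords[idx], t.times[idx])


def superpose_to_first(
    t: TrajectoryEnsemble, selection=BACKBONE_NAMES
) -> TrajectoryEnsemble:
    """Rigidly fit every snapshot onto snapshot 1 using the named atoms
    (default backbone N, CA, C, O). Snapshot 1 is returned unchanged."""
    mask = t.template.name_mask(selection)
    if mask.sum() < 3:
        raise DegenerateFitError("selection matched fewer than 3 atoms")
    ref = t.coords[0][mask]
    out = t.coords.copy()
    for k in range(1, t.n_snapshots):
        R, trans, _ = kabsch(ref, t.coords[k][mask])
        out[k] = apply_transform(t.coords[k], R, trans)
    return TrajectoryEnsemble(t.template, out, t.times.copy())


def rmsd_series(t: TrajectoryEnsemble, selection_mask: np.ndarray):
    """Per-snapshot RMSD of the selected atoms against snapshot 1.

    The ensemble is assumed already superposed (see
    :func:`superpose_to_first`); no refitting is done here.
    """
    mask = np.asarray(selection_mask, dtype=bool)
    if mask.sum() == 0:
        raise SelectionError("empty selection for RMSD series")
    ref = t.coords[0][mask]
    out = []
    for k in range(t.n_snapshots):
        d = t.coords[k][mask] - ref
        out.append((float(t.times[k]), float(np.sqrt((d**2).sum() / mask.sum()))))
    return out
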