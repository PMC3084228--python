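"""Topology construction: resolved parameters, bonded lists, exclusions."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import ParameterizationError
from ..structio import ComplexModel, Structure
from .forcefield import ForceFieldSpec

# fallback covalent-ish bond detection radius per element (A)
_COVALENT = {"H": 0.4, "C": 0.85, "N": 0.8, "O": 0.75, "S": 1.05, "P": 1.1}


@dataclass
class ParameterizedSystem:
    """A structure with fully resolved force-field parameters.

    ``pair_scale_vdw`` / ``pair_scale_ee`` are dense (n, n) matrices holding
    0 for excluded 1-2/1-3 pairs and self, the 1-4 scale factors, and 1
    elsewhere; fine at the few-hundred-atom scale this toolkit targets.
    """

    structure: Structure
    types: list[str]
    charge: np.ndarray
    epsilon: np.ndarray
    rmin_half: np.ndarray
    mass: np.ndarray
    gb_radius: np.ndarray
    gb_screen: np.ndarray
    lcpo_radius: np.ndarray
    lcpo_p: np.ndarray  # (n, 4)
    bonds: np.ndarray  # (nb, 2) int
    bond_k: np.ndarray
    bond_r0: np.ndarray
    angles: np.ndarray  # (na, 3) int
    angle_k: np.ndarray
    angle_t0: np.ndarray  # radians
    torsions: list  # list of (i, j, k, l, [(vn, n, phase_rad), ...])
    pair_scale_vdw: np.ndarray
    pair_scale_ee: np.ndarray
    globals: dict
    receptor_mask: np.ndarray | None = None
    ligand_mask: np.ndarray | None = None

    @property
    def n_atoms(self) -> int:
        return self.structure.n_atoms

    def subsystem(self, mask: np.ndarray) -> "ParameterizedSystem":
        """Slice out a subsystem (e.g. receptor-only) keeping intramolecular
        terms; bonded terms crossing the mask boundary are dropped."""
        mask = np.asarray(mask, dtype=bool)
        idx = np.flatnonzero(mask)
        remap = -np.ones(self.n_atoms, dtype=int)
        remap[idx] = np.arange(idx.size)

        def keep(rows):
            return np.array([all(mask[i] for i in row) for row in rows], dtype=bool)

        bk = keep(self.bonds) if len(self.bonds) else np.zeros(0, bool)
        ak = keep(self.angles) if len(self.angles) else np.zeros(0, bool)
        new_torsions = [
            (remap[i], remap[j], remap[k], remap[l], terms)
            for i, j, k, l, terms in self.torsions
            if mask[i] and mask[j] and mask[k] and mask[l]
        ]
        return ParameterizedSystem(
            structure=self.structure.subset(mask),
            types=[t for t, m in zip(self.types, mask) if m],
            charge=self.charge[mask],
            epsilon=self.epsilon[mask],
            rmin_half=self.rmin_half[mask],
            mass=self.mass[mask],
            gb_radius=self.gb_radius[mask],
            gb_screen=self.gb_screen[mask],
            lcpo_radius=self.lcpo_radius[mask],
            lcpo_p=self.lcpo_p[mask],
            bonds=remap[self.bonds[bk]] if bk.any() else np.zeros((0, 2), int),
            bond_k=self.bond_k[bk],
            bond_r0=self.bond_r0[bk],
            angles=remap[self.angles[ak]] if ak.any() else np.zeros((0, 3), int),
            angle_k=self.angle_k[ak],
            angle_t0=self.angle_t0[ak],
            torsions=new_torsions,
            pair_scale_vdw=self.pair_scale_vdw[np.ix_(mask, mask)],
            pair_scale_ee=self.pair_scale_ee[np.ix_(mask, mask)],
            globals=self.globals,
        )


def _detect_bonds(structure: Structure) -> list[tuple[int, int]]:
    coords = structure.coords
    elems = [a.element for a in structure.atoms]
    bonds = []
    n = structure.n_atoms
    for i in range(n):
        for j in range(i + 1, n):
            cutoff = 1.25 * (
                _COVALENT.get(elems[i], 0.85) + _COVALENT.get(elems[j], 0.85)
            )
            if np.linalg.norm(coords[i] - coords[j]) < cutoff:
                bonds.append((i, j))
    return bonds


def build_system(
    c: ComplexModel,
    ff: ForceFieldSpec,
    bonds: list[tuple[int, int]] | None = None,
) -> ParameterizedSystem:
    """Resolve parameters for a complex and derive the bonded topology.

    Bonds come from (in order of preference) the ``bonds`` argument, the
    parameter file's explicit ``topology`` section, or covalent-distance
    detection. Angles and torsions are enumerated from the bond graph;
    1-2/1-3 pairs are excluded from nonbonded sums and 1-4 pairs scaled.
    """
    merged = c.merged()
    n = merged.n_atoms
    types, params = [], []
    for a in merged.atoms:
        t = ff.assign_type(a.residue_name, a.name, a.element)
        if t not in ff.atom_types:
            raise ParameterizationError(f"atom type {t!r} has no parameters")
        types.append(t)
        params.append(ff.atom_types[t])

    if bonds is None:
        bonds = ff.explicit_bonds if ff.explicit_bonds is not None else _detect_bonds(merged)

    bond_idx, bond_k, bond_r0 = [], [], []
    for b in bonds:
        if len(b) >= 4:  # inline (i, j, k, r0)
            i, j = sorted((int(b[0]), int(b[1])))
            bond_idx.append((i, j))
            bond_k.append(float(b[2]))
            bond_r0.append(float(b[3]))
        else:
            i, j = sorted((int(b[0]), int(b[1])))
            bp = ff.bond_params(types[i], types[j])
            if bp is None:
                raise ParameterizationError(
                    f"no bond parameters for {types[i]}-{types[j]}"
                )
            bond_idx.append((i, j))
            bond_k.append(bp["k"])
            bond_r0.append(bp["r0"])

    neighbors: list[set[int]] = [set() for _ in range(n)]
    for i, j in bond_idx:
        neighbors[i].add(j)
        neighbors[j].add(i)

    angle_idx, angle_k, angle_t0 = [], [], []
    if ff.explicit_angles is not None:
        for i, j, k, kc, t0 in ff.explicit_angles:
            angle_idx.append((int(i), int(j), int(k)))
            angle_k.append(float(kc))
            angle_t0.append(np.deg2rad(float(t0)))
    else:
        for j in range(n):
            nb = sorted(neighbors[j])
            for ai in range(len(nb)):
                for ci in range(ai + 1, len(nb)):
                    i, k = nb[ai], nb[ci]
                    ap = ff.angle_params(types[i], types[j], types[k])
                    if ap is None:
                        continue  # coarse models omit some angle classes
                    angle_idx.append((i, j, k))
                    angle_k.append(ap["k"])
                    angle_t0.append(np.deg2rad(ap["theta0"]))

    torsions = []
    for j, k in bond_idx:
        for i in sorted(neighbors[j] - {k}):
            for l in sorted(neighbors[k] - {j}):
                if i == l:
                    continue
                tp = ff.torsion_params(types[i], types[j], types[k], types[l])
                if tp is None:
                    continue
                terms = [
                    (t["vn"], int(t["n"]), np.deg2rad(t.get("phase", 0.0)))
                    for t in tp
                ]
                torsions.append((i, j, k, l, terms))

    g = ff.globals
    scale_vdw = np.ones((n, n))
    scale_ee = np.ones((n, n))
    np.fill_diagonal(scale_vdw, 0.0)
    np.fill_diagonal(scale_ee, 0.0)
    # structural 1-2 and 1-3 exclusions from the bond graph
    for i, j in bond_idx:
        scale_vdw[i, j] = scale_vdw[j, i] = 0.0
        scale_ee[i, j] = scale_ee[j, i] = 0.0
    for j in range(n):
        nb = sorted(neighbors[j])
        for ai in range(len(nb)):
            for ci in range(ai + 1, len(nb)):
                i, k = nb[ai], nb[ci]
                scale_vdw[i, k] = scale_vdw[k, i] = 0.0
                scale_ee[i, k] = scale_ee[k, i] = 0.0
    # structural 1-4 pairs scaled (unless excluded by a shorter path)
    for j, k in bond_idx:
        for i in neighbors[j] - {k}:
            for l in neighbors[k] - {j}:
                if i != l and scale_vdw[i, l] != 0.0:
                    scale_vdw[i, l] = scale_vdw[l, i] = g["scale_vdw_14"]
                    scale_ee[i, l] = scale_ee[l, i] = g["scale_ee_14"]

    n_rec = c.receptor.n_atoms
    rec_mask = np.zeros(n, dtype=bool)
    rec_mask[:n_rec] = True

    return ParameterizedSystem(
        structure=merged,
        types=types,
        charge=np.array([p.charge for p in params]),
        epsilon=np.array([p.epsilon for p in params]),
        rmin_half=np.array([p.rmin_half for p in params]),
        mass=np.array([p.mass for p in params]),
        gb_radius=np.array([p.gb_radius for p in params]),
        gb_screen=np.array([p.gb_screen for p in params]),
        lcpo_radius=np.array([p.lcpo_radius for p in params]),
        lcpo_p=np.array([p.lcpo_p for p in params]),
        bonds=np.array(bond_idx, int).reshape(-1, 2),
        bond_k=np.array(bond_k),
        bond_r0=np.array(bond_r0),
        angles=np.array(angle_idx, int).reshape(-1, 3),
        angle_k=np.array(angle_k),
        angle_t0=np.array(angle_t0),
        torsions=torsions,
        pair_scale_vdw=scale_vdw,
        pair_scale_ee=scale_ee,
        globals=dict(g),
        receptor_mask=rec_mask,
        ligand_mask=~rec_mask,
    )
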