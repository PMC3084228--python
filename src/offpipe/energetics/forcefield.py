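"""Force-field parameter files: schema, validation and synthetic blocks.

The parameter file is JSON with four sections:

``atom_types``
    per-type: ``charge`` (e), ``epsilon`` (kcal/mol), ``rmin_half`` (A),
    ``mass`` (amu), ``gb_radius`` (A, intrinsic Born radius), ``gb_screen``
    (dimensionless descreening factor) and ``lcpo`` (``radius`` in A plus
    coefficients ``p1..p4``).
``type_rules``
    ordered matching rules ``{"residue", "name", "element", "type"}`` (any
    field may be ``"*"``); the first matching rule assigns the atom type.
``bonds`` / ``angles`` / ``torsions``
    harmonic bond ``k`` (kcal/mol/A^2) and ``r0`` (A); harmonic angle ``k``
    (kcal/mol/rad^2) and ``theta0`` (degrees); torsion Fourier terms
    ``[{"vn", "n", "phase"}]`` (kcal/mol, periodicity, degrees). Keys are
    '-'-joined type names, matched in either direction.
``topology`` (optional)
    explicit ``bonds`` as atom-index pairs ``[i, j]`` or, with inline
    parameters, ``[i, j, k, r0]``; optional explicit ``angles``
    ``[i, j, k, k_const, theta0_deg]``. Used by coarse-grained synthetic
    systems whose bead spacing defeats covalent-distance detection and whose
    reference geometry is the generated fold itself.
``globals``
    defaulted when absent: eps_in 1.0, eps_out 78.5 (interior/solvent
    dielectric), gamma 0.0072 kcal/mol/A^2, k_coulomb 332.0636
    kcal*A/mol/e^2, probe_radius 1.4 A, temperature 298 K, 1-4 scalings
    0.5 (vdW) and 1/1.2 (electrostatics).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from ..errors import SchemaError
from ..structio import ComplexModel

DEFAULT_GLOBALS = {
    "eps_in": 1.0,
    "eps_out": 78.5,
    "gamma": 0.0072,
    "k_coulomb": 332.0636,
    "probe_radius": 1.4,
    "temperature": 298.0,
    "scale_vdw_14": 0.5,
    "scale_ee_14": 1.0 / 1.2,
    "gb_offset": 0.09,
}

# modified-Bondi-style intrinsic Born radii (A) and HCT screening factors by
# element; editable through the parameter file's atom_types section
MBONDI2_RADII = {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.50, "S": 1.80, "P": 1.85}
GB_SCREEN = {"H": 0.85, "C": 0.72, "N": 0.79, "O": 0.85, "S": 0.96, "P": 0.86}

_MANDATORY_TYPE_FIELDS = ("charge", "epsilon", "rmin_half", "mass")


@dataclass
class AtomType:
    charge: float
    epsilon: float
    rmin_half: float
    mass: float
    gb_radius: float
    gb_screen: float
    lcpo_radius: float
    lcpo_p: tuple[float, float, float, float]


@dataclass
class ForceFieldSpec:
    atom_types: dict[str, AtomType]
    type_rules: list[dict]
    bonds: dict[str, dict]
    angles: dict[str, dict]
    torsions: dict[str, list]
    globals: dict[str, float]
    explicit_bonds: list[tuple] | None = None
    explicit_angles: list[tuple] | None = None

    def assign_type(self, residue: str, name: str, element: str) -> str:
        for rule in self.type_rules:
            if (
                rule.get("residue", "*") in ("*", residue)
                and rule.get("name", "*") in ("*", name)
                and rule.get("element", "*") in ("*", element)
            ):
                return rule["type"]
        raise SchemaError(
            f"no type rule matches atom {name!r} in residue {residue!r}"
        )

    def bond_params(self, ta: str, tb: str):
        for key in (f"{ta}-{tb}", f"{tb}-{ta}"):
            if key in self.bonds:
                return self.bonds[key]
        return None

    def angle_params(self, ta: str, tb: str, tc: str):
        for key in (f"{ta}-{tb}-{tc}", f"{tc}-{tb}-{ta}"):
            if key in self.angles:
                return self.angles[key]
        return None

    def torsion_params(self, ta: str, tb: str, tc: str, td: str):
        for key in (f"{ta}-{tb}-{tc}-{td}", f"{td}-{tc}-{tb}-{ta}"):
            if key in self.torsions:
                return self.torsions[key]
        # wildcard middle-bond torsion
        for key in (f"*-{tb}-{tc}-*", f"*-{tc}-{tb}-*"):
            if key in self.torsions:
                return self.torsions[key]
        return None


def _parse_atom_type(name: str, raw: dict) -> AtomType:
    for f in _MANDATORY_TYPE_FIELDS:
        if f not in raw:
            raise SchemaError(f"atom type {name!r}: missing field {f!r}")
    lcpo = raw.get("lcpo", {})
    at = AtomType(
        charge=float(raw["charge"]),
        epsilon=float(raw["epsilon"]),
        rmin_half=float(raw["rmin_half"]),
        mass=float(raw["mass"]),
        gb_radius=float(raw.get("gb_radius", 1.7)),
        gb_screen=float(raw.get("gb_screen", 0.72)),
        lcpo_radius=float(lcpo.get("radius", raw.get("rmin_half", 1.7))),
        lcpo_p=(
            float(lcpo.get("p1", 1.0)),
            float(lcpo.get("p2", 0.0)),
            float(lcpo.get("p3", 0.0)),
            float(lcpo.get("p4", 0.0)),
        ),
    )
    if at.epsilon < 0:
        raise SchemaError(f"atom type {name!r}: epsilon must be >= 0")
    if at.rmin_half <= 0 or at.gb_radius <= 0 or at.lcpo_radius <= 0:
        raise SchemaError(f"atom type {name!r}: radii must be > 0")
    if at.mass <= 0:
        raise SchemaError(f"atom type {name!r}: mass must be > 0")
    return at


def load_forcefield(source) -> ForceFieldSpec:
    """Load and validate a parameter file (path, file object or dict)."""
    if isinstance(source, dict):
        raw = source
    elif hasattr(source, "read"):
        raw = json.load(source)
    else:
        with open(source) as fh:
            raw = json.load(fh)
    if "atom_types" not in raw or not raw["atom_types"]:
        raise SchemaError("parameter file has no atom_types section")
    atom_types = {
        name: _parse_atom_type(name, spec) for name, spec in raw["atom_types"].items()
    }
    g = dict(DEFAULT_GLOBALS)
    g.update(raw.get("globals", {}))
    if not g["eps_out"] > g["eps_in"] >= 1.0:
        raise SchemaError("dielectrics must satisfy eps_out > eps_in >= 1")
    rules = raw.get("type_rules", [])
    for rule in rules:
        if "type" not in rule or rule["type"] not in atom_types:
            raise SchemaError(f"type rule {rule!r} names an unknown atom type")
    topo = raw.get("topology", {})
    explicit_b = topo.get("bonds")
    explicit_a = topo.get("angles")
    return ForceFieldSpec(
        atom_types=atom_types,
        type_rules=rules,
        bonds=raw.get("bonds", {}),
        angles=raw.get("angles", {}),
        torsions=raw.get("torsions", {}),
        globals=g,
        explicit_bonds=(
            [tuple(b) for b in explicit_b] if explicit_b is not None else None
        ),
        explicit_angles=(
            [tuple(a) for a in explicit_a] if explicit_a is not None else None
        ),
    )


# LCPO coefficients for the coarse synthetic carbon bead (radius 1.7 A),
# calibrated once against numerical sphere-sampling areas on a training set
# of random clusters; see docs/methods.md.
_SYNTH_LCPO = {
    "radius": 1.70,
    "p1": 1.00063417,
    "p2": -0.99589893,
    "p3": -0.03340681,
    "p4": 0.00724938,
}


def synthetic_parameter_block(c: ComplexModel) -> dict:
    """Minimal parameter block matching a synthetic complex.

    The coarse-grained model uses three atom types — receptor backbone bead
    (CAB), receptor side-chain bead (CBB) and ligand carbon (LIG) — with
    alternating small charges (net-neutral-ish) and soft LJ beads. Bonds
    (CA(i)-CA(i+1), CA(i)-CB(i), sequential ligand chain) and angles carry
    inline equilibrium values measured from the generated geometry, making
    the emitted fold its own bonded reference state; bead spacing is far
    beyond covalent detection range, hence the explicit topology.
    """
    merged = c.merged()
    coords = merged.coords
    n_rec = c.receptor.n_atoms
    pairs: list[tuple[int, int, float]] = []  # (i, j, k_bond)
    ca_idx = [i for i, a in enumerate(c.receptor.atoms) if a.name == "CA"]
    cb_idx = {a.residue_number: i for i, a in enumerate(c.receptor.atoms) if a.name == "CB"}
    for k in range(len(ca_idx) - 1):
        pairs.append((ca_idx[k], ca_idx[k + 1], 10.0))
    for i in ca_idx:
        resnum = c.receptor.atoms[i].residue_number
        if resnum in cb_idx:
            pairs.append((i, cb_idx[resnum], 10.0))
    for j in range(c.ligand.n_atoms - 1):
        pairs.append((n_rec + j, n_rec + j + 1, 100.0))
    bonds = [
        [i, j, kb, round(float(np.linalg.norm(coords[i] - coords[j])), 4)]
        for i, j, kb in pairs
    ]
    neighbors: dict[int, list[int]] = {}
    for i, j, _ in pairs:
        neighbors.setdefault(i, []).append(j)
        neighbors.setdefault(j, []).append(i)
    angles = []
    for j, nb in sorted(neighbors.items()):
        nb = sorted(nb)
        for a in range(len(nb)):
            for b in range(a + 1, len(nb)):
                i, k = nb[a], nb[b]
                v1, v2 = coords[i] - coords[j], coords[k] - coords[j]
                theta = np.degrees(
                    np.arccos(
                        np.clip(
                            v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)),
                            -1.0,
                            1.0,
                        )
                    )
                )
                angles.append([i, j, k, 5.0, round(float(theta), 3)])

    def bead(charge):
        return {
            "charge": charge,
            "epsilon": 0.1094,
            "rmin_half": 1.908,
            "mass": 12.011,
            "gb_radius": MBONDI2_RADII["C"],
            "gb_screen": GB_SCREEN["C"],
            "lcpo": dict(_SYNTH_LCPO),
        }

    return {
        "atom_types": {"CAB": bead(-0.10), "CBB": bead(0.10), "LIG": bead(-0.05)},
        "type_rules": [
            {"residue": "LIG", "name": "*", "element": "*", "type": "LIG"},
            {"residue": "*", "name": "CA", "element": "*", "type": "CAB"},
            {"residue": "*", "name": "CB", "element": "*", "type": "CBB"},
        ],
        "bonds": {},
        "angles": {},
        "torsions": {
            "*-CAB-CAB-*": [{"vn": 0.2, "n": 3, "phase": 0.0}],
            "*-LIG-LIG-*": [{"vn": 0.2, "n": 3, "phase": 0.0}],
        },
        "topology": {"bonds": bonds, "angles": angles},
        "globals": {},
    }
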