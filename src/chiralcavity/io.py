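"""Reading and writing molecular structures and topology files.

Coordinates travel in the standard small-molecule formats (PDB, XYZ, MOL2,
parsed through MDAnalysis); interaction metadata -- charges, vdW types,
H-bond roles, masses, bonded terms -- travels in a package-defined JSON/TOML
topology file keyed by atom order.  MOL2 is the only structure format that
also carries charges and connectivity.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np

from .structures import (
    AngleTerm,
    Atom,
    BondTerm,
    ParameterizedMolecule,
    TorsionTerm,
)

__all__ = [
    "FormatError",
    "read_structure",
    "write_structure",
    "load_topology",
    "save_topology",
    "apply_topology",
]


class FormatError(ValueError):
    """A structure file does not parse in the named dialect."""


_EXT_FORMATS = {".pdb": "pdb", ".xyz": "xyz", ".mol2": "mol2"}


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in ("pdb", "xyz", "mol2"):
            raise ValueError(f"unsupported format {fmt!r}")
        return fmt
    try:
        return _EXT_FORMATS[path.suffix.lower()]
    except KeyError:
        raise ValueError(
            f"cannot infer structure format from suffix {path.suffix!r}"
        ) from None


def _validate_pdb(path: Path) -> None:
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")):
            if len(line.rstrip("\n")) < 54:
                raise FormatError(
                    f"{path.name}:{lineno}: truncated PDB atom record: {line!r}"
                )
            try:
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
            except ValueError:
                raise FormatError(
                    f"{path.name}:{lineno}: unparseable PDB coordinates: {line!r}"
                ) from None


def _validate_xyz(path: Path) -> None:
    lines = path.read_text().splitlines()
    if not lines:
        raise FormatError(f"{path.name}:1: empty XYZ file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise FormatError(
            f"{path.name}:1: XYZ files start with the atom count"
        ) from None
    if len(lines) < n + 2:
        raise FormatError(f"{path.name}: expected {n} atom lines, file too short")
    for k in range(n):
        lineno = k + 3
        parts = lines[k + 2].split()
        if len(parts) < 4:
            raise FormatError(
                f"{path.name}:{lineno}: XYZ atom line needs 'element x y z'"
            )
        try:
            [float(x) for x in parts[1:4]]
        except ValueError:
            raise FormatError(
                f"{path.name}:{lineno}: unparseable XYZ coordinates"
            ) from None


def read_structure(
    path,
    format: str | None = None,
    topology=None,
    warn_missing_topology: bool = True,
) -> ParameterizedMolecule:
    """Read a molecule from a PDB, XYZ or MOL2 file.

    ``topology`` may be a path to a JSON/TOML topology file or an already
    loaded topology dict; without one, bonded-term lists are left empty (a
    warning is issued) and charges/types default to zero/element symbol
    except for MOL2, which supplies charges and connectivity itself.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "pdb":
        _validate_pdb(path)
    elif fmt == "xyz":
        _validate_xyz(path)

    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(path), format=fmt.upper() if fmt == "xyz" else None)
        except Exception as exc:  # noqa: BLE001 - normalize backend errors
            raise FormatError(f"{path.name}: {exc}") from exc

        if hasattr(u.atoms, "elements") and all(u.atoms.elements):
            elements = [str(e).capitalize() for e in u.atoms.elements]
        else:
            elements = [
                "".join(c for c in str(nm) if c.isalpha())[:2].capitalize() or "X"
                for nm in u.atoms.names
            ]
        charges = (
            u.atoms.charges.astype(float)
            if hasattr(u.atoms, "charges")
            else np.zeros(len(u.atoms))
        )
        positions = u.atoms.positions.astype(float)
        atoms = [
            Atom(
                element=el,
                position=pos,
                charge=float(q),
                vdw_type=el,
                hbond_role="none",
            )
            for el, pos, q in zip(elements, positions, charges)
        ]
        mol = ParameterizedMolecule(atoms=atoms, name=path.stem)
        if fmt == "mol2" and hasattr(u, "bonds"):
            xyz = mol.coords()
            for bond in u.bonds:
                i, j = (int(x) for x in bond.indices)
                r = float(np.linalg.norm(xyz[j] - xyz[i]))
                # connectivity only: zero force constant at current length
                mol.bonds.append(BondTerm(i, j, 0.0, r))

    if topology is not None:
        topo = load_topology(topology) if not isinstance(topology, dict) else topology
        apply_topology(mol, topo)
    elif warn_missing_topology and fmt != "mol2":
        warnings.warn(
            f"{path.name}: no topology file given; bonded terms empty and "
            "charges/types defaulted",
            stacklevel=2,
        )
    return mol


def write_structure(mol: ParameterizedMolecule, path, format: str | None = None):
    """Write a molecule to PDB, XYZ or MOL2 (1-based serials per format)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    xyz = mol.coords()
    if fmt == "xyz":
        lines = [str(mol.n_atoms), mol.name or "written by chiralcavity"]
        for el, p in zip(mol.elements(), xyz):
            lines.append(f"{el:<4s} {p[0]:18.8f} {p[1]:18.8f} {p[2]:18.8f}")
        path.write_text("\n".join(lines) + "\n")
        return
    if fmt == "pdb":
        lines = []
        for k, (el, p) in enumerate(zip(mol.elements(), xyz), start=1):
            name = f"{el}{k}"[:4]
            lines.append(
                f"HETATM{k:5d} {name:<4s} MOL A   1    "
                f"{p[0]:8.3f}{p[1]:8.3f}{p[2]:8.3f}  1.00  0.00"
                f"          {el:>2s}"
            )
        lines.append("END")
        path.write_text("\n".join(lines) + "\n")
        return
    # MOL2
    lines = [
        "@<TRIPOS>MOLECULE",
        mol.name or "chiralcavity",
        f"{mol.n_atoms} {len(mol.bonds)} 0 0 0",
        "SMALL",
        "USER_CHARGES",
        "@<TRIPOS>ATOM",
    ]
    for k, a in enumerate(mol.atoms, start=1):
        p = a.position
        lines.append(
            f"{k:>7d} {a.element}{k:<4d} {p[0]:12.6f} {p[1]:12.6f} "
            f"{p[2]:12.6f} {a.element:<5s} 1 MOL {a.charge:12.6f}"
        )
    lines.append("@<TRIPOS>BOND")
    for k, b in enumerate(mol.bonds, start=1):
        lines.append(f"{k:>6d} {b.i + 1:>5d} {b.j + 1:>5d} 1")
    path.write_text("\n".join(lines) + "\n")


# ----------------------------------------------------------------- topology
def load_topology(path) -> dict:
    path = Path(path)
    if path.suffix == ".toml":
        import tomllib

        return tomllib.loads(path.read_text())
    return json.loads(path.read_text())


def apply_topology(mol: ParameterizedMolecule, topo: dict) -> ParameterizedMolecule:
    """Apply a topology dict (charges, types, roles, bonded terms) in place."""
    atoms = topo.get("atoms", [])
    if atoms and len(atoms) != mol.n_atoms:
        raise ValueError(
            f"topology lists {len(atoms)} atoms, structure has {mol.n_atoms}"
        )
    for a, spec in zip(mol.atoms, atoms):
        if "charge" in spec:
            a.charge = float(spec["charge"])
        if "vdw_type" in spec:
            a.vdw_type = str(spec["vdw_type"])
        if "hbond_role" in spec:
            a.hbond_role = str(spec["hbond_role"])
        if "mass" in spec:
            a.mass = float(spec["mass"])
        if "element" in spec:
            a.element = str(spec["element"])
    mol.bonds = [
        BondTerm(int(b[0]), int(b[1]), float(b[2]), float(b[3]))
        for b in topo.get("bonds", [])
    ]
    mol.angles = [
        AngleTerm(int(a[0]), int(a[1]), int(a[2]), float(a[3]), float(a[4]))
        for a in topo.get("angles", [])
    ]
    mol.torsions = [
        TorsionTerm(
            int(t["atoms"][0]), int(t["atoms"][1]),
            int(t["atoms"][2]), int(t["atoms"][3]),
            terms=tuple(
                (float(x[0]), int(x[1]), float(x[2])) for x in t["terms"]
            ),
        )
        for t in topo.get("torsions", [])
    ]
    if "chiral_center_index" in topo:
        idx = topo["chiral_center_index"]
        mol.chiral_center_index = None if idx is None else int(idx)
    mol.validate()
    return mol


def save_topology(mol: ParameterizedMolecule, path) -> None:
    topo = {
        "atoms": [
            {
                "element": a.element,
                "charge": a.charge,
                "vdw_type": a.vdw_type,
                "hbond_role": a.hbond_role,
                "mass": a.mass,
            }
            for a in mol.atoms
        ],
        "bonds": [[b.i, b.j, b.k_r, b.r_eq] for b in mol.bonds],
        "angles": [[a.i, a.j, a.k, a.k_theta, a.theta_eq] for a in mol.angles],
        "torsions": [
            {"atoms": [t.i, t.j, t.k, t.l], "terms": [list(x) for x in t.terms]}
            for t in mol.torsions
        ],
        "chiral_center_index": mol.chiral_center_index,
    }
    Path(path).write_text(json.dumps(topo, indent=2))
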