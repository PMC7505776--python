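"""Force-field parameter tables and precomputed host-guest pair tables.

Nonbonded parameters live in a package-defined TOML/JSON table: per-type van
der Waals well parameters (r*, eps) and per-type-pair hydrogen-bond 10-12
coefficients (C, D).  Combining rules follow the additive-radius convention:
``r*_ij = r*_i + r*_j`` and ``eps_ij = sqrt(eps_i eps_j)``, giving
``A_ij = eps_ij r*_ij^12`` and ``B_ij = 2 eps_ij r*_ij^6``.

A :class:`PairTable` flattens everything the energy kernels need for one
host-guest pair of molecules into dense arrays: per-pair A, B, scaled charge
products, and the list of donor-H/acceptor pairs with their 10-12
coefficients and donor parent atoms (for the angular gate).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .constants import COULOMB_CONSTANT, HBOND_ANGLE_MIN, HBOND_RMAX
from .structures import HostFrame, ParameterizedMolecule

__all__ = [
    "ParameterTable",
    "PairTable",
    "DielectricModel",
    "ParameterLookupError",
    "default_table",
    "load_parameter_table",
    "save_parameter_table",
]


class ParameterLookupError(KeyError):
    """An atom's vdw_type is absent from the loaded parameter table."""


@dataclass(frozen=True)
class DielectricModel:
    """Scalar relative permittivity scaling the electrostatic term."""

    epsilon: float = 1.0

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("dielectric constant must be positive")


@dataclass
class ParameterTable:
    """vdW (r*, eps) per type and H-bond (C, D) per type pair."""

    vdw: dict = field(default_factory=dict)      # type -> (rstar A, eps kcal/mol)
    hbond: dict = field(default_factory=dict)    # (t1, t2) sorted -> (C, D)

    def vdw_params(self, vdw_type: str):
        try:
            return self.vdw[vdw_type]
        except KeyError:
            raise ParameterLookupError(
                f"vdw_type {vdw_type!r} not in parameter table"
            ) from None

    def lj_ab(self, type_i: str, type_j: str):
        ri, ei = self.vdw_params(type_i)
        rj, ej = self.vdw_params(type_j)
        rstar = ri + rj
        eps = float(np.sqrt(ei * ej))
        return eps * rstar ** 12, 2.0 * eps * rstar ** 6

    def hbond_cd(self, type_i: str, type_j: str):
        """(C, D) for a donor-H/acceptor type pair, or None if not tabulated."""
        key = tuple(sorted((type_i, type_j)))
        return self.hbond.get(key)

    def merged(self, other: "ParameterTable") -> "ParameterTable":
        vdw = dict(self.vdw)
        vdw.update(other.vdw)
        hb = dict(self.hbond)
        hb.update(other.hbond)
        return ParameterTable(vdw=vdw, hbond=hb)

    # -- serialization ----------------------------------------------
    def to_dict(self) -> dict:
        return {
            "vdw": {t: {"rstar": r, "eps": e} for t, (r, e) in self.vdw.items()},
            "hbond": {
                f"{a}:{b}": {"C": c, "D": d}
                for (a, b), (c, d) in self.hbond.items()
            },
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ParameterTable":
        vdw = {
            t: (float(v["rstar"]), float(v["eps"]))
            for t, v in data.get("vdw", {}).items()
        }
        hbond = {}
        for key, v in data.get("hbond", {}).items():
            a, b = key.split(":")
            hbond[tuple(sorted((a, b)))] = (float(v["C"]), float(v["D"]))
        return cls(vdw=vdw, hbond=hbond)


def load_parameter_table(path) -> ParameterTable:
    """Read a parameter table from a .json or .toml file."""
    path = Path(path)
    if path.suffix == ".toml":
        import tomllib

        data = tomllib.loads(path.read_text())
    else:
        data = json.loads(path.read_text())
    return ParameterTable.from_dict(data)


def save_parameter_table(table: ParameterTable, path) -> None:
    Path(path).write_text(json.dumps(table.to_dict(), indent=2))


def default_table() -> ParameterTable:
    """Built-in nonbonded parameters.

    Covers the coarse fixture site types plus a small subset of AMBER-style
    all-atom types (aliphatic/aromatic carbon, amine/hydroxyl hydrogen and
    oxygen/nitrogen acceptors).  The generic donor-H/acceptor 10-12 pair
    bottoms out near -0.5 kcal/mol at ~1.95 A.
    """
    vdw = {
        # AMBER-style all-atom subset (r* per atom in A, eps in kcal/mol)
        "CT": (1.908, 0.1094),
        "CA": (1.908, 0.0860),
        "HC": (1.487, 0.0157),
        "H": (0.600, 0.0157),
        "HO": (0.200, 0.0200),
        "OH": (1.721, 0.2104),
        "O": (1.661, 0.2100),
        "O2": (1.661, 0.2100),
        "N": (1.824, 0.1700),
        "N3": (1.824, 0.1700),
        # coarse fixture site types (each bead stands for a whole chemical
        # group, hence the deep wells relative to single-atom parameters)
        "RING": (1.80, 0.70),
        "SITE_A": (1.70, 0.40),
        "SITE_B": (1.70, 0.40),
        "SITE_C": (1.70, 0.80),
        "SUB_1": (1.60, 0.25),
        "SUB_2": (1.60, 0.25),
        "SUB_3": (1.70, 0.45),
        "SUB_4": (1.20, 0.05),
        "CORE": (1.70, 0.20),
        "PROBE": (1.90, 0.60),
        "WALL": (1.80, 0.70),
        "RIM_D": (0.60, 0.02),
        "RIM_A": (1.66, 0.25),
    }
    hbond = {
        tuple(sorted(("H", "O"))): (7557.0, 2385.0),
        tuple(sorted(("HO", "O"))): (7557.0, 2385.0),
        tuple(sorted(("H", "OH"))): (7557.0, 2385.0),
        tuple(sorted(("RIM_D", "RIM_A"))): (7557.0, 2385.0),
        tuple(sorted(("RIM_D", "SUB_3"))): (7557.0, 2385.0),
        tuple(sorted(("SUB_4", "RIM_A"))): (7557.0, 2385.0),
    }
    return ParameterTable(vdw=vdw, hbond=hbond)


def _donor_parents(mol: ParameterizedMolecule) -> dict:
    """Map donor-hydrogen atom index -> parent heavy atom index.

    The parent is the bonded partner when the molecule carries bonds,
    otherwise the nearest non-hydrogen atom.
    """
    xyz = mol.coords()
    parents = {}
    bonded = {}
    for b in mol.bonds:
        bonded.setdefault(b.i, []).append(b.j)
        bonded.setdefault(b.j, []).append(b.i)
    for i, a in enumerate(mol.atoms):
        if a.hbond_role != "donor_hydrogen":
            continue
        cands = bonded.get(i)
        if not cands:
            cands = [
                j
                for j, other in enumerate(mol.atoms)
                if j != i and not other.element.startswith("H")
            ]
        if not cands:
            cands = [j for j in range(mol.n_atoms) if j != i]
        d = np.linalg.norm(xyz[cands] - xyz[i], axis=1)
        parents[i] = int(cands[int(np.argmin(d))])
    return parents


@dataclass
class PairTable:
    """Dense per-pair interaction arrays for one host-guest system.

    Shapes are ``(n_guest, n_host)``.  ``lj_active`` masks out donor-H /
    acceptor pairs, which are scored by the 10-12 hydrogen-bond term while
    their geometric gate passes and by the plain Lennard-Jones term
    otherwise.  H-bond pair metadata is stored in flat arrays so numba
    kernels can iterate them directly.
    """

    a: np.ndarray
    b: np.ndarray
    qq: np.ndarray          # k_c q_i q_j / eps, ready to divide by r
    hb_gi: np.ndarray       # guest atom index of each H-bond pair
    hb_hi: np.ndarray       # host atom index
    hb_c: np.ndarray
    hb_d: np.ndarray
    hb_parent: np.ndarray   # donor parent atom index (own molecule)
    hb_parent_is_guest: np.ndarray  # parent on guest side?
    hb_rmax: float = HBOND_RMAX
    #: gate passes when cos(donor-H...acceptor angle) <= hb_cos_max
    hb_cos_max: float = float(np.cos(np.deg2rad(HBOND_ANGLE_MIN)))
    epsilon: float = 1.0

    @classmethod
    def build(
        cls,
        host: HostFrame | ParameterizedMolecule,
        guest: ParameterizedMolecule,
        table: ParameterTable,
        model: DielectricModel = DielectricModel(),
        hb_rmax: float = HBOND_RMAX,
        hb_angle_min: float = HBOND_ANGLE_MIN,
    ) -> "PairTable":
        hmol = host.molecule if isinstance(host, HostFrame) else host
        nh, ng = hmol.n_atoms, guest.n_atoms
        a = np.zeros((ng, nh))
        b = np.zeros((ng, nh))
        htypes, gtypes = hmol.vdw_types(), guest.vdw_types()
        for gi in range(ng):
            for hi in range(nh):
                a[gi, hi], b[gi, hi] = table.lj_ab(gtypes[gi], htypes[hi])
        qq = (
            COULOMB_CONSTANT
            / model.epsilon
            * np.outer(guest.charges(), hmol.charges())
        )
        g_parents = _donor_parents(guest)
        h_parents = _donor_parents(hmol)
        hb = []
        for gi, ga in enumerate(guest.atoms):
            for hi, ha in enumerate(hmol.atoms):
                pair = None
                if ga.hbond_role == "donor_hydrogen" and ha.hbond_role == "acceptor":
                    cd = table.hbond_cd(gtypes[gi], htypes[hi])
                    if cd is not None:
                        pair = (gi, hi, cd[0], cd[1], g_parents[gi], True)
                elif ga.hbond_role == "acceptor" and ha.hbond_role == "donor_hydrogen":
                    cd = table.hbond_cd(gtypes[gi], htypes[hi])
                    if cd is not None:
                        pair = (gi, hi, cd[0], cd[1], h_parents[hi], False)
                if pair is not None:
                    hb.append(pair)
        if hb:
            hb_gi, hb_hi, hb_c, hb_d, hb_parent, hb_pg = map(np.array, zip(*hb))
        else:
            hb_gi = hb_hi = hb_parent = np.zeros(0, dtype=np.int64)
            hb_c = hb_d = np.zeros(0)
            hb_pg = np.zeros(0, dtype=bool)
        return cls(
            a=a,
            b=b,
            qq=qq,
            hb_gi=hb_gi.astype(np.int64),
            hb_hi=hb_hi.astype(np.int64),
            hb_c=hb_c.astype(float),
            hb_d=hb_d.astype(float),
            hb_parent=hb_parent.astype(np.int64),
            hb_parent_is_guest=hb_pg.astype(bool),
            hb_rmax=float(hb_rmax),
            hb_cos_max=float(np.cos(np.deg2rad(hb_angle_min))),
            epsilon=model.epsilon,
        )
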