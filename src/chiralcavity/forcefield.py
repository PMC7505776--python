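"""AMBER-type interaction energies and analytic forces.

The interaction energy between host and guest is decomposed, as in the
classic Weiner force field, into

``E = E_inter + E_intra``,
``E_inter = E_LJ + E_ele + E_Hbond``,
``E_intra = E_bond + E_angle + E_torsion``,

with a 12-6 Lennard-Jones term, a dielectric-scaled Coulomb term, a gated
12-10 hydrogen-bond term, and harmonic bond/angle plus Fourier torsion
intramolecular terms.  All energies are kcal/mol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .constants import COULOMB_CONSTANT, E_CAP
from .parameters import DielectricModel, PairTable, ParameterTable, default_table
from .structures import (
    GeometryError,
    HostFrame,
    ParameterizedMolecule,
    Pose,
)

__all__ = [
    "EnergyBreakdown",
    "HostGuestSystem",
    "lj_pair_energy",
    "coulomb_pair_energy",
    "hbond_pair_energy",
    "inter_energy",
    "intra_energy",
    "relax_internal",
    "force_and_torque",
]


@dataclass
class EnergyBreakdown:
    """The six energy components with derived inter/intra/total sums.

    ``capped`` marks configurations where a clash pushed a component past
    the cap and it was clipped.
    """

    e_lj: float = 0.0
    e_ele: float = 0.0
    e_hbond: float = 0.0
    e_bond: float = 0.0
    e_angle: float = 0.0
    e_torsion: float = 0.0
    capped: bool = False

    @property
    def e_inter(self) -> float:
        return self.e_lj + self.e_ele + self.e_hbond

    @property
    def e_intra(self) -> float:
        return self.e_bond + self.e_angle + self.e_torsion

    @property
    def e_total(self) -> float:
        return self.e_inter + self.e_intra

    def __add__(self, other: "EnergyBreakdown") -> "EnergyBreakdown":
        return EnergyBreakdown(
            self.e_lj + other.e_lj,
            self.e_ele + other.e_ele,
            self.e_hbond + other.e_hbond,
            self.e_bond + other.e_bond,
            self.e_angle + other.e_angle,
            self.e_torsion + other.e_torsion,
            self.capped or other.capped,
        )

    def as_dict(self) -> dict:
        return {
            "E_LJ": self.e_lj,
            "E_ele": self.e_ele,
            "E_Hbond": self.e_hbond,
            "E_bond": self.e_bond,
            "E_angle": self.e_angle,
            "E_torsion": self.e_torsion,
            "E_inter": self.e_inter,
            "E_intra": self.e_intra,
            "E": self.e_total,
        }


# ------------------------------------------------------------ pair formulas
def lj_pair_energy(r: float, a: float, b: float) -> float:
    """12-6 Lennard-Jones pair energy A/r^12 - B/r^6."""
    if r <= 0:
        raise ValueError("pair distance must be positive")
    return a / r ** 12 - b / r ** 6


def coulomb_pair_energy(
    r: float, qi: float, qj: float, model: DielectricModel = DielectricModel()
) -> float:
    """Dielectric-scaled Coulomb energy k_c qi qj / (eps r)."""
    if r <= 0:
        raise ValueError("pair distance must be positive")
    return COULOMB_CONSTANT * qi * qj / (model.epsilon * r)


def hbond_pair_energy(
    r: float, c: float, d: float, geometry_ok: bool = True
) -> float:
    """Gated 12-10 hydrogen-bond energy C/r^12 - D/r^10.

    Contributes only while the donor-H...acceptor geometry fits; the pair's
    Lennard-Jones term is suppressed while the gate passes.
    """
    if r <= 0:
        raise ValueError("pair distance must be positive")
    if not geometry_ok:
        return 0.0
    return c / r ** 12 - d / r ** 10


# --------------------------------------------------------------- the system
class HostGuestSystem:
    """A host frame and a rigid guest with precomputed pair tables.

    This is the unit the scanning and dynamics engines consume; it caches
    the flattened pair arrays so per-pose evaluations stay cheap.
    """

    def __init__(
        self,
        host: HostFrame,
        guest: ParameterizedMolecule,
        table: ParameterTable | None = None,
        model: DielectricModel = DielectricModel(),
        e_cap: float = E_CAP,
        hb_rmax: float | None = None,
        hb_angle_min: float | None = None,
    ):
        self.host = host
        self.guest = guest
        self.table = table if table is not None else default_table()
        self.model = model
        self.e_cap = float(e_cap)
        kwargs = {}
        if hb_rmax is not None:
            kwargs["hb_rmax"] = hb_rmax
        if hb_angle_min is not None:
            kwargs["hb_angle_min"] = hb_angle_min
        self.pairs = PairTable.build(host, guest, self.table, model, **kwargs)
        self.host_xyz = host.molecule.coords()
        self.guest_ref = guest.coords() - guest.center_of_mass()

    def _kernel_args(self):
        p = self.pairs
        return (
            self.host_xyz, p.a, p.b, p.qq,
            p.hb_gi, p.hb_hi, p.hb_c, p.hb_d, p.hb_parent,
            p.hb_parent_is_guest, p.hb_rmax, p.hb_cos_max,
        )

    def inter_components(self, guest_rot: np.ndarray, coms: np.ndarray):
        """Batch (m, 3) [LJ, ELE, HB] components + capped flags."""
        return _kernels.energy_components(
            guest_rot, coms, *self._kernel_args(), self.e_cap
        )

    def inter_energy(self, pose: Pose) -> EnergyBreakdown:
        rot = pose.rotation.apply(self.guest_ref)
        comp, capped = self.inter_components(
            rot, pose.com.reshape(1, 3)
        )
        return EnergyBreakdown(
            e_lj=float(comp[0, 0]),
            e_ele=float(comp[0, 1]),
            e_hbond=float(comp[0, 2]),
            capped=bool(capped[0]),
        )

    def force_torque(self, pose: Pose):
        gxyz = pose.rotation.apply(self.guest_ref) + pose.com
        return _kernels.force_torque(gxyz, pose.com, *self._kernel_args())


# ----------------------------------------------------------- module surface
def inter_energy(
    host: HostFrame,
    guest: ParameterizedMolecule,
    pose: Pose,
    model: DielectricModel = DielectricModel(),
    table: ParameterTable | None = None,
    e_cap: float = E_CAP,
) -> EnergyBreakdown:
    """Intermolecular energy components for one guest pose."""
    return HostGuestSystem(host, guest, table, model, e_cap).inter_energy(pose)


def force_and_torque(
    host: HostFrame,
    guest: ParameterizedMolecule,
    pose: Pose,
    model: DielectricModel = DielectricModel(),
    table: ParameterTable | None = None,
):
    """Analytic intermolecular force and torque (about COM) on the guest."""
    sys = HostGuestSystem(host, guest, table, model)
    f, tau = sys.force_torque(pose)
    return np.asarray(f), np.asarray(tau)


def _dihedral(p0, p1, p2, p3) -> float:
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    n1n = np.linalg.norm(n1)
    n2n = np.linalg.norm(n2)
    b1n = np.linalg.norm(b1)
    if n1n < 1e-10 or n2n < 1e-10 or b1n < 1e-10:
        raise GeometryError("undefined dihedral: collinear atom triple")
    m1 = np.cross(n1, b1 / b1n)
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return math.atan2(y, x)


def intra_energy(
    mol: ParameterizedMolecule, conformation: np.ndarray | None = None
) -> EnergyBreakdown:
    """Intramolecular bond/angle/torsion energy of one conformation.

    ``E_bond = sum K_r (r - r_eq)^2``, ``E_angle = sum K_theta
    (theta - theta_eq)^2``, ``E_torsion = sum (V_n/2)(1 + cos(n phi -
    gamma))`` over the molecule's bonded-term lists.
    """
    xyz = np.asarray(conformation, float) if conformation is not None else mol.coords()
    e_bond = 0.0
    for b in mol.bonds:
        r = np.linalg.norm(xyz[b.j] - xyz[b.i])
        e_bond += b.k_r * (r - b.r_eq) ** 2
    e_angle = 0.0
    for a in mol.angles:
        v1 = xyz[a.i] - xyz[a.j]
        v2 = xyz[a.k] - xyz[a.j]
        n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
        if n1 < 1e-10 or n2 < 1e-10:
            raise GeometryError("undefined angle: coincident atoms")
        cosang = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
        e_angle += a.k_theta * (math.acos(cosang) - a.theta_eq) ** 2
    e_torsion = 0.0
    for t in mol.torsions:
        phi = _dihedral(xyz[t.i], xyz[t.j], xyz[t.k], xyz[t.l])
        for half_v, n, gamma in t.terms:
            e_torsion += half_v * (1.0 + math.cos(n * phi - gamma))
    return EnergyBreakdown(e_bond=e_bond, e_angle=e_angle, e_torsion=e_torsion)


def _rotatable_torsions(mol: ParameterizedMolecule):
    """Unique central bonds (j, k) of torsions plus the atom set each
    rotation moves (the k-side of the bond graph with edge j-k cut)."""
    adj = {}
    for b in mol.bonds:
        adj.setdefault(b.i, set()).add(b.j)
        adj.setdefault(b.j, set()).add(b.i)
    seen = set()
    out = []
    for t in mol.torsions:
        key = (min(t.j, t.k), max(t.j, t.k))
        if key in seen:
            continue
        seen.add(key)
        # BFS from k without crossing the j-k edge
        moving = {t.k}
        stack = [t.k]
        while stack:
            cur = stack.pop()
            for nb in adj.get(cur, ()):
                if cur == t.k and nb == t.j:
                    continue
                if nb not in moving and nb != t.j:
                    moving.add(nb)
                    stack.append(nb)
        moving.discard(t.k)
        if moving and t.j not in moving:
            out.append((t.j, t.k, sorted(moving)))
    return out


def relax_internal(
    host: HostFrame,
    guest: ParameterizedMolecule,
    pose: Pose,
    model: DielectricModel = DielectricModel(),
    table: ParameterTable | None = None,
    max_steps: int = 50,
    step_deg: float = 2.0,
    max_total_deg: float = 30.0,
):
    """Relax the guest's rotatable torsions at a fixed rigid pose.

    Backtracking gradient descent on the torsion angles of the guest's
    rotatable bonds, minimizing the total energy E = E_inter + E_intra with
    the host held rigid.  Guaranteed monotone non-increasing E; total
    angular displacement per torsion is bounded by ``max_total_deg``.
    Returns ``(relaxed_guest, EnergyBreakdown)``.  With no rotatable
    torsions this is an exact no-op.
    """
    softs = _rotatable_torsions(guest)
    sys0 = HostGuestSystem(host, guest, table, model)

    def total_energy(g: ParameterizedMolecule) -> EnergyBreakdown:
        s = HostGuestSystem(host, g, table, model)
        return s.inter_energy(pose) + intra_energy(g)

    if not softs:
        return guest.copy(), sys0.inter_energy(pose) + intra_energy(guest)

    work = guest.copy()

    def rotate_torsion(g, j, k, moving, delta_rad):
        xyz = g.coords()
        axis = xyz[k] - xyz[j]
        axis = axis / np.linalg.norm(axis)
        from scipy.spatial.transform import Rotation as _R

        rot = _R.from_rotvec(axis * delta_rad)
        xyz[moving] = rot.apply(xyz[moving] - xyz[k]) + xyz[k]
        g.set_coords(xyz)

    angles = np.zeros(len(softs))  # cumulative displacement per torsion
    e_cur = total_energy(work)
    h = math.radians(0.05)
    for _ in range(max_steps):
        grad = np.zeros(len(softs))
        for s, (j, k, moving) in enumerate(softs):
            probe = work.copy()
            rotate_torsion(probe, j, k, moving, h)
            e_plus = total_energy(probe).e_total
            probe = work.copy()
            rotate_torsion(probe, j, k, moving, -h)
            e_minus = total_energy(probe).e_total
            grad[s] = (e_plus - e_minus) / (2 * h)
        if not np.all(np.isfinite(grad)):
            raise FloatingPointError("non-finite torsion gradient")
        gnorm = np.abs(grad).max()
        if gnorm < 1e-10:
            break
        step = math.radians(step_deg)
        improved = False
        while step > 1e-7:
            deltas = -grad / gnorm * step
            cap = math.radians(max_total_deg)
            deltas = np.clip(angles + deltas, -cap, cap) - angles
            trial = work.copy()
            for s, (j, k, moving) in enumerate(softs):
                if deltas[s] != 0.0:
                    rotate_torsion(trial, j, k, moving, deltas[s])
            e_new = total_energy(trial)
            if e_new.e_total < e_cur.e_total - 1e-14:
                work = trial
                angles = angles + deltas
                e_cur = e_new
                improved = True
                break
            step *= 0.5
        if not improved:
            break
    return work, e_cur
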