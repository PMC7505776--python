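"""Molecular structures, rigid poses and the host-fixed coordinate frame.

The package works on parameterized all-atom molecules: each atom carries a
position, a partial charge, a van der Waals type key and an H-bond role.
Bonded terms (bonds, angles, torsions) live on the molecule and feed the
intramolecular energy.  A :class:`HostFrame` is a host molecule expressed in
its body frame -- cavity axis along Z, origin at the cavity center of mass --
together with the rim planes and a radius profile used for inside/outside
tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .constants import ELEMENT_MASSES

__all__ = [
    "Atom",
    "BondTerm",
    "AngleTerm",
    "TorsionTerm",
    "ParameterizedMolecule",
    "Pose",
    "HostFrame",
    "GeometryError",
    "mirror_molecule",
    "align_host",
    "guest_axis_angles",
]

HBOND_ROLES = ("donor_hydrogen", "acceptor", "none")


class GeometryError(ValueError):
    """Raised for degenerate molecular geometry (collinear atoms, etc.)."""


@dataclass
class Atom:
    """A point particle with interaction metadata.

    Parameters
    ----------
    element : str
        Chemical symbol ("X" for coarse fixture sites).
    position : (3,) array_like
        Cartesian coordinates, Angstrom.
    charge : float
        Partial charge, elementary charges.
    vdw_type : str
        Key into the van der Waals parameter table.
    hbond_role : {"donor_hydrogen", "acceptor", "none"}
    mass : float, optional
        Atomic mass in amu; defaults to the element mass.
    """

    element: str
    position: np.ndarray
    charge: float = 0.0
    vdw_type: str = ""
    hbond_role: str = "none"
    mass: Optional[float] = None

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("atom position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("atom position must be finite")
        if not math.isfinite(self.charge):
            raise ValueError("atom charge must be finite")
        if self.hbond_role not in HBOND_ROLES:
            raise ValueError(f"unknown hbond_role {self.hbond_role!r}")
        if self.mass is None:
            self.mass = ELEMENT_MASSES.get(self.element, 12.0)


@dataclass(frozen=True)
class BondTerm:
    i: int
    j: int
    k_r: float      # kcal mol^-1 A^-2
    r_eq: float     # A


@dataclass(frozen=True)
class AngleTerm:
    i: int
    j: int
    k: int
    k_theta: float  # kcal mol^-1 rad^-2
    theta_eq: float  # rad


@dataclass(frozen=True)
class TorsionTerm:
    i: int
    j: int
    k: int
    l: int
    #: sequence of (V_n/2 [kcal/mol], n [int], gamma [rad]) Fourier terms
    terms: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "terms", tuple(tuple(t) for t in self.terms))
        if len(self.terms) == 0:
            raise ValueError("torsion must carry at least one Fourier term")


@dataclass
class ParameterizedMolecule:
    """Atoms plus the bonded terms every energy routine consumes."""

    atoms: list
    bonds: list = field(default_factory=list)
    angles: list = field(default_factory=list)
    torsions: list = field(default_factory=list)
    chiral_center_index: Optional[int] = None
    name: str = ""

    # -- array views -------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (self.n_atoms, 3):
            raise ValueError("coordinate array shape mismatch")
        for a, p in zip(self.atoms, xyz):
            a.position = np.array(p, dtype=float)

    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    def elements(self) -> list:
        return [a.element for a in self.atoms]

    def vdw_types(self) -> list:
        return [a.vdw_type for a in self.atoms]

    def total_mass(self) -> float:
        return float(self.masses().sum())

    def center_of_mass(self) -> np.ndarray:
        m = self.masses()
        return (self.coords() * m[:, None]).sum(axis=0) / m.sum()

    def copy(self) -> "ParameterizedMolecule":
        return ParameterizedMolecule(
            atoms=[replace(a, position=a.position.copy()) for a in self.atoms],
            bonds=list(self.bonds),
            angles=list(self.angles),
            torsions=list(self.torsions),
            chiral_center_index=self.chiral_center_index,
            name=self.name,
        )

    def validate(self) -> None:
        n = self.n_atoms
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise ValueError("bond index out of range")
        for a in self.angles:
            if not all(0 <= x < n for x in (a.i, a.j, a.k)):
                raise ValueError("angle index out of range")
        for t in self.torsions:
            if not all(0 <= x < n for x in (t.i, t.j, t.k, t.l)):
                raise ValueError("torsion index out of range")
        if self.chiral_center_index is not None and not (
            0 <= self.chiral_center_index < n
        ):
            raise ValueError("chiral_center_index out of range")

    # -- geometry ----------------------------------------------------
    def inertia_tensor(self, about_com: bool = True) -> np.ndarray:
        xyz = self.coords()
        m = self.masses()
        if about_com:
            xyz = xyz - self.center_of_mass()
        r2 = (xyz ** 2).sum(axis=1)
        eye = np.eye(3)
        return (m[:, None, None] * (r2[:, None, None] * eye
                                    - xyz[:, :, None] * xyz[:, None, :])).sum(axis=0)

    def principal_frame(self):
        """Principal moments and the body->reference rotation.

        Returns ``(moments, rotation)`` where ``moments`` are the principal
        moments of inertia (amu A^2, ascending) and ``rotation`` maps
        body-frame coordinates onto COM-centred reference coordinates.
        """
        inertia = self.inertia_tensor()
        w, v = np.linalg.eigh(inertia)
        if np.linalg.det(v) < 0:
            v[:, 2] = -v[:, 2]
        return w, Rotation.from_matrix(v)


@dataclass
class Pose:
    """Guest rigid-body disposition: COM position + orientation quaternion.

    The quaternion is stored scalar-first ``(w, x, y, z)`` and rotates the
    guest's COM-centred reference coordinates into the host frame.
    """

    com: np.ndarray
    orientation: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 0.0, 0.0, 0.0])
    )

    def __post_init__(self):
        self.com = np.asarray(self.com, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=float)
        n = np.linalg.norm(self.orientation)
        if abs(n - 1.0) > 1e-9:
            raise ValueError("pose quaternion must be unit norm")

    @property
    def rotation(self) -> Rotation:
        return Rotation.from_quat(self.orientation, scalar_first=True)

    @classmethod
    def from_rotation(cls, com, rot: Rotation) -> "Pose":
        q = rot.as_quat(scalar_first=True)
        q = q / np.linalg.norm(q)
        return cls(com=np.asarray(com, float), orientation=q)

    def apply(self, mol: ParameterizedMolecule) -> np.ndarray:
        """Guest atom coordinates in the host frame under this pose."""
        ref = mol.coords() - mol.center_of_mass()
        return self.rotation.apply(ref) + self.com


@dataclass
class HostFrame:
    """Host molecule in its body frame plus cavity geometry.

    Convention: cavity axis along Z, origin at the host center of mass, wide
    rim toward +Z (default; selectable via ``rim_spec`` in
    :func:`align_host`).  ``radius_profile_z``/``radius_profile_r`` give a
    piecewise-linear cavity radius versus z used by inside/outside tests.
    """

    molecule: ParameterizedMolecule
    z_narrow: float
    z_wide: float
    radius_profile_z: np.ndarray = None
    radius_profile_r: np.ndarray = None

    def __post_init__(self):
        self.radius_profile_z = np.asarray(self.radius_profile_z, dtype=float)
        self.radius_profile_r = np.asarray(self.radius_profile_r, dtype=float)
        if self.radius_profile_z.shape != self.radius_profile_r.shape:
            raise ValueError("radius profile arrays must have equal length")
        if np.any(self.radius_profile_r <= 0):
            raise ValueError("radius profile must be positive")

    @property
    def z_lo(self) -> float:
        return min(self.z_narrow, self.z_wide)

    @property
    def z_hi(self) -> float:
        return max(self.z_narrow, self.z_wide)

    def radius_at(self, z) -> np.ndarray:
        return np.interp(z, self.radius_profile_z, self.radius_profile_r)

    def is_inside(self, points) -> np.ndarray:
        """Whether each point lies inside the cavity volume.

        A point counts as inside iff its z lies between the rim planes and
        its distance from the axis does not exceed the cavity radius there.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        z = pts[:, 2]
        rad = np.hypot(pts[:, 0], pts[:, 1])
        ok = (z >= self.z_lo) & (z <= self.z_hi) & (rad <= self.radius_at(z))
        return ok if pts.ndim == 2 and np.asarray(points).ndim == 2 else ok


def mirror_molecule(
    mol: ParameterizedMolecule, plane: Literal["yz", "xz", "xy"] = "yz"
) -> ParameterizedMolecule:
    """Reflect a molecule through a coordinate plane.

    Charges, types, masses and bonded terms are untouched; only coordinates
    change sign along the plane normal.  Applying the same reflection twice
    restores the original coordinates exactly.
    """
    axis = {"yz": 0, "xz": 1, "xy": 2}[plane]
    out = mol.copy()
    for a in out.atoms:
        a.position[axis] = -a.position[axis]
    return out


def _slab_radius_profile(xyz: np.ndarray, n_slabs: int = 8):
    """Per-slab minimal radial atom distance along z (piecewise linear)."""
    z = xyz[:, 2]
    rad = np.hypot(xyz[:, 0], xyz[:, 1])
    z_lo, z_hi = z.min(), z.max()
    if z_hi - z_lo < 1e-9:
        return np.array([z_lo, z_hi + 1e-9]), np.array([rad.min(), rad.min()])
    edges = np.linspace(z_lo, z_hi, n_slabs + 1)
    centers, radii = [], []
    for k in range(n_slabs):
        sel = (z >= edges[k] - 1e-12) & (z <= edges[k + 1] + 1e-12)
        if not sel.any():
            continue
        centers.append(0.5 * (edges[k] + edges[k + 1]))
        radii.append(rad[sel].min())
    centers = np.array(centers)
    radii = np.array(radii)
    # extend to the rim planes so interpolation covers the full z extent
    zs = np.concatenate([[z_lo], centers, [z_hi]])
    rs = np.concatenate([[radii[0]], radii, [radii[-1]]])
    keep = np.concatenate([[True], np.diff(zs) > 1e-12])
    return zs[keep], rs[keep]


def align_host(
    mol: ParameterizedMolecule,
    rim_spec: Literal["wide_up", "narrow_up"] = "wide_up",
    n_slabs: int = 8,
) -> HostFrame:
    """Move a host into its body frame and derive the cavity geometry.

    The origin goes to the center of mass and Z to the principal symmetry
    axis, identified as the inertia eigenvector whose eigenvalue is most
    separated from the other two (for ring- and cone-shaped cavities the
    symmetry axis is the non-degenerate principal moment; it may be either
    the largest or the smallest).  The transverse orientation is fixed
    deterministically by placing the atom farthest from the axis (lowest
    index on ties) in the +X half-plane, which makes the frame invariant to
    rigid motions of the input.
    """
    if mol.n_atoms < 4:
        raise GeometryError("host needs at least 4 atoms")
    work = mol.copy()
    work.set_coords(work.coords() - work.center_of_mass())

    inertia = work.inertia_tensor()
    w, v = np.linalg.eigh(inertia)
    if w[0] < 1e-9 * max(1.0, w[2]):
        raise GeometryError("degenerate inertia tensor: collinear atoms")
    span = w[2] - w[0]
    if span < 1e-9 * max(1.0, abs(w[2])):
        raise GeometryError("degenerate inertia tensor: no unique cavity axis")
    # symmetry axis = eigenvalue most separated from the other two
    seps = np.array([
        min(abs(w[0] - w[1]), abs(w[0] - w[2])),
        min(abs(w[1] - w[0]), abs(w[1] - w[2])),
        min(abs(w[2] - w[0]), abs(w[2] - w[1])),
    ])
    axis_idx = int(np.argmax(seps))
    gap = seps[axis_idx]
    if gap < 1e-9 * max(1.0, abs(w[2])):
        raise GeometryError("degenerate inertia tensor: no unique cavity axis")
    z_axis = v[:, axis_idx]
    others = [i for i in range(3) if i != axis_idx]
    x_axis = v[:, others[0]]
    y_axis = np.cross(z_axis, x_axis)
    rot = np.column_stack([x_axis, y_axis, z_axis]).T  # lab -> body
    xyz = work.coords() @ rot.T

    def _orient(xyz):
        """Flip z (if needed) per rim_spec, then pin the azimuth."""
        z = xyz[:, 2]
        rad = np.hypot(xyz[:, 0], xyz[:, 1])
        z_lo, z_hi = z.min(), z.max()
        thick = max(z_hi - z_lo, 1e-9)
        top = z >= z_hi - 0.25 * thick
        bot = z <= z_lo + 0.25 * thick
        r_top = rad[top].min() if top.any() else 0.0
        r_bot = rad[bot].min() if bot.any() else 0.0
        wide_up = r_top >= r_bot
        want_wide_up = rim_spec == "wide_up"
        if wide_up != want_wide_up:
            # rotate pi about x to flip z while keeping right-handedness
            xyz = xyz * np.array([1.0, -1.0, -1.0])
        # pin azimuth: farthest-from-axis atom (lowest index on ties) at phi=0
        rad = np.hypot(xyz[:, 0], xyz[:, 1])
        ref = int(np.argmax(np.round(rad, 8)))  # argmax takes first on ties
        phi = math.atan2(xyz[ref, 1], xyz[ref, 0])
        c, s = math.cos(-phi), math.sin(-phi)
        rotz = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        return xyz @ rotz.T

    xyz = _orient(xyz)
    work.set_coords(xyz)
    prof_z, prof_r = _slab_radius_profile(xyz, n_slabs=n_slabs)
    z_lo, z_hi = xyz[:, 2].min(), xyz[:, 2].max()
    if rim_spec == "wide_up":
        z_narrow, z_wide = z_lo, z_hi
    else:
        z_narrow, z_wide = z_hi, z_lo
    return HostFrame(
        molecule=work,
        z_narrow=z_narrow,
        z_wide=z_wide,
        radius_profile_z=prof_z,
        radius_profile_r=prof_r,
    )


def guest_axis_angles(mol: ParameterizedMolecule, pose: Pose):
    """Spherical angles (theta, phi) of the guest's molecular axis.

    The axis is the unit vector from the chiral center to the most distant
    carbon atom (largest distance; lowest atom index on ties), expressed in
    the host frame under ``pose``.  Returns degrees with theta in [0, 180]
    and phi in [0, 360).
    """
    if mol.chiral_center_index is None:
        raise ValueError("molecule has no chiral_center_index")
    ic = mol.chiral_center_index
    xyz = mol.coords()
    carbons = [
        i for i, a in enumerate(mol.atoms) if a.element == "C" and i != ic
    ]
    if not carbons:
        raise ValueError("no carbon atoms to define the molecular axis")
    d = np.linalg.norm(xyz[carbons] - xyz[ic], axis=1)
    best = carbons[int(np.argmax(np.round(d, 8)))]
    vec = xyz[best] - xyz[ic]
    u = pose.rotation.apply(vec / np.linalg.norm(vec))
    theta = math.degrees(math.acos(np.clip(u[2], -1.0, 1.0)))
    phi = math.degrees(math.atan2(u[1], u[0])) % 360.0
    return theta, phi
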