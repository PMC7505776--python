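"""Deterministic toy hosts and guests with known symmetry properties.

Real cavity hosts (cyclodextrin-class macrocycles) and chiral guests need
curated coordinates and charges; these generators build coarse stand-ins
with the geometric features that matter -- a truncated-cone cavity, rim
H-bond sites, a stereocenter -- so every engine in the package can be
exercised and its symmetry properties verified without external data.  All
generators are pure functions of their arguments: the same spec always
yields bitwise-identical molecules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .structures import (
    Atom,
    HostFrame,
    ParameterizedMolecule,
    _slab_radius_profile,
    align_host,
    mirror_molecule,
)

__all__ = [
    "FixtureSpec",
    "ProbeHost",
    "make_achiral_cone_host",
    "make_chiral_probe_host",
    "swap_probe_handedness",
    "make_chiral_tetra_guest",
    "make_cd_like_host",
    "make_lj_probe_guest",
    "make",
]

_TETRA_DIRS = np.array(
    [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
) / math.sqrt(3.0)


@dataclass(frozen=True)
class FixtureSpec:
    kind: str
    geometry: dict = field(default_factory=dict)
    seed: int = 0


def _ring(radius: float, z: float, n: int, element: str, vdw_type: str,
          charge: float = 0.0, role: str = "none", mass: float | None = None,
          phase: float = 0.0):
    atoms = []
    for k in range(n):
        phi = 2.0 * math.pi * k / n + phase
        atoms.append(
            Atom(
                element=element,
                position=np.array(
                    [radius * math.cos(phi), radius * math.sin(phi), z]
                ),
                charge=charge,
                vdw_type=vdw_type,
                hbond_role=role,
                mass=mass,
            )
        )
    return atoms


def make_achiral_cone_host(
    ring_radii=(4.0, 6.0),
    ring_z=(-2.0, 2.0),
    atoms_per_ring: int = 12,
    vdw_type: str = "RING",
    ring_charges=None,
) -> HostFrame:
    """Two or more coaxial atom rings forming a truncated-cone shell.

    Mirror-symmetric through every plane containing the axis, hence achiral
    by construction.  ``ring_charges`` (one per ring) must balance to keep
    the host neutral; the default is uncharged.
    """
    if len(ring_radii) < 2 or len(ring_radii) != len(ring_z):
        raise ValueError("need >= 2 rings with matching radii and z offsets")
    if atoms_per_ring < 6:
        raise ValueError("need >= 6 atoms per ring")
    if len(set(np.round(ring_radii, 9))) < 2:
        raise ValueError("degenerate ring radii: not a cone")
    if ring_charges is None:
        ring_charges = [0.0] * len(ring_radii)
    if abs(sum(ring_charges) * atoms_per_ring) > 1e-9:
        raise ValueError("ring charges must balance")
    atoms = []
    for r, z, q in zip(ring_radii, ring_z, ring_charges):
        atoms.extend(_ring(r, z, atoms_per_ring, "C", vdw_type, charge=q))
    mol = ParameterizedMolecule(atoms=atoms, name="achiral_cone_host")
    return align_host(mol)


@dataclass
class ProbeHost:
    """An engineered enantiopreferring host: cone + three-point chiral motif.

    ``favored`` records which guest enantiomer of the reference tetrahedral
    probe guest the construction is designed to bind more strongly; it is a
    design input of the fixture, verified by the package's own scans.
    """

    host: HostFrame
    favored: str
    site_types: tuple


def make_chiral_probe_host(
    site_types=("SITE_A", "SITE_B", "SITE_C"),
    site_charges=(0.60, -0.60, 0.0),
    site_radius: float = 3.0,
    site_z=(-1.0, 0.5, 0.5),
    site_azimuths_deg=(0.0, 60.0, -60.0),
    favored: str = "D",
    **cone_kwargs,
) -> ProbeHost:
    """Achiral cone plus three distinct interaction sites with a handedness.

    The charged sites A (+) and B (-) plus the deep-well site C sit inside
    the cavity at azimuths (0, +d, -d); sites 2 and 3 share a z-offset and
    mirror-image azimuths, so swapping their types is exactly the mirror
    image of the original host (and flips the recorded favored enantiomer).
    The default geometry was sized against the package's own scans so that
    the D-enantiomer of the reference tetrahedral guest binds more strongly
    by roughly 3 k_B T at 293 K; ``favored`` records that design constant.  The host keeps the cone's body frame (the sites
    would otherwise tilt the principal axes off the cavity axis).  With all
    site charges zero and site well depths zeroed in the parameter table,
    the energetics reduce to the bare cone.
    """
    if len(set(site_types)) != 3:
        raise ValueError("three distinct site types required")
    if abs(site_z[1] - site_z[2]) > 1e-12:
        raise ValueError("sites 2 and 3 must share a z-offset")
    if abs(sum(site_charges)) > 1e-9:
        raise ValueError("site charges must balance")
    if abs(site_azimuths_deg[1] + site_azimuths_deg[2]) > 1e-12:
        raise ValueError("sites 2 and 3 must sit at mirror-image azimuths")
    cone = make_achiral_cone_host(**cone_kwargs)
    atoms = [a for a in cone.molecule.atoms]
    for t, q, z, az in zip(site_types, site_charges, site_z, site_azimuths_deg):
        phi = math.radians(az)
        atoms.append(
            Atom(
                element="X",
                position=np.array(
                    [site_radius * math.cos(phi), site_radius * math.sin(phi), z]
                ),
                charge=q,
                vdw_type=t,
                hbond_role="none",
                mass=20.0,
            )
        )
    mol = ParameterizedMolecule(atoms=atoms, name="chiral_probe_host")
    # collinear-site guard (three points on a line carry no handedness)
    p = mol.coords()[-3:]
    if np.linalg.norm(np.cross(p[1] - p[0], p[2] - p[0])) < 1e-9:
        raise ValueError("probe sites are collinear")
    prof_z, prof_r = _slab_radius_profile(mol.coords())
    host = HostFrame(
        molecule=mol,
        z_narrow=cone.z_narrow,
        z_wide=cone.z_wide,
        radius_profile_z=prof_z,
        radius_profile_r=prof_r,
    )
    return ProbeHost(host=host, favored=favored, site_types=tuple(site_types))


def swap_probe_handedness(
    probe: ProbeHost, site_charges=(0.60, -0.60, 0.0), **kwargs
) -> ProbeHost:
    """The mirror-image probe host: sites 2 and 3 exchange types AND
    charges (interaction parameters travel with the type).

    ``site_charges`` and extra geometry kwargs must match those used to
    build ``probe``.
    """
    st = probe.site_types
    q = site_charges
    return make_chiral_probe_host(
        site_types=(st[0], st[2], st[1]),
        site_charges=(q[0], q[2], q[1]),
        favored="D" if probe.favored == "L" else "L",
        **kwargs,
    )


def make_chiral_tetra_guest(
    bond_length: float = 1.5,
    sub_types=("SUB_1", "SUB_2", "SUB_3", "SUB_4"),
    sub_charges=(-0.30, 0.30, 0.0, 0.0),
    sub_elements=("F", "N", "C", "H"),
    sub_masses=(19.0, 14.0, 12.0, 1.0),
):
    """A minimal stereocenter: central atom with four distinct substituents.

    Returns ``(guest_L, guest_D)`` where D is the mirror image of L through
    the yz plane.  Four distinct substituent types are required -- with any
    two equal the molecule is achiral and the generator refuses.
    """
    if len(set(sub_types)) != 4:
        raise ValueError("substituent types must be four and distinct (else achiral)")
    atoms = [
        Atom(element="C", position=np.zeros(3), charge=0.0, vdw_type="CORE")
    ]
    for d, t, q, el, m in zip(
        _TETRA_DIRS, sub_types, sub_charges, sub_elements, sub_masses
    ):
        atoms.append(
            Atom(element=el, position=bond_length * d, charge=q,
                 vdw_type=t, hbond_role="none", mass=m)
        )
    guest_l = ParameterizedMolecule(
        atoms=atoms, chiral_center_index=0, name="tetra_guest_L"
    )
    guest_d = mirror_molecule(guest_l, "yz")
    guest_d.name = "tetra_guest_D"
    return guest_l, guest_d


def make_lj_probe_guest(vdw_type: str = "PROBE", element: str = "Ar"):
    """A single uncharged Lennard-Jones site (orientation-blind probe)."""
    return ParameterizedMolecule(
        atoms=[Atom(element=element, position=np.zeros(3), vdw_type=vdw_type)],
        name="lj_probe",
    )


def make_cd_like_host(n_units: int = 7) -> HostFrame:
    """Coarse cyclodextrin-like macrocycle: n repeated 3-site motifs.

    Each unit contributes a mid-wall site, a wide-rim H-bond acceptor and a
    narrow-rim donor hydrogen, all at the unit's azimuth on a truncated
    cone (7 units approximate the beta-CD geometry).  The construction is
    C_n symmetric and achiral; rim charges balance within each unit.
    """
    if n_units < 5:
        raise ValueError("need at least 5 units for a cavity")
    atoms = []
    atoms.extend(_ring(4.6, 0.0, n_units, "C", "WALL", charge=0.0))
    atoms.extend(
        _ring(5.6, 2.0, n_units, "O", "RIM_A", charge=-0.18, role="acceptor")
    )
    atoms.extend(
        _ring(3.9, -2.0, n_units, "H", "RIM_D", charge=0.18,
              role="donor_hydrogen", mass=1.008)
    )
    mol = ParameterizedMolecule(atoms=atoms, name="cd_like_host")
    return align_host(mol)


def make(spec: FixtureSpec):
    """Dispatch a FixtureSpec to its generator."""
    table = {
        "achiral_cone_host": make_achiral_cone_host,
        "chiral_probe_host": make_chiral_probe_host,
        "cd_like_host": make_cd_like_host,
        "chiral_tetra_guest": make_chiral_tetra_guest,
        "lj_probe_guest": make_lj_probe_guest,
    }
    try:
        fn = table[spec.kind]
    except KeyError:
        raise ValueError(f"unknown fixture kind {spec.kind!r}") from None
    return fn(**spec.geometry)
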