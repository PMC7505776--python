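"""Energy model: pair closed forms, decomposition, symmetries, forces."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import chiralcavity as cc
from chiralcavity.constants import COULOMB_CONSTANT
from chiralcavity.forcefield import relax_internal
from chiralcavity.structures import (
    AngleTerm,
    Atom,
    BondTerm,
    GeometryError,
    ParameterizedMolecule,
    TorsionTerm,
)

from conftest import naive_inter_energy, random_pose


# ------------------------------------------------------------- closed forms
def test_lj_closed_forms():
    a, b = 5.0e5, 1.2e3
    r_min = (2 * a / b) ** (1 / 6)
    assert cc.lj_pair_energy(r_min, a, b) == pytest.approx(
        -b ** 2 / (4 * a), abs=1e-8
    )
    # derivative vanishes at the minimum
    h = 1e-6
    d = (cc.lj_pair_energy(r_min + h, a, b) - cc.lj_pair_energy(r_min - h, a, b)) / (2 * h)
    assert d == pytest.approx(0.0, abs=1e-6)
    assert cc.lj_pair_energy(3.0, 0.0, 0.0) == 0.0
    # approaches zero from below past the minimum
    rs = np.linspace(r_min, 40.0, 200)
    es = [cc.lj_pair_energy(r, a, b) for r in rs]
    assert all(e < 0 for e in es)
    assert np.all(np.diff(es) > 0)
    with pytest.raises(ValueError):
        cc.lj_pair_energy(0.0, a, b)


def test_coulomb_closed_forms():
    assert cc.coulomb_pair_energy(1.0, 1.0, 1.0) == pytest.approx(
        COULOMB_CONSTANT, abs=1e-8
    )
    assert cc.coulomb_pair_energy(2.5, 0.0, 1.0) == 0.0
    e1 = cc.coulomb_pair_energy(1.7, 0.3, -0.4, cc.DielectricModel(1.0))
    e2 = cc.coulomb_pair_energy(1.7, 0.3, -0.4, cc.DielectricModel(2.0))
    assert e1 == pytest.approx(2.0 * e2, rel=1e-14)


def test_hbond_closed_forms():
    c, d = 7557.0, 2385.0
    assert cc.hbond_pair_energy(2.0, c, d, geometry_ok=False) == 0.0
    r_min = math.sqrt(6 * c / (5 * d))
    h = 1e-6
    slope = (
        cc.hbond_pair_energy(r_min + h, c, d) - cc.hbond_pair_energy(r_min - h, c, d)
    ) / (2 * h)
    assert slope == pytest.approx(0.0, abs=1e-6)
    # the tabulated generic donor/acceptor pair bottoms out near -0.5 kcal/mol
    assert cc.hbond_pair_energy(r_min, c, d) == pytest.approx(-0.5, abs=0.01)


# ----------------------------------------------------------- decompositions
def test_single_pair_matches_formulas(table):
    host_mol = ParameterizedMolecule(
        atoms=[Atom(element="O", position=[0, 0, 0], charge=-0.3, vdw_type="O",
                    hbond_role="acceptor")]
    )
    # align_host needs >=4 atoms; build the frame by hand for a point host
    host = cc.HostFrame(
        molecule=host_mol, z_narrow=-1.0, z_wide=1.0,
        radius_profile_z=[-1.0, 1.0], radius_profile_r=[1.0, 1.0],
    )
    guest = ParameterizedMolecule(
        atoms=[Atom(element="C", position=[0, 0, 0], charge=0.2, vdw_type="CT")]
    )
    r = 3.3
    pose = cc.Pose(com=[r, 0, 0])
    e = cc.inter_energy(host, guest, pose, table=table)
    a, b = table.lj_ab("CT", "O")
    assert e.e_lj == pytest.approx(cc.lj_pair_energy(r, a, b), abs=1e-12)
    assert e.e_ele == pytest.approx(
        cc.coulomb_pair_energy(r, 0.2, -0.3), abs=1e-12
    )
    assert e.e_hbond == 0.0


def test_inter_energy_matches_naive_oracle(cd_host, tetra_guests, table):
    gl, _ = tetra_guests
    rng = np.random.default_rng(11)
    for _ in range(12):
        pose = random_pose(rng)
        got = cc.inter_energy(cd_host, gl, pose, table=table)
        lj, ele, hb = naive_inter_energy(cd_host, gl, pose, table)
        assert got.e_lj == pytest.approx(lj, rel=1e-10, abs=1e-10)
        assert got.e_ele == pytest.approx(ele, rel=1e-10, abs=1e-10)
        assert got.e_hbond == pytest.approx(hb, rel=1e-10, abs=1e-10)


def test_zero_charges_zero_electrostatics(cone_host, tetra_guests):
    gl, _ = tetra_guests
    gl = gl.copy()
    for a in gl.atoms:
        a.charge = 0.0
    e = cc.inter_energy(cone_host, gl, cc.Pose(com=[0.5, -0.3, 0.8]))
    assert e.e_ele == 0.0


def test_breakdown_sums_consistent(cd_host, tetra_guests):
    gl, _ = tetra_guests
    rng = np.random.default_rng(5)
    for _ in range(10):
        e = cc.inter_energy(cd_host, gl, random_pose(rng))
        assert e.e_inter == pytest.approx(e.e_lj + e.e_ele + e.e_hbond, abs=1e-10)
        assert e.e_total == pytest.approx(e.e_inter + e.e_intra, abs=1e-10)


def test_parity_invariance(cd_host, tetra_guests, table):
    """Jointly reflecting host and guest leaves every component unchanged."""
    gl, _ = tetra_guests
    mirrored_host = cc.HostFrame(
        molecule=cc.mirror_molecule(cd_host.molecule, "xz"),
        z_narrow=cd_host.z_narrow, z_wide=cd_host.z_wide,
        radius_profile_z=cd_host.radius_profile_z,
        radius_profile_r=cd_host.radius_profile_r,
    )
    gm = cc.mirror_molecule(gl, "xz")
    rng = np.random.default_rng(23)
    for _ in range(25):
        pose = random_pose(rng)
        # mirror of the pose under M=diag(1,-1,1): COM reflected and the
        # rotation conjugated, whose quaternion is exactly (w, -x, y, -z)
        w, x, y, z = pose.orientation
        pose_m = cc.Pose(pose.com * np.array([1, -1, 1]),
                         orientation=[w, -x, y, -z])
        e = cc.inter_energy(cd_host, gl, pose, table=table)
        em = cc.inter_energy(mirrored_host, gm, pose_m, table=table)
        assert em.e_lj == pytest.approx(e.e_lj, abs=1e-10)
        assert em.e_ele == pytest.approx(e.e_ele, abs=1e-10)
        assert em.e_hbond == pytest.approx(e.e_hbond, abs=1e-10)


def test_rigid_motion_invariance(cone_host, tetra_guests, table):
    """Moving host and guest together leaves the energy unchanged."""
    gl, _ = tetra_guests
    rng = np.random.default_rng(4)
    pose = random_pose(rng, com_scale=2.0)
    e0 = cc.inter_energy(cone_host, gl, pose, table=table).e_inter
    for _ in range(5):
        rot = Rotation.from_rotvec(rng.normal(size=3))
        shift = rng.normal(scale=3.0, size=3)
        hmol = cone_host.molecule.copy()
        hmol.set_coords(rot.apply(hmol.coords()) + shift)
        host2 = cc.HostFrame(
            molecule=hmol, z_narrow=cone_host.z_narrow, z_wide=cone_host.z_wide,
            radius_profile_z=cone_host.radius_profile_z,
            radius_profile_r=cone_host.radius_profile_r,
        )
        pose2 = cc.Pose.from_rotation(
            rot.apply(pose.com) + shift, rot * pose.rotation
        )
        e1 = cc.inter_energy(host2, gl, pose2, table=table).e_inter
        assert e1 == pytest.approx(e0, abs=1e-9)


# ------------------------------------------------------------------- intra
def _chain_molecule():
    """Four-atom chain with one bond/angle/torsion term each."""
    atoms = [
        Atom(element="C", position=[0.0, 0.0, 0.0], vdw_type="CT"),
        Atom(element="C", position=[1.5, 0.0, 0.0], vdw_type="CT"),
        Atom(element="C", position=[2.25, 1.3, 0.0], vdw_type="CT"),
        Atom(element="C", position=[3.75, 1.3, 0.5], vdw_type="CT"),
    ]
    mol = ParameterizedMolecule(atoms=atoms)
    mol.bonds = [
        BondTerm(0, 1, 300.0, 1.5),
        BondTerm(1, 2, 300.0, 1.5012),
        BondTerm(2, 3, 300.0, 1.5811),
    ]
    theta = math.acos(
        np.dot([-1.5, 0, 0], [0.75, 1.3, 0])
        / (1.5 * np.linalg.norm([0.75, 1.3, 0]))
    )
    mol.angles = [AngleTerm(0, 1, 2, 50.0, theta)]
    mol.torsions = [TorsionTerm(0, 1, 2, 3, terms=((1.4, 3, 0.0),))]
    return mol


def test_intra_energy_terms():
    mol = _chain_molecule()
    e = cc.intra_energy(mol)
    # bonds 1 and 2 are at their equilibrium lengths; angle at equilibrium
    assert e.e_bond == pytest.approx(
        300.0 * (1.5012 - np.linalg.norm([0.75, 1.3, 0])) ** 2
        + 300.0 * (1.5811 - np.linalg.norm([1.5, 0, 0.5])) ** 2,
        abs=1e-6,
    )
    assert e.e_angle == pytest.approx(0.0, abs=1e-12)
    # stretch one bond by a known amount
    mol2 = mol.copy()
    xyz = mol2.coords()
    xyz[0, 0] -= 0.2
    mol2.set_coords(xyz)
    de = cc.intra_energy(mol2).e_bond - e.e_bond
    assert de == pytest.approx(300.0 * 0.2 ** 2, abs=1e-9)


def test_torsion_energy_range():
    mol = _chain_molecule()
    e = cc.intra_energy(mol)
    # one 3-fold term with half-barrier 1.4: E_torsion in [0, 2.8]
    assert 0.0 <= e.e_torsion <= 2.8


def test_intra_collinear_dihedral_raises():
    mol = _chain_molecule()
    xyz = mol.coords()
    xyz[2] = [3.0, 0.0, 0.0]  # makes 0-1-2 collinear
    mol.set_coords(xyz)
    with pytest.raises(GeometryError):
        cc.intra_energy(mol)


# ------------------------------------------------------------------- forces
def test_forces_match_finite_differences(cone_host, tetra_guests, table):
    gl, _ = tetra_guests
    rng = np.random.default_rng(9)
    sys_ = cc.HostGuestSystem(cone_host, gl, table)
    h = 1e-5
    for _ in range(6):
        pose = random_pose(rng, com_scale=2.5)
        f, tau = sys_.force_torque(pose)
        for k in range(3):
            dp = np.zeros(3)
            dp[k] = h
            ep = sys_.inter_energy(cc.Pose(pose.com + dp, pose.orientation))
            em = sys_.inter_energy(cc.Pose(pose.com - dp, pose.orientation))
            f_num = -(ep.e_inter - em.e_inter) / (2 * h)
            assert f[k] == pytest.approx(f_num, rel=1e-6, abs=1e-6)
        # torque against rotational finite differences about each lab axis
        for k in range(3):
            axis = np.zeros(3)
            axis[k] = h
            rp = Rotation.from_rotvec(axis) * pose.rotation
            rm = Rotation.from_rotvec(-axis) * pose.rotation
            ep = sys_.inter_energy(cc.Pose.from_rotation(pose.com, rp))
            em = sys_.inter_energy(cc.Pose.from_rotation(pose.com, rm))
            t_num = -(ep.e_inter - em.e_inter) / (2 * h)
            assert tau[k] == pytest.approx(t_num, rel=1e-5, abs=1e-6)


def test_isolated_guest_zero_force(tetra_guests, table):
    gl, _ = tetra_guests
    far = cc.Pose(com=[0.0, 0.0, 500.0])
    host = cc.fixtures.make_achiral_cone_host() if hasattr(cc, "fixtures") else None
    from chiralcavity import fixtures as fx

    host = fx.make_achiral_cone_host()
    f, tau = cc.force_and_torque(host, gl, far, table=table)
    assert np.linalg.norm(f) < 1e-12
    assert np.linalg.norm(tau) < 1e-12


def test_spherical_guest_zero_torque(cone_host, lj_probe, table):
    rng = np.random.default_rng(2)
    for _ in range(5):
        pose = random_pose(rng, com_scale=3.0)
        _, tau = cc.force_and_torque(cone_host, lj_probe, pose, table=table)
        assert np.linalg.norm(tau) == 0.0


# ----------------------------------------------------------------- caps
def test_clash_pose_is_capped(cone_host, tetra_guests):
    gl, _ = tetra_guests
    # drop the guest right onto a host ring atom
    target = cone_host.molecule.coords()[0]
    e = cc.inter_energy(cone_host, gl, cc.Pose(com=target))
    assert e.capped
    assert min(e.e_inter, cc.E_CAP) == cc.E_CAP


# ------------------------------------------------------------------- relax
def test_relax_noop_without_soft_coordinates(cone_host, tetra_guests, table):
    gl, _ = tetra_guests
    pose = cc.Pose(com=[0, 0, 0.5])
    relaxed, e = relax_internal(cone_host, gl, pose, table=table)
    np.testing.assert_array_equal(relaxed.coords(), gl.coords())
    ref = cc.inter_energy(cone_host, gl, pose, table=table) + cc.intra_energy(gl)
    assert e.e_total == pytest.approx(ref.e_total, abs=1e-12)


def test_relax_descends_torsion(cone_host, table):
    """A displaced single-term torsion relaxes back toward its minimum."""
    mol = _chain_molecule()
    pose = cc.Pose(com=[0.0, 0.0, 100.0])  # far away: intra-only problem
    host = cone_host
    e0 = cc.intra_energy(mol).e_torsion
    relaxed, e = relax_internal(
        host, mol, pose, table=table, max_steps=200, step_deg=5.0,
        max_total_deg=120.0,
    )
    e1 = cc.intra_energy(relaxed).e_torsion
    assert e1 <= e0 + 1e-12
    # 3-fold term with gamma=0 has minima where cos(3 phi) = -1
    from chiralcavity.forcefield import _dihedral

    xyz = relaxed.coords()
    phi = _dihedral(xyz[0], xyz[1], xyz[2], xyz[3])
    assert math.cos(3 * phi) == pytest.approx(-1.0, abs=1e-3)
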