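"""Shared fixtures and independent oracles for the test suite."""

import math

import numpy as np
import pytest

import chiralcavity as cc
from chiralcavity import fixtures as fx
from chiralcavity.constants import COULOMB_CONSTANT


@pytest.fixture(scope="session")
def cone_host():
    return fx.make_achiral_cone_host()


@pytest.fixture(scope="session")
def cd_host():
    return fx.make_cd_like_host()


@pytest.fixture(scope="session")
def probe_host():
    return fx.make_chiral_probe_host()


@pytest.fixture(scope="session")
def tetra_guests():
    return fx.make_chiral_tetra_guest()


@pytest.fixture(scope="session")
def lj_probe():
    return fx.make_lj_probe_guest()


@pytest.fixture(scope="session")
def table():
    return cc.default_table()


def naive_inter_energy(host, guest, pose, table, epsilon=1.0,
                       hb_rmax=2.5, hb_angle_min=135.0):
    """Independent pair-sum oracle: plain Python loops over the formulas.

    Reimplements the LJ / Coulomb / gated 10-12 decomposition from scratch
    (no shared code with the compiled kernels) for small systems.
    """
    hmol = host.molecule if hasattr(host, "molecule") else host
    gxyz = pose.apply(guest)
    hxyz = hmol.coords()
    e_lj = e_ele = e_hb = 0.0
    for gi, ga in enumerate(guest.atoms):
        for hi, ha in enumerate(hmol.atoms):
            r = math.dist(gxyz[gi], hxyz[hi])
            ri, ei = table.vdw_params(ga.vdw_type)
            rj, ej = table.vdw_params(ha.vdw_type)
            rstar, eps = ri + rj, math.sqrt(ei * ej)
            a, b = eps * rstar ** 12, 2 * eps * rstar ** 6
            lj = a / r ** 12 - b / r ** 6
            e_ele += COULOMB_CONSTANT * ga.charge * ha.charge / (epsilon * r)
            # H-bond gate
            roles = {ga.hbond_role, ha.hbond_role}
            cd = table.hbond_cd(ga.vdw_type, ha.vdw_type)
            gated = False
            if roles == {"donor_hydrogen", "acceptor"} and cd is not None:
                if ga.hbond_role == "donor_hydrogen":
                    hpos, apos = gxyz[gi], hxyz[hi]
                    ppos = _nearest_heavy(guest, gxyz, gi)
                else:
                    hpos, apos = hxyz[hi], gxyz[gi]
                    ppos = _nearest_heavy(hmol, hxyz, hi)
                if r <= hb_rmax:
                    u = ppos - hpos
                    v = apos - hpos
                    cosang = float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))
                    if cosang <= math.cos(math.radians(hb_angle_min)):
                        gated = True
            if gated:
                e_hb += cd[0] / r ** 12 - cd[1] / r ** 10
            else:
                e_lj += lj
    return e_lj, e_ele, e_hb


def _nearest_heavy(mol, xyz, i):
    best, bd = None, np.inf
    for j, a in enumerate(mol.atoms):
        if j == i or a.element.startswith("H"):
            continue
        d = float(np.linalg.norm(xyz[j] - xyz[i]))
        if d < bd:
            best, bd = j, d
    return xyz[best]


def random_pose(rng, com_scale=4.0):
    from scipy.spatial.transform import Rotation

    com = rng.uniform(-com_scale, com_scale, size=3)
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    return cc.Pose(com=com, orientation=q)
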