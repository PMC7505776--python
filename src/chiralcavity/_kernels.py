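"""Numba-compiled numerical kernels.

Everything here operates on plain float64/int64 arrays prepared by
:class:`~chiralcavity.parameters.PairTable` and the dynamics module.  The
kernels are deliberately branch-stable and use fixed summation orders so that
repeated runs (and the exhaustive-loop test oracles that call the same code
through the public API) agree bitwise.

Conventions: coordinates in A, energies kcal/mol, masses amu, time fs.
Quaternions are scalar-first (w, x, y, z) and rotate body-frame vectors into
the lab (host) frame.
"""

import numpy as np
from numba import njit

from .constants import KCAL_MOL_FS2

__all__ = [
    "energy_components",
    "force_torque",
    "run_rigid_md",
    "leapfrog_step_arrays",
]


# ----------------------------------------------------------------- energies
@njit(cache=True)
def _pair_components(
    guest_xyz, host_xyz, a, b, qq,
    hb_gi, hb_hi, hb_c, hb_d, hb_parent, hb_parent_is_guest,
    hb_rmax, hb_cos_max, e_cap,
):
    """LJ / electrostatic / H-bond sums for one guest placement.

    Donor-H/acceptor pairs whose geometric gate passes are scored by the
    10-12 term and removed from the LJ sum; otherwise they keep their plain
    LJ contribution.  Components are raw (near-overlaps contribute e_cap per
    pair instead of diverging); the returned flag marks poses whose total
    exceeds ``e_cap`` -- consumers store such totals as the cap.
    """
    ng = guest_xyz.shape[0]
    nh = host_xyz.shape[0]
    e_lj = 0.0
    e_ele = 0.0
    e_hb = 0.0
    capped = False
    for gi in range(ng):
        gx = guest_xyz[gi, 0]
        gy = guest_xyz[gi, 1]
        gz = guest_xyz[gi, 2]
        for hi in range(nh):
            dx = gx - host_xyz[hi, 0]
            dy = gy - host_xyz[hi, 1]
            dz = gz - host_xyz[hi, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < 1e-12:
                e_lj += e_cap
                capped = True
                continue
            r6 = r2 * r2 * r2
            r12 = r6 * r6
            e_lj += a[gi, hi] / r12 - b[gi, hi] / r6
            q = qq[gi, hi]
            if q != 0.0:
                e_ele += q / np.sqrt(r2)
    for p in range(hb_gi.shape[0]):
        gi = hb_gi[p]
        hi = hb_hi[p]
        dx = guest_xyz[gi, 0] - host_xyz[hi, 0]
        dy = guest_xyz[gi, 1] - host_xyz[hi, 1]
        dz = guest_xyz[gi, 2] - host_xyz[hi, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < 1e-12:
            continue
        r = np.sqrt(r2)
        if r > hb_rmax:
            continue
        # donor-H ... acceptor angle at the hydrogen vertex
        if hb_parent_is_guest[p]:
            hpos = guest_xyz[gi]
            apos = host_xyz[hi]
            ppos = guest_xyz[hb_parent[p]]
        else:
            hpos = host_xyz[hi]
            apos = guest_xyz[gi]
            ppos = host_xyz[hb_parent[p]]
        ux = ppos[0] - hpos[0]
        uy = ppos[1] - hpos[1]
        uz = ppos[2] - hpos[2]
        vx = apos[0] - hpos[0]
        vy = apos[1] - hpos[1]
        vz = apos[2] - hpos[2]
        un = np.sqrt(ux * ux + uy * uy + uz * uz)
        vn = np.sqrt(vx * vx + vy * vy + vz * vz)
        if un < 1e-12 or vn < 1e-12:
            continue
        cosang = (ux * vx + uy * vy + uz * vz) / (un * vn)
        if cosang > hb_cos_max:
            continue
        # gate passes: move this pair from the LJ sum to the H-bond term
        r6 = r2 * r2 * r2
        r12 = r6 * r6
        r10 = r12 / r2
        e_lj -= a[gi, hi] / r12 - b[gi, hi] / r6
        e_hb += hb_c[p] / r12 - hb_d[p] / r10
    if e_lj + e_ele + e_hb > e_cap:
        capped = True
    return e_lj, e_ele, e_hb, capped


@njit(cache=True)
def energy_components(
    guest_rot, coms, host_xyz, a, b, qq,
    hb_gi, hb_hi, hb_c, hb_d, hb_parent, hb_parent_is_guest,
    hb_rmax, hb_cos_max, e_cap,
):
    """Batch intermolecular components for one orientation over many COMs.

    ``guest_rot``: (n_guest, 3) rotated, COM-centred guest coordinates.
    ``coms``: (m, 3) COM placements.  Returns (m, 3) components [LJ, ELE,
    HB] and an (m,) capped flag.
    """
    m = coms.shape[0]
    ng = guest_rot.shape[0]
    out = np.empty((m, 3))
    capped = np.zeros(m, dtype=np.bool_)
    gxyz = np.empty((ng, 3))
    for k in range(m):
        for gi in range(ng):
            gxyz[gi, 0] = guest_rot[gi, 0] + coms[k, 0]
            gxyz[gi, 1] = guest_rot[gi, 1] + coms[k, 1]
            gxyz[gi, 2] = guest_rot[gi, 2] + coms[k, 2]
        lj, ele, hb, cap = _pair_components(
            gxyz, host_xyz, a, b, qq,
            hb_gi, hb_hi, hb_c, hb_d, hb_parent, hb_parent_is_guest,
            hb_rmax, hb_cos_max, e_cap,
        )
        out[k, 0] = lj
        out[k, 1] = ele
        out[k, 2] = hb
        capped[k] = cap
    return out, capped


# ------------------------------------------------------------------- forces
@njit(cache=True)
def force_torque(
    guest_xyz, com, host_xyz, a, b, qq,
    hb_gi, hb_hi, hb_c, hb_d, hb_parent, hb_parent_is_guest,
    hb_rmax, hb_cos_max,
):
    """Analytic intermolecular force and torque (about COM) on the guest.

    Gradients are those of the smooth branch currently active for each
    H-bond pair; the geometric gate itself is treated as locked, so forces
    are discontinuous exactly at gate boundaries.  Near-overlaps are guarded
    at r = 1e-6 A.  Units: kcal mol^-1 A^-1 and kcal mol^-1.
    """
    ng = guest_xyz.shape[0]
    forces = np.zeros((ng, 3))
    for gi in range(ng):
        for hi in range(host_xyz.shape[0]):
            dx = guest_xyz[gi, 0] - host_xyz[hi, 0]
            dy = guest_xyz[gi, 1] - host_xyz[hi, 1]
            dz = guest_xyz[gi, 2] - host_xyz[hi, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < 1e-12:
                r2 = 1e-12
            r = np.sqrt(r2)
            r6 = r2 * r2 * r2
            r12 = r6 * r6
            # dE/dr for LJ + Coulomb
            dedr = (-12.0 * a[gi, hi] / r12 + 6.0 * b[gi, hi] / r6) / r
            q = qq[gi, hi]
            if q != 0.0:
                dedr += -q / r2
            scale = -dedr / r
            forces[gi, 0] += scale * dx
            forces[gi, 1] += scale * dy
            forces[gi, 2] += scale * dz
    for p in range(hb_gi.shape[0]):
        gi = hb_gi[p]
        hi = hb_hi[p]
        dx = guest_xyz[gi, 0] - host_xyz[hi, 0]
        dy = guest_xyz[gi, 1] - host_xyz[hi, 1]
        dz = guest_xyz[gi, 2] - host_xyz[hi, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < 1e-12:
            continue
        r = np.sqrt(r2)
        if r > hb_rmax:
            continue
        if hb_parent_is_guest[p]:
            hpos = guest_xyz[gi]
            apos = host_xyz[hi]
            ppos = guest_xyz[hb_parent[p]]
        else:
            hpos = host_xyz[hi]
            apos = guest_xyz[gi]
            ppos = host_xyz[hb_parent[p]]
        ux = ppos[0] - hpos[0]
        uy = ppos[1] - hpos[1]
        uz = ppos[2] - hpos[2]
        vx = apos[0] - hpos[0]
        vy = apos[1] - hpos[1]
        vz = apos[2] - hpos[2]
        un = np.sqrt(ux * ux + uy * uy + uz * uz)
        vn = np.sqrt(vx * vx + vy * vy + vz * vz)
        if un < 1e-12 or vn < 1e-12:
            continue
        cosang = (ux * vx + uy * vy + uz * vz) / (un * vn)
        if cosang > hb_cos_max:
            continue
        r6 = r2 * r2 * r2
        r12 = r6 * r6
        r10 = r12 / r2
        # swap the pair's LJ gradient for the 10-12 gradient
        dedr_lj = (-12.0 * a[gi, hi] / r12 + 6.0 * b[gi, hi] / r6) / r
        dedr_hb = (-12.0 * hb_c[p] / r12 + 10.0 * hb_d[p] / r10) / r
        scale = -(dedr_hb - dedr_lj) / r
        forces[gi, 0] += scale * dx
        forces[gi, 1] += scale * dy
        forces[gi, 2] += scale * dz
    ftot = np.zeros(3)
    torque = np.zeros(3)
    for gi in range(ng):
        ftot[0] += forces[gi, 0]
        ftot[1] += forces[gi, 1]
        ftot[2] += forces[gi, 2]
        rx = guest_xyz[gi, 0] - com[0]
        ry = guest_xyz[gi, 1] - com[1]
        rz = guest_xyz[gi, 2] - com[2]
        torque[0] += ry * forces[gi, 2] - rz * forces[gi, 1]
        torque[1] += rz * forces[gi, 0] - rx * forces[gi, 2]
        torque[2] += rx * forces[gi, 1] - ry * forces[gi, 0]
    return ftot, torque


# -------------------------------------------------------------- quaternions
@njit(cache=True)
def quat_mul(p, q):
    out = np.empty(4)
    out[0] = p[0] * q[0] - p[1] * q[1] - p[2] * q[2] - p[3] * q[3]
    out[1] = p[0] * q[1] + p[1] * q[0] + p[2] * q[3] - p[3] * q[2]
    out[2] = p[0] * q[2] - p[1] * q[3] + p[2] * q[0] + p[3] * q[1]
    out[3] = p[0] * q[3] + p[1] * q[2] - p[2] * q[1] + p[3] * q[0]
    return out


@njit(cache=True)
def quat_to_mat(q):
    w, x, y, z = q[0], q[1], q[2], q[3]
    m = np.empty((3, 3))
    m[0, 0] = 1.0 - 2.0 * (y * y + z * z)
    m[0, 1] = 2.0 * (x * y - w * z)
    m[0, 2] = 2.0 * (x * z + w * y)
    m[1, 0] = 2.0 * (x * y + w * z)
    m[1, 1] = 1.0 - 2.0 * (x * x + z * z)
    m[1, 2] = 2.0 * (y * z - w * x)
    m[2, 0] = 2.0 * (x * z - w * y)
    m[2, 1] = 2.0 * (y * z + w * x)
    m[2, 2] = 1.0 - 2.0 * (x * x + y * y)
    return m


@njit(cache=True)
def quat_exp_body(w_body, dt):
    """Unit quaternion for rotation by the body rotation vector w_body*dt."""
    theta = np.sqrt(
        w_body[0] * w_body[0] + w_body[1] * w_body[1] + w_body[2] * w_body[2]
    ) * dt
    out = np.empty(4)
    if theta < 1e-14:
        out[0] = 1.0
        out[1] = 0.5 * w_body[0] * dt
        out[2] = 0.5 * w_body[1] * dt
        out[3] = 0.5 * w_body[2] * dt
        n = np.sqrt(out[0] ** 2 + out[1] ** 2 + out[2] ** 2 + out[3] ** 2)
        for i in range(4):
            out[i] /= n
        return out
    half = 0.5 * theta
    s = np.sin(half) / (theta / dt)
    out[0] = np.cos(half)
    out[1] = s * w_body[0]
    out[2] = s * w_body[1]
    out[3] = s * w_body[2]
    return out


# --------------------------------------------------------------- integrator
@njit(cache=True)
def _guest_positions(body_xyz, q, com):
    rmat = quat_to_mat(q)
    ng = body_xyz.shape[0]
    out = np.empty((ng, 3))
    for i in range(ng):
        for k in range(3):
            out[i, k] = (
                rmat[k, 0] * body_xyz[i, 0]
                + rmat[k, 1] * body_xyz[i, 1]
                + rmat[k, 2] * body_xyz[i, 2]
                + com[k]
            )
    return out


@njit(cache=True)
def _rescale(vec, mass_like, target_int):
    """Isokinetic rescale of v (scalar mass) in place; no-op on ~zero KE."""
    ke = 0.5 * mass_like * (vec[0] ** 2 + vec[1] ** 2 + vec[2] ** 2)
    if ke > 1e-300:
        f = np.sqrt(target_int / ke)
        vec[0] *= f
        vec[1] *= f
        vec[2] *= f


@njit(cache=True)
def _rescale_rot(w, inertia, target_int):
    ke = 0.5 * (
        inertia[0] * w[0] ** 2 + inertia[1] * w[1] ** 2 + inertia[2] * w[2] ** 2
    )
    if ke > 1e-300:
        f = np.sqrt(target_int / ke)
        w[0] *= f
        w[1] *= f
        w[2] *= f


@njit(cache=True)
def _omega_half_implicit(w0, taub, inertia, dt):
    """Solve w_h = w0 + dt/2 * I^-1 (taub - w_h x (I w_h)) by fixed point."""
    wh = w0.copy()
    for _ in range(100):
        lx = inertia[0] * wh[0]
        ly = inertia[1] * wh[1]
        lz = inertia[2] * wh[2]
        gx = wh[1] * lz - wh[2] * ly
        gy = wh[2] * lx - wh[0] * lz
        gz = wh[0] * ly - wh[1] * lx
        nx = w0[0] + 0.5 * dt * (taub[0] - gx) / inertia[0]
        ny = w0[1] + 0.5 * dt * (taub[1] - gy) / inertia[1]
        nz = w0[2] + 0.5 * dt * (taub[2] - gz) / inertia[2]
        d = abs(nx - wh[0]) + abs(ny - wh[1]) + abs(nz - wh[2])
        wh[0] = nx
        wh[1] = ny
        wh[2] = nz
        if d < 1e-16:
            break
    return wh


@njit(cache=True)
def _kick_rot_explicit(wh, taub, inertia, dt):
    """w1 = wh + dt/2 * I^-1 (taub - wh x (I wh)) -- mirror of the implicit
    half-kick, which makes the full step time-reversible."""
    lx = inertia[0] * wh[0]
    ly = inertia[1] * wh[1]
    lz = inertia[2] * wh[2]
    gx = wh[1] * lz - wh[2] * ly
    gy = wh[2] * lx - wh[0] * lz
    gz = wh[0] * ly - wh[1] * lx
    out = np.empty(3)
    out[0] = wh[0] + 0.5 * dt * (taub[0] - gx) / inertia[0]
    out[1] = wh[1] + 0.5 * dt * (taub[1] - gy) / inertia[1]
    out[2] = wh[2] + 0.5 * dt * (taub[2] - gz) / inertia[2]
    return out


@njit(cache=True)
def leapfrog_step_arrays(
    com, q, v, w, body_xyz, mass, inertia,
    host_xyz, a, b, qq,
    hb_gi, hb_hi, hb_c, hb_d, hb_parent, hb_parent_is_guest,
    hb_rmax, hb_cos_max,
    dt, thermostat, ke_trans_int, ke_rot_int,
):
    """One constrained-temperature rigid-body KDK leapfrog step.

    Half-kick (translation explicit, rotation implicit-midpoint), drift with
    the exact quaternion exponential map, force refresh, mirrored half-kick.
    With the thermostat on, v and w are rescaled to the exact target kinetic
    energies after every half-kick.  Returns updated (com, q, v, w).
    """
    gxyz = _guest_positions(body_xyz, q, com)
    f, tau = force_torque(
        gxyz, com, host_xyz, a, b, qq,
        hb_gi, hb_hi, hb_c, hb_d, hb_parent, hb_parent_is_guest,
        hb_rmax, hb_cos_max,
    )
    rmat = quat_to_mat(q)
    taub = np.empty(3)
    for k in range(3):
        taub[k] = (
            rmat[0, k] * tau[0] + rmat[1, k] * tau[1] + rmat[2, k] * tau[2]
        ) * KCAL_MOL_FS2
    acc = f * (KCAL_MOL_FS2 / mass)

    vh = v + 0.5 * dt * acc
    if thermostat:
        _rescale(vh, mass, ke_trans_int)
    wh = _omega_half_implicit(w, taub, inertia, dt)
    if thermostat:
        _rescale_rot(wh, inertia, ke_rot_int)

    com1 = com + dt * vh
    q1 = quat_mul(q, quat_exp_body(wh, dt))
    n = np.sqrt(q1[0] ** 2 + q1[1] ** 2 + q1[2] ** 2 + q1[3] ** 2)
    for i in range(4):
        q1[i] /= n

    gxyz = _guest_positions(body_xyz, q1, com1)
    f1, tau1 = force_torque(
        gxyz, com1, host_xyz, a, b, qq,
        hb_gi, hb_hi, hb_c, hb_d, hb_parent, hb_parent_is_guest,
        hb_rmax, hb_cos_max,
    )
    rmat1 = quat_to_mat(q1)
    taub1 = np.empty(3)
    for k in range(3):
        taub1[k] = (
            rmat1[0, k] * tau1[0] + rmat1[1, k] * tau1[1] + rmat1[2, k] * tau1[2]
        ) * KCAL_MOL_FS2
    acc1 = f1 * (KCAL_MOL_FS2 / mass)

    v1 = vh + 0.5 * dt * acc1
    if thermostat:
        _rescale(v1, mass, ke_trans_int)
    w1 = _kick_rot_explicit(wh, taub1, inertia, dt)
    if thermostat:
        _rescale_rot(w1, inertia, ke_rot_int)
    return com1, q1, v1, w1


@njit(cache=True)
def run_rigid_md(
    com, q, v, w, body_xyz, mass, inertia,
    host_xyz, a, b, qq,
    hb_gi, hb_hi, hb_c, hb_d, hb_parent, hb_parent_is_guest,
    hb_rmax, hb_cos_max, e_cap,
    dt, n_steps, record_every, thermostat, ke_trans_int, ke_rot_int,
    escape_radius,
):
    """Integrate one trajectory, recording pose + energy every few steps.

    Returns (n_rec, rec_step, rec_com, rec_quat, rec_energy[LJ,ELE,HB],
    rec_capped, term_code, final com/q/v/w, ke_dev[2]).  term_code: 0 =
    reached n_steps, 1 = escaped (|COM| > escape_radius).  ke_dev holds the
    maximum absolute deviation of the translational and rotational kinetic
    energies from their (3/2) k_B T targets over every step, in internal
    units (amu A^2 fs^-2).
    """
    max_rec = n_steps // record_every + 1
    rec_step = np.zeros(max_rec, dtype=np.int64)
    rec_com = np.zeros((max_rec, 3))
    rec_quat = np.zeros((max_rec, 4))
    rec_energy = np.zeros((max_rec, 3))
    rec_capped = np.zeros(max_rec, dtype=np.bool_)

    gxyz = _guest_positions(body_xyz, q, com)
    lj, ele, hb, cap = _pair_components(
        gxyz, host_xyz, a, b, qq,
        hb_gi, hb_hi, hb_c, hb_d, hb_parent, hb_parent_is_guest,
        hb_rmax, hb_cos_max, e_cap,
    )
    rec_step[0] = 0
    rec_com[0] = com
    rec_quat[0] = q
    rec_energy[0, 0] = lj
    rec_energy[0, 1] = ele
    rec_energy[0, 2] = hb
    rec_capped[0] = cap
    n_rec = 1

    term = 0
    ke_dev = np.zeros(2)
    for step in range(1, n_steps + 1):
        com, q, v, w = leapfrog_step_arrays(
            com, q, v, w, body_xyz, mass, inertia,
            host_xyz, a, b, qq,
            hb_gi, hb_hi, hb_c, hb_d, hb_parent, hb_parent_is_guest,
            hb_rmax, hb_cos_max,
            dt, thermostat, ke_trans_int, ke_rot_int,
        )
        ke_t = 0.5 * mass * (v[0] * v[0] + v[1] * v[1] + v[2] * v[2])
        ke_r = 0.5 * (
            inertia[0] * w[0] ** 2 + inertia[1] * w[1] ** 2
            + inertia[2] * w[2] ** 2
        )
        if abs(ke_t - ke_trans_int) > ke_dev[0]:
            ke_dev[0] = abs(ke_t - ke_trans_int)
        if abs(ke_r - ke_rot_int) > ke_dev[1]:
            ke_dev[1] = abs(ke_r - ke_rot_int)
        if step % record_every == 0:
            gxyz = _guest_positions(body_xyz, q, com)
            lj, ele, hb, cap = _pair_components(
                gxyz, host_xyz, a, b, qq,
                hb_gi, hb_hi, hb_c, hb_d, hb_parent, hb_parent_is_guest,
                hb_rmax, hb_cos_max, e_cap,
            )
            rec_step[n_rec] = step
            rec_com[n_rec] = com
            rec_quat[n_rec] = q
            rec_energy[n_rec, 0] = lj
            rec_energy[n_rec, 1] = ele
            rec_energy[n_rec, 2] = hb
            rec_capped[n_rec] = cap
            n_rec += 1
        if (
            com[0] * com[0] + com[1] * com[1] + com[2] * com[2]
            > escape_radius * escape_radius
        ):
            term = 1
            break
    return (
        n_rec, rec_step, rec_com, rec_quat, rec_energy, rec_capped, term,
        com, q, v, w, ke_dev,
    )
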