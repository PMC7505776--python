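"""Rigid-body integrator: conservation, reversibility, constraints, runs."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import chiralcavity as cc
from chiralcavity import _kernels
from chiralcavity import fixtures as fx
from chiralcavity.constants import K_BOLTZMANN, KCAL_MOL_FS2
from chiralcavity.dynamics import (
    RigidBody,
    RigidState,
    Trajectory,
    init_velocities,
    leapfrog_step,
)


def _free_body(inertia=(1.0, 1.0, 1.0), mass=10.0):
    return RigidBody(
        body_xyz=np.zeros((1, 3)),
        inertia=np.array(inertia, float),
        mass=mass,
        ref_rotation=Rotation.identity(),
    )


def _zero_force(com, q):
    return np.zeros(3), np.zeros(3)


def test_init_velocities_exact_kinetic_energies(tetra_guests):
    gl, gd = tetra_guests
    bl, bd = RigidBody.from_molecule(gl), RigidBody.from_molecule(gd)
    v, w = init_velocities(bl, 293.0, seed=42)
    ke = 1.5 * K_BOLTZMANN * 293.0
    assert 0.5 * bl.mass * (v @ v) / KCAL_MOL_FS2 == pytest.approx(ke, abs=1e-12)
    assert 0.5 * (bl.inertia @ w ** 2) / KCAL_MOL_FS2 == pytest.approx(ke, abs=1e-12)
    # direction stream is guest-independent: unit directions match exactly
    heavy = RigidBody(
        body_xyz=np.zeros((1, 3)), inertia=np.array([9.0, 5.0, 2.0]),
        mass=500.0, ref_rotation=Rotation.identity(),
    )
    v2, w2 = init_velocities(heavy, 293.0, seed=42)
    np.testing.assert_allclose(v / np.linalg.norm(v), v2 / np.linalg.norm(v2),
                               atol=1e-15)
    np.testing.assert_allclose(w / np.linalg.norm(w), w2 / np.linalg.norm(w2),
                               atol=1e-15)


def test_free_motion_is_uniform():
    body = _free_body()
    cfg = cc.MDConfig(thermostat="off", dt=1.0, t_max_ps=1.0, seed=0)
    v0 = np.array([1e-3, -2e-3, 5e-4])
    w0 = np.array([0.01, 0.02, -0.005])
    state = RigidState(com=np.zeros(3), q=np.array([1.0, 0, 0, 0]),
                       v=v0.copy(), w_body=w0.copy(), body=body)
    n = 500
    for _ in range(n):
        state = leapfrog_step(state, _zero_force, cfg)
    np.testing.assert_allclose(state.com, n * cfg.dt * v0, atol=1e-12)
    np.testing.assert_allclose(state.v, v0, atol=1e-15)
    # spherical top: |omega| conserved to machine precision
    assert np.linalg.norm(state.w_body) == pytest.approx(
        np.linalg.norm(w0), abs=1e-12
    )
    assert np.linalg.norm(state.q) == pytest.approx(1.0, abs=1e-12)


def test_harmonic_oscillator_phase_error_is_second_order():
    """1-D harmonic force: phase error shrinks ~4x when dt halves."""
    k = 2.0  # kcal mol^-1 A^-2
    mass = 10.0
    omega = math.sqrt(k * KCAL_MOL_FS2 / mass)  # rad/fs

    def force(com, q):
        return np.array([-k * com[0], 0.0, 0.0]), np.zeros(3)

    def phase_error(dt, t_total=2000.0):
        cfg = cc.MDConfig(thermostat="off", dt=dt, t_max_ps=1.0, seed=0)
        body = _free_body(mass=mass)
        x0 = 1.0
        state = RigidState(com=np.array([x0, 0, 0]), q=np.array([1.0, 0, 0, 0]),
                           v=np.zeros(3), w_body=np.zeros(3), body=body)
        n = int(round(t_total / dt))
        for _ in range(n):
            state = leapfrog_step(state, force, cfg)
        exact = x0 * math.cos(omega * t_total)
        return abs(state.com[0] - exact)

    e1, e2 = phase_error(1.0), phase_error(0.5)
    assert e1 < 5e-3
    assert e1 / e2 == pytest.approx(4.0, rel=0.3)


def test_torque_free_symmetric_top_precession():
    """Body-frame precession rate matches omega_spin (I_a - I_p) / I_p."""
    ip, ia = 1.0, 2.0
    body = _free_body(inertia=(ip, ip, ia))
    w_spin, w_t = 0.02, 0.005
    cfg = cc.MDConfig(thermostat="off", dt=1.0, t_max_ps=1.0, seed=0)
    state = RigidState(com=np.zeros(3), q=np.array([1.0, 0, 0, 0]),
                       v=np.zeros(3), w_body=np.array([w_t, 0.0, w_spin]),
                       body=body)
    n = 10000  # 10 ps
    phases = []
    for i in range(n):
        state = leapfrog_step(state, _zero_force, cfg)
    phase = math.atan2(state.w_body[1], state.w_body[0])
    expected = w_spin * (ia - ip) / ip * n * cfg.dt
    # unwrap: add the integer number of turns
    turns = round((expected - phase) / (2 * math.pi))
    phase_unwrapped = phase + 2 * math.pi * turns
    assert phase_unwrapped == pytest.approx(expected, rel=1e-3)
    # spin component about the symmetry axis is an exact invariant
    assert state.w_body[2] == pytest.approx(w_spin, rel=1e-12)


def _system_force_fn(system, body):
    def force(com, q):
        pose = body.body_quat_to_pose(com, q)
        return system.force_torque(pose)

    return force


def test_nve_energy_conservation(cone_host, tetra_guests, table):
    """Thermostat off, guest bound in the attractive well: total energy
    drift < 1e-4 relative over 10 ps at dt = 1 fs."""
    gl, _ = tetra_guests
    system = cc.HostGuestSystem(cone_host, gl, table)
    body = RigidBody.from_molecule(gl)
    # settle into the scanned energy minimum, then thermalize gently
    grid = cc.GridSpec(bounds=((-2, 2), (-2, 2), (-2, 2)), spacing=0.5)
    scan = cc.scan_min(cone_host, gl, grid, cc.enumerate_orientations(6, 6, 6),
                       table=table, system=system)
    mc = cc.global_minimum(scan, gl)
    q0 = body.pose_to_body_quat(cc.Pose(com=mc.com, orientation=mc.orientation))
    v0, w0 = init_velocities(body, 100.0, seed=3)
    state = RigidState(com=mc.com.astype(float).copy(), q=q0,
                       v=v0, w_body=w0, body=body)
    cfg = cc.MDConfig(thermostat="off", dt=1.0, t_max_ps=1.0, seed=0)
    force = _system_force_fn(system, body)

    def total_energy(s):
        e = system.inter_energy(s.pose).e_inter
        return e + s.ke_translational() + s.ke_rotational()

    e0 = total_energy(state)
    worst = 0.0
    for i in range(10000):  # 10 ps
        state = leapfrog_step(state, force, cfg)
        if i % 200 == 0:
            worst = max(worst, abs(total_energy(state) - e0))
    worst = max(worst, abs(total_energy(state) - e0))
    assert worst / abs(e0) < 1e-4


def test_time_reversal_returns_to_start(cone_host, tetra_guests, table):
    gl, _ = tetra_guests
    system = cc.HostGuestSystem(cone_host, gl, table)
    body = RigidBody.from_molecule(gl)
    v0, w0 = init_velocities(body, 293.0, seed=5)
    start = RigidState(com=np.array([0.3, -0.2, 0.4]),
                       q=np.array([1.0, 0, 0, 0]),
                       v=v0.copy(), w_body=w0.copy(), body=body)
    cfg = cc.MDConfig(thermostat="off", dt=1.0, t_max_ps=1.0, seed=0)
    force = _system_force_fn(system, body)
    state = start
    n = 500
    for _ in range(n):
        state = leapfrog_step(state, force, cfg)
    state = RigidState(com=state.com, q=state.q, v=-state.v,
                       w_body=-state.w_body, body=body)
    for _ in range(n):
        state = leapfrog_step(state, force, cfg)
    np.testing.assert_allclose(state.com, start.com, atol=1e-8)
    # orientation comes back too (up to quaternion sign)
    dq = min(np.linalg.norm(state.q - start.q), np.linalg.norm(state.q + start.q))
    assert dq < 1e-8


def test_isokinetic_constraint_every_step(cone_host, tetra_guests, table):
    gl, _ = tetra_guests
    cfg = cc.MDConfig(t_max_ps=10.0, record_every=100, escape_radius=50.0,
                      seed=7, thermostat="constrained")
    traj = cc.run_trajectory(cone_host, gl, cc.Pose(com=[0, 0, -0.5]), cfg,
                             table=table)
    assert traj.ke_max_dev[0] < 1e-10
    assert traj.ke_max_dev[1] < 1e-10


def test_quaternion_norm_stays_unit(cone_host, tetra_guests, table):
    gl, _ = tetra_guests
    cfg = cc.MDConfig(t_max_ps=20.0, record_every=1000, escape_radius=50.0,
                      seed=11)
    traj = cc.run_trajectory(cone_host, gl, cc.Pose(com=[0, 0, 0]), cfg,
                             table=table)
    norms = np.linalg.norm(traj.quats, axis=1)
    assert np.abs(norms - 1.0).max() < 1e-9


def test_trajectory_determinism_bitwise(probe_host, tetra_guests, table):
    gl, _ = tetra_guests
    cfg = cc.MDConfig(t_max_ps=5.0, record_every=100, standoff=4.0, seed=13)
    t1 = cc.run_trajectory(probe_host.host, gl, cc.Pose(com=[0, 0, 0.5]), cfg,
                           table=table)
    t2 = cc.run_trajectory(probe_host.host, gl, cc.Pose(com=[0, 0, 0.5]), cfg,
                           table=table)
    np.testing.assert_array_equal(t1.coms, t2.coms)
    np.testing.assert_array_equal(t1.quats, t2.quats)
    np.testing.assert_array_equal(t1.e_lj, t2.e_lj)


def test_recorded_sample_count():
    """1 ps at dt=1 fs recording every 100 steps: 10 samples plus initial."""
    host = fx.make_achiral_cone_host()
    gl, _ = fx.make_chiral_tetra_guest()
    cfg = cc.MDConfig(t_max_ps=1.0, record_every=100, escape_radius=50.0,
                      seed=1)
    traj = cc.run_trajectory(host, gl, cc.Pose(com=[0, 0, 0]), cfg)
    assert traj.n_samples == 11
    np.testing.assert_allclose(np.diff(traj.times), 0.1, atol=1e-12)


def test_mirror_equivalence_exact(tetra_guests, table):
    """Jointly mirrored host, guest, start pose and velocities give the
    mirror trajectory bitwise (parity covariance of the integrator)."""
    gl, _ = tetra_guests
    host = fx.make_chiral_probe_host().host
    system = cc.HostGuestSystem(host, gl, table)
    body = RigidBody.from_molecule(gl)
    p = system.pairs
    v0, w0 = init_velocities(body, 293.0, seed=17)
    com0 = np.array([0.2, 0.4, 0.6])
    q0 = np.array([0.8, 0.1, -0.3, 0.5])
    q0 /= np.linalg.norm(q0)

    mhost_xyz = system.host_xyz * np.array([1.0, -1.0, 1.0])
    mbody_xyz = body.body_xyz * np.array([1.0, -1.0, 1.0])
    mq0 = q0 * np.array([1.0, -1.0, 1.0, -1.0])
    mv0 = v0 * np.array([1.0, -1.0, 1.0])
    mw0 = w0 * np.array([-1.0, 1.0, -1.0])
    mcom0 = com0 * np.array([1.0, -1.0, 1.0])

    args = (p.a, p.b, p.qq, p.hb_gi, p.hb_hi, p.hb_c, p.hb_d, p.hb_parent,
            p.hb_parent_is_guest, p.hb_rmax, p.hb_cos_max, system.e_cap,
            1.0, 2000, 100, True,
            1.5 * K_BOLTZMANN * 293.0 * KCAL_MOL_FS2,
            1.5 * K_BOLTZMANN * 293.0 * KCAL_MOL_FS2, 50.0)
    out = _kernels.run_rigid_md(
        com0.copy(), q0.copy(), v0.copy(), w0.copy(), body.body_xyz,
        body.mass, body.inertia, system.host_xyz, *args)
    out_m = _kernels.run_rigid_md(
        mcom0.copy(), mq0.copy(), mv0.copy(), mw0.copy(), mbody_xyz,
        body.mass, body.inertia, mhost_xyz, *args)
    n = out[0]
    np.testing.assert_array_equal(
        out_m[2][:n], out[2][:n] * np.array([1.0, -1.0, 1.0])
    )
    np.testing.assert_array_equal(out_m[4][:n], out[4][:n])  # energies equal


def test_escape_from_repulsive_host():
    """A tight repulsive cavity ejects the guest well before t_max."""
    host = fx.make_achiral_cone_host(ring_radii=(2.0, 3.0))
    gl, _ = fx.make_chiral_tetra_guest()
    cfg = cc.MDConfig(t_max_ps=50.0, record_every=100, escape_radius=6.0,
                      seed=2, thermostat="off")
    traj = cc.run_trajectory(host, gl, cc.Pose(com=[0, 0, 1.0]), cfg)
    assert traj.termination == "escaped"
    assert traj.duration_ps < 50.0


# ----------------------------------------------------------- classification
def _synthetic_trajectory(coms, spacing_ps=0.1):
    n = len(coms)
    return Trajectory(
        times=np.arange(n) * spacing_ps,
        coms=np.asarray(coms, float),
        quats=np.tile([1.0, 0, 0, 0], (n, 1)),
        e_lj=np.zeros(n), e_ele=np.zeros(n), e_hb=np.zeros(n),
        e_intra_ref=0.0, e_cap=100.0, capped=np.zeros(n, bool),
        inside=np.zeros(n, bool),
        record_spacing_ps=spacing_ps,
    )


def test_classification_contracts(cone_host):
    far = _synthetic_trajectory([[0, 0, 9.0]] * 11)
    cls = cc.classify_trajectory(far, cone_host)
    assert cls.kind == "external" and cls.residence_time == 0.0

    home = _synthetic_trajectory([[0, 0, 0]] * 11)
    cls = cc.classify_trajectory(home, cone_host)
    assert cls.kind == "inner"
    assert cls.residence_time == pytest.approx(home.duration_ps)

    half = _synthetic_trajectory([[0, 0, 0]] * 6 + [[0, 0, 9.0]] * 5)
    # t=0 inside + 5 more inside samples out of 10 timed samples
    cls = cc.classify_trajectory(half, cone_host)
    assert cls.residence_time == pytest.approx(half.duration_ps / 2.0)


# ------------------------------------------------------------ start poses
def test_generate_start_set(cone_host, tetra_guests):
    gl, gd = tetra_guests
    poses = cc.generate_start_set(cone_host, gl, n=20, standoff=8.0)
    assert len(poses) == 20
    z = np.array([p.com[2] for p in poses])
    assert (z > cone_host.z_hi).sum() == 10
    assert (z < cone_host.z_lo).sum() == 10
    assert np.all(np.abs(z) > max(abs(cone_host.z_hi), abs(cone_host.z_lo)))
    # deterministic and guest-independent
    again = cc.generate_start_set(cone_host, gd, n=20, standoff=8.0)
    for p1, p2 in zip(poses, again):
        np.testing.assert_array_equal(p1.com, p2.com)
        np.testing.assert_array_equal(p1.orientation, p2.orientation)


def test_disposition_pairing_self_mirror(cone_host, lj_probe, table):
    """An achiral guest pairs with itself: zero energy and distance gaps."""
    cands = [cc.Pose(com=[0, 0, 5.0]), cc.Pose(com=[0, 0, -5.0])]
    pairs = cc.select_initial_dispositions(
        cone_host, lj_probe, lj_probe, cands, table=table, n_azimuth=4
    )
    for _, _, de, dd in pairs:
        assert de == pytest.approx(0.0, abs=1e-12)
        assert dd == pytest.approx(0.0, abs=1e-12)


def test_disposition_pairing_matches_brute_force(cone_host, tetra_guests, table):
    gl, gd = tetra_guests
    cands = cc.generate_start_set(cone_host, gl, n=3, standoff=5.0)
    n_az = 5
    pairs = cc.select_initial_dispositions(
        cone_host, gl, gd, cands, table=table, n_azimuth=n_az
    )
    sys_l = cc.HostGuestSystem(cone_host, gl, table)
    sys_d = cc.HostGuestSystem(cone_host, gd, table)
    d_poses = []
    for pose in cands:
        for k in range(n_az):
            rot = Rotation.from_euler("Z", 2 * math.pi * k / n_az) * pose.rotation
            d_poses.append(cc.Pose.from_rotation(pose.com, rot))
    for (pose_l, pose_d, de, _), cand in zip(pairs, cands):
        e_l = sys_l.inter_energy(pose_l).e_lj
        gaps = np.array([abs(sys_d.inter_energy(p).e_lj - e_l) for p in d_poses])
        # within the documented near-tie tolerance of the selection rule
        assert de <= gaps.min() + 1.1e-9
    with pytest.raises(ValueError):
        cc.select_initial_dispositions(cone_host, gl, gd, [], table=table)
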