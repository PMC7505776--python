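"""Constrained-temperature rigid-body molecular dynamics.

The host is held fixed and the guest moves as a rigid body: its COM obeys
the total intermolecular force and its orientation, propagated as a unit
quaternion to avoid Euler-angle singularities, obeys the total torque about
the COM.  Integration is a kick-drift-kick leapfrog variant in which the
rotational half-kicks treat the gyroscopic term at the midpoint angular
velocity (implicit on the way in, explicit on the way out), making the step
exactly time-reversible; in constrained-temperature mode the translational
and rotational kinetic energies are separately rescaled to (3/2) k_B T after
every half-kick (isokinetic constraint).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.spatial.transform import Rotation

from . import _kernels
from .constants import K_BOLTZMANN, KCAL_MOL_FS2
from .forcefield import HostGuestSystem, intra_energy
from .parameters import DielectricModel, ParameterTable
from .structures import HostFrame, ParameterizedMolecule, Pose

__all__ = [
    "MDConfig",
    "RigidBody",
    "RigidState",
    "Trajectory",
    "TrajectoryClassification",
    "init_velocities",
    "leapfrog_step",
    "run_trajectory",
    "classify_trajectory",
    "generate_start_set",
    "select_initial_dispositions",
    "run_paired_simulation",
    "write_trajectory_xyz",
]


@dataclass
class MDConfig:
    """Simulation settings (K, fs, ps)."""

    temperature: float = 293.0
    dt: float = 1.0                 # fs
    t_max_ps: float = 5000.0        # 5 ns
    record_every: int = 100         # steps
    escape_radius: float = 12.0     # A from the cavity origin
    seed: int = 0
    thermostat: str = "constrained"  # or "off"
    standoff: float = 8.0           # start distance beyond the rim plane, A

    def __post_init__(self):
        if self.dt <= 0 or self.t_max_ps <= 0:
            raise ValueError("dt and t_max must be positive")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")
        if self.thermostat not in ("constrained", "off"):
            raise ValueError("thermostat must be 'constrained' or 'off'")

    @property
    def n_steps(self) -> int:
        return int(round(self.t_max_ps * 1000.0 / self.dt))

    def ke_target_internal(self) -> float:
        """(3/2) k_B T in internal units (amu A^2 fs^-2)."""
        return 1.5 * K_BOLTZMANN * self.temperature * KCAL_MOL_FS2


@dataclass
class RigidBody:
    """A guest frozen into its principal-axis body frame."""

    body_xyz: np.ndarray      # (n, 3) COM-centred principal-frame coordinates
    inertia: np.ndarray       # (3,) principal moments, amu A^2
    mass: float               # amu
    ref_rotation: Rotation    # body frame -> reference (file) frame

    @classmethod
    def from_molecule(cls, mol: ParameterizedMolecule) -> "RigidBody":
        moments, rot = mol.principal_frame()
        centred = mol.coords() - mol.center_of_mass()
        body = rot.inv().apply(centred)
        moments = np.maximum(moments, 1e-8)  # guard single-atom degeneracy
        return cls(
            body_xyz=body,
            inertia=np.asarray(moments, float),
            mass=mol.total_mass(),
            ref_rotation=rot,
        )

    def pose_to_body_quat(self, pose: Pose) -> np.ndarray:
        q = (pose.rotation * self.ref_rotation).as_quat(scalar_first=True)
        return q / np.linalg.norm(q)

    def body_quat_to_pose(self, com: np.ndarray, q: np.ndarray) -> Pose:
        rot = Rotation.from_quat(q, scalar_first=True) * self.ref_rotation.inv()
        return Pose.from_rotation(com, rot)


@dataclass
class RigidState:
    """Instantaneous MD state: pose plus linear and angular velocity.

    ``q`` is the body(principal)->lab quaternion; ``w_body`` the angular
    velocity in the body frame (rad/fs); ``v`` the COM velocity (A/fs).
    """

    com: np.ndarray
    q: np.ndarray
    v: np.ndarray
    w_body: np.ndarray
    body: RigidBody

    @property
    def pose(self) -> Pose:
        return self.body.body_quat_to_pose(self.com, self.q)

    def ke_translational(self) -> float:
        """kcal/mol."""
        return 0.5 * self.body.mass * float(self.v @ self.v) / KCAL_MOL_FS2

    def ke_rotational(self) -> float:
        """kcal/mol."""
        return (
            0.5 * float(self.body.inertia @ (self.w_body ** 2)) / KCAL_MOL_FS2
        )


def init_velocities(
    body: RigidBody, temperature: float, seed
) -> tuple[np.ndarray, np.ndarray]:
    """Draw initial velocities consistent with the temperature.

    Speeds satisfy (1/2) m v^2 = (3/2) k_B T and (1/2) w^T I w = (3/2)
    k_B T exactly; directions are drawn from the seeded stream first, so the
    same seed yields the same unit directions for every guest.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    rng = np.random.default_rng(seed)
    v_dir = rng.normal(size=3)
    v_dir /= np.linalg.norm(v_dir)
    w_dir = rng.normal(size=3)
    w_dir /= np.linalg.norm(w_dir)
    ke = 1.5 * K_BOLTZMANN * temperature * KCAL_MOL_FS2
    v = v_dir * math.sqrt(2.0 * ke / body.mass)
    denom = float(body.inertia @ (w_dir ** 2))
    w = w_dir * math.sqrt(2.0 * ke / denom)
    return v, w


# ------------------------------------------------------------ single step
def leapfrog_step(
    state: RigidState,
    force_fn: Callable[[np.ndarray, np.ndarray], tuple],
    config: MDConfig,
) -> RigidState:
    """One rigid-body KDK leapfrog step with an arbitrary force provider.

    ``force_fn(com, q) -> (force, torque)`` returns the lab-frame force
    (kcal mol^-1 A^-1) and torque about the COM (kcal/mol).  The host-guest
    production path runs the same scheme inside a compiled kernel; this
    Python version exists for custom force fields and validation.
    """
    dt = config.dt
    thermo = config.thermostat == "constrained"
    ket = config.ke_target_internal()
    inertia = state.body.inertia
    mass = state.body.mass

    def _rescale(vec, ke):
        if ke > 1e-300:
            return vec * math.sqrt(ket / ke)
        return vec

    f, tau = force_fn(state.com, state.q)
    rmat = _kernels.quat_to_mat(state.q)
    taub = rmat.T @ np.asarray(tau, float) * KCAL_MOL_FS2
    acc = np.asarray(f, float) * (KCAL_MOL_FS2 / mass)

    vh = state.v + 0.5 * dt * acc
    if thermo:
        vh = _rescale(vh, 0.5 * mass * float(vh @ vh))
    wh = _kernels._omega_half_implicit(state.w_body.copy(), taub, inertia, dt)
    if thermo:
        wh = _rescale(wh, 0.5 * float(inertia @ (wh ** 2)))

    com1 = state.com + dt * vh
    q1 = _kernels.quat_mul(state.q, _kernels.quat_exp_body(wh, dt))
    q1 = q1 / np.linalg.norm(q1)

    f1, tau1 = force_fn(com1, q1)
    if not (np.all(np.isfinite(f1)) and np.all(np.isfinite(tau1))):
        raise FloatingPointError("non-finite force/torque during integration")
    rmat1 = _kernels.quat_to_mat(q1)
    taub1 = rmat1.T @ np.asarray(tau1, float) * KCAL_MOL_FS2
    acc1 = np.asarray(f1, float) * (KCAL_MOL_FS2 / mass)

    v1 = vh + 0.5 * dt * acc1
    if thermo:
        v1 = _rescale(v1, 0.5 * mass * float(v1 @ v1))
    w1 = _kernels._kick_rot_explicit(wh, taub1, inertia, dt)
    if thermo:
        w1 = _rescale(w1, 0.5 * float(inertia @ (w1 ** 2)))
    return RigidState(com=com1, q=q1, v=np.asarray(v1), w_body=np.asarray(w1),
                      body=state.body)


# ------------------------------------------------------------- trajectories
@dataclass
class Trajectory:
    """Recorded samples of one MD run (times in ps)."""

    times: np.ndarray          # (n,) ps
    coms: np.ndarray           # (n, 3)
    quats: np.ndarray          # (n, 4) body->lab
    e_lj: np.ndarray
    e_ele: np.ndarray
    e_hb: np.ndarray
    e_intra_ref: float
    e_cap: float
    capped: np.ndarray
    inside: np.ndarray         # (n,) bool
    start_id: int = 0
    termination: str = "t_max"
    record_spacing_ps: float = 0.1
    final_state: Optional[RigidState] = None
    #: max |KE - (3/2) k_B T| over every step (kcal/mol), trans and rot
    ke_max_dev: tuple = (float("nan"), float("nan"))

    @property
    def n_samples(self) -> int:
        return len(self.times)

    def e_inter(self) -> np.ndarray:
        """Capped total intermolecular energy per sample."""
        return np.minimum(self.e_lj + self.e_ele + self.e_hb, self.e_cap)

    def e_total(self) -> np.ndarray:
        return self.e_inter() + self.e_intra_ref

    @property
    def duration_ps(self) -> float:
        return float(self.times[-1]) if len(self.times) else 0.0


@dataclass
class TrajectoryClassification:
    kind: str                  # "inner" | "external"
    residence_time: float      # ps


def classify_trajectory(traj: Trajectory, host: HostFrame) -> TrajectoryClassification:
    """Inner/external classification with total (possibly non-contiguous)
    residence time.

    A sample is inside iff the COM z lies between the rim planes and its
    axial distance does not exceed the cavity radius at that z.  Each
    recorded sample after the initial one stands for one record interval.
    """
    if traj.n_samples == 0:
        raise ValueError("empty trajectory")
    inside = host.is_inside(traj.coms)
    n_inside = int(np.count_nonzero(inside[1:]))  # t=0 sample carries no time
    residence = n_inside * traj.record_spacing_ps
    kind = "inner" if bool(inside.any()) else "external"
    return TrajectoryClassification(kind=kind, residence_time=residence)


def run_trajectory(
    host: HostFrame,
    guest: ParameterizedMolecule,
    start_pose: Pose,
    config: MDConfig,
    model: DielectricModel = DielectricModel(),
    table: ParameterTable | None = None,
    v0: np.ndarray | None = None,
    w0: np.ndarray | None = None,
    system: HostGuestSystem | None = None,
    start_id: int = 0,
) -> Trajectory:
    """Integrate one host-guest trajectory with the compiled kernel.

    Runs until ``t_max`` or until the COM leaves the ``escape_radius``
    sphere; pose and energy components are recorded every ``record_every``
    steps.  The guest is rigid: its intramolecular energy enters recorded
    totals as the reference-conformation constant.
    """
    sys_ = system or HostGuestSystem(host, guest, table, model)
    body = RigidBody.from_molecule(guest)
    if v0 is None or w0 is None:
        v0_, w0_ = init_velocities(body, config.temperature, config.seed)
        v0 = v0 if v0 is not None else v0_
        w0 = w0 if w0 is not None else w0_
    q0 = body.pose_to_body_quat(start_pose)
    p = sys_.pairs
    (
        n_rec, rec_step, rec_com, rec_quat, rec_energy, rec_capped, term,
        com_f, q_f, v_f, w_f, ke_dev,
    ) = _kernels.run_rigid_md(
        np.asarray(start_pose.com, float).copy(), q0.copy(),
        np.asarray(v0, float).copy(), np.asarray(w0, float).copy(),
        body.body_xyz, body.mass, body.inertia,
        sys_.host_xyz, p.a, p.b, p.qq,
        p.hb_gi, p.hb_hi, p.hb_c, p.hb_d, p.hb_parent, p.hb_parent_is_guest,
        p.hb_rmax, p.hb_cos_max, sys_.e_cap,
        config.dt, config.n_steps, config.record_every,
        config.thermostat == "constrained",
        config.ke_target_internal(), config.ke_target_internal(),
        config.escape_radius,
    )
    spacing_ps = config.record_every * config.dt / 1000.0
    times = rec_step[:n_rec] * config.dt / 1000.0
    coms = rec_com[:n_rec]
    e_intra_ref = intra_energy(guest).e_intra
    final = RigidState(com=com_f, q=q_f, v=v_f, w_body=w_f, body=body)
    return Trajectory(
        times=times,
        coms=coms,
        quats=rec_quat[:n_rec],
        e_lj=rec_energy[:n_rec, 0],
        e_ele=rec_energy[:n_rec, 1],
        e_hb=rec_energy[:n_rec, 2],
        e_intra_ref=e_intra_ref,
        e_cap=sys_.e_cap,
        capped=rec_capped[:n_rec],
        inside=host.is_inside(coms),
        start_id=start_id,
        termination="escaped" if term == 1 else "t_max",
        record_spacing_ps=spacing_ps,
        final_state=final,
        ke_max_dev=(
            float(ke_dev[0]) / KCAL_MOL_FS2,
            float(ke_dev[1]) / KCAL_MOL_FS2,
        ),
    )


def write_trajectory_xyz(traj: Trajectory, guest: ParameterizedMolecule,
                         path) -> None:
    """Persist a trajectory as multi-frame XYZ (guest atoms only).

    Each recorded sample becomes one frame; the comment line carries the
    time (ps) and the capped intermolecular energy (kcal/mol).
    """
    body = RigidBody.from_molecule(guest)
    elements = guest.elements()
    e_inter = traj.e_inter()
    lines = []
    for k in range(traj.n_samples):
        pose = body.body_quat_to_pose(traj.coms[k], traj.quats[k])
        xyz = pose.apply(guest)
        lines.append(str(guest.n_atoms))
        lines.append(
            f"t = {traj.times[k]:.4f} ps  E_inter = {e_inter[k]:.6f} kcal/mol"
        )
        for el, p in zip(elements, xyz):
            lines.append(f"{el:<4s} {p[0]:14.6f} {p[1]:14.6f} {p[2]:14.6f}")
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")


# ----------------------------------------------------- start dispositions
def generate_start_set(
    host: HostFrame,
    guest: ParameterizedMolecule,
    n: int = 20,
    standoff: float = 8.0,
) -> list:
    """Deterministic start poses outside the cavity facing the rims.

    Poses alternate between the two rims at ``standoff`` beyond the rim
    plane on the cavity axis, cycling through orientation families: guest
    axis parallel to the rim plane (at stepped azimuths) or pointing toward
    the cavity.  The same set is returned for both enantiomers.
    """
    if n < 1:
        raise ValueError("need at least one start pose")
    z_top = host.z_hi + standoff
    z_bot = host.z_lo - standoff
    poses = []
    n_var = max(1, (n + 3) // 4)
    for i in range(n):
        top = i % 2 == 0
        family = (i // 2) % 2
        variant = i // 4
        az = 2.0 * math.pi * variant / n_var
        if family == 0:
            # molecular axis parallel to the rim plane
            rot = Rotation.from_euler("ZX", [az, math.pi / 2.0])
        else:
            # axis along the cavity axis, pointing toward the cavity
            flip = math.pi if top else 0.0
            rot = Rotation.from_euler("ZX", [az, flip])
        com = np.array([0.0, 0.0, z_top if top else z_bot])
        poses.append(Pose.from_rotation(com, rot))
    return poses


def _vdw_energy(sys_: HostGuestSystem, pose: Pose) -> float:
    return sys_.inter_energy(pose).e_lj


def select_initial_dispositions(
    host: HostFrame,
    guest_l: ParameterizedMolecule,
    guest_d: ParameterizedMolecule,
    candidates: list,
    model: DielectricModel = DielectricModel(),
    table: ParameterTable | None = None,
    n_azimuth: int = 24,
) -> list:
    """Pair each L start pose with the best-matching D start pose.

    For every candidate L pose, the D pose is chosen over the candidate set
    augmented with ``n_azimuth`` rotations about the cavity axis so as to
    minimize |E_vdW(L) - E_vdW(D)|; near-ties (within 1e-9 kcal/mol) are
    broken by the smaller mean atom-to-mirror-atom distance.  Returns a list
    of ``(pose_L, pose_D, dE_vdW, d_mean)`` tuples.
    """
    if not candidates:
        raise ValueError("empty candidate set")
    sys_l = HostGuestSystem(host, guest_l, table, model)
    sys_d = HostGuestSystem(host, guest_d, table, model)
    d_poses = []
    for pose in candidates:
        for k in range(n_azimuth):
            az = 2.0 * math.pi * k / n_azimuth
            rot = Rotation.from_euler("Z", az) * pose.rotation
            d_poses.append(Pose.from_rotation(pose.com, rot))
    e_d = np.array([_vdw_energy(sys_d, p) for p in d_poses])
    out = []
    for pose_l in candidates:
        e_l = _vdw_energy(sys_l, pose_l)
        de = np.abs(e_d - e_l)
        best = de.min()
        tied = np.flatnonzero(de <= best + 1e-9)
        xyz_l = pose_l.apply(guest_l)
        dists = []
        for j in tied:
            xyz_d = d_poses[j].apply(guest_d)
            dists.append(float(np.linalg.norm(xyz_d - xyz_l, axis=1).mean()))
        j = tied[int(np.argmin(np.round(dists, 9)))]
        out.append((pose_l, d_poses[j], float(de[j]), dists[int(np.argmin(np.round(dists, 9)))]))
    return out


def run_paired_simulation(
    host: HostFrame,
    guest_l: ParameterizedMolecule,
    guest_d: ParameterizedMolecule,
    config: MDConfig,
    n_trajectories: int = 20,
    model: DielectricModel = DielectricModel(),
    table: ParameterTable | None = None,
    pair_dispositions: bool = True,
) -> tuple[list, list]:
    """The full two-enantiomer MD protocol.

    Builds the shared start set, pairs D dispositions to L dispositions,
    then integrates ``n_trajectories`` per enantiomer with per-trajectory
    velocity streams derived from the master seed (identical unit directions
    for L and D).  Returns (trajectories_L, trajectories_D).
    """
    starts = generate_start_set(host, guest_l, n_trajectories, config.standoff)
    if pair_dispositions:
        paired = select_initial_dispositions(
            host, guest_l, guest_d, starts, model, table
        )
    else:
        paired = [(p, p, 0.0, 0.0) for p in starts]
    sys_l = HostGuestSystem(host, guest_l, table, model)
    sys_d = HostGuestSystem(host, guest_d, table, model)
    body_l = RigidBody.from_molecule(guest_l)
    body_d = RigidBody.from_molecule(guest_d)
    trajs_l, trajs_d = [], []
    for i, (pose_l, pose_d, _, _) in enumerate(paired):
        seed_i = np.random.SeedSequence([config.seed, i])
        v_l, w_l = init_velocities(body_l, config.temperature, seed_i)
        v_d, w_d = init_velocities(body_d, config.temperature, seed_i)
        trajs_l.append(
            run_trajectory(host, guest_l, pose_l, config, model, table,
                           v0=v_l, w0=w_l, system=sys_l, start_id=i)
        )
        trajs_d.append(
            run_trajectory(host, guest_d, pose_d, config, model, table,
                           v0=v_d, w0=w_d, system=sys_d, start_id=i)
        )
    return trajs_l, trajs_d
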