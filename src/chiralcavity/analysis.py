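"""Trajectory-set summaries: densities, binding free energies, elution.

The enantioselectivity readout is the difference in average binding free
energy between the enantiomers, Delta F_mean = F_mean(L) - F_mean(D).  A
positive difference means the D-enantiomer is the more tightly bound, so
the L-enantiomer is eluted first.  External trajectories (the guest never
enters the cavity) are excluded from every average.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .constants import K_BOLTZMANN
from .dynamics import Trajectory, TrajectoryClassification, classify_trajectory
from .structures import HostFrame, ParameterizedMolecule, Pose, guest_axis_angles

__all__ = [
    "DensityGrid",
    "SimulationSummary",
    "PreferredConfiguration",
    "position_density",
    "binding_free_energy",
    "summarize",
    "elution_order",
    "most_probable_configuration",
]


@dataclass
class DensityGrid:
    """Position probability density of the guest COM on a cubic grid."""

    spacing: float
    origin: np.ndarray        # lower corner of cell (0,0,0)
    counts: np.ndarray        # (nx, ny, nz) int
    probability: np.ndarray   # counts / total samples

    def cell_center(self, idx) -> np.ndarray:
        return self.origin + (np.asarray(idx, float) + 0.5) * self.spacing

    def project(self, plane: str = "XZ") -> np.ndarray:
        axis = {"XY": 2, "XZ": 1, "YZ": 0}[plane]
        return self.probability.sum(axis=axis)


def position_density(trajs: list, spacing: float = 0.5) -> DensityGrid:
    """Bin all recorded COM positions and normalize by the total count.

    The grid origin is aligned to integer multiples of the spacing so the
    same cell decomposition is used regardless of the sample cloud.
    """
    if not trajs:
        raise ValueError("no trajectories given")
    coms = np.concatenate([t.coms for t in trajs], axis=0)
    if coms.shape[0] == 0:
        raise ValueError("trajectories contain no samples")
    idx = np.floor(coms / spacing).astype(np.int64)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0)
    shape = tuple((hi - lo + 1).tolist())
    counts = np.zeros(shape, dtype=np.int64)
    np.add.at(counts, tuple((idx - lo).T), 1)
    prob = counts / counts.sum()
    return DensityGrid(
        spacing=spacing,
        origin=lo.astype(float) * spacing,
        counts=counts,
        probability=prob,
    )


def binding_free_energy(
    traj: Trajectory,
    temperature: float = 293.0,
    mode: str = "time_average",
) -> float:
    """Binding free energy of one trajectory from its inside samples.

    The reference is the separated pair: zero intermolecular energy plus the
    relaxed intramolecular constant, so F measures the net stabilization of
    the complex.  mode="time_average" is the plain mean of E - E_ref over
    inside samples; mode="boltzmann" is -k_B T ln < exp(-(E - E_ref)/k_B T) >,
    which by Jensen's inequality never exceeds the time average.
    """
    inside = traj.inside
    n_in = int(np.count_nonzero(inside))
    if n_in == 0:
        raise ValueError("no inner samples: external trajectory")
    de = traj.e_inter()[inside]  # (E_inter + E_intra_ref) - (0 + E_intra_ref)
    if mode == "time_average":
        return float(de.mean())
    if mode == "boltzmann":
        kt = K_BOLTZMANN * temperature
        m = de.min()
        return float(m - kt * np.log(np.exp(-(de - m) / kt).mean()))
    raise ValueError("mode must be 'time_average' or 'boltzmann'")


def elution_order(delta_f_mean: float, tol: float = 0.05) -> str:
    """Elution rule: Delta F_mean > 0 means D binds tighter, L elutes first."""
    if delta_f_mean > tol:
        return "L_first"
    if delta_f_mean < -tol:
        return "D_first"
    return "tie"


@dataclass
class EnantiomerStats:
    n_trajectories: int
    n_inner: int
    f_mean: float
    f_sd: float
    t_mean: float
    f_values: np.ndarray = field(default_factory=lambda: np.zeros(0))
    non_binding: bool = False


@dataclass
class SimulationSummary:
    """Per-enantiomer averages plus the elution-order call."""

    stats_l: EnantiomerStats
    stats_d: EnantiomerStats
    delta_f_mean: float
    order: str
    temperature: float
    f_mode: str = "time_average"

    def as_dict(self) -> dict:
        return {
            "n_trajectories_L": self.stats_l.n_trajectories,
            "n_trajectories_D": self.stats_d.n_trajectories,
            "n_inner_L": self.stats_l.n_inner,
            "n_inner_D": self.stats_d.n_inner,
            "F_mean_L": self.stats_l.f_mean,
            "F_sd_L": self.stats_l.f_sd,
            "F_mean_D": self.stats_d.f_mean,
            "F_sd_D": self.stats_d.f_sd,
            "t_mean_L": self.stats_l.t_mean,
            "t_mean_D": self.stats_d.t_mean,
            "delta_F_mean": self.delta_f_mean,
            "elution_order": self.order,
        }


def _enantiomer_stats(
    trajs: list, host: HostFrame, temperature: float, mode: str
) -> EnantiomerStats:
    if not trajs:
        raise ValueError("empty trajectory set")
    fs, ts = [], []
    for t in trajs:
        cls = classify_trajectory(t, host)
        if cls.kind != "inner":
            continue
        fs.append(binding_free_energy(t, temperature, mode))
        ts.append(cls.residence_time)
    fs = np.array(fs)
    if len(fs) == 0:
        return EnantiomerStats(
            n_trajectories=len(trajs), n_inner=0,
            f_mean=float("nan"), f_sd=float("nan"), t_mean=float("nan"),
            non_binding=True,
        )
    return EnantiomerStats(
        n_trajectories=len(trajs),
        n_inner=len(fs),
        f_mean=float(fs.mean()),
        f_sd=float(fs.std(ddof=1)) if len(fs) > 1 else 0.0,
        t_mean=float(np.mean(ts)),
        f_values=fs,
    )


def summarize(
    trajs_l: list,
    trajs_d: list,
    host: HostFrame,
    temperature: float = 293.0,
    f_mode: str = "time_average",
    tie_tol: float = 0.05,
) -> SimulationSummary:
    """Build the per-enantiomer summary table and the elution-order call.

    External trajectories are excluded from F_mean and t_mean; their counts
    remain visible through ``n_trajectories`` vs ``n_inner``.  If every
    trajectory of an enantiomer is external, that enantiomer is flagged
    non-binding and the order is reported as a tie.
    """
    sl = _enantiomer_stats(trajs_l, host, temperature, f_mode)
    sd = _enantiomer_stats(trajs_d, host, temperature, f_mode)
    if sl.non_binding or sd.non_binding:
        delta = float("nan")
        order = "tie"
    else:
        delta = sl.f_mean - sd.f_mean
        order = elution_order(delta, tie_tol)
    return SimulationSummary(
        stats_l=sl, stats_d=sd, delta_f_mean=delta, order=order,
        temperature=temperature, f_mode=f_mode,
    )


@dataclass
class PreferredConfiguration:
    """Modal COM cell plus the modal guest orientation within that cell."""

    cell_index: tuple
    cell_center: np.ndarray
    occupancy: float
    theta: float
    phi: float
    angle_tied: bool = False


def most_probable_configuration(
    trajs: list,
    density: DensityGrid,
    guest: ParameterizedMolecule,
    angle_bin_deg: float = 10.0,
) -> PreferredConfiguration:
    """Locate the modal density cell and the modal orientation inside it.

    Orientation is summarized by the guest-axis spherical angles (theta,
    phi), histogrammed at ``angle_bin_deg`` resolution over the samples
    falling in the modal cell; ties are broken lexicographically (lower
    theta bin, then lower phi bin) and flagged.
    """
    if density.probability.size == 0:
        raise ValueError("empty density grid")
    flat = int(np.argmax(density.probability))
    idx = np.unravel_index(flat, density.probability.shape)
    occupancy = float(density.probability[idx])

    from .dynamics import RigidBody

    body = RigidBody.from_molecule(guest)
    angles = []
    for t in trajs:
        cell = np.floor(t.coms / density.spacing).astype(np.int64)
        cell -= np.floor(density.origin / density.spacing).astype(np.int64)
        in_cell = np.all(cell == np.asarray(idx), axis=1)
        for k in np.flatnonzero(in_cell):
            # trajectory quaternions are body->lab; convert to a pose
            pose = body.body_quat_to_pose(
                t.coms[k], t.quats[k] / np.linalg.norm(t.quats[k])
            )
            angles.append(guest_axis_angles(guest, pose))
    if not angles:
        raise ValueError("no samples fall in the modal cell")
    angles = np.array(angles)
    tb = np.minimum((angles[:, 0] / angle_bin_deg).astype(int),
                    int(180 / angle_bin_deg) - 1)
    pb = (angles[:, 1] / angle_bin_deg).astype(int) % int(360 / angle_bin_deg)
    nt, npb = int(180 / angle_bin_deg), int(360 / angle_bin_deg)
    hist = np.zeros((nt, npb), dtype=np.int64)
    np.add.at(hist, (tb, pb), 1)
    best = int(np.argmax(hist))  # first occurrence = lexicographic tie-break
    bi = np.unravel_index(best, hist.shape)
    tied = int((hist == hist[bi]).sum()) > 1
    return PreferredConfiguration(
        cell_index=tuple(int(i) for i in idx),
        cell_center=density.cell_center(idx),
        occupancy=occupancy,
        theta=(bi[0] + 0.5) * angle_bin_deg,
        phi=(bi[1] + 0.5) * angle_bin_deg,
        angle_tied=tied,
    )
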