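"""Grid/orientation energy scanning: PES, penetration potential, maps.

The guest's center of mass is placed on a regular Cartesian grid in the
host frame and, at every grid point, the interaction energy is evaluated for
a systematic set of rigid orientations.  Assigning each point the minimum
over orientations gives the potential energy surface (PES); assigning the
Boltzmann-weighted orientation average gives the thermal PES.  The
penetration potential W(z) is the minimum of the intermolecular energy over
each plane perpendicular to the cavity axis, and enantiodiscrimination maps
are plane projections of the energy difference between the two enantiomers'
surfaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial.transform import Rotation

from .constants import E_CAP, K_BOLTZMANN
from .forcefield import EnergyBreakdown, HostGuestSystem, intra_energy
from .parameters import DielectricModel, ParameterTable
from .structures import HostFrame, ParameterizedMolecule, Pose, guest_axis_angles

__all__ = [
    "GridSpec",
    "OrientationSet",
    "ScanResult",
    "PenetrationProfile",
    "DiscriminationMap",
    "MinimumConfiguration",
    "enumerate_orientations",
    "scan_min",
    "scan_boltzmann",
    "penetration_potential",
    "discrimination_map",
    "global_minimum",
]

_COMPONENTS = ("total", "lj", "ele", "hb")


@dataclass(frozen=True)
class GridSpec:
    """Cartesian COM grid: per-axis bounds (A) and spacing (A)."""

    bounds: tuple = ((-5.0, 5.0), (-5.0, 5.0), (-5.0, 5.0))
    spacing: float = 0.1

    def __post_init__(self):
        # normalize so value equality works regardless of list/tuple input
        object.__setattr__(
            self,
            "bounds",
            tuple((float(lo), float(hi)) for lo, hi in self.bounds),
        )
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        for lo, hi in self.bounds:
            if hi < lo:
                raise ValueError("grid bounds must be ordered")

    def axes(self):
        out = []
        for lo, hi in self.bounds:
            n = int(round((hi - lo) / self.spacing)) + 1
            out.append(lo + self.spacing * np.arange(n))
        return tuple(out)

    @property
    def shape(self):
        return tuple(len(ax) for ax in self.axes())

    def points(self) -> np.ndarray:
        """All grid points, C-ordered (x slowest, z fastest), shape (m, 3)."""
        x, y, z = self.axes()
        gx, gy, gz = np.meshgrid(x, y, z, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])


@dataclass
class OrientationSet:
    """Systematic rigid orientations: ZYZ Euler grid and quaternions."""

    euler: np.ndarray      # (n, 3) alpha, beta, gamma in rad
    quats: np.ndarray      # (n, 4) scalar-first
    counts: tuple = (0, 0, 0)

    def __len__(self) -> int:
        return self.quats.shape[0]

    def rotations(self) -> Rotation:
        return Rotation.from_quat(self.quats, scalar_first=True)


def enumerate_orientations(
    n_alpha: int = 24, n_beta: int = 40, n_gamma: int = 24
) -> OrientationSet:
    """ZYZ Euler orientation grid of size n_alpha * n_beta * n_gamma.

    alpha and gamma are uniform on [0, 2 pi); beta comes from a uniform grid
    in cos(beta) on [1, -1] so orientations sample the rotation group without
    polar crowding.  The identity is included whenever the counts permit
    (alpha = gamma = 0, cos beta = 1).  The default 24 x 40 x 24 grid has
    23,040 members.
    """
    if n_alpha < 1 or n_beta < 1 or n_gamma < 1:
        raise ValueError("orientation counts must be >= 1")
    alpha = 2.0 * np.pi * np.arange(n_alpha) / n_alpha
    cosb = np.linspace(1.0, -1.0, n_beta) if n_beta > 1 else np.array([1.0])
    beta = np.arccos(np.clip(cosb, -1.0, 1.0))
    gamma = 2.0 * np.pi * np.arange(n_gamma) / n_gamma
    aa, bb, gg = np.meshgrid(alpha, beta, gamma, indexing="ij")
    euler = np.column_stack([aa.ravel(), bb.ravel(), gg.ravel()])
    quats = Rotation.from_euler("ZYZ", euler).as_quat(scalar_first=True)
    norms = np.linalg.norm(quats, axis=1, keepdims=True)
    quats = quats / norms
    return OrientationSet(euler=euler, quats=quats, counts=(n_alpha, n_beta, n_gamma))


@dataclass
class ScanResult:
    """Grid-indexed energies plus enough context to extract minima.

    ``values`` holds, per grid point, the minimum (mode="min") or the
    Boltzmann orientation average (mode="boltzmann") of the capped
    intermolecular energy.  In min mode ``argmin_orientation`` stores the
    first orientation index attaining the minimum and ``component_minima``
    the independent per-component minima used by the penetration potential.
    """

    grid: GridSpec
    values: np.ndarray
    mode: str
    component: str = "total_inter"
    argmin_orientation: Optional[np.ndarray] = None
    component_minima: dict = field(default_factory=dict)
    temperature: Optional[float] = None
    system: Optional[HostGuestSystem] = None
    orientations: Optional[OrientationSet] = None

    def compatible_with(self, other: "ScanResult") -> bool:
        return self.grid == other.grid and self.mode == other.mode


def _capped_total(comp: np.ndarray, e_cap: float) -> np.ndarray:
    return np.minimum(comp[:, 0] + comp[:, 1] + comp[:, 2], e_cap)


def scan_min(
    host: HostFrame,
    guest: ParameterizedMolecule,
    grid: GridSpec,
    orients: OrientationSet,
    model: DielectricModel = DielectricModel(),
    table: ParameterTable | None = None,
    e_cap: float = E_CAP,
    system: HostGuestSystem | None = None,
) -> ScanResult:
    """Minimum-over-orientations PES of the intermolecular energy.

    Deterministic: grid points are visited in C order and the stored argmin
    is the first orientation attaining each point's minimum.
    """
    sys_ = system or HostGuestSystem(host, guest, table, model, e_cap=e_cap)
    pts = grid.points()
    m = pts.shape[0]
    best = np.full(m, np.inf)
    best_o = np.zeros(m, dtype=np.int64)
    comp_min = {c: np.full(m, np.inf) for c in _COMPONENTS}
    rots = orients.rotations()
    for oi in range(len(orients)):
        guest_rot = rots[oi].apply(sys_.guest_ref)
        comp, _ = sys_.inter_components(guest_rot, pts)
        total = _capped_total(comp, sys_.e_cap)
        better = total < best
        best_o[better] = oi
        np.minimum(best, total, out=best)
        np.minimum(comp_min["total"], total, out=comp_min["total"])
        np.minimum(comp_min["lj"], comp[:, 0], out=comp_min["lj"])
        np.minimum(comp_min["ele"], comp[:, 1], out=comp_min["ele"])
        np.minimum(comp_min["hb"], comp[:, 2], out=comp_min["hb"])
    shape = grid.shape
    return ScanResult(
        grid=grid,
        values=best.reshape(shape),
        mode="min",
        argmin_orientation=best_o.reshape(shape),
        component_minima={c: v.reshape(shape) for c, v in comp_min.items()},
        system=sys_,
        orientations=orients,
    )


def scan_boltzmann(
    host: HostFrame,
    guest: ParameterizedMolecule,
    grid: GridSpec,
    orients: OrientationSet,
    model: DielectricModel = DielectricModel(),
    temperature: float = 293.0,
    table: ParameterTable | None = None,
    e_cap: float = E_CAP,
    system: HostGuestSystem | None = None,
) -> ScanResult:
    """Boltzmann-averaged-over-orientations PES.

    Per grid point ``<E> = sum_k E_k w_k / sum_k w_k`` with ``w_k =
    exp(-(E_k - E_min) / k_B T)``; the running minimum shift keeps the
    accumulation stable at any temperature.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    sys_ = system or HostGuestSystem(host, guest, table, model, e_cap=e_cap)
    kt = K_BOLTZMANN * temperature
    pts = grid.points()
    m = pts.shape[0]
    e_min = np.full(m, np.inf)
    sw = np.zeros(m)
    sew = np.zeros(m)
    rots = orients.rotations()
    for oi in range(len(orients)):
        guest_rot = rots[oi].apply(sys_.guest_ref)
        comp, _ = sys_.inter_components(guest_rot, pts)
        total = _capped_total(comp, sys_.e_cap)
        new_min = np.minimum(e_min, total)
        with np.errstate(over="ignore", invalid="ignore"):
            shift = np.where(
                np.isfinite(e_min), np.exp((new_min - e_min) / kt), 0.0
            )
            sw *= shift
            sew *= shift
            w = np.exp(-(total - new_min) / kt)
        sw += w
        sew += total * w
        e_min = new_min
    values = sew / sw
    return ScanResult(
        grid=grid,
        values=values.reshape(grid.shape),
        mode="boltzmann",
        temperature=temperature,
        system=sys_,
        orientations=orients,
    )


@dataclass
class PenetrationProfile:
    """Minimum energy per z-plane: total W plus independent component minima."""

    z: np.ndarray
    w: np.ndarray
    w_lj: np.ndarray
    w_ele: np.ndarray
    w_hb: np.ndarray

    def as_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"z": self.z, "W": self.w, "W_LJ": self.w_lj,
             "W_ELE": self.w_ele, "W_HB": self.w_hb}
        )


def penetration_potential(
    host: HostFrame,
    guest: ParameterizedMolecule,
    grid: GridSpec,
    orients: OrientationSet,
    model: DielectricModel = DielectricModel(),
    table: ParameterTable | None = None,
    scan: ScanResult | None = None,
) -> PenetrationProfile:
    """Penetration potential along the cavity axis.

    For each z-plane of the grid, the minimum over all (x, y) positions and
    orientations of the capped intermolecular energy (W) and, independently,
    of each of its components (W_LJ, W_ELE, W_HB).  Component curves are
    independent minima -- each component minimized over its own best pose.
    """
    if scan is None:
        scan = scan_min(host, guest, grid, orients, model, table)
    if scan.mode != "min" or not scan.component_minima:
        raise ValueError("penetration potential needs a min-mode scan")
    z = scan.grid.axes()[2]
    mins = scan.component_minima
    return PenetrationProfile(
        z=z,
        w=mins["total"].min(axis=(0, 1)),
        w_lj=mins["lj"].min(axis=(0, 1)),
        w_ele=mins["ele"].min(axis=(0, 1)),
        w_hb=mins["hb"].min(axis=(0, 1)),
    )


@dataclass
class DiscriminationMap:
    """Projected E_L - E_D difference map; negative cells favor L."""

    plane: str            # "XY" or "XZ"
    axis_1: np.ndarray
    axis_2: np.ndarray
    values: np.ndarray    # (n1, n2)
    rule: str = "at_L_min"


def discrimination_map(
    scan_l: ScanResult,
    scan_d: ScanResult,
    plane: str = "XZ",
    rule: str = "at_L_min",
) -> DiscriminationMap:
    """Project the enantiomer energy difference onto a coordinate plane.

    rule="at_L_min": each projected cell takes E_L - E_D at the grid point
    minimizing E_L along the collapsed axis.  rule="plane_min": the
    difference of the two independent minima along the collapsed axis (this
    variant is exactly antisymmetric under enantiomer exchange).
    """
    if scan_l.grid != scan_d.grid or scan_l.mode != scan_d.mode:
        raise ValueError("discrimination map needs scans on identical grids")
    axes = scan_l.grid.axes()
    if plane == "XY":
        collapse = 2
        a1, a2 = axes[0], axes[1]
    elif plane == "XZ":
        collapse = 1
        a1, a2 = axes[0], axes[2]
    else:
        raise ValueError("plane must be 'XY' or 'XZ'")
    el = np.moveaxis(scan_l.values, collapse, -1)
    ed = np.moveaxis(scan_d.values, collapse, -1)
    if rule == "at_L_min":
        idx = np.argmin(el, axis=-1)
        vals = (
            np.take_along_axis(el, idx[..., None], axis=-1)
            - np.take_along_axis(ed, idx[..., None], axis=-1)
        )[..., 0]
    elif rule == "plane_min":
        vals = el.min(axis=-1) - ed.min(axis=-1)
    else:
        raise ValueError("rule must be 'at_L_min' or 'plane_min'")
    return DiscriminationMap(plane=plane, axis_1=a1, axis_2=a2, values=vals, rule=rule)


@dataclass
class MinimumConfiguration:
    """Global PES minimum: energy breakdown, COM, axis angles, orientation."""

    e_min: float
    breakdown: EnergyBreakdown
    com: np.ndarray
    theta: float
    phi: float
    orientation: np.ndarray
    grid_index: tuple = ()
    orientation_index: int = 0


def global_minimum(
    scan: ScanResult, guest: ParameterizedMolecule | None = None
) -> MinimumConfiguration:
    """Extract the lowest-energy complex configuration from a min-mode scan.

    Ties are broken lexicographically in (ix, iy, iz) and, per point, by the
    first orientation attaining the minimum.  The full energy breakdown is
    re-evaluated at the minimizing pose (intramolecular terms from the
    guest's reference conformation).
    """
    if scan.mode != "min":
        raise ValueError("global minimum needs a min-mode scan")
    if scan.values.size == 0:
        raise ValueError("empty scan")
    if scan.system is None or scan.orientations is None:
        raise ValueError("scan carries no system context")
    guest = guest if guest is not None else scan.system.guest
    flat = int(np.argmin(scan.values))  # first occurrence = lexicographic
    idx = np.unravel_index(flat, scan.values.shape)
    oi = int(scan.argmin_orientation[idx])
    axes = scan.grid.axes()
    com = np.array([axes[k][idx[k]] for k in range(3)])
    quat = scan.orientations.quats[oi]
    pose = Pose(com=com, orientation=quat / np.linalg.norm(quat))
    breakdown = scan.system.inter_energy(pose) + intra_energy(guest)
    theta, phi = (
        guest_axis_angles(guest, pose)
        if guest.chiral_center_index is not None
        else (float("nan"), float("nan"))
    )
    return MinimumConfiguration(
        e_min=float(scan.values[idx]),
        breakdown=breakdown,
        com=com,
        theta=theta,
        phi=phi,
        orientation=pose.orientation,
        grid_index=tuple(int(i) for i in idx),
        orientation_index=oi,
    )
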