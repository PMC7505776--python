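"""Superimposability tests: minimum RMSD over rigid rotations.

Chirality claims are settled operationally: a molecule is achiral iff its
mirror image can be superimposed on it by a proper rotation (allowing
permutations of interaction-equivalent atoms).  The search seeds an
orientation grid, matches atoms within equivalence classes by the Hungarian
algorithm, and polishes the best candidates with Kabsch/rematch iterations.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.transform import Rotation

from .structures import ParameterizedMolecule, mirror_molecule

__all__ = ["min_rmsd_over_rotations", "mirror_rmsd", "is_superimposable"]


def _atom_classes(mol: ParameterizedMolecule):
    return [
        (a.element, a.vdw_type, round(a.charge, 6), round(a.mass, 6))
        for a in mol.atoms
    ]


def _matched_rmsd(xa: np.ndarray, xb: np.ndarray, classes_a, classes_b):
    """Best per-class assignment RMSD between two fixed point clouds."""
    total = 0.0
    n = len(classes_a)
    perm = np.zeros(n, dtype=int)
    for cls in set(classes_a):
        ia = [i for i, c in enumerate(classes_a) if c == cls]
        ib = [i for i, c in enumerate(classes_b) if c == cls]
        d2 = ((xa[ia][:, None, :] - xb[ib][None, :, :]) ** 2).sum(axis=2)
        ri, ci = linear_sum_assignment(d2)
        total += d2[ri, ci].sum()
        for r, c in zip(ri, ci):
            perm[ia[r]] = ib[c]
    return np.sqrt(total / n), perm


def min_rmsd_over_rotations(
    mol_a: ParameterizedMolecule,
    mol_b: ParameterizedMolecule,
    n_seeds: int = 576,
    n_refine: int = 12,
) -> float:
    """Minimum RMSD of b onto a over all proper rotations and
    class-preserving atom permutations.

    Returns ``inf`` when the atom equivalence-class histograms differ.
    Centroid-centred; rotations are seeded on a deterministic orientation
    grid and the best seeds are polished by alternating optimal-rotation
    (Kabsch) and optimal-assignment steps.
    """
    classes_a = _atom_classes(mol_a)
    classes_b = _atom_classes(mol_b)
    if sorted(classes_a) != sorted(classes_b):
        return float("inf")
    xa = mol_a.coords()
    xb = mol_b.coords()
    xa = xa - xa.mean(axis=0)
    xb = xb - xb.mean(axis=0)

    # deterministic rotation seeds: ZYZ grid
    n = max(2, int(round(n_seeds ** (1.0 / 3.0))))
    alpha = 2 * np.pi * np.arange(n) / n
    beta = np.arccos(np.linspace(1, -1, n))
    gamma = 2 * np.pi * np.arange(n) / n
    aa, bb, gg = np.meshgrid(alpha, beta, gamma, indexing="ij")
    seeds = Rotation.from_euler(
        "ZYZ", np.column_stack([aa.ravel(), bb.ravel(), gg.ravel()])
    )

    results = []
    for rot in seeds:
        xr = rot.apply(xb)
        rmsd, perm = _matched_rmsd(xa, xr, classes_a, classes_b)
        results.append((rmsd, rot, perm))
    results.sort(key=lambda t: t[0])

    best = results[0][0]
    for rmsd, rot, perm in results[:8]:
        cur_rot = rot
        for _ in range(n_refine):
            xr = cur_rot.apply(xb)
            _, perm = _matched_rmsd(xa, xr, classes_a, classes_b)
            # optimal proper rotation for this correspondence
            opt, _ = Rotation.align_vectors(xa[perm.argsort()], xb)
            # align_vectors maps xb onto xa[perm.argsort()]; recompute rmsd
            xr2 = opt.apply(xb)
            rmsd2, _ = _matched_rmsd(xa, xr2, classes_a, classes_b)
            if rmsd2 >= rmsd - 1e-12:
                break
            rmsd, cur_rot = rmsd2, opt
        best = min(best, rmsd)
    return float(best)


def mirror_rmsd(mol: ParameterizedMolecule, **kwargs) -> float:
    """Min RMSD between a molecule and its mirror image (0 iff achiral)."""
    return min_rmsd_over_rotations(mol, mirror_molecule(mol, "yz"), **kwargs)


def is_superimposable(
    mol_a: ParameterizedMolecule,
    mol_b: ParameterizedMolecule,
    tol: float = 1e-6,
    **kwargs,
) -> bool:
    return min_rmsd_over_rotations(mol_a, mol_b, **kwargs) < tol
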