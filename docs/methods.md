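# Methods

`chiralcavity` models the inclusion of a small chiral guest in a rigid
cavity-shaped host (a cyclodextrin-class macrocycle) and asks whether the
host discriminates between the guest's two enantiomers. Two engines share
one energy model: a molecular-mechanics scanning engine that maps potential
energy surfaces over guest dispositions, and a rigid-body molecular-dynamics
engine that turns trajectory ensembles into binding free energies and an
elution-order prediction.

## Energy model

The interaction energy decomposes in the classic AMBER (Weiner-type) form

    E = E_inter + E_intra
    E_inter = E_LJ + E_ele + E_Hbond
    E_intra = E_bond + E_angle + E_torsion

with all energies in kcal/mol, lengths in Å, charges in elementary charges.

* **Lennard-Jones 12-6**: `A/r^12 − B/r^6` per host–guest atom pair, with
  additive-radius combining `r*_ij = r*_i + r*_j`, geometric-mean
  `ε_ij = √(ε_i ε_j)`, `A = ε r*^12`, `B = 2 ε r*^6`. No cutoff — fixture
  systems have ≲ 50 atoms total — and no periodic boundary (gas phase).
* **Electrostatics**: `k_c q_i q_j / (ε r)` with `k_c = 332.0637
  kcal·Å·mol⁻¹·e⁻²` and a scalar relative permittivity ε (default 1,
  vacuum). No Ewald/PME, no polarizability.
* **Hydrogen bonds**: a 10-12 term `C/r^12 − D/r^10` for donor-hydrogen /
  acceptor pairs, active only while the geometry fits: H···acceptor
  distance ≤ 2.5 Å and donor–H···acceptor angle ≥ 135° (both configurable).
  While the gate passes, the pair's plain LJ term is suppressed (the 10-12
  replaces the 6-12, as in the Weiner field); when the gate fails the pair
  reverts to plain LJ. The shipped generic donor/acceptor pair
  (C = 7557, D = 2385) bottoms out at −0.501 kcal/mol near 1.95 Å. The
  donor's parent heavy atom (needed for the angle) is the bonded partner
  when bonds are present, else the nearest non-hydrogen atom.
* **Bonded terms**: harmonic bonds `K_r (r−r_eq)²` and angles
  `K_θ (θ−θ_eq)²`, Fourier torsions `Σ (V_n/2)(1 + cos(nφ − γ))`.
  Intramolecular non-bonded (1-4) terms are deliberately excluded: E_intra
  is exactly the bond/angle/torsion sum.
* **Clash cap**: the scalar total used by scans, Boltzmann weights and MD
  records is clipped at `E_cap = +100 kcal/mol` and flagged; component
  values are reported raw (finite — near-overlaps contribute E_cap per pair
  instead of diverging). The cap is applied to the *total*, never to a
  single component, so a capped repulsive LJ wall can never be outweighed
  by an uncapped attractive Coulomb singularity.

Forces and torques on the rigid guest are the analytic gradients of
E_inter; the H-bond gate is treated as locked during differentiation, so
forces are discontinuous exactly at gate boundaries (a measure-zero set the
integrator crosses without special handling). Energy–force consistency is
tested against central differences at 1e-6 relative.

## Host frame and cavity geometry

Hosts are expressed in a body frame: origin at the center of mass, cavity
axis along Z, wide rim toward +Z by default (`rim_spec` flips it). The
axis is the inertia eigenvector whose eigenvalue is most separated from the
other two. For a flat ring the symmetry axis carries the *largest*
principal moment, for an elongated cavity the smallest; picking the
non-degenerate moment handles both, and degenerate tensors (collinear or
near-spherical atom sets) raise a geometry error. The transverse
orientation is pinned deterministically (farthest-from-axis atom, lowest
index on ties, placed in the +X half-plane), which makes alignment
idempotent and invariant to rigid motions of the input to ~1e-8 Å.

The cavity boundary is a piecewise-linear radius profile r(z): the minimal
radial atom distance per z-slab between the rim planes. A point is "inside"
iff its z lies between the rims and its axial distance is ≤ r(z). This is
deliberately conservative — interaction sites placed inside the cavity
shrink the profile locally.

## Scanning engine

The guest COM visits a regular Cartesian grid (default −5…5 Å at 0.1 Å,
reduced in tests) and, at each point, a systematic orientation set: a ZYZ
Euler grid with α, γ uniform on [0, 2π) and β drawn from a uniform grid in
cos β, default 24×40×24 = 23,040 orientations. Per grid point the engine
records either the minimum over orientations (the PES) or the
Boltzmann-weighted orientation average
`⟨E⟩ = Σ E_k w_k / Σ w_k, w_k = exp(−(E_k − E_min)/k_B T)`,
accumulated with a running min-shift so any temperature from the T→0 limit
(the PES) to the T→∞ limit (the plain mean) is numerically stable.

Derived outputs:

* **Penetration potential W(z)** — the minimum of the capped intermolecular
  energy over each z-plane (all x, y, orientations); component curves
  W_LJ, W_ELE, W_HB are *independent* minima of each component over its own
  best pose (the alternative — components evaluated at the W-minimizing
  pose — is not exposed because the independent form is the only one whose
  curves are comparable across systems).
* **Discrimination maps** — plane projections of E_L − E_D. The default
  rule evaluates the difference at the grid point minimizing E_L along the
  collapsed axis; the `plane_min` rule differences the two independent
  plane minima and is exactly antisymmetric under enantiomer exchange
  (used by the symmetry tests).
* **Global minimum** — lowest grid value with lexicographic (ix, iy, iz,
  orientation) tie-breaking, re-evaluated as a full six-component breakdown,
  with the guest-axis spherical angles (θ, φ) of the chiral-center →
  most-distant-carbon unit vector.

Scans evaluate E_inter only; for rigid fixture guests E_intra is a
constant. `relax_internal` (backtracking gradient descent on the guest's
rotatable torsion angles, monotone non-increasing E, bounded displacement)
is available for flexible guests and for refining minima.

## Dynamics engine

The host is fixed (infinite mass); the guest is a rigid body whose
intramolecular coordinates stay frozen at the reference conformation, so
E_intra enters recorded energies as a constant. The state is COM position,
COM velocity, a scalar-first body→lab unit quaternion, and the body-frame
angular velocity in the guest's principal-axis frame.

Integration is a kick-drift-kick leapfrog variant:

1. translational half-kick; rotational half-kick solving
   `ω_h = ω_0 + (dt/2) I⁻¹(τ_b − ω_h×(I ω_h))` implicitly (fixed point to
   1e-16),
2. drift: `x += dt v_h` and an exact quaternion exponential-map rotation by
   `ω_h dt` (norm-preserving),
3. force/torque refresh, then the mirrored explicit half-kicks with the
   gyroscopic term still evaluated at ω_h.

The implicit/explicit mirror symmetry makes the step exactly
time-reversible (verified to 1e-8 Å over 500 steps out-and-back), the
exponential map keeps quaternion norms at 1 to ~1e-12 over 10⁶ steps, and
torque-free symmetric-top precession matches the closed form
`ω_prec = ω_spin (I_a − I_p)/I_p` to 0.1% over 10 ps. NVE energy drift
scales as dt² and is ~1e-6 relative over 10 ps at dt = 1 fs for a guest
thermalized at 100 K in the cone fixture's energy minimum (an unbound start
converts several kcal/mol of potential energy into hard wall collisions,
which is a statement about the steep coarse-bead walls, not the scheme).

**Constrained temperature**: after every half-kick, v and ω are rescaled so
the translational and rotational kinetic energies each equal (3/2) k_B T
exactly (separate isokinetic constraints, Brown–Clarke style). The
per-step deviation is tracked inside the kernel and stays below 1e-15
kcal/mol over 100 ps runs. No Nosé–Hoover option.

**Protocol**: trajectories start outside the cavity facing the rims
(default standoff 8 Å beyond the rim plane, reduced to 4 Å for the 50 ps
toy protocols so entry is likely within the run), alternating rims and
orientation families (axis parallel to the rim plane at stepped azimuths,
or pointing at the cavity). D-enantiomer starts are paired to L starts by
minimizing the vdW-energy gap over an azimuth-augmented candidate set with
the mean atom-to-mirror-atom distance as near-tie (1e-9 kcal/mol)
criterion. Initial speeds satisfy the temperature exactly; directions come
from a per-trajectory stream derived from the master seed, identical for
both enantiomers. Integration stops at t_max or when the COM leaves the
escape sphere (default 12 Å; "near the cavity" is not otherwise
quantified). Runs are bitwise deterministic given the seed.

**Classification and observables**: a recorded sample is inside iff the COM
passes the cavity test; a trajectory is *inner* if any sample is inside,
else *external*. Residence time counts (possibly non-contiguous) inside
samples times the record spacing; the t = 0 sample carries no time. The
binding free energy of a trajectory is computed over its inside samples
against the separated-reactants reference (zero E_inter plus the constant
E_intra), either as the time average (default) or as
`−k_B T ln⟨exp(−ΔE/k_B T)⟩` (which Jensen's inequality keeps ≤ the time
average); the underlying reference the field cites gives no closed formula,
so both candidates ship and neither is asserted as canonical. External
trajectories are excluded from every average but remain visible as counts.
ΔF_mean = F_mean(L) − F_mean(D) > 0 means D binds tighter and L elutes
first; the tie tolerance defaults to 0.05 kcal/mol. Position probability
densities bin COM samples on a 0.5 Å grid aligned to spacing multiples and
normalize by the total count; the preferred configuration is the modal cell
plus the modal (θ, φ) at 10° bins within it, lexicographic on ties.

## Synthetic fixtures: what they emulate and what they do not

Real inputs for this problem class — crystallographic macrocycle
coordinates with literature charges, quantum-chemically optimized guest
geometries — are curated data the package treats as inputs, not something
it computes. The fixtures module generates coarse stand-ins that preserve
the *symmetry structure* of the problem:

* `make_achiral_cone_host` — coaxial atom rings of different radii
  (default 4 and 6 Å at z = ∓2): a truncated-cone shell, mirror-symmetric
  through every plane containing the axis, hence achiral.
* `make_cd_like_host` — n repeated 3-site motifs (mid-wall site, wide-rim
  acceptor, narrow-rim donor-H; n = 7 for the cyclodextrin-like geometry),
  C_n-symmetric and achiral, with balanced ±0.18 e rim charges.
* `make_chiral_tetra_guest` — a minimal stereocenter: a central carbon with
  four distinct single-site substituents (charges −0.3/+0.3/0/0 e) at
  tetrahedral geometry; the D form is the mirror image.
* `make_chiral_probe_host` — the cone plus three distinct interior sites
  (A: +0.6 e, B: −0.6 e, C: deep LJ well) at radius 3 Å, azimuths
  0°/+60°/−60°, z = −1/+0.5/+0.5 Å. Sites B and C share z and mirror-image
  azimuths, so exchanging their types *and charges* is exactly the mirror
  host. The geometry was sized against the package's own scans so the
  D-guest binds more strongly by ≈ 1.7 kcal/mol (≈ 3 k_B T at 293 K); the
  favored enantiomer is recorded on the generator as a design constant.

Interaction parameters for the coarse bead types are deliberately deep
(ε up to 0.8 kcal/mol) because each bead stands for a whole chemical group;
they were sized so fixture binding energies land in the −5…−25 kcal/mol
range typical of small-guest inclusion complexes. Every chirality claim is
verified operationally by a superimposability oracle (minimum RMSD over
rotation seeds with Hungarian atom matching within interaction-equivalence
classes and Kabsch polishing).

Passing tests on these fixtures demonstrates that the machinery respects
the symmetries the science depends on — parity invariance of the energy,
zero discrimination by achiral hosts, sign recovery of an engineered
preference — and that the protocol is deterministic and internally
consistent. It does *not* validate force-field accuracy for any real
host–guest pair; real systems need real coordinates, charges and parameter
tables supplied through the structure/topology file interface.

## Default study sizes

Full-resolution scans (101³ × 23,040 orientations) and 5 ns trajectories
are supported but compute-heavy; the shipped tests and the acceptance
script use reduced settings as the package's default toy-system study:
grids of 11³–13³ points at 0.5 Å, 512–1000 orientations, 10–20 trajectories
of 50 ps per enantiomer at dt = 1 fs recording every 100 steps. The MD
inner loop is a compiled (numba) kernel; the pure-Python step exists for
arbitrary force providers and is validated against closed forms.

## Known limitations

* Host fixed and internally rigid; guest internally rigid during MD
  (relaxation available only as a static refinement). Systems where
  induced-fit matters are outside scope.
* Scalar dielectric only; no explicit solvent, no cutoffs/PME (fine at
  these sizes, wrong for large systems).
* The isokinetic constraint fixes kinetic energies exactly; ensembles are
  not canonical and kinetic temperature fluctuations are suppressed.
* Orientation grids sample SO(3) systematically but not uniformly in the
  Haar sense; minima converge monotonically as counts grow (tested), but
  reported (θ, φ) minima are grid-resolution limited.
* The elution-order call is the sign of ΔF_mean; no kinetic model of
  chromatographic retention is attempted.
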