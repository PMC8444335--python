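# Methods

This note records the model, the discretization and numerical choices,
and what the synthetic test systems do and do not probe.

## Model

The solute is a collection of atomic sites.  Environment sites carry
fixed multipoles — charge q (e), dipole μs (e·bohr), traceless Cartesian
(Buckingham) quadrupole Θ (e·bohr²) — and an isotropic polarizability α
(bohr³) that produces induced point dipoles.  An optional *probe* set
carries fixed multipoles only (α ≡ 0) and stands in for a QM density:
its interactions with the environment and with the continuum are
included, its internal energy is not (that slot belongs to the absent
electronic-structure host).  All internal units are Hartree atomic
units; file inputs in Å are converted on read.

Sign conventions, used everywhere: `E = −∇V`, `G = ∇E`, `H = ∇G`; the
energy of a multipole in an external potential is
`U = qV − μ·E − (1/3)Θ:G`.  Quadrupoles are stored traceless; the input
pipeline symmetrizes and detraces, so adding any multiple of the
identity to a raw quadrupole is gauge-irrelevant.

### Induced dipoles

Two response branches (d and p) are carried, distinguished by the
exclusion scaling of the inducing field of the fixed multipoles
(`d_scale`, `p_scale`, default 1.0 each, in which case the branches
coincide).  The polarization operator is
`(Tμ)_i = μ_i/α_i − Σ_{j≠i} T^thole_ij μ_j` with Thole's exponential
damping: all damped pair kernels derive from one scalar ladder
`B_{n+1} = −(1/r) dB_n/dr` with `B_1 = λ₃/r³`,
`λ₃ = 1 − e^{−v}`, `v = a r³/√(α_i α_j)`, giving
`λ₅, λ₇, λ₉, λ₁₁` for the higher kernels.  Defining the ladder by the
derivative recursion (rather than quoting factors independently) makes
every damped field exactly the gradient of the damped field one level
below, which is what the analytical forces require; the closed forms
were generated symbolically and are pinned by finite-difference tests.
Default damping width a = 0.39.  Pairs in which either site has α = 0
(in particular all probe interactions) are undamped.  The damped
potential of a charge is never needed by any energy term and is left
bare.

### Continuum (ddCOSMO)

One sphere per atom (solvent-accessible radii), per-sphere angular
quadrature, local expansions of the reaction potential
`W_j(r) = Σ_lm X_j^lm (|r−x_j|/r_j)^l Y_lm`.  The discrete operator is
derived from the Schwarz decomposition: on each sphere's grid the
conductor condition (total potential zero) is imposed on the exposed
part and, on the buried part, the local solution is matched to a
switching-weighted average of the neighbours' local solutions, with
weights `ω_ijn = c_ijn/C_in · (1 − U_in)` built from the per-neighbour
penetrations c.  Projection by quadrature gives
`(LX)_i = −X_i + Σ_{j≠i} P_ij X_j`; the −Identity diagonal carries the
conductor sign so that `L X = Φ` with Φ assembled from the *positive*
solute potential yields a stabilizing energy `E = f(ε)/2 ⟨Ψ, X⟩`.
This normalization is not copied from any source; it is pinned uniquely
by the analytic Born and off-center Kirkwood limits, which the tests
enforce to 1e-9.

`f(ε) = (ε−1)/ε` by default (`f_scheme = "half"` selects
`(ε−1)/(ε+1/2)`); ε = 1 switches the layer off exactly (two-layer
limit), ε = ∞ is the conductor limit.  Default ε = 15, a value between
typical protein-interior and bulk estimates.  Ψ is strictly local:
per-sphere rows at l = 0, 1, 2 built from the derivatives of the scaled
solid harmonics at the sphere center, so that ⟨Ψ_i, X_i⟩ is exactly the
interaction of the site multipole with its local expansion.

### Switching function and cavity

`U_in = Π_k (1 − c_k)` with a quintic smoothstep in the scaled
penetration depth over a shell of relative width η = 0.1 just inside
each sphere surface; C² regularity comfortably covers the C¹ needed by
the ∂U force terms.  Default radii: 1.1 × van der Waals plus a 1.4 Å
solvent probe (each overridable per atom in the parameter table).

### Angular grids

Genuine Lebedev rules are used for the orders with exact closed-form
constants (6, 14, 26, 38, 50 points; degrees 3–11).  The request keys
110/194/302 are served by Gauss–Legendre × uniform product rules of the
same polynomial exactness degree (17/23/29) — more points, identical
exactness, and the product family extends to arbitrary degree, which
the off-center Kirkwood check requires: matching the truncated series
at d/R = 0.7 to 1e-9 needs quadrature degree ≈ 60+ because the aliasing
error of the surface potential decays as (d/R)^(degree − lmax).  Every
contraction in the package depends only on the weight sum (4π) and the
exactness degree, both preserved.  Grids are canonical per sphere; an
optional orientation matrix co-rotates them with the system, which
makes rigid-rotation invariance exact (see Limitations).

### Coupling and the Lagrangian

Ξ (dipole potentials projected on the cavity harmonics) and its adjoint
(minus the field of the pseudo-charges ξ at the dipole sites) are
evaluated matrix-free as two-step processes so the tree code can serve
the O(N·M) half; Ω and Ω† are strictly local and O(N).  The Lagrangian
pairs the multiplier of each branch with the *other* branch's coupling
terms (S_p with X_d and μ_d, S_d with X_p and μ_p) with prefactor f/4 —
the unique sign/prefactor placement for which stationarity reproduces
the closed d and p triplets and for which the polarization constraint
can be rewritten via
`T μ_d − E(ρ) − E_d(M) = −½ f(ε)(Ω†X_d + Ξ†S_d)`.  The energy uses the
symmetric d/p convention (`−½(μ_d·F_p + μ_p·F_d)`), which reduces to
the standard single-branch expression when the scalings coincide; it is
the only convention implemented (`energy_dipole_branch = "symmetric"`).

### Solvers

L and L† are solved by block-Jacobi sweeps (the diagonal is −Identity)
with DIIS acceleration (depth 10); T by conjugate gradients with the
diagonal (α) preconditioner and explicit detection of loss of positive
definiteness.  The coupled triplets are solved independently per branch
by outer fixed-point iterations on μ with warm-started inner solves;
macro convergence is measured on the relative change of μ.  Default
relative-residual tolerance 1e-8 (tests use 1e-10 … 1e-12 where force
accuracy demands it).  Dense constructions of L, T, Ξ, Ω are retained
as test oracles for small systems.

### Forces

Because the energy is stationary in all six unknowns, forces are the
partial position-derivative of the Lagrangian at fixed unknowns,
grouped as: static multipole pair forces (with local-frame
rotation-matrix terms, obtained by exact complex-step differentiation
of the analytic frame construction); polarization terms (damped kernels
differentiate consistently through the B-ladder); continuum-geometric
terms (∂L via solid-harmonic gradients and ∂ω, plus ∂U contractions);
Ψ-derivative terms (rotation matrices only — zero for charges and
induced dipoles); and Φ-derivative terms recast as pseudo-charge
Coulomb interactions (field, field-gradient and field-Hessian
contractions at the sources; induced dipoles follow the same pattern
without rotation terms).  Gradients of regular/irregular solid
harmonics use exact constant coupling matrices (the gradient of a
degree-l solid harmonic is a fixed combination of degree l∓1 ones),
determined once per lmax by solving the identity on sample points with
complex-step right-hand sides.  Every term and the total are validated
against central finite differences of fully re-solved energies
(h = 1e-4 bohr, solver tolerance 1e-10, agreement ≤ 1e-6 hartree/bohr).

### Acceleration

A dual-tree fast summation evaluates potentials/fields/field gradients
of charge+dipole distributions.  Sources and targets are organized in
binary kd-trees (split along the widest extent, cells centered on their
points — essential to keep bounding radii tight for anisotropic
distributions such as chains); a dual traversal accepts a cell pair
when r_A + r_B < θ·d and otherwise splits the wider cell.  Accepted
source multipole expansions (real solid harmonics, default order
p = 8, θ = 0.5) are sampled on a spherical quadrature around the target
cell and projected onto a local regular-harmonic expansion — an exact
projection because the far field is harmonic there and the rule
integrates the required degree — which is passed down the target tree
by exact polynomial re-expansion and evaluated once per target; fields
and field gradients come from the exact gradient coupling matrices.
All per-pair work is cell-sized, so the cost is O(N + M) up to tree
depth; the measured log-log cost exponent over 1k–8k sites is ~1.06.
Far-field error is bounded by ~θ^{p+1}/(1−θ) geometry factors,
decreases monotonically in p, and θ = 0 reproduces exact direct
summation; tight settings (p = 14, θ = 0.3) bring end-to-end coupled
energies within 1e-8 hartree (in practice ~1e-12) of the direct path.
Quadrupole far fields go through the direct path, whose cost is bounded
by the small number of fixed-multipole sources per target batch.

## Synthetic systems

The generators produce everything the tests consume: Born spheres with
closed-form expectations; random clusters with minimum-separation
(≥ 2 bohr), valid frames and traceless quadrupoles; and nested "shell"
families — a charged, dipolar probe inside one fixed realization of a
polar, polarizable environment with ±1 e ionic sites, cropped at
increasing radii.  Ion charges alternate in radial order, so generic
radial croppings frequently carry net charge ±1 while every
even-ion-count prefix is exactly neutral (the neutral-cropping mode
selects those).  This reproduces the phenomenology of interest — probe
energies oscillate with cropping radius, worse for charged croppings,
and an outer dielectric (ε = 15) damps the oscillations by an order of
magnitude — but none of the chemistry of real proteins: no covalent
topology, no realistic parameter correlations, no solvent structure.
Passing these tests validates the electrostatic machinery, not force
fields or biomolecular predictions.

Problem sizes used by the default test run and the acceptance script —
clusters of 4–10 sites at lmax 2–3 with 26-point grids for
finite-difference force validation, a 30-sphere system for dense-oracle
comparisons, a 500-sphere chain (lmax 2, 26 nodes, matching the
coarse-discretization regime in which such models are typically
benchmarked) for the accelerated/direct energy comparison, and 1k–8k
sites for the cost-exponent fit — were chosen to exercise every code
path at interactive runtimes; all tolerances quoted above are
independent of these sizes.

## Numerical details and edge cases

* Associated-Legendre recursions are formulated polynomially (no
  divisions), stable to lmax = 16 and analytic in the coordinates, so
  complex-step differentiation of any harmonic quantity is exact.
* Coincident source/target pairs raise a singular-geometry error unless
  the pair is masked (exclusion weight 0), in which case the kernel is
  sanitized and the pair contributes nothing.
* Thole damping with v ≥ 700 is treated as exactly undamped; λ factors
  near v = 0 use expm1 to limit cancellation.
* DIIS falls back to plain Jacobi when its (tiny) linear system is
  singular; rhs = 0 short-circuits every solver.
* Ties in the switching partition (a node buried by several spheres)
  are resolved by penetration-proportional weights, C¹ by construction.
* Degenerate inputs rejected with typed errors: coincident equal
  spheres, non-positive radii, frames with collinear or missing
  neighbours, off-center sources in Ψ/Ω, α < 0, probe sites with α > 0.

## Known limitations

* The discrete continuum energy with fixed (lab-frame) per-sphere grids
  is rotation-invariant only up to quadrature error; consequently the
  net *torque* of the analytical forces with the continuum on is
  O(grid error) (~1e-3 hartree/bohr·bohr at lmax = 2 / 26 nodes,
  decreasing under refinement), while the net *force* vanishes exactly
  and the two-layer torque balance is exact.  This is a property of all
  grid-based COSMO discretizations, not of the implementation; the
  optional grid-orientation argument exists so invariance can be tested
  exactly by co-rotating the discretization.
* Dielectric ddPCM (exact ε dependence), ionic screening, periodic
  boundary conditions, anisotropic polarizabilities, and AMOEBA's full
  frame-rule zoo (z-bisector, 3-fold) are out of scope; the two
  implemented frame rules cover the synthetic systems and the reader
  rejects others explicitly.
* Exclusion rules are global per-branch scale factors, not per-group
  bonded-neighbour lists; with defaults (1.0) no interactions are
  excluded.
* The tree code accelerates charge+dipole sources only; T matrix-vector
  products use direct summation (quadratic in the number of polarizable
  sites), which is not the bottleneck at the sizes exercised here.
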