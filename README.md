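# ddembed

A fully coupled **polarizable-multipole / continuum** embedding engine:
AMOEBA-style electrostatics (fixed atomic charges, dipoles and
quadrupoles plus Thole-damped induced dipoles) self-consistently coupled
to the **domain-decomposition conductor-like screening model (ddCOSMO)**,
with energies, analytical forces, and linear-scaling evaluation of the
electrostatic couplings.

The package is aimed at method developers and computational chemists who
need the *classical* half of a three-layer QM/polarizable-MM/continuum
model as a standalone, testable component.  A fixed "probe" multipole
distribution stands in for the QM density, so the entire coupled
machinery — both response branches, the reaction field, and every force
term — runs and is verifiable without an electronic-structure host.

## The model

The environment is a set of sites carrying fixed multipoles
M = (q, μ<sub>s</sub>, Θ) and isotropic polarizabilities α; the continuum
is a conductor scaled by f(ε) = (ε−1)/ε surrounding a solvent-accessible
cavity with one sphere per atom.  Because neither the induced-dipole
model nor ddCOSMO is variational, the coupled problem is formulated as a
Lagrangian over **six** sets of unknowns: induced dipoles μ<sub>d</sub>,
μ<sub>p</sub>, and two pairs of ddCOSMO solutions/multipliers
(X<sub>d</sub>, S<sub>d</sub>), (X<sub>p</sub>, S<sub>p</sub>).
Stationarity yields two independent coupled triplets (b = d, p):

```
T μ_b   = E(ρ) + E_b(M) − ½ f(ε) (Ω† X_b + Ξ† S_b)
L X_b   = Φ(ρ) + Φ(M) + Ξ μ_b
L† S_b  = Ψ(ρ) + Ψ(M) + Ω μ_b
```

where T is the Thole-damped polarization matrix, L the sparse ddCOSMO
operator, Ξ maps dipoles to their potential in the per-sphere
spherical-harmonic basis, and Ω is the (strictly local) Ψ of the dipole
distribution.  At the solution the energy reduces to

```
E = E_static − ½ (μ_d·F_p + μ_p·F_d) + ½ μ_p·T μ_d
    + f/4 [ ⟨X_d, Ψ + Ω μ_p⟩ + ⟨X_p, Ψ + Ω μ_d⟩ ]
```

and, because the formulation is a Lagrangian, analytical forces need no
response equations: every term is differentiated at fixed unknowns,
including the geometric derivatives of L and of the smooth switching
function U, the local-frame rotation-matrix terms of Ψ, and the
potential-derivative terms recast through pseudo-charges ξ so that a
Barnes–Hut tree code can evaluate them in sub-quadratic time.

## Worked example

Generate a ten-site polarizable cluster with a two-site probe and
compute its embedding energy and forces:

```bash
ddembed make-fixture cluster demo --n 10 --seed 7
ddembed energy demo/cluster.xyz demo/cluster.prm --config demo/cluster.toml
```

which prints (hartree):

```
Embedding energy (hartree)
  static_env    0.006493569659
  probe_env     0.002745249119
  induced       0.002653627462
  continuum    -0.157896249285
  coupling     -0.002664080192
  total        -0.148667883236
```

`static_env` is the fixed-multipole self-energy of the environment,
`probe_env` the probe–environment interaction, `induced` the
induced-dipole energy, `continuum` the reaction-field term
f/4 ⟨Ψ, X<sub>d</sub>+X<sub>p</sub>⟩, and `coupling` the
dipole–continuum cross term.  `ddembed forces ...` adds the per-atom
force decomposition, and

```bash
ddembed check-gradients demo/cluster.xyz demo/cluster.prm --config demo/cluster.toml
```

re-solves the coupled systems at displaced geometries and reports the
maximum deviation between analytical and finite-difference forces
(typically below 1e-8 hartree/bohr for a tightly converged state).

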