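"""The coupled six-variable problem: system container, Lagrangian,
macro/micro solver, and the embedding energy.

Unknowns: induced dipoles mu_d, mu_p and two pairs of ddCOSMO solutions
and multipliers (X_d, S_d), (X_p, S_p).  With F_b the branch inducing
field, Phi_s / Psi_s the static (probe + fixed multipole) right-hand
sides and f = f(eps), the Lagrangian reads

  L = E_static
      - 1/2 (mu_d . F_p + mu_p . F_d) + 1/2 mu_p . T mu_d
      + f/4 [ <S_d + S_p, Phi_s> + <X_d + X_p, Psi_s>
              + <S_p, Xi mu_d> + <S_d, Xi mu_p>
              + <X_p, Omega mu_d> + <X_d, Omega mu_p>
              - <S_p, L X_d> - <S_d, L X_p> ]

The sign/prefactor placement is the unique one for which stationarity
yields the two closed triplets

  T mu_b  = F_b - f/2 (Omega^T X_b + Xi^T S_b)
  L X_b   = Phi_s + Xi mu_b
  L^T S_b = Psi_s + Omega mu_b          (b = d, p)

and for which the polarization constraint can be rewritten through the
identity T mu_d - F_d = -f/2 (Omega^T X_d + Xi^T S_d).  At a solved
state the ddCOSMO constraints cancel and the energy reduces to

  E = E_static - 1/2 (mu_d . F_p + mu_p . F_d) + 1/2 mu_p . T mu_d
      + f/4 [ <X_d, Psi_s + Omega mu_p> + <X_p, Psi_s + Omega mu_d> ]

which is what :func:`embedding_energy` evaluates (the cross d/p
pairings here are the same two contractions that drive the geometric
force terms).  The d and p triplets do not couple to each other through
the linear systems, only through the energy, and are solved
independently by outer fixed-point iterations on mu with warm-started
inner solves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .cavity import Cavity, build_cavity
from .config import RunConfig
from .coupling import apply_Omega, apply_Omega_adj, apply_Xi, apply_Xi_adj
from .ddcosmo import (
    DDWorkspace,
    HarmonicCoeffs,
    apply_L,
    apply_Ladj,
    assemble_Phi,
    assemble_Psi,
    inner,
    solve_L,
    solve_Ladj,
)
from .errors import SolverError, StructuralError
from .multipoles import (
    MultipoleSet,
    interaction_energy,
    properties_direct,
    self_energy,
)
from .polarization import apply_T, rhs_fields, solve_T


@dataclass
class EmbeddingState:
    """The six coupled unknowns plus solver diagnostics."""

    mu_d: np.ndarray
    mu_p: np.ndarray
    X_d: HarmonicCoeffs
    S_d: HarmonicCoeffs
    X_p: HarmonicCoeffs
    S_p: HarmonicCoeffs
    iterations: dict = field(default_factory=dict)
    residuals: dict = field(default_factory=dict)
    solved: bool = False
    tol: float = 0.0


@dataclass
class EnergyBreakdown:
    """Embedding energy decomposed by physical origin (hartree)."""

    static_env: float  # fixed-multipole self-energy of the environment
    probe_env: float  # probe density interacting with the fixed multipoles
    induced: float  # induced-dipole energy (field + T terms)
    continuum: float  # f/4 <Psi_s, X_d + X_p>
    coupling: float  # f/4 [<Omega mu_d, X_p> + <Omega mu_p, X_d>]
    total: float

    def as_dict(self):
        return {
            "static_env": self.static_env,
            "probe_env": self.probe_env,
            "induced": self.induced,
            "continuum": self.continuum,
            "coupling": self.coupling,
            "total": self.total,
        }


class EmbeddingSystem:
    """An environment multipole set, an optional probe set, and a cavity.

    Atom ordering for forces and cavity spheres: probe atoms first, then
    environment atoms.  ``cavity_radii`` are final sphere radii in bohr
    (van der Waals plus probe already applied by the reader/generator).
    """

    def __init__(
        self,
        env: MultipoleSet,
        probe: Optional[MultipoleSet] = None,
        cavity_radii: Optional[np.ndarray] = None,
        config: Optional[RunConfig] = None,
        grid: Optional[tuple] = None,
        orientation: Optional[np.ndarray] = None,
    ):
        self.env = env
        self.probe = probe
        self.config = config or RunConfig()
        n_all = env.n_sites + (probe.n_sites if probe is not None else 0)
        if cavity_radii is None:
            cavity_radii = np.full(n_all, 4.0)
        self.cavity_radii = np.broadcast_to(
            np.asarray(cavity_radii, dtype=float), (n_all,)
        ).copy()
        self._grid = grid
        self._orientation = orientation
        self.accelerator = None
        if self.config.acceleration:
            from .tree import TreeAccelerator

            self.accelerator = TreeAccelerator(self.config.tree)
        self._build()

    def _build(self):
        from .harmonics import HarmonicBasis

        cfg = self.config
        self.basis = HarmonicBasis(cfg.lmax)
        self.cavity = build_cavity(
            self.all_positions,
            self.cavity_radii,
            probe=0.0,
            grid_order=cfg.grid_order,
            eta=cfg.eta,
            orientation=self._orientation,
            grid=self._grid,
        )
        self.workspace = DDWorkspace(self.cavity, self.basis)
        self.pol_local = np.nonzero(self.env.polarizable)[0]
        self.pol_spheres = self.n_probe + self.pol_local  # sphere index per dipole
        self.pol_positions = self.env.positions[self.pol_local]
        self._cache = {}

    # --- geometry ---------------------------------------------------------
    @property
    def n_probe(self) -> int:
        return 0 if self.probe is None else self.probe.n_sites

    @property
    def n_atoms(self) -> int:
        return self.n_probe + self.env.n_sites

    @property
    def all_positions(self) -> np.ndarray:
        if self.probe is None:
            return self.env.positions
        return np.vstack([self.probe.positions, self.env.positions])

    def displaced(self, new_positions: np.ndarray) -> "EmbeddingSystem":
        """Same system at displaced atom positions (frames re-rotated)."""
        new_positions = np.asarray(new_positions, dtype=float)
        np_ = self.n_probe
        probe = (
            None
            if self.probe is None
            else self.probe.with_positions(new_positions[:np_])
        )
        env = self.env.with_positions(new_positions[np_:])
        return EmbeddingSystem(
            env,
            probe,
            self.cavity_radii,
            self.config,
            grid=self._grid,
            orientation=self._orientation,
        )

    # --- assembled static quantities -------------------------------------
    def static_potential_at_nodes(self) -> np.ndarray:
        """V of all fixed sources at every cavity node, shape (N, g)."""
        if "Vnodes" not in self._cache:
            pts = self.cavity.node_positions().reshape(-1, 3)
            V = np.zeros(len(pts))
            for mset in (self.probe, self.env):
                if mset is None or mset.n_sites == 0:
                    continue
                if self.accelerator is not None:
                    V += self.accelerator.potential_split(mset, pts)
                else:
                    V += properties_direct(mset, pts, order="V").V
            self._cache["Vnodes"] = V.reshape(
                self.cavity.n_spheres, self.cavity.n_nodes
            )
        return self._cache["Vnodes"]

    def Phi_s(self) -> HarmonicCoeffs:
        if "Phi" not in self._cache:
            self._cache["Phi"] = assemble_Phi(
                self.cavity, self.static_potential_at_nodes(), self.basis
            )
        return self._cache["Phi"]

    def Psi_s(self) -> HarmonicCoeffs:
        if "Psi" not in self._cache:
            psi = assemble_Psi(self._combined_static(), self.cavity, self.basis)
            self._cache["Psi"] = psi
        return self._cache["Psi"]

    def _combined_static(self) -> MultipoleSet:
        if self.probe is None:
            return self.env
        return MultipoleSet(
            self.all_positions,
            np.concatenate([self.probe.q, self.env.q]),
            np.vstack([self.probe.mu, self.env.mu]),
            np.vstack([self.probe.theta, self.env.theta]),
            np.zeros(self.n_atoms),
            thole=self.env.thole,
        )

    def branch_field(self, branch: str) -> np.ndarray:
        key = f"F{branch}"
        if key not in self._cache:
            self._cache[key] = rhs_fields(
                self.probe,
                self.env,
                branch,
                d_scale=self.config.d_scale,
                p_scale=self.config.p_scale,
            )
        return self._cache[key]

    # --- operator shorthands ---------------------------------------------
    def Xi(self, mu) -> HarmonicCoeffs:
        return apply_Xi(
            mu, self.pol_positions, self.cavity, self.basis, self.accelerator
        )

    def Xi_adj(self, S) -> np.ndarray:
        return apply_Xi_adj(
            S, self.pol_positions, self.cavity, self.basis, self.accelerator
        )

    def Omega(self, mu) -> HarmonicCoeffs:
        return apply_Omega(mu, self.pol_spheres, self.cavity, self.basis)

    def Omega_adj(self, X) -> np.ndarray:
        return apply_Omega_adj(X, self.pol_spheres, self.cavity, self.basis)

    def T(self, mu) -> np.ndarray:
        return apply_T(
            mu, self.pol_positions, self.env.alpha[self.pol_local], self.config.thole
        )

    @property
    def n_pol(self) -> int:
        return len(self.pol_local)

    def static_energy(self):
        e_env = self_energy(self.env)
        e_pe = (
            interaction_energy(self.probe, self.env)
            if self.probe is not None and self.probe.n_sites and self.env.n_sites
            else 0.0
        )
        return e_env, e_pe


def _zero_coeffs(system) -> HarmonicCoeffs:
    return HarmonicCoeffs(
        np.zeros((system.cavity.n_spheres, system.basis.nbasis))
    )


def solve_coupled(
    system: EmbeddingSystem,
    config: Optional[RunConfig] = None,
    guess: Optional[EmbeddingState] = None,
) -> EmbeddingState:
    """Solve both coupled triplets; macroiterations over mu with
    warm-started ddCOSMO microiterations."""
    cfg = config or system.config
    scfg = cfg.solver_config()
    f = cfg.f
    npol = system.n_pol
    macro_tol = cfg.macro_tol or cfg.tol
    iters: dict = {}
    resid: dict = {}
    out = {}
    for branch in ("d", "p"):
        F = system.branch_field(branch) if npol else np.zeros((0, 3))
        mu = (
            getattr(guess, f"mu_{branch}").copy()
            if guess is not None
            else np.zeros((npol, 3))
        )
        Xg = getattr(guess, f"X_{branch}") if guess is not None else None
        Sg = getattr(guess, f"S_{branch}") if guess is not None else None
        if f == 0.0:
            X = _zero_coeffs(system)
            S = _zero_coeffs(system)
            if npol:
                mu, it = solve_T(
                    F,
                    system.pol_positions,
                    system.env.alpha[system.pol_local],
                    cfg.thole,
                    tol=cfg.tol,
                    guess=mu,
                )
                iters[f"T_{branch}"] = it
        else:
            n_macro = 0
            for macro in range(cfg.macro_max_iter):
                n_macro = macro + 1
                rhs_X = system.Phi_s().data + (
                    system.Xi(mu).data if npol else 0.0
                )
                X, itx = solve_L(HarmonicCoeffs(rhs_X), system.workspace, scfg, guess=Xg)
                rhs_S = system.Psi_s().data + (
                    system.Omega(mu).data if npol else 0.0
                )
                S, its = solve_Ladj(HarmonicCoeffs(rhs_S), system.workspace, scfg, guess=Sg)
                Xg, Sg = X, S
                iters[f"L_{branch}"] = iters.get(f"L_{branch}", 0) + itx
                iters[f"Ladj_{branch}"] = iters.get(f"Ladj_{branch}", 0) + its
                if not npol:
                    break
                rhs_mu = F - 0.5 * f * (system.Omega_adj(X) + system.Xi_adj(S))
                mu_new, itt = solve_T(
                    rhs_mu,
                    system.pol_positions,
                    system.env.alpha[system.pol_local],
                    cfg.thole,
                    tol=cfg.tol,
                    guess=mu,
                )
                iters[f"T_{branch}"] = iters.get(f"T_{branch}", 0) + itt
                dmu = float(np.linalg.norm(mu_new - mu)) / max(
                    1.0, float(np.linalg.norm(mu_new))
                )
                mu = mu_new
                if dmu <= macro_tol:
                    break
            else:
                raise SolverError(
                    f"macroiterations for branch {branch} did not converge "
                    f"({n_macro} iterations)",
                )
            iters[f"macro_{branch}"] = n_macro
        out[branch] = (mu, X, S)
        if npol and f != 0.0:
            r = system.T(mu) - (
                F - 0.5 * f * (system.Omega_adj(X) + system.Xi_adj(S))
            )
            resid[f"T_{branch}"] = float(np.linalg.norm(r))
    state = EmbeddingState(
        mu_d=out["d"][0],
        mu_p=out["p"][0],
        X_d=out["d"][1],
        S_d=out["d"][2],
        X_p=out["p"][1],
        S_p=out["p"][2],
        iterations=iters,
        residuals=resid,
        solved=True,
        tol=cfg.tol,
    )
    return state


def _check_dims(state: EmbeddingState, system: EmbeddingSystem):
    if state.mu_d.shape != (system.n_pol, 3) or state.X_d.data.shape != (
        system.cavity.n_spheres,
        system.basis.nbasis,
    ):
        raise StructuralError("state dimensions do not match the system")


def lagrangian_value(state: EmbeddingState, system: EmbeddingSystem) -> float:
    """Full Lagrangian, term by term, at an arbitrary (not necessarily
    solved) state; at a stationary point it equals the embedding energy."""
    _check_dims(state, system)
    cfg = system.config
    f = cfg.f
    e_env, e_pe = system.static_energy()
    val = e_env + e_pe
    npol = system.n_pol
    mu_d, mu_p = state.mu_d, state.mu_p
    if npol:
        Fd = system.branch_field("d")
        Fp = system.branch_field("p")
        val -= 0.5 * (np.sum(mu_d * Fp) + np.sum(mu_p * Fd))
        val += 0.5 * np.sum(mu_p * system.T(mu_d))
    if f != 0.0:
        ws = system.workspace
        Phi, Psi = system.Phi_s(), system.Psi_s()
        val += 0.25 * f * (
            inner(state.S_d, Phi)
            + inner(state.S_p, Phi)
            + inner(state.X_d, Psi)
            + inner(state.X_p, Psi)
            - inner(state.S_p, apply_L(state.X_d, ws))
            - inner(state.S_d, apply_L(state.X_p, ws))
        )
        if npol:
            val += 0.25 * f * (
                inner(state.S_p, system.Xi(mu_d))
                + inner(state.S_d, system.Xi(mu_p))
                + inner(state.X_p, system.Omega(mu_d))
                + inner(state.X_d, system.Omega(mu_p))
            )
    return float(val)


def embedding_energy(state: EmbeddingState, system: EmbeddingSystem) -> EnergyBreakdown:
    """Energy at a solved state (constraints eliminated)."""
    if not state.solved:
        raise StructuralError(
            "state is not solved; run solve_coupled before requesting the energy"
        )
    _check_dims(state, system)
    cfg = system.config
    f = cfg.f
    e_env, e_pe = system.static_energy()
    npol = system.n_pol
    induced = 0.0
    coupling = 0.0
    continuum = 0.0
    if npol:
        Fd = system.branch_field("d")
        Fp = system.branch_field("p")
        induced = -0.5 * (
            float(np.sum(state.mu_d * Fp)) + float(np.sum(state.mu_p * Fd))
        ) + 0.5 * float(np.sum(state.mu_p * system.T(state.mu_d)))
    if f != 0.0:
        Psi = system.Psi_s()
        continuum = 0.25 * f * (inner(state.X_d, Psi) + inner(state.X_p, Psi))
        if npol:
            coupling = 0.25 * f * (
                inner(state.X_p, system.Omega(state.mu_d))
                + inner(state.X_d, system.Omega(state.mu_p))
            )
    total = e_env + e_pe + induced + continuum + coupling
    return EnergyBreakdown(
        static_env=e_env,
        probe_env=e_pe,
        induced=induced,
        continuum=continuum,
        coupling=coupling,
        total=total,
    )
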