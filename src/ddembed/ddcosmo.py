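"""Domain-decomposition COSMO: the sparse operator L, right-hand sides
Phi and Psi, iterative solvers, pseudo-charges and the continuum energy.

Discretization (derived once, pinned by the Born/Kirkwood tests):

* each sphere j carries a local harmonic expansion of the reaction
  potential, ``W_j(r) = sum_lm X_j^lm (|r-x_j|/r_j)^l Y_lm``;
* the conductor condition on exposed surface (total potential zero) and
  the Schwarz exchange condition on buried surface (the local solution
  matches a switching-weighted average of the neighbours' local
  solutions) are enforced by quadrature projection on each sphere's
  grid.  This yields ``L X = Phi`` with

  ``(L X)_i = -X_i + sum_{j != i} P_ij X_j``,

  where ``P_ij`` projects the trace of W_j, weighted by
  ``omega_ijn = c_ijn / C_in * (1 - U_in)``, onto sphere i's harmonics
  (``c_ijn`` is the penetration of node n of sphere i into sphere j and
  ``C_in`` their sum).  The -Identity diagonal carries the conductor
  sign, so that the solution of ``L X = Phi`` with Phi assembled from
  the *positive* solute potential gives a stabilizing (negative) energy
  ``E = f(eps)/2 <Psi, X>``.

Off-diagonal blocks exist only between geometrically intersecting
spheres; applying L (or its exact adjoint) costs O(N_spheres x
neighbours).  Both systems are solved by block-Jacobi sweeps with DIIS
acceleration; a dense construction is retained as a test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .cavity import Cavity
from .errors import (
    ConfigurationError,
    IncompleteInputError,
    SolverError,
    UnsupportedGeometryError,
)
from .harmonics import (
    HarmonicBasis,
    eval_harmonics,
    regular_gradient_ops,
    solid_harmonics_with_grad,
)
from .multipoles import MultipoleSet


@dataclass
class HarmonicCoeffs:
    """Per-sphere vectors of real-spherical-harmonic coefficients."""

    data: np.ndarray  # (n_spheres, (lmax+1)^2)
    role: str = "generic"

    def __post_init__(self):
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))

    def copy(self, role: Optional[str] = None):
        return HarmonicCoeffs(self.data.copy(), role or self.role)


def inner(a: HarmonicCoeffs, b: HarmonicCoeffs) -> float:
    """Euclidean inner product of two coefficient sets."""
    return float(np.sum(a.data * b.data))


def f_of_eps(epsilon: float, scheme: str = "cosmo") -> float:
    """Conductor-to-dielectric scaling f(eps).

    ``cosmo``: (eps-1)/eps; ``half``: (eps-1)/(eps+1/2).  ``epsilon``
    may be ``inf`` (conductor limit, f = 1).
    """
    if np.isinf(epsilon):
        return 1.0
    if epsilon < 1.0:
        raise ConfigurationError("epsilon must be >= 1")
    if epsilon == 1.0:
        return 0.0  # vacuum outside: the continuum layer switches off
    if scheme == "cosmo":
        return (epsilon - 1.0) / epsilon
    if scheme == "half":
        return (epsilon - 1.0) / (epsilon + 0.5)
    raise ConfigurationError(f"unknown f_scheme {scheme!r}")


@dataclass
class SolverConfig:
    """Discretization and solver settings for the continuum layer."""

    lmax: int = 6
    grid_order: int = 110
    epsilon: float = 15.0
    f_scheme: str = "cosmo"
    tol: float = 1e-8
    max_iter: int = 500
    diis_depth: int = 10

    def __post_init__(self):
        if self.lmax < 0:
            raise ConfigurationError("lmax must be >= 0")
        if not (self.epsilon >= 1.0 or np.isinf(self.epsilon)):
            raise ConfigurationError("epsilon must be >= 1")
        if self.tol <= 0:
            raise ConfigurationError("tol must be positive")
        f_of_eps(self.epsilon, self.f_scheme)

    @property
    def f(self) -> float:
        return f_of_eps(self.epsilon, self.f_scheme)


class DDWorkspace:
    """Precomputed geometry shared by all L / L^T / Xi / Omega actions.

    Holds, per ordered intersecting pair (i, j), the node subset of
    sphere i penetrating sphere j, the switching weights omega_ijn, and
    the solid-harmonic trace matrix of sphere j at those nodes.
    """

    def __init__(self, cav: Cavity, basis: HarmonicBasis):
        self.cavity = cav
        self.basis = basis
        self.Ynodes = eval_harmonics(cav.nodes, basis)  # (g, nb)
        from .cavity import penetration_grad

        n = cav.n_spheres
        self.pair_index: dict = {}
        self.pairs: list = []
        csum = [np.zeros(cav.n_nodes) for _ in range(n)]
        raw = []
        for i in range(n):
            pts = cav.node_positions(i)
            for j in cav.neighbors[i]:
                c, _ = penetration_grad(pts, cav.centers[j], cav.radii[j], cav.eta)
                idx = np.nonzero(c > 0.0)[0]
                if len(idx) == 0:
                    continue
                raw.append((i, j, idx, c[idx]))
                csum[i][idx] += c[idx]
        for (i, j, idx, c) in raw:
            omega = c / csum[i][idx] * (1.0 - cav.U[i, idx])
            pts = cav.node_positions(i)[idx]
            vals, _ = solid_harmonics_with_grad(pts, cav.centers[j], cav.radii[j], basis)
            self.pair_index[(i, j)] = len(self.pairs)
            self.pairs.append(
                {"i": i, "j": j, "idx": idx, "c": c, "omega": omega, "trace": vals}
            )
        self.csum = csum

    @property
    def n_spheres(self):
        return self.cavity.n_spheres


def apply_L(X: HarmonicCoeffs, ws: DDWorkspace) -> HarmonicCoeffs:
    """Block-sparse action of the ddCOSMO operator."""
    cav = ws.cavity
    out = -X.data.copy()
    w = cav.weights
    for p in ws.pairs:
        i, j, idx = p["i"], p["j"], p["idx"]
        vals = p["trace"] @ X.data[j]
        out[i] += ws.Ynodes[idx].T @ (w[idx] * p["omega"] * vals)
    return HarmonicCoeffs(out, "generic")


def apply_Ladj(S: HarmonicCoeffs, ws: DDWorkspace) -> HarmonicCoeffs:
    """Exact adjoint of :func:`apply_L` (by construction, <S, LX> = <L^T S, X>)."""
    cav = ws.cavity
    out = -S.data.copy()
    w = cav.weights
    for p in ws.pairs:
        i, j, idx = p["i"], p["j"], p["idx"]
        surf = ws.Ynodes[idx] @ S.data[i]
        out[j] += p["trace"].T @ (w[idx] * p["omega"] * surf)
    return HarmonicCoeffs(out, "generic")


def assemble_Phi(cav: Cavity, V_at_nodes: np.ndarray, basis: HarmonicBasis) -> HarmonicCoeffs:
    """Quadrature projection Phi_i^lm = sum_n W_in Y_lm(y_n) V(r_i^n)."""
    V = np.asarray(V_at_nodes, dtype=float)
    if V.shape != (cav.n_spheres, cav.n_nodes):
        raise IncompleteInputError(
            f"need node potentials of shape {(cav.n_spheres, cav.n_nodes)}, got {V.shape}"
        )
    if not np.all(np.isfinite(V[cav.U > 0])):
        raise IncompleteInputError("missing/non-finite potentials at exposed nodes")
    Y = eval_harmonics(cav.nodes, basis)
    return HarmonicCoeffs((cav.W * np.where(cav.U > 0, V, 0.0)) @ Y, "Phi")


def assemble_Psi(sources: MultipoleSet, cav: Cavity, basis: HarmonicBasis) -> HarmonicCoeffs:
    """Solute density in the harmonic basis: strictly local rows.

    ``<Psi_i, X_i>`` equals the interaction of sphere i's multipole with
    the local expansion W_i: charge * W_i(x_i) + mu . grad W_i(x_i) +
    (1/3) Theta : grad grad W_i(x_i); consequently only l = 0 (charge),
    l = 1 (dipole) and l = 2 (quadrupole) components are nonzero.
    Requires each source at its sphere's center.
    """
    if sources.n_sites != cav.n_spheres:
        raise UnsupportedGeometryError("one sphere per source site required")
    if np.abs(sources.positions - cav.centers).max(initial=0.0) > 1e-10:
        raise UnsupportedGeometryError("every source must sit at its sphere's center")
    nb = basis.nbasis
    psi = np.zeros((cav.n_spheres, nb))
    s4pi = np.sqrt(4.0 * np.pi)
    psi[:, 0] = sources.q / s4pi
    if basis.lmax >= 1:
        D = regular_gradient_ops(basis.lmax)
        # grad of scaled solid harmonic at the center: row l=1, column (0,0)
        g10 = D[:, 1:4, 0] / s4pi  # (3 coords, 3 m-components)
        psi[:, 1:4] = np.einsum("na,am->nm", sources.mu, g10) / cav.radii[:, None]
    if basis.lmax >= 2:
        D = regular_gradient_ops(basis.lmax)
        # second derivatives at center: (D_a D_b)[l=2 rows, col 00]
        gg = np.einsum("amk,bk->abm", D[:, 4:9, 1:4], D[:, 1:4, 0]) / s4pi
        psi[:, 4:9] = (
            np.einsum("nab,abm->nm", sources.theta, gg) / 3.0 / cav.radii[:, None] ** 2
        )
    return HarmonicCoeffs(psi, "Psi")


def psi_offcenter_charge(
    cav: Cavity, sphere: int, position: np.ndarray, q: float, basis: HarmonicBasis
) -> HarmonicCoeffs:
    """Psi of a point charge at an arbitrary interior point of one sphere.

    Generalizes :func:`assemble_Psi` for charges (used e.g. for the
    off-center Kirkwood setup): ``Psi_i^lm = q (d/r_i)^l Y_lm(d_hat)``.
    """
    from .harmonics import eval_solid_harmonics

    psi = np.zeros((cav.n_spheres, basis.nbasis))
    psi[sphere] = q * eval_solid_harmonics(
        np.asarray(position, dtype=float), cav.centers[sphere], cav.radii[sphere], basis
    )
    return HarmonicCoeffs(psi, "Psi")


@dataclass
class PseudoCharges:
    """Grid-point charges xi_in re-expressing <S, Phi(V)> as sum xi V."""

    xi: np.ndarray  # (n_spheres, n_nodes)
    cavity: Cavity

    def flat(self, with_spheres: bool = False):
        """(positions, charges[, sphere indices]) of the nonzero pseudo-charges."""
        mask = self.xi != 0.0
        pos = self.cavity.node_positions()[mask]
        if with_spheres:
            sph = np.broadcast_to(
                np.arange(self.cavity.n_spheres)[:, None], self.xi.shape
            )[mask]
            return pos, self.xi[mask], sph
        return pos, self.xi[mask]


def pseudo_charges(S: HarmonicCoeffs, cav: Cavity, basis: HarmonicBasis) -> PseudoCharges:
    """xi_in = W_in sum_lm S_i^lm Y_lm(y_n); vanishes on buried nodes."""
    Y = eval_harmonics(cav.nodes, basis)
    xi = cav.W * (S.data @ Y.T)
    return PseudoCharges(xi, cav)


def continuum_energy(
    Psi: HarmonicCoeffs, X: HarmonicCoeffs, epsilon: float, f_scheme: str = "cosmo"
) -> float:
    """E = f(eps)/2 <Psi, X> (negative for a stabilized charged solute)."""
    return 0.5 * f_of_eps(epsilon, f_scheme) * inner(Psi, X)


# ---------------------------------------------------------------------------
# solvers


def _diis_extrapolate(trail_x, trail_r):
    m = len(trail_r)
    B = np.empty((m + 1, m + 1))
    B[:m, :m] = [[float(np.vdot(ri, rj)) for rj in trail_r] for ri in trail_r]
    B[m, :] = -1.0
    B[:, m] = -1.0
    B[m, m] = 0.0
    rhs = np.zeros(m + 1)
    rhs[m] = -1.0
    try:
        coef = np.linalg.solve(B, rhs)[:m]
    except np.linalg.LinAlgError:
        return trail_x[-1], trail_r[-1]
    x = sum(c * xi for c, xi in zip(coef, trail_x))
    r = sum(c * ri for c, ri in zip(coef, trail_r))
    return x, r


def _solve_jacobi_diis(apply_fn, rhs, tol, max_iter, diis_depth, guess=None):
    """Solve op(X) = rhs for an operator with -Identity diagonal blocks.

    Jacobi sweep X <- X + (op(X) - rhs) accelerated by DIIS; returns
    (X, n_iter, residual_history).
    """
    nrm = float(np.linalg.norm(rhs))
    if nrm == 0.0:
        return np.zeros_like(rhs), 0, [0.0]
    X = np.zeros_like(rhs) if guess is None else guess.copy()
    hist = []
    trail_x, trail_r = [], []
    for it in range(1, max_iter + 1):
        r = apply_fn(X) - rhs
        res = float(np.linalg.norm(r)) / nrm
        hist.append(res)
        if res <= tol:
            return X, it - 1, hist
        trail_x.append(X.copy())
        trail_r.append(r.copy())
        if len(trail_r) > diis_depth:
            trail_x.pop(0)
            trail_r.pop(0)
        Xe, re = _diis_extrapolate(trail_x, trail_r)
        X = Xe + re  # Jacobi step on the extrapolated iterate
    raise SolverError(
        f"ddCOSMO solver did not reach {tol} in {max_iter} iterations", residuals=hist
    )


def solve_L(
    rhs: HarmonicCoeffs,
    ws: DDWorkspace,
    config: SolverConfig,
    guess: Optional[HarmonicCoeffs] = None,
):
    """Solve L X = rhs; returns (X, n_iter)."""
    fn = lambda d: apply_L(HarmonicCoeffs(d), ws).data
    X, it, _ = _solve_jacobi_diis(
        fn, rhs.data, config.tol, config.max_iter, config.diis_depth,
        guess=None if guess is None else guess.data,
    )
    return HarmonicCoeffs(X, "X"), it


def solve_Ladj(
    rhs: HarmonicCoeffs,
    ws: DDWorkspace,
    config: SolverConfig,
    guess: Optional[HarmonicCoeffs] = None,
):
    """Solve L^T S = rhs; returns (S, n_iter)."""
    fn = lambda d: apply_Ladj(HarmonicCoeffs(d), ws).data
    S, it, _ = _solve_jacobi_diis(
        fn, rhs.data, config.tol, config.max_iter, config.diis_depth,
        guess=None if guess is None else guess.data,
    )
    return HarmonicCoeffs(S, "S"), it


def dense_L(ws: DDWorkspace) -> np.ndarray:
    """Dense matrix of L (test oracle; O(N^2 nb^2) memory)."""
    n, nb = ws.n_spheres, ws.basis.nbasis
    size = n * nb
    M = np.empty((size, size))
    for k in range(size):
        e = np.zeros(size)
        e[k] = 1.0
        M[:, k] = apply_L(HarmonicCoeffs(e.reshape(n, nb)), ws).data.ravel()
    return M
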