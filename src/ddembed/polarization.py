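"""Induced-dipole subsystem: the polarization operator T, inducing
fields, and a preconditioned conjugate-gradient solver.

The polarization linear system is ``T mu = F`` with

``(T mu)_i = mu_i / alpha_i - sum_{j != i} T^thole_ij mu_j``,

``T^thole`` the Thole-damped dipole field tensor.  T is symmetric and,
for physical polarizabilities, positive definite; CG with the diagonal
(alpha) preconditioner is therefore the natural solver.  Two branches of
inducing field (d and p) are supported through per-branch scale factors
on the fixed-multipole contribution; with equal factors the branches
coincide.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ModelParameterError, SolverError
from .multipoles import MultipoleSet, properties_direct


@dataclass
class InducedDipoles:
    """The two sets of induced dipoles, defined on polarizable sites only."""

    mu_d: np.ndarray  # (npol, 3)
    mu_p: np.ndarray  # (npol, 3)


def apply_T(
    mu: np.ndarray, positions: np.ndarray, alpha: np.ndarray, a_thole: float = 0.39
) -> np.ndarray:
    """Action of the polarization matrix on per-site dipoles."""
    mu = np.atleast_2d(np.asarray(mu, dtype=float))
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0):
        raise ModelParameterError("apply_T requires all sites polarizable (alpha > 0)")
    n = len(mu)
    out = mu / alpha[:, None]
    if n > 1:
        dip = MultipoleSet(positions, np.zeros(n), mu, None, alpha, thole=a_thole)
        mask = 1.0 - np.eye(n)
        E = properties_direct(
            dip, positions, order="VE", mask=mask, damp_alpha_targets=alpha
        ).E
        out = out - E
    return out


def dense_T(positions, alpha, a_thole: float = 0.39) -> np.ndarray:
    """Dense (3n x 3n) polarization matrix (test oracle)."""
    n = len(alpha)
    M = np.empty((3 * n, 3 * n))
    for k in range(3 * n):
        e = np.zeros((n, 3))
        e[k // 3, k % 3] = 1.0
        M[:, k] = apply_T(e, positions, alpha, a_thole).ravel()
    return 0.5 * (M + M.T)


def rhs_fields(
    probe: Optional[MultipoleSet],
    environment: MultipoleSet,
    branch: str = "d",
    d_scale: float = 1.0,
    p_scale: float = 1.0,
) -> np.ndarray:
    """Inducing field E(rho) + E_branch(M) at the polarizable sites.

    The probe (QM stand-in) field is never scaled; the fixed-multipole
    field of the environment is Thole damped and multiplied by the
    branch's exclusion scale factor.  The polarizable site's own fixed
    multipole never polarizes it.
    """
    if branch not in ("d", "p"):
        raise ValueError("branch must be 'd' or 'p'")
    scale = d_scale if branch == "d" else p_scale
    pol = environment.polarizable
    targets = environment.positions[pol]
    alpha_t = environment.alpha[pol]
    F = np.zeros((len(targets), 3))
    if probe is not None and probe.n_sites:
        F += properties_direct(
            probe, targets, order="VE", damp_alpha_targets=alpha_t
        ).E
    mask = np.ones((len(targets), environment.n_sites))
    mask[np.arange(len(targets)), np.nonzero(pol)[0]] = 0.0
    F += scale * properties_direct(
        environment, targets, order="VE", mask=mask, damp_alpha_targets=alpha_t
    ).E
    return F


def solve_T(
    rhs: np.ndarray,
    positions: np.ndarray,
    alpha: np.ndarray,
    a_thole: float = 0.39,
    tol: float = 1e-8,
    max_iter: int = 500,
    guess: Optional[np.ndarray] = None,
):
    """Preconditioned CG solve of T mu = rhs; returns (mu, n_iter).

    Detects loss of positive definiteness (unphysically large
    polarizabilities) and raises :class:`ModelParameterError`.
    """
    rhs = np.atleast_2d(np.asarray(rhs, dtype=float))
    alpha = np.asarray(alpha, dtype=float)
    nrm = float(np.linalg.norm(rhs))
    if nrm == 0.0:
        return np.zeros_like(rhs), 0
    x = np.zeros_like(rhs) if guess is None else np.asarray(guess, dtype=float).copy()
    r = rhs - apply_T(x, positions, alpha, a_thole)
    z = r * alpha[:, None]
    p = z.copy()
    rz = float(np.sum(r * z))
    hist = []
    for it in range(1, max_iter + 1):
        res = float(np.linalg.norm(r)) / nrm
        hist.append(res)
        if res <= tol:
            return x, it - 1
        Ap = apply_T(p, positions, alpha, a_thole)
        pAp = float(np.sum(p * Ap))
        if pAp <= 0.0:
            raise ModelParameterError(
                "polarization matrix is not positive definite; "
                "check polarizabilities / Thole damping"
            )
        a_cg = rz / pAp
        x = x + a_cg * p
        r = r - a_cg * Ap
        z = r * alpha[:, None]
        rz_new = float(np.sum(r * z))
        p = z + (rz_new / rz) * p
        rz = rz_new
    raise SolverError(
        f"CG on the polarization system did not reach {tol} in {max_iter} iterations",
        residuals=hist,
    )
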