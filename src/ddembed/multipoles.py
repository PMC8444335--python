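"""Fixed-multipole electrostatics: potentials, fields, field gradients,
field Hessians, with optional Thole damping.

Conventions (used consistently across the package):

* ``R = r_target - r_source``, ``E = -grad V``, ``G = grad E``,
  ``H = grad G`` (so ``G_ab = dE_a/dx_b``, symmetric).
* Quadrupoles are traceless Cartesian (Buckingham): for a primitive
  second moment ``P_ab = sum q x_a x_b``, ``Theta = (3P - tr(P) I)/2``.
  With that convention the potential is ``V = (R.Theta.R)/r^5`` and the
  energy of a multipole in an external potential is
  ``U = q V - mu.E - (1/3) Theta : G``.

All interactions are expressed through the scalar ladder
``B_0 = 1/r``, ``B_{n+1} = -(1/r) dB_n/dr`` (bare: ``B_n = (2n-1)!!/r^{2n+1}``).
Thole damping replaces ``B_n`` by ``lambda_{2n+1}(v) B_n`` with
``v = a r^3 / sqrt(alpha_i alpha_j)``; because the damped ladder is
defined by the same derivative recursion, the identities ``E = -grad V``
etc. hold exactly for damped interactions too, which the tests verify by
finite differences.  Pairs where either polarizability vanishes are
undamped (v -> infinity).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ModelParameterError, SingularGeometryError

_DFACT = np.array([1.0, 1.0, 3.0, 15.0, 105.0, 945.0, 10395.0])  # (2n-1)!!


def traceless(theta: np.ndarray) -> np.ndarray:
    """Symmetrize and remove the trace of quadrupole tensors (n,3,3)."""
    theta = np.asarray(theta, dtype=float)
    sym = 0.5 * (theta + np.swapaxes(theta, -1, -2))
    tr = np.trace(sym, axis1=-2, axis2=-1)
    return sym - tr[..., None, None] / 3.0 * np.eye(3)


@dataclass
class MultipoleSet:
    """Per-site positions and electrostatic parameters (atomic units).

    ``role`` is either ``"environment"`` or ``"probe"``; a probe set
    stands in for the QM density, carries no polarizability, and its
    internal (probe-probe) energy is excluded from the embedding energy.
    """

    positions: np.ndarray
    q: np.ndarray
    mu: np.ndarray
    theta: np.ndarray
    alpha: np.ndarray
    role: str = "environment"
    frame_defs: Optional[list] = None
    mu_frame: Optional[np.ndarray] = None
    theta_frame: Optional[np.ndarray] = None
    thole: float = 0.39
    labels: Optional[list] = None

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        n = len(self.positions)
        self.q = np.broadcast_to(np.asarray(self.q, dtype=float), (n,)).copy()
        self.mu = np.zeros((n, 3)) if self.mu is None else np.array(self.mu, dtype=float).reshape(n, 3)
        self.theta = (
            np.zeros((n, 3, 3))
            if self.theta is None
            else np.array(self.theta, dtype=float).reshape(n, 3, 3)
        )
        self.alpha = np.broadcast_to(np.asarray(self.alpha, dtype=float), (n,)).copy()
        sym_err = np.abs(self.theta - np.swapaxes(self.theta, -1, -2)).max(initial=0.0)
        tr_err = np.abs(np.trace(self.theta, axis1=-2, axis2=-1)).max(initial=0.0)
        if sym_err > 1e-12 or tr_err > 1e-12:
            raise ModelParameterError(
                f"quadrupoles must be symmetric and traceless to 1e-12 "
                f"(asymmetry {sym_err:.2e}, trace {tr_err:.2e}); see traceless()"
            )
        if np.any(self.alpha < 0):
            raise ModelParameterError("polarizabilities must be >= 0")
        if self.role not in ("environment", "probe"):
            raise ModelParameterError(f"unknown role {self.role!r}")
        if self.role == "probe" and np.any(self.alpha != 0):
            raise ModelParameterError("probe sites must carry alpha = 0")

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def polarizable(self) -> np.ndarray:
        """Boolean mask of polarizable sites."""
        return self.alpha > 0

    def with_positions(self, new_positions: np.ndarray) -> "MultipoleSet":
        """Copy of the set at displaced positions.

        When frame data is present the lab-frame dipoles and quadrupoles
        are re-rotated for the new geometry (frame neighbours are
        indices within this set), so displaced copies remain consistent
        with the local-frame parameterization.
        """
        from .local_frames import rotate_to_lab

        new_positions = np.asarray(new_positions, dtype=float).reshape(
            self.positions.shape
        )
        mu = self.mu.copy()
        theta = self.theta.copy()
        if self.frame_defs is not None:
            for i, fd in enumerate(self.frame_defs):
                if fd is None or fd.rule == "none":
                    continue
                mu[i], theta[i] = rotate_to_lab(
                    self.mu_frame[i], self.theta_frame[i], fd, i, new_positions
                )
        out = MultipoleSet(
            new_positions,
            self.q.copy(),
            mu,
            theta,
            self.alpha.copy(),
            role=self.role,
            frame_defs=self.frame_defs,
            mu_frame=None if self.mu_frame is None else self.mu_frame.copy(),
            theta_frame=None if self.theta_frame is None else self.theta_frame.copy(),
            thole=self.thole,
            labels=self.labels,
        )
        return out


@dataclass
class FieldSamples:
    """Electrostatic properties sampled at target positions."""

    positions: np.ndarray
    V: Optional[np.ndarray] = None
    E: Optional[np.ndarray] = None
    G: Optional[np.ndarray] = None
    H: Optional[np.ndarray] = None


def thole_factors(v: np.ndarray, nmax: int) -> np.ndarray:
    """Damping factors lambda_{2n+1}(v), n = 0..nmax, shape (nmax+1, ...).

    Derived from the Thole exponential smeared density: lambda_3 =
    1 - e^-v and the ladder recursion; lambda_1 is never needed and the
    n = 0 slot is set to 1 (the damped potential of a charge is not used
    by any code path).
    """
    v = np.minimum(np.asarray(v, dtype=float), 700.0)  # v >= 700 means undamped
    ev = np.exp(-v)
    out = np.ones((nmax + 1,) + v.shape)
    lam = [
        None,
        -np.expm1(-v),  # lambda_3
        1.0 - (1.0 + v) * ev,  # lambda_5
        1.0 - (1.0 + v + 0.6 * v**2) * ev,  # lambda_7
        1.0 - (1.0 + v + (18.0 * v**2 + 9.0 * v**3) / 35.0) * ev,  # lambda_9
        1.0
        - (1.0 + v + (53.0 * v**2 + 18.0 * v**3 + 9.0 * v**4) / 105.0) * ev,  # l_11
    ]
    for n in range(1, nmax + 1):
        out[n] = lam[n]
    return out


def _bn_ladder(r, nmax, v=None):
    """B_n(r), n = 0..nmax; damped by thole_factors when v is given."""
    out = np.empty((nmax + 1,) + r.shape)
    inv_r2 = 1.0 / (r * r)
    cur = 1.0 / r
    out[0] = cur
    for n in range(1, nmax + 1):
        cur = cur * inv_r2
        out[n] = _DFACT[n] * cur
    if v is not None:
        out *= thole_factors(v, nmax)
    return out


def properties_direct(
    sources: MultipoleSet,
    targets: np.ndarray,
    order: str = "VEG",
    mask: Optional[np.ndarray] = None,
    damp_alpha_targets: Optional[np.ndarray] = None,
    chunk: int = 512,
) -> FieldSamples:
    """Exact O(N*M) Coulomb properties of q, mu, Theta at the targets.

    ``order`` is one of ``V``, ``VE``, ``VEG``, ``VEGH``.  ``mask`` is an
    (n_targets, n_sources) multiplicative weight (0 excludes a pair; any
    float implements scaled exclusion rules).  When
    ``damp_alpha_targets`` is given, interactions are Thole damped using
    the source polarizabilities, the given target polarizabilities and
    the source set's damping width.
    """
    if order not in ("V", "VE", "VEG", "VEGH"):
        raise ValueError(f"unknown order {order!r}")
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    m, n = len(targets), sources.n_sites
    lvl = {"V": 0, "VE": 1, "VEG": 2, "VEGH": 3}[order]
    nmax = lvl + 2  # quadrupole term at each level needs B_{lvl+2}
    out = FieldSamples(positions=targets)
    out.V = np.zeros(m)
    if lvl >= 1:
        out.E = np.zeros((m, 3))
    if lvl >= 2:
        out.G = np.zeros((m, 3, 3))
    if lvl >= 3:
        out.H = np.zeros((m, 3, 3, 3))
    eye = np.eye(3)
    for i0 in range(0, m, chunk):
        sl = slice(i0, min(i0 + chunk, m))
        R = targets[sl, None, :] - sources.positions[None, :, :]  # (c, n, 3)
        r2 = np.einsum("cna,cna->cn", R, R)
        w = None if mask is None else np.asarray(mask, dtype=float)[sl]
        bad = r2 < 1e-20
        if np.any(bad if w is None else bad & (w != 0)):
            ci, si = np.argwhere(bad if w is None else bad & (w != 0))[0]
            raise SingularGeometryError(
                f"target {i0 + ci} coincides with source {si}"
            )
        # masked coincident pairs carry weight 0; keep their kernels finite
        r = np.sqrt(np.where(bad, 1.0, r2))
        if damp_alpha_targets is not None:
            aa = np.sqrt(
                np.outer(np.asarray(damp_alpha_targets, dtype=float)[sl], sources.alpha)
            )
            with np.errstate(divide="ignore"):
                v = np.where(aa > 0, sources.thole * r**3 / np.where(aa > 0, aa, 1.0), np.inf)
            B = _bn_ladder(r, nmax, v=v)
        else:
            B = _bn_ladder(r, nmax)
        if w is not None:
            B = B * w[None]
        q = sources.q
        mu = sources.mu
        th = sources.theta
        muR = np.einsum("na,cna->cn", mu, R)
        ThR = np.einsum("nab,cnb->cna", th, R)
        S = np.einsum("cna,cna->cn", ThR, R)
        out.V[sl] += np.einsum("n,cn->c", q, B[0]) + np.einsum("cn,cn->c", muR, B[1]) + (
            np.einsum("cn,cn->c", S, B[2]) / 3.0
        )
        if lvl >= 1:
            E = np.einsum("n,cna,cn->ca", q, R, B[1])
            E += -np.einsum("na,cn->ca", mu, B[1]) + np.einsum("cn,cna,cn->ca", muR, R, B[2])
            E += -(2.0 / 3.0) * np.einsum("cna,cn->ca", ThR, B[2]) + (1.0 / 3.0) * np.einsum(
                "cn,cna,cn->ca", S, R, B[3]
            )
            out.E[sl] += E
        if lvl >= 2:
            G = np.einsum("n,cn->c", q, B[1])[:, None, None] * eye - np.einsum(
                "n,cna,cnb,cn->cab", q, R, R, B[2]
            )
            G += (
                np.einsum("na,cnb,cn->cab", mu, R, B[2])
                + np.einsum("nb,cna,cn->cab", mu, R, B[2])
                + np.einsum("cn,cn->c", muR, B[2])[:, None, None] * eye
                - np.einsum("cn,cna,cnb,cn->cab", muR, R, R, B[3])
            )
            G += (
                -(2.0 / 3.0) * np.einsum("nab,cn->cab", th, B[2])
                + (2.0 / 3.0)
                * (
                    np.einsum("cna,cnb,cn->cab", ThR, R, B[3])
                    + np.einsum("cnb,cna,cn->cab", ThR, R, B[3])
                )
                + (1.0 / 3.0) * np.einsum("cn,cn->c", S, B[3])[:, None, None] * eye
                - (1.0 / 3.0) * np.einsum("cn,cna,cnb,cn->cab", S, R, R, B[4])
            )
            out.G[sl] += G
        if lvl >= 3:
            nc = R.shape[0]
            H = np.zeros((nc, 3, 3, 3))
            # charge: -[d_ab A_d + d_ad A_b + d_bd A_a] + q RRR B3, A = q R B2
            A = np.einsum("n,tnx,tn->tx", q, R, B[2])
            H -= np.einsum("ab,td->tabd", eye, A)
            H -= np.einsum("ad,tb->tabd", eye, A)
            H -= np.einsum("bd,ta->tabd", eye, A)
            H += np.einsum("n,tna,tnb,tnd,tn->tabd", q, R, R, R, B[3])
            # dipole
            muB2 = np.einsum("nx,tn->tx", mu, B[2])
            H += np.einsum("ta,bd->tabd", muB2, eye)
            H += np.einsum("tb,ad->tabd", muB2, eye)
            H += np.einsum("td,ab->tabd", muB2, eye)
            H -= np.einsum("na,tnb,tnd,tn->tabd", mu, R, R, B[3])
            H -= np.einsum("nb,tna,tnd,tn->tabd", mu, R, R, B[3])
            H -= np.einsum("nd,tna,tnb,tn->tabd", mu, R, R, B[3])
            muRB3R = np.einsum("tn,tnx,tn->tx", muR, R, B[3])
            H -= np.einsum("td,ab->tabd", muRB3R, eye)
            H -= np.einsum("tb,ad->tabd", muRB3R, eye)
            H -= np.einsum("ta,bd->tabd", muRB3R, eye)
            H += np.einsum("tn,tna,tnb,tnd,tn->tabd", muR, R, R, R, B[4])
            # quadrupole
            H += (2.0 / 3.0) * (
                np.einsum("nab,tnd,tn->tabd", th, R, B[3])
                + np.einsum("nad,tnb,tn->tabd", th, R, B[3])
                + np.einsum("nbd,tna,tn->tabd", th, R, B[3])
            )
            ThRB3 = np.einsum("tnx,tn->tx", ThR, B[3])
            H += (2.0 / 3.0) * (
                np.einsum("ta,bd->tabd", ThRB3, eye)
                + np.einsum("tb,ad->tabd", ThRB3, eye)
                + np.einsum("td,ab->tabd", ThRB3, eye)
            )
            H -= (2.0 / 3.0) * (
                np.einsum("tna,tnb,tnd,tn->tabd", ThR, R, R, B[4])
                + np.einsum("tnb,tna,tnd,tn->tabd", ThR, R, R, B[4])
                + np.einsum("tnd,tna,tnb,tn->tabd", ThR, R, R, B[4])
            )
            SRB4 = np.einsum("tn,tnx,tn->tx", S, R, B[4])
            H -= (1.0 / 3.0) * (
                np.einsum("td,ab->tabd", SRB4, eye)
                + np.einsum("tb,ad->tabd", SRB4, eye)
                + np.einsum("ta,bd->tabd", SRB4, eye)
            )
            H += (1.0 / 3.0) * np.einsum("tn,tna,tnb,tnd,tn->tabd", S, R, R, R, B[5])
            out.H[sl] += H
    return out


def thole_pair_tensor(
    pos_a: np.ndarray,
    pos_b: np.ndarray,
    alpha_a: float,
    alpha_b: float,
    a_thole: float = 0.39,
) -> np.ndarray:
    """Damped dipole-dipole interaction tensor.

    Applied to a dipole at b it yields the (damped) field at a:
    ``E(a) = T mu_b`` with ``T = B2 R R^T - B1 I``.  Symmetric in both
    index exchange and a <-> b swap, and reduces to the bare tensor at
    large separation.
    """
    R = np.asarray(pos_a, dtype=float) - np.asarray(pos_b, dtype=float)
    r = float(np.linalg.norm(R))
    if r == 0.0 and alpha_a * alpha_b == 0.0:
        raise SingularGeometryError("coincident undamped pair")
    aa = np.sqrt(alpha_a * alpha_b)
    v = np.array(a_thole * r**3 / aa) if aa > 0 else np.array(np.inf)
    lam = thole_factors(v, 2)
    if r == 0.0:
        # damped limit: B1 -> a/sqrt(alpha_a alpha_b), B2 r_a r_b -> 0
        return -float(a_thole / aa) * np.eye(3)
    b1 = float(lam[1]) / r**3
    b2 = 3.0 * float(lam[2]) / r**5
    return b2 * np.outer(R, R) - b1 * np.eye(3)


def multipole_energy(
    targets: MultipoleSet, samples: FieldSamples, weights: Optional[np.ndarray] = None
) -> float:
    """Energy of a multipole set in an external property sample.

    ``U = sum q V - mu.E - (1/3) Theta:G`` per site; ``weights`` scales
    per-site contributions (used for half-counting in self energies).
    """
    u = targets.q * samples.V
    if samples.E is not None:
        u = u - np.einsum("na,na->n", targets.mu, samples.E)
    if samples.G is not None:
        u = u - np.einsum("nab,nab->n", targets.theta, samples.G) / 3.0
    if weights is not None:
        u = u * weights
    return float(np.sum(u))


def interaction_energy(set_a: MultipoleSet, set_b: MultipoleSet) -> float:
    """Coulomb interaction energy between two disjoint multipole sets."""
    samples = properties_direct(set_b, set_a.positions, order="VEG")
    return multipole_energy(set_a, samples)


def self_energy(mset: MultipoleSet) -> float:
    """Pairwise Coulomb energy within one set (each pair counted once)."""
    if mset.n_sites < 2:
        return 0.0
    mask = 1.0 - np.eye(mset.n_sites)
    samples = properties_direct(mset, mset.positions, order="VEG", mask=mask)
    return 0.5 * multipole_energy(mset, samples)
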