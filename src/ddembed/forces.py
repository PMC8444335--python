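"""Analytical gradients of the embedding energy with respect to every
atom position.

The Lagrangian formulation makes response terms unnecessary: at a
solved state the total derivative of the energy equals the partial
derivative of the Lagrangian with all six unknowns held fixed.  The
contributions are grouped by physical origin:

* ``static``       — fixed-multipole pair forces (environment self and
                     probe-environment), including local-frame rotation
                     terms;
* ``polarization`` — derivatives of the induced-dipole terms (damped
                     inducing fields and the Thole dipole-dipole
                     operator; Thole lambda' terms enter automatically
                     through the damped B-ladder);
* ``continuum_geometric`` — contractions of the adjoint solutions with
                     the geometric derivatives of L and of the
                     switching function U, for the two cross d/p
                     pairings (S_p with X_d, mu_d and S_d with X_p,
                     mu_p);
* ``phi_derivative`` — potential-derivative terms recast through
                     pseudo-charges: the field of xi at the sources
                     (with field-gradient/Hessian contractions for
                     dipoles and quadrupoles and rotation-matrix terms
                     for frame-defined multipoles) plus the source
                     fields at the moving grid nodes; induced dipoles
                     contribute the same pattern without rotation
                     terms;
* ``psi_derivative`` — rotation-matrix derivatives of Psi contracted
                     with X_d + X_p (zero for charges and induced
                     dipoles).

Every term is validated against central finite differences of the total
energy with fully re-solved states.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .cavity import penetration_grad
from .coupled import EmbeddingState, EmbeddingSystem
from .ddcosmo import HarmonicCoeffs, pseudo_charges
from .errors import StructuralError
from .harmonics import regular_gradient_ops, solid_harmonics_with_grad
from .local_frames import frame_rotation_derivatives
from .multipoles import MultipoleSet, properties_direct


@dataclass
class ForceReport:
    """Per-atom force vectors (hartree/bohr) decomposed by origin."""

    static: np.ndarray
    polarization: np.ndarray
    continuum_geometric: np.ndarray
    phi_derivative: np.ndarray
    psi_derivative: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return (
            self.static
            + self.polarization
            + self.continuum_geometric
            + self.phi_derivative
            + self.psi_derivative
        )


# ---------------------------------------------------------------------------
# generic pair-interaction forces


def _rotation_term(mset: MultipoleSet, samples, scale, out):
    """Add frame-rotation force contributions for a multipole set.

    ``samples`` holds E (and G) of the partner distribution at the
    set's sites; forces land on the atoms defining each site's frame
    (indices local to the set; ``out`` is the per-set force array).
    """
    if mset.frame_defs is None:
        return
    for i, fd in enumerate(mset.frame_defs):
        if fd is None or fd.rule == "none":
            continue
        ders = frame_rotation_derivatives(
            mset.mu_frame[i], mset.theta_frame[i], fd, i, mset.positions
        )
        for atom, (dmu, dth) in ders.items():
            f = scale * (samples.E[i] @ dmu)
            if samples.G is not None:
                f = f + scale / 3.0 * np.einsum("ab,abk->k", samples.G[i], dth)
            out[atom] += f


def interaction_forces(
    targets: MultipoleSet,
    sources: MultipoleSet,
    mask: Optional[np.ndarray] = None,
    damped: bool = False,
    scale: float = 1.0,
    need_hessian: bool = True,
):
    """Forces from ``U = scale * sum_pairs (q_t V_s - mu_t.E_s - Theta_t:G_s/3)``.

    Returns ``(F_targets, F_sources)``; local-frame rotation
    contributions are accumulated onto the atoms of the owning set.
    """
    order = "VEGH" if need_hessian else "VEG"
    kw = dict(damp_alpha_targets=targets.alpha) if damped else {}
    fw = properties_direct(sources, targets.positions, order=order, mask=mask, **kw)
    Ft = targets.q[:, None] * fw.E + np.einsum("tab,tb->ta", fw.G, targets.mu)
    if fw.H is not None:
        Ft += np.einsum("tab,tabk->tk", targets.theta, fw.H) / 3.0
    Ft *= scale
    _rotation_term(targets, fw, scale, Ft)
    kw2 = dict(damp_alpha_targets=sources.alpha) if damped else {}
    maskT = None if mask is None else np.asarray(mask).T
    rv = properties_direct(targets, sources.positions, order=order, mask=maskT, **kw2)
    Fs = sources.q[:, None] * rv.E + np.einsum("tab,tb->ta", rv.G, sources.mu)
    if rv.H is not None:
        Fs += np.einsum("tab,tabk->tk", sources.theta, rv.H) / 3.0
    Fs *= scale
    _rotation_term(sources, rv, scale, Fs)
    return Ft, Fs


def _dipole_set(mu, positions, alpha, thole):
    n = len(positions)
    return MultipoleSet(
        positions, np.zeros(n), mu, None, alpha, thole=thole
    )


def _charge_set(q, positions):
    n = len(positions)
    return MultipoleSet(positions, q, None, None, np.zeros(n))


# ---------------------------------------------------------------------------
# static and polarization forces


def static_forces(system: EmbeddingSystem) -> np.ndarray:
    """Forces of the fixed-multipole electrostatics (probe-probe excluded)."""
    F = np.zeros((system.n_atoms, 3))
    np_ = system.n_probe
    env = system.env
    if env.n_sites > 1:
        mask = 1.0 - np.eye(env.n_sites)
        Ft, Fs = interaction_forces(env, env, mask=mask, scale=0.5)
        F[np_:] += Ft + Fs
    if system.probe is not None and np_ and env.n_sites:
        Ft, Fs = interaction_forces(system.probe, env)
        F[:np_] += Ft
        F[np_:] += Fs
    return F


def polarization_forces(state: EmbeddingState, system: EmbeddingSystem) -> np.ndarray:
    """Gradient of the induced-dipole terms of the Lagrangian (negated)."""
    F = np.zeros((system.n_atoms, 3))
    npol = system.n_pol
    if npol == 0:
        return F
    cfg = system.config
    np_ = system.n_probe
    pol_glob = system.pol_spheres  # global atom index of each dipole site
    alpha_pol = system.env.alpha[system.pol_local]
    ppos = system.pol_positions
    # -(1/2)(mu_d.F_p + mu_p.F_d), probe part: field unscaled
    mu_bar = 0.5 * (state.mu_d + state.mu_p)
    if system.probe is not None and np_:
        tset = _dipole_set(mu_bar, ppos, alpha_pol, cfg.thole)
        Ft, Fs = interaction_forces(tset, system.probe, damped=True)
        np.add.at(F, pol_glob, Ft)
        F[:np_] += Fs
    # environment part with branch exclusion scales
    mu_env = 0.5 * (cfg.p_scale * state.mu_d + cfg.d_scale * state.mu_p)
    tset = _dipole_set(mu_env, ppos, alpha_pol, cfg.thole)
    mask = np.ones((npol, system.env.n_sites))
    mask[np.arange(npol), system.pol_local] = 0.0
    Ft, Fs = interaction_forces(tset, system.env, mask=mask, damped=True)
    np.add.at(F, pol_glob, Ft)
    F[np_:] += Fs
    # +(1/2) mu_p . T mu_d, off-diagonal (dipole-dipole, damped)
    if npol > 1:
        tset = _dipole_set(0.5 * state.mu_p, ppos, alpha_pol, cfg.thole)
        sset = _dipole_set(state.mu_d, ppos, alpha_pol, cfg.thole)
        m2 = 1.0 - np.eye(npol)
        Ft, Fs = interaction_forces(tset, sset, mask=m2, damped=True)
        np.add.at(F, pol_glob, Ft + Fs)
    return F


# ---------------------------------------------------------------------------
# switching-function machinery


def _sphere_switch_data(system: EmbeddingSystem, i: int):
    """Per-neighbour penetration values and center-derivatives on all
    nodes of sphere i."""
    cav = system.cavity
    pts = cav.node_positions(i)
    data = []
    for j in cav.neighbors[i]:
        c, dcdc = penetration_grad(pts, cav.centers[j], cav.radii[j], cav.eta)
        if np.any(c > 0):
            data.append((j, c, dcdc))
    return data


def switch_gradient_contraction(system: EmbeddingSystem, coeff: np.ndarray) -> np.ndarray:
    """Gradient of ``sum_in coeff_in U_in`` with respect to all sphere
    centers; ``coeff`` has shape (n_spheres, n_nodes)."""
    cav = system.cavity
    out = np.zeros((cav.n_spheres, 3))
    for i in range(cav.n_spheres):
        if not cav.neighbors[i]:
            continue
        data = _sphere_switch_data(system, i)
        if not data:
            continue
        cs = [c for (_, c, _) in data]
        for k, (j, c, dcdc) in enumerate(data):
            # product of (1 - c) over the *other* neighbours
            uex = np.ones(cav.n_nodes)
            for k2, c2 in enumerate(cs):
                if k2 != k:
                    uex *= 1.0 - c2
            w = coeff[i] * uex  # dU/dc_j = -uex
            g = np.einsum("n,na->a", w, dcdc)
            out[j] -= g
            out[i] += g
    return out


def L_geometric_gradient(system: EmbeddingSystem, pairings) -> np.ndarray:
    """Gradient of ``sum_w wgt <S, A X>`` over sphere centers.

    ``pairings`` is a list of ``(S, X, wgt)``; A is the off-diagonal
    (exchange) part of L.  Includes both the solid-harmonic trace
    derivatives and the derivatives of the switching weights omega.
    """
    cav = system.cavity
    ws = system.workspace
    basis = system.basis
    out = np.zeros((cav.n_spheres, 3))
    Y = ws.Ynodes
    w = cav.weights
    for i in range(cav.n_spheres):
        data = _sphere_switch_data(system, i)
        if not data:
            continue
        # sigma_in per pairing
        sigmas = [(Y @ S.data[i]) * w * wgt for (S, X, wgt) in pairings]
        cs = [c for (_, c, _) in data]
        C = np.sum(cs, axis=0)
        U = cav.U[i]
        with np.errstate(divide="ignore", invalid="ignore"):
            invC = np.where(C > 0, 1.0 / np.where(C > 0, C, 1.0), 0.0)
        pts = cav.node_positions(i)
        # per-neighbour exclusive products prod_{m' != m} (1 - c_m')
        uex = []
        for k in range(len(data)):
            u = np.ones(cav.n_nodes)
            for k2, c2 in enumerate(cs):
                if k2 != k:
                    u *= 1.0 - c2
            uex.append(u)
        # accumulate per pairing
        for (S, X, wgt), sig in zip(pairings, sigmas):
            for k, (j, c, dcdc) in enumerate(data):
                active = c > 0
                if not np.any(active):
                    continue
                vals, grads = solid_harmonics_with_grad(
                    pts[active], cav.centers[j], cav.radii[j], basis
                )
                Wj = vals @ X.data[j]
                dWj = np.einsum("nbk,b->nk", grads, X.data[j])
                omega = (c * (1.0 - U) * invC)[active]
                sig_a = sig[active]
                # 1) trace-argument derivative: node rides sphere i,
                #    expansion center is sphere j
                g1 = np.einsum("n,n,nk->k", sig_a, omega, dWj)
                out[i] += g1
                out[j] -= g1
                # 2) omega derivatives through each neighbour's c_m
                b = sig_a * Wj  # coefficient of d(omega)/d(...)
                for k2, (m, c2, dcdc2) in enumerate(data):
                    act2 = active & (c2 > 0)
                    if not np.any(act2):
                        continue
                    sel = act2[active]  # restriction to sphere-j active nodes
                    # domega/dc_m = [delta_mj (1-U) + c_j uex_m] / C
                    #               - c_j (1-U) / C^2
                    dj = 1.0 if m == j else 0.0
                    dodc = (
                        dj * (1.0 - U[act2])
                        + c[act2] * uex[k2][act2]
                    ) * invC[act2] - c[act2] * (1.0 - U[act2]) * invC[act2] ** 2
                    gg = np.einsum("n,n,nk->k", b[sel], dodc, dcdc2[act2])
                    out[m] += gg
                    out[i] -= gg
    return out


# ---------------------------------------------------------------------------
# continuum force groups


def psi_derivative_forces(state: EmbeddingState, system: EmbeddingSystem) -> np.ndarray:
    """Rotation-matrix contributions of the Psi contraction.

    Zero for point charges and induced dipoles; for frame-defined fixed
    dipoles and quadrupoles, the contraction of X_d + X_p with the
    derivatives of the rotated multipoles.
    """
    F = np.zeros((system.n_atoms, 3))
    f = system.config.f
    if f == 0.0:
        return F
    Xbar = 0.25 * f * (state.X_d.data + state.X_p.data)
    cav = system.cavity
    D = regular_gradient_ops(max(system.basis.lmax, 2))
    s4pi = np.sqrt(4.0 * np.pi)
    g10 = D[:, 1:4, 0] / s4pi  # (coord, m)
    gg = np.einsum("amk,bk->abm", D[:, 4:9, 1:4], D[:, 1:4, 0]) / s4pi
    offsets = [0, system.n_probe]
    for mset, off in zip((system.probe, system.env), offsets):
        if mset is None or mset.frame_defs is None:
            continue
        for i, fd in enumerate(mset.frame_defs):
            if fd is None or fd.rule == "none":
                continue
            sph = off + i
            a_vec = (g10 @ Xbar[sph, 1:4]) / cav.radii[sph]
            b_mat = (
                np.einsum("abm,m->ab", gg, Xbar[sph, 4:9])
                / 3.0
                / cav.radii[sph] ** 2
                if system.basis.lmax >= 2
                else np.zeros((3, 3))
            )
            ders = frame_rotation_derivatives(
                mset.mu_frame[i], mset.theta_frame[i], fd, i, mset.positions
            )
            for atom, (dmu, dth) in ders.items():
                F[off + atom] -= a_vec @ dmu + np.einsum("ab,abk->k", b_mat, dth)
    return F


def phi_derivative_forces(state: EmbeddingState, system: EmbeddingSystem) -> np.ndarray:
    """Potential-derivative terms via pseudo-charges (Coulomb recast)."""
    F = np.zeros((system.n_atoms, 3))
    f = system.config.f
    if f == 0.0:
        return F
    cav = system.cavity
    basis = system.basis
    pcs_d = pseudo_charges(state.S_d, cav, basis)
    pcs_p = pseudo_charges(state.S_p, cav, basis)
    np_ = system.n_probe
    # --- static sources against xi_bar = f/4 (xi_d + xi_p)
    xi_bar = 0.25 * f * (pcs_d.xi + pcs_p.xi)
    F += _xi_multipole_forces(system, xi_bar, system.probe, 0)
    F += _xi_multipole_forces(system, xi_bar, system.env, np_)
    # --- induced dipoles: f/4 (xi_p with mu_d) + f/4 (xi_d with mu_p)
    if system.n_pol:
        for xi, mu in (
            (0.25 * f * pcs_p.xi, state.mu_d),
            (0.25 * f * pcs_d.xi, state.mu_p),
        ):
            dset = _dipole_set(mu, system.pol_positions, np.zeros(system.n_pol), 0.39)
            F += _xi_multipole_forces(system, xi, dset, None,
                                      atom_index=system.pol_spheres)
    return F


def _xi_multipole_forces(system, xi, mset, offset, atom_index=None):
    """Forces of the contraction sum_in xi_in V[mset](r_i^n).

    Multipole-side forces (field/gradient/Hessian of xi at the sources,
    plus rotation terms) land on the set's atoms; node-side forces (the
    set's field at the moving grid points) land on the sphere atoms.
    """
    F = np.zeros((system.n_atoms, 3))
    if mset is None or mset.n_sites == 0 or not np.any(xi):
        return F
    cav = system.cavity
    mask = xi != 0.0
    pos = cav.node_positions()[mask]
    sph = np.broadcast_to(np.arange(cav.n_spheres)[:, None], xi.shape)[mask]
    charges = _charge_set(xi[mask], pos)
    Ft, Fs = interaction_forces(mset, charges)
    if atom_index is None:
        F[offset : offset + mset.n_sites] += Ft
    else:
        np.add.at(F, atom_index, Ft)
    np.add.at(F, sph, Fs)
    return F


def continuum_geometric_forces(
    state: EmbeddingState, system: EmbeddingSystem
) -> np.ndarray:
    """Contractions of the adjoints with the geometric derivatives of L
    and of the switching function U (the two d/p pairings)."""
    F = np.zeros((system.n_atoms, 3))
    f = system.config.f
    if f == 0.0:
        return F
    cav = system.cavity
    Y = system.workspace.Ynodes
    w = cav.weights
    # dU parts of <S_d + S_p, Phi_s> and the Xi couplings
    sigma_d = state.S_d.data @ Y.T
    sigma_p = state.S_p.data @ Y.T
    Vs = system.static_potential_at_nodes()
    coeff = 0.25 * f * w[None, :] * (sigma_d + sigma_p) * Vs
    if system.n_pol:
        from .coupling import dipole_potential_at_nodes

        Vd = dipole_potential_at_nodes(
            state.mu_d, system.pol_positions, cav, system.accelerator
        )
        Vp = dipole_potential_at_nodes(
            state.mu_p, system.pol_positions, cav, system.accelerator
        )
        coeff = coeff + 0.25 * f * w[None, :] * (sigma_p * Vd + sigma_d * Vp)
    F -= switch_gradient_contraction(system, coeff)
    # dA part of -(f/4)[<S_p, L X_d> + <S_d, L X_p>]
    grad = L_geometric_gradient(
        system,
        [(state.S_p, state.X_d, -0.25 * f), (state.S_d, state.X_p, -0.25 * f)],
    )
    F -= grad
    return F


# ---------------------------------------------------------------------------


def forces_total(state: EmbeddingState, system: EmbeddingSystem) -> ForceReport:
    """Assemble all analytical force contributions for a solved state."""
    if not state.solved:
        raise StructuralError("forces require a solved EmbeddingState")
    rep = ForceReport(
        static=static_forces(system),
        polarization=polarization_forces(state, system),
        continuum_geometric=continuum_geometric_forces(state, system),
        phi_derivative=phi_derivative_forces(state, system),
        psi_derivative=psi_derivative_forces(state, system),
    )
    return rep
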