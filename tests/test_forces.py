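"""Analytical forces against finite differences of the re-solved total
energy, plus isolated-term oracles for the continuum geometric pieces."""

import numpy as np
import pytest

from ddembed.config import RunConfig
from ddembed.coupled import EmbeddingSystem, embedding_energy, solve_coupled
from ddembed.ddcosmo import HarmonicCoeffs, apply_L, inner
from ddembed.errors import StructuralError
from ddembed.forces import (
    L_geometric_gradient,
    forces_total,
    switch_gradient_contraction,
)

from conftest import make_env, make_probe, small_system


def _fd_forces(system, h=1e-4):
    X0 = system.all_positions
    out = np.zeros((system.n_atoms, 3))
    for k in range(system.n_atoms):
        for a in range(3):
            for sgn in (1.0, -1.0):
                Xp = X0.copy()
                Xp[k, a] += sgn * h
                s2 = system.displaced(Xp)
                e = embedding_energy(solve_coupled(s2), s2).total
                out[k, a] -= sgn * e / (2.0 * h)
    return out


CASES = {
    "charges": dict(charges=True, dipoles=False, quads=False, pol=False),
    "dipoles": dict(charges=False, dipoles=True, quads=False, pol=False, frames=True),
    "quadrupoles": dict(charges=False, dipoles=False, quads=True, pol=False, frames=True),
    "polarizable": dict(charges=True, dipoles=False, quads=False, pol=True),
    "mixed": dict(charges=True, dipoles=True, quads=True, pol=True, frames=True),
}


@pytest.mark.parametrize("case", list(CASES))
@pytest.mark.parametrize("continuum", [True, False])
def test_forces_match_finite_differences(case, continuum):
    """Componentwise agreement with central differences of the total
    energy (re-solved at each displacement) to 1e-6 hartree/bohr, for
    each multipole class with and without the continuum layer."""
    seed = 47 + hash(case) % 100
    system = small_system(
        59 + list(CASES).index(case),
        n_env=4,
        lmax=2,
        grid_order=26,
        epsilon=15.0 if continuum else 1.0,
        tol=1e-10,
        **CASES[case],
    )
    state = solve_coupled(system)
    an = forces_total(state, system)
    fd = _fd_forces(system)
    assert np.abs(an.total - fd).max() < 1e-6
    # decomposition sums exactly to the total
    parts = (
        an.static
        + an.polarization
        + an.continuum_geometric
        + an.phi_derivative
        + an.psi_derivative
    )
    assert np.abs(parts - an.total).max() < 1e-12


def test_net_force_and_rotation_invariance():
    """Zero net force; rigid rotation of the whole system (grids
    co-rotated, lab-frame multipoles rotated by hand) leaves the energy
    unchanged, the rotational-invariance statement behind zero net
    torque."""
    system = small_system(61, n_env=6, lmax=3, grid_order=26, tol=1e-10, frames=True)
    state = solve_coupled(system)
    F = forces_total(state, system).total
    assert np.abs(F.sum(axis=0)).max() < 1e-8
    rng = np.random.default_rng(3)
    Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    rot = EmbeddingSystem(
        system.env.with_positions(system.env.positions @ Q.T),
        None if system.probe is None else
        system.probe.with_positions(system.probe.positions @ Q.T),
        system.cavity_radii,
        system.config,
        orientation=Q,
    )
    # frame-defined multipoles co-rotate exactly; lab-frame ones must be
    # rotated by hand
    for mset, orig in ((rot.env, system.env), (rot.probe, system.probe)):
        if mset is None:
            continue
        for i, fdef in enumerate(mset.frame_defs or [None] * mset.n_sites):
            if fdef is None or fdef.rule == "none":
                mset.mu[i] = Q @ orig.mu[i]
                mset.theta[i] = Q @ orig.theta[i] @ Q.T
    rot._cache = {}
    e0 = embedding_energy(state, system).total
    e1 = embedding_energy(solve_coupled(rot), rot).total
    assert e1 == pytest.approx(e0, abs=1e-8)


def test_net_torque_vanishes_for_frame_attached_multipoles():
    """When every dipole/quadrupole rides a local frame, the two-layer
    energy is invariant under rigid rotations of the atoms alone, so the
    atomic forces carry zero net torque.  With the continuum on, the
    fixed per-sphere grids break exact rotational invariance of the
    *discretized* energy; the residual torque is pure quadrature error
    and shrinks under refinement."""
    rng = np.random.default_rng(8)
    env = make_env(rng, 5, frames="all")
    cfg = RunConfig(lmax=2, grid_order=26, epsilon=1.0, tol=1e-11)
    system = EmbeddingSystem(env, None, np.full(5, 2.6), cfg)
    state = solve_coupled(system)
    F = forces_total(state, system).total
    assert np.abs(F.sum(axis=0)).max() < 1e-8
    tau = np.cross(system.all_positions, F).sum(axis=0)
    assert np.abs(tau).max() < 1e-8

    def continuum_torque(lmax, grid_order):
        c = RunConfig(lmax=lmax, grid_order=grid_order, epsilon=15.0, tol=1e-11)
        s = EmbeddingSystem(env, None, np.full(5, 2.6), c)
        Fc = forces_total(solve_coupled(s), s).total
        assert np.abs(Fc.sum(axis=0)).max() < 1e-8  # translation stays exact
        return np.abs(np.cross(s.all_positions, Fc).sum(axis=0)).max()

    assert continuum_torque(6, 194) < 0.5 * continuum_torque(2, 26)


def test_single_sphere_has_no_geometric_continuum_force():
    rng = np.random.default_rng(5)
    env = make_env(rng, 1, quads=False, pol=False)
    cfg = RunConfig(lmax=3, grid_order=26, tol=1e-10)
    system = EmbeddingSystem(env, None, np.array([2.5]), cfg)
    state = solve_coupled(system)
    from ddembed.forces import continuum_geometric_forces

    assert np.abs(continuum_geometric_forces(state, system)).max() < 1e-14


def test_L_geometric_gradient_matches_fd():
    """The dA contraction gradient against finite differences of
    <S, A(positions) X> with frozen coefficient vectors (seeded
    two-sphere system)."""
    rng = np.random.default_rng(53)
    system = small_system(53, n_env=2, with_probe=False, lmax=2, grid_order=26)
    nb = system.basis.nbasis
    S = HarmonicCoeffs(rng.normal(size=(2, nb)))
    X = HarmonicCoeffs(rng.normal(size=(2, nb)))

    def value(sys_):
        # <S, A X> = <S, (L + I) X>
        return inner(S, apply_L(X, sys_.workspace)) + inner(S, X)

    grad = L_geometric_gradient(system, [(S, X, 1.0)])
    h = 1e-6
    for k in range(2):
        for a in range(3):
            pp = system.all_positions.copy()
            pp[k, a] += h
            pm = system.all_positions.copy()
            pm[k, a] -= h
            fd = (value(system.displaced(pp)) - value(system.displaced(pm))) / (2 * h)
            assert grad[k, a] == pytest.approx(fd, abs=1e-6)


def test_switch_gradient_contraction_matches_fd():
    system = small_system(54, n_env=3, with_probe=False, lmax=2, grid_order=26)
    rng = np.random.default_rng(54)
    coeff = rng.normal(size=system.cavity.U.shape)

    def value(sys_):
        return float(np.sum(coeff * sys_.cavity.U))

    grad = switch_gradient_contraction(system, coeff)
    h = 1e-6
    for k in range(3):
        for a in range(3):
            pp = system.all_positions.copy()
            pp[k, a] += h
            pm = system.all_positions.copy()
            pm[k, a] -= h
            fd = (value(system.displaced(pp)) - value(system.displaced(pm))) / (2 * h)
            assert grad[k, a] == pytest.approx(fd, abs=1e-7)


def test_psi_forces_vanish_for_charges_only():
    system = small_system(
        57, n_env=4, charges=True, dipoles=False, quads=False, pol=False
    )
    state = solve_coupled(system)
    from ddembed.forces import psi_derivative_forces

    assert np.abs(psi_derivative_forces(state, system)).max() == 0.0


def test_quadrupole_without_frame_has_no_rotation_force():
    system = small_system(
        58, n_env=4, charges=False, dipoles=False, quads=True, pol=False, frames=False
    )
    state = solve_coupled(system)
    from ddembed.forces import psi_derivative_forces

    assert np.abs(psi_derivative_forces(state, system)).max() == 0.0


def test_unsolved_state_is_refused():
    system = small_system(59, n_env=3)
    state = solve_coupled(system)
    state.solved = False
    with pytest.raises(StructuralError):
        forces_total(state, system)
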