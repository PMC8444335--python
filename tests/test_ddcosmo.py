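"""Continuum core: analytic limits, adjoint/algebraic identities, and
the dense oracle."""

import numpy as np
import pytest

from ddembed.cavity import build_cavity
from ddembed.ddcosmo import (
    DDWorkspace,
    HarmonicCoeffs,
    SolverConfig,
    apply_L,
    apply_Ladj,
    assemble_Phi,
    assemble_Psi,
    continuum_energy,
    dense_L,
    f_of_eps,
    inner,
    pseudo_charges,
    psi_offcenter_charge,
    solve_L,
    solve_Ladj,
)
from ddembed.errors import (
    ConfigurationError,
    IncompleteInputError,
    SolverError,
    UnsupportedGeometryError,
)
from ddembed.grids import product_grid
from ddembed.harmonics import HarmonicBasis
from ddembed.multipoles import MultipoleSet, properties_direct, traceless

BASIS = HarmonicBasis(6)
CONDUCTOR = SolverConfig(lmax=6, epsilon=np.inf, tol=1e-12)


def _solve_central_charge(R, q, grid_order=110):
    cav = build_cavity([[0, 0, 0]], [R], grid_order=grid_order)
    ws = DDWorkspace(cav, BASIS)
    src = MultipoleSet([[0, 0, 0]], [q], None, None, [0.0])
    V = properties_direct(src, cav.node_positions().reshape(-1, 3), "V").V
    Phi = assemble_Phi(cav, V.reshape(1, -1), BASIS)
    X, _ = solve_L(Phi, ws, CONDUCTOR)
    Psi = assemble_Psi(src, cav, BASIS)
    return Psi, X


def test_f_of_eps_schemes():
    assert f_of_eps(np.inf) == 1.0
    assert f_of_eps(2.0) == pytest.approx(0.5)
    assert f_of_eps(2.0, "half") == pytest.approx(0.4)
    assert f_of_eps(1.0) == 0.0
    with pytest.raises(ConfigurationError):
        f_of_eps(0.5)
    with pytest.raises(ConfigurationError):
        f_of_eps(2.0, "weird")


@pytest.mark.parametrize("R,q", [(2.0, 1.0), (1.5, -0.7), (4.0, 2.0)])
def test_born_energy(R, q):
    """Single sphere, central charge: E = -f(eps) q^2 / (2R) exactly."""
    Psi, X = _solve_central_charge(R, q)
    for eps in (np.inf, 2.0, 15.0, 78.4):
        f = f_of_eps(eps)
        assert continuum_energy(Psi, X, eps) == pytest.approx(
            -f * q * q / (2 * R), abs=1e-10
        )


def test_central_charge_excites_only_monopole():
    Psi, X = _solve_central_charge(2.0, 1.0)
    assert np.abs(X.data[0, 1:]).max() < 1e-12
    assert np.abs(Psi.data[0, 1:]).max() == 0.0


def test_offcenter_kirkwood_truncated_series():
    """Off-center charge in one sphere reproduces the conductor Kirkwood
    series truncated at lmax (quadrature of ample degree)."""
    cav = build_cavity([[0, 0, 0]], [1.0], grid=product_grid(75))
    ws = DDWorkspace(cav, BASIS)
    d = 0.5
    src = MultipoleSet([[0, 0, d]], [1.0], None, None, [0.0])
    V = properties_direct(src, cav.node_positions().reshape(-1, 3), "V").V
    X, _ = solve_L(assemble_Phi(cav, V.reshape(1, -1), BASIS), ws, CONDUCTOR)
    Psi = psi_offcenter_charge(cav, 0, [0, 0, d], 1.0, BASIS)
    expected = -0.5 * sum(d ** (2 * l) for l in range(7))
    assert continuum_energy(Psi, X, np.inf) == pytest.approx(expected, abs=1e-10)
    assert expected == pytest.approx(-0.66663, abs=5e-6)


def _random_workspace(seed, n=4, lmax=3, grid_order=26):
    rng = np.random.default_rng(seed)
    pos = rng.uniform(-3.5, 3.5, size=(n, 3))
    rad = rng.uniform(1.8, 2.6, size=n)
    cav = build_cavity(pos, rad, grid_order=grid_order)
    return cav, DDWorkspace(cav, HarmonicBasis(lmax)), rng


@pytest.mark.parametrize("seed", [13, 14, 15])
def test_adjoint_identity(seed):
    cav, ws, rng = _random_workspace(seed)
    nb = ws.basis.nbasis
    X = HarmonicCoeffs(rng.normal(size=(cav.n_spheres, nb)))
    S = HarmonicCoeffs(rng.normal(size=(cav.n_spheres, nb)))
    lhs = inner(S, apply_L(X, ws))
    rhs = inner(apply_Ladj(S, ws), X)
    assert abs(lhs - rhs) < 1e-12 * max(1.0, abs(lhs))


def test_disjoint_spheres_have_no_coupling():
    cav = build_cavity([[0, 0, 0], [10.0, 0, 0]], [2.0, 2.0], grid_order=26)
    ws = DDWorkspace(cav, HarmonicBasis(3))
    assert len(ws.pairs) == 0
    X = HarmonicCoeffs(np.random.default_rng(0).normal(size=(2, 16)))
    assert np.abs(apply_L(X, ws).data + X.data).max() == 0.0  # L = -Id


@pytest.mark.parametrize("seed", [9, 17])
def test_pseudo_charge_identity(seed):
    """<S, Phi(V)> = sum_in xi_in V(r_i^n) for any S and V."""
    cav, ws, rng = _random_workspace(seed)
    nb = ws.basis.nbasis
    S = HarmonicCoeffs(rng.normal(size=(cav.n_spheres, nb)))
    V = rng.normal(size=(cav.n_spheres, cav.n_nodes))
    pc = pseudo_charges(S, cav, ws.basis)
    assert np.all(pc.xi[cav.U == 0.0] == 0.0)
    lhs = inner(S, assemble_Phi(cav, V, ws.basis))
    rhs = float(np.sum(pc.xi * V))
    assert abs(lhs - rhs) < 1e-12 * max(1.0, abs(lhs))
    zero = pseudo_charges(HarmonicCoeffs(np.zeros((cav.n_spheres, nb))), cav, ws.basis)
    assert np.abs(zero.xi).max() == 0.0


def test_iterative_solvers_match_dense_oracle():
    cav, ws, rng = _random_workspace(99, n=5)
    nb = ws.basis.nbasis
    M = dense_L(ws)
    rhs = rng.normal(size=(cav.n_spheres, nb))
    cfg = SolverConfig(lmax=3, tol=1e-12)
    X, _ = solve_L(HarmonicCoeffs(rhs), ws, cfg)
    S, _ = solve_Ladj(HarmonicCoeffs(rhs), ws, cfg)
    assert np.abs(X.data.ravel() - np.linalg.solve(M, rhs.ravel())).max() < 1e-9
    assert np.abs(S.data.ravel() - np.linalg.solve(M.T, rhs.ravel())).max() < 1e-9


def test_adjoint_solution_consistency():
    """<Psi, L^-1 Phi> = <L^-T Psi, Phi> to solver tolerance."""
    cav, ws, rng = _random_workspace(23, n=5)
    nb = ws.basis.nbasis
    Phi = HarmonicCoeffs(rng.normal(size=(cav.n_spheres, nb)))
    Psi = HarmonicCoeffs(rng.normal(size=(cav.n_spheres, nb)))
    cfg = SolverConfig(lmax=3, tol=1e-12)
    X, _ = solve_L(Phi, ws, cfg)
    S, _ = solve_Ladj(Psi, ws, cfg)
    assert inner(Psi, X) == pytest.approx(inner(S, Phi), rel=1e-9, abs=1e-10)


def test_solver_edge_cases():
    cav, ws, _ = _random_workspace(31)
    nb = ws.basis.nbasis
    cfg = SolverConfig(lmax=3, tol=1e-10)
    X, it = solve_L(HarmonicCoeffs(np.zeros((cav.n_spheres, nb))), ws, cfg)
    assert it == 0 and np.abs(X.data).max() == 0.0
    rng = np.random.default_rng(0)
    with pytest.raises(SolverError) as err:
        solve_L(
            HarmonicCoeffs(rng.normal(size=(cav.n_spheres, nb))),
            ws,
            SolverConfig(lmax=3, tol=1e-14, max_iter=2),
        )
    assert len(err.value.residuals) > 0


def test_assemble_inputs_are_validated():
    cav = build_cavity([[0, 0, 0]], [2.0], grid_order=26)
    b = HarmonicBasis(2)
    with pytest.raises(IncompleteInputError):
        assemble_Phi(cav, np.zeros((2, 5)), b)
    off = MultipoleSet([[0.5, 0, 0]], [1.0], None, None, [0.0])
    with pytest.raises(UnsupportedGeometryError):
        assemble_Psi(off, cav, b)


def test_psi_locality_and_order():
    """Charge-only sources excite only l=0; zero multipoles give Psi=0;
    Psi is independent of the other spheres."""
    cav, ws, rng = _random_workspace(37, n=3)
    b = ws.basis
    q = rng.normal(size=3)
    src = MultipoleSet(cav.centers, q, None, None, np.zeros(3))
    Psi = assemble_Psi(src, cav, b)
    assert np.abs(Psi.data[:, 1:]).max() == 0.0
    assert Psi.data[:, 0] == pytest.approx(q / np.sqrt(4 * np.pi))
    zero = MultipoleSet(cav.centers, np.zeros(3), None, None, np.zeros(3))
    assert np.abs(assemble_Psi(zero, cav, b).data).max() == 0.0


def test_psi_normalization_oracle():
    """<Psi, X> equals the explicit interaction of the sources with the
    local expansions (value, gradient, Hessian at the centers)."""
    from ddembed.harmonics import eval_solid_harmonics

    cav, ws, rng = _random_workspace(41, n=3)
    b = ws.basis
    src = MultipoleSet(
        cav.centers,
        rng.normal(size=3),
        rng.normal(size=(3, 3)),
        traceless(rng.normal(size=(3, 3, 3))),
        np.zeros(3),
    )
    Psi = assemble_Psi(src, cav, b)
    X = HarmonicCoeffs(rng.normal(size=(cav.n_spheres, b.nbasis)))
    total = 0.0
    h = 1e-4
    for i in range(3):
        def W(p):
            return float(X.data[i] @ eval_solid_harmonics(p, cav.centers[i], cav.radii[i], b))

        c = cav.centers[i]
        g = np.zeros(3)
        hess = np.zeros((3, 3))
        for a in range(3):
            ea = np.zeros(3); ea[a] = h
            g[a] = (W(c + ea) - W(c - ea)) / (2 * h)
            for bb in range(3):
                eb = np.zeros(3); eb[bb] = h
                hess[a, bb] = (
                    W(c + ea + eb) - W(c + ea - eb) - W(c - ea + eb) + W(c - ea - eb)
                ) / (4 * h * h)
        total += src.q[i] * W(c) + src.mu[i] @ g + np.sum(src.theta[i] * hess) / 3.0
    assert inner(Psi, X) == pytest.approx(total, rel=1e-7, abs=1e-7)


def test_energy_bilinearity():
    Psi, X = _solve_central_charge(2.0, 1.0, grid_order=26)
    e1 = continuum_energy(Psi, X, 15.0)
    Psi2 = HarmonicCoeffs(2 * Psi.data)
    X2 = HarmonicCoeffs(2 * X.data)
    assert continuum_energy(Psi2, X2, 15.0) == pytest.approx(4 * e1, rel=1e-12)
    assert continuum_energy(HarmonicCoeffs(np.zeros_like(Psi.data)), X, 15.0) == 0.0


def test_rigid_motion_invariance():
    """Rotating + translating the whole system (grids co-rotated) leaves
    the continuum energy unchanged."""
    rng = np.random.default_rng(53)
    pos = rng.uniform(-3, 3, size=(4, 3))
    rad = rng.uniform(1.8, 2.6, size=4)
    q = rng.normal(size=4)
    b = HarmonicBasis(4)
    cfg = SolverConfig(lmax=4, epsilon=15.0, tol=1e-12)

    def energy(positions, orientation=None):
        cav = build_cavity(positions, rad, grid_order=26, orientation=orientation)
        ws = DDWorkspace(cav, b)
        src = MultipoleSet(positions, q, None, None, np.zeros(4))
        V = properties_direct(src, cav.node_positions().reshape(-1, 3), "V").V
        X, _ = solve_L(
            assemble_Phi(cav, V.reshape(4, -1), b), ws, cfg
        )
        return continuum_energy(assemble_Psi(src, cav, b), X, 15.0)

    e0 = energy(pos)
    A = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    shift = np.array([3.0, -2.0, 5.0])
    e1 = energy(pos @ Q.T + shift, orientation=Q)
    assert e1 == pytest.approx(e0, abs=1e-9)
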