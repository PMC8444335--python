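"""The six-variable coupled problem: stationarity, energy identities,
limits, and invariances."""

import copy

import numpy as np
import pytest

from ddembed.config import RunConfig
from ddembed.coupled import (
    EmbeddingSystem,
    embedding_energy,
    lagrangian_value,
    solve_coupled,
)
from ddembed.errors import StructuralError
from ddembed.multipoles import MultipoleSet, self_energy, interaction_energy

from conftest import make_env, make_probe, small_system

BLOCKS = ("mu_d", "mu_p", "X_d", "S_d", "X_p", "S_p")


def _perturb(state, block, delta):
    s2 = copy.deepcopy(state)
    obj = getattr(s2, block)
    if isinstance(obj, np.ndarray):
        setattr(s2, block, obj + delta)
    else:
        obj.data += delta
    return s2


@pytest.mark.parametrize("seed", [43, 44, 45])
def test_lagrangian_stationarity(seed):
    """At the solved state, central finite differences of the Lagrangian
    in every variable block vanish, and a perturbation changes the value
    only at second order."""
    system = small_system(seed, n_env=5, tol=1e-11)
    state = solve_coupled(system)
    rng = np.random.default_rng(seed)
    base = lagrangian_value(state, system)
    for block in BLOCKS:
        obj = getattr(state, block)
        arr = obj if isinstance(obj, np.ndarray) else obj.data
        d = rng.normal(size=arr.shape)
        d /= np.linalg.norm(d)
        h = 1e-4
        lp = lagrangian_value(_perturb(state, block, h * d), system)
        lm = lagrangian_value(_perturb(state, block, -h * d), system)
        assert abs(lp - lm) / (2 * h) < 1e-6
        # quadratic behaviour: first-order change absent
        assert abs(lp - base) < 1e-6 * max(1.0, abs(base)) + 1e-5 * h


def test_energy_equals_lagrangian_at_solution():
    system = small_system(46, n_env=6, tol=1e-11)
    state = solve_coupled(system)
    bd = embedding_energy(state, system)
    assert bd.total == pytest.approx(lagrangian_value(state, system), abs=1e-9)
    parts = bd.static_env + bd.probe_env + bd.induced + bd.continuum + bd.coupling
    assert bd.total == pytest.approx(parts, abs=1e-12)


def test_degenerate_branches_coincide():
    system = small_system(47, n_env=5)
    state = solve_coupled(system)
    assert np.abs(state.mu_d - state.mu_p).max() < 1e-10
    assert np.abs(state.X_d.data - state.X_p.data).max() < 1e-10
    assert np.abs(state.S_d.data - state.S_p.data).max() < 1e-10


def test_distinct_branch_scalings_split_the_branches():
    rng = np.random.default_rng(48)
    env = make_env(rng, 5)
    probe = make_probe(rng)
    cfg = RunConfig(lmax=2, grid_order=26, tol=1e-10, d_scale=1.0, p_scale=0.6)
    system = EmbeddingSystem(env, probe, np.full(7, 2.6), cfg)
    state = solve_coupled(system)
    assert np.abs(state.mu_d - state.mu_p).max() > 1e-6


def test_decoupled_limit_is_bare_electrostatics():
    """No polarizable sites and f -> 0: all unknowns vanish and the
    energy is the plain fixed-multipole electrostatics."""
    rng = np.random.default_rng(49)
    env = make_env(rng, 5, pol=False)
    probe = make_probe(rng)
    cfg = RunConfig(lmax=2, grid_order=26, epsilon=1.0, tol=1e-10)
    system = EmbeddingSystem(env, probe, np.full(7, 2.6), cfg)
    state = solve_coupled(system)
    assert np.abs(state.mu_d).size == 0 or np.abs(state.mu_d).max() == 0.0
    assert np.abs(state.X_d.data).max() == 0.0
    bd = embedding_energy(state, system)
    expected = self_energy(env) + interaction_energy(probe, env)
    assert bd.total == pytest.approx(expected, rel=1e-12)


def test_warm_start_consistency():
    system = small_system(50, n_env=5, tol=1e-10)
    state1 = solve_coupled(system)
    e1 = embedding_energy(state1, system).total
    state2 = solve_coupled(system, guess=state1)
    e2 = embedding_energy(state2, system).total
    assert abs(e1 - e2) <= 10 * system.config.tol * max(1.0, abs(e1))
    assert state2.iterations["macro_d"] <= state1.iterations["macro_d"]


def test_variational_lowering():
    """With degenerate branches, the solved energy sits below the energy
    with dipoles and continuum frozen at zero."""
    for seed in range(60, 80):
        system = small_system(seed, n_env=4, lmax=2, tol=1e-9)
        state = solve_coupled(system)
        frozen = copy.deepcopy(state)
        frozen.mu_d[:] = 0.0
        frozen.mu_p[:] = 0.0
        for blk in ("X_d", "S_d", "X_p", "S_p"):
            getattr(frozen, blk).data[:] = 0.0
        assert (
            embedding_energy(state, system).total
            <= lagrangian_value(frozen, system) + 1e-12
        )


def test_size_extensivity():
    """Two copies 1000 bohr apart give twice the single-copy energy."""
    rng = np.random.default_rng(51)
    env = make_env(rng, 4, charges=False)  # neutral copies
    cfg = RunConfig(lmax=2, grid_order=26, tol=1e-11)
    radii = np.full(4, 2.6)
    one = EmbeddingSystem(env, None, radii, cfg)
    e1 = embedding_energy(solve_coupled(one), one).total
    env2 = MultipoleSet(
        np.vstack([env.positions, env.positions + np.array([1000.0, 0, 0])]),
        np.tile(env.q, 2),
        np.tile(env.mu, (2, 1)),
        np.tile(env.theta, (2, 1, 1)),
        np.tile(env.alpha, 2),
    )
    two = EmbeddingSystem(env2, None, np.tile(radii, 2), cfg)
    e2 = embedding_energy(solve_coupled(two), two).total
    assert e2 == pytest.approx(2 * e1, rel=1e-8)


def test_unsolved_state_is_refused():
    system = small_system(52, n_env=3)
    state = solve_coupled(system)
    state.solved = False
    with pytest.raises(StructuralError):
        embedding_energy(state, system)


def test_dimension_mismatch_is_refused():
    sys_a = small_system(53, n_env=3)
    sys_b = small_system(53, n_env=4)
    state = solve_coupled(sys_a)
    with pytest.raises(StructuralError):
        lagrangian_value(state, sys_b)
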