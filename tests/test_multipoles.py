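"""Fixed-multipole electrostatics and Thole damping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ddembed.errors import ModelParameterError, SingularGeometryError
from ddembed.multipoles import (
    MultipoleSet,
    interaction_energy,
    properties_direct,
    self_energy,
    thole_factors,
    thole_pair_tensor,
    traceless,
)


def _random_set(rng, n, box=6.0, scale=1.0, pol=False):
    pos = rng.normal(size=(n, 3)) * box / 2
    return MultipoleSet(
        pos,
        rng.normal(size=n) * scale,
        rng.normal(size=(n, 3)) * scale,
        traceless(rng.normal(size=(n, 3, 3)) * scale),
        np.abs(rng.normal(size=n)) + 0.3 if pol else np.zeros(n),
    )


def test_coulomb_closed_forms():
    charge = MultipoleSet([[0, 0, 0]], [1.0], None, None, [0.0])
    assert properties_direct(charge, [[3, 0, 0]], "V").V[0] == pytest.approx(1 / 3)
    dip = MultipoleSet([[0, 0, 0]], [0.0], [[0, 0, 1.0]], None, [0.0])
    fs = properties_direct(dip, [[0, 0, 2.0]], "VE")
    assert fs.V[0] == pytest.approx(0.25)
    assert fs.E[0, 2] == pytest.approx(0.25)


@pytest.mark.parametrize("damped", [False, True])
def test_derivative_ladder_consistency(damped):
    """G = grad E and H = grad G by central differences for bare and
    Thole-damped kernels; E = -grad V additionally for the bare kernel
    (the damped potential slot is deliberately bare: no energy term uses
    it, and the damped ladder is self-consistent from the field level)."""
    rng = np.random.default_rng(3)
    src = _random_set(rng, 5, pol=True)
    targets = rng.normal(size=(4, 3)) * 5
    kw = (
        {"damp_alpha_targets": np.abs(rng.normal(size=4)) + 0.4}
        if damped
        else {}
    )
    fs = properties_direct(src, targets, order="VEGH", **kw)
    h = 1e-5
    for a in range(3):
        e = np.zeros(3)
        e[a] = h
        fp = properties_direct(src, targets + e, order="VEG", **kw)
        fm = properties_direct(src, targets - e, order="VEG", **kw)
        if not damped:
            assert np.abs(-(fp.V - fm.V) / (2 * h) - fs.E[:, a]).max() < 1e-8
        assert np.abs((fp.E - fm.E) / (2 * h) - fs.G[:, :, a]).max() < 1e-8
        assert np.abs((fp.G - fm.G) / (2 * h) - fs.H[:, :, :, a]).max() < 1e-8


def test_interaction_energy_symmetry(rng):
    a = _random_set(rng, 3)
    b = _random_set(rng, 4)
    b.positions += 9.0
    assert interaction_energy(a, b) == pytest.approx(
        interaction_energy(b, a), abs=1e-12
    )


def test_traceless_gauge_invariance(rng):
    """Adding c*I to a quadrupole before detracing changes nothing."""
    th = np.asarray(rng.normal(size=(1, 3, 3)))
    th_shifted = th + 2.7 * np.eye(3)
    a = MultipoleSet([[0, 0, 0]], [0.0], None, traceless(th), [0.0])
    b = MultipoleSet([[0, 0, 0]], [0.0], None, traceless(th_shifted), [0.0])
    t = rng.normal(size=(3, 3)) * 4
    fa = properties_direct(a, t, "VEG")
    fb = properties_direct(b, t, "VEG")
    assert np.abs(fa.V - fb.V).max() < 1e-12
    assert np.abs(fa.G - fb.G).max() < 1e-12


def test_validation_and_singularities():
    with pytest.raises(ModelParameterError):
        MultipoleSet([[0, 0, 0]], [0.0], None, [np.eye(3)], [0.0])
    with pytest.raises(ModelParameterError):
        MultipoleSet([[0, 0, 0]], [0.0], None, None, [-0.1])
    with pytest.raises(ModelParameterError):
        MultipoleSet([[0, 0, 0]], [0.0], None, None, [1.0], role="probe")
    src = MultipoleSet([[0, 0, 0]], [1.0], None, None, [0.0])
    with pytest.raises(SingularGeometryError):
        properties_direct(src, [[0, 0, 0]], "V")
    # a masked coincident pair is allowed
    fs = properties_direct(src, [[0, 0, 0]], "V", mask=np.zeros((1, 1)))
    assert fs.V[0] == 0.0


def test_thole_tensor_limits_and_symmetry():
    far = thole_pair_tensor([0, 0, 0], [50.0, 0, 0], 1.0, 1.0)
    R = np.array([50.0, 0, 0])
    bare = 3 * np.outer(R, R) / 50.0**5 - np.eye(3) / 50.0**3
    assert np.abs(far - bare).max() < 1e-12 * np.abs(bare).max()
    zero = thole_pair_tensor([0, 0, 0], [0, 0, 0], 1.0, 1.0)
    assert np.all(np.isfinite(zero))
    t_ab = thole_pair_tensor([1, 2, 3], [0, 0, 1], 1.2, 0.8)
    t_ba = thole_pair_tensor([0, 0, 1], [1, 2, 3], 0.8, 1.2)
    assert np.abs(t_ab - t_ba.T).max() == 0.0


def test_thole_ladder_recursion():
    """lambda_{2n+3} follows from lambda_{2n+1} by the B-ladder
    derivative recursion B_{n+1} = -(1/r) dB_n/dr, so damped kernels
    stay exact derivatives of each other."""
    a = 0.39
    dfact = [1.0, 1.0, 3.0, 15.0, 105.0, 945.0]
    h = 1e-6

    def B(n, r):
        lam = thole_factors(a * np.asarray(r) ** 3, n)
        return dfact[n] * lam[n] / np.asarray(r) ** (2 * n + 1)

    for r in (0.5, 0.9, 1.4, 2.5):
        for n in range(1, 5):
            dB = (B(n, r + h) - B(n, r - h)) / (2 * h)
            assert -dB / r == pytest.approx(B(n + 1, r), rel=1e-6)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_self_energy_matches_pair_sum(seed):
    """Property: the set self-energy equals the explicit sum over pairs."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 6))
    mset = _random_set(rng, n, box=10.0)
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            a = MultipoleSet(
                mset.positions[[i]], mset.q[[i]], mset.mu[[i]], mset.theta[[i]], [0.0]
            )
            b = MultipoleSet(
                mset.positions[[j]], mset.q[[j]], mset.mu[[j]], mset.theta[[j]], [0.0]
            )
            total += interaction_energy(a, b)
    assert self_energy(mset) == pytest.approx(total, rel=1e-10, abs=1e-12)
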