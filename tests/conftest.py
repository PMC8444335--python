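"""Shared builders for small, well-separated test systems."""

import numpy as np
import pytest

from ddembed.config import RunConfig
from ddembed.coupled import EmbeddingSystem
from ddembed.local_frames import FrameDef, rotate_to_lab
from ddembed.multipoles import MultipoleSet, traceless


def random_positions(rng, n, box=8.0, min_sep=2.2):
    """Rejection-sampled positions with a minimum-separation guarantee."""
    pts = []
    while len(pts) < n:
        cand = rng.uniform(-box / 2, box / 2, size=3)
        if all(np.linalg.norm(cand - p) >= min_sep for p in pts):
            pts.append(cand)
    return np.array(pts)


def make_env(
    rng,
    n,
    charges=True,
    dipoles=True,
    quads=True,
    pol=True,
    frames=False,
    box=8.0,
    scale=0.3,
):
    pos = random_positions(rng, n, box=box)
    q = rng.normal(size=n) * scale if charges else np.zeros(n)
    mu_f = rng.normal(size=(n, 3)) * scale if dipoles else np.zeros((n, 3))
    th_f = (
        traceless(rng.normal(size=(n, 3, 3)) * scale * 0.6)
        if quads
        else np.zeros((n, 3, 3))
    )
    alpha = (
        np.where(rng.random(n) < 0.6, rng.uniform(0.5, 1.2, size=n), 0.0)
        if pol
        else np.zeros(n)
    )
    fdefs = [FrameDef("none")] * n
    if frames and n >= 3:
        keep = (lambda i: True) if frames == "all" else (lambda i: i % 2 == 0)
        fdefs = [
            FrameDef("z-then-x", (i + 1) % n, (i + 2) % n) if keep(i) else
            FrameDef("none")
            for i in range(n)
        ]
    mu = mu_f.copy()
    th = th_f.copy()
    for i, fd in enumerate(fdefs):
        if fd.rule != "none":
            mu[i], th[i] = rotate_to_lab(mu_f[i], th_f[i], fd, i, pos)
    return MultipoleSet(
        pos, q, mu, traceless(th), alpha,
        frame_defs=fdefs, mu_frame=mu_f, theta_frame=traceless(th_f),
    )


def make_probe(rng, offset=(7.0, 0.0, 0.0), n=2):
    pos = rng.uniform(-1.2, 1.2, size=(n, 3)) + np.asarray(offset)
    return MultipoleSet(
        pos,
        rng.normal(size=n) * 0.4,
        rng.normal(size=(n, 3)) * 0.2,
        traceless(rng.normal(size=(n, 3, 3)) * 0.1),
        np.zeros(n),
        role="probe",
    )


def small_system(
    seed,
    n_env=5,
    with_probe=True,
    lmax=3,
    grid_order=26,
    epsilon=15.0,
    tol=1e-10,
    frames=False,
    **env_kwargs,
):
    rng = np.random.default_rng(seed)
    env = make_env(rng, n_env, frames=frames, **env_kwargs)
    probe = make_probe(rng) if with_probe else None
    n_all = n_env + (probe.n_sites if probe is not None else 0)
    radii = rng.uniform(2.3, 2.9, size=n_all)
    cfg = RunConfig(lmax=lmax, grid_order=grid_order, epsilon=epsilon, tol=tol)
    return EmbeddingSystem(env, probe, radii, cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
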