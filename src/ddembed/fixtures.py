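"""Seeded synthetic-system generators.

Everything the tests and the acceptance checks consume is generated
here, as a pure function of the arguments and the seed: a Born sphere
with its closed-form expectation, random multipole clusters with
minimum-separation and valid-frame guarantees, and nested "shell"
families that emulate cropping a large polar environment at increasing
radii (the situation in which charged croppings make embedding
properties oscillate and an outer continuum damps them).

Shell fixtures use +-1 e charges on single sites to emulate charged
residues; there is no attempt to mimic real molecular geometry — the
phenomenon under study is the electrostatics of cropped, possibly
net-charged environments, not chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .config import RunConfig
from .coupled import EmbeddingSystem
from .ddcosmo import f_of_eps
from .errors import GenerationError
from .local_frames import FrameDef, rotate_to_lab
from .multipoles import MultipoleSet, traceless


@dataclass
class GeneratedSystem:
    """In-memory fixture: multipole sets, cavity radii and expectations."""

    env: MultipoleSet
    probe: Optional[MultipoleSet]
    cavity_radii: np.ndarray
    config: RunConfig
    expectation: dict = field(default_factory=dict)

    def system(self, **kwargs) -> EmbeddingSystem:
        return EmbeddingSystem(
            self.env, self.probe, self.cavity_radii, self.config, **kwargs
        )

    def write(self, directory, prefix="system"):
        from .io import write_system

        paths = write_system(
            directory, self.env, self.probe, self.cavity_radii, self.config, prefix
        )
        if self.expectation:
            import json
            from pathlib import Path

            p = Path(directory) / f"{prefix}.expect.json"
            p.write_text(json.dumps(self.expectation, indent=1) + "\n")
            return (*paths, p)
        return paths


def make_born(R: float = 2.0, q: float = 1.0, epsilon: float = np.inf,
              config: Optional[RunConfig] = None) -> GeneratedSystem:
    """Single sphere of radius R (bohr) with a central charge.

    The analytic continuum energy ``-f(eps) q^2 / (2R)`` is recorded in
    the expectation sidecar.
    """
    if R <= 0:
        raise GenerationError("Born radius must be positive")
    cfg = config or RunConfig(epsilon=epsilon)
    env = MultipoleSet(
        np.zeros((1, 3)), [q], None, None, [0.0], frame_defs=[FrameDef("none")],
        mu_frame=np.zeros((1, 3)), theta_frame=np.zeros((1, 3, 3)),
    )
    exp = {"continuum_energy": -f_of_eps(epsilon, cfg.f_scheme) * q * q / (2.0 * R)}
    return GeneratedSystem(env, None, np.array([R]), cfg, exp)


def _pack_positions(rng, n, box, min_sep, tries=2000):
    pts = []
    for _ in range(tries):
        cand = rng.uniform(-box / 2, box / 2, size=3)
        if all(np.linalg.norm(cand - p) >= min_sep for p in pts):
            pts.append(cand)
            if len(pts) == n:
                return np.array(pts)
    raise GenerationError(
        f"could not pack {n} sites with separation {min_sep} in box {box}"
    )


def _random_frames(rng, n, positions, frame_fraction=0.5):
    """Assign valid z-then-x / bisector frames to a fraction of sites."""
    fdefs = []
    for i in range(n):
        if n < 3 or rng.random() > frame_fraction:
            fdefs.append(FrameDef("none"))
            continue
        others = [j for j in range(n) if j != i]
        rng.shuffle(others)
        zn, xn = others[0], others[1]
        # reject nearly collinear frames
        vz = positions[zn] - positions[i]
        vx = positions[xn] - positions[i]
        cosang = abs(np.dot(vz, vx)) / (np.linalg.norm(vz) * np.linalg.norm(vx))
        if cosang > 0.95:
            fdefs.append(FrameDef("none"))
            continue
        rule = "z-then-x" if rng.random() < 0.7 else "bisector"
        fdefs.append(FrameDef(rule, zn, xn))
    return fdefs


def make_cluster(
    n: int,
    seed: int,
    multipole_orders: tuple = ("charge", "dipole", "quadrupole"),
    polarizable_fraction: float = 0.5,
    box: float = 12.0,
    min_sep: float = 2.0,
    with_probe: bool = False,
    charge_scale: float = 0.3,
    config: Optional[RunConfig] = None,
) -> GeneratedSystem:
    """Reproducible random cluster with a minimum-separation guarantee.

    ``multipole_orders`` selects which fixed moments are populated;
    polarizabilities are drawn for the requested fraction of sites.
    """
    if n < 1:
        raise GenerationError("cluster needs n >= 1")
    rng = np.random.default_rng(seed)
    cfg = config or RunConfig()
    pos = _pack_positions(rng, n, box, min_sep)
    q = rng.normal(size=n) * charge_scale if "charge" in multipole_orders else np.zeros(n)
    mu_f = (
        rng.normal(size=(n, 3)) * charge_scale
        if "dipole" in multipole_orders
        else np.zeros((n, 3))
    )
    th_f = (
        traceless(rng.normal(size=(n, 3, 3)) * charge_scale * 0.6)
        if "quadrupole" in multipole_orders
        else np.zeros((n, 3, 3))
    )
    alpha = np.where(
        rng.random(n) < polarizable_fraction, rng.uniform(0.5, 1.5, size=n), 0.0
    )
    fdefs = (
        _random_frames(rng, n, pos)
        if ("dipole" in multipole_orders or "quadrupole" in multipole_orders)
        else [FrameDef("none")] * n
    )
    mu = mu_f.copy()
    th = th_f.copy()
    for i, fd in enumerate(fdefs):
        if fd.rule != "none":
            mu[i], th[i] = rotate_to_lab(mu_f[i], th_f[i], fd, i, pos)
    env = MultipoleSet(
        pos, q, mu, traceless(th), alpha,
        frame_defs=fdefs, mu_frame=mu_f, theta_frame=traceless(th_f),
        thole=cfg.thole,
    )
    probe = None
    radii_env = rng.uniform(2.2, 3.0, size=n)
    radii = radii_env
    if with_probe:
        side = box / 2 + 5.0
        ppos = rng.uniform(-1.5, 1.5, size=(2, 3)) + np.array([side, 0.0, 0.0])
        probe = MultipoleSet(
            ppos, [0.4, -0.5], rng.normal(size=(2, 3)) * 0.2,
            traceless(rng.normal(size=(2, 3, 3)) * 0.1), np.zeros(2), role="probe",
        )
        radii = np.concatenate([rng.uniform(2.2, 3.0, size=2), radii_env])
    return GeneratedSystem(env, probe, radii, cfg)


def make_shell_system(
    core_charge: float = -1.0,
    shell_radii=None,
    charged_fraction: float = 0.25,
    seed: int = 71,
    n_env: int = 120,
    extent: float = 40.0,
    config: Optional[RunConfig] = None,
    neutral_cropping: bool = False,
) -> list:
    """Family of nested systems: one environment realization cropped at
    each radius (bohr), around a charged dipolar probe at the origin.

    The environment mixes neutral polar (dipole + polarizability) sites
    with +-1 e "ionic" sites; generic croppings may carry net charge.
    With ``neutral_cropping`` the returned radii are adjusted so every
    cropping is net neutral (ions are placed in near-radius pairs so
    such radii exist).  Returns a list of (radius, GeneratedSystem).
    """
    rng = np.random.default_rng(seed)
    cfg = config or RunConfig()
    if shell_radii is None:
        shell_radii = np.arange(10.0, extent + 1e-9, 3.0)
    shell_radii = np.asarray(shell_radii, dtype=float)
    if np.any(np.diff(shell_radii) <= 0):
        raise GenerationError("shell radii must be increasing")
    # probe: charged + dipolar core
    ppos = np.array([[0.0, 0.0, 0.0], [2.2, 0.0, 0.0]])
    probe = MultipoleSet(
        ppos, [core_charge, 0.0], np.array([[0.0, 0.0, 0.4], [0.3, 0.0, 0.0]]),
        None, np.zeros(2), role="probe",
    )
    # environment sites at radii 6..extent
    n_ion = int(round(charged_fraction * n_env))
    n_ion -= n_ion % 2  # pairs, so neutral radii exist
    pts = []
    tries = 0
    while len(pts) < n_env:
        tries += 1
        if tries > 200 * n_env:
            raise GenerationError("could not place the shell environment sites")
        cand = rng.uniform(-extent, extent, size=3)
        r = np.linalg.norm(cand)
        if not (6.0 <= r <= extent):
            continue
        if all(np.linalg.norm(cand - p) >= 2.5 for p in pts) and all(
            np.linalg.norm(cand - pp) >= 4.0 for pp in ppos
        ):
            pts.append(cand)
    pts = np.array(pts)
    order = np.argsort(np.linalg.norm(pts, axis=1))
    pts = pts[order]
    q = np.zeros(n_env)
    # ions at random radii, charges alternating outward: generic radial
    # croppings often cut after an odd ion count (net charge +-1), while
    # every even-count prefix is exactly neutral
    ion_slots = np.sort(rng.choice(n_env, size=n_ion, replace=False))
    q[ion_slots] = [1.0 if k % 2 == 0 else -1.0 for k in range(n_ion)]
    mu = rng.normal(size=(n_env, 3)) * 0.35
    alpha = rng.uniform(0.6, 1.2, size=n_env)
    radial = np.linalg.norm(pts, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(q)])
    out = []
    for R in shell_radii:
        m = int(np.sum(radial <= R))
        if neutral_cropping:
            # largest neutral prefix not exceeding the requested radius
            while m > 0 and abs(cum[m]) > 1e-9:
                m -= 1
        sel = slice(0, m)
        env = MultipoleSet(
            pts[sel], q[sel], mu[sel], None, alpha[sel], thole=cfg.thole
        )
        radii = np.concatenate([np.full(2, 3.0), np.full(m, 3.0)])
        out.append((float(R), GeneratedSystem(env, probe, radii, cfg)))
    return out
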