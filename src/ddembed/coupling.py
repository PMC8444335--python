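"""Operators coupling induced dipoles to the continuum.

* ``Xi``: potential of the induced dipoles projected on the cavity
  harmonics — evaluated as a two-step process (dipole potential at all
  exposed grid nodes, then the Phi quadrature), so the first step can be
  served by the tree accelerator and the matrix is never materialized.
* ``Xi^T``: the exact adjoint — pseudo-charges of S, then (minus) their
  electric field at the dipole sites.
* ``Omega``: Psi of the induced-dipole distribution (strictly local,
  l = 1 rows only) and its adjoint.

All four maps are linear, matrix-free, and satisfy the adjoint
identities ``<S, Xi mu> = <Xi^T S, mu>`` and ``<X, Omega mu> =
<Omega^T X, mu>`` to machine precision by construction.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .cavity import Cavity
from .ddcosmo import HarmonicCoeffs, assemble_Phi, pseudo_charges
from .errors import UnsupportedGeometryError
from .harmonics import HarmonicBasis, regular_gradient_ops
from .multipoles import MultipoleSet, properties_direct


def _dipole_rows(basis: HarmonicBasis) -> np.ndarray:
    """(3, 3) matrix mapping a dipole vector to unscaled l=1 Psi rows."""
    D = regular_gradient_ops(max(basis.lmax, 1))
    return D[:, 1:4, 0] / np.sqrt(4.0 * np.pi)  # [coord a, m-row]


def dipole_potential_at_nodes(
    mu: np.ndarray, positions: np.ndarray, cav: Cavity, accelerator=None
) -> np.ndarray:
    """Bare Coulomb potential of point dipoles at every exposed node."""
    n = len(positions)
    dip = MultipoleSet(positions, np.zeros(n), mu, None, np.zeros(n))
    pts = cav.node_positions().reshape(-1, 3)
    if accelerator is not None:
        V = accelerator.potential(dip, pts)
    else:
        V = properties_direct(dip, pts, order="V").V
    return V.reshape(cav.n_spheres, cav.n_nodes)


def apply_Xi(
    mu: np.ndarray,
    positions: np.ndarray,
    cav: Cavity,
    basis: HarmonicBasis,
    accelerator=None,
) -> HarmonicCoeffs:
    """Xi mu: quadrature projection of the dipole potential (as Phi)."""
    V = dipole_potential_at_nodes(np.atleast_2d(mu), positions, cav, accelerator)
    out = assemble_Phi(cav, V, basis)
    out.role = "generic"
    return out


def apply_Xi_adj(
    S: HarmonicCoeffs,
    positions: np.ndarray,
    cav: Cavity,
    basis: HarmonicBasis,
    accelerator=None,
) -> np.ndarray:
    """Xi^T S: per-dipole 3-vectors, d<S, Xi mu>/dmu.

    Two-step: pseudo-charges of S, then minus their field at the dipole
    sites (minus because the potential of a dipole at the nodes is the
    *negative* of the field of node charges contracted with the dipole).
    """
    pc = pseudo_charges(S, cav, basis)
    pos, xi = pc.flat()
    if len(xi) == 0:
        return np.zeros((len(positions), 3))
    charges = MultipoleSet(pos, xi, None, None, np.zeros(len(xi)))
    if accelerator is not None:
        E = accelerator.field(charges, np.atleast_2d(positions))
    else:
        E = properties_direct(charges, np.atleast_2d(positions), order="VE").E
    return -E


def apply_Omega(
    mu: np.ndarray,
    site_spheres: np.ndarray,
    cav: Cavity,
    basis: HarmonicBasis,
) -> HarmonicCoeffs:
    """Omega mu = Psi of the induced dipoles: l = 1 rows on their spheres."""
    mu = np.atleast_2d(np.asarray(mu, dtype=float))
    site_spheres = np.asarray(site_spheres, dtype=int)
    rows = _dipole_rows(basis)
    out = np.zeros((cav.n_spheres, basis.nbasis))
    if basis.lmax < 1:
        raise UnsupportedGeometryError("Omega requires lmax >= 1")
    out[site_spheres, 1:4] = np.einsum("na,am->nm", mu, rows) / cav.radii[
        site_spheres, None
    ]
    return HarmonicCoeffs(out, "generic")


def apply_Omega_adj(
    X: HarmonicCoeffs,
    site_spheres: np.ndarray,
    cav: Cavity,
    basis: HarmonicBasis,
) -> np.ndarray:
    """Omega^T X: per-dipole vectors c_k = <Psi(unit dipole k), X_i>."""
    site_spheres = np.asarray(site_spheres, dtype=int)
    rows = _dipole_rows(basis)
    return (
        np.einsum("nm,am->na", X.data[site_spheres, 1:4], rows)
        / cav.radii[site_spheres, None]
    )
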