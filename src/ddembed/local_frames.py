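"""Local-frame rotation of per-site multipoles and its derivatives.

Parameter-file dipoles and quadrupoles are stored in a molecular frame
defined by bonded neighbours; at run time they are rotated to the
laboratory frame, ``mu_lab = R mu_frame``, ``Theta_lab = R Theta R^T``.
Because the frame axes depend on atomic positions, the rotation
contributes position derivatives to the forces (the "rotation matrix"
terms); induced dipoles are lab-frame objects and never pass through
this module.

Supported rules:

* ``z-then-x`` — z axis towards the z neighbour, x axis the
  orthogonalized direction to the x neighbour;
* ``bisector`` — z axis along the bisector of the two neighbour
  directions, x axis orthogonalized towards the x neighbour;
* ``none`` — parameters are already lab-frame; all derivatives vanish.

Derivatives are exact: the axis construction is analytic in the
coordinates, and we differentiate it by the complex-step method
(imaginary perturbation 1e-200), which carries no truncation error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import FrameDefinitionError

_RULES = ("none", "z-then-x", "bisector")
_DEGEN_TOL = 1e-8


@dataclass(frozen=True)
class FrameDef:
    """Frame rule for one site; neighbour fields are site indices."""

    rule: str = "none"
    z_neighbor: Optional[int] = None
    x_neighbor: Optional[int] = None

    def __post_init__(self):
        if self.rule not in _RULES:
            raise FrameDefinitionError(
                f"unsupported frame rule {self.rule!r}; supported: {_RULES}"
            )
        if self.rule != "none" and (self.z_neighbor is None or self.x_neighbor is None):
            raise FrameDefinitionError(f"rule {self.rule!r} needs z and x neighbours")

    def involved(self, site: int) -> tuple:
        """Indices whose positions enter the rotation (empty for 'none')."""
        if self.rule == "none":
            return ()
        if site in (self.z_neighbor, self.x_neighbor):
            raise FrameDefinitionError(
                f"site {site}: frame neighbours must differ from the site"
            )
        return (site, self.z_neighbor, self.x_neighbor)


def _normalize(v):
    n = np.sqrt(np.sum(v * v))
    return v / n, n


def rotation_matrix(frame_def: FrameDef, site: int, positions: np.ndarray) -> np.ndarray:
    """Frame rotation matrix R (columns = lab components of local x, y, z)."""
    if frame_def.rule == "none":
        return np.eye(3, dtype=positions.dtype)
    p = positions[site]
    vz = positions[frame_def.z_neighbor] - p
    vx = positions[frame_def.x_neighbor] - p
    if frame_def.rule == "bisector":
        uz1, n1 = _normalize(vz)
        uz2, n2 = _normalize(vx)
        if min(abs(n1), abs(n2)) < _DEGEN_TOL:
            raise FrameDefinitionError(f"site {site}: coincident frame neighbour")
        vz = uz1 + uz2
    z, nz = _normalize(vz)
    if abs(nz) < _DEGEN_TOL:
        raise FrameDefinitionError(f"site {site}: degenerate z axis")
    x = vx - np.sum(vx * z) * z
    xn, nx = _normalize(x)
    if abs(nx) < _DEGEN_TOL:
        raise FrameDefinitionError(f"site {site}: x reference parallel to z axis")
    y = np.cross(z, xn)
    return np.stack([xn, y, z], axis=1)


def rotate_to_lab(
    mu_frame: np.ndarray,
    theta_frame: np.ndarray,
    frame_def: FrameDef,
    site: int,
    positions: np.ndarray,
):
    """Rotate one site's frame multipoles to the laboratory frame."""
    R = rotation_matrix(frame_def, site, np.asarray(positions, dtype=float))
    mu = R @ np.asarray(mu_frame, dtype=float)
    th = R @ np.asarray(theta_frame, dtype=float) @ R.T
    return mu, th


def frame_rotation_derivatives(
    mu_frame: np.ndarray,
    theta_frame: np.ndarray,
    frame_def: FrameDef,
    site: int,
    positions: np.ndarray,
):
    """Derivatives of the lab multipoles with respect to atomic positions.

    Returns ``{atom: (dmu, dtheta)}`` with ``dmu[a, k] = d mu_lab_a /
    d x_atom_k`` and ``dtheta[a, b, k]`` likewise, for each involved
    atom; uninvolved atoms are absent (their derivatives vanish).
    """
    involved = frame_def.involved(site)
    out = {}
    if not involved:
        return out
    positions = np.asarray(positions, dtype=float)
    rotation_matrix(frame_def, site, positions)  # validate geometry up front
    mu_f = np.asarray(mu_frame, dtype=float)
    th_f = np.asarray(theta_frame, dtype=float)
    h = 1e-200
    for atom in involved:
        dmu = np.zeros((3, 3))
        dth = np.zeros((3, 3, 3))
        for k in range(3):
            pc = positions.astype(complex)
            pc[atom, k] += 1j * h
            R = rotation_matrix(frame_def, site, pc)
            dR = R.imag / h
            Rr = R.real
            dmu[:, k] = dR @ mu_f
            dth[:, :, k] = dR @ th_f @ Rr.T + Rr @ th_f @ dR.T
        out[atom] = (dmu, dth)
    return out
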