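"""Solvent-accessible cavity: one sphere per atom, per-sphere angular
grids, and the smooth characteristic function U with its derivatives.

The switching function follows the regularized-COSMO construction: a
node of sphere i is weighted by ``U_in = prod_{k != i} (1 - c_k)`` where
``c_k`` measures penetration into sphere k through a quintic smoothstep
over a shell of relative width ``eta`` just inside the sphere surface
(``c = 1`` deeper than the shell, ``c = 0`` outside).  U is C^1 (in fact
C^2) in all sphere centers, which the force terms involving dU require.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .errors import DegenerateCavityError, InvalidCavityError
from .grids import unit_sphere_grid


def smoothstep(x):
    """Quintic smoothstep: 0 for x <= 0, 1 for x >= 1, C^2 everywhere."""
    x = np.clip(x, 0.0, 1.0)
    return x * x * x * (10.0 + x * (-15.0 + 6.0 * x))


def smoothstep_d(x):
    """Derivative of :func:`smoothstep`."""
    inside = (x > 0.0) & (x < 1.0)
    x = np.clip(x, 0.0, 1.0)
    return np.where(inside, 30.0 * x * x * (1.0 - x) ** 2, 0.0)


@dataclass
class Cavity:
    """Spheres, per-sphere quadrature nodes, and switching weights.

    ``U[i, n]`` is the exposure of node n of sphere i in [0, 1];
    ``W[i, n] = w[n] * U[i, n]`` are the exposed-point quadrature
    weights used in every surface contraction.
    """

    centers: np.ndarray
    radii: np.ndarray
    grid_order: int
    nodes: np.ndarray  # (g, 3) unit directions (possibly rotated)
    weights: np.ndarray  # (g,) summing to 4*pi
    U: np.ndarray  # (N, g)
    W: np.ndarray  # (N, g)
    eta: float
    neighbors: list = field(repr=False, default_factory=list)  # per-sphere index lists

    @property
    def n_spheres(self) -> int:
        return len(self.centers)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def node_positions(self, i: Optional[int] = None) -> np.ndarray:
        """Cartesian grid-node positions of sphere i (or all: (N, g, 3))."""
        if i is not None:
            return self.centers[i] + self.radii[i] * self.nodes
        return self.centers[:, None, :] + self.radii[:, None, None] * self.nodes


def build_cavity(
    positions: np.ndarray,
    radii: np.ndarray,
    probe: float = 0.0,
    grid_order: int = 110,
    eta: float = 0.1,
    orientation: Optional[np.ndarray] = None,
    grid: Optional[tuple] = None,
) -> Cavity:
    """Build the cavity: spheres of radius ``radii + probe`` with grids.

    ``orientation`` optionally rotates the canonical grid directions
    (used to make rigid-rotation tests exact); ``grid`` may supply an
    explicit ``(nodes, weights)`` rule overriding ``grid_order``.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    radii = np.broadcast_to(np.asarray(radii, dtype=float), (len(positions),)).copy()
    radii = radii + probe
    if np.any(radii <= 0):
        raise InvalidCavityError("all sphere radii must be positive")
    if not (0.0 < eta < 1.0):
        raise InvalidCavityError("switching width eta must be in (0, 1)")
    if grid is not None:
        nodes, weights = grid
        nodes = np.asarray(nodes, dtype=float)
        weights = np.asarray(weights, dtype=float)
    else:
        nodes, weights = unit_sphere_grid(grid_order)
    if orientation is not None:
        nodes = nodes @ np.asarray(orientation, dtype=float).T
    n = len(positions)
    # neighbour detection; also reject exactly coincident equal spheres
    if n > 1:
        tree = cKDTree(positions)
        pairs = tree.query_pairs(float(2.0 * radii.max()), output_type="ndarray")
    else:
        pairs = np.empty((0, 2), dtype=int)
    neighbors = [[] for _ in range(n)]
    for a, b in pairs:
        d = np.linalg.norm(positions[a] - positions[b])
        if d < 1e-12 and abs(radii[a] - radii[b]) < 1e-12:
            raise DegenerateCavityError(
                f"spheres {a} and {b} coincide with identical radii"
            )
        if d < radii[a] + radii[b]:
            neighbors[a].append(b)
            neighbors[b].append(a)
    cav = Cavity(
        centers=positions,
        radii=radii,
        grid_order=grid_order,
        nodes=nodes,
        weights=weights,
        U=np.ones((n, len(nodes))),
        W=np.zeros((n, len(nodes))),
        eta=eta,
        neighbors=neighbors,
    )
    for i in range(n):
        pts = cav.node_positions(i)
        for k in neighbors[i]:
            cav.U[i] *= 1.0 - _penetration(pts, positions[k], radii[k], eta)
    cav.W[:] = cav.U * weights[None, :]
    return cav


def _penetration(points, center, radius, eta):
    """c_k in [0, 1]: 1 deep inside sphere k, 0 outside, quintic in the shell."""
    d = np.linalg.norm(points - center, axis=-1)
    t = d / radius
    return 1.0 - smoothstep((t - 1.0 + eta) / eta)


def penetration_grad(points, center, radius, eta):
    """(c, dc/dcenter) for nodes vs one sphere; dc/dpoint = -dc/dcenter."""
    rel = points - center
    d = np.linalg.norm(rel, axis=-1)
    t = d / radius
    x = (t - 1.0 + eta) / eta
    c = 1.0 - smoothstep(x)
    fp = smoothstep_d(x) / (eta * radius)
    with np.errstate(invalid="ignore", divide="ignore"):
        dirn = np.where(d[..., None] > 0, rel / np.where(d[..., None] > 0, d[..., None], 1.0), 0.0)
    # dc/dcenter = -F'(x)/(eta r) * d|s-x|/dcenter = +F'/(eta r) * (s-x)/d
    dc_dcenter = fp[..., None] * dirn
    return c, dc_dcenter


def grad_U(cav: Cavity, i: int, n: int, k: int) -> np.ndarray:
    """dU_in / dx_k (3-vector); zero unless k is sphere i or a switching
    neighbour whose shell contains the node."""
    s = cav.node_positions(i)[n]
    total = np.zeros(3)
    for j in cav.neighbors[i]:
        c, dc_dc = penetration_grad(s[None], cav.centers[j], cav.radii[j], cav.eta)
        c = float(c[0])
        if c == 0.0:
            continue
        others = cav.U[i, n] / (1.0 - c) if c < 1.0 else _u_excluding(cav, i, n, j)
        # dU/dx = -(prod over others) * dc_j/dx; dc_j/dx_j = dc_dc,
        # and the node rides with sphere i so dc_j/dx_i = -dc_dc.
        if k == j:
            total += -others * dc_dc[0]
        elif k == i:
            total += others * dc_dc[0]
    return total


def _u_excluding(cav, i, n, j):
    s = cav.node_positions(i)[n]
    val = 1.0
    for m in cav.neighbors[i]:
        if m == j:
            continue
        c, _ = penetration_grad(s[None], cav.centers[m], cav.radii[m], cav.eta)
        val *= 1.0 - float(c[0])
    return val
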