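"""Quadrature rules on the unit sphere.

Two families are provided behind a single lookup:

* genuine Lebedev rules for the small octahedral orders whose nodes and
  weights have exact closed forms (6, 14, 26, 38, 50 points; polynomial
  exactness degrees 3, 5, 7, 9, 11);
* Gauss-Legendre (in cos theta) x uniform (in phi) product rules of
  arbitrary odd exactness degree.

The request keys 110, 194 and 302 are accepted for convenience and are
served by product rules of the matching exactness degree (17, 23, 29).
All weights are normalized so that they sum to the sphere surface 4*pi.
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigurationError

#: Orders accepted by :func:`unit_sphere_grid`.
SUPPORTED_ORDERS = (6, 14, 26, 38, 50, 110, 194, 302)

# exactness degree of the classical Lebedev rule with that point count
_DEGREE = {6: 3, 14: 5, 26: 7, 38: 9, 50: 11, 110: 17, 194: 23, 302: 29}


def _orbit_a1():
    return np.array(
        [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
        dtype=float,
    )


def _orbit_a2():
    s = 1.0 / np.sqrt(2.0)
    pts = []
    for i in range(3):
        for j in range(i + 1, 3):
            for si in (1, -1):
                for sj in (1, -1):
                    p = [0.0, 0.0, 0.0]
                    p[i] = si * s
                    p[j] = sj * s
                    pts.append(p)
    return np.array(pts)


def _orbit_a3():
    s = 1.0 / np.sqrt(3.0)
    return np.array(
        [[sx * s, sy * s, sz * s] for sx in (1, -1) for sy in (1, -1) for sz in (1, -1)]
    )


def _orbit_llm(l, m):
    pts = []
    for pos in range(3):  # slot holding m
        for sx in (1, -1):
            for sy in (1, -1):
                for sz in (1, -1):
                    p = [sx * l, sy * l, sz * l]
                    p[pos] = [sx, sy, sz][pos] * m
                    pts.append(p)
    return np.array(pts)


def _orbit_pq0(p, q):
    pts = []
    for perm in ((0, 1), (1, 0), (1, 2), (2, 1), (0, 2), (2, 0)):
        for sp in (1, -1):
            for sq in (1, -1):
                v = [0.0, 0.0, 0.0]
                v[perm[0]] = sp * p
                v[perm[1]] = sq * q
                pts.append(v)
    return np.array(pts)


def _lebedev(order):
    if order == 6:
        nodes = [_orbit_a1()]
        w = [np.full(6, 1.0 / 6.0)]
    elif order == 14:
        nodes = [_orbit_a1(), _orbit_a3()]
        w = [np.full(6, 1.0 / 15.0), np.full(8, 3.0 / 40.0)]
    elif order == 26:
        nodes = [_orbit_a1(), _orbit_a2(), _orbit_a3()]
        w = [np.full(6, 1.0 / 21.0), np.full(12, 4.0 / 105.0), np.full(8, 9.0 / 280.0)]
    elif order == 38:
        q = np.sqrt((1.0 - 1.0 / np.sqrt(3.0)) / 2.0)
        p = np.sqrt(1.0 - q * q)
        nodes = [_orbit_a1(), _orbit_a3(), _orbit_pq0(p, q)]
        w = [np.full(6, 1.0 / 105.0), np.full(8, 9.0 / 280.0), np.full(24, 1.0 / 35.0)]
    elif order == 50:
        l = 1.0 / np.sqrt(11.0)
        m = 3.0 / np.sqrt(11.0)
        nodes = [_orbit_a1(), _orbit_a2(), _orbit_a3(), _orbit_llm(l, m)]
        w = [
            np.full(6, 4.0 / 315.0),
            np.full(12, 64.0 / 2835.0),
            np.full(8, 27.0 / 1280.0),
            np.full(24, 14641.0 / 725760.0),
        ]
    else:  # pragma: no cover
        raise ConfigurationError(f"no closed-form Lebedev rule with {order} points")
    y = np.vstack(nodes)
    wt = 4.0 * np.pi * np.concatenate(w)
    return y, wt


def product_grid(degree: int):
    """Gauss-Legendre x uniform product rule exact to the given degree.

    Returns ``(nodes, weights)`` with nodes on the unit sphere and
    weights summing to 4*pi. Exact for all spherical harmonics of
    degree <= ``degree``.
    """
    if degree < 1:
        raise ConfigurationError("product grid degree must be >= 1")
    ntheta = (degree + 2) // 2  # GL with n points integrates degree 2n-1
    nphi = max(2 * ntheta, degree + 1)
    x, wx = np.polynomial.legendre.leggauss(ntheta)
    phi = 2.0 * np.pi * np.arange(nphi) / nphi
    st = np.sqrt(1.0 - x**2)
    nodes = np.empty((ntheta * nphi, 3))
    nodes[:, 0] = np.outer(st, np.cos(phi)).ravel()
    nodes[:, 1] = np.outer(st, np.sin(phi)).ravel()
    nodes[:, 2] = np.outer(x, np.ones(nphi)).ravel()
    weights = np.outer(wx, np.full(nphi, 2.0 * np.pi / nphi)).ravel()
    return nodes, weights


def unit_sphere_grid(order: int):
    """Return ``(nodes, weights)`` for a supported grid order.

    Orders 6..50 are served by closed-form Lebedev rules; 110, 194 and
    302 by product rules of the matching polynomial exactness degree.
    """
    if order not in SUPPORTED_ORDERS:
        raise ConfigurationError(
            f"unsupported grid order {order}; supported: {SUPPORTED_ORDERS}"
        )
    if order <= 50:
        return _lebedev(order)
    return product_grid(_DEGREE[order])


def grid_degree(order: int) -> int:
    """Polynomial exactness degree of the rule behind a supported order."""
    if order not in _DEGREE:
        raise ConfigurationError(f"unsupported grid order {order}")
    return _DEGREE[order]
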