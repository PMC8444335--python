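"""Real spherical harmonics and solid harmonics up to a configurable lmax.

Conventions (fixed once, used everywhere):

* real orthonormal harmonics, ``int_{S^2} Y_lm^2 dOmega = 1`` with the
  surface measure totalling 4*pi;
* no Condon-Shortley phase (the sectoral P_mm are taken positive);
* ordering ``(l, m)`` with ``m = -l..l``; flat index ``l*(l+1) + m``.

Evaluation is recurrence based (associated Legendre three-term recursion
reformulated so that every intermediate is a *polynomial* in x, y, z).
This serves three purposes: numerical stability to lmax = 16, direct
evaluation of regular solid harmonics ``R_lm(r) = |r|^l Y_lm(r/|r|)``
without special-casing the origin, and analyticity in each coordinate so
that complex-step differentiation is exact (used to pin the gradient
coupling matrices and as an independent oracle in the tests).

Gradients are *exact*: the gradient of a regular solid harmonic of
degree l is a fixed linear combination of the degree l-1 harmonics, and
the gradient of an irregular solid harmonic ``I_lm = Y_lm / r^{l+1}`` is
a fixed combination of degree l+1 irregular ones.  The (sparse, constant)
coefficient matrices are determined once per lmax by solving the exact
linear relation on a sample of points, with complex-step derivatives as
the right-hand side; the residual of the fit is at machine precision
because the relation is an identity, and it is verified by tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .errors import InvalidCavityError, NormalizationError

MAX_LMAX = 16


@dataclass(frozen=True)
class HarmonicBasis:
    """Real spherical-harmonic basis truncated at ``lmax``."""

    lmax: int

    def __post_init__(self):
        if not (0 <= int(self.lmax) <= MAX_LMAX):
            raise ValueError(f"lmax must be in [0, {MAX_LMAX}]")

    @property
    def nbasis(self) -> int:
        return (self.lmax + 1) ** 2

    def index(self, l: int, m: int) -> int:
        """Flat index of (l, m)."""
        if not (0 <= l <= self.lmax and -l <= m <= l):
            raise IndexError(f"(l={l}, m={m}) outside basis")
        return l * (l + 1) + m

    def l_of_index(self) -> np.ndarray:
        """Array of l values per flat index."""
        return np.repeat(np.arange(self.lmax + 1), 2 * np.arange(self.lmax + 1) + 1)


@lru_cache(maxsize=None)
def _norm_constants(lmax: int) -> np.ndarray:
    """N_lm such that Y_lm = N_lm * T_l|m| * (c_m | 1 | s_|m|)."""
    out = np.empty((lmax + 1) ** 2)
    for l in range(lmax + 1):
        for m in range(-l, l + 1):
            am = abs(m)
            ratio = math.factorial(l - am) / math.factorial(l + am)
            n = math.sqrt((2 * l + 1) / (4.0 * math.pi) * ratio)
            if m != 0:
                n *= math.sqrt(2.0)
            out[l * (l + 1) + m] = n
    return out


def regular_solid(points: np.ndarray, lmax: int) -> np.ndarray:
    """Regular solid harmonics ``R_lm(p) = |p|^l Y_lm(p/|p|)``.

    ``points``: (..., 3), real or complex (complex supports complex-step
    differentiation).  Returns shape (..., (lmax+1)^2).  Every entry is a
    polynomial in the coordinates; the origin is regular (R_00 = Y_00,
    higher l vanish).
    """
    points = np.asarray(points)
    x, y, z = points[..., 0], points[..., 1], points[..., 2]
    r2 = x * x + y * y + z * z
    nb = (lmax + 1) ** 2
    out = np.zeros(points.shape[:-1] + (nb,), dtype=points.dtype)

    # c_m = Re[(x+iy)^m], s_m = Im[(x+iy)^m] as polynomials
    c = [np.ones_like(x)]
    s = [np.zeros_like(x)]
    for m in range(1, lmax + 1):
        c.append(c[-1] * x - s[-1] * y)
        s.append(s[-1] * x + c[-2] * y)

    # T_lm = r^l P_l|m|(z/r) / (r sin)^|m|, polynomial recursion in l
    norms = _norm_constants(lmax)
    for m in range(lmax + 1):
        t_prev = None
        t = np.full_like(x, float(_double_factorial(2 * m - 1)))
        for l in range(m, lmax + 1):
            if m == 0:
                out[..., l * (l + 1)] = norms[l * (l + 1)] * t
            else:
                out[..., l * (l + 1) + m] = norms[l * (l + 1) + m] * t * c[m]
                out[..., l * (l + 1) - m] = norms[l * (l + 1) - m] * t * s[m]
            if l < lmax:
                if l == m:
                    t_next = (2 * l + 1) * z * t
                else:
                    t_next = ((2 * l + 1) * z * t - (l + m) * r2 * t_prev) / (
                        l + 1 - m
                    )
                t_prev, t = t, t_next
    return out


def _double_factorial(n: int) -> int:
    return math.prod(range(n, 0, -2)) if n > 0 else 1


def irregular_solid(points: np.ndarray, lmax: int) -> np.ndarray:
    """Irregular solid harmonics ``I_lm(p) = Y_lm(p/|p|) / |p|^{l+1}``."""
    points = np.asarray(points)
    r2 = np.sum(points * points, axis=-1)
    reg = regular_solid(points, lmax)
    lofi = np.repeat(np.arange(lmax + 1), 2 * np.arange(lmax + 1) + 1)
    # I_lm = R_lm / r^(2l+1)
    scale = np.power.outer(r2, -(lofi.astype(float)) - 0.5)
    return reg * scale


def eval_harmonics(direction: np.ndarray, basis: HarmonicBasis) -> np.ndarray:
    """Y_lm at unit directions; rejects non-unit input.

    ``direction`` may be a single 3-vector or an (n, 3) array.
    """
    d = np.asarray(direction, dtype=float)
    norms = np.sqrt(np.sum(d * d, axis=-1))
    if not np.allclose(norms, 1.0, rtol=0.0, atol=1e-12):
        raise NormalizationError("direction vectors must have unit norm (1e-12)")
    return regular_solid(d, basis.lmax)


def eval_solid_harmonics(
    point: np.ndarray, center: np.ndarray, radius: float, basis: HarmonicBasis
) -> np.ndarray:
    """Scaled regular solid harmonics ``(|r-c|/a)^l Y_lm((r-c)/|r-c|)``.

    These are the local-expansion basis functions of a sphere with
    center ``c`` and radius ``a``: a ddCOSMO local solution reads
    ``W(r) = sum_lm X_lm * eval_solid_harmonics(r, c, a)_lm``.
    """
    if radius <= 0:
        raise InvalidCavityError("sphere radius must be positive")
    p = np.asarray(point, dtype=float) - np.asarray(center, dtype=float)
    reg = regular_solid(p, basis.lmax)
    lofi = basis.l_of_index().astype(float)
    return reg * radius ** (-lofi)


@lru_cache(maxsize=None)
def regular_gradient_ops(lmax: int):
    """Constant matrices D[a] with ``grad_a R_lm = sum D[a][lm, l'm'] R_{l-1,m'}``.

    Returns a (3, nb, nb) array; row lm has support only on the l-1
    block.  Determined by least squares on random points with
    complex-step right-hand sides; the relation is exact, so the fit is
    at machine precision.
    """
    nb = (lmax + 1) ** 2
    rng = np.random.default_rng(20240 + lmax)
    npts = 4 * nb + 20
    pts = rng.normal(size=(npts, 3))
    vals = regular_solid(pts, lmax)
    h = 1e-200
    ops = np.zeros((3, nb, nb))
    for a in range(3):
        cpts = pts.astype(complex)
        cpts[:, a] += 1j * h
        dvals = regular_solid(cpts, lmax).imag / h
        for l in range(1, lmax + 1):
            rows = slice(l * l, (l + 1) * (l + 1))
            cols = slice((l - 1) * (l - 1), l * l)
            coef, *_ = np.linalg.lstsq(vals[:, cols], dvals[:, rows], rcond=None)
            ops[a, rows, cols] = coef.T
    return ops


@lru_cache(maxsize=None)
def irregular_gradient_ops(lmax: int):
    """Constant matrices E[a]: ``grad_a I_lm = sum E[a][lm, l'm'] I_{l+1,m'}``.

    Shape (3, (lmax+1)^2, (lmax+2)^2).
    """
    nb = (lmax + 1) ** 2
    nb1 = (lmax + 2) ** 2
    rng = np.random.default_rng(40960 + lmax)
    npts = 4 * nb1 + 20
    pts = rng.normal(size=(npts, 3))
    pts += np.sign(pts) * 0.3  # keep away from the origin
    vals1 = irregular_solid(pts, lmax + 1)
    h = 1e-200
    ops = np.zeros((3, nb, nb1))
    for a in range(3):
        cpts = pts.astype(complex)
        cpts[:, a] += 1j * h
        dvals = irregular_solid(cpts, lmax).imag / h
        for l in range(0, lmax + 1):
            rows = slice(l * l, (l + 1) * (l + 1))
            cols = slice((l + 1) * (l + 1), (l + 2) * (l + 2))
            coef, *_ = np.linalg.lstsq(vals1[:, cols], dvals[:, rows], rcond=None)
            ops[a, rows, cols] = coef.T
    return ops


def solid_harmonics_with_grad(
    point: np.ndarray, center: np.ndarray, radius: float, basis: HarmonicBasis
):
    """Values and point-gradients of :func:`eval_solid_harmonics`.

    Returns ``(vals, grads)`` with shapes (..., nb) and (..., nb, 3).
    """
    if radius <= 0:
        raise InvalidCavityError("sphere radius must be positive")
    p = np.asarray(point, dtype=float) - np.asarray(center, dtype=float)
    reg = regular_solid(p, basis.lmax)
    ops = regular_gradient_ops(basis.lmax)
    lofi = basis.l_of_index().astype(float)
    scale = radius ** (-lofi)
    vals = reg * scale
    grads = np.stack([reg @ ops[a].T for a in range(3)], axis=-1) * scale[:, None]
    return vals, grads
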