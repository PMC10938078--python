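"""Spherical harmonics, solid spherical harmonics, and Clebsch-Gordan machinery.

Everything downstream (surface fitting, the elastic solver, stress assembly)
is built on the complex *orthonormal* spherical harmonics ``Ynm(theta, phi)``
with the Condon-Shortley phase, ``theta`` the polar angle from +z in
``[0, pi]`` and ``phi`` the azimuth in ``[0, 2*pi)``::

    Y00 = 1/sqrt(4*pi),   Y10 = sqrt(3/(4*pi)) cos(theta),
    Y11 = -sqrt(3/(8*pi)) sin(theta) e^{i phi}, ...

Solid spherical harmonics come in a regular family ``Rnm = r**n * Ynm``
(finite at the origin) and an irregular family ``Inm = Ynm / r**(n+1)``
(decaying at infinity); both are harmonic away from their singular sets and
form the expansion basis of the Love/Trefftz displacement ansatz.

This module provides

* point evaluation of ``Ynm``, ``Rnm``, ``Inm`` and vectorized tables of all
  harmonics up to a truncation degree,
* a coefficient container :class:`SHCoeffs` with the conjugate-symmetry
  convention for real-valued functions,
* Clebsch-Gordan coefficients from Racah's closed-form sum in exact integer
  arithmetic (floating point enters only through the final square root),
* the linearization of a product of two spherical harmonics into single
  harmonics, and
* exact degree-lowering/raising expansions of the Cartesian derivatives of
  regular and irregular solid harmonics (the gradient of a degree-n solid
  harmonic is a vector of degree-(n-1), resp. degree-(n+1), solid harmonics).

Real-valued fields are represented throughout by complex coefficients
constrained by ``c[n,-m] == (-1)**m * conj(c[n,m])`` rather than by a real
basis, so the product-linearization and coupling formulas apply verbatim.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache

import numpy as np
from scipy import special as _sp

CONVENTION = "complex-orthonormal-condon-shortley"

__all__ = [
    "CONVENTION",
    "HarmonicIndex",
    "SHCoeffs",
    "num_coeffs",
    "flat_index",
    "index_arrays",
    "eval_ynm",
    "ynm_table",
    "eval_regular_ssh",
    "eval_irregular_ssh",
    "regular_ssh_table",
    "irregular_ssh_table",
    "clebsch_gordan",
    "linearize_sh_product",
    "cartesian_gradient_rssh",
    "cartesian_gradient_issh",
    "gradient_matrices_regular",
    "gradient_matrices_irregular",
]


# ----------------------------------------------------------------------------
# Indexing
# ----------------------------------------------------------------------------

@dataclass(frozen=True)
class HarmonicIndex:
    """Degree/order pair (n, m) with |m| <= n."""

    n: int
    m: int

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError(f"degree must be >= 0, got n={self.n}")
        if abs(self.m) > self.n:
            raise ValueError(f"order out of range: |m|={abs(self.m)} > n={self.n}")


def num_coeffs(N: int) -> int:
    """Number of (n, m) pairs with n <= N."""
    return (N + 1) ** 2


def flat_index(n, m):
    """Flat position of (n, m) in degree-major order: n**2 + n + m."""
    return n * n + n + m


@lru_cache(maxsize=64)
def index_arrays(N: int):
    """Arrays (ns, ms) listing all degrees/orders up to N in flat order."""
    ns = np.concatenate([np.full(2 * n + 1, n) for n in range(N + 1)])
    ms = np.concatenate([np.arange(-n, n + 1) for n in range(N + 1)])
    return ns, ms


# ----------------------------------------------------------------------------
# Spherical harmonics
# ----------------------------------------------------------------------------

def eval_ynm(n: int, m: int, theta, phi):
    """Orthonormal complex spherical harmonic Ynm (Condon-Shortley phase).

    ``theta`` is the polar angle from +z in [0, pi], ``phi`` the azimuth.
    Raises for |m| > n (domain error) rather than returning 0.
    """
    if abs(m) > n:
        raise ValueError(f"|m|={abs(m)} exceeds degree n={n}")
    return _sp.sph_harm_y(n, m, theta, phi)


def ynm_table(N: int, theta, phi):
    """All Ynm with n <= N at the given angles.

    Returns an array of shape ``broadcast(theta, phi).shape + (num_coeffs(N),)``
    in flat (degree-major) coefficient order.
    """
    ns, ms = index_arrays(N)
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    shape = np.broadcast_shapes(theta.shape, phi.shape)
    t = np.broadcast_to(theta, shape)[..., None]
    p = np.broadcast_to(phi, shape)[..., None]
    return _sp.sph_harm_y(ns, ms, t, p)


def _spherical_from_point(point):
    x, y, z = np.asarray(point, dtype=float)
    r = math.sqrt(x * x + y * y + z * z)
    if r == 0.0:
        return 0.0, 0.0, 0.0
    theta = math.acos(max(-1.0, min(1.0, z / r)))
    phi = math.atan2(y, x)
    return r, theta, phi


def eval_regular_ssh(n: int, m: int, point):
    """Regular solid harmonic Rnm = r**n * Ynm at a Cartesian point."""
    r, theta, phi = _spherical_from_point(point)
    if r == 0.0:
        return complex(1.0 / math.sqrt(4.0 * math.pi)) if n == 0 else 0.0j
    return (r ** n) * eval_ynm(n, m, theta, phi)


def eval_irregular_ssh(n: int, m: int, point):
    """Irregular solid harmonic Inm = Ynm / r**(n+1); singular at the origin."""
    r, theta, phi = _spherical_from_point(point)
    if r == 0.0:
        raise ZeroDivisionError("irregular solid harmonic is singular at r = 0")
    return eval_ynm(n, m, theta, phi) / r ** (n + 1)


def _rtp_from_points(points):
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    r = np.linalg.norm(pts, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ct = np.where(r > 0, pts[..., 2] / np.where(r > 0, r, 1.0), 1.0)
    theta = np.arccos(np.clip(ct, -1.0, 1.0))
    phi = np.arctan2(pts[..., 1], pts[..., 0])
    return r, theta, phi


def regular_ssh_table(N: int, points):
    """All Rnm (n <= N) at Cartesian points; shape (npoints, num_coeffs(N))."""
    r, theta, phi = _rtp_from_points(points)
    ns, _ = index_arrays(N)
    tab = ynm_table(N, theta, phi) * r[..., None] ** ns
    # r = 0: all n >= 1 terms vanish, Y00 remains
    zero = r == 0.0
    if np.any(zero):
        tab[zero] = 0.0
        tab[zero, 0] = 1.0 / math.sqrt(4.0 * math.pi)
    return tab


def irregular_ssh_table(N: int, points):
    """All Inm (n <= N) at Cartesian points; shape (npoints, num_coeffs(N))."""
    r, theta, phi = _rtp_from_points(points)
    if np.any(r == 0.0):
        raise ZeroDivisionError("irregular solid harmonic is singular at r = 0")
    ns, _ = index_arrays(N)
    return ynm_table(N, theta, phi) / r[..., None] ** (ns + 1)


# ----------------------------------------------------------------------------
# Coefficient container
# ----------------------------------------------------------------------------

@dataclass
class SHCoeffs:
    """Truncated spherical-harmonic expansion f = sum c[n,m] Ynm, n <= N.

    Coefficients are stored densely in flat degree-major order.  A real-valued
    f obeys the conjugate symmetry ``c[n,-m] == (-1)**m conj(c[n,m])``.
    """

    N: int
    data: np.ndarray = None
    convention: str = CONVENTION

    def __post_init__(self) -> None:
        if self.data is None:
            self.data = np.zeros(num_coeffs(self.N), dtype=complex)
        else:
            self.data = np.asarray(self.data, dtype=complex)
            if self.data.shape != (num_coeffs(self.N),):
                raise ValueError(
                    f"expected {num_coeffs(self.N)} coefficients for N={self.N}, "
                    f"got shape {self.data.shape}"
                )

    def __getitem__(self, nm) -> complex:
        n, m = nm
        HarmonicIndex(n, m)
        return complex(self.data[flat_index(n, m)])

    def __setitem__(self, nm, value) -> None:
        n, m = nm
        HarmonicIndex(n, m)
        if n > self.N:
            raise ValueError(f"degree n={n} exceeds truncation N={self.N}")
        self.data[flat_index(n, m)] = value

    def items(self):
        ns, ms = index_arrays(self.N)
        for n, m, c in zip(ns, ms, self.data):
            yield (int(n), int(m)), complex(c)

    def copy(self) -> "SHCoeffs":
        return SHCoeffs(self.N, self.data.copy(), self.convention)

    def padded(self, N: int) -> "SHCoeffs":
        """Same expansion embedded at a (weakly) larger truncation degree."""
        if N < self.N:
            raise ValueError("cannot pad to a smaller degree")
        out = SHCoeffs(N, convention=self.convention)
        out.data[: self.data.size] = self.data
        return out

    def max_realness_violation(self) -> float:
        """max |c[n,-m] - (-1)**m conj(c[n,m])| over all (n, m)."""
        worst = 0.0
        for n in range(self.N + 1):
            for m in range(0, n + 1):
                lhs = self.data[flat_index(n, -m)]
                rhs = (-1) ** m * np.conj(self.data[flat_index(n, m)])
                worst = max(worst, abs(lhs - rhs))
        return worst

    def is_real_function(self, tol: float = 1e-9) -> bool:
        scale = max(1.0, float(np.max(np.abs(self.data), initial=0.0)))
        return self.max_realness_violation() <= tol * scale

    def enforce_conjugate_symmetry(self) -> "SHCoeffs":
        """Project onto the conjugate-symmetric (real-function) subspace."""
        out = self.copy()
        for n in range(self.N + 1):
            out.data[flat_index(n, 0)] = out.data[flat_index(n, 0)].real
            for m in range(1, n + 1):
                cp = out.data[flat_index(n, m)]
                cm = out.data[flat_index(n, -m)]
                avg = 0.5 * (cp + (-1) ** m * np.conj(cm))
                out.data[flat_index(n, m)] = avg
                out.data[flat_index(n, -m)] = (-1) ** m * np.conj(avg)
        return out

    def evaluate(self, theta, phi):
        """Evaluate the expansion at angles; real part returned only by caller."""
        tab = ynm_table(self.N, theta, phi)
        return tab @ self.data


# ----------------------------------------------------------------------------
# Clebsch-Gordan coefficients (Racah's closed form, exact arithmetic)
# ----------------------------------------------------------------------------

def _fact(k: int) -> int:
    return math.factorial(k)


@lru_cache(maxsize=None)
def _cg_cached(l1, m1, l2, m2, L, M) -> float:
    # Racah's single-sum formula; every factorial is an exact integer and the
    # k-sum is accumulated as a Fraction, so cancellation is exact.  The only
    # floating-point step is the final square root.
    delta2 = Fraction(
        _fact(l1 + l2 - L) * _fact(l1 - l2 + L) * _fact(-l1 + l2 + L),
        _fact(l1 + l2 + L + 1),
    )
    pref2 = (
        Fraction(2 * L + 1)
        * delta2
        * _fact(L + M) * _fact(L - M)
        * _fact(l1 - m1) * _fact(l1 + m1)
        * _fact(l2 - m2) * _fact(l2 + m2)
    )
    kmin = max(0, l2 - L - m1, l1 - L + m2)
    kmax = min(l1 + l2 - L, l1 - m1, l2 + m2)
    ssum = Fraction(0)
    for k in range(kmin, kmax + 1):
        den = (
            _fact(k)
            * _fact(l1 + l2 - L - k)
            * _fact(l1 - m1 - k)
            * _fact(l2 + m2 - k)
            * _fact(L - l2 + m1 + k)
            * _fact(L - l1 - m2 + k)
        )
        ssum += Fraction((-1) ** k, den)
    if ssum == 0:
        return 0.0
    sign = 1.0 if ssum > 0 else -1.0
    return sign * math.sqrt(float(pref2 * ssum * ssum))


def clebsch_gordan(l1: int, m1: int, l2: int, m2: int, L: int, M: int) -> float:
    """Clebsch-Gordan coefficient <l1 m1; l2 m2 | L M>.

    Invalid couplings (M != m1 + m2, L outside the triangle |l1-l2|..l1+l2,
    or out-of-range orders) return 0.0 rather than raising.
    """
    for l, m in ((l1, m1), (l2, m2), (L, M)):
        if l < 0 or abs(m) > l:
            return 0.0
    if M != m1 + m2 or L < abs(l1 - l2) or L > l1 + l2:
        return 0.0
    return _cg_cached(l1, m1, l2, m2, L, M)


@lru_cache(maxsize=None)
def linearize_sh_product(l1: int, m1: int, l2: int, m2: int):
    """Expand the product Y[l1,m1] * Y[l2,m2] in single harmonics.

    Returns a tuple of ``(L, M, coeff)`` with real coefficients::

        Y[l1,m1] Y[l2,m2] = sum_L  coeff(L) * Y[L, m1+m2],

        coeff(L) = sqrt((2 l1 + 1)(2 l2 + 1) / (4 pi (2 L + 1)))
                   * <l1 0; l2 0 | L 0> * <l1 m1; l2 m2 | L, m1+m2>.

    Only L of the same parity as l1 + l2 contribute (the parity CG vanishes
    otherwise); zero terms are dropped.
    """
    HarmonicIndex(l1, m1)
    HarmonicIndex(l2, m2)
    M = m1 + m2
    out = []
    for L in range(abs(l1 - l2), l1 + l2 + 1):
        if abs(M) > L:
            continue
        c0 = clebsch_gordan(l1, 0, l2, 0, L, 0)
        if c0 == 0.0:
            continue
        cm = clebsch_gordan(l1, m1, l2, m2, L, M)
        if cm == 0.0:
            continue
        pref = math.sqrt(
            (2 * l1 + 1) * (2 * l2 + 1) / (4.0 * math.pi * (2 * L + 1))
        )
        out.append((L, M, pref * c0 * cm))
    return tuple(out)


# ----------------------------------------------------------------------------
# Cartesian derivatives of solid harmonics
# ----------------------------------------------------------------------------
#
# With the ladder operators d+ = dx + i dy, d- = dx - i dy one has, for the
# regular family Rnm = r**n Ynm (orthonormal Y, Condon-Shortley phase):
#
#   dz Rnm =      sqrt((2n+1)/(2n-1) (n-m)(n+m))     R[n-1, m]
#   d+ Rnm =      sqrt((2n+1)/(2n-1) (n-m)(n-m-1))   R[n-1, m+1]
#   d- Rnm =    - sqrt((2n+1)/(2n-1) (n+m)(n+m-1))   R[n-1, m-1]
#
# and for the irregular family Inm = Ynm / r**(n+1):
#
#   dz Inm =    - sqrt((2n+1)/(2n+3) (n-m+1)(n+m+1)) I[n+1, m]
#   d+ Inm =      sqrt((2n+1)/(2n+3) (n+m+1)(n+m+2)) I[n+1, m+1]
#   d- Inm =    - sqrt((2n+1)/(2n+3) (n-m+1)(n-m+2)) I[n+1, m-1]
#
# These are verified against central finite differences in the test suite.

@lru_cache(maxsize=None)
def cartesian_gradient_rssh(n: int, m: int):
    """(d/dx, d/dy, d/dz) of Rnm as degree-(n-1) regular solid harmonics.

    Returns a dict ``{"x": [...], "y": [...], "z": [...]}`` whose entries are
    lists of ``(n-1, mu, coeff)`` with complex ``coeff``.  ``n = 0`` returns
    empty lists (the gradient of a constant vanishes).
    """
    HarmonicIndex(n, m)
    out = {"x": [], "y": [], "z": []}
    if n == 0:
        return out
    f = (2 * n + 1) / (2 * n - 1)
    cz = math.sqrt(f * (n - m) * (n + m))
    cp = math.sqrt(f * (n - m) * (n - m - 1)) if n - m >= 2 else 0.0
    cm = -math.sqrt(f * (n + m) * (n + m - 1)) if n + m >= 2 else 0.0
    if cz:
        out["z"].append((n - 1, m, complex(cz)))
    # dx = (d+ + d-)/2,  dy = (d+ - d-)/(2i)
    if cp:
        out["x"].append((n - 1, m + 1, cp / 2.0 + 0.0j))
        out["y"].append((n - 1, m + 1, cp / 2.0j))
    if cm:
        out["x"].append((n - 1, m - 1, cm / 2.0 + 0.0j))
        out["y"].append((n - 1, m - 1, -cm / 2.0j))
    return out


@lru_cache(maxsize=None)
def cartesian_gradient_issh(n: int, m: int):
    """(d/dx, d/dy, d/dz) of Inm as degree-(n+1) irregular solid harmonics."""
    HarmonicIndex(n, m)
    f = (2 * n + 1) / (2 * n + 3)
    cz = -math.sqrt(f * (n - m + 1) * (n + m + 1))
    cp = math.sqrt(f * (n + m + 1) * (n + m + 2))
    cm = -math.sqrt(f * (n - m + 1) * (n - m + 2))
    out = {"x": [], "y": [], "z": []}
    if cz:
        out["z"].append((n + 1, m, complex(cz)))
    if cp:
        out["x"].append((n + 1, m + 1, cp / 2.0 + 0.0j))
        out["y"].append((n + 1, m + 1, cp / 2.0j))
    if cm:
        out["x"].append((n + 1, m - 1, cm / 2.0 + 0.0j))
        out["y"].append((n + 1, m - 1, -cm / 2.0j))
    return out


@lru_cache(maxsize=32)
def gradient_matrices_regular(N: int):
    """Sparse-as-dense derivative operators on regular solid-harmonic vectors.

    Returns ``(Gx, Gy, Gz)`` of shape ``(num_coeffs(N-1), num_coeffs(N))``
    (for N = 0: zero rows) acting on flat coefficient vectors ``b`` of
    ``f = sum b Rnm``:  ``df/dx = sum (Gx b) R[n-1, mu]`` etc.
    """
    rows = num_coeffs(N - 1) if N >= 1 else 0
    cols = num_coeffs(N)
    G = {ax: np.zeros((rows, cols), dtype=complex) for ax in "xyz"}
    ns, ms = index_arrays(N)
    for n, m in zip(ns, ms):
        if n == 0:
            continue
        terms = cartesian_gradient_rssh(int(n), int(m))
        col = flat_index(n, m)
        for ax in "xyz":
            for (n1, mu, coeff) in terms[ax]:
                G[ax][flat_index(n1, mu), col] += coeff
    return G["x"], G["y"], G["z"]


@lru_cache(maxsize=32)
def gradient_matrices_irregular(N: int):
    """Derivative operators on irregular solid-harmonic coefficient vectors.

    Shapes ``(num_coeffs(N+1), num_coeffs(N))``; same contract as the regular
    version but degree-raising.
    """
    rows = num_coeffs(N + 1)
    cols = num_coeffs(N)
    G = {ax: np.zeros((rows, cols), dtype=complex) for ax in "xyz"}
    ns, ms = index_arrays(N)
    for n, m in zip(ns, ms):
        terms = cartesian_gradient_issh(int(n), int(m))
        col = flat_index(n, m)
        for ax in "xyz":
            for (n1, mu, coeff) in terms[ax]:
                G[ax][flat_index(n1, mu), col] += coeff
    return G["x"], G["y"], G["z"]
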