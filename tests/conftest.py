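"""Shared fixtures and helpers for the test suite.

Random boundary geometries, solved beads, and finite-difference scalar
Laplacians are used across several modules; they live here so that each test
file stays focused on the property it checks.
"""

import math

import numpy as np
import pytest

from beadstress.harmonics import SHCoeffs
from beadstress.solver import ElasticSolution, Material, solve
from beadstress.surface import BeadGeometry


def random_displacement_coeffs(
    N: int, rng, amplitude: float = 0.05, d00: float = 0.05, include_degree1: bool = False
) -> SHCoeffs:
    """Conjugate-symmetric boundary coefficients with 1/n**2 decay."""
    d = SHCoeffs(N)
    d[(0, 0)] = d00 * math.sqrt(4.0 * math.pi)
    n_start = 1 if include_degree1 else 2
    for n in range(n_start, N + 1):
        sd = amplitude / n**2
        d[(n, 0)] = rng.normal(0.0, sd)
        for m in range(1, n + 1):
            v = (rng.normal(0.0, sd) + 1j * rng.normal(0.0, sd)) / math.sqrt(2.0)
            d[(n, m)] = v
            d[(n, -m)] = (-1) ** m * np.conj(v)
    return d


def random_geometry(N: int, rng, r0: float = 1.0, **kw) -> BeadGeometry:
    return BeadGeometry(r0, random_displacement_coeffs(N, rng, **kw))


def random_solution(N: int, rng, material: Material | None = None, r0: float = 1.0, **kw) -> ElasticSolution:
    if material is None:
        material = Material(720.0, 0.45)
    return solve(random_geometry(N, rng, r0=r0, **kw), material)


def random_interior_points(rng, n: int, r0: float = 1.0, rmin: float = 0.1, rmax: float = 0.85):
    """Points strictly inside the bead, away from the origin and interface."""
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v * (rng.uniform(rmin, rmax, n) * r0)[:, None]


def random_exterior_points(rng, n: int, r0: float = 1.0, rmin: float = 1.2, rmax: float = 3.0):
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return v * (rng.uniform(rmin, rmax, n) * r0)[:, None]


def fd_laplacian(f, point, h: float):
    """Central 7-point finite-difference Laplacian of a scalar callable."""
    p = np.asarray(point, dtype=float)
    total = -6.0 * f(p)
    for i in range(3):
        e = np.zeros(3)
        e[i] = h
        total += f(p + e) + f(p - e)
    return total / h**2


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def material():
    """Material parameters of the experimental polyacrylamide beads."""
    return Material(720.0, 0.491)
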