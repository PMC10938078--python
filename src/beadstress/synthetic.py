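"""Synthetic bead surfaces emulating microscopy-derived point clouds.

Real inputs to the pipeline are scattered surface points of a deformed
hydrogel bead segmented from light-sheet or confocal stacks.  The generator
reproduces their essential features -- a smooth star-shaped surface given by
a truncated spherical-harmonic radius function, a few thousand points spread
area-uniformly over the sphere, small isotropic localization noise -- so
that every pipeline stage can be exercised end to end without any external
data.  It does not simulate image formation (point-spread function,
voxelization, segmentation artifacts).

Random shapes decay as 1/n**2 in degree, mimicking the smooth surfaces that
beads embedded in tissue exhibit, and keep the relative deformation within
the linear-elastic regime (relative amplitude <= 0.3; experimentally
observed normal strains reach about 0.2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .harmonics import SHCoeffs
from .surface import PointCloud, ShapeExpansion, SQRT4PI

__all__ = [
    "SyntheticSpec",
    "make_sphere_shape",
    "make_uniaxial_shape",
    "make_random_shape",
    "sample_surface_points",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic bead observation.

    ``r0`` initial radius [length]; ``N`` truncation degree of the shape;
    ``amplitude`` relative coefficient scale (<= 0.3 for linear-theory
    validity); ``npoints`` surface samples (>= (2N+1)**2 so that order
    selection can reach the interpolation regime); ``noise_sd`` isotropic
    3D localization noise [length]; ``seed`` for reproducibility.
    """

    r0: float = 1.0
    N: int = 5
    amplitude: float = 0.1
    npoints: int = 3000
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.r0 <= 0:
            raise ValueError("r0 must be positive")
        if not 0.0 <= self.amplitude <= 0.3:
            raise ValueError(
                "relative amplitude must lie in [0, 0.3] (linear-theory regime)"
            )
        if self.npoints < (2 * self.N + 1) ** 2:
            raise ValueError(
                f"npoints={self.npoints} < (2N+1)**2={(2*self.N+1)**2}: too few "
                "points to resolve the shape and select the order"
            )


def make_sphere_shape(r1: float) -> ShapeExpansion:
    """Shape of an exactly spherical (possibly shrunk/dilated) bead."""
    if r1 <= 0:
        raise ValueError("radius must be positive")
    c = SHCoeffs(0)
    c[(0, 0)] = SQRT4PI * r1
    return ShapeExpansion(c)


def make_uniaxial_shape(r0: float, d20: float) -> ShapeExpansion:
    """Uniaxially deformed bead: s = sqrt(4 pi) r0 Y00 + d20 Y20.

    The m = 0 quadrupole deforms the sphere along the z axis only, the
    classic test case with a phi-independent stress pattern.
    """
    if abs(d20) >= r0:
        raise ValueError("|d20| must be smaller than r0 for a positive surface")
    c = SHCoeffs(2)
    c[(0, 0)] = SQRT4PI * r0
    c[(2, 0)] = d20
    return ShapeExpansion(c)


def make_random_shape(spec: SyntheticSpec) -> ShapeExpansion:
    """Random smooth star-shaped surface around radius r0.

    Degree-n coefficients (2 <= n <= N) are drawn conjugate-symmetric with
    standard deviation ``amplitude * r0 / n**2``; degree 1 is left at zero so
    no rigid translation leaks into the displacement.
    """
    rng = np.random.default_rng(spec.seed)
    c = SHCoeffs(max(spec.N, 1))
    c[(0, 0)] = SQRT4PI * spec.r0
    for n in range(2, spec.N + 1):
        sd = spec.amplitude * spec.r0 / n**2
        c[(n, 0)] = rng.normal(0.0, sd)
        for m in range(1, n + 1):
            v = (rng.normal(0.0, sd) + 1j * rng.normal(0.0, sd)) / math.sqrt(2.0)
            c[(n, m)] = v
            c[(n, -m)] = (-1) ** m * np.conj(v)
    return ShapeExpansion(c)


def sample_surface_points(
    shape: ShapeExpansion, npoints: int, noise_sd: float = 0.0, seed: int = 0
) -> PointCloud:
    """Sample the surface at area-uniform random angles plus isotropic noise.

    cos(theta) is uniform on [-1, 1] and phi uniform on [0, 2 pi), matching
    scattered microscopy points rather than a regular grid (and thereby
    exercising the least-squares conditioning).  The returned cloud keeps the
    generating origin as its center.
    """
    rng = np.random.default_rng(seed)
    ct = rng.uniform(-1.0, 1.0, npoints)
    theta = np.arccos(ct)
    phi = rng.uniform(0.0, 2.0 * math.pi, npoints)
    r = shape.radius(theta, phi)
    if np.min(r) <= 0:
        raise ValueError("shape radius is non-positive; cannot sample surface")
    st = np.sin(theta)
    pts = np.column_stack([r * st * np.cos(phi), r * st * np.sin(phi), r * ct])
    if noise_sd > 0.0:
        pts = pts + rng.normal(0.0, noise_sd, pts.shape)
    return PointCloud(pts, center=np.zeros(3))
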