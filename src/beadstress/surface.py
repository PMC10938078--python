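"""From measured surface points to a spherical-harmonic shape model.

A deformed bead surface observed by microscopy arrives as a scattered 3D
point cloud.  Provided the surface is star-shaped about the chosen center it
is fully described by a radius function ``s(theta, phi)`` which we expand in
orthonormal spherical harmonics,

    s(theta, phi) = sum_{n<=N} sum_m s_nm Ynm(theta, phi),

by linear least squares on the measured radii (a scattered-data replacement
for the projection integral that a continuum surface would allow).  The
initial, undeformed bead is reconstructed as the sphere enclosing the same
volume as the fitted surface (the bead material is treated as incompressible
for this step only), and the radial surface displacement follows as the
coefficient-wise difference between the initial sphere and the fit:

    d_00 = sqrt(4 pi) r0 - s_00,     d_nm = -s_nm  (n >= 1)

which encodes the boundary displacement u|_{r0} = (r0 - s) e_r.  Note this
printed sign convention makes the displacement point from the *deformed*
surface back to the initial sphere; pass ``sign="flipped"`` to
:func:`displacement_coeffs` for the initial-to-deformed direction (which
flips the sign of every stress component downstream).
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.polynomial.legendre import leggauss

from .harmonics import (
    SHCoeffs,
    flat_index,
    index_arrays,
    num_coeffs,
    ynm_table,
)

__all__ = [
    "PointCloud",
    "ShapeExpansion",
    "BeadGeometry",
    "PointCloudError",
    "ConditioningError",
    "read_point_cloud",
    "fit_shape",
    "select_order",
    "OrderSelection",
    "enclosed_volume",
    "initial_radius",
    "displacement_coeffs",
    "recenter",
]

SQRT4PI = math.sqrt(4.0 * math.pi)

#: fraction of r0 above which linear elasticity becomes questionable
LINEAR_THEORY_WARN = 0.3


class PointCloudError(ValueError):
    """Malformed or insufficient surface point data."""


class ConditioningError(RuntimeError):
    """The least-squares fit is rank deficient / ill conditioned."""


# ----------------------------------------------------------------------------
# Data containers
# ----------------------------------------------------------------------------

@dataclass
class PointCloud:
    """Scattered surface points with the expansion origin.

    ``points`` is (npoints, 3) in the input length units (e.g. um); ``center``
    is the origin about which the star-shaped radius function is taken and
    defaults to the centroid of the points.
    """

    points: np.ndarray
    center: np.ndarray = None

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise PointCloudError(
                f"points must be (npoints, 3), got {self.points.shape}"
            )
        if self.center is None:
            self.center = self.points.mean(axis=0)
        self.center = np.asarray(self.center, dtype=float).reshape(3)

    def __len__(self) -> int:
        return self.points.shape[0]

    def spherical(self):
        """(r, theta, phi) of every point about ``center``."""
        rel = self.points - self.center
        r = np.linalg.norm(rel, axis=1)
        if np.any(r == 0.0):
            raise PointCloudError("a point coincides with the expansion center")
        theta = np.arccos(np.clip(rel[:, 2] / r, -1.0, 1.0))
        phi = np.mod(np.arctan2(rel[:, 1], rel[:, 0]), 2.0 * math.pi)
        return r, theta, phi

    def shifted(self, new_center) -> "PointCloud":
        return PointCloud(self.points, np.asarray(new_center, dtype=float))


@dataclass
class ShapeExpansion:
    """Spherical-harmonic model of the deformed surface radius s(theta, phi)."""

    coeffs: SHCoeffs
    rms_residual: float = 0.0
    max_residual: float = 0.0
    condition_number: float = 1.0

    @property
    def N(self) -> int:
        return self.coeffs.N

    def __getitem__(self, nm) -> complex:
        return self.coeffs[nm]

    def radius(self, theta, phi):
        """Evaluate s(theta, phi); raises if the surface is not positive."""
        vals = self.coeffs.evaluate(theta, phi)
        out = np.real(vals)
        return out

    def check_positive(self, ngrid: int = 50) -> None:
        th = np.linspace(1e-3, math.pi - 1e-3, ngrid)
        ph = np.linspace(0.0, 2.0 * math.pi, ngrid, endpoint=False)
        T, P = np.meshgrid(th, ph, indexing="ij")
        if np.min(self.radius(T, P)) <= 0.0:
            raise ValueError(
                "shape expansion takes non-positive radii: surface is not "
                "star-shaped about the chosen center"
            )


@dataclass
class BeadGeometry:
    """Initial sphere radius and radial-displacement boundary coefficients."""

    r0: float
    d: SHCoeffs

    def __post_init__(self) -> None:
        if self.r0 <= 0.0:
            raise ValueError(f"initial radius must be positive, got {self.r0}")
        if abs(self.d[(0, 0)].imag) > 1e-9 * max(1.0, abs(self.d[(0, 0)])):
            raise ValueError("monopole displacement coefficient must be real")

    def max_relative_displacement(self, ngrid: int = 40) -> float:
        th = np.linspace(1e-3, math.pi - 1e-3, ngrid)
        ph = np.linspace(0.0, 2.0 * math.pi, ngrid, endpoint=False)
        T, P = np.meshgrid(th, ph, indexing="ij")
        vals = np.real(self.d.evaluate(T, P))
        return float(np.max(np.abs(vals)) / self.r0)


# ----------------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------------

def read_point_cloud(source, format: str | None = None) -> PointCloud:
    """Load surface points from CSV (one ``x,y,z`` row per point) or PLY.

    The CSV dialect accepts an optional non-numeric header row; any other
    malformed row raises :class:`PointCloudError` naming the line.  PLY files
    are read through :mod:`trimesh` (vertices only).  The expansion center
    defaults to the centroid.
    """
    path = Path(source)
    if format is None:
        format = "ply" if path.suffix.lower() == ".ply" else "csv"
    if format == "ply":
        import trimesh  # optional dependency, only needed for PLY input

        mesh = trimesh.load(path, process=False)
        pts = np.asarray(mesh.vertices, dtype=float)
    elif format == "csv":
        pts = _read_csv_points(path)
    else:
        raise ValueError(f"unknown point-cloud format: {format!r}")
    if pts.shape[0] < 4:
        raise PointCloudError(
            f"need at least 4 surface points, got {pts.shape[0]}"
        )
    return PointCloud(pts)


def _read_csv_points(path: Path) -> np.ndarray:
    rows = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader, start=1):
            row = [c for c in row if c.strip() != ""]
            if not row:
                continue
            try:
                vals = [float(c) for c in row]
            except ValueError:
                if lineno == 1:  # header row
                    continue
                raise PointCloudError(
                    f"{path}: line {lineno}: non-numeric entry in {row!r}"
                ) from None
            if len(vals) != 3:
                raise PointCloudError(
                    f"{path}: line {lineno}: expected 3 columns (x,y,z), "
                    f"got {len(vals)}"
                )
            rows.append(vals)
    return np.asarray(rows, dtype=float).reshape(-1, 3)


# ----------------------------------------------------------------------------
# Fitting
# ----------------------------------------------------------------------------

def _real_design_matrix(N: int, theta, phi):
    """Real re-parameterization of a conjugate-symmetric expansion.

    Columns: for each n, the m = 0 harmonic (real), then for m = 1..n the
    pair (2 Re Ynm, -2 Im Ynm) multiplying (Re s_nm, Im s_nm).
    """
    tab = ynm_table(N, theta, phi)
    cols = []
    for n in range(N + 1):
        cols.append(tab[:, flat_index(n, 0)].real)
        for m in range(1, n + 1):
            y = tab[:, flat_index(n, m)]
            cols.append(2.0 * y.real)
            cols.append(-2.0 * y.imag)
    return np.column_stack(cols)


def _coeffs_from_real_params(N: int, params) -> SHCoeffs:
    c = SHCoeffs(N)
    k = 0
    for n in range(N + 1):
        c[(n, 0)] = params[k]
        k += 1
        for m in range(1, n + 1):
            val = params[k] + 1j * params[k + 1]
            k += 2
            c[(n, m)] = val
            c[(n, -m)] = (-1) ** m * np.conj(val)
    return c


def fit_shape(
    cloud: PointCloud,
    N: int,
    ridge: float = 0.0,
    cond_limit: float = 1e12,
) -> ShapeExpansion:
    """Least-squares spherical-harmonic fit of the radius function.

    Minimizes ``sum_i |s(theta_i, phi_i) - r_i|**2`` over conjugate-symmetric
    coefficients (via a real re-parameterization).  ``ridge`` adds an L2
    penalty for badly conditioned angular samplings.  Requires
    ``(N+1)**2 <= len(cloud)``.
    """
    npar = num_coeffs(N)
    if npar > len(cloud):
        raise PointCloudError(
            f"degree N={N} needs {npar} coefficients but only "
            f"{len(cloud)} points are available"
        )
    r, theta, phi = cloud.spherical()
    A = _real_design_matrix(N, theta, phi)
    if ridge > 0.0:
        A_aug = np.vstack([A, math.sqrt(ridge) * np.eye(npar)])
        b_aug = np.concatenate([r, np.zeros(npar)])
    else:
        A_aug, b_aug = A, r
    params, _, rank, sv = np.linalg.lstsq(A_aug, b_aug, rcond=None)
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else math.inf
    if rank < npar or cond > cond_limit:
        raise ConditioningError(
            f"rank-deficient surface fit at degree {N}: rank {rank}/{npar}, "
            f"condition number {cond:.3g} (clustered angular sampling?)"
        )
    resid = A @ params - r
    coeffs = _coeffs_from_real_params(N, params)
    return ShapeExpansion(
        coeffs,
        rms_residual=float(np.sqrt(np.mean(resid**2))),
        max_residual=float(np.max(np.abs(resid))),
        condition_number=cond,
    )


@dataclass
class OrderSelection:
    """Result of the automatic truncation-order search."""

    nmax: int
    n_star: int            #: first degree where the fit interpolates the data
    converged: bool        #: False if the point count capped the search
    residuals: dict = field(default_factory=dict)  #: degree -> max residual


def select_order(cloud: PointCloud, exact_tol: float | None = None) -> OrderSelection:
    """Choose the truncation degree from the data.

    The fit degree is raised until the maximum pointwise residual drops below
    ``exact_tol`` (default ``1e-3 * median radius``) -- the regime where the
    expansion interpolates the data points and starts tracking noise.  Calling
    that degree ``n*``, the returned working order is ``nmax = n* // 2``,
    which fits the data closely while staying smooth between points.  If the
    interpolation regime is never reached before the point count caps the
    admissible degree, the largest admissible degree is used and
    ``converged`` is False.
    """
    r, _, _ = cloud.spherical()
    if exact_tol is None:
        exact_tol = 1e-3 * float(np.median(r))
    n_allowed = int(math.isqrt(len(cloud))) - 1
    if n_allowed < 0:
        raise PointCloudError("no points")
    residuals: dict[int, float] = {}
    for n in range(n_allowed + 1):
        fit = fit_shape(cloud, n)
        residuals[n] = fit.max_residual
        if fit.max_residual < exact_tol:
            return OrderSelection(n // 2, n, True, residuals)
    warnings.warn(
        "interpolation regime not reached before the point-count limit; "
        f"using the largest admissible degree {n_allowed}",
        stacklevel=2,
    )
    return OrderSelection(n_allowed // 2, n_allowed, False, residuals)


# ----------------------------------------------------------------------------
# Volume and displacement
# ----------------------------------------------------------------------------

def _quadrature(N: int):
    """Gauss-Legendre (cos theta) x uniform (phi) nodes/weights, exact for
    spherical polynomials of degree >= 3N + 1 (enough for s**3)."""
    deg = 3 * N + 2
    nth = deg // 2 + 2
    nph = deg + 2
    x, w = leggauss(nth)
    theta = np.arccos(x)
    phi = np.arange(nph) * 2.0 * math.pi / nph
    T, P = np.meshgrid(theta, phi, indexing="ij")
    W = np.outer(w, np.full(nph, 2.0 * math.pi / nph))
    return T.ravel(), P.ravel(), W.ravel()


def enclosed_volume(shape: ShapeExpansion) -> float:
    """Volume enclosed by the fitted surface: V = (1/3) ∮ s**3 dOmega."""
    T, P, W = _quadrature(shape.N)
    s = shape.radius(T, P)
    if np.min(s) <= 0.0:
        raise ValueError(
            "surface radius is non-positive on the quadrature grid; "
            "the shape is not star-shaped about the center"
        )
    return float(np.sum(W * s**3) / 3.0)


def initial_radius(volume: float) -> float:
    """Radius of the volume-equivalent sphere: r0 = (3V / 4 pi)**(1/3)."""
    if volume <= 0.0:
        raise ValueError("volume must be positive")
    return (3.0 * volume / (4.0 * math.pi)) ** (1.0 / 3.0)


def displacement_coeffs(
    shape: ShapeExpansion, r0: float, sign: str = "as-printed"
) -> BeadGeometry:
    """Radial-displacement boundary coefficients from shape and initial radius.

    ``sign="as-printed"`` uses u|_{r0} = (r0 - s) e_r, i.e.

        d_00 = sqrt(4 pi) r0 - s_00,   d_nm = -s_nm  (n >= 1);

    ``sign="flipped"`` negates every coefficient (displacement from the
    initial sphere to the deformed surface), which flips the sign of the
    reconstructed stress.
    """
    if r0 <= 0.0:
        raise ValueError("r0 must be positive")
    if sign not in ("as-printed", "flipped"):
        raise ValueError(f"unknown displacement sign convention: {sign!r}")
    d = SHCoeffs(shape.N)
    d.data[:] = -shape.coeffs.data
    d.data[0] += SQRT4PI * r0
    if sign == "flipped":
        d.data[:] = -d.data
    geom = BeadGeometry(r0, d)
    rel = geom.max_relative_displacement()
    if rel > LINEAR_THEORY_WARN:
        warnings.warn(
            f"max |displacement| = {rel:.2f} r0 exceeds {LINEAR_THEORY_WARN} r0; "
            "linear elasticity may be inaccurate",
            stacklevel=2,
        )
    return geom


# ----------------------------------------------------------------------------
# Recentering
# ----------------------------------------------------------------------------

def recenter(
    cloud: PointCloud,
    tol: float | None = None,
    max_iter: int = 20,
    fit_degree: int = 4,
) -> PointCloud:
    """Shift the origin until the degree-1 shape coefficients vanish.

    Degree-1 radius modes are (to first order) rigid translations of the
    surface, which would otherwise masquerade as a displacement field.  The
    translation implied by the fitted degree-1 coefficients is removed
    iteratively.  Off by default in the pipeline because segmentation
    pipelines usually center the cloud already.
    """
    r, _, _ = cloud.spherical()
    scale = float(np.median(r))
    if tol is None:
        tol = 1e-9 * scale
    n_allowed = int(math.isqrt(len(cloud))) - 1
    deg = min(fit_degree, n_allowed)
    if deg < 1:
        raise PointCloudError("too few points to estimate a center shift")
    current = cloud
    for _ in range(max_iter):
        fit = fit_shape(current, deg)
        t = _translation_from_degree1(fit.coeffs)
        if np.linalg.norm(t) < tol:
            return current
        current = current.shifted(current.center + t)
    warnings.warn(
        "recentering did not converge; returning the best iterate",
        stacklevel=2,
    )
    return current


def _translation_from_degree1(coeffs: SHCoeffs) -> np.ndarray:
    """Translation t whose radius perturbation t . e_r matches the degree-1
    coefficients:  t.e_r = sqrt(2 pi/3) [(tx + i ty) Y1,-1 + (-tx + i ty) Y11]
    + sqrt(4 pi/3) tz Y10."""
    c_m1 = coeffs[(1, -1)]
    c_0 = coeffs[(1, 0)]
    w = c_m1 / math.sqrt(2.0 * math.pi / 3.0)
    tx, ty = w.real, w.imag
    tz = c_0.real / math.sqrt(4.0 * math.pi / 3.0)
    return np.array([tx, ty, tz])
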