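"""Elastostatic solver: from the radial boundary condition to the displacement field.

The bead interior is a homogeneous isotropic linear-elastic body in static
equilibrium with no body forces, so the displacement field obeys the
Navier-Lame equation

    1/(1 - 2 nu) grad(div u) + laplacian(u) = 0.

We represent u by the Love/Trefftz ansatz

    u = U + (r**2 - r0**2) grad(psi),

where psi and every *Cartesian* component of U are harmonic.  Expanding both
in solid spherical harmonics (regular inside the initial sphere of radius r0,
irregular outside, with continuity prefactors),

    psi = sum a_nm (r/r0)**n Ynm,      U_j = sum K_nm^j (r/r0)**n Ynm   (r < r0)

the ansatz solves the Navier-Lame equation iff each degree-(n-1) part of psi
is slaved to the divergence of the degree-n part of U.  Writing

    div U = sum_{n,m} c_nm (r/r0)**(n-1) Y_{n-1,m}

(the r0 scaling absorbed into c_nm), the coupling implemented here is

    a_{n-1,m} = -c_nm / (2 (3n - 2 - 2 nu (2n - 1))),    n >= 2.

This coupling is derived directly from the ansatz (substitute, use
r . grad f = n f for degree-n homogeneous f, and match degrees); its
correctness is enforced by the finite-difference Navier-residual oracle in
the test suite rather than taken on faith.  The denominator is nonzero for
every physical nu < 1/2 and n >= 2.  A degree-0 psi never enters u or the
stress (its gradient vanishes), so no a_0m is generated: degree-1 boundary
terms (uniform dilation, rigid translation) need no psi at all.

The boundary condition itself is the radial surface displacement

    u|_{r0} = sum d_nm Ynm e_r ,

which determines U completely because the (r**2 - r0**2) factor kills the
psi term on the boundary.  Converting to Cartesian components, e_r is a pure
degree-1 harmonic vector, so each component of the boundary field is a sum
of products Ynm * Y1mu; the Clebsch-Gordan product linearization turns these
into single harmonics whose degree-n content defines K_nm.  A boundary of
degree N therefore produces K up to degree N + 1 and a up to degree N.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .harmonics import (
    SHCoeffs,
    flat_index,
    gradient_matrices_irregular,
    gradient_matrices_regular,
    index_arrays,
    linearize_sh_product,
    num_coeffs,
    regular_ssh_table,
    irregular_ssh_table,
    ynm_table,
)
from .surface import BeadGeometry

__all__ = [
    "Material",
    "VectorBoundaryExpansion",
    "DivergenceExpansion",
    "ScalarPotentialExpansion",
    "ElasticSolution",
    "ER_CARTESIAN_TERMS",
    "boundary_to_cartesian",
    "divergence_coeffs",
    "psi_coeffs",
    "solve",
    "displacement_field",
    "evaluate_potentials",
    "navier_residual",
]


# ----------------------------------------------------------------------------
# Material
# ----------------------------------------------------------------------------

@dataclass(frozen=True)
class Material:
    """Isotropic linear-elastic material: shear modulus G [Pa], Poisson nu."""

    G: float
    nu: float

    def __post_init__(self) -> None:
        if not self.G > 0.0:
            raise ValueError(f"shear modulus must be positive, got G={self.G}")
        if not (-1.0 < self.nu < 0.5):
            raise ValueError(
                f"Poisson's ratio must satisfy -1 < nu < 0.5 strictly "
                f"(nu = 0.5 is exactly incompressible), got nu={self.nu}"
            )


# ----------------------------------------------------------------------------
# Expansions
# ----------------------------------------------------------------------------

@dataclass
class VectorBoundaryExpansion:
    """Cartesian-component coefficients K_nm defining the harmonic vector U.

    ``K`` has shape (num_coeffs(N), 3); column j holds the expansion of the
    j-th Cartesian component of U in the (r/r0)**n Ynm basis (interior) /
    (r0/r)**(n+1) Ynm basis (exterior).
    """

    N: int
    K: np.ndarray = None

    def __post_init__(self) -> None:
        if self.K is None:
            self.K = np.zeros((num_coeffs(self.N), 3), dtype=complex)
        else:
            self.K = np.asarray(self.K, dtype=complex)
            if self.K.shape != (num_coeffs(self.N), 3):
                raise ValueError(
                    f"K must have shape ({num_coeffs(self.N)}, 3), got {self.K.shape}"
                )

    def component(self, axis: int) -> SHCoeffs:
        return SHCoeffs(self.N, self.K[:, axis].copy())

    def max_realness_violation(self) -> float:
        return max(self.component(j).max_realness_violation() for j in range(3))


@dataclass
class DivergenceExpansion:
    """Coefficients c_nm of div U = sum c_nm (r/r0)**(n-1) Y_{n-1,m}.

    Indexed by the *source* degree n of U (as in the psi coupling), with m the
    order at target degree n - 1; stored for n = 1 .. N.
    """

    N: int
    c: dict

    def __getitem__(self, nm) -> complex:
        return self.c.get(tuple(nm), 0.0 + 0.0j)


@dataclass
class ScalarPotentialExpansion:
    """Coefficients a_nm of psi = sum a_nm (r/r0)**n Ynm (interior branch)."""

    coeffs: SHCoeffs

    @property
    def N(self) -> int:
        return self.coeffs.N

    def __getitem__(self, nm) -> complex:
        return self.coeffs[nm]


@dataclass
class ElasticSolution:
    """Complete elastic solution for one bead: r0, material, K and a tables."""

    r0: float
    material: Material
    K: VectorBoundaryExpansion
    a: ScalarPotentialExpansion

    def copy(self) -> "ElasticSolution":
        return ElasticSolution(
            self.r0,
            self.material,
            VectorBoundaryExpansion(self.K.N, self.K.K.copy()),
            ScalarPotentialExpansion(self.a.coeffs.copy()),
        )


# ----------------------------------------------------------------------------
# Boundary condition in Cartesian components
# ----------------------------------------------------------------------------

_S2PI3 = math.sqrt(2.0 * math.pi / 3.0)
_S4PI3 = math.sqrt(4.0 * math.pi / 3.0)

#: e_r = (sin t cos p, sin t sin p, cos t) written in degree-1 harmonics:
#: list of (axis, mu, coefficient) with e_r[axis] = sum coeff * Y[1, mu].
ER_CARTESIAN_TERMS = (
    (0, -1, _S2PI3 + 0.0j),
    (0, 1, -_S2PI3 + 0.0j),
    (1, -1, 1j * _S2PI3),
    (1, 1, 1j * _S2PI3),
    (2, 0, _S4PI3 + 0.0j),
)


def boundary_to_cartesian(geom: BeadGeometry) -> VectorBoundaryExpansion:
    """Cartesian harmonic expansion K_nm of the boundary field d(theta,phi) e_r.

    Each Cartesian component of ``sum d_nm Ynm e_r`` is a sum of products
    Ynm * Y1mu which the Clebsch-Gordan linearization reduces to single
    harmonics of degrees n - 1 and n + 1 (the degree-n term is killed by
    parity), so the output truncation degree is the boundary degree plus one.
    """
    N_out = geom.d.N + 1
    K = VectorBoundaryExpansion(N_out)
    for (n, m), d in geom.d.items():
        if d == 0.0:
            continue
        for axis, mu, e in ER_CARTESIAN_TERMS:
            for (L, M, p) in linearize_sh_product(n, m, 1, mu):
                K.K[flat_index(L, M), axis] += d * e * p
    return K


def divergence_coeffs(K: VectorBoundaryExpansion, r0: float) -> DivergenceExpansion:
    """Coefficients c_nm with div U = sum c_nm (r/r0)**(n-1) Y_{n-1,m}.

    Obtained by applying the exact Cartesian-derivative expansions of the
    regular solid harmonics to every component of U and collecting the
    degree-lowered terms; the interior (1/r0**n) scaling is absorbed so that
    c_nm is dimensionless (K carries length units).
    """
    if r0 <= 0.0:
        raise ValueError("r0 must be positive")
    Gx, Gy, Gz = gradient_matrices_regular(K.N)
    # div U = sum_j d(U_j)/dx_j ; rows index (n-1, m) flat, columns (n, m)
    div_vec = Gx @ K.K[:, 0] + Gy @ K.K[:, 1] + Gz @ K.K[:, 2]
    c: dict = {}
    if K.N >= 1:
        ns, ms = index_arrays(K.N - 1)
        for n1, m, val in zip(ns, ms, div_vec):
            if val != 0.0:
                # r**(n-1) Y_{n-1,m} / r0**n = (1/r0) (r/r0)**(n-1) Y_{n-1,m}
                c[(int(n1) + 1, int(m))] = complex(val) / r0
    return DivergenceExpansion(K.N, c)


def psi_coeffs(c: DivergenceExpansion, nu: float) -> ScalarPotentialExpansion:
    """Scalar-potential coefficients slaved to the divergence of U:

        a_{n-1,m} = -c_nm / (2 (3n - 2 - 2 nu (2n - 1))),   n >= 2.

    The n = 1 row (a degree-0 psi) is pure gauge -- grad(psi_0) = 0 -- and is
    omitted.  The denominator cannot vanish for physical nu < 1/2.
    """
    if not nu < 0.5:
        raise ValueError("psi coupling requires nu < 0.5")
    N_a = max(c.N - 1, 0)
    a = SHCoeffs(N_a)
    for (n, m), val in c.c.items():
        if n < 2:
            continue
        den = 2.0 * (3.0 * n - 2.0 - 2.0 * nu * (2.0 * n - 1.0))
        if abs(den) < 1e-14:
            raise ZeroDivisionError(
                f"singular psi coupling at n={n}, nu={nu}"
            )
        a[(n - 1, m)] = -val / den
    return ScalarPotentialExpansion(a)


def solve(geom: BeadGeometry, material: Material) -> ElasticSolution:
    """Full solve: boundary coefficients -> (K, a) -> ElasticSolution."""
    K = boundary_to_cartesian(geom)
    c = divergence_coeffs(K, geom.r0)
    a = psi_coeffs(c, material.nu)
    return ElasticSolution(geom.r0, material, K, a)


# ----------------------------------------------------------------------------
# Field evaluation
# ----------------------------------------------------------------------------

def _scaled_interior(vec: np.ndarray, N: int, r0: float) -> np.ndarray:
    """Coefficients b with f = sum b Rnm from f = sum vec (r/r0)**n Ynm."""
    ns, _ = index_arrays(N)
    return vec / r0 ** ns


def _scaled_exterior(vec: np.ndarray, N: int, r0: float) -> np.ndarray:
    """Coefficients b with f = sum b Inm from f = sum vec (r0/r)**(n+1) Ynm."""
    ns, _ = index_arrays(N)
    return vec * r0 ** (ns + 1)


def displacement_field(sol: ElasticSolution, r, theta, phi):
    """Displacement u = U + (r**2 - r0**2) grad(psi) at spherical points.

    Accepts scalars or broadcastable arrays; returns real Cartesian
    components of shape ``broadcast.shape + (3,)``.  The interior branch is
    used for r <= r0 and the exterior branch (irregular harmonics, decaying
    at infinity) for r > r0; the two match continuously at r0.  The assembled
    field from a conjugate-symmetric coefficient set is real; the residual
    imaginary part is checked against a 1e-10 relative tolerance.
    """
    r = np.asarray(r, dtype=float)
    theta = np.asarray(theta, dtype=float)
    phi = np.asarray(phi, dtype=float)
    shape = np.broadcast_shapes(r.shape, theta.shape, phi.shape)
    r_b = np.broadcast_to(r, shape).ravel()
    t_b = np.broadcast_to(theta, shape).ravel()
    p_b = np.broadcast_to(phi, shape).ravel()
    pts = np.column_stack(
        [
            r_b * np.sin(t_b) * np.cos(p_b),
            r_b * np.sin(t_b) * np.sin(p_b),
            r_b * np.cos(t_b),
        ]
    )
    out = np.zeros((pts.shape[0], 3), dtype=complex)
    interior = r_b <= sol.r0
    if np.any(interior):
        out[interior] = _displacement_cartesian(sol, pts[interior], "interior")
    if np.any(~interior):
        out[~interior] = _displacement_cartesian(sol, pts[~interior], "exterior")
    scale = max(float(np.max(np.abs(out))), 1e-300)
    imag_max = float(np.max(np.abs(out.imag)))
    if imag_max > 1e-10 * scale:
        raise FloatingPointError(
            f"assembled displacement has imaginary part {imag_max:.3g} "
            f"(scale {scale:.3g}); coefficients are not conjugate-symmetric"
        )
    return out.real.reshape(shape + (3,))


def _displacement_cartesian(sol: ElasticSolution, pts: np.ndarray, branch: str):
    NK, Na = sol.K.N, sol.a.N
    r0 = sol.r0
    r2 = np.sum(pts**2, axis=1)
    if branch == "interior":
        bK = np.column_stack(
            [_scaled_interior(sol.K.K[:, j], NK, r0) for j in range(3)]
        )
        ba = _scaled_interior(sol.a.coeffs.data, Na, r0)
        tabU = regular_ssh_table(NK, pts)
        U = tabU @ bK
        if Na >= 1:
            Gx, Gy, Gz = gradient_matrices_regular(Na)
            tabG = tabU[:, : num_coeffs(Na - 1)]
            gpsi = np.column_stack([tabG @ (G @ ba) for G in (Gx, Gy, Gz)])
        else:
            gpsi = np.zeros_like(pts, dtype=complex)
    elif branch == "exterior":
        bK = np.column_stack(
            [_scaled_exterior(sol.K.K[:, j], NK, r0) for j in range(3)]
        )
        ba = _scaled_exterior(sol.a.coeffs.data, Na, r0)
        tabU = irregular_ssh_table(NK, pts)
        U = tabU @ bK
        Gx, Gy, Gz = gradient_matrices_irregular(Na)
        tabG = irregular_ssh_table(Na + 1, pts)
        gpsi = np.column_stack([tabG @ (G @ ba) for G in (Gx, Gy, Gz)])
    else:  # pragma: no cover
        raise ValueError(branch)
    return U + (r2 - r0**2)[:, None] * gpsi


def evaluate_potentials(sol: ElasticSolution, points):
    """Values of (psi, U) at Cartesian points, branch chosen by |x| vs r0.

    Returns ``(psi, U)`` with shapes ``(npoints,)`` and ``(npoints, 3)``;
    values are complex but are real (to round-off) for conjugate-symmetric
    coefficient sets.  Both psi and every Cartesian component of U are
    harmonic on each branch -- the defining property of the ansatz, checked
    by finite differences in the test suite.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    r = np.linalg.norm(pts, axis=1)
    psi = np.zeros(pts.shape[0], dtype=complex)
    U = np.zeros((pts.shape[0], 3), dtype=complex)
    NK, Na, r0 = sol.K.N, sol.a.N, sol.r0
    interior = r <= r0
    for mask, branch in ((interior, "interior"), (~interior, "exterior")):
        if not np.any(mask):
            continue
        if branch == "interior":
            tab = regular_ssh_table(max(NK, Na), pts[mask])
            bK = np.column_stack(
                [_scaled_interior(sol.K.K[:, j], NK, r0) for j in range(3)]
            )
            ba = _scaled_interior(sol.a.coeffs.data, Na, r0)
        else:
            tab = irregular_ssh_table(max(NK, Na), pts[mask])
            bK = np.column_stack(
                [_scaled_exterior(sol.K.K[:, j], NK, r0) for j in range(3)]
            )
            ba = _scaled_exterior(sol.a.coeffs.data, Na, r0)
        U[mask] = tab[:, : num_coeffs(NK)] @ bK
        psi[mask] = tab[:, : num_coeffs(Na)] @ ba
    return psi, U


def displacement_at_points(sol: ElasticSolution, points):
    """Displacement at Cartesian points (helper for finite-difference oracles)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    r = np.linalg.norm(pts, axis=1)
    theta = np.arccos(np.clip(np.divide(pts[:, 2], np.where(r > 0, r, 1.0)), -1, 1))
    phi = np.arctan2(pts[:, 1], pts[:, 0])
    return displacement_field(sol, r, theta, phi)


# ----------------------------------------------------------------------------
# Navier residual oracle
# ----------------------------------------------------------------------------

def navier_residual(sol: ElasticSolution, point, h: float | None = None):
    """Central-finite-difference residual of the Navier-Lame equation.

    Evaluates ``1/(1-2 nu) grad(div u) + laplacian(u)`` at an interior
    Cartesian point using second-order stencils of step ``h`` (default
    ``1e-4 * r0``).  Returns ``(residual_vector, relative_magnitude)`` where
    the magnitude is normalized by ``max|u| / r0**2`` over the stencil.  The
    point must be at least 2h away from both the origin's coordinate
    singularity (harmless) and the r0 interface, where the piecewise field is
    only C0.
    """
    p = np.asarray(point, dtype=float).reshape(3)
    if h is None:
        h = 1e-4 * sol.r0
    r = float(np.linalg.norm(p))
    if r >= sol.r0 - 2.0 * h:
        raise ValueError(
            f"stencil at r={r:.4g} crosses the r0={sol.r0:.4g} interface; "
            "the Navier residual is defined on the interior"
        )
    nu = sol.material.nu

    # all stencil points in one batch: center, +-e_i h, and +-h (+-h) pairs
    offsets = [np.zeros(3)]
    for i in range(3):
        for s in (+1, -1):
            e = np.zeros(3)
            e[i] = s * h
            offsets.append(e)
    pair_index = {}
    for i in range(3):
        for j in range(i + 1, 3):
            for si in (+1, -1):
                for sj in (+1, -1):
                    e = np.zeros(3)
                    e[i] = si * h
                    e[j] = sj * h
                    pair_index[(i, j, si, sj)] = len(offsets)
                    offsets.append(e)
    pts = p[None, :] + np.array(offsets)
    u = displacement_at_points(sol, pts)  # (npts, 3)

    def u_ax(i, s):
        return u[1 + 2 * i + (0 if s > 0 else 1)]

    lap = np.zeros(3)
    for i in range(3):
        lap += (u_ax(i, +1) + u_ax(i, -1) - 2.0 * u[0]) / h**2

    # hessian of each component: H[i, j] = d_i d_j u  (vector valued)
    H = np.zeros((3, 3, 3))
    for i in range(3):
        H[i, i] = (u_ax(i, +1) + u_ax(i, -1) - 2.0 * u[0]) / h**2
    for i in range(3):
        for j in range(i + 1, 3):
            upp = u[pair_index[(i, j, +1, +1)]]
            upm = u[pair_index[(i, j, +1, -1)]]
            ump = u[pair_index[(i, j, -1, +1)]]
            umm = u[pair_index[(i, j, -1, -1)]]
            H[i, j] = H[j, i] = (upp - upm - ump + umm) / (4.0 * h**2)
    graddiv = np.zeros(3)
    for i in range(3):
        graddiv[i] = sum(H[i, j][j] for j in range(3))

    res = graddiv / (1.0 - 2.0 * nu) + lap
    scale = max(float(np.max(np.abs(u))), 1e-300) / sol.r0**2
    return res, float(np.max(np.abs(res))) / scale
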