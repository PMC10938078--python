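"""Stress- and strain-tensor assembly from the elastic solution.

With the Love/Trefftz representation ``u = U + (r**2 - r0**2) grad(psi)``
Hooke's law takes the closed form

    T = 2 G [ nu/(1-2 nu) (div U + 2 r . grad psi) E
              + Def(U) + r (x) grad psi + (r (x) grad psi)^T
              + (r**2 - r0**2) grad (x) grad psi ]

where ``E`` is the identity, ``(x)`` the outer product and ``Def`` the
symmetrized gradient.  Every ingredient is available analytically from the
solid-harmonic expansions (gradients and Hessians of ``r**n Ynm`` are exact
finite expansions of lower degree), so no numerical differentiation is
involved in either assembly route:

* :func:`stress_tensor` -- the reference route: evaluates the assembled
  fields (div U, grad psi, Jacobian of U, Hessian of psi) at the point and
  combines them.

* :func:`stress_tensor_expanded` -- the series route: compiles, once per
  solution, each tensor component into an explicit finite series
  ``sum c * r**(2k) * R[L, M]`` (k = 0 or 1).  The outer products with the
  position vector are reduced with a second pass of Clebsch-Gordan product
  linearization.  Agreement of the two routes to ~1e-8 gates the
  transcription of the series form; agreement with the independent
  finite-difference Hooke oracle (:func:`hooke_oracle_stress`) to ~1e-4
  validates the physics.

Stress is only evaluated in the bead interior: the exterior medium is the
tissue, whose moduli are different and unknown.  Surface maps are taken just
inside r0 because the two-branch field is only C0-matched at the interface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .harmonics import (
    flat_index,
    gradient_matrices_regular,
    index_arrays,
    linearize_sh_product,
    num_coeffs,
    regular_ssh_table,
)
from .solver import ER_CARTESIAN_TERMS, ElasticSolution, Material, displacement_at_points

__all__ = [
    "StressTensor",
    "StrainTensor",
    "stress_tensor",
    "stress_tensor_expanded",
    "spherical_components",
    "isotropic_sphere_stress",
    "strain_tensor",
    "hooke_oracle_stress",
    "surface_stress_map",
]


# ----------------------------------------------------------------------------
# Tensors
# ----------------------------------------------------------------------------

@dataclass
class StressTensor:
    """Symmetric 3x3 stress tensor [Pa] with basis tag and location."""

    components: np.ndarray
    basis: str = "cartesian"  # "cartesian" | "spherical"
    location: tuple = None    # (r, theta, phi)

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float).reshape(3, 3)
        asym = np.max(np.abs(self.components - self.components.T))
        scale = max(np.max(np.abs(self.components)), 1e-300)
        if asym > 1e-9 * scale:
            raise ValueError(f"stress tensor not symmetric: asymmetry {asym:.3g}")

    def eigenvalues(self) -> np.ndarray:
        return np.linalg.eigvalsh(self.components)


@dataclass
class StrainTensor:
    """Symmetric 3x3 strain tensor [dimensionless] with basis tag/location."""

    components: np.ndarray
    basis: str = "cartesian"
    location: tuple = None

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float).reshape(3, 3)

    def trace(self) -> float:
        return float(np.trace(self.components))


def _point_from_sph(r, theta, phi):
    return np.array(
        [
            r * math.sin(theta) * math.cos(phi),
            r * math.sin(theta) * math.sin(phi),
            r * math.cos(theta),
        ]
    )


def _check_interior(sol: ElasticSolution, r: float) -> None:
    if r > sol.r0 * (1.0 + 1e-12):
        raise ValueError(
            f"stress is only defined inside the bead (r={r:.4g} > r0={sol.r0:.4g}); "
            "the exterior medium has different, unknown moduli"
        )


def _realize(M: np.ndarray, label: str) -> np.ndarray:
    scale = max(float(np.max(np.abs(M))), 1e-300)
    imag = float(np.max(np.abs(M.imag)))
    if imag > 1e-8 * scale:
        raise FloatingPointError(
            f"{label} has imaginary part {imag:.3g} at scale {scale:.3g}"
        )
    return M.real


# ----------------------------------------------------------------------------
# Route 1: assembled-field evaluation
# ----------------------------------------------------------------------------

def stress_tensor(sol: ElasticSolution, r, theta, phi) -> StressTensor:
    """Cartesian stress tensor at an interior point (reference route)."""
    _check_interior(sol, r)
    x = _point_from_sph(r, theta, phi)
    NK, Na = sol.K.N, sol.a.N
    r0 = sol.r0
    nsK, _ = index_arrays(NK)
    nsa, _ = index_arrays(Na)
    bK = sol.K.K / r0 ** nsK[:, None]
    ba = sol.a.coeffs.data / r0 ** nsa

    tab = regular_ssh_table(max(NK, Na), x[None, :])[0]

    GxK, GyK, GzK = gradient_matrices_regular(NK)
    tabK1 = tab[: num_coeffs(NK - 1)] if NK >= 1 else tab[:0]
    # Jacobian J[i, j] = d_i U_j
    J = np.zeros((3, 3), dtype=complex)
    for i, G in enumerate((GxK, GyK, GzK)):
        for j in range(3):
            J[i, j] = tabK1 @ (G @ bK[:, j]) if NK >= 1 else 0.0
    divU = np.trace(J)
    defU = 0.5 * (J + J.T)

    gpsi = np.zeros(3, dtype=complex)
    hess = np.zeros((3, 3), dtype=complex)
    if Na >= 1:
        Ga = gradient_matrices_regular(Na)
        taba1 = tab[: num_coeffs(Na - 1)]
        gvecs = [G @ ba for G in Ga]
        gpsi = np.array([taba1 @ g for g in gvecs])
        if Na >= 2:
            Ga1 = gradient_matrices_regular(Na - 1)
            taba2 = tab[: num_coeffs(Na - 2)]
            for i in range(3):
                for j in range(i, 3):
                    hess[i, j] = hess[j, i] = taba2 @ (Ga1[j] @ gvecs[i])
    # r . grad psi = sum n a_nm (r/r0)**n Ynm  (Euler's homogeneity relation)
    rdotg = tab[: num_coeffs(Na)] @ (nsa * ba)

    nu, G = sol.material.nu, sol.material.G
    T = np.zeros((3, 3), dtype=complex)
    T += nu / (1.0 - 2.0 * nu) * (divU + 2.0 * rdotg) * np.eye(3)
    T += defU
    T += np.outer(x, gpsi) + np.outer(gpsi, x)
    T += (r * r - r0 * r0) * hess
    T *= 2.0 * G
    comp = _realize(T, "stress tensor")
    comp = 0.5 * (comp + comp.T)
    return StressTensor(comp, "cartesian", (float(r), float(theta), float(phi)))


# ----------------------------------------------------------------------------
# Route 2: compiled explicit series
# ----------------------------------------------------------------------------

#: x_i = sum over (axis, mu, coeff) of coeff * R[1, mu]  (same table as e_r)
_X_TERMS = ER_CARTESIAN_TERMS


def _compile_series(sol: ElasticSolution):
    """Compile T/(2G) into per-component series sum c * r**(2k) * R[L, M].

    Returns ``(Nmax, terms)`` where ``terms[i][j]`` maps ``k in {0, 1}`` to a
    dense coefficient vector over flat (L, M) indices up to Nmax.
    """
    NK, Na = sol.K.N, sol.a.N
    r0 = sol.r0
    nu = sol.material.nu
    nsK, _ = index_arrays(NK)
    nsa, _ = index_arrays(Na)
    bK = sol.K.K / r0 ** nsK[:, None]
    ba = sol.a.coeffs.data / r0 ** nsa
    Nmax = max(NK, Na)
    size = num_coeffs(Nmax)

    terms = [[{0: np.zeros(size, complex), 1: np.zeros(size, complex)}
              for _ in range(3)] for _ in range(3)]

    def add(i, j, k, vec):
        terms[i][j][k][: vec.size] += vec

    # isotropic part: nu/(1-2nu) (div U + 2 r.grad psi)
    iso = np.zeros(size, dtype=complex)
    if NK >= 1:
        GK = gradient_matrices_regular(NK)
        div_vec = GK[0] @ bK[:, 0] + GK[1] @ bK[:, 1] + GK[2] @ bK[:, 2]
        iso[: div_vec.size] += div_vec
    iso[: ba.size] += 2.0 * nsa * ba
    iso *= nu / (1.0 - 2.0 * nu)
    for i in range(3):
        add(i, i, 0, iso)

    # Def(U)
    if NK >= 1:
        GK = gradient_matrices_regular(NK)
        for i in range(3):
            for j in range(3):
                vec = 0.5 * (GK[i] @ bK[:, j] + GK[j] @ bK[:, i])
                add(i, j, 0, vec)

    if Na >= 1:
        Ga = gradient_matrices_regular(Na)
        gvecs = [G @ ba for G in Ga]  # grad psi over R[p, mu], p <= Na-1

        # x_i d_j psi + x_j d_i psi via product linearization:
        # R[1,mu1] * R[p,mu] = P(p+1) R[p+1,M] + P(p-1) r**2 R[p-1,M]
        nsg, msg = index_arrays(Na - 1)
        for j in range(3):
            for p, mu, coeff in zip(nsg, msg, gvecs[j]):
                if coeff == 0.0:
                    continue
                for axis, mu1, xc in _X_TERMS:
                    for (L, M, P) in linearize_sh_product(1, mu1, int(p), int(mu)):
                        k = 0 if L == p + 1 else 1
                        vec = coeff * xc * P
                        i = axis
                        idx = flat_index(L, M)
                        terms[i][j][k][idx] += vec
                        terms[j][i][k][idx] += vec

        # (r**2 - r0**2) Hessian
        if Na >= 2:
            Ga1 = gradient_matrices_regular(Na - 1)
            for i in range(3):
                for j in range(i, 3):
                    hvec = Ga1[j] @ gvecs[i]
                    add(i, j, 1, hvec)
                    add(i, j, 0, -r0 * r0 * hvec)
                    if i != j:
                        add(j, i, 1, hvec)
                        add(j, i, 0, -r0 * r0 * hvec)
    return Nmax, terms


def stress_tensor_expanded(sol: ElasticSolution, r, theta, phi) -> StressTensor:
    """Cartesian stress from the compiled explicit series (fast route).

    Must agree with :func:`stress_tensor`; the equivalence is enforced in the
    test suite and gates the transcription of the series form.  The compiled
    series is cached on the solution object, so per-point evaluation reduces
    to a handful of dot products.
    """
    _check_interior(sol, r)
    cached = getattr(sol, "_compiled_series", None)
    if cached is None:
        cached = _compile_series(sol)
        object.__setattr__(sol, "_compiled_series", cached)
    Nmax, terms = cached
    x = _point_from_sph(r, theta, phi)
    tab = regular_ssh_table(Nmax, x[None, :])[0]
    r2 = float(r) * float(r)
    T = np.zeros((3, 3), dtype=complex)
    for i in range(3):
        for j in range(3):
            T[i, j] = tab @ terms[i][j][0] + r2 * (tab @ terms[i][j][1])
    T *= 2.0 * sol.material.G
    comp = _realize(T, "stress tensor (series route)")
    comp = 0.5 * (comp + comp.T)
    return StressTensor(comp, "cartesian", (float(r), float(theta), float(phi)))


# ----------------------------------------------------------------------------
# Basis change and closed forms
# ----------------------------------------------------------------------------

def spherical_basis(theta: float, phi: float) -> np.ndarray:
    """Rows are (e_r, e_theta, e_phi) at the given angles.

    At theta = 0 the convention degenerates gracefully to
    (e_r, e_theta, e_phi) = (z, x, y) for phi = 0.
    """
    st, ct = math.sin(theta), math.cos(theta)
    sp, cp = math.sin(phi), math.cos(phi)
    return np.array(
        [
            [st * cp, st * sp, ct],
            [ct * cp, ct * sp, -st],
            [-sp, cp, 0.0],
        ]
    )


def spherical_components(T: StressTensor) -> StressTensor:
    """Similarity transform to the local (e_r, e_theta, e_phi) basis."""
    if T.basis == "spherical":
        return T
    if T.location is None:
        raise ValueError("tensor location unknown; cannot build the local basis")
    _, theta, phi = T.location
    Q = spherical_basis(theta, phi)
    comp = Q @ T.components @ Q.T
    return StressTensor(0.5 * (comp + comp.T), "spherical", T.location)


def isotropic_sphere_stress(
    material: Material, r0: float, r1: float, displacement_sign: str = "as-printed"
) -> StressTensor:
    """Closed-form stress of a bead uniformly deformed from radius r0 to r1.

    The displacement field is linear-radial, so the stress is isotropic:

        T = 2 G (1 + nu)/(1 - 2 nu) * (r0 - r1)/r0 * E    (as-printed sign)

    with the sign negated under the "flipped" (initial-to-deformed)
    displacement convention.  The scalar prefactor 2 is calibrated against
    the full pipeline on the uniform case; a familiar variant of this formula
    quotes an 8*pi prefactor, which presumes a monopole coefficient carrying
    the 1/sqrt(4 pi)-normalization of Y00 instead of the plain radius
    difference used here (see docs/methods.md).
    """
    if r0 <= 0.0:
        raise ValueError("r0 must be positive")
    scalar = 2.0 * material.G * (1.0 + material.nu) / (1.0 - 2.0 * material.nu)
    scalar *= (r0 - r1) / r0
    if displacement_sign == "flipped":
        scalar = -scalar
    elif displacement_sign != "as-printed":
        raise ValueError(f"unknown displacement sign convention: {displacement_sign!r}")
    return StressTensor(scalar * np.eye(3), "cartesian", None)


# ----------------------------------------------------------------------------
# Finite-difference oracles (validation only)
# ----------------------------------------------------------------------------

def strain_tensor(sol: ElasticSolution, r, theta, phi, h: float | None = None) -> StrainTensor:
    """Strain from central finite differences of the displacement field."""
    if h is None:
        h = 1e-4 * sol.r0
    _check_interior(sol, r + 2.0 * h)
    x = _point_from_sph(r, theta, phi)
    pts = []
    for i in range(3):
        for s in (+1, -1):
            e = np.zeros(3)
            e[i] = s * h
            pts.append(x + e)
    u = displacement_at_points(sol, np.array(pts))
    J = np.zeros((3, 3))
    for i in range(3):
        J[i] = (u[2 * i] - u[2 * i + 1]) / (2.0 * h)
    eps = 0.5 * (J + J.T)
    return StrainTensor(eps, "cartesian", (float(r), float(theta), float(phi)))


def hooke_oracle_stress(sol: ElasticSolution, r, theta, phi, h: float | None = None) -> StressTensor:
    """Independent stress route: Hooke's law applied to finite-difference strain.

        T = 2 G [ nu/(1-2 nu) tr(eps) E + eps ].

    Used only for validation of the analytic assembly routes.
    """
    eps = strain_tensor(sol, r, theta, phi, h)
    nu, G = sol.material.nu, sol.material.G
    T = 2.0 * G * (
        nu / (1.0 - 2.0 * nu) * eps.trace() * np.eye(3) + eps.components
    )
    return StressTensor(T, "cartesian", eps.location)


# ----------------------------------------------------------------------------
# Surface maps
# ----------------------------------------------------------------------------

def surface_stress_map(
    sol: ElasticSolution,
    n_theta: int = 32,
    n_phi: int = 64,
    offset: float = 1e-6,
) -> pd.DataFrame:
    """Spherical-basis stress components on the initial sphere.

    Evaluates at r = r0 * (1 - offset), just inside the C0 interface, on a
    regular (theta, phi) grid (cell-centered in theta to avoid the poles).
    Returns a DataFrame with columns
    ``theta, phi, Trr, Ttt, Tpp, Trt, Trp, Ttp`` (angles in radians,
    stresses in Pa) ready for ``to_csv``.
    """
    if n_theta < 8 or n_phi < 8:
        raise ValueError("grid must be at least 8x8")
    r = sol.r0 * (1.0 - offset)
    thetas = (np.arange(n_theta) + 0.5) * math.pi / n_theta
    phis = np.arange(n_phi) * 2.0 * math.pi / n_phi
    rows = []
    for th in thetas:
        for ph in phis:
            T = spherical_components(stress_tensor_expanded(sol, r, th, ph))
            c = T.components
            rows.append(
                (th, ph, c[0, 0], c[1, 1], c[2, 2], c[0, 1], c[0, 2], c[1, 2])
            )
    return pd.DataFrame(
        rows, columns=["theta", "phi", "Trr", "Ttt", "Tpp", "Trt", "Trp", "Ttp"]
    )
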