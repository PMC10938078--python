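# Methods

This note records the mathematical model, the conventions, and the numerical
choices implemented in `beadstress`, at the level of detail needed to audit or
re-derive the code.

## 1. Physical model and assumptions

- The bead is a homogeneous, isotropic, linear-elastic sphere of initial
  radius `r0`, shear modulus `G` [Pa] and Poisson's ratio `ν ∈ (−1, 1/2)`
  (strictly below the incompressible limit; the ψ-coupling denominators and
  Hooke's law both degenerate at ν = 1/2).
- Deformations are small: the boundary displacement obeys
  `max |d| / r0 ≲ 0.3`. Beyond that the kinematics are no longer linear and
  the package emits a warning (`displacement_coeffs`) or flags the run
  (`linear_theory_ok` in the pipeline summary).
- Only the **radial** component of the surface displacement is observable
  from a segmented surface (tangential surface motion leaves the shape
  unchanged), so the boundary condition is `u(r0, θ, φ) = d(θ, φ) e_r`.
  This is the standard identification for shape-based sensing and is exact
  for torsion-free loadings; tangential boundary displacement, if present in
  reality, is not recoverable from shape alone and is assumed zero.
- The bead surface must be star-shaped about its center (the radius
  `s(θ, φ)` must be single-valued). Strongly folded or cusped beads are out
  of scope.
- Stress is only evaluated **inside** the bead (`r ≤ r0`); the surrounding
  medium has unknown moduli. The exterior displacement branch (decaying
  irregular harmonics) exists only to provide a complete, bounded field and
  to anchor the boundary condition.

## 2. Conventions

- **Spherical harmonics**: complex orthonormal `Ynm(θ, φ)` with the
  Condon–Shortley phase, evaluated via `scipy.special.sph_harm_y`;
  `θ ∈ [0, π]` is the polar angle. A real field has conjugate-symmetric
  coefficients `c_{n,−m} = (−1)^m conj(c_{n,m})`; this is asserted wherever
  physical fields are assembled.
- **Solid harmonics**: regular `Rnm = rⁿ Ynm` (interior), irregular
  `Inm = Ynm / rⁿ⁺¹` (exterior). Interior expansions are stored against the
  dimensionless profile `(r/r0)ⁿ Ynm`, exterior against `(r0/r)ⁿ⁺¹ Ynm`; the
  two branches match continuously (C⁰) at `r0`.
- **Displacement sign**: the default (`displacement_sign="as-printed"`)
  defines the boundary data from the shape coefficients `s_nm` as
  `d_00 = √(4π) r0 − s_00`, `d_nm = −s_nm` for `n ≥ 1`, i.e. displacement
  measured deformed → initial; a shrunk bead then carries *positive*
  (compressive) isotropic stress. The `"flipped"` option negates `d`,
  giving the initial → deformed convention; all stresses change sign.
- **Uniform closed form**: a sphere uniformly rescaled from `r0` to `r1`
  carries the isotropic stress
  `T = 2 G (1 + ν)/(1 − 2ν) · (r0 − r1)/r0 · E` (as-printed sign). The
  scalar prefactor 2 is what the full pipeline produces; variants of this
  formula with an `8π`-type prefactor correspond to quoting the *monopole
  coefficient* `d_00 = √(4π) (r0 − r1)` instead of the plain radius change
  and to an unnormalized-harmonic convention. The pipeline and the closed
  form agree to machine precision in the tests.

## 3. Elastic solution

Write `u = U + (r² − r0²) ∇ψ` with ψ, `U_x`, `U_y`, `U_z` harmonic.

**Boundary regrouping.** Each Cartesian component of `d(θ,φ) e_r` is a sum of
products `Ynm · Y1μ` (the unit radial vector is a combination of degree-1
harmonics with prefactors `√(2π/3)` and `√(4π/3)`). The products are reduced
to single harmonics with the standard two-Clebsch–Gordan linearization; parity
kills the degree-n term, so a degree-N boundary produces Cartesian components
of degree ≤ N + 1. Clebsch–Gordan coefficients are computed in-package by the
Racah sum in exact integer/rational arithmetic (floats only at the final
square root); `sympy` serves as an independent oracle in the tests.

**Equilibrium coupling.** Substituting the ansatz into the Navier–Lamé
equation `∇(∇·u)/(1 − 2ν) + ∇²u = 0` and writing
`∇·U = Σ c_{n,m} (r/r0)^{n−1} Y_{n−1,m}` (the `1/r0` scaling absorbed into
`c`) yields, degree by degree,

```
a_{n−1,m} = − c_{n,m} / ( 2 (3n − 2 − 2ν(2n − 1)) ),    n ≥ 2,
```

for the interior ψ expansion `ψ = Σ a_nm (r/r0)ⁿ Ynm`. The `n = 1` row
(a degree-0, constant ψ) is pure gauge — `∇ψ₀ = 0` — and is omitted; degree-1
U (uniform dilation and rigid translation) satisfies equilibrium with no ψ at
all. The divergence coefficients come from exact ladder identities for the
Cartesian derivatives of solid harmonics (degree-lowering for regular,
degree-raising for irregular), validated against finite differences. The
denominator cannot vanish for ν < 1/2.

Because the printed forms of this coupling differ across sources, the
implemented formula is *certified numerically*: a second-order
finite-difference evaluation of the Navier–Lamé residual (full 25-point
stencil, step `h = 10⁻⁴ r0`) is part of the test suite, together with a
negative control in which coefficients are deliberately corrupted by 10 % and
the residual must inflate by ≥ 100×.

**Stress.** Two independent routes are implemented and cross-checked to
`10⁻⁸` relative:

1. *Assembled fields* (`stress_tensor`): evaluate `∇·U`, the symmetric
   gradient of U, `∇ψ`, the Hessian of ψ and `r·∇ψ` (Euler homogeneity:
   `r·∇ψ = Σ n a_nm (r/r0)ⁿ Ynm`) from the coefficient tables and combine
   them according to Hooke's law applied to the ansatz strain.
2. *Compiled series* (`stress_tensor_expanded`): expand each stress component
   symbolically into terms `coeff · r^{2k} · R_{L,M}` (k ∈ {0, 1}); the
   `x_i ⊗ ∇ψ` products require a second Clebsch–Gordan pass. The compiled
   form is cached per solution.

A third, physics-level oracle (`hooke_oracle_stress`) applies Hooke's law to
the finite-difference strain of the displacement field and agrees to `10⁻⁴`
relative (the FD truncation floor).

## 4. Surface fitting and geometry

- The complex expansion of the radius is re-parameterized over real degrees
  of freedom (`Y_n0` real part; `2 Re Y_nm`, `−2 Im Y_nm` for m > 0), so the
  fit is an ordinary real least squares (`numpy.linalg.lstsq`). Conjugate
  symmetry is exact by construction. Rank deficiency or condition number
  > 10¹² raises `ConditioningError`.
- **Order selection** (`select_order`): the degree is raised until the
  maximum fit residual drops below `10⁻³ ×` the median radius (the
  "exact-interpolation" degree `n*`), and the working order is `nmax = n*/2`
  — fitting at half the interpolating degree suppresses noise over-fitting.
  The search is capped by the number of points; a non-converged cap is
  reported and warned.
- **Initial radius**: `r0 = (3V/4π)^{1/3}` from the enclosed volume
  `V = (1/3) ∮ s³ dΩ`, computed with a Gauss–Legendre × uniform-φ product
  rule exact for the polynomial degree of `s³`. This encodes
  volume conservation of the hydrogel; for noticeably compressible beads the
  caller can supply `r0` directly via `displacement_coeffs`.
- **Recentering** (`recenter` / `--recenter`): the center is chosen to null
  the degree-1 content of the fitted shape (a pure translation of a surface
  appears, to first order, as degree-1 radius variation). Note that the
  centroid of a finite point sample is offset from the true center by
  ~`r0/√n_points`, which otherwise masquerades as degree-1 deformation.

## 5. Synthetic data generator

`beadstress.synthetic` produces controlled test inputs only — spheres,
uniaxial (`Y20`) shapes and random smooth shapes with `1/n²`-decaying,
conjugate-symmetric coefficients (degree 1 held at zero so no rigid
translation leaks into the displacement). Sampling is area-uniform
(`cos θ` uniform) with optional isotropic Gaussian localization noise. The
generator enforces the linear-theory amplitude cap and a point-count floor of
`(2N+1)²`. It makes no attempt to model real microscopy artifacts
(anisotropic PSF noise, segmentation bias, partial surfaces).

## 6. Numerical choices

- Truncation: the solver's Cartesian expansion carries degree `N + 1` for a
  degree-N boundary — exact, not a truncation. Default surface maps use a
  32 × 64 (θ × φ) grid, cell-centered in θ; the map is evaluated at
  `r = r0 (1 − 10⁻⁶)`, just inside the C⁰ interface.
- Finite-difference steps: `h = 10⁻⁴ r0` for Laplacian/Navier oracles
  (balancing O(h²) truncation against the ~10⁻¹⁴ relative special-function
  evaluation noise amplified by 1/h²), `10⁻⁶ r0` for first derivatives.
- FD validation points avoid the origin (coordinate singularity), the `r0`
  interface (field is only C⁰ there) and the near-field exterior (steep
  `1/rⁿ⁺¹` growth of higher derivatives).
- Problem sizes in tests and the acceptance script (degrees ≤ 6 for random
  solutions, 3000-point clouds, 100-seed noise ensembles) are the package's
  own choices for fast, well-conditioned checks, not physical constants.

## 7. Limitations

- Linear elasticity only; no large-deformation or viscoelastic corrections.
- Radial-displacement boundary data only (see §1); tangential tractions that
  produce no shape change are invisible.
- No exterior stress: the method reports the stress *in the bead*, which at
  the surface equals the traction exerted by the surroundings only through
  the `T·e_r` components.
- Star-shaped surfaces with moderate spectral content; the least-squares fit
  degrades for sparsely or unevenly sampled clouds (monitor the reported
  condition number and residuals).
- Homogeneous moduli: spatial variations in G or ν inside the bead are not
  modeled.
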