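# beadstress

Analytical reconstruction of the full linear-elastic stress tensor acting on a
spherical hydrogel bead, from the measured shape of its deformed surface.

Soft elastic microbeads (e.g. polyacrylamide spheres) embedded in living
tissue act as local stress sensors: the surrounding material deforms them, and
the deformed surface — imaged by microscopy and segmented into a 3D point
cloud — encodes the stresses that produced it. `beadstress` turns such a
point cloud into stress maps by solving the linear elastostatic boundary-value
problem *analytically*, with no meshing and no iterative PDE solver.

## Model

The bead is an isotropic, homogeneous, linear-elastic sphere of initial radius
`r0`, shear modulus `G` and Poisson's ratio `ν`. The displacement field is
taken in the classical harmonic-potential (Love/Trefftz) form

```
u(x) = U(x) + (r² − r0²) ∇ψ(x)
```

where ψ and every Cartesian component of U are harmonic functions, expanded in
solid spherical harmonics (regular `rⁿ Ynm` inside the bead, decaying
`Ynm / rⁿ⁺¹` outside). Substituting this ansatz into the Navier–Lamé
equilibrium equation slaves the ψ coefficients to the divergence of U, so the
entire elastic field is determined by the radial surface displacement alone:

1. **Fit** — the segmented surface points are fitted with a real spherical-
   harmonic expansion of the radius `s(θ, φ)`; the undeformed radius `r0` is
   recovered from the enclosed volume (hydrogels are effectively
   volume-conserving at ν close to 1/2).
2. **Solve** — the radial boundary displacement `d(θ, φ) e_r` is regrouped
   into Cartesian harmonic components via Clebsch–Gordan product
   linearization, fixing U; the equilibrium coupling then fixes ψ.
3. **Stress** — strains and stresses follow in closed form from term-by-term
   differentiation of the expansions; results are reported in the local
   spherical basis `(e_r, e_θ, e_φ)` on the bead surface.

Everything downstream of the fit is exact linear algebra on expansion
coefficients — the only numerics are one least-squares solve and evaluations
of special functions. See [docs/methods.md](docs/methods.md) for conventions,
assumptions and limitations.

## Worked example

Generate a synthetic uniaxially stretched bead (radius 1, quadrupole
coefficient `d20 = 0.1`), then run the full pipeline with the elastic moduli
of common polyacrylamide beads (`G = 720 Pa`, `ν = 0.491`):

```sh
beadstress synth --kind uniaxial --r0 1.0 --d20 0.1 --npoints 3000 -o cloud.csv
beadstress run cloud.csv --recenter --order 4 -G 720 --nu 0.491 --outdir out
```

which logs

```
INFO beadstress: loaded 3000 surface points from cloud.csv
INFO beadstress: fit at degree 4: rms residual 6.13e-13, max residual 1.96e-12, cond 1.55
INFO beadstress: done: r0=1.001, nmax=4, Trr in [-186.3, 235.6] Pa
```

and writes four artifacts into `out/`: `shape.json` (surface expansion),
`solution.json` (elastic potentials), `stress_map.csv` (surface stress
components on a θ×φ grid) and `summary.json`. Selected summary values from
this run:

```
nmax                        4
r0                          1.0008
fit_rms_residual            6.1e-13
max_relative_displacement   0.062
linear_theory_ok            true
Trr_surface_min             -186.3   Pa
Trr_surface_max              235.6   Pa
```

The map is φ-independent (the shape is axisymmetric) with the normal stress
`Trr ≈ −186 Pa` at the poles (tension along the stretch axis) and
`+236 Pa` compression at the equator:

```
      theta       phi        Trr         Ttt         Tpp       Trt      Trp      Ttp
0  0.049087  0.000000 -186.30074 -441.24105 -441.24105 -9.404651  8.6e-08  1.3e-15
1  0.049087  0.098175 -186.30074 -441.24105 -441.24105 -9.404651  8.7e-08 -8.3e-15
```

The same pipeline is available programmatically:

```python
from beadstress import RunConfig, run_pipeline
summary = run_pipeline(RunConfig(input="cloud.csv", recenter=True, order=4,
                                 G=720.0, nu=0.491, outdir="out"))
```

A useful closed-form anchor: a bead uniformly compressed by 5 %
(`r1 = 0.95 r0`) at these moduli carries an isotropic stress of **5964 Pa**,

```python
>>> from beadstress import Material, isotropic_sphere_stress
>>> float(isotropic_sphere_stress(Material(720.0, 0.491), 1.0, 0.95).components[0, 0])
5964.0
```

and the full pipeline reproduces this number to machine precision (see
`tests/test_acceptance.py::test_uniform_case_closed_form`).

## Command-line interface

| command | purpose |
|---|---|
| `beadstress synth` | generate synthetic bead point clouds (sphere / uniaxial / random) |
| `beadstress fit` | fit the spherical-harmonic shape model to a point cloud |
| `beadstress solve` | solve for the elastic potentials from a fitted shape |
| `beadstress stress` | evaluate the surface stress map from a solution |
| `beadstress run` | full pipeline: fit → solve → stress map → summary |

Input point clouds are CSV (`x,y,z` per row, optional header) or PLY
(vertices; requires `trimesh`). Use `--recenter` when the cloud's coordinate
origin is not the bead center: it chooses the center that removes the
degree-1 (pure-translation) content of the fitted shape.
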