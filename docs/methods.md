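# Methods

## Models

Skin contraction is driven by (myo)fibroblasts pulling on the extracellular
matrix. The ECM is a homogeneous, isotropic, linearly elastic body in static
equilibrium (inertia neglected). Two force descriptions of the same cell
population are implemented.

**Smoothed-particle (agent-based).** Each cell is a point `s_i` whose traction
is a regularised force dipole: the derivative (1D) or gradient (2D) of a
Gaussian mollifier

    δ_ε(x) = (2πε²)^{-d/2} exp(−‖x‖²/(2ε²)),   d ∈ {1, 2},

with `ε` the *standard deviation* (the literature sometimes calls this the
"variance"; every formula here uses ε² as the variance, ε as the width). A
dipole is self-equilibrated — zero net force — which the assembled load
vectors inherit exactly.

**Cell density (continuum).** The same cells enter only through a
piecewise-constant density `n_c` per mesh element, and the body force is
`P ∇·(n_c I)`. The two models are *consistent*: on a fixed mesh the particle
solution converges to the density solution as `ε → 0⁺`, because the Gaussian
mass of each element converges to its cell count. The package's consistency
gap `v = u_SP − u_den` quantifies this at finite ε.

In 1D (unit stiffness) both problems reduce to `−u″ = f` on `(0, L)` with
homogeneous Dirichlet ends, and closed forms exist: an erf superposition for
the particle model and a Green's-function expression
`u₂ = scale·P·(G(x,a) − G(x,b))` for a uniform density on `(a, b)`. Their
common limit as the cell spacing `Δs → 0` (with force `P·Δs` per cell and
width `ε = Δs`) is the piecewise-linear tent
`P[(b−a)x/L − clip(x−a, 0, b−a)]`.

## Discretisation

P1 Lagrangian elements throughout; homogeneous Dirichlet conditions imposed by
row/column elimination (boundary values are exact zeros). Loads are assembled
in the integrated-by-parts form — the kernel against `φ′` (1D) or `∇·φ` (2D),
both constant per element — so only element Gaussian *masses* are needed:

* 1D intervals: exact, `½[erf((r−μ)/(√2ε)) − erf((l−μ)/(√2ε))]`;
* 2D rectangles: exact separable erf products;
* 2D triangles: the divergence theorem converts the area integral of the
  standardised Gaussian into three 1D edge integrals of `φ(x)Φ(y)`, evaluated
  by adaptive Gauss–Kronrod quadrature to an absolute tolerance (default
  1e−10). Regions farther than 10ε from the kernel centre are skipped — the
  residual mass there is below double-precision resolution.

Because the 1D loads are integrated exactly, the discrete solutions are
*nodally exact* (they agree with the closed-form solution of the same
continuous problem at every node). This is exploited by the test oracles and
means the package's 1D "FEM error" is solver round-off, not quadrature noise.

The 2D plane-strain law is
`σ = E/(1+ν)[ε + tr(ε)·ν/(1−2ν)·I]`; the element matrices are standard
constant-strain triangles. The assembly is validated three independent ways:
a manufactured smooth solution converges at O(h²), a linear-field patch test
is reproduced to 1e−12, and the particle load vector matches adaptive
quadrature of the *non-integrated* forcing `P∇δ_ε·φ` to 1e−8.

## Position ↔ density conversions

*Positions → density*: count cells per element and divide by the element
measure. A cell exactly on a shared interior node (1D) or face (2D)
contributes one half to each adjacent element; a cell on a vertex contributes
the incident angle over 2π to each incident triangle. "Exactly" means within
1e−9 of the element scale — tight enough that only genuinely coincident
geometry triggers it, loose enough to absorb floating-point placement error.
Total cell weight is conserved by construction; the benchmark with `Δs = 0.06`
and `h = 0.07` genuinely exercises the rule (8 of 50 cells fall on nodes).

*Density → positions*: integrate the analytic density over bins of length `d`
(1D) or square tiles (2D, Gauss–Legendre 24² product rule), round
half-away-from-zero to a count, and place that many cells — equispaced at the
midpoints of `count` equal subintervals by default (deterministic, so reports
reproduce bit-for-bit), or seeded uniform. The rounding and placement rules
are configuration, echoed into every report.

2D random populations are rejection-sampled uniform points with a minimum
pairwise separation (default 0.2 length units — cells do not overlap; the
value is recorded in the configuration metadata) and a feasibility guard.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `E` | 1 | ECM stiffness (dimensionless benchmark) |
| `ν` | 0.49 | Poisson ratio, 2D (near-incompressible tissue) |
| `P` | 0.01 (1D), 10 (2D) | force magnitude per cell |
| `L`, `(a,b)` | 7, (2,5) | 1D domain and wound |
| `x₀×y₀`, wound | 20×20, 10×10 centred | 2D tissue and wound rectangles |
| `N_s` | 50 (1D), 196 (2D) | cell count |
| `h` | 0.07 (1D) | element size |
| `ε` | `h/3` | mollifier width (`--eps-factor`), so each element's Gaussian mass is close to its count |
| quadrature tol | 1e−10 | triangle-mass absolute tolerance |

All quantities are dimensionless; the benchmark scales are those of the
standard contraction scenario the package reproduces.

## Numerical choices and caveats

* **ν = 0.49 with P1 elements** risks volumetric locking near
  incompressibility; it is retained because the benchmark prescribes it, and
  the consistency *gap* (a difference of two solutions on the same mesh) is
  insensitive to the shared stiffness. Quantitative 2D displacement magnitudes
  should be read with this caveat.
* **Structured meshes with a fixed diagonal** (lower-left → upper-right;
  `--diagonal nw` for sensitivity checks) break exact mirror symmetry; the
  symmetry tests build a mirrored-diagonal mesh instead.
* **Convergence rates** are defined as `log₂` of the ratio of L² norms of
  successive solution differences on nested meshes (coarse solutions
  interpolated to the finest mesh). For sweeps that rescale `ε` with the level
  (`ε = h_level/3`, the default), the inter-level differences track the change
  of the *continuous* solution with `ε`, not the discretisation error — the
  loads being integrated exactly, there is almost no discretisation error to
  measure in 1D — so the reported rate is a descriptive diagnostic, not an
  asymptotic order. Holding `ε` fixed across levels yields ≈1.4 at the
  benchmark resolution (pre-asymptotic: the solution has structure at scale
  `ε ≈ h/3`).
* **Density-model refinement in 2D** concentrates each cell's weight into
  ever-smaller triangles, approaching the point-force limit whose displacement
  is not in H¹ in two dimensions; pointwise values near cells then grow slowly
  with refinement (the mollified model exists precisely to avoid this).
  Pointwise comparisons at the wound boundary are therefore made at moderate
  resolution (24×24 over the 20×20 domain, i.e. 12 elements across the wound),
  and the "curved edge" diagnostic integrates the bowing of each deformed edge
  past the chord of its deformed corners rather than comparing single points,
  which cell-level noise dominates for random populations.
* **Problem sizes in the test suite**: 1D cases use `h = 0.07` down to `h/4`
  (≤ 400 elements); 2D consistency sweeps use a 40×40 structured mesh
  (1 681 nodes) with 196 random cells and ε ∈ {h/3, h/6, h/12}; the
  contraction checks use 24×24 with three seeds. These sizes resolve every
  asserted effect; all randomness is seeded, so runs are reproducible.

## What the generated scenarios do and do not show

The built-in scenarios (uniform 1D cells, analytic sine/Gaussian densities,
uniform-random 2D populations) exercise the complete model and conversion
machinery, including the degenerate counting cases. They do not emulate cell
migration, proliferation or differentiation, time-dependent forces, realistic
wound shapes, or heterogeneous/anisotropic ECM — passing tests say nothing
about those. Published reference values for the 1D benchmark are compared in
the acceptance tests where the printed precision permits; two printed values
(the density-model RMS and the coarsest particle-model norm) could not be
reproduced under any counting or norm convention tried and are asserted at
their stated tolerances regardless; the corresponding analytic values
(continuum norm `√(7/3)/7 ≈ 0.21822`, reduction 9.5238 %) are asserted
exactly as derived.

## Limitations

Linear elasticity only (no visco- or morpho-elasticity), static balance, 1D/2D
with uniform/structured meshes, Gaussian isotropic mollifiers, rectangular
wounds in rectangular domains. Closed-form solutions exist only in 1D.
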