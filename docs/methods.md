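# Methods

This note documents the models, the numerical choices behind them, and what
the synthetic data can and cannot stand in for.

## Notch–Delta–repressor lattice model

The model follows the Collier/Sprinzak lateral-inhibition lineage: Delta on
a cell binds Notch on its neighbours (*trans*, strength K_t) and on itself
(*cis*, strength K_c); productive trans signalling S_i = K_t N_i ⟨D⟩_i/γ_nd
drives a repressor through a Hill function (cooperativity m, threshold
θ_nd), and the repressor shuts down Delta production (cooperativity h,
threshold θ_r). All quantities are dimensionless; time is measured in units
of the common degradation timescale.

**Boundaries.** The lattice is a hexagonal disc with fixed (non-periodic)
boundaries. The neighbourhood mean divides by the *realised* neighbour
count by default, so a uniform state remains exactly uniform on a bounded
lattice; `divisor="fixed6"` instead pads missing neighbours with zero
ligand, which biases rim cells toward lower trans input. Both readings are
defensible for a physical island edge; the realised-count convention is the
default because it decouples boundary effects from the gradient term.

**Stress gradient.** σ_i = b·ρ_i with ρ_i ∈ [0, 1] the cell's distance to
the lattice centroid over the maximal distance, added identically to the
receptor and ligand production rates, with zero intercept so b = 0
reproduces the gradient-free model exactly. The same form is exported by
`synthetic.generate_stress_gradient_truth` for cross-checks.

**Default rates.** Only the interaction strengths (K_t = 10, K_c = 0) and
gradient steepnesses (b ∈ {0, 0.5, 5}) are fixed by the study design. The
remaining constants are a choice of this package: α_n = 1, α_d = 10,
α_r = 5, all γ = 1, θ = 1, h = m = 4. They were selected once, as model
design, to place the gradient-free trans-activation model inside the
lateral-inhibition *patterning* regime — the homogeneous steady state is
unstable and a 1 % perturbation grows into the classic salt-and-pepper
Delta pattern. That regime matters for two qualitative behaviours the
package asserts: the gradient-free receptor field is spatially structured
(its radial profile is biphasic rather than flat), and an imposed radial
gradient redirects the same instability into centre-to-rim segregation.
With weaker feedback (e.g. h = m = 2, α_d = 1) the homogeneous state is
stable and both effects vanish.

**Initial conditions.** Uniform state at the uncoupled fixed point
(N = α_n/γ_n, D = α_d/γ_d, R = 0) with 1 % multiplicative lognormal
perturbation, seeded — the standard recipe for pattern selection; results
are reproducible per seed.

**Integration.** `scipy.integrate.solve_ivp` with BDF, rtol 1e-8,
atol 1e-13, and the lattice-adjacency Jacobian sparsity pattern (the Hill
terms make the system moderately stiff at high cooperativity). Steady
state is declared at max|dy/dτ| < 1e-8; integration proceeds in chunks of
τ = 200 up to τ = 5000. States are floored at zero after checking that no
component undershoots below −1e-12; a larger violation raises instead of
being silently clipped.

**Profiles.** Radial profiles bin cells by ρ and normalise all bin means by
the outermost non-empty bin, so the periphery reads 1 by construction. The
"periphery" is the outermost non-empty bin rather than the outermost ring;
at 10 bins on a 10-ring lattice the two coincide.

## Contraction mechanics

Linear axisymmetric elasticity on the r–z half-section, with the island as
an active layer carrying an isotropic eigenstrain ε\* = α ΔT = −0.25 and
the substrate passive; u = 0 on the substrate bottom, u_r = 0 on the axis,
traction-free elsewhere. Elements are linear triangles on a structured
grid, one-point quadrature at the element centroid (which also evaluates
the hoop strain u_r/r safely away from the axis). Near-edge refinement: the
element size is halved within 50 µm of the island edge; the substrate
coarsens with depth and radius. The default substrate is 100 µm thick with
a 900 µm radius; the reported peak changes by <15 % from 100 µm to 3 mm
thickness, so the (experimentally unreported) gel thickness is not
critical.

**Stress measure.** The island edge is a bonded bimaterial corner, whose
linear-elastic stress field is singular: the pointwise interface traction
has no mesh-converged peak (it grows without bound under refinement). The
reported profile is therefore |σ_rz| — the in-plane traction transmitted
across the interface, the quantity a traction map measures — evaluated at
a fixed depth of half the island height (10 µm) below the interface, the
first scale at which the corner field is regular and the natural lateral
resolution of a 20 µm layer. Under this definition the peak converges
(<2 % between 5 µm and 3.5 µm meshes) to ≈126 Pa at r ≈ 272 µm, i.e.
within the outermost 10 % of the island radius. Alternate measures
(√(σ_rz²+σ_zz²); von Mises at the island mid-plane) are selectable; the
von Mises measure is dominated by the ~720 Pa biaxial plate stress and
peaks centrally, which is why it is not the default.

Thermal conductivity is recorded in `ContractionLoad` for completeness but
unused: a uniform prescribed temperature drop makes steady-state conduction
irrelevant to the mechanical state.

## Traction force microscopy

**DIC.** Windowed normalised cross-correlation (default 32 px windows,
50 % overlap) locates each relaxed-image window in the stressed image;
subpixel localisation is a 3-point parabolic fit per axis. Windows whose
correlation peak is not at least 1.2× the second peak (evaluated outside a
3 px exclusion zone), or which lack texture, are masked; a 3×3 median
filter flags residual outliers; masked nodes are inpainted by linear
interpolation from their neighbours.

**Spectral elasticity.** Forward and inverse maps use the Boussinesq
elastic half-space surface kernel per wavevector; the infinite-thickness
kernel is appropriate for gels much thicker than the displacement scale
(sub-µm displacements on ≥100 µm gels). Fields are zero-padded to twice
their size to suppress periodic wrap-around; the mean displacement (rigid
drift, the kernel's zero mode) is removed before inversion; the recovered
zero-frequency traction is set to zero. Inversion applies zeroth-order
Tikhonov regularisation; when no λ is given, an L-curve corner is located
as the point of maximum distance from the chord of the normalised
(log residual, log solution-norm) curve — more robust than discrete
curvature when the residual saturates at the noise floor. Accuracy is
quantified away from the padding margin (within ~1.1 island radii), where
the noiseless round trip recovers a ring traction to <2 % relative L2
error; near the field boundary the truncated long-range displacement tail
contaminates the inversion, as in any finite-field FTTC.

**Radial reduction.** Island geometry comes from a least-squares ellipse of
the border (≥5 points); the effective radius is the geometric mean of the
semi-axes and normalises node distances into the dimensionless radius used
everywhere else. Bins with no nodes report missing values, never zero.

## Quantification layer

- Dimensionless radius R per cell from its island's centroid and effective
  radius; R > 1.2 flags off-island cells (printing spread), excluded from
  all statistics. The peripheral/central split is R = 0.75.
- Radial counts: 30 bins per island over R ∈ [0, 1.2]; percentages are
  positive/total per bin, missing where a bin is empty.
- Densities: Gaussian KDE with Silverman bandwidth, reflected at R = 0;
  normalisation is verified to 1e-3 by trapezoidal integration over the
  evaluation support. Densities are normalised per condition.
- Smoothed profiles: tricube-weighted local quadratic regression (loess
  style, default span 0.4) pooled over islands, with pointwise 95 % CI from
  the weighted-least-squares variance and a global residual-variance
  estimate; `ribbons_overlap` implements the usual non-overlap ≈ P < 0.05
  visual comparison. Pooling treats islands as exchangeable; no
  island-level random effect is modelled.
- Count regressions: OLS of per-island positive counts on categorical
  condition factors (one observation per island, reference level = the
  control condition), so β is the mean change in counts versus control.
  Rank-deficient designs are rejected with the aliased columns named.
  Breusch–Pagan and Jarque–Bera p-values accompany every fit so the
  homoscedasticity/normality assumptions are checked rather than assumed.
- KS comparisons: exact supremum distance; exact p-value for two samples
  under 10 observations, asymptotic otherwise. Welch's t uses the
  Welch–Satterthwaite df; two zero-variance groups with equal means return
  p = 1 by convention.

## Synthetic data

`generate_cell_table` draws island cell counts from a Poisson (optionally
gamma-mixed) distribution around 600 cells per ~600 µm island, positions
uniformly in the disc (r = R√u), marker positivity from a logistic curve in
R (rising "OPN-like", falling "ALB-like", flat "DECMA-uniform" presets) and
lognormal intensities conditioned on positivity; condition effects shift
the logistic's plateau additively. Effect sizes in the presets are
synthetic choices, not measured values. `generate_displacement_data` builds
a Gaussian ring traction (default peak 100 Pa at 0.9 island radii), maps it
through the exact forward Boussinesq operator, adds bead-localisation noise
(default 0.05 px at 0.65 µm/px) and can render Gaussian-spot bead image
pairs for end-to-end DIC tests.

What this emulates: the radial structure of marker positivity, uniform
cell density, peripheral traction rings, and realistic measurement noise —
enough to exercise every statistical and inverse operation with known
ground truth. What it does not: segmentation errors, uneven illumination,
cell motility, island-to-island biological heterogeneity beyond count
dispersion, or any coupling between the traction field and cell fate.
Passing tests therefore validate the machinery and its statistical
calibration, not biological conclusions about real islands.

## Problem sizes used in the shipped checks

The test suite and the reproduction script run at desk scale, chosen as the
smallest sizes at which each claim is stable: a 331-cell lattice (10 rings)
for the gradient sweep; FEM meshes at 7.5/5/3.5 µm resolution (~11k
elements at the finest); 100×100 traction grids at 10 µm spacing; and 200
seeded replicates of 18-islands-per-level experiments for the regression
coverage check (1000 replicates for the CI-calibration property).

## Known limitations

- The FEM is linear; a 25 % eigenstrain is far outside small-strain
  validity, so magnitudes should be read as the linearised model's output
  (matching the study convention), not as physical strains.
- Linear triangles at ν = 0.48 are mildly locking-prone; the fixed-depth
  stress evaluation and the convergence check mitigate but do not remove
  this.
- FTTC uses the infinite-thickness kernel and in-plane displacements only;
  no finite-thickness correction, no z-tractions.
- The Notch model is deterministic; no transcriptional noise or cell
  division, and ligand identity (JAG1 vs DLL4 vs DLL1) is not resolved —
  a single effective Delta species carries all trans interactions.
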