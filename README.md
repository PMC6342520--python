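# islandfate

Analysis toolkit for **spatially patterned cell-fate specification on
circular micropatterned islands** — the setting in which bipotential liver
progenitor cells seeded on ~600 µm protein islands differentiate toward a
biliary fate at the island periphery and a hepatocytic fate at the centre,
coincident with peripherally concentrated mechanical stress.

The package bundles the four computational layers such a study needs, plus a
synthetic-data generator so that every layer is testable without microscopy
data:

| module | what it does |
|---|---|
| `islandfate.notch` | Notch–Delta–repressor lateral-inhibition ODE model on a bounded hexagonal lattice, with a radial stress gradient feeding receptor and ligand production |
| `islandfate.mechanics` | axisymmetric thermoelastic finite-element model of a contracting cell layer bonded to a passive elastic substrate |
| `islandfate.tfm` | traction force microscopy: DIC bead-displacement fields and regularised Fourier-transform traction cytometry (Boussinesq half-space) |
| `islandfate.quant` | radial spatial statistics on per-cell tables: dimensionless radius, 30-bin counts/percentages, KDE densities, loess profiles with 95 % CI ribbons, per-island OLS count regressions, Kolmogorov–Smirnov and Welch tests |
| `islandfate.synthetic` | seeded generators of cell tables (logistic-in-radius marker positivity, uniform density) and ring-traction displacement data with ground truth |

## The models in brief

**Notch lattice.** Each cell *i* on a hexagonal disc lattice carries Notch
receptor *N*, Delta ligand *D* and repressor *R*:

```
dN_i/dτ = α_n − K_t N_i ⟨D⟩_i − K_c N_i D_i − γ_n N_i + σ_i
dD_i/dτ = α_d / (1 + (R_i/θ_r)^h) − K_t D_i ⟨N⟩_i − K_c N_i D_i − γ_d D_i + σ_i
dR_i/dτ = α_r S_i^m / (θ_nd^m + S_i^m) − γ_R R_i ,   S_i = K_t N_i ⟨D⟩_i / γ_nd
```

with ⟨·⟩ the mean over a cell's realised neighbours (fixed, non-periodic
boundaries) and σ_i = b·ρ_i a stress source linear in the dimensionless
radius ρ_i, modelling mechanically upregulated receptor/ligand expression.
In the trans-activation regime (K_t = 10, K_c = 0), increasing the gradient
steepness b shifts signalling activity S to the island rim.

**Island mechanics.** The cell layer (600 µm ⌀ × 20 µm, E = 1.5 kPa,
ν = 0.48) contracts through an isotropic eigenstrain ε\* = α ΔT
(0.05 K⁻¹ × −5 K) while bonded to an elastic substrate (E = 30 kPa,
ν = 0.48) with fixed bottom. The linear axisymmetric solve yields an
interface traction profile that concentrates at the island edge; because
the bonded bimaterial corner is singular, the profile is reported half an
island height below the interface, where it is mesh-convergent.

**TFM.** Displacements u(k) and tractions t(k) are linked per wavevector by
the Boussinesq surface kernel `G(k) = 2(1+ν)/(E k³) [...]`; the inverse
problem is solved spectrally with zeroth-order Tikhonov regularisation (λ
chosen by an L-curve corner heuristic when not supplied).

## Worked example

```python
from islandfate.lattice import build_disc_hex_lattice
from islandfate.notch import NotchParams, run_condition_sweep
from islandfate import mechanics as mech

lattice = build_disc_hex_lattice(10)            # 331 cells
params = NotchParams(k_t=10.0, k_c=0.0)        # trans-activation regime
records = run_condition_sweep(params, b_values=[0.0, 0.5, 5.0], seeds=[1],
                              lattice=lattice, n_bins=10)
for rec in records:
    ratio = rec.summary["S_peripheral_central_ratio"]
    print(f"b={rec.b:<4} peripheral/central signalling ratio = {ratio:.2f}")

mesh = mech.build_axisymmetric_mesh(mech.IslandGeometry(), resolution=5.0)
sol = mech.solve_contraction(mesh)
prof = mech.interface_stress_profile(sol)
print(f"peak interface stress = {prof.peak:.0f} Pa at r = {prof.peak_radius:.0f} µm")
```

prints

```
b=0.0  peripheral/central signalling ratio = 1.01
b=0.5  peripheral/central signalling ratio = 1.24
b=5.0  peripheral/central signalling ratio = 2.37

peak interface stress = 124 Pa at r = 272 µm
```

Without a stress gradient (b = 0) the lattice settles into the classic
salt-and-pepper lateral-inhibition pattern with no net radial bias (ratio
≈ 1) and a biphasic radial receptor profile; steepening the gradient
produces progressively stronger peripheral Notch activation — the same
centre-vs-rim segregation seen in the stained islands. The mechanical model
independently places the stress maximum at the island rim (r ≈ 272 of
300 µm), at ~10² Pa.

There is also a thin CLI over the same functions:

```bash
islandfate notch-sim --config cfg.yaml --out out/
islandfate fem       --config cfg.yaml --out out/
islandfate tfm       --ref ref.tif --relaxed rel.tif --pixel-size 0.65 --out out/
islandfate quantify  --cells cells.csv --islands islands.csv --out out/
islandfate generate  cells --seed 3 --out out/
```

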