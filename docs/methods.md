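# Model and methods

## The model

`atherosim` simulates early atherosclerotic plaque growth in a 2D cross
section of the arterial intima, the thin layer between the endothelium
(lumen side, boundary Γ_I) and the media (boundary Γ_M).  Fourteen species
interact: the lipoproteins LDL `L` and HDL `H`, oxidised LDL `L_ox`, free
radicals `r`; the signalling proteins MCP-1 `P`, IFN-γ `I_γ`, IL-12 `I_12`,
PDGF `G`; the enzyme pair MMP `Q` and TIMP `Q_r`; and the cells —
macrophages `M`, T cells `T`, smooth muscle cells `S` and foam cells `F`.
All concentrations and densities are in g/cm³; lengths in cm; times in
days.  Blood lipid levels are supplied in mg/dL (1 mg/dL = 10⁻⁵ g/cm³).

Each species obeys an advection–reaction–diffusion equation

    ∂X/∂t + ∇·(u X) − D_X ΔX = F_X ,

where the advection term is present only for the cells (and is carried by
the common tissue velocity `u`), and the reaction network `F_X` is listed
in `atherosim.model`.  The backbone of the network:

* free radicals are supplied at rate `r0` and decay at `d_r`; they oxidise
  LDL (`k_L L r`) and HDL (`k_H H r`);
* ox-LDL accumulates from oxidation and is cleared by macrophage
  ingestion, `λ_ox · M/(K_ing+M) · L_ox/(K_Lox+L_ox)`; ingestion converts
  macrophages to foam cells at rate `λ_F M φ`;
* monocytes enter through Γ_I with an influx coefficient that grows with
  local ox-LDL and is damped by local HDL,
  `β_M (1 + L_ox/K_MLox) / (1 + H/K_MH)`;
* IL-12 production needs macrophages (hill factor `M/(K_M+M)`) and is
  damped by HDL; T cells are activated by IL-12 in conjunction with
  antigen presentation (a second `M/(K_M+M)` factor) and damped by HDL;
  T cells secrete IFN-γ, which sustains macrophage activation;
* SMCs enter from the media (enhanced by MCP-1 and PDGF), produce MMP;
  MMP and TIMP bind mutually and degrade; MMP attacks the ECM.

The quadratic macrophage dependence of the T-cell arm — IL-12 production
and antigen presentation each carry one hill factor — makes adaptive
inflammation the steepest lipid-sensing stage of the network, and is what
separates a doubling plaque at (LDL, HDL) = (190, 40) mg/dL from a
vanishing one at (70, 60).

### Tissue mechanics and the free boundary

Cells and ECM are modelled as an incompressible mixture: the total density

    M + T + S + F + ρ = C_tot = 1 g/cm³

is constant, and cell production must be accommodated by motion.  The
tissue is a porous medium with Darcy velocity `u = −∇σ`.  All four cell
species are integrated and the ECM density is the exact closure residual
`ρ = C_tot − (M+T+S+F)`; summing the five transport equations (one common
cell diffusivity `D`, one velocity) yields the pressure equation

    −Δσ = f + g ,

with `f` the sum of the local cell sources and `g` the ECM balance

    g = λ_ρ ρ (1 − ρ/ρ0) − d_ρQ Q ρ ,      ρ0 = C_tot .

With `ρ0 = C_tot` the logistic factor equals the local cell fraction, so
remodeling is carried by resident cells and vanishes in acellular tissue;
MMP attack shifts the balance toward domain contraction.  On the free
boundary Γ_I cell-to-cell adhesion pins `σ = γ κ` with κ the signed
curvature (positive where the plaque bulges into the lumen), and the
boundary moves with `V_n = −∂σ/∂n`.  The adhesion constant is small
(`γ = 10⁻⁹` pressure·cm): it regularises the interface at the node scale
without competing with growth — at order-one values, curvature flow would
flatten any plaque in a fraction of a day at these domain sizes.

### Boundary conditions

Flux (Robin) conditions on Γ_I for `L, H, M, T`:

    D_X ∂X/∂n + η_X β_X (X − X_0) = 0 ,

with `X_0` the blood level, `β_X` the tabulated influx rate (1/cm) and
`η_X` a boundary mass-transfer coefficient: the endothelial permeability
`eta_lipid` for the lipoproteins and the transendothelial migration
coefficient `eta_cell` for cells.  `eta_lipid` is finite (tissue
lipoproteins approach blood levels over weeks, τ ≈ 60 days), which makes
the influx rates `β_L, β_H` control the early lipid *exposure* of a
lesion.  SMCs enter through Γ_M with
`β_S (1 + P/P0 + G/K_SG)`; the lateral channel boundaries are periodic;
all other species are no-flux.

### The observable

The plaque weight is `W = ∫_Ω (M+T+S+F) dx` per unit vessel depth (the
model is 2D, so W has units g/cm).  Because the advective fluxes cancel
against boundary motion, W changes only through reactions and boundary
influx — domain growth and compression redistribute cell mass without
creating it.

## Numerics

* P1 (linear triangle) Galerkin elements on mapped structured meshes: the
  channel strip and the annulus are graphs over a base coordinate, meshed
  by a tensor grid pushed through the boundary profile.  Remeshing after
  free-boundary motion regenerates the mapped grid from the displaced
  boundary polyline (which doubles as tangential node redistribution) and
  transfers fields by per-column linear interpolation.
* Backward Euler in time, dt = 0.5 day by default, with halving on
  rejected steps (overcrowding or boundary-speed violations) and recovery
  after sustained success.  Each species' own linear loss is implicit
  (including the state-linearised ingestion and MMP/TIMP binding rates);
  cross-species couplings are explicit.  Verified second order in space
  by manufactured solutions (observed orders ≈ 1.9–2.0).
* Advection uses the transport form `u·∇X` plus the exact divergence
  `∇·u = f + g` as a nodal implicit rate.  This is algebraically the
  conservation form but needs no advective boundary-flux terms; cell
  Péclet numbers stay below one at the Darcy velocities this model
  produces.
* Periodic lateral boundaries by master/slave degree-of-freedom
  identification; the pressure is pinned by Dirichlet values `γκ` on Γ_I.
  Linear systems are solved by sparse LU with iterative refinement; the
  normwise backward error is required to be ≤ 10⁻¹⁰.
* Negative nodal concentrations after a step (tiny undershoots of the
  Galerkin transport) are clipped to zero and the clipped mass is logged.
* The free boundary moves explicitly with a displacement cap of 0.2 of
  the local edge length per move; moves are scheduled adaptively well
  before the cap is reached.  The boundary velocity is evaluated from
  one-sided P1 gradients (periodic partners pool their stencils) and
  smoothed with two passes of a 1-2-1 tangential filter.

## Parameters

The canonical constants live in `atherosim.parameters.PARAMETER_REGISTRY`
with units and provenance-style descriptions; `validate()` checks the
invariants (positivity, `k_L > k_H`, equal cell diffusivities).  Two
derivation utilities document how several constants arise: a molar↔mass
bimolecular rate conversion (the MMP/TIMP binding pair 4.98×10⁸ and
1.04×10⁹ cm³/g/day corresponds to one molar rate ≈ 3×10⁵ /M/s applied at
52 and 25 kDa, so their ratio is exactly 52/25) and an
accessible-surface-area diffusivity law `D ∝ MW^0.73`, pinned at the
free-radical entry.  The tabulated diffusivities are canonical; the law is
supplied for provenance and is deliberately not used to overwrite them
(the tabulated values are not mutually consistent under any single power
law).

Several constants of the published description are not recoverable from
the available text (the displayed formulas are lost) and were fixed here
as model conventions, jointly calibrated once so that the five-scenario
structure of the study is reproduced:

| constant | value | role |
|---|---|---|
| `d_r` | 0.26 /day | free-radical decay (radicals are short-lived; without a sink the model has no steady states) |
| `K_ing` | 2×10⁻⁷ g/cm³ | macrophage half-saturation of ox-LDL ingestion |
| `K_MLox` | 2×10⁻⁹ g/cm³ | ox-LDL scale of enhanced monocyte recruitment |
| `K_MH` | 7×10⁻⁵ g/cm³ | HDL scale of inflammation damping |
| `K_SG` | 10⁻⁵ g/cm³ | PDGF scale of SMC recruitment |
| `eta_cell` | 6×10⁻⁵ cm²/day | transendothelial migration of monocytes/T cells |
| `eta_media` | 2×10⁻⁶ cm²/day | SMC migration across Γ_M |
| `eta_lipid` | 2×10⁻⁴ cm²/day | endothelial permeability to lipoproteins |
| `chi_P, chi_G` | 0.1 cm⁵/g/day | SMC chemotaxis (subdominant to Darcy drift) |
| `chi_rho` | 10⁻³ cm⁵/g/day | SMC haptotaxis |
| `gamma_adh` | 10⁻⁹ pressure·cm | interface adhesion/regularisation |

These were chosen before the acceptance suite was frozen and are not
tuned per test.

## The fixture: an established plaque

The study never specifies the initial lesion.  The repo convention: a
small seed infiltrate (macrophages at 0.08 of blood monocyte density,
foam cells at 0.04, T cells at 0.002 of blood density, a trace of SMCs)
under a Gaussian bump of the intima (length 0.1 cm, thickness 0.01 cm,
bump amplitude 0.005 cm, width 0.02 cm), grown for 220 days under an
intermediate blood profile of (145, 47) mg/dL with default constants.
The spin-up runs once per process on the coarse mesh, is cached, and is
interpolated to the requested resolution.  Tissue lipoproteins are then
set to the benign corner of the observed blood ranges (70, 40 mg/dL):
each run's actual blood profile enters through the endothelium at the
finite permeability, so the lesion experiences its lipid environment
dynamically rather than instantaneously.

At this state the plaque weighs ≈ 10⁻⁵ g/cm and is T-cell/macrophage
dominated; foam cells form a small, strongly lipid-sensitive component.

## What the analyses compute

* **Scenarios** (`run_scenario`): W(t) for one (L0, H0) pair.  With the
  defaults, (190, 40) roughly doubles by day 300, (130, 50) stays within
  ~20% of its initial weight, and (70, 60) decays to below a quarter.
* **Risk map** (`riskmap.sweep`): the relative change
  R = (W(100 d) − W(0))/W(0) on an (LDL, HDL) grid, partitioned into
  regions I (R ≥ +0.10), II, III (R ≤ −0.10).  The thresholds are a repo
  convention (the study prints a colour scale, not numbers).  The
  published map uses 121×21 grid points; desk-scale runs use reduced
  grids, which is adequate because R is smooth and monotone in both
  coordinates.
* **Sensitivity** (`sensitivity.run_sensitivity`): Latin hypercube over
  the 22 tabulated ranges (15 production rates, 5 influx rates, L0, H0),
  one simulation per draw, PRCC of each parameter against W at the
  horizon.  Desk-scale default: n = 60 draws, 100-day horizon, coarse
  mesh, dt = 1 day.  With k = 22 parameters, n = 30 leaves only 7
  residual degrees of freedom and the partial correlations of even the
  dominant parameters become seed-dependent; n = 60 (37 degrees of
  freedom) is the smallest design we found that reproduces the sign
  pattern of the dominant parameters across independent seeds.

## Problem sizes used by the shipped checks

Scenario runs: ~1.1k nodes (h = 10⁻³ cm), dt = 0.5 day, 300 days.
Risk map: 5×3 grid, 63-node mesh (h = 5×10⁻³), 100 days.  Sensitivity:
n = 60, 63-node mesh, dt = 1 day, 100 days, three seeds.  These sizes
were chosen so the full suite completes on a laptop-class machine; the
100-day weight ratio changes by well under 10% between the 63-node and
1.1k-node meshes, so the coarse analyses are faithful to the fine ones.

## What the synthetic conditions do and do not show

Everything here is simulation of a mechanistic model: the "data" are the
model's own fields.  Passing tests demonstrate internal consistency
(closure, conservation, convergence, oracle agreement) and that the
reconstructed network reproduces the published qualitative structure —
the five-scenario ordering, the monotone risk map, the sensitivity signs.
They do not validate the model against clinical measurements; the
absolute weights, time scales and thresholds inherit the (partly
irrecoverable, partly crude) provenance of the published constants.

## Known limitations

* The displayed equations of the source are lost; every functional form
  here is a reconstruction constrained by the printed constants, units
  and term descriptions.  Different reconstructions could reproduce the
  same headline numbers with different mechanisms.
* Foam cells are a minor mass component at these parameter values; the
  plaque bulk is T-cell/macrophage.  The published figures suggest a
  foam-dominated lesion, which these constants cannot produce (ingestion
  capacity `λ_ox` and conversion `λ_F` bound the foam inventory).
* The MMP→weight pathway acts only through compression and
  concentration of the cellular phase (the ECM is the closure residual);
  its PRCC is positive but small.
* 2D only; no shear stress, rupture mechanics, or topology changes of
  the interface; the channel's lumen boundary moves as a whole.
* The periodic Gaussian bump has a weak curvature kink at the seam; with
  the small adhesion constant it only produces a slightly elevated local
  boundary velocity.
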