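# Methods

## The model

`edemasim` simulates glioblastoma growth on a 2D brain slice together with
the tumor-associated vasogenic edema that dominates what is visible on
T2/FLAIR MRI, and the response of both to an anti-angiogenic
(bevacizumab-like) course.  Six fields live on the gray/white-matter mask:

* `c` — normoxic (well-oxygenated) tumor cells,
* `h` — hypoxic tumor cells (migrate but do not divide),
* `n` — necrotic cells (immobile),
* `v` — vascular endothelial cells,
* `a` — a generic angiogenic-factor pool (VEGF-like), mmol/cc tissue,
* `l` — edematous extracellular fluid, normalized to the capillary level.

With total occupancy `T = (c+h+n+v)/K` (carrying capacity `K`) and vascular
efficiency `V = v/(v+c+h)` as the oxygen-supply surrogate, the coupled
reaction–diffusion system is

```
∂c/∂t = ∇·(D(x)(1−T)∇c) + ρc(1−T) + γhV − βc(1−V) − αₙ(n/K)c
∂h/∂t = ∇·(D(x)(1−T)∇h) − γhV + βc(1−V) − αₕh(1−V) − αₙ(n/K)h
∂n/∂t = αₕh(1−V) + αₙ(n/K)(c+h+v)
∂v/∂t = ∇·(Dᵥ(1−T)∇v) + μ·a/(Kₘ+a)·v(1−T) − αₙ(n/K)v
∂a/∂t = ∇·(Dₐ∇a) + δ_c c + δ_h h − q·μ·a/(Kₘ+a)·v(1−T) − ωav − λa
∂l/∂t = ∇·(D_l∇l) + K_trans(a)·(l_v − l) − δ_l l
```

with the saturating vessel permeability `K_trans(a) = K_max·a/(a+K_half)`.
The invasion rate `D(x)` is piecewise constant: `D_w` in white matter,
`D_g` in gray matter, zero in CSF — and CSF/outside voxels are excluded
from the unknown set entirely, so neither cells nor fluid can enter them.
Homogeneous Neumann (no-flux) conditions hold at the brain boundary.

Conventions adopted where the printed system is ambiguous: the
hypoxic→necrotic switch uses `(1−V)` in both the `h` and `n` equations
(internal consistency of the necrosis bookkeeping); angiogenic factors
disperse with their own coefficient `Dₐ`; the contact-necrosis terms are
normalized by `K` so `αₙ` keeps units 1/year; at cell vacuum
(`v+c+h = 0`) `V := 0` — no vasculature means no oxygen delivery.

Cell densities are stored internally as fractions of `K`, which cancels
`K` out of the cellular dynamics; `l` is a fraction of the capillary fluid
level `l_v = 1`, so the 50% imaging threshold reads `l ≥ 0.5`.

## Parameters

All constants live in a registry (`edemasim.parameters`) carrying value,
units, and a provenance note, overridable from YAML.  The edema block is
fixed by the quantitative anchors of the problem: `K_max = 36`/day (grade-IV
K_trans on DCE-MRI), `K_half = 5.75e−7` mmol/cc, `D_l = 0.77e−3` mm²/s (the
ADC of normal brain), `δ_l = 0.3·K_max`.  Drainage is constant by default;
a config switch (`drainage_model="permeability"`) makes it track
`0.3·K_trans(a)` instead.

The cellular/angiogenic constants (γ, β, αₕ, αₙ, μ, Kₘ, q, ω, λ, δ_c, δ_h,
Dᵥ, Dₐ, K) are not pinned by any printed anchor.  They are order-of-
magnitude literature-scale choices, calibrated **once** against the model's
own documented phenomenology and then frozen:

* γ = 1/day, β = 0.05/day — phenotype switching; recovery under restored
  oxygen is fast relative to hypoxic conversion.
* αₕ = 0.02/day, αₙ = 0.01/day — hypoxic cells survive for weeks; necrotic
  cores consolidate over months, keeping the viable rim broad enough to
  sustain factor production over a simulated course of treatment.
* μ = 0.1/day with Kₘ = 10·K_half — building vessels requires an order of
  magnitude more sustained stimulus than leaking them; this keeps
  vasculature from overgrowing regions that factors merely diffuse into.
* δ_h = 1.5e−3, δ_c = 8e−6 (mmol/cc/year per unit cell fraction) — hypoxic
  cells dominate factor output by ~200×.  δ_h sets how far beyond the bulk
  tumor margin the permeability threshold reaches (untreated edema tracks
  the bulk-tumor radius); δ_c sets the residual factor level once treatment
  collapses the hypoxic pool, i.e. how completely edema can clear.
* λ = 0.1/day, Dₐ = 630 mm²/yr — a factor decay length √(Dₐ/λ) ≈ 4 mm,
  which carries the permeability front to the imageable tumor margin.
* K = 1e5 cells/mm³ (1e8 cells/cc).

## Numerics

First-order finite volumes on the voxel grid; face conductances are
harmonic means of the per-voxel `D·(1−T)` over `spacing²`, so a face to a
*fully* saturated voxel carries zero flux (no room), and faces to
CSF/outside carry none by construction.  Time integration is operator
splitting with a fixed 1-day step: a reaction step, then an implicit
(backward-Euler) diffusion solve per mobile species with the `(1−T)` gate
frozen at the step's start — lagging the gate keeps every solve linear, and
first-order splitting already caps the accuracy.  Sparse LU factorizations
are reused until the gate moves by more than 1% in max-norm (a performance
contract only); the ungated operators for `a` and `l` factorize once.

Reactions use TR-BDF2 (trapezoidal stage to γₛ = 2−√2, then BDF2), with
per-voxel Newton iteration (forward-difference Jacobians, per-species
relative tolerance 1e−8, max 25 iterations) batched over the active voxels;
voxels indistinguishable from the empty background — an exact fixed point —
are skipped.  Two amendments matter:

* **The edema fluid is integrated exactly.**  Its relaxation rate
  `K_trans + δ_l` reaches ~47/day, far outside TR-BDF2's positivity region
  at a 1-day step (the stability function turns negative below z ≈ −2.4,
  which produced ~20% negative fluid undershoots at the edema diffusion
  skirt).  Since `l` feeds back into no other equation, it takes the exact
  exponential update of its linear ODE with the permeability frozen at the
  step-mean factor level — unconditionally positive and exact for constant
  `a`.
* **Automatic sub-stepping.**  The treated parameter set boosts γ to
  10/day; the reaction step subdivides so the fastest linear rate stays
  within the positivity region (`reaction_substeps`).

Final negative undershoots within 10× the Newton tolerance (per species
scale) clamp to zero; anything larger raises.  The trigger is evaluated
once per simulated day on the T1Gd circle-equivalent radius; treatment
covers the half-open window `[trigger, trigger+duration)` — exactly 100
treated days.

## Virtual imaging

T1Gd-enhancing region: `(c+h+n+v)/K ≥ 0.80`; bulk tumor: `(c+h+n)/K ≥
0.16` (vasculature excluded; five-fold below the T1Gd level); edema:
`l/l_v ≥ 0.5`.  All thresholds are closed (≥).  Region size is summarized
as the circle-equivalent radius `√(area/π)`; a sphere-equivalent mode
exists but requires an explicit slab thickness.  No connected-component
filtering is applied.

## The phantom

A synthetic axial slice stands in for an atlas-derived geometry: nested
ellipses give a gray-matter cortical rim around a white-matter interior,
with two elliptical CSF ventricles; the default grid is 147×185 voxels at
1 mm ([0,147]×[0,185] mm).  The shape is fixed and versioned; the seed
argument only drives optional cortical-rim wobble (off by default), so
the canonical phantom is identical across seeds.  The phantom reproduces
the topology that matters for the model — a bounded gray/white domain with
internal CSF obstacles — not the shape of any particular brain; conclusions
about anatomical detail (ventricle impingement, cortical folding) are out
of reach.

The initial state is the printed Gaussian inoculum
`c₀ = 1000·exp(−100·r²)` cells/mm³ centered at (103, 83) mm with
vasculature at 3% of `K` in all gray/white matter and everything else zero.
The seed center snaps to the nearest voxel center, so the seed voxel
carries exactly the 1000 cells/mm³ peak; with falloff 100/mm² the inoculum
is effectively a single voxel at 1 mm spacing.

## Virtual experiments

Treatment (`therapy` module) is a pure parameter modification over the
course window: β/10, γ×10, and Kₘ, K_half ×2 — the "required level of
factor" doubling is applied to both vascular growth and vessel
permeability, reading the two effects conjunctively.  The course starts
when the T1Gd radius first reaches 1 cm and lasts 100 days.

Runs end at the first of: a 1,500-day cap; for untreated runs, the
bulk-tumor radius reaching 80% of the phantom's inscribed radius (boundary
artifacts); for treated runs, 150 days after the course ends.  Treated runs
are never cut by the boundary rule: on this phantom (inscribed radius
≈36 mm) the aggressive case crosses it mid-course, and truncating there
would discard exactly the response being studied.  The matched untreated
control runs to the treated run's final day, and the bulk growth-rate
ratio is the ratio of linear-fit slopes of `r_tumor(day)` over the shared
post-trigger window (radial growth is asymptotically linear for this model
family).

Response categories operationalize the observed taxonomy: *resolved*
(imageable edema reaches zero during treatment), *stabilized* (dips below
80% of its trigger level without regrowing before the course ends),
*progressing-through-treatment* (everything else); thresholds are
configurable.

## Test profile and known limitations

The behavioral test suite runs on a half-resolution phantom (2 mm, 74×93)
to keep runtimes in minutes; the trigger-fidelity check and the acceptance
script use the full 1 mm grid.  At 2 mm, a single voxel is 4 mm² — radius
series show ~0.05–0.3 mm rasterization jitter, which is why the
treated-case checks compare against the trigger-day level rather than
demanding day-over-day monotonicity through a sub-voxel plateau.

Limitations worth keeping in mind:

* The unpinned kinetic constants are a calibrated, self-consistent set,
  not a fit to any patient data; passing tests demonstrate the documented
  qualitative mechanisms (edema tracking, decoupling under treatment,
  kinetics-dependent response), not quantitative prediction.
* The pulled invasion front converges to `2√(Dρ)` slowly (relative deficit
  ≈ 3/(4ρt)) and a 1 mm grid under-resolves the front width `√(D/ρ)` for
  fast-proliferating tumors, so measured front speeds sit a few percent
  below the asymptote.
* No mass effect / tissue deformation, no interstitial-pressure dynamics,
  no MRI signal physics, no drug pharmacokinetics (parameters switch
  instantaneously), 2D only.
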