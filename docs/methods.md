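# Methods

## Model overview

`skinetc` treats skin as a perfused porous medium. A representative
elementary volume (REV) of a tissue layer contains a bundle of capillaries
whose diameters λ follow the fractal scaling law `N(≥λ) = (λmax/λ)^Df` on
the REV cross-section. Everything else is derived from that law:

- **Size distribution.** The pdf is `f(λ) = Df λmin^Df λ^(−Df−1)`, the cdf
  `R(λ) = 1 − (λmin/λ)^Df`. The normalization deficit
  `(λmin/λmax)^Df` must be ≈ 0 for the fractal description to be valid;
  `PoreNetworkSpec` stores it and warns above a configurable threshold
  (default 0.01, appropriate for diameter ratios of 10⁻² – 10⁻⁴).
- **Porosity ↔ fractal dimension.** `Df = DE − ln ϕ / ln(λmin/λmax)` with
  the Euclidean dimension `DE = 2` used throughout (the pore maps and the
  solved PDE are two-dimensional; `DE = 3` remains available). `Df → 2`
  as `ϕ → 1`. Layers with `ϕ = 0` carry no pore network at all — the
  relation diverges there, and the avascular epidermis needs none.
- **Geometry.** Total pore area
  `Ac = π Df λmax^Df (λmax^(2−Df) − λmin^(2−Df)) / (4(2−Df))`, with the
  removable `Df → 2` singularity replaced by its analytic log limit
  `(π/2) λmax² ln(λmax/λmin)`. REV side `L0 = √(Ac/ϕ)`; tortuous capillary
  length `L(λ) = L0^DT λ^(1−DT)` with `DT ≥ 1` (`DT = 1` is straight).

## Monte Carlo sampling

Pore diameters are drawn by inverse-transform sampling,
`λ = λmin (1 − R)^(−1/Df)`. Raw uniforms are rescaled to
`[0, 1 − (λmin/λmax)^Df]` before inversion so that every draw lies inside
`[λmin, λmax]`: the analytic cdf never quite reaches 1 on a truncated
range, and an unrescaled uniform near 1 would overshoot λmax. The medium
builder draws **one diameter per grid cell** from the owning layer's
distribution rather than packing discrete disks: the PDE consumes only
`keff*(x̄,ȳ)`, and per-cell sampling gives a well-defined i.i.d.
statistical model that produces the left–right asymmetry and heterogeneity
expected of a random capillary bed. A single uniform field per grid (then
transformed per layer) makes a split homogeneous stack bit-identical to
the unsplit one under the same seed.

## Capillary flow

Blood is a power-law fluid: index `n` (0.6 for blood, 1 Newtonian),
consistency `m` in Pa·sⁿ (documented, not converted across n; default
0.0035, the Newtonian viscosity of blood). Fully developed laminar flow in
a tube of diameter λ and tortuous length `L(λ)` driven by the pressure
gradient `G = dp/dL0` gives

    u = n/(3n+1) · (λ/2) · [G λ^DT / (4 m L0^(DT−1))]^(1/n),

the generalized Hagen–Poiseuille mean velocity. It recovers
`u = G λ²/(32 m)` exactly at `n = DT = 1` and scales as `λ^(1+DT/n)`.
`G` is not a measurable skin quantity; it is calibrated once so the
largest pore reaches `Pe = ρb Cb λ u / kb = 16.3` under the validation
settings (ϕ = 0.05, DT = 1, n = 1), giving `G ≈ 2.13 × 10³ Pa/m`, and is
then held fixed across porosity/rheology sweeps so that only geometry and
rheology vary.

## Effective conductivity

Superposing the conductive flux through the tissue fraction and the flux
through one capillary gives `keff = kt(1−ϕ) + kb Λ(λ)` with the geometry
factor implemented as `Λ = ϕ π λ^(DT+1) / (4 Ac L0^(DT−1))` (algebraically
identical to the expanded fractal form, and finite at `Df = 2`). The
dimensionless, perfusion-weighted conductivity used in the PDE is

    keff* = (1−ϕ) + (Pe/2)(kb/k_layer) Λ(λ) · k_layer/k_ref,

evaluated at each cell's sampled diameter, with `Pe` computed from the
same diameter through the flow model. The Peclet weighting admits a
`Pe²/2` variant (exposed as `peclet_exponent=2`); the linear reading is
the default because it passes the Weinbaum–Jiji validation comfortably.
All values are normalized by the single reference conductivity
`k_ref = 0.293 W/m·°C` that also defines the thermal diffusivity of the
dimensionless time; per-layer conductivities (0.25 / 0.45 / 0.2 W/m·°C
for epidermis/dermis/hypodermis) enter as multipliers.

The Weinbaum–Jiji reference `keff/kt = 1 + (Pe0²/2)(A + Bȳ + Cȳ²)` with
`Pe0 = 20`, `A = 6.32×10⁻⁵`, `B = −15.9×10⁻⁵`, `C = 10×10⁻⁵` is used as
printed, although the polynomial then decreases with depth; it is a
validation reference, not part of the model.

## Bioheat solver

Dimensionless variables: `x̄ = x/H`, `ȳ = y/H`, `τ = t αt/H²`,
`θ = (T−T∞)/(Tc−T∞)` with `Tc = 37 °C`, `T∞ = 25 °C`. The tissue slab is
`H` deep and `W = 2H` wide. `H = 0.03 m` by construction: it is the depth
at which the dimensionless metabolic heat
`Φm = qm H²/(kt ΔT) = 0.094` with the standard property set
(`qm = 368.1 W/m³`, `kt = 0.293 W/m·°C`, ΔT = 12 °C). Other groups:
`Bi = hH/kt ≈ 0.512` (`h = 5 W/m²·°C`), `f* = H qapp/(kt ΔT) ≈ 1.706`
(`qapp = 200 W/m²`).

The governing equation `∂θ/∂τ = ∇·(keff* ∇θ) + Φm` is integrated
explicitly in conservative (flux) form on grid nodes: face fluxes use
harmonic-mean conductivities (continuous flux across layer interfaces),
and boundary nodes own half cells of the dual mesh, which makes the
discrete heat content exactly conserved under insulated boundaries and the
Neumann/Robin conditions second-order accurate. Boundary conditions:
`θ = 1` at `ȳ = 0` (body core), zero-gradient sides, and on the surface
`∂θ/∂ȳ = f*` inside the central-fifth patch `x̄ ∈ [0.8, 1.2]` while
`τ ≤ τapp = 0.09`, Robin `∂θ/∂ȳ = −Bi θ` elsewhere and afterwards.
Heating enters as a positive influx (it raises surface θ); the patch is
the central fifth of the surface, matching the central application zone of
the physical setup. Metabolic heating is active in every scenario.

Time step: `Δτ = s / (2 max(keff*) (1/Δx̄² + 1/Δȳ²))` with safety
`s = 0.9`, then shrunk so `τapp` is an integer number of steps (the
heating switch is exact). Default grid 201×101 (`Δx̄ = Δȳ = 0.01`),
horizon `τ_end = 0.5`. An unstable update is detected (non-finite θ) and
reported with the offending cell. In the validation driver both arms run
with the *same* `Δτ` (the stiffer field's bound) so the comparison is
purely about the conductivity model.

## Study configurations

- **Validation.** One layer, ϕ = 0.05, DT = 1, n = 1, `kb/kt = 1.9863`,
  Monte Carlo ETC vs WJ ETC, difference metric
  `max |T_fractal − T_WJ| / T_WJ` over all cells of the dimensional (°C)
  fields at τ = 0.09 — the strictest natural reading of a contour-level
  comparison; alternates can be computed from the exported fields.
- **One-layer dynamic tests.** ϕ ∈ [0.01, 0.5], DT ∈ [1, 1.1],
  n ∈ [0.6, 1]; heating to τ = 0.09, relaxation to τ = 0.5; peak
  temperature stays below the 44 °C damage threshold (the model contains
  no damage kinetics and is not meant to be used above it).
- **Three-layer runs.** Fractions 0.04/0.48/0.48 (epidermis top),
  porosities 0/0.5/0.05, DT = 1.05, n = 0.6. Interface rows belong to the
  lower layer; depth profiles change slope at ȳ = 0.48 and 0.96 in
  proportion to the conductivity contrast (flux continuity).

## Numerical and design notes

- Scale separation: default λmin = 5×10⁻⁶ m, λmax = 5×10⁻⁴ m
  (ratio 10⁻²).
- `PoreNetworkSpec` enforces consistency between ϕ and Df to 10⁻¹²;
  specs are built from porosity, not from free-floating Df.
- The sampled-pore count per REV export is a free parameter (the model
  itself always samples one pore per PDE cell).
- Rare dermis cells that draw near-maximal pores dominate `max keff*`
  (values of order 10 at ϕ = 0.5 with n = 0.6); the stability bound and
  hence the cost scale with that maximum. The test suite therefore runs
  three-layer scenarios at 81×41 while the headline validation and
  one-layer dynamic runs use the full 201×101 grid.
- The tortuosity effect on keff* is strongest near DT = 1 (convex,
  front-loaded decay `∝ (λ/L0)^((DT−1)(1+1/n))`), but at the validation
  scale separation the decay spans most of DT ∈ [1, 2] rather than
  saturating by DT ≈ 1.3.

## What the synthetic medium does and does not capture

The Monte Carlo fields emulate the *statistics* of a capillary bed:
correct marginal pore-size distribution per layer, spatial independence
between cells, sharp layer interfaces at fixed depth fractions. They do
not represent vascular topology (branching, countercurrent pairs),
spatially correlated porosity, anatomically varying layer thickness, or
3D transport. Passing tests therefore demonstrate the internal consistency
and the parametric behaviour of the model — not anatomical fidelity of any
single realization.

## Known limitations

- Blood rheology is purely power-law: no yield stress, viscoelasticity or
  pulsatility.
- The pressure gradient is a single calibrated constant, not a perfusion
  map.
- Explicit time stepping only; very heterogeneous fields make the stable
  step small.
- The WJ reference is used only through its final polynomial form.
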