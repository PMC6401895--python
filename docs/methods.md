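# Methods

`cryophase` simulates freeze concentration of a dilute aqueous solution
(sucrose-parameterised, as a stand-in for protein formulations) at the
mesoscale: a few tens of micrometres of solution containing a handful of
ice crystals, cooled rapidly from a supercooled state.  This note
describes the model, its scaling, the numerical scheme, and the choices
made where the design was genuinely open.

## Model

Four coupled fields evolve on a periodic square of side 2πL (L = 10 µm):

* **Phase field** φ_sl ∈ [−1, 1] (ice +1, liquid −1), non-conserved
  (Allen–Cahn type).  Its rate balances interfacial diffusion Ch²∇̃²φ_sl,
  a thermal driving term Λ_sl (1−φ_c) P′(φ_sl) (T̃−T̃_eq)/[(1+εT̃)(1+εT̃_eq)]
  with ε = ΔT/T0 (the scaled form of the dimensional driving
  (T−T_eq)/(T·T_eq)), the double-well restoring force (1−φ_c)(φ_sl−φ_sl³),
  and a mixing barrier −(R/h_sl) χ′ G that penalises freezing where solute
  is present.  T̃_eq = −5.5 φ_c² is the scaled sucrose liquidus
  (T_eq = T0 − 55 φ_c²).
* **Solute volume fraction** φ_c, conserved (Cahn–Hilliard type with
  degenerate mobility φ_c(1−φ_c)).  Its flux combines a composite
  diffusion coefficient D̃[(1−φ_c)/N + φ_c + φ_c(1−φ_c) χ G″], a drift
  down the gradient of the phase-interpolated Flory parameter χ(φ_sl)
  (this is the solute-exclusion mechanism: χ_s > χ_l makes mixing costly
  in the crystal), and a gradient-energy (4th-order) term.
* **Scaled temperature** T̃ = (T−T0)/ΔT: conduction Le ∇̃·(k̃_T/(ρ̃c̃_p) ∇̃T̃),
  latent-heat and mixing-energy sources proportional to the material rates
  of the two phase fields, and a uniform volumetric heat sink Ω̇˜ that
  stands in for bulk cooling at β_f (no walls are modelled).
* **Velocity**, quasi-incompressible and inertialess.  ∇̃·ṽ is set by the
  density drop on freezing (ice is ~8 % lighter): the "blowing" flux that
  pushes liquid away from advancing fronts.  The solenoidal part obeys a
  Stokes balance with strongly variable viscosity (the crystal is a fluid
  4 orders of magnitude more viscous; rigidity is emergent) and Boussinesq
  buoyancy +Gr(1−ρ̃) ŷ, which makes crystals drift upward.

All coefficients come from one place (`scaling.py`): the characteristic
times τ_sl = τ_φc = τ_conv = 0.4762 s (Pe = 1 convention: τ_sl defaults to
L²/D0 and U = L/τ_sl), τ_T = 9.86×10⁻⁵ s, τ_vis = ρ0L²/η0 = 5.55×10⁻⁵ s,
τ_f = ΔT/β_f = 0.1 s, and the groups Λ_sl ≈ 313, Ch = 0.1, Le ≈ 4831,
Ste1 ≈ 0.0621, Ste2 ≈ 0.0136, Ω̇˜ ≈ 4.76, Sc ≈ 8573, Re ≈ 1.17×10⁻⁴,
Gr ≈ 25.9·(1−ρ̃).

### Property correlations (supercooled regime)

Dimensional, SI; scaled by the reference values in `MaterialParams`:

* ρ_l = ρ0 − 0.017(T−T0)², ρ_s = 0.917ρ0 + 0.15(T0−T), ρ_c = 1587 kg/m³.
* c_p,s = c_p0 + 8(T−T0); c_p,l = 4180[1 − 0.953φ_c(1−0.588φ_c) + 10⁻³(T−T0)].
* k_T,s = k_T0 + 0.013(T0−T); k_T,l = 0.58[1 − 0.905φ_c(1−0.588φ_c) + 2.6×10⁻³(T−T0)].
* η_l: Vogel–Fulcher–Tammann 4.442×10⁻⁵ exp[2.288·168.9/(T−168.9)] times the
  Mooney factor exp[6.3φ_c/(1−0.85φ_c)]; η_s = 10⁴ η0.
* D_l = D0 T η0/(T0 η_l) (Stokes–Einstein); D_s = 10⁻⁴ D0.

The reference c_p0 = 2110 J/(kg·K) and k_T0 = 2.14 W/(m·K) are the *ice*
values at T0; this is the convention under which the published group
values (Le, Ste1) and the heat sink ρ0c_p0β_f ≈ 2×10⁸ J/(m³·s) are
recovered, and it is applied consistently in the scaled equations.

The fifth-order interpolation weight P(φ_sl) (P(−1)=1 liquid, P(+1)=0
solid, P′=P″=0 at ±1) blends every two-phase property.  **Its argument is
clamped to [−1, 1]**: the raw polynomial's derivative becomes nonzero
again beyond the wells, and because the mixing force carries the factor
R/h_sl ≈ 3.2×10³, even P′(±1.05) ≈ −0.01 would exert an order-10 spurious
body force that drags both bulk phases off ±1 (we observed exactly this
before adopting the clamp).  Clamping makes every driving force vanish
identically outside the physical phases while the double well confines
the field.

## Numerics

Fourier pseudo-spectral on an n×n periodic grid (integer wavenumbers),
2/3-rule dealiasing of nonlinear products, forward Euler at the uniform
scaled step dt̃ = 2×10⁻⁴ with semi-implicit treatment of the stiff linear
operators:

* φ_sl: exact backward Euler on Ch²∇̃².
* φ_c and T̃: "add–subtract" constant-coefficient stabilisation at the
  domain maximum of the respective diffusion coefficients (k² and k⁴ for
  the solute; Le·max[k̃_T/(ρ̃c̃_p)]·k² for temperature).  This splitting is
  first-order consistent, unconditionally stable, preserves uniform
  states exactly, and conserves the solute mean to round-off (the
  transport is assembled in spectral divergence form, whose k = 0 mode is
  identically zero).

**Velocity solve.**  Helmholtz decomposition: the potential part comes
from one Poisson solve of the continuity source (dealiased; its domain
mean — net expansion, which a periodic box cannot accommodate — is
removed by the gauge), using the phase-change rate of the previous step
(the fluid starts at rest).  The solenoidal part performs one explicit
relaxation step of the inertialess momentum balance per time step,
stabilised by a backward-Euler split at the domain-maximum viscosity
(10⁴ in the crystal) and Leray-projected.  Because the split constant is
the crystal viscosity, the liquid-phase flow relaxes toward its
quasi-steady Stokes balance over many steps rather than instantly:
velocity magnitudes lag their steady values during fast transients, while
directions and signs (blowing at fronts, buoyant updraft of crystals,
sinking of dense concentrated liquid) are preserved.  Pressure is the
projection multiplier.  With Pe = 1 and observed |ṽ| ≲ 0.2, advective
corrections are small, so this approximation has little feedback on the
phase/solute/thermal fields.

**Solute-equation regularisation.**  The physical gradient-energy
coefficient Ch²h_sl/R implies a spinodal interface width
√(Ch²h_sl/R) ≈ 2×10⁻³ — unresolvable at any feasible grid (the published
1600² grid has dx ≈ 4×10⁻³).  Wherever solute is trapped inside the
crystal at φ_c ≳ 0.2, the crystal-side χ_s = 2.5 makes the composite
diffusion coefficient negative (spinodal regime) and unresolved backward
diffusion blows up at the grid scale.  We therefore augment the
gradient-energy coefficient by a grid-scale term
4χ_s(4/n)²·(1−P) that caps the fastest-growing spinodal mode at ≈ n/4
*inside the crystal only*; the liquid (χ_l = 0.5) is parabolically stable
for φ_c ≲ 0.5 and is left untouched, so interstitial concentration peaks
are not artificially flattened.  The term vanishes as n⁻² under
refinement.

**Known discretisation features.**  At coarse resolution (128²–192²) the
phase field overshoots ±1 in bands behind fast fronts and the solute
field shows Gibbs oscillations near gap closures (φ_c locally below 0);
both shrink strongly with resolution (at 256² the phase field stays
within [−1.04, 1.02] and φ_c within [−10⁻³, 1]).  A 1-D refinement study
of a driven front shows overshoot ≲ 0.02 converging to zero, confirming
these are resolution artifacts, not model behaviour.  Properties are
always evaluated on clamped fields, so transients remain bounded.

## Scenarios and problem sizes

The base scenario seeds 5 crystals (radius 3Ch, symmetric quincunx
placement — published runs do not report coordinates), φ_c = 0.05 in the
liquid and 0 inside seeds, uniform T̃ = −1, cooling at β_f = 100 K/s, run
to t̃ = 2.5.  A denser variant seeds 25 crystals (more on the left half)
at φ_c = 0.02.  Seed placement can also be uniform-random with a minimum
separation and a recorded RNG seed.

Grid sizes are chosen per purpose: unit tests run at 64², the
equilibrium-interface and conservation benchmarks at 128², the base
scenario regression at 192², and the acceptance script at 256²; the peak
interstitial concentration is the most resolution-sensitive observable
(≈ 0.20 at 128², ≈ 0.30 at 192², higher still at 256²) because it lives
in gaps a few cells wide, so scaled-down runs systematically
underestimate it relative to fine-grid references.

The planar-front benchmarks hold the temperature field fixed at its
prescribed value.  The phase-change number Λ_sl ≈ 313 amplifies
micro-Kelvin recalescence residuals into order-0.1 driving forces, so an
evolving temperature in a closed periodic box would measure heat-budget
drift rather than interface kinetics; with T̃ held, a slab at the liquidus
is stationary to ~10⁻⁹ per unit scaled time and relaxes to the tanh
profile of width √2·Ch (the same profile that fixes the interfacial
energy γ_sl = (2√2/3)ρ0h_slW_slT0 ≈ 0.0375 J/m²).

## What the model does and does not capture

The simulated conditions reproduce the intended mechanism chain: solute
exclusion at fronts, freezing-point depression and viscosity rise in the
interstitial liquid, latent-heat release localised at interfaces,
thermally-limited growth under bulk cooling, blowing flow at fronts and
weak buoyant drift.  Not modelled (by design): anisotropic interfacial
energy and dendrites, nucleation kinetics (sites are prescribed), thermal
stress/elasticity, solute crystallisation or entanglement, protein–ice
adsorption, radiation/van der Waals interactions, 3-D domains, and
container-scale heat transfer (the uniform sink replaces it).

One caveat on temperature: with the tabulated Lewis number (Le ≈ 4831)
the domain is nearly isothermal at all times — spatial temperature
spreads are O(10⁻²) in T̃ units, set by the source/conduction balance.
Wide instantaneous temperature ranges across a domain of this size are
not reachable under these equations; temperature variation appears
almost entirely in the domain mean (recalescence followed by cooling).

## Numerical parameters (defaults)

| quantity | value | note |
| --- | --- | --- |
| dt̃ | 2×10⁻⁴ | uniform scaled step |
| dealiasing | 2/3 rule | all nonlinear products |
| φ_c clip | [10⁻⁶, 1−10⁻⁶] | before mobility/mixing terms |
| φ_sl clamp | [−1, 1] | before P, P′, χ, χ′ |
| seed radius | 3 Ch | resolvable, small vs domain |
| solute regularisation | 4χ_s(4/n)²(1−P) | converges as n⁻² |
| velocity relaxation | 1 sweep/step | split at max η̃ |
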