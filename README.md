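# cryophase

Mesoscale phase-field simulation of **freeze concentration** in aqueous
sugar/protein solutions.

When a bulk protein formulation is frozen for storage, solutes are
excluded from the growing ice crystals and accumulate in the shrinking
interstitial liquid.  The resulting concentration spikes — amplified by
space confinement between crystals, freezing-point depression, latent
heat release and the steep viscosity rise of the supercooled liquid —
are a leading stress on protein stability in biopharmaceutical
manufacturing.  `cryophase` simulates this process on a periodic 2-D
domain a few tens of micrometres across, for process modellers and
formulation scientists who want mechanistic insight at the crystal
scale.

## Model

Two phase fields are evolved together with temperature and flow, in
scaled units (length L = 10 µm, time τ_sl = 0.476 s, temperature
T̃ = (T−T0)/ΔT):

* **Ice/liquid order parameter** φ_sl (Allen–Cahn):

  ∂φ_sl/∂t̃ + Pe ṽ·∇̃φ_sl = Ch²∇̃²φ_sl + Λ_sl(1−φ_c)P′(φ_sl)(T̃−T̃_eq)/[(1+εT̃)(1+εT̃_eq)]
  + (1−φ_c)(φ_sl−φ_sl³) − (R/h_sl)χ′G

* **Solute volume fraction** φ_c (Cahn–Hilliard, Flory–Huggins mixing,
  degenerate mobility): conservative transport with composite diffusion,
  a drift down the gradient of the phase-interpolated Flory parameter
  χ(φ_sl) (solute exclusion: χ_s = 2.5 > χ_l = 0.5), and a
  gradient-energy term.

* **Temperature**: conduction with Le ≈ 4831, latent-heat/mixing sources
  ∝ 1/Ste1, and a uniform volumetric heat sink Ω̇˜ = 4.76 standing in for
  bulk cooling at β_f = 100 K/s.

* **Quasi-incompressible flow**: a potential "blowing" component from
  the ~8 % density drop on freezing, plus an inertialess solenoidal
  component with variable viscosity (crystal = very viscous fluid,
  η_s = 10⁴η0) and Boussinesq buoyancy Gr(1−ρ̃) ≈ 25.9(1−ρ̃).

Supercooled-regime property correlations (CRC/VTF/Mooney/Stokes–Einstein,
sucrose liquidus T_eq = T0 − 55φ_c²) are built in; all parameters live in
`MaterialParams` and every scaled coefficient is derived in `scaling.py`.
The solver is Fourier pseudo-spectral (2/3-rule dealiasing) with
semi-implicit stabilisation at the scaled step dt̃ = 2×10⁻⁴.  See
`docs/methods.md` for assumptions, numerical choices and limitations.

## Worked example

Print the characteristic scales and dimensionless groups:

```bash
$ cryophase groups
                           quantity       value
                 length scale L [m]    0.000010
     interfacial thickness W_sl [m]    0.000001
interfacial energy gamma_sl [J/m^2]    0.037489
             velocity scale U [m/s]    0.000021
                         tau_sl [s]    0.476190
                                ...
                          Lambda_sl  312.978952
                                 Le 4830.575684
                               Ste1    0.062059
                               Ste2    0.013574
                        Omega_tilde    4.761905
                                 Sc 8573.143200
 Gr coefficient (x (1 - rho_tilde))   25.920741
```

γ_sl ≈ 0.0375 J/m² is the ice/solution interfacial energy implied by the
equilibrium tanh interface (about half the surface tension of water);
Λ_sl ≈ 313 says the latent-heat driving dwarfs the interfacial energy
scale, and Ste1 ≈ 0.06 that the sensible heat of 10 K of supercooling is
an order of magnitude smaller than the latent heat — freezing here is
limited by heat removal, not by supercooling.

Run the base scenario (5 seeded crystals, φ_c = 0.05, T̃ = −1) on a small
grid and render the solute field:

```bash
$ cryophase run --n 128 --t-end 1.0 --outdir demo
t_tilde=  0.100  max_phi_c=0.0790  T_tilde=[-0.292, -0.280]  crystal=0.131  wall=    7.1s
t_tilde=  0.200  max_phi_c=0.0861  T_tilde=[-0.296, -0.286]  crystal=0.162  wall=   14.2s
...
t_tilde=  0.900  max_phi_c=0.1665  T_tilde=[-0.330, -0.318]  crystal=0.359  wall=   64.1s
t_tilde=  1.000  max_phi_c=0.1515  T_tilde=[-0.340, -0.333]  crystal=0.385  wall=   70.4s
wrote demo/final.h5 and demo/diagnostics.csv
$ cryophase render demo/final.h5 --field phi_c -o demo/phi_c.png
```

The log shows the signature dynamics: recalescence (the domain warms
from T̃ = −1 toward the liquidus as the first burst of freezing releases
latent heat), then thermally-limited growth under continued cooling,
with the interstitial solute maximum climbing as crystals crowd the
liquid.  In the full scenario (t̃ = 2.5) the peak solute fraction reaches
several times its initial value in the narrow gaps and Plateau borders
between crystals.

Python API:

```python
from cryophase import SpectralGrid, Simulation, SeedSpec, init_fields

grid = SpectralGrid(128)
sim = Simulation(grid)                      # default material parameters
state = init_fields(grid, SeedSpec(count=5), 0.05, -1.0, sim.groups.Ch)
state, diags = sim.advance(state, 2e-4, 5000, diag_every=500)
print(diags[-1].max_phi_c, diags[-1].crystal_area_fraction)
```

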