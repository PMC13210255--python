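# Methods

`neurorelease` simulates the enzymatically triggered release of a
core–shell nanocomposite scaffold (rGO core, chitosan inner layer,
poly-γ-glutamic-acid outer shell) from an affinity-based hydrogel depot
into injured spinal-cord tissue, together with the glutamate handling that
release is meant to restore. Three coupled models share one parameter set.

## 1. The release network (batch reactor)

Five delivery species: free scaffold `SC`, free peptide `p`, free
peptide–scaffold complex `pSC`, matrix-immobilized peptide `mp`, and
matrix-immobilized complex `mpSC`. Two processes act on them:

* **Reversible binding.** Scaffold associates with either peptide pool at
  rate `kf1` (m³·mol⁻¹·s⁻¹) and dissociates at `kr1` (s⁻¹):
  `SC + p ⇌ pSC` and `SC + mp ⇌ mpSC`, with a single dissociation constant
  `K = kr1/kf1`.
* **Enzymatic matrix degradation.** A matrix-degrading enzyme cleaves the
  glutamate-bearing outer shell of the immobilized species with
  Michaelis–Menten kinetics `v = Vmax·c/(KM + c)`, converting `mp → p` and
  `mpSC → pSC`. One shared `(Vmax, KM)` pair serves both substrates, each
  with its own saturation term. Every degradation event releases one GABA
  and one CO₂ (irreversible decarboxylation of an L-glutamate unit); the
  enzyme is a catalyst and its concentration never changes.

Matrix-bound species are stored per unit area (mol/m²) and enter every
bulk balance multiplied by the specific surface area `Ssa` (1/m). Written
in bulk equivalents `v_mp = c_mp·Ssa`, the net rates are

```
R_SC    = −kf1·c_SC·(v_mp + c_p) + kr1·(v_mpSC + c_pSC)
R_p     = −kf1·c_SC·c_p  + kr1·c_pSC  + MM(v_mp)
R_pSC   = +kf1·c_SC·c_p  − kr1·c_pSC  + MM(v_mpSC)
R_vmp   = −kf1·c_SC·v_mp + kr1·v_mpSC − MM(v_mp)
R_vmpSC = +kf1·c_SC·v_mp − kr1·v_mpSC − MM(v_mpSC)
R_GABA  = R_CO2 = MM(v_mp) + MM(v_mpSC)
```

Two moieties are algebraically conserved: total scaffold
(`SC + pSC + mpSC·Ssa`) and total peptide
(`p + pSC + (mp + mpSC)·Ssa`); total matrix sites (`mp + mpSC`) are
monotonically non-increasing. These identities are the suite's master
invariants (drift tolerances 1e-8 batch, 1e-6 spatial; both run at ~1e-15
in practice).

**Initial condition.** The depot is loaded with the binding network at
equilibrium: given moiety totals and the immobilized fraction of peptide,
the free-scaffold concentration is the positive root of the binding
quadratic `c_SC² + c_SC(K + P − S) − S·K = 0` and every other pool follows
in closed form. No degradation has occurred at t = 0, so GABA and CO₂
start at zero; enzyme starts at `enzyme0 = 2e-6 mol/m³`.

**Integration.** LSODA (stiff-safe, adaptive) at rtol 1e-10/atol 1e-14; a
fixed-step classical RK4 mode exists for the time-step study. Output
non-negativity comes from solver tolerance, not clipping (values are only
zero-floored below the absolute tolerance).

### Parameter defaults and provenance

The model's rate constants are not printed in the source material
available to this package, so the defaults are documented choices frozen
in `data/defaults.yaml` and flagged per-value in the fixture's provenance
notes:

| parameter | default | unit | provenance |
|---|---|---|---|
| `kf1` | 100 | m³/(mol·s) | affinity-delivery literature scale (1e5 M⁻¹s⁻¹) |
| `kr1` | 0.01 | 1/s | gives K_D = 1e-7 M, a typical peptide affinity |
| `Vmax` | 0.288 | mol/(m³·s) | calibrated **once** so the mpSC 1%-depletion time of the default batch run lands at 16 s, then frozen |
| `KM` | 1.0 | mol/m³ | mM-scale enzyme constant; substrates sit deep in the first-order regime |
| `Ssa` | 1e5 | 1/m | hydrogel-fiber surface density scale |
| `enzyme0` | 2e-6 | mol/m³ | transcribed anchor |
| loading | 1 µM scaffold, 10 µM peptide, 90% immobilized | mol/m³ | depot-scale choice, 10× peptide excess |

Molecular weights: exact for GABA/GLU/GLN/NH₃/CO₂; documented placeholders
for the engineered species (peptide 1 kDa, scaffold 10 kDa, enzyme 65 kDa,
complexes = sum of parts, enforced by the fixture).

## 2. Diffusivities

Water diffusivity from molecular weight: `D = A·MW^(−1/3)·s` evaluated in
cm²/s with `A = 260 cm²/(s·Da^(1/3))` and scale `s = 1e-7`, then converted
to m²/s. The 1e-7 scale places a 1 kDa peptide at 2.6e-10 m²/s and a
10 kDa protein at 1.2e-10 m²/s — the porous-hydrogel protein range; the
scale is a config knob (`transport.eq2_scale`) should a different
normalization of the correlation be wanted. Gel diffusivities are
`0.9 × D_water` (configurable `gel_factor`). Loading validates every
diffusive species into the physically plausible 1e-12…1e-8 m²/s band.
Matrix-bound species do not diffuse.

## 3. The glutamate–glutamine–GABA cycle

Six pools in three compartments: extracellular glutamate, astrocytic
glutamate and glutamine, neuronal glutamine, glutamate and GABA. Steps:
Michaelis–Menten astrocytic uptake (`uptake_Vmax = 0.01 mol/(m³·s)`,
`uptake_KM = 0.05 mol/m³`, a GLT-1-scale affinity), glutamine-synthetase
conversion, astrocyte→neuron glutamine shuttle, neuronal glutaminase, and
irreversible GAD decarboxylation to GABA (first-order constants, default
0.05 s⁻¹). Ammonia is constant and folded into the GS rate; ATP is
bookkept at `atp_per_glu = 1.5` per glutamate taken up ("more than one"
being the only constraint). Every flux transfers carbon between tracked
pools, so the cycle is closed and the pool sum is exactly conserved.

**The 90% conversion cap.** GS shuts off when cumulative conversion
reaches `completion_cap = 0.90` of cumulative uptake. The default
enforcement is a continuous headroom ramp: full flux until the converted
fraction is within 0.1% of the cap, then flux proportional to the
remaining headroom, so the fraction approaches the cap exponentially from
below and never overshoots — an adaptive stiff solver traverses it without
chattering. A logistic smooth switch (`cap_mode="smooth"`, width 1% of the
cap) is available but lets the fraction creep logarithmically past the cap
on long horizons, which is why it is not the default. A third mode
(`cap_mode="pool"`) gates on the astrocytic glutamine *fraction* instead
of cumulative amounts; unlike the cumulative modes it admits a genuine
steady cycling state.

**Post-injury vs resting.** The default run starts at the post-injury
extracellular level 0.53 mol/m³ (0.53 mM) with re-release off, so
extracellular glutamate decreases monotonically below the 0.05–0.10 mM
excitotoxicity band. A documented `resting_preset()` (slow loop turnover
2.9e-3 s⁻¹, neuronal re-release on, GAD off, pool cap mode) has a
closed-form steady state (`resting_state()`) calibrated to sit at ~2 µM,
inside the normal 1–5 µM band. The cycle's timescale is not anchored by
any printed constant; the defaults are calibrated choices, not
transcriptions.

## 4. The axisymmetric spatial model

Finite-volume, cell-centered, uniform (r, z) grid on the 12 mm × 3 mm
cylinder. Radial faces carry area `2π·r_face·Δz` (the axis face has zero
area, which *is* the ∂c/∂r = 0 symmetry condition), axial faces
`2π·r·Δr`, volumes `2π·r·Δr·Δz`. All outer boundaries are no-flux, making
the domain closed; face diffusivities are harmonic means, so fluxes are
continuous across the gel/tissue interface. The scheme is conservative by
construction (the volume-weighted operator sums to zero to rounding) and
second order in space (observed order ≥ 1.8 on a radial-Gaussian
free-diffusion oracle).

Three zones: cellular zone (k=1), biomaterial depot (k=2), surrounding
media (k=3). The full network including degradation runs in the depot;
only binding/dissociation elsewhere (`Vmax` forced to 0). Bound species
live only on depot cells. The enzyme initializes in the cellular zone at
`enzyme0` and diffuses as a passive tracer — degradation is gated by
domain, not by local enzyme concentration, mirroring the constant-`Vmax`
treatment of the kinetics. The zone geometry is not dictated by the
physical setup, so it is a named, overridable preset: coaxial depot
(inner half-radius, central third of length), cellular end-cap slab
(outer sixth of length), remainder media; `depot-only` and `abutting`
presets support reduction tests and interface studies.

**Integration.** Method of lines. At the default parameters the
semi-discrete system is non-stiff (reaction rates ≲ 0.3 s⁻¹, diffusion
stability limit 0.3–1 s even at 64×256), so the default integrator is
adaptive explicit RK45 (rtol 1e-6); `rk4` provides a fixed-step mode whose
step is automatically capped below the diffusion stability bound, and
implicit methods remain selectable for small grids. Output defaults to a
geometric schedule over [0, 60 s], dense enough to capture the ~16 s
depletion transient.

## 5. Verification studies

* **Mesh convergence**: uniform ×2 refinements of both `nr` and `nz`;
  metric = maximum over cells and output times of the tracked species
  (default `SC`, the released glutamate-bearing scaffold, standing in for
  free glutamate which the delivery network does not resolve — the choice
  is configurable). Pass criterion: finest-pair relative change
  `|m₃−m₂|/m₃ < 1%`. The default study runs 16×64 → 32×128 → 64×256 and
  lands at ~0.06%.
* **Time-step independence**: fixed-step RK4 at several steps vs the
  finest; sup-norm differences plus an oscillation detector (repeated
  sign changes of the second difference above a relative amplitude
  floor). The default 0.01 s vs 0.005 s comparison is clean; a
  deliberately stiffened case with a 2 s step is flagged.
* **Conservation audit**: max relative drift of scaffold moiety, peptide
  moiety and enzyme; pass thresholds 1e-8 (batch) and 1e-6 (spatial).

All reports are pure functions of their configs (deterministic solver
settings), so reruns reproduce them bit-for-bit.

## 6. What the synthetic fixtures do and do not emulate

The fixture generator supplies everything the pipeline consumes:
parameter bundles with per-value provenance notes, equilibrium depot
loadings, initial fields (delivery species confined to the depot, enzyme
to the cellular zone), and seeded log-uniform parameter ensembles (×/÷10
around the defaults for `kf1`, `kr1`, `Vmax`, `KM`) for sensitivity
sweeps. They emulate the *structure* of the study conditions — not real
tissue: no electrostatics of the charged glutamate in the ECM, no
receptor-level pharmacology, no swelling or convection, a well-mixed
isotropic continuum per zone, and fixed 37 °C / pH 7.4 constants. Passing
tests therefore demonstrate internal consistency of the model and solver,
not predictive accuracy for in vivo release.

## 7. Problem sizes and numerical choices

Default runs are desk-scale by design: 60 s batch horizon at 0.05 s output
sampling, 600 s cycle horizon, spatial grids from 16×64 to 64×256 in the
convergence study (the full three-level study completes in seconds).
Degenerate inputs are validated loudly (`ConfigError`), integrator
failures carry the last good state (`NumericalError`), thresholds never
crossed return an infinite sentinel rather than raising, and depletion and
threshold times are linearly interpolated between output samples.

## Known limitations

* All engineered-species molecular weights and every rate constant are
  documented stand-ins or one-time calibrations; absolute concentrations
  should be read as scale-consistent, not measured.
* The zone geometry inside the cylinder is an interpretation (presets).
* The glutamate cycle is spatially lumped; its coupling into the spatial
  solver's zones is a config hook (`cycle_sources`) left off by default.
* One generic matrix-degrading enzyme carries both the proteolytic and
  the decarboxylating role, with GABA produced stoichiometrically.
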