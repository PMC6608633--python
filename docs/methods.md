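# Methods

This note records the physical models, conventions and numerical choices
behind `smxdose`, and what the synthetic-data tests do and do not
demonstrate.

## Cross-sections and linear coefficients

Dose deposition at 1–25 keV is dominated by photoabsorption; Compton recoil
electrons add a small energy-transfer term, and coherent scattering
attenuates without depositing. The per-atom cross-sections are computed,
not read from an embedded grid:

* **Photoelectric** — from the Cromer–Liberman anomalous-dispersion
  parametrization shipped with `gemmi`, through the optical theorem
  σ_pe = 2 r_e λ f″(E). Absorption edges are part of the parametrization,
  so edge discontinuities (e.g. Ni K at 8.333 keV, jump ≈ 8×) come out
  naturally and no grid interpolation is needed or performed.
* **Incoherent (Compton)** — Klein–Nishina differential cross-section
  weighted by a Waller–Hartree-style incoherent scattering function
  S(q, Z) ≈ Z − f₀(q)²/Z built from IT92 atomic form factors, integrated
  with 256-point Gauss–Legendre quadrature. The same integral yields the
  mean fractional energy transferred to the recoil electron.
* **Coherent (Rayleigh)** — Thomson differential cross-section weighted by
  f₀(q)², same quadrature.

Accuracy against published mass-attenuation references: transition metals
~1% (Ni at 8.05 keV: 47.2 vs ≈47 cm² g⁻¹), light-element compounds 2–4%
(water at 10 keV: 5.17 vs 5.33 cm² g⁻¹; at 20 keV: 0.808 vs 0.810 cm² g⁻¹).
The few-percent light-element deficit is a known property of the
Cromer–Liberman photoabsorption relative to XCOM-class tabulations; tests
therefore use a 5% band where an independent tabulated value is asserted.
Provenance is exposed via `xray_physics.tabulation_info()`.

Linear coefficients of a unit cell follow the mixture rule
μ = (1/V_cell) Σᵢ nᵢσᵢ. Two conventions are provided for the
energy-absorption coefficient: photoelectric + Compton energy-transfer
share (default) or photoelectric only (`photoelectric_only=True`); they
differ by ≲1% below 20 keV. The published coefficients for the reference
crystal (1.736 mm⁻¹ at 8.05 keV, 0.804 mm⁻¹ at 17.997 keV) are matched by
the **total attenuation** coefficient (computed 1.741 and 0.767 mm⁻¹);
the energy-absorption value is ~5–10% lower because of the nickel coherent
term, which identifies the printed quantity as attenuation.

The photoelectron ionization count uses floor((E_γ − E_b)/W) with
W = 25 eV per ionization for organic material; an 18 keV photoelectron
yields 720 secondary ionizations, which is why one absorption event spreads
damage far beyond one unit cell.

## Reference crystal

The study sample emulated throughout is a nickel dipeptide heptahydrate
(catena-bis(μ₂-glycyl-histidinato)-nickel(II)·7H₂O, CSD entry FINWUW). The
deposited CIF is not redistributed; `data/finwuw_synthetic.cif` is a
clearly-labelled synthetic stand-in built from published summary
characteristics:

* formula Ni(C₈H₁₁N₄O₃)₂·7H₂O (C₁₆H₃₆N₈NiO₁₃, M = 607.2), one formula unit
  per asymmetric unit (P2₁, Z = 2);
* cell volume fixed by the published hydrate volume fraction: seven waters
  occupying 19.7% of the cell under the 18 Å³-per-non-H-atom packing rule
  gives V/Z = 7·18/0.197 = 639.6 Å³ (the cell edges and monoclinic angle
  are plausible but arbitrary; only volume, composition and the derived
  density, 1.576 g cm⁻³, are meaningful).

This reconstruction independently reproduces the compound's published water
mass fraction (20.8% computed vs 20.6%) and linear absorption coefficients
(above), so dose calculations against it are quantitatively representative
of the real sample.

## Composition rules

* The 18 Å³ rule credits each non-hydrogen atom 18 Å³; a cell is "full"
  when |void fraction| ≤ 10% (default tolerance — molecular packing
  efficiency genuinely varies by about that much). When underfull, void/18
  estimates the number of missing (solvent) non-H atoms.
* Voids are **never** auto-filled: `fill_voids` acts only on an explicit
  solvent request and refuses additions that would overfill beyond
  tolerance.
* Water volume fractions depend on a per-molecule volume convention:
  default 30 Å³ (bulk-density water); pass 18 Å³ to count channel water
  under the same packing rule as the framework — the convention that
  reproduces the published 19.7% figure for the reference hydrate.
* Partial-occupancy sites contribute their fractional occupancy, so mass is
  conserved for disordered structures.

## Beam model

The beam is a 2D flux-density field (photons s⁻¹ µm⁻²) on a regular grid
(default pitch 2 µm, extent 4× FWHM or 2× the aperture, whichever is
larger), normalized so the grid integral equals the total flux. Circular
collimation zeroes the field outside a centred disc with sub-pixel rim
coverage (8×8 sampling), keeping transmitted flux accurate to ≪0.5%; it is
idempotent and never increases flux. Measured screen maps are
background-subtracted by the border median (clamped at zero), rescaled from
pixels to µm, and normalized to the separately calibrated flux.

Diode calibration: flux = I·w_pair/(q_e·E_eV·f_abs) with
f_abs = 1 − exp(−μ_att,Si·t), silicon thickness 500 µm and pair-creation
energy 3.66 eV by default. Total attenuation of Si is used for the absorbed
fraction (at ≤25 keV and 500 µm essentially all interacting photons deposit
their energy in the diode).

Quoted beamline flux densities are reproduced with the *aperture-mean*
convention: total transmitted flux divided by the collimating-disc area.
When the calibrated flux is measured downstream of the aperture (the usual
diode position), apply `rescale_to_flux` after collimation; 8 × 10⁹ ph s⁻¹
through a 100 µm disc then averages 1.02 × 10¹² ph s⁻¹ mm⁻², consistent
with the ~1.12 × 10¹² figure quoted for the emulated beamline within its
session-to-session calibration spread. Peak density is reported alongside,
since quoted figures do not always state the convention.

## Dose engine

Geometry: beam along +x, ω rotation axis along +y (horizontal,
perpendicular to the beam), z vertical. The cuboid crystal's first
dimension lies along the rotation axis (rod-shaped samples are mounted
along the spindle). On the emulated fixed-χ goniometer the φ axis is
treated as collinear with ω, so a wedge at φ offsets the ω range; for a
rotating cuboid the dose field is insensitive to this convention.

Each wedge is sampled at 60 time steps (midpoint angles) by default. Per
step and voxel: incident density is read from the beam field by bilinear
interpolation at the voxel's projected transverse position, attenuated by
exp(−μ_att·ℓ) with ℓ the exact ray–cuboid upstream path in the crystal
frame (slab intersection, no ray marching error), and converted to dose via
μ_abs·E_γ/ρ. Boundary voxels carry partial-volume weights, so total volume
and absorbed energy are conserved exactly for non-divisible dimensions.

**DWD conventions.** The time-resolved DWD weights the mid-step cumulative
dose by the instantaneous fluence: Σ_steps,voxels φ·D_cum / Σφ. Mid-step
weighting makes the uniform-static closed form exact at any step count
(DWD = D_final/2: dose grows linearly while photons arrive uniformly). The
end-state variant (fluence-weighted *final* dose) is reported alongside; it
equals the average dose for a beam much larger than the crystal and is the
quantity bounded by the min/max voxel dose. For the emulated beamline
geometry (large, fairly uniform beam) the time-resolved DWD is ≈ half the
maximum voxel dose, the relationship quoted for such experiments. A 170°
scan of the 55 × 10 × 10 µm reference crystal at 1% of 8 × 10¹¹ ph s⁻¹
accrues ≈0.6 MGy DWD in ~750 s — consistent with the reported per-scan
doses, whose exact exposure times are not published, so only transmission
*ratios* (0.5×/2× at 0.5%/2%) are asserted exactly.

Assumptions: no photoelectron or fluorescence escape (crystal dimensions
≫ nothing at these sizes — escape would lower the dose of ≤10 µm crystals;
deliberately out of scope), no radiolysis feedback on composition, dose
linear in flux, time and transmission (rate-independence holds at these
flux densities).

Numerical checks: grid convergence of DWD < 1% on pitch halving for the
reference geometry; energy balance against the analytic photon budget to
0.5%; Beer–Lambert depth profile exact to discretization.

## Decay analysis

* **Equivalence classes** use the Laue group of a user-supplied point group
  (default P2₁ → 2/m, Friedel mates included), mapped through `gemmi`
  symmetry operations to a canonical representative.
* **Rmerge** = Σ|Iᵢ − ⟨I⟩|/ΣIᵢ over multiply-observed uniques; with no
  multiples it is reported as undefined (None), never as zero. Bins are
  equal-count in 1/d³.
* **CC½** splits each unique's observations randomly into two halves
  (seeded, seed reported) and correlates the per-bin half-set means across
  ≥3 uniques; smaller bins are undefined (NaN). No smoothing is applied
  before the threshold crossing — interpolation only, to avoid hidden
  parameters.
* **Resolution limit**: first crossing of CC½ = 0.3 scanning from low to
  high resolution, interpolated linearly in 1/d between bin centres; a
  curve that never crosses returns the geometric data edge.
* **Fits**: exponentials are started in log space and refined by nonlinear
  least squares (unweighted by default); linear laws use ordinary least
  squares. Confidence intervals use the Student-t quantile at the residual
  degrees of freedom. Flat intensity series yield λ→0 and are flagged with
  an infinite half-dose rather than an error.
* The dose coordinate of scan *s* is the cumulative DWD after *s* scans
  (the per-scan DWD ladder), matching per-scan dose accounting.

## Synthetic generator

The generator emits what the analysis consumes. Reflection templates
enumerate the lattice to d_min, reduce to Laue uniques, and draw base
intensities from a Wilson-like model (exp(−2B₀(1/2d)²) falloff × unit-mean
exponential variates, B₀ = 1.5 Å²). Scan *s* at cumulative dose D applies

I = I₀ · exp(−ln2·D/D_half) · exp(−2·ΔB·(1/2d)²) · noise,  ΔB = b_rate·D

with lognormal multiplicative noise (mean-preserving) and optional additive
Gaussian noise with a consistent sigma column. Cell volumes inflate
linearly, Ueq grows exponentially. Everything is reproducible bit-for-bit
from the seed.

Default conditions are those of the emulated baseline experiment: 16 scans
× 0.63 MGy, D_half = 4.4 MGy, resolution decay 1 Å/10 MGy from 0.6 Å, cell
expansion 2%/10 MGy, 2% multiplicative noise, Ueq₀ = 0.012 Å² growing at
0.05 MGy⁻¹. Two defaults are not stated anywhere and were chosen once as
field-typical values: the B-increment rate (0.8 Å² MGy⁻¹, a mid-range
cryo damage coefficient) and the Ueq growth rate (0.05 MGy⁻¹, giving the
observed ~50% Ueq growth over a ~9 MGy series). Temperature and dose-rate
study arms are emulated as scalar multipliers on the decay rates (a
factor-of-two span), not as mechanistic models.

The global exponential and the linear resolution decay are **independent
knobs**: measured series show both behaviours but no established functional
link between them, so none is imposed. Consequently the reflection-level
series has an *apparent* summed-intensity half-dose below the generative
global value (the high-resolution shells fade faster) — the same asymmetry
real data show. Direct summary-level generators
(`generate_intensity_series`, `generate_resolution_series`) produce each
law in isolation for calibration studies.

**What the synthetic tests show** — that every estimator recovers its
generative parameter exactly without noise, without bias across ≥100 seeds
at realistic noise, and with correctly calibrated confidence intervals.
**What they do not show** — correctness on real integrated data, which
carries scaling/absorption artefacts, non-factorized damage, specific
(site-level) chemistry, and detector effects the generator deliberately
omits.

## Known limitations

* No photoelectron/fluorescence escape; doses for crystals ≲10 µm in an
  18 keV beam are therefore slight overestimates.
* Cuboid crystals only; no meshes or spheres.
* No solvent-accessible-void geometry (rolling-probe) — the 18 Å³ audit is
  an occupancy estimate, not a cavity map.
* Structure-model metrics (R-factors, residual densities, site splitting)
  are accepted as input columns where relevant, never computed: structure
  solution and refinement are out of scope.
* Problem sizes used in the test suite (voxel pitches 1–2 µm on ≤55 µm
  crystals, ≤60 time steps per wedge, reflection templates to 0.8–1.5 Å)
  were chosen for fast, converged runs; grid-convergence tests justify
  them.
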