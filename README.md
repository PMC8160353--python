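# microdose

Microdosimetric characterization of therapy beams: lineal-energy spectrum
analysis, MKM cell-survival and RBE estimation, voxelized dose-averaged LET
accumulation, and resampling-based uncertainty propagation — with a synthetic
TEPC (tissue-equivalent proportional counter) event generator in place of
Monte Carlo particle transport, so the whole pipeline runs and is testable at
desk scale.

## Who this is for

Medical physicists and computational radiobiologists comparing radiation
qualities — photons, clinical electrons, very-high-energy electrons (VHEE,
E > 70 MeV), protons, carbon and neon ions — in terms of biologically
relevant quantities rather than absorbed dose alone.

## The model

**Microdosimetry.** A single event imparting energy ε (keV) to a site of mean
chord length l̄ (µm) has lineal energy y = ε/l̄ (keV/µm). A beam at a point is
described by the probability density f(y) on a 150-bin logarithmic grid
spanning 7 decades from 0.01 keV/µm, its dose-weighted density
d(y) = y f(y)/∫y f(y)dy, the frequency mean ȳ_F = ∫y f(y)dy, the dose mean
ȳ_D = ∫y² f(y)dy / ∫y f(y)dy, and the saturation-corrected dose mean
(overkill correction, Kase form)

    ȳ* = y₀² ∫(1 − e^{−(y/y₀)²}) f(y) dy / ∫ y f(y) dy .

**MKM survival and RBE.** The microdosimetric kinetic model ties the LQ
survival curve S(D) = exp(−α D − β D²) to the spectrum through

    α_MKM = α₀ + β/(ρ π r_d²) · 0.1602 · ȳ* ,

with the Kase HSG (human salivary gland) parameters α₀ = 0.13 Gy⁻¹,
β = 0.05 Gy⁻², y₀ = 150 keV/µm, r_d = 0.42 µm, ρ = 1 g/cm³, and 0.1602 the
keV/(g cm⁻³ µm³) → Gy conversion. RBE₁₀ is the dose ratio (reference over
test) at 10% survival against the Co-60 reference curve (α = 0.157 Gy⁻¹).

**Dose-averaged LET.** The macroscopic analogue
L̄_d = ∫S_el(E) D(E) dE / ∫D(E) dE is tallied per voxel from step logs:
each charged step contributes E_d·S_el(E_k) and E_d to numerator/denominator
sums. Dose uncertainty uses the history-by-history estimator, the L̄_d
uncertainty is twice the dose uncertainty, and voxels below 0.1% of the
maximum dose are masked.

**Synthetic TEPC events.** Chords of a 1 µm sphere are sampled under
µ-randomness (f(l) = 2l/d², l = d√u) and combined with a parametric LET
distribution and multiplicative straggling: ε = L·l·(1+η). Constant-LET
crossers then obey the exact oracles ȳ_F = L and ȳ_D = (9/8)L, and shipped
presets are calibrated to published ȳ_D values per beam class (photon 1.85,
clinical electron 1.307, VHEE 1.251, proton plateau/peak 5.3/12.86, carbon
peak 325.4, neon peak 990.7 keV/µm).

## Worked example

```sh
$ microdose simulate --preset photon-like --n 100000 --seed 1 --out-spectrum photon.tsv
simulated 100000 events from preset 'photon-like' (y_D target 1.85)
$ microdose analyze photon.tsv
# tool=microdose 0.1.0
# config_hash=6f9f90217a4e
# seed=12345
y_F	y_D	y_star	alpha_mkm	rbe10	sd_y_D	sd_alpha	sd_rbe
1.12343327	1.85445991	1.85395283	0.156799743	0.999712528	0.00855964872	0.000123514549	0.000177286493
```

The simulated photon-scale beam lands on the calibration target
ȳ_D ≈ 1.85 keV/µm; the saturation correction is negligible at these lineal
energies (ȳ* ≈ ȳ_D), giving α_MKM ≈ 0.157 Gy⁻¹ and an RBE₁₀ of 1.00 against
the Co-60 reference — a photon-like beam is its own reference. The `sd_*`
columns are 1000-replicate resampling uncertainties from the per-bin standard
errors; their 10⁻³–10⁻⁴ scale matches the published uncertainty scale for
low-LET beams.

`microdose table1` recomputes the published α_MKM/RBE₁₀ benchmark table from
its printed inputs and reports the deltas (all within ±0.002, the rounding of
the printed α inputs); `microdose let-accumulate` runs the voxel LET tally on
a step log; `microdose presets` lists the beam classes.

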