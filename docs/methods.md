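# Methods

This note documents the models, numerical choices and limitations behind the
`microdose` pipeline, in the order data flows through it.

## Synthetic single-event generator

The generator replaces Monte Carlo particle transport with the simplest event
model that has exact moment oracles. An event is a charged-particle crosser
of a spherical site (default diameter 1 µm, mean chord l̄ = 2d/3): a chord is
drawn under µ-randomness by the inverse CDF l = d√u (pdf 2l/d²), an LET value
L is drawn from a parametric distribution, and the energy imparted is
ε = L·l·(1+η) with η a multiplicative straggling factor,
Normal(0, σ) truncated to (−1, 1) by redraw so that ε > 0. The lineal energy
is y = ε/l̄.

Closed forms used as oracles (no straggling, constant L): E[l] = 2d/3,
E[l²] = d²/2, hence ȳ_F = L and ȳ_D = (9/8)L; with straggling σ the second
moment picks up a factor 1+σ² (the truncation bias is below 0.1% at σ ≤ 0.2,
the default for "realistic" presets; oracle tests use σ = 0).

**LET families.** Constant, lognormal (median, geometric SD), and finite
mixtures. All are 1-homogeneous in their scale parameter: multiplying every
LET draw by c multiplies ȳ_D by exactly c. Preset calibration exploits this —
it simulates once (default n = 2·10⁵ events), rescales the model by
target/measured, and verifies on a fresh sample to within 5%. A bracketing
search would converge to the same point; the rescale reaches it in one step
because ȳ_D is exactly linear in the scale.

**Presets.** One per beam class, calibrated to published dose-mean lineal
energies at the corresponding depth (photon 1.85, clinical electron 1.307,
VHEE 1.251, proton plateau 5.3 and peak 12.86, carbon peak 325.4, neon peak
990.7 keV/µm). Low-LET classes use a broad lognormal (GSD 1.8), ion peaks a
narrow one (GSD 1.5 down to 1.15), mirroring the qualitative widths of
measured yd(y) spectra. The GSD values are shape choices, not fits: only ȳ_D
is calibrated.

**Fidelity limits.** Only crossers are modeled — no stoppers, starters or
insiders, no delta-ray escape, no detector response (gas gain, wall effects,
pile-up). Consequently the generator reproduces the first two moments and the
coarse spectral width of each beam class, not the detailed spectral shape;
passing tests demonstrate the correctness of the downstream formalism, not
transport realism.

## Spectra and moments

Histograms live on a geometric grid, by default 150 bins over 7 decades from
0.01 keV/µm (ratio 10^(7/150) ≈ 1.1134). Bin densities are
f_i = count_i/(n·Δy_i) with Poisson standard errors √count_i/(n·Δy_i).
Out-of-range events are tallied as underflow/overflow and excluded from the
normalization with a logged warning, never dropped silently.

The representative value of a bin is its geometric midpoint
√(edge_i·edge_{i+1}) — the unbiased choice for log-uniform bins, keeping the
histogram-path ȳ_D within ~0.1% of the event path on the default grid. When
raw events are available the exact sample moments are used instead; the
histogram path is the fallback for imported spectra.

The saturation-corrected mean uses `-expm1(-(y/y0)^2)` so that the low-y
limit (ȳ* → ȳ_D) is accurate to machine precision rather than losing digits
to cancellation; the high-y limit ȳ* → y₀²/ȳ_F follows from the same
expression. All histogram moments are ratios of weighted sums and hence
invariant under global rescaling of f — required by the resampling stage.

Degenerate inputs (empty samples, all-zero spectra, zero first moments) raise
explicit errors rather than returning NaN, so a pathological spectrum cannot
silently propagate into a survival curve.

## MKM and RBE

The α relation uses the single named constant 0.1602176634 Gy per
keV/(g cm⁻³ µm³) (exact SI keV→J over the mass of 1 µm³ at unit density) to
close the units of β·ȳ*/(ρπr_d²). LQ inversion uses the cancellation-free
root D = −2 ln S / (α + √(α² − 4β ln S)), which is exact for β = 0 and stable
for small β. The reference curve defaults to the calculated Co-60 one
(α = 0.157 Gy⁻¹, β shared at 0.05 Gy⁻²); the experimental 200 kV X-ray fit
(α = 0.164 Gy⁻¹) ships as an alternative preset. β is shared between
reference and test beams — an MKM assumption — but remains a parameter.

## LET accumulation

The voxel tally accumulates, per charged step, E_d and E_d·S_el(E_k); the
ratio is L̄_d. Stopping-power lookup interpolates linearly in log–log space
(exact for power laws, the standard behavior of electronic stopping-power
tables); energies outside the table are clamped to the end values with a
logged warning rather than failing, since end-of-range steps below the first
tabulated energy are common and their contribution is bounded.

The step log is brought into a canonical sort order before summation, so the
tally is bit-identical under any permutation of the input — an order-
independence guarantee that pure streaming float addition cannot give.
An optional `kinds=` filter restricts the LET sums to chosen particle labels
(e.g. the primary species only); the dose map always counts all deposits.

Dose uncertainty is the history-by-history relative standard error
√((Σx_h²/N − (Σx_h/N)²)/(N−1)) / x̄ over per-history deposits x_h; the L̄_d
relative uncertainty is exactly twice it (the dose enters the ratio twice).
N defaults to the number of distinct history ids in the log and can be
overridden with the true primary count. Voxels below 0.1% of the maximum
dose (configurable) are masked in reported profiles; the underlying sums are
untouched. Dose is reported in deposited-energy units per voxel — only
relative profiles are meaningful, absolute gray conversion is out of scope.

## Resampling uncertainties

Each replicate redraws every bin independently from Normal(f_i, σ_i),
clipping negatives to zero; the estimator is evaluated per replicate and the
standard deviation over replicates (default 1000) is the reported
uncertainty. Replicates are not renormalized: all shipped estimators are
scale-invariant ratios, and renormalizing would hide total-count uncertainty
for any estimator that is not (a `normalize` call is available when wanted).
The clipped-bin fraction is reported so the positivity bias is visible, and
replicates whose estimator is non-finite are excluded and counted, flagging
the report when they exceed 1%. No bin-to-bin covariance is modeled.

## Problem sizes and tolerances in the test suite

Oracle tests run at n = 10⁵ events (moment tolerances are explicit 3-standard-
error bands computed from the chord-pdf moments, e.g. relative SE 7.6·10⁻⁴
for ȳ_D of constant-LET crossers), calibration at n = 1–2·10⁵, LET-tally
convergence at 10⁵ steps, and resampling convergence at 10³ vs 10⁴
replicates. These sizes put every Monte Carlo check at least 3σ away from its
closed form while keeping the full suite in the seconds range. File formats
round-trip at 9 significant digits, which is idempotent for the `%.9g`
representation.

## Known limitations

* Crosser-only event model; spectral shapes are schematic (see above).
* L̄_d and ȳ_D depend on the scoring volume size; the defaults (voxel tally
  vs 1 µm site) are different scales by construction and their absolute
  values are not directly comparable — only cross-beam ratios are.
* No variance model between spectrum bins; resampling treats bins as
  independent.
* The step-log tally keeps per-(voxel, history) partial sums in memory, which
  is fine for the intended desk-scale logs but not for production transport
  output.
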