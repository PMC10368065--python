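# Methods

This note records the model, the numerical choices, and the scope of the
synthetic validation, in the package's internal units (mm, ps; optical
coefficients in mm⁻¹, converted to cm⁻¹ only at public surfaces).

## Forward model

Light propagation is modelled with the diffusion approximation for a
semi-infinite medium of N plane layers (z = 0 at the surface, the last
layer semi-infinite). Conventions:

* diffusion coefficient D = 1/(3 µ′ₛ), independent of absorption;
* isotropic point source at z₀ = 1/µ′ₛ of the top layer;
* extrapolated boundary at z = −z_b with z_b = 2 A D, where
  A = (1 + r_d)/(1 − r_d) and r_d is the Groenhuis polynomial fit of the
  diffuse reflection coefficient in the relative refractive index
  n/n_ext (n_ext defaults to 1.0, air). All layers must share one n;
  a differing per-layer n is carried in the type but triggers a warning
  and the top layer's value is used;
* reflectance = outward diffuse flux D ∂Φ/∂z at z = 0;
* speed of light c = 0.299792458 mm/ps, v = c/n.

**Homogeneous medium.** The image-source solution gives the closed form

R(ρ,t) = (4πDv)^(−3/2) t^(−5/2) exp(−µₐvt − ρ²/4Dvt) · ½ ·
[z₀ e^(−z₀²/4Dvt) + (z₀+2z_b) e^(−(z₀+2z_b)²/4Dvt)],

evaluated directly at the bin centers (zero for t ≤ 0). A single-layer
medium routes here.

**Layered medium.** In the (radial spatial frequency s, temporal
frequency ω) domain the surface flux of the layered problem is, with
α_k² = s² + (µₐ,k + iω/v)/D_k and the deeper stack folded into an
effective admittance Z (tanh recursion for N ≥ 3, Z = D₂α₂ for N = 2,
β = Z/(D₁α₁)):

flux(s,ω) = front · [(1+β) + e^(−2α₁(L−z₀))(1−β)] /
                    [(1+β) + e^(−2α₁(L+z_b))(1−β)],
front = ½ (e^(−α₁z₀) + e^(−α₁(z₀+2z_b))).

Rather than inverting this directly, the implementation splits

flux = flux_top + front·(1−β)(e^(−2α₁(L−z₀)) − e^(−2α₁(L+z_b)))/denominator,

where flux_top (β = 1) is exactly the homogeneous top-layer flux, whose
time-domain form is the closed form above. Only the perturbation term —
the influence of the deeper layers — is carried through the numerical
inverse. This choice is load-bearing: the full integrand decays only
like e^(−s z₀) and its Hankel integral at ρ ≈ 30 mm loses 6–7 digits to
J₀-oscillation cancellation, which capped accuracy at the percent level
in strongly scattering configurations. The perturbation integrand decays
like e^(−s(2L−z₀)) (set by the shortest path to depth L and back), needs
an order of magnitude fewer quadrature nodes, has little cancellation,
and makes the equal-layer limit exact by construction. Measured
equal-layer agreement with the closed form is ~1e-8 relative; the
contract enforced by tests is 0.5% wherever the curve exceeds 1e-6 of
its peak.

Numerical parameters (all fixed, none tuned per call):

* radial frequency: Gauss–Legendre on [0, s_max] with
  s_max = 35/(2L − z₀) (integrand < ~1e-15 of its scale at the cutoff)
  and n = max(128, 0.75·s_max·ρ + 32) nodes (≥ ~5 nodes per J₀ period);
* temporal frequency: uniform grid of the FFT window, window length
  ≥ 4× the requested time span (rounded to a fast FFT length); modes
  kept up to ω_c = 2Dv(32/ρ)², beyond which the spectrum is < ~1e-13 of
  DC; spectrum entries below 1e-12 of the spectrum peak are zeroed
  (a 1e-8 floor measurably distorts the DTOF rising edge);
* the inverse FFT's residual negative ringing is clipped to zero; if it
  ever exceeds 1e-4 of the curve peak an error is raised instead.

Bin-center sampling uses t₀ = 0 by default so that IRF convolution is
exactly additive in bin index.

**Validation oracles.** The homogeneous curve is checked against an
independently coded steady-state (CW) formula by time integration and
against a 0.1 ps brute-force grid; the layered curve against the
equal-layer and thick-superficial limits, the time-domain Beer–Lambert
scaling e^(−Δµₐvt) (1e-6 relative), and an isotropic random-walk Monte
Carlo simulation of the two-layer slab (2×10⁶ photons, matched
refractive index so that the absorbing-surface MC corresponds to the
diffusion boundary factor; agreement required within max(3.5σ, 10%) for
t ≥ 600 ps — earlier bins are transport-dominated and outside the
diffusion model's validity).

## Moments and their noise

Moments are computed over an inclusive channel range selected on the
*baseline* DTOF — 25% of peak on the rising edge to 3% on the tail for
the two-layer analysis, 85%/1% for curve fitting — and the same range is
reused for every measured and simulated DTOF, which is what makes the
moment *changes* insensitive to the range choice. Whole-bin thresholds,
peak ties broken toward the earlier bin. Counts stay real-valued after
background subtraction (no clipping inside the range; a warning is
logged if negative mass exceeds 0.1% of the total).

ΔA uses the natural logarithm; only the pairing with s_A = √(2/Ntot)
matters for the weighting and that pairing is exact in ln units. IRF
moment subtraction (m₁, V, m₃C) exploits cumulant additivity of
convolution. Photon-noise uncertainties of the changes, from the
baseline histogram only (both states assumed equally noisy):
s_A = √(2/Ntot), s_m1 = √(2V/Ntot), s_V = √(2(m4C−V²)/Ntot). The noise
formulas are evaluated on the raw background-subtracted histogram within
the analysis range (not the IRF-deconvolved moments).

## Inverse problems

**Homogeneous curve fit** (absolute µₐ, µ′ₛ): amplitude × (model ⊛ IRF)
fitted to the measured DTOF over the 85%/1% range with Poisson weights
1/√max(counts, 1); the amplitude is profiled out analytically each
iteration, leaving a 2-parameter bounded least-squares problem
(µₐ ∈ [0.001, 1] cm⁻¹, µ′ₛ ∈ [1, 40] cm⁻¹, default start 0.1/10 cm⁻¹,
ftol 1e-10, xtol 1e-8). Background is the mean of the leading 50 bins,
which must all stay below 1% of peak.

**Two-layer moments fit** (Δµₐ per layer): residuals
(Δm₁_sim − Δm₁)/√V and (ΔV_sim − ΔV)/√(m4C−V²) — plus (ΔA_sim − ΔA)
behind a flag — minimized over (Δµₐ,Sup, Δµₐ,Deep) with
scipy.optimize.least_squares(method="trf"), a damped trust-region
least-squares algorithm of the Levenberg–Marquardt family chosen because
the parameter box |Δµₐ| ≤ 0.5 cm⁻¹ (and the physical floor µₐ ≥ 0)
requires bound support. Each candidate evaluation simulates both DTOFs
through the same IRF-convolution and fixed-range moment pipeline as the
measurement. The simulated baseline moments are cached; with the
perturbation-split engine one candidate costs ~10 ms, a fit well under a
second. The initial guess is the linearized sensitivity-factor solution
(central differences at ±2% of each layer's baseline µₐ); the solution
is verified to be initial-guess-independent to 1e-4 cm⁻¹.

**χ² landscapes.** The scaled norm (the 2Ntotχ² form) is mapped over a
default 61×61 grid of −0.05…+0.15 cm⁻¹ per axis. One practical caveat,
reflected in the tests: the continuous error norm has a single minimum,
but sampling its narrow curved valley on a square grid produces shallow
single-cell dips along the valley floor (< 1e-3 of the landscape scale).
These are discretization artifacts — the damped fit started inside any
of them escapes to the truth — so the tests assert "unique significant
minimum + escape", not naive strict-local-minimum counting.

## Chromophores

Absolute µₐ spectra are converted to hemoglobin concentrations by
unconstrained linear unmixing after subtracting 0.985 × the water
spectrum (the water-plus-lipid volume fraction of the phantom mixtures);
StO₂ = 100·C_HbO2/(C_HbO2+C_Hb). Unmixing is deliberately unconstrained:
biased inputs (e.g. an unmodelled scattering change) can and should
surface as negative concentrations and out-of-range StO₂ rather than be
clipped. Spectral channels follow the 16-channel layout 680–867.5 nm at
12.5 nm spacing (channel k at 680 + 12.5(k−1) nm); the default unmixing
band is channels 3–11 (705–805 nm). The packaged extinction table is a
*synthetic* rendition of published hemoglobin and water spectra, point-
sampled at the channel centers (see the data file header): it preserves
the features the analysis depends on — the deoxyhemoglobin band near
760 nm, the isosbestic crossing near 800 nm, the water shoulder near
740 nm — and the digital twin uses the same table for forward synthesis
and inversion, so all concentration tests are exact self-consistency
checks. Quantitative re-analysis of real spectra would substitute a
measured table.

## Phantom digital twin

The twin reproduces the study conditions of the two-compartment
blood–lipid phantom:

* nominal properties: µ′ₛ = ε′ₛ,SL · V_SL/V_total with
  ε′ₛ,SL = 21.5 mm⁻¹ at 750 nm; µₐ = µₐ,water + (V_ink·d_ink/V_total)·
  ε_eff,ink·(1−Λ) with ε_eff,ink = A_p/d_ink and albedo Λ = 0.15.
  Ingredient masses (grams) convert to volumes at density 1 g/ml
  (< 2% error at these dilutions);
* ink protocol: 20 targeted steps 0.05→0.25 cm⁻¹ in one compartment,
  the other fixed at 0.10 cm⁻¹, µ′ₛ = 10.7 cm⁻¹, L = 14.5 mm, ρ = 30 mm;
* blood protocol: yeast in the deep compartment at minute 0 and the
  superficial at minute 31; oxygen windows 13–15, 45–47, 60–62,
  77–79 min; compartment recipes 3366/180/54 g (deep) and half that
  (superficial), i.e. 93.5% PBS-water, 5% lipid, 1.5% blood, 0.1% yeast;
* kinetics (the protocol states plateaus, not rates): first-order
  desaturation with τ = 3 min (< 2% left within a 13-min cycle), linear
  reoxygenation to 100% across each 2-min window, desaturation resuming
  when the window closes;
* yeast raises µ′ₛ by +0.3 cm⁻¹ (deep, minute 0) and +0.2 cm⁻¹
  (superficial, minute 31), applied as steps; an optional late downward
  µ′ₛ drift is off by default;
* total hemoglobin is a calibration constant of the twin, set so the
  fully deoxygenated mixture reaches µₐ(705 nm) = 0.17 cm⁻¹ (≈ 41 µM —
  plausible for a 1.5% blood volume fraction);
* frames default to 3 s sampling; Poisson noise at a caller-chosen
  expected total count, seeded, byte-reproducible;
* the synthetic IRF is a Gaussian (default FWHM 400 ps) plus a 1%
  after-pulse replica 1 ns later.

What the twin does *not* emulate: laser power drifts and attenuator
changes (the reason ΔA is excluded by default), IRF shape drift,
detector nonlinearity and instrumental (non-Poisson) noise, temperature
and pH chemistry of the yeast, and wall effects of the physical tank.
Passing round-trip tests therefore demonstrate correctness of the
analysis pipeline under the model's own physics and Poisson statistics,
not robustness to every instrumental artifact of a real measurement.

## Problem sizes in the test suite

The suite is sized to run comfortably on one CPU: the Monte Carlo oracle
uses 2×10⁶ photons; Poisson repetition studies use 50 replicates at
Ntot = 10⁶ (fits) and 2000 replicates (moment-noise oracle); the blood
round trip analyzes 9 wavelengths at ~10 selected frames (two per
deoxygenation cycle plus the two baselines) rather than every 3 s frame;
the landscape checks use the full default 61×61 grid. These are the
package's chosen study sizes; all thresholds were fixed from the study
conditions, not adjusted to outcomes.

## Known limitations

* µ′ₛ changes are not fitted: a superficial scattering change between
  baseline and measurement biases the recovered Δµₐ (reproduced
  deliberately by the cycle-3 test). Fitting Δµ′ₛ or L is out of scope.
* The method requires all baseline parameters; errors in them propagate
  as mapped by the baseline-error study (underestimating L pulls the
  recovered deep change toward the superficial one; deep µ′ₛ errors are
  nearly harmless).
* Diffusion-theory validity: early times (≲ 0.5 ns at ρ = 30 mm) and
  low-scattering/thin-layer geometries (L ≤ z₀ = 1/µ′ₛ is rejected) are
  outside the model.
* Single source–detector distance; multi-distance extensions are not
  implemented.
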