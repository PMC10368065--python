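# tdnirs

Two-layer absorption and oxygenation from changes in moments of photon
time-of-flight distributions (time-domain near-infrared spectroscopy).

## The problem

Tissues such as the head are layered: a superficial layer (scalp, skull)
sits above the layer of interest (brain). A time-domain NIRS measurement
records the distribution of times of flight of photons (DTOF) at a
source–detector distance ρ; because late photons travel deeper, the DTOF
carries depth-resolved information. This package determines **large**
absorption changes Δµ<sub>a</sub> separately in the superficial and deep
layers of a two-layered turbid medium — and, by adding them to known
baseline values, absolute µ<sub>a</sub> and hemoglobin oxygen saturation
StO₂ per layer.

The measurands are changes in the statistical moments of the DTOF between
a baseline and a perturbed state: attenuation ΔA = −ln(N*/N), mean time
of flight Δm₁, and variance ΔV. Their depth selectivity increases with
moment order. For a candidate pair (Δµ<sub>a,Sup</sub>, Δµ<sub>a,Deep</sub>)
the layered diffusion model predicts the same changes; the fit minimizes
the photon-noise-weighted error norm

```
2 Ntot χ² = (ΔA_sim − ΔA)² + (Δm₁_sim − Δm₁)²/V + (ΔV_sim − ΔV)²/(m4C − V²)
```

with a damped (Levenberg–Marquardt-type) iterative least-squares search,
so the classical small-perturbation (sensitivity-factor) linearization is
needed only for the initial guess. By default the intensity term ΔA is
excluded (it is the moment most exposed to source-power drifts); the pair
{Δm₁, ΔV} identifies both unknowns.

The forward model is the diffusion-equation Green's function for an
N-layered semi-infinite medium under extrapolated boundary conditions,
evaluated in the frequency domain over radial spatial frequency and
inverted to the time domain by FFT, then convolved with the instrument
response function (IRF).

A digital twin of a two-layered blood–lipid phantom drives validation:
nominal-property calculators for ink/lipid recipes, a 20-step ink
titration protocol, and a blood protocol with six yeast/oxygen
deoxygenation cycles producing multi-wavelength DTOF time series, with
optional Poisson counting noise.

## Worked example

Simulate a deep-layer absorption step of +0.05 cm⁻¹ under a 15 mm
superficial layer and recover it from the moment changes:

```python
from tdnirs import (
    BaselineState, IRFModel, TimeGrid, TwoLayerScenario,
    fit_two_layer, simulate_dtof_pair, synth_irf,
)
from tdnirs.units import per_mm_to_per_cm as per_cm

grid = TimeGrid(bin_width=12.22, n_bins=1024)
irf = synth_irf(IRFModel(), grid)

baseline = BaselineState(
    mua_sup=0.01, mua_deep=0.01,      # 0.10 cm^-1 in both layers
    musp_sup=1.0, musp_deep=1.0,      # 10 cm^-1
    L=15.0, n=1.33, rho=30.0,
)
scenario = TwoLayerScenario(baseline, dmua_sup=0.0, dmua_deep=0.005,
                            irf=irf, grid=grid)
dtof_baseline, dtof_after = simulate_dtof_pair(scenario, ntot_baseline=5e6)

fit = fit_two_layer(dtof_baseline, dtof_after, baseline, irf)
print(f"dmua_sup  = {per_cm(fit.dmua_sup):+.4f} cm^-1")
print(f"dmua_deep = {per_cm(fit.dmua_deep):+.4f} cm^-1")
print(f"absolute mua: sup {per_cm(fit.mua_sup_abs):.4f}, "
      f"deep {per_cm(fit.mua_deep_abs):.4f} cm^-1")
print(f"converged = {fit.converged}, chi2 = {fit.chi2:.2e}")
```

prints

```
dmua_sup  = -0.0000 cm^-1
dmua_deep = +0.0500 cm^-1
absolute mua: sup 0.1000, deep 0.1500 cm^-1
converged = True, chi2 = 4.19e-25
```

The superficial change is recovered as zero and the deep step exactly,
even though the step (50% of baseline) is far outside the linear regime —
the sensitivity-factor initial guess alone misses it by roughly a third.
StO₂ per layer follows by running the fit at several wavelengths and
unmixing the resulting µ<sub>a</sub> spectra with
`tdnirs.fit_concentrations`.

A command-line surface mirrors the library:

```
tdnirs make-irf irf.dtof
tdnirs simulate-ink --out-dir ink_run --seed 1
tdnirs fit-2layer --baseline b.dtof --after a.dtof --irf irf.dtof --config base.yaml
tdnirs landscape --baseline b.dtof --after a.dtof --irf irf.dtof \
       --config base.yaml chi2_map.txt
tdnirs sto2 --spectrum mua_spectrum.txt
```

All files are plain text; every stochastic command takes `--seed` and
reruns are byte-identical.

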