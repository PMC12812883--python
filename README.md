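# hydrolipid

Quantitative analysis of how the **onset timing of hydrodynamic
perturbation** tunes growth kinetics, single-cell neutral-lipid
accumulation and photophysiology in motile microalgae (raphidophytes such
as *Heterosigma akashiwo*), for experimentalists running orbital-shaker
perturbation studies with microscopy-based counting, Nile-Red lipid
imaging and PAM fluorometry.

The package implements the full analysis chain and a ground-truth
synthetic-data generator for every input kind, so each stage is testable
without raw instrument data.

## What it computes

**Hydrodynamic forcing.** The mean energy dissipation rate of an
orbital-shaken culture tube, from the shake-flask correlation

    ε = 1.94 · n³ D⁴ / V_f^(2/3) · Re^(−0.2),   Re = ρ_f n D² / μ_f

(n platform speed, D tube inner diameter, V_f working volume).  Protocol
constants — counting-chamber volume, dye dilution, irradiance → photon
flux — are computed by small closed-form calculators.

**Growth kinetics.** Cell concentrations counted from millifluidic
time-lapse stacks (median-background subtraction, thresholding, connected
components, mean count / chamber volume) are fitted to the logistic model

    P(t) = K / (1 + ((K − P0)/P0) e^(−rt)),   Td = ln 2 / r

per replicate; carrying capacity K and doubling time Td are compared
across conditions with Welch two-sample t-tests, and the growth index
IG(t) = P_perturbed(t)/P_static(t) tracks the divergence of the fitted
curves.

**Single-cell lipid quantification.** Nile-Red micrographs are segmented
(cell body, then droplets within it); each droplet's maximum/minimum
Feret diameters (a, b) give a prolate-spheroid volume proxy
V = (π/6)·a·b² and an equivalent-sphere standardized area
A = π(3V/4π)^(2/3).  Per cell, the normalized lipid area
A_norm = ΣA / cell area; across conditions the lipid index
IL = mean A_norm (perturbed) / mean A_norm (static), with a seeded
20-cell subsample per replicate.

**Photophysiology.** From dark-adapted (F0, Fm) and rapid-light-curve
steps (F′, Fm′ at 16 irradiances, 0–2500 µmol photons m⁻² s⁻¹):
Fv/Fm = (Fm−F0)/Fm, Y(II) = (Fm′−F′)/Fm′, NPQ = (Fm−Fm′)/Fm′,
rETR = E·Y(II)·0.5; the rETR–E curve is fitted with the Eilers–Peeters
model rETR(E) = E/(aE²+bE+c) (rETR_max = 1/(b+2√(ac))), and NPQ at
500 µmol m⁻² s⁻¹ is interpolated by local regression over the bracketing
steps.

## Worked example

```python
from hydrolipid.shaker import ShakerSystem, energy_dissipation
from hydrolipid.pipeline import ScenarioConfig, run_pipeline

sys = ShakerSystem(n=110, D=0.023, V_f=27e-6, rho_f=1025, mu_f=1.1e-3,
                   n_unit="rpm")
print(f"epsilon = {energy_dissipation(sys):.3e} W/kg")

report = run_pipeline(ScenarioConfig.from_preset("scenario1", master_seed=7,
                                                 n_cells_per_replicate=20))
cmp = report.growth_comparison
print(f"Td ratio = {cmp.Td_perturbed[0] / cmp.Td_static[0]:.2f}, "
      f"K p = {cmp.p_K:.3f}, Td p = {cmp.p_Td:.4f}")
print(f"lipid index IL = {report.lipid_index:.2f}")
```

prints

```
epsilon = 9.528e-04 W/kg
Td ratio = 0.52, K p = 0.756, Td p = 0.0048
lipid index IL = 4.31
```

— a 110-rpm shaker dissipates ≈ 9.5×10⁻⁴ W kg⁻¹; under the
immediate-onset preset the perturbed population's doubling time roughly
halves (significant at α = 0.05) while its carrying capacity is
statistically unchanged, and perturbed cells carry about 4× the
normalized lipid area of static controls.  The `scenario2` preset
(120-h-delayed onset) instead lowers the carrying capacity to ≈ 0.69 of
the control with an unchanged doubling time.

The same stages are scriptable from the shell:

```sh
hydrolipid run --preset scenario1 --seed 7 --out report/
hydrolipid eps --config exp.yaml
hydrolipid count --stack stack.tif --dilution 1
```

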