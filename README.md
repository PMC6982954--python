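# bmcal — bimaterial-microcantilever calorimetry

`bmcal` models a photothermally heated **bimaterial microcantilever (BMC)**
used as a calorimeter for micro-scale samples — the motivating case being a
single yeast cell resting on a 600 × 76 µm Si₃N₄/Al beam. It is written for
MEMS/biosensor researchers who want to simulate the instrument, fit its
transient response, and invert the measurement to a sample heat capacity,
all without any external data.

## The model in brief

A uniform absorbed flux `q_s` heats the beam, which (its Biot number
`Bi = hD/k ≪ 1`) behaves as a lumped thermal mass:

```
tc dT/dt + T − T_amb = q_s/h_eff,     tc = ρC_p L_c / h_eff,
```

so the tip deflection — a linear map of the temperature rise through the
bimorph curvature `κ = 6Δα(t₁+t₂)/(t₂²K)·ΔT` — follows

```
v(t) = v∞ − (v∞ − v₀) e^{−t/τ}.
```

Fitting `τ` for the bare beam (calibration, `τ_B`) and for the loaded beam
(`τ_T`) and eliminating `h` through the volume-mixture rule gives the
sample's time constant and volumetric heat capacity:

```
τ_S = (L_c,S/L_c,B) [ τ_T + (V_B/V_S)(τ_T − τ_B) ],
(ρC_p)_S = τ_S h_eff / L_c,S.
```

The package provides: domain types for beam/layers/sample/environment with
a config system and bundled profiles; exact lumped integration plus a 1-D
distributed (Crank–Nicolson fin) model that certifies spatial uniformity;
bimorph mechanics with an independent Timoshenko-strip oracle;
statsmodels-style `ExponentialDecayModel` → results with covariance;
`HeatCapacityModel` with first-order error propagation and conditioning
diagnostics; a seeded synthetic-trace generator and replicated recovery
experiments; and the `bmc` CLI. See `docs/methods.md` for assumptions,
conventions, and the documented discrepancies of the reference scenario.

## Worked example

```python
from bmcal import (reference_profile, SyntheticSpec, generate_trace,
                   fit_exponential, HeatCapacityModel)

model = reference_profile()                      # bundled scenario
calib = generate_trace(SyntheticSpec(model=model.without_sample()))
loaded = generate_trace(SyntheticSpec(model=model, noise_sigma=0.01, seed=3))

fit_b = fit_exponential(calib)
fit_t = fit_exponential(loaded)
print(fit_b.summary())
est = HeatCapacityModel(fit_b, fit_t, model).fit(density=1100.0)
print(est.summary())
```

prints

```
Exponential approach fit: v(t) = v_inf - (v_inf - v0) exp(-t/tau)
  n obs             : 500
  v_inf             :      27.7510 um  (se 1.13e-14)
  v0                :       0.0000 um  (se 3.37e-14)
  tau               :      84.6250 ms  (se 1.92e-13)
  RSS               : 1.105340e-35 m^2
  R-squared         : 1.000000000
  converged         : True
Sample heat-capacity estimate (lumped-capacitance inversion)
  tau_B (calibration) :     84.625 ms
  tau_T (loaded)      :     83.926 ms
  tau_S (sample)      :     66.179 ms  (se 14)
  V_B / V_S           :     34.000
  Lc_S / Lc_B         :      1.100
  (rho Cp)_S          :     2.4065 MJ/(m^3 K)  (se 0.5)
  cp_S  (rho = 1100 kg/m^3)    :     2.1877 kJ/(kg K)
  valid               : True
  ! ill-conditioned subtraction: |1.175e+08 - 1.151e+08| cancels by a factor 48.8; the estimate amplifies fit noise
```

Reading it: the noiseless calibration recovers the forward model's 84.6 ms
time constant exactly (27.75 µm steady tip at a 12.5 K rise). The loaded
run, with 1 % noise, yields a recovered volumetric heat capacity of 2.41
MJ/(m³K) against a ground truth of 2.387 (yeast-like sample: 1100 kg/m³ ×
2170 J/kgK) — about 1 % off, while the propagated 1σ of 0.5 MJ/(m³K)
shows how strongly the V_B/V_S = 34 subtraction amplifies trace noise,
which is exactly what the attached conditioning warning says.

The same pipeline from the shell:

```
bmc simulate --no-sample --out calib.csv
bmc simulate --noise-sigma 0.01 --seed 3 --out loaded.csv
bmc fit --in calib.csv --out calib.json
bmc fit --in loaded.csv --out loaded.json
bmc invert --calib calib.json --loaded loaded.json --out estimate.json
bmc demo        # reference-scenario comparison table, discrepancies flagged
```

`bmc demo` evaluates the inversion chain at the scenario's reported fitted
time constants and shows that the reported 230 ms sample time constant and
2.165 kJ/(kg·K) specific heat do **not** follow from the stated inputs
(the chain gives 180.95 ms, and the specific heat needs an unstated
density); the package documents this instead of tuning constants.

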