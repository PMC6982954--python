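# Methods

## The measurement principle

A bimaterial microcantilever (BMC) — a thin Si₃N₄ beam with an aluminium
underside — bends when heated because the two layers expand at different
rates. Under a uniform absorbed optical flux the beam warms toward a steady
temperature with a first-order (exponential) transient, and because the tip
displacement is a linear map of the temperature rise, the *deflection*
trace is exponential with the same time constant. That time constant is set
by how much heat the system stores per unit temperature versus how fast it
loses heat by convection:

    τ = ρC_p · L_c / h,        L_c = V / A.

A sample resting on the beam adds heat storage without (appreciably) adding
loss area, so the loaded system responds more slowly. Comparing the fitted
time constant of a calibration run (bare beam, τ_B) with a loaded run
(beam + sample, τ_T) therefore yields the sample's volumetric heat
capacity — a calorimeter whose only observable is a bending beam.

## Forward thermal model

**Lumped capacitance.** The beam is treated as a single thermal mass at
temperature `T_s(t)`:

    tc · dT_s/dt + T_s − T_amb = q_s / h_eff,      tc = C'' / h_eff,

where `C''` is the heat capacity per unit footprint area (for the bare
two-layer beam, `Σ ρᵢC_pᵢtᵢ = 3.385 J/m²K` with the default material
table) and `h_eff` the effective loss coefficient. With constant flux the
solution is `T_s = T_amb + q_s/h_eff + (T_s(0) − T_amb − q_s/h_eff)
e^{−t/tc}`. The integrator uses the exact exponential propagator on each
interval (piecewise-constant flux), so it has no truncation error; this is
verified against the closed form to ~1e-14 of the rise.

The lumped treatment is justified by the Biot number `Bi = hD/k`: for the
cell-sized sample (`h = 20 W/m²K`, `D = 5 µm`, `k = 0.03 W/mK`)
`Bi ≈ 0.003`, far below the classical 0.1 threshold (configurable).

**Distributed check.** A 1-D fin-type model,

    c(x) ∂T/∂t = (Σ kᵢtᵢ) ∂²T/∂x² + q_s(t) − h_eff (T − T_amb),

solved by Crank–Nicolson on a banded system (default 200 nodes, internal
step capped at tc/50), verifies the spatial-uniformity assumption: with the
default adiabatic anchor the reference profile's steady spatial spread is
below 1e-4 of the rise, and the full field collapses onto the lumped
solution. A fixed-ambient anchor is available; it produces the expected
persistent fin gradient and is used to exercise non-uniform regimes. In
the distributed model the sample adds areal heat capacity locally over its
footprint, which is how the position-independence of the response is
demonstrated.

## Mechanics

Curvature of the heated bimorph (subscripts 1 = top, 2 = bottom,
`m = t₁/t₂`, `n = E₁/E₂`):

    κ = 6 Δα (t₁+t₂) / (t₂² K) · ΔT,
    K = 4 + 6m + 4m² + n m³ + 1/(n m).

This is algebraically identical to Timoshenko's classical two-metal-strip
curvature, which is implemented independently and used as an oracle (the
two agree to <1e-10 relative over randomized parameter draws — an
equivalence test, not a shared code path). Deflection follows from
integrating `z'' = κ(x)` twice (trapezoidal, clamped anchor); for a
spatially uniform rise the tip is exactly `κL²/2`.

Sign convention: deflections are positive toward the top (Si₃N₄) layer, so
heating the Al-under-Si₃N₄ beam gives positive tips. Only linear
(small-deflection) kinematics are implemented; tip deflections comparable
to the published ~178 µm on a 600 µm beam are geometrically nonlinear in
reality, which is one reason only order-of-magnitude agreement is claimed
for that number (see "Known discrepancies").

## Fitting

Deflection traces are fit by unweighted nonlinear least squares to

    v(t) = v∞ − (v∞ − v₀) e^{−t/τ},

in exactly that parameterisation, using Levenberg–Marquardt with an
analytic Jacobian (`xtol = ftol = 1e-14`), moment-based starting values
(last-decile mean for v∞, first point for v₀, interpolated e-folding time
for τ), no burn-in trimming, and covariance from the Jacobian at the
optimum. Noiseless synthetic traces are recovered to ~1e-9 relative; at 1 %
noise (fraction of the trace excursion, 500 points over 500 ms) the τ
standard error is ~0.4 %.

## Inversion

With `h` identical in both runs and the loaded system described by the
volume-weighted mixture `(ρC_p)_T = [(ρC_p)_B V_B + (ρC_p)_S V_S]/(V_B+V_S)`
referenced to the beam's characteristic length, eliminating `h` gives

    τ_S = (L_c,S / L_c,B) · [ τ_T + (V_B/V_S)(τ_T − τ_B) ],
    (ρC_p)_S = τ_S · h_eff / L_c,S.

Two routes are implemented — the time-constant chain above and the explicit
mixture inversion in heat-capacity units — and tested to be the same
algebra. Standard errors propagate first-order from the two independent fit
covariances: `Var(τ_S) = (L_c,S/L_c,B)²[(1+R)² Var(τ_T) + R² Var(τ_B)]`
with `R = V_B/V_S`.

**Modelling convention that matters.** The loaded *forward* model defines
`τ_T = (ρC_p)_T,mix · L_c,B / h_eff` — the same convention the inversion
assumes — which makes the simulate → fit → invert round trip exact (the
noiseless recovery error is at the fit tolerance, ~1e-11). The physically
additive alternative, `τ_T = (C_beam + C_sample)/(h_eff A)`, is *not*
compatible with the chain above: substituting it leaves an additive bias of
order τ_T itself, i.e. the chain would return roughly
`(ρC_p)_B + (ρC_p)_S`. Users replacing the forward model with measured data
should be aware the inversion presumes the mixture convention.

A corollary: whether loading *slows* the response under this convention
depends on the sign of `(ρC_p)_S − (ρC_p)_B,eff`, where `(ρC_p)_B,eff =
C''/L_c,B`. In the reference profile L_c,B is pinned to 1.0 µm (the printed
value) while the stack is 1.5 µm thick, making `(ρC_p)_B,eff = 3.385
MJ/m³K`, *above* the yeast-like sample's 2.387 MJ/m³K — so there τ_T is
slightly below τ_B. In the box-derived profile (`L_c,B = V/A = 1.5 µm`,
`(ρC_p)_B,eff = 2.257 MJ/m³K`) the loaded system is slower, as physical
intuition expects; the ordering test runs there. The inversion itself is
exact either way.

**Ill-conditioning.** `(ρC_p)_S` comes from the difference of two nearly
equal large numbers; the error amplification is ≈ `(1+R)` at fixed fit
noise. At the reference `R = 34` and 1 % trace noise the per-replicate
scatter of the recovered heat capacity is ~27 % (1σ), with 1σ-interval
coverage ≈ 0.7 as expected; the estimator is unbiased, so the median over
100 replicates lands within a few percent of truth. A conditioning warning
is attached to every estimate whose subtraction cancels by more than 10×.

## Synthetic data

The generator replays the package's own forward model (lumped by default,
distributed optionally) on a uniform grid — by default 500 points over
500 ms, matching the reference traces — and adds i.i.d. Gaussian noise
whose σ is a stated fraction of the trace excursion. All randomness flows
from one integer seed (`numpy.random.default_rng`); replicate seeds are
spawned via `SeedSequence`. Same seed + config ⇒ bit-identical trace.

What it deliberately does **not** emulate: FEM-resolved 2-D/3-D conduction,
the laser spot profile (the absorbed flux is uniform by assumption),
wavelength-dependent absorption, geometric nonlinearity of large
deflections, drift/1-f noise or quantisation of a real optical-lever
readout, and conduction resistance between sample and beam (the sample is
isothermal with the beam and enters only through heat capacity). Passing
recovery tests therefore demonstrate the *consistency and conditioning* of
the estimation chain, not robustness to real-instrument artefacts.

## Defaults and tunable parameters

| Parameter | Default | Why |
|---|---|---|
| Beam planform | 600 × 76 µm | reference hardware |
| Layers | Si₃N₄ 1.0 µm over Al 0.5 µm | reference hardware |
| Material table | handbook values (Si₃N₄ ρ=3100, C_p=700, k=20, α=2.3e-6, E=250 GPa; Al ρ=2700, C_p=900, k=237, α=23.1e-6, E=70 GPa; yeast ρ=1100, C_p=2170, k=0.03) | constants are not part of the published scenario; every entry overridable in config |
| Absorbed flux | 500 W/m² | stated scenario value |
| h | 20 W/m²K | free-convection scale, stated |
| Convection sides | both (h_eff = 2h) | the scenario describes losses from all surfaces; `one` available |
| Radiation | off | negligible at ~10 K rise; linearised `4εσT³` optional |
| T_ambient | 293.15 K | room temperature |
| L_c,B / L_c,S (reference profile) | 1.0 µm / 1.1 µm | pinned printed values (see discrepancies) |
| V_B/V_S (reference profile) | 34 (override) | pinned printed value, not derivable from the box dimensions |
| Volume convention (generic) | 3d_boxes | self-consistent; `2d_extruded` and `override` available |
| Distributed anchor BC | adiabatic | matches the lumped treatment (no base loss); `fixed` optional |
| n_nodes / internal Δt | 200 / ≤ tc/50 | spread and lumped-limit errors ≪ the 1e-4 / 1e-6 verification bands |
| Biot validity threshold | 0.1 | classical lumped criterion |
| Fit tolerances | xtol=ftol=1e-14, LM | parameters at machine precision on clean data |
| Synthetic sampling | 500 pts, 0.5 s | matches the reference traces |
| Monte-Carlo sizes | 100 replicates (30 per point for ratio sweeps) | stabilises medians/RMSE while keeping the suite fast |

## Known discrepancies and limitations

These are properties of the published scenario that the package documents
rather than reproduces (run `bmc demo` for the table):

* **τ_S = 230 ms.** The chain evaluated at the printed inputs (τ_B = 66.5
  ms, τ_T = 69.3 ms, R = 34, L_c ratio 1.1) gives **180.95 ms**. The
  printed 230 ms does not follow from those inputs under the stated
  formula; no constant is tuned to force it.
* **c_p = 2.165 kJ/(kg·K).** Converting any τ_S to a *specific* heat needs
  a sample density that was never stated (230 ms with h = 20 and L_c = 1.1
  µm corresponds to ρC_p ≈ 4.18 MJ/m³K, implying ~1932 kg/m³ — implausibly
  dense for a cell). The package therefore reports volumetric heat capacity
  unless a density is supplied explicitly.
* **V_B/V_S = 34 and L_c,S = 1.1 µm** are not derivable from the printed
  box dimensions (3-D boxes give ≈ 912–1368 depending on the thickness
  convention, 2-D extrusion gives 60; Vol/Area of a 5×2×5 µm box is 2.0
  µm). Both are shipped as pinned overrides of the reference profile.
* **178 µm tip deflection.** With handbook constants the steady tip is
  27.7 µm (both-side convection) or 55.4 µm (single-side): order-of-
  magnitude agreement only, as the published layer constants are unknown
  and such deflections exceed the linear-kinematics regime anyway.
* The fitted 66.5/69.3 ms time constants are likewise not reproduced as
  outputs of the physics (the forward default gives 84.6 ms); they are
  treated as inputs wherever they matter.

Other limitations: two layers only, rectangular planform, temperature-
independent properties, no resonant/dynamic behaviour, no thermal
conductivity/diffusivity estimation.
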