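# Methods

## Scope and model

The package estimates condition-level physiology of a hydrogenotrophic
methanogen grown (i) in a sparged chemostat at two aqueous H₂ levels, (ii) in
sealed serum bottles under an H₂:CO₂ headspace, and (iii) in sealed-bottle
coculture with a fermentative heterotroph that supplies all H₂ (interspecies
H₂ transfer, 4 H₂ + CO₂ → CH₄). Alongside the kinetics it computes
carbon-isotope fractionation factors between CO₂ and CH₄, including the
closed-reservoir (Rayleigh) correction needed when a bottle draws its CO₂
down substantially. No mechanistic (Monod/ODE) growth model is fitted
anywhere: every estimator is a regression or an algebraic balance, which is
exactly what the measured quantities support.

## Kinetics estimators

* **Growth rate.** k is the OLS slope of ln(count) on time
  (`scipy.stats.linregress`), with an explicit index window for the
  exponential phase (default: all points). Non-positive counts are rejected,
  never dropped, because silently censoring zeros biases the slope. k is
  invariant to rescaling counts by a positive constant, so per-ml and
  per-bottle counts fit identically.
* **Chemostat.** rate = [CH₄]_gas·F_gas + [CH₄]_medium·D·V (mol/h);
  q = rate / (X·10³·V); Y = D·X·10³·V / rate. Dividing the per-ml rate by
  per-ml cells equals dividing the vessel rate by total cells, so there is
  only one defensible normalization and the package implements exactly that.
  Y·q = D is an algebraic identity and is tested as such.
* **Batch.** Y is the slope of cells against product amount with a free
  intercept (bottles start with a nonzero inoculum); a through-origin mode
  exists behind a flag. q = k/(ln 2·Y), with ln 2 at full precision (0.693
  is a printed rounding). Replicates are always estimated individually and
  then aggregated as mean ± SE; the mean of per-replicate q differs from the
  formula applied to mean k and mean Y, and the per-replicate order of
  operations is the one that matches how replicate means are reported in
  practice.

## Gas chemistry

Ideal-gas behaviour throughout (≤ 2.4 atm, ≥ 295 K): isochoric heating
P₂ = P₁·T₂/T₁, amounts n = PV/RT with R = 0.082057 l·atm·mol⁻¹·K⁻¹. Room
temperature for bottle fills is fixed at 22 °C (295.15 K); any choice in
20–25 °C reproduces the same 1.2 atm at 82 °C to one decimal. Aqueous
concentrations use Henry's law with a van 't Hoff correction,
c = p·k_H·exp(B(1/T − 1/T_ref)); shipped constants (freshwater, 298.15 K
reference) are k_H = 7.8×10⁻⁴ mol·l⁻¹·atm⁻¹, B = 500 K for H₂;
1.4×10⁻³, 1700 K for CH₄; 3.4×10⁻², 2400 K for CO₂. Salinity (Setschenow)
corrections and activity coefficients are omitted — this is why aqueous
estimates are quoted to ~10 % only, versus full speciation software.
Sparged-reactor composition is the flow-fraction mixture at 1 atm (open
vessel at ambient pressure).

## Isotope machinery

δ ↔ ratio conversions use R_VPDB = 0.0112372 and are exact inverses.
α = (δ_CO2 + 10³)/(δ_CH4 + 10³), ε = (α − 1)·10³; δ values are carried at
full precision and rounded to 0.1 ‰ only at reporting.

**DIC → CO₂(aq).** The equilibrium fractionation between CO₂(aq) and HCO₃⁻
is ε(T) = −9866/T + 24.12 ‰ (T in kelvin), ≈ −3.7 ‰ at 82 °C. These
coefficients were chosen because they reproduce, to 0.05 ‰, the published
pairing of measured bottle DIC values (+22.6, +19.2 ‰) with their CO₂(aq)
counterparts (+18.9, +15.5 ‰) at 82 °C; the coefficient set is configurable
(`MookParams`). Without a pH the DIC pool is treated as pure bicarbonate
(valid near pH 6 where the cultures sit); with a pH, DIC is partitioned
between CO₂(aq) and HCO₃⁻ via pK₁ (default 6.35) and isotope mass balance
over the two species is solved before returning the CO₂(aq) delta.
Carbonate is neglected (< 1 % below pH 8).

**Rayleigh forward.** The reservoir is consumed in n log-spaced increments
of f (default n = 10⁵). Fractionation is applied in ratio space — the
instantaneous product carries (δ_res + 10³)/α — never as an additive ‰
offset, which drifts visibly at ε > 50 ‰. The residual is updated by exact
mass balance at every increment, so f·δ_res + (1−f)·δ_prod = δ₀ holds to
float precision at every step; the scheme is first-order in 1/n and agrees
with the retained closed-form solution
δ_res = (δ₀ + 10³)·f^(1/α − 1) − 10³ to ≲ 10⁻³ ‰ at the default step count.
The step recursion collapses to a cumulative product, so the simulator is
vectorised and costs milliseconds.

**Rayleigh inversion.** Given (δ₀, final residual, final accumulated
product), f follows exactly from the linear mass balance
f = (δ₀ − δ_prod)/(δ_res − δ_prod); ε is then the root of the 1-D residual
equation, bracketed on (0, 200] ‰ and solved with Brent's method on the
closed form. Decoupling the two unknowns this way makes the solve robust
(monotone in ε) and avoids a fragile 2-D fit. The degenerate no-drawdown
input returns (ε = 0, f = 1). For the drawdown bottle with δ₀ = −26.1 ‰,
residual +18.9 ‰ and product −32.9 ‰ the inversion gives ε = 22.8 ‰ with
f = 0.131 — within the 1.3 ‰ uncertainty of the reference estimate for that
experiment; the residual-series choice (CO₂(aq), not raw DIC) matters, and
both are exposed as inputs.

**Uncertainty.** σ_ε is first-order quadrature with ∂ε/∂δ_CO2 =
10³/(δ_CH4 + 10³) and ∂ε/∂δ_CH4 = −10³·α/(δ_CH4 + 10³); 0.3 ‰ on both
deltas gives 0.46 ‰ at chemostat compositions. Monte-Carlo propagation
through the full inversion (500 draws) gives SD ≈ 0.45 ‰ for the drawdown
bottle, consistent with the quadrature scale.

## Synthetic-data generator

The generator produces the inputs the estimators consume, with the noise
structure the analysis assumes — and nothing more.

* **Count noise** is multiplicative lognormal with mean 1 (counts are
  positive; microscopy error scales with the count), CV 0.05 by default. No
  measured counting error was available, so 0.05 is a stand-in typical of
  counting-chamber work, exposed as a parameter. Mean-one lognormal noise
  leaves the log-linear slope exactly unbiased.
* **Isotope noise** is additive Gaussian, SD 0.3 ‰ (replicate-injection
  scatter of IRMS measurements).
* **Chemostat runs** are constructed so the emitted concentrations are an
  exact inverse of the rate estimator at zero noise; a small fixed fraction
  (0.2 %) of the CH₄ leaves dissolved, matching the Henry's-law magnitude at
  82 °C.
* **Coculture** is a quasi-steady mass balance: the heterotroph grows
  exponentially; H₂ and acetate accrue in proportion to its cell increase;
  the methanogen instantly consumes all H₂ at 4:1 and accrues cells at
  Y_CH4 per mol, so the free H₂ pool is identically zero and CH₄ equals a
  quarter of the transferred H₂ at every time point. There are no dissolved
  H₂ pool dynamics and no H₂-inhibition feedback — the data give no basis to
  parameterise them. Per-cell rate parameters use the same per-doubling
  convention as q = k/(ln 2·Y), so generator → estimator round trips are
  exact identities rather than off by ln 2.
* **Determinism.** Every generator call draws from one `numpy` generator
  seeded from its `SimConfig`; identical configs give bit-identical output,
  and seeds plus parameters are recorded in metadata (sidecar files on
  disk).

Default study conditions (dilution rates 0.6 and 0.21 h⁻¹ from three volume
turnovers in ~5 h and ~14 h of a 1.5-l vessel; q = 496 and 139
fmol·cell⁻¹·h⁻¹; coculture k = 0.16 h⁻¹, Y_CH4 = 9.1×10¹² and 13.5×10¹²
cells/mol) mirror the experimental setting the package analyses. What
passing tests show is that the estimators recover these parameters under
the assumed noise; they do not show robustness to features real data may
have (growth-phase transitions, H₂ inhibition transients, correlated GC
drift).

## Reporting pipeline

Plain TSV in and out with a fixed header vocabulary; INI configs
(key = value with sections) for full runs, flags for single-shot
calculations. Run logs record the package version, config hash and seeds,
and contain no timestamps, so reruns are byte-identical. Condition
summaries report ε via the direct α/ε definition for open-reservoir
conditions (sparged chemostat, CO₂-replete coculture) and via Rayleigh
inversion for drawdown bottles, selected per condition in the config.

## Problem sizes and numerical choices

Time-series fixtures use 8–9 points over 4–12 h; Monte-Carlo checks use
200–500 seeds; Rayleigh convergence is demonstrated at n_steps ∈ {10, 10³,
10⁵}. Root-finding tolerances: brentq xtol 10⁻⁹ on ε; mass-balance
conservation asserted to 10⁻⁶ ‰. Ties and degenerate inputs: constant count
series fit k = 0 with r² reported as 0; all-zero product columns are
rejected rather than fit; f = 1 reports the cumulative product as NaN.

## Known limitations

No Monod/K_s kinetics, no Gibbs-energy or pathway-reversibility modelling,
no full carbonate speciation, no hydrogen-isotope or clumped-isotope
systematics. The aqueous-solubility module is a deliberate simplification
(~10 %); the coculture generator cannot emulate H₂-inhibition dynamics; and
figure-level replicate means from unpublished raw series are not
reproducible desk-side — the round-trip suite covers those estimators
instead.
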