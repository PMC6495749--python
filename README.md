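# methanofrac

Quantitative analysis of hyperthermophilic methanogen growth under H₂
limitation and interspecies H₂ transfer: growth and CH₄-production kinetics
(chemostat and sealed-bottle), headspace gas chemistry, and carbon-isotope
fractionation including a closed-system Rayleigh drawdown inversion. It is
aimed at microbial physiologists and isotope geochemists who need the
condition-level numbers — specific growth rate *k*, cell-specific rate *q*,
cell yield *Y*, and ε_CO2−CH4 — from raw time series and headspace
measurements, plus a synthetic-data generator that emulates those
measurements for testing and power analysis.

## The quantities

**Kinetics.** The specific growth rate *k* (h⁻¹) is the OLS slope of
ln(cells) against time. In a chemostat at steady state the CH₄ production
rate is the headspace concentration times the gas flow plus the dissolved
concentration times the medium outflow *D·V*; dividing by total cells gives
the cell-specific rate *q* (fmol·cell⁻¹·h⁻¹), and the cell yield is
*Y = D·X·V / rate* (cells per mol CH₄), so *Y·q = D* identically. In sealed
bottles *Y* is the slope of cells against product amount and
*q = k/(ln 2 · Y)*. The same formula applies to the heterotroph's acetate,
formate and H₂ yields. Coculture bottles couple a fermentative H₂ producer
(*Thermococcus paralvinellae*) to a hydrogenotrophic methanogen
(*Methanocaldococcus jannaschii*) via 4 H₂ + CO₂ → CH₄.

**Isotopes.** δ¹³C is the per-mille deviation of ¹³C/¹²C from VPDB
(R = 0.0112372). The fractionation factor between substrate and product is

    α_CO2−CH4 = (δ¹³C_CO2 + 10³)/(δ¹³C_CH4 + 10³),   ε = (α − 1)·10³ ‰

Measured DIC is converted to CO₂(aq) with the temperature-dependent
CO₂(aq)–HCO₃⁻ equilibrium fractionation (−9866/T + 24.12 ‰, about −3.7 ‰ at
82 °C). When a sealed bottle draws its CO₂ reservoir down substantially, the
final deltas no longer give the intrinsic ε directly; the package inverts
the Rayleigh model instead — the fraction remaining *f* follows exactly from
isotope mass balance, and ε is root-found so that the Rayleigh residual
curve passes through the observed final CO₂. A stepwise forward simulator
(ratio-space fractionation, mass balance at every increment) is kept
alongside the closed-form solution and converges to it.

**Gas chemistry.** Sealed-bottle pressures scale isochorically (P·T₂/T₁),
headspace amounts follow PV = nRT, aqueous concentrations follow Henry's law
with a van 't Hoff temperature correction, and sparged-reactor partial
pressures follow the blended flow fractions at 1 atm.

## Worked example

```
$ methanofrac simulate --seed 1 --out-dir demo
$ methanofrac run-condition --config demo/analysis.ini
high_H2 (n=3): k=0.60/h q=482.1 fmol/cell/h Y=1.25e+12 cells/mol
low_H2 (n=3): k=0.21/h q=132.7 fmol/cell/h Y=1.59e+12 cells/mol
maltose (n=3): k=0.15/h q=25.3 fmol/cell/h Y=8.78e+12 cells/mol
formate (n=4): k=0.16/h q=18.1 fmol/cell/h Y=1.31e+13 cells/mol
```

`simulate` writes a full synthetic study (two chemostat H₂ levels with three
replicates each, two coculture substrates, plus a metadata sidecar per table
recording seed and parameters); `run-condition` re-estimates the
condition-level kinetics from those tables. With 5 % count noise the
estimates scatter around the generating parameters (q = 496 and
139 fmol·cell⁻¹·h⁻¹ for the chemostats, Y = 9.1×10¹² and 13.5×10¹²
cells/mol for the cocultures); at zero noise the recovery is exact.

Single-shot calculations:

```
$ methanofrac isotope --dco2 -29.0 --dch4 -55.9 --sigma-co2 0.3 --sigma-ch4 0.3
alpha = 1.028493, epsilon = 28.5 permil +/- 0.5 permil
$ methanofrac rayleigh-invert --delta0 -26.1 --residual 18.9 --product -32.9
epsilon = 22.8 permil, f_remaining = 0.1313
```

The first computes the fractionation factor for a high-H₂ chemostat run
(apparent ε = 28.5 ‰, with the 0.3 ‰ injection SD propagated to ±0.5 ‰); the
second inverts the closed-system drawdown of a monoculture serum bottle —
only 13 % of the initial CO₂ remained, and the intrinsic fractionation that
reproduces both final deltas is 22.8 ‰, well below the coculture values,
consistent with fractionation increasing as H₂ becomes limiting.

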