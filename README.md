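# endophys

Flow-through respirometry processing and comparative thermal/hygric
physiology for endotherms.

Standard physiological phenotyping of a mammal or bird — basal metabolic
rate, body temperature, evaporative water loss, thermal conductance,
water economy — starts from multichannel chamber traces: dry excurrent
O₂ and CO₂ fractions, excurrent relative humidity, probe temperature and
mass-flow rate, recorded every 10–30 s with animal-free baseline
segments before and after each trial. `endophys` implements the full
chain from those traces to population-level inference, plus a
physiologically structured synthetic-trace generator so the whole
pipeline is testable against known ground truth.

## What it computes

**Gas exchange.** With dry incurrent air of known composition and
analyzers downstream of a desiccant, the dry-nitrogen mass balance is
exact:

    V̇E,dry = V̇I · (1 − FiO₂ − FiCO₂) / (1 − FeO₂ − FeCO₂)
    V̇O₂    = V̇I·FiO₂ − V̇E,dry·FeO₂
    V̇CO₂   = V̇E,dry·FeCO₂ − V̇I·FiCO₂

Water loss comes from psychrometry: Pw = RH·Psat(T)/100 (Magnus form),
vapour flow V̇E,dry·Pw/(BP − Pw), mass via 18.016 mg mmol⁻¹ /
22.414 ml mmol⁻¹. Analyzer drift is removed with a linear baseline
through the pre/post baseline means, and resting values are taken over
the steady-and-minimal window (≥ 20 min, bounded VO₂ CV and slope,
minimal mean).

**Derived variables.** RER = V̇CO₂/V̇O₂; metabolic heat and water
production via RER-interpolated oxycalorific and hygric coefficients;
evaporative heat loss at 2.4 J mg⁻¹ H₂O; wet and dry thermal
conductance C_wet = MHP/(Tb − Ta), C_dry = (MHP − EHL)/(Tb − Ta)
(mass-specific, J g⁻¹ h⁻¹ °C⁻¹); relative water economy RWE = MWP/EWL
and its crossing point PRWE (the Ta where RWE = 1); mass-independent
values X/mᵇ with marsupial-style exponents (metabolic rate 0.74,
EWL 0.68, C_wet 0.57).

**Comparison.** Per-population quadratic thermal-response curves are
fitted as linear mixed models (centred/scaled Ta polynomial, random
intercept per individual, REML), with large-sample Wald tests for
location and Ta×location effects, a 50:50 χ²₀:χ²₁ boundary-mixture
likelihood-ratio test for the random intercept, and one-way ANOVA with
Student–Newman–Keuls letter grouping for standard values at
thermoneutrality.

**Synthesis.** The generator couples a Scholander–Irving model (heat
production on the conductance line below the thermoneutral zone, BMR
within it, linear metabolic/thermal rise and exponential EWL rise above
it) to a first-order chamber washout (τ = volume/flow), analyzer noise
and drift, emitting canonical trace CSVs plus a truth table.

## Worked example

```python
import numpy as np
import endophys as ep
from endophys.synthetic_data import (
    PRESETS, ChamberConfig, draw_individuals, steady_physiology, simulate_trace,
)

# hand-checkable mass balance: 3 L/min of room air, depleted excurrent
vo2, vco2, ve = ep.compute_gas_exchange(fe_o2=0.2050, fe_co2=0.0040,
                                        fi_o2=0.2095, fi_co2=0.0004,
                                        flow_in_stpd=3000.0)
print(f"VO2 = {vo2:.1f} ml/h, VCO2 = {vco2:.1f} ml/h, RER = {vco2/vo2:.3f}")
ewl = ep.compute_ewl(rh_pct=25.0, t_probe_C=25.0, ve_dry_stpd=ve)
print(f"EWL = {ewl:.0f} mg/h")

# one synthetic trial at thermoneutrality, processed end to end
scenario = PRESETS["arid"]
indiv = draw_individuals(scenario, np.random.default_rng(1))[0]
truth = steady_physiology(scenario, indiv, ta=26.0)
trace = simulate_trace(truth, ChamberConfig(), seed=0, ta=26.0, mass_g=indiv.mass_g)
series = ep.correct_series(trace, ep.fit_baseline(trace))
window = ep.find_steady_window(series)
record = ep.assemble_record(window, trace.meta)
print(f"truth VO2 = {truth.vo2_ml_h:.1f} ml/h, recovered = {record.vo2_ml_h:.1f} ml/h")
print(f"RER = {record.rer:.3f}, RWE = {record.rwe:.3f}, "
      f"C_wet = {record.cwet_J_g_h_C:.3f} J/g/h/degC")
```

prints

```
VO2 = 852.0 ml/h, VCO2 = 647.2 ml/h, RER = 0.760
EWL = 1136 mg/h
truth VO2 = 555.4 ml/h, recovered = 552.3 ml/h
RER = 0.855, RWE = 0.622, C_wet = 0.736 J/g/h/degC
```

The first block is the exact nitrogen-balance inversion (an RER of 0.76
indicates mostly lipid oxidation); the second shows the full pipeline —
baseline drift correction, chamber-equilibration trimming, steady-window
selection — recovering a known generative truth to about half a percent
under realistic analyzer noise. An RWE of 0.62 at 26 °C means metabolic
water covers 62% of evaporative loss at thermoneutrality; RWE rises as
Ta falls, reaching 1 at the PRWE.

The same workflow is available from the shell:

```sh
endophys simulate --out cohort/ --seed 1
endophys process cohort/trace_*.csv --out records.csv
endophys compare records.csv --out report/ --reference arid
```

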