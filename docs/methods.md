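# Methods

This note documents the models, numerical choices and limitations of
`endophys` — what the pipeline assumes, which knobs matter, and what the
synthetic-data tests do and do not demonstrate about real measurements.

## Measurement model and gas-exchange inversion

The pipeline assumes a push-mode flow-through system: dry incurrent air
of known composition (defaults FiO₂ = 0.2095, FiCO₂ = 0.0004,
configurable) enters the chamber at a mass-flow-regulated STPD rate; a
subsample of excurrent air passes an RH/temperature probe and is then
desiccated before the O₂/CO₂ analyzers. Two consequences:

* the analysed gas fractions are *dry*, so no water-vapour dilution
  correction is applied to them — the configuration where analyzers see
  moist air would need one, and is out of scope;
* all excurrent vapour is evaporative loss, because the incurrent
  stream is dry.

Under these assumptions the dry-nitrogen balance is closed-form and the
inversion in `compute_gas_exchange` is exact algebra (the test suite
verifies forward-simulate → invert to ≤ 1e-9 relative error). A
negative computed VO₂ is reported, not raised: it indicates a baseline
or calibration fault and is excluded from steady-window candidacy.

Saturation vapour pressure uses the Magnus form
Psat(T) = 0.61094·exp(17.625·T/(T + 243.04)) kPa. The constants are
configuration (`gas_exchange.MAGNUS`, pinned by tests); swapping in
another psychrometric correlation changes EWL by well under 1% over
0–40 °C. Vapour mass uses 18.016 mg mmol⁻¹ and 22.414 ml mmol⁻¹ STPD.
Barometric pressure defaults to 101.325 kPa with a warning when a trial
does not record one.

## Baselines and drift

Analyzer drift is modelled per channel as the line through the two
baseline means, anchored at the baseline midpoint times; the
drift-corrected baseline value at each animal-phase timestamp serves as
the incurrent reference. Two anchors support only a linear shape —
there is no information in a pre/post design for anything higher-order.
Baselines shorter than 20 min (configurable) are an error. The RH
channel's baseline (probe offset on desiccated air) is subtracted from
measured RH before the psychrometric inversion.

## Chamber equilibration and the steady window

Gas fractions relax toward equilibrium with time constant
τ = volume/flow (2.67 min at the default 8 L chamber and 3 L min⁻¹).
Because the pipeline uses the equilibrium method rather than an
instantaneous (Z-transform) washout correction, `correct_series`
discards the first 8 τ of the animal phase: the residual transient is
e⁻⁸ ≈ 0.03% of the step, negligible against analyzer noise. Without
this trim, windows containing the washout ramp can satisfy generous
CV/slope bounds while their means are biased low by >1% — the
minimal-mean selection rule actively rewards the ramp.

`find_steady_window` then searches every (start, length) candidate of
at least 20 min (configurable) inside the remaining animal phase.
A candidate is *steady* when its VO₂ coefficient of variation is
≤ 0.10 and its fitted linear slope is ≤ 5% of its own mean per hour;
among steady windows the minimal-mean one wins, ties resolved to the
earliest start then the longest window. If nothing qualifies the
minimal-CV window is returned flagged non-steady. CO₂, EWL and probe
temperature inherit the VO₂ window so each trial has one common
analysis period. The quantitative meaning of "steady" is this
package's policy; the CV and slope ceilings are deliberately loose
enough that realistic analyzer noise (per-sample VO₂ CV of a few
percent) does not disqualify honest windows. The O(n²) sweep is
evaluated with windowed cumulative sums (algebraically identical to
per-window statistics) and is checked against an exhaustive
brute-force oracle in the tests.

## Derived variables

Oxycalorific and hygric coefficients are linear interpolations between
configured knots — defaults 0.71 → 19.6 and 1.00 → 21.1 J ml⁻¹ O₂, and
0.71 → 0.53 and 1.00 → 0.67 mg H₂O ml⁻¹ O₂ — clamped to the knot domain
for lookups while the raw RER is preserved (and flagged when outside
[0.7, 1.0]). These are the conventional mixed-fuel values; they are
configuration, not claims, and tests pin the configured numbers.
Evaporative heat loss uses 2.4 J mg⁻¹ H₂O.

Conductance is computed mass-specifically — C_wet = (MHP/m)/(Tb − Ta) —
because its conventional units are J g⁻¹ h⁻¹ °C⁻¹. Below a 0.5 °C
body-to-air gradient the ratio is numerically meaningless and the
record is flagged `conductance_undefined` instead of raising; C_dry may
legitimately be negative above thermoneutrality (EHL > MHP) and is
reported as computed. Tb is the single post-trial cloacal measurement
paired with the whole window, mirroring standard protocol.

Mass-independent values divide by mᵇ with exponents 0.74 (metabolic
rate), 0.68 (EWL) and 0.57 (C_wet) by default. Published reports in
this field sometimes print metabolic units on a 0.75 exponent while
stating 0.74 in their methods; the registry here defaults to 0.74 and
all three exponents are configurable.

## Statistical models

Thermal responses are quadratic in Ta, fitted per population and
variable as linear mixed models with a per-individual random intercept
(statsmodels `MixedLM`, REML). Ta is centred and scaled to unit SD
before polynomial expansion — raw-scale quadratics in °C are badly
conditioned — and the coding is stored on the fit so predictions are
coding-independent (verified to 1e-8 under an affine recoding of Ta).

Inference is large-sample: Wald chi-square tests for the location main
effect and Ta×location interaction in the joint model, and normal-based
contrasts against a declared reference population. This differs from
small-sample Satterthwaite degrees of freedom; with cohorts of ~190
observations the difference is minor, and the null simulations in the
acceptance suite confirm near-uniform null p-values at this design
size. The random intercept is tested by a likelihood-ratio test on ML
fits against the 50:50 χ²₀:χ²₁ boundary mixture, since the variance
sits on the edge of its parameter space under the null; simulations
show the rejection rate at or below nominal. Optimisation falls back
from L-BFGS through gradient-free Powell/Nelder-Mead near the variance
boundary; a fit whose random variance collapses to numerical zero is
flagged `boundary`, not discarded.

PRWE is the root of the fitted RWE(Ta) = 1, located by bisection
(`brentq`) on sign changes over a dense grid spanning the measured Ta
range ± 5 °C; the root nearest the measured range wins, an analytic
quadratic root beyond the grid is reported with an extrapolation flag,
and a curve identically 1 is flagged degenerate.

Standard values at thermoneutrality (records within 26 ± 1 °C by
default) are compared by one-way ANOVA followed by Student–Newman–Keuls
stepwise grouping on the studentized range, with the harmonic mean of
group sizes under imbalance, and a compact letter display. The SNK
step-down rule (spans inside a non-significant span are not tested) is
implemented directly and checked against the defining property of the
letter display.

## Synthetic data

The generator's physiological truth is a Scholander–Irving endotherm:
below the TNZ, mass-specific heat production follows the conductance
line C_wet·(Tb − Ta); within the TNZ VO₂ = BMR; above it VO₂ and Tb
rise linearly and EWL rises exponentially. The conductance line is
closed through BMR at the lower critical temperature — C_wet is
*derived* per individual as BMR_g·oxycal(RER)/(Tb − tnz_lower) — so
VO₂(tnz_lower) equals BMR exactly rather than approximately.
Individual random effects scale BMR and EWL lognormally (8% and 12%
CV) and offset Tb (SD 0.2 °C).

The measurement chain applies the exact first-order washout solution
F(t) = Fss + (F₀ − Fss)·e^(−t/τ) (piecewise when an optional activity
bout shifts the target), Gaussian analyzer noise, and linear per-channel
drift. Baseline segments sample the incurrent supply through a bypass —
the standard protocol — so they carry noise and drift but no washout;
simulating a chamber-washout tail into the post-baseline would
contaminate the 20-min baseline mean with the exponential tail and is
not how the reference configuration operates. The RH probe reads ~1%
on desiccated air (its low calibration point), which keeps the
clipped-at-zero channel from biasing baseline means.

Default conditions mirror the reference design: 8000 ml chamber,
3 L min⁻¹, 15 s sampling, 20 min baselines, 8 h trials (6 h at
Ta ≥ 34 °C), four population presets (arid / mesic / montane /
tropical, 6 individuals each) spanning realistic contrasts for
1.8–2.4 kg marsupials, measured on a regular Ta grid of 6–34 °C. Noise
SDs (6e-5 O₂, 4e-5 CO₂, 0.4% RH per sample) give per-sample VO₂ CV of
roughly 2–6% and window-mean standard errors of a few tenths of a
percent; a white-noise channel cannot produce percent-level
window-mean SE without violating the 0.10 per-window CV ceiling, so
the defaults favour consistency with the window policy.

What passing recovery tests show: the inversion, baseline, window and
assembly logic are mutually consistent and unbiased to well under the
3% tolerance at these noise levels. What they do not show: robustness
to activity bouts beyond the simple injected rectangle, circadian or
torpor dynamics, chamber temperature gradients, nonlinear analyzer
drift, or RH sensor hysteresis — none of which the generator emulates.

## Numerical details and edge cases

* Windowed statistics use cumulative sums with the time axis shifted to
  its mean; ties in window selection use a 1e-9 relative band.
* Trace CSVs store floats via `repr` and are parsed with pandas'
  round-trip parser, so write → read is bit-exact; fractions are stored
  dimensionless with an opt-in percent declaration for foreign files.
* `compute_rer` requires VO₂ > 0; RWE requires EWL > 0; zero-width
  calibration spans, missing baselines and sub-minimum windows raise
  typed errors naming the offending row/phase.
* All simulation randomness flows from numpy `default_rng` seeds;
  equal seeds give byte-identical traces.

## Scale of the shipped checks

The acceptance script and slow tests run the study-scale versions: a
192-trace cohort once (about a minute), 200-seed record-level
simulations for PRWE and the null calibrations, 100 series for the
window oracle, and 10,000 draws for the mass-balance oracle. These
sizes were chosen as the smallest that make the binomial/KS margins
informative; the generators accept larger sizes unchanged.
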