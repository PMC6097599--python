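"""Physiologically structured synthetic chamber traces.

The generator couples a Scholander-Irving endotherm model to a forward
model of the measurement chain, so that every pipeline stage can be
exercised against known truth:

* **Physiology.** Below the thermoneutral zone (TNZ) mass-specific heat
  production follows the conductance line MHP = C_wet * (Tb - Ta);
  within the TNZ VO2 sits at BMR; above the TNZ VO2 and Tb rise
  linearly and EWL rises exponentially.  The conductance line is closed
  through BMR at the lower critical temperature, so VO2(tnz_lower) ==
  BMR exactly.  Per-individual random effects scale BMR and EWL
  (lognormal) and offset Tb (normal).
* **Chamber.** Excurrent fractions relax toward the steady state implied
  by inverting the dry-gas mass balance, with the exact first-order
  washout solution F(t) = Fss + (F0 - Fss) * exp(-t/tau), tau =
  volume/flow.  The RH channel follows the psychrometric forward model.
* **Instruments.** Gaussian analyser noise and linear drift per channel.
  Baseline segments sample the incurrent supply through a bypass (the
  standard protocol), so they carry drift and noise but no washout.

Everything is reproducible from a single integer seed.  Record-level
generators (quadratic thermal responses, a linear-RWE cohort) are also
provided for calibrating the statistical machinery without the expense
of trace simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .gas_exchange import (
    MAGNUS,
    MG_PER_MMOL_H2O,
    ML_PER_MMOL_GAS,
    saturation_vapor_pressure_kPa,
)
from .io_calibration import RawTrace, TrialMeta
from .thermal_physiology import (
    ConversionTable,
    DEFAULT_EXPONENTS,
    DEFAULT_TABLE,
    ScalingExponents,
    evaporative_heat,
    mass_independent,
    metabolic_heat,
    metabolic_water,
    relative_water_economy,
    thermal_conductance,
)

__all__ = [
    "EndothermScenario",
    "ChamberConfig",
    "IndividualDraw",
    "PhysioTruth",
    "RestlessSegment",
    "PRESETS",
    "draw_individuals",
    "steady_physiology",
    "simulate_trace",
    "generate_cohort",
    "quadratic_record_cohort",
    "linear_rwe_cohort",
]

DEFAULT_TA_GRID = (6.0, 10.0, 14.0, 18.0, 22.0, 26.0, 30.0, 34.0)


@dataclass(frozen=True)
class EndothermScenario:
    """Generative truth for one population.

    ``bmr_ml_gb_h`` and ``basal_ewl_mg_gb_h`` are mass-independent
    (allometric) coefficients on the configured exponents; whole-animal
    rates are recovered as coefficient * mass**exponent.  Wet thermal
    conductance below the TNZ is *derived* per individual from the
    Scholander closure C_wet = BMR_g * oxycal(RER) / (Tb - tnz_lower),
    which makes the conductance line pass exactly through BMR at the
    lower critical temperature.
    """

    population_id: str
    mass_mean_g: float = 2000.0
    mass_sd_g: float = 100.0
    tb_set_C: float = 35.0
    tb_slope_above_tnz: float = 0.15  # degC per degC of Ta above tnz_upper
    bmr_ml_gb_h: float = 2.0
    tnz_lower_C: float = 26.0
    tnz_upper_C: float = 32.0
    vo2_rise_frac_per_C: float = 0.04  # fractional BMR rise per degC above TNZ
    basal_ewl_mg_gb_h: float = 4.0
    ewl_rise_rate_per_C: float = 0.20  # exponential rate above tnz_upper
    rer_below: float = 0.80
    rer_within: float = 0.85
    rer_above: float = 0.85
    bmr_sd_frac: float = 0.08
    ewl_sd_frac: float = 0.12
    tb_sd_C: float = 0.20
    ta_grid: tuple[float, ...] = DEFAULT_TA_GRID
    n_individuals: int = 6
    mass_exponent: float = DEFAULT_EXPONENTS.metabolic_rate
    ewl_exponent: float = DEFAULT_EXPONENTS.ewl

    def __post_init__(self) -> None:
        if not self.tnz_lower_C < self.tnz_upper_C:
            raise ValueError("tnz_lower must be below tnz_upper")
        for name in ("bmr_ml_gb_h", "basal_ewl_mg_gb_h", "mass_mean_g"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tb_set_C <= self.tnz_upper_C:
            raise ValueError("tb_set must exceed tnz_upper")


@dataclass(frozen=True)
class ChamberConfig:
    """Measurement-chain configuration shared across a cohort."""

    volume_ml: float = 8000.0
    flow_ml_min: float = 3000.0
    fi_o2: float = 0.2095
    fi_co2: float = 0.0004
    bp_kPa: float = 101.325
    sample_interval_s: float = 15.0
    baseline_s: float = 1200.0
    animal_s: float = 28800.0  # 8 h trial; trials at Ta >= 34 are shortened
    hot_animal_s: float = 21600.0
    hot_ta_C: float = 34.0
    o2_noise_sd: float = 6e-5
    co2_noise_sd: float = 4e-5
    rh_noise_sd: float = 0.4
    #: probe reading on desiccated air (the 1% RH calibration point);
    #: keeps the clipped-at-zero RH channel from biasing baseline means
    rh_dry_offset_pct: float = 1.0
    t_noise_sd: float = 0.05
    tb_noise_sd: float = 0.1  # cloacal thermocouple measurement error, degC
    o2_drift_per_h: float = -2e-5
    co2_drift_per_h: float = 5e-6
    rh_drift_per_h: float = 0.10

    def __post_init__(self) -> None:
        if self.volume_ml <= 0 or self.flow_ml_min <= 0:
            raise ValueError("volume and flow must be positive")
        for name in ("o2_noise_sd", "co2_noise_sd", "rh_noise_sd", "t_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def tau_s(self) -> float:
        """First-order washout time constant, seconds."""
        return 60.0 * self.volume_ml / self.flow_ml_min


@dataclass(frozen=True)
class IndividualDraw:
    """One animal's realised random effects."""

    individual_id: str
    mass_g: float
    bmr_mult: float
    ewl_mult: float
    tb_offset_C: float


@dataclass(frozen=True)
class PhysioTruth:
    """Steady-state whole-animal truth for one trial."""

    vo2_ml_h: float
    vco2_ml_h: float
    ewl_mg_h: float
    tb_C: float
    rer: float


@dataclass(frozen=True)
class RestlessSegment:
    """Optional activity bout: VO2/VCO2/EWL scaled by ``factor`` over a
    time interval of the animal phase (seconds from animal-phase start).
    Exists to exercise the steady-window search."""

    start_s: float
    end_s: float
    factor: float = 1.5


def draw_individuals(
    scenario: EndothermScenario, rng: np.random.Generator
) -> list[IndividualDraw]:
    """Draw the cohort's per-individual random effects."""
    out = []
    for i in range(scenario.n_individuals):
        mass = float(rng.normal(scenario.mass_mean_g, scenario.mass_sd_g))
        mass = max(mass, 0.2 * scenario.mass_mean_g)
        out.append(
            IndividualDraw(
                individual_id=f"{scenario.population_id}-{i + 1:02d}",
                mass_g=mass,
                bmr_mult=float(np.exp(rng.normal(0.0, scenario.bmr_sd_frac))),
                ewl_mult=float(np.exp(rng.normal(0.0, scenario.ewl_sd_frac))),
                tb_offset_C=float(rng.normal(0.0, scenario.tb_sd_C)),
            )
        )
    return out


def individual_cwet(
    scenario: EndothermScenario,
    indiv: IndividualDraw,
    table: ConversionTable = DEFAULT_TABLE,
) -> float:
    """Wet conductance (J g-1 h-1 degC-1) from the Scholander closure."""
    bmr_g = (
        scenario.bmr_ml_gb_h
        * indiv.bmr_mult
        * indiv.mass_g ** (scenario.mass_exponent - 1.0)
    )
    tb = scenario.tb_set_C + indiv.tb_offset_C
    return bmr_g * table.oxycal(scenario.rer_below) / (tb - scenario.tnz_lower_C)


def steady_physiology(
    scenario: EndothermScenario,
    indiv: IndividualDraw,
    ta: float,
    table: ConversionTable = DEFAULT_TABLE,
) -> PhysioTruth:
    """Whole-animal steady-state truth at ambient temperature ``ta``."""
    mass = indiv.mass_g
    bmr_g = scenario.bmr_ml_gb_h * indiv.bmr_mult * mass ** (scenario.mass_exponent - 1.0)
    tb0 = scenario.tb_set_C + indiv.tb_offset_C
    ewl_whole = (
        scenario.basal_ewl_mg_gb_h * indiv.ewl_mult * mass**scenario.ewl_exponent
    )

    if ta < scenario.tnz_lower_C:
        rer = scenario.rer_below
        cwet = individual_cwet(scenario, indiv, table)
        vo2_g = cwet * (tb0 - ta) / table.oxycal(rer)
        tb = tb0
    elif ta <= scenario.tnz_upper_C:
        rer = scenario.rer_within
        vo2_g = bmr_g
        tb = tb0
    else:
        rer = scenario.rer_above
        excess = ta - scenario.tnz_upper_C
        vo2_g = bmr_g * (1.0 + scenario.vo2_rise_frac_per_C * excess)
        tb = tb0 + scenario.tb_slope_above_tnz * excess
        ewl_whole = ewl_whole * math.exp(scenario.ewl_rise_rate_per_C * excess)

    vo2 = vo2_g * mass
    return PhysioTruth(
        vo2_ml_h=vo2,
        vco2_ml_h=rer * vo2,
        ewl_mg_h=ewl_whole,
        tb_C=tb,
        rer=rer,
    )


# ---------------------------------------------------------------------------
# Forward measurement model
# ---------------------------------------------------------------------------

def _steady_fractions(truth: PhysioTruth, chamber: ChamberConfig, ta: float):
    """Steady-state excurrent (FeO2, FeCO2, RH%) implied by the mass balance."""
    vi = chamber.flow_ml_min
    vo2_min = truth.vo2_ml_h / 60.0
    vco2_min = truth.vco2_ml_h / 60.0
    ve_dry = vi - vo2_min + vco2_min
    fe_o2 = (vi * chamber.fi_o2 - vo2_min) / ve_dry
    fe_co2 = (vi * chamber.fi_co2 + vco2_min) / ve_dry
    vap_ml_min = truth.ewl_mg_h / 60.0 * (ML_PER_MMOL_GAS / MG_PER_MMOL_H2O)
    pw = chamber.bp_kPa * vap_ml_min / (ve_dry + vap_ml_min)
    rh = 100.0 * pw / saturation_vapor_pressure_kPa(ta)
    return fe_o2, fe_co2, rh


def _washout(t_rel: np.ndarray, targets: np.ndarray, f0: float, tau_s: float) -> np.ndarray:
    """Exact piecewise first-order washout.

    ``targets`` gives the steady-state value at each sample; whenever the
    target changes the exponential restarts from the current value, so
    the discrete sequence equals the continuous ODE solution at sample
    times to machine precision.
    """
    out = np.empty_like(targets)
    current = f0
    seg_start = t_rel[0]
    seg_target = targets[0]
    for i, (t, tgt) in enumerate(zip(t_rel, targets)):
        if tgt != seg_target:
            # close previous segment at this sample's predecessor time
            seg_target = tgt
            seg_start = t_rel[i - 1] if i > 0 else t
            current = out[i - 1] if i > 0 else f0
        out[i] = seg_target + (current - seg_target) * math.exp(-(t - seg_start) / tau_s)
    return out


def simulate_trace(
    truth: PhysioTruth,
    chamber: ChamberConfig,
    seed: int | np.random.Generator,
    *,
    animal_id: str = "A-01",
    population_id: str = "pop",
    species: str = "synthetic",
    ta: float = 25.0,
    mass_g: float = 2000.0,
    animal_s: float | None = None,
    restless: RestlessSegment | None = None,
) -> RawTrace:
    """Forward-simulate one chamber trace for a fixed steady truth.

    Baseline segments sample the incurrent supply via a bypass, so they
    carry analyser noise and drift but no chamber washout; the animal
    phase starts at incurrent composition and relaxes exponentially to
    the excurrent steady state.  Fully reproducible from ``seed``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dt = chamber.sample_interval_s
    if animal_s is None:
        animal_s = chamber.hot_animal_s if ta >= chamber.hot_ta_C else chamber.animal_s

    n_base = int(round(chamber.baseline_s / dt))
    n_animal = int(round(animal_s / dt))
    n = n_base + n_animal + n_base
    time = np.arange(n) * dt
    phase = np.empty(n, dtype="<U13")
    phase[:n_base] = "baseline_pre"
    phase[n_base : n_base + n_animal] = "animal"
    phase[n_base + n_animal :] = "baseline_post"

    fe_o2_ss, fe_co2_ss, rh_ss = _steady_fractions(truth, chamber, ta)

    o2 = np.full(n, chamber.fi_o2)
    co2 = np.full(n, chamber.fi_co2)
    rh = np.zeros(n)

    am = slice(n_base, n_base + n_animal)
    t_animal = time[am] - time[am][0]
    o2_targets = np.full(n_animal, fe_o2_ss)
    co2_targets = np.full(n_animal, fe_co2_ss)
    rh_targets = np.full(n_animal, rh_ss)
    if restless is not None:
        seg = (t_animal >= restless.start_s) & (t_animal < restless.end_s)
        bumped = replace(
            truth,
            vo2_ml_h=truth.vo2_ml_h * restless.factor,
            vco2_ml_h=truth.vco2_ml_h * restless.factor,
            ewl_mg_h=truth.ewl_mg_h * restless.factor,
        )
        o2_b, co2_b, rh_b = _steady_fractions(bumped, chamber, ta)
        o2_targets[seg], co2_targets[seg], rh_targets[seg] = o2_b, co2_b, rh_b

    tau = chamber.tau_s
    o2[am] = _washout(t_animal, o2_targets, chamber.fi_o2, tau)
    co2[am] = _washout(t_animal, co2_targets, chamber.fi_co2, tau)
    rh[am] = _washout(t_animal, rh_targets, 0.0, tau)
    rh += chamber.rh_dry_offset_pct

    hours = time / 3600.0
    o2 = o2 + chamber.o2_drift_per_h * hours + rng.normal(0.0, chamber.o2_noise_sd, n)
    co2 = co2 + chamber.co2_drift_per_h * hours + rng.normal(0.0, chamber.co2_noise_sd, n)
    rh = rh + chamber.rh_drift_per_h * hours + rng.normal(0.0, chamber.rh_noise_sd, n)
    rh = np.clip(rh, 0.0, 100.0)
    t_probe = ta + rng.normal(0.0, chamber.t_noise_sd, n)
    flow = np.full(n, chamber.flow_ml_min)

    mass_after = mass_g - truth.ewl_mg_h * (animal_s / 3600.0) / 1000.0
    tb_meas = truth.tb_C + float(rng.normal(0.0, chamber.tb_noise_sd))

    meta = TrialMeta(
        animal_id=animal_id,
        population_id=population_id,
        species=species,
        mass_before_g=mass_g,
        mass_after_g=mass_after,
        tb_final_C=tb_meas,
        ta_target_C=ta,
        chamber_volume_ml=chamber.volume_ml,
        barometric_pressure_kPa=chamber.bp_kPa,
        sample_interval_s=dt,
        fi_o2=chamber.fi_o2,
        fi_co2=chamber.fi_co2,
        calibrated=True,
    )
    return RawTrace(
        time_s=time,
        o2_frac=o2,
        co2_frac=co2,
        rh_pct=rh,
        t_probe_C=t_probe,
        flow_stpd_ml_min=flow,
        phase=phase,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

#: Four illustrative population presets spanning the qualitative contrasts
#: seen across arid, mesic-cool, montane and tropical habitats.  Magnitudes
#: are realistic for 1.8-2.4 kg marsupials; they are presets, not claims.
PRESETS: dict[str, EndothermScenario] = {
    "arid": EndothermScenario(
        population_id="arid",
        mass_mean_g=1800.0,
        tb_set_C=34.8,
        bmr_ml_gb_h=2.0,
        basal_ewl_mg_gb_h=3.1,
        ewl_rise_rate_per_C=0.28,
        vo2_rise_frac_per_C=0.03,
    ),
    "mesic": EndothermScenario(
        population_id="mesic",
        mass_mean_g=2000.0,
        tb_set_C=34.9,
        bmr_ml_gb_h=1.8,
        basal_ewl_mg_gb_h=4.1,
        ewl_rise_rate_per_C=0.16,
        vo2_rise_frac_per_C=0.04,
    ),
    "montane": EndothermScenario(
        population_id="montane",
        mass_mean_g=2370.0,
        tb_set_C=36.2,
        bmr_ml_gb_h=2.8,
        basal_ewl_mg_gb_h=6.5,
        ewl_rise_rate_per_C=0.16,
        vo2_rise_frac_per_C=0.04,
    ),
    "tropical": EndothermScenario(
        population_id="tropical",
        mass_mean_g=2010.0,
        tb_set_C=34.9,
        bmr_ml_gb_h=2.5,
        basal_ewl_mg_gb_h=5.4,
        ewl_rise_rate_per_C=0.30,
        vo2_rise_frac_per_C=0.05,
    ),
}


def truth_record(
    scenario: EndothermScenario,
    indiv: IndividualDraw,
    ta: float,
    truth: PhysioTruth,
    table: ConversionTable = DEFAULT_TABLE,
    exponents: ScalingExponents = DEFAULT_EXPONENTS,
) -> dict:
    """Full truth row mirroring the PhysioRecord fields."""
    mhp = metabolic_heat(truth.vo2_ml_h, truth.rer, table)
    mwp = metabolic_water(truth.vo2_ml_h, truth.rer, table)
    ehl = evaporative_heat(truth.ewl_mg_h, table)
    cwet, cdry, defined = thermal_conductance(mhp, ehl, truth.tb_C, ta, indiv.mass_g)
    return {
        "population_id": scenario.population_id,
        "animal_id": indiv.individual_id,
        "ta_C": ta,
        "tb_C": truth.tb_C,
        "mass_g": indiv.mass_g,
        "vo2_ml_h": truth.vo2_ml_h,
        "vco2_ml_h": truth.vco2_ml_h,
        "ewl_mg_h": truth.ewl_mg_h,
        "rer": truth.rer,
        "mhp_J_h": mhp,
        "mwp_mg_h": mwp,
        "ehl_J_h": ehl,
        "cwet_J_g_h_C": cwet if defined else np.nan,
        "cdry_J_g_h_C": cdry if defined else np.nan,
        "rwe": relative_water_economy(mwp, truth.ewl_mg_h),
        "mi_vo2": mass_independent(truth.vo2_ml_h, indiv.mass_g, exponents.metabolic_rate),
        "mi_ewl": mass_independent(truth.ewl_mg_h, indiv.mass_g, exponents.ewl),
        "mi_cwet": (
            mass_independent(cwet * indiv.mass_g, indiv.mass_g, exponents.cwet)
            if defined
            else np.nan
        ),
    }


def generate_cohort(
    scenarios: Iterable[EndothermScenario] | None = None,
    chamber: ChamberConfig | None = None,
    seed: int = 0,
) -> tuple[list[RawTrace], pd.DataFrame]:
    """Simulate one trace per population x individual x Ta, plus truth.

    With the default presets (4 populations x 6 individuals x 8 Ta)
    this yields 192 traces.  The truth table carries every
    physiological-record field computed from the generative truth, so
    end-to-end recovery can be scored trial by trial.
    """
    scenarios = list(scenarios) if scenarios is not None else list(PRESETS.values())
    chamber = chamber or ChamberConfig()
    rng = np.random.default_rng(seed)
    traces: list[RawTrace] = []
    rows: list[dict] = []
    for scenario in scenarios:
        for indiv in draw_individuals(scenario, rng):
            for ta in scenario.ta_grid:
                truth = steady_physiology(scenario, indiv, ta)
                trace = simulate_trace(
                    truth,
                    chamber,
                    rng,
                    animal_id=indiv.individual_id,
                    population_id=scenario.population_id,
                    ta=ta,
                    mass_g=indiv.mass_g,
                )
                traces.append(trace)
                rows.append(truth_record(scenario, indiv, ta, truth))
    return traces, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Record-level generators for statistical calibration
# ---------------------------------------------------------------------------

def quadratic_record_cohort(
    n_populations: int = 4,
    n_individuals: int = 6,
    ta_grid: Sequence[float] = DEFAULT_TA_GRID,
    coef: tuple[float, float, float] = (2.0, -0.05, 0.004),
    indiv_sd: float = 0.15,
    resid_sd: float = 0.15,
    pop_effects: Sequence[float] | None = None,
    seed: int = 0,
    variable: str = "mi_vo2",
) -> pd.DataFrame:
    """Records drawn from a quadratic thermal response (centred at 26 degC).

    ``value = a + b*(Ta-26) + c*(Ta-26)^2 + pop_effect + u_indiv + eps``.
    With ``pop_effects=None`` all populations are identical (the null).
    """
    rng = np.random.default_rng(seed)
    a, b, c = coef
    if pop_effects is None:
        pop_effects = [0.0] * n_populations
    rows = []
    for p in range(n_populations):
        for i in range(n_individuals):
            u = rng.normal(0.0, indiv_sd)
            for ta in ta_grid:
                x = ta - 26.0
                mu = a + b * x + c * x * x + pop_effects[p] + u
                rows.append(
                    {
                        "population_id": f"pop{p + 1}",
                        "animal_id": f"pop{p + 1}-{i + 1:02d}",
                        "ta_C": float(ta),
                        variable: mu + rng.normal(0.0, resid_sd),
                    }
                )
    return pd.DataFrame(rows)


def linear_rwe_cohort(
    prwe_C: float = 10.4,
    slope_per_C: float = -0.075,
    n_individuals: int = 6,
    ta_grid: Sequence[float] = DEFAULT_TA_GRID,
    indiv_sd: float = 0.05,
    noise_sd: float = 0.05,
    seed: int = 0,
    population_id: str = "pop1",
) -> pd.DataFrame:
    """RWE records linear in Ta with a known crossing of RWE = 1.

    The truth is ``RWE(Ta) = 1 + slope * (Ta - prwe_C)``, so the point
    of relative water economy is exactly ``prwe_C``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_individuals):
        u = rng.normal(0.0, indiv_sd)
        for ta in ta_grid:
            rwe = 1.0 + slope_per_C * (ta - prwe_C) + u + rng.normal(0.0, noise_sd)
            rows.append(
                {
                    "population_id": population_id,
                    "animal_id": f"{population_id}-{i + 1:02d}",
                    "ta_C": float(ta),
                    "rwe": rwe,
                }
            )
    return pd.DataFrame(rows)
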