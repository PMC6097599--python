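"""Standard thermal and hygric physiology derived from window means.

Given the steady-window means of VO2, VCO2 and EWL plus the trial
metadata (body masses, final body temperature, ambient temperature),
this module derives the standard variables of endotherm energetics:

* RER = VCO2/VO2 — respiratory exchange ratio, indexing metabolic fuel;
* MHP = VO2 * oxycalorific(RER) — metabolic heat production, J h-1;
* MWP = VO2 * hygric(RER) — metabolic water production, mg h-1;
* EHL = EWL * latent heat (2.4 J mg-1 H2O) — evaporative heat loss;
* C_wet = (MHP/m)/(Tb - Ta), C_dry = ((MHP - EHL)/m)/(Tb - Ta) —
  mass-specific wet/dry thermal conductance, J g-1 h-1 degC-1;
* RWE = MWP/EWL — relative water economy;
* mass-independent values X / m^b with marsupial scaling exponents
  (metabolic rate 0.74, EWL 0.68, C_wet 0.57 by default).

The RER-dependent oxycalorific and hygric coefficients are linear
interpolations between configured knots (defaults 0.71 -> 19.6 and
1.00 -> 21.1 J ml-1 O2; 0.71 -> 0.53 and 1.00 -> 0.67 mg ml-1 O2),
clamped to the knot domain for lookups while the raw RER is preserved
in the record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .gas_exchange import SteadyWindow
from .io_calibration import TrialMeta

__all__ = [
    "ConversionTable",
    "ScalingExponents",
    "PhysioRecord",
    "compute_rer",
    "metabolic_heat",
    "metabolic_water",
    "evaporative_heat",
    "thermal_conductance",
    "relative_water_economy",
    "mass_independent",
    "assemble_record",
    "records_to_frame",
    "DEFAULT_TABLE",
    "DEFAULT_EXPONENTS",
]


@dataclass(frozen=True)
class ConversionTable:
    """RER-dependent energy/water coefficients and the latent heat.

    Knot values follow the conventional oxycalorific/hygric tables for
    mixed fuels; both maps are linear between knots and clamped outside.
    """

    oxycal_knots: tuple[tuple[float, float], ...] = ((0.71, 19.6), (1.00, 21.1))
    hygric_knots: tuple[tuple[float, float], ...] = ((0.71, 0.53), (1.00, 0.67))
    latent_heat_J_mg: float = 2.4

    def __post_init__(self) -> None:
        for name, knots in (("oxycal", self.oxycal_knots), ("hygric", self.hygric_knots)):
            rers = [k[0] for k in knots]
            vals = [k[1] for k in knots]
            if sorted(rers) != list(rers) or len(set(rers)) != len(rers):
                raise ValueError(f"{name} knots must have strictly increasing RER")
            if sorted(vals) != list(vals):
                raise ValueError(f"{name} table must be monotone in RER")
        if self.latent_heat_J_mg <= 0:
            raise ValueError("latent heat must be positive")

    def _interp(self, knots, rer: float) -> float:
        xs = np.array([k[0] for k in knots])
        ys = np.array([k[1] for k in knots])
        return float(np.interp(rer, xs, ys))  # np.interp clamps at the edges

    def oxycal(self, rer: float) -> float:
        """J per ml O2 at the given RER (clamped to the knot domain)."""
        return self._interp(self.oxycal_knots, rer)

    def hygric(self, rer: float) -> float:
        """mg H2O per ml O2 at the given RER (clamped to the knot domain)."""
        return self._interp(self.hygric_knots, rer)

    @property
    def rer_domain(self) -> tuple[float, float]:
        return (self.oxycal_knots[0][0], self.oxycal_knots[-1][0])


@dataclass(frozen=True)
class ScalingExponents:
    """Allometric mass exponents used for mass-independent values."""

    metabolic_rate: float = 0.74
    ewl: float = 0.68
    cwet: float = 0.57


DEFAULT_TABLE = ConversionTable()
DEFAULT_EXPONENTS = ScalingExponents()

#: Minimum body-to-air gradient (degC) below which conductance is undefined.
GRADIENT_FLOOR_C = 0.5


def compute_rer(vo2: float, vco2: float) -> tuple[float, bool]:
    """RER = VCO2/VO2; returns ``(rer, in_range)``.

    Values outside the physiological [0.7, 1.0] band are returned as-is
    with ``in_range=False``; coefficient lookups clamp separately.
    """
    if vo2 <= 0:
        raise ValueError("vo2 must be positive to form an RER")
    rer = vco2 / vo2
    return rer, 0.7 <= rer <= 1.0


def metabolic_heat(vo2: float, rer: float, table: ConversionTable = DEFAULT_TABLE) -> float:
    """Metabolic heat production, J h-1 (VO2 in ml h-1)."""
    if vo2 < 0:
        raise ValueError("vo2 must be non-negative")
    return vo2 * table.oxycal(rer)


def metabolic_water(vo2: float, rer: float, table: ConversionTable = DEFAULT_TABLE) -> float:
    """Metabolic water production, mg h-1 (VO2 in ml h-1)."""
    if vo2 < 0:
        raise ValueError("vo2 must be non-negative")
    return vo2 * table.hygric(rer)


def evaporative_heat(ewl: float, table: ConversionTable = DEFAULT_TABLE) -> float:
    """Evaporative heat loss, J h-1 (EWL in mg h-1)."""
    if ewl < 0:
        raise ValueError("ewl must be non-negative")
    return ewl * table.latent_heat_J_mg


def thermal_conductance(
    mhp: float,
    ehl: float,
    tb: float,
    ta: float,
    mass_g: float,
    gradient_floor_C: float = GRADIENT_FLOOR_C,
) -> tuple[float | None, float | None, bool]:
    """Mass-specific wet and dry thermal conductance.

    Returns ``(cwet, cdry, defined)`` in J g-1 h-1 degC-1.  When the
    body-to-air gradient is below ``gradient_floor_C`` (common above
    thermoneutrality) the values are undefined and ``(None, None,
    False)`` is returned rather than an exception.  C_dry may be
    negative when EHL exceeds MHP; it is reported as computed.
    """
    if mass_g <= 0:
        raise ValueError("mass must be positive")
    gradient = tb - ta
    if gradient < gradient_floor_C:
        return None, None, False
    cwet = (mhp / mass_g) / gradient
    cdry = ((mhp - ehl) / mass_g) / gradient
    return cwet, cdry, True


def relative_water_economy(mwp: float, ewl: float) -> float:
    """RWE = MWP/EWL; dimensionless. RWE = 1 defines the PRWE."""
    if ewl <= 0:
        raise ValueError("ewl must be positive to form RWE")
    return mwp / ewl


def mass_independent(value: float, mass_g: float, exponent: float) -> float:
    """Allometric mass correction: value / mass**exponent."""
    if mass_g <= 0:
        raise ValueError("mass must be positive")
    return value / mass_g**exponent


# ---------------------------------------------------------------------------
# Record assembly
# ---------------------------------------------------------------------------

@dataclass
class PhysioRecord:
    """One trial's standard physiological values.

    ``flags`` accumulates quality markers: ``non_steady`` (no window met
    the stability policy), ``rer_out_of_range``, ``conductance_undefined``
    (gradient below floor), ``tb_missing``.
    """

    animal_id: str
    population_id: str
    ta_C: float
    tb_C: float | None
    mass_g: float
    vo2_ml_h: float
    vco2_ml_h: float
    ewl_mg_h: float
    rer: float
    mhp_J_h: float
    mwp_mg_h: float
    ehl_J_h: float
    cwet_J_g_h_C: float | None
    cdry_J_g_h_C: float | None
    rwe: float
    mi_vo2: float
    mi_ewl: float
    mi_cwet: float | None
    exponents: ScalingExponents
    flags: list[str] = field(default_factory=list)


def assemble_record(
    window: SteadyWindow,
    meta: TrialMeta,
    table: ConversionTable = DEFAULT_TABLE,
    exponents: ScalingExponents = DEFAULT_EXPONENTS,
    gradient_floor_C: float = GRADIENT_FLOOR_C,
) -> PhysioRecord:
    """Populate a full physiological record from a steady window.

    Ta is the window-mean probe temperature (the probe sits in the
    excurrent stream at chamber temperature); Tb is the single post-trial
    cloacal measurement paired with the whole window.  A missing Tb
    yields a record with the conductance fields absent and flagged.
    """
    flags: list[str] = []
    if not window.steady:
        flags.append("non_steady")

    vo2 = window.means["vo2_ml_h"]
    vco2 = window.means["vco2_ml_h"]
    ewl = window.means["ewl_mg_h"]
    ta = window.means.get("t_probe_C", meta.ta_target_C)
    mass = meta.mean_mass_g

    rer, in_range = compute_rer(vo2, vco2)
    if not in_range:
        flags.append("rer_out_of_range")
    mhp = metabolic_heat(vo2, rer, table)
    mwp = metabolic_water(vo2, rer, table)
    ehl = evaporative_heat(max(ewl, 0.0), table)
    rwe = relative_water_economy(mwp, ewl) if ewl > 0 else float("nan")

    tb = meta.tb_final_C
    if tb is None:
        flags.append("tb_missing")
        cwet = cdry = None
    else:
        cwet, cdry, defined = thermal_conductance(
            mhp, ehl, tb, ta, mass, gradient_floor_C=gradient_floor_C
        )
        if not defined:
            flags.append("conductance_undefined")

    return PhysioRecord(
        animal_id=meta.animal_id,
        population_id=meta.population_id,
        ta_C=ta,
        tb_C=tb,
        mass_g=mass,
        vo2_ml_h=vo2,
        vco2_ml_h=vco2,
        ewl_mg_h=ewl,
        rer=rer,
        mhp_J_h=mhp,
        mwp_mg_h=mwp,
        ehl_J_h=ehl,
        cwet_J_g_h_C=cwet,
        cdry_J_g_h_C=cdry,
        rwe=rwe,
        mi_vo2=mass_independent(vo2, mass, exponents.metabolic_rate),
        mi_ewl=mass_independent(ewl, mass, exponents.ewl),
        mi_cwet=(
            mass_independent(cwet * mass, mass, exponents.cwet) if cwet is not None else None
        ),
        exponents=exponents,
        flags=flags,
    )


def records_to_frame(records: Iterable[PhysioRecord]) -> pd.DataFrame:
    """Tidy one-row-per-trial table of physiological records."""
    rows = []
    for r in records:
        rows.append(
            {
                "animal_id": r.animal_id,
                "population_id": r.population_id,
                "ta_C": r.ta_C,
                "tb_C": np.nan if r.tb_C is None else r.tb_C,
                "mass_g": r.mass_g,
                "vo2_ml_h": r.vo2_ml_h,
                "vco2_ml_h": r.vco2_ml_h,
                "ewl_mg_h": r.ewl_mg_h,
                "rer": r.rer,
                "mhp_J_h": r.mhp_J_h,
                "mwp_mg_h": r.mwp_mg_h,
                "ehl_J_h": r.ehl_J_h,
                "cwet_J_g_h_C": np.nan if r.cwet_J_g_h_C is None else r.cwet_J_g_h_C,
                "cdry_J_g_h_C": np.nan if r.cdry_J_g_h_C is None else r.cdry_J_g_h_C,
                "rwe": r.rwe,
                "mi_vo2": r.mi_vo2,
                "mi_ewl": r.mi_ewl,
                "mi_cwet": np.nan if r.mi_cwet is None else r.mi_cwet,
                "flags": ";".join(r.flags),
            }
        )
    return pd.DataFrame(rows)
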