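"""Baseline correction, mass-balance gas exchange, EWL, steady windows.

The measurement model: dry incurrent air of known composition (FiO2,
FiCO2) enters the chamber at a mass-flow-regulated STPD rate; the animal
consumes O2, produces CO2 and adds water vapour; a subsample of
excurrent air passes an RH/temperature probe, is then dried and analysed
for O2 and CO2.  Because the analysed excurrent stream is dry, gas
fractions need no vapour-dilution correction, and the nitrogen balance
gives the dry excurrent flow exactly:

    VE_dry = VI * (1 - FiO2 - FiCO2) / (1 - FeO2 - FeCO2)
    VO2    = VI * FiO2 - VE_dry * FeO2
    VCO2   = VE_dry * FeCO2 - VI * FiCO2

Water vapour is recovered psychrometrically from the RH probe: the
partial pressure Pw = RH/100 * Psat(T) (Magnus form), the vapour
volumetric flow is VE_dry * Pw / (BP - Pw), and mass follows from
18.016 mg mmol-1 over 22.414 ml mmol-1.  Incurrent air is dry, so all
excurrent vapour is evaporative water loss.

Analyser drift is handled with animal-free baselines (>= 20 min before
and after the trial): the incurrent reference for each channel is the
line through the two baseline means, evaluated at each timestamp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_calibration import RawTrace, STANDARD_PRESSURE_KPA

__all__ = [
    "MAGNUS",
    "MG_PER_MMOL_H2O",
    "ML_PER_MMOL_GAS",
    "GasExchangeError",
    "ChannelBaseline",
    "BaselineModel",
    "GasExchangeSeries",
    "SteadyWindow",
    "fit_baseline",
    "compute_gas_exchange",
    "saturation_vapor_pressure_kPa",
    "compute_ewl",
    "correct_series",
    "find_steady_window",
]

#: Magnus saturation-vapour-pressure constants (kPa, -, degC):
#: Psat(T) = a * exp(b*T / (T + c)).  Configurable so tests can pin them.
MAGNUS = (0.61094, 17.625, 243.04)

MG_PER_MMOL_H2O = 18.016
ML_PER_MMOL_GAS = 22.414


class GasExchangeError(ValueError):
    """Physically impossible input to a gas-exchange computation."""


# ---------------------------------------------------------------------------
# Baselines
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChannelBaseline:
    """Linear drift model for one channel, anchored at the two baseline means."""

    pre_mean: float
    post_mean: float
    pre_mid_s: float
    post_mid_s: float
    noise_sd: float

    @property
    def slope_per_s(self) -> float:
        span = self.post_mid_s - self.pre_mid_s
        if span <= 0:
            return 0.0
        return (self.post_mean - self.pre_mean) / span

    def at(self, t: np.ndarray | float) -> np.ndarray | float:
        """Drift-corrected incurrent reference at time(s) ``t``."""
        return self.pre_mean + self.slope_per_s * (np.asarray(t, dtype=float) - self.pre_mid_s)


@dataclass(frozen=True)
class BaselineModel:
    o2: ChannelBaseline
    co2: ChannelBaseline
    rh: ChannelBaseline
    pre_duration_s: float
    post_duration_s: float


def fit_baseline(trace: RawTrace, min_baseline_s: float = 1200.0) -> BaselineModel:
    """Fit per-channel linear drift from the pre/post baseline segments.

    The drift function for each channel passes through (pre-window
    midpoint, pre mean) and (post-window midpoint, post mean).  The
    reported noise SD pools the residuals about the two phase means.

    Raises
    ------
    GasExchangeError
        If a baseline phase is missing or shorter than ``min_baseline_s``.
    """
    masks = {}
    for phase in ("baseline_pre", "baseline_post"):
        m = trace.phase_mask(phase)
        if not m.any():
            raise GasExchangeError(f"baseline phase {phase!r} missing")
        dur = trace.phase_duration_s(phase)
        if dur < min_baseline_s:
            raise GasExchangeError(
                f"baseline phase {phase!r} lasts {dur:.0f} s, "
                f"below the {min_baseline_s:.0f} s minimum"
            )
        masks[phase] = m

    pre, post = masks["baseline_pre"], masks["baseline_post"]
    t = trace.time_s
    pre_mid = float(t[pre].mean())
    post_mid = float(t[post].mean())

    def channel(arr: np.ndarray) -> ChannelBaseline:
        resid = np.concatenate([arr[pre] - arr[pre].mean(), arr[post] - arr[post].mean()])
        return ChannelBaseline(
            pre_mean=float(arr[pre].mean()),
            post_mean=float(arr[post].mean()),
            pre_mid_s=pre_mid,
            post_mid_s=post_mid,
            noise_sd=float(resid.std(ddof=1)) if resid.size > 1 else 0.0,
        )

    return BaselineModel(
        o2=channel(trace.o2_frac),
        co2=channel(trace.co2_frac),
        rh=channel(trace.rh_pct),
        pre_duration_s=trace.phase_duration_s("baseline_pre"),
        post_duration_s=trace.phase_duration_s("baseline_post"),
    )


# ---------------------------------------------------------------------------
# Mass balance
# ---------------------------------------------------------------------------

def compute_gas_exchange(
    fe_o2,
    fe_co2,
    fi_o2: float = 0.2095,
    fi_co2: float = 0.0004,
    flow_in_stpd=None,
):
    """Invert the dry-nitrogen mass balance. Vectorised over inputs.

    Parameters are dry gas fractions (dimensionless) and the incurrent
    dry STPD flow in ml min-1.

    Returns
    -------
    (vo2_ml_h, vco2_ml_h, ve_dry_ml_min)
        O2 consumption and CO2 production in ml STPD h-1 and the dry
        excurrent flow in ml min-1.  Exact algebra, no iteration; a
        negative VO2 is returned as-is (callers flag it — it signals a
        baseline or calibration fault, never raises).
    """
    if flow_in_stpd is None:
        raise GasExchangeError("flow_in_stpd is required")
    fe_o2 = np.asarray(fe_o2, dtype=float)
    fe_co2 = np.asarray(fe_co2, dtype=float)
    fi_o2 = np.asarray(fi_o2, dtype=float)
    fi_co2 = np.asarray(fi_co2, dtype=float)
    flow = np.asarray(flow_in_stpd, dtype=float)

    for name, arr in (("fe_o2", fe_o2), ("fe_co2", fe_co2), ("fi_o2", fi_o2), ("fi_co2", fi_co2)):
        if ((arr < 0) | (arr >= 1)).any():
            raise GasExchangeError(f"{name} outside [0, 1)")
    if (flow <= 0).any():
        raise GasExchangeError("flow must be positive")
    if (fe_o2 + fe_co2 >= 1).any():
        raise GasExchangeError("FeO2 + FeCO2 >= 1: no nitrogen in excurrent stream")

    ve_dry = flow * (1.0 - fi_o2 - fi_co2) / (1.0 - fe_o2 - fe_co2)
    vo2 = (flow * fi_o2 - ve_dry * fe_o2) * 60.0
    vco2 = (ve_dry * fe_co2 - flow * fi_co2) * 60.0
    if vo2.ndim == 0:
        return float(vo2), float(vco2), float(ve_dry)
    return vo2, vco2, ve_dry


def saturation_vapor_pressure_kPa(t_C, magnus: tuple[float, float, float] = MAGNUS):
    """Magnus saturation vapour pressure over water, in kPa."""
    a, b, c = magnus
    t = np.asarray(t_C, dtype=float)
    out = a * np.exp(b * t / (t + c))
    return float(out) if out.ndim == 0 else out


def compute_ewl(
    rh_pct,
    t_probe_C,
    ve_dry_stpd,
    bp_kPa: float = STANDARD_PRESSURE_KPA,
    magnus: tuple[float, float, float] = MAGNUS,
):
    """Evaporative water loss (mg H2O h-1) from excurrent RH. Vectorised.

    Pw = RH/100 * Psat(T_probe); the vapour volumetric flow riding on the
    dry excurrent stream is VE_dry * Pw / (BP - Pw) (ml min-1), converted
    to mass by 18.016/22.414 mg ml-1 and to per-hour by 60.
    """
    rh = np.asarray(rh_pct, dtype=float)
    if ((rh < 0) | (rh > 100)).any():
        raise GasExchangeError("rh_pct outside [0, 100]")
    pw = rh / 100.0 * saturation_vapor_pressure_kPa(t_probe_C, magnus)
    if (pw >= bp_kPa).any():
        raise GasExchangeError("water vapour pressure >= barometric pressure")
    vap_ml_min = np.asarray(ve_dry_stpd, dtype=float) * pw / (bp_kPa - pw)
    ewl = vap_ml_min * 60.0 * (MG_PER_MMOL_H2O / ML_PER_MMOL_GAS)
    return float(ewl) if ewl.ndim == 0 else ewl


# ---------------------------------------------------------------------------
# Series correction
# ---------------------------------------------------------------------------

@dataclass
class GasExchangeSeries:
    """Per-timestamp VO2, VCO2 and EWL over the animal phase."""

    time_s: np.ndarray
    vo2_ml_h: np.ndarray
    vco2_ml_h: np.ndarray
    ewl_mg_h: np.ndarray
    t_probe_C: np.ndarray
    sample_interval_s: float

    @property
    def n_negative_vo2(self) -> int:
        return int((self.vo2_ml_h < 0).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "vo2_ml_h": self.vo2_ml_h,
                "vco2_ml_h": self.vco2_ml_h,
                "ewl_mg_h": self.ewl_mg_h,
                "t_probe_C": self.t_probe_C,
            }
        )


def correct_series(
    trace: RawTrace,
    baseline: BaselineModel,
    magnus: tuple[float, float, float] = MAGNUS,
    settle_tau: float = 8.0,
) -> GasExchangeSeries:
    """Baseline-correct the animal phase and invert to physical rates.

    At each animal-phase timestamp the incurrent gas reference is the
    drift-corrected baseline value for that channel, and the excurrent
    value is the measured sample.  Measured RH has the RH-channel drift
    (analyser offset on dry incurrent air) subtracted before the
    psychrometric inversion.

    The equilibrium mass balance is only valid once the chamber has
    washed out, so the first ``settle_tau`` time constants (tau =
    volume/flow) of the animal phase are discarded; at the default 8
    tau the residual washout transient is e^-8 ~ 0.03% of the step.
    Pass ``settle_tau=0`` to keep the full phase.
    """
    m = trace.phase_mask("animal")
    if not m.any():
        raise GasExchangeError("trace has no animal phase")
    if settle_tau > 0:
        flow_mean = float(trace.flow_stpd_ml_min[m].mean())
        tau_s = 60.0 * trace.meta.chamber_volume_ml / flow_mean
        t_start = trace.time_s[m][0] + settle_tau * tau_s
        m = m & (trace.time_s >= t_start)
        if not m.any():
            raise GasExchangeError(
                "animal phase shorter than the chamber equilibration period "
                f"({settle_tau:g} tau = {settle_tau * tau_s:.0f} s)"
            )
    t = trace.time_s[m]
    fi_o2_t = np.asarray(baseline.o2.at(t), dtype=float)
    fi_co2_t = np.clip(np.asarray(baseline.co2.at(t), dtype=float), 0.0, None)
    rh = np.clip(trace.rh_pct[m] - np.asarray(baseline.rh.at(t), dtype=float), 0.0, 100.0)

    vo2, vco2, ve_dry = compute_gas_exchange(
        trace.o2_frac[m],
        trace.co2_frac[m],
        fi_o2=fi_o2_t,
        fi_co2=fi_co2_t,
        flow_in_stpd=trace.flow_stpd_ml_min[m],
    )
    ewl = compute_ewl(
        rh, trace.t_probe_C[m], ve_dry, bp_kPa=trace.meta.pressure_kPa(), magnus=magnus
    )
    dt = float(np.median(np.diff(t))) if len(t) > 1 else trace.meta.sample_interval_s
    return GasExchangeSeries(
        time_s=t,
        vo2_ml_h=np.atleast_1d(vo2),
        vco2_ml_h=np.atleast_1d(vco2),
        ewl_mg_h=np.atleast_1d(ewl),
        t_probe_C=trace.t_probe_C[m],
        sample_interval_s=dt,
    )


# ---------------------------------------------------------------------------
# Steady-and-minimal window
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SteadyWindow:
    """Selected analysis window ``[start_s, end_s)`` with its diagnostics."""

    start_s: float
    end_s: float
    means: dict
    cv: float
    slope_frac_per_h: float
    steady: bool
    n_samples: int

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def _window_stats(x: np.ndarray, t: np.ndarray, length: int):
    """Windowed mean, CV and per-second slope for every start, one length.

    Uses cumulative sums so the all-(start, length) sweep is O(n) per
    length; algebraically identical to per-window mean/std/least squares.
    """
    n = len(x)
    cs = np.concatenate([[0.0], np.cumsum(x)])
    cs2 = np.concatenate([[0.0], np.cumsum(x * x)])
    ct = np.concatenate([[0.0], np.cumsum(t)])
    ct2 = np.concatenate([[0.0], np.cumsum(t * t)])
    ctx = np.concatenate([[0.0], np.cumsum(t * x)])

    L = length
    sx = cs[L:] - cs[:-L]
    sx2 = cs2[L:] - cs2[:-L]
    st = ct[L:] - ct[:-L]
    st2 = ct2[L:] - ct2[:-L]
    stx = ctx[L:] - ctx[:-L]

    mean = sx / L
    var = np.maximum(sx2 / L - mean * mean, 0.0)
    denom = L * st2 - st * st
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(denom > 0, (L * stx - st * sx) / np.where(denom > 0, denom, 1.0), 0.0)
    return mean, np.sqrt(var), slope


def find_steady_window(
    series: GasExchangeSeries,
    min_duration_s: float = 1200.0,
    cv_max: float = 0.10,
    slope_max_frac_per_h: float = 0.05,
) -> SteadyWindow:
    """Find the steady-and-minimal analysis window on the VO2 channel.

    Candidates are every (start sample, length) pair with duration at
    least ``min_duration_s`` that lies inside the animal phase and
    contains no negative VO2 sample.  A candidate qualifies as *steady*
    when its VO2 coefficient of variation is <= ``cv_max`` and the
    magnitude of its fitted linear slope is <= ``slope_max_frac_per_h``
    of its own mean per hour.  Among qualifying windows the one with the
    minimal mean VO2 wins; ties go to the earliest start, then the
    longest window.  If no window qualifies, the minimal-CV candidate is
    returned flagged ``steady=False``.

    CO2, EWL and probe-temperature means are reported over the same
    window (one common analysis period per trial).
    """
    x = series.vo2_ml_h
    t = series.time_s
    n = len(x)
    dt = series.sample_interval_s
    min_len = max(2, int(np.ceil(min_duration_s / dt)))
    if n < min_len:
        raise GasExchangeError(
            f"animal phase has {n} samples ({n * dt:.0f} s), "
            f"shorter than the {min_duration_s:.0f} s minimum window"
        )

    neg = np.concatenate([[0], np.cumsum((x < 0).astype(np.int64))])
    tc = t - t.mean()  # shift origin: slope is invariant, cumsums better conditioned

    best = None  # (mean, start_idx, length)
    best_cv = None  # (cv, start_idx, length) fallback

    for L in range(min_len, n + 1):
        mean, sd, slope = _window_stats(x, tc, L)
        starts = np.arange(n - L + 1)
        clean = (neg[L:] - neg[:-L]) == 0
        pos = mean > 0

        with np.errstate(divide="ignore", invalid="ignore"):
            cv = np.where(pos, sd / np.where(pos, mean, 1.0), np.inf)
            rel_slope_h = np.where(pos, np.abs(slope) * 3600.0 / np.where(pos, mean, 1.0), np.inf)

        ok = clean & pos & (cv <= cv_max) & (rel_slope_h <= slope_max_frac_per_h)
        if ok.any():
            idx = starts[ok]
            means_ok = mean[ok]
            j = int(np.lexsort((idx, means_ok))[0])
            cand = (float(means_ok[j]), int(idx[j]), L)
            best = _better_min_mean(best, cand)

        valid = clean & pos & np.isfinite(cv)
        if valid.any():
            idx = starts[valid]
            cvs = cv[valid]
            j = int(np.lexsort((idx, cvs))[0])
            cand_cv = (float(cvs[j]), int(idx[j]), L)
            best_cv = _better_min_cv(best_cv, cand_cv)

    steady = best is not None
    if best is None:
        if best_cv is None:
            # every window touches a negative sample: fall back to the whole phase
            best = (float(x.mean()), 0, n)
        else:
            best = (best_cv[0], best_cv[1], best_cv[2])
            best = (float(x[best[1] : best[1] + best[2]].mean()), best[1], best[2])

    _, s, L = best
    sl = slice(s, s + L)
    w = x[sl]
    tw = t[sl]
    mean = float(w.mean())
    cv = float(w.std() / mean) if mean > 0 else float("inf")
    slope = float(np.polyfit(tw, w, 1)[0]) if len(w) > 1 else 0.0
    return SteadyWindow(
        start_s=float(tw[0]),
        end_s=float(tw[-1] + dt),
        means={
            "vo2_ml_h": mean,
            "vco2_ml_h": float(series.vco2_ml_h[sl].mean()),
            "ewl_mg_h": float(series.ewl_mg_h[sl].mean()),
            "t_probe_C": float(series.t_probe_C[sl].mean()),
        },
        cv=cv,
        slope_frac_per_h=(slope * 3600.0 / mean) if mean > 0 else float("inf"),
        steady=steady,
        n_samples=L,
    )


_TIE_RTOL = 1e-9


def _better_min_mean(best, cand):
    """Lexicographic min on (mean, start, -length) with a relative tie band."""
    if best is None:
        return cand
    m0, s0, l0 = best
    m1, s1, l1 = cand
    tol = _TIE_RTOL * max(1.0, abs(m0), abs(m1))
    if m1 < m0 - tol:
        return cand
    if abs(m1 - m0) <= tol:
        if s1 < s0 or (s1 == s0 and l1 > l0):
            return cand
    return best


def _better_min_cv(best, cand):
    if best is None:
        return cand
    c0, s0, l0 = best
    c1, s1, l1 = cand
    tol = _TIE_RTOL * max(1.0, abs(c0), abs(c1))
    if c1 < c0 - tol:
        return cand
    if abs(c1 - c0) <= tol and (s1 < s0 or (s1 == s0 and l1 > l0)):
        return cand
    return best
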