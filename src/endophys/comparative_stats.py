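"""Population comparison of thermal-response curves and standard values.

Repeated measures (each animal measured at several ambient temperatures)
are handled with linear mixed models: a quadratic fixed effect of Ta —
centred and scaled to unit SD before polynomial expansion, with the
coding stored so predictions are coding-independent — and a random
intercept per individual, fitted by REML (statsmodels ``MixedLM``).

Inference follows the large-sample route: Wald chi-square tests for the
fixed location and Ta x location interaction terms, and a likelihood
ratio test for the random intercept against the 50:50 chi2_0 / chi2_1
boundary mixture (the variance is tested on the edge of its parameter
space, so the naive chi2_1 reference would be conservative by a factor
of two).

Standard (basal) values at thermoneutrality are compared across
populations with a one-way ANOVA followed by Student-Newman-Keuls
stepwise grouping on the studentized range, with the harmonic mean of
group sizes for unbalanced designs; groupings are reported as the usual
compact letter display.

The point of relative water economy (PRWE) — the Ta at which the fitted
RWE curve crosses 1 — is located by bisection on the fitted polynomial,
taking the root nearest the measured Ta range and flagging
extrapolation beyond it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
import statsmodels.api as sm

__all__ = [
    "StatsError",
    "ThermalResponseFit",
    "EffectTest",
    "Contrast",
    "ComparisonResult",
    "PRWEEstimate",
    "fit_thermal_response",
    "lrt_random_effect",
    "compare_locations",
    "estimate_prwe",
    "anova_snk",
]


class StatsError(ValueError):
    """Ill-posed statistical request (too few groups, missing reference...)."""


# ---------------------------------------------------------------------------
# Per-population thermal response
# ---------------------------------------------------------------------------

@dataclass
class ThermalResponseFit:
    """Quadratic mixed-model fit of one variable against Ta.

    Coefficients are on the centred/scaled coding z = (Ta - center)/scale;
    :meth:`predict` undoes the coding so fitted values never depend on it.
    """

    population_id: str
    variable: str
    coef: np.ndarray  # (intercept, z, z^2)
    se: np.ndarray
    var_random: float
    var_resid: float
    n_individuals: int
    n_obs: int
    ta_center: float
    ta_scale: float
    loglik_ml: float
    has_random: bool
    boundary: bool  # random-intercept variance collapsed to ~0
    ta_range: tuple[float, float] = (0.0, 0.0)

    def predict(self, ta) -> np.ndarray:
        z = (np.asarray(ta, dtype=float) - self.ta_center) / self.ta_scale
        out = self.coef[0] + self.coef[1] * z + self.coef[2] * z * z
        return float(out) if out.ndim == 0 else out

    def to_dict(self) -> dict:
        return {
            "population_id": self.population_id,
            "variable": self.variable,
            "intercept": float(self.coef[0]),
            "ta_linear": float(self.coef[1]),
            "ta_quadratic": float(self.coef[2]),
            "se_intercept": float(self.se[0]),
            "se_ta_linear": float(self.se[1]),
            "se_ta_quadratic": float(self.se[2]),
            "var_random": self.var_random,
            "var_resid": self.var_resid,
            "n_individuals": self.n_individuals,
            "n_obs": self.n_obs,
            "ta_center": self.ta_center,
            "ta_scale": self.ta_scale,
            "boundary": self.boundary,
        }


def _fit_mixed(model: sm.MixedLM, reml: bool):
    """Fit a MixedLM, falling back across optimizers.

    Near the variance boundary the gradient-based optimizers can hit a
    singular profiled covariance; the gradient-free ones are slower but
    robust, so they are the backstop.
    """
    last_exc: Exception | None = None
    for method in ("lbfgs", "bfgs", "powell", "nm"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return model.fit(reml=reml, method=method, maxiter=2000)
        except (np.linalg.LinAlgError, ValueError, OverflowError) as exc:
            last_exc = exc
    raise StatsError(f"mixed-model fit failed: {last_exc}")


def _coding(ta: np.ndarray) -> tuple[float, float]:
    center = float(ta.mean())
    scale = float(ta.std(ddof=0))
    if scale == 0:
        raise StatsError("Ta has no variation; cannot fit a thermal response")
    return center, scale


def _design(ta: np.ndarray, center: float, scale: float) -> np.ndarray:
    z = (ta - center) / scale
    return np.column_stack([np.ones_like(z), z, z * z])


def fit_thermal_response(
    records: pd.DataFrame,
    variable: str,
    population: str | None = None,
    include_random: bool = True,
    reml: bool = True,
) -> ThermalResponseFit:
    """Fit ``variable ~ poly(Ta, 2)`` with a per-individual random intercept.

    ``records`` needs columns ``animal_id``, ``ta_C``, ``population_id``
    and ``variable``.  Requires >= 2 individuals and >= 3 distinct Ta.
    ``include_random=False`` drops the random intercept (ordinary least
    squares), for use as the null model in the random-effect LRT.

    A fit whose random-intercept variance collapses to (numerically)
    zero is returned with ``boundary=True`` rather than raising.
    """
    df = records
    if population is not None:
        df = df[df["population_id"] == population]
    df = df.dropna(subset=[variable, "ta_C"])
    if population is None:
        pops = df["population_id"].unique()
        if len(pops) != 1:
            raise StatsError("records span several populations; pass `population`")
        population = str(pops[0])

    n_indiv = df["animal_id"].nunique()
    if n_indiv < 2:
        raise StatsError(f"need >= 2 individuals, got {n_indiv}")
    if df["ta_C"].nunique() < 3:
        raise StatsError("need >= 3 distinct Ta values for a quadratic fit")

    ta = df["ta_C"].to_numpy(dtype=float)
    y = df[variable].to_numpy(dtype=float)
    center, scale = _coding(ta)
    X = _design(ta, center, scale)

    if include_random:
        groups = df["animal_id"].to_numpy()
        model = sm.MixedLM(y, X, groups=groups)
        res = _fit_mixed(model, reml=reml)
        res_ml = res if not reml else _fit_mixed(model, reml=False)
        var_random = float(np.asarray(res.cov_re).ravel()[0])
        var_resid = float(res.scale)
        coef = np.asarray(res.fe_params, dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # sqrt of a degenerate covariance
            se = np.asarray(res.bse_fe, dtype=float)
        loglik_ml = float(res_ml.llf)
        boundary = var_random <= 1e-8 * max(var_resid, 1e-300)
    else:
        res = sm.OLS(y, X).fit()
        var_random = 0.0
        var_resid = float(res.scale)
        coef = np.asarray(res.params, dtype=float)
        se = np.asarray(res.bse, dtype=float)
        loglik_ml = float(res.llf)
        boundary = False

    return ThermalResponseFit(
        population_id=population,
        variable=variable,
        coef=coef,
        se=se,
        var_random=var_random,
        var_resid=var_resid,
        n_individuals=n_indiv,
        n_obs=len(df),
        ta_center=center,
        ta_scale=scale,
        loglik_ml=loglik_ml,
        has_random=include_random,
        boundary=boundary,
        ta_range=(float(ta.min()), float(ta.max())),
    )


def lrt_random_effect(
    fit_full: ThermalResponseFit, fit_no_random: ThermalResponseFit
) -> tuple[float, float]:
    """Likelihood ratio test of the random intercept.

    Both fits must share the fixed structure and data.  The statistic is
    2 * (loglik_full - loglik_reduced) on the ML likelihoods, floored at
    zero; the p-value uses the 50:50 chi2_0 : chi2_1 boundary mixture,
    i.e. p = 0.5 * P(chi2_1 > stat) (and p = 1 at stat = 0).
    """
    if not fit_full.has_random or fit_no_random.has_random:
        raise StatsError("pass (mixed fit, fixed-only fit) in that order")
    same = (
        fit_full.variable == fit_no_random.variable
        and fit_full.n_obs == fit_no_random.n_obs
        and fit_full.population_id == fit_no_random.population_id
        and np.isclose(fit_full.ta_center, fit_no_random.ta_center)
        and np.isclose(fit_full.ta_scale, fit_no_random.ta_scale)
    )
    if not same:
        raise StatsError("fits are not on the same data/fixed structure")
    stat = max(0.0, 2.0 * (fit_full.loglik_ml - fit_no_random.loglik_ml))
    p = 1.0 if stat == 0.0 else 0.5 * float(stats.chi2.sf(stat, df=1))
    return stat, p


# ---------------------------------------------------------------------------
# Joint location comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectTest:
    statistic: float
    df: int
    pvalue: float
    kind: str = "wald_chi2"


@dataclass(frozen=True)
class Contrast:
    population_id: str
    estimate: float
    se: float
    zvalue: float
    pvalue: float


@dataclass
class ComparisonResult:
    """Joint-model tests and/or ANOVA + SNK output for one variable."""

    variable: str
    reference: str | None = None
    main_effect: EffectTest | None = None
    interaction: EffectTest | None = None
    lrt_random: tuple[float, float] | None = None
    contrasts: list[Contrast] = field(default_factory=list)
    group_means: dict | None = None
    anova_F: float | None = None
    anova_df: tuple[int, int] | None = None
    anova_p: float | None = None
    snk_letters: dict | None = None
    alpha: float = 0.05


def _wald_chi2(beta: np.ndarray, cov: np.ndarray, idx: Sequence[int]) -> EffectTest:
    idx = list(idx)
    b = beta[idx]
    V = cov[np.ix_(idx, idx)]
    stat = float(b @ np.linalg.solve(V, b))
    df = len(idx)
    return EffectTest(stat, df, float(stats.chi2.sf(stat, df)))


def compare_locations(
    records: pd.DataFrame,
    variable: str,
    reference_population: str,
) -> ComparisonResult:
    """Joint mixed model: population main effect and Ta x population interaction.

    The model is ``variable ~ population * (z + z^2)`` with a random
    intercept per individual, z the centred/scaled Ta (pooled coding).
    Wald chi-square tests use the large-sample normal reference; the
    per-population contrasts are the treatment-coded main-effect terms
    against ``reference_population``.  Also runs the random-intercept
    LRT on the joint model.
    """
    df = records.dropna(subset=[variable, "ta_C"]).copy()
    pops = sorted(df["population_id"].unique())
    if len(pops) < 2:
        raise StatsError("need >= 2 populations to compare locations")
    if reference_population not in pops:
        raise StatsError(f"reference population {reference_population!r} not in data")
    others = [p for p in pops if p != reference_population]

    ta = df["ta_C"].to_numpy(dtype=float)
    center, scale = _coding(ta)
    z = (ta - center) / scale
    y = df[variable].to_numpy(dtype=float)
    groups = df["animal_id"].to_numpy()

    cols: list[np.ndarray] = [np.ones(len(df)), z, z * z]
    names = ["intercept", "z", "z2"]
    main_idx: list[int] = []
    inter_idx: list[int] = []
    for p in others:
        d = (df["population_id"] == p).to_numpy(dtype=float)
        main_idx.append(len(cols))
        cols.append(d)
        names.append(f"pop[{p}]")
    for p in others:
        d = (df["population_id"] == p).to_numpy(dtype=float)
        inter_idx.extend([len(cols), len(cols) + 1])
        cols.extend([d * z, d * z * z])
        names.extend([f"pop[{p}]:z", f"pop[{p}]:z2"])
    X = np.column_stack(cols)

    model = sm.MixedLM(y, X, groups=groups)
    res = _fit_mixed(model, reml=True)
    res_ml = _fit_mixed(model, reml=False)
    beta = np.asarray(res.fe_params, dtype=float)
    k = X.shape[1]
    cov = np.asarray(res.cov_params())[:k, :k]

    ols = sm.OLS(y, X).fit()
    stat = max(0.0, 2.0 * (float(res_ml.llf) - float(ols.llf)))
    p_lrt = 1.0 if stat == 0.0 else 0.5 * float(stats.chi2.sf(stat, df=1))

    contrasts = [
        Contrast(
            population_id=p,
            estimate=float(beta[i]),
            se=float(np.sqrt(cov[i, i])),
            zvalue=float(beta[i] / np.sqrt(cov[i, i])),
            pvalue=float(2 * stats.norm.sf(abs(beta[i] / np.sqrt(cov[i, i])))),
        )
        for p, i in zip(others, main_idx)
    ]

    return ComparisonResult(
        variable=variable,
        reference=reference_population,
        main_effect=_wald_chi2(beta, cov, main_idx),
        interaction=_wald_chi2(beta, cov, inter_idx),
        lrt_random=(stat, p_lrt),
        contrasts=contrasts,
    )


# ---------------------------------------------------------------------------
# PRWE
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PRWEEstimate:
    """Ta at which the fitted RWE curve crosses 1."""

    prwe_C: float | None
    found: bool
    extrapolated: bool
    degenerate: bool
    population_id: str


def estimate_prwe(
    fit_or_records: "ThermalResponseFit | pd.DataFrame",
    population: str | None = None,
    margin_C: float = 5.0,
) -> PRWEEstimate:
    """Locate the point of relative water economy from a fitted RWE curve.

    Accepts either a :class:`ThermalResponseFit` of the ``rwe`` variable
    or a record table (which is then fitted).  Roots of RWE(Ta) = 1 are
    bracketed on a dense grid over the measured Ta range extended by
    ``margin_C`` on each side and polished by bisection (``brentq``);
    the root nearest the measured range wins.  If the fitted quadratic
    only crosses 1 outside the extended grid, its analytic root is
    reported with ``extrapolated=True``.  A curve identically equal to 1
    is flagged degenerate.
    """
    if isinstance(fit_or_records, pd.DataFrame):
        fit = fit_thermal_response(fit_or_records, "rwe", population)
    else:
        fit = fit_or_records
    lo = fit.ta_range[0] - margin_C
    hi = fit.ta_range[1] + margin_C

    grid = np.linspace(lo, hi, 2001)
    vals = np.asarray(fit.predict(grid)) - 1.0

    if np.max(np.abs(vals)) < 1e-9:
        return PRWEEstimate(None, False, False, True, fit.population_id)

    roots: list[float] = []
    sign = np.sign(vals)
    crossings = np.nonzero(np.diff(sign) != 0)[0]
    for i in crossings:
        root = optimize.brentq(lambda x: fit.predict(x) - 1.0, grid[i], grid[i + 1])
        roots.append(float(root))

    extrapolated = False
    if not roots:
        # analytic quadratic roots on the coded scale, beyond the grid
        c0, c1, c2 = fit.coef[0] - 1.0, fit.coef[1], fit.coef[2]
        if abs(c2) > 1e-12:
            disc = c1 * c1 - 4 * c2 * c0
            if disc < 0:
                return PRWEEstimate(None, False, False, False, fit.population_id)
            zr = np.array([(-c1 - np.sqrt(disc)) / (2 * c2), (-c1 + np.sqrt(disc)) / (2 * c2)])
        elif abs(c1) > 1e-12:
            zr = np.array([-c0 / c1])
        else:
            return PRWEEstimate(None, False, False, False, fit.population_id)
        roots = list(fit.ta_center + fit.ta_scale * zr)
        extrapolated = True

    ta_lo, ta_hi = fit.ta_range

    def dist(r: float) -> float:
        return 0.0 if ta_lo <= r <= ta_hi else min(abs(r - ta_lo), abs(r - ta_hi))

    best = min(roots, key=dist)
    if not (ta_lo - margin_C <= best <= ta_hi + margin_C):
        extrapolated = True
    return PRWEEstimate(best, True, extrapolated, False, fit.population_id)


# ---------------------------------------------------------------------------
# ANOVA + Student-Newman-Keuls
# ---------------------------------------------------------------------------

from functools import lru_cache


@lru_cache(maxsize=256)
def _q_crit(alpha: float, r: int, df_err: int) -> float:
    """Studentized-range quantile, memoised (scipy's ppf is expensive)."""
    return float(stats.studentized_range.ppf(1.0 - alpha, r, df_err))


def _snk_letters(
    means: np.ndarray, labels: list[str], n_h: float, mse: float, df_err: int, alpha: float
) -> dict[str, str]:
    """Stepwise SNK grouping -> compact letter display.

    Means are sorted ascending; the range over a span of r ordered means
    is significant when q = (max-min)/sqrt(MSE/n_h) exceeds the
    studentized-range quantile at (alpha, r, df_err).  Spans inside a
    non-significant span are not tested (the SNK stepdown rule); maximal
    non-significant spans become the letter groups.
    """
    order = np.argsort(means, kind="stable")
    m = means[order]
    k = len(m)
    sem = np.sqrt(mse / n_h)

    homogeneous: list[tuple[int, int]] = []

    def test_span(i: int, j: int) -> None:
        if i >= j:
            homogeneous.append((i, j))
            return
        r = j - i + 1
        q = (m[j] - m[i]) / sem
        qcrit = _q_crit(alpha, r, df_err)
        if q <= qcrit:
            homogeneous.append((i, j))
        else:
            test_span(i, j - 1)
            test_span(i + 1, j)

    test_span(0, k - 1)
    # keep maximal spans only
    spans = sorted(set(homogeneous))
    maximal = [
        s for s in spans if not any(o != s and o[0] <= s[0] and s[1] <= o[1] for o in spans)
    ]
    maximal.sort()
    letters = {lab: "" for lab in labels}
    for letter_i, (i, j) in enumerate(maximal):
        ch = chr(ord("a") + letter_i)
        for pos in range(i, j + 1):
            letters[labels[order[pos]]] += ch
    return letters


def anova_snk(
    records: pd.DataFrame,
    variable: str,
    alpha: float = 0.05,
    group_col: str = "population_id",
) -> ComparisonResult:
    """One-way ANOVA with Student-Newman-Keuls post-hoc letter grouping.

    Intended for standard values at thermoneutrality (one observation
    per individual).  Unbalanced designs use the harmonic mean of group
    sizes in the SNK standard error.
    """
    df = records.dropna(subset=[variable])
    groups = sorted(df[group_col].unique())
    if len(groups) < 2:
        raise StatsError("need >= 2 groups for ANOVA")
    samples = [df.loc[df[group_col] == g, variable].to_numpy(dtype=float) for g in groups]
    ns = np.array([len(s) for s in samples])
    if (ns < 2).any():
        raise StatsError("each group needs >= 2 observations")

    grand = np.concatenate(samples)
    n_total = len(grand)
    k = len(groups)
    means = np.array([s.mean() for s in samples])
    ss_within = sum(((s - s.mean()) ** 2).sum() for s in samples)
    df_err = n_total - k
    if ss_within <= 0:
        raise StatsError("zero within-group variance everywhere; ANOVA undefined")
    mse = ss_within / df_err
    ss_between = float((ns * (means - grand.mean()) ** 2).sum())
    F = (ss_between / (k - 1)) / mse
    p = float(stats.f.sf(F, k - 1, df_err))

    n_h = k / np.sum(1.0 / ns)  # harmonic mean group size
    letters = _snk_letters(means, list(groups), n_h, mse, df_err, alpha)

    return ComparisonResult(
        variable=variable,
        group_means={g: float(mu) for g, mu in zip(groups, means)},
        anova_F=float(F),
        anova_df=(k - 1, int(df_err)),
        anova_p=p,
        snk_letters=letters,
        alpha=alpha,
    )
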