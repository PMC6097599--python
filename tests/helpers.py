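"""Independent oracles used by several test modules."""

import math

import numpy as np


def brute_force_window(
    series,
    min_duration_s: float = 1200.0,
    cv_max: float = 0.10,
    slope_max_frac_per_h: float = 0.05,
):
    """Exhaustive steady-window search by plain per-window loops.

    Mirrors the documented policy — every (start, length) pair, CV and
    relative-slope bounds on VO2, windows containing negative samples
    excluded, minimal mean with earliest-start-then-longest ties, and a
    minimal-CV fallback flagged non-steady — but computes each window's
    statistics directly with numpy/polyfit rather than cumulative sums.
    Returns ``(start_index, length, steady)``.
    """
    x = series.vo2_ml_h
    t = series.time_s
    dt = series.sample_interval_s
    n = len(x)
    min_len = max(2, math.ceil(min_duration_s / dt))
    tie = 1e-9

    best = None  # (mean, start, length)
    best_cv = None  # (cv, start, length)
    for L in range(min_len, n + 1):
        for s in range(0, n - L + 1):
            w = x[s : s + L]
            if (w < 0).any():
                continue
            mean = w.mean()
            if mean <= 0:
                continue
            cv = w.std() / mean
            slope = np.polyfit(t[s : s + L], w, 1)[0]
            rel_slope = abs(slope) * 3600.0 / mean

            if cv <= cv_max and rel_slope <= slope_max_frac_per_h:
                if best is None:
                    best = (mean, s, L)
                else:
                    tol = tie * max(1.0, abs(best[0]), abs(mean))
                    if mean < best[0] - tol:
                        best = (mean, s, L)
                    elif abs(mean - best[0]) <= tol and (
                        s < best[1] or (s == best[1] and L > best[2])
                    ):
                        best = (mean, s, L)

            if np.isfinite(cv):
                if best_cv is None:
                    best_cv = (cv, s, L)
                else:
                    tol = tie * max(1.0, abs(best_cv[0]), abs(cv))
                    if cv < best_cv[0] - tol:
                        best_cv = (cv, s, L)
                    elif abs(cv - best_cv[0]) <= tol and (
                        s < best_cv[1] or (s == best_cv[1] and L > best_cv[2])
                    ):
                        best_cv = (cv, s, L)

    if best is not None:
        return best[1], best[2], True
    if best_cv is not None:
        return best_cv[1], best_cv[2], False
    return 0, n, False


def random_vo2_series(rng, n=None):
    """Random rate series with plateaus, trends and occasional negatives."""
    from endophys.gas_exchange import GasExchangeSeries

    if n is None:
        n = int(rng.integers(60, 141))
    dt = 15.0
    t = np.arange(n) * dt
    level = rng.uniform(300.0, 900.0)
    x = np.full(n, level)
    # random plateau at a lower level
    if rng.random() < 0.7:
        a = int(rng.integers(0, n - 20))
        b = int(rng.integers(a + 15, n))
        x[a:b] = level * rng.uniform(0.6, 0.95)
    if rng.random() < 0.5:
        x = x + rng.uniform(-30, 30) * (t / t[-1])  # slow trend
    x = x + rng.normal(0.0, level * rng.uniform(0.005, 0.08), n)
    if rng.random() < 0.2:
        k = int(rng.integers(0, n))
        x[k] = -abs(x[k])  # analyser glitch below zero
    return GasExchangeSeries(
        time_s=t,
        vo2_ml_h=x,
        vco2_ml_h=0.85 * x,
        ewl_mg_h=np.abs(x),
        t_probe_C=np.full(n, 25.0),
        sample_interval_s=dt,
    )
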