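"""Inference stages for growth-heterogeneity readouts.

Covers the measurement side of the growth-arrest analysis: flow-cytometry
gating and distribution moments, log-linear growth-rate extraction from OD
curves, the uniform vs heterogeneous mean-fluorescence models of a
constitutive reporter (with arrest parameters p_arr and s), AIC comparison of
linear vs quadratic dose-response fits, biexponential (biphasic) kill-curve
fits with a persister fraction, and paired log10 survival ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares, minimize

__all__ = [
    "FlowSample",
    "FluorescenceModel",
    "KillCurve",
    "gate_events",
    "distribution_moments",
    "fit_growth_rate",
    "predict_mean_fluorescence",
    "fit_arrest_parameters",
    "compare_polynomial_models",
    "aic_ols",
    "fit_biphasic_kill",
    "survival_ratio_stats",
]


class EmptyGateError(ValueError):
    """All events were removed by gating."""


@dataclass
class FlowSample:
    """Per-event fluorescence and scatter values with sample metadata."""

    events: pd.DataFrame  # columns: fl, fsc, ssc
    condition: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        missing = {"fl", "fsc", "ssc"} - set(self.events.columns)
        if missing:
            raise ValueError(f"missing event columns: {sorted(missing)}")
        vals = self.events[["fl", "fsc", "ssc"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("event values must be finite")
        if np.any(self.events["fl"].to_numpy() <= 0):
            raise ValueError("fluorescence must be > 0")

    def __len__(self) -> int:
        return len(self.events)


@dataclass
class FluorescenceModel:
    """Reporter calibration F_cal(g) = a + b/g plus arrest parameters.

    A constitutively expressed reporter dilutes with growth, so its
    concentration falls with the growth rate; ``p_arr`` is the fluorescence
    of arrested cells and ``s`` the switching rate into arrest (1/h).
    """

    a: float = 0.0
    b: float = 1.0
    p_arr: float = 0.0
    s: float = 0.0

    def __post_init__(self) -> None:
        if self.a < 0 or self.b <= 0 or self.p_arr < 0 or self.s < 0:
            raise ValueError("require a >= 0, b > 0, p_arr >= 0, s >= 0")

    def calibration(self, growth_rate):
        return self.a + self.b / np.asarray(growth_rate, dtype=float)


@dataclass
class KillCurve:
    """CFU/ml time course under bactericidal treatment, with detection limit."""

    time: np.ndarray  # hours
    cfu: np.ndarray  # CFU/ml, detection limit substituted where censored
    detection_limit: float = 1.0
    censored: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.cfu = np.asarray(self.cfu, dtype=float)
        if self.censored is None:
            self.censored = self.cfu < self.detection_limit
        self.censored = np.asarray(self.censored, dtype=bool)
        if np.any(self.cfu < 0):
            raise ValueError("CFU must be nonnegative")


# ---------------------------------------------------------------------------
# gating and moments


def gate_events(
    sample: FlowSample,
    scatter_sd: float = 0.5,
    outlier_fold: float = 6.0,
    reference_mean: Optional[float] = None,
) -> FlowSample:
    """Scatter-gate then fluorescence-outlier-filter a flow sample.

    Step 1 keeps events within ``scatter_sd`` standard deviations of the mean
    forward and side scatter (linear coordinates).  Step 2 removes events
    whose fluorescence exceeds ``outlier_fold`` times ``reference_mean`` (the
    mean fluorescence of a low-dose reference condition; defaults to this
    sample's own mean).  With a fixed reference the operation is idempotent.
    """
    if scatter_sd <= 0:
        raise ValueError("scatter_sd must be > 0")
    ev = sample.events
    fsc = ev["fsc"].to_numpy(dtype=float)
    ssc = ev["ssc"].to_numpy(dtype=float)
    keep = (np.abs(fsc - fsc.mean()) <= scatter_sd * fsc.std()) & (
        np.abs(ssc - ssc.mean()) <= scatter_sd * ssc.std()
    )
    gated = ev.loc[keep]
    if reference_mean is None:
        reference_mean = float(gated["fl"].mean()) if len(gated) else float("nan")
    if not reference_mean > 0:
        raise ValueError("reference_mean must be > 0")
    gated = gated.loc[gated["fl"] <= outlier_fold * reference_mean]
    if len(gated) == 0:
        raise EmptyGateError("no events remain after gating")
    return FlowSample(
        gated.reset_index(drop=True), sample.condition, sample.replicate
    )


def distribution_moments(values) -> dict:
    """Mean, CV, skewness and excess kurtosis (population moments)."""
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 values")
    mean = x.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    sd = x.std()  # population SD
    return {
        "mean": float(mean),
        "cv": float(sd / mean),
        "skewness": float(stats.skew(x, bias=True)),
        "excess_kurtosis": float(stats.kurtosis(x, fisher=True, bias=True)),
    }


# ---------------------------------------------------------------------------
# growth rates from OD curves


class NoExponentialWindowError(ValueError):
    """No early-exponential window satisfying the selection rule was found."""


def fit_growth_rate(
    time,
    od,
    blank: float = 0.0,
    slope_tolerance: float = 0.2,
    min_points: int = 5,
    early_fraction: float = 0.1,
    window: Optional[slice] = None,
) -> dict:
    """Log-linear growth rate from the early-exponential phase of an OD curve.

    The default window is the longest contiguous run of points that (i) lie
    above twice the blank, (ii) lie in the early phase, below
    ``early_fraction`` of the maximum blank-corrected OD (excluding the
    approach to saturation), and (iii) have a local log-slope within the
    ``slope_tolerance`` band below the maximum local slope (slopes are
    estimated on a lightly smoothed log curve so measurement noise does not
    fragment the window).  Returns the OLS slope of ln(OD - blank) vs time
    and its R^2.
    """
    time = np.asarray(time, dtype=float)
    od = np.asarray(od, dtype=float)
    net = od - blank
    if window is None:
        valid = (od > 2.0 * blank) & (net > 0)
        if valid.any():
            valid &= net <= early_fraction * net[valid].max() + 1e-300
        if valid.sum() < min_points:
            raise NoExponentialWindowError(
                "too few points above blank in the early phase"
            )
        logod = np.where(net > 0, np.log(np.where(net > 0, net, 1.0)), np.nan)
        n = len(time)
        L = int(np.clip(n // 8, 5, 51)) | 1  # odd boxcar length
        kernel = np.ones(L) / L

        def boxcar(x):
            return np.convolve(np.pad(x, L // 2, mode="edge"), kernel, mode="valid")

        # smooth the curve and the slopes: local slope noise must stay well
        # below the stability band or the window fragments
        slopes = boxcar(np.gradient(boxcar(logod), time))
        ok = valid & np.isfinite(slopes) & (slopes > 0)
        if not ok.any():
            raise NoExponentialWindowError("no positive log-slope region found")
        # robust reference slope: a high quantile, not the noisy maximum
        ref_slope = np.percentile(slopes[ok], 75)
        ok &= slopes >= (1.0 - 0.5 * slope_tolerance) * ref_slope
        window = _longest_true_run(ok)
        if window is None or window.stop - window.start < min_points:
            raise NoExponentialWindowError(
                "no exponential window with a stable positive log-slope"
            )
    t_w = time[window]
    y_w = np.log(net[window])
    if t_w.size < min_points or not np.all(np.isfinite(y_w)):
        raise NoExponentialWindowError("selected window has too few points")
    res = stats.linregress(t_w, y_w)
    return {
        "rate": float(res.slope),
        "intercept": float(res.intercept),
        "r_squared": float(res.rvalue**2),
        "window": window,
        "n_points": int(t_w.size),
    }


def _longest_true_run(mask):
    """Longest contiguous run of True; returns a slice or None."""
    best = None
    i = 0
    n = len(mask)
    while i < n:
        if not mask[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and mask[j + 1]:
            j += 1
        if best is None or (j - i) > (best.stop - best.start - 1):
            best = slice(i, j + 1)
        i = j + 1
    return best


# ---------------------------------------------------------------------------
# uniform vs heterogeneous fluorescence models


def predict_mean_fluorescence(
    growth_rate, model: FluorescenceModel, mode: str = "uniform"
):
    """Mean reporter fluorescence for a measured population growth rate.

    uniform: every cell grows at the population rate, F = F_cal(g_pop).
    heterogeneous: growing cells grow at g_grow = g_pop + s so that the net
    population rate is g_pop; a fraction phi = s/g_grow is arrested and
    fluoresces at p_arr: F = (1-phi) F_cal(g_grow) + phi p_arr.
    """
    g = np.asarray(growth_rate, dtype=float)
    if np.any(g <= 0):
        raise ValueError("growth_rate must be > 0")
    if mode == "uniform":
        out = model.calibration(g)
    elif mode == "heterogeneous":
        g_grow = g + model.s
        phi = model.s / g_grow
        out = (1.0 - phi) * model.calibration(g_grow) + phi * model.p_arr
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out if out.ndim else float(out)


class NonIdentifiableError(RuntimeError):
    """The sum-of-squares surface is flat; (p_arr, s) are not identifiable."""


def fit_arrest_parameters(
    growth_rates,
    mean_fluorescence,
    calibration: FluorescenceModel,
    p_arr_grid=None,
    s_grid=None,
) -> dict:
    """Fit (p_arr, s) of the heterogeneous growth model by least squares.

    Grid search over the (p_arr, s) plane followed by local refinement.
    Returns the best parameters, the full sum-of-squares surface, and the
    Pearson correlation between predicted and observed fluorescence for both
    the uniform and heterogeneous modes.
    """
    g = np.asarray(growth_rates, dtype=float)
    f_obs = np.asarray(mean_fluorescence, dtype=float)
    if g.size < 3:
        raise ValueError("need at least 3 conditions")
    if p_arr_grid is None:
        p_arr_grid = np.linspace(0.0, 2.0 * f_obs.max(), 60)
    if s_grid is None:
        s_grid = np.linspace(0.0, 5.0 * g.max(), 60)
    p_arr_grid = np.asarray(p_arr_grid, dtype=float)
    s_grid = np.asarray(s_grid, dtype=float)

    def ss(p_arr, s):
        m = FluorescenceModel(calibration.a, calibration.b, p_arr, s)
        pred = predict_mean_fluorescence(g, m, "heterogeneous")
        return float(np.sum((f_obs - pred) ** 2))

    surface = np.array([[ss(p, s) for s in s_grid] for p in p_arr_grid])
    if np.ptp(surface) <= 1e-12 * max(surface.max(), 1.0):
        raise NonIdentifiableError("sum-of-squares surface is flat")
    i, j = np.unravel_index(np.argmin(surface), surface.shape)
    x0 = np.array([p_arr_grid[i], s_grid[j]])
    res = minimize(
        lambda x: ss(max(x[0], 0.0), max(x[1], 0.0)),
        x0,
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-14},
    )
    p_arr, s = np.maximum(res.x, 0.0)

    best = FluorescenceModel(calibration.a, calibration.b, p_arr, s)
    pred_het = predict_mean_fluorescence(g, best, "heterogeneous")
    pred_uni = predict_mean_fluorescence(g, calibration, "uniform")

    def safe_corr(a, b):
        if np.std(a) == 0 or np.std(b) == 0:
            return float("nan")
        return float(np.corrcoef(a, b)[0, 1])

    return {
        "p_arr": float(p_arr),
        "s": float(s),
        "sum_of_squares": float(res.fun),
        "ss_surface": surface,
        "p_arr_grid": p_arr_grid,
        "s_grid": s_grid,
        "corr_heterogeneous": safe_corr(pred_het, f_obs),
        "corr_uniform": safe_corr(pred_uni, f_obs),
        "ss_uniform": float(np.sum((f_obs - pred_uni) ** 2)),
    }


# ---------------------------------------------------------------------------
# AIC model comparison


def aic_ols(x, y, degree: int) -> float:
    """AIC of a polynomial OLS fit under the Gaussian-likelihood convention.

    AIC = n ln(2 pi RSS / n) + n + 2 (k + 1) with k regression coefficients;
    the +1 counts the error variance, matching R's AIC for lm() fits.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    coeffs = np.polyfit(x, y, degree)
    rss = float(np.sum((y - np.polyval(coeffs, x)) ** 2))
    rss = max(rss, 1e-300)
    k = degree + 1
    return n * np.log(2.0 * np.pi * rss / n) + n + 2.0 * (k + 1)


def compare_polynomial_models(dose, response) -> dict:
    """AIC comparison of linear vs quadratic dose-response models."""
    dose = np.asarray(dose, dtype=float)
    response = np.asarray(response, dtype=float)
    if response.size <= 4:
        raise ValueError("need more than 4 points")
    if np.ptp(dose) == 0:
        raise np.linalg.LinAlgError("collinear design: dose has no variation")
    aic_lin = aic_ols(dose, response, 1)
    aic_quad = aic_ols(dose, response, 2)
    return {
        "aic_linear": float(aic_lin),
        "aic_quadratic": float(aic_quad),
        "preferred": "quadratic" if aic_quad < aic_lin else "linear",
    }


# ---------------------------------------------------------------------------
# kill curves and survival ratios


class KillFitError(RuntimeError):
    pass


def fit_biphasic_kill(curve: KillCurve) -> dict:
    """Biexponential kill-curve fit with persister fraction.

    Fits N(t) = N0 [(1-f) e^{-k1 t} + f e^{-k2 t}] with k1 > k2 >= 0 by least
    squares on log10 CFU.  Censored points enter at the detection limit and
    are flagged.  Degenerate fits (f ~ 0 or k1 ~ k2) are flagged non-biphasic.
    """
    t = curve.time
    y = np.maximum(curve.cfu, curve.detection_limit)
    if np.count_nonzero(~curve.censored) < 5:
        raise ValueError("need at least 5 uncensored points")
    logy = np.log10(y)

    def model_log10(params):
        log_n0, log_k1, log_k2, logit_f = params
        k1 = np.exp(log_k1)
        k2 = np.exp(log_k2)
        f = 1.0 / (1.0 + np.exp(-logit_f))
        n = 10.0**log_n0 * ((1 - f) * np.exp(-k1 * t) + f * np.exp(-k2 * t))
        return np.log10(np.maximum(n, 1e-300))

    # initial guesses: fast slope from the head, slow slope from the tail
    n0_guess = max(y[0], curve.detection_limit)
    k1_guess = max((logy[0] - logy[min(2, len(t) - 1)]) * np.log(10)
                   / max(t[min(2, len(t) - 1)] - t[0], 1e-6), 1e-3)
    tail = slice(max(len(t) - 3, 0), len(t))
    k2_guess = max(
        (logy[tail][0] - logy[tail][-1]) * np.log(10)
        / max(t[tail][-1] - t[tail][0], 1e-6),
        1e-6,
    )
    f_guess = np.clip(10.0 ** (logy[-1] + k2_guess * t[-1] / np.log(10) - logy[0]), 1e-8, 0.5)

    best = None
    for f0 in (f_guess, 1e-3, 1e-5):
        x0 = [np.log10(n0_guess), np.log(k1_guess), np.log(max(k2_guess, 1e-6)),
              np.log(f0 / (1 - f0))]
        try:
            res = least_squares(
                lambda p: model_log10(p) - logy, x0, method="lm", max_nfev=20000
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise KillFitError("biexponential fit failed to converge")

    log_n0, log_k1, log_k2, logit_f = best.x
    k1, k2 = np.exp(log_k1), np.exp(log_k2)
    f = 1.0 / (1.0 + np.exp(-logit_f))
    if k2 > k1:  # enforce k1 > k2 by swapping branches
        k1, k2 = k2, k1
        f = 1.0 - f
    non_biphasic = bool(f < 1e-8 or k1 / max(k2, 1e-300) < 1.5)
    return {
        "n0": float(10.0**log_n0),
        "k_fast": float(k1),
        "k_slow": float(k2),
        "persister_fraction": float(f),
        "breakpoint": float(np.log(max(k1, 1e-300) / max(k2, 1e-300))
                            / max(k1 - k2, 1e-300)) if k1 > k2 else float("nan"),
        "rss_log10": float(2 * best.cost),
        "non_biphasic": non_biphasic,
        "n_censored": int(curve.censored.sum()),
    }


def survival_ratio_stats(
    treated: Sequence[float],
    untreated: Sequence[float],
    detection_limit: float = 1.0,
) -> dict:
    """Per-replicate log10 survival ratios log10(x_i / y_i), mean and SEM.

    Treated and untreated replicates are matched by position; zero treated
    counts are substituted with the detection limit and flagged as censored.
    """
    x = np.asarray(treated, dtype=float)
    y = np.asarray(untreated, dtype=float)
    if x.shape != y.shape:
        raise ValueError("treated/untreated replicates are unmatched")
    if np.any(y <= 0):
        raise ValueError("untreated counts must be > 0")
    censored = x <= 0
    x = np.where(censored, detection_limit, x)
    ratios = np.log10(x / y)
    n = ratios.size
    sem = float(ratios.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return {
        "ratios": ratios,
        "mean": float(ratios.mean()),
        "sem": sem,
        "censored": censored,
    }
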