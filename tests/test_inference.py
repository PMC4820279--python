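"""Gating, moments, growth rates, fluorescence models, AIC, kill curves."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from satgrowth.inference import (
    EmptyGateError,
    FlowSample,
    FluorescenceModel,
    KillCurve,
    NoExponentialWindowError,
    aic_ols,
    compare_polynomial_models,
    distribution_moments,
    fit_arrest_parameters,
    fit_biphasic_kill,
    fit_growth_rate,
    gate_events,
    predict_mean_fluorescence,
    survival_ratio_stats,
)
from satgrowth.synth import (
    DoseResponseConfig,
    FluorPairsConfig,
    KillConfig,
    ODConfig,
    gen_dose_response,
    gen_fluorescence_pairs,
    gen_kill_curve,
    gen_od_curves,
)


# ---------------------------------------------------------------------------
# gating


def _sample(fl, fsc, ssc):
    return FlowSample(pd.DataFrame({"fl": fl, "fsc": fsc, "ssc": ssc}))


def test_gate_keeps_events_at_scatter_mean():
    rng = np.random.default_rng(0)
    n = 500
    fl = rng.lognormal(4, 0.3, n)
    sample = _sample(fl, np.full(n, 100.0), np.full(n, 80.0))
    gated = gate_events(sample, reference_mean=float(fl.mean()))
    assert len(gated) == n  # zero scatter spread: nothing removed


def test_gate_removes_planted_fluorescence_outliers():
    rng = np.random.default_rng(1)
    n = 1000
    ref = 50.0
    fl = rng.uniform(10, 100, n)
    fl[:10] = 6.0 * ref * 10  # planted >6-fold outliers
    sample = _sample(fl, np.full(n, 100.0), np.full(n, 80.0))
    gated = gate_events(sample, reference_mean=ref)
    assert len(gated) == n - 10


def test_gate_scatter_step_removes_extreme_event():
    n = 200
    fsc = np.full(n, 100.0) + np.random.default_rng(2).normal(0, 1, n)
    fsc[7] = 1e4
    sample = _sample(np.full(n, 30.0), fsc, np.full(n, 80.0))
    gated = gate_events(sample, scatter_sd=0.5, reference_mean=30.0)
    assert len(gated) < n


def test_gate_is_idempotent_with_fixed_reference():
    rng = np.random.default_rng(3)
    n = 2000
    sample = _sample(
        rng.lognormal(4, 0.5, n), rng.normal(100, 10, n), rng.normal(80, 8, n)
    )
    once = gate_events(sample, reference_mean=60.0)
    twice = gate_events(once, reference_mean=60.0)
    # the scatter gate recomputes its statistics on the surviving events, so
    # idempotency is checked on a scatter-tight sample where step 1 is a no-op
    tight = _sample(rng.lognormal(4, 0.5, n), np.full(n, 100.0), np.full(n, 80.0))
    g1 = gate_events(tight, reference_mean=60.0)
    g2 = gate_events(g1, reference_mean=60.0)
    pd.testing.assert_frame_equal(g1.events, g2.events)


def test_gate_empty_result_raises():
    sample = _sample([100.0] * 10, [100.0] * 10, [80.0] * 10)
    with pytest.raises(EmptyGateError):
        gate_events(sample, reference_mean=1.0)  # 6-fold filter removes all


# ---------------------------------------------------------------------------
# moments


def test_moments_of_gaussian_draws_are_symmetric():
    x = np.random.default_rng(4).normal(0.0, 1.0, 100_000) + 10.0
    m = distribution_moments(x)
    assert abs(m["skewness"]) < 0.05
    assert abs(m["excess_kurtosis"]) < 0.05


def test_moments_lognormal_right_skew():
    x = np.random.default_rng(5).lognormal(0.0, 0.5, 50_000)
    assert distribution_moments(x)["skewness"] > 0.5


def test_moments_constant_vector_has_zero_cv():
    assert distribution_moments([3.0, 3.0, 3.0, 3.0])["cv"] == 0.0


def test_moments_zero_mean_rejected():
    with pytest.raises(ValueError):
        distribution_moments([-1.0, 1.0, -1.0, 1.0])


# ---------------------------------------------------------------------------
# growth rates


def test_exact_exponential_recovered_to_machine_precision():
    t = np.linspace(0.0, 5.0, 120)
    fit = fit_growth_rate(t, 0.01 * np.exp(0.6 * t))
    assert fit["rate"] == pytest.approx(0.6, abs=1e-12)
    assert fit["r_squared"] == pytest.approx(1.0)


def test_noisy_exponential_recovered_within_tolerance():
    t = np.linspace(0.0, 5.0, 150)
    rng = np.random.default_rng(6)
    od = 0.01 * np.exp(0.6 * t) * np.exp(rng.normal(0, 0.01, t.size))
    fit = fit_growth_rate(t, od)
    assert fit["rate"] == pytest.approx(0.6, abs=0.02)


def test_logistic_window_excludes_plateau():
    df = gen_od_curves(ODConfig(noise_cv=0.0), seed=0)
    one = df[df["replicate"] == 0]
    fit = fit_growth_rate(
        one["time"].to_numpy(), one["od"].to_numpy(), blank=0.005
    )
    assert fit["rate"] == pytest.approx(0.6, rel=0.05)


def test_flat_curve_has_no_window():
    t = np.linspace(0, 10, 60)
    with pytest.raises(NoExponentialWindowError):
        fit_growth_rate(t, np.full_like(t, 0.08), blank=0.04)


# ---------------------------------------------------------------------------
# fluorescence models


def test_heterogeneous_reduces_to_uniform_without_switching():
    m = FluorescenceModel(a=50.0, b=400.0, p_arr=900.0, s=0.0)
    g = np.array([0.4, 0.8, 1.2])
    np.testing.assert_allclose(
        predict_mean_fluorescence(g, m, "heterogeneous"),
        predict_mean_fluorescence(g, m, "uniform"),
    )


def test_heavy_switching_pins_fluorescence_at_arrested_level():
    m = FluorescenceModel(a=10.0, b=100.0, p_arr=5000.0, s=500.0)
    f = predict_mean_fluorescence(1.0, m, "heterogeneous")
    assert f == pytest.approx(5000.0, rel=0.01)


def test_arrest_parameter_recovery_roundtrip():
    cal = FluorescenceModel(a=50.0, b=400.0)
    df = gen_fluorescence_pairs(FluorPairsConfig(), seed=11)
    truth = df.attrs["truth"]
    fit = fit_arrest_parameters(df["growth_rate"], df["fluorescence"], cal)
    assert fit["p_arr"] == pytest.approx(truth["p_arr"], rel=0.10)
    assert fit["s"] == pytest.approx(truth["s"], rel=0.10)
    assert fit["corr_heterogeneous"] > fit["corr_uniform"]


def test_uniform_data_yields_negligible_switching():
    cal = FluorescenceModel(a=50.0, b=400.0)
    g = np.linspace(0.3, 1.2, 8)
    f = predict_mean_fluorescence(g, cal, "uniform")
    fit = fit_arrest_parameters(g, f, cal)
    assert fit["s"] < 0.02
    assert fit["sum_of_squares"] <= fit["ss_uniform"] + 1e-12


def test_heterogeneous_model_nests_uniform():
    """The optimal heterogeneous SS never exceeds the uniform-model SS."""
    cal = FluorescenceModel(a=20.0, b=300.0)
    rng = np.random.default_rng(7)
    g = np.linspace(0.2, 1.5, 9)
    f = predict_mean_fluorescence(g, cal, "uniform") * (1 + rng.normal(0, 0.1, 9))
    fit = fit_arrest_parameters(g, f, cal)
    assert fit["sum_of_squares"] <= fit["ss_uniform"] + 1e-9


# ---------------------------------------------------------------------------
# AIC comparison


def test_exact_quadratic_prefers_quadratic():
    x = np.linspace(0, 10, 20)
    y = 1.0 + 0.5 * x - 0.08 * x**2
    res = compare_polynomial_models(x, y)
    assert res["preferred"] == "quadratic"
    assert res["aic_quadratic"] < res["aic_linear"] - 100


def test_pure_line_prefers_linear_on_average():
    wins = 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        x = np.linspace(0, 10, 30)
        y = 1.0 + 0.3 * x + rng.normal(0, 0.1, 30)
        if compare_polynomial_models(x, y)["preferred"] == "linear":
            wins += 1
    assert wins > 50


def test_quadratic_truth_with_noise_prefers_quadratic():
    wins = 0
    for seed in range(50):
        df = gen_dose_response(DoseResponseConfig(), seed=seed)
        if compare_polynomial_models(df["dose"], df["rate"])["preferred"] == "quadratic":
            wins += 1
    assert wins >= 48


def test_collinear_design_rejected():
    with pytest.raises(np.linalg.LinAlgError):
        compare_polynomial_models([2.0] * 6, [1, 2, 3, 4, 5, 6])


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
def test_aic_convention_matches_r_lm():
    """The Gaussian AIC convention must reproduce R's AIC for lm() fits."""
    rng = np.random.default_rng(8)
    x = np.linspace(0, 10, 25)
    y = 0.3 + 0.04 * x - 0.003 * x**2 + rng.normal(0, 0.02, 25)
    script = (
        "x <- c(" + ",".join(f"{float(v)!r}" for v in x) + ")\n"
        "y <- c(" + ",".join(f"{float(v)!r}" for v in y) + ")\n"
        "cat(sprintf('%.9f', c(AIC(lm(y ~ x)), AIC(lm(y ~ x + I(x^2))))), sep='\\n')\n"
    )
    out = subprocess.run(
        ["Rscript", "-e", script], capture_output=True, text=True, check=True
    )
    r_lin, r_quad = (float(v) for v in out.stdout.split())
    assert aic_ols(x, y, 1) == pytest.approx(r_lin, abs=1e-6)
    assert aic_ols(x, y, 2) == pytest.approx(r_quad, abs=1e-6)


# ---------------------------------------------------------------------------
# kill curves and survival ratios


def test_single_exponential_flagged_non_biphasic():
    t = np.linspace(0, 24, 12)
    curve = KillCurve(t, 1e8 * np.exp(-0.8 * t), detection_limit=1e-3)
    fit = fit_biphasic_kill(curve)
    assert fit["non_biphasic"] or fit["persister_fraction"] < 1e-6


def test_biphasic_parameters_recovered():
    curve = gen_kill_curve(KillConfig(), seed=3)
    truth = curve.truth
    fit = fit_biphasic_kill(curve)
    assert fit["k_fast"] == pytest.approx(truth["k_fast"], rel=0.25)
    assert fit["k_slow"] == pytest.approx(truth["k_slow"], rel=0.25)
    assert fit["persister_fraction"] == pytest.approx(
        truth["persister_fraction"], rel=0.25
    )


def test_persister_fraction_orders_slow_phase():
    """Larger true persister fractions raise the fitted slow-phase level."""
    fits = [
        fit_biphasic_kill(gen_kill_curve(KillConfig(persister_fraction=f), seed=9))
        for f in (1e-4, 1e-3, 1e-2)
    ]
    fracs = [f["persister_fraction"] for f in fits]
    assert fracs[0] < fracs[1] < fracs[2]


def test_censored_points_are_flagged():
    cfg = KillConfig(detection_limit=1e6)
    curve = gen_kill_curve(cfg, seed=1)
    assert curve.censored.sum() > 0
    assert np.all(curve.cfu[curve.censored] == cfg.detection_limit)


def test_survival_ratio_identity_and_arithmetic():
    res = survival_ratio_stats([10.0, 100.0], [1000.0, 1000.0])
    np.testing.assert_allclose(res["ratios"], [-2.0, -1.0])
    assert res["mean"] == pytest.approx(-1.5)


def test_survival_ratio_sem_matches_closed_form():
    x, y = np.array([10.0, 20.0, 40.0]), np.array([100.0, 100.0, 100.0])
    res = survival_ratio_stats(x, y)
    ratios = np.log10(x / y)
    assert res["sem"] == pytest.approx(ratios.std(ddof=1) / np.sqrt(3))


def test_survival_ratio_zero_treated_censored():
    res = survival_ratio_stats([0.0, 10.0], [100.0, 100.0], detection_limit=1.0)
    assert res["censored"][0] and not res["censored"][1]
    assert res["ratios"][0] == pytest.approx(-2.0)


def test_survival_ratio_unmatched_replicates_rejected():
    with pytest.raises(ValueError):
        survival_ratio_stats([1.0, 2.0], [1.0])
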