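"""Synthetic measurement generators with known ground truth.

Each generator emulates the statistical structure one inference stage
assumes — a two-subpopulation lognormal fluorescence mixture, logistic OD
curves with multiplicative noise, biphasic kill curves with a detection
limit, and replicate dose-response tables with quadratic mean structure —
and stores its ground truth beside the data so recovery can be tested.
All draws are deterministic under (seed, config).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inference import FlowSample, KillCurve

__all__ = [
    "FlowConfig",
    "ODConfig",
    "KillConfig",
    "DoseResponseConfig",
    "FluorPairsConfig",
    "SyntheticConfig",
    "gen_flow_sample",
    "gen_fluorescence_pairs",
    "gen_od_curves",
    "gen_kill_curve",
    "gen_dose_response",
]


@dataclass(frozen=True)
class FlowConfig:
    """Two-subpopulation fluorescence mixture: growing + arrested cells."""

    n_events: int = 20000
    arrest_fraction: float = 0.0  # phi
    mu: float = 4.0  # ln-scale location of growing cells
    sigma: float = 0.4  # ln-scale width (multiplicative noise)
    mu_arr: float = 6.0  # arrested cells are brighter
    sigma_arr: float = 0.4
    fsc_mean: float = 100.0
    fsc_sd: float = 10.0
    ssc_mean: float = 80.0
    ssc_sd: float = 8.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.arrest_fraction <= 1.0:
            raise ValueError("arrest_fraction must be in [0, 1]")
        if min(self.sigma, self.sigma_arr, self.fsc_sd, self.ssc_sd) <= 0:
            raise ValueError("all SDs must be > 0")


@dataclass(frozen=True)
class ODConfig:
    """Logistic growth curve sampled like a plate reader."""

    n0: float = 0.001  # initial OD above blank
    rate: float = 0.6  # exponential rate (1/h)
    capacity: float = 0.5  # carrying capacity (OD)
    blank: float = 0.005
    noise_cv: float = 0.01  # multiplicative noise
    t_end: float = 24.0  # hours
    dt: float = 1.0 / 30.0  # one reading every two minutes
    n_replicates: int = 3


@dataclass(frozen=True)
class KillConfig:
    """Biexponential killing with persisters and a detection limit."""

    n0: float = 1e8  # CFU/ml at treatment start
    k_fast: float = 1.0  # fast killing rate (1/h)
    k_slow: float = 0.05  # persister killing rate (1/h)
    persister_fraction: float = 1e-3
    noise_cv: float = 0.05  # lognormal counting noise
    detection_limit: float = 10.0
    times: tuple = (0.0, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 16.0, 20.0, 24.0)

    def __post_init__(self) -> None:
        if not self.k_fast > self.k_slow >= 0:
            raise ValueError("need k_fast > k_slow >= 0")
        if not 0.0 <= self.persister_fraction <= 1.0:
            raise ValueError("persister_fraction must be in [0, 1]")


@dataclass(frozen=True)
class DoseResponseConfig:
    """Replicate growth rates with quadratic mean structure over dose."""

    a: float = 0.3  # intercept
    b: float = 0.04  # linear coefficient
    c: float = -0.0008  # quadratic coefficient; < 0 for an interior maximum
    noise_sd: float = 0.01
    doses: tuple = (0.1, 0.5, 1.0, 2.5, 5.0, 10.0, 20.0, 30.0, 40.0, 50.0)
    n_replicates: int = 3


@dataclass(frozen=True)
class FluorPairsConfig:
    """(growth rate, mean fluorescence) pairs from the heterogeneous model.

    Ten conditions spanning the observed growth-rate range, three replicate
    measurements each, with multiplicative measurement noise on the mean
    fluorescence.
    """

    a: float = 50.0  # calibration intercept (AU)
    b: float = 400.0  # calibration scale (AU * h)
    p_arr: float = 1200.0  # fluorescence of arrested cells (AU)
    s: float = 0.3  # switching rate into arrest (1/h)
    g_min: float = 0.25  # slowest population growth rate (1/h)
    g_max: float = 1.4
    n_conditions: int = 10
    n_replicates: int = 3
    noise_cv: float = 0.02


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int = 0
    flow: FlowConfig = field(default_factory=FlowConfig)
    od: ODConfig = field(default_factory=ODConfig)
    kill: KillConfig = field(default_factory=KillConfig)
    dose: DoseResponseConfig = field(default_factory=DoseResponseConfig)


def gen_flow_sample(
    config: FlowConfig = FlowConfig(), seed: int = 0, condition: str = "synthetic"
) -> FlowSample:
    """Draw a mixture flow sample: arrested (bright) vs growing events."""
    rng = np.random.default_rng(seed)
    n = config.n_events
    arrested = rng.random(n) < config.arrest_fraction
    fl = np.where(
        arrested,
        rng.lognormal(config.mu_arr, config.sigma_arr, n),
        rng.lognormal(config.mu, config.sigma, n),
    )
    fsc = rng.normal(config.fsc_mean, config.fsc_sd, n)
    ssc = rng.normal(config.ssc_mean, config.ssc_sd, n)
    events = pd.DataFrame({"fl": fl, "fsc": fsc, "ssc": ssc})
    sample = FlowSample(events, condition=condition)
    sample.truth = {  # type: ignore[attr-defined]
        "arrest_fraction": config.arrest_fraction,
        "seed": seed,
        "n_arrested": int(arrested.sum()),
    }
    return sample


def gen_fluorescence_pairs(
    config: FluorPairsConfig = FluorPairsConfig(), seed: int = 0
) -> pd.DataFrame:
    """Growth-rate / mean-fluorescence pairs with heterogeneous-model truth.

    Columns: growth_rate, fluorescence, replicate; the generating
    FluorescenceModel parameters sit in ``df.attrs['truth']``.
    """
    from .inference import FluorescenceModel, predict_mean_fluorescence

    rng = np.random.default_rng(seed)
    g = np.linspace(config.g_min, config.g_max, config.n_conditions)
    model = FluorescenceModel(config.a, config.b, config.p_arr, config.s)
    rows = []
    for rep in range(config.n_replicates):
        f = predict_mean_fluorescence(g, model, "heterogeneous")
        f = f * (1.0 + rng.normal(0.0, config.noise_cv, g.size))
        rows.append(
            pd.DataFrame({"growth_rate": g, "fluorescence": f, "replicate": rep})
        )
    df = pd.concat(rows, ignore_index=True)
    df.attrs["truth"] = {
        "a": config.a, "b": config.b, "p_arr": config.p_arr, "s": config.s,
        "seed": seed,
    }
    return df


def gen_od_curves(config: ODConfig = ODConfig(), seed: int = 0) -> pd.DataFrame:
    """Logistic OD time series per replicate, with the true rate attached.

    Columns: time, od, replicate; ``df.attrs['truth']`` holds the ground
    truth (rate, blank).  Replicates share the deterministic curve and differ
    only through sub-seeded multiplicative noise.
    """
    t = np.arange(0.0, config.t_end + 1e-9, config.dt)
    k, n0, r = config.capacity, config.n0, config.rate
    logistic = k * n0 * np.exp(r * t) / (k + n0 * (np.exp(r * t) - 1.0))
    frames = []
    for rep in range(config.n_replicates):
        rng = np.random.default_rng((seed, rep))
        noise = rng.normal(0.0, config.noise_cv, t.size) if config.noise_cv > 0 else 0.0
        od = config.blank + logistic * np.exp(noise)
        frames.append(pd.DataFrame({"time": t, "od": od, "replicate": rep}))
    df = pd.concat(frames, ignore_index=True)
    df.attrs["truth"] = {"rate": r, "blank": config.blank, "seed": seed}
    return df


def gen_kill_curve(config: KillConfig = KillConfig(), seed: int = 0) -> KillCurve:
    """Sample a biphasic kill curve; values below detection are censored."""
    rng = np.random.default_rng(seed)
    t = np.asarray(config.times, dtype=float)
    f = config.persister_fraction
    mean = config.n0 * (
        (1.0 - f) * np.exp(-config.k_fast * t) + f * np.exp(-config.k_slow * t)
    )
    noise = rng.normal(0.0, config.noise_cv, t.size) if config.noise_cv > 0 else 0.0
    cfu = mean * np.exp(noise)
    censored = cfu < config.detection_limit
    cfu = np.where(censored, config.detection_limit, cfu)
    curve = KillCurve(t, cfu, config.detection_limit, censored)
    curve.truth = {  # type: ignore[attr-defined]
        "n0": config.n0,
        "k_fast": config.k_fast,
        "k_slow": config.k_slow,
        "persister_fraction": f,
        "seed": seed,
    }
    return curve


def gen_dose_response(
    config: DoseResponseConfig = DoseResponseConfig(), seed: int = 0
) -> pd.DataFrame:
    """Replicate dose-response table y = a + b x + c x^2 + noise.

    Columns: dose, rate, replicate; ground truth in ``df.attrs['truth']``.
    """
    rng = np.random.default_rng(seed)
    doses = np.asarray(config.doses, dtype=float)
    rows = []
    for rep in range(config.n_replicates):
        mean = config.a + config.b * doses + config.c * doses**2
        eps = rng.normal(0.0, config.noise_sd, doses.size)
        rows.append(
            pd.DataFrame({"dose": doses, "rate": mean + eps, "replicate": rep})
        )
    df = pd.concat(rows, ignore_index=True)
    truth = {"a": config.a, "b": config.b, "c": config.c, "seed": seed}
    if config.c < 0:
        truth["argmax"] = -config.b / (2.0 * config.c)
    df.attrs["truth"] = truth
    return df
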