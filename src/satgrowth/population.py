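"""Metastable population models of growth arrest.

Two levels of description:

* a two-compartment model in which a growing subpopulation (rate ``g``)
  irreversibly switches into a non-growing arrested state at rate ``s``; the
  population grows at lambda = g - s and, for g > s, a constant fraction s/g
  of the population is arrested at long times;
* a four-state framework (balanced growth, shifted growth, arrested, dead)
  whose transition timescales tau1, tau-1, tau2, tau-2, tau3 interpolate
  between classical balanced growth and the metastable limit.

The switching rate itself follows the probability that the noisy
production/consumption flux ratio x = V+/V- exceeds the saturation point
x = 1: s = s_max * Phi((x - 1) / sigma_x).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.stats import norm

from .meanfield import BenefitForm, benefit_factor

__all__ = [
    "SwitchingModelParams",
    "TimescaleParams",
    "switching_rate",
    "metastable_growth_rate",
    "framework_growth_rate",
    "fitness_surface",
]


@dataclass(frozen=True)
class SwitchingModelParams:
    """Two-compartment model rates; time unit is hours."""

    g: float = 1.0  # growth rate of the growing subpopulation (1/h)
    s_max: float = 2.0  # maximal switching rate into arrest (1/h)
    sigma_x: float = 0.1  # noise width of the flux-ratio distribution
    x: float = 0.5  # ratio of mean fluxes V+/V-
    delta: float = 0.5  # demand, used by the fitness surface

    def __post_init__(self) -> None:
        if self.g < 0 or self.s_max < 0 or self.x < 0:
            raise ValueError("rates and flux ratio must be nonnegative")
        if self.sigma_x <= 0:
            raise ValueError("sigma_x must be > 0")
        if self.delta <= 0:
            raise ValueError("delta must be > 0")


@dataclass(frozen=True)
class TimescaleParams:
    """Characteristic switching timescales of the four-state framework (h)."""

    tau1: float = 10.0  # balanced -> shifted
    tau_m1: float = 1.0  # shifted -> balanced
    tau2: float = 5.0  # shifted -> arrested
    tau_m2: float = 50.0  # arrested -> balanced (resumption)
    tau3: float = 100.0  # arrested -> dead
    g: float = 1.0  # balanced growth rate (1/h)
    g_hat: float = 0.5  # growth rate in the shifted state (1/h)

    def __post_init__(self) -> None:
        for name in ("tau1", "tau_m1", "tau2", "tau_m2", "tau3"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0 (use np.inf for no switching)")


def switching_rate(params: SwitchingModelParams) -> float:
    """Noise-driven switching rate s = s_max * Phi((x - 1)/sigma_x).

    The Gaussian CDF gives the probability mass of flux-ratio fluctuations
    beyond the saturation point x = 1 where the consuming enzyme can no
    longer keep up; s rises from ~0 far below threshold to s_max far above.
    """
    return float(params.s_max * norm.cdf((params.x - 1.0) / params.sigma_x))


def metastable_growth_rate(
    params: SwitchingModelParams,
    horizon: float | None = None,
    s: float | None = None,
) -> dict:
    """Asymptotic population growth rate and arrested fraction.

    Closed form of the linear two-compartment model
    ``Ng' = (g - s) Ng, Na' = s Ng``: lambda = g - s and, for g > s, the
    arrested fraction tends to s/g.  When ``horizon`` is given the system is
    also integrated numerically and the closed form is cross-checked.
    """
    g = params.g
    if s is None:
        s = switching_rate(params)
    lam = g - s
    arrested = s / g if g > s else 1.0
    out = {"lambda": lam, "arrested_fraction": arrested, "s": s}
    if horizon is not None:
        sol = solve_ivp(
            lambda t, y: [(g - s) * y[0], s * y[0]],
            (0.0, horizon),
            [1.0, 0.0],
            method="LSODA",
            rtol=1e-10,
            atol=1e-14,
        )
        ng, na = sol.y[:, -1]
        out["lambda_numeric"] = float(np.log(ng) / horizon) if ng > 0 else -np.inf
        out["arrested_fraction_numeric"] = float(na / (ng + na))
    return out


def framework_growth_rate(params: TimescaleParams) -> dict:
    """Dominant growth rate of the four-state timescale framework.

    Builds the 4x4 growth-plus-transition generator over states (balanced,
    shifted, arrested, dead) and returns its leading eigenvalue and the
    corresponding occupancy fractions.  Limits: tau1 -> inf gives classical
    balanced growth (lambda -> g); small tau2 with large tau_m1, tau_m2, tau3
    recovers the metastable two-compartment model with s = 1/tau1.
    """
    r1 = 1.0 / params.tau1
    rm1 = 1.0 / params.tau_m1
    r2 = 1.0 / params.tau2
    rm2 = 1.0 / params.tau_m2
    r3 = 1.0 / params.tau3
    A = np.array(
        [
            [params.g - r1, rm1, rm2, 0.0],
            [r1, params.g_hat - rm1 - r2, 0.0, 0.0],
            [0.0, r2, -rm2 - r3, 0.0],
            [0.0, 0.0, r3, 0.0],
        ]
    )
    eigvals, eigvecs = np.linalg.eig(A)
    order = np.argsort(eigvals.real)[::-1]
    lam = float(eigvals.real[order[0]])
    vec = np.abs(eigvecs[:, order[0]].real)
    occ = vec / vec.sum() if vec.sum() > 0 else np.full(4, 0.25)
    return {
        "lambda": lam,
        "occupancy": {
            "balanced": float(occ[0]),
            "shifted": float(occ[1]),
            "arrested": float(occ[2]),
            "dead": float(occ[3]),
        },
        "matrix": A,
    }


def fitness_surface(
    delta_grid,
    x_grid,
    g_max: float = 1.0,
    s_max: float = 2.0,
    sigma_x: float = 0.1,
    vmax: float = 1.0,
    benefit_form: BenefitForm = BenefitForm.PIECEWISE_LINEAR,
):
    """Normalized population growth rate over (demand, flux ratio).

    The growing subpopulation's rate is demand-limited,
    ``g = g_max * f_gr(V-, delta)`` with ``V- = min(V+, Vmax)`` and
    ``V+ = x * Vmax``, while the switching rate rises through the saturation
    point x = 1.  Returns (lambda_norm, arrested_fraction) matrices with rows
    indexed by delta and columns by x; lambda_norm may be negative where
    switching outpaces growth.
    """
    delta_grid = np.asarray(delta_grid, dtype=float)
    x_grid = np.asarray(x_grid, dtype=float)
    lam = np.empty((delta_grid.size, x_grid.size))
    arrested = np.empty_like(lam)
    for i, delta in enumerate(delta_grid):
        for j, x in enumerate(x_grid):
            v_minus = min(x * vmax, vmax)
            g = g_max * benefit_factor(v_minus, delta, benefit_form)
            p = SwitchingModelParams(
                g=max(g, 0.0), s_max=s_max, sigma_x=sigma_x, x=x, delta=delta
            )
            s = switching_rate(p)
            lam[i, j] = (g - s) / g_max
            arrested[i, j] = s / g if g > s else 1.0
    return lam, arrested
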