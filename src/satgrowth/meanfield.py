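"""Deterministic cost/benefit models of a saturable metabolic pathway.

A producing enzyme A supplies an intracellular metabolite M at flux ``v_plus``;
a consuming enzyme B removes it at a Michaelis-Menten flux ``V-(M)``.  The
consumption flux feeds growth (benefit factor ``f_gr``, saturating at the
demand ``delta``) while either M itself or a co-produced byproduct T inhibits
growth (toxicity factor ``f_tox`` with threshold ``theta``).  Because ``V-``
saturates, production can exceed every removal route and the metabolite (or
byproduct) builds up without bound: the model then has no admissible steady
state and the cell is driven into growth arrest.

Three regimes result: starvation (I, steady state with sub-saturated benefit),
satiation (II, benefit saturated), and surfeit (III, no steady state).  This
module finds steady states by root analysis, classifies regimes, scans phase
diagrams, and computes first-passage times into the runaway branch.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "ToxicityVariant",
    "BenefitForm",
    "ConsumptionForm",
    "PathwayParams",
    "PathwayState",
    "RegimePhaseMap",
    "RescaledParams",
    "benefit_factor",
    "toxicity_factor",
    "consumption_flux",
    "growth_rate",
    "pathway_rhs",
    "solve_steady_state",
    "steady_state_oracle",
    "classify_regime",
    "phase_diagram",
    "regime_iii_onset",
    "rescale_parameters",
    "existence_map",
    "first_passage_time",
]


class ToxicityVariant(str, enum.Enum):
    """Which species carries the growth-inhibiting cost."""

    SUBSTRATE = "substrate"  # the metabolite M itself is toxic
    BYPRODUCT = "byproduct"  # a co-imported byproduct T (e.g. symported protons)
    NONE = "none"  # no toxicity; f_tox == 1


class BenefitForm(str, enum.Enum):
    PIECEWISE_LINEAR = "piecewise_linear"  # min(flux/delta, 1): sharp I/II border
    MICHAELIS_MENTEN = "michaelis_menten"  # (flux/delta)/(1+flux/delta): blurred border


class ConsumptionForm(str, enum.Enum):
    MICHAELIS_MENTEN = "michaelis_menten"  # saturable: Vmax*M/(Km+M)
    LINEAR = "linear"  # non-saturating: (Vmax/Km)*M


@dataclass(frozen=True)
class PathwayParams:
    """Constants of the deterministic pathway model.

    Units are molecules per unit cell volume and seconds throughout; the cell
    volume is taken as 1 so counts and concentrations coincide.
    """

    v_plus: float = 1.0  # metabolite production flux
    delta: float = 0.5  # demand: consumption flux saturating the growth benefit
    theta: float = 100.0  # toxicity threshold (half-inhibition level)
    vmax_b: float = 1.0  # maximal consumption rate of enzyme B
    km_b: float = 0.1  # Michaelis constant of enzyme B
    g_max: float = 6e-4  # maximum growth rate (1/s)
    toxicity_variant: ToxicityVariant = ToxicityVariant.SUBSTRATE
    benefit_form: BenefitForm = BenefitForm.PIECEWISE_LINEAR
    consumption_form: ConsumptionForm = ConsumptionForm.MICHAELIS_MENTEN
    byproduct_yield: float = 1.0  # toxin produced per imported metabolite
    hill_tox: float = 1.0  # Hill exponent of the toxicity function

    def __post_init__(self) -> None:
        variant = ToxicityVariant(self.toxicity_variant)
        object.__setattr__(self, "toxicity_variant", variant)
        object.__setattr__(self, "benefit_form", BenefitForm(self.benefit_form))
        object.__setattr__(
            self, "consumption_form", ConsumptionForm(self.consumption_form)
        )
        for name in ("v_plus", "vmax_b", "g_max", "byproduct_yield"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.delta <= 0:
            raise ValueError("delta must be > 0")
        if self.km_b <= 0:
            raise ValueError("km_b must be > 0")
        if variant is not ToxicityVariant.NONE and self.theta <= 0:
            raise ValueError("theta must be > 0 unless toxicity_variant is 'none'")
        if self.hill_tox <= 0:
            raise ValueError("hill_tox must be > 0")

    @property
    def m_max_default(self) -> float:
        """Cap below which steady-state roots are searched."""
        if self.toxicity_variant is ToxicityVariant.NONE:
            return 1e6 * max(self.km_b, 1.0)
        return 1e6 * self.theta


@dataclass(frozen=True)
class PathwayState:
    """Metabolite and (for the byproduct variant) toxin levels."""

    m: float
    t: float = 0.0

    def __post_init__(self) -> None:
        if self.m < 0 or self.t < 0:
            raise ValueError("state variables must be nonnegative")


@dataclass
class RescaledParams:
    """Dimensionless control parameters of steady-state existence."""

    r_ratio: float  # R = V+/Vmax_B, ratio of maximal enzyme activities
    theta_scaled: float  # Theta = theta/Km_B, toxicity threshold in Km units


@dataclass
class RegimePhaseMap:
    """Regime labels and normalized growth over a (v_plus, delta) grid."""

    v_plus_grid: np.ndarray
    delta_grid: np.ndarray
    regime: np.ndarray  # shape (len(delta_grid), len(v_plus_grid)), values 'I'/'II'/'III'
    norm_growth: np.ndarray  # same shape, g(M*)/g_max in [0,1]; 0 where regime III

    def to_frame(self):
        """Tidy table with columns v_plus, delta, regime, norm_growth."""
        import pandas as pd

        vv, dd = np.meshgrid(self.v_plus_grid, self.delta_grid)
        return pd.DataFrame(
            {
                "v_plus": vv.ravel(),
                "delta": dd.ravel(),
                "regime": self.regime.ravel(),
                "norm_growth": self.norm_growth.ravel(),
            }
        )


# ---------------------------------------------------------------------------
# elementary factors


def benefit_factor(consumption_flux, delta, form=BenefitForm.PIECEWISE_LINEAR):
    """Growth benefit f_gr in [0,1] from pathway output relative to demand.

    Piecewise-linear: min(flux/delta, 1).  Michaelis-Menten:
    (flux/delta)/(1+flux/delta), a saturating relaxation that blurs the
    starvation/satiation border.
    """
    flux = np.asarray(consumption_flux, dtype=float)
    if np.any(flux < 0):
        raise ValueError("consumption flux must be >= 0")
    if delta <= 0:
        raise ValueError("delta must be > 0")
    x = flux / delta
    form = BenefitForm(form)
    if form is BenefitForm.PIECEWISE_LINEAR:
        out = np.minimum(x, 1.0)
    else:
        out = x / (1.0 + x)
    return out if out.ndim else float(out)


def toxicity_factor(toxic_level, theta, hill=1.0):
    """Toxicity factor f_tox = 1/(1+(x/theta)^hill); 1 at x=0, 1/2 at x=theta."""
    x = np.asarray(toxic_level, dtype=float)
    if np.any(x < 0):
        raise ValueError("toxic level must be >= 0")
    if theta <= 0:
        raise ValueError("theta must be > 0")
    out = 1.0 / (1.0 + (x / theta) ** hill)
    return out if out.ndim else float(out)


def consumption_flux(m, params: PathwayParams):
    """Consumption flux V-(M) of enzyme B."""
    m = np.asarray(m, dtype=float)
    if params.consumption_form is ConsumptionForm.LINEAR:
        out = (params.vmax_b / params.km_b) * m
    else:
        out = params.vmax_b * m / (params.km_b + m)
    return out if out.ndim else float(out)


def _toxic_level(state: PathwayState, params: PathwayParams) -> float:
    if params.toxicity_variant is ToxicityVariant.SUBSTRATE:
        return state.m
    if params.toxicity_variant is ToxicityVariant.BYPRODUCT:
        return state.t
    return 0.0


def growth_rate(state: PathwayState, params: PathwayParams) -> float:
    """Instantaneous growth rate g = g_max * f_gr(V-(M)) * f_tox."""
    f_gr = benefit_factor(consumption_flux(state.m, params), params.delta, params.benefit_form)
    if params.toxicity_variant is ToxicityVariant.NONE:
        f_tox = 1.0
    else:
        f_tox = toxicity_factor(_toxic_level(state, params), params.theta, params.hill_tox)
    return params.g_max * f_gr * f_tox


def pathway_rhs(state: PathwayState, params: PathwayParams, volume: float = 1.0):
    """Time derivatives (dM/dt, dT/dt).

    ``volume`` rescales the enzyme-driven fluxes (production and consumption)
    relative to the dilution term: a larger cell accumulates per-volume
    metabolite more slowly for the same enzyme copy numbers.
    """
    g = growth_rate(state, params)
    dm = (params.v_plus - consumption_flux(state.m, params)) / volume - g * state.m
    if params.toxicity_variant is ToxicityVariant.BYPRODUCT:
        dt = params.byproduct_yield * params.v_plus / volume - g * state.t
    else:
        dt = 0.0
    return dm, dt


# ---------------------------------------------------------------------------
# steady states by root analysis


def _growth_at_m(m: float, params: PathwayParams) -> Optional[float]:
    """Growth rate at metabolite level m with the toxin (if any) at its own
    steady state.  Returns None when no self-consistent growing toxin balance
    exists (byproduct runaway at this m)."""
    vm = consumption_flux(m, params)
    f_gr = benefit_factor(vm, params.delta, params.benefit_form)
    g_up = params.g_max * f_gr
    if params.toxicity_variant is ToxicityVariant.SUBSTRATE:
        return g_up * toxicity_factor(m, params.theta, params.hill_tox)
    if params.toxicity_variant is ToxicityVariant.NONE:
        return g_up
    # byproduct: T* = yield*v_plus/g, solve g = g_up * f_tox(T*(g))
    a = params.byproduct_yield * params.v_plus
    if a == 0.0:
        return g_up
    if g_up <= 0.0:
        return None

    def psi(g):
        return g_up * toxicity_factor(a / g, params.theta, params.hill_tox) - g

    # scan for the largest root on (0, g_up]
    gs = g_up * np.logspace(-14, 0, 300)
    vals = np.array([psi(g) for g in gs])
    idx = np.where(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)[0]
    root = None
    for i in idx:
        root = brentq(psi, gs[i], gs[i + 1], xtol=1e-15, rtol=1e-12)
    if root is None and abs(psi(g_up)) <= 1e-12 * params.g_max:
        root = g_up
    return root


def _net_production(m: float, params: PathwayParams) -> Optional[float]:
    """F(M) = v_plus - V-(M) - g(M)*M, or None if no toxin balance exists."""
    g = _growth_at_m(m, params)
    if g is None:
        return None
    return params.v_plus - consumption_flux(m, params) - g * m


def solve_steady_state(
    params: PathwayParams, m_max: Optional[float] = None
) -> Optional[PathwayState]:
    """Smallest stable nonnegative steady state reachable from M = 0.

    Scans F(M) = dM/dt on [0, m_max] for its first down-crossing (stability:
    dF/dM < 0) and polishes the root with Brent's method.  Returns ``None``
    when no root exists below ``m_max`` (runaway: regime III).
    """
    if m_max is None:
        m_max = params.m_max_default
    if params.v_plus == 0.0:
        return PathwayState(0.0, 0.0)

    lo = 1e-9 * max(params.km_b, 1.0)
    grid = np.concatenate([[0.0], np.geomspace(lo, m_max, 600)])
    if params.toxicity_variant is ToxicityVariant.BYPRODUCT:
        vals = np.array(
            [np.nan if (f := _net_production(m, params)) is None else f for m in grid]
        )
    else:
        # no inner toxin balance: F(M) evaluates vectorized
        vm = consumption_flux(grid, params)
        f_gr = benefit_factor(vm, params.delta, params.benefit_form)
        if params.toxicity_variant is ToxicityVariant.SUBSTRATE:
            f_tox = toxicity_factor(grid, params.theta, params.hill_tox)
        else:
            f_tox = 1.0
        vals = params.v_plus - vm - params.g_max * f_gr * f_tox * grid
    finite = ~np.isnan(vals)
    sign = np.sign(vals)
    for i in range(len(grid) - 1):
        if not (finite[i] and finite[i + 1]):
            continue
        if sign[i] > 0 and sign[i + 1] <= 0:
            f = lambda m: _net_production(m, params)
            try:
                root = brentq(f, grid[i], grid[i + 1], xtol=1e-12, rtol=1e-12)
            except ValueError as exc:  # pragma: no cover - bracketing guard
                raise RuntimeError(
                    f"root bracketing failed on [{grid[i]}, {grid[i+1]}]"
                ) from exc
            resid = _net_production(root, params)
            tol = 1e-9 * max(params.v_plus, params.vmax_b)
            if resid is None or abs(resid) > tol:
                raise RuntimeError(
                    f"steady-state residual {resid} above tolerance {tol}"
                )
            g = _growth_at_m(root, params)
            if params.toxicity_variant is ToxicityVariant.BYPRODUCT:
                t = params.byproduct_yield * params.v_plus / g if g > 0 else 0.0
            else:
                t = 0.0
            return PathwayState(root, t)
    return None


def steady_state_oracle(
    params: PathwayParams,
    m_max: Optional[float] = None,
    t_long: Optional[float] = None,
) -> Optional[PathwayState]:
    """Brute-force steady-state finder by long ODE integration from (0, 0).

    Runaway is declared when M (or T) exceeds ``m_max`` while still rising;
    otherwise the endpoint of the integration is returned.  Independent of the
    root-analysis route; used as its oracle.
    """
    if m_max is None:
        m_max = params.m_max_default
    if t_long is None:
        t_long = 1e5 / params.g_max

    def rhs(t, y):
        return pathway_rhs(PathwayState(max(y[0], 0.0), max(y[1], 0.0)), params)

    def escape(t, y):
        return max(y[0], y[1]) - m_max

    escape.terminal = True
    escape.direction = 1.0

    sol = solve_ivp(
        rhs,
        (0.0, t_long),
        [0.0, 0.0],
        method="LSODA",
        events=escape,
        rtol=1e-8,
        atol=1e-12,
    )
    if not sol.success and sol.status != 1:
        raise RuntimeError(f"oracle integration failed: {sol.message}")
    if sol.status == 1:  # escaped above m_max while rising
        return None
    m, t = float(sol.y[0, -1]), float(sol.y[1, -1])
    dm, dt = pathway_rhs(PathwayState(max(m, 0.0), max(t, 0.0)), params)
    # still drifting upward near the cap -> runaway that has not yet escaped
    if max(m, t) > 0.5 * m_max and max(dm, dt) > 0:
        return None
    return PathwayState(max(m, 0.0), max(t, 0.0))


# ---------------------------------------------------------------------------
# regimes and phase diagrams

REGIME_STARVATION = "I"
REGIME_SATIATION = "II"
REGIME_SURFEIT = "III"


def classify_regime(
    params: PathwayParams,
    starvation_cutoff: float = 0.9,
    m_max: Optional[float] = None,
) -> str:
    """Label the growth regime: I starvation, II satiation, III surfeit.

    III when no steady state exists below ``m_max``; otherwise I when the
    benefit factor at steady state falls below ``starvation_cutoff`` (the
    sharp piecewise benefit uses f_gr < 1).
    """
    if not 0.0 < starvation_cutoff <= 1.0:
        raise ValueError("starvation_cutoff must be in (0, 1]")
    ss = solve_steady_state(params, m_max=m_max)
    if ss is None:
        return REGIME_SURFEIT
    f_gr = benefit_factor(
        consumption_flux(ss.m, params), params.delta, params.benefit_form
    )
    if params.benefit_form is BenefitForm.PIECEWISE_LINEAR:
        cutoff = 1.0 - 1e-9
    else:
        cutoff = starvation_cutoff
    return REGIME_STARVATION if f_gr < cutoff else REGIME_SATIATION


def phase_diagram(
    v_plus_grid,
    delta_grid,
    params: PathwayParams = PathwayParams(),
    starvation_cutoff: float = 0.9,
) -> RegimePhaseMap:
    """Regime labels and normalized growth g(M*)/g_max over a (V+, delta) grid."""
    v_plus_grid = np.asarray(v_plus_grid, dtype=float)
    delta_grid = np.asarray(delta_grid, dtype=float)
    if v_plus_grid.size == 0 or delta_grid.size == 0:
        raise ValueError("grid axes must be non-empty")
    if np.any(np.diff(v_plus_grid) <= 0) or np.any(np.diff(delta_grid) <= 0):
        raise ValueError("grid axes must be strictly increasing")
    if np.any(v_plus_grid < 0) or np.any(delta_grid <= 0):
        raise ValueError("grid axes must be positive")

    regime = np.empty((delta_grid.size, v_plus_grid.size), dtype=object)
    norm_growth = np.zeros_like(regime, dtype=float)
    for i, delta in enumerate(delta_grid):
        for j, v_plus in enumerate(v_plus_grid):
            p = replace(params, v_plus=float(v_plus), delta=float(delta))
            ss = solve_steady_state(p)
            if ss is None:
                regime[i, j] = REGIME_SURFEIT
                norm_growth[i, j] = 0.0
            else:
                regime[i, j] = classify_regime(p, starvation_cutoff)
                norm_growth[i, j] = growth_rate(ss, p) / p.g_max
    return RegimePhaseMap(v_plus_grid, delta_grid, regime, norm_growth)


def regime_iii_onset(
    params: PathwayParams, v_plus_grid
) -> Optional[float]:
    """Smallest V+ on the grid where the steady state is lost (regime III)."""
    for v_plus in np.asarray(v_plus_grid, dtype=float):
        p = replace(params, v_plus=float(v_plus))
        if solve_steady_state(p) is None:
            return float(v_plus)
    return None


def rescale_parameters(params: PathwayParams) -> RescaledParams:
    """Dimensionless controls: R = V+/Vmax_B and Theta = theta/Km_B."""
    return RescaledParams(
        r_ratio=params.v_plus / params.vmax_b,
        theta_scaled=params.theta / params.km_b,
    )


def existence_map(r_grid, theta_scaled_grid, params: PathwayParams = PathwayParams()):
    """Steady-state existence over the rescaled (R, Theta) plane.

    Returns a boolean matrix (rows: Theta, cols: R); raising R or lowering
    Theta can eliminate the steady state.
    """
    r_grid = np.asarray(r_grid, dtype=float)
    th_grid = np.asarray(theta_scaled_grid, dtype=float)
    exists = np.zeros((th_grid.size, r_grid.size), dtype=bool)
    for i, th in enumerate(th_grid):
        for j, r in enumerate(r_grid):
            p = replace(
                params,
                v_plus=float(r * params.vmax_b),
                theta=float(th * params.km_b),
            )
            exists[i, j] = solve_steady_state(p) is not None
    return exists


# ---------------------------------------------------------------------------
# first-passage times


def first_passage_time(
    params: PathwayParams,
    volume: float = 1.0,
    m_threshold: float = 1000.0,
    m_from: float = 0.0,
    t_max: float = 1e6,
) -> Optional[float]:
    """Time for M to first reach ``m_threshold`` starting from ``m_from``.

    Integrates the pathway dynamics with enzyme-driven fluxes scaled by the
    relative cell ``volume``.  Returns ``None`` when a steady state below the
    threshold is reached instead (the threshold is never crossed).
    """
    if volume <= 0:
        raise ValueError("volume must be > 0")
    if not m_threshold > m_from >= 0:
        raise ValueError("need m_threshold > m_from >= 0")

    def rhs(t, y):
        return pathway_rhs(PathwayState(max(y[0], 0.0), max(y[1], 0.0)), params, volume)

    def crossing(t, y):
        return y[0] - m_threshold

    crossing.terminal = True
    crossing.direction = 1.0

    sol = solve_ivp(
        rhs,
        (0.0, t_max),
        [m_from, 0.0],
        method="LSODA",
        events=crossing,
        rtol=1e-10,
        atol=1e-12,
    )
    if not sol.success and sol.status != 1:
        raise RuntimeError(f"first-passage integration failed: {sol.message}")
    if sol.status == 1:
        return float(sol.t_events[0][0])
    dm, _ = rhs(0.0, sol.y[:, -1])
    if dm > 1e-12 * max(params.v_plus, 1.0):
        # still rising at t_max: not settled, caller should extend t_max
        raise RuntimeError("no steady state and threshold not reached by t_max")
    return None
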