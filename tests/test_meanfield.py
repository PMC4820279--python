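"""Deterministic pathway model: factors, steady states, regimes, passage times."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from satgrowth.meanfield import (
    BenefitForm,
    ConsumptionForm,
    PathwayParams,
    PathwayState,
    ToxicityVariant,
    benefit_factor,
    classify_regime,
    consumption_flux,
    existence_map,
    first_passage_time,
    pathway_rhs,
    phase_diagram,
    regime_iii_onset,
    rescale_parameters,
    solve_steady_state,
    steady_state_oracle,
    toxicity_factor,
)


@pytest.mark.parametrize(
    "flux, delta, form, expected",
    [
        (0.0, 400.0, BenefitForm.PIECEWISE_LINEAR, 0.0),
        (400.0, 400.0, BenefitForm.PIECEWISE_LINEAR, 1.0),
        (800.0, 400.0, BenefitForm.PIECEWISE_LINEAR, 1.0),
        (400.0, 400.0, BenefitForm.MICHAELIS_MENTEN, 0.5),
    ],
)
def test_benefit_factor_values(flux, delta, form, expected):
    assert benefit_factor(flux, delta, form) == pytest.approx(expected)


@pytest.mark.parametrize(
    "x, theta, hill, expected",
    [(0.0, 1.0, 1.0, 1.0), (1.0, 1.0, 1.0, 0.5), (5.0, 5.0, 3.0, 0.5),
     (10.0, 1.0, 1.0, 1.0 / 11.0)],
)
def test_toxicity_factor_values(x, theta, hill, expected):
    assert toxicity_factor(x, theta, hill) == pytest.approx(expected)


def test_factor_domain_errors():
    with pytest.raises(ValueError):
        benefit_factor(-1.0, 400.0)
    with pytest.raises(ValueError):
        benefit_factor(1.0, 0.0)
    with pytest.raises(ValueError):
        toxicity_factor(-0.1, 1.0)


@settings(max_examples=100, deadline=None)
@given(
    x=st.floats(0.0, 1e6),
    y=st.floats(0.0, 1e6),
    delta=st.floats(1e-3, 1e4),
    theta=st.floats(1e-3, 1e4),
    hill=st.floats(0.5, 4.0),
)
def test_factor_bounds_and_monotonicity(x, y, delta, theta, hill):
    """f_gr is nondecreasing in flux, f_tox strictly decreasing, both in [0,1]."""
    lo, hi = sorted((x, y))
    for form in BenefitForm:
        b_lo, b_hi = benefit_factor(lo, delta, form), benefit_factor(hi, delta, form)
        assert 0.0 <= b_lo <= b_hi <= 1.0
    t_lo, t_hi = toxicity_factor(lo, theta, hill), toxicity_factor(hi, theta, hill)
    assert 0.0 <= t_hi <= t_lo <= 1.0
    if (hi - lo) / theta > 1e-9 and t_lo > 1e-12:
        # strictly decreasing once the difference is resolvable in float
        assert t_hi < t_lo


def test_rhs_at_zero_state_is_pure_production():
    p = PathwayParams(v_plus=3.0, toxicity_variant="byproduct", byproduct_yield=2.0)
    dm, dt = pathway_rhs(PathwayState(0.0, 0.0), p)
    assert dm == pytest.approx(3.0)
    assert dt == pytest.approx(6.0)


def test_steady_state_satisfies_rhs():
    p = PathwayParams(v_plus=0.7)
    ss = solve_steady_state(p)
    dm, _ = pathway_rhs(ss, p)
    assert abs(dm) < 1e-9 * max(p.v_plus, p.vmax_b)


def test_no_toxicity_trajectory_converges():
    p = PathwayParams(v_plus=0.8, toxicity_variant="none")
    ss = steady_state_oracle(p)
    assert ss is not None
    root = solve_steady_state(p)
    assert root.m == pytest.approx(ss.m, rel=1e-4)


def test_zero_production_gives_zero_state():
    assert solve_steady_state(PathwayParams(v_plus=0.0)).m == 0.0


def test_impossible_flux_balance_is_none():
    p = PathwayParams(v_plus=1e12)
    assert solve_steady_state(p) is None


@pytest.mark.parametrize("variant", ["substrate", "byproduct", "none"])
def test_root_route_matches_integration_oracle(variant):
    """Steady-state existence by root analysis equals brute-force integration."""
    rng = np.random.default_rng(42)
    for _ in range(8):
        p = PathwayParams(
            v_plus=float(10 ** rng.uniform(-2, 0.7)),
            delta=float(10 ** rng.uniform(-1.3, 0.3)),
            theta=float(10 ** rng.uniform(1, 3)),
            km_b=float(10 ** rng.uniform(-2, 1)),
            toxicity_variant=variant,
            benefit_form=rng.choice(["piecewise_linear", "michaelis_menten"]),
        )
        m_max = 1e3 * p.theta
        root = solve_steady_state(p, m_max=m_max)
        oracle = steady_state_oracle(p, m_max=m_max)
        assert (root is None) == (oracle is None), p
        if root is not None:
            assert root.m == pytest.approx(oracle.m, rel=1e-3, abs=1e-6)


def test_regimes_starvation_limit():
    assert classify_regime(PathwayParams(v_plus=1e-6)) == "I"


def test_no_regime_three_without_toxicity_or_saturation():
    """Without toxicity, or with non-saturating consumption, runaway is impossible."""
    v_grid = np.linspace(0.05, 3.0, 12)
    for p in (
        PathwayParams(toxicity_variant="none"),
        PathwayParams(consumption_form=ConsumptionForm.LINEAR, km_b=1.0, vmax_b=10.0),
    ):
        assert regime_iii_onset(p, v_grid) is None


def test_phase_diagram_contains_three_connected_regimes():
    pm = phase_diagram(np.linspace(0.05, 2.0, 14), np.linspace(0.05, 1.5, 12))
    labels = set(pm.regime.ravel())
    assert labels == {"I", "II", "III"}
    order = {"I": 0, "II": 1, "III": 2}
    for i in range(pm.delta_grid.size):
        codes = [order[r] for r in pm.regime[i]]
        assert codes == sorted(codes), "regimes must be ordered I<II<III along V+"
    # normalized growth is zero exactly on regime III
    assert np.array_equal(pm.norm_growth == 0, pm.regime == "III")
    # fastest growth happens where the benefit saturates but toxicity is mild
    best = np.unravel_index(np.argmax(pm.norm_growth), pm.norm_growth.shape)
    assert pm.regime[best] != "III"
    assert pm.norm_growth.max() > 0.8


def test_high_demand_eliminates_satiation():
    """Above the regime convergence point no production level reaches satiation."""
    pm = phase_diagram(np.linspace(0.05, 2.5, 16), np.array([1.3, 1.45]))
    assert "II" not in set(pm.regime.ravel())


def test_byproduct_loses_steady_state_at_lower_production():
    v_grid = np.linspace(0.05, 3.0, 30)
    base = dict(theta=2000.0, vmax_b=1.0, km_b=0.1, g_max=6e-4)
    onset_sub = regime_iii_onset(PathwayParams(toxicity_variant="substrate", **base), v_grid)
    onset_byp = regime_iii_onset(PathwayParams(toxicity_variant="byproduct", **base), v_grid)
    assert onset_byp is not None and onset_sub is not None
    assert onset_byp <= onset_sub


def test_rescaled_parameters_definition():
    r = rescale_parameters(PathwayParams(v_plus=1.0, vmax_b=2.0, theta=5.0, km_b=10.0))
    assert (r.r_ratio, r.theta_scaled) == (0.5, 0.5)


def test_existence_monotone_in_rescaled_plane():
    """If (R, Theta) admits a steady state, so does any (R' <= R, Theta' >= Theta)."""
    r_grid = np.linspace(0.1, 2.5, 8)
    th_grid = np.linspace(50.0, 5000.0, 6)
    exists = existence_map(r_grid, th_grid, PathwayParams(delta=0.5))
    assert exists[:, 0].all(), "R -> 0 always admits a steady state"
    # monotone along both axes
    assert np.all(exists[:, 1:] <= exists[:, :-1] + (exists[:, 1:] & exists[:, :-1]))
    for j in range(r_grid.size):
        col = exists[:, j].astype(int)
        assert np.all(np.diff(col) >= 0), "raising Theta cannot destroy the steady state"
    for i in range(th_grid.size):
        row = exists[i, :].astype(int)
        assert np.all(np.diff(row) <= 0), "raising R cannot create a steady state"


S7F = dict(delta=500.0, vmax_b=1.0, theta=100.0, g_max=6e-4)


def test_first_passage_none_without_production():
    assert first_passage_time(PathwayParams(v_plus=0.0, **S7F), 1.0, 1000.0) is None


def test_first_passage_decreases_with_production():
    times = [
        first_passage_time(PathwayParams(v_plus=v, km_b=10.0, **S7F), 1.0, 1000.0)
        for v in (1.2, 1.5, 2.0)
    ]
    assert all(t is not None for t in times)
    assert times[0] > times[1] > times[2]


@pytest.mark.parametrize("km", [1.0, 10.0, 100.0])
def test_larger_cells_cross_threshold_later(km):
    """A 10% volume increase delays reaching the toxic threshold (runaway regime)."""
    p = PathwayParams(v_plus=1.5, km_b=km, **S7F)
    assert solve_steady_state(p) is None, "parameters must be in the runaway region"
    t10 = first_passage_time(p, 1.0, 1000.0)
    t11 = first_passage_time(p, 1.1, 1000.0)
    assert t11 - t10 > 0


def test_runaway_branch_is_irreversible():
    """Past the last balance point the metabolite level can only increase."""
    p = PathwayParams(v_plus=2.0)  # no steady state at defaults
    assert solve_steady_state(p) is None
    from scipy.integrate import solve_ivp

    sol = solve_ivp(
        lambda t, y: [pathway_rhs(PathwayState(max(y[0], 0.0)), p)[0]],
        (0, 2e5), [0.0], method="LSODA", rtol=1e-8,
    )
    m = sol.y[0]
    assert np.all(np.diff(m) >= -1e-9 * max(m.max(), 1.0))
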