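"""Exact stochastic simulation of the growth-feedback pathway network.

The reaction system couples a two-enzyme metabolic pathway (substrate import
by enzyme A, conversion to product by enzyme B) to stochastic gene expression
and to growth itself: transcription and dilution propensities carry the factor
f_tox(I) * f_gr(P), so pathway output feeds back on expression and removal of
every diluted species.  Thirteen reaction types (expanded over the two enzyme
genes into 22 concrete channels) are simulated with the Gillespie direct
method; no approximation is used.

Species order used throughout (index into the state vector):
0 gA_off, 1 gA_on, 2 gB_off, 3 gB_on, 4 mA, 5 mB, 6 A, 7 B,
8 AS (complex A.S), 9 BI (complex B.I), 10 I (intermediate), 11 P (product).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
from numba import njit
from scipy.integrate import solve_ivp
from scipy.optimize import root as _scipy_root

SPECIES = (
    "gA_off",
    "gA_on",
    "gB_off",
    "gB_on",
    "mA",
    "mB",
    "A",
    "B",
    "AS",
    "BI",
    "I",
    "P",
)
N_SPECIES = len(SPECIES)
N_REACTION_TYPES = 13
N_CHANNELS = 22
N_GENE_TOGGLE_PAIRS = 2

_IDX = {name: i for i, name in enumerate(SPECIES)}

__all__ = [
    "SPECIES",
    "ReactionSystemSpec",
    "CellState",
    "TrajectorySummary",
    "EnsembleSummary",
    "build_reaction_system",
    "mean_field_init_state",
    "simulate_trajectory",
    "simulate_deterministic",
    "run_ensemble",
    "arrest_fraction",
    "production_scan",
]


@dataclass(frozen=True)
class ReactionSystemSpec:
    """Rate constants and feedback parameters of the reaction network.

    Defaults are the model's standard parameterization; ``k_im`` is the
    composite substrate-import parameter scanned over [1e-5, 10] and ``theta``
    is 1e4 in the low-toxicity condition or 1 in the high-toxicity condition.
    """

    k_ta: float = 0.05  # transcription of gene A mRNA (1/s), varied in scans
    k_tb: float = 0.05  # transcription of gene B mRNA (1/s)
    k_mdeg: float = 0.0033  # mRNA decay (1/s)
    k_tsn: float = 0.05  # translation (1/s per mRNA)
    k_g: float = 0.0006  # maximum dilution/growth rate (1/s)
    k_gon: float = 0.00045  # gene activation (1/s)
    k_goff: float = 0.0028  # gene deactivation (1/s)
    k_im: float = 0.1  # composite substrate import (1/s)
    k_minus1: float = 2.0  # A.S dissociation (1/s)
    k_cat1: float = 1.0  # A.S -> A + I (1/s)
    k_2: float = 2.0  # B + I association (volume/(count*s))
    k_minus2: float = 2.0  # B.I dissociation (1/s)
    k_cat2: float = 1.0  # B.I -> B + P (1/s)
    k_u: float = 2.0  # product demand/consumption (1/s)
    omega: float = 1.0  # cell volume
    theta: float = 1e4  # toxicity threshold on intermediate I
    delta: float = 400.0  # demand saturating the growth benefit of P
    hill_tox: float = 1.0
    benefit_form: str = "piecewise_linear"  # or "michaelis_menten"
    benefit_floor: float = 0.0  # optional floor epsilon on f_gr
    gene_copies: int = 1

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if isinstance(value, (int, float)) and value < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.benefit_form not in ("piecewise_linear", "michaelis_menten"):
            raise ValueError(f"unknown benefit_form {self.benefit_form!r}")

    def rate_vector(self) -> np.ndarray:
        return np.array(
            [
                self.k_ta,
                self.k_tb,
                self.k_mdeg,
                self.k_tsn,
                self.k_g,
                self.k_gon,
                self.k_goff,
                self.k_im,
                self.k_minus1,
                self.k_cat1,
                self.k_2,
                self.k_minus2,
                self.k_cat2,
                self.k_u,
                self.omega,
                self.theta,
                self.delta,
                self.hill_tox,
                1.0 if self.benefit_form == "piecewise_linear" else 0.0,
                self.benefit_floor,
            ]
        )


_CONFIG_KEYS = frozenset(ReactionSystemSpec.__dataclass_fields__)


def build_reaction_system(config: Optional[dict] = None) -> ReactionSystemSpec:
    """Build the 13-reaction-type network spec from a config mapping.

    Unknown keys are rejected so silent misconfiguration cannot occur.
    """
    config = dict(config or {})
    unknown = set(config) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown reaction config keys: {sorted(unknown)}")
    return ReactionSystemSpec(**config)


@dataclass
class CellState:
    """Integer molecule counts of the network."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_SPECIES,):
            raise ValueError(f"counts must have shape ({N_SPECIES},)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    def __getitem__(self, name: str) -> int:
        return int(self.counts[_IDX[name]])


@dataclass
class TrajectorySummary:
    seed: int
    times: np.ndarray  # sampling grid (s)
    species_mean: np.ndarray  # time-averaged counts, one per species
    growth_mean: float  # time-averaged instantaneous growth rate (1/s)
    final_counts: np.ndarray
    final_growth: float
    arrested: bool
    samples: Optional[np.ndarray] = None  # (n_samples, N_SPECIES+1) if kept


@dataclass
class EnsembleSummary:
    n_traj: int
    seeds: np.ndarray
    growth_mean: float
    growth_se: float
    per_traj_growth: np.ndarray
    per_traj_species: np.ndarray  # (n_traj, N_SPECIES) time averages
    per_traj_arrested: np.ndarray
    correlations: dict  # species name -> Pearson r with growth (nan if degenerate)
    arrest_fraction: float
    hist_counts: np.ndarray  # 2-D density of (growth rate, I) over all samples
    growth_edges: np.ndarray
    i_edges: np.ndarray


# ---------------------------------------------------------------------------
# propensities / stoichiometry
#
# 22 channels (parent reaction-type number 1-13 in parentheses):
#  0 (1) transcription A     : gA_on -> gA_on + mA        a = k_ta*f*gA_on
#  1 (1) transcription B     : gB_on -> gB_on + mB        a = k_tb*f*gB_on
#  2 (2) mRNA A decay        : mA -> 0                    a = k_mdeg*mA
#  3 (2) mRNA B decay        : mB -> 0
#  4 (3) translation A       : mA -> mA + A               a = k_tsn*mA
#  5 (3) translation B       : mB -> mB + B
#  6 (4) enzyme A dilution   : A -> 0                     a = k_g*f*A
#  7 (4) enzyme B dilution   : B -> 0
#  8 (5) gene A on           : gA_off -> gA_on            a = k_gon*gA_off
#  9 (5) gene A off          : gA_on -> gA_off            a = k_goff*gA_on
# 10 (5) gene B on           : gB_off -> gB_on
# 11 (5) gene B off          : gB_on -> gB_off
# 12 (6) substrate binding   : A -> AS                    a = k_im*A
# 13 (6) substrate release   : AS -> A                    a = k_minus1*AS
# 14 (7) catalysis 1         : AS -> A + I                a = k_cat1*AS
# 15 (8) intermediate binding: B + I -> BI                a = k_2*B*I/omega
# 16 (8) intermediate release: BI -> B + I                a = k_minus2*BI
# 17 (9) catalysis 2         : BI -> B + P                a = k_cat2*BI
# 18 (10) complex AS dilution: AS -> 0                    a = k_g*f*AS
# 19 (11) complex BI dilution: BI -> 0                    a = k_g*f*BI
# 20 (12) intermediate diln. : I -> 0                     a = k_g*f*I
# 21 (13) product demand     : P -> 0                     a = k_u*P
# with f = f_tox(I)*f_gr(P).

_STOICH = np.zeros((N_CHANNELS, N_SPECIES), dtype=np.int64)


def _s(ch, **changes):
    for name, d in changes.items():
        _STOICH[ch, _IDX[name]] = d


_s(0, mA=+1)
_s(1, mB=+1)
_s(2, mA=-1)
_s(3, mB=-1)
_s(4, A=+1)
_s(5, B=+1)
_s(6, A=-1)
_s(7, B=-1)
_s(8, gA_off=-1, gA_on=+1)
_s(9, gA_off=+1, gA_on=-1)
_s(10, gB_off=-1, gB_on=+1)
_s(11, gB_off=+1, gB_on=-1)
_s(12, A=-1, AS=+1)
_s(13, A=+1, AS=-1)
_s(14, A=+1, AS=-1, I=+1)
_s(15, B=-1, I=-1, BI=+1)
_s(16, B=+1, I=+1, BI=-1)
_s(17, B=+1, BI=-1, P=+1)
_s(18, AS=-1)
_s(19, BI=-1)
_s(20, I=-1)
_s(21, P=-1)
STOICH = _STOICH


@njit(cache=False)
def _feedback(i_count, p_count, theta, delta, hill, piecewise, floor):
    """f_tox(I) * f_gr(P) with the configured forms."""
    if hill == 1.0:  # fast path: pow is the single hottest operation
        f_tox = theta / (theta + i_count)
    else:
        f_tox = 1.0 / (1.0 + (i_count / theta) ** hill)
    x = p_count / delta
    if piecewise > 0.5:
        f_gr = x if x < 1.0 else 1.0
    else:
        f_gr = x / (1.0 + x)
    if f_gr < floor:
        f_gr = floor
    return f_tox * f_gr


@njit(cache=False)
def _propensities(state, rates, out):
    (k_ta, k_tb, k_mdeg, k_tsn, k_g, k_gon, k_goff, k_im, k_m1, k_cat1,
     k_2, k_m2, k_cat2, k_u, omega, theta, delta, hill, piecewise, floor) = (
        rates[0], rates[1], rates[2], rates[3], rates[4], rates[5], rates[6],
        rates[7], rates[8], rates[9], rates[10], rates[11], rates[12],
        rates[13], rates[14], rates[15], rates[16], rates[17], rates[18],
        rates[19],
    )
    f = _feedback(state[10], state[11], theta, delta, hill, piecewise, floor)
    out[0] = k_ta * f * state[1]
    out[1] = k_tb * f * state[3]
    out[2] = k_mdeg * state[4]
    out[3] = k_mdeg * state[5]
    out[4] = k_tsn * state[4]
    out[5] = k_tsn * state[5]
    out[6] = k_g * f * state[6]
    out[7] = k_g * f * state[7]
    out[8] = k_gon * state[0]
    out[9] = k_goff * state[1]
    out[10] = k_gon * state[2]
    out[11] = k_goff * state[3]
    out[12] = k_im * state[6]
    out[13] = k_m1 * state[8]
    out[14] = k_cat1 * state[8]
    out[15] = k_2 * state[7] * state[10] / omega
    out[16] = k_m2 * state[9]
    out[17] = k_cat2 * state[9]
    out[18] = k_g * f * state[8]
    out[19] = k_g * f * state[9]
    out[20] = k_g * f * state[10]
    out[21] = k_u * state[11]
    return f


@njit(cache=False)
def _ssa_core(init, rates, t_end, sample_dt, seed):
    """Gillespie direct method; samples species and growth on a fixed grid.

    Fully inlined scalar kernel: propensities are recomputed every event
    (the feedback factor is state-dependent), and channel selection scans
    the fast metabolic channels first.
    """
    np.random.seed(seed)
    (k_ta, k_tb, k_mdeg, k_tsn, k_g, k_gon, k_goff, k_im, k_m1, k_cat1,
     k_2, k_m2, k_cat2, k_u, omega, theta, delta, hill, piecewise, floor) = (
        rates[0], rates[1], rates[2], rates[3], rates[4], rates[5], rates[6],
        rates[7], rates[8], rates[9], rates[10], rates[11], rates[12],
        rates[13], rates[14], rates[15], rates[16], rates[17], rates[18],
        rates[19],
    )
    k2w = k_2 / omega
    n_samples = int(t_end / sample_dt) + 1
    out = np.zeros((n_samples, 13))
    ga_off = float(init[0]); ga_on = float(init[1])
    gb_off = float(init[2]); gb_on = float(init[3])
    ma = float(init[4]); mb = float(init[5])
    A = float(init[6]); B = float(init[7])
    AS = float(init[8]); BI = float(init[9])
    I = float(init[10]); P = float(init[11])
    t = 0.0
    next_sample = 0
    while True:
        # feedback factor f_tox(I) * f_gr(P)
        if hill == 1.0:
            f_tox = theta / (theta + I)
        else:
            f_tox = 1.0 / (1.0 + (I / theta) ** hill)
        x = P / delta
        if piecewise > 0.5:
            f_gr = x if x < 1.0 else 1.0
        else:
            f_gr = x / (1.0 + x)
        if f_gr < floor:
            f_gr = floor
        f = f_tox * f_gr

        # fast metabolic channels
        a15 = k2w * B * I
        a12 = k_im * A
        a13 = k_m1 * AS
        a16 = k_m2 * BI
        a14 = k_cat1 * AS
        a17 = k_cat2 * BI
        a21 = k_u * P
        # expression / gene / dilution channels
        a0 = k_ta * f * ga_on
        a1 = k_tb * f * gb_on
        a2 = k_mdeg * ma
        a3 = k_mdeg * mb
        a4 = k_tsn * ma
        a5 = k_tsn * mb
        kgf = k_g * f
        a6 = kgf * A
        a7 = kgf * B
        a8 = k_gon * ga_off
        a9 = k_goff * ga_on
        a10 = k_gon * gb_off
        a11 = k_goff * gb_on
        a18 = kgf * AS
        a19 = kgf * BI
        a20 = kgf * I

        total = (a15 + a12 + a13 + a16 + a14 + a17 + a21
                 + a0 + a1 + a2 + a3 + a4 + a5 + a6 + a7
                 + a8 + a9 + a10 + a11 + a18 + a19 + a20)
        if total <= 0.0:
            t_next = t_end + 1.0  # frozen state: jump past the end
        else:
            t_next = t - np.log(np.random.random()) / total
        # record samples the jump passes over (state constant in between)
        while next_sample < n_samples and next_sample * sample_dt <= t_next:
            out[next_sample, 0] = ga_off
            out[next_sample, 1] = ga_on
            out[next_sample, 2] = gb_off
            out[next_sample, 3] = gb_on
            out[next_sample, 4] = ma
            out[next_sample, 5] = mb
            out[next_sample, 6] = A
            out[next_sample, 7] = B
            out[next_sample, 8] = AS
            out[next_sample, 9] = BI
            out[next_sample, 10] = I
            out[next_sample, 11] = P
            out[next_sample, 12] = k_g * f
            next_sample += 1
        if next_sample >= n_samples or t_next >= t_end or total <= 0.0:
            break
        t = t_next
        r = np.random.random() * total
        # selection: cumulative scan, fast metabolic channels first
        c = a15
        if r < c:
            B -= 1.0; I -= 1.0; BI += 1.0
        else:
            c += a12
            if r < c:
                A -= 1.0; AS += 1.0
            else:
                c += a13
                if r < c:
                    A += 1.0; AS -= 1.0
                else:
                    c += a16
                    if r < c:
                        B += 1.0; I += 1.0; BI -= 1.0
                    else:
                        c += a14
                        if r < c:
                            A += 1.0; AS -= 1.0; I += 1.0
                        else:
                            c += a17
                            if r < c:
                                B += 1.0; BI -= 1.0; P += 1.0
                            else:
                                c += a21
                                if r < c:
                                    P -= 1.0
                                else:
                                    c += a0
                                    if r < c:
                                        ma += 1.0
                                    else:
                                        c += a1
                                        if r < c:
                                            mb += 1.0
                                        else:
                                            c += a2
                                            if r < c:
                                                ma -= 1.0
                                            else:
                                                c += a3
                                                if r < c:
                                                    mb -= 1.0
                                                else:
                                                    c += a4
                                                    if r < c:
                                                        A += 1.0
                                                    else:
                                                        c += a5
                                                        if r < c:
                                                            B += 1.0
                                                        else:
                                                            c += a6
                                                            if r < c:
                                                                A -= 1.0
                                                            else:
                                                                c += a7
                                                                if r < c:
                                                                    B -= 1.0
                                                                else:
                                                                    c += a8
                                                                    if r < c:
                                                                        ga_off -= 1.0; ga_on += 1.0
                                                                    else:
                                                                        c += a9
                                                                        if r < c:
                                                                            ga_off += 1.0; ga_on -= 1.0
                                                                        else:
                                                                            c += a10
                                                                            if r < c:
                                                                                gb_off -= 1.0; gb_on += 1.0
                                                                            else:
                                                                                c += a11
                                                                                if r < c:
                                                                                    gb_off += 1.0; gb_on -= 1.0
                                                                                else:
                                                                                    c += a18
                                                                                    if r < c:
                                                                                        AS -= 1.0
                                                                                    else:
                                                                                        c += a19
                                                                                        if r < c:
                                                                                            BI -= 1.0
                                                                                        else:
                                                                                            c += a20
                                                                                            if I > 0.0:  # roundoff guard on the last bin
                                                                                                I -= 1.0
    return out


def simulate_trajectory(
    spec: ReactionSystemSpec,
    init: CellState,
    t_end: float = 8000.0,
    seed: int = 0,
    sample_dt: float = 10.0,
    arrest_epsilon: float = 0.01,
    keep_samples: bool = False,
) -> TrajectorySummary:
    """One exact SSA trajectory; identical (spec, init, seed) -> identical output.

    The instantaneous growth rate k_g*f_tox(I)*f_gr(P) and all species counts
    are recorded every ``sample_dt`` seconds.  A trajectory is flagged as
    growth-arrested when, at the end time, its instantaneous growth rate is
    below ``arrest_epsilon * k_g`` *and* the intermediate metabolite exceeds
    the toxicity threshold: the second condition separates toxic arrest
    (runaway metabolite) from plain substrate-limited starvation, which also
    has near-zero growth but low metabolite.
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    samples = _ssa_core(
        np.asarray(init.counts, dtype=np.int64),
        spec.rate_vector(),
        float(t_end),
        float(sample_dt),
        np.uint32(seed % (2**32)),
    )
    times = np.arange(samples.shape[0]) * sample_dt
    growth = samples[:, -1]
    if np.any(growth < -1e-15) or np.any(growth > spec.k_g * (1 + 1e-9)):
        raise AssertionError("growth rate left [0, k_g]")  # pragma: no cover
    summary = TrajectorySummary(
        seed=int(seed),
        times=times,
        species_mean=samples[:, :-1].mean(axis=0),
        growth_mean=float(growth.mean()),
        final_counts=samples[-1, :-1].astype(np.int64),
        final_growth=float(growth[-1]),
        arrested=bool(
            growth[-1] < arrest_epsilon * spec.k_g
            and samples[-1, _IDX["I"]] > spec.theta
        ),
        samples=samples if keep_samples else None,
    )
    return summary


# ---------------------------------------------------------------------------
# deterministic rate equations of the same network


def _deterministic_rhs(y, rates, clamp_tox=False):
    a = np.zeros(N_CHANNELS)
    r = rates.copy()
    if clamp_tox:
        r = r.copy()
        r[15] = np.inf  # theta -> infinity: f_tox == 1
    state = np.maximum(y, 0.0)
    _propensities(state, r, a)
    return STOICH.T @ a


def simulate_deterministic(
    spec: ReactionSystemSpec, init: np.ndarray, t_end: float, n_out: int = 200
):
    """Integrate the mean-field rate equations of the same reaction network."""
    rates = spec.rate_vector()
    sol = solve_ivp(
        lambda t, y: _deterministic_rhs(y, rates),
        (0.0, t_end),
        np.asarray(init, dtype=float),
        method="LSODA",
        t_eval=np.linspace(0.0, t_end, n_out),
        rtol=1e-8,
        atol=1e-10,
    )
    if not sol.success:
        raise RuntimeError(f"deterministic integration failed: {sol.message}")
    return sol.t, sol.y.T


def mean_field_init_state(spec: ReactionSystemSpec, _return_float: bool = False):
    """Deterministic steady state of the rate equations, rounded to counts.

    Solved by root-finding from an analytic sketch of the balance (enzyme
    totals are set by transcription/translation/dilution and are independent
    of the feedback factor).  When no stable steady state exists (runaway
    regime), the steady state of the network with f_tox clamped to 1 is used
    as the documented fallback.
    """
    rates = spec.rate_vector()

    gene_frac = spec.k_gon / (spec.k_gon + spec.k_goff) if (spec.k_gon + spec.k_goff) > 0 else 0.0
    n_genes = spec.gene_copies
    # enzyme totals (free + complex) are independent of the feedback factor:
    # both production (transcription) and removal (dilution) carry it
    denom = spec.k_mdeg * spec.k_g
    a_tot = spec.k_tsn * spec.k_ta * gene_frac * n_genes / denom if denom > 0 else 0.0
    b_tot = spec.k_tsn * spec.k_tb * gene_frac * n_genes / denom if denom > 0 else 0.0

    def guess(f):
        a_free = a_tot * (spec.k_minus1 + spec.k_cat1) / (
            spec.k_minus1 + spec.k_cat1 + spec.k_im + 1e-300
        )
        a_s = a_tot - a_free
        flux = spec.k_cat1 * a_s
        p = flux / spec.k_u if spec.k_u > 0 else 0.0
        y = np.full(N_SPECIES, 0.0)
        y[_IDX["gA_off"]] = n_genes * (1 - gene_frac)
        y[_IDX["gA_on"]] = n_genes * gene_frac
        y[_IDX["gB_off"]] = n_genes * (1 - gene_frac)
        y[_IDX["gB_on"]] = n_genes * gene_frac
        if spec.k_mdeg > 0:
            y[_IDX["mA"]] = spec.k_ta * f * gene_frac * n_genes / spec.k_mdeg
            y[_IDX["mB"]] = spec.k_tb * f * gene_frac * n_genes / spec.k_mdeg
        y[_IDX["A"]] = a_free
        y[_IDX["B"]] = b_tot * 0.5
        y[_IDX["AS"]] = a_s
        y[_IDX["BI"]] = b_tot * 0.5
        y[_IDX["I"]] = max(flux / max(spec.k_cat2, 1e-12), 1.0)
        y[_IDX["P"]] = max(p, 1e-6)
        return y

    # gene occupancies are linear-conserved, so they are fixed at their
    # mean-field values and only the 8 expression/pathway species are solved
    free = [_IDX[n] for n in ("mA", "mB", "A", "B", "AS", "BI", "I", "P")]

    def solve_from(y0, clamp):
        # relax toward the steady state first (robust far from it), then
        # polish with a Newton-type root solve on the non-conserved species
        runaway_cap = max(1e4 * spec.theta, 1e7)

        def rhs_t(t, y):
            return _deterministic_rhs(y, rates, clamp_tox=clamp)

        def escape(t, y):
            return max(y[_IDX["I"]], y[_IDX["P"]]) - runaway_cap

        escape.terminal = True
        escape.direction = 1.0
        sol_ivp = solve_ivp(rhs_t, (0.0, 2e6), y0, method="LSODA",
                            events=escape, rtol=1e-10, atol=1e-12)
        if sol_ivp.status == 1:  # runaway: no steady state on this branch
            return None
        y0 = np.maximum(sol_ivp.y[:, -1], 0.0)
        if not np.all(np.isfinite(y0)):
            return None

        def fun(z):
            y = y0.copy()
            y[free] = z
            return _deterministic_rhs(y, rates, clamp_tox=clamp)[free]

        sol = _scipy_root(fun, y0[free], method="hybr", tol=1e-14)
        y = y0.copy()
        if sol.success and np.all(sol.x > -1e-6):
            y[free] = np.maximum(sol.x, 0.0)
        a = np.zeros(N_CHANNELS)
        r = rates.copy()
        if clamp:
            r[15] = np.inf
        _propensities(y, r, a)
        resid = np.abs(STOICH.T @ a)
        scale = max(a.max(), 1e-12)
        if not np.all(np.isfinite(y)) or not resid.max() <= 1e-6 * scale:
            return None
        return y

    y = solve_from(guess(0.5), clamp=False)
    used_fallback = False
    if y is None:
        used_fallback = True
        y = solve_from(guess(0.5), clamp=True)
    if y is None:
        # deep runaway: even with f_tox clamped the pathway has no fixed
        # point (import exceeds consumption capacity).  Start from the
        # expression balance with an empty pathway; metabolite and product
        # then build up from zero, as for a cell entering the condition.
        y = guess(1.0)
        y[_IDX["I"]] = 0.0
        y[_IDX["P"]] = 0.0
        b = y[_IDX["B"]] + y[_IDX["BI"]]
        y[_IDX["B"]] = b
        y[_IDX["BI"]] = 0.0
    if _return_float:
        return y, used_fallback
    counts = np.rint(y).astype(np.int64)
    # restore gene-copy conservation after rounding
    counts[_IDX["gA_on"]] = min(counts[_IDX["gA_on"]], n_genes)
    counts[_IDX["gA_off"]] = n_genes - counts[_IDX["gA_on"]]
    counts[_IDX["gB_on"]] = min(counts[_IDX["gB_on"]], n_genes)
    counts[_IDX["gB_off"]] = n_genes - counts[_IDX["gB_on"]]
    counts = np.maximum(counts, 0)
    return CellState(counts)


# ---------------------------------------------------------------------------
# ensembles


def run_ensemble(
    spec: ReactionSystemSpec,
    n_traj: int = 200,
    t_end: float = 8000.0,
    seed_base: int = 0,
    sample_dt: float = 10.0,
    arrest_epsilon: float = 0.01,
    init: Optional[CellState] = None,
    n_growth_bins: int = 40,
    n_i_bins: int = 40,
) -> EnsembleSummary:
    """Independent seeded trajectories from the mean-field initial state.

    Per-trajectory seeds are ``seed_base + index`` (recorded in the summary).
    Correlations are Pearson r between per-trajectory time-averaged species
    counts and time-averaged growth rate; the 2-D histogram pools every grid
    sample of (growth rate, intermediate I) across trajectories.
    """
    if n_traj < 2:
        raise ValueError("n_traj must be >= 2")
    if init is None:
        init = mean_field_init_state(spec)
    seeds = np.array([(seed_base + i) % (2**31) for i in range(n_traj)])
    growth = np.empty(n_traj)
    species = np.empty((n_traj, N_SPECIES))
    arrested = np.zeros(n_traj, dtype=bool)
    all_g = []
    all_i = []
    for k, s in enumerate(seeds):
        tr = simulate_trajectory(
            spec, init, t_end=t_end, seed=int(s), sample_dt=sample_dt,
            arrest_epsilon=arrest_epsilon, keep_samples=True,
        )
        growth[k] = tr.growth_mean
        species[k] = tr.species_mean
        arrested[k] = tr.arrested
        all_g.append(tr.samples[:, -1])
        all_i.append(tr.samples[:, _IDX["I"]])
    all_g = np.concatenate(all_g)
    all_i = np.concatenate(all_i)

    correlations = {}
    gs = growth.std()

    def corr_with_growth(x):
        if x.std() == 0.0 or gs == 0.0:
            return float("nan")
        return float(np.corrcoef(x, growth)[0, 1])

    for j, name in enumerate(SPECIES):
        correlations[name] = corr_with_growth(species[:, j])
    # total enzyme pools (free + substrate-bound), the physical readouts
    correlations["A_tot"] = corr_with_growth(
        species[:, _IDX["A"]] + species[:, _IDX["AS"]]
    )
    correlations["B_tot"] = corr_with_growth(
        species[:, _IDX["B"]] + species[:, _IDX["BI"]]
    )

    g_edges = np.linspace(0.0, spec.k_g, n_growth_bins + 1)
    i_max = max(all_i.max(), 1.0)
    i_edges = np.concatenate([[-0.5], np.geomspace(0.5, i_max + 0.5, n_i_bins)])
    hist, g_edges, i_edges = np.histogram2d(all_g, all_i, bins=[g_edges, i_edges])

    return EnsembleSummary(
        n_traj=n_traj,
        seeds=seeds,
        growth_mean=float(growth.mean()),
        growth_se=float(growth.std(ddof=1) / np.sqrt(n_traj)),
        per_traj_growth=growth,
        per_traj_species=species,
        per_traj_arrested=arrested,
        correlations=correlations,
        arrest_fraction=float(arrested.mean()),
        hist_counts=hist,
        growth_edges=g_edges,
        i_edges=i_edges,
    )


def arrest_fraction(ensemble: EnsembleSummary) -> float:
    """Fraction of trajectories flagged growth-arrested at the end time."""
    return ensemble.arrest_fraction


# default 7-rung production ladder: from deep starvation to well past the
# consumption capacity of enzyme B (set by the fixed k_tb)
PRODUCTION_LADDER = tuple(np.geomspace(1e-3, 0.13, 7))


def production_scan(
    k_ta_ladder=PRODUCTION_LADDER,
    base_config: Optional[dict] = None,
    n_traj: int = 200,
    t_end: float = 8000.0,
    seed_base: int = 0,
) -> list:
    """Ensembles along a metabolite-production ladder.

    Production is scanned by the transcription rate of enzyme A, which sets
    the enzyme-A copy number and with it the import flux, while enzyme B
    (fixed k_tb) sets the consumption capacity.  Low rungs starve the
    pathway; rungs past the capacity of enzyme B drive runaway metabolite
    buildup and growth arrest, so the ensemble mean growth rate is
    non-monotone with an interior maximum.

    Returns one EnsembleSummary per rung, with independent seed blocks.
    """
    base_config = dict(base_config or {})
    out = []
    for r, k_ta in enumerate(np.asarray(k_ta_ladder, dtype=float)):
        spec = build_reaction_system({**base_config, "k_ta": float(k_ta)})
        out.append(
            run_ensemble(
                spec,
                n_traj=n_traj,
                t_end=t_end,
                seed_base=seed_base + r * max(n_traj, 1000),
            )
        )
    return out
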