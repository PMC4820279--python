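# Methods

`satgrowth` models how a saturable metabolic pathway can arrest the growth of
single cells while the population keeps growing, and provides the inference
stages needed to detect that heterogeneity in measurements. This note
records the models, their assumptions, the numerical choices, and what the
synthetic-data tests do and do not demonstrate.

## Deterministic cost/benefit pathway (`satgrowth.meanfield`)

A producing enzyme A supplies an intracellular metabolite M at flux `v_plus`
(molecules per unit volume per second); a consuming enzyme B removes it at

    V-(M) = Vmax_B * M / (Km_B + M)        (or (Vmax_B/Km_B)*M, non-saturating variant)

Growth couples to the pathway twice:

* benefit `f_gr = min(V-/delta, 1)` — consumption flux feeds growth until it
  meets the demand `delta`; a Michaelis–Menten form `(V-/delta)/(1+V-/delta)`
  is available and blurs the starvation/satiation border;
* cost `f_tox = 1/(1+(x/theta)^h)` — either M itself (substrate variant) or a
  co-produced toxin T (byproduct variant, `dT/dt = y*v_plus - g*T`) inhibits
  growth with half-inhibition at `theta`; Hill exponent `h` defaults to 1.

The metabolite obeys `dM/dt = v_plus - V-(M) - g*M` with
`g = g_max * f_gr * f_tox`. Because `V-` saturates and the dilution term
`g*M` is capped (as M grows, `f_tox*M -> theta*...` stays bounded for h = 1),
total removal has a finite ceiling: production above it leaves no steady
state and M (or T) grows without bound. Three regimes result —
starvation (I: steady state, benefit unsaturated), satiation (II: benefit
saturated), surfeit (III: no steady state, growth stalls). The exact
benefit/toxicity forms here are minimal stand-ins chosen to reproduce this
regime geometry; they are configuration-switchable.

Numerics: steady states are found by scanning `F(M) = dM/dt` on
`[0, M_max]` (600 geometrically spaced points, `M_max = 1e6*theta` by
default) for the first down-crossing and polishing with Brent's method
(residual below `1e-9*max(v_plus, Vmax_B)`); the first down-crossing from
`F(0) = v_plus > 0` is the smallest stable root, matching a cell that enters
the condition with low metabolite. For the byproduct variant the toxin is
first balanced at fixed M (`g = g_up*f_tox(y*v_plus/g)`, largest root in g;
closed form `g = g_up - y*v_plus/theta` at h = 1). The independent oracle is
long LSODA integration from (0, 0) for `1e5/g_max` seconds, declaring
runaway when the state exceeds `M_max` while still rising; the two routes are
compared on randomized parameter draws across all variants.

First-passage times to a metabolite threshold integrate the same dynamics
with an event. Cell volume enters as a reconstruction (the source for the
scaling is not available in algebraic form): enzyme-driven fluxes `v_plus`
and `Vmax_B` are divided by the relative volume — a bigger cell needs more
molecules to raise its concentration while its enzyme copy numbers are held
fixed — whereas the dilution term is per-concentration and unchanged. This
reproduces the qualitative claims the scaling must satisfy: a 10% larger
volume delays threshold crossing everywhere in the runaway region, with a
Km-dependent delay.

## Stochastic growth-feedback simulator (`satgrowth.ssa`)

The reaction network has 13 reaction types — transcription, mRNA decay,
translation, growth-coupled dilution of every enzyme/complex/metabolite
species, two-state gene toggling, substrate binding/release and catalysis
for enzymes A and B, and a product demand reaction — expanded over the two
enzyme genes into 22 concrete channels. Transcription and all dilution
propensities carry the state-dependent factor `f_tox(I)*f_gr(P)`: the
toxicity argument is the intermediate I (the only species that can build
up), the benefit argument is the pathway product P consumed by the demand
reaction (`delta = 400` in counts). Default rate constants are the model's
standard parameterization; `omega` (cell volume) is 1 so counts equal
concentrations, and bimolecular binding uses `k_2*B*I/omega`.

Simulation is the exact Gillespie direct method, written as a fully inlined
scalar kernel (numba) because propensities must be re-evaluated at every
event. Species and the instantaneous growth rate `k_g*f_tox*f_gr` are
recorded on a 10 s grid; per-trajectory summaries are time averages, and
ensemble correlations are Pearson correlations between per-trajectory
time-averaged quantities (the alternative — endpoint values — is not
distinguished by the available description; time averages are less noisy).
Correlations are reported for every species and for the total enzyme pools
A+A.S and B+B.I, which are the physically meaningful "enzyme A/B" readouts:
during runaway nearly all of B is substrate-bound, so the free-B correlation
is dominated by partitioning noise.

Initial conditions are the deterministic (mean-field) steady state of the
same network, solved by relaxation (LSODA) plus Newton polish on the eight
non-conserved species, rounded to integers. Gene occupancies are conserved
and set to their stationary fractions before rounding. When no steady state
exists the initializer falls back, in order: (i) the network with `f_tox`
clamped to 1 (toxicity-driven runaway), then (ii) the expression-balance
state with an empty pathway, I = P = 0 (deep runaway where import exceeds
consumption capacity even without toxicity) — the state of a cell that has
just entered the condition. No cell division occurs within a trajectory.

**Arrest flag.** A trajectory is growth-arrested when, at the end time, its
instantaneous growth rate is below 1% of `k_g` *and* the intermediate
exceeds `theta`. The growth condition alone cannot work: substrate-starved
trajectories also have near-zero growth (benefit, not toxicity, is limiting)
but must not count as arrested. The metabolite condition identifies the
high-metabolite subpopulation that has crossed into the surfeit regime,
which is irreversible in practice because transcription of the consuming
enzyme is growth-coupled while mRNA decay is not.

**Production ladder.** Metabolite production is scanned through the
transcription rate of enzyme A (`k_tA`, geometric ladder 1e-3 to 0.13 in 7
rungs, with `k_im = 10` so that import itself is not limiting and
`k_tB = 0.05` fixed). This is the expression-ratio scan: enzyme A's copy
number sets the import flux, enzyme B's fixed expression sets a consumption
capacity of roughly 175 events/s, and rungs past that capacity undergo
deterministic runaway. Scanning the import constant `k_im` alone cannot
produce this phenomenology: `k_im/(k_im+3)` saturates, so the import flux
never exceeds B's capacity and growth stays monotone in `k_im`. With the
`k_tA` ladder the ensemble mean growth rate is non-monotone with an interior
peak, the top rung arrests every trajectory, and the growth correlations
change sign across the peak. Study-scale ensembles are 200 trajectories of
8000 s per rung, a size chosen so that Monte-Carlo errors stay far smaller
than the effects tested while the full ladder remains practical on one CPU;
larger ensembles (10,000 trajectories) sharpen the density plots but do not
change the tested statistics.

Simulator validity is checked in the system-size limit: volume scaled to
`omega = 100` (transcription rates x100, so all counts scale x100 and the
bimolecular propensity scales /100), genes frozen on, toxicity threshold
effectively infinite — ensemble means must match the deterministic rate
equations of the same network within 3 standard errors. At small copy
numbers the SSA means sit a percent or two away from the ODE (real
finite-size covariance corrections, not an error).

## Population models (`satgrowth.population`)

Two-compartment metastable model: growing cells (rate `g`, per hour) switch
irreversibly into a non-growing arrested class at rate `s`; arrested cells
neither divide nor die. Then `lambda = g - s` and the arrested fraction
tends to `s/g` when `g > s`; the module checks the closed forms against
numerical integration. The switching rate follows the tail mass of the
noisy flux ratio `x = V+/V-` beyond the saturation point:
`s = s_max * Phi((x-1)/sigma_x)` with a Gaussian CDF — the distribution
family is a modeling choice (only "a CDF in x" is specified); `sigma_x`
defaults to 0.1 and `s_max` to twice the maximal growth rate so that deep
surfeit drives the population extinct (`lambda < 0`).

The fitness surface over demand and flux ratio uses
`g = g_max * f_gr(min(V+, Vmax), delta)` for the growing class — a
reconstruction of how demand enters — and shows an interior optimum just
below `x = 1` with a negative-growth region beyond it.

Four-state framework: balanced growth (rate `g`), a shifted state (rate
`g_hat`, a free parameter since the direction of the shift is unspecified),
viable arrest, and death, with transition rates `1/tau1` (balanced to
shifted), `1/tau_-1` (back), `1/tau2` (shifted to arrested), `1/tau_-2`
(arrested back to balanced growth), `1/tau3` (arrested to dead). The
population growth rate is the leading eigenvalue of the 4x4
growth-plus-transition generator; occupancies come from the leading
eigenvector. Limits: `tau1 -> inf` gives balanced growth (`lambda -> g`);
small `tau2` with large `tau_-1`, `tau_-2`, `tau3` recovers the metastable
model with `s = 1/tau1`.

## Inference stages (`satgrowth.inference`)

* **Gating:** scatter gate first (keep events within 0.5 SD of the mean
  forward and side scatter, linear coordinates), then remove events brighter
  than 6-fold the reference mean fluorescence (the low-dose condition's
  mean). With a fixed reference the operation is idempotent; recomputing the
  reference would be the one deviation, so the reference is an explicit
  argument.
* **Moments:** population (biased) moments; CV = SD/mean, skewness
  `m3/m2^1.5`, excess kurtosis `m4/m2^2 - 3`.
* **Growth rates:** OLS of `ln(OD - blank)` vs time on an early-exponential
  window: points above twice the blank, below 10% of the maximal
  blank-corrected OD (staying clear of saturation), with boxcar-smoothed
  local log-slopes within a 20% band below a robust (75th-percentile)
  reference slope. Slopes are double-smoothed because per-point slope noise
  otherwise fragments the window at realistic 2-minute sampling.
* **Fluorescence models:** a constitutive reporter concentrates as growth
  slows; the calibration is `F_cal(g) = a + b/g` (an exponential variant
  `a + b*exp(-c*g)` can be substituted). Uniform model: every cell grows at
  the population rate, `F = F_cal(g_pop)`. Heterogeneous model: growing
  cells grow at `g_grow = g_pop + s` so the net population rate is `g_pop`;
  the arrested fraction `phi = s/g_grow` (from the irreversible
  two-compartment bookkeeping — a reconstruction) fluoresces at `p_arr`, so
  `F = (1-phi)*F_cal(g_grow) + phi*p_arr`. Fitting is a 60x60 grid search
  over `(p_arr, s)` plus Nelder–Mead refinement on the sum of squares; the
  full SS surface and the predicted-vs-observed correlations of both modes
  are returned, and a flat surface raises a non-identifiability error. The
  heterogeneous model nests the uniform one at `s = 0`, so its optimal SS
  never exceeds the uniform SS.
* **AIC:** `AIC = n*ln(2*pi*RSS/n) + n + 2*(k+1)` with `k` regression
  coefficients — the Gaussian convention that counts the error variance and
  keeps the constants, verified in the test suite to agree with R's
  `AIC(lm(...))` to printed precision.
* **Kill curves:** `N(t) = N0*[(1-f)*exp(-k1*t) + f*exp(-k2*t)]`, `k1 > k2`,
  fitted by least squares on log10 CFU with log/logit internal
  parametrization and multi-start; censored points are substituted with the
  detection limit and flagged rather than dropped. Fits with `f ~ 0` or
  `k1/k2 < 1.5` are flagged non-biphasic.
* **Survival ratios:** matched-pair `log10(x_i/y_i)` with mean and SEM;
  zero treated counts enter at the detection limit, censor-flagged.

## Synthetic data (`satgrowth.synth`)

Every generator is deterministic under (seed, config) and stores its ground
truth beside the data. Fluorescence events are a two-component lognormal
mixture (growing dim, arrested bright) with Gaussian scatter — standard
stand-ins for how such instruments behave. OD curves are logistic
with multiplicative noise at 2-minute sampling; kill curves are
biexponential with lognormal counting noise and a detection limit; the
dose–response generator produces replicate rates with quadratic mean
structure (negative curvature, interior optimum near mid-dose). The
fluorescence-pair generator uses 10 conditions x 3 replicates at 2%
measurement noise, mirroring the triplicate design of the experiments it
emulates; with single measurements per condition the switching rate is only
identifiable to ~20% at that noise level.

What passing these tests shows: the inference stages invert the generative
models they assume, at realistic noise, sample sizes and censoring. What it
does not show: robustness to instrument artifacts (spillover, doublets),
non-lognormal event noise, model misspecification of the calibration curve,
or growth conditions outside the exponential-plus-saturation shape.

## Known limitations

* The benefit/toxicity functional forms and the volume scaling are stated
  reconstructions; all are config-switchable and the regime geometry, not
  the exact algebra, is the tested claim.
* Steady-state existence is decided below a finite cap `M_max`; a root
  beyond the cap is classified as runaway (both the analysis route and the
  oracle use the same cap, and the cap is configurable).
* Ensembles use 200 trajectories; quantities
  reported are means, fractions and correlation signs, for which 200
  trajectories give standard errors well below the tested effect sizes.
* The four-state framework is linear; density dependence, lag distributions
  and age structure are out of scope, as are cell division within SSA
  trajectories and spatial/colony effects.
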