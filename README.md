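# satgrowth

Models and inference for **enzyme-saturation-driven growth arrest** in
microbial populations.

When a metabolic pathway's consuming enzyme saturates, production can outrun
every removal route: the intracellular metabolite (or a toxic byproduct)
builds up without bound, growth stalls, and — because dilution and
growth-coupled gene expression stall with it — the state is effectively
irreversible. A population sitting near this threshold splits into a
fast-growing majority and a continuously produced arrested minority, which
shows up experimentally as heterogeneous reporter fluorescence, dead-cell
staining, and antibiotic-tolerant persisters. This package is for systems
biologists who want to simulate that mechanism quantitatively and apply the
matching inference to flow-cytometry, growth-curve and kill-curve data.

## What is inside

| module | content |
| --- | --- |
| `satgrowth.meanfield` | deterministic pathway `dM/dt = V⁺ − V⁻(M) − g·M` with `g = g_max·f_gr(V⁻/δ)·f_tox(x/θ)`; steady states, regime classification (I starvation / II satiation / III surfeit), phase diagrams, rescaled parameters R = V⁺/Vmax_B and Θ = θ/Km_B, first-passage times |
| `satgrowth.ssa` | exact Gillespie simulation of the 13-reaction growth-feedback network (gene toggling, transcription·f_tox·f_gr, translation, growth-coupled dilution, two-enzyme catalysis, product demand); mean-field initial states; ensembles with arrest fractions and growth correlations |
| `satgrowth.population` | metastable two-compartment model (λ = g − s, arrested fraction s/g, switching rate s = s_max·Φ((x−1)/σ_x)) and the four-state balanced/shifted/arrested/dead timescale framework (leading eigenvalue of the growth-transition generator) |
| `satgrowth.inference` | flow gating (0.5 SD scatter, 6-fold fluorescence filter), distribution moments, log-linear growth rates, uniform vs heterogeneous mean-fluorescence models with arrest parameters (p_arr, s), AIC model comparison, biphasic kill-curve fits, log10 survival ratios |
| `satgrowth.synth` | seeded generators with stored ground truth for every inference stage |
| `satgrowth.io` / `satgrowth.cli` | CSV/JSON table I/O, run manifests, and the `satgrowth` command-line tool |

## Worked example

Classify the growth regimes of the default substrate-toxicity pathway and
ask how fast a population grows when cells switch irreversibly into arrest:

```python
import numpy as np
from satgrowth.meanfield import PathwayParams, classify_regime, solve_steady_state
from satgrowth.population import SwitchingModelParams, metastable_growth_rate

for v_plus in (0.2, 0.8, 2.0):
    p = PathwayParams(v_plus=v_plus)          # delta=0.5, theta=100, Vmax_B=1
    ss = solve_steady_state(p)
    m = "none" if ss is None else f"{ss.m:.2f}"
    print(f"V+ = {v_plus:4.1f}  regime {classify_regime(p):3s}  M* = {m}")

res = metastable_growth_rate(SwitchingModelParams(g=1.0), horizon=40.0, s=0.25)
print(f"lambda = {res['lambda']:.2f} /h, arrested fraction = {res['arrested_fraction']:.2f}")
```

prints

```
V+ =  0.2  regime I    M* = 0.02
V+ =  0.8  regime II   M* = 0.40
V+ =  2.0  regime III  M* = none
```

— at low production the steady state exists but benefit is unsaturated
(starvation); at intermediate production the demand δ = 0.5 is met
(satiation); at high production no steady state exists and the metabolite
runs away (surfeit, growth arrest) — and

```
lambda = 0.75 /h, arrested fraction = 0.25
```

— a population growing at g = 1/h while losing cells to arrest at
s = 0.25/h still grows at λ = g − s = 0.75/h with a quarter of its cells
arrested at long times.

The stochastic ensemble scan (the expensive computation) runs from the CLI:

```bash
satgrowth simulate ensemble --k-ta 0.05 --k-im 10 --theta 1e4 --n 200 --t-end 8000 --seed 1 --out results/ens
satgrowth phase-diagram --out results/phase
satgrowth popmodel framework --tau1 1e9   # balanced-growth limit: lambda -> g
```

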