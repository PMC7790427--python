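# tmesim

A hybrid agent-based simulator of macrophage–T cell–tumor interactions in
the early tumor microenvironment, for computational immunologists studying
why macrophage-targeted immunotherapies succeed or fail and how on/off
treatment cycling changes their effect.

## The model

A 100 × 100 single-occupancy lattice (15 µm sites, a 1.5 × 1.5 mm tissue
slice) carries three agent types — cancer cells, macrophages (M0/M1/M2),
and T cells — coupled to a reaction–diffusion layer for three diffusible
factors *C_i* (macrophage activation factor, IL-4, IFN-γ):

    ∂C_i/∂t = D ∇²C_i − λC_i + k_sec,i · Cells(x, y)

Cancer cells proliferate under contact inhibition and release antigen when
they die. T cells are recruited at a death-driven saturating rate

    r(t) = k_a · N_c,death · r_1 / (k_i + N_c,death)

and become fully active only on antigen contact, with probability

    P_act = antigenPresence · σ( k·((antigenPresence − numM2/(numM1+1)) − s) )

so neighboring M2 macrophages suppress, and M1 macrophages promote, T-cell
activation. Active T cells kill by a timed engagement with a finite kill
budget (exhaustion), and secrete IFN-γ. Macrophages differentiate from
their local IL-4/IFN-γ readout via an intracellular decision model: marker
responses are collapsed into an M1/M2 score (product of M1 markers over
product of M2 markers; score > 1 → M1), and a one-hidden-layer, 4-neuron
sigmoid neural network trained on 100,000 Monte-Carlo samples of that
model replaces it as a fast surrogate (>98% held-out accuracy).

Three therapies act on the macrophage compartment, continuously or in
on/off cycles: **depletion** (per-step apoptosis, or bulk removal at cycle
starts), **recruitment inhibition** (rate scaled by 1 − strength), and
**PI3K inhibition** (re-education: the differentiation decision sees
PI3K activity 1 − strength, flipping M2 macrophages to M1).

See `docs/methods.md` for assumptions, parameter rationale, and
limitations.

## Worked example

Simulate one tumor with no treatment and one with continuous PI3K
inhibition started at day 100:

```python
from tmesim import SimParams, TreatmentSpec, run

params = SimParams()                      # 100x100 lattice, 200-day horizon
tc0, base = run(params, seed=1)
spec = TreatmentSpec("pi3k_inhibition", strength=1.0, start_day=100.0)
tc1, treated = run(params, treatment=spec, seed=1)
print(base.outcome, base.final_tumor, base.max_m1, base.max_active_t)
print(treated.outcome, round(treated.elimination_day, 1), treated.max_m1)
```

```
persisted 3517 0 92
eliminated 114.5 411
```

Untreated, the tumor persists for the full 200 days under immune pressure
(zero M1 macrophages ever appear and active T cells peak below 100: the
peritumoral M2 ring keeps T cells switched off). Under full PI3K
inhibition the macrophage compartment re-educates — 411 M1 macrophages at
peak — which unlocks T-cell activation and eliminates the tumor 14.5 days
after treatment starts. The time courses `tc0`/`tc1` are per-hour
DataFrames (cell counts, mean/max cytokine levels, treatment state).

The same machinery scales up to sweeps and sensitivity analyses:

```bash
tmesim run --seed 1 --out run_out                 # single run, CSV + JSON
tmesim sweep --strategy pi3k_inhibition \
             --strengths 0.0,0.5,1.0 --replicates 20
tmesim lhs --n-sets 50 --seed 1 --out lhs.csv     # Latin-hypercube analysis
```

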