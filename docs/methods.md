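# Methods

`tmesim` is a hybrid, on-lattice agent-based model of early tumor growth
and immune control in a 2-D tissue slice, built to study how
macrophage-targeted immunotherapies change the T-cell response. This note
documents the model, its assumptions, the shipped parameterization, and
the numerical choices, in the order a reader needs them to interpret
simulation output.

## Model structure

**Lattice.** A `height x width` grid (default 100 x 100) of 15-µm sites —
one cell diameter — representing a 1.5 x 1.5 mm slice. Each site holds at
most one cell; there is no pushing, compression, or off-lattice mechanics.
Boundaries are hard walls for cells and zero-flux for diffusibles: the
slice is closed.

**Cell types.** Three agent classes:

* *Cancer cells* proliferate on an internal clock with period
  `24 h / proliferation_rate_per_day` (30 h at the 0.8/day default; a
  1.2/day variant gives 20 h). A cell at its division time with no empty
  Moore neighbor becomes quiescent and re-checks for space every step. Cells
  die at the end of a lifespan (default 240 h; a division-budget mode is
  available, see Limitations). Cancer cells secrete the macrophage
  activation factor and IL-4 every step.
* *Macrophages* enter naive (M0), either as tissue residents (initial
  Bernoulli scatter, density 2e-3/site) or by constant-rate recruitment.
  Once the local activation factor crosses a threshold they differentiate
  using the intracellular model below, and re-evaluate ("redifferentiate")
  at most every 24 h. M2 macrophages secrete IL-4; M1 macrophages secrete
  nothing and act only through the T-cell activation rule. Lifespan 240 h.
* *T cells* are recruited at a rate driven by logged cancer-cell deaths
  (antigen release), arrive unactivated, and become fully active only by
  contacting antigen — an adjacent cancer cell or M1 macrophage — with a
  probability shaped by neighboring macrophage phenotypes (below). Active
  cells secrete IFN-γ, proliferate on a 24-h clock into empty neighbors
  (daughters arrive unactivated), and kill: an active T cell adjacent to a
  free cancer cell locks both into a mutual engagement for 6 h, after which
  the cancer cell dies. Each T cell can kill at most `kill_budget`
  (default 5) cells, then is exhausted. Lifespan 120 h.

**Diffusible factors.** Three fields on the same grid, in per-site molecule
counts: the tumor-secreted macrophage activation factor (representing
HMG-B1), IL-4 (tumor- and M2-secreted; M2-polarizing), and IFN-γ
(active-T-cell-secreted; M1-polarizing). Each obeys

    dC/dt = D ∇²C − λC + k_sec · [secreting cells]

The first-order decay term (default λ = 1/h) is an extension: with pure
diffusion plus secretion, per-site molecule counts grow without bound under
sustained secretion; λ = 0 recovers the undamped equations exactly. With
D = 2 µm²/s the diffusion length √(D/λ) ≈ 5.7 sites, giving the fields
genuine spatial structure on the lattice (near-tumor IL-4 tens of
molecules/site, distal sites near zero).

**T-cell activation.** The probability that an unactivated T cell in
contact with antigen becomes fully active is

    P_act = antigenPresence · σ( k·((antigenPresence − numM2/(numM1+1)) − s) )

with `antigenPresence` ∈ {0,1}, neighbor counts over the Moore
neighborhood, and σ the logistic function. M2 neighbors suppress
activation; M1 neighbors both provide antigen and buffer M2 suppression.
Shipped constants k = 6, s = 0.6 give P_act ≈ 0.92 with no macrophage
neighbors, ≈ 0.03 with a single M2 neighbor, and < 1e-4 when
numM2/(numM1+1) ≥ 3. The steepness matters: activation is redrawn every
1-h step, so a per-step suppressed probability of 0.1 would still activate
within half a day of contact and the M2 shield would be cosmetic. The
shipped values make suppression effective on the hours-to-days scale while
leaving bare-antigen contact near-certain, which is what produces the
signature baseline state (an M2 ring, very few active T cells, a
persistent immune-controlled tumor).

**T-cell recruitment.** Dying cancer cells (killed or end-of-lifespan) are
appended to a death log. The recruitment rate is

    r(t) = ka · N_death · r1 / (ki + N_death)

where N_death counts logged deaths inside the closed window of width
`t_window` (2 d) centered at `t − t_delay` (delay 3 d, covering priming
and trafficking). Defaults ka = 1, r1 = 60/day, ki = 10 deaths.
Fractional arrivals accumulate in a deterministic carry so long-run
arrivals match the rate exactly (a Poisson mode is selectable). Recruits
land on uniformly random empty sites, as do macrophage recruits (default
60/day); when the lattice fills, unplaced recruits are logged as
shortfall, so recruitment declines inherently in a crowded slice.

**Movement.** All motile cells chemotax toward the tumor by a biased
random walk on the activation-factor field: with probability
`chemotaxis_bias` (default 0.5) the cell steps to its highest-concentration
empty neighbor (never downhill; ties uniform), otherwise to a uniformly
random empty neighbor. Bias 1 is deterministic steepest ascent, bias 0 a
pure random walk. The stochastic component is deliberate: on a
single-occupancy lattice, deterministic ascent packs every recruited
immune cell into a static multi-shell ring that physically cages the tumor
and dominates the dynamics with a spatial artifact. A half-biased walk
keeps the peritumoral cloud loose and fluctuating — cells still
accumulate near the tumor (the M2 shield still forms) but a rim cancer
cell with any transiently free neighbor can still divide.

## Macrophage differentiation: stand-in model, score, surrogate

The differentiation decision maps the macrophage's local (IL-4, IFN-γ)
readout plus the current PI3K activity to a phenotype.

1. **Mechanistic stand-in.** The underlying biology is an intracellular
   signaling network whose published ODE description is outside this
   package; we ship an algebraic stand-in with the same input/output
   contract, exposed as a plug-in so a full time-course model can be
   substituted. Five M1 markers (iNOS, TNF-α, CXCL9, CXCL10, IL-12)
   respond to IFN-γ as `1 + α_j·H(ifng; K_I)`; three M2 markers (IL-10,
   Arg-1, VEGF) respond to IL-4 as `1 + β_j·pi3k·H(il4; K_4)`, with
   `H(x;K) = x/(x+K)`, staggered gains α = (0.8…1.2), β = (1.5, 2.0, 2.5)
   and K_I = K_4 = 20 molecules/site (mid-range of the simulator's
   realized concentrations). All markers are 1 at baseline; PI3K activity
   scales the M2 drive, so full PI3K inhibition abolishes it.
2. **M1/M2 score.** The product of M1 marker levels divided by the product
   of M2 marker levels, averaged over a 24-h window (for the steady-state
   stand-in the average equals the instantaneous value). Score > 1 commits
   to M1; a tie (the baseline state) falls to M2, the environment's
   default attractor. With the shipped constants the decision boundary is
   a nontrivial curve through the sampled box, e.g. at pi3k = 1 high IL-4
   regions are firmly M2 and high-IFN-γ/low-IL-4 regions firmly M1.
3. **Neural surrogate.** A network with one hidden layer of four sigmoid
   neurons (inputs IL-4, IFN-γ, PI3K activity normalized to [0,1] over the
   sampled ranges; one sigmoid output thresholded at 0.5) is trained on
   100,000 Monte-Carlo samples drawn uniformly over the simulator's
   cytokine ranges (IL-4, IFN-γ ∈ [0,100] molecules/site, PI3K ∈ [0,1])
   and labeled by (1)+(2). Training uses scikit-learn's MLP (logistic
   activations, adam, early stopping on a validation split); the fitted
   weights are extracted into a pure-numpy forward pass so prediction is
   deterministic and JSON-serializable. Held-out accuracy is recorded on
   the model and lands above 98%; agreement with the mechanistic label on
   a regular 50x50x3 input grid is also ≥ 98% for the default pipeline.
   Out-of-range queries are clamped to the box edges and counted. The
   simulator can use either decider; the mechanistic stand-in is the
   default (it is already a closed-form expression, so the surrogate's
   speed advantage only matters when a genuine ODE model is plugged in),
   and the surrogate path is exercised and validated in the test suite.

## Treatments

Three strategies, each with strength ∈ [0,1], a start day (default 100),
and a continuous or cycled schedule (`days_on` per `cycle_duration`;
on-time ≥ cycle length is rejected as it is just continuous treatment):

* **Depletion** — continuous: every macrophage dies with probability =
  strength per step (phenotype-blind); cycled: an exact round-half-up
  fraction = strength of all macrophages, sampled without replacement, is
  removed at each cycle start.
* **Recruitment inhibition** — macrophage recruitment rate scaled by
  (1 − strength) while on.
* **PI3K inhibition (re-education)** — the PI3K-activity input of every
  differentiation decision becomes (1 − strength) while on. Nothing else
  is touched: the therapy acts purely through the differentiation model,
  so M2 macrophages flip to M1 at their next 24-h re-evaluation, which
  recruits the M1 → T-cell-activation → IFN-γ → M1 feedback loop.

Schedules are pure functions of time; a strength-0 arm of any strategy
consumes no random draws and reproduces the untreated trajectory
bit-exactly under the same seed.

## Engine step and reproducibility

Each 1-h step executes: (1) secretion by current secreters, then
diffusion/decay; (2) macrophage recruitment (treatment-adjusted); (3)
macrophages in a freshly permuted random order; (4) T-cell recruitment,
then T cells in random order; (5) cancer cells in random order; (6) dead
agents removed; (7) treatment events (continuous depletion draws,
cycle-start bulk removal); (8) recording. Engaged pairs are frozen — they
do not age, move, secrete, or divide — until the engagement timer expires.
A run stops at elimination, at a tumor-cell cap (default 5,000; by then
recruitment is space-starved), or at 200 days. One PCG64 stream seeded
from the config drives every draw, so (seed, params, treatment) determine
every output byte; the experiment layer derives distinct, logged replicate
seeds from a SeedSequence.

The per-step depletion probability, activation redraws, and all per-step
clocks are dt-dependent; shipped thresholds are calibrated at dt = 1 h and
will shift if the step is changed.

## Numerics

The diffusion solver is an explicit 5-point finite-difference scheme with
reflecting (zero-flux) boundaries. A macro step is internally sub-cycled
into the minimal number of sub-steps obeying D·dt/h² ≤ 1/4, which makes
the update a convex combination: non-negativity is preserved exactly and,
with zero decay and secretion, total mass is conserved to floating-point
accuracy (verified to 1e-10 relative over 10,000 sub-steps). Decay is
applied per sub-step as an exact exponential factor. The kernel is
numba-compiled; with the default constants a 1-h step on 100 x 100 costs
~128 sub-steps per field.

Cycled-treatment cycle starts are detected by comparing cycle indices of
consecutive step endpoints, so no start can be skipped regardless of dt.
Round-half-up is used for the cycled-depletion removal count.

## Parameterization and calibration

Most rate constants of the source system are not published; the shipped
values are the package's own calibration, chosen once to reproduce the
documented qualitative regime and then frozen:

| parameter | default | rationale |
|---|---|---|
| dt | 1 h | resolves the 6-h engagement and 24-h clocks |
| D (all factors) | 2 µm²/s | protein-scale diffusivity in dense tissue; 5.7-site diffusion length |
| λ (all factors) | 1 /h | cytokine half-life ~40 min |
| k_sec tumor (activation, IL-4) | 30 /h | near-tumor IL-4 ≈ 10–80 molecules/site, brackets K_4 |
| k_sec M2 (IL-4) | 15 /h | half the tumor rate |
| k_sec active T (IFN-γ) | 30 /h | symmetric to IL-4 drive |
| activation threshold | 1 molecule/site | licenses differentiation within ~20 sites of an established tumor; distal residents stay M0 for the first days |
| macrophage recruitment | 60 /day | sustains a peritumoral M2 population of several hundred |
| ka, r1, ki | 1, 60 /day, 10 deaths | saturating T influx comparable to the macrophage supply |
| t_delay, t_window | 3 d, 2 d | priming/trafficking delay; closed accumulation window |
| lifespans (mac, T, cancer) | 240, 120, 240 h | tissue-macrophage ≫ effector-T turnover; cancer churn feeds antigen release |
| kill budget, engagement | 5 kills, 6 h | lattice-ABM killing convention |
| k, s (activation) | 6, 0.6 | see T-cell activation above |

Under these defaults, a 100 x 100 no-treatment run persists for the full
200 days under immune pressure: growth is slowed far below the
immune-free curve (a few thousand tumor cells by day 200 instead of the
5,000-cell cap within ~40 days), several hundred M2 macrophages ring the
tumor, no M1 macrophage ever appears, and T cells hold around 400 with
fewer than 100 active. Started at day 100, continuous PI3K inhibition
1.0, depletion 0.05/step, and complete recruitment inhibition each
eliminate the tumor within two to four weeks of onset — PI3K re-education
fastest into its characteristic M1 and active-T surge, recruitment
inhibition slowest and without any M1. These are emergent outcomes of the
calibration, not fitted targets; the precise equilibrium size and the
exact threshold strengths depend on the unpublished constants and on dt,
and are reproduced qualitatively, not numerically.

## Desk-scale experiment profile

Replicate experiments in the test suite use a scaled profile chosen for
tractable runtimes and fixed before the acceptance tests were written:
a 50 x 50 lattice with recruitment scaled by the area ratio (15/day each),
tumor cap 1,500, horizons of 30–60 days, and treatment starting at day 20,
after the scaled system has settled. All other constants are the
full-scale defaults.

## What the simulations do and do not show

The model demonstrates mechanisms, not patient-level predictions. It omits
angiogenesis, hypoxia, nutrient limitation, stroma, lymph-node dynamics,
antigen heterogeneity, Treg/Th subsets, checkpoint-ligand mechanics, and
any difference in physical cell size. Cytokine "concentrations" are
per-site molecule counts with no volume convention. The synthetic dynamics
share the published system's qualitative structure but none of its fitted
constants, so passing tests certify internal consistency and qualitative
mechanism reproduction — threshold strengths, equilibrium sizes, and
timing should not be read as quantitative predictions for any real tumor.

Known limitations worth flagging:

* In the division-budget lifespan mode, space-trapped interior cells never
  spend their budget, so a fully quiescent tumor core is immortal and —
  with no natural deaths — T-cell recruitment never ignites. The
  hours-based lifespan (default) avoids this degeneracy and is the mode
  the shipped dynamics assume.
* Immune cells occupy lattice sites, so very large immune populations
  always exert some residual spatial drag on tumor growth even with all
  immune function disabled; the biased-walk movement keeps this small but
  cannot remove it entirely on a single-occupancy lattice.
* The surrogate's decision boundary at PI3K ≈ 0 is discontinuous in the
  stand-in (any positive IFN-γ flips the label), which bounds achievable
  grid agreement slightly below 100% no matter the training budget.
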