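# Methods

## Model

`telosim` simulates a capped pool of replicating cells (default `N = 400`)
in discrete time steps of `dt = 0.1 h`.  Each cell carries five attributes:
a dimensionless DNA-damage level `D`, a birth time, a pre-drawn survival
time, a telomere length `T` (bp), and a mutation counter `n_mut`.

Three damage-driven rules define the dynamics, all using the saturating
sigmoid `g(D) = D^2 / (D^2 + 1)` by default:

* **Mutation.**  A cell mutates with per-division hazard
  `r_M = alpha * g(D)` (default `alpha = 1` per division).  Because the
  simulation advances in hours, the per-step Bernoulli probability is
  `r_M * dt / doubling_time`, so a cell held at `D` for one doubling time
  (24 h) accrues `r_M` expected mutations.  At the "physiological" damage
  `D = 0.5` this gives the reference rate 0.2 per cell per division.
* **Death.**  Each cell's lifetime is drawn at birth from an exponential
  law with rate `beta0 + beta * g(D)` — a damage-independent background
  rate (`beta0 = 0.02 /h`) plus p53-mediated, damage-dependent removal
  (`beta = 0.1 /h` scale).  Both rates are treated as per hour; with this
  reading the total death rate at physiological damage is about `0.04 /h`,
  i.e. a mean cell turnover on the order of the 24 h doubling time.
* **Telomere attrition.**  `dT/dt = -gamma * D_eff^p * T` with
  `gamma = 1.5e-3 /h` and exponent `p = 1` by default; integrated by
  forward Euler per step (`T <- T * (1 - gamma * D_eff^p * dt)`), which at
  `dt = 0.1 h` stays within 0.01 % per day of the exact exponential.  At
  low damage `D = 0.2` a full-length 15 kb telomere loses ~108 bp per
  division, matching the experimental 50–100 bp/division calibration.
  `D_eff` is the cell's own damage under **SITS** (stress-induced telomere
  shortening) or a fixed constant under **TS** (classical constant-rate
  shortening).  A discrete variant applies one doubling time's worth of
  attrition at division instead.

Cells whose telomere reaches the critical length (2000 bp) become senescent
and leave the replicating pool, as do cells whose age reaches their drawn
survival time.  Every vacancy below the cap is filled by dividing one cell
chosen uniformly among division-mature cells; the two daughters inherit the
parent's telomere length and mutation count and draw fresh damage and
survival times.  Damage is redrawn only at division: fluctuations on the
cell-cycle timescale are the regime where cell-to-cell heterogeneity
matters.

### Damage assignment

Per-cell damage is drawn from a Gaussian with mean `mu_D` and spread
`sigma_D`, with negative proposals rejected and resampled (damage cannot be
negative).  Rejection keeps the realised density proportional to the
Gaussian on `[0, inf)`; a `clip` option (atom at zero) exists for
comparison.  Because of the truncation — and because damage-dependent death
preferentially removes high-damage cells — the realized mean damage `<D>`
(cell-time-weighted average over replicating cells) exceeds `mu_D` and is
the quantity reported on damage axes.  The helper
`calibrate_damage_mean` bisects `mu_D` against short pilot ensembles
(common random numbers across iterations) to hit a target `<D>`; note that
a target `<D> = 0.25` at CV 1.5 requires a *negative* `mu_D` (about
−0.084), i.e. most of the Gaussian mass is rejected and the realised
distribution is a heavy right tail.  Lognormal (moment-matched) and
two-component Gaussian mixture families are available for robustness
checks; the mixture re-proposes its component when rejecting negatives.

### Initial conditions and founder maturity

The founding population starts at the cap with full-length telomeres
(15 kb), zero mutations, `t_birth = 0`, and independent damage/survival
draws.  Founders are division-mature immediately, whereas daughters must
reach age 24 h before they may divide.  This matters: with mean cell
lifetimes of ~40 h, a fully synchronized founding cohort that cannot divide
for its first 24 h would lose nearly half its members with no replacement,
crash below half the cap within a few doublings, and corrupt the longevity
observable with an initialisation artefact.  Treating founders as members
of a pre-existing asynchronous culture (mature at `t = 0`) removes the
artefact without touching any model rule that applies from the first
division onward.

## Observables

* **Longevity `L`** — first recorded time, in cell doublings (24 h), at
  which the replicating population drops below half the cap (200 of 400).
  Runs truncated by a `max_time` bound report their longevity explicitly
  flagged as censored.
* **Mutation rate** — total mutation events divided by integrated
  cell-time (in cell·doublings), i.e. the event rate per cell per doubling
  averaged over the whole run.  This definition is unbiased under
  population-size changes.  A slope-based alternative (growth rate of the
  population-mean counter `<M>(t)`, which is additionally affected by the
  selective removal of highly mutated cells) is available as
  `mean_mutation_slope` for comparison.
* **Realized mean damage `<D>`** — cell-time-weighted average damage.
* Time series of population size, mean telomere length, mean mutation
  count, and 250 bp telomere-length histograms, recorded every simulated
  doubling.

Note that the population-mean telomere length is *not* monotonically
non-increasing: late in a SITS run, senescent (shortest-telomere) cells are
continuously replaced by daughters of longer-telomere cells, which can
raise the average by a few bp per doubling and holds `<T>` just above the
critical length for tens of doublings — this plateau is precisely the
SITS longevity mechanism, so only lineage-wise monotonicity is asserted.

## The SITS-vs-TS experiment

`compare_sits_ts` runs paired ensembles: the SITS arm as configured, and a
TS arm identical in every way (same replicate seeds, same damage statistics
for mutation and apoptosis) except that attrition sees the fixed effective
damage `Const`, set to the SITS arm's realized `<D>` so the attrition
mechanism is the only difference.  The headline ratios are ratios of
ensemble means, `R_M = <rate_SITS>/<rate_TS>` and `R_L = <L_SITS>/<L_TS>`.

Under TS with the continuous update, every cell's telomere follows the
same deterministic decay (daughters inherit the parent's length and all
cells shorten by the same factor), so the whole population senesces at
once: `L_TS = ln(T0/Tc) / (gamma * Const * 24)` doublings (~224 at
`Const = 0.25`) with near-zero variance.  Under SITS, heterogeneous damage
histories widen the telomere distribution and the population maintains
itself above the critical length substantially longer (`R_L ≈ 1.13` at
`<D> = 0.25`, CV 1.5 with 20 replicates per arm), while the mutation-event
rate is slightly reduced (`R_M` just below 1): the two arms share the same
stationary damage distribution, so the event-rate difference comes only
from the late phase, where SITS senescence preferentially truncates the
cell-time of high-damage (high-hazard) cells.  The slope-based rate, which
also feels the removal of accumulated mutation loads, shows a larger
effect; the event-rate definition is the conservative primary choice.

With zero cell-to-cell spread (`sigma_D = 0`) and `Const = mu_D`, the two
arms are the same stochastic process and paired seeds give bit-identical
trajectories — the null case used both as an engine test and as the CV = 0
anchor of the heterogeneity scan.

## Ensembles, seeds and determinism

Replicate seeds derive from a base seed via `numpy.random.SeedSequence`
spawning (kept below 2^31 so each replicate is re-runnable in isolation).
A run is a deterministic function of `(params, seed)`: each step consumes
the stream in a fixed order (mutation uniforms, division-parent selection,
daughter damage, daughter survival), with daughter draws taken from
pre-drawn blocks whose size is a fixed constant of the implementation.
Failed replicates are excluded with a warning, never silently averaged.

## Problem sizes

Default experiments use the full population (400 cells; trajectories of
250–300 doublings ≈ 60–70 k steps, a few seconds each).  Ensemble sizes in
the package's own test suite and acceptance script are 16–20 replicates per
arm for the reference comparison and 5–12 for robustness scans (system size
1600, alternative hazard shapes, attrition exponent 2) — chosen so the
strong longevity effect and the small mutation-rate effect are resolved
against Monte-Carlo error at desk scale; scientific production runs should
use ~100 replicates as a matter of course.  Pilot ensembles inside the
damage calibration are truncated at 150 doublings, where the damage
statistics are already stationary.

## Known limitations

* One telomere per cell; real cells senesce on the shortest of 92.
* No telomerase, stem-cell compartment, T-SCE recombination, or coupling
  between p53 and telomere state; no spatial structure or signalling.
* The per-hour reading of `beta0` and `beta` is a reconciliation choice:
  the sources constrain `gamma` (bp/division calibration) and `alpha`
  (per division) but do not state the time base of the death rates.  With
  the per-hour reading the stated parameter values reproduce the intended
  population behaviour (turnover ~ doubling time; hundreds of doublings of
  longevity); a per-division reading would slow turnover ~25-fold.
* At heavy genotoxic load (realized `<D>` well above ~0.4) daughter
  maturation cannot keep up with turnover and the population sags below
  the cap even without attrition; observables there describe a declining
  pool.
* The fixed-timestep scheme resolves hazards to `O(dt)`; events within a
  step are ordered (attrition, mutation, removal, division) rather than
  exact in continuous time.
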