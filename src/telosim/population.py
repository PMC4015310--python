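"""Fixed-timestep simulation loop over the replicating cell population.

The population is held in preallocated numpy buffers (one slot per cell,
capacity = population cap) so each 0.1 h step is a handful of vectorised
operations.  One step performs, in order:

1. telomere attrition for every cell (continuous update mode),
2. a Bernoulli mutation trial per cell at the thinned per-step probability,
3. removal of cells that turned senescent (``T <= critical_telomere``) or
   whose age reached their pre-drawn survival time,
4. division: for every vacancy below the population cap, one cell chosen
   uniformly among the division-mature cells is replaced by two daughters
   that inherit its telomere length and mutation count and get freshly drawn
   damage and survival time.  Daughters mature ``doubling_time`` hours after
   birth; the founding cells stand in for a pre-existing asynchronous
   population and are mature from t = 0 (otherwise the synchronized founding
   cohort — born together, mean lifetime shorter than one doubling time —
   would crash the population in the first few doublings, an initialisation
   artefact rather than model behaviour).

Deaths are processed for all cells before any division, and parents are
sampled without replacement, so the step is independent of cell ordering.
If vacancies outnumber mature cells the deficit persists — that is how the
population declines and eventually goes extinct.

The random stream is consumed in a fixed order each step (mutation uniforms,
parent selection, daughter damage, daughter survival times), making a run a
deterministic function of ``(params, seed)``.
"""

from __future__ import annotations

from typing import List, Optional

import numpy as np

from .model import (CellState, draw_damage, draw_survival_time,
                    step_mutation_probability)
from .observables import RunRecord
from .params import ModelParams

__all__ = ["PopulationState", "initialize_population", "advance_one_step",
           "run_simulation"]

_BUFFERS = ("damage", "birth_time", "death_time", "mature_time",
            "telomere", "mutations", "attr_factor", "mut_p")


class PopulationState:
    """Buffer-backed state of the replicating pool at one instant.

    The public array attributes (``damage``, ``telomere``, ...) are views of
    the live prefix of the underlying buffers; treat them as read-only
    snapshots.
    """

    __slots__ = tuple("_" + b for b in _BUFFERS) + (
        "n", "clock", "terminated",
        "total_mutation_events", "cell_time_hours", "damage_time")

    def __init__(self, damage, birth_time, death_time, telomere, mutations,
                 attr_factor, mut_p, clock: float = 0.0, mature_time=None,
                 capacity: Optional[int] = None):
        n = len(damage)
        cap = max(capacity or n, n)
        if mature_time is None:
            # default: cells may divide as soon as they exist (founder
            # semantics); daughters created by the engine mature one
            # doubling time after birth
            mature_time = np.asarray(birth_time, dtype=float).copy()
        values = dict(damage=damage, birth_time=birth_time,
                      death_time=death_time, mature_time=mature_time,
                      telomere=telomere, mutations=mutations,
                      attr_factor=attr_factor, mut_p=mut_p)
        for name, val in values.items():
            dtype = np.int64 if name == "mutations" else float
            buf = np.zeros(cap, dtype=dtype)
            buf[:n] = val
            setattr(self, "_" + name, buf)
        self.n = n
        self.clock = clock
        self.terminated = False
        # run accumulators
        self.total_mutation_events = 0
        self.cell_time_hours = 0.0
        self.damage_time = 0.0              # integral of sum_i D_i dt

    def _grow(self, capacity: int) -> None:
        for name in _BUFFERS:
            buf = getattr(self, "_" + name)
            if buf.shape[0] < capacity:
                new = np.zeros(capacity, dtype=buf.dtype)
                new[:self.n] = buf[:self.n]
                setattr(self, "_" + name, new)

    @property
    def size(self) -> int:
        return self.n

    @property
    def cells(self) -> List[CellState]:
        """Materialise per-cell views (convenience; not used in the hot loop)."""
        return [
            CellState(damage=float(self.damage[i]),
                      birth_time=float(self.birth_time[i]),
                      survival_time=float(self.death_time[i] - self.birth_time[i]),
                      telomere_length=float(self.telomere[i]),
                      mutation_count=int(self.mutations[i]))
            for i in range(self.n)
        ]


def _add_view(name: str) -> None:
    def get(self: PopulationState) -> np.ndarray:
        return getattr(self, "_" + name)[:self.n]
    setattr(PopulationState, name, property(get))


for _name in _BUFFERS:
    _add_view(_name)
del _name


def _effective_damage(damage: np.ndarray, params: ModelParams) -> np.ndarray:
    if params.telomere_mode == "TS":
        return np.full_like(damage, params.ts_constant)
    return damage


def _per_step_factors(damage: np.ndarray, params: ModelParams):
    """Precompute each cell's attrition multiplier and mutation probability."""
    d_eff = _effective_damage(damage, params)
    if params.telomere_update == "continuous":
        attr = np.maximum(
            1.0 - params.gamma * d_eff ** params.attrition_exponent * params.dt, 0.0)
    else:
        attr = np.ones_like(d_eff)
    return attr, step_mutation_probability(damage, params)


def initialize_population(params: ModelParams,
                          rng: np.random.Generator) -> PopulationState:
    """Founding population: cap cells, full-length telomeres, no mutations.

    Founders have ``t_birth = 0`` and are division-mature immediately.
    """
    n = params.population_cap
    damage = draw_damage(params, rng, size=n)
    tau = draw_survival_time(damage, params, rng)
    attr, mut_p = _per_step_factors(damage, params)
    return PopulationState(
        damage=damage,
        birth_time=np.zeros(n),
        death_time=np.asarray(tau, dtype=float),
        telomere=np.full(n, float(params.initial_telomere)),
        mutations=np.zeros(n, dtype=np.int64),
        attr_factor=attr,
        mut_p=mut_p,
    )


class _DrawCache:
    """Block-drawn damage / survival-time reservoir for the hot loop.

    Divisions usually create one or two daughters per step; drawing their
    damage and survival times in blocks of a few thousand amortises the
    fixed cost of the vectorised samplers.  The block size is a constant of
    the implementation, so a run remains a deterministic function of
    ``(params, seed)``.
    """

    __slots__ = ("params", "rng", "block", "damage", "tau", "attr", "mut_p",
                 "pos")

    def __init__(self, params: ModelParams, rng: np.random.Generator):
        self.params = params
        self.rng = rng
        self.block = max(4096, 2 * params.population_cap)
        self.pos = self.block        # trigger refill on first take

    def _refill(self) -> None:
        d = draw_damage(self.params, self.rng, size=self.block)
        self.damage = d
        self.tau = draw_survival_time(d, self.params, self.rng)
        self.attr, self.mut_p = _per_step_factors(d, self.params)
        self.pos = 0

    def take(self, k: int):
        if self.pos + k > self.block:
            self._refill()
        sl = slice(self.pos, self.pos + k)
        self.pos += k
        return self.damage[sl], self.tau[sl], self.attr[sl], self.mut_p[sl]


def _remove(state: PopulationState, idx: np.ndarray) -> None:
    """Swap-delete the given slots (cheap: removals per step are few)."""
    bufs = [getattr(state, "_" + b) for b in _BUFFERS]
    n = state.n
    for i in sorted(map(int, idx), reverse=True):
        n -= 1
        if i != n:
            for buf in bufs:
                buf[i] = buf[n]
    state.n = n


def _divide(state: PopulationState, params: ModelParams,
            rng: np.random.Generator, t_now: float,
            cache: Optional[_DrawCache] = None) -> None:
    """Fill vacancies below the cap by dividing mature cells."""
    deficit = params.population_cap - state.n
    if deficit <= 0 or state.n == 0:
        return
    mature = np.nonzero(t_now >= state._mature_time[:state.n])[0]
    n_div = min(deficit, mature.size)
    if n_div == 0:
        return
    parents = (mature if n_div == mature.size
               else rng.choice(mature, size=n_div, replace=False))

    child_t = state._telomere[parents]
    if params.telomere_update == "discrete":
        d_eff = _effective_damage(state._damage[parents], params)
        child_t = np.maximum(
            child_t * (1.0 - params.gamma * d_eff ** params.attrition_exponent
                       * params.doubling_time), 0.0)
    # slot order below is (all parent slots, then tail slots): daughter i of
    # parent j must land at position j in each half, hence tile not repeat
    child_t = np.tile(child_t, 2)
    child_mut = np.tile(state._mutations[parents], 2)

    n_child = 2 * n_div
    if cache is not None:
        child_d, child_tau, child_attr, child_mut_p = cache.take(n_child)
    else:
        child_d = draw_damage(params, rng, size=n_child)
        child_tau = draw_survival_time(child_d, params, rng)
        child_attr, child_mut_p = _per_step_factors(child_d, params)

    # each parent slot takes one daughter; the other goes to the tail
    tail = np.arange(state.n, state.n + n_div)
    slots = np.concatenate([np.asarray(parents), tail])
    state.n += n_div
    state._damage[slots] = child_d
    state._birth_time[slots] = t_now
    state._death_time[slots] = t_now + child_tau
    state._mature_time[slots] = t_now + params.doubling_time
    state._telomere[slots] = child_t
    state._mutations[slots] = child_mut
    state._attr_factor[slots] = child_attr
    state._mut_p[slots] = child_mut_p


def advance_one_step(state: PopulationState, params: ModelParams,
                     rng: np.random.Generator,
                     cache: Optional[_DrawCache] = None) -> PopulationState:
    """Advance the population by one dt (in place; returns the state)."""
    if state.n == 0:
        state.terminated = True
        return state
    if state._damage.shape[0] < params.population_cap:
        state._grow(params.population_cap)
    n = state.n
    dt = params.dt
    t_new = state.clock + dt

    # exposure accumulators (cell-time weighting of observables)
    state.cell_time_hours += n * dt
    state.damage_time += float(state._damage[:n].sum()) * dt

    # telomere attrition (continuous mode; discrete mode updates at division)
    if params.telomere_update == "continuous":
        state._telomere[:n] *= state._attr_factor[:n]

    # mutation Bernoulli trials
    hits = np.nonzero(rng.random(n) < state._mut_p[:n])[0]
    if hits.size:
        state._mutations[hits] += 1
        state.total_mutation_events += hits.size

    # senescence / death removal (batch: all deaths before any division)
    dead = np.nonzero((state._telomere[:n] <= params.critical_telomere)
                      | (t_new >= state._death_time[:n]))[0]
    if dead.size:
        _remove(state, dead)

    # division with replacement
    _divide(state, params, rng, t_new, cache)

    state.clock = t_new
    if state.n == 0:
        state.terminated = True
    return state


def run_simulation(params: ModelParams, seed: int,
                   record_histograms: bool = True) -> RunRecord:
    """Run one trajectory to extinction (or to ``max_time``) and record it.

    Observables are recorded every ``params.record_every`` hours plus once at
    the terminal step.  Times in the returned :class:`RunRecord` are in units
    of cell doublings (``doubling_time`` hours).
    """
    if params.max_time == 0 and not params.can_terminate():
        raise ValueError(
            "this configuration has no telomere attrition and may never "
            "terminate; set max_time to run it")
    rng = np.random.default_rng(seed)
    state = initialize_population(params, rng)
    cache = _DrawCache(params, rng)

    edges = np.arange(0.0, params.initial_telomere + 250.0, 250.0)
    times, pop, mean_t, mean_m, hists = [], [], [], [], []

    def _record() -> None:
        times.append(state.clock)
        pop.append(state.n)
        if state.n:
            mean_t.append(float(state.telomere.mean()))
            mean_m.append(float(state.mutations.mean()))
            if record_histograms:
                hists.append(np.histogram(state.telomere, bins=edges)[0])
        else:
            mean_t.append(np.nan)
            mean_m.append(np.nan)
            if record_histograms:
                hists.append(np.zeros(edges.size - 1, dtype=np.int64))

    _record()
    next_record = params.record_every
    truncated = False
    eps = 1e-6
    while state.n > 0:
        advance_one_step(state, params, rng, cache)
        if state.clock >= next_record - eps and state.n > 0:
            _record()
            next_record += params.record_every
        if params.max_time and state.clock >= params.max_time - eps:
            truncated = True
            break
    if not times or abs(times[-1] - state.clock) > eps or state.n == 0:
        _record()  # terminal point (possibly N = 0)

    div = params.doubling_time
    return RunRecord(
        times=np.asarray(times) / div,
        population_size=np.asarray(pop, dtype=np.int64),
        mean_telomere=np.asarray(mean_t),
        mean_mutations=np.asarray(mean_m),
        telomere_histogram=(np.asarray(hists) if record_histograms else None),
        histogram_edges=(edges if record_histograms else None),
        realized_mean_damage=(state.damage_time / state.cell_time_hours
                              if state.cell_time_hours > 0 else 0.0),
        total_mutation_events=state.total_mutation_events,
        total_cell_time=state.cell_time_hours / div,
        terminal_time=state.clock / div,
        truncated=truncated,
        params=params,
        seed=seed,
    )
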