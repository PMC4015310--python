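"""Model parameters and validation.

All rates are per hour unless noted otherwise; the mutation-hazard scale
``alpha`` is per cell division and is converted to the per-step timescale
inside the population engine (``r_M * dt / doubling_time``).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Tuple

DAMAGE_FAMILIES = ("gaussian_truncated", "lognormal", "bimodal")
TELOMERE_MODES = ("SITS", "TS")
TELOMERE_UPDATES = ("continuous", "discrete")
HAZARD_FORMS = ("hill2", "linear", "hill1", "hill4")
NEGATIVE_DAMAGE_POLICIES = ("resample", "clip")


@dataclass(frozen=True)
class ModelParams:
    """Complete configuration of one simulated cell population.

    Defaults are the reference parameterisation of the model: a pool of 400
    replicating human-fibroblast-like cells, initial telomere length 15 kb,
    senescence below 2 kb, per-division mutation-hazard scale ``alpha = 1``,
    damage-dependent apoptosis scale ``beta = 0.1`` /h on top of a
    damage-independent background death rate ``beta0 = 0.02`` /h, and
    telomere attrition constant ``gamma = 1.5e-3`` /h (about 50--100 bp lost
    per division at low damage ``D = 0.2``).
    """

    # hazard scales
    alpha: float = 1.0          # mutation-hazard scale, per cell division
    beta: float = 0.1           # apoptosis-hazard scale, per hour
    beta0: float = 0.02         # background (damage-independent) death rate, per hour
    gamma: float = 1.5e-3       # telomere attrition constant, per hour

    # damage-assignment distribution
    damage_mean: float = 0.25   # mu_D; may be negative for the truncated Gaussian
    damage_sd: float = 0.375    # sigma_D >= 0
    damage_family: str = "gaussian_truncated"
    negative_damage: str = "resample"   # gaussian_truncated only: resample | clip
    bimodal_means: Optional[Tuple[float, float]] = None
    bimodal_sds: Optional[Tuple[float, float]] = None
    bimodal_weight: float = 0.5         # weight of the first (low) component

    # telomere dynamics
    telomere_mode: str = "SITS"         # SITS: attrition uses per-cell D; TS: constant
    ts_constant: Optional[float] = None  # effective damage used by TS mode
    attrition_exponent: float = 1.0     # power p applied to damage in the attrition law
    telomere_update: str = "continuous"  # continuous (per step) | discrete (at division)

    # hazard shapes (robustness scans)
    mutation_form: str = "hill2"
    apoptosis_form: str = "hill2"

    # population / geometry
    population_cap: int = 400
    initial_telomere: float = 15000.0   # bp
    critical_telomere: float = 2000.0   # bp
    doubling_time: float = 24.0         # hours; minimum age before division
    dt: float = 0.1                     # hours
    longevity_threshold: Optional[int] = None   # default: population_cap // 2

    # run control
    max_time: float = 0.0               # hours; 0 disables the safety bound
    record_every: float = 24.0          # hours between recorded observables

    def __post_init__(self) -> None:
        if self.longevity_threshold is None:
            object.__setattr__(self, "longevity_threshold", self.population_cap // 2)
        if self.bimodal_means is not None:
            object.__setattr__(self, "bimodal_means", tuple(self.bimodal_means))
        if self.bimodal_sds is not None:
            object.__setattr__(self, "bimodal_sds", tuple(self.bimodal_sds))
        self.validate()

    def validate(self) -> None:
        def _require(cond: bool, msg: str) -> None:
            if not cond:
                raise ValueError(f"invalid ModelParams: {msg}")

        _require(self.alpha >= 0, f"alpha must be >= 0, got {self.alpha}")
        _require(self.beta >= 0, f"beta must be >= 0, got {self.beta}")
        _require(self.beta0 >= 0, f"beta0 must be >= 0, got {self.beta0}")
        _require(self.gamma >= 0, f"gamma must be >= 0, got {self.gamma}")
        _require(self.damage_sd >= 0, f"damage_sd must be >= 0, got {self.damage_sd}")
        _require(self.damage_family in DAMAGE_FAMILIES,
                 f"damage_family must be one of {DAMAGE_FAMILIES}, got {self.damage_family!r}")
        _require(self.negative_damage in NEGATIVE_DAMAGE_POLICIES,
                 f"negative_damage must be one of {NEGATIVE_DAMAGE_POLICIES}, "
                 f"got {self.negative_damage!r}")
        _require(self.telomere_mode in TELOMERE_MODES,
                 f"telomere_mode must be one of {TELOMERE_MODES}, got {self.telomere_mode!r}")
        if self.telomere_mode == "TS":
            _require(self.ts_constant is not None,
                     "telomere_mode='TS' requires ts_constant")
            _require(self.ts_constant >= 0,
                     f"ts_constant must be >= 0, got {self.ts_constant}")
        _require(self.attrition_exponent > 0,
                 f"attrition_exponent must be > 0, got {self.attrition_exponent}")
        _require(self.telomere_update in TELOMERE_UPDATES,
                 f"telomere_update must be one of {TELOMERE_UPDATES}, "
                 f"got {self.telomere_update!r}")
        _require(self.mutation_form in HAZARD_FORMS,
                 f"mutation_form must be one of {HAZARD_FORMS}, got {self.mutation_form!r}")
        _require(self.apoptosis_form in HAZARD_FORMS,
                 f"apoptosis_form must be one of {HAZARD_FORMS}, got {self.apoptosis_form!r}")
        _require(self.population_cap >= 1,
                 f"population_cap must be >= 1, got {self.population_cap}")
        _require(self.initial_telomere > 0,
                 f"initial_telomere must be > 0, got {self.initial_telomere}")
        _require(self.critical_telomere > 0,
                 f"critical_telomere must be > 0, got {self.critical_telomere}")
        _require(self.critical_telomere < self.initial_telomere,
                 f"critical_telomere ({self.critical_telomere}) must be below "
                 f"initial_telomere ({self.initial_telomere})")
        _require(self.doubling_time > 0,
                 f"doubling_time must be > 0, got {self.doubling_time}")
        _require(self.dt > 0, f"dt must be > 0, got {self.dt}")
        _require(self.dt < self.doubling_time,
                 f"dt ({self.dt}) must be below doubling_time ({self.doubling_time})")
        _require(1 <= self.longevity_threshold <= self.population_cap,
                 f"longevity_threshold ({self.longevity_threshold}) must be in "
                 f"[1, population_cap={self.population_cap}]")
        _require(self.max_time >= 0, f"max_time must be >= 0, got {self.max_time}")
        _require(self.record_every > 0,
                 f"record_every must be > 0, got {self.record_every}")
        if self.damage_family == "lognormal":
            _require(self.damage_mean > 0,
                     "lognormal damage family requires damage_mean > 0")
        _require(0.0 <= self.bimodal_weight <= 1.0,
                 f"bimodal_weight must be in [0, 1], got {self.bimodal_weight}")

    def replace(self, **changes) -> "ModelParams":
        """Return a copy with the given fields changed (re-validated)."""
        if "population_cap" in changes and "longevity_threshold" not in changes:
            # keep the cap/2 default in sync when only the cap changes
            if self.longevity_threshold == self.population_cap // 2:
                changes["longevity_threshold"] = None
        return dataclasses.replace(self, **changes)

    def can_terminate(self) -> bool:
        """Whether the run is guaranteed to end without a max_time bound.

        Termination is guaranteed when telomeres actually shorten (so every
        lineage eventually senesces) or when some death channel is active
        while attrition is absent is NOT sufficient (deaths are replaced by
        divisions); hence attrition is the criterion.
        """
        if self.gamma == 0:
            return False
        if self.telomere_mode == "TS" and self.ts_constant == 0:
            return False
        if (self.telomere_mode == "SITS" and self.damage_sd == 0
                and self.damage_mean <= 0):
            return False
        return True
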