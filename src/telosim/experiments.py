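"""Replicate ensembles, SITS-vs-TS paired comparisons, and parameter sweeps.

The headline statistics of the study are the SITS/TS ratios

    R_M = <mutation rate>_SITS / <mutation rate>_TS
    R_L = <longevity>_SITS / <longevity>_TS

computed from replicate ensembles (ratios of ensemble means, not means of
per-replicate ratios).  The TS arm's constant effective damage is set to the
SITS arm's realized mean damage <D>, so the two arms differ only in the
telomere-attrition mechanism, not in the damage statistics.

Replicate seeds are derived from a base seed with ``numpy``'s
``SeedSequence`` spawning, so any single replicate can be re-run in
isolation; SITS and TS arms of a comparison share the same seed list
(common random numbers), which removes most of the between-replicate noise
from the ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .observables import (RunRecord, longevity, mean_mutation_rate,
                          realized_mean_damage)
from .params import ModelParams
from .population import run_simulation

__all__ = ["EnsembleSummary", "ComparisonResult", "SweepPoint", "SweepTable",
           "replicate_seeds", "run_ensemble", "compare_sits_ts", "sweep",
           "calibrate_damage_mean"]


def replicate_seeds(base_seed: int, n: int) -> List[int]:
    """Derive ``n`` independent replicate seeds (< 2**31) from a base seed."""
    children = np.random.SeedSequence(base_seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2 ** 31)) for c in children]


@dataclass
class EnsembleSummary:
    """Replicate-averaged observables at one parameter point."""

    params: ModelParams
    n_replicates: int
    seeds: List[int]
    mean_longevity: float           # cell doublings
    sd_longevity: float
    mean_mutation_rate: float       # events per cell per doubling
    sd_mutation_rate: float
    mean_realized_damage: float
    longevities: np.ndarray = field(repr=False)
    mutation_rates: np.ndarray = field(repr=False)
    realized_damages: np.ndarray = field(repr=False)
    n_censored: int = 0
    failed_seeds: List[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_replicates": self.n_replicates,
            "mean_longevity": self.mean_longevity,
            "sd_longevity": self.sd_longevity,
            "mean_mutation_rate": self.mean_mutation_rate,
            "sd_mutation_rate": self.sd_mutation_rate,
            "mean_realized_damage": self.mean_realized_damage,
            "n_censored": self.n_censored,
            "n_failed": len(self.failed_seeds),
        }


def _sd(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1)) if x.size > 1 else 0.0


def run_ensemble(params: ModelParams, n_replicates: int, base_seed: int,
                 seeds: Optional[Sequence[int]] = None) -> EnsembleSummary:
    """Run independent replicates and aggregate the scalar observables.

    A replicate that raises is excluded from the averages with a warning,
    never silently folded in.  Longevities censored by ``max_time`` are
    counted in ``n_censored`` (their censoring time enters the mean).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if seeds is None:
        seeds = replicate_seeds(base_seed, n_replicates)
    elif len(seeds) != n_replicates:
        raise ValueError("len(seeds) must equal n_replicates")

    lons, rates, dams = [], [], []
    n_cens, failed = 0, []
    for seed in seeds:
        try:
            rec = run_simulation(params, seed, record_histograms=False)
            lon = longevity(rec)
            lons.append(lon.time)
            n_cens += int(lon.censored)
            rates.append(mean_mutation_rate(rec))
            dams.append(realized_mean_damage(rec))
        except Exception as exc:  # noqa: BLE001 - per-replicate isolation
            warnings.warn(f"replicate seed={seed} failed and was excluded: {exc}",
                          stacklevel=2)
            failed.append(seed)
    if not lons:
        raise RuntimeError("all replicates failed")

    lons = np.asarray(lons)
    rates = np.asarray(rates)
    dams = np.asarray(dams)
    return EnsembleSummary(
        params=params, n_replicates=len(lons), seeds=list(seeds),
        mean_longevity=float(lons.mean()), sd_longevity=_sd(lons),
        mean_mutation_rate=float(rates.mean()), sd_mutation_rate=_sd(rates),
        mean_realized_damage=float(dams.mean()),
        longevities=lons, mutation_rates=rates, realized_damages=dams,
        n_censored=n_cens, failed_seeds=failed,
    )


@dataclass
class ComparisonResult:
    """Paired SITS-vs-TS comparison at one parameter point."""

    r_m: float                     # SITS/TS ratio of mean mutation rates
    r_l: float                     # SITS/TS ratio of mean longevities
    ts_constant: float             # effective damage used by the TS arm
    sits: EnsembleSummary
    ts: EnsembleSummary


def compare_sits_ts(params: ModelParams, n_replicates: int, base_seed: int,
                    ts_constant: Optional[float] = None) -> ComparisonResult:
    """Run paired SITS and TS ensembles and form the ratios R_M and R_L.

    ``params`` specifies the SITS arm.  The TS arm uses the same seeds and
    parameters except that telomere attrition sees the fixed effective
    damage ``ts_constant`` — by default the SITS arm's realized mean damage,
    which isolates the attrition mechanism as the only difference.
    """
    if params.telomere_mode != "SITS":
        raise ValueError("compare_sits_ts expects params for the SITS arm")
    seeds = replicate_seeds(base_seed, n_replicates)
    sits = run_ensemble(params, n_replicates, base_seed, seeds=seeds)
    if ts_constant is None:
        ts_constant = params.ts_constant
    if ts_constant is None:
        ts_constant = sits.mean_realized_damage
    ts_params = params.replace(telomere_mode="TS", ts_constant=ts_constant)
    ts = run_ensemble(ts_params, n_replicates, base_seed, seeds=seeds)
    if ts.mean_mutation_rate == 0:
        raise ZeroDivisionError("TS mean mutation rate is zero; R_M undefined")
    if ts.mean_longevity == 0:
        raise ZeroDivisionError("TS mean longevity is zero; R_L undefined")
    return ComparisonResult(
        r_m=sits.mean_mutation_rate / ts.mean_mutation_rate,
        r_l=sits.mean_longevity / ts.mean_longevity,
        ts_constant=float(ts_constant), sits=sits, ts=ts)


@dataclass
class SweepPoint:
    mu_d: float
    cv: float                       # assigned sigma_D / mu_D
    realized_damage: float          # measured <D> of the SITS arm
    comparison: Optional[ComparisonResult]
    error: Optional[str] = None


@dataclass
class SweepTable:
    """Grid of paired comparisons over (mean damage, damage CV)."""

    points: List[SweepPoint]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pt in self.points:
            row = {"mu_d": pt.mu_d, "cv": pt.cv,
                   "realized_damage": pt.realized_damage, "error": pt.error}
            if pt.comparison is not None:
                c = pt.comparison
                row.update({
                    "r_m": c.r_m, "r_l": c.r_l, "ts_constant": c.ts_constant,
                    "sits_mean_mutation_rate": c.sits.mean_mutation_rate,
                    "sits_sd_mutation_rate": c.sits.sd_mutation_rate,
                    "ts_mean_mutation_rate": c.ts.mean_mutation_rate,
                    "ts_sd_mutation_rate": c.ts.sd_mutation_rate,
                    "sits_mean_longevity": c.sits.mean_longevity,
                    "sits_sd_longevity": c.sits.sd_longevity,
                    "ts_mean_longevity": c.ts.mean_longevity,
                    "ts_sd_longevity": c.ts.sd_longevity,
                })
            rows.append(row)
        return pd.DataFrame(rows)

    def ratios_frame(self) -> pd.DataFrame:
        df = self.to_frame()
        return df[["realized_damage", "cv", "r_m", "r_l"]].dropna(
            subset=["r_m", "r_l"]) if "r_m" in df else df


def sweep(damage_means: Sequence[float], cv_values: Sequence[float],
          n_replicates: int, base_seed: int,
          params: Optional[ModelParams] = None) -> SweepTable:
    """Paired comparisons over a (mu_D, CV) grid.

    For each grid point the assignment distribution is Gaussian with mean
    ``mu_D`` and sd ``cv * |mu_D|`` (the mean itself is altered to scan the
    damage axis, as in the underlying study); the reported x-coordinate is
    the realized <D> of the SITS arm, which differs from mu_D through the
    nonnegativity of damage and the damage-dependent removal of cells.
    Failures at single points are recorded and do not abort the sweep.
    """
    if len(damage_means) == 0 or len(cv_values) == 0:
        raise ValueError("sweep grids must be non-empty")
    if params is None:
        params = ModelParams()
    points: List[SweepPoint] = []
    ss = np.random.SeedSequence(base_seed)
    point_seeds = [int(c.generate_state(1)[0] % (2 ** 31))
                   for c in ss.spawn(len(damage_means) * len(cv_values))]
    k = 0
    for mu in damage_means:
        for cv in cv_values:
            seed = point_seeds[k]
            k += 1
            try:
                pt_params = params.replace(
                    telomere_mode="SITS", ts_constant=None,
                    damage_mean=mu, damage_sd=cv * abs(mu))
                comp = compare_sits_ts(pt_params, n_replicates, seed)
                points.append(SweepPoint(
                    mu_d=mu, cv=cv,
                    realized_damage=comp.sits.mean_realized_damage,
                    comparison=comp))
            except Exception as exc:  # noqa: BLE001 - per-point isolation
                warnings.warn(f"sweep point (mu={mu}, cv={cv}) failed: {exc}",
                              stacklevel=2)
                points.append(SweepPoint(mu_d=mu, cv=cv,
                                         realized_damage=np.nan,
                                         comparison=None, error=str(exc)))
    return SweepTable(points)


def calibrate_damage_mean(target_realized: float, damage_sd: float,
                          params: Optional[ModelParams] = None,
                          base_seed: int = 0, n_pilot: int = 4,
                          pilot_doublings: float = 150.0,
                          tol: float = 0.004, max_iter: int = 40,
                          ) -> Tuple[float, float]:
    """Find mu_D such that the realized mean damage <D> hits a target.

    The realized <D> is a monotone function of the assignment mean mu_D but
    has no closed form (nonnegativity plus damage-dependent removal), so it
    is bracketed and bisected using short pilot SITS ensembles that share
    seeds across iterations (common random numbers make the pilot response
    smooth in mu_D).  Returns ``(mu_d, realized)``.
    """
    if params is None:
        params = ModelParams()
    base = params.replace(telomere_mode="SITS", ts_constant=None,
                          damage_sd=damage_sd,
                          max_time=pilot_doublings * params.doubling_time)
    seeds = replicate_seeds(base_seed, n_pilot)

    def realized(mu: float) -> float:
        p = base.replace(damage_mean=mu)
        vals = [realized_mean_damage(run_simulation(p, s, record_histograms=False))
                for s in seeds]
        return float(np.mean(vals))

    lo, hi = target_realized - 3 * max(damage_sd, 0.1), target_realized
    f_hi = realized(hi) - target_realized
    if f_hi <= 0:   # realized(mu) >= mu always; equality only at sd == 0
        return hi, f_hi + target_realized
    f_lo = realized(lo) - target_realized
    tries = 0
    while f_lo > 0:
        tries += 1
        if tries > 8:
            raise RuntimeError("could not bracket the damage-mean calibration")
        lo -= 2 * max(damage_sd, 0.1)
        f_lo = realized(lo) - target_realized
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = realized(mid) - target_realized
        if abs(f_mid) < tol:
            return mid, f_mid + target_realized
        if f_mid > 0:
            hi = mid
        else:
            lo = mid
    return mid, f_mid + target_realized
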