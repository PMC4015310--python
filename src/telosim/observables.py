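"""Trajectory records and the derived population observables.

A :class:`RunRecord` is the full account of one trajectory: the recorded
time series (population size, mean telomere length, mean mutation count,
telomere-length histograms) plus run-level scalars.  The three headline
scalars of the study are computed here:

* ``longevity`` — first recorded time, in cell doublings, at which the
  replicating population drops below a threshold (half the cap by default);
* ``mean_mutation_rate`` — total mutation events divided by integrated
  cell-time, i.e. the event rate per cell per doubling averaged over the
  whole run, unbiased under population-size changes;
* ``realized_mean_damage`` — the cell-time-weighted average damage <D>,
  which differs from the assignment mean mu_D because negative draws are
  excluded and highly damaged cells die sooner.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd

from .params import ModelParams

__all__ = ["RunRecord", "Longevity", "longevity", "mean_mutation_rate",
           "realized_mean_damage", "record_to_frame", "histogram_to_frame",
           "record_summary"]


@dataclass
class RunRecord:
    """Time series and summary scalars of one simulated trajectory."""

    times: np.ndarray                 # cell doublings
    population_size: np.ndarray       # N(t)
    mean_telomere: np.ndarray         # <T>(t), bp (nan once empty)
    mean_mutations: np.ndarray        # <M>(t)
    telomere_histogram: Optional[np.ndarray]   # (n_times, n_bins) counts
    histogram_edges: Optional[np.ndarray]      # bp bin edges (250 bp wide)
    realized_mean_damage: float       # cell-time-weighted <D>
    total_mutation_events: int
    total_cell_time: float            # cell * doublings
    terminal_time: float              # doublings
    truncated: bool                   # stopped by max_time, not extinction
    params: ModelParams
    seed: Optional[int] = None


class Longevity(NamedTuple):
    """Longevity with an explicit censoring flag (never silently censored)."""
    time: float          # cell doublings
    censored: bool       # True if the threshold was never crossed

    def __float__(self) -> float:
        return float(self.time)


def longevity(record: RunRecord, threshold: Optional[int] = None) -> Longevity:
    """First recorded time N(t) < threshold, in cell doublings.

    If the population never dropped below the threshold within the run
    (possible only for truncated runs), the terminal time is returned with
    ``censored=True``.
    """
    if record.times.size == 0:
        raise ValueError("empty record")
    if threshold is None:
        threshold = record.params.longevity_threshold
    if threshold > record.params.population_cap:
        raise ValueError(
            f"longevity threshold {threshold} exceeds population cap "
            f"{record.params.population_cap}")
    below = np.nonzero(record.population_size < threshold)[0]
    if below.size:
        return Longevity(float(record.times[below[0]]), False)
    return Longevity(float(record.terminal_time), True)


def mean_mutation_rate(record: RunRecord) -> float:
    """Mutation events per cell per doubling, averaged over time and cells."""
    if record.times.size == 0:
        raise ValueError("empty record")
    if record.total_cell_time <= 0:
        raise ValueError("record has zero integrated cell-time")
    return record.total_mutation_events / record.total_cell_time


def realized_mean_damage(record: RunRecord) -> float:
    """Cell-time-weighted average DNA damage <D> over the run."""
    if record.times.size == 0:
        raise ValueError("empty record")
    return record.realized_mean_damage


def mean_mutation_slope(record: RunRecord) -> float:
    """Average growth rate of the population-mean mutation count <M>(t).

    Secondary observable: the slope (<M>(end) - <M>(0)) / duration of the
    recorded mean-count series, using the last time point with live cells.
    Unlike :func:`mean_mutation_rate` it is affected by selective removal of
    highly mutated cells, not only by the event rate.
    """
    ok = ~np.isnan(record.mean_mutations)
    t, m = record.times[ok], record.mean_mutations[ok]
    if t.size < 2:
        raise ValueError("record too short for a slope")
    return float((m[-1] - m[0]) / (t[-1] - t[0]))


def record_to_frame(record: RunRecord) -> pd.DataFrame:
    """Tidy one-row-per-report-time view of the trajectory."""
    return pd.DataFrame({
        "time_doublings": record.times,
        "population_size": record.population_size,
        "mean_telomere_bp": record.mean_telomere,
        "mean_mutations": record.mean_mutations,
    })


def histogram_to_frame(record: RunRecord) -> pd.DataFrame:
    """Long-format telomere-length histograms (for heatmap-style plots)."""
    if record.telomere_histogram is None:
        raise ValueError("run was recorded without histograms")
    n_t, n_b = record.telomere_histogram.shape
    lo = record.histogram_edges[:-1]
    return pd.DataFrame({
        "time_doublings": np.repeat(record.times[:n_t], n_b),
        "telomere_bin_low_bp": np.tile(lo, n_t),
        "count": record.telomere_histogram.ravel(),
    })


def record_summary(record: RunRecord) -> dict:
    """Scalar summary (JSON-friendly) of one run."""
    lon = longevity(record)
    return {
        "seed": record.seed,
        "longevity_doublings": lon.time,
        "longevity_censored": lon.censored,
        "mean_mutation_rate": mean_mutation_rate(record),
        "realized_mean_damage": realized_mean_damage(record),
        "total_mutation_events": int(record.total_mutation_events),
        "total_cell_time_doublings": record.total_cell_time,
        "terminal_time_doublings": record.terminal_time,
        "truncated": record.truncated,
    }
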