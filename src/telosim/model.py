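"""Per-cell state and the elementary model rules.

Three rules drive the dynamics:

* a per-division mutation hazard  ``r_M(D) = alpha * g(D)``,
* a per-hour apoptosis hazard     ``r_apopt(D) = beta * g(D)``  acting on top
  of the background death rate ``beta0``, and
* telomere attrition              ``dT/dt = -gamma * D_eff**p * T``,

with the saturating sigmoid ``g(D) = D^2 / (D^2 + 1)`` by default.  ``D`` is
the cell's dimensionless DNA-damage level, drawn anew at every division;
``D_eff`` is the cell's own damage under stress-induced telomere shortening
(SITS) or a fixed constant under constant-rate shortening (TS).

All operations are vectorised: ``damage`` may be a scalar or an ndarray.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ModelParams

__all__ = [
    "CellState",
    "mutation_hazard",
    "apoptosis_hazard",
    "hazard_shape",
    "draw_damage",
    "draw_survival_time",
    "telomere_step",
    "mutation_step",
]


@dataclass
class CellState:
    """Attributes of a single replicating cell.

    ``survival_time`` is the pre-drawn lifetime from birth (exponential with
    rate ``beta0 + r_apopt(D)``); the cell dies when its age reaches it,
    unless senescence (telomere at/below the critical length) removes it
    first.
    """

    damage: float               # D, dimensionless, >= 0
    birth_time: float           # t_birth, hours
    survival_time: float        # tau_surv, hours (may be +inf)
    telomere_length: float      # T, basepairs
    mutation_count: int = 0     # n_mut

    def age(self, t: float) -> float:
        return t - self.birth_time


def _saturating_shape(damage, form: str):
    """Dimensionless hazard shape g(D) in [0, 1], monotone in D."""
    d = np.asarray(damage, dtype=float)
    if np.any(d < 0):
        raise ValueError("damage must be nonnegative")
    if form == "hill2":
        d2 = d * d
        return d2 / (d2 + 1.0)
    if form == "hill1":
        return d / (d + 1.0)
    if form == "hill4":
        d4 = d ** 4
        return d4 / (d4 + 1.0)
    if form == "linear":
        # ramp clipped at the same saturation level as the Hill forms
        return np.minimum(d, 1.0)
    raise ValueError(f"unknown hazard form {form!r}")


def hazard_shape(damage, form: str = "hill2"):
    """Evaluate a hazard shape g(D); exposed for robustness scans."""
    return _saturating_shape(damage, form)


def mutation_hazard(damage, params: ModelParams):
    """Per-division mutation hazard r_M(D) = alpha * g(D), bounded by alpha."""
    return params.alpha * _saturating_shape(damage, params.mutation_form)


def apoptosis_hazard(damage, params: ModelParams):
    """Per-hour p53-mediated death hazard r_apopt(D) = beta * g(D)."""
    return params.beta * _saturating_shape(damage, params.apoptosis_form)


def draw_damage(params: ModelParams, rng: np.random.Generator, size: int | None = None):
    """Draw nonnegative damage values from the configured family.

    gaussian_truncated
        Normal(mu_D, sigma_D) with negative draws rejected and resampled
        (default), or clipped to zero under ``negative_damage='clip'``.
        Rejection keeps the realised density proportional to the Gaussian on
        [0, inf); clipping instead places an atom at zero.
    lognormal
        Lognormal with mean mu_D and standard deviation sigma_D (moment
        matched), support (0, inf).
    bimodal
        Two-Gaussian mixture, components ``bimodal_means``/``bimodal_sds``
        with weight ``bimodal_weight`` on the first; negatives handled as for
        the Gaussian.  Defaults place the components at mu_D -/+ sigma_D with
        spread sigma_D / 4, so the mixture keeps mean mu_D.
    """
    n = 1 if size is None else int(size)
    mu, sd = params.damage_mean, params.damage_sd

    if params.damage_family == "lognormal":
        if sd == 0:
            out = np.full(n, mu)
        else:
            s2 = np.log1p((sd / mu) ** 2)
            out = rng.lognormal(np.log(mu) - 0.5 * s2, np.sqrt(s2), size=n)
    else:
        if params.damage_family == "bimodal":
            means = params.bimodal_means or (mu - sd, mu + sd)
            sds = params.bimodal_sds or (sd / 4.0, sd / 4.0)

            def _propose(k: int) -> np.ndarray:
                comp = rng.random(k) >= params.bimodal_weight
                return rng.normal(np.where(comp, means[1], means[0]),
                                  np.where(comp, sds[1], sds[0]), size=k)
        else:
            def _propose(k: int) -> np.ndarray:
                return rng.normal(mu, sd, size=k)

        out = _propose(n)
        if params.negative_damage == "clip":
            np.maximum(out, 0.0, out=out)
        else:
            # rejection keeps the law proportional to the proposal density
            # on [0, inf); mixtures re-propose the component as well
            neg = out < 0
            tries = 0
            while np.any(neg):
                tries += 1
                if tries > 10_000:
                    raise ValueError(
                        "damage distribution produces (almost) no nonnegative "
                        "mass; cannot resample negatives")
                idx = np.nonzero(neg)[0]
                out[idx] = _propose(idx.size)
                neg[idx] = out[idx] < 0
    return float(out[0]) if size is None else out


def draw_survival_time(damage, params: ModelParams, rng: np.random.Generator):
    """Draw tau_surv ~ Exponential(beta0 + r_apopt(D)); +inf at zero rate."""
    rate = params.beta0 + apoptosis_hazard(damage, params)
    rate = np.asarray(rate, dtype=float)
    draws = rng.standard_exponential(size=rate.shape)
    with np.errstate(divide="ignore"):
        tau = np.where(rate > 0, draws / np.where(rate > 0, rate, 1.0), np.inf)
    return float(tau) if np.isscalar(damage) or np.ndim(damage) == 0 else tau


def telomere_step(telomere_length, effective_damage, params: ModelParams,
                  duration: float | None = None):
    """One attrition update T -> T * (1 - gamma * D_eff**p * duration).

    ``duration`` defaults to ``params.dt`` (the continuous per-step update);
    the discrete mode passes ``params.doubling_time`` to apply a whole
    division's worth of attrition at once.  The result is clamped at zero so
    an oversized step cannot produce a negative length (such a cell is
    immediately senescent anyway).
    """
    d = np.asarray(effective_damage, dtype=float)
    if np.any(d < 0):
        raise ValueError("effective damage must be nonnegative")
    if duration is None:
        duration = params.dt
    factor = 1.0 - params.gamma * d ** params.attrition_exponent * duration
    out = np.maximum(np.asarray(telomere_length, dtype=float) * factor, 0.0)
    return float(out) if np.ndim(telomere_length) == 0 else out


def step_mutation_probability(damage, params: ModelParams):
    """Per-step mutation probability: r_M(D) (per division) thinned to dt.

    alpha is a per-division scale; with one division per ``doubling_time``
    the per-step Bernoulli probability is r_M * dt / doubling_time, so a cell
    held at D for one doubling time accrues r_M expected mutations.
    """
    p = mutation_hazard(damage, params) * params.dt / params.doubling_time
    return np.minimum(p, 1.0)


def mutation_step(cell: CellState, params: ModelParams,
                  rng: np.random.Generator) -> CellState:
    """Bernoulli mutation update for one cell over one time step."""
    if rng.random() < step_mutation_probability(cell.damage, params):
        cell.mutation_count += 1
    return cell
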