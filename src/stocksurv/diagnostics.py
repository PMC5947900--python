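"""Model-checking procedures: Kaplan–Meier shape check, Cox–Snell
residuals, and finite-population SDs of the random effects.

Three graphical checks back the Weibull analysis:

* If durations are Weibull, the points (log t, log(−log Ŝ(t))) from the
  Kaplan–Meier estimate Ŝ fall on a line whose slope is the shape τ.
* Cox–Snell residuals r_i = λ̂_i t_i^τ̂ are unit-exponential under a
  correctly specified model, so their empirical cumulative hazard plotted
  against r should follow the line y = x.
* The finite-population SD of each factor's realized level effects
  compares how much variance each categorical factor actually accounts
  for, on a common scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter

from .data import EventTable
from .model import PosteriorSamples

__all__ = [
    "KMEstimate",
    "kaplan_meier",
    "weibull_shape_check",
    "cox_snell_residuals",
    "cumulative_hazard_slope",
    "finite_population_sd",
]


@dataclass
class KMEstimate:
    """Product-limit survival estimate at the distinct event times."""

    times: np.ndarray      # sorted distinct event times
    survival: np.ndarray   # S(t) just after each event time
    at_risk: np.ndarray    # risk-set size at each event time
    deaths: np.ndarray     # events at each event time

    def survival_at(self, t: float) -> float:
        """Step-function evaluation; Ŝ(t) = 1 before the first event."""
        j = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if j < 0 else float(self.survival[j])


def kaplan_meier(time, event) -> KMEstimate:
    """Kaplan–Meier product-limit estimator under right censoring.

    Ŝ(t) = Π_{t_j ≤ t} (1 − d_j / n_j) over distinct event times t_j with
    d_j events and n_j at risk.  Ties are handled with the standard
    convention that events are processed before censorings at the same
    time, so censored observations at t_j remain in the risk set n_j.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if time.size == 0:
        raise ValueError("empty input")
    if np.any(time <= 0):
        raise ValueError("all times must be positive")

    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    et = kmf.event_table
    rows = et[et["observed"] > 0]
    times = rows.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(times).to_numpy(dtype=float)
    return KMEstimate(
        times=times,
        survival=surv,
        at_risk=rows["at_risk"].to_numpy(dtype=float),
        deaths=rows["observed"].to_numpy(dtype=float),
    )


def weibull_shape_check(km: KMEstimate) -> tuple[float, float, np.ndarray]:
    """Slope of log(−log Ŝ) on log t: the empirical Weibull shape.

    Points with Ŝ = 0 or 1 are excluded (the double-log transform is
    undefined there); the fit is unweighted ordinary least squares over
    the remaining event-time points.

    Returns (slope, intercept, points) with points as an (m, 2) array of
    (log t, log(−log Ŝ)) pairs.
    """
    mask = (km.survival > 0) & (km.survival < 1) & (km.times > 0)
    if mask.sum() < 3:
        raise ValueError(
            "need at least 3 event times with 0 < S < 1 for the shape check"
        )
    x = np.log(km.times[mask])
    y = np.log(-np.log(km.survival[mask]))
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept), np.column_stack([x, y])


def cox_snell_residuals(
    posterior: PosteriorSamples, table: EventTable
) -> tuple[np.ndarray, np.ndarray]:
    """Cox–Snell residuals at the posterior mean of the linear predictor.

    r_i = λ̄_i t_i^τ̄ with λ̄_i = exp(mean over draws of log λ_i) and τ̄
    the posterior mean of τ.  Censoring indicators carry over: the residual
    of a censored stock is itself a censored observation of the
    unit-exponential reference distribution.
    """
    loglam_bar = posterior.log_lambda_draws(
        table.X, table.factor_idx).mean(axis=0)
    tau_bar = float(posterior.tau_flat().mean())
    r = np.exp(loglam_bar) * table.time**tau_bar
    if not np.all(np.isfinite(r)):
        bad = int(np.flatnonzero(~np.isfinite(r))[0])
        raise FloatingPointError(f"non-finite residual at index {bad}")
    return r, np.asarray(table.event, int).copy()


def cumulative_hazard_slope(
    residuals: np.ndarray, event: np.ndarray
) -> float:
    """OLS slope of the residuals' empirical cumulative hazard against r.

    A well-specified model gives unit-exponential residuals, whose
    cumulative hazard is H(r) = r: the slope should be 1 (the y = x line).
    """
    km = kaplan_meier(residuals, event)
    mask = (km.survival > 0) & (km.survival < 1)
    h = -np.log(km.survival[mask])
    r = km.times[mask]
    slope = float(np.sum(r * h) / np.sum(r * r))  # through the origin
    return slope


def finite_population_sd(effect_draws: np.ndarray) -> np.ndarray:
    """Posterior draws of the SD of one factor's realized level effects.

    For each draw, s = sqrt( Σ_j (e_j − ē)² / (J − 1) ) over the J levels
    present in the data — the variance the factor actually accounts for,
    as opposed to the superpopulation scale parameter.
    """
    e = np.asarray(effect_draws, float)
    e = e.reshape(-1, e.shape[-1])
    if e.shape[-1] < 2:
        raise ValueError("finite-population SD requires at least 2 levels")
    return e.std(axis=-1, ddof=1)
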