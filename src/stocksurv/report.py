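"""Posterior summaries, effect transformations, marginal curves and
regional projections of the proportion of stocks assessed.

Effect sizes are reported three ways:

* on the log-rate scale (the raw coefficients β and random effects),
* as hazard ratios exp(β) — the multiplicative change in the annual
  assessment rate per unit covariate change (one unit = two SDs for the
  continuous covariates, 0→1 for the FMP flag),
* as acceleration factors exp(−β/τ) — the multiplicative change in the
  median time-to-assessment.

Projections roll each still-unassessed stock's Weibull clock forward from
the censoring year: a stock censored at elapsed time t₀ is assessed by
calendar year y with conditional probability 1 − S(t₀ + y − 2013)/S(t₀).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import FINAL_YEAR, EventTable, StockRecord
from .model import PosteriorSamples

__all__ = [
    "ProjectionResult",
    "effect_summaries",
    "transform_effects",
    "marginal_probability_curve",
    "project_proportion_assessed",
    "descriptive_tables",
]

_QUANTILES = (0.025, 0.25, 0.5, 0.75, 0.975)


def _qrow(name: str, draws: np.ndarray, kind: str) -> dict:
    q = np.quantile(draws, _QUANTILES)
    return {
        "parameter": name, "kind": kind,
        "q2.5": q[0], "q25": q[1], "median": q[2], "q75": q[3],
        "q97.5": q[4], "mean": float(np.mean(draws)),
    }


def effect_summaries(
    posterior: PosteriorSamples,
    nesting: Mapping[str, Mapping[str, str]] | None = None,
) -> pd.DataFrame:
    """Quantile summaries (2.5/25/50/75/97.5%) for every parameter.

    Factor effects are reported after a per-draw sum-to-zero centering
    within each factor, since only deviations from the factor mean are
    identified in the interceptless parameterization.  When a nesting map
    is supplied, order effects are additionally reported relative to their
    class (their centered effect, grouped under the parent class label).
    """
    if posterior.n_draws == 0:
        raise ValueError("empty posterior")
    rows = [_qrow("tau", posterior.tau_flat(), "shape")]
    B = posterior.beta_flat()
    for j, c in enumerate(posterior.colnames):
        rows.append(_qrow(f"beta[{c}]", B[:, j], "coefficient"))
    for f in posterior.effects:
        E = posterior.effects_flat(f)
        centered = E - E.mean(axis=1, keepdims=True)
        for j, lab in enumerate(posterior.levels[f]):
            rows.append(_qrow(f"effect[{f}:{lab}]", centered[:, j],
                              "random effect"))
        rows.append(_qrow(f"sd[{f}]", posterior.re_sd[f].reshape(-1),
                          "scale"))
    if nesting and "tax_order" in posterior.effects:
        E = posterior.effects_flat("tax_order")
        centered = E - E.mean(axis=1, keepdims=True)
        parent = nesting.get("tax_order", {})
        for j, lab in enumerate(posterior.levels["tax_order"]):
            cls = parent.get(lab, "?")
            rows.append(_qrow(f"order_rel[{cls}:{lab}]", centered[:, j],
                              "order relative to class"))
    return pd.DataFrame(rows)


def transform_effects(beta_draw, tau_draw):
    """Hazard ratio exp(β) and acceleration factor exp(−β/τ).

    Under S(t) = exp(−λ t^τ) with log λ linear in the covariates, a unit
    covariate change multiplies the hazard by exp(β) and the median (or any
    quantile of) time-to-assessment by exp(−β/τ); the two satisfy
    HR · AF^τ = 1.
    """
    beta = np.asarray(beta_draw, float)
    tau = np.asarray(tau_draw, float)
    if np.any(tau <= 0):
        raise ValueError("tau must be positive")
    return np.exp(beta), np.exp(-beta / tau)


def marginal_probability_curve(
    posterior: PosteriorSamples,
    factor: str,
    level: str,
    tgrid,
) -> tuple[np.ndarray, pd.DataFrame]:
    """P(T ≤ t) for a stock of the focal category, per draw and summarized.

    Per draw, log λ_k is the focal level's (uncentered) effect plus the
    population mean of each non-focal factor's effects, with continuous
    covariates at 0 (their standardized mean): the factor means jointly
    carry the absorbed baseline, so the curve is on the data's own scale.
    The curve is F(t) = 1 − exp(−λ_k t^τ).

    Returns (curves, summary): curves has shape (draws, len(tgrid)); the
    summary frame holds pointwise median and 95% band.
    """
    if factor not in posterior.effects:
        raise KeyError(f"unknown factor {factor!r}")
    if level not in posterior.levels[factor]:
        raise KeyError(f"unknown level {level!r} of factor {factor!r}")
    t = np.asarray(tgrid, float)
    if np.any(t < 0):
        raise ValueError("time grid must be non-negative")

    j = posterior.levels[factor].index(level)
    loglam = posterior.effects_flat(factor)[:, j].copy()
    for f in posterior.effects:
        if f != factor:
            loglam += posterior.effects_flat(f).mean(axis=1)
    lam = np.exp(loglam)
    tau = posterior.tau_flat()

    with np.errstate(divide="ignore"):
        ttau = np.where(t[None, :] > 0,
                        np.exp(np.outer(tau, np.log(np.maximum(t, 1e-300)))),
                        0.0)
    curves = -np.expm1(-lam[:, None] * ttau)
    q = np.quantile(curves, [0.025, 0.5, 0.975], axis=0)
    summary = pd.DataFrame({
        "t": t, "lower": q[0], "median": q[1], "upper": q[2],
    })
    return curves, summary


@dataclass
class ProjectionResult:
    """Per-region, per-year projected proportion of stocks assessed."""

    table: pd.DataFrame  # columns: region, year, median, lower, upper
    draws: dict[str, np.ndarray]  # region -> (n draws, n years)
    years: np.ndarray

    def for_region(self, region: str) -> pd.DataFrame:
        return self.table[self.table["region"] == region].reset_index(
            drop=True)


def project_proportion_assessed(
    posterior: PosteriorSamples,
    table: EventTable,
    records: Sequence[StockRecord],
    horizon_year: int,
    conditional: bool = True,
    final_year: int = FINAL_YEAR,
) -> ProjectionResult:
    """Expected proportion of stocks assessed by calendar year, per region.

    Already-assessed stocks contribute 1.  Each unassessed stock i, censored
    at elapsed time t₀ᵢ, contributes its probability of first assessment by
    year y under its own clock, conditional on being unassessed at
    ``final_year``:

        p_i(y) = 1 − S_i(t₀ᵢ + y − final_year) / S_i(t₀ᵢ).

    With ``conditional=False`` the unconditional F_i(t_i(y)) is used
    instead (this double-counts risk already survived and is provided for
    comparison only).  The per-draw region proportion is the mean over the
    region's stocks; the result is summarized over posterior draws.
    """
    if horizon_year < final_year:
        raise ValueError("horizon_year must not precede the censoring year")
    years = np.arange(final_year, horizon_year + 1)
    regions = sorted({r.region for r in records})
    event = np.asarray(table.event, int)
    time = np.asarray(table.time, float)
    reg = np.array([r.region for r in records])

    loglam = posterior.log_lambda_draws(table.X, table.factor_idx)
    tau = posterior.tau_flat()[:, None]

    rows = []
    draws_by_region: dict[str, np.ndarray] = {}
    for region in regions:
        in_r = reg == region
        n_r = int(in_r.sum())
        n_assessed = int((event[in_r] == 1).sum())
        un = in_r & (event == 0)
        lam_u = np.exp(loglam[:, un])
        t0 = time[un][None, :]
        props = np.empty((posterior.n_draws, len(years)))
        base = lam_u * t0**tau if conditional else 0.0
        for k, y in enumerate(years):
            ty = t0 + (y - final_year)
            haz = lam_u * ty**tau
            p = -np.expm1(-(haz - base)) if conditional else -np.expm1(-haz)
            props[:, k] = (n_assessed + p.sum(axis=1)) / n_r
        draws_by_region[region] = props
        q = np.quantile(props, [0.025, 0.5, 0.975], axis=0)
        for k, y in enumerate(years):
            rows.append({
                "region": region, "year": int(y),
                "median": q[1, k], "lower": q[0, k], "upper": q[2, k],
            })
    return ProjectionResult(
        table=pd.DataFrame(rows), draws=draws_by_region, years=years
    )


def descriptive_tables(records: Sequence[StockRecord]) -> dict[str, pd.DataFrame]:
    """Counts and proportions assessed, by region and by FMP membership."""
    df = pd.DataFrame({
        "region": [r.region for r in records],
        "in_fmp": [r.in_fmp for r in records],
        "assessed": [r.assessed for r in records],
    })

    def agg(group_col: str) -> pd.DataFrame:
        g = df.groupby(group_col, sort=True)["assessed"].agg(
            n_stocks="size", n_assessed="sum")
        g["proportion_assessed"] = g["n_assessed"] / g["n_stocks"]
        return g.reset_index()

    total = pd.DataFrame([{
        "n_stocks": len(df),
        "n_assessed": int(df["assessed"].sum()),
        "proportion_assessed": float(df["assessed"].mean()),
    }])
    return {"by_region": agg("region"), "by_fmp": agg("in_fmp"),
            "total": total}
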