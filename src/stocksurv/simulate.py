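"""Synthetic stock cohorts with known generating parameters.

The generator emulates the statistical structure the time-to-event analysis
assumes: a cohort of commercially landed stocks with right-skewed landings
and prices, a nested class → order → family taxonomy, four regions, six
habitat categories, first landings spread over the database period, and
first-assessment times drawn from a Weibull hazard whose log-rate is a
linear function of the standardized covariates plus one random effect per
factor level.  Stocks whose latent assessment time runs past the censoring
year are recorded as unassessed, exactly as the real cohort is censored at
the end of the landings record.

Because the model carries no global intercept, the generator holds an
explicit ``baseline_log_rate`` that sets the overall assessment rate; in a
fitted model this baseline is absorbed by the factor effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .data import FINAL_YEAR, HABITATS, ORIGIN_YEAR, REGIONS, StockRecord

__all__ = ["SimulationConfig", "generate_stocks", "simulate_weibull_times"]


def _default_beta() -> dict[str, float]:
    # Sign pattern of the fitted cohort: landings and price raise the
    # assessment rate, their interaction lowers it (price matters most when
    # landings are small), larger-bodied species are assessed faster.
    return {
        "log10_price": 0.9,
        "log10_landings": 1.1,
        "price_x_landings": -0.4,
        "log10_length": 0.35,
    }


def _default_re_sds() -> dict[str, float]:
    # Taxonomic factors carry more residual variance than habitat or region.
    return {
        "region": 0.20,
        "habitat": 0.25,
        "tax_class": 0.50,
        "tax_order": 0.50,
        "tax_family": 0.40,
    }


def _default_n_levels() -> dict[str, int]:
    return {"tax_class": 3, "tax_order": 8, "tax_family": 16}


def _default_covariates() -> dict[str, tuple[float, float]]:
    # (mean, sd) of the base-10 log: median landings 100 t with heavy right
    # skew, median price ~2 US$/kg, median maximum length ~45 cm.
    return {
        "log10_landings": (2.0, 1.2),
        "log10_price": (0.3, 0.3),
        "log10_length": (1.65, 0.3),
    }


@dataclass
class SimulationConfig:
    """Generating parameters for a synthetic cohort.

    Defaults reproduce the shape of the study cohort: 569 stocks of which
    roughly 37% are assessed by the 2013 censoring year, Weibull shape 2.6
    (assessment rate increasing with elapsed time), and the fitted sign
    pattern of the covariate effects on the 2-SD standardized scale.
    """

    n_stocks: int = 569
    true_tau: float = 2.6
    true_beta: dict[str, float] = field(default_factory=_default_beta)
    random_effect_sds: dict[str, float] = field(default_factory=_default_re_sds)
    n_levels: dict[str, int] = field(default_factory=_default_n_levels)
    covariate_distributions: dict[str, tuple[float, float]] = field(
        default_factory=_default_covariates
    )
    fmp_probability: float = 0.5
    fmp_effect: float = 0.0          # >0 adds an FMP term to the log-rate
    baseline_log_rate: float = -10.2  # calibrated to ~37% assessed at defaults
    landings_start_window: tuple[int, int] = (1950, 2000)
    origin_year: int = ORIGIN_YEAR
    censor_year: int = FINAL_YEAR
    seed: int = 0

    def validate(self) -> None:
        if self.n_stocks < 1:
            raise ValueError("n_stocks must be positive")
        if self.true_tau <= 0:
            raise ValueError("true_tau must be positive")
        for f, s in self.random_effect_sds.items():
            if s <= 0:
                raise ValueError(f"random-effect SD for {f!r} must be > 0")
        nl = self.n_levels
        if not (nl["tax_class"] <= nl["tax_order"] <= nl["tax_family"]):
            raise ValueError(
                "nesting requires n_classes <= n_orders <= n_families"
            )
        if not 0.0 <= self.fmp_probability <= 1.0:
            raise ValueError("fmp_probability must lie in [0, 1]")
        y0, y1 = self.landings_start_window
        if y0 > y1 or y1 > self.censor_year:
            raise ValueError("invalid landings_start_window")


def simulate_weibull_times(
    lambda_: np.ndarray, tau: float, u: np.ndarray
) -> np.ndarray:
    """Invert the Weibull survivor function S(t) = exp(−λ t^τ).

    Given uniforms u ∈ (0, 1), ``t = (−ln u / λ)^(1/τ)`` has the Weibull
    distribution with shape τ and rate λ.
    """
    lam = np.asarray(lambda_, dtype=float)
    u = np.asarray(u, dtype=float)
    if tau <= 0:
        raise ValueError("tau must be positive")
    if np.any(lam <= 0):
        raise ValueError("all rates must be positive")
    if np.any((u <= 0) | (u >= 1)):
        raise ValueError("uniforms must lie strictly in (0, 1)")
    return (-np.log(u) / lam) ** (1.0 / tau)


def generate_stocks(
    config: SimulationConfig | None = None,
    seed: int | None = None,
) -> tuple[list[StockRecord], dict]:
    """Draw a synthetic cohort and return it with its generating truth.

    Returns
    -------
    records
        Stock records ready for :func:`stocksurv.data.build_event_table`.
    truth
        The generating parameters: tau, beta (standardized scale), per-level
        random effects, their SDs, the baseline log-rate, per-stock latent
        log-rates and event times, and the realized assessed fraction.
    """
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_stocks

    # nested taxonomy: orders assigned round-robin to classes, families to
    # orders, so every child has exactly one parent
    n_cls = config.n_levels["tax_class"]
    n_ord = config.n_levels["tax_order"]
    n_fam = config.n_levels["tax_family"]
    order_parent = {f"order{o:02d}": f"class{o % n_cls:02d}"
                    for o in range(n_ord)}
    family_parent = {f"family{f:02d}": f"order{f % n_ord:02d}"
                     for f in range(n_fam)}
    families = sorted(family_parent)

    fam_of = rng.choice(families, size=n)
    ord_of = np.array([family_parent[f] for f in fam_of])
    cls_of = np.array([order_parent[o] for o in ord_of])
    region = rng.choice(REGIONS, size=n)
    habitat = rng.choice(HABITATS, size=n)

    # covariates on the log10 scale; betas act on the 2-SD standardized scale
    dists = config.covariate_distributions
    log_land = rng.normal(*dists["log10_landings"], size=n)
    log_price = rng.normal(*dists["log10_price"], size=n)
    log_len = rng.normal(*dists["log10_length"], size=n)
    z_land = (log_land - dists["log10_landings"][0]) / (
        2 * dists["log10_landings"][1])
    z_price = (log_price - dists["log10_price"][0]) / (
        2 * dists["log10_price"][1])
    z_len = (log_len - dists["log10_length"][0]) / (
        2 * dists["log10_length"][1])
    # product of two independent N(0, 0.5) columns has SD 0.25; dividing by
    # twice that SD matches the re-standardization the design builder applies
    z_inter = (z_price * z_land) / (2 * 0.25)
    in_fmp = rng.random(n) < config.fmp_probability

    beta = config.true_beta
    loglam = np.full(n, config.baseline_log_rate)
    loglam += (beta["log10_price"] * z_price
               + beta["log10_landings"] * z_land
               + beta["price_x_landings"] * z_inter
               + beta["log10_length"] * z_len)
    if config.fmp_effect:
        loglam += config.fmp_effect * in_fmp

    effects: dict[str, dict[str, float]] = {}
    factor_labels = {
        "region": (region, sorted(REGIONS)),
        "habitat": (habitat, sorted(HABITATS)),
        "tax_class": (cls_of, sorted({order_parent[o] for o in order_parent})),
        "tax_order": (ord_of, sorted(order_parent)),
        "tax_family": (fam_of, families),
    }
    for f, (labels, lv) in factor_labels.items():
        draws = rng.normal(0.0, config.random_effect_sds[f], size=len(lv))
        effects[f] = dict(zip(lv, draws.tolist()))
        loglam += np.array([effects[f][l] for l in labels])

    lam = np.exp(loglam)
    u = rng.uniform(np.finfo(float).tiny, 1.0, size=n)
    t_latent = simulate_weibull_times(lam, config.true_tau, u)

    y0, y1 = config.landings_start_window
    first_landed = rng.integers(y0, y1 + 1, size=n)
    origin = np.maximum(first_landed, config.origin_year)
    calendar = origin + t_latent
    assessed = calendar <= config.censor_year
    assess_year = np.where(
        assessed, np.clip(np.round(calendar), origin, config.censor_year), 0
    ).astype(int)

    records = []
    for i in range(n):
        records.append(StockRecord(
            stock_id=f"S{i:04d}",
            species=f"sp_{fam_of[i]}_{i:04d}",
            region=str(region[i]),
            habitat=str(habitat[i]),
            tax_class=str(cls_of[i]),
            tax_order=str(ord_of[i]),
            tax_family=str(fam_of[i]),
            max_length_cm=float(10 ** log_len[i]),
            first_landed_year=int(first_landed[i]),
            assessment_year=int(assess_year[i]) if assessed[i] else None,
            max_landings_t=float(10 ** log_land[i]),
            mean_price_usd_kg=float(10 ** log_price[i]),
            in_fmp=bool(in_fmp[i]),
        ))

    truth = {
        "tau": config.true_tau,
        "beta": dict(beta),
        "fmp_effect": config.fmp_effect,
        "baseline_log_rate": config.baseline_log_rate,
        "random_effect_sds": dict(config.random_effect_sds),
        "effects": effects,
        "log_lambda": loglam,
        "latent_time": t_latent,
        "assessed_fraction": float(assessed.mean()),
        "n_assessed": int(assessed.sum()),
    }
    return records, truth
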