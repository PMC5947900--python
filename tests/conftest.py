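"""Shared fixtures: hand-built records, a default synthetic cohort, and
one converged fit of the default cohort reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from stocksurv.data import StockRecord, build_event_table
from stocksurv.model import ModelConfig, PosteriorSamples, sample_posterior
from stocksurv.simulate import SimulationConfig, generate_stocks


def make_records(n: int = 12) -> list[StockRecord]:
    """Deterministic hand-built records covering all factor levels needed."""
    regions = ["Alaska", "WestCoast", "Northeast", "Southeast"]
    habitats = ["demersal", "pelagic", "benthic", "reef_associated",
                "benthopelagic", "deep_sea"]
    taxa = [  # (class, order, family) with consistent nesting
        ("Actinopterygii", "Perciformes", "Serranidae"),
        ("Actinopterygii", "Pleuronectiformes", "Pleuronectidae"),
        ("Malacostraca", "Decapoda", "Cancridae"),
    ]
    out = []
    for i in range(n):
        cls, order, family = taxa[i % len(taxa)]
        assessed = i % 2 == 0
        yl = 1950 + 4 * (i % 10)
        out.append(StockRecord(
            stock_id=f"T{i:03d}",
            species=f"species_{i}",
            region=regions[i % 4],
            habitat=habitats[i % 6],
            tax_class=cls,
            tax_order=order,
            tax_family=family,
            max_length_cm=20.0 + 10 * i,
            first_landed_year=yl,
            assessment_year=max(yl, 1960) + 5 + i if assessed else None,
            max_landings_t=10.0 * (i + 1),
            mean_price_usd_kg=0.5 + 0.25 * i,
            in_fmp=i % 3 == 0,
        ))
    return out


@pytest.fixture()
def small_records() -> list[StockRecord]:
    return make_records(12)


@pytest.fixture(scope="session")
def default_cohort():
    """Paper-scale synthetic cohort (n=569) with its generating truth."""
    return generate_stocks(SimulationConfig(seed=5))


@pytest.fixture(scope="session")
def default_table(default_cohort):
    records, _ = default_cohort
    return build_event_table(records)


@pytest.fixture(scope="session")
def default_fit(default_table) -> PosteriorSamples:
    """One fit of the default cohort at the default (scaled-down) protocol."""
    return sample_posterior(default_table, ModelConfig(seed=2))


def toy_posterior(
    tau: float = 1.0,
    beta: np.ndarray | None = None,
    levels: dict[str, list[str]] | None = None,
    effects: dict[str, np.ndarray] | None = None,
    colnames: list[str] | None = None,
) -> PosteriorSamples:
    """A degenerate single-draw posterior for closed-form checks."""
    colnames = colnames or ["x"]
    p = len(colnames)
    beta = np.zeros(p) if beta is None else np.asarray(beta, float)
    levels = levels if levels is not None else {"region": ["A", "B"]}
    effects = effects or {
        f: np.zeros((1, 1, len(lv))) for f, lv in levels.items()
    }
    return PosteriorSamples(
        tau=np.full((1, 1), float(tau)),
        beta=beta.reshape(1, 1, p),
        effects=effects,
        re_sd={f: np.ones((1, 1)) for f in levels},
        colnames=colnames,
        levels=levels,
        convergence=pd.DataFrame(),
        config=ModelConfig(),
    )
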