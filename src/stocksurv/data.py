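"""Stock tables, censoring construction, and standardized design structures.

The unit of analysis is a *stock*: a managed population of one fished species
within one US region.  Each stock either received its first quantitative
assessment in a known calendar year, or is right-censored at the end of the
landings record (2013).  The analysis clock starts at 1960 — the year of the
first quantitative assessment in the record — or at first landings if later,
so the observed duration for stock *i* is

    T_i = min(Ya_i − Yl_i, Ya_i − 1960)

with Ya the first-assessment year (2013 for unassessed stocks) and Yl the
first-landings year.

Continuous covariates (ex-vessel price, maximum pre-assessment landings,
their interaction, and species maximum length) enter the model as base-10
logarithms standardized by *twice* the standard deviation, which puts their
coefficients on the same scale as the binary FMP indicator.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("stocksurv")

# ---------------------------------------------------------------------------
# constants

ORIGIN_YEAR = 1960       # first quantitative stock assessment on record
FINAL_YEAR = 2013        # last year of the landings database (censoring year)
DATABASE_START = 1950    # landings records begin here
HALF_YEAR = 0.5          # replacement for zero durations (Weibull support t>0)

REGIONS = ("Alaska", "Northeast", "Southeast", "WestCoast")
HABITATS = (
    "benthic",
    "benthopelagic",
    "deep_sea",
    "demersal",
    "pelagic",
    "reef_associated",
)

#: continuous design columns, in fixed order (FMP appended when enabled)
CONTINUOUS_COLUMNS = (
    "log10_price",
    "log10_landings",
    "price_x_landings",
    "log10_length",
)
FMP_COLUMN = "fmp"

FACTORS = ("region", "habitat", "tax_class", "tax_order", "tax_family")


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ValidationError(ValueError):
    """One or more rows violate the stock-record invariants."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__(
            "invalid stock records:\n" + "\n".join(self.problems)
        )


class DegenerateDesignError(ValueError):
    """The design matrix or factor structure cannot support the model."""


# ---------------------------------------------------------------------------
# records


@dataclass
class StockRecord:
    """One landed stock with covariates, taxonomy and assessment outcome."""

    stock_id: str
    species: str
    region: str
    habitat: str
    tax_class: str
    tax_order: str
    tax_family: str
    max_length_cm: float
    first_landed_year: int
    max_landings_t: float
    mean_price_usd_kg: float
    in_fmp: bool = False
    assessment_year: int | None = None

    @property
    def assessed(self) -> bool:
        return self.assessment_year is not None

    def problems(self) -> list[str]:
        """Return invariant violations (empty list when valid)."""
        out: list[str] = []
        if self.region not in REGIONS:
            out.append(
                f"region {self.region!r} not one of {sorted(REGIONS)}"
            )
        if self.habitat not in HABITATS:
            out.append(
                f"habitat {self.habitat!r} not one of {sorted(HABITATS)}"
            )
        if not DATABASE_START <= self.first_landed_year <= FINAL_YEAR:
            out.append(
                f"first_landed_year {self.first_landed_year} outside "
                f"[{DATABASE_START}, {FINAL_YEAR}]"
            )
        if self.assessment_year is not None:
            if self.assessment_year < ORIGIN_YEAR:
                out.append(
                    f"assessment_year {self.assessment_year} precedes the "
                    f"first possible assessment year {ORIGIN_YEAR}"
                )
            if self.assessment_year < self.first_landed_year:
                out.append(
                    f"assessment_year {self.assessment_year} precedes "
                    f"first_landed_year {self.first_landed_year}"
                )
            if self.assessment_year > FINAL_YEAR:
                out.append(
                    f"assessment_year {self.assessment_year} after "
                    f"{FINAL_YEAR}"
                )
        if not self.max_length_cm > 0:
            out.append(f"max_length_cm {self.max_length_cm} not positive")
        if not self.max_landings_t > 0:
            out.append(f"max_landings_t {self.max_landings_t} not positive")
        if not self.mean_price_usd_kg > 0:
            out.append(
                f"mean_price_usd_kg {self.mean_price_usd_kg} not positive"
            )
        return out


#: canonical column names for the stock-table CSV
DEFAULT_SCHEMA: dict[str, str] = {
    "stock_id": "stock_id",
    "species": "species",
    "region": "region",
    "habitat": "habitat",
    "tax_class": "tax_class",
    "tax_order": "tax_order",
    "tax_family": "tax_family",
    "max_length_cm": "max_length_cm",
    "first_landed_year": "first_landed_year",
    "assessment_year": "assessment_year",
    "max_landings_t": "max_landings_t",
    "mean_price_usd_kg": "mean_price_usd_kg",
    "in_fmp": "in_fmp",
}


def read_stock_table(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
) -> list[StockRecord]:
    """Read and validate a stock table CSV.

    Parameters
    ----------
    path
        CSV file with one row per stock (UTF-8, header row).
    schema
        Optional map from canonical field names (keys of
        :data:`DEFAULT_SCHEMA`) to the column names used in the file.

    Raises
    ------
    SchemaError
        if a required column is missing.
    ValidationError
        listing row numbers and offending cells for rows that fail the
        record invariants or cannot be parsed.
    """
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    df = pd.read_csv(path)
    required = [k for k in colmap if k != "assessment_year"]
    missing = [colmap[k] for k in required if colmap[k] not in df.columns]
    if colmap["assessment_year"] not in df.columns:
        df[colmap["assessment_year"]] = np.nan
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")

    records: list[StockRecord] = []
    problems: list[str] = []
    for i, row in df.iterrows():
        rowno = int(i) + 2  # header is line 1
        try:
            ay = row[colmap["assessment_year"]]
            assessment_year = None if pd.isna(ay) else int(ay)
            rec = StockRecord(
                stock_id=str(row[colmap["stock_id"]]),
                species=str(row[colmap["species"]]),
                region=str(row[colmap["region"]]),
                habitat=str(row[colmap["habitat"]]),
                tax_class=str(row[colmap["tax_class"]]),
                tax_order=str(row[colmap["tax_order"]]),
                tax_family=str(row[colmap["tax_family"]]),
                max_length_cm=float(row[colmap["max_length_cm"]]),
                first_landed_year=int(row[colmap["first_landed_year"]]),
                assessment_year=assessment_year,
                max_landings_t=float(row[colmap["max_landings_t"]]),
                mean_price_usd_kg=float(row[colmap["mean_price_usd_kg"]]),
                in_fmp=_parse_bool(row[colmap["in_fmp"]]),
            )
        except (TypeError, ValueError) as exc:
            problems.append(f"row {rowno}: unparseable value ({exc})")
            continue
        for p in rec.problems():
            problems.append(f"row {rowno}: {p}")
        records.append(rec)
    if problems:
        raise ValidationError(problems)
    return records


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if isinstance(value, (int, float, np.integer, np.floating)):
        return bool(int(value))
    s = str(value).strip().lower()
    if s in {"true", "t", "yes", "y", "1"}:
        return True
    if s in {"false", "f", "no", "n", "0"}:
        return False
    raise ValueError(f"cannot interpret {value!r} as boolean")


def write_stock_table(records: Iterable[StockRecord], path: str | Path) -> None:
    """Write records as a canonical stock-table CSV."""
    rows = []
    for r in records:
        d = {k: getattr(r, k) for k in DEFAULT_SCHEMA}
        rows.append(d)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# event times


def derive_event_time(
    record: StockRecord,
    origin_year: int = ORIGIN_YEAR,
    final_year: int = FINAL_YEAR,
) -> tuple[float, int]:
    """Observed duration and event indicator for one stock.

    Assessed stocks: ``T = min(Ya − Yl, Ya − origin_year)`` with event 1.
    Unassessed stocks: time elapsed to ``final_year`` with event 0.
    Durations of exactly zero (assessed in the origin or first-landings
    year) are replaced by half a year, since the Weibull has support t > 0.
    """
    yl = record.first_landed_year
    if record.assessment_year is not None:
        ya = record.assessment_year
        if ya < yl:
            raise ValidationError(
                [f"stock {record.stock_id}: assessment year {ya} precedes "
                 f"first landings {yl}"]
            )
        t = float(min(ya - yl, ya - origin_year))
        event = 1
    else:
        t = float(min(final_year - yl, final_year - origin_year))
        event = 0
    if t <= 0:
        t = HALF_YEAR
    return t, event


def compute_preassessment_covariates(
    landings_series: pd.DataFrame,
    cutoff_year: int,
    tons_to_kg: bool = True,
) -> tuple[float, float]:
    """Derive the two economic covariates from an annual landings series.

    Parameters
    ----------
    landings_series
        Long-format frame for one stock with columns ``year``, ``tonnage_t``
        (metric tons) and ``value_usd``.
    cutoff_year
        Exclusive upper bound of the window: the first-assessment year for
        assessed stocks, or one past the final database year for unassessed
        stocks.
    tons_to_kg
        Convert tonnage to kilograms when forming the price, giving US$/kg
        (the default reporting unit); landings themselves stay in tons.

    Returns
    -------
    (max_landings_t, mean_price_usd_kg)
        Maximum annual tonnage and mean ex-vessel price over years before
        the cutoff.  Years with zero tonnage or value are excluded from the
        price average.
    """
    window = landings_series[landings_series["year"] < cutoff_year]
    if window.empty:
        raise ValueError(
            f"no landings records before cutoff year {cutoff_year}"
        )
    max_landings = float(window["tonnage_t"].max())
    usable = window[(window["tonnage_t"] > 0) & (window["value_usd"] > 0)]
    if usable.empty:
        raise ValueError(
            f"no non-zero landings/value records before {cutoff_year}"
        )
    denom = usable["tonnage_t"] * (1000.0 if tons_to_kg else 1.0)
    price = float((usable["value_usd"] / denom).mean())
    return max_landings, price


# ---------------------------------------------------------------------------
# standardization


@dataclass
class ScaledColumn:
    """A 2-SD standardized column with the constants needed to invert it."""

    scaled: np.ndarray
    mean: float
    sd: float
    transform: str = "log10"

    def inverse(self) -> np.ndarray:
        """Recover the transformed (pre-scaling) values."""
        return self.scaled * 2.0 * self.sd + self.mean


def standardize(
    values: Sequence[float] | np.ndarray,
    transform: str = "log10",
) -> ScaledColumn:
    """Standardize by twice the standard deviation after transforming.

    The resulting column has sample mean 0 and sample SD 0.5, which puts
    a "two standard deviation" change of the covariate on the same footing
    as flipping a binary indicator.
    """
    x = np.asarray(values, dtype=float)
    if transform == "log10":
        if np.any(x <= 0):
            raise ValueError("log10 transform requires positive values")
        x = np.log10(x)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0:
        raise ValueError("zero-variance column cannot be standardized")
    return ScaledColumn((x - mean) / (2.0 * sd), mean, sd, transform)


# ---------------------------------------------------------------------------
# event table


@dataclass
class EventTable:
    """Model-ready durations, design matrix and factor index vectors."""

    time: np.ndarray               # (n,) durations, > 0
    event: np.ndarray              # (n,) 1 = assessed, 0 = censored
    X: np.ndarray                  # (n, p) standardized design
    colnames: list[str]
    factor_idx: dict[str, np.ndarray]      # factor -> (n,) int indices
    levels: dict[str, list[str]]           # factor -> ordered level labels
    scaling: dict[str, dict]               # column -> {mean, sd, transform}
    nesting: dict[str, dict[str, str]] = field(default_factory=dict)
    stock_ids: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.time)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def to_csv(self, path: str | Path, metadata_path: str | Path) -> None:
        """Serialize as CSV plus a JSON sidecar with scaling and level maps."""
        df = pd.DataFrame({"stock_id": self.stock_ids,
                           "time": self.time, "event": self.event})
        for j, name in enumerate(self.colnames):
            df[name] = self.X[:, j]
        for f in self.factor_idx:
            df[f"{f}_idx"] = self.factor_idx[f]
        df.to_csv(path, index=False)
        meta = {
            "colnames": self.colnames,
            "levels": self.levels,
            "scaling": self.scaling,
            "nesting": self.nesting,
        }
        Path(metadata_path).write_text(json.dumps(meta, indent=2))


def build_event_table(
    records: Sequence[StockRecord],
    include_fmp: bool = False,
    include_interaction: bool = True,
    origin_year: int = ORIGIN_YEAR,
    final_year: int = FINAL_YEAR,
) -> EventTable:
    """Assemble the model's input from validated stock records.

    Continuous columns (in order): standardized log10 price, log10 maximum
    landings, their interaction, and log10 maximum length.  The interaction
    is the elementwise product of the two standardized main-effect columns,
    itself re-standardized by twice its SD so its coefficient is comparable
    to the mains.  The FMP indicator, when included, enters raw (0/1).
    Factor levels are ordered lexicographically and frozen at build time.
    """
    problems: list[str] = []
    for r in records:
        problems.extend(f"stock {r.stock_id}: {p}" for p in r.problems())
    if problems:
        raise ValidationError(problems)

    times = np.empty(len(records))
    events = np.empty(len(records), dtype=int)
    for i, r in enumerate(records):
        times[i], events[i] = derive_event_time(r, origin_year, final_year)

    price = standardize([r.mean_price_usd_kg for r in records])
    landings = standardize([r.max_landings_t for r in records])
    length = standardize([r.max_length_cm for r in records])

    cols = [price.scaled, landings.scaled]
    names = ["log10_price", "log10_landings"]
    scaling = {
        "log10_price": _meta(price),
        "log10_landings": _meta(landings),
    }
    if include_interaction:
        inter = standardize(price.scaled * landings.scaled, transform="none")
        cols.append(inter.scaled)
        names.append("price_x_landings")
        scaling["price_x_landings"] = _meta(inter)
    cols.append(length.scaled)
    names.append("log10_length")
    scaling["log10_length"] = _meta(length)
    if include_fmp:
        cols.append(np.array([float(r.in_fmp) for r in records]))
        names.append(FMP_COLUMN)

    X = np.column_stack(cols)

    factor_idx: dict[str, np.ndarray] = {}
    levels: dict[str, list[str]] = {}
    for f in FACTORS:
        labels = [getattr(r, f) for r in records]
        lv = sorted(set(labels))
        if len(lv) < 2:
            raise DegenerateDesignError(
                f"factor {f!r} has a single level {lv!r}; at least two are "
                "required to estimate its variance"
            )
        index = {l: k for k, l in enumerate(lv)}
        factor_idx[f] = np.array([index[l] for l in labels], dtype=int)
        levels[f] = lv

    nesting = {
        "tax_order": _nesting_map(records, "tax_order", "tax_class"),
        "tax_family": _nesting_map(records, "tax_family", "tax_order"),
    }

    return EventTable(
        time=times,
        event=events,
        X=X,
        colnames=names,
        factor_idx=factor_idx,
        levels=levels,
        scaling=scaling,
        nesting=nesting,
        stock_ids=[r.stock_id for r in records],
    )


def _meta(col: ScaledColumn) -> dict:
    return {"mean": col.mean, "sd": col.sd, "transform": col.transform}


def _nesting_map(
    records: Sequence[StockRecord], child: str, parent: str
) -> dict[str, str]:
    """Child level -> parent level; error if a child sits under two parents."""
    out: dict[str, str] = {}
    for r in records:
        c, p = getattr(r, child), getattr(r, parent)
        if c in out and out[c] != p:
            raise DegenerateDesignError(
                f"{child} level {c!r} appears under both {parent} levels "
                f"{out[c]!r} and {p!r}; nesting must be a function"
            )
        out[c] = p
    return out


def impute_missing_prices(
    df: pd.DataFrame,
    price_col: str = "mean_price_usd_kg",
    species_col: str = "species",
) -> pd.DataFrame:
    """Fill missing/zero prices with the species median, else global median.

    Whole-stock exclusion would change the analysis n, so stocks without a
    usable price are retained with an imputed value and a logged warning.
    """
    out = df.copy()
    bad = out[price_col].isna() | (out[price_col] <= 0)
    if not bad.any():
        return out
    good = out.loc[~bad]
    global_median = float(good[price_col].median())
    for i in out.index[bad]:
        sp = out.at[i, species_col]
        sp_prices = good.loc[good[species_col] == sp, price_col]
        value = float(sp_prices.median()) if len(sp_prices) else global_median
        out.at[i, price_col] = value
        msg = (f"stock row {i}: missing/zero price imputed with "
               f"{'species' if len(sp_prices) else 'global'} median {value:.3g}")
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    return out
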