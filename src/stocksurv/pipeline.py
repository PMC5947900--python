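"""Reproducible pipeline: config parsing, run manifests, stage wiring.

A single YAML config drives any contiguous subset of the stages
simulate → fit → diagnose → project → report.  All randomness flows from
the one configured seed (stage seeds are derived from it), inputs are
checksummed into a JSON run manifest, and re-running an identical config
reproduces identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import build_event_table, read_stock_table, write_stock_table
from .diagnostics import (cox_snell_residuals, cumulative_hazard_slope,
                          finite_population_sd, kaplan_meier,
                          weibull_shape_check)
from .model import ModelConfig, PosteriorSamples, sample_posterior
from .report import (descriptive_tables, effect_summaries,
                     project_proportion_assessed)
from .simulate import SimulationConfig, generate_stocks

logger = logging.getLogger("stocksurv")

STAGES = ("simulate", "fit", "diagnose", "project", "report")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _derive_seed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    unknown = set(cfg) - set(STAGES) - {"seed", "output_dir"}
    if unknown:
        raise ValueError(f"unknown config section(s): {sorted(unknown)}")
    cfg.setdefault("seed", 0)
    cfg.setdefault("output_dir", "stocksurv_out")
    return cfg


def run_pipeline(config: str | Path | Mapping[str, Any]) -> dict[str, Path]:
    """Execute the configured stages; return the artifact paths.

    Each stage writes CSV/JSON artifacts into ``output_dir`` and the run
    closes with a manifest recording the config snapshot, input checksums,
    seed, package version, convergence summary and per-stage timings.
    """
    cfg = load_config(config) if isinstance(config, (str, Path)) else dict(config)
    seed = int(cfg.get("seed", 0))
    outdir = Path(cfg.get("output_dir", "stocksurv_out"))
    outdir.mkdir(parents=True, exist_ok=True)

    artifacts: dict[str, Path] = {}
    timings: dict[str, float] = {}
    checksums: dict[str, str] = {}
    convergence_summary = None
    manifest_path = outdir / "manifest.json"

    records = None
    table = None
    posterior: PosteriorSamples | None = None

    def finish(status: str) -> None:
        manifest = {
            "status": status,
            "config": _jsonable(cfg),
            "seed": seed,
            "version": __version__,
            "input_checksums": checksums,
            "convergence": convergence_summary,
            "timings_s": {k: round(v, 3) for k, v in timings.items()},
            "finished_utc": time.strftime("%Y-%m-%dT%H:%M:%SZ",
                                          time.gmtime()),
            "artifacts": {k: str(v) for k, v in artifacts.items()},
        }
        manifest_path.write_text(json.dumps(manifest, indent=2))
        artifacts["manifest"] = manifest_path

    try:
        if "simulate" in cfg:
            t0 = time.time()
            sim_cfg = SimulationConfig(
                **{**(cfg["simulate"] or {}),
                   "seed": _derive_seed(seed, "simulate")})
            records, truth = generate_stocks(sim_cfg)
            stocks_path = outdir / "stocks.csv"
            write_stock_table(records, stocks_path)
            truth_path = outdir / "truth.json"
            truth_path.write_text(json.dumps(_jsonable(truth), indent=2))
            artifacts["stocks"] = stocks_path
            artifacts["truth"] = truth_path
            checksums["stocks.csv"] = _checksum(stocks_path)
            timings["simulate"] = time.time() - t0
            logger.info("simulate: %d stocks (%.1f%% assessed) -> %s",
                        len(records), 100 * truth["assessed_fraction"],
                        stocks_path)

        needs_data = any(s in cfg for s in ("fit", "diagnose", "project",
                                            "report"))
        if needs_data and records is None:
            src = (cfg.get("fit") or {}).get("stock_table") \
                or str(outdir / "stocks.csv")
            records = read_stock_table(src)
            checksums[Path(src).name] = _checksum(Path(src))

        if needs_data:
            fit_cfg = dict(cfg.get("fit") or {})
            table = build_event_table(
                records,
                include_fmp=bool(fit_cfg.get("include_fmp", False)),
            )

        if "fit" in cfg:
            t0 = time.time()
            fit_cfg = dict(cfg["fit"] or {})
            fit_cfg.pop("stock_table", None)
            fit_cfg.pop("include_fmp", None)
            mc = ModelConfig(**{**fit_cfg, "seed": _derive_seed(seed, "fit")})
            posterior = sample_posterior(table, mc)
            post_path = outdir / "posterior.csv"
            posterior.to_dataframe().to_csv(post_path, index=False)
            fit_manifest = outdir / "fit_manifest.json"
            convergence_summary = posterior.convergence.to_dict("records")
            fit_manifest.write_text(json.dumps({
                "config": _jsonable(dataclasses.asdict(mc)),
                "colnames": posterior.colnames,
                "levels": posterior.levels,
                "converged": posterior.converged,
                "rhat": convergence_summary,
                "scaling": table.scaling,
            }, indent=2))
            artifacts["posterior"] = post_path
            artifacts["fit_manifest"] = fit_manifest
            timings["fit"] = time.time() - t0
            logger.info("fit: %d retained draws, converged=%s",
                        posterior.n_draws, posterior.converged)
            for row in posterior.convergence.itertuples():
                logger.info("  %-24s rhat=%.4f ess=%.0f", row.parameter,
                            row.rhat, row.ess)

        if posterior is None and any(s in cfg for s in ("diagnose",
                                                        "project")):
            posterior = _load_posterior(outdir)

        if "diagnose" in cfg:
            t0 = time.time()
            km = kaplan_meier(table.time, table.event)
            slope, intercept, _ = weibull_shape_check(km)
            res, res_event = cox_snell_residuals(posterior, table)
            cs_slope = cumulative_hazard_slope(res, res_event)
            pd.DataFrame({
                "stock_id": table.stock_ids,
                "cox_snell_residual": res,
                "event": res_event,
            }).to_csv(outdir / "residuals.csv", index=False)
            fps = {
                f: float(np.median(finite_population_sd(posterior.effects[f])))
                for f in posterior.effects
            }
            diag = {
                "km_loglog_slope": slope,
                "km_loglog_intercept": intercept,
                "cox_snell_slope": cs_slope,
                "finite_population_sd_median": fps,
            }
            diag_path = outdir / "diagnostics.json"
            diag_path.write_text(json.dumps(diag, indent=2))
            artifacts["residuals"] = outdir / "residuals.csv"
            artifacts["diagnostics"] = diag_path
            timings["diagnose"] = time.time() - t0

        if "project" in cfg:
            t0 = time.time()
            horizon = int((cfg["project"] or {}).get("horizon_year", 2043))
            proj = project_proportion_assessed(posterior, table, records,
                                               horizon)
            proj_path = outdir / "projection.csv"
            proj.table.to_csv(proj_path, index=False)
            artifacts["projection"] = proj_path
            timings["project"] = time.time() - t0

        if "report" in cfg:
            t0 = time.time()
            tables = descriptive_tables(records)
            for name, df in tables.items():
                p = outdir / f"descriptive_{name}.csv"
                df.to_csv(p, index=False)
                artifacts[f"descriptive_{name}"] = p
            if posterior is not None:
                eff = effect_summaries(posterior, nesting=table.nesting)
                eff_path = outdir / "effects.csv"
                eff.to_csv(eff_path, index=False)
                artifacts["effects"] = eff_path
            timings["report"] = time.time() - t0
    except Exception:
        finish("failed")
        raise
    finish("ok")
    return artifacts


def _load_posterior(outdir: Path) -> PosteriorSamples:
    manifest = json.loads((outdir / "fit_manifest.json").read_text())
    df = pd.read_csv(outdir / "posterior.csv")
    return PosteriorSamples.from_dataframe(
        df, colnames=manifest["colnames"], levels=manifest["levels"]
    )


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
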