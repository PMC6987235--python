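"""End-to-end orchestration: simulate -> chronologies -> SPEI -> events ->
indices -> models -> report.

Every stage writes its outputs into the run directory and a manifest
records the configuration hash, seed and a hash over all numeric
artefacts, so that a rerun with the same seed is verifiably identical.
Randomness is split into one child stream per stage derived from the
master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .chronology import build_chronology
from .drought import (COMMON_PERIOD, detect_event, select_window,
                      site_event_search_window, site_mean_trw)
from .exceptions import ConfigError
from .models import ResilienceLMM, soil_fertility_pc1
from .resilience import build_records, growth_pattern_bootstrap
from .ring_io import assemble_dataset
from .spei import aridity_index, spei_grid
from .synthetic import SyntheticConfig, generate_dataset

log = logging.getLogger("treesilience")

__all__ = ["RunConfig", "run_pipeline", "report"]

RESPONSES = ("resilience", "resistance", "recovery")


@dataclass
class RunConfig:
    """Configuration of a pipeline run."""

    out_dir: str
    synthetic: SyntheticConfig = None      # or provide input paths below
    rwl_paths: list = None
    metadata_csv: str = None
    climate_csv: str = None
    soil_csv: str = None
    window_m: int = 4
    metrics: tuple = ("TRW", "BAI")
    common_period: tuple = COMMON_PERIOD
    calibration_span: tuple = None         # None = full record
    aridity_span: tuple = (1970, 2000)
    n_boot: int = 1000
    seed: int = 0
    fit_models: bool = True

    def __post_init__(self):
        if not 1 <= self.window_m <= 8:
            raise ConfigError(f"window_m must be in 1..8, got {self.window_m}")
        for m in self.metrics:
            if m not in ("TRW", "BAI"):
                raise ConfigError(f"unknown metric {m!r}")
        if self.synthetic is None and not (
                self.rwl_paths and self.metadata_csv and self.climate_csv
                and self.soil_csv):
            raise ConfigError("provide either a synthetic block or all input "
                              "paths (rwl, metadata, climate, soil)")

    def config_hash(self):
        payload = {k: str(v) for k, v in dataclasses.asdict(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _hash_file(path):
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def run_pipeline(config):
    """Execute all stages; returns the run directory path.

    Stage failures raise with the stage name and offending site/tree ids
    in the message; skip decisions (short series, eventless sites, trees
    without coverage) are persisted in the run directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # -- stage 1: inputs ---------------------------------------------------
    if config.synthetic is not None:
        log.info("stage simulate: %d sites", config.synthetic.n_sites)
        paths = generate_dataset(config.synthetic, out / "inputs")
        rwl, meta = paths["rwl"], paths["metadata"]
        clim, soil = paths["climate"], paths["soil"]
    else:
        rwl, meta = config.rwl_paths, config.metadata_csv
        clim, soil = config.climate_csv, config.soil_csv
    dataset = assemble_dataset(rwl, meta, clim, soil)
    log.info("stage assemble: %d trees, %d sites",
             len(dataset.series), len(dataset.sites))

    # -- stage 2: chronologies --------------------------------------------
    chronologies = {}
    for site in dataset.sites:
        try:
            chronologies[site] = build_chronology(dataset.site_series(site),
                                                  site_id=site)
        except Exception as exc:
            raise RuntimeError(f"stage chronology failed at site {site}: {exc}") \
                from exc
    pd.concat([c.to_frame() for c in chronologies.values()]).to_csv(
        out / "chronologies.csv", index=False)

    # -- stage 3: SPEI grids, aridity -------------------------------------
    grids, aridity = {}, {}
    for site in dataset.sites:
        sc = dataset.site_climate(site)
        hemi = dataset.hemisphere(site)
        grids[site] = spei_grid(sc, hemisphere=hemi,
                                calibration_span=config.calibration_span,
                                site_id=site)
        aridity[site] = aridity_index(sc, span=config.aridity_span,
                                      site_id=site).aridity
    pd.concat([g.to_frame() for g in grids.values()]).to_csv(
        out / "spei_grid.csv", index=False)

    # -- stage 4: window selection and events ------------------------------
    selections, events, spei_best = {}, {}, {}
    event_rows, skip_rows = [], []
    for site in dataset.sites:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sel = select_window(chronologies[site], grids[site],
                                common_period=config.common_period)
        selections[site] = sel
        spei_best[site] = grids[site][sel.best]
        deaths = [s.last_year for s in dataset.site_series(site)
                  if s.status == "now-dead"]
        if not deaths:
            skip_rows.append({"site": site, "stage": "events",
                              "reason": "no now-dead trees"})
            events[site] = None
            continue
        lo, hi, _ = site_event_search_window(deaths)
        ev = detect_event(site_mean_trw(dataset.site_series(site)),
                          spei_best[site], (lo, hi), site_id=site)
        events[site] = ev
        if ev is None:
            skip_rows.append({"site": site, "stage": "events",
                              "reason": "no qualifying drought year"})
        else:
            event_rows.append({
                "site": site, "year": ev.year, "spei_i": ev.spei_i,
                "threshold": ev.spei_threshold, "growth_drop": ev.growth_drop,
                "lag": ev.drop_year_lag, "window_lo": lo, "window_hi": hi,
                "best_month": sel.best[0], "best_scale": sel.best[1],
            })
    pd.concat([s.table.assign(site=k) for k, s in selections.items()]).to_csv(
        out / "window_selection.csv", index=False)
    pd.DataFrame(event_rows).to_csv(out / "events.csv", index=False)
    log.info("stage events: %d/%d sites with an event",
             len(event_rows), len(dataset.sites))

    # -- stage 5: covariates and records -----------------------------------
    soil_scores, _, soil_varfrac = soil_fertility_pc1(dataset.soil)
    records, skipped = build_records(
        dataset, events, spei_best, window_m=config.window_m,
        metrics=config.metrics, aridity=aridity,
        soil_pc1=soil_scores.to_dict())
    # drop single-status sites from the model table (matched-pairs design)
    if len(records):
        records = records[~records["site"].isin(dataset.single_status_sites)]
    records.to_csv(out / "records.csv", index=False)
    skip_rows += [{"site": t.split("T")[0], "stage": "records",
                   "reason": f"{t} ({m}): {r}"} for t, m, r in skipped]
    pd.DataFrame(skip_rows).to_csv(out / "skipped.csv", index=False)

    boot = growth_pattern_bootstrap(dataset, events, window_m=config.window_m,
                                    n_boot=config.n_boot, seed=config.seed)
    boot.to_csv(out / "growth_patterns.csv", index=False)

    # -- stage 6: models ----------------------------------------------------
    model_summaries = {}
    if config.fit_models and len(records):
        for metric in config.metrics:
            for response in RESPONSES:
                key = f"{response}_{metric}"
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        fit = ResilienceLMM(records, response=response,
                                            metric=metric,
                                            drop_aliased=True).fit()
                    model_summaries[key] = fit.to_dict()
                    (out / f"model_{key}.txt").write_text(fit.summary() + "\n")
                    fit.adjusted_means().to_csv(
                        out / f"adjusted_means_{key}.csv", index=False)
                except Exception as exc:
                    raise RuntimeError(
                        f"stage models failed for {key}: {exc}") from exc
        (out / "models.json").write_text(
            json.dumps(model_summaries, indent=1, default=float))
    log.info("stage models: %d fits", len(model_summaries))

    # -- manifest -----------------------------------------------------------
    artefacts = sorted(p.name for p in out.glob("*.csv"))
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "soil_pc1_variance_fraction": soil_varfrac,
        "n_trees": len(dataset.series),
        "n_sites": len(dataset.sites),
        "n_events": len(event_rows),
        "artefact_hashes": {a: _hash_file(out / a) for a in artefacts},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def report(run_dir):
    """Assemble a human-readable summary of a completed run."""
    run = Path(run_dir)
    needed = ["manifest.json", "events.csv", "records.csv"]
    missing = [n for n in needed if not (run / n).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete run {run}: missing {missing}")
    manifest = json.loads((run / "manifest.json").read_text())
    lines = [
        "# Drought-resilience run report",
        f"version {manifest['version']}, seed {manifest['seed']}, "
        f"config {manifest['config_hash']}",
        f"{manifest['n_trees']} trees, {manifest['n_sites']} sites, "
        f"{manifest['n_events']} drought events detected",
        "",
        "## Drought events",
    ]
    events = pd.read_csv(run / "events.csv")
    lines.append(events.to_string(index=False) if len(events) else "(none)")
    if (run / "models.json").exists():
        models = json.loads((run / "models.json").read_text())
        lines.append("\n## Status-contrast models")
        for key, m in models.items():
            surv = m["coefficients"].get("surviving", {})
            lines.append(
                f"- {key}: surviving std beta = {surv.get('std_beta', float('nan')):.3f} "
                f"(p = {surv.get('p', float('nan')):.3g}), "
                f"R2m/R2c = {m['r2m']:.2f}/{m['r2c']:.2f}, "
                f"dAIC(status) = {m['delta_aic_status']:.1f}, n = {m['n']}")
    boot_path = run / "growth_patterns.csv"
    if boot_path.exists():
        boot = pd.read_csv(boot_path)
        if len(boot):
            lines.append("\n## Growth trajectories (log ratio to pre-drought mean)")
            ev = boot[boot["rel_year"] == 0]
            for _, r in ev.iterrows():
                lines.append(f"- {r['group']}/{r['status']}: event-year "
                             f"log ratio {r['mean_log_ratio']:.3f} "
                             f"[{r['ci_lo']:.3f}, {r['ci_hi']:.3f}] "
                             f"(n = {int(r['n_trees'])})")
    text = "\n".join(lines) + "\n"
    (run / "report.md").write_text(text)
    return text
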