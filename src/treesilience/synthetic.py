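"""Synthetic study-input generator with recoverable ground truth.

Emulates the structure of a pancontinental tree-ring case-control
database: per-site monthly climate (precipitation and PET) with a
planted extreme-drought year, per-tree annual ring-width series whose
log-growth couples to the SPEI at one "true" window per site, and
status-specific deficits at the event (now-dead angiosperms resist less;
now-dead gymnosperms recover less), plus per-site soil tables with a
latent fertility factor and nested site/species/genus taxonomy.

The growth model is multiplicative lognormal,

    log TRW(t) = log trend(age) + beta_climate * SPEI(t) + e(t),

with a modified negative-exponential size trend and AR(1) noise ``e``.
Now-dead trees additionally have their event-year growth multiplied by
``resist_deficit_dead`` and their post-event-window growth by
``resist_deficit_dead * recov_deficit_dead`` (so the planted dead/surviving
ratios of resistance and recovery equal the two deficits), and their
series terminate at a death year drawn uniformly 10-40 years after the
event.  Everything is driven by one seeded RNG, so identical
configurations yield byte-identical bundles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import spei as spei_mod
from .exceptions import ConfigError
from .ring_io import RingSeries, write_rwl

__all__ = ["SyntheticConfig", "GroundTruthLedger", "generate_climate",
           "generate_tree_series", "generate_soil_table", "generate_dataset",
           "generate_bundle"]

_GENERA = [("Quercus", "angiosperm"), ("Fagus", "angiosperm"),
           ("Pinus", "gymnosperm"), ("Abies", "gymnosperm"),
           ("Nothofagus", "angiosperm"), ("Picea", "gymnosperm")]


@dataclass
class SyntheticConfig:
    """Study conditions of a synthetic dataset (one value = one condition)."""

    n_sites: int = 5
    trees_per_site_surviving: int = 10
    trees_per_site_dead: int = 10
    taxon_per_site: list = None          # "angiosperm"/"gymnosperm" per site
    span: tuple = (1901, 2013)
    true_window: list = None             # (target_month, scale) per site
    event_year: list = None              # calendar year per site
    beta_climate: float = 0.12           # log-growth per SPEI unit
    ar_coef: float = 0.3                 # lag-1 autocorrelation of noise
    noise_sd: float = 0.15               # stationary sd of log-growth noise
    climate_noise_sd: float = 0.25       # interannual lognormal sd of monthly P
    resist_deficit_dead: dict = None     # per taxon, in (0, 1]
    recov_deficit_dead: dict = None
    trend_params: tuple = (1.5, 0.03, 1.0)   # a*exp(-b*age)+c, mm
    hemisphere: str = "N"
    seed: int = 0

    def __post_init__(self):
        ns = self.n_sites
        if self.taxon_per_site is None:
            self.taxon_per_site = [_GENERA[i % len(_GENERA)][1] for i in range(ns)]
        if self.true_window is None:
            months = spei_mod.target_months(self.hemisphere)
            pool = [(months[i % 5], [1, 3, 6, 12, 24][(i // 5) % 5])
                    for i in range(ns)]
            self.true_window = pool
        if self.event_year is None:
            lo = self.span[0] + 54
            self.event_year = [lo + 3 * (i % 4) for i in range(ns)]
        if self.resist_deficit_dead is None:
            self.resist_deficit_dead = {"angiosperm": 0.7, "gymnosperm": 0.9}
        if self.recov_deficit_dead is None:
            self.recov_deficit_dead = {"angiosperm": 1.0, "gymnosperm": 0.7}
        self.validate()

    def validate(self):
        if self.n_sites < 1 or self.trees_per_site_surviving < 1 \
                or self.trees_per_site_dead < 1:
            raise ConfigError("all counts must be >= 1")
        if self.span[1] - self.span[0] + 1 < 50:
            raise ConfigError("span must cover at least 50 years")
        for i, ey in enumerate(self.event_year):
            if not (self.span[0] + 4 <= ey <= self.span[1] - 4):
                raise ConfigError(
                    f"site {i}: event year {ey} needs >= 4 years margin in span")
            if ey + 10 > self.span[1] - 1:
                raise ConfigError(
                    f"site {i}: event year {ey} leaves no room for deaths "
                    "10+ years later")
        for m, k in self.true_window:
            if not 1 <= k <= 24:
                raise ConfigError(f"scale {k} outside 1..24")
            if m not in spei_mod.target_months(self.hemisphere):
                raise ConfigError(f"target month {m} not a candidate for "
                                  f"hemisphere {self.hemisphere}")
        for d in (*self.resist_deficit_dead.values(),
                  *self.recov_deficit_dead.values()):
            if not 0 < d <= 1:
                raise ConfigError(f"deficit {d} must be in (0, 1]")
        if not 0 <= self.ar_coef < 1:
            raise ConfigError("ar_coef must be in [0, 1)")

    @property
    def years(self):
        return np.arange(self.span[0], self.span[1] + 1)


@dataclass
class GroundTruthLedger:
    """What was planted, for downstream recovery checks."""

    sites: dict = field(default_factory=dict)   # site -> {true_window, event_year, taxon}
    trees: dict = field(default_factory=dict)   # tree -> {status, death_year, ratios}

    def to_json(self, path):
        payload = {"sites": self.sites, "trees": self.trees}
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path):
        payload = json.loads(Path(path).read_text())
        return cls(sites=payload["sites"], trees=payload["trees"])


def _seasonal_means(hemisphere):
    """Monthly climatological means for P (mm) and PET (mm)."""
    months = np.arange(1, 13)
    peak = 7 if hemisphere == "N" else 1          # warmest month
    phase = np.cos(2 * np.pi * (months - peak) / 12)
    pet = 60 + 45 * phase                          # 15..105 mm/month
    prcp = 70 - 25 * phase                         # wetter winters
    return prcp, pet


def generate_climate(config, site_index, rng):
    """Monthly precipitation and PET for one site with a planted drought.

    The planted event year is forced to carry the most negative
    accumulated water balance at the site's true (month, scale) window,
    by removing precipitation (and, if exhausted, adding PET) in the
    window months until the event-year aggregate undercuts every other
    year by one standard deviation of the aggregated series.
    """
    years = config.years
    n_years = years.size
    prcp_clim, pet_clim = _seasonal_means(config.hemisphere)
    prcp = np.tile(prcp_clim, n_years)
    pet = np.tile(pet_clim, n_years)
    sd = config.climate_noise_sd
    if sd > 0:
        # lognormal multiplicative interannual noise, mean-one
        fac_p = np.exp(rng.normal(-0.5 * sd ** 2, sd, 12 * n_years))
        fac_e = np.exp(rng.normal(-0.5 * (sd / 3) ** 2, sd / 3, 12 * n_years))
        prcp = prcp * fac_p
        pet = pet * fac_e

    month, scale = config.true_window[site_index]
    event_year = config.event_year[site_index]
    d = spei_mod.water_balance(prcp, pet)
    agg = spei_mod.aggregate(d, years, scale, month, config.hemisphere)
    others = agg.drop(index=event_year)
    margin = max(float(others.std()), 1.0)
    deficit_needed = float(agg.loc[event_year] - (others.min() - margin))
    if deficit_needed > 0:
        # indices of the k window months ending at (event_year, month)
        yi = int(np.where(years == event_year)[0][0])
        off = -1 if (config.hemisphere == "S" and month == 12) else 0
        end = (yi + off) * 12 + month
        idx = np.arange(end - scale, end)
        avail = prcp[idx].sum()
        cut = min(deficit_needed, avail * 0.95)
        prcp[idx] *= 1.0 - cut / avail
        remainder = deficit_needed - cut
        if remainder > 0:
            pet[idx] += remainder / scale
    clim = pd.DataFrame({
        "year": np.repeat(years, 12),
        "month": np.tile(np.arange(1, 13), n_years),
        "prcp_mm": np.round(prcp, 4),
        "pet_mm": np.round(pet, 4),
    })
    return clim


def _true_spei(config, site_index, climate):
    month, scale = config.true_window[site_index]
    d = spei_mod.water_balance(climate["prcp_mm"].to_numpy(),
                               climate["pet_mm"].to_numpy())
    agg = spei_mod.aggregate(d, config.years, scale, month, config.hemisphere)
    return spei_mod.standardize_loglogistic(agg)


def generate_tree_series(config, site_index, climate, rng, ledger=None):
    """Generate the RingSeries of one site (surviving + now-dead trees)."""
    site_id = f"S{site_index + 1:03d}"
    taxon = config.taxon_per_site[site_index]
    genus = next(g for g, t in _GENERA if t == taxon)
    # distinct species per site so species nests strictly inside genus
    species = f"{genus} sp{site_index + 1}"
    event_year = config.event_year[site_index]
    spei_t = _true_spei(config, site_index, climate)
    years = config.years
    spei_full = spei_t.reindex(years).fillna(0.0).to_numpy()
    a, b, c = config.trend_params
    rd = config.resist_deficit_dead[taxon]
    cd = config.recov_deficit_dead[taxon]

    out = []
    n_s, n_d = config.trees_per_site_surviving, config.trees_per_site_dead
    statuses = ["surviving"] * n_s + ["now-dead"] * n_d
    for j, status in enumerate(statuses):
        start = years[0] + int(rng.integers(0, 10))
        if status == "now-dead":
            death = event_year + int(rng.integers(10, 41))
            death = min(death, int(years[-1]) - 1)
            tyears = np.arange(start, death + 1)
        else:
            tyears = np.arange(start, years[-1] + 1)
        n = tyears.size
        age = np.arange(1, n + 1)
        innov_sd = config.noise_sd * np.sqrt(1 - config.ar_coef ** 2)
        e = np.empty(n)
        e[0] = rng.normal(0, config.noise_sd)
        eps = rng.normal(0, innov_sd, n)
        for t in range(1, n):
            e[t] = config.ar_coef * e[t - 1] + eps[t]
        sp = spei_full[np.searchsorted(years, tyears)]
        log_trw = np.log(a * np.exp(-b * age) + c) \
            + config.beta_climate * sp + e
        if status == "now-dead":
            ev = tyears == event_year
            post = (tyears > event_year) & (tyears <= event_year + 4)
            log_trw[ev] += np.log(rd)
            log_trw[post] += np.log(rd * cd)
        trw = np.round(np.exp(log_trw), 3)
        trw = np.maximum(trw, 0.01)
        dbh = round(2 * trw.sum() / 10 + 0.2, 1)
        tid = f"{site_id}T{j + 1:03d}"
        out.append(RingSeries(tid, tyears, trw, site_id=site_id,
                              species=species, genus=genus, group=taxon,
                              status=status, dbh_cm=dbh))
        if ledger is not None:
            ledger.trees[tid] = {
                "site": site_id, "status": status,
                "death_year": int(tyears[-1]) if status == "now-dead" else None,
                "expected_resistance_ratio": rd if status == "now-dead" else 1.0,
                "expected_recovery_ratio": cd if status == "now-dead" else 1.0,
            }
    if ledger is not None:
        ledger.sites[site_id] = {
            "true_window": list(config.true_window[site_index]),
            "event_year": int(event_year), "taxon": taxon,
            "species": species, "genus": genus,
        }
    return out


def generate_soil_table(n_sites, rng):
    """Per-site table of ten soil characteristics with a latent fertility axis.

    The latent factor loads positively on total nitrogen, organic carbon
    and available water capacity, so a correctly oriented soil PC1 is
    positively associated with nitrogen concentration.
    """
    if n_sites < 3:
        raise ConfigError("need at least 3 sites for a soil table")
    f = rng.normal(0, 1, n_sites)
    z = lambda s: rng.normal(0, s, n_sites)
    oc = np.clip(18 + 6 * f + z(2.0), 2, None)          # g/kg
    tn = np.clip(1.3 + 0.4 * f + z(0.12), 0.2, None)    # g/kg
    cn = oc / tn
    bulk = np.clip(1.35 - 0.08 * f + z(0.05), 0.8, 1.8)  # kg/dm3
    awc = np.clip(13 + 3 * f + z(1.0), 3, None)          # cm/m
    depth = np.clip(120 + 40 * rng.normal(0, 1, n_sites), 20, None)  # cm
    ph = np.clip(6.2 - 0.25 * f + z(0.2), 3.5, 9.0)
    clay = np.clip(25 + 4 * f + z(3.0), 5, 60)
    silt = np.clip(35 + z(4.0), 5, 70)
    sand = 100.0 - clay - silt
    bad = sand < 5
    if np.any(bad):                                       # renormalise texture
        tot = clay[bad] + silt[bad]
        clay[bad] *= 95.0 / tot
        silt[bad] *= 95.0 / tot
        sand[bad] = 5.0
    return pd.DataFrame({
        "site": [f"S{i + 1:03d}" for i in range(n_sites)],
        "organic_carbon": np.round(oc, 3),
        "total_nitrogen": np.round(tn, 3),
        "cn_ratio": np.round(cn, 3),
        "bulk_density": np.round(bulk, 3),
        "awc": np.round(awc, 3),
        "depth_bedrock": np.round(depth, 1),
        "ph": np.round(ph, 3),
        "clay": np.round(clay, 4),
        "silt": np.round(silt, 4),
        "sand": np.round(100.0 - np.round(clay, 4) - np.round(silt, 4), 4),
    })


def simulate_record_table(n_sites=100, trees_per_site=30, status_effect=-0.10,
                          sd_genus=0.05, sd_species=0.05, sd_site=0.10,
                          sd_resid=0.30, n_genera=10, baseline=-0.05,
                          seed=0):
    """Record table drawn directly from the mixed-model generating equation.

    log-index = baseline + status_effect * surviving + u_genus + u_species
    + u_site + e, with nested Gaussian random intercepts; half the trees
    at each site are surviving.  Used for fast parameter-recovery and
    type-I simulations of the status-contrast model without running the
    ring-level pipeline.
    """
    rng = np.random.default_rng(seed)
    n_species = max(n_genera, n_sites // 5)
    u_g = rng.normal(0, sd_genus, n_genera)
    u_sp = rng.normal(0, sd_species, n_species)
    u_si = rng.normal(0, sd_site, n_sites)
    rows = []
    for i in range(n_sites):
        sp = i % n_species
        g = sp % n_genera
        n_dead = trees_per_site // 2
        for j in range(trees_per_site):
            surviving = j >= n_dead
            mu = baseline + (status_effect if surviving else 0.0) \
                + u_g[g] + u_sp[sp] + u_si[i]
            y = mu + rng.normal(0, sd_resid)
            rows.append({
                "tree_id": f"S{i:03d}T{j:03d}", "site": f"S{i:03d}",
                "species": f"sp{sp:03d}", "genus": f"g{g:02d}",
                "group": "gymnosperm" if g % 2 else "angiosperm",
                "status": "surviving" if surviving else "now-dead",
                "metric": "TRW",
                "resilience": float(np.exp(y)),
            })
    return pd.DataFrame(rows)


def generate_bundle(config):
    """Generate the full in-memory bundle.

    Returns ``(series, metadata, climate, soil, ledger)``; one child RNG
    stream per generation stage, all derived from ``config.seed``.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_clim, rng_tree, rng_soil = [np.random.default_rng(s) for s in ss.spawn(3)]
    ledger = GroundTruthLedger()
    all_series, climates = [], []
    for i in range(config.n_sites):
        clim = generate_climate(config, i, rng_clim)
        clim.insert(0, "site", f"S{i + 1:03d}")
        climates.append(clim)
        all_series.extend(generate_tree_series(config, i, clim, rng_tree, ledger))
    climate = pd.concat(climates, ignore_index=True)
    soil = generate_soil_table(config.n_sites, rng_soil)
    metadata = pd.DataFrame([{
        "tree_id": s.tree_id, "site": s.site_id, "species": s.species,
        "genus": s.genus, "group": s.group, "status": s.status,
        "dbh_cm": s.dbh_cm, "last_year": s.last_year,
        "hemisphere": config.hemisphere,
    } for s in all_series])
    return all_series, metadata, climate, soil, ledger


def generate_dataset(config, out_dir):
    """Write a complete synthetic bundle to ``out_dir``.

    Produces one .rwl per site, metadata.csv, climate.csv, soil.csv and
    ledger.json; returns the paths dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    series, metadata, climate, soil, ledger = generate_bundle(config)
    rwl_paths = []
    for site, grp in metadata.groupby("site", sort=True):
        site_series = [s for s in series if s.site_id == site]
        p = out / f"{site}.rwl"
        write_rwl(site_series, p, units_dialect="0.001mm")
        rwl_paths.append(p)
    paths = {
        "rwl": rwl_paths,
        "metadata": out / "metadata.csv",
        "climate": out / "climate.csv",
        "soil": out / "soil.csv",
        "ledger": out / "ledger.json",
    }
    metadata.to_csv(paths["metadata"], index=False)
    climate.to_csv(paths["climate"], index=False)
    soil.to_csv(paths["soil"], index=False)
    ledger.to_json(paths["ledger"])
    return paths
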