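"""Lloret resilience indices, BAI, SPEI covariates and growth trajectories.

For a drought year *i* with window *m* (default 4 years):

    resistance = Dr / PreDr
    recovery   = PostDr / Dr
    resilience = PostDr / PreDr = resistance * recovery

where PreDr and PostDr are arithmetic means of raw growth (TRW or BAI)
over the m years strictly before/after the event and Dr is the event-year
growth.  Drought-intensity covariates follow the same pattern on the
SPEI scale:

    SPEIdiff_resist = SPEI_i - PreSPEI
    SPEIdiff_recov  = PostSPEI - SPEI_i
    SPEIdiff_resil  = PostSPEI - PreSPEI

Basal area increment (BAI, mm^2) is reconstructed outside-in from the
DBH at sampling, so the geometric trend of ring width on a growing stem
is reduced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["compute_bai", "dbh_at_year", "lloret_indices", "spei_covariates",
           "build_records", "growth_pattern_bootstrap", "LloretIndices"]

DEFAULT_WINDOW_M = 4


@dataclass
class LloretIndices:
    resistance: float
    recovery: float
    resilience: float


def compute_bai(ring_series):
    """Annual basal area increment (mm^2) from widths and DBH at sampling.

    Radii are reconstructed outside-in: the radius at the last ring is
    DBH/2 and each earlier radius subtracts the later ring width.
    Missing (locally absent) rings are bridged linearly for the radius
    accumulation only.  If the reconstruction reaches a non-positive
    radius, the series start is truncated with a warning.
    """
    if not np.isfinite(ring_series.dbh_cm):
        raise ValueError(f"{ring_series.tree_id}: DBH unknown; cannot compute BAI")
    trw = pd.Series(ring_series.trw, index=ring_series.years)
    filled = trw.interpolate(limit_direction="both")
    r_last = ring_series.dbh_cm * 10.0 / 2.0
    # r[t] after ring t; r[t-1] = r[t] - trw[t]
    rev_cum = filled[::-1].cumsum()[::-1]
    r_after = r_last - (rev_cum - filled)     # radius after each year's ring
    r_before = r_after - filled
    bad = r_before < -1e-9          # a zero radius (ring from pith) is valid
    if bad.any():
        first_ok = (~bad).idxmax()
        warnings.warn(
            f"{ring_series.tree_id}: ring widths exceed DBH/2 before "
            f"{first_ok}; BAI series truncated", stacklevel=2)
        r_after, r_before = r_after[first_ok:], r_before[first_ok:]
    bai = np.pi * (r_after ** 2 - r_before ** 2)
    bai.name = ring_series.tree_id
    return bai


def dbh_at_year(ring_series, year):
    """DBH (cm) at the end of a given year, reconstructed from rings."""
    if not (ring_series.first_year <= year <= ring_series.last_year):
        raise ValueError(f"{ring_series.tree_id}: year {year} outside series")
    trw = pd.Series(ring_series.trw, index=ring_series.years)
    later = trw[trw.index > year].fillna(0.0)
    dbh = ring_series.dbh_cm - 2.0 * later.sum() / 10.0
    if dbh <= 0:
        raise ValueError(
            f"{ring_series.tree_id}: reconstructed DBH at {year} is "
            f"non-positive ({dbh:.2f} cm); inconsistent inputs")
    return float(dbh)


def lloret_indices(growth, event_year, window_m=DEFAULT_WINDOW_M):
    """Resistance, recovery and resilience around an event year.

    ``growth`` is a year-indexed series of raw TRW or BAI.  The pre/post
    windows are the m years strictly before/after the event (the event
    year itself is excluded).  Raises ``ValueError`` when coverage is
    incomplete — now-dead trees that died within m years of the event
    cannot be scored at that window.
    """
    if not 1 <= window_m <= 8:
        raise ValueError(f"window_m must be in 1..8, got {window_m}")
    need = list(range(event_year - window_m, event_year + window_m + 1))
    vals = growth.reindex(need)
    if vals.isna().any():
        missing = [int(y) for y in vals.index[vals.isna()]]
        raise ValueError(f"growth missing for years {missing}")
    if (vals <= 0).any():
        raise ValueError("growth must be positive for ratio indices")
    pre = float(vals.loc[event_year - window_m:event_year - 1].mean())
    dr = float(vals.loc[event_year])
    post = float(vals.loc[event_year + 1:event_year + window_m].mean())
    return LloretIndices(resistance=dr / pre, recovery=post / dr,
                         resilience=post / pre)


def spei_covariates(spei_series, event_year, window_m=DEFAULT_WINDOW_M):
    """SPEI_i, PreSPEI, PostSPEI and the three SPEI differences."""
    need = list(range(event_year - window_m, event_year + window_m + 1))
    vals = spei_series.reindex(need)
    if vals.isna().any():
        missing = [int(y) for y in vals.index[vals.isna()]]
        raise ValueError(f"SPEI missing for years {missing}")
    spei_i = float(vals.loc[event_year])
    pre = float(vals.loc[event_year - window_m:event_year - 1].mean())
    post = float(vals.loc[event_year + 1:event_year + window_m].mean())
    return {
        "spei_i": spei_i, "pre_spei": pre, "post_spei": post,
        "speidiff_resist": spei_i - pre,
        "speidiff_recov": post - spei_i,
        "speidiff_resil": post - pre,
    }


def _growth_series(ring_series, metric):
    if metric == "TRW":
        return ring_series.to_series()
    if metric == "BAI":
        return compute_bai(ring_series)
    raise ValueError(f"metric must be 'TRW' or 'BAI', got {metric!r}")


def build_records(dataset, events, spei_at_best, window_m=DEFAULT_WINDOW_M,
                  metrics=("TRW", "BAI"), aridity=None, soil_pc1=None):
    """Assemble the per-tree record table feeding the mixed models.

    Parameters
    ----------
    dataset : ring_io.Dataset
    events : dict site -> DroughtEvent (sites without events are skipped)
    spei_at_best : dict site -> year-indexed SPEI series at the selected window
    aridity, soil_pc1 : dict site -> float covariates (optional)

    Returns
    -------
    (records, skipped) : (pd.DataFrame, list of (tree_id, metric, reason))
        One row per (tree, metric) with full coverage of the event
        window; trees lacking coverage (e.g. dying within m years of the
        event) are logged with the reason.
    """
    rows, skipped = [], []
    aridity = aridity or {}
    soil_pc1 = soil_pc1 or {}
    for site, event in events.items():
        if event is None:
            continue
        cov = spei_covariates(spei_at_best[site], event.year, window_m)
        for s in dataset.site_series(site):
            for metric in metrics:
                try:
                    growth = _growth_series(s, metric)
                    idx = lloret_indices(growth, event.year, window_m)
                    dbh_i = dbh_at_year(s, event.year)
                except ValueError as exc:
                    skipped.append((s.tree_id, metric, str(exc)))
                    continue
                rows.append({
                    "tree_id": s.tree_id, "site": site, "species": s.species,
                    "genus": s.genus, "group": s.group, "status": s.status,
                    "metric": metric, "window_m": window_m,
                    "event_year": event.year,
                    "resistance": idx.resistance, "recovery": idx.recovery,
                    "resilience": idx.resilience,
                    "dbh_i": dbh_i,
                    "delta_time": s.last_year - event.year,
                    "aridity": aridity.get(site, np.nan),
                    "soil_pc1": soil_pc1.get(site, np.nan),
                    **cov,
                })
    records = pd.DataFrame(rows)
    return records, skipped


def growth_pattern_bootstrap(dataset, events, half_window=8, window_m=4,
                             n_boot=1000, seed=0, min_trees=5):
    """Mean log-ratio growth trajectories around the event, with bootstrap CIs.

    For every tree with coverage of [event - window_m, event + half_window],
    the trajectory is log(TRW(t) / PreDr) on relative years
    t = -window_m..half_window.  Per (group, status) stratum, trees are
    resampled with replacement ``n_boot`` times and the 2.5/97.5
    percentile envelope of the stratum mean is reported.  Strata with
    fewer than ``min_trees`` trees are skipped with a warning.
    """
    rng = np.random.default_rng(seed)
    rel_years = np.arange(-window_m, half_window + 1)
    strata = {}
    for site, event in events.items():
        if event is None:
            continue
        for s in dataset.site_series(site):
            growth = s.to_series()
            need = event.year + rel_years
            vals = growth.reindex(need)
            if vals.isna().any() or (vals <= 0).any():
                continue
            pre = vals.loc[event.year - window_m:event.year - 1].mean()
            traj = np.log(vals.to_numpy() / pre)
            strata.setdefault((s.group, s.status), []).append(traj)
    rows = []
    for (group, status), trajs in sorted(strata.items()):
        trajs = np.asarray(trajs)
        n = trajs.shape[0]
        if n < min_trees:
            warnings.warn(f"stratum ({group}, {status}): only {n} trees; "
                          "skipped", stacklevel=2)
            continue
        boot = np.empty((n_boot, rel_years.size))
        for b in range(n_boot):
            take = rng.integers(0, n, n)
            boot[b] = trajs[take].mean(axis=0)
        lo, hi = np.percentile(boot, [2.5, 97.5], axis=0)
        mean = trajs.mean(axis=0)
        for j, t in enumerate(rel_years):
            rows.append({"group": group, "status": status, "rel_year": int(t),
                         "mean_log_ratio": mean[j], "ci_lo": lo[j],
                         "ci_hi": hi[j], "n_trees": n})
    return pd.DataFrame(rows)
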