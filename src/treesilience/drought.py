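"""Per-site SPEI window selection and extreme-drought-event detection.

Each site's residual chronology is regressed on every candidate SPEI
window (5 target months x 24 scales = 120 ordinary least-squares fits
over a fixed common period) and the window with the lowest AIC is
carried forward.  The single extreme drought event per site is then the
most extreme year (minimum SPEI) inside the eligibility window that
satisfies both filters: SPEI below the site's 10th percentile, and a
site-mean TRW reduction of more than 5% relative to the previous 4-year
average in the same year or the year after.  Sites with no qualifying
year yield no event and are excluded downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spei import target_months, SCALES

__all__ = ["WindowSelection", "DroughtEvent", "candidate_windows",
           "select_window", "site_event_search_window", "detect_event",
           "site_mean_trw", "COMMON_PERIOD"]

COMMON_PERIOD = (1931, 1980)
SPEI_PERCENTILE = 10.0
GROWTH_DROP_THRESHOLD = 0.05
LOOKBACK = 4


@dataclass
class WindowSelection:
    site_id: str
    best: tuple                    # (target_month, scale)
    table: pd.DataFrame            # 120 rows: target_month, scale, slope, r2, aic


@dataclass
class DroughtEvent:
    site_id: str
    year: int
    spei_i: float                  # SPEI at the best window in the event year
    spei_threshold: float          # site-specific 10th percentile
    growth_drop: float             # fractional TRW reduction at drop_year_lag
    drop_year_lag: int             # 0 = same year, 1 = year after
    search_window: tuple           # (first_allowed, last_allowed)


def candidate_windows(hemisphere="N"):
    """All 120 (target_month, scale) candidates, in tie-break order.

    Ordered by (scale ascending, target month in seasonal order) so that
    index order resolves AIC ties toward shorter scales and earlier
    months.
    """
    months = target_months(hemisphere)
    return [(m, k) for k in SCALES for m in months]


def _gaussian_aic(rss, n, k_params):
    # Gaussian maximum-likelihood AIC; k_params counts the error variance
    return n * np.log(2 * np.pi * rss / n) + n + 2 * k_params


def select_window(chronology, spei_grid, common_period=COMMON_PERIOD,
                  min_overlap=20):
    """Select the SPEI window that best explains the residual chronology.

    Ordinary least-squares fits (Gaussian errors, identity link) of the
    chronology on each candidate window's SPEI over the common period;
    minimum AIC wins, ties broken toward smaller scale then earlier
    target month.
    """
    chron = chronology.to_series()
    lo, hi = common_period
    chron = chron[(chron.index >= lo) & (chron.index <= hi)]
    rows = []
    best = None
    for pos, (m, k) in enumerate(candidate_windows(spei_grid.hemisphere)):
        s = spei_grid[(m, k)]
        s = s[(s.index >= lo) & (s.index <= hi)]
        joined = pd.concat([chron, s], axis=1, join="inner").dropna()
        n = len(joined)
        if n < min_overlap:
            warnings.warn(f"window ({m},{k}): only {n} overlapping years; "
                          "dropped", stacklevel=2)
            rows.append((m, k, np.nan, np.nan, np.nan))
            continue
        y = joined.iloc[:, 0].to_numpy()
        x = joined.iloc[:, 1].to_numpy()
        X = np.column_stack([np.ones(n), x])
        coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        rss = float(resid @ resid)
        tss = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - rss / tss if tss > 0 else 0.0
        aic = _gaussian_aic(max(rss, 1e-300), n, 3)
        rows.append((m, k, float(coef[1]), r2, aic))
        if best is None or aic < best[0] - 1e-12:
            best = (aic, pos, (m, k))
    table = pd.DataFrame(rows, columns=["target_month", "scale", "slope",
                                        "r2", "aic"])
    if best is None:
        raise ValueError(f"site {chronology.site_id}: no candidate window has "
                         f">= {min_overlap} overlapping years")
    return WindowSelection(site_id=chronology.site_id, best=best[2], table=table)


def site_event_search_window(death_years):
    """Eligibility window for the drought-event search at a site.

    Now-dead trees that died more than 50 years before the site's last
    death are excluded; the search window then spans 10 to 40 years
    before the first retained death.
    """
    death_years = sorted(int(d) for d in death_years)
    if not death_years:
        raise ValueError("site has no death years; not eligible")
    last = death_years[-1]
    retained = [d for d in death_years if d >= last - 50]
    first = min(retained)
    return first - 40, first - 10, retained


def site_mean_trw(series_list):
    """Per-year mean TRW across all trees (both statuses) with data."""
    frame = pd.concat([s.to_series() for s in series_list], axis=1).sort_index()
    return frame.mean(axis=1)


def detect_event(mean_trw, spei_series, search_window,
                 percentile=SPEI_PERCENTILE,
                 drop_threshold=GROWTH_DROP_THRESHOLD, site_id=""):
    """Detect the single extreme drought event of a site, or None.

    Among years in ``search_window`` with SPEI below the site's
    ``percentile``-th percentile (computed over the full SPEI record at
    the selected window, linear interpolation between order statistics)
    and a site-mean TRW drop of more than ``drop_threshold`` relative to
    the preceding 4-year mean in the same year or the year after, the
    year with the minimum SPEI is returned.
    """
    spei = spei_series.dropna()
    threshold = float(np.percentile(spei.to_numpy(), percentile))
    lo, hi = int(search_window[0]), int(search_window[1])
    candidates = []
    for year in range(lo, hi + 1):
        if year not in spei.index or spei.loc[year] >= threshold:
            continue
        qualifying = None
        for lag in (0, 1):
            t = year + lag
            window = [t - j for j in range(1, LOOKBACK + 1)]
            if t not in mean_trw.index or any(w not in mean_trw.index
                                              for w in window):
                continue
            ref = float(mean_trw.loc[window].mean())
            if ref <= 0 or not np.isfinite(ref):
                continue
            drop = 1.0 - float(mean_trw.loc[t]) / ref
            if drop > drop_threshold:
                qualifying = (lag, drop)
                break
        if qualifying is not None:
            candidates.append((float(spei.loc[year]), year, qualifying))
    if not candidates:
        return None
    spei_i, year, (lag, drop) = min(candidates, key=lambda c: c[0])
    return DroughtEvent(site_id=site_id, year=year, spei_i=spei_i,
                        spei_threshold=threshold, growth_drop=drop,
                        drop_year_lag=lag, search_window=(lo, hi))
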