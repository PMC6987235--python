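"""Standardised Precipitation-Evapotranspiration Index (SPEI) and aridity.

The SPEI is a multiscale drought index.  For a time scale of *k* months
the monthly climatic water balance D = precipitation - PET is accumulated
over the *k* months ending in a target month, a three-parameter
log-logistic distribution is fitted to the accumulated values of a
calibration period by unbiased probability-weighted moments (PWM), and
each value is mapped through the fitted CDF and the standard-normal
quantile function.  Negative SPEI values indicate relatively dry
conditions, positive values relatively wet ones.

Site-level SPEI grids cover 24 scales (1-24 months) ending in five target
months of summer and early autumn: June-October in the Northern
Hemisphere and, shifted by half a year, December (of the previous
calendar year) to April in the Southern Hemisphere.  Southern windows
that cross the calendar year are assigned to the ring-growth year
containing the later months of the window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gamma as _gamma
from scipy.stats import fisk, norm

__all__ = [
    "SpeiGrid",
    "SiteClimateSummary",
    "target_months",
    "water_balance",
    "aggregate",
    "fit_loglogistic_pwm",
    "standardize_loglogistic",
    "spei_grid",
    "aridity_index",
]

SCALES = tuple(range(1, 25))

#: target months per hemisphere; in the south, month 12 refers to December
#: of the calendar year preceding the labelled ring-growth year.
_TARGET_MONTHS = {"N": (6, 7, 8, 9, 10), "S": (12, 1, 2, 3, 4)}


def target_months(hemisphere):
    """Five summer / early-autumn target months for a hemisphere."""
    try:
        return _TARGET_MONTHS[hemisphere]
    except KeyError:
        raise ValueError(f"hemisphere must be 'N' or 'S', got {hemisphere!r}") from None


@dataclass
class SpeiGrid:
    """Per-site SPEI series keyed by (target_month, scale)."""

    site_id: str
    entries: dict                  # (month, scale) -> pd.Series indexed by year
    calibration_span: tuple        # (first_year, last_year) used for fitting
    hemisphere: str = "N"

    def __getitem__(self, key):
        return self.entries[key]

    def to_frame(self) -> pd.DataFrame:
        """Long format: site, year, target_month, scale, spei."""
        rows = []
        for (m, k), s in self.entries.items():
            rows.append(pd.DataFrame({
                "site": self.site_id, "year": s.index,
                "target_month": m, "scale": k, "spei": s.values,
            }))
        return pd.concat(rows, ignore_index=True)


@dataclass
class SiteClimateSummary:
    site_id: str
    aridity: float   # mean annual P / mean annual PET; higher = wetter


def water_balance(prcp, pet):
    """Monthly climatic water balance D = precipitation - PET (mm)."""
    prcp = np.asarray(prcp, dtype=float)
    pet = np.asarray(pet, dtype=float)
    if prcp.shape != pet.shape:
        raise ValueError("precipitation and PET series differ in length")
    return prcp - pet


def aggregate(d, years, scale_k, target_month, hemisphere="N"):
    """Accumulate the water balance over ``scale_k`` months ending in a target month.

    Parameters
    ----------
    d : array, length 12 * len(years)
        Monthly water balance starting in January of ``years[0]``.
    years : sequence of consecutive calendar years.
    scale_k : int in 1..24
    target_month : int in 1..12; for hemisphere "S", month 12 means
        December of the calendar year before the labelled year.

    Returns
    -------
    pd.Series
        Accumulated balance indexed by (ring-growth) year.  Years whose
        window reaches before the record start are absent, not zero.
    """
    if not 1 <= scale_k <= 24:
        raise ValueError(f"scale must be in 1..24, got {scale_k}")
    if not 1 <= target_month <= 12:
        raise ValueError(f"target_month must be in 1..12, got {target_month}")
    d = np.asarray(d, dtype=float)
    years = np.asarray(years, dtype=int)
    if d.size != 12 * years.size:
        raise ValueError("water balance length must be 12 * number of years")
    csum = np.concatenate([[0.0], np.cumsum(d)])
    out_years, out_vals = [], []
    for i, y in enumerate(years):
        cal_year_offset = -1 if (hemisphere == "S" and target_month == 12) else 0
        end = (i + cal_year_offset) * 12 + target_month   # 1-based month count
        start = end - scale_k
        if start < 0 or end > d.size:
            continue
        out_years.append(y)
        out_vals.append(csum[end] - csum[start])
    return pd.Series(out_vals, index=pd.Index(out_years, name="year"), name="D")


def _unbiased_pwm(x):
    """First three unbiased probability-weighted moments b0, b1, b2."""
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    j = np.arange(1, n + 1)
    b0 = x.mean()
    b1 = np.sum((j - 1) / (n - 1) * x) / n
    b2 = np.sum((j - 1) * (j - 2) / ((n - 1) * (n - 2)) * x) / n
    return b0, b1, b2


def fit_loglogistic_pwm(x):
    """Fit a 3-parameter log-logistic distribution by unbiased PWMs.

    Returns ``(shape, scale, loc)`` matching ``scipy.stats.fisk(c=shape,
    scale=scale, loc=loc)``.  Raises ``ValueError`` when the moment
    estimates do not define a valid distribution covering the data
    (shape <= 1 or an observation at or below the location bound).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 values for a PWM fit")
    b0, b1, b2 = _unbiased_pwm(x)
    # the SPEI convention writes the estimators in terms of the
    # (1-F)-weighted moments w_s: w0 = b0, w1 = b0 - b1, w2 = b0 - 2 b1 + b2,
    # with beta = (2 w1 - w0)/(6 w1 - w0 - 6 w2)
    denom = 6.0 * b1 - b0 - 6.0 * b2
    if denom == 0:
        raise ValueError("degenerate PWMs")
    beta = (b0 - 2.0 * b1) / denom
    if not np.isfinite(beta) or beta <= 1.0:
        raise ValueError(f"invalid log-logistic shape {beta}")
    g = _gamma(1.0 + 1.0 / beta) * _gamma(1.0 - 1.0 / beta)
    alpha = (2.0 * b1 - b0) * beta / g
    if not np.isfinite(alpha) or alpha <= 0:
        raise ValueError(f"invalid log-logistic scale {alpha}")
    gamma_loc = b0 - alpha * g
    if np.any(x <= gamma_loc):
        raise ValueError("observations at or below the fitted location bound")
    return beta, alpha, gamma_loc


def standardize_loglogistic(agg_series, calibration_span=None):
    """Map accumulated balances to SPEI values.

    A log-logistic distribution is fitted to the calibration-period
    values; every value is mapped through the fitted CDF and then the
    standard-normal quantile function.  When the PWM fit fails, the
    function falls back to empirical-quantile standardisation (Weibull
    plotting positions of the calibration sample) with a warning; the
    fallback preserves the ordering of the log-logistic map.
    """
    s = agg_series if isinstance(agg_series, pd.Series) else pd.Series(agg_series)
    if calibration_span is None:
        calib = s
    else:
        lo, hi = calibration_span
        calib = s[(s.index >= lo) & (s.index <= hi)]
    vals = calib.to_numpy(dtype=float)
    if vals.size < 30:
        raise ValueError(f"need >= 30 calibration values, got {vals.size}")
    if np.ptp(vals) == 0:
        raise ValueError("constant accumulated balance; SPEI undefined")
    eps = 1e-8
    try:
        shape, scale, loc = fit_loglogistic_pwm(vals)
        cdf = fisk.cdf(s.to_numpy(dtype=float), shape, loc=loc, scale=scale)
    except ValueError as exc:
        warnings.warn(
            f"log-logistic PWM fit failed ({exc}); falling back to "
            "empirical-quantile standardisation", stacklevel=2)
        order = np.sort(vals)
        ranks = np.searchsorted(order, s.to_numpy(dtype=float), side="right")
        cdf = ranks / (vals.size + 1.0)
    spei = norm.ppf(np.clip(cdf, eps, 1 - eps))
    return pd.Series(spei, index=s.index, name="spei")


def spei_grid(climate, hemisphere="N", calibration_span=None, site_id=""):
    """Compute the full 5 x 24 SPEI grid for one site.

    Parameters
    ----------
    climate : DataFrame with columns year, month, prcp_mm, pet_mm
        Complete monthly coverage of the span (every month of every year).
    hemisphere : {"N", "S"}
    calibration_span : (first, last) years or None for the full record.
    """
    clim = climate.sort_values(["year", "month"]).reset_index(drop=True)
    years = np.sort(clim["year"].unique())
    expected = pd.MultiIndex.from_product([years, range(1, 13)])
    got = pd.MultiIndex.from_frame(clim[["year", "month"]])
    missing = expected.difference(got)
    if len(missing):
        raise ValueError(f"missing climate months: {list(missing[:6])}")
    d = water_balance(clim["prcp_mm"].to_numpy(), clim["pet_mm"].to_numpy())
    entries = {}
    for m in target_months(hemisphere):
        for k in SCALES:
            agg = aggregate(d, years, k, m, hemisphere)
            entries[(m, k)] = standardize_loglogistic(agg, calibration_span)
    span = calibration_span or (int(years[0]), int(years[-1]))
    return SpeiGrid(site_id=site_id, entries=entries,
                    calibration_span=tuple(span), hemisphere=hemisphere)


def aridity_index(climate, span=(1970, 2000), site_id=""):
    """Ratio of mean annual precipitation to mean annual PET over a span.

    Values above 1 indicate humid conditions, below 1 increasingly arid
    ones.  The reference span mirrors the 1970-2000 period of global
    aridity climatologies.
    """
    sub = climate[(climate["year"] >= span[0]) & (climate["year"] <= span[1])]
    if sub.empty:
        raise ValueError(f"no climate data in span {span}")
    annual = sub.groupby("year")[["prcp_mm", "pet_mm"]].sum()
    pet = annual["pet_mm"].mean()
    if pet <= 0:
        raise ValueError("mean annual PET must be positive")
    return SiteClimateSummary(site_id=site_id,
                              aridity=float(annual["prcp_mm"].mean() / pet))
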