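"""Standardisation of ring-width series and site residual chronologies.

Each tree's TRW series is detrended with a cubic smoothing spline whose
frequency response is 0.50 at a wavelength of 67% of the series length
(the classic flexible-spline standard in dendrochronology), the ratio
indices are prewhitened with an AIC-selected autoregressive model, the
residuals are rescaled to mean one, and the per-site residual chronology
is the Tukey biweight robust mean of the individual indices in each year.
This keeps the high-frequency climate signal while removing low-frequency
age/size trends and serial autocorrelation before the SPEI window search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from statsmodels.tsa.ar_model import AutoReg

from .exceptions import SeriesTooShortError

__all__ = [
    "SiteChronology",
    "spline_smoothing_parameter",
    "spline_detrend",
    "ar_prewhiten",
    "scale_to_mean_one",
    "biweight_mean",
    "build_chronology",
]

MIN_SERIES_LENGTH = 15


@dataclass
class SiteChronology:
    """Site-level residual chronology (dimensionless, mean near one)."""

    site_id: str
    years: np.ndarray
    index: np.ndarray
    sample_depth: np.ndarray

    def to_series(self) -> pd.Series:
        return pd.Series(self.index, index=self.years, name=self.site_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"site": self.site_id, "year": self.years,
                             "index": self.index,
                             "sample_depth": self.sample_depth})


def spline_smoothing_parameter(wavelength, frequency_response=0.5):
    """Smoothing parameter lambda with a given frequency response.

    Uses the Cook-Peters relation between the stiffness of a cubic
    smoothing spline (penalised residual sum of squares with penalty
    ``lam * int s''(x)^2 dx`` on unit-spaced data) and the wavelength at
    which its transfer function equals ``frequency_response``:

        lam = ((1 - f) / f) * (cos w + 2) / (12 * (1 - cos w)^2),  w = 2*pi/wavelength

    The constant follows from the spectral form of the natural cubic
    spline penalty on unit-spaced data, ``12 (1 - cos w)^2 / (2 + cos w)``,
    which reduces to the familiar ``w^4`` low-pass behaviour for long
    wavelengths.
    """
    if wavelength <= 2:
        raise ValueError("wavelength must exceed 2 samples")
    f = frequency_response
    if not 0 < f < 1:
        raise ValueError("frequency_response must lie in (0, 1)")
    w = 2.0 * np.pi / wavelength
    return (1.0 - f) / f * (np.cos(w) + 2.0) / (12.0 * (1.0 - np.cos(w)) ** 2)


def spline_detrend(trw, wavelength_fraction=0.67, frequency_response=0.5):
    """Detrend a TRW series with the standard flexible smoothing spline.

    Returns ``(fitted_curve, ratio_indices)`` where the indices are
    ``trw / fitted``.  If the spline produces a non-positive fitted value
    the function falls back to a horizontal-mean detrend with a warning,
    so the ratio indices stay well defined.
    """
    y = np.asarray(trw, dtype=float)
    n = y.size
    if n < MIN_SERIES_LENGTH:
        raise SeriesTooShortError(
            f"need >= {MIN_SERIES_LENGTH} years for spline detrending, got {n}")
    if np.any(~np.isfinite(y)) or np.any(y <= 0):
        raise ValueError("TRW must be finite and positive for detrending")
    lam = spline_smoothing_parameter(wavelength_fraction * n, frequency_response)
    x = np.arange(n, dtype=float)
    fitted = make_smoothing_spline(x, y, lam=lam)(x)
    if np.any(fitted <= 0):
        warnings.warn("spline fit non-positive; falling back to horizontal-mean "
                      "detrend", stacklevel=2)
        fitted = np.full(n, y.mean())
    return fitted, y / fitted


def ar_prewhiten(indices, max_order=None):
    """Remove serial autocorrelation with an AIC-selected AR model.

    The AR order is chosen by AIC among 0..min(10, n // 4) (conditional
    maximum likelihood with an intercept).  The model residuals are
    re-centred on the mean of the input before any further scaling, so a
    white-noise input passes through essentially unchanged.

    Returns ``(residual_series, order, coefficients)``; the first
    ``order`` values of the input have no residual and are dropped.
    """
    x = np.asarray(indices, dtype=float)
    n = x.size
    if n < MIN_SERIES_LENGTH:
        raise SeriesTooShortError(f"need >= {MIN_SERIES_LENGTH} observations")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance input; AR model undefined")
    if max_order is None:
        max_order = min(10, n // 4)
    best = (np.inf, 0, None)
    for p in range(max_order + 1):
        # common sample across candidate orders so AICs are comparable
        res = AutoReg(x, lags=p, trend="c", hold_back=max_order).fit()
        if res.aic < best[0]:
            best = (res.aic, p, res)
    _, order, res = best
    if order == 0:
        resid = x - x.mean()
        coeffs = np.array([])
        resid_full = resid
    else:
        fit = AutoReg(x, lags=order, trend="c").fit()
        coeffs = fit.params[1:]
        resid_full = fit.resid            # length n - order
    out = resid_full + x.mean()
    return out, order, np.asarray(coeffs)


def scale_to_mean_one(values):
    """Divide by the mean so the output mean is exactly one."""
    x = np.asarray(values, dtype=float)
    m = x.mean()
    if not np.isfinite(m) or m <= 0:
        raise ValueError(f"mean must be positive to standardise, got {m}")
    return x / m


def biweight_mean(values, tuning_c=9.0, tol=1e-10, max_iter=50):
    """Tukey biweight robust mean (bounded-influence location estimate).

    Iterates the weighted mean with weights ``(1 - u^2)^2`` for
    ``|u| < 1``, ``u = (x - M) / (c * MAD)``, starting from the median,
    until the update is below ``tol``.  Falls back to the median when the
    MAD is zero (e.g. all values identical).
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("biweight mean of an empty set")
    if x.size == 1:
        return float(x[0])
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return float(med)
    m = med
    for _ in range(max_iter):
        u = (x - m) / (tuning_c * mad)
        w = np.where(np.abs(u) < 1, (1 - u ** 2) ** 2, 0.0)
        if w.sum() == 0:
            return float(med)
        m_new = float(np.sum(w * x) / w.sum())
        if abs(m_new - m) < tol:
            return m_new
        m = m_new
    return m


def standardize_series(ring_series):
    """Detrend, prewhiten and rescale one tree's TRW to residual indices.

    Returns a pd.Series of mean-one residual indices aligned on calendar
    years (the first AR-order years are dropped).
    """
    trw = ring_series.trw
    years = ring_series.years
    ok = np.isfinite(trw)
    trw, years = trw[ok], years[ok]
    _, ratio = spline_detrend(trw)
    resid, order, _ = ar_prewhiten(ratio)
    idx = scale_to_mean_one(resid)
    return pd.Series(idx, index=years[order:], name=ring_series.tree_id)


def build_chronology(series_list, site_id=""):
    """Build the site residual chronology from a set of RingSeries.

    Trees too short for detrending are skipped with a warning; the
    chronology is the per-year Tukey biweight mean of the usable trees'
    residual indices.  Both now-dead and surviving trees contribute.
    """
    indexed = []
    for s in series_list:
        try:
            indexed.append(standardize_series(s))
        except SeriesTooShortError as exc:
            warnings.warn(f"{s.tree_id}: {exc}; skipped", stacklevel=2)
    if not indexed:
        raise ValueError(f"site {site_id}: no series usable for a chronology")
    frame = pd.concat(indexed, axis=1)
    frame = frame.sort_index()
    years = frame.index.to_numpy()
    depth = frame.notna().sum(axis=1).to_numpy()
    keep = depth >= 1
    chron = np.array([biweight_mean(row[np.isfinite(row)])
                      for row in frame.to_numpy()[keep]])
    return SiteChronology(site_id=site_id, years=years[keep], index=chron,
                          sample_depth=depth[keep])
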