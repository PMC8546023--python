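"""Exponent fitting and cross-observable consistency checks.

Spectra and MSD curves are power laws over broad bands; exponents are
extracted by ordinary least squares on log-log axes, with spectra log-binned
first (periodogram scatter is multiplicative and heteroscedastic).  The
spectral exponent beta is fitted as a common slope across measurement times
(pooled regression with one intercept per t_m), after which the aging
exponent z comes from the amplitude-vs-t_m regression; the EA-TA-MSD lag and
aging exponents are fitted the same way.  Uncertainties are OLS slope
standard errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .estimate import (MsdEstimate, Spectrum, default_fit_band, log_bin,
                       psd_amplitude)
from .theory import InvertedExponents, exponents_invert

__all__ = [
    "ExponentFit",
    "FlatSpectrumError",
    "fit_power_law",
    "estimate_beta_z",
    "estimate_msd_exponents",
    "consistency_check",
    "noise_floor_band",
]


@dataclass
class ExponentFit:
    """A fitted log-log slope with its standard error and fit window."""

    exponent: float
    stderr: float
    intercept: float
    band: tuple[float, float]
    n_points: int


class FlatSpectrumError(ValueError):
    """No power-law (sloped) region found in the spectrum."""


def fit_power_law(x, y, band: tuple[float, float] | None = None,
                  weights=None) -> ExponentFit:
    """OLS fit of ``log y = intercept + exponent * log x`` over a band."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if band is not None:
        keep = (x >= band[0]) & (x <= band[1])
        x, y = x[keep], y[keep]
        if weights is not None:
            weights = np.asarray(weights, dtype=float)[keep]
    if x.size < 3:
        raise ValueError("need at least 3 points in the fit band")
    if np.any(y <= 0) or np.any(x <= 0):
        raise ValueError("power-law fit requires positive values")
    lx, ly = np.log(x), np.log(y)
    if weights is None:
        res = stats.linregress(lx, ly)
        slope, intercept, stderr = res.slope, res.intercept, res.stderr
    else:
        w = np.asarray(weights, dtype=float)
        wx = np.average(lx, weights=w)
        wy = np.average(ly, weights=w)
        sxx = np.sum(w * (lx - wx) ** 2)
        slope = float(np.sum(w * (lx - wx) * (ly - wy)) / sxx)
        intercept = float(wy - slope * wx)
        resid = ly - intercept - slope * lx
        dof = max(1, x.size - 2)
        s2 = float(np.sum(w * resid**2) / dof)
        stderr = math.sqrt(s2 / sxx)
    return ExponentFit(exponent=float(slope), stderr=float(stderr),
                       intercept=float(intercept),
                       band=(float(x.min()), float(x.max())),
                       n_points=int(x.size))


def _pooled_common_slope(groups: list[tuple[np.ndarray, np.ndarray]]):
    """OLS with one shared slope and a free intercept per group.

    Returns (slope, slope_se, intercepts).  Equivalent to regressing the
    within-group-centered data, with the correct residual dof.
    """
    n_groups = len(groups)
    xs = [np.log(g[0]) for g in groups]
    ys = [np.log(g[1]) for g in groups]
    sxx = syx = 0.0
    n_total = 0
    for lx, ly in zip(xs, ys):
        cx = lx - lx.mean()
        cy = ly - ly.mean()
        sxx += float(np.sum(cx * cx))
        syx += float(np.sum(cx * cy))
        n_total += lx.size
    if sxx <= 0:
        raise ValueError("degenerate abscissa in pooled fit")
    slope = syx / sxx
    rss = 0.0
    intercepts = []
    for lx, ly in zip(xs, ys):
        b = float(ly.mean() - slope * lx.mean())
        intercepts.append(b)
        rss += float(np.sum((ly - b - slope * lx) ** 2))
    dof = max(1, n_total - n_groups - 1)
    slope_se = math.sqrt(rss / dof / sxx)
    return slope, slope_se, np.array(intercepts)


def estimate_beta_z(spectra: list[Spectrum], band_policy="default",
                    bins_per_decade: int = 16,
                    ) -> tuple[ExponentFit, ExponentFit]:
    """Fit ``<S> ~ omega^-beta t_m^z`` from spectra at several t_m.

    beta is a common slope across the log-binned spectra; z is then the
    log-log slope of the amplitudes ``A(t_m)`` obtained at the fitted beta
    (``psd_amplitude``) against t_m.
    """
    if len(spectra) < 3:
        raise ValueError("need spectra at >= 3 distinct measurement times")
    tms = np.array([sp.t_m for sp in spectra])
    if np.unique(tms).size != tms.size:
        raise ValueError("measurement times must be distinct")
    bands = [_resolve_band(sp, band_policy) for sp in spectra]
    groups = []
    for sp, band in zip(spectra, bands):
        keep = (sp.omegas >= band[0]) & (sp.omegas <= band[1])
        if keep.sum() < 3:
            raise ValueError(f"band {band} leaves < 3 bins at t_m={sp.t_m}")
        bw, bv = log_bin(sp.omegas[keep], sp.values[keep],
                         bins_per_decade=bins_per_decade)
        groups.append((bw, bv))
    slope, slope_se, _ = _pooled_common_slope(groups)
    beta_fit = ExponentFit(
        exponent=-slope, stderr=slope_se, intercept=np.nan,
        band=(float(min(b[0] for b in bands)), float(max(b[1] for b in bands))),
        n_points=int(sum(g[0].size for g in groups)))
    amps = []
    amp_ses = []
    for sp, band in zip(spectra, bands):
        keep = (sp.omegas >= band[0]) & (sp.omegas <= band[1]) & (sp.values > 0)
        la = np.log(sp.values[keep]) - slope * np.log(sp.omegas[keep])
        amps.append(float(np.exp(la.mean())))
        # periodogram bins are near-independent across frequencies, so the
        # scatter of the compensated bins gives the amplitude uncertainty
        amp_ses.append(float(la.std(ddof=1) / math.sqrt(la.size)))
    z_fit = _weighted_slope_fit(np.log(tms), np.log(amps), np.array(amp_ses))
    z_fit = ExponentFit(exponent=z_fit[0], stderr=z_fit[1],
                        intercept=z_fit[2],
                        band=(float(tms.min()), float(tms.max())),
                        n_points=int(tms.size))
    return beta_fit, z_fit


def _weighted_slope_fit(x: np.ndarray, y: np.ndarray,
                        y_se: np.ndarray) -> tuple[float, float, float]:
    """GLS slope with known per-point errors; the slope stderr is propagated
    from ``y_se`` (not residual-based, which is unstable at few points)."""
    y_se = np.maximum(np.asarray(y_se, float), 1e-12)
    w = 1.0 / y_se**2
    xbar = np.average(x, weights=w)
    ybar = np.average(y, weights=w)
    sxx = float(np.sum(w * (x - xbar) ** 2))
    slope = float(np.sum(w * (x - xbar) * (y - ybar)) / sxx)
    intercept = float(ybar - slope * xbar)
    return slope, math.sqrt(1.0 / sxx), intercept


def _resolve_band(spec: Spectrum, band_policy) -> tuple[float, float]:
    if band_policy == "default":
        return default_fit_band(spec)
    if band_policy == "noise-aware":
        lo, hi = default_fit_band(spec)
        try:
            nlo, nhi = noise_floor_band(spec)
        except FlatSpectrumError:
            raise
        return (max(lo, nlo), min(hi, nhi))
    if callable(band_policy):
        return band_policy(spec)
    lo, hi = band_policy
    return (float(lo), float(hi))


def estimate_msd_exponents(ea_ta_msds: list[MsdEstimate],
                           max_lag_fraction: float = 0.25,
                           amplitude_se=None,
                           ) -> tuple[ExponentFit, ExponentFit]:
    """Fit ``<delta^2> ~ tau^(1-alpha+2aH) / t_m^(1-alpha)`` from EA-TA-MSD
    curves at several measurement times.

    The lag exponent is a pooled common slope over lags (restricted to
    ``tau <= max_lag_fraction * t_m`` where the scaling form holds); the
    aging exponent is the slope of the per-t_m amplitudes against t_m.
    ``amplitude_se`` optionally carries known per-curve standard errors of
    the log amplitude (e.g. from between-trajectory scatter, which residuals
    over strongly correlated lags cannot measure); when given, the aging fit
    and its stderr use them.
    """
    if len(ea_ta_msds) < 2:
        raise ValueError("need EA-TA-MSD curves at >= 2 measurement times")
    tms = np.array([m.t_m for m in ea_ta_msds])
    groups = []
    for m in ea_ta_msds:
        keep = ((m.abscissa > 0) & (m.values > 0)
                & (m.abscissa <= max_lag_fraction * m.t_m))
        if keep.sum() < 3:
            raise ValueError("insufficient positive lags in an MSD curve")
        groups.append((m.abscissa[keep], m.values[keep]))
    slope, slope_se, intercepts = _pooled_common_slope(groups)
    lag_fit = ExponentFit(
        exponent=float(slope), stderr=slope_se, intercept=np.nan,
        band=(float(min(g[0].min() for g in groups)),
              float(max(g[0].max() for g in groups))),
        n_points=int(sum(g[0].size for g in groups)))
    if amplitude_se is not None:
        slope_a, se_a, int_a = _weighted_slope_fit(
            np.log(tms), intercepts, np.asarray(amplitude_se, float))
    else:
        res = stats.linregress(np.log(tms), intercepts)
        slope_a, se_a, int_a = (float(res.slope), float(res.stderr),
                                float(res.intercept))
    aging_fit = ExponentFit(exponent=slope_a, stderr=se_a, intercept=int_a,
                            band=(float(tms.min()), float(tms.max())),
                            n_points=int(tms.size))
    return lag_fit, aging_fit


def consistency_check(psd_alpha_h: InvertedExponents,
                      msd_alpha_h: InvertedExponents,
                      n_sigma: float = 2.0) -> dict:
    """Cross-observable agreement of (alpha, H): PSD route vs MSD route.

    Two estimates agree when their ``+- n_sigma`` stderr intervals overlap;
    the report carries per-exponent verdicts and a combined pass/fail.
    """
    report: dict = {"n_sigma": n_sigma}
    verdicts = []
    for name in ("alpha", "hurst"):
        v1 = getattr(psd_alpha_h, name)
        v2 = getattr(msd_alpha_h, name)
        s1 = getattr(psd_alpha_h, f"{name}_se") or 0.0
        s2 = getattr(msd_alpha_h, f"{name}_se") or 0.0
        gap = abs(v1 - v2)
        agree = gap <= n_sigma * (s1 + s2)
        verdicts.append(agree)
        report[name] = {"psd": v1, "msd": v2, "psd_se": s1, "msd_se": s2,
                        "discrepancy": gap, "agree": agree}
    report["consistent"] = all(verdicts)
    return report


def noise_floor_band(spec: Spectrum, bins_per_decade: int = 16,
                     abs_slope_floor: float = 0.2,
                     rel_threshold: float = 0.7,
                     smooth: int = 3) -> tuple[float, float]:
    """Largest low-frequency band with a non-flat local log-log slope.

    Used to exclude the white localization-noise floor from beta fits.  The
    binned local slope is smoothed over ``smooth`` bins; the reference slope
    is the median over the first quarter of the band, and the band ends where
    the local slope magnitude falls below ``rel_threshold`` times the
    reference (never below ``abs_slope_floor``).  For an exact power law
    ``A omega^-beta`` plus a constant floor this cuts where the floor reaches
    about half the power-law signal.  A spectrum that is flat from the start
    raises :class:`FlatSpectrumError`.
    """
    if spec.omegas.size < 16:
        raise ValueError("need at least 16 spectral bins")
    bw, bv = log_bin(spec.omegas, spec.values, bins_per_decade=bins_per_decade)
    if bw.size < 6:
        raise ValueError("too few populated log-bins")
    slopes = np.diff(np.log(bv)) / np.diff(np.log(bw))
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        padded = np.concatenate([np.repeat(slopes[0], smooth // 2), slopes,
                                 np.repeat(slopes[-1], smooth // 2)])
        slopes = np.convolve(padded, kernel, mode="valid")
    n_ref = max(3, slopes.size // 4)
    ref = float(np.median(slopes[:n_ref]))
    if abs(ref) <= abs_slope_floor:
        raise FlatSpectrumError(
            f"reference slope {ref:.3f} is flat; no power-law region")
    threshold = max(abs_slope_floor, rel_threshold * abs(ref))
    flat = np.nonzero(np.abs(slopes) < threshold)[0]
    if flat.size == 0:
        return (float(spec.omegas.min()), float(spec.omegas.max()))
    cut = int(flat[0])
    if cut < 3:
        raise FlatSpectrumError("spectrum flattens immediately; no band")
    return (float(spec.omegas.min()), float(bw[cut]))
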