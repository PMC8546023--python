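"""End-to-end exponent extraction from a track table.

Mirrors the experimental workflow: window tracks at several observation
times, estimate aging spectra and EA-TA-MSD curves, fit (beta, z) and the
MSD lag/aging exponents, invert both routes to (alpha, H), and check that
the two independent measurements agree.

Localization noise handling: i.i.d. localization error of variance sigma^2
adds a white floor ``sigma^2 * dt`` to the periodogram and a constant offset
``2 sigma^2`` to the time-averaged MSD.  The pipeline estimates the floor
from the high-frequency end of the longest-observation spectrum, subtracts
both contributions, and restricts fits to bins where the physical signal
dominates the floor.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .estimate import Spectrum, default_fit_band, ea_ta_msd, ensemble_psd
from .infer import (FlatSpectrumError, consistency_check, estimate_beta_z,
                    estimate_msd_exponents, noise_floor_band)
from .theory import exponents_invert
from .tracks import TrackTable, window_tracks

__all__ = ["analyze_tracks", "estimate_noise_floor"]


def estimate_noise_floor(spec: Spectrum) -> float:
    """Estimate the white localization-noise floor of a spectrum.

    Fits the crossover model ``S(omega) = A omega^-b + F`` to the log-binned
    spectrum in log space (initialized from the low-frequency slope and the
    spectral minimum) and returns the fitted floor ``F`` in spectrum units;
    the localization variance is ``sigma^2 = F / dt``.
    """
    from scipy.optimize import curve_fit

    from .estimate import log_bin

    bw, bv = log_bin(spec.omegas, spec.values)
    third = max(3, bw.size // 3)
    slope0 = np.polyfit(np.log(bw[:third]), np.log(bv[:third]), 1)

    def model(lw, log_a, b, log_f):
        return np.log(np.exp(log_a) * np.exp(-b * lw) + np.exp(log_f))

    p0 = (slope0[1], -slope0[0], np.log(bv.min()))
    popt, _ = curve_fit(model, np.log(bw), np.log(bv), p0=p0, maxfev=20000)
    return float(np.exp(popt[2]))


def _tail_is_flat(spec: Spectrum, top_fraction: float = 0.25,
                  max_slope: float = 0.5) -> bool:
    """True when the top-frequency end of the spectrum is a white plateau."""
    n = spec.omegas.size
    start = int((1.0 - top_fraction) * n)
    lw = np.log(spec.omegas[start:])
    lv = np.log(spec.values[start:])
    slope = float(np.polyfit(lw, lv, 1)[0])
    return abs(slope) < max_slope


def _subtract_floor(spec: Spectrum, floor: float,
                    snr: float = 3.0) -> Spectrum:
    """Remove a white floor and keep only bins where signal > snr * floor."""
    corrected = spec.values - floor
    keep = spec.values > snr * floor
    return replace(spec, omegas=spec.omegas[keep], values=corrected[keep])


def analyze_tracks(table: TrackTable, tm_list=None, n_lags: int = 24,
                   noise_correction: bool = True) -> dict:
    """Run the full PSD + MSD exponent-extraction pipeline.

    Returns a report with the (beta, z) and MSD exponent fits, the inverted
    (alpha, H) from each route, and the two-route consistency verdict.
    """
    if tm_list is None:
        n_min = int(table.track_lengths().min())
        # nested prefix windows; each must keep >= 64 points so the default
        # spectral fit band (4 <= k <= N/8) retains enough bins
        cands = [(n_min - 1) // 4, (n_min - 1) // 2, n_min - 1]
        wins = [w for w in cands if w >= 63]
        if len(wins) < 3:
            wins = np.unique(np.round(np.geomspace(
                min(63, n_min - 1), n_min - 1, 3)).astype(int)).tolist()
        tm_list = [w * table.dt for w in wins]
    ensembles = window_tracks(table, tm_list)
    spectra = [ensemble_psd(ens) for ens in ensembles.values()]
    floor = 0.0
    if noise_correction:
        floor = estimate_noise_floor(spectra[-1])
        # only subtract when the high-frequency end is actually a plateau
        # (a sloped tail means the power law still dominates up to Nyquist)
        if _tail_is_flat(spectra[-1]):
            spectra = [_subtract_floor(sp, floor) for sp in spectra]
        else:
            floor = 0.0
    beta_fit, z_fit = estimate_beta_z(spectra, band_policy=_default_band)
    psd_inverted = exponents_invert(beta=beta_fit.exponent, z=z_fit.exponent,
                                    branch="I", beta_se=beta_fit.stderr,
                                    z_se=z_fit.stderr)
    msd_offset = 2.0 * floor / table.dt  # 2 sigma^2
    msds = []
    amp_ses = []
    for ens in ensembles.values():
        j_max = max(2, (ens.n_points - 1) // 4)
        lags = np.unique(np.round(np.geomspace(1, j_max, n_lags)).astype(int))
        msd = ea_ta_msd(ens, lags=lags * ens.dt)
        # amplitude uncertainty from between-trajectory scatter of the
        # TA-MSD (the lags of one curve are too correlated to use residuals)
        j_mid = int(lags[len(lags) // 2])
        d = ens.positions[:, j_mid:] - ens.positions[:, : ens.n_points - j_mid]
        per_traj = np.mean(d * d, axis=1)
        amp_ses.append(float(per_traj.std(ddof=1)
                             / (per_traj.mean() * np.sqrt(per_traj.size))))
        if msd_offset > 0.0:
            corrected = msd.values - msd_offset
            keep = msd.values > 2.0 * msd_offset
            msd = replace(msd, abscissa=msd.abscissa[keep],
                          values=corrected[keep])
        msds.append(msd)
    lag_fit, aging_fit = estimate_msd_exponents(msds, amplitude_se=amp_ses)
    msd_inverted = exponents_invert(
        branch="MSD", msd_lag_exp=lag_fit.exponent,
        msd_aging_exp=aging_fit.exponent, msd_lag_se=lag_fit.stderr,
        msd_aging_se=aging_fit.stderr)
    report = {
        "tm_list": [float(t) for t in ensembles],
        "noise_floor": floor,
        "beta": beta_fit, "z": z_fit,
        "msd_lag": lag_fit, "msd_aging": aging_fit,
        "psd_alpha_h": psd_inverted,
        "msd_alpha_h": msd_inverted,
        "consistency": consistency_check(psd_inverted, msd_inverted),
        "combined": _combine_routes(psd_inverted, msd_inverted),
    }
    return report


def _combine_routes(psd_inv, msd_inv) -> dict:
    """Inverse-variance weighted (alpha, H) across the PSD and MSD routes."""
    out = {}
    for name in ("alpha", "hurst"):
        vals = np.array([getattr(psd_inv, name), getattr(msd_inv, name)])
        ses = np.array([getattr(psd_inv, f"{name}_se") or np.nan,
                        getattr(msd_inv, f"{name}_se") or np.nan])
        if np.isnan(ses).any():
            out[name] = float(vals.mean())
            out[f"{name}_se"] = None
            continue
        w = 1.0 / ses**2
        out[name] = float(np.average(vals, weights=w))
        out[f"{name}_se"] = float(np.sqrt(1.0 / w.sum()))
    return out


def _default_band(spec):
    """Default fit band intersected with the detected noise-floor band."""
    lo, hi = default_fit_band(spec)
    try:
        _, floor_hi = noise_floor_band(spec)
    except (FlatSpectrumError, ValueError):
        return (lo, hi)
    return (lo, min(hi, floor_hi))
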