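"""Empirical observables: periodogram/PSD, autocorrelation, MSD estimators.

All estimators work on uniformly sampled trajectories.  The spectral
estimator is the plain periodogram at the discrete frequencies
``omega_k = 2 pi k / t_m`` (no windowing, no Welch averaging): the aging
Wiener-Khinchin theory addresses exactly this object.  Spectra can be
log-binned before fitting because periodogram scatter is multiplicative.

Normalization convention (stated bit-exactly so tests are unambiguous):

    S(omega_k, t_m) = (1/t_m) * | dt * sum_{n=0}^{N-1} x(n dt) e^{-i omega_k n dt} |^2

with ``N = t_m/dt`` samples (the final grid point is not part of the DFT
window) and ``k = 1 .. N//2``; the DC bin ``k = 0`` is excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import Ensemble, Trajectory

__all__ = [
    "Spectrum",
    "AcfEstimate",
    "MsdEstimate",
    "periodogram",
    "ensemble_psd",
    "psd_amplitude",
    "log_bin",
    "default_fit_band",
    "ta_acf",
    "ea_acf",
    "ea_msd",
    "ea_ta_msd",
    "default_lag_grid",
]


@dataclass
class Spectrum:
    """One-sided spectrum at ``omega_k = 2 pi k / t_m`` (length^2 * time)."""

    omegas: np.ndarray
    values: np.ndarray
    t_m: float
    dt: float
    n_averaged: int = 1

    def __post_init__(self) -> None:
        self.omegas = np.asarray(self.omegas, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.omegas.shape != self.values.shape:
            raise ValueError("omegas and values must have the same shape")


@dataclass
class AcfEstimate:
    """Autocorrelation estimate; kind is 'EA' or 'TA'.

    ``t_or_tm`` is the aging time t for EA estimates and the measurement
    time t_m for TA estimates.
    """

    kind: str
    lags: np.ndarray
    values: np.ndarray
    t_or_tm: float


@dataclass
class MsdEstimate:
    """MSD estimate; kind 'EA' (vs time t) or 'EA-TA' (vs lag tau)."""

    kind: str
    abscissa: np.ndarray
    values: np.ndarray
    t_m: float | None = None


def periodogram(traj: Trajectory) -> Spectrum:
    """Periodogram of one trajectory at ``omega_k = 2 pi k / t_m``."""
    if traj.n_points < 4:
        raise ValueError("need at least 4 samples")
    n = traj.n_points - 1  # DFT window excludes the final grid point
    x = traj.values[:n]
    xhat = np.fft.rfft(x)
    k_max = n // 2
    values = (traj.dt**2 / traj.t_m) * np.abs(xhat[1 : k_max + 1]) ** 2
    omegas = 2.0 * np.pi * np.arange(1, k_max + 1) / traj.t_m
    return Spectrum(omegas=omegas, values=values, t_m=traj.t_m, dt=traj.dt)


def ensemble_psd(ens: Ensemble, chunk: int = 256) -> Spectrum:
    """Ensemble-averaged periodogram ``<S(omega_k, t_m)>``.

    Member periodograms are averaged pointwise; the FFTs run in row chunks to
    bound memory for large ensembles.
    """
    if len(ens) == 0:
        raise ValueError("empty ensemble")
    n = ens.n_points - 1
    if n < 3:
        raise ValueError("trajectories too short for a spectrum")
    k_max = n // 2
    acc = np.zeros(k_max)
    for start in range(0, len(ens), chunk):
        block = ens.positions[start : start + chunk, :n]
        xhat = np.fft.rfft(block, axis=1)
        acc += (np.abs(xhat[:, 1 : k_max + 1]) ** 2).sum(axis=0)
    values = acc * ens.dt**2 / ens.t_m / len(ens)
    omegas = 2.0 * np.pi * np.arange(1, k_max + 1) / ens.t_m
    return Spectrum(omegas=omegas, values=values, t_m=ens.t_m, dt=ens.dt,
                    n_averaged=len(ens))


def psd_amplitude(spec: Spectrum, beta: float = 2.0,
                  band: tuple[float, float] | None = None) -> float:
    """Least-squares amplitude A of the model ``S = A * omega**(-beta)``.

    Fitted in log space over the frequency band (inclusive), i.e.
    ``log A = mean(log S + beta log omega)``; exact for exact power laws.
    """
    if band is None:
        band = default_fit_band(spec)
    lo, hi = band
    mask = (spec.omegas >= lo) & (spec.omegas <= hi) & (spec.values > 0)
    if not mask.any():
        raise ValueError(f"no positive spectrum values in band {band}")
    log_a = np.mean(np.log(spec.values[mask])
                    + beta * np.log(spec.omegas[mask]))
    return float(np.exp(log_a))


def default_fit_band(spec: Spectrum) -> tuple[float, float]:
    """Default band omega*t_m in [2*pi*4, ...], omega <= pi/(4 dt).

    Excludes the lowest finite-size bins (k < 4) and the upper quarter-decade
    below Nyquist where sampling artifacts live.
    """
    return (8.0 * np.pi / spec.t_m, 0.25 * np.pi / spec.dt)


def log_bin(x: np.ndarray, y: np.ndarray,
            bins_per_decade: int = 16) -> tuple[np.ndarray, np.ndarray]:
    """Geometric-mean binning on a logarithmic abscissa grid.

    Returns per-bin geometric means of both coordinates (so exact power laws
    stay exact power laws); non-positive ``y`` values are dropped.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    keep = (x > 0) & (y > 0)
    x, y = x[keep], y[keep]
    if x.size == 0:
        raise ValueError("nothing to bin")
    lx, ly = np.log10(x), np.log10(y)
    idx = np.floor(lx * bins_per_decade).astype(int)
    idx -= idx.min()
    n_bins = idx.max() + 1
    counts = np.bincount(idx, minlength=n_bins)
    sum_lx = np.bincount(idx, weights=lx, minlength=n_bins)
    sum_ly = np.bincount(idx, weights=ly, minlength=n_bins)
    filled = counts > 0
    bx = 10.0 ** (sum_lx[filled] / counts[filled])
    by = 10.0 ** (sum_ly[filled] / counts[filled])
    return bx, by


def _lag_indices(lags, dt: float, n_points: int) -> np.ndarray:
    lags = np.atleast_1d(np.asarray(lags, dtype=float))
    idx = np.round(lags / dt).astype(int)
    if np.any(np.abs(idx * dt - lags) > 1e-9 * max(dt, 1.0)):
        raise ValueError("lags must be integer multiples of dt")
    if np.any(idx < 0) or np.any(idx >= n_points):
        raise ValueError("lags must satisfy 0 <= lag < t_m + dt")
    return idx


def ta_acf(traj: Trajectory, lags=None) -> AcfEstimate:
    """Time-averaged ACF ``C_TA(t_m, tau)`` of a single trajectory.

    Discrete rectangle rule: ``C(j dt) = (1/M) sum_i x_i x_{i+j}`` with
    ``M = n_points - j`` summed products.  With ``lags=None`` every lag is
    computed at once through an FFT autocorrelation (identical sums).
    """
    x = traj.values
    n = x.size
    if lags is None:
        m = 1 << (2 * n - 1).bit_length()
        xhat = np.fft.rfft(x, m)
        raw = np.fft.irfft(np.abs(xhat) ** 2, m)[:n]
        values = raw / (n - np.arange(n))
        lags_out = np.arange(n) * traj.dt
        return AcfEstimate(kind="TA", lags=lags_out, values=values,
                           t_or_tm=traj.t_m)
    idx = _lag_indices(lags, traj.dt, n)
    values = np.array([np.dot(x[: n - j], x[j:]) / (n - j) for j in idx])
    return AcfEstimate(kind="TA", lags=idx * traj.dt, values=values,
                       t_or_tm=traj.t_m)


def ea_acf(ens: Ensemble, t: float, lags) -> AcfEstimate:
    """Ensemble-averaged ACF ``C_EA(t, tau) = <x(t) x(t+tau)>``."""
    i = int(round(t / ens.dt))
    idx = _lag_indices(lags, ens.dt, ens.n_points)
    if i + idx.max() >= ens.n_points:
        raise ValueError("t + max(lag) exceeds the trajectory length")
    base = ens.positions[:, i]
    values = np.array([np.mean(base * ens.positions[:, i + j]) for j in idx])
    return AcfEstimate(kind="EA", lags=idx * ens.dt, values=values, t_or_tm=t)


def ea_msd(ens: Ensemble, times=None) -> MsdEstimate:
    """Ensemble-averaged MSD from the origin, ``<x^2(t)>`` (zero-start)."""
    if times is None:
        times = np.arange(ens.n_points) * ens.dt
    idx = _lag_indices(times, ens.dt, ens.n_points)
    values = np.mean(ens.positions[:, idx] ** 2, axis=0)
    return MsdEstimate(kind="EA", abscissa=idx * ens.dt, values=values,
                       t_m=ens.t_m)


def default_lag_grid(ens: Ensemble, n_lags: int = 40,
                     max_fraction: float = 0.25) -> np.ndarray:
    """Log-spaced integer lag grid up to ``max_fraction * t_m``."""
    j_max = max(2, int(ens.n_points * max_fraction))
    raw = np.unique(np.round(np.geomspace(1, j_max, n_lags)).astype(int))
    return raw * ens.dt


def ea_ta_msd(ens: Ensemble, lags=None, chunk: int = 256) -> MsdEstimate:
    """Ensemble average of the time-averaged MSD,
    ``<delta^2(tau, t_m)> = < (1/M) sum_i [x_{i+j} - x_i]^2 >``.

    Rectangle rule with ``M = n_points - j`` summed squared increments per
    trajectory, then averaged over the ensemble.
    """
    if lags is None:
        lags = default_lag_grid(ens)
    idx = _lag_indices(lags, ens.dt, ens.n_points)
    if np.any(idx == 0):
        raise ValueError("EA-TA-MSD lags must be positive")
    n_pts = ens.n_points
    values = np.empty(idx.size)
    for a, j in enumerate(idx):
        acc = 0.0
        for start in range(0, len(ens), chunk):
            block = ens.positions[start : start + chunk]
            diff = block[:, j:] - block[:, : n_pts - j]
            acc += float(np.einsum("ij,ij->", diff, diff))
        values[a] = acc / (len(ens) * (n_pts - j))
    return MsdEstimate(kind="EA-TA", abscissa=idx * ens.dt, values=values,
                       t_m=ens.t_m)
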