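"""Simulation of subordinated fractional Brownian motion.

The model couples two classic ingredients of anomalous diffusion:

* a *renewal clock* with heavy-tailed (Pareto) waiting times,
  ``psi(tau) = alpha * t0**alpha / tau**(1 + alpha)`` for ``tau >= t0`` with
  tail exponent ``0 < alpha <= 1`` (infinite-mean waits for ``alpha < 1``);
* a discrete *fractional Brownian motion* (fBM) ``x_0, x_1, ...`` with Hurst
  exponent ``H`` and position covariance
  ``<x_n x_{n+dn}> = dx**2 * (n**(2H) + (n+dn)**(2H) - dn**(2H))``.

The particle position at clock time ``t`` is ``x(t) = x_{n(t)}`` where
``n(t)`` counts renewals in ``(0, t]``: the walker is frozen between renewal
epochs and advances along the fBM path one step per renewal.  Trajectories
are returned sampled on a uniform grid, which is how single-particle-tracking
data are recorded.

fBM synthesis uses circulant embedding (Davies-Harte) of the increment
process, which realizes the covariance above exactly; a Cholesky factorization
of the increment covariance is used as a fallback when the embedding is not
non-negative definite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

__all__ = [
    "WaitingTimeModel",
    "FbmParams",
    "RenewalPath",
    "Trajectory",
    "Ensemble",
    "draw_waiting_times",
    "build_renewal_path",
    "generate_fbm",
    "fbm_covariance",
    "subordinate",
    "simulate_ensemble",
    "spawn_trajectory_seeds",
]


def _as_rng(seed) -> np.random.Generator:
    """Accept an int seed, a SeedSequence, or an existing Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class WaitingTimeModel:
    """Pareto waiting-time law ``psi(tau) = alpha t0^alpha / tau^(1+alpha)``.

    Parameters
    ----------
    alpha : float
        Tail exponent, ``0 < alpha <= 1``.  For ``alpha < 1`` the mean
        waiting time is infinite, which is what produces aging.
    t0 : float
        Lower cutoff of the Pareto law (time units); the shortest possible
        waiting time.

    Notes
    -----
    Two time-scale conventions coexist in the renewal literature.  Sampling
    uses the plain Pareto cutoff ``t0``.  The asymptotic renewal formulas
    (mean renewal number, CTRW correlation functions and spectra) are written
    in terms of a scale ``t0*`` defined through
    ``psi(tau) ~ [alpha / Gamma(1 - alpha)] t0*^alpha / tau^(1+alpha)``,
    i.e. ``t0* = Gamma(1 - alpha)^(1/alpha) * t0``.  Use
    :attr:`renewal_scale` when plugging a sampled model into those formulas.
    """

    alpha: float
    t0: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if not self.t0 > 0.0:
            raise ValueError(f"t0 must be positive, got {self.t0}")

    @property
    def renewal_scale(self) -> float:
        """Scale ``t0* = Gamma(1-alpha)^(1/alpha) t0`` of the asymptotic
        renewal formulas (defined for ``alpha < 1``)."""
        if self.alpha >= 1.0:
            raise ValueError("renewal_scale is defined only for alpha < 1")
        return math.gamma(1.0 - self.alpha) ** (1.0 / self.alpha) * self.t0

    def mean_renewals(self, t):
        """Asymptotic mean renewal number ``<n(t)> = t^alpha /
        (t0*^alpha Gamma(1+alpha))`` for ``alpha < 1``."""
        scale = self.renewal_scale
        return np.asarray(t, dtype=float) ** self.alpha / (
            scale**self.alpha * math.gamma(1.0 + self.alpha)
        )


@dataclass(frozen=True)
class FbmParams:
    """Discrete fBM parameters: Hurst exponent and step amplitude.

    ``dx`` has units of length; the position variance is
    ``Var(x_n) = 2 dx^2 n^(2H)``.  The default ``dx = sqrt(1/2)`` makes the
    ``H = 1/2`` walk a cumulative sum of standard-normal increments.
    """

    hurst: float
    dx: float = math.sqrt(0.5)

    def __post_init__(self) -> None:
        if not 0.0 < self.hurst < 1.0:
            raise ValueError(f"hurst must be in (0, 1), got {self.hurst}")
        if not self.dx > 0.0:
            raise ValueError(f"dx must be positive, got {self.dx}")


@dataclass(frozen=True)
class RenewalPath:
    """Realized renewal epochs of the operational-time process on (0, t_m].

    ``epochs`` are the cumulative waiting-time sums that fall inside the
    observation window; ``counts(t)`` is the renewal counting function,
    the number of epochs in the half-open interval ``(0, t]``.
    """

    epochs: np.ndarray
    t_m: float

    def __post_init__(self) -> None:
        epochs = np.asarray(self.epochs, dtype=float)
        object.__setattr__(self, "epochs", epochs)
        if not self.t_m > 0.0:
            raise ValueError("t_m must be positive")
        if epochs.size and not np.all(np.diff(epochs) > 0.0):
            raise ValueError("epochs must be strictly increasing")
        if epochs.size and (epochs[0] <= 0.0 or epochs[-1] > self.t_m):
            raise ValueError("epochs must lie in (0, t_m]")

    @property
    def waits(self) -> np.ndarray:
        """Waiting times ``tau_n = t_n - t_(n-1)`` of the kept epochs."""
        return np.diff(self.epochs, prepend=0.0)

    @property
    def n_renewals(self) -> int:
        return int(self.epochs.size)

    def counts(self, t):
        """Number of renewals in ``(0, t]`` (vectorized over ``t``)."""
        return np.searchsorted(self.epochs, t, side="right")


def draw_waiting_times(model: WaitingTimeModel, count: int, seed) -> np.ndarray:
    """Draw i.i.d. Pareto waiting times by inverse-CDF sampling.

    Returns ``count`` samples ``tau = t0 * (1 - U)^(-1/alpha)`` with
    ``U ~ Uniform[0, 1)``; every sample is ``>= t0``.
    """
    if count < 1:
        raise ValueError(f"count must be >= 1, got {count}")
    rng = _as_rng(seed)
    u = rng.random(int(count))
    return model.t0 * (1.0 - u) ** (-1.0 / model.alpha)


def build_renewal_path(model: WaitingTimeModel, t_m: float, seed) -> RenewalPath:
    """Accumulate waiting times into renewal epochs, truncated at ``t_m``.

    Waits are drawn in blocks until their running sum exceeds ``t_m``; epochs
    beyond ``t_m`` are discarded (the walker is still waiting at the end of
    the observation window).
    """
    if not t_m > 0.0:
        raise ValueError(f"t_m must be positive, got {t_m}")
    rng = _as_rng(seed)
    if model.alpha < 1.0:
        expected = float(model.mean_renewals(t_m))
    else:  # alpha = 1: log-corrected growth; a crude overestimate is fine
        expected = t_m / model.t0 / max(1.0, math.log(1.0 + t_m / model.t0))
    block = max(64, int(1.5 * expected) + 8)
    chunks: list[np.ndarray] = []
    total = 0.0
    while total <= t_m:
        w = draw_waiting_times(model, block, rng)
        chunks.append(w)
        total += float(w.sum())
    waits = np.concatenate(chunks)
    epochs = np.cumsum(waits)
    keep = np.searchsorted(epochs, t_m, side="right")
    return RenewalPath(epochs=epochs[:keep], t_m=float(t_m))


# ---------------------------------------------------------------------------
# fBM synthesis

_EIGEN_CACHE: dict[tuple[float, int], np.ndarray | None] = {}


def _fgn_autocov(hurst: float, lags: np.ndarray) -> np.ndarray:
    """Autocovariance of standard fractional Gaussian noise (unit variance)."""
    k = np.abs(lags).astype(float)
    return 0.5 * ((k + 1.0) ** (2 * hurst) - 2.0 * k ** (2 * hurst)
                  + np.abs(k - 1.0) ** (2 * hurst))


def _dh_eigenvalues(hurst: float, m: int) -> np.ndarray | None:
    """Eigenvalues of the circulant embedding; None if not non-negative."""
    key = (hurst, m)
    if key in _EIGEN_CACHE:
        return _EIGEN_CACHE[key]
    half = m // 2
    row = np.empty(m)
    row[: half + 1] = _fgn_autocov(hurst, np.arange(half + 1))
    row[half + 1:] = row[1:half][::-1]
    lam = np.fft.fft(row).real
    if lam.min() < -1e-8 * lam.max():
        result = None
    else:
        result = np.clip(lam, 0.0, None)
    _EIGEN_CACHE[key] = result
    return result


def _fgn_standard(hurst: float, n: int, rng: np.random.Generator,
                  size: int) -> np.ndarray:
    """(size, n) array of standard-fGn samples."""
    if hurst == 0.5:
        return rng.standard_normal((size, n))
    m = 1 << max(2, (2 * n - 1)).bit_length()
    lam = _dh_eigenvalues(hurst, m)
    if lam is None or n <= 16:
        # Cholesky of the (stationary, positive definite) increment covariance
        from scipy.linalg import toeplitz

        cov = toeplitz(_fgn_autocov(hurst, np.arange(n)))
        chol = np.linalg.cholesky(cov)
        return rng.standard_normal((size, n)) @ chol.T
    half = m // 2
    spec = np.zeros((size, m), dtype=complex)
    spec[:, 0] = math.sqrt(lam[0] / m) * rng.standard_normal(size)
    spec[:, half] = math.sqrt(lam[half] / m) * rng.standard_normal(size)
    coef = np.sqrt(lam[1:half] / (2.0 * m))
    u = rng.standard_normal((size, half - 1))
    v = rng.standard_normal((size, half - 1))
    spec[:, 1:half] = coef * (u + 1j * v)
    spec[:, half + 1:] = np.conj(spec[:, 1:half][:, ::-1])
    return np.fft.fft(spec, axis=1).real[:, :n]


def generate_fbm(params: FbmParams, n_steps: int, seed,
                 size: int | None = None) -> np.ndarray:
    """Sample discrete fBM paths ``x_0 = 0, x_1, ..., x_n`` with the exact
    covariance ``<x_n x_m> = dx^2 (n^(2H) + m^(2H) - |n-m|^(2H))``.

    Parameters
    ----------
    n_steps : int
        Number of steps; the returned path has ``n_steps + 1`` points.
    size : int, optional
        If given, return ``(size, n_steps + 1)`` independent paths.
    """
    if n_steps < 1:
        raise ValueError(f"n_steps must be >= 1, got {n_steps}")
    rng = _as_rng(seed)
    batch = 1 if size is None else int(size)
    fgn = _fgn_standard(params.hurst, int(n_steps), rng, batch)
    x = np.zeros((batch, n_steps + 1))
    np.cumsum(fgn, axis=1, out=x[:, 1:])
    x *= math.sqrt(2.0) * params.dx
    return x[0] if size is None else x


def fbm_covariance(params: FbmParams, n_steps: int) -> np.ndarray:
    """Exact position covariance matrix of the discrete fBM on 0..n_steps."""
    n = np.arange(n_steps + 1, dtype=float)
    two_h = 2.0 * params.hurst
    return params.dx**2 * (n[:, None] ** two_h + n[None, :] ** two_h
                           - np.abs(n[:, None] - n[None, :]) ** two_h)


# ---------------------------------------------------------------------------
# Subordination

@dataclass
class Trajectory:
    """One uniformly sampled path: values at grid times 0, dt, ..., t_m."""

    dt: float
    values: np.ndarray
    t_m: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not self.t_m > 0.0:
            raise ValueError("t_m must be positive")
        expected = int(round(self.t_m / self.dt)) + 1
        if self.values.size != expected:
            raise ValueError(
                f"expected {expected} samples for t_m={self.t_m}, dt={self.dt}; "
                f"got {self.values.size}"
            )

    @property
    def n_points(self) -> int:
        return int(self.values.size)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_points) * self.dt


def subordinate(fbm_path: np.ndarray, renewal: RenewalPath,
                dt: float) -> Trajectory:
    """Run an fBM step sequence on the operational time of a renewal clock.

    The trajectory value at grid time ``t`` is ``x_{n(t)}`` with ``n(t)`` the
    renewal count; the path is piecewise constant between epochs (the walker
    is immobilized while waiting).
    """
    fbm_path = np.asarray(fbm_path, dtype=float)
    n_pts = int(round(renewal.t_m / dt)) + 1
    grid = np.arange(n_pts) * dt
    counts = renewal.counts(grid)
    if counts[-1] >= fbm_path.size:
        raise ValueError(
            f"fbm_path has {fbm_path.size} entries but the clock realized "
            f"{int(counts[-1])} renewals; need at least counts(t_m)+1"
        )
    return Trajectory(dt=dt, values=fbm_path[counts], t_m=float(renewal.t_m))


@dataclass
class Ensemble:
    """Collection of trajectories sharing the sampling grid (dt, t_m).

    ``positions`` is a ``(n_real, n_points)`` array, one trajectory per row.
    """

    positions: np.ndarray
    dt: float
    t_m: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        expected = int(round(self.t_m / self.dt)) + 1
        if self.positions.shape[1] != expected:
            raise ValueError(
                f"positions have {self.positions.shape[1]} columns; expected "
                f"{expected} for t_m={self.t_m}, dt={self.dt}"
            )

    def __len__(self) -> int:
        return int(self.positions.shape[0])

    def __iter__(self) -> Iterator[Trajectory]:
        for row in self.positions:
            yield Trajectory(dt=self.dt, values=row, t_m=self.t_m,
                             meta=dict(self.meta))

    @property
    def n_points(self) -> int:
        return int(self.positions.shape[1])

    def truncated(self, t_m: float) -> "Ensemble":
        """Prefix-truncate every trajectory to a shorter observation time."""
        if t_m > self.t_m:
            raise ValueError("cannot truncate to a longer t_m")
        n_pts = int(round(t_m / self.dt)) + 1
        return Ensemble(positions=self.positions[:, :n_pts], dt=self.dt,
                        t_m=float(t_m), meta=dict(self.meta))

    @classmethod
    def from_trajectories(cls, trajectories: list[Trajectory]) -> "Ensemble":
        if not trajectories:
            raise ValueError("empty ensemble")
        dt, t_m = trajectories[0].dt, trajectories[0].t_m
        for tr in trajectories:
            if tr.dt != dt or tr.t_m != t_m:
                raise ValueError("mixed dt or t_m within ensemble")
        return cls(positions=np.stack([tr.values for tr in trajectories]),
                   dt=dt, t_m=t_m)


def spawn_trajectory_seeds(seed, n_real: int) -> list[tuple]:
    """Deterministic master-seed -> per-trajectory seed scheme.

    ``SeedSequence(seed)`` is spawned into ``n_real`` children; each child is
    spawned once more into a ``(clock, walk)`` pair so the renewal clock and
    the fBM path use independent streams.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    children = ss.spawn(int(n_real))
    return [tuple(child.spawn(2)) for child in children]


def simulate_ensemble(wt: WaitingTimeModel, fp: FbmParams, t_m: float,
                      dt: float = 1.0, n_real: int = 1,
                      seed=None) -> Ensemble:
    """Simulate ``n_real`` independent subordinated-fBM trajectories.

    Reproducible: the same master ``seed`` yields bit-identical ensembles.
    """
    if n_real < 1:
        raise ValueError(f"n_real must be >= 1, got {n_real}")
    n_pts = int(round(t_m / dt)) + 1
    grid = np.arange(n_pts) * dt
    positions = np.empty((n_real, n_pts))
    for i, (clock_seed, walk_seed) in enumerate(
            spawn_trajectory_seeds(seed, n_real)):
        renewal = build_renewal_path(wt, t_m, np.random.default_rng(clock_seed))
        n = renewal.n_renewals
        if n == 0:
            positions[i] = 0.0
            continue
        path = generate_fbm(fp, n, np.random.default_rng(walk_seed))
        positions[i] = path[renewal.counts(grid)]
    meta = {"alpha": wt.alpha, "t0": wt.t0, "hurst": fp.hurst, "dx": fp.dx,
            "seed": seed, "n_real": n_real}
    return Ensemble(positions=positions, dt=float(dt), t_m=float(t_m),
                    meta=meta)
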