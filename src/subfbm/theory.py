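"""Analytic layer: scale-invariant correlation functions, the aging
Wiener-Khinchin quadrature, CTRW closed forms, asymptotic spectral laws,
and the exponent algebra connecting (alpha, H) to (beta, z, gamma).

The model's non-stationary autocorrelation has the scale-invariant form
``C_EA(t, tau) ~ t**gamma * phi_EA(tau/t)`` with aging exponent
``gamma = 2*alpha*H``.  Its time-averaged counterpart follows from

    phi_TA(y) = y**(1+gamma)/(1-y) * integral_{y/(1-y)}^inf phi_EA(z)/z**(2+gamma) dz,

and the aging Wiener-Khinchin theorem gives the mean periodogram at the
discrete frequencies ``omega_k t_m = 2 pi k``:

    <S(omega, t_m)> = 2 t_m**(1+gamma) * integral_0^1 (1-y) phi_TA(y) cos(omega t_m y) dy.

Large-frequency expansion of that integral yields the power laws
``<S> ~ omega**(-beta) * t_m**z`` with

* regime I  (H < 1/2):            beta = 2 - alpha + 2*alpha*H,  z = alpha - 1
* regime II (H > 1/2, 2aH < 1):   beta = 2,                      z = 2*alpha*H - 1  (aging)
* regime III (2aH > 1):           beta = 2,                      z = 2*alpha*H - 1  (rejuvenation)

All time scales here use the renewal convention in which the waiting-time
density behaves as ``[alpha/Gamma(1-alpha)] t0**alpha / tau**(1+alpha)``;
pass ``WaitingTimeModel.renewal_scale`` for ``t0`` when comparing against
Pareto-sampled simulations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.interpolate import PchipInterpolator

from .estimate import AcfEstimate, Spectrum

__all__ = [
    "ScalingFunction",
    "ExponentSet",
    "AsymptoticConstants",
    "DivergentTailError",
    "phi_ta_from_phi_ea",
    "aging_wk_psd",
    "ctrw_phi_ea",
    "ctrw_phi_ta",
    "ctrw_ta_acf",
    "ctrw_psd_asymptote",
    "asymptotic_psd",
    "psd_msd_relation",
    "exponents_forward",
    "exponents_invert",
    "InvertedExponents",
    "classify_regime",
    "fit_asymptotic_constants",
]


class DivergentTailError(ValueError):
    """The tail integral of the phi_EA -> phi_TA transform diverges."""


@dataclass
class ScalingFunction:
    """Scale-invariant correlation function ``t**gamma * phi(y)``.

    ``kind`` is 'EA' (y = tau/t) or 'TA' (y = tau/t_m, defined on [0, 1)).
    ``phi`` is a callable; tabulated functions carry their grid in
    ``y``/``values`` and are evaluated by monotone (PCHIP) interpolation.
    """

    gamma: float
    kind: str
    phi: object
    y: np.ndarray | None = None
    values: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("EA", "TA"):
            raise ValueError("kind must be 'EA' or 'TA'")

    def __call__(self, y):
        return self.phi(np.asarray(y, dtype=float))

    @classmethod
    def from_table(cls, gamma: float, kind: str, y: np.ndarray,
                   values: np.ndarray) -> "ScalingFunction":
        y = np.asarray(y, float)
        values = np.asarray(values, float)
        interp = PchipInterpolator(y, values, extrapolate=True)
        return cls(gamma=gamma, kind=kind, phi=interp, y=y, values=values)


def phi_ta_from_phi_ea(ea: ScalingFunction, y_grid: np.ndarray | None = None,
                       epsabs: float = 0.0,
                       epsrel: float = 1e-10) -> ScalingFunction:
    """Transform phi_EA into phi_TA by adaptive quadrature on a y-grid.

    For each grid point the improper tail integral
    ``integral_{y/(1-y)}^inf phi_EA(z) z**(-2-gamma) dz`` is evaluated with
    ``scipy.integrate.quad``; a divergent tail (phi_EA growing at least as
    fast as z**(1+gamma)) is detected up front and reported.
    """
    if ea.kind != "EA":
        raise ValueError("input must be an EA-kind scaling function")
    g = ea.gamma
    # tail-growth probe: integrand ~ phi(z)/z^(2+g) must decay faster than 1/z
    z1, z2 = 1e6, 1e8
    p1, p2 = float(ea.phi(np.array(z1))), float(ea.phi(np.array(z2)))
    if p1 > 0 and p2 > 0:
        growth = math.log(p2 / p1) / math.log(z2 / z1)
        if growth >= 1.0 + g:
            raise DivergentTailError(
                f"phi_EA grows like z^{growth:.3f} >= z^(1+gamma); the "
                "transform integral diverges")
    if y_grid is None:
        # refined toward both endpoints: phi_TA often has a branch point at
        # y = 1 (e.g. (1-y)^alpha) and steep variation near y = 0
        left = np.geomspace(1e-5, 0.5, 257)
        right = 1.0 - np.geomspace(1e-5, 0.5, 257)[::-1]
        y_grid = np.unique(np.concatenate([[0.0], left, right]))
    # substitute u = a/z with a = y/(1-y): the improper tail integral becomes
    # phi_TA(y) = (1-y)^gamma * integral_0^1 phi_EA(a/u) u^gamma du,
    # a finite-interval quadrature with the singular prefactor cancelled
    vals = np.empty(y_grid.size)
    for i, y in enumerate(y_grid):
        if y == 0.0:
            # a -> 0 limit: the inner integral tends to phi_EA(0)/(1+gamma)
            vals[i] = float(ea.phi(np.array(0.0))) / (1.0 + g)
            continue
        a = y / (1.0 - y)
        inner, _ = quad(lambda u: float(ea.phi(np.array(a / u))) * u**g,
                        0.0, 1.0, epsabs=epsabs, epsrel=epsrel, limit=400)
        vals[i] = (1.0 - y) ** g * inner
    if not np.all(np.isfinite(vals)):
        raise DivergentTailError("transform integral did not converge")
    return ScalingFunction.from_table(g, "TA", y_grid, vals)


_GAUSS_ORDER = 24
_GAUSS_NODES, _GAUSS_WEIGHTS = np.polynomial.legendre.leggauss(_GAUSS_ORDER)


def aging_wk_psd(ta: ScalingFunction, t_m: float, k_max: int,
                 breakpoints=None) -> Spectrum:
    """Aging Wiener-Khinchin quadrature: mean periodogram from phi_TA.

    Evaluates ``2 t_m^(1+gamma) * integral_0^1 (1-y) phi_TA(y) cos(2 pi k y) dy``
    for ``k = 1 .. k_max``.  The integration interval is split at the zeros
    of the cosine (plus any user-supplied ``breakpoints`` where phi_TA is not
    smooth) and each piece is integrated by Gauss-Legendre quadrature; the
    signed pieces are summed with compensated accumulation.
    """
    if ta.kind != "TA":
        raise ValueError("input must be a TA-kind scaling function")
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    g = ta.gamma
    extra = (np.asarray(breakpoints, dtype=float)
             if breakpoints is not None else np.empty(0))
    if extra.size and (extra.min() <= 0.0 or extra.max() >= 1.0):
        raise ValueError("breakpoints must lie strictly inside (0, 1)")
    values = np.empty(int(k_max))
    for k in range(1, int(k_max) + 1):
        zeros = (2.0 * np.arange(2 * k) + 1.0) / (4.0 * k)
        edges = np.unique(np.concatenate([[0.0], zeros, extra, [1.0]]))
        a, b = edges[:-1], edges[1:]
        half = 0.5 * (b - a)
        mid = 0.5 * (a + b)
        y = mid[:, None] + half[:, None] * _GAUSS_NODES[None, :]
        f = (1.0 - y) * ta.phi(y) * np.cos(2.0 * np.pi * k * y)
        pieces = half * (f @ _GAUSS_WEIGHTS)
        values[k - 1] = 2.0 * t_m ** (1.0 + g) * math.fsum(pieces.tolist())
    omegas = 2.0 * np.pi * np.arange(1, int(k_max) + 1) / t_m
    return Spectrum(omegas=omegas, values=values, t_m=float(t_m), dt=np.nan)


# ---------------------------------------------------------------------------
# CTRW (2H = 1) closed forms

def ctrw_phi_ea(alpha: float, dx: float = math.sqrt(0.5),
                t0: float = 1.0) -> ScalingFunction:
    """Constant EA scaling function of the CTRW:
    ``phi_EA = 2 dx^2 / (t0^alpha Gamma(1+alpha))``, gamma = alpha."""
    k = 2.0 * dx**2 / (t0**alpha * math.gamma(1.0 + alpha))
    return ScalingFunction(gamma=alpha, kind="EA",
                           phi=lambda z: np.full_like(np.asarray(z, float), k))


def ctrw_phi_ta(alpha: float, dx: float = math.sqrt(0.5),
                t0: float = 1.0) -> ScalingFunction:
    """TA scaling function of the CTRW:
    ``phi_TA(y) = 2 dx^2 (1-y)^alpha / (t0^alpha Gamma(2+alpha))``."""
    c = 2.0 * dx**2 / (t0**alpha * math.gamma(2.0 + alpha))
    return ScalingFunction(gamma=alpha, kind="TA",
                           phi=lambda y: c * (1.0 - np.asarray(y, float)) ** alpha)


def ctrw_ta_acf(alpha: float, dx: float, t0: float, t_m: float,
                lags) -> AcfEstimate:
    """Mean TA-ACF of the CTRW:
    ``<C_TA(t_m, tau)> = 2 dx^2 t_m^alpha (1 - tau/t_m)^alpha / (t0^alpha Gamma(2+alpha))``."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    lags = np.atleast_1d(np.asarray(lags, dtype=float))
    if np.any(lags >= t_m) or np.any(lags < 0):
        raise ValueError("lags must satisfy 0 <= tau < t_m")
    sf = ctrw_phi_ta(alpha, dx, t0)
    values = t_m**alpha * sf(lags / t_m)
    return AcfEstimate(kind="TA", lags=lags, values=values, t_or_tm=float(t_m))


def ctrw_psd_asymptote(alpha: float, dx: float, t0: float, t_m: float,
                       omegas) -> np.ndarray:
    """Leading large-(omega t_m) PSD of the CTRW:
    ``<S> ~ 4 dx^2 / (t0^alpha Gamma(1+alpha)) * t_m^(alpha-1) omega^-2``."""
    omegas = np.asarray(omegas, dtype=float)
    amp = 4.0 * dx**2 / (t0**alpha * math.gamma(1.0 + alpha))
    return amp * t_m ** (alpha - 1.0) / omegas**2


# ---------------------------------------------------------------------------
# Exponent algebra and regimes

@dataclass(frozen=True)
class ExponentSet:
    """Model exponents (alpha, H) and every induced observable exponent."""

    alpha: float
    hurst: float
    beta: float
    z: float
    gamma: float
    msd_lag_exp: float
    msd_aging_exp: float
    regime: str


@dataclass(frozen=True)
class AsymptoticConstants:
    """Prefactors of the asymptotic PSD laws: c (regime I), D (II/III).

    These are fitted from reference simulations, never claimed analytic.
    """

    c: float
    D: float

    def __post_init__(self) -> None:
        if self.c <= 0 or self.D <= 0:
            raise ValueError("c and D must be positive")


def classify_regime(alpha: float, hurst: float) -> str:
    """Phase-diagram label: 'I' (H<1/2), 'II' (H>1/2, 2aH<1), 'III'
    (2aH>1, rejuvenating), or 'boundary' (H=1/2 or 2aH=1)."""
    _check_range(alpha, hurst)
    two_ah = 2.0 * alpha * hurst
    if hurst == 0.5 or two_ah == 1.0:
        return "boundary"
    if hurst < 0.5:
        return "I"
    return "III" if two_ah > 1.0 else "II"


def _check_range(alpha: float, hurst: float) -> None:
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if not 0.0 < hurst < 1.0:
        raise ValueError(f"hurst must be in (0, 1), got {hurst}")


def exponents_forward(alpha: float, hurst: float) -> ExponentSet:
    """Map the model exponents (alpha, H) to all induced observables.

    beta = 2 - alpha + 2 alpha H for H <= 1/2 and beta = 2 for H >= 1/2;
    z = alpha - 1 for H <= 1/2 and z = 2 alpha H - 1 for H >= 1/2 (the two
    branches agree at H = 1/2).  gamma = 2 alpha H; the EA-TA-MSD scales as
    tau^(1 - alpha + 2 alpha H) / t_m^(1 - alpha).
    """
    _check_range(alpha, hurst)
    if hurst <= 0.5:
        beta = 2.0 - alpha + 2.0 * alpha * hurst
        z = alpha - 1.0
    else:
        beta = 2.0
        z = 2.0 * alpha * hurst - 1.0
    return ExponentSet(
        alpha=alpha, hurst=hurst, beta=beta, z=z,
        gamma=2.0 * alpha * hurst,
        msd_lag_exp=1.0 - alpha + 2.0 * alpha * hurst,
        msd_aging_exp=-(1.0 - alpha),
        regime=classify_regime(alpha, hurst),
    )


@dataclass(frozen=True)
class InvertedExponents:
    """Result of inverting observable exponents back to (alpha, H).

    In regime II/III only the product alpha*H is identifiable from the PSD
    (beta is pinned at 2), flagged by ``identifiable = False``.
    """

    alpha: float | None
    hurst: float | None
    alpha_se: float | None = None
    hurst_se: float | None = None
    branch: str = "I"
    identifiable: bool = True
    alpha_hurst_product: float | None = None


def exponents_invert(beta: float | None = None, z: float | None = None,
                     branch: str = "I",
                     msd_lag_exp: float | None = None,
                     msd_aging_exp: float | None = None,
                     beta_se: float | None = None, z_se: float | None = None,
                     msd_lag_se: float | None = None,
                     msd_aging_se: float | None = None,
                     beta_tol: float = 0.25) -> InvertedExponents:
    """Invert observable exponents to (alpha, H).

    branch 'I'      : alpha = 1 + z, H = (beta - 2 + alpha) / (2 alpha);
                      requires z < 0.
    branch 'II/III' : beta must equal 2 (within ``beta_tol``); only
                      alpha*H = (1 + z)/2 is identifiable.
    branch 'MSD'    : inputs are the EA-TA-MSD lag and aging exponents;
                      alpha = 1 + msd_aging_exp,
                      H = (msd_lag_exp - 1 + alpha) / (2 alpha).

    When standard errors are provided they are propagated to first order.
    """
    if branch == "I":
        if beta is None or z is None:
            raise ValueError("branch 'I' needs beta and z")
        if z >= 0:
            raise ValueError("branch 'I' requires z < 0 (aging spectrum)")
        alpha = 1.0 + z
        hurst = (beta - 2.0 + alpha) / (2.0 * alpha)
        a_se = z_se
        h_se = None
        if beta_se is not None or z_se is not None:
            bs = beta_se or 0.0
            zs = z_se or 0.0
            # H = (beta-2)/(2a) + 1/2; dH/dbeta = 1/(2a); dH/dalpha = -(beta-2)/(2a^2)
            h_se = math.hypot(bs / (2 * alpha),
                              zs * (beta - 2.0) / (2.0 * alpha**2))
        return InvertedExponents(alpha=alpha, hurst=hurst, alpha_se=a_se,
                                 hurst_se=h_se, branch="I")
    if branch in ("II/III", "II", "III"):
        if beta is None or z is None:
            raise ValueError("branch 'II/III' needs beta and z")
        if abs(beta - 2.0) > beta_tol:
            raise ValueError(
                f"branch 'II/III' requires beta = 2 (got {beta}); the "
                "frequency exponent is alpha/H-independent there")
        product = (1.0 + z) / 2.0
        return InvertedExponents(alpha=None, hurst=None, branch="II/III",
                                 identifiable=False,
                                 alpha_hurst_product=product)
    if branch == "MSD":
        if msd_lag_exp is None or msd_aging_exp is None:
            raise ValueError("branch 'MSD' needs msd_lag_exp and msd_aging_exp")
        alpha = 1.0 + msd_aging_exp
        if not 0.0 < alpha <= 1.0:
            raise ValueError(f"implied alpha = {alpha} outside (0, 1]")
        hurst = (msd_lag_exp - 1.0 + alpha) / (2.0 * alpha)
        a_se = msd_aging_se
        h_se = None
        if msd_lag_se is not None or msd_aging_se is not None:
            ls = msd_lag_se or 0.0
            as_ = msd_aging_se or 0.0
            h_se = math.hypot(ls / (2 * alpha),
                              as_ * (msd_lag_exp - 1.0) / (2.0 * alpha**2))
        return InvertedExponents(alpha=alpha, hurst=hurst, alpha_se=a_se,
                                 hurst_se=h_se, branch="MSD")
    raise ValueError(f"unknown branch {branch!r}")


def asymptotic_psd(es: ExponentSet, consts: AsymptoticConstants, omega,
                   t_m: float) -> np.ndarray:
    """Regime-appropriate leading-order PSD law.

    regime I : 2 c t_m^-(1-alpha) omega^-(2-alpha+2aH)
    II / III : 2 D t_m^(2aH-1) omega^-2
    H = 1/2  : 2 (c + D) t_m^-(1-alpha) omega^-2 (both branches merge)
    """
    omega = np.asarray(omega, dtype=float)
    if np.any(omega * t_m < 16.0 * np.pi):
        warnings.warn("asymptotic PSD requested at omega*t_m < 2*pi*8; the "
                      "large-frequency expansion may be inaccurate",
                      stacklevel=2)
    if es.hurst < 0.5:
        return 2.0 * consts.c * t_m ** (es.alpha - 1.0) * omega ** (-es.beta)
    if es.hurst > 0.5:
        return (2.0 * consts.D * t_m ** (2.0 * es.alpha * es.hurst - 1.0)
                * omega**-2.0)
    return (2.0 * (consts.c + consts.D) * t_m ** (es.alpha - 1.0)
            * omega**-2.0)


def psd_msd_relation(msd_slope_at_tm: float, es: ExponentSet,
                     omega) -> np.ndarray:
    """PSD implied by the time derivative of the EA-MSD at t_m.

    ``<S> ~ (2/alpha) * dMSD/dt_m / omega^2`` for the CTRW (2H = 1) and
    ``<S> ~ dMSD/dt_m / (2 alpha H omega^2)`` for H > 1/2.  No such printed
    relation exists for regime I (H < 1/2), where the request is refused.
    """
    omega = np.asarray(omega, dtype=float)
    if es.hurst == 0.5:
        return 2.0 / es.alpha * msd_slope_at_tm / omega**2
    if es.hurst > 0.5:
        return msd_slope_at_tm / (2.0 * es.alpha * es.hurst * omega**2)
    raise ValueError("no PSD-MSD relation in regime I (H < 1/2)")


def fit_asymptotic_constants(spec: Spectrum, es: ExponentSet) -> AsymptoticConstants:
    """Fit c or D from a reference simulated spectrum at known (alpha, H).

    The amplitude of the regime law is extracted in log space over the
    default band; the constant of the *other* regime is set equal so the
    2H -> 1 seam formula ``2(c + D)`` stays usable.
    """
    from .estimate import default_fit_band, psd_amplitude

    amp = psd_amplitude(spec, beta=es.beta, band=default_fit_band(spec))
    level = amp / (2.0 * spec.t_m**es.z)
    return AsymptoticConstants(c=level, D=level)
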