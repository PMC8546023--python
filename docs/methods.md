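# Methods

## The model

A particle position is `x(t) = x_{n(t)}`, where `x_0, x_1, ...` is a discrete
fractional Brownian motion and `n(t)` counts the renewals of an independent
clock with i.i.d. Pareto waiting times.  The two ingredients:

**Renewal clock.**  Waits are sampled from
`psi(tau) = alpha t0^alpha / tau^(1+alpha)` for `tau >= t0` by inverse-CDF
(`tau = t0 (1-U)^(-1/alpha)`), with tail exponent `0 < alpha <= 1` and cutoff
`t0 > 0` (defaults `t0 = 1` in simulation units, one frame interval for SPT
fixtures).  For `alpha < 1` the mean wait is infinite; the mean renewal
number grows as `t^alpha` and every time-averaged observable acquires an
explicit dependence on the measurement time `t_m` (aging, weak ergodicity
breaking).  Renewal epochs are accumulated in blocks until they pass `t_m`
and truncated there; the counting convention is half-open, `n(t)` = number of
epochs in `(0, t]`, so a renewal landing exactly on a sampling time takes
effect at that sample.

*Two time-scale conventions.*  The asymptotic renewal formulas are written
for a density with tail coefficient `alpha t0*^alpha / Gamma(1-alpha)`.  A
Pareto cutoff `b` therefore corresponds to the asymptotic scale
`t0* = Gamma(1-alpha)^(1/alpha) b`, exposed as
`WaitingTimeModel.renewal_scale`.  All closed forms in `subfbm.theory` take
`t0*`; forgetting the conversion mis-scales amplitudes by up to
`Gamma(1-alpha)` (a factor ~2.7 at `alpha = 0.7`).

**Discrete fBM.**  Zero-mean Gaussian with the exact position covariance
`<x_n x_m> = dx^2 (n^2H + m^2H - |n-m|^2H)`, i.e. `Var(x_n) = 2 dx^2 n^2H`;
with the default `dx^2 = 1/2` and `H = 1/2` the steps are i.i.d. standard
normal.  Synthesis is by circulant embedding (Davies–Harte) of the increment
process, which realizes this covariance exactly up to floating point; a
Cholesky factorization of the increment Toeplitz covariance is used for
short paths (`n <= 16`) or if an embedding eigenvalue were negative (none
was observed for `H` in (0, 1); the guard clips eigenvalues below
`-1e-8 * max` and falls back).  Because the renewal path is generated first,
the exact number of fBM steps needed is known and no resampling is required.

**Seeding.**  `SeedSequence(master).spawn(n_real)` gives one child per
trajectory; each child spawns a `(clock, walk)` pair so the renewal clock
and the fBM use independent streams (the generating paper does not state its
scheme; independence is assumed).  Identical master seeds give bit-identical
ensembles.

## Estimators

*Periodogram.*  `S(omega_k, t_m) = |dt * DFT|^2 / t_m` at
`omega_k = 2 pi k / t_m`, `k = 1 .. N/2`, no windowing or Welch averaging —
the aging Wiener–Khinchin theory addresses exactly this object.  Spectra are
log-binned (16 bins/decade, geometric means of both coordinates, so exact
power laws remain exact) before slope fitting, because periodogram scatter
is multiplicative.

*ACF and MSD.*  Time averages are rectangle-rule sums on the sampling grid
divided by the number of summed terms (this removes the O(dt) bias of
dividing by `t_m - tau` at large `tau/t_m`).  All-lag TA-ACFs go through an
FFT autocorrelation that is an exact identity with the direct sum.  EA-TA-MSD
lags default to a log-spaced integer grid capped at `t_m/4`, where the
`tau^(1-alpha+2aH)/t_m^(1-alpha)` scaling form holds.

## Analytic layer

The `phi_EA -> phi_TA` transform is evaluated per grid point by adaptive
quadrature after the substitution `u = a/z` (`a = y/(1-y)`), which maps the
improper tail integral onto `(0, 1]` and cancels the `y^(1+gamma)/(1-y)`
prefactor analytically — the direct form loses four digits near `y -> 1`.
The result is tabulated on a grid refined toward both endpoints (513 points,
geometric spacing down to 1e-5) and interpolated monotonically (PCHIP);
divergent tails (`phi_EA` growing at least as `z^(1+gamma)`) are detected by
a log-log probe and reported, never silently truncated.

The aging-WK integral `2 t_m^(1+gamma) ∫ (1-y) phi_TA(y) cos(2 pi k y) dy`
is split at the cosine zeros (plus caller-supplied breakpoints for kinks in
`phi_TA`), each half-period integrated with 24-node Gauss–Legendre, and the
signed pieces summed with compensated accumulation.  Against the closed-form
CTRW asymptote the quadrature agrees to 0.6% at `k = 64` and the error
decreases monotonically in `k`; against a tent test function with a known
cosine series it is exact to machine precision once the kink is a breakpoint.

The exponent maps `(alpha, H) -> (beta, z, gamma, MSD exponents)` and their
inverses are closed-form.  In regimes II/III only the product `alpha H` is
identifiable from the PSD (`beta` is pinned at 2); the inversion returns the
product and flags non-identifiability rather than guessing.  The asymptotic
prefactors `c` and `D` are *fitted from reference simulations* when needed;
no analytic values are claimed.

## SPT pipeline and localization noise

Track tables are CSV with columns `track_id, frame, t, x[, y]` (0-based
consecutive frames, seconds, micrometers).  Observation-time windows are
*prefixes* of each track: aging statistics are anchored to the process
start, which for channel tracking is delivery to the membrane.  Coordinates
are analyzed as independent 1-D realizations; their spectra enter one pooled
ensemble.

I.i.d. localization error of variance `sigma^2` adds `sigma^2 dt` (white) to
the periodogram and `2 sigma^2` to the TA-MSD at every positive lag.  The
pipeline fits the crossover model `A omega^-b + F` to the longest-window
spectrum (only when the high-frequency end is actually flat), subtracts `F`
from spectra and `2F/dt` from MSDs, and restricts fits to bins with signal
above three times the floor.  Without this correction the short-lag MSD
flattens and both `H` estimates bias low by ~0.1 at 20 nm noise.

Fit uncertainties: `beta` and the MSD lag exponent are pooled common slopes
across windows (one intercept per `t_m`, OLS standard errors).  The aging
exponents come from 2–3 amplitude points, where residual-based errors are
meaningless (1 dof) and lag points are strongly correlated; their standard
errors are therefore *propagated* from the amplitude uncertainties —
frequency-bin scatter for spectra, between-trajectory TA-MSD scatter for
MSDs — via weighted least squares.  The two `(alpha, H)` routes are declared
consistent when their 2-sigma intervals overlap, and are also combined by
inverse-variance weighting.

## Synthetic fixture defaults

`make_fixture` emulates the sodium-channel data set: 87 tracks x 256
localizations at `dt = 50 ms`, step amplitude `dx = 0.1 um` (giving TA-MSDs
of a few 1e-2 um^2 at second lags, typical for confined membrane proteins),
waiting-time cutoff `t0 = dt` (traps shorter than a frame are unresolvable),
and 20 nm localization noise (standard for TIRF SPT).  What it does *not*
emulate: finite nanodomain size (motion inside traps), blinking/gap frames,
non-Gaussian localization errors, and correlations between the x and y
coordinates — so passing recovery tests show estimator correctness under the
model, not robustness to every experimental artifact.

## Problem sizes and numerical tolerances

Simulated study conditions use 2000 realizations at `t_m = 2^16` for the
CTRW reference (EA-MSD slope fitted over `t in [1e2, 1e4]`), 2000
realizations at `t_m = 2^14` for the three regime points, and the 87-track
fixture for experimental-scale recovery.  At these sizes the asymptotic
renewal formulas still carry visible finite-time corrections: the mean
renewal number sits ~5% above its asymptote at `t_m = 1e4`, the closed-form
CTRW TA-ACF ~10% below the simulation at `t_m = 2^12`, and the regime-III
aging exponent is ~+0.1 at `t_m = 2^14` versus its limit +0.2 (converging
only beyond `t_m ~ 1e5`, where only the sign is asserted).  Tests state
these margins explicitly rather than asserting the limits.

Known limitations: 1-D theory only (higher dimensions via independent
coordinates); no tempered or truncated waiting-time laws; no Levy flights;
the exact hypergeometric spectral closed forms are replaced by the
quadrature route throughout; `alpha = 1` is supported by the simulator but
the closed-form layer requires `alpha < 1`.
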